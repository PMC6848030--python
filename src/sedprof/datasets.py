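"""Packaged reference tables for the 11 Columbia River estuary sediment
metagenomes (lateral-bay samples collected August 2011 and 2013).

The per-sample summary and environmental-metadata tables are transcribed
from the study's published per-metagenome statistics so that summary
arithmetic (total assembly size, mean effective genome size, genome
equivalents, per-bay chemistry means) can be reproduced without access to
the IMG/M-ER deposits.  The gene-level annotations themselves are *not*
packaged; synthetic tables stand in for them (see :mod:`sedprof.simulate`).
"""

from __future__ import annotations

from importlib import resources

from .io import SampleMetadata, SampleSummaryRow, read_metadata_table, read_summary_table

#: Sample groups found by 2D clustering of the study's family/genus-level
#: taxon abundances (and confirmed on functional profiles).  Cluster A:
#: 2013 Baker Bay, diatom-rich, early bloom degradation; B: late-stage
#: degradation with extreme chloroplast RuBisCO enrichment; C: the 2011
#: Baker Bay sample with methylotroph/syntroph signal; D: low-diatom
#: Youngs/Cathlamet samples with chemolithotroph signal.
STUDY_CLUSTERS: dict[str, tuple[str, ...]] = {
    "A": ("S.184_BBB", "S.182_BBI", "S.186_BBA", "S.180_BBC"),
    "B": ("S.43_YBM", "S.188_CBA"),
    "C": ("S.41_BBB",),
    "D": ("S.178_YBM", "S.42_YBB", "S.190_CBC", "S.174_CBK"),
}


def _data_path(name: str):
    return resources.files("sedprof") / "data" / name


def load_study_summary() -> list[SampleSummaryRow]:
    """Per-sample assembly/annotation statistics of the 11 metagenomes."""
    with resources.as_file(_data_path("study_summary.tsv")) as path:
        return read_summary_table(path)


def load_study_metadata() -> list[SampleMetadata]:
    """Bay, collection date and bulk chemistry of the 11 samples."""
    with resources.as_file(_data_path("study_metadata.tsv")) as path:
        return read_metadata_table(path)


def default_config_path():
    """Path to the packaged default simulation/pipeline configuration."""
    return _data_path("default_config.yaml")
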