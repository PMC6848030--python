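"""Taxonomic and functional abundance profiling of gene-annotation tables.

Two denominators are used for taxon abundances, mirroring common practice
in gene-centric metagenomics of eukaryote-contaminated assemblies:

* ``percent_total_annotated`` — a taxon's gene count divided by all
  taxonomically annotated CDS in the sample (domain-level composition).
* ``percent_ABV`` — the denominator restricted to genes annotated as
  Archaea, Bacteria or Viruses ("total ABV") at the >=30% identity /
  >=70% alignment-coverage level, making prokaryote/virus profiles
  insensitive to the very uneven diatom (eukaryote) gene load.

Functional profiles are normalized per effective bacterial genome:
gene count divided by the sample's genome equivalents, where genome
equivalents are reconstructed from assembly size, the bacterial and
taxonomically-annotated fractions, and the effective genome size (EGS).
EGS itself is an input, not estimated here.

Identity/coverage gates follow the annotation convention: >=30%/>=70%
for domain-level calls, >=60%/>=70% for family- and genus-level calls,
both inclusive at the boundary.  RNA genes are excluded from every
CDS-based numerator and denominator by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import GeneRecord, GeneTable, SampleMetadata, SampleSummaryRow

logger = logging.getLogger(__name__)

#: identity (%) and coverage (fraction) gate for domain-level annotation
DOMAIN_GATE = (30.0, 0.70)
#: stricter identity gate resolving family/genus-level annotation
FAMILY_GATE = (60.0, 0.70)

ABV_DOMAINS = ("Archaea", "Bacteria", "Viruses")
RANKS = ("domain", "phylum", "class", "family", "genus")

MODES = ("percent_total_annotated", "percent_ABV", "genes_per_genome")


@dataclass
class AbundanceMatrix:
    """Features x samples abundance matrix tagged with its normalization.

    ``values`` is a pandas DataFrame indexed by feature id with one column
    per sample.  ``mode`` records the unit; ``provenance`` accumulates a
    human-readable trail of the cutoffs and selections applied.
    """

    values: pd.DataFrame
    mode: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown abundance mode {self.mode!r}")
        if (self.values.to_numpy(dtype=float) < -1e-12).any():
            raise ValidationError("abundance values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path, sidecar: bool = True) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")
        if sidecar:
            with open(f"{path}.provenance.txt", "w", encoding="utf-8") as fh:
                fh.write(f"mode: {self.mode}\n")
                for line in self.provenance:
                    fh.write(f"{line}\n")

    @classmethod
    def from_tsv(cls, path, mode: str, provenance: list[str] | None = None
                 ) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        df.index = df.index.astype(str)
        return cls(values=df, mode=mode, provenance=provenance or [])


@dataclass(frozen=True)
class EGSRecord:
    """Effective genome size and derived genome equivalents for a sample."""

    sample_id: str
    egs_mbp: float
    genome_equivalents: float

    def validate(self) -> None:
        if self.egs_mbp <= 0:
            raise ValidationError(f"{self.sample_id}: egs_mbp must be > 0")
        if self.genome_equivalents < 0:
            raise ValidationError(
                f"{self.sample_id}: genome_equivalents must be >= 0")


@dataclass(frozen=True)
class SummaryStats:
    """Cohort-level arithmetic over per-sample summary rows."""

    n_samples: int
    total_assembly_gbp: float
    total_cds_millions: float
    mean_egs_mbp: float
    mean_genome_equivalents: float | None
    min_genome_equivalents: float | None
    max_genome_equivalents: float | None
    #: group label -> metadata column -> mean (only when metadata supplied)
    group_means: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene-level filters


def _passes(rec: GeneRecord, min_identity: float, min_coverage: float) -> bool:
    return (rec.pct_identity is not None and rec.aln_coverage is not None
            and rec.pct_identity >= min_identity
            and rec.aln_coverage >= min_coverage)


def filter_by_identity(table: GeneTable, min_identity: float = DOMAIN_GATE[0],
                       min_coverage: float = DOMAIN_GATE[1]) -> GeneTable:
    """Keep records at or above the identity/coverage gate (inclusive).

    Taxonomically unannotated records are dropped: they carry no identity
    or coverage and cannot pass any gate.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ValidationError("min_identity must lie in [0, 100]")
    if not 0.0 <= min_coverage <= 1.0:
        raise ValidationError("min_coverage must lie in [0, 1]")
    return table.subset(lambda r: _passes(r, min_identity, min_coverage))


def _cds_only(table: GeneTable, include_rna: bool) -> GeneTable:
    return table if include_rna else table.subset(lambda r: not r.is_rna)


def _taxon_group(rec: GeneRecord) -> str:
    if rec.domain != "Eukaryota":
        return rec.domain
    if rec.lineage.get("phylum") == "Bacillariophyta":
        return "Bacillariophyta"
    return "other Eukaryota"


# ---------------------------------------------------------------------------
# taxonomic abundance


def domain_composition(table: GeneTable, include_rna: bool = False
                       ) -> AbundanceMatrix:
    """Domain-level composition as percent of all annotated CDS.

    ``table`` should already be gated at 30%/70%.  Eukaryotes are split
    into diatoms (Bacillariophyta) and everything else; the five groups
    partition the annotated set, so columns sum to 100 within rounding.
    Samples without annotated genes get an absent (NaN) column.
    """
    cds = _cds_only(table, include_rna)
    groups = ("Archaea", "Bacteria", "Viruses", "Bacillariophyta", "other Eukaryota")
    counts = pd.DataFrame(0.0, index=list(groups), columns=cds.sample_ids)
    for rec in cds:
        counts.loc[_taxon_group(rec), rec.sample_id] += 1.0
    totals = counts.sum(axis=0)
    values = counts.divide(totals, axis=1) * 100.0
    for sid in values.columns[totals == 0]:
        logger.warning("sample %s has no annotated genes; composition absent", sid)
    return AbundanceMatrix(values=values, mode="percent_total_annotated",
                           provenance=["domain composition over annotated CDS",
                                       f"include_rna={include_rna}"])


def taxon_abundance_abv(table: GeneTable, rank: str,
                        min_identity: float = FAMILY_GATE[0],
                        min_coverage: float = FAMILY_GATE[1],
                        include_rna: bool = False) -> AbundanceMatrix:
    """Taxon abundance as percent of total ABV genes.

    The denominator is the per-sample count of Archaea/Bacteria/Viruses
    genes passing the 30%/70% gate; eukaryotic genes never enter it.  The
    numerator counts ABV genes labelled with each taxon at ``rank`` and
    passing the (possibly stricter) ``min_identity``/``min_coverage`` gate
    used for that rank's annotation.
    """
    if rank not in RANKS:
        raise ValidationError(f"rank must be one of {RANKS}, got {rank!r}")
    cds = _cds_only(table, include_rna)
    denom = pd.Series(0.0, index=cds.sample_ids)
    numer: dict[str, pd.Series] = {}
    for rec in cds:
        if rec.domain not in ABV_DOMAINS:
            continue
        if _passes(rec, *DOMAIN_GATE):
            denom[rec.sample_id] += 1.0
        if not _passes(rec, min_identity, min_coverage):
            continue
        taxon = rec.domain if rank == "domain" else rec.lineage.get(rank)
        if taxon is None:
            continue
        row = numer.get(taxon)
        if row is None:
            row = numer[taxon] = pd.Series(0.0, index=cds.sample_ids)
        row[rec.sample_id] += 1.0
    counts = (pd.DataFrame(numer).T.sort_index()
              if numer else pd.DataFrame(columns=cds.sample_ids, dtype=float))
    counts = counts.reindex(columns=cds.sample_ids, fill_value=0.0)
    values = counts.divide(denom.where(denom > 0), axis=1) * 100.0
    for sid in denom.index[denom == 0]:
        logger.warning("sample %s has zero ABV denominator; values absent", sid)
    return AbundanceMatrix(
        values=values.fillna(np.nan), mode="percent_ABV",
        provenance=[f"rank={rank}",
                    f"numerator gate >= {min_identity}% identity, "
                    f">= {min_coverage:.2f} coverage",
                    "denominator: ABV at >=30% identity, >=70% coverage"])


# ---------------------------------------------------------------------------
# effective-genome normalization


def genome_equivalents(summary: SampleSummaryRow) -> EGSRecord:
    """Reconstruct the number of effective bacterial genomes in a sample.

    genome_equivalents = assembly_mbp x (bacterial fraction) x
    (taxonomically annotated fraction) / EGS_mbp.  A sample without
    bacterial genes yields zero equivalents and a logged warning, since a
    zero denominator makes per-genome functional abundances undefined.
    """
    summary.validate()
    ge = (summary.assembly_size_mbp
          * (summary.pct_bacteria / 100.0)
          * (summary.pct_tax_annotated / 100.0)
          / summary.egs_mbp)
    if ge == 0:
        logger.warning("sample %s has zero genome equivalents", summary.sample_id)
    return EGSRecord(sample_id=summary.sample_id, egs_mbp=summary.egs_mbp,
                     genome_equivalents=ge)


def functional_abundance(table: GeneTable, namespace: str,
                         egs: Iterable[EGSRecord],
                         include_rna: bool = False) -> AbundanceMatrix:
    """Per-term gene counts divided by genome equivalents (genes/genome).

    A gene carrying k distinct terms in the namespace contributes one
    count to each of the k term rows (no fractional splitting).
    """
    if namespace not in ("COG", "PF", "KO", "EC"):
        raise ValidationError(f"unknown namespace {namespace!r}")
    by_sample = {r.sample_id: r for r in egs}
    cds = _cds_only(table, include_rna)
    for sid in cds.sample_ids:
        if sid not in by_sample:
            raise ConfigError(f"no EGSRecord for sample {sid!r}")
        if by_sample[sid].genome_equivalents <= 0:
            raise ConfigError(
                f"sample {sid!r} has non-positive genome equivalents")
    counts: dict[str, pd.Series] = {}
    for rec in cds:
        for term in rec.terms(namespace):
            row = counts.get(term)
            if row is None:
                row = counts[term] = pd.Series(0.0, index=cds.sample_ids)
            row[rec.sample_id] += 1.0
    matrix = (pd.DataFrame(counts).T.sort_index()
              if counts else pd.DataFrame(columns=cds.sample_ids, dtype=float))
    matrix = matrix.reindex(columns=cds.sample_ids, fill_value=0.0)
    denom = pd.Series({sid: by_sample[sid].genome_equivalents
                       for sid in cds.sample_ids})
    values = matrix.divide(denom, axis=1)
    return AbundanceMatrix(values=values, mode="genes_per_genome",
                           provenance=[f"namespace={namespace}",
                                       "normalized per effective bacterial genome"])


# ---------------------------------------------------------------------------
# feature selection


def select_features_taxonomic(m: AbundanceMatrix, min_pct: float = 0.35,
                              stat: str = "max") -> AbundanceMatrix:
    """Keep taxa reaching ``min_pct`` percent of total ABV.

    With the default ``stat="max"`` a taxon qualifies if it reaches the
    threshold in at least one sample; ``stat="mean"`` uses the across-
    sample mean instead.
    """
    if m.mode != "percent_ABV":
        raise ValidationError("taxonomic selection expects a percent_ABV matrix")
    if stat not in ("max", "mean"):
        raise ValidationError(f"stat must be 'max' or 'mean', got {stat!r}")
    score = m.values.max(axis=1) if stat == "max" else m.values.mean(axis=1)
    kept = m.values.loc[score >= min_pct]
    return AbundanceMatrix(values=kept, mode=m.mode,
                           provenance=m.provenance
                           + [f"selected features with {stat} >= {min_pct}%"])


def select_features_functional(m: AbundanceMatrix, min_gpg: float = 1.0,
                               min_samples: int = 2) -> AbundanceMatrix:
    """Keep terms with >= ``min_gpg`` genes/genome in >= ``min_samples`` samples."""
    if m.mode != "genes_per_genome":
        raise ValidationError("functional selection expects a genes_per_genome matrix")
    if min_samples > len(m.sample_ids):
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {len(m.sample_ids)} samples")
    n_hits = (m.values >= min_gpg).sum(axis=1)
    kept = m.values.loc[n_hits >= min_samples]
    return AbundanceMatrix(values=kept, mode=m.mode,
                           provenance=m.provenance
                           + [f"selected features with >= {min_gpg} genes/genome "
                              f"in >= {min_samples} samples"])


# ---------------------------------------------------------------------------
# cohort summaries


_METADATA_NUMERIC = ("ph", "pct_om", "no3_ppm", "nh4_ppm", "mn_ppm", "fe_ppm")


def summarize_samples(rows: Sequence[SampleSummaryRow],
                      metadata: Sequence[SampleMetadata] | None = None,
                      ) -> SummaryStats:
    """Totals and means across samples, plus per-bay metadata means."""
    if not rows:
        raise ValidationError("summarize_samples requires at least one row")
    ge = [r.genome_equivalents for r in rows if r.genome_equivalents is not None]
    group_means: dict[str, dict[str, float]] = {}
    if metadata:
        frame = pd.DataFrame(
            [{"bay": m.bay, **{c: getattr(m, c) for c in _METADATA_NUMERIC}}
             for m in metadata])
        for bay, sub in frame.groupby("bay"):
            group_means[bay] = {c: float(sub[c].mean())
                                for c in _METADATA_NUMERIC
                                if sub[c].notna().any()}
    return SummaryStats(
        n_samples=len(rows),
        total_assembly_gbp=sum(r.assembly_size_mbp for r in rows) / 1000.0,
        total_cds_millions=sum(r.cds_count_millions for r in rows),
        mean_egs_mbp=float(np.mean([r.egs_mbp for r in rows])),
        mean_genome_equivalents=float(np.mean(ge)) if ge else None,
        min_genome_equivalents=float(np.min(ge)) if ge else None,
        max_genome_equivalents=float(np.max(ge)) if ge else None,
        group_means=group_means,
    )
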