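import pytest

from sedprof.io import GeneRecord, GeneTable


def make_record(gene_id, sample_id="S1", length_bp=500, domain="Bacteria",
                lineage=None, pct_identity=75.0, aln_coverage=0.9,
                func_terms=None, organelle="not_applicable", is_rna=False):
    """GeneRecord with sensible defaults for terse test construction."""
    if domain == "unannotated":
        pct_identity = aln_coverage = None
    return GeneRecord(
        gene_id=gene_id, sample_id=sample_id, length_bp=length_bp,
        domain=domain, lineage=lineage or {},
        pct_identity=pct_identity, aln_coverage=aln_coverage,
        func_terms={ns: frozenset(ts) for ns, ts in (func_terms or {}).items()},
        organelle=organelle, is_rna=is_rna)


def diatom_record(gene_id, sample_id="S1", organelle="nuclear", rubisco=False,
                  ec=None, genus=None, length_bp=800):
    lineage = {"phylum": "Bacillariophyta", "class": "Bacillariophyceae"}
    if genus:
        lineage["genus"] = genus
    terms = {}
    if rubisco:
        terms = {"EC": {"4.1.1.39"}, "KO": {"K01601"}}
    elif ec:
        terms = {"EC": {ec}}
    return make_record(gene_id, sample_id, length_bp=length_bp,
                       domain="Eukaryota", lineage=lineage,
                       func_terms=terms, organelle=organelle)


@pytest.fixture
def mk():
    return make_record


@pytest.fixture
def mk_diatom():
    return diatom_record


@pytest.fixture
def small_table():
    """One sample: 6 Bacteria, 2 Archaea, 1 Virus, 1 diatom gene."""
    recs = [make_record(f"b{i}", domain="Bacteria") for i in range(6)]
    recs += [make_record(f"a{i}", domain="Archaea") for i in range(2)]
    recs += [make_record("v0", domain="Viruses")]
    recs += [diatom_record("d0")]
    return GeneTable.from_records(recs)
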