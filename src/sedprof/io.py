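"""Reading, validating and writing per-gene annotation tables.

The pipeline's universal input is a long-form table with one row per
predicted protein-coding gene (CDS), carrying the sample it came from, its
nucleotide length, a domain-level taxonomic call with an optional
phylum/class/family/genus lineage, the percent amino-acid identity and
alignment-coverage fraction of its best reference hit, functional term
assignments in the COG / Pfam (PF) / KEGG Orthology (KO) / ENZYME (EC)
namespaces, an organelle flag for eukaryotic genes, and an RNA-gene marker.

All files are tab-separated UTF-8 with a header row.  Multi-valued cells
(functional terms) are ";"-separated.  Missing numeric values are empty
cells — the strings "NA"/"NaN" are rejected, and only "." is accepted as a
decimal point, so parsing is locale-independent.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DOMAINS = ("Archaea", "Bacteria", "Viruses", "Eukaryota", "unannotated")
ORGANELLES = ("nuclear", "chloroplast", "not_applicable")
LINEAGE_RANKS = ("phylum", "class", "family", "genus")
NAMESPACES = ("COG", "PF", "KO", "EC")

GENE_TABLE_COLUMNS = (
    "gene_id", "sample_id", "length_bp", "domain",
    "phylum", "class", "family", "genus",
    "pct_identity", "aln_coverage",
    "cog", "pf", "ko", "ec",
    "organelle", "is_rna",
)

SUMMARY_COLUMNS = (
    "sample_id", "assembly_size_mbp", "cds_count_millions", "egs_mbp",
    "pct_tax_annotated", "pct_bacteria", "pct_archaea", "pct_viruses",
    "pct_bacillariophyta", "pct_other_euk", "genome_equivalents",
)

METADATA_COLUMNS = (
    "sample_id", "bay", "collection_date",
    "ph", "pct_om", "no3_ppm", "nh4_ppm", "mn_ppm", "fe_ppm",
)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneRecord:
    """One predicted CDS (or RNA gene) with its annotations."""

    gene_id: str
    sample_id: str
    length_bp: int
    domain: str = "unannotated"
    lineage: Mapping[str, str] = field(default_factory=dict)
    pct_identity: float | None = None
    aln_coverage: float | None = None
    func_terms: Mapping[str, frozenset[str]] = field(default_factory=dict)
    organelle: str = "not_applicable"
    is_rna: bool = False

    def validate(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not (isinstance(self.length_bp, int) and self.length_bp > 0):
            raise ValidationError(
                f"{self.gene_id}: length_bp must be a positive integer")
        if self.domain not in DOMAINS:
            raise ValidationError(f"{self.gene_id}: unknown domain {self.domain!r}")
        for rank in self.lineage:
            if rank not in LINEAGE_RANKS:
                raise ValidationError(f"{self.gene_id}: unknown lineage rank {rank!r}")
        annotated = self.domain != "unannotated"
        if annotated != (self.pct_identity is not None):
            raise ValidationError(
                f"{self.gene_id}: pct_identity must be present iff taxonomically annotated")
        if annotated != (self.aln_coverage is not None):
            raise ValidationError(
                f"{self.gene_id}: aln_coverage must be present iff taxonomically annotated")
        if self.pct_identity is not None and not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"{self.gene_id}: pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_coverage is not None and not 0.0 <= self.aln_coverage <= 1.0:
            raise ValidationError(
                f"{self.gene_id}: aln_coverage {self.aln_coverage} outside [0, 1]")
        for ns in self.func_terms:
            if ns not in NAMESPACES:
                raise ValidationError(f"{self.gene_id}: unknown namespace {ns!r}")
        if self.organelle not in ORGANELLES:
            raise ValidationError(f"{self.gene_id}: unknown organelle {self.organelle!r}")
        if self.organelle != "not_applicable" and self.domain != "Eukaryota":
            raise ValidationError(
                f"{self.gene_id}: organelle flag set on non-eukaryotic gene")

    def terms(self, namespace: str) -> frozenset[str]:
        return self.func_terms.get(namespace, frozenset())


@dataclass
class GeneTable:
    """Ordered collection of :class:`GeneRecord` across one or more samples."""

    records: list[GeneRecord]
    sample_ids: list[str]

    @classmethod
    def from_records(cls, records: Iterable[GeneRecord],
                     sample_ids: list[str] | None = None,
                     validate: bool = True) -> "GeneTable":
        records = list(records)
        if validate:
            seen: set[str] = set()
            for rec in records:
                rec.validate()
                if rec.gene_id in seen:
                    raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
                seen.add(rec.gene_id)
        if sample_ids is None:
            sample_ids = list(dict.fromkeys(rec.sample_id for rec in records))
        else:
            known = set(sample_ids)
            for rec in records:
                if rec.sample_id not in known:
                    raise ValidationError(
                        f"{rec.gene_id}: sample {rec.sample_id!r} not in sample_ids")
        return cls(records=records, sample_ids=list(sample_ids))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def subset(self, predicate) -> "GeneTable":
        """New table keeping records where ``predicate(record)`` is true.

        The sample roster is preserved even for samples left empty, so
        per-sample denominators of zero remain visible downstream.
        """
        return GeneTable(records=[r for r in self.records if predicate(r)],
                         sample_ids=list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame view for vectorized profiling (one row per gene)."""
        rows = []
        for r in self.records:
            rows.append((
                r.gene_id, r.sample_id, r.length_bp, r.domain,
                r.lineage.get("phylum"), r.lineage.get("class"),
                r.lineage.get("family"), r.lineage.get("genus"),
                r.pct_identity, r.aln_coverage, r.organelle, r.is_rna,
            ))
        return pd.DataFrame(rows, columns=[
            "gene_id", "sample_id", "length_bp", "domain",
            "phylum", "class", "family", "genus",
            "pct_identity", "aln_coverage", "organelle", "is_rna",
        ])


@dataclass(frozen=True)
class SampleSummaryRow:
    """Per-sample assembly and annotation statistics."""

    sample_id: str
    assembly_size_mbp: float
    cds_count_millions: float
    egs_mbp: float
    pct_tax_annotated: float
    pct_bacteria: float
    pct_archaea: float
    pct_viruses: float
    pct_bacillariophyta: float
    pct_other_euk: float
    genome_equivalents: int | None = None

    def validate(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        for name in ("assembly_size_mbp", "cds_count_millions", "egs_mbp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.sample_id}: {name} must be > 0")
        for name in ("pct_tax_annotated", "pct_bacteria", "pct_archaea",
                     "pct_viruses", "pct_bacillariophyta", "pct_other_euk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{self.sample_id}: {name}={v} outside [0, 100]")
        if self.genome_equivalents is not None and self.genome_equivalents <= 0:
            raise ValidationError(
                f"{self.sample_id}: genome_equivalents must be positive")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample environmental metadata (bay, date, bulk chemistry)."""

    sample_id: str
    bay: str
    collection_date: str
    ph: float | None = None
    pct_om: float | None = None
    no3_ppm: float | None = None
    nh4_ppm: float | None = None
    mn_ppm: float | None = None
    fe_ppm: float | None = None

    def validate(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        for name in ("ph", "pct_om", "no3_ppm", "nh4_ppm", "mn_ppm", "fe_ppm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0")


# ---------------------------------------------------------------------------
# cell-level parsing helpers


def _parse_float(cell: str, column: str) -> float:
    cell = cell.strip()
    ok = cell and all(c.isascii() and (c.isdigit() or c in ".-+eE") for c in cell)
    if not ok:
        raise FormatError(f"column {column!r}: malformed number {cell!r}")
    try:
        return float(cell)
    except ValueError as exc:
        raise FormatError(f"column {column!r}: malformed number {cell!r}") from exc


def _parse_opt_float(cell: str, column: str) -> float | None:
    return None if cell.strip() == "" else _parse_float(cell, column)


def _parse_int(cell: str, column: str) -> int:
    cell = cell.strip()
    if not (cell and (cell.lstrip("+-").isdigit())):
        raise FormatError(f"column {column!r}: malformed integer {cell!r}")
    return int(cell)


def _parse_bool(cell: str, column: str) -> bool:
    v = cell.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0", ""):
        return False
    raise FormatError(f"column {column!r}: malformed boolean {cell!r}")


def _parse_terms(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(t.strip() for t in cell.split(";") if t.strip())


def _fmt_float(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))


def _open_reader(path):
    handle = open(path, "r", encoding="utf-8", newline="")
    return handle, csv.reader(handle, delimiter="\t", lineterminator="\n")


def _check_header(header: list[str] | None, expected: tuple[str, ...],
                  path) -> None:
    if header is None:
        raise FormatError(f"{path}: empty file, expected header row")
    for col in expected:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    if list(header) != list(expected):
        raise FormatError(
            f"{path}: header columns {header!r} do not match the documented "
            f"order {list(expected)!r}")


# ---------------------------------------------------------------------------
# gene tables


def _record_from_row(row: list[str]) -> GeneRecord:
    if len(row) != len(GENE_TABLE_COLUMNS):
        raise FormatError(f"expected {len(GENE_TABLE_COLUMNS)} cells, got {len(row)}")
    cell = dict(zip(GENE_TABLE_COLUMNS, row))
    lineage = {rank: cell[rank].strip()
               for rank in LINEAGE_RANKS if cell[rank].strip()}
    func_terms = {}
    for ns, col in (("COG", "cog"), ("PF", "pf"), ("KO", "ko"), ("EC", "ec")):
        terms = _parse_terms(cell[col])
        if terms:
            func_terms[ns] = terms
    rec = GeneRecord(
        gene_id=cell["gene_id"].strip(),
        sample_id=cell["sample_id"].strip(),
        length_bp=_parse_int(cell["length_bp"], "length_bp"),
        domain=cell["domain"].strip() or "unannotated",
        lineage=lineage,
        pct_identity=_parse_opt_float(cell["pct_identity"], "pct_identity"),
        aln_coverage=_parse_opt_float(cell["aln_coverage"], "aln_coverage"),
        func_terms=func_terms,
        organelle=cell["organelle"].strip() or "not_applicable",
        is_rna=_parse_bool(cell["is_rna"], "is_rna"),
    )
    rec.validate()
    return rec


def read_gene_table(path, strict: bool = True) -> GeneTable:
    """Read a gene-annotation TSV.

    In strict mode any malformed row aborts with the offending line number;
    otherwise malformed rows are dropped and the drop count is logged.
    Duplicate gene_ids are an error in either mode.
    """
    handle, reader = _open_reader(path)
    records: list[GeneRecord] = []
    n_dropped = 0
    with handle:
        header = next(reader, None)
        _check_header(header, GENE_TABLE_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append(_record_from_row(row))
            except (FormatError, ValidationError) as exc:
                if strict:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                n_dropped += 1
                logger.warning("%s:%d: dropped malformed row (%s)", path, lineno, exc)
    if n_dropped:
        logger.info("%s: dropped %d malformed rows", path, n_dropped)
    # records already validated row-wise; enforce table-level uniqueness
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return GeneTable.from_records(records, validate=False)


def write_gene_table(table: GeneTable, path) -> None:
    """Write a gene table in the canonical TSV dialect (round-trip stable)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS)
        for r in table.records:
            writer.writerow([
                r.gene_id, r.sample_id, str(r.length_bp), r.domain,
                r.lineage.get("phylum", ""), r.lineage.get("class", ""),
                r.lineage.get("family", ""), r.lineage.get("genus", ""),
                _fmt_float(r.pct_identity), _fmt_float(r.aln_coverage),
                ";".join(sorted(r.terms("COG"))), ";".join(sorted(r.terms("PF"))),
                ";".join(sorted(r.terms("KO"))), ";".join(sorted(r.terms("EC"))),
                r.organelle, "true" if r.is_rna else "false",
            ])


# ---------------------------------------------------------------------------
# summary and metadata tables


def read_summary_table(path) -> list[SampleSummaryRow]:
    """Read per-sample assembly/annotation summary rows."""
    handle, reader = _open_reader(path)
    rows: list[SampleSummaryRow] = []
    with handle:
        header = next(reader, None)
        _check_header(header, SUMMARY_COLUMNS, path)
        for lineno, raw in enumerate(reader, start=2):
            if not raw:
                continue
            if len(raw) != len(SUMMARY_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong cell count")
            cell = dict(zip(SUMMARY_COLUMNS, raw))
            ge = cell["genome_equivalents"].strip()
            row = SampleSummaryRow(
                sample_id=cell["sample_id"].strip(),
                assembly_size_mbp=_parse_float(cell["assembly_size_mbp"], "assembly_size_mbp"),
                cds_count_millions=_parse_float(cell["cds_count_millions"], "cds_count_millions"),
                egs_mbp=_parse_float(cell["egs_mbp"], "egs_mbp"),
                pct_tax_annotated=_parse_float(cell["pct_tax_annotated"], "pct_tax_annotated"),
                pct_bacteria=_parse_float(cell["pct_bacteria"], "pct_bacteria"),
                pct_archaea=_parse_float(cell["pct_archaea"], "pct_archaea"),
                pct_viruses=_parse_float(cell["pct_viruses"], "pct_viruses"),
                pct_bacillariophyta=_parse_float(cell["pct_bacillariophyta"], "pct_bacillariophyta"),
                pct_other_euk=_parse_float(cell["pct_other_euk"], "pct_other_euk"),
                genome_equivalents=None if ge == "" else _parse_int(ge, "genome_equivalents"),
            )
            try:
                row.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            rows.append(row)
    _check_unique_samples(rows, path)
    return rows


def write_summary_table(rows: Iterable[SampleSummaryRow], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SUMMARY_COLUMNS)
        for r in rows:
            ge = "" if r.genome_equivalents is None else str(r.genome_equivalents)
            writer.writerow([
                r.sample_id, _fmt_float(r.assembly_size_mbp),
                _fmt_float(r.cds_count_millions), _fmt_float(r.egs_mbp),
                _fmt_float(r.pct_tax_annotated), _fmt_float(r.pct_bacteria),
                _fmt_float(r.pct_archaea), _fmt_float(r.pct_viruses),
                _fmt_float(r.pct_bacillariophyta), _fmt_float(r.pct_other_euk),
                ge,
            ])


def read_metadata_table(path) -> list[SampleMetadata]:
    """Read per-sample environmental metadata rows."""
    handle, reader = _open_reader(path)
    rows: list[SampleMetadata] = []
    with handle:
        header = next(reader, None)
        _check_header(header, METADATA_COLUMNS, path)
        for lineno, raw in enumerate(reader, start=2):
            if not raw:
                continue
            if len(raw) != len(METADATA_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong cell count")
            cell = dict(zip(METADATA_COLUMNS, raw))
            row = SampleMetadata(
                sample_id=cell["sample_id"].strip(),
                bay=cell["bay"].strip(),
                collection_date=cell["collection_date"].strip(),
                ph=_parse_opt_float(cell["ph"], "ph"),
                pct_om=_parse_opt_float(cell["pct_om"], "pct_om"),
                no3_ppm=_parse_opt_float(cell["no3_ppm"], "no3_ppm"),
                nh4_ppm=_parse_opt_float(cell["nh4_ppm"], "nh4_ppm"),
                mn_ppm=_parse_opt_float(cell["mn_ppm"], "mn_ppm"),
                fe_ppm=_parse_opt_float(cell["fe_ppm"], "fe_ppm"),
            )
            try:
                row.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            rows.append(row)
    _check_unique_samples(rows, path)
    return rows


def write_metadata_table(rows: Iterable[SampleMetadata], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for r in rows:
            writer.writerow([
                r.sample_id, r.bay, r.collection_date,
                _fmt_float(r.ph), _fmt_float(r.pct_om), _fmt_float(r.no3_ppm),
                _fmt_float(r.nh4_ppm), _fmt_float(r.mn_ppm), _fmt_float(r.fe_ppm),
            ])


def _check_unique_samples(rows, path) -> None:
    seen: set[str] = set()
    for r in rows:
        if r.sample_id in seen:
            raise ValidationError(f"{path}: duplicate sample_id {r.sample_id!r}")
        seen.add(r.sample_id)
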