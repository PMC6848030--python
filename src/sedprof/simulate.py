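"""Synthetic gene-annotation tables with planted community structure.

The generator emulates the statistical shape of an assembled, annotated
sediment metagenome survey without simulating any sequence content:
genes are abstract annotated entities.  Per sample it draws

* a category composition (RNA, unannotated, diatom, and a roster of
  prokaryote/virus taxa) from a Dirichlet distribution centred on the
  sample's cluster profile — the standard overdispersed
  (Dirichlet-multinomial) model for community profiles;
* gene counts from a multinomial at ``genes_per_sample``;
* functional terms per taxon as independent Bernoulli marks at
  configured per-gene rates, so taxon-function correlations exist by
  construction;
* best-hit identity and alignment coverage from a mixture straddling
  the 30%/70% and 60%/70% annotation gates;
* diatom genes split into chloroplast and nuclear compartments and then
  thinned by an exponential-survival decay model in which nuclear DNA
  decays faster than the better-membrane-protected chloroplast DNA
  (default rate ratio 2:1), driving the % RuBisCO proxy up with the
  sample's decay state ``d``.

Everything is drawn from a single integer seed; identical configs give
byte-identical outputs.  A :class:`TruthRecord` reporting the planted
composition, decay states and expected proxy values is emitted alongside
every table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diatom import RUBISCO_EC, RUBISCO_KO
from .errors import ConfigError
from .io import GeneRecord, GeneTable, SampleMetadata, SampleSummaryRow
from .profiling import AbundanceMatrix, genome_equivalents

#: EC pools used to decorate diatom genes that are not rbcL
_CHLOROPLAST_EC = ("1.97.1.12", "2.7.7.6", "6.1.1.20")
_NUCLEAR_EC = ("1.1.1.1", "2.7.1.1", "4.2.1.11", "6.3.1.2", "2.6.1.1",
               "3.1.3.11", "1.2.1.12", "5.3.1.9")

#: per-bay bulk-chemistry baselines used for metadata decoration
_BAY_CHEMISTRY = {
    "Baker": dict(ph=7.5, pct_om=1.3, no3_ppm=4.0, nh4_ppm=15.0,
                  mn_ppm=30.0, fe_ppm=80.0),
    "Youngs": dict(ph=6.7, pct_om=5.1, no3_ppm=2.8, nh4_ppm=110.0,
                   mn_ppm=140.0, fe_ppm=200.0),
    "Cathlamet": dict(ph=7.0, pct_om=1.7, no3_ppm=4.3, nh4_ppm=27.0,
                      mn_ppm=61.0, fe_ppm=104.0),
}
_DEFAULT_CHEMISTRY = dict(ph=7.0, pct_om=2.0, no3_ppm=4.0, nh4_ppm=30.0,
                          mn_ppm=60.0, fe_ppm=100.0)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class DecayParams:
    """Exponential-survival model for diatom DNA after cell death.

    A chloroplast gene survives decay state ``d`` with probability
    exp(-k_chl * d), a nuclear gene with exp(-k_nuc * d).
    """

    k_nuc: float = 0.6
    k_chl: float = 0.3
    frac_chl0: float = 0.05
    rbcl_frac_chl: float = 0.15
    ec_frac_chl_other: float = 0.15
    ec_frac_nuc: float = 0.5

    def validate(self) -> None:
        if not self.k_nuc >= self.k_chl >= 0:
            raise ConfigError("decay rates must satisfy k_nuc >= k_chl >= 0")
        if not 0 < self.frac_chl0 < 1:
            raise ConfigError("frac_chl0 must lie in (0, 1)")
        if self.rbcl_frac_chl + self.ec_frac_chl_other > 1:
            raise ConfigError("chloroplast EC fractions exceed 1")
        if not 0 <= self.ec_frac_nuc <= 1:
            raise ConfigError("ec_frac_nuc must lie in [0, 1]")

    def expected_pct_rubisco(self, d: float) -> float:
        """Closed-form expectation of the inclusive % RuBisCO proxy at d."""
        s_c = math.exp(-self.k_chl * d)
        s_n = math.exp(-self.k_nuc * d)
        num = self.frac_chl0 * s_c * self.rbcl_frac_chl
        den = (self.frac_chl0 * s_c * (self.rbcl_frac_chl + self.ec_frac_chl_other)
               + (1 - self.frac_chl0) * s_n * self.ec_frac_nuc)
        return 100.0 * num / den


@dataclass(frozen=True)
class IdentityNoise:
    """Mixture for best-hit identity (%) and alignment coverage."""

    frac_pass60: float = 0.6
    frac_pass30: float = 0.9
    frac_cov70: float = 0.95

    def validate(self) -> None:
        if not 0 <= self.frac_pass60 <= self.frac_pass30 <= 1:
            raise ConfigError("need 0 <= frac_pass60 <= frac_pass30 <= 1")
        if not 0 <= self.frac_cov70 <= 1:
            raise ConfigError("frac_cov70 must lie in [0, 1]")


@dataclass(frozen=True)
class SampleSpec:
    cluster: str
    bay: str
    decay_state: float
    egs_mbp: float


@dataclass(frozen=True)
class ClusterProfile:
    diatom_fraction: float
    taxa: Mapping[str, float]


@dataclass
class SimulationConfig:
    """Full description of a synthetic community."""

    seed: int
    genes_per_sample: int
    dirichlet_concentration: float
    frac_unannotated: float
    frac_rna: float
    decay: DecayParams
    identity_noise: IdentityNoise
    samples: dict[str, SampleSpec]
    taxa: dict[str, dict[str, str]]
    cluster_profiles: dict[str, ClusterProfile]
    func_term_rates: dict[str, dict[str, float]]
    diatom_genera: dict[str, float] = field(default_factory=lambda: {"unresolved": 1.0})

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if self.genes_per_sample <= 0:
            raise ConfigError("genes_per_sample must be positive")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be positive")
        if not 0 <= self.frac_unannotated < 1 or not 0 <= self.frac_rna < 1:
            raise ConfigError("frac_unannotated and frac_rna must lie in [0, 1)")
        self.decay.validate()
        self.identity_noise.validate()
        if not self.samples:
            raise ConfigError("at least one sample required")
        for name, lineage in self.taxa.items():
            if "domain" not in lineage:
                raise ConfigError(f"taxon {name!r} lacks a domain")
        for sid, spec in self.samples.items():
            if spec.cluster not in self.cluster_profiles:
                raise ConfigError(f"sample {sid!r}: unknown cluster {spec.cluster!r}")
            if spec.decay_state < 0:
                raise ConfigError(f"sample {sid!r}: decay_state must be >= 0")
            if spec.egs_mbp <= 0:
                raise ConfigError(f"sample {sid!r}: egs_mbp must be > 0")
        for cl, prof in self.cluster_profiles.items():
            if not 0 <= prof.diatom_fraction < 1:
                raise ConfigError(f"cluster {cl!r}: diatom_fraction must lie in [0, 1)")
            total = 0.0
            for taxon, p in prof.taxa.items():
                if taxon not in self.taxa:
                    raise ConfigError(f"cluster {cl!r}: unknown taxon {taxon!r}")
                if p < 0:
                    raise ConfigError(f"cluster {cl!r}: negative proportion for {taxon!r}")
                total += p
            if total > 1 + 1e-9:
                raise ConfigError(f"cluster {cl!r}: taxon proportions sum to {total} > 1")
        for taxon in self.func_term_rates:
            if taxon != "*" and taxon not in self.taxa:
                raise ConfigError(f"func_term_rates: unknown taxon {taxon!r}")
        for rates in self.func_term_rates.values():
            for key, rate in rates.items():
                ns = key.split(":", 1)[0]
                if ns not in ("COG", "PF", "KO", "EC"):
                    raise ConfigError(f"func_term_rates: bad term key {key!r}")
                if not 0 <= rate <= 1:
                    raise ConfigError(f"func_term_rates: rate for {key!r} outside [0, 1]")
        if not self.diatom_genera or min(self.diatom_genera.values()) < 0:
            raise ConfigError("diatom_genera must be non-empty with weights >= 0")

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        try:
            cfg = cls(
                seed=int(raw["seed"]),
                genes_per_sample=int(raw["genes_per_sample"]),
                dirichlet_concentration=float(raw["dirichlet_concentration"]),
                frac_unannotated=float(raw["frac_unannotated"]),
                frac_rna=float(raw.get("frac_rna", 0.0)),
                decay=DecayParams(**raw.get("decay", {})),
                identity_noise=IdentityNoise(**raw.get("identity_noise", {})),
                samples={sid: SampleSpec(**spec)
                         for sid, spec in raw["samples"].items()},
                taxa={name: dict(lin) for name, lin in raw["taxa"].items()},
                cluster_profiles={
                    cl: ClusterProfile(diatom_fraction=float(p["diatom_fraction"]),
                                       taxa=dict(p["taxa"]))
                    for cl, p in raw["cluster_profiles"].items()},
                func_term_rates={t: dict(r)
                                 for t, r in raw.get("func_term_rates", {}).items()},
                diatom_genera=dict(raw.get("diatom_genera", {"unresolved": 1.0})),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed simulation config: {exc}") from exc
        cfg.validate()
        return cfg


def load_config(path) -> SimulationConfig:
    """Load and validate a simulation config from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return SimulationConfig.from_dict(raw)


def default_config() -> SimulationConfig:
    """The packaged 11-sample, 4-cluster default scenario."""
    from .datasets import default_config_path
    from importlib import resources
    with resources.as_file(default_config_path()) as path:
        return load_config(path)


# ---------------------------------------------------------------------------
# truth


@dataclass(frozen=True)
class SampleTruth:
    sample_id: str
    cluster: str
    bay: str
    decay_state: float
    category_probs: Mapping[str, float]
    taxon_counts: Mapping[str, int]
    n_diatom_pre: int
    n_chl_surviving: int
    n_nuc_surviving: int
    n_rbcl: int
    expected_pct_rubisco: float


@dataclass
class TruthRecord:
    """Planted composition and decay states, emitted with every table."""

    samples: dict[str, SampleTruth]

    def cluster_labels(self) -> dict[str, str]:
        return {sid: t.cluster for sid, t in self.samples.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.samples.values():
            row = {"sample_id": t.sample_id, "cluster": t.cluster, "bay": t.bay,
                   "decay_state": t.decay_state,
                   "n_diatom_pre": t.n_diatom_pre,
                   "n_chl_surviving": t.n_chl_surviving,
                   "n_nuc_surviving": t.n_nuc_surviving,
                   "n_rbcl": t.n_rbcl,
                   "expected_pct_rubisco": t.expected_pct_rubisco}
            for taxon, n in t.taxon_counts.items():
                row[f"n_{taxon}"] = n
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# draws


def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    lengths = rng.lognormal(mean=math.log(480.0), sigma=0.45, size=n)
    return np.clip(np.rint(lengths), 120, 6000).astype(int)


def _draw_identity(rng: np.random.Generator, noise: IdentityNoise, n: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    u = rng.random(n)
    ident = np.where(u < noise.frac_pass60, rng.uniform(60.0, 98.0, n),
                     np.where(u < noise.frac_pass30, rng.uniform(30.0, 59.9, n),
                              rng.uniform(5.0, 29.9, n)))
    v = rng.random(n)
    cov = np.where(v < noise.frac_cov70, rng.uniform(0.70, 1.0, n),
                   rng.uniform(0.30, 0.699, n))
    return ident, cov


def simulate_diatom_decay(n0: int, frac_chl0: float, d: float, k_nuc: float,
                          k_chl: float, seed: int | np.random.Generator = 0,
                          ) -> tuple[int, int]:
    """Thin a pool of diatom genes by post-mortem DNA decay.

    Splits ``n0`` genes deterministically into chloroplast
    (``round(n0 * frac_chl0)``) and nuclear compartments, then survives
    each gene independently with probability exp(-k * d) using the
    compartment's rate.  Returns (surviving chloroplast, surviving
    nuclear) counts.  At d = 0 all genes survive.
    """
    if n0 <= 0:
        raise ConfigError("n0 must be positive")
    if k_nuc < 0 or k_chl < 0 or d < 0:
        raise ConfigError("rates and decay state must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_chl0 = int(round(n0 * frac_chl0))
    n_nuc0 = n0 - n_chl0
    n_chl = int(rng.binomial(n_chl0, math.exp(-k_chl * d))) if n_chl0 else 0
    n_nuc = int(rng.binomial(n_nuc0, math.exp(-k_nuc * d))) if n_nuc0 else 0
    return n_chl, n_nuc


def _diatom_records(rng: np.random.Generator, cfg: SimulationConfig,
                    sample_id: str, n0: int, d: float, ids: "_IdSource",
                    ) -> tuple[list[GeneRecord], int, int, int]:
    """Surviving diatom gene records plus (n_chl, n_nuc, n_rbcl)."""
    dec = cfg.decay
    n_chl, n_nuc = simulate_diatom_decay(n0, dec.frac_chl0, d, dec.k_nuc,
                                         dec.k_chl, rng)
    n_surv = n_chl + n_nuc
    if n_surv == 0:
        return [], 0, 0, 0
    p_rbcl = dec.rbcl_frac_chl
    p_other = dec.ec_frac_chl_other
    n_rbcl, n_chl_ec, _ = rng.multinomial(n_chl,
                                          [p_rbcl, p_other, 1 - p_rbcl - p_other])
    genera = list(cfg.diatom_genera)
    gw = np.array([cfg.diatom_genera[g] for g in genera], dtype=float)
    gw /= gw.sum()
    genus_of = rng.choice(len(genera), size=n_surv, p=gw)
    ident, cov = _draw_identity(rng, cfg.identity_noise, n_surv)
    lengths = _draw_lengths(rng, n_surv)
    # rbcL fragments: broad length range straddling the 500 bp gate
    n_marked = n_rbcl + n_chl_ec
    lengths[:n_rbcl] = rng.integers(250, 1470, size=n_rbcl, endpoint=True)
    nuc_ec = rng.random(n_surv - n_chl) < dec.ec_frac_nuc
    records = []
    for i in range(n_surv):
        is_chl = i < n_chl
        if i < n_rbcl:
            terms = {"EC": frozenset([RUBISCO_EC]), "KO": frozenset([RUBISCO_KO])}
        elif i < n_marked:
            terms = {"EC": frozenset([_CHLOROPLAST_EC[rng.integers(len(_CHLOROPLAST_EC))]])}
        elif not is_chl and nuc_ec[i - n_chl]:
            terms = {"EC": frozenset([_NUCLEAR_EC[rng.integers(len(_NUCLEAR_EC))]])}
        else:
            terms = {}
        lineage = {"phylum": "Bacillariophyta", "class": "Bacillariophyceae"}
        genus = genera[genus_of[i]]
        if genus != "unresolved":
            lineage["genus"] = genus
        records.append(GeneRecord(
            gene_id=ids.next(), sample_id=sample_id, length_bp=int(lengths[i]),
            domain="Eukaryota", lineage=lineage,
            pct_identity=float(ident[i]), aln_coverage=float(cov[i]),
            func_terms=terms,
            organelle="chloroplast" if is_chl else "nuclear"))
    return records, n_chl, n_nuc, int(n_rbcl)


class _IdSource:
    def __init__(self, sample_id: str) -> None:
        self.sample_id = sample_id
        self.i = 0

    def next(self) -> str:
        self.i += 1
        return f"{self.sample_id}_g{self.i:06d}"


def _taxon_records(rng: np.random.Generator, cfg: SimulationConfig,
                   sample_id: str, taxon: str, k: int, ids: _IdSource,
                   ) -> list[GeneRecord]:
    lineage_full = dict(cfg.taxa[taxon])
    domain = lineage_full.pop("domain")
    lineage = {r: v for r, v in lineage_full.items() if v}
    ident, cov = _draw_identity(rng, cfg.identity_noise, k)
    lengths = _draw_lengths(rng, k)
    term_sets: list[dict[str, set[str]]] = [dict() for _ in range(k)]
    rates: dict[str, float] = {}
    rates.update(cfg.func_term_rates.get("*", {}))
    rates.update(cfg.func_term_rates.get(taxon, {}))
    for key, rate in rates.items():
        ns, term = key.split(":", 1)
        n_with = rng.binomial(k, rate)
        if n_with == 0:
            continue
        for idx in rng.choice(k, size=n_with, replace=False):
            term_sets[idx].setdefault(ns, set()).add(term)
    return [GeneRecord(
        gene_id=ids.next(), sample_id=sample_id, length_bp=int(lengths[i]),
        domain=domain, lineage=lineage,
        pct_identity=float(ident[i]), aln_coverage=float(cov[i]),
        func_terms={ns: frozenset(ts) for ns, ts in term_sets[i].items()})
        for i in range(k)]


def _plain_records(rng: np.random.Generator, cfg: SimulationConfig,
                   sample_id: str, k: int, ids: _IdSource, is_rna: bool,
                   ) -> list[GeneRecord]:
    lengths = _draw_lengths(rng, k)
    return [GeneRecord(gene_id=ids.next(), sample_id=sample_id,
                       length_bp=int(lengths[i]), is_rna=is_rna)
            for i in range(k)]


# ---------------------------------------------------------------------------
# top-level simulation


_UNCLASSIFIED = "__unclassified_bacteria__"


def simulate_annotation_table(cfg: SimulationConfig
                              ) -> tuple[GeneTable, list[SampleSummaryRow],
                                         list[SampleMetadata], TruthRecord]:
    """Generate a full annotated survey per the configuration.

    Returns the gene table, per-sample summary rows (computed from the
    realized table, so counts agree exactly), metadata rows with per-bay
    chemistry, and the :class:`TruthRecord` of planted values.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa_names = list(cfg.taxa)
    records: list[GeneRecord] = []
    summaries: list[SampleSummaryRow] = []
    metadata: list[SampleMetadata] = []
    truth: dict[str, SampleTruth] = {}
    for sample_id, spec in cfg.samples.items():
        prof = cfg.cluster_profiles[spec.cluster]
        taxa_mass = 1.0 - cfg.frac_rna - cfg.frac_unannotated - prof.diatom_fraction
        if taxa_mass <= 0:
            raise ConfigError(
                f"sample {sample_id!r}: rna+unannotated+diatom fractions >= 1")
        props = [prof.taxa.get(t, 0.0) for t in taxa_names]
        remainder = 1.0 - sum(props)
        categories = (["__rna__", "__unannotated__", "__diatom__"]
                      + taxa_names + [_UNCLASSIFIED])
        base = np.array([cfg.frac_rna, cfg.frac_unannotated, prof.diatom_fraction]
                        + [taxa_mass * p for p in props]
                        + [taxa_mass * remainder])
        pos = base > 0
        p = np.zeros_like(base)
        p[pos] = rng.dirichlet(cfg.dirichlet_concentration * base[pos])
        counts = rng.multinomial(cfg.genes_per_sample, p)
        by_cat = dict(zip(categories, counts))

        ids = _IdSource(sample_id)
        sample_records: list[GeneRecord] = []
        sample_records += _plain_records(rng, cfg, sample_id,
                                         by_cat["__rna__"], ids, is_rna=True)
        sample_records += _plain_records(rng, cfg, sample_id,
                                         by_cat["__unannotated__"], ids, is_rna=False)
        n_chl = n_nuc = n_rbcl = 0
        if by_cat["__diatom__"] > 0:
            drecs, n_chl, n_nuc, n_rbcl = _diatom_records(
                rng, cfg, sample_id, by_cat["__diatom__"], spec.decay_state, ids)
            sample_records += drecs
        taxon_counts = {}
        for taxon in taxa_names:
            k = by_cat[taxon]
            taxon_counts[taxon] = int(k)
            if k > 0:
                sample_records += _taxon_records(rng, cfg, sample_id, taxon, k, ids)
        k_un = by_cat[_UNCLASSIFIED]
        taxon_counts["unclassified_bacteria"] = int(k_un)
        if k_un > 0:
            ident, cov = _draw_identity(rng, cfg.identity_noise, k_un)
            lengths = _draw_lengths(rng, k_un)
            sample_records += [GeneRecord(
                gene_id=ids.next(), sample_id=sample_id,
                length_bp=int(lengths[i]), domain="Bacteria",
                pct_identity=float(ident[i]), aln_coverage=float(cov[i]))
                for i in range(k_un)]

        records += sample_records
        summaries.append(_summary_from_records(sample_records, sample_id,
                                               spec.egs_mbp))
        metadata.append(_metadata_row(rng, sample_id, spec))
        truth[sample_id] = SampleTruth(
            sample_id=sample_id, cluster=spec.cluster, bay=spec.bay,
            decay_state=spec.decay_state,
            category_probs=dict(zip(categories, p.tolist())),
            taxon_counts=taxon_counts,
            n_diatom_pre=int(by_cat["__diatom__"]),
            n_chl_surviving=n_chl, n_nuc_surviving=n_nuc, n_rbcl=n_rbcl,
            expected_pct_rubisco=cfg.decay.expected_pct_rubisco(spec.decay_state))
    table = GeneTable.from_records(records,
                                   sample_ids=list(cfg.samples),
                                   validate=False)
    return table, summaries, metadata, TruthRecord(samples=truth)


def _summary_from_records(recs: Sequence[GeneRecord], sample_id: str,
                          egs_mbp: float) -> SampleSummaryRow:
    cds = [r for r in recs if not r.is_rna]
    n_cds = len(cds)
    gated = [r for r in cds
             if r.pct_identity is not None and r.pct_identity >= 30.0
             and r.aln_coverage is not None and r.aln_coverage >= 0.70]
    n_gated = len(gated)

    def share(pred) -> float:
        return 100.0 * sum(1 for r in gated if pred(r)) / n_gated if n_gated else 0.0

    row = SampleSummaryRow(
        sample_id=sample_id,
        assembly_size_mbp=sum(r.length_bp for r in recs) / 1e6,
        cds_count_millions=n_cds / 1e6,
        egs_mbp=egs_mbp,
        pct_tax_annotated=100.0 * n_gated / n_cds if n_cds else 0.0,
        pct_bacteria=share(lambda r: r.domain == "Bacteria"),
        pct_archaea=share(lambda r: r.domain == "Archaea"),
        pct_viruses=share(lambda r: r.domain == "Viruses"),
        pct_bacillariophyta=share(lambda r: r.domain == "Eukaryota"
                                  and r.lineage.get("phylum") == "Bacillariophyta"),
        pct_other_euk=share(lambda r: r.domain == "Eukaryota"
                            and r.lineage.get("phylum") != "Bacillariophyta"),
    )
    ge_int = int(round(genome_equivalents(row).genome_equivalents))
    return replace(row, genome_equivalents=ge_int if ge_int > 0 else None)


def _metadata_row(rng: np.random.Generator, sample_id: str, spec: SampleSpec
                  ) -> SampleMetadata:
    base = _BAY_CHEMISTRY.get(spec.bay, _DEFAULT_CHEMISTRY)
    noise = rng.lognormal(0.0, 0.2, size=5)
    return SampleMetadata(
        sample_id=sample_id, bay=spec.bay, collection_date="2013-08-23",
        ph=round(max(base["ph"] + rng.normal(0.0, 0.2), 0.0), 1),
        pct_om=round(base["pct_om"] * noise[0], 2),
        no3_ppm=round(base["no3_ppm"] * noise[1], 2),
        nh4_ppm=round(base["nh4_ppm"] * noise[2], 1),
        mn_ppm=round(base["mn_ppm"] * noise[3], 1),
        fe_ppm=round(base["fe_ppm"] * noise[4], 1),
    )


# ---------------------------------------------------------------------------
# focused generators for calibration and decay studies


def simulate_decay_series(d_values: Sequence[float], n0: int = 20_000,
                          decay: DecayParams | None = None, seed: int = 0,
                          ) -> tuple[GeneTable, list[float]]:
    """Diatom-only multi-sample table across a gradient of decay states.

    Sample ``Dk`` receives ``n0`` pre-decay diatom genes thinned at
    ``d_values[k]``.  Returns the table and the closed-form expected
    % RuBisCO per sample.  Intended for proxy validation: running the
    viability proxy on the table and correlating against ``d_values``
    isolates the decay model from community structure.
    """
    decay = decay or DecayParams()
    decay.validate()
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        seed=seed, genes_per_sample=n0, dirichlet_concentration=1.0,
        frac_unannotated=0.0, frac_rna=0.0, decay=decay,
        identity_noise=IdentityNoise(),
        samples={}, taxa={}, cluster_profiles={}, func_term_rates={})
    records: list[GeneRecord] = []
    expected = []
    sample_ids = [f"D{k:02d}" for k in range(len(d_values))]
    for sid, d in zip(sample_ids, d_values):
        ids = _IdSource(sid)
        recs, _, _, _ = _diatom_records(rng, cfg, sid, n0, float(d), ids)
        records += recs
        expected.append(decay.expected_pct_rubisco(float(d)))
    return GeneTable.from_records(records, sample_ids=sample_ids,
                                  validate=False), expected


def simulate_null_table(n_samples: int, n_features: int, seed: int = 0
                        ) -> AbundanceMatrix:
    """Exchangeable null abundance matrix for SIMPROF calibration.

    Every feature's values are i.i.d. log-normal draws sharing a
    per-feature location, so samples are exchangeable by construction
    and any apparent sample structure is noise.
    """
    if n_samples < 3:
        raise ConfigError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, size=n_features)
    values = rng.lognormal(mean=mu[:, None], sigma=0.6,
                           size=(n_features, n_samples))
    df = pd.DataFrame(values,
                      index=[f"F{i:04d}" for i in range(n_features)],
                      columns=[f"S{j:02d}" for j in range(n_samples)])
    return AbundanceMatrix(values=df, mode="genes_per_genome",
                           provenance=[f"exchangeable null, seed={seed}"])
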