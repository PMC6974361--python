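"""Synthetic breeding-experiment generator and rate estimators.

Forward-simulates the G1/G2 crossing experiments used to measure drive
performance: replicate parents each contribute a multinomial draw of scored
offspring from the inheritance-cube row of the cross, and each offspring is
scored for the cargo fluorescence marker (tdTomato, present iff it carries
a G allele), the Cas9 marker (dsRed, present iff it carries a C allele) and
eye phenotype.

Phenotype map: the cargo insertion and out-of-frame resistant alleles are
null for eye pigmentation, so eyes are white iff both target-locus alleles
are in {G, r2}; in-frame r1 alleles restore pigment.  Somatic mosaicism is
modelled phenomenologically: offspring that retain a cleavable ``w`` allele
and are exposed to Cas9 (their own C+G machinery, or maternal carryover)
are scored mosaic with a fixed probability.

Estimators recover transmission and cleavage/HDR rates from count tables
with exact (Clopper-Pearson) binomial intervals, and test super-Mendelian
inheritance against the 50% null by an exact binomial test (default) or by
a t-test over replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .genetics import (
    ConfigurationError,
    DriveParams,
    GeneticSystem,
    InheritanceCube,
    build_cube,
)

__all__ = [
    "CrossDesign",
    "PhenotypeModel",
    "CrossCounts",
    "simulate_cross",
    "estimate_rates",
    "estimate_cleavage_hdr",
    "super_mendelian_test",
    "calibrate_deposition_rate",
    "white_fraction_among_nonmarker",
]

PHENOTYPES = ("black", "mosaic", "white")


@dataclass(frozen=True)
class CrossDesign:
    """One cross: parent genotypes, replicate structure, offspring counts.

    Twenty replicate mothers with individually scored broods is the default
    replicate structure.
    """

    mother: str
    father: str
    system: str = "split"
    n_offspring: int = 50
    n_replicates: int = 20

    def __post_init__(self) -> None:
        if self.n_offspring <= 0:
            raise ConfigurationError("n_offspring must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")


@dataclass(frozen=True)
class PhenotypeModel:
    """Phenomenological somatic-phenotype parameters.

    ``mosaicism_rate`` is the probability that a Cas9-exposed offspring
    retaining a cleavable ``w`` allele shows mosaic (patchy) eyes.
    """

    mosaicism_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mosaicism_rate <= 1.0:
            raise ConfigurationError("mosaicism_rate must lie in [0, 1]")


@dataclass
class CrossCounts:
    """Offspring tallies by (replicate, cargo marker, Cas9 marker, phenotype)."""

    design: CrossDesign
    table: pd.DataFrame  # columns: replicate, cargo_marker, cas9_marker, phenotype, count

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def pooled(self, column: str) -> int:
        return int(self.table.loc[self.table[column], "count"].sum())

    def per_replicate_fraction(self, column: str) -> np.ndarray:
        g = self.table.groupby("replicate")
        num = g.apply(
            lambda d: d.loc[d[column], "count"].sum(), include_groups=False
        )
        den = g["count"].sum()
        return (num / den).to_numpy(dtype=float)

    def phenotype_fraction(self, phenotype: str) -> float:
        sel = self.table["phenotype"] == phenotype
        return float(self.table.loc[sel, "count"].sum()) / self.total

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: Optional[CrossDesign] = None) -> "CrossCounts":
        df = pd.read_csv(path)
        if design is None:
            design = CrossDesign("unknown", "unknown", n_offspring=1, n_replicates=1)
        return cls(design, df)


def _white_mask(system: GeneticSystem) -> np.ndarray:
    """Genotypes with no functional pigmentation allele at the target locus."""
    null = {"G", "H", "r2"}
    return np.array([set(g[-1]) <= null for g in system.genotypes])


def _mosaic_eligible(system: GeneticSystem, mother_deposits: bool) -> np.ndarray:
    """Genotypes that can show mosaicism: a cleavable w allele plus Cas9 exposure."""
    out = np.zeros(system.n, dtype=bool)
    for i, g in enumerate(system.genotypes):
        has_w = "w" in g[-1]
        if system.name == "split":
            own = ("C" in g[0]) and ("G" in g[1])
        elif system.name == "linked":
            own = "H" in g[0]
        else:
            own = False
        out[i] = has_w and (own or mother_deposits)
    return out


def simulate_cross(
    design: CrossDesign,
    drive: DriveParams,
    phenotype_model: Optional[PhenotypeModel] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    cube: Optional[InheritanceCube] = None,
) -> CrossCounts:
    """Simulate scored offspring for every replicate parent."""
    rng = rng if rng is not None else np.random.default_rng()
    phenotype_model = phenotype_model if phenotype_model is not None else PhenotypeModel()
    cube = cube if cube is not None else build_cube(drive, design.system)
    system = cube.system
    row = cube.row(design.mother, design.father).astype(float).copy()
    row[row.argmax()] += 1.0 - row.sum()

    mother_idx = system.genotype_index(design.mother)
    mother_deposits = bool(system.deposits[mother_idx]) and drive.deposition_rate > 0.0
    cargo = system.carrier
    cas9 = system.n_cas9 > 0
    white = _white_mask(system)
    mosaic_ok = _mosaic_eligible(system, mother_deposits)

    records = []
    for rep in range(design.n_replicates):
        counts = rng.multinomial(design.n_offspring, row)
        for g in np.flatnonzero(counts):
            n = int(counts[g])
            if white[g]:
                split = {"white": n, "mosaic": 0, "black": 0}
            elif mosaic_ok[g] and phenotype_model.mosaicism_rate > 0.0:
                m = int(rng.binomial(n, phenotype_model.mosaicism_rate))
                split = {"white": 0, "mosaic": m, "black": n - m}
            else:
                split = {"white": 0, "mosaic": 0, "black": n}
            for phen, k in split.items():
                if k > 0:
                    records.append(
                        {
                            "replicate": rep,
                            "cargo_marker": bool(cargo[g]),
                            "cas9_marker": bool(cas9[g]),
                            "phenotype": phen,
                            "count": k,
                        }
                    )
    table = pd.DataFrame.from_records(
        records, columns=["replicate", "cargo_marker", "cas9_marker", "phenotype", "count"]
    )
    return CrossCounts(design, table)


@dataclass(frozen=True)
class RateEstimate:
    """A pooled proportion with its exact binomial confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    successes: int
    total: int
    per_replicate: Tuple[float, ...] = ()


def _exact_ci(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")  # Clopper-Pearson
    return float(lo), float(hi)


@dataclass(frozen=True)
class RateEstimates:
    transmission: RateEstimate
    mutant_phenotype: RateEstimate


def estimate_rates(counts: CrossCounts, alpha: float = 0.05) -> RateEstimates:
    """Pooled and per-replicate transmission and mutant-phenotype rates.

    Transmission is the fraction of scored offspring carrying the cargo
    marker; the mutant-phenotype (cleavage/mosaicism) rate is the fraction
    scored mosaic or white.  Intervals are exact Clopper-Pearson.
    """
    n = counts.total
    if n == 0:
        raise ConfigurationError("no scored offspring")
    k_t = counts.pooled("cargo_marker")
    mutant_sel = counts.table["phenotype"].isin(["mosaic", "white"])
    k_m = int(counts.table.loc[mutant_sel, "count"].sum())
    per_rep = tuple(counts.per_replicate_fraction("cargo_marker"))
    t_ci = _exact_ci(k_t, n, alpha)
    m_ci = _exact_ci(k_m, n, alpha)
    return RateEstimates(
        transmission=RateEstimate(k_t / n, *t_ci, k_t, n, per_rep),
        mutant_phenotype=RateEstimate(k_m / n, *m_ci, k_m, n),
    )


def estimate_cleavage_hdr(
    counts: CrossCounts, rho1: float = 1.0 / 6.0
) -> Tuple[float, float]:
    """Recover (cleavage c, HDR-given-cleavage h) from a null-father cross.

    Requires a cross of a drive-active heterozygous mother to a father
    whose target alleles are both pigmentation-null and marker-free (e.g.
    ``+/+;r2/r2``): then every pigmented offspring inherited a functional
    maternal allele (w or r1), so with t the cargo-marker fraction and W
    the white fraction,

        t = 1/2 + c*h/2          W - t = c*(1-h)*(1-rho1)/2

    which inverts to c = (2t-1) + 2(W-t)/(1-rho1), h = (2t-1)/c.
    """
    n = counts.total
    t = counts.pooled("cargo_marker") / n
    W = counts.phenotype_fraction("white")
    ch = 2.0 * t - 1.0
    c = ch + 2.0 * max(W - t, 0.0) / (1.0 - rho1)
    if c <= 0.0:
        return float("nan"), float("nan")
    return float(min(c, 1.0)), float(min(max(ch, 0.0) / c, 1.0))


@dataclass(frozen=True)
class SuperMendelianResult:
    estimate: float
    p_value: float
    reject: bool
    method: str
    alpha: float


def super_mendelian_test(
    counts: CrossCounts, method: str = "binomial", alpha: float = 0.05
) -> SuperMendelianResult:
    """One-sided test of cargo transmission > 50%.

    ``method="binomial"`` (default) is an exact binomial test on the pooled
    count; ``method="t"`` is a one-sample t-test of the per-replicate
    transmission fractions against 0.5, matching the replicate-mean t-test
    convention of the breeding experiments.
    """
    n = counts.total
    if n == 0:
        raise ConfigurationError("no scored offspring")
    k = counts.pooled("cargo_marker")
    if method == "binomial":
        p = stats.binomtest(k, n, p=0.5, alternative="greater").pvalue
    elif method == "t":
        fracs = counts.per_replicate_fraction("cargo_marker")
        if len(fracs) < 2:
            raise ConfigurationError("t-test requires >= 2 replicates")
        p = stats.ttest_1samp(fracs, 0.5, alternative="greater").pvalue
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return SuperMendelianResult(k / n, float(p), bool(p < alpha), method, alpha)


def white_fraction_among_nonmarker(
    cube: InheritanceCube, mother: str, father: str
) -> float:
    """P(white eyes | offspring carries neither transgene marker)."""
    system = cube.system
    row = cube.row(mother, father)
    no_marker = ~system.carrier & (system.n_cas9 == 0)
    denom = row[no_marker].sum()
    if denom == 0.0:
        return float("nan")
    white = _white_mask(system)
    return float(row[no_marker & white].sum() / denom)


def calibrate_deposition_rate(
    target: float = 0.0031,
    drive: Optional[DriveParams] = None,
    mother: str = "C/+;G/w",
    father: str = "+/+;w/w",
    system: str = "split",
) -> float:
    """Deposition rate reproducing an observed maternal-carryover footprint.

    Solves for the deposition rate at which the expected fraction of
    offspring lacking both transgene markers that nevertheless show white
    mutant eyes equals ``target`` (0.31% by default, the rate at which
    trans-heterozygous mothers transmitted white phenotypes to progeny that
    inherited neither transgene).
    """
    drive = drive if drive is not None else DriveParams()

    def excess(d: float) -> float:
        cube = build_cube(replace(drive, deposition_rate=d), system)
        return white_fraction_among_nonmarker(cube, mother, father) - target

    if excess(0.0) > 0.0:
        raise ConfigurationError("target already exceeded with zero deposition")
    if excess(1.0) < 0.0:
        raise ConfigurationError("target unreachable even with full deposition")
    return float(optimize.brentq(excess, 0.0, 1.0, xtol=1e-12))
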