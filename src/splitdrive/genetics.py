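"""Inheritance genetics for CRISPR homing gene-drive systems.

Offspring-genotype probability tensors ("inheritance cubes") for three
genetic architectures in *Aedes aegypti*:

``split``
    The Cas9 endonuclease (alleles ``C``/``+``) and the gRNA/cargo element
    (``G``) sit at two unlinked autosomal loci.  Homing occurs only in the
    germline of ``G/w`` heterozygotes that also carry at least one ``C``.
``linked``
    A hypothetical single-locus construct (``H``) carrying Cas9, gRNA and
    cargo together; homing occurs in every ``H/w`` germline.
``refractory``
    An inert disease-refractory allele (``R``) inherited Mendelianly, used
    as the inundative-release comparator.

Cleavage of a wild-type (``w``) chromatid in an active germline is repaired
either by homology-directed repair (HDR), producing another drive allele, or
by end joining, producing an in-frame/cost-free resistant allele (``r1``)
with probability ``rho1`` or an out-of-frame/costly one (``r2``) otherwise.
Sex-specific cleavage and HDR rates, per-Cas9-allele female fecundity costs,
a lifespan cost in cargo-homozygous classes and optional maternal deposition
of the Cas9/gRNA complex are all parameters of :class:`DriveParams`.

The two split-drive loci are modelled as unlinked autosomes.  The real
*white* locus is sex-linked in *Ae. aegypti*; that linkage is deliberately
not modelled here (it cancels when both sexes are considered and keeps the
genotype space small).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DriveParams",
    "GeneticSystem",
    "InheritanceCube",
    "gamete_distribution",
    "build_cube",
    "fitness_modifiers",
    "fecundity_multipliers",
    "mortality_multipliers",
]

SYSTEMS = ("split", "linked", "refractory")

CAS9_ALLELES = ("C", "+")
TARGET_ALLELES = {
    "split": ("G", "w", "r1", "r2"),
    "linked": ("H", "w", "r1", "r2"),
    "refractory": ("R", "w"),
}
CARGO_ALLELE = {"split": "G", "linked": "H", "refractory": "R"}
# Genotypes whose target-locus pair is drawn entirely from this set pay the
# homozygous-cargo lifespan cost.  By default the out-of-frame r2 allele
# shares the class (both alleles ablate the target gene); set
# DriveParams.r2_shares_cost_class=False to restrict the cost to cargo
# homozygotes proper.
COST_CLASS_ALLELES = {"split": ("G", "r2"), "linked": ("H", "r2"), "refractory": ("R",)}


class ConfigurationError(ValueError):
    """Inconsistent parameters, genotype labels or system names."""


class InvariantError(RuntimeError):
    """A model invariant (non-negativity, probability law) was violated."""


@dataclass(frozen=True)
class DriveParams:
    """Drive efficacy and fitness parameters.

    Defaults are the measured rates of the best-performing strain pair
    (U6b-gRNA cargo element with nup50-Cas9): germline cleavage of 100% in
    females and 51.0% in males, HDR given cleavage of 80.5% (females) and
    66.9% (males), one sixth of non-HDR repair yielding in-frame resistant
    alleles, a 7.8% female fecundity reduction per Cas9 allele and a 10%
    mean-lifespan reduction in cargo-homozygous classes.

    ``h_f``/``h_m`` are interpreted as P(HDR | cleavage) per chromatid, so
    the effective transmission from an active female germline is
    0.5 + 0.5*c_f*h_f = 0.9025.  Set ``hdr_is_transmission=True`` to read
    them instead as the effective transmission rate itself.

    ``deposition_rate`` is the probability that a ``w`` allele in the
    offspring of a mother carrying the full drive machinery is converted to
    a resistant allele by maternally deposited Cas9/gRNA (default 0).
    """

    c_f: float = 1.0
    c_m: float = 0.51
    h_f: float = 0.805
    h_m: float = 0.669
    rho1: float = 1.0 / 6.0
    fec_cost_per_cas9: float = 0.078
    lifespan_cost_hom: float = 0.10
    deposition_rate: float = 0.0
    hdr_is_transmission: bool = False
    r2_shares_cost_class: bool = True

    def __post_init__(self) -> None:
        for name in ("c_f", "c_m", "h_f", "h_m", "rho1", "deposition_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} must lie in [0, 1]")
        for name in ("fec_cost_per_cas9", "lifespan_cost_hom"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name}={v!r} must lie in [0, 1)")

    def cleavage_prob(self, sex: str) -> float:
        return self.c_f if sex == "female" else self.c_m

    def hdr_prob(self, sex: str) -> float:
        """P(HDR | cleavage) for the given sex, under either h semantics."""
        h = self.h_f if sex == "female" else self.h_m
        if not self.hdr_is_transmission:
            return h
        c = self.cleavage_prob(sex)
        if c == 0.0:
            return 0.0
        eff = (2.0 * h - 1.0) / c
        if not 0.0 <= eff <= 1.0:
            raise ConfigurationError(
                f"transmission rate {h} with cleavage {c} implies "
                f"P(HDR|cleavage)={eff:.4f} outside [0, 1]"
            )
        return eff


def _sex(sex: str) -> str:
    s = sex.lower()
    if s not in ("female", "male"):
        raise ConfigurationError(f"sex must be 'female' or 'male', got {sex!r}")
    return s


Pair = Tuple[str, str]
GenotypeSpec = Union[int, str, Tuple[Pair, ...]]


class GeneticSystem:
    """Genotype bookkeeping for one drive architecture.

    Genotypes are unordered diploid allele pairs per locus, canonically
    sorted by the declared allele order, so each genotype has exactly one
    representation (30 genotypes for the split system, 10 for the linked,
    3 for the refractory).
    """

    def __init__(self, name: str):
        if name not in SYSTEMS:
            raise ConfigurationError(f"unknown system {name!r}; expected one of {SYSTEMS}")
        self.name = name
        if name == "split":
            self.locus_alleles: Tuple[Tuple[str, ...], ...] = (
                CAS9_ALLELES,
                TARGET_ALLELES["split"],
            )
        else:
            self.locus_alleles = (TARGET_ALLELES[name],)
        self.cargo = CARGO_ALLELE[name]

        pairs = [
            list(itertools.combinations_with_replacement(a, 2)) for a in self.locus_alleles
        ]
        self.genotypes: Tuple[Tuple[Pair, ...], ...] = tuple(
            tuple(combo) for combo in itertools.product(*pairs)
        )
        self.n = len(self.genotypes)
        self.labels = tuple(";".join("/".join(p) for p in g) for g in self.genotypes)
        self._by_label = {lab: i for i, lab in enumerate(self.labels)}
        self._by_pairs = {g: i for i, g in enumerate(self.genotypes)}
        self._allele_rank = [
            {a: k for k, a in enumerate(locus)} for locus in self.locus_alleles
        ]

        self.alleles = tuple(a for locus in self.locus_alleles for a in locus)
        self._allele_pos = {a: k for k, a in enumerate(self.alleles)}
        self.allele_count = np.zeros((self.n, len(self.alleles)))
        for i, g in enumerate(self.genotypes):
            for pair in g:
                for a in pair:
                    self.allele_count[i, self._allele_pos[a]] += 1

        self.carrier = np.array([self.cargo in g[-1] for g in self.genotypes])
        cost = set(COST_CLASS_ALLELES[name])
        self.cost_class = np.array([set(g[-1]) <= cost for g in self.genotypes])
        if name == "split":
            self.n_cas9 = np.array([g[0].count("C") for g in self.genotypes])
        elif name == "linked":
            self.n_cas9 = np.array([g[0].count("H") for g in self.genotypes])
        else:
            self.n_cas9 = np.zeros(self.n, dtype=int)
        # mothers whose eggs receive deposited Cas9/gRNA complex
        if name == "split":
            self.deposits = np.array(
                [("C" in g[0]) and ("G" in g[1]) for g in self.genotypes]
            )
        elif name == "linked":
            self.deposits = np.array([("H" in g[0]) for g in self.genotypes])
        else:
            self.deposits = np.zeros(self.n, dtype=bool)

        wt_pairs = tuple(
            (("+", "+") if locus is CAS9_ALLELES else ("w", "w"))
            for locus in self.locus_alleles
        )
        self.wild_type = self._by_pairs[wt_pairs]

    # -- genotype lookup -------------------------------------------------

    def _parse_pair(self, text: str, locus: int) -> Pair:
        alleles = self.locus_alleles[locus]
        if "/" in text:
            parts = tuple(text.split("/"))
        else:
            # compact form like "CC" or "Gr1": greedy longest-allele match
            parts_list = []
            rest = text
            while rest:
                for a in sorted(alleles, key=len, reverse=True):
                    if rest.startswith(a):
                        parts_list.append(a)
                        rest = rest[len(a):]
                        break
                else:
                    raise ConfigurationError(
                        f"cannot parse {text!r} over alleles {alleles}"
                    )
            parts = tuple(parts_list)
        if len(parts) != 2 or any(a not in alleles for a in parts):
            raise ConfigurationError(
                f"{text!r} is not a diploid pair over alleles {alleles}"
            )
        rank = self._allele_rank[locus]
        return tuple(sorted(parts, key=rank.__getitem__))  # type: ignore[return-value]

    def genotype_index(self, genotype: GenotypeSpec) -> int:
        """Resolve an index, label (``"C/+;G/w"`` or ``"CC;GG"``) or pair tuple."""
        if isinstance(genotype, (int, np.integer)):
            if not 0 <= genotype < self.n:
                raise ConfigurationError(f"genotype index {genotype} out of range")
            return int(genotype)
        if isinstance(genotype, str):
            if genotype in self._by_label:
                return self._by_label[genotype]
            parts = genotype.split(";")
            if len(parts) != len(self.locus_alleles):
                raise ConfigurationError(
                    f"{genotype!r} has {len(parts)} loci; system {self.name!r} "
                    f"has {len(self.locus_alleles)}"
                )
            pairs = tuple(self._parse_pair(p, k) for k, p in enumerate(parts))
            return self._by_pairs[pairs]
        pairs = tuple(
            tuple(sorted(p, key=self._allele_rank[k].__getitem__))
            for k, p in enumerate(genotype)
        )
        try:
            return self._by_pairs[pairs]  # type: ignore[index]
        except KeyError:
            raise ConfigurationError(f"unknown genotype {genotype!r} for {self.name}")

    def label(self, index: int) -> str:
        return self.labels[index]

    def pair_index(self, ordered: Sequence[str], locus: int) -> Pair:
        rank = self._allele_rank[locus]
        return tuple(sorted(ordered, key=rank.__getitem__))  # type: ignore[return-value]

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticSystem({self.name!r}, n={self.n})"


def _mendelian(pair: Pair) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for a in pair:
        out[a] = out.get(a, 0.0) + 0.5
    return out


def _homing(drive: str, c: float, h: float, rho1: float) -> Dict[str, float]:
    out = {
        drive: 0.5 + 0.5 * c * h,
        "w": 0.5 * (1.0 - c),
        "r1": 0.5 * c * (1.0 - h) * rho1,
        "r2": 0.5 * c * (1.0 - h) * (1.0 - rho1),
    }
    return {a: p for a, p in out.items() if p > 0.0}


def gamete_distribution(
    system: GeneticSystem,
    genotype: GenotypeSpec,
    sex: str,
    params: DriveParams,
) -> Dict[Tuple[str, ...], float]:
    """Distribution over haploid allele combinations produced by one parent.

    In a ``G/w`` (or ``H/w``) germline with Cas9 available, each ``w``
    chromatid is cleaved with probability ``c``; given cleavage it is
    converted to the drive allele by HDR with probability ``h``, otherwise
    it becomes ``r1`` with probability ``rho1`` and ``r2`` with probability
    ``1 - rho1``.  Uncut ``w`` transmits as ``w``; all other genotypes
    transmit Mendelianly.  Alleles at the two split-system loci assort
    independently.
    """
    sex = _sex(sex)
    g = system.genotypes[system.genotype_index(genotype)]
    c = params.cleavage_prob(sex)
    h = params.hdr_prob(sex)
    per_locus = []
    if system.name == "split":
        cas9_pair, target_pair = g
        per_locus.append(_mendelian(cas9_pair))
        if "C" in cas9_pair and set(target_pair) == {"G", "w"} and c > 0.0:
            per_locus.append(_homing("G", c, h, params.rho1))
        else:
            per_locus.append(_mendelian(target_pair))
    else:
        (pair,) = g
        if system.name == "linked" and set(pair) == {"H", "w"} and c > 0.0:
            per_locus.append(_homing("H", c, h, params.rho1))
        else:
            per_locus.append(_mendelian(pair))

    out: Dict[Tuple[str, ...], float] = {}
    for combo in itertools.product(*[d.items() for d in per_locus]):
        alleles = tuple(a for a, _ in combo)
        p = 1.0
        for _, q in combo:
            p *= q
        if p > 0.0:
            out[alleles] = out.get(alleles, 0.0) + p
    return out


def _exact_simplex(flat: np.ndarray) -> np.ndarray:
    """Normalise rows to sum to exactly 1.0 in floating point.

    The rounding residual is pushed into each row's largest entry so that
    downstream multinomial sampling never sees a row summing above 1.
    """
    flat = flat / flat.sum(axis=1, keepdims=True)
    m = flat.shape[0]
    amax = flat.argmax(axis=1)
    flat[np.arange(m), amax] += 1.0 - flat.sum(axis=1)
    return flat


def _deposition_matrix(system: GeneticSystem, params: DriveParams) -> np.ndarray:
    """Offspring-genotype transition matrix for maternal Cas9/gRNA carryover.

    Each ``w`` allele of the offspring is independently converted with
    probability ``deposition_rate``, becoming ``r1`` with probability
    ``rho1`` and ``r2`` otherwise.
    """
    d = params.deposition_rate
    conv = {"w": {"w": 1.0 - d, "r1": d * params.rho1, "r2": d * (1.0 - params.rho1)}}
    tgt = len(system.locus_alleles) - 1
    D = np.zeros((system.n, system.n))
    for i, g in enumerate(system.genotypes):
        a1, a2 = g[-1]
        o1 = conv.get(a1, {a1: 1.0})
        o2 = conv.get(a2, {a2: 1.0})
        for b1, p1 in o1.items():
            for b2, p2 in o2.items():
                if p1 * p2 == 0.0:
                    continue
                new_pair = system.pair_index((b1, b2), tgt)
                j = system._by_pairs[g[:-1] + (new_pair,)]
                D[i, j] += p1 * p2
    return D


@dataclass
class InheritanceCube:
    """Probability tensor mapping (mother, father) genotypes to offspring.

    ``tensor[m, f, k]`` is the probability that a mating of mother genotype
    ``m`` with father genotype ``f`` produces an offspring of genotype
    ``k``.  Every (m, f) row is a probability distribution.
    """

    system: GeneticSystem
    tensor: np.ndarray
    params: DriveParams

    def row(self, mother: GenotypeSpec, father: GenotypeSpec) -> np.ndarray:
        i = self.system.genotype_index(mother)
        j = self.system.genotype_index(father)
        return self.tensor[i, j]

    def carrier_probability(
        self, mother: GenotypeSpec, father: GenotypeSpec, allele: str | None = None
    ) -> float:
        """P(offspring carries >=1 copy of ``allele``) for one parental pair."""
        allele = allele or self.system.cargo
        if allele not in self.system._allele_pos:
            raise ConfigurationError(f"unknown allele {allele!r}")
        mask = self.system.allele_count[:, self.system._allele_pos[allele]] > 0
        return float(self.row(mother, father)[mask].sum())

    def validate(self, atol: float = 1e-12) -> None:
        if np.any(self.tensor < 0):
            raise InvariantError("negative probability in inheritance cube")
        rows = self.tensor.sum(axis=2)
        if np.max(np.abs(rows - 1.0)) > atol:
            raise InvariantError("inheritance cube rows do not sum to 1")

    # -- plain-text round trip ------------------------------------------

    def to_text(self, path) -> None:
        labels = self.system.labels
        idx = [f"{m} x {f}" for m in labels for f in labels]
        df = pd.DataFrame(
            self.tensor.reshape(self.system.n**2, self.system.n),
            index=idx,
            columns=list(labels),
        )
        with open(path, "w") as fh:
            fh.write(f"# system: {self.system.name}\n")
            df.to_csv(fh, index_label="mother x father", float_format="%.17g")

    @classmethod
    def from_text(cls, path) -> "InheritanceCube":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# system:"):
                raise ConfigurationError(f"{path}: missing '# system:' header line")
            system = GeneticSystem(header.split(":", 1)[1].strip())
            df = pd.read_csv(fh, index_col=0)
        if tuple(df.columns) != system.labels:
            raise ConfigurationError(f"{path}: genotype labels do not match {system}")
        tensor = df.to_numpy().reshape(system.n, system.n, system.n)
        cube = cls(system, tensor, DriveParams())
        cube.validate(atol=1e-9)
        return cube


def build_cube(
    params: DriveParams, system: Union[str, GeneticSystem]
) -> InheritanceCube:
    """Construct the inheritance cube for a system under ``params``.

    The tensor is the outer product of maternal and paternal gamete
    distributions for every parental pair, followed by the maternal
    deposition transform for mothers that carry the full drive machinery.
    """
    sysobj = system if isinstance(system, GeneticSystem) else GeneticSystem(system)
    n = sysobj.n
    maternal = [
        gamete_distribution(sysobj, i, "female", params) for i in range(n)
    ]
    paternal = [gamete_distribution(sysobj, i, "male", params) for i in range(n)]

    # precompute child index for each (maternal gamete, paternal gamete)
    tensor = np.zeros((n, n, n))
    child_cache: Dict[Tuple[Tuple[str, ...], Tuple[str, ...]], int] = {}

    def child_index(gm: Tuple[str, ...], gp: Tuple[str, ...]) -> int:
        key = (gm, gp)
        if key not in child_cache:
            pairs = tuple(
                sysobj.pair_index((gm[k], gp[k]), k) for k in range(len(gm))
            )
            child_cache[key] = sysobj._by_pairs[pairs]
        return child_cache[key]

    for im in range(n):
        for ip in range(n):
            row = tensor[im, ip]
            for gm, pm in maternal[im].items():
                for gp, pp in paternal[ip].items():
                    row[child_index(gm, gp)] += pm * pp

    if params.deposition_rate > 0.0 and sysobj.deposits.any():
        D = _deposition_matrix(sysobj, params)
        dep = sysobj.deposits
        tensor[dep] = tensor[dep] @ D

    flat = _exact_simplex(tensor.reshape(n * n, n))
    cube = InheritanceCube(sysobj, flat.reshape(n, n, n), params)
    cube.validate()
    return cube


def fitness_modifiers(
    system: GeneticSystem, genotype: GenotypeSpec, params: DriveParams
) -> Tuple[float, float]:
    """(fecundity multiplier, adult mortality-rate multiplier) for a genotype.

    Fecundity is reduced multiplicatively per Cas9-bearing allele and
    applies to females only; the lifespan reduction in the homozygous cargo
    cost class is mapped to a mortality-rate inflation of
    ``1/(1 - lifespan_cost_hom)`` under exponential adult survival.
    """
    i = system.genotype_index(genotype)
    fec = (1.0 - params.fec_cost_per_cas9) ** system.n_cas9[i]
    mort = 1.0 / (1.0 - params.lifespan_cost_hom) if cost_class_mask(system, params)[i] else 1.0
    return float(fec), float(mort)


def cost_class_mask(system: GeneticSystem, params: DriveParams) -> np.ndarray:
    """Genotypes paying the homozygous-cargo lifespan cost."""
    cost = set(COST_CLASS_ALLELES[system.name])
    if not params.r2_shares_cost_class:
        cost.discard("r2")
    return np.array([set(g[-1]) <= cost for g in system.genotypes])


def fecundity_multipliers(system: GeneticSystem, params: DriveParams) -> np.ndarray:
    return (1.0 - params.fec_cost_per_cas9) ** system.n_cas9.astype(float)


def mortality_multipliers(system: GeneticSystem, params: DriveParams) -> np.ndarray:
    out = np.ones(system.n)
    out[cost_class_mask(system, params)] = 1.0 / (1.0 - params.lifespan_cost_hom)
    return out
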