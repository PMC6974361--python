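"""Daily-step, stage-structured mosquito demography.

Eggs, larvae and pupae are tracked in day-binned age cohorts with fixed
stage durations; adults are tracked by genotype, with once-mating females
indexed by (own genotype, mate genotype).  Each simulated day applies, in
order: egg laying, survival thinning (with density-dependent larval
mortality evaluated at the pre-thinning larval census), cohort advancement
with emergence and fair-coin sex assignment, and mating of newly emerged
females against the current adult-male genotype frequencies.

The density-independent juvenile daily mortality ``muJ`` (shared by egg,
larva and pupa) is calibrated so that the per-generation growth rate in the
absence of density dependence equals ``Rm``:

    (beta / muAd) * (1 - muJ)^(tE + tL + tP) * 1/2 = Rm

where ``beta/muAd`` is lifetime egg output per female and the factor 1/2 is
the female fraction at emergence.  Additional density-dependent larval
mortality uses daily survival ``(alpha / (alpha + L))^(1/tL)``, with
``alpha`` solved so the wild-type fixed point has ``N_eq`` adults.  At that
fixed point the density-dependent survival over the whole larval stage is
exactly ``1/Rm``, which yields ``alpha`` in closed form.

Counts are non-negative integers with Poisson (egg laying), binomial
(survival, sex) and multinomial (offspring genotype, mate choice) sampling;
passing ``rng=None`` to :meth:`Dynamics.step` instead propagates expected
values, providing the deterministic mode used for calibration and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genetics import (
    ConfigurationError,
    DriveParams,
    GeneticSystem,
    InheritanceCube,
    InvariantError,
    fecundity_multipliers,
    mortality_multipliers,
)

__all__ = [
    "LifeHistoryParams",
    "PatchState",
    "Dynamics",
    "calibrate_juvenile_mortality",
    "solve_density_parameter",
    "equilibrium_state",
]


@dataclass(frozen=True)
class LifeHistoryParams:
    """Aedes aegypti life-history parameters (daily rates, days, counts).

    Defaults: 20 eggs/female/day, 5 d egg, 6 d larva and 4 d pupa stages,
    9%/day adult mortality, per-generation growth rate 1.096 and an
    equilibrium adult population of 10,000 — standard values for this
    modelling framework; every field is overridable.
    """

    beta: float = 20.0
    t_egg: int = 5
    t_larva: int = 6
    t_pupa: int = 4
    mu_adult: float = 0.09
    growth_rate: float = 1.096
    n_eq: float = 10_000.0

    def __post_init__(self) -> None:
        for name in ("t_egg", "t_larva", "t_pupa"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigurationError(f"{name}={v!r} must be a positive integer")
        if self.beta < 0:
            raise ConfigurationError(f"beta={self.beta!r} must be non-negative")
        if not 0.0 <= self.mu_adult < 1.0:
            raise ConfigurationError(f"mu_adult={self.mu_adult!r} must lie in [0, 1)")
        if not self.n_eq > 0:
            raise ConfigurationError(f"n_eq={self.n_eq!r} must be positive")
        if not self.growth_rate > 0:
            raise ConfigurationError(f"growth_rate={self.growth_rate!r} must be positive")

    @property
    def juvenile_days(self) -> int:
        return self.t_egg + self.t_larva + self.t_pupa

    @property
    def generation_days(self) -> float:
        """Mean egg-to-egg generation time: juvenile development + adult life."""
        if self.mu_adult == 0.0:
            raise ConfigurationError("generation time undefined for immortal adults")
        return self.juvenile_days + 1.0 / self.mu_adult


def calibrate_juvenile_mortality(params: LifeHistoryParams) -> float:
    """Daily juvenile mortality consistent with the stated growth rate.

    Solves (beta/muAd) * (1-muJ)^juvenile_days * 1/2 = Rm by bisection.
    """
    if params.mu_adult == 0.0 or params.beta == 0.0:
        raise ConfigurationError(
            "calibration requires beta > 0 and mu_adult > 0 (finite lifetime egg output)"
        )
    lifetime_eggs = params.beta / params.mu_adult

    def excess(mu: float) -> float:
        return 0.5 * lifetime_eggs * (1.0 - mu) ** params.juvenile_days - params.growth_rate

    f0 = excess(0.0)
    if f0 < 0.0:
        raise ConfigurationError(
            f"growth_rate={params.growth_rate} unreachable: beta={params.beta}, "
            f"mu_adult={params.mu_adult} support at most Rm={0.5 * lifetime_eggs:.4g} "
            "even with zero juvenile mortality"
        )
    if f0 == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    return 0.5 * (lo + hi)


def _equilibrium_profile(params: LifeHistoryParams, mu_j: float):
    """Closed-form wild-type stationary cohort sizes (per-day, one patch)."""
    s_j = 1.0 - mu_j
    eggs_daily = params.beta * params.n_eq / 2.0
    eggs = eggs_daily * s_j ** np.arange(params.t_egg)
    l0 = eggs_daily * s_j**params.t_egg
    s_dd = params.growth_rate ** (-1.0 / params.t_larva)
    q = s_j * s_dd
    larvae = l0 * q ** np.arange(params.t_larva)
    p0 = l0 * q**params.t_larva
    pupae = p0 * s_j ** np.arange(params.t_pupa)
    return eggs, larvae, pupae


def solve_density_parameter(params: LifeHistoryParams, mu_j: float) -> float:
    """Density-dependence strength alpha fixing the adult equilibrium at n_eq.

    At the wild-type fixed point the density-dependent survival over the
    larval stage equals 1/Rm, so alpha = L_eq / (Rm - 1) where L_eq is the
    equilibrium total larval census.  Requires Rm > 1 (as Rm -> 1+ density
    dependence vanishes and alpha diverges).
    """
    if params.growth_rate <= 1.0:
        raise ConfigurationError(
            f"growth_rate={params.growth_rate} must exceed 1 for a positive "
            "density-dependence parameter"
        )
    _, larvae, _ = _equilibrium_profile(params, mu_j)
    return float(larvae.sum() / (params.growth_rate - 1.0))


@dataclass
class PatchState:
    """Genotype-resolved counts for one patch.

    ``eggs``/``larvae``/``pupae`` have shape (stage duration, n_genotypes)
    with row 0 the youngest cohort; ``males`` has shape (n_genotypes,);
    ``females`` has shape (own genotype, mate genotype); ``unmated`` holds
    emerged females that found no male and retry mating daily.
    """

    eggs: np.ndarray
    larvae: np.ndarray
    pupae: np.ndarray
    males: np.ndarray
    females: np.ndarray
    unmated: np.ndarray

    @classmethod
    def empty(
        cls, n_genotypes: int, params: LifeHistoryParams, dtype=np.int64
    ) -> "PatchState":
        return cls(
            eggs=np.zeros((params.t_egg, n_genotypes), dtype=dtype),
            larvae=np.zeros((params.t_larva, n_genotypes), dtype=dtype),
            pupae=np.zeros((params.t_pupa, n_genotypes), dtype=dtype),
            males=np.zeros(n_genotypes, dtype=dtype),
            females=np.zeros((n_genotypes, n_genotypes), dtype=dtype),
            unmated=np.zeros(n_genotypes, dtype=dtype),
        )

    def copy(self) -> "PatchState":
        return PatchState(
            self.eggs.copy(),
            self.larvae.copy(),
            self.pupae.copy(),
            self.males.copy(),
            self.females.copy(),
            self.unmated.copy(),
        )

    @property
    def female_by_genotype(self) -> np.ndarray:
        """Adult females by own genotype (mated + unmated)."""
        return self.females.sum(axis=1) + self.unmated

    @property
    def total_adults(self) -> float:
        return float(self.males.sum() + self.females.sum() + self.unmated.sum())

    @property
    def total_juveniles(self) -> float:
        return float(self.eggs.sum() + self.larvae.sum() + self.pupae.sum())

    @property
    def total(self) -> float:
        return self.total_adults + self.total_juveniles

    def validate(self) -> None:
        for name in ("eggs", "larvae", "pupae", "males", "females", "unmated"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise InvariantError(f"negative count in {name}")


class Dynamics:
    """Daily-step kernel for one patch: inheritance cube + life history.

    Precomputes the flattened cube, genotype fitness vectors and the
    calibrated ``muJ``/``alpha`` so that :meth:`step` is cheap.  With an
    ``rng`` the step is the integer stochastic model; with ``rng=None`` it
    propagates expectations on float-valued states.
    """

    def __init__(
        self,
        cube: InheritanceCube,
        drive: DriveParams,
        life: LifeHistoryParams,
        *,
        mu_juvenile: Optional[float] = None,
        alpha: Optional[float] = None,
    ):
        self.cube = cube
        self.system: GeneticSystem = cube.system
        self.drive = drive
        self.life = life
        self.mu_juvenile = (
            calibrate_juvenile_mortality(life) if mu_juvenile is None else mu_juvenile
        )
        self.alpha = (
            solve_density_parameter(life, self.mu_juvenile) if alpha is None else alpha
        )
        n = self.system.n
        self.n = n
        self.cube_flat = np.ascontiguousarray(cube.tensor.reshape(n * n, n))
        self.fecundity = fecundity_multipliers(self.system, drive)
        death = np.minimum(life.mu_adult * mortality_multipliers(self.system, drive), 1.0)
        self.adult_survival = 1.0 - death

    # -- states ----------------------------------------------------------

    def empty_state(self, stochastic: bool = True) -> PatchState:
        return PatchState.empty(
            self.n, self.life, dtype=np.int64 if stochastic else np.float64
        )

    def equilibrium_state(self, stochastic: bool = True) -> PatchState:
        """Wild-type stationary age distribution (rounded if stochastic)."""
        eggs, larvae, pupae = _equilibrium_profile(self.life, self.mu_juvenile)
        state = self.empty_state(stochastic=stochastic)
        wt = self.system.wild_type
        half = self.life.n_eq / 2.0
        if stochastic:
            state.eggs[:, wt] = np.rint(eggs).astype(np.int64)
            state.larvae[:, wt] = np.rint(larvae).astype(np.int64)
            state.pupae[:, wt] = np.rint(pupae).astype(np.int64)
            state.males[wt] = int(round(half))
            state.females[wt, wt] = int(round(half))
        else:
            state.eggs[:, wt] = eggs
            state.larvae[:, wt] = larvae
            state.pupae[:, wt] = pupae
            state.males[wt] = half
            state.females[wt, wt] = half
        return state

    # -- the daily step --------------------------------------------------

    def larval_dd_survival(self, larval_census: float) -> float:
        if larval_census <= 0.0 or not np.isfinite(self.alpha):
            return 1.0
        return float(
            (self.alpha / (self.alpha + larval_census)) ** (1.0 / self.life.t_larva)
        )

    def step(self, state: PatchState, rng: Optional[np.random.Generator] = None) -> PatchState:
        """Advance ``state`` by one day in place (also returns it)."""
        life = self.life
        stochastic = rng is not None

        # 1. egg laying
        lam = life.beta * self.fecundity[:, None] * state.females
        if stochastic:
            lam_flat = lam.ravel()
            nz = np.flatnonzero(lam_flat)
            newborn = np.zeros(self.n, dtype=np.int64)
            if nz.size:
                counts = rng.poisson(lam_flat[nz])
                pos = counts > 0
                if pos.any():
                    draws = rng.multinomial(counts[pos], self.cube_flat[nz[pos]])
                    newborn = draws.sum(axis=0)
        else:
            newborn = lam.ravel() @ self.cube_flat

        # 2. survival (density-dependent larval survival uses the census
        #    before thinning)
        s_j = 1.0 - self.mu_juvenile
        s_l = s_j * self.larval_dd_survival(float(state.larvae.sum()))
        s_a = self.adult_survival
        if stochastic:
            state.eggs = rng.binomial(state.eggs, s_j)
            state.larvae = rng.binomial(state.larvae, s_l)
            state.pupae = rng.binomial(state.pupae, s_j)
            state.males = rng.binomial(state.males, s_a)
            state.females = rng.binomial(state.females, s_a[:, None])
            state.unmated = rng.binomial(state.unmated, s_a)
        else:
            state.eggs = state.eggs * s_j
            state.larvae = state.larvae * s_l
            state.pupae = state.pupae * s_j
            state.males = state.males * s_a
            state.females = state.females * s_a[:, None]
            state.unmated = state.unmated * s_a

        # 3. advancement: survivors age one day; final-day cohorts graduate
        graduating_eggs = state.eggs[-1].copy()
        state.eggs[1:] = state.eggs[:-1]
        state.eggs[0] = newborn
        graduating_larvae = state.larvae[-1].copy()
        state.larvae[1:] = state.larvae[:-1]
        state.larvae[0] = graduating_eggs
        emerged = state.pupae[-1].copy()
        state.pupae[1:] = state.pupae[:-1]
        state.pupae[0] = graduating_larvae

        if stochastic:
            new_females = rng.binomial(emerged, 0.5)
        else:
            new_females = 0.5 * emerged
        state.males = state.males + (emerged - new_females)

        # 4. mating: emerging (and previously unmated) females draw a mate
        #    genotype from current adult-male frequencies
        candidates = new_females + state.unmated
        total_males = state.males.sum()
        if candidates.sum() > 0 and total_males > 0:
            p_mate = state.males / total_males
            if stochastic:
                p_mate = p_mate.astype(float)
                p_mate[p_mate.argmax()] += 1.0 - p_mate.sum()
                state.females = state.females + rng.multinomial(candidates, p_mate)
            else:
                state.females = state.females + candidates[:, None] * p_mate[None, :]
            state.unmated = np.zeros_like(state.unmated)
        else:
            state.unmated = candidates
        return state


def equilibrium_state(
    cube: InheritanceCube,
    drive: DriveParams,
    params: LifeHistoryParams,
    stochastic: bool = True,
) -> PatchState:
    """Convenience wrapper: calibrated wild-type equilibrium PatchState."""
    return Dynamics(cube, drive, params).equilibrium_state(stochastic=stochastic)
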