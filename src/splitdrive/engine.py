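"""Ensemble simulation engine and summary metrics.

Runs seeded ensembles of the full model (daily life-history step per patch,
then migration, then scheduled releases), records genotype-resolved adult
trajectories and computes the release-programme metrics: the fraction of
adult females carrying at least one cargo allele, allele frequencies among
adults, the window of protection (days the mean carrier fraction stays
above a threshold) and release-number x fitness-cost heatmaps.

Reproducibility: every realization draws from generators spawned off a
single ``SeedSequence``; one child stream per patch plus one for migration,
so a landscape with zero migration evolves each patch exactly as the same
patch stream would alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genetics import (
    ConfigurationError,
    DriveParams,
    GeneticSystem,
    build_cube,
)
from .life_history import Dynamics, LifeHistoryParams, PatchState
from .landscape import (
    Landscape,
    ReleaseSchedule,
    apply_migration,
    apply_releases,
    generation_time_days,
    migration_matrix,
    per_generation_to_daily_migration,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "EnsembleSummary",
    "WindowOfProtection",
    "two_patch_release_config",
    "homozygous_release_genotype",
    "build_dynamics",
    "run_realization",
    "run_ensemble",
    "carrier_fraction",
    "window_of_protection",
    "max_sustained_level",
    "heatmap_experiment",
]

logger = logging.getLogger("splitdrive")


def homozygous_release_genotype(system: Union[str, GeneticSystem]) -> str:
    name = system.name if isinstance(system, GeneticSystem) else system
    return {"split": "C/C;G/G", "linked": "H/H", "refractory": "R/R"}[name]


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to reproduce an ensemble."""

    system: str = "split"
    drive: DriveParams = field(default_factory=DriveParams)
    life: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    n_patches: int = 2
    migration_rate_per_generation: float = 0.01
    releases: ReleaseSchedule = field(default_factory=ReleaseSchedule)
    horizon_days: int = 1825
    n_realizations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be >= 1")
        if self.n_realizations < 1:
            raise ConfigurationError("n_realizations must be >= 1")
        if self.n_patches < 1:
            raise ConfigurationError("n_patches must be >= 1")

    @property
    def daily_migration(self) -> float:
        return per_generation_to_daily_migration(
            self.migration_rate_per_generation, generation_time_days(self.life)
        )


def two_patch_release_config(
    system: str = "split",
    *,
    n_eq: float = 10_000.0,
    n_releases: int = 10,
    release_size: int = 10_000,
    start_day: int = 50,
    release_patch: int = 0,
    interval: int = 7,
    horizon_days: int = 1825,
    n_realizations: int = 20,
    n_patches: int = 2,
    migration_rate_per_generation: float = 0.01,
    seed: int = 0,
    drive: Optional[DriveParams] = None,
    life: Optional[LifeHistoryParams] = None,
) -> SimConfig:
    """The two-patch confinement/reversibility study scenario.

    Defaults: two 10,000-adult patches exchanging 1% of mosquitoes per
    generation; 10 weekly releases of 10,000 drive-homozygous males into
    patch 0 starting on day 50 (post burn-in); 5-year horizon.
    """
    drive = drive if drive is not None else DriveParams()
    life = life if life is not None else LifeHistoryParams(n_eq=n_eq)
    schedule = (
        ReleaseSchedule.weekly(
            n_releases,
            release_size,
            homozygous_release_genotype(system),
            start_day=start_day,
            patch=release_patch,
            interval=interval,
        )
        if n_releases > 0
        else ReleaseSchedule()
    )
    return SimConfig(
        system=system,
        drive=drive,
        life=life,
        n_patches=n_patches,
        migration_rate_per_generation=migration_rate_per_generation,
        releases=schedule,
        horizon_days=horizon_days,
        n_realizations=n_realizations,
        seed=seed,
    )


def build_dynamics(config: SimConfig) -> Dynamics:
    cube = build_cube(config.drive, config.system)
    return Dynamics(cube, config.drive, config.life)


def _new_landscape(dynamics: Dynamics, config: SimConfig, stochastic: bool) -> Landscape:
    patches = [
        dynamics.equilibrium_state(stochastic=stochastic)
        for _ in range(config.n_patches)
    ]
    M = migration_matrix(config.n_patches, config.daily_migration)
    return Landscape(patches, M)


@dataclass
class Trajectory:
    """Day-by-day genotype-resolved adult counts for one realization.

    ``males``/``females`` have shape (horizon+1, n_patches, n_genotypes);
    index 0 is the pre-release initial state.  Females include unmated
    females and are indexed by own genotype.
    """

    system: GeneticSystem
    days: np.ndarray
    males: np.ndarray
    females: np.ndarray

    @property
    def n_patches(self) -> int:
        return self.males.shape[1]

    def female_total(self, patch: int) -> np.ndarray:
        return self.females[:, patch].sum(axis=1)

    def female_carrier_fraction(
        self, patch: int, allele: Optional[str] = None
    ) -> np.ndarray:
        """Fraction of adult females with >=1 copy of ``allele`` (default cargo).

        Days with no females are NaN.
        """
        allele = allele or self.system.cargo
        pos = self.system._allele_pos[allele]
        mask = self.system.allele_count[:, pos] > 0
        fem = self.females[:, patch]
        total = fem.sum(axis=1).astype(float)
        carriers = fem[:, mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, carriers / total, np.nan)

    def allele_frequency(self, allele: str, patch: int) -> np.ndarray:
        """Frequency of ``allele`` among all adults (2N allele copies)."""
        if allele not in self.system._allele_pos:
            raise ConfigurationError(f"unknown allele {allele!r}")
        counts = self.system.allele_count[:, self.system._allele_pos[allele]]
        adults = self.males[:, patch] + self.females[:, patch]
        num = adults @ counts
        den = 2.0 * adults.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    def adult_total(self, patch: int) -> np.ndarray:
        return self.males[:, patch].sum(axis=1) + self.female_total(patch)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-day, per-patch export (CSV-friendly)."""
        rows = []
        for p in range(self.n_patches):
            df = pd.DataFrame(
                {
                    "day": self.days,
                    "patch": p,
                    "adult_males": self.males[:, p].sum(axis=1),
                    "adult_females": self.female_total(p),
                    "female_carrier_fraction": self.female_carrier_fraction(p),
                }
            )
            for allele in self.system.alleles:
                df[f"freq_{allele}"] = self.allele_frequency(allele, p)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def carrier_fraction(
    trajectory: Trajectory, day: int, patch: int, allele: Optional[str] = None
) -> float:
    """Fraction of adult females with >=1 copy of ``allele`` on ``day``.

    NaN if the patch holds no adult females that day.
    """
    return float(trajectory.female_carrier_fraction(patch, allele)[day])


def run_realization(
    config: SimConfig,
    seed: Union[int, np.random.SeedSequence, None] = None,
    *,
    deterministic: bool = False,
    dynamics: Optional[Dynamics] = None,
) -> Trajectory:
    """Run one full realization; bit-reproducible from (config, seed)."""
    dyn = dynamics if dynamics is not None else build_dynamics(config)
    P = config.n_patches
    if deterministic:
        rngs: List[Optional[np.random.Generator]] = [None] * P
        mig_rng = None
    else:
        if seed is None:
            seed = config.seed
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(P + 1)
        rngs = [np.random.default_rng(c) for c in children[:P]]
        mig_rng = np.random.default_rng(children[P])

    landscape = _new_landscape(dyn, config, stochastic=not deterministic)
    T = config.horizon_days
    n = dyn.n
    dtype = np.float64 if deterministic else np.int64
    males = np.zeros((T + 1, P, n), dtype=dtype)
    females = np.zeros((T + 1, P, n), dtype=dtype)

    def record(t: int) -> None:
        for p, patch in enumerate(landscape.patches):
            males[t, p] = patch.males
            females[t, p] = patch.female_by_genotype

    record(0)
    for day in range(1, T + 1):
        try:
            for p, patch in enumerate(landscape.patches):
                dyn.step(patch, rngs[p])
            apply_migration(landscape, mig_rng)
            apply_releases(landscape, dyn.system, config.releases, day)
        except Exception as exc:  # annotate failures with simulation context
            raise type(exc)(f"day {day}: {exc}") from exc
        record(day)
    return Trajectory(dyn.system, np.arange(T + 1), males, females)


@dataclass(frozen=True)
class WindowOfProtection:
    """Days a carrier-fraction trajectory spends above a threshold.

    ``longest_days`` (the headline figure) is the longest contiguous
    supra-threshold run; ``total_days`` counts all supra-threshold days.
    """

    longest_days: int
    total_days: int


def window_of_protection(trajectory: Sequence[float], threshold: float = 0.80) -> WindowOfProtection:
    traj = np.asarray(trajectory, dtype=float)
    above = np.zeros(traj.shape, dtype=bool)
    valid = ~np.isnan(traj)
    above[valid] = traj[valid] > threshold
    total = int(above.sum())
    if total == 0:
        return WindowOfProtection(0, 0)
    padded = np.concatenate(([0], above.astype(int), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return WindowOfProtection(int((ends - starts).max()), total)


def max_sustained_level(trajectory: Sequence[float], min_days: int) -> float:
    """Highest level the trajectory stays above for >= ``min_days`` straight.

    Computed as the maximum over all ``min_days``-long windows of the
    window minimum; NaN entries count as 0.
    """
    traj = np.nan_to_num(np.asarray(trajectory, dtype=float), nan=0.0)
    if len(traj) < min_days:
        return float("nan")
    windows = np.lib.stride_tricks.sliding_window_view(traj, min_days)
    return float(windows.min(axis=1).max())


@dataclass
class EnsembleSummary:
    """Per-day metrics across stochastic realizations.

    Arrays are indexed (realization, day, patch); allele frequencies are
    additionally indexed by allele (over ``alleles``).  Carrier/allele
    metrics follow the panel definitions: the carrier fraction is over
    adult females, allele frequencies over all adults.
    """

    config: SimConfig
    alleles: tuple
    days: np.ndarray
    female_total: np.ndarray
    female_carrier: np.ndarray
    adult_total: np.ndarray
    allele_freq: np.ndarray  # (R, T+1, P, A)

    @property
    def n_realizations(self) -> int:
        return self.female_total.shape[0]

    def carrier_fractions(self, patch: int) -> np.ndarray:
        """(realization, day) carrier fractions among females; NaN if none."""
        total = self.female_total[:, :, patch].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.female_carrier[:, :, patch] / total, np.nan)

    def mean_carrier_fraction(self, patch: int) -> np.ndarray:
        return np.nanmean(self.carrier_fractions(patch), axis=0)

    def mean_allele_frequency(self, allele: str, patch: int) -> np.ndarray:
        try:
            a = self.alleles.index(allele)
        except ValueError:
            raise ConfigurationError(f"unknown allele {allele!r}")
        return np.nanmean(self.allele_freq[:, :, patch, a], axis=0)

    def mean_female_total(self, patch: int) -> np.ndarray:
        return self.female_total[:, :, patch].mean(axis=0)

    def quantile_carrier_fraction(self, patch: int, q) -> np.ndarray:
        return np.nanquantile(self.carrier_fractions(patch), q, axis=0)

    def window_of_protection(
        self, patch: int, threshold: float = 0.80, per_realization: bool = False
    ):
        """Window of protection on the ensemble-mean carrier trajectory.

        With ``per_realization=True``, returns one result per realization
        instead.
        """
        if per_realization:
            fractions = self.carrier_fractions(patch)
            return [window_of_protection(fractions[r], threshold) for r in range(len(fractions))]
        return window_of_protection(self.mean_carrier_fraction(patch), threshold)

    def max_sustained_level(self, patch: int, min_days: int) -> float:
        return max_sustained_level(self.mean_carrier_fraction(patch), min_days)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in range(self.config.n_patches):
            df = pd.DataFrame(
                {
                    "day": self.days,
                    "patch": p,
                    "mean_adult_females": self.mean_female_total(p),
                    "mean_carrier_fraction": self.mean_carrier_fraction(p),
                }
            )
            for a in self.alleles:
                df[f"mean_freq_{a}"] = self.mean_allele_frequency(a, p)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def run_ensemble(
    config: SimConfig, *, dynamics: Optional[Dynamics] = None
) -> EnsembleSummary:
    """Run ``config.n_realizations`` seeded realizations and summarise them."""
    dyn = dynamics if dynamics is not None else build_dynamics(config)
    system = dyn.system
    R = config.n_realizations
    seeds = np.random.SeedSequence(config.seed).spawn(R)
    T, P, A = config.horizon_days, config.n_patches, len(system.alleles)

    female_total = np.zeros((R, T + 1, P))
    female_carrier = np.zeros((R, T + 1, P))
    adult_total = np.zeros((R, T + 1, P))
    allele_freq = np.full((R, T + 1, P, A), np.nan)

    counts = system.allele_count  # (G, A)
    carrier_mask = system.carrier
    for r in range(R):
        traj = run_realization(config, seeds[r], dynamics=dyn)
        for p in range(P):
            fem = traj.females[:, p]
            adults = fem + traj.males[:, p]
            female_total[r, :, p] = fem.sum(axis=1)
            female_carrier[r, :, p] = fem[:, carrier_mask].sum(axis=1)
            adult_total[r, :, p] = adults.sum(axis=1)
            den = 2.0 * adults.sum(axis=1)
            num = adults @ counts
            with np.errstate(invalid="ignore", divide="ignore"):
                allele_freq[r, :, p] = np.where(den[:, None] > 0, num / den[:, None], np.nan)
        logger.info("realization %d/%d complete", r + 1, R)
    return EnsembleSummary(
        config=config,
        alleles=tuple(system.alleles),
        days=np.arange(T + 1),
        female_total=female_total,
        female_carrier=female_carrier,
        adult_total=adult_total,
        allele_freq=allele_freq,
    )


def heatmap_experiment(
    config: SimConfig,
    fitness_cost_grid: Sequence[float],
    release_count_grid: Sequence[int],
    *,
    release_size: Optional[int] = None,
    start_day: int = 50,
    release_patch: int = 0,
    threshold: float = 0.80,
    n_realizations: Optional[int] = None,
) -> pd.DataFrame:
    """Window of protection (longest run, days) over a parameter grid.

    Rows are numbers of weekly releases, columns the lifespan cost in
    cargo homozygotes.  Each cell is one ensemble at the (possibly
    reduced) ``n_realizations``, sharing the base config's seed so cells
    differ only through their parameters (common random numbers).
    """
    if len(fitness_cost_grid) == 0 or len(release_count_grid) == 0:
        raise ConfigurationError("heatmap grids must be non-empty")
    size = int(release_size if release_size is not None else config.life.n_eq)
    R = n_realizations if n_realizations is not None else config.n_realizations
    genotype = homozygous_release_genotype(config.system)
    out = np.zeros((len(release_count_grid), len(fitness_cost_grid)))
    for i, n_rel in enumerate(release_count_grid):
        for j, cost in enumerate(fitness_cost_grid):
            schedule = (
                ReleaseSchedule.weekly(
                    int(n_rel), size, genotype, start_day=start_day, patch=release_patch
                )
                if n_rel > 0
                else ReleaseSchedule()
            )
            cfg = replace(
                config,
                drive=replace(config.drive, lifespan_cost_hom=float(cost)),
                releases=schedule,
                n_realizations=R,
            )
            summary = run_ensemble(cfg)
            out[i, j] = summary.window_of_protection(release_patch, threshold).longest_days
            logger.info(
                "heatmap cell releases=%s cost=%s -> %d days", n_rel, cost, out[i, j]
            )
    return pd.DataFrame(
        out,
        index=pd.Index(release_count_grid, name="weekly_releases"),
        columns=pd.Index(fitness_cost_grid, name="lifespan_cost_hom"),
    )
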