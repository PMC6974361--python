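"""Two-patch (or n-patch) metapopulation layer: migration and releases.

Adults migrate between patches by per-mosquito daily movement draws; mated
females carry their stored mate genotype with them.  Juveniles do not move.
The field-standard "1% per mosquito per generation" exchange rate is
converted to a daily probability by compounding over the mean generation
time (juvenile development plus mean adult lifespan, rounded to whole
days).

Releases add homozygous adults (typically males) to a patch's pool on
scheduled days; they compete for matings from the next mating draw onward
and are assumed mating-competitive at parity with wild males.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics import ConfigurationError, GeneticSystem
from .life_history import LifeHistoryParams, PatchState

__all__ = [
    "Landscape",
    "ReleaseEvent",
    "ReleaseSchedule",
    "generation_time_days",
    "per_generation_to_daily_migration",
    "migration_matrix",
    "apply_migration",
    "apply_releases",
]


def generation_time_days(params: LifeHistoryParams) -> int:
    """Mean generation time in whole days: tE + tL + tP + 1/muAd, rounded."""
    return int(round(params.generation_days))


def per_generation_to_daily_migration(
    rate_per_generation: float, generation_time: float
) -> float:
    """Daily movement probability p with 1 - (1-p)^G = per-generation rate."""
    if not 0.0 <= rate_per_generation < 1.0:
        raise ConfigurationError(
            f"rate_per_generation={rate_per_generation!r} must lie in [0, 1)"
        )
    if generation_time <= 0:
        raise ConfigurationError("generation_time must be positive")
    return 1.0 - (1.0 - rate_per_generation) ** (1.0 / generation_time)


def migration_matrix(n_patches: int, daily_prob: float) -> np.ndarray:
    """Symmetric daily movement matrix; off-diagonal mass split evenly."""
    if n_patches < 1:
        raise ConfigurationError("n_patches must be >= 1")
    if n_patches == 1:
        return np.ones((1, 1))
    M = np.full((n_patches, n_patches), daily_prob / (n_patches - 1))
    np.fill_diagonal(M, 1.0 - daily_prob)
    return M


@dataclass(frozen=True)
class ReleaseEvent:
    day: int
    patch: int
    sex: str
    genotype: str
    count: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ConfigurationError("release day must be non-negative")
        if self.count <= 0 or int(self.count) != self.count:
            raise ConfigurationError("release count must be a positive integer")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"release sex must be male/female, got {self.sex!r}")


@dataclass(frozen=True)
class ReleaseSchedule:
    events: Tuple[ReleaseEvent, ...] = ()

    @classmethod
    def weekly(
        cls,
        n_releases: int,
        size: int,
        genotype: str,
        *,
        start_day: int = 50,
        patch: int = 0,
        sex: str = "male",
        interval: int = 7,
    ) -> "ReleaseSchedule":
        events = tuple(
            ReleaseEvent(start_day + k * interval, patch, sex, genotype, size)
            for k in range(n_releases)
        )
        return cls(events)

    def on(self, day: int) -> List[ReleaseEvent]:
        return [e for e in self.events if e.day == day]

    @property
    def last_day(self) -> Optional[int]:
        return max((e.day for e in self.events), default=None)

    def to_csv(self, path) -> None:
        pd.DataFrame([e.__dict__ for e in self.events]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReleaseSchedule":
        df = pd.read_csv(path)
        events = tuple(
            ReleaseEvent(int(r.day), int(r.patch), str(r.sex), str(r.genotype), int(r.count))
            for r in df.itertuples()
        )
        return cls(events)


@dataclass
class Landscape:
    """Ordered patches plus a daily movement probability matrix.

    ``migration[i, j]`` is the daily probability that an adult in patch i
    is in patch j the next day; rows sum to 1 (diagonal = stay).
    """

    patches: List[PatchState]
    migration: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.migration, dtype=float)
        if M.shape != (len(self.patches), len(self.patches)):
            raise ConfigurationError("migration matrix shape does not match patches")
        if np.any(M < 0) or np.any(M > 1):
            raise ConfigurationError("migration entries must lie in [0, 1]")
        if np.max(np.abs(M.sum(axis=1) - 1.0)) > 1e-9:
            raise ConfigurationError("migration rows must sum to 1")
        self.migration = M

    @property
    def n_patches(self) -> int:
        return len(self.patches)


def _move(stacked: np.ndarray, M: np.ndarray, rng: Optional[np.random.Generator]):
    """Redistribute a (patch, class) count array across patches."""
    P = stacked.shape[0]
    flat = stacked.reshape(P, -1)
    if rng is None:
        return (M.T @ flat).reshape(stacked.shape)
    out = np.zeros_like(flat)
    for i in range(P):
        p = M[i].astype(float).copy()
        p[p.argmax()] += 1.0 - p.sum()
        draws = rng.multinomial(flat[i], p)  # (n_classes, P)
        out += draws.T
    return out.reshape(stacked.shape)


def apply_migration(
    landscape: Landscape, rng: Optional[np.random.Generator] = None
) -> Landscape:
    """Move adults between patches in place; juveniles stay put.

    Mated females migrate as whole (own, mate) classes, carrying their
    stored sperm genotype.  Total counts of every class are conserved.
    """
    P = landscape.n_patches
    M = landscape.migration
    if P == 1 or np.all(M[~np.eye(P, dtype=bool)] == 0.0):
        return landscape
    for attr in ("males", "unmated", "females"):
        stacked = np.stack([getattr(p, attr) for p in landscape.patches])
        moved = _move(stacked, M, rng)
        for i, patch in enumerate(landscape.patches):
            setattr(patch, attr, moved[i])
    return landscape


def apply_releases(
    landscape: Landscape,
    system: GeneticSystem,
    schedule: ReleaseSchedule,
    day: int,
) -> Landscape:
    """Add scheduled individuals to the target patch's adult pools.

    Released males join the male pool; released females join the unmated
    pool and mate at the next daily mating draw.
    """
    for event in schedule.on(day):
        if not 0 <= event.patch < landscape.n_patches:
            raise ConfigurationError(f"release patch {event.patch} out of range")
        idx = system.genotype_index(event.genotype)
        patch = landscape.patches[event.patch]
        if event.sex == "male":
            patch.males[idx] += event.count
        else:
            patch.unmated[idx] += event.count
    return landscape
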