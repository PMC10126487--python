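"""Synthetic study systems: abundance time series with a planted abrupt
compositional shift, and toy cross-feeding communities with controllable
dependency structure.

The time-series generator emulates the qualitative dynamics of a long
co-culture experiment: a diverse initial community, a rapid compositional
shift around a chosen day in which most of the abundance moves to a small
disjoint "quasi-stable" species set, and an optional later recovery phase
in which the displaced species gradually return.  The community generator
builds boolean required/secreted metabolite sets with a tunable fraction
of cross-fed requirements, guaranteed full-community growth, and an exact
number of planted directed dependency cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exchange import CommunityModel, SpeciesModel
from .timeseries import AbundanceSeries

__all__ = [
    "TimeSeriesSpec",
    "ExchangeSpec",
    "simulate_timeseries",
    "simulate_exchange_community",
]

#: geometric rank-abundance decay within the dominant species set
_RANK_DECAY = 0.7
#: total community abundance of the deterministic skeleton (arbitrary units)
_TOTAL = 100.0
#: at full recovery, this fraction of the shifted mass has returned
_RECOVERY_FRACTION = 0.5


@dataclass(frozen=True)
class TimeSeriesSpec:
    """Parameters of the planted-shift abundance simulation.

    Defaults mirror the emulated experiment: 32 species followed daily for
    110 days with a rapid shift around day 18 that leaves a low-diversity
    quasi-stable community, and a slow recovery starting around day 60.
    """

    n_species: int = 32
    n_days: int = 110
    shift_day: int = 18
    shift_magnitude: float = 0.9
    noise_scale: float = 0.3
    quasi_stable_richness: int = 4
    recovery_day: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.shift_magnitude <= 1.0:
            raise ValueError("shift_magnitude must lie in [0, 1]")
        if not 1 <= self.shift_day <= self.n_days:
            raise ValueError("shift_day must lie in [1, n_days]")
        if self.quasi_stable_richness > self.n_species:
            raise ValueError("quasi_stable_richness must be <= n_species")
        if self.shift_magnitude > 0 and not (
            1 <= self.quasi_stable_richness <= self.n_species - 1
        ):
            raise ValueError(
                "with a positive shift_magnitude, quasi_stable_richness must "
                "lie in [1, n_species - 1] so the post-shift set is non-empty "
                "and disjoint from the pre-shift set"
            )
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.recovery_day is not None and not (
            self.shift_day <= self.recovery_day <= self.n_days
        ):
            raise ValueError("recovery_day must lie in [shift_day, n_days]")


def _rank_profile(indices: np.ndarray, n_species: int) -> np.ndarray:
    profile = np.zeros(n_species)
    if indices.size:
        weights = _RANK_DECAY ** np.arange(indices.size)
        profile[indices] = _TOTAL * weights / weights.sum()
    return profile


def simulate_timeseries(spec: TimeSeriesSpec) -> AbundanceSeries:
    """Simulate a species-by-day abundance matrix with a planted shift.

    A deterministic skeleton is built first: before ``shift_day`` the
    community is a geometric rank-abundance profile over the pre-shift
    species set; from ``shift_day`` onward a fraction ``shift_magnitude``
    of the total abundance is transferred to a disjoint set of
    ``quasi_stable_richness`` species.  If ``recovery_day`` is set, the
    transferred fraction ramps back down linearly afterwards, so displaced
    species reappear and richness rises.  Per-day multiplicative
    log-normal noise of scale ``noise_scale`` is then applied; columns are
    left unnormalized.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    q = spec.quasi_stable_richness
    post_idx = np.arange(spec.n_species - q, spec.n_species)
    pre_idx = np.arange(spec.n_species - q) if spec.shift_magnitude > 0 else np.arange(spec.n_species)
    pre_profile = _rank_profile(pre_idx, spec.n_species)
    post_profile = _rank_profile(post_idx, spec.n_species)

    days = np.arange(1, spec.n_days + 1)
    values = np.empty((spec.n_species, spec.n_days))
    for j, day in enumerate(days):
        if day < spec.shift_day:
            col = pre_profile
        else:
            m = spec.shift_magnitude
            if spec.recovery_day is not None and day >= spec.recovery_day:
                span = max(1, spec.n_days - spec.recovery_day)
                ramp = (day - spec.recovery_day) / span
                m *= 1.0 - _RECOVERY_FRACTION * ramp
            col = (1.0 - m) * pre_profile + m * post_profile
        values[:, j] = col
    values = values * rng.lognormal(mean=0.0, sigma=spec.noise_scale, size=values.shape)
    width = len(str(spec.n_species))
    species = [f"sp{i + 1:0{width}d}" for i in range(spec.n_species)]
    return AbundanceSeries(species, days, values)


@dataclass(frozen=True)
class ExchangeSpec:
    """Parameters of the toy cross-feeding community generator."""

    n_species: int = 12
    n_metabolites: int = 40
    medium_size: int = 6
    crossfeed_density: float = 0.6
    loop_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.medium_size < 0 or self.medium_size > self.n_metabolites:
            raise ValueError("medium_size must lie in [0, n_metabolites]")
        if not 0.0 <= self.crossfeed_density <= 1.0:
            raise ValueError("crossfeed_density must lie in [0, 1]")
        if self.loop_count < 0:
            raise ValueError("loop_count must be >= 0")
        if self.loop_count > 0 and self.n_species < 2 * self.loop_count + 1:
            raise ValueError(
                "loop_count too large: each planted loop uses 2 dedicated "
                "species and at least one non-loop helper must remain "
                "(n_species >= 2*loop_count + 1)"
            )
        needed = self.medium_size + self.n_species + 2 * self.loop_count
        if self.n_metabolites < needed:
            raise ValueError(
                f"n_metabolites too small: generator layout needs medium_size "
                f"+ n_species byproducts + 2*loop_count loop metabolites = {needed}"
            )


def simulate_exchange_community(spec: ExchangeSpec) -> CommunityModel:
    """Build a toy community with guaranteed growth and planted loops.

    Layout: the metabolite universe holds ``medium_size`` freely available
    medium metabolites, one dedicated secreted byproduct per species, and
    two dedicated metabolites per planted loop.  Non-loop species form an
    index-ordered backbone: each requires one medium metabolite plus one
    extra requirement that, with probability ``crossfeed_density``, is the
    byproduct of a lower-index species (otherwise a medium metabolite).
    Each planted loop is a pair of species that require each other's loop
    metabolite; one or two non-loop "helper" species also secrete the loop
    metabolites so the pair can bootstrap.  By construction every species
    grows in the full community and the designed dependency digraph
    contains exactly ``loop_count`` directed cycles.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, ms, nl = spec.n_species, spec.medium_size, spec.loop_count
    mwidth = len(str(spec.n_metabolites))
    medium = [f"e{i + 1:0{mwidth}d}" for i in range(ms)]
    byproducts = [f"b{i + 1:0{mwidth}d}" for i in range(n)]
    loop_mets = [f"x{i + 1:0{mwidth}d}" for i in range(2 * nl)]
    pad = spec.n_metabolites - ms - n - 2 * nl
    padding = [f"u{i + 1:0{mwidth}d}" for i in range(pad)]
    metabolites = medium + byproducts + loop_mets + padding

    # same id scheme as simulate_timeseries so the two generators align
    swidth = len(str(n))
    species_ids = [f"sp{i + 1:0{swidth}d}" for i in range(n)]
    n_nonloop = n - 2 * nl  # loop members occupy the highest indices
    required = [set() for _ in range(n)]
    secreted = [set() for _ in range(n)]
    for i in range(n):
        secreted[i].add(byproducts[i])
        if ms > 0:
            required[i].add(medium[i % ms])
    # backbone cross-feeding over non-loop species; providers have lower index
    for i in range(1, n_nonloop):
        if rng.random() < spec.crossfeed_density:
            provider = int(rng.integers(0, i))
            required[i].add(byproducts[provider])
        elif ms > 0:
            required[i].add(medium[int(rng.integers(0, ms))])
    # planted loops with helper producers so the pair can bootstrap
    for j in range(nl):
        u, v = n_nonloop + 2 * j, n_nonloop + 2 * j + 1
        x0, x1 = loop_mets[2 * j], loop_mets[2 * j + 1]
        required[u].add(x0)
        secreted[u].add(x1)
        required[v].add(x1)
        secreted[v].add(x0)
        helpers = rng.choice(n_nonloop, size=min(2, n_nonloop), replace=False)
        secreted[int(helpers[0])].add(x0)
        if helpers.size > 1:
            secreted[int(helpers[1])].add(x1)

    model = CommunityModel(
        metabolites,
        frozenset(medium),
        [
            SpeciesModel.make(species_ids[i], required[i], secreted[i])
            for i in range(n)
        ],
    )
    return model
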