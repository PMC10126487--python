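"""Set-based cross-feeding model: growth closure, species coupling scores,
metabolite-transfer attribution, and community-scale interaction indices.

This is a deliberately simplified, fully enumerable analog of
constraint-based community metabolic modeling.  Each species is a pair of
metabolite sets: ``required`` (all needed for growth) and ``secreted``
(emitted when, and only when, growing).  Community growth is the least
fixed point of the rule "a species grows once all of its required
metabolites are available", starting from the medium.  There is no
stoichiometry and no flux; every quantity is exactly computable by
subset enumeration, which keeps all downstream statistics brute-force
verifiable.

Quantities
----------
species coupling score (SCS)
    Directional dependency of a recipient on a donor: over sub-communities
    containing both in which the recipient grows, the fraction in which
    removing the donor abolishes the recipient's growth.  0 = complete
    independence, 1 = essentiality.
metabolic interaction potential (MIP)
    Number of external metabolites the community can dispense with thanks
    to exchange: minimal medium size without interactions (= the union of
    all requirements) minus the minimal medium size with interactions.
metabolic resource overlap (MRO)
    Mean pairwise proportion of shared nutritional requirements; a proxy
    for potential competition.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesModel",
    "CommunityModel",
    "CouplingResult",
    "CommunityScores",
    "ReplicateResult",
    "MipResult",
    "growth_closure",
    "species_coupling_score",
    "coupling_matrix",
    "transfer_attribution",
    "metabolite_frequencies",
    "standardize_frequencies",
    "metabolic_interaction_potential",
    "metabolic_resource_overlap",
    "replicate_runs",
]

#: above this community size, exhaustive subset enumeration (2^(n-2) per
#: ordered pair) is replaced by Monte-Carlo sampling in "auto" mode
EXHAUSTIVE_LIMIT = 12
#: above this many candidate metabolites, the minimal-medium search for
#: MIP falls back to greedy elimination (flagged as a lower bound)
MIP_EXACT_LIMIT = 20


@dataclass(frozen=True)
class SpeciesModel:
    """One species: identifier plus required/secreted metabolite sets."""

    id: str
    required: frozenset[str]
    secreted: frozenset[str]

    @classmethod
    def make(cls, id: str, required: Iterable[str], secreted: Iterable[str]):
        return cls(id, frozenset(required), frozenset(secreted))


@dataclass
class CommunityModel:
    """A community: metabolite universe, freely available medium, species."""

    metabolite_ids: list[str]
    medium: frozenset[str]
    species: list[SpeciesModel]

    def __post_init__(self) -> None:
        universe = set(self.metabolite_ids)
        self.medium = frozenset(self.medium)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("species ids must be unique")
        if not self.medium <= universe:
            raise ValueError("medium contains metabolites outside the universe")
        for s in self.species:
            if not (s.required | s.secreted) <= universe:
                raise ValueError(f"species {s.id} uses metabolites outside the universe")

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get(self, species_id: str) -> SpeciesModel:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(f"unknown species id: {species_id}")

    def subset(self, ids: Iterable[str]) -> "CommunityModel":
        keep = set(ids)
        unknown = keep - set(self.species_ids)
        if unknown:
            raise KeyError(f"unknown species ids: {sorted(unknown)}")
        return CommunityModel(
            list(self.metabolite_ids),
            self.medium,
            [s for s in self.species if s.id in keep],
        )

    def dependency_graph(self):
        """Designed dependency digraph: edge donor -> recipient for every
        metabolite the donor secretes that the recipient requires and the
        medium does not supply."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.species_ids)
        for donor in self.species:
            for recipient in self.species:
                if donor.id == recipient.id:
                    continue
                if (donor.secreted & recipient.required) - self.medium:
                    g.add_edge(donor.id, recipient.id)
        return g

    # --- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "metabolites": list(self.metabolite_ids),
            "medium": sorted(self.medium),
            "species": [
                {
                    "id": s.id,
                    "required": sorted(s.required),
                    "secreted": sorted(s.secreted),
                }
                for s in self.species
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityModel":
        return cls(
            list(d["metabolites"]),
            frozenset(d["medium"]),
            [SpeciesModel.make(s["id"], s["required"], s["secreted"]) for s in d["species"]],
        )

    @classmethod
    def from_json(cls, path) -> "CommunityModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# growth closure
# ---------------------------------------------------------------------------

def growth_closure(
    model: CommunityModel,
    members: Optional[Iterable[str]] = None,
    medium: Optional[Iterable[str]] = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Least fixed point of community growth under boolean exchange.

    Start with the medium available and nobody growing; repeatedly add any
    member whose full requirement set is available and pool its secretions;
    stop at stability.  The iteration is monotone, so the result is the
    unique least fixed point and independent of evaluation order.

    Returns ``(growing species ids, available metabolites)``.
    """
    ids = model.species_ids
    member_set = set(ids) if members is None else set(members)
    unknown = member_set - set(ids)
    if unknown:
        raise KeyError(f"unknown species ids: {sorted(unknown)}")
    available = set(model.medium if medium is None else medium)
    pending = [s for s in model.species if s.id in member_set]
    growing: set[str] = set()
    changed = True
    while changed and pending:
        changed = False
        still = []
        for s in pending:
            if s.required <= available:
                growing.add(s.id)
                available |= s.secreted
                changed = True
            else:
                still.append(s)
        pending = still
    return frozenset(growing), frozenset(available)


def _grows(
    model: CommunityModel,
    recipient: str,
    members: frozenset[str],
    cache: Optional[dict] = None,
) -> bool:
    if cache is not None and members in cache:
        return recipient in cache[members]
    growing, _ = growth_closure(model, members)
    if cache is not None:
        cache[members] = growing
    return recipient in growing


# ---------------------------------------------------------------------------
# species coupling score
# ---------------------------------------------------------------------------

def _score_pair(
    model: CommunityModel,
    recipient: str,
    donor: str,
    subsets: Iterable[frozenset[str]],
    cache: dict,
    context: str,
) -> float:
    conditioned = dependent = 0
    for members in subsets:
        if not _grows(model, recipient, members, cache):
            continue
        conditioned += 1
        if not _grows(model, recipient, members - {donor}, cache):
            dependent += 1
    if conditioned == 0:
        warnings.warn(
            f"empty conditioning set for recipient={recipient}, donor={donor} "
            f"({context}); coupling score reported as 0",
            stacklevel=3,
        )
        return 0.0
    return dependent / conditioned


def _exhaustive_subsets(others: Sequence[str], recipient: str, donor: str):
    base = {recipient, donor}
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            yield frozenset(base.union(combo))


def _sampled_subsets(
    others: Sequence[str], recipient: str, donor: str, n_samples: int, rng
):
    base = frozenset({recipient, donor})
    k = len(others)
    arr = np.array(others, dtype=object)
    for _ in range(n_samples):
        mask = rng.random(k) < 0.5
        yield base | frozenset(arr[mask].tolist())


def species_coupling_score(
    model: CommunityModel,
    recipient: str,
    donor: str,
    mode: Literal["auto", "exhaustive", "montecarlo"] = "auto",
    n_samples: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> float:
    """Dependency of ``recipient`` on ``donor`` in [0, 1].

    Over sub-communities S with both species present in which the recipient
    grows, the score is the fraction of those S in which the recipient no
    longer grows in S minus the donor.  Exhaustive enumeration covers all
    2^(n-2) sub-communities; Monte-Carlo mode samples sub-communities
    uniformly (each other species included with probability 1/2).
    """
    if recipient == donor:
        raise ValueError("recipient and donor must differ")
    model.get(recipient), model.get(donor)  # id checks
    others = [s for s in model.species_ids if s not in (recipient, donor)]
    if mode == "auto":
        mode = "exhaustive" if len(model.species) <= exhaustive_limit else "montecarlo"
    cache: dict = {}
    if mode == "exhaustive":
        subsets = _exhaustive_subsets(others, recipient, donor)
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        subsets = _sampled_subsets(others, recipient, donor, n_samples, rng)
    else:
        raise ValueError(f"unknown mode: {mode}")
    return _score_pair(model, recipient, donor, subsets, cache, f"mode={mode}")


@dataclass
class CouplingResult:
    """Directed coupling-score matrix plus transfer attribution for one run."""

    scs: pd.DataFrame  # rows = donor, columns = recipient
    transfers: pd.DataFrame  # columns donor, recipient, metabolite
    run_seed: int
    mode: str
    n_samples: Optional[int] = None

    def to_long(self) -> pd.DataFrame:
        long = self.scs.stack().rename_axis(["donor", "recipient"]).rename("scs")
        long = long.reset_index()
        return long[long.donor != long.recipient]


def coupling_matrix(
    model: CommunityModel,
    mode: Literal["auto", "exhaustive", "montecarlo"] = "auto",
    n_samples: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> CouplingResult:
    """All ordered donor -> recipient coupling scores for one seeded run.

    Growth evaluations are memoized across pairs (the same sub-community
    recurs many times), which makes the exhaustive matrix cost close to one
    closure per distinct subset rather than per (pair, subset).
    """
    ids = model.species_ids
    if mode == "auto":
        mode = "exhaustive" if len(ids) <= exhaustive_limit else "montecarlo"
    cache: dict = {}
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    mat.index.name = "donor"
    mat.columns.name = "recipient"
    for recipient in ids:
        for donor in ids:
            if donor == recipient:
                continue
            others = [s for s in ids if s not in (recipient, donor)]
            if mode == "exhaustive":
                subsets = _exhaustive_subsets(others, recipient, donor)
            else:
                subsets = _sampled_subsets(others, recipient, donor, n_samples, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mat.loc[donor, recipient] = _score_pair(
                    model, recipient, donor, subsets, cache, f"mode={mode}"
                )
    transfers = transfer_attribution(model)
    return CouplingResult(
        scs=mat,
        transfers=transfers,
        run_seed=seed,
        mode=mode,
        n_samples=n_samples if mode == "montecarlo" else None,
    )


# ---------------------------------------------------------------------------
# transfer attribution
# ---------------------------------------------------------------------------

def transfer_attribution(
    model: CommunityModel, members: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Who can feed whom with what, among species growing in the community.

    For each ordered pair of growing species (donor, recipient) and each
    metabolite the donor secretes, the recipient requires, and the medium
    does not supply, emit one record.  Returns a DataFrame with columns
    (donor, recipient, metabolite).
    """
    growing, _ = growth_closure(model, members)
    rows = []
    grow_models = [s for s in model.species if s.id in growing]
    for donor in grow_models:
        for recipient in grow_models:
            if donor.id == recipient.id:
                continue
            for met in sorted((donor.secreted & recipient.required) - model.medium):
                rows.append((donor.id, recipient.id, met))
    return pd.DataFrame(rows, columns=["donor", "recipient", "metabolite"])


def metabolite_frequencies(transfers: pd.DataFrame) -> pd.Series:
    """Number of distinct (donor, recipient) pairs transferring each metabolite."""
    if transfers.empty:
        return pd.Series(dtype=int, name="count")
    freq = (
        transfers.drop_duplicates()
        .groupby("metabolite")
        .size()
        .sort_values(ascending=False)
    )
    return freq.rename("count")


def standardize_frequencies(freq: pd.Series) -> pd.Series:
    """Scale transfer frequencies so that they total 1 (per time point)."""
    total = freq.sum()
    if total == 0:
        return freq.astype(float).rename("standardized")
    return (freq / total).rename("standardized")


# ---------------------------------------------------------------------------
# community-scale indices
# ---------------------------------------------------------------------------

class MipResult(NamedTuple):
    mip: int
    minimal_medium: frozenset[str]
    exact: bool


def _all_grow(model: CommunityModel, medium: frozenset[str]) -> bool:
    growing, _ = growth_closure(model, medium=medium)
    return len(growing) == len(model.species)


def metabolic_interaction_potential(
    model: CommunityModel, exact_limit: int = MIP_EXACT_LIMIT
) -> MipResult:
    """Metabolic interaction potential of a community.

    MIP = |union of all requirements| (the minimal medium when nobody
    exchanges) minus the size of a minimal medium under exchange.  Any
    required metabolite that no species secretes must be in every feasible
    medium; the search therefore only branches over "producible"
    candidates.  When those exceed ``exact_limit`` a greedy elimination is
    used instead and the result is flagged inexact (a lower bound on MIP).
    """
    union = frozenset().union(*(s.required for s in model.species)) if model.species else frozenset()
    if not union:
        return MipResult(0, frozenset(), True)
    secreted = frozenset().union(*(s.secreted for s in model.species))
    forced = union - secreted
    candidates = sorted(union & secreted)
    if not _all_grow(model, union):
        raise ValueError("infeasible community: not all species grow even on the full requirement union")
    if len(candidates) <= exact_limit:
        for k in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, k):
                medium = forced | frozenset(combo)
                if _all_grow(model, medium):
                    return MipResult(len(union) - len(medium), medium, True)
        raise AssertionError("unreachable: full union is feasible")
    # greedy elimination: minimal-by-inclusion medium, so MIP is a lower bound
    medium = set(union)
    for met in candidates:
        trial = frozenset(medium - {met})
        if _all_grow(model, trial):
            medium.discard(met)
    return MipResult(len(union) - len(medium), frozenset(medium), False)


def metabolic_resource_overlap(
    model: CommunityModel,
    denominator: Literal["min", "union", "mean"] = "min",
) -> float:
    """Mean pairwise proportion of shared nutritional requirements.

    For each unordered species pair the overlap is |Req_a & Req_b| divided
    by the chosen denominator (min of the two set sizes by default); pairs
    whose denominator is zero are skipped.
    """
    if len(model.species) < 2:
        raise ValueError("MRO needs at least two species")
    vals = []
    for a, b in itertools.combinations(model.species, 2):
        inter = len(a.required & b.required)
        if denominator == "min":
            den = min(len(a.required), len(b.required))
        elif denominator == "union":
            den = len(a.required | b.required)
        elif denominator == "mean":
            den = (len(a.required) + len(b.required)) / 2
        else:
            raise ValueError(f"unknown denominator variant: {denominator}")
        if den == 0:
            continue
        vals.append(inter / den)
    if not vals:
        raise ValueError("no scorable pairs (all requirement sets empty)")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# replicate runs
# ---------------------------------------------------------------------------

@dataclass
class CommunityScores:
    """MIP / MRO with replicate-run statistics and metadata.

    The overlap field is called ``mro_mean`` (not ``mro``) because ``mro``
    shadows ``type.mro`` and confuses dataclass default detection.
    """

    mip: int
    mro_mean: float
    mip_sd: float
    mro_sd: float
    n_runs: int
    mip_exact: bool
    mro_denominator: str

    def to_dict(self) -> dict:
        return {
            "mip": self.mip,
            "mro": self.mro_mean,
            "mip_sd": self.mip_sd,
            "mro_sd": self.mro_sd,
            "n_runs": self.n_runs,
            "mip_exact": self.mip_exact,
            "mro_denominator": self.mro_denominator,
        }


@dataclass
class ReplicateResult:
    runs: list[CouplingResult]
    scs_mean: pd.DataFrame
    scs_sd: pd.DataFrame
    scores: CommunityScores

    def to_long(self) -> pd.DataFrame:
        mean = self.scs_mean.stack().rename("scs_mean")
        sd = self.scs_sd.stack().rename("scs_sd")
        long = pd.concat([mean, sd], axis=1).rename_axis(["donor", "recipient"]).reset_index()
        return long[long.donor != long.recipient]


def _sd(stack: np.ndarray) -> np.ndarray:
    # sample SD across runs; a single run has no spread
    if stack.shape[0] < 2:
        return np.zeros(stack.shape[1:])
    return stack.std(axis=0, ddof=1)


def replicate_runs(
    model: CommunityModel,
    n_runs: int = 10,
    base_seed: int = 0,
    mode: Literal["auto", "exhaustive", "montecarlo"] = "auto",
    n_samples: int = 1000,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
    mro_denominator: Literal["min", "union", "mean"] = "min",
    mip_exact_limit: int = MIP_EXACT_LIMIT,
) -> ReplicateResult:
    """Seeded replicate coupling runs with per-edge mean/SD and community scores.

    Runs differ only in their seed (relevant in Monte-Carlo mode).  In
    exhaustive mode the matrix is seed-independent, so it is computed once
    and replicated across the run records; the SD is exactly zero.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if mode == "auto":
        mode = "exhaustive" if len(model.species) <= exhaustive_limit else "montecarlo"
    seeds = [int(base_seed) + i for i in range(n_runs)]
    runs: list[CouplingResult] = []
    if mode == "exhaustive":
        first = coupling_matrix(model, mode=mode, seed=seeds[0], exhaustive_limit=exhaustive_limit)
        for s in seeds:
            runs.append(
                CouplingResult(first.scs.copy(), first.transfers.copy(), run_seed=s, mode=mode)
            )
    else:
        for s in seeds:
            runs.append(
                coupling_matrix(
                    model, mode=mode, n_samples=n_samples, seed=s,
                    exhaustive_limit=exhaustive_limit,
                )
            )
    stack = np.stack([r.scs.to_numpy() for r in runs])
    template = runs[0].scs
    scs_mean = pd.DataFrame(stack.mean(axis=0), index=template.index, columns=template.columns)
    scs_sd = pd.DataFrame(_sd(stack), index=template.index, columns=template.columns)
    mip = metabolic_interaction_potential(model, exact_limit=mip_exact_limit)
    mro = metabolic_resource_overlap(model, denominator=mro_denominator)
    scores = CommunityScores(
        mip=mip.mip, mro_mean=mro, mip_sd=0.0, mro_sd=0.0, n_runs=n_runs,
        mip_exact=mip.exact, mro_denominator=mro_denominator,
    )
    return ReplicateResult(runs=runs, scs_mean=scs_mean, scs_sd=scs_sd, scores=scores)
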