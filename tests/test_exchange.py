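"""Set-based cross-feeding model: closure, coupling scores, transfers,
MIP and MRO, replicate runs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crossfeednet import (
    CommunityModel,
    SpeciesModel,
    coupling_matrix,
    growth_closure,
    metabolic_interaction_potential,
    metabolic_resource_overlap,
    metabolite_frequencies,
    replicate_runs,
    species_coupling_score,
    standardize_frequencies,
    transfer_attribution,
)


def model_of(medium, **species):
    """species: id=(required, secreted)"""
    mets = sorted(
        set(medium) | {m for req, sec in species.values() for m in (*req, *sec)}
    )
    return CommunityModel(
        mets,
        frozenset(medium),
        [SpeciesModel.make(sid, req, sec) for sid, (req, sec) in species.items()],
    )


class TestGrowthClosure:
    def test_unconstrained_species_always_grows(self):
        m = model_of([], a=((), ()))
        growing, _ = growth_closure(m)
        assert growing == {"a"}

    def test_two_step_chain(self, chain_model):
        growing, available = growth_closure(chain_model)
        assert growing == {"a", "b"}
        assert available == {"m0", "m1"}

    def test_unseeded_cycle_never_starts(self, deadlock_model):
        growing, available = growth_closure(deadlock_model)
        assert growing == frozenset()
        assert available == frozenset()

    def test_unknown_member_rejected(self, chain_model):
        with pytest.raises(KeyError):
            growth_closure(chain_model, members={"nope"})

    def test_monotone_in_members_and_medium(self, redundant_donor_model):
        m = redundant_donor_model
        ids = m.species_ids
        for size in range(len(ids) + 1):
            for members in itertools.combinations(ids, size):
                small, _ = growth_closure(m, members)
                big, _ = growth_closure(m, ids)
                assert small <= big
        less, _ = growth_closure(m, medium=set())
        more, _ = growth_closure(m, medium={"e", "x"})
        assert less <= more


def brute_force_scs(model, recipient, donor):
    """Independent enumeration over all sub-communities with both present."""
    others = [s for s in model.species_ids if s not in (recipient, donor)]
    cond = dep = 0
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            members = frozenset({recipient, donor, *combo})
            grow_with, _ = growth_closure(model, members)
            if recipient not in grow_with:
                continue
            cond += 1
            grow_without, _ = growth_closure(model, members - {donor})
            if recipient not in grow_without:
                dep += 1
    return dep / cond if cond else 0.0


class TestSpeciesCouplingScore:
    def test_medium_independent_recipient_scores_zero(self):
        m = model_of(["e"], r=(("e",), ()), d=(("e",), ("z",)), b=(("e",), ()))
        for donor in ("d", "b"):
            assert species_coupling_score(m, "r", donor, mode="exhaustive") == 0.0

    def test_unique_essential_donor_scores_one(self):
        m = model_of(
            ["e"],
            r=(("m",), ()),
            d=(("e",), ("m",)),
            b1=(("e",), ()),
            b2=(("e",), ()),
        )
        assert species_coupling_score(m, "r", "d", mode="exhaustive") == 1.0

    def test_redundant_donors_match_brute_force(self, redundant_donor_model):
        m = redundant_donor_model
        for donor in ("d1", "d2"):
            got = species_coupling_score(m, "r", donor, mode="exhaustive")
            assert got == pytest.approx(brute_force_scs(m, "r", donor))
        # symmetric construction: the two donors are interchangeable
        assert species_coupling_score(m, "r", "d1", mode="exhaustive") == pytest.approx(
            species_coupling_score(m, "r", "d2", mode="exhaustive")
        )

    def test_matrix_agrees_with_pairwise_scores(self, redundant_donor_model):
        mat = coupling_matrix(redundant_donor_model, mode="exhaustive").scs
        for donor in redundant_donor_model.species_ids:
            for recipient in redundant_donor_model.species_ids:
                if donor == recipient:
                    assert mat.loc[donor, recipient] == 0.0
                else:
                    assert mat.loc[donor, recipient] == pytest.approx(
                        brute_force_scs(redundant_donor_model, recipient, donor)
                    )

    def test_empty_conditioning_set_warns_and_returns_zero(self, deadlock_model):
        with pytest.warns(UserWarning, match="empty conditioning set"):
            assert species_coupling_score(deadlock_model, "a", "b", mode="exhaustive") == 0.0

    def test_same_species_rejected(self, chain_model):
        with pytest.raises(ValueError):
            species_coupling_score(chain_model, "a", "a")

    def test_montecarlo_estimates_exhaustive_value(self, redundant_donor_model):
        exact = species_coupling_score(redundant_donor_model, "r", "d1", mode="exhaustive")
        estimates = [
            species_coupling_score(
                redundant_donor_model, "r", "d1", mode="montecarlo",
                n_samples=2000, seed=seed,
            )
            for seed in range(10)
        ]
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - exact) <= 3 * max(se, 1e-6)


class TestTransfers:
    def test_no_crossfeeding_gives_empty_table(self):
        m = model_of(["e"], a=(("e",), ()), b=(("e",), ()))
        assert transfer_attribution(m).empty

    def test_chain_yields_single_record(self, chain_model):
        t = transfer_attribution(chain_model)
        assert len(t) == 1
        assert tuple(t.iloc[0]) == ("a", "b", "m1")

    def test_non_growing_species_do_not_transfer(self, deadlock_model):
        assert transfer_attribution(deadlock_model).empty

    def test_standardized_frequencies_sum_to_one(self):
        m = model_of(
            ["e"],
            a=(("e",), ("m1", "m2")),
            b=(("m1",), ("m3",)),
            c=(("m2", "m3"), ()),
        )
        freq = metabolite_frequencies(transfer_attribution(m))
        std = standardize_frequencies(freq)
        assert std.sum() == pytest.approx(1.0)
        assert set(freq.index) == {"m1", "m2", "m3"}


class TestMip:
    def test_no_secretions_means_zero(self):
        m = model_of(["e1", "e2"], a=(("e1",), ()), b=(("e2",), ()))
        res = metabolic_interaction_potential(m)
        assert res.mip == 0 and res.exact

    def test_chain_saves_one_metabolite(self, chain_model):
        res = metabolic_interaction_potential(chain_model)
        assert res.mip == 1
        assert res.minimal_medium == {"m0"}

    def test_matches_exhaustive_subset_search(self, redundant_donor_model):
        # independent oracle: try every subset of the requirement union
        m = redundant_donor_model
        union = frozenset().union(*(s.required for s in m.species))
        best = None
        for r in range(len(union) + 1):
            for combo in itertools.combinations(sorted(union), r):
                growing, _ = growth_closure(m, medium=frozenset(combo))
                if growing == frozenset(m.species_ids):
                    best = r
                    break
            if best is not None:
                break
        res = metabolic_interaction_potential(m)
        assert res.mip == len(union) - best

    def test_bounded_by_requirement_union(self):
        rng = np.random.default_rng(0)
        from crossfeednet import ExchangeSpec, simulate_exchange_community

        for seed in range(5):
            model = simulate_exchange_community(
                ExchangeSpec(n_species=7, crossfeed_density=1.0, loop_count=1, seed=seed)
            )
            res = metabolic_interaction_potential(model)
            union = frozenset().union(*(s.required for s in model.species))
            assert 1 <= res.mip <= len(union)


class TestMro:
    def test_identical_requirements_give_one(self):
        m = model_of(["e"], a=(("p", "q"), ()), b=(("p", "q"), ()), c=(("p", "q"), ()))
        assert metabolic_resource_overlap(m) == pytest.approx(1.0)

    def test_disjoint_requirements_give_zero(self):
        m = model_of(["e"], a=(("p",), ()), b=(("q",), ()), c=(("r",), ()))
        assert metabolic_resource_overlap(m) == 0.0

    def test_hand_computed_mixture(self):
        m = model_of(["e"], a=(("x", "y"), ()), b=(("y", "z"), ()), c=(("w",), ()))
        # pairs: (a,b)=1/2, (a,c)=0, (b,c)=0
        assert metabolic_resource_overlap(m) == pytest.approx(1 / 6)

    def test_invariant_to_species_order_and_relabeling(self):
        base = model_of(["e"], a=(("x", "y"), ()), b=(("y", "z"), ()), c=(("w",), ()))
        reordered = CommunityModel(
            base.metabolite_ids, base.medium, list(reversed(base.species))
        )
        relabeled = model_of(
            ["e"], a=(("p1", "p2"), ()), b=(("p2", "p3"), ()), c=(("p4",), ())
        )
        assert metabolic_resource_overlap(base) == metabolic_resource_overlap(reordered)
        assert metabolic_resource_overlap(base) == metabolic_resource_overlap(relabeled)

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            metabolic_resource_overlap(model_of(["e"], a=(("e",), ())))


class TestReplicateRuns:
    def test_exhaustive_runs_identical_with_zero_sd(self, redundant_donor_model):
        rep = replicate_runs(redundant_donor_model, n_runs=4, base_seed=9, mode="exhaustive")
        assert len(rep.runs) == 4
        assert len({r.run_seed for r in rep.runs}) == 4
        for r in rep.runs[1:]:
            pd.testing.assert_frame_equal(r.scs, rep.runs[0].scs)
        assert (rep.scs_sd.to_numpy() == 0).all()

    def test_ten_runs_bookkeeping(self, redundant_donor_model):
        rep = replicate_runs(redundant_donor_model, n_runs=10, base_seed=1)
        assert len(rep.runs) == 10
        assert sorted(r.run_seed for r in rep.runs) == list(range(1, 11))
        stack = np.stack([r.scs.to_numpy() for r in rep.runs])
        np.testing.assert_allclose(rep.scs_mean.to_numpy(), stack.mean(axis=0))

    def test_montecarlo_mean_converges_to_exhaustive(self, redundant_donor_model):
        exact = coupling_matrix(redundant_donor_model, mode="exhaustive").scs
        errors = []
        for n_samples in (100, 1000):
            rep = replicate_runs(
                redundant_donor_model, n_runs=5, base_seed=3,
                mode="montecarlo", n_samples=n_samples,
            )
            errors.append(np.abs(rep.scs_mean.to_numpy() - exact.to_numpy()).max())
        assert errors[-1] <= errors[0] + 0.02
        assert errors[-1] < 0.05

    def test_json_roundtrip_of_model(self, tmp_path, redundant_donor_model):
        path = tmp_path / "model.json"
        redundant_donor_model.to_json(path)
        back = CommunityModel.from_json(path)
        assert back.to_dict() == redundant_donor_model.to_dict()
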