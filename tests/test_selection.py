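"""CRS selection: stages, postconditions, baselines, sklearn estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare
from sklearn.base import clone

from snpanel.errors import IndistinguishableVarietiesError, ValidationError
from snpanel.selection import (
    CRSSelector,
    HighPICSelector,
    RandomSelector,
    SelectionConfig,
    brute_force_min_set,
    distinguishes_all,
    edv_polymorphic_candidates,
    haplotype_groups,
    run_crs,
    run_crs_multi,
    select_hps,
    select_rs,
    stage1_screen,
    stage2_prune,
)
from snpanel.identity import EDVPartition
from snpanel.simulate import fig3_like_fixture

from conftest import make_panel, random_panel


def assert_irreducible(panel, marker_ids):
    """Exhaustive single-removal check: the set resolves everything but no
    proper subset obtained by dropping one marker does."""
    assert distinguishes_all(panel, marker_ids)
    for m in marker_ids:
        rest = [x for x in marker_ids if x != m]
        assert not distinguishes_all(panel, rest), f"{m} is redundant"


class TestHaplotypeGroups:
    def test_empty_selection_one_group(self):
        panel = make_panel([[0], [2]])
        assert haplotype_groups(panel, []) == [["v0", "v1"]]

    def test_hand_grouping(self):
        panel = make_panel([[0, 0], [0, 0], [0, 2], [2, 2]])
        groups = haplotype_groups(panel, ["m0", "m1"])
        assert sorted(map(sorted, groups)) == [["v0", "v1"], ["v2"], ["v3"]]

    def test_distinguishes_agrees_with_pairwise_oracle(self, rng):
        for _ in range(20):
            panel = random_panel(rng, 6, 8, distinct=False)
            sel = list(rng.choice(panel.marker_ids, size=4, replace=False))
            idx = [panel.marker_ids.index(m) for m in sel]
            oracle = all(
                not np.array_equal(panel.codes[i, idx], panel.codes[j, idx])
                for i, j in itertools.combinations(range(panel.n_varieties), 2)
            )
            assert distinguishes_all(panel, sel) == oracle


class TestStage1:
    def test_identical_varieties_error_names_pair(self):
        panel = make_panel([[0, 2], [0, 2], [2, 0]])
        with pytest.raises(IndistinguishableVarietiesError) as err:
            stage1_screen(panel, panel.marker_ids)
        assert ["v0", "v1"] in err.value.groups

    def test_postcondition_on_simulated_panel(self, rng):
        panel = random_panel(rng, 50, 200)
        out = stage1_screen(panel, panel.marker_ids, SelectionConfig(seed=5))
        assert distinguishes_all(panel, out)

    def test_missing_codes_rejected(self):
        panel = make_panel([[0, -1], [2, 0]])
        with pytest.raises(ValidationError, match="complete"):
            stage1_screen(panel, panel.marker_ids)


class TestStage2:
    def test_duplicate_column_removed(self):
        # m0 and m2 are identical; exactly one survives
        panel = make_panel([[0, 0, 0], [0, 2, 0], [2, 0, 2], [2, 2, 2]])
        out = stage2_prune(panel, panel.marker_ids, seed=0)
        assert out.size == 2
        assert_irreducible(panel, out.marker_ids)

    def test_irreducible_input_unchanged_any_seed(self):
        panel = make_panel([[0, 0], [0, 2], [2, 0], [2, 2]])
        for seed in range(5):
            out = stage2_prune(panel, panel.marker_ids, seed=seed)
            assert out.marker_ids == panel.marker_ids

    def test_output_always_irreducible(self, rng):
        for trial in range(20):
            panel = random_panel(rng, 10, 20)
            out = stage2_prune(panel, panel.marker_ids, seed=trial)
            assert_irreducible(panel, out.marker_ids)

    def test_nonresolving_input_rejected(self):
        panel = make_panel([[0, 0], [0, 0]])
        with pytest.raises(ValidationError):
            stage2_prune(panel, panel.marker_ids)


class TestRunCRS:
    def test_deterministic_under_seed(self, rng):
        panel = random_panel(rng, 20, 60)
        cfg = SelectionConfig(seed=11)
        assert run_crs(panel, config=cfg).marker_ids == run_crs(panel, config=cfg).marker_ids

    def test_information_floor(self, rng):
        panel = random_panel(rng, 30, 100)
        out = run_crs(panel, config=SelectionConfig(seed=1))
        assert out.size >= np.ceil(np.log(30) / np.log(3))

    def test_not_smaller_than_exhaustive_minimum(self, rng):
        for trial in range(10):
            panel = random_panel(rng, 6, 10)
            minimum = brute_force_min_set(panel)
            out = run_crs(panel, config=SelectionConfig(seed=trial))
            assert out.size >= len(minimum)

    def test_monotonicity_adding_markers_preserves_resolution(self, rng):
        panel = random_panel(rng, 12, 30)
        out = run_crs(panel, config=SelectionConfig(seed=2))
        extra = [m for m in panel.marker_ids if m not in out.marker_ids][:5]
        assert distinguishes_all(panel, out.marker_ids + extra)


class TestRunCRSMulti:
    def test_disjoint_and_each_resolving(self, rng):
        panel = random_panel(rng, 15, 120)
        sets = run_crs_multi(panel, n_runs=3, config=SelectionConfig(seed=4))
        assert len(sets) == 3
        for a, b in itertools.combinations(sets, 2):
            assert not set(a.marker_ids) & set(b.marker_ids)
        for s in sets:
            assert distinguishes_all(panel, s.marker_ids)

    def test_single_run_equals_run_crs(self, rng):
        panel = random_panel(rng, 10, 40)
        cfg = SelectionConfig(seed=9)
        assert run_crs_multi(panel, n_runs=1, config=cfg)[0].marker_ids == run_crs(
            panel, config=cfg
        ).marker_ids

    def test_pool_exhaustion_returns_fewer_sets(self, rng):
        # 4 distinct varieties over only 2 binary markers: exactly one
        # resolving set exists, so the second disjoint run is infeasible
        panel = make_panel([[0, 0], [0, 2], [2, 0], [2, 2]])
        sets = run_crs_multi(panel, n_runs=3, config=SelectionConfig(seed=0))
        assert len(sets) == 1

    def test_first_run_infeasible_raises(self):
        panel = make_panel([[0], [0]])
        with pytest.raises(IndistinguishableVarietiesError):
            run_crs_multi(panel, n_runs=2)


class TestEDVPolymorphicCandidates:
    def test_matches_per_component_scan(self, rng):
        panel = random_panel(rng, 8, 15, distinct=False)
        partition = EDVPartition(
            components=[["v0", "v1", "v2"], ["v3"], ["v4", "v5"], ["v6"], ["v7"]],
            representatives=["v0", "v3", "v4", "v6", "v7"],
            threshold=0.975,
        )
        got = set(edv_polymorphic_candidates(panel, partition))
        expected = set()
        for comp in partition.components:
            if len(comp) < 2:
                continue
            rows = [panel.variety_index(v) for v in comp]
            for j, m in enumerate(panel.marker_ids):
                if len(set(panel.codes[rows, j])) > 1:
                    expected.add(m)
        assert got == expected

    def test_vacuous_without_multimember_component(self):
        panel = make_panel([[0, 2], [2, 0]])
        partition = EDVPartition([["v0"], ["v1"]], ["v0", "v1"], 0.975)
        assert edv_polymorphic_candidates(panel, partition) == panel.marker_ids


class TestBaselines:
    def test_rs_full_pool_and_determinism(self):
        pool = [f"m{i}" for i in range(10)]
        s = select_rs(pool, 10, seed=1)
        assert sorted(s.marker_ids) == sorted(pool)
        assert select_rs(pool, 3, seed=2).marker_ids == select_rs(pool, 3, seed=2).marker_ids
        with pytest.raises(ValidationError):
            select_rs(pool, 11)

    def test_rs_draws_are_uniform(self):
        pool = [f"m{i}" for i in range(10)]
        counts = {m: 0 for m in pool}
        for seed in range(10_000):
            counts[select_rs(pool, 1, seed=seed).marker_ids[0]] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3

    def test_hps_strict_pic_boundary(self):
        stats = pd.DataFrame({"id": ["a", "b", "c"], "pic": [0.4, 0.41, 0.5]})
        s = select_hps(["a", "b", "c"], stats, 2, pic_min=0.4, seed=0)
        assert set(s.marker_ids) == {"b", "c"}  # pic exactly 0.4 excluded
        with pytest.raises(ValidationError, match="2"):
            select_hps(["a", "b", "c"], stats, 3, pic_min=0.4)

    def test_hps_eligibility_matches_recomputed_stats(self, rng):
        from snpanel.stats import pic, stats_table

        panel = random_panel(rng, 12, 40, distinct=False)
        stats = stats_table(panel)
        eligible = {m for j, m in enumerate(panel.marker_ids) if pic(panel.codes[:, j]) > 0.4}
        s = select_hps(panel.marker_ids, stats, min(3, len(eligible)), seed=0)
        assert set(s.marker_ids) <= eligible


class TestBruteForce:
    def test_binary_four_varieties_min_two(self):
        panel = make_panel([[0, 0, 0], [0, 2, 0], [2, 0, 2], [2, 2, 2]])
        assert len(brute_force_min_set(panel)) == 2

    def test_duplicate_varieties_infeasible(self):
        panel = make_panel([[0], [0]])
        with pytest.raises(IndistinguishableVarietiesError):
            brute_force_min_set(panel)

    def test_minimum_verified_by_enumeration(self, rng):
        panel = random_panel(rng, 5, 8)
        minimum = brute_force_min_set(panel)
        for size in range(1, len(minimum)):
            for comb in itertools.combinations(panel.marker_ids, size):
                assert not distinguishes_all(panel, list(comb))


class TestSelectorEstimators:
    def test_crs_selector_transform_and_sets(self, rng):
        panel = random_panel(rng, 12, 60)
        sel = CRSSelector(n_runs=2, random_state=3).fit(panel.codes)
        assert len(sel.sets_) == 2
        assert not set(sel.sets_[0]) & set(sel.sets_[1])
        reduced = sel.transform(panel.codes)
        assert reduced.shape == (12, int(sel.support_.sum()))
        for s in sel.sets_:
            sub = [panel.marker_ids[i] for i in s]
            assert distinguishes_all(panel, sub)

    def test_crs_selector_deterministic(self, rng):
        X = random_panel(rng, 10, 40).codes
        a = CRSSelector(n_runs=1, random_state=7).fit(X)
        b = CRSSelector(n_runs=1, random_state=7).fit(X)
        assert a.sets_ == b.sets_

    def test_clone_contract(self):
        for est in (CRSSelector(), RandomSelector(5, 1), HighPICSelector(5, 0.3, 1)):
            assert clone(est).get_params() == est.get_params()

    def test_random_selector_sizes(self, rng):
        X = random_panel(rng, 6, 20, distinct=False).codes
        sel = RandomSelector(n_markers=7, random_state=0).fit(X)
        assert int(sel.support_.sum()) == 7

    def test_fig3_fixture_reaches_size_three(self):
        panel = fig3_like_fixture()
        sizes = {run_crs(panel, config=SelectionConfig(seed=s)).size for s in range(10)}
        assert 3 in sizes
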