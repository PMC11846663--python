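import numpy as np
import pytest

from guideset.candidates import BindingSite
from guideset.select import (
    STATUS_INFEASIBLE,
    SelectionInstance,
    brute_force_select,
    conflict_pairs,
    select_max_activity,
    select_min_sgrnas,
    verify_set,
)

from .oracles import naive_conflict_pairs


def make_site(owner, start, score, strand="+", chrom="c"):
    return BindingSite(
        chrom=chrom, start=start, strand=strand, spacer_seq="A" * 20,
        pam_seq="TGG", mismatches=0, owner=owner, score=score,
    )


def random_instance(rng, formulation, n_cand=None, n_sites=None, gap=None):
    n_cand = n_cand or int(rng.integers(3, 10))
    n_sites = n_sites or int(rng.integers(n_cand, 26))
    gap = gap if gap is not None else int(rng.integers(0, 40))
    spacers = [f"SP{j:02d}" for j in range(n_cand)]
    sites = [
        make_site(
            spacers[int(rng.integers(n_cand))],
            int(rng.integers(0, 300)),
            float(np.round(rng.uniform(0.05, 1.0), 3)),
            strand="+" if rng.random() < 0.5 else "-",
        )
        for _ in range(n_sites)
    ]
    if formulation == 1:
        return SelectionInstance(spacers, sites, gap=gap, formulation=1,
                                 K=int(rng.integers(1, n_cand + 1)))
    total = sum(s.score for s in sites)
    return SelectionInstance(spacers, sites, gap=gap, formulation=2,
                             T=float(np.round(rng.uniform(0.1, 0.9) * total, 3)))


class TestConflictPairs:
    def test_gap_zero_is_conflict_free(self):
        sites = [make_site("A", p, 1.0) for p in (0, 0, 5)]
        assert conflict_pairs(sites, 0) == []

    def test_simple_triplet(self):
        sites = [make_site("A", 0, 1), make_site("A", 10, 1), make_site("B", 50, 1)]
        assert conflict_pairs(sites, 30) == [(0, 1)]

    def test_matches_quadratic_check(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            sites = [
                make_site("A", int(rng.integers(0, 200)), 1.0,
                          chrom=f"c{int(rng.integers(2))}")
                for _ in range(n)
            ]
            gap = int(rng.integers(0, 60))
            got = set(conflict_pairs(sites, gap))
            want = naive_conflict_pairs([(s.chrom, s.start) for s in sites], gap)
            assert got == want


class TestFormulation1:
    def test_unconstrained_counts_everything(self):
        sites = [make_site(f"S{i}", i * 100, 0.5) for i in range(4)]
        inst = SelectionInstance([f"S{i}" for i in range(4)], sites,
                                 gap=30, formulation=1, K=4)
        res = select_max_activity(inst)
        assert res.on_target_score == pytest.approx(2.0)
        assert len(res.counted_sites) == 4
        verify_set(inst, res)

    def test_same_position_conflict_keeps_best(self):
        sites = [make_site("A", 100, 0.8), make_site("B", 100, 0.6)]
        inst = SelectionInstance(["A", "B"], sites, gap=30, formulation=1, K=2)
        res = select_max_activity(inst)
        assert res.on_target_score == pytest.approx(0.8)
        verify_set(inst, res)

    def test_same_locus_not_double_counted_at_gap_zero(self):
        # identical (start, strand) under two owners may be counted once even
        # with no gap constraint
        sites = [make_site("A", 100, 0.8), make_site("B", 100, 0.6)]
        inst = SelectionInstance(["A", "B"], sites, gap=0, formulation=1, K=2)
        assert select_max_activity(inst).on_target_score == pytest.approx(0.8)

    def test_empty_instance(self):
        inst = SelectionInstance([], [], formulation=1, K=1)
        res = select_max_activity(inst)
        assert res.spacers == [] and res.on_target_score == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            inst = random_instance(rng, 1)
            milp_res = select_max_activity(inst)
            bf = brute_force_select(inst)
            assert milp_res.on_target_score == pytest.approx(bf.on_target_score)
            verify_set(inst, milp_res)

    def test_monotone_in_k_and_candidates(self, rng):
        for _ in range(5):
            base = random_instance(rng, 1, n_cand=6, n_sites=20)
            prev = -1.0
            for K in range(1, 7):
                inst = SelectionInstance(base.spacers, base.sites,
                                         gap=base.gap, formulation=1, K=K)
                obj = select_max_activity(inst).on_target_score
                assert obj >= prev - 1e-9
                prev = obj
            # adding a candidate with a fresh positive site can only help
            extra_sites = base.sites + [make_site("ZZZ", 10_000, 0.7)]
            grown = SelectionInstance(base.spacers + ["ZZZ"], extra_sites,
                                      gap=base.gap, formulation=1, K=6)
            assert select_max_activity(grown).on_target_score >= prev - 1e-9


class TestFormulation2:
    def test_single_sgrna_reaches_floor(self):
        sites = [make_site("A", i * 40, 1.0) for i in range(6)]
        inst = SelectionInstance(["A"], sites, gap=30, formulation=2, T=5.0)
        res = select_min_sgrnas(inst)
        assert res.spacers == ["A"]
        assert res.on_target_score >= 5.0
        verify_set(inst, res)

    def test_unreachable_floor_reports_infeasible(self):
        sites = [make_site("A", 0, 1.0), make_site("A", 100, 1.0)]
        inst = SelectionInstance(["A"], sites, gap=30, formulation=2, T=5.0)
        res = select_min_sgrnas(inst)
        assert res.status == STATUS_INFEASIBLE
        assert res.best_achievable == pytest.approx(2.0)

    def test_matches_brute_force_cardinality(self, rng):
        for _ in range(40):
            inst = random_instance(rng, 2)
            milp_res = select_min_sgrnas(inst)
            bf = brute_force_select(inst)
            assert (milp_res.status == STATUS_INFEASIBLE) == (
                bf.status == STATUS_INFEASIBLE
            )
            if milp_res.status != STATUS_INFEASIBLE:
                assert len(milp_res.spacers) == len(bf.spacers)
                verify_set(inst, milp_res)

    def test_cardinality_monotone_as_floor_drops(self, rng):
        for _ in range(5):
            base = random_instance(rng, 1, n_cand=6, n_sites=20)
            total = sum(s.score for s in base.sites)
            prev_card = None
            for frac in (0.8, 0.6, 0.4, 0.2, 0.1):
                inst = SelectionInstance(base.spacers, base.sites, gap=base.gap,
                                         formulation=2, T=frac * total)
                res = select_min_sgrnas(inst)
                if res.status == STATUS_INFEASIBLE:
                    prev_card = None
                    continue
                if prev_card is not None:
                    assert len(res.spacers) <= prev_card
                prev_card = len(res.spacers)

    def test_duality_with_formulation_1(self, rng):
        """F2 with T = the F1 optimum for some K needs at most K sgRNAs."""
        for _ in range(10):
            base = random_instance(rng, 1, n_cand=6, n_sites=18)
            obj = select_max_activity(base).on_target_score
            if obj <= 0:
                continue
            inst = SelectionInstance(base.spacers, base.sites, gap=base.gap,
                                     formulation=2, T=obj - 1e-6)
            res = select_min_sgrnas(inst)
            assert res.status != STATUS_INFEASIBLE
            assert len(res.spacers) <= base.K


class TestBruteForce:
    def test_refuses_large_instances(self):
        sites = [make_site("A", i, 1.0) for i in range(31)]
        inst = SelectionInstance(["A"], sites, formulation=1, K=1)
        with pytest.raises(ValueError):
            brute_force_select(inst)

    def test_empty_instance(self):
        res = brute_force_select(SelectionInstance([], [], formulation=1, K=1))
        assert res.on_target_score == 0.0
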