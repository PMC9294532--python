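"""Proportion z-test, BH adjustment, population comparison and UpSet rows."""

import itertools
import math
import random

import numpy as np
import pytest

from kinvar.compare import (
    bh_adjust,
    compare_populations,
    exclusive_intersections,
    one_prop_ztest,
    significant_pairs,
)
from kinvar.errors import InputError
from kinvar.exchange import count_exchanges


def normal_sf_oracle(z: float) -> float:
    """Independent upper-tail normal probability via the error function."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def bh_oracle(pvalues):
    """Hand-coded BH step-up with monotonicity enforcement."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


class TestZTest:
    def test_worked_example(self):
        z, p = one_prop_ztest(30, 100, 0.2)
        assert z == pytest.approx(2.5)
        assert p == pytest.approx(0.01242, abs=5e-6)

    def test_null_case(self):
        z, p = one_prop_ztest(20, 100, 0.2)
        assert z == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_degenerate_null_proportion_rejected(self, p0):
        with pytest.raises(InputError):
            one_prop_ztest(10, 100, p0)

    def test_matches_independent_cdf_on_random_grid(self):
        """z and p agree with a from-scratch formula + erfc tail to 1e-9."""
        rng = random.Random(42)
        for _ in range(1000):
            n = rng.randint(1, 10_000)
            k = rng.randint(0, n)
            p0 = rng.uniform(0.01, 0.99)
            z, p = one_prop_ztest(k, n, p0)
            z_expect = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
            p_expect = min(2.0 * normal_sf_oracle(abs(z_expect)), 1.0)
            assert abs(z - z_expect) < 1e-9
            assert abs(p - p_expect) < 1e-9

    def test_z_sign_tracks_direction(self):
        rng = random.Random(1)
        for _ in range(200):
            n = rng.randint(2, 500)
            k = rng.randint(0, n)
            p0 = rng.uniform(0.05, 0.95)
            z, _ = one_prop_ztest(k, n, p0)
            assert (z > 0) == (k / n > p0) and (z < 0) == (k / n < p0)


class TestBH:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_executed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_permutation_equivariance(self):
        p = [0.001, 0.2, 0.8, 0.04, 0.04]
        q = bh_adjust(p)
        perm = [3, 0, 4, 1, 2]
        q_perm = bh_adjust([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    def test_matches_step_up_oracle_on_all_small_subsets(self):
        """BH equals the hand-coded oracle on every subset of <=6 random p-values."""
        rng = random.Random(7)
        pool = [round(rng.random(), 6) for _ in range(6)]
        for size in range(1, 7):
            for subset in itertools.combinations(pool, size):
                assert bh_adjust(list(subset)) == pytest.approx(
                    bh_oracle(list(subset)), abs=1e-12
                )

    def test_adjusted_never_below_raw(self):
        rng = random.Random(3)
        p = [rng.random() for _ in range(50)]
        q = bh_adjust(p)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))


class TestComparePopulations:
    def test_identical_matrices_yield_no_significant_pairs(self, small_cohorts):
        m = count_exchanges(small_cohorts.variants["POP1"])
        results, _ = compare_populations(m, m)
        assert all(not r.significant for r in results)
        # identical proportions give z == 0 exactly
        assert all(r.z == 0.0 for r in results)

    def test_null_pairs_not_tested(self, small_cohorts):
        m1 = count_exchanges(small_cohorts.variants["POP1"])
        m2 = count_exchanges(small_cohorts.variants["POP2"])
        results, skipped = compare_populations(m1, m2)
        tested = {(r.ref_aa, r.alt_aa) for r in results}
        for i, ref in enumerate("ACDEFGHIKLMNPQRSTVWY"):
            for j, alt in enumerate("ACDEFGHIKLMNPQRSTVWY"):
                if ref != alt and m1.counts[i, j] == 0 and m2.counts[i, j] == 0:
                    assert (ref, alt) not in tested

    def test_empty_focal_errors(self, small_cohorts):
        with pytest.raises(InputError):
            compare_populations(count_exchanges([]), count_exchanges(small_cohorts.variants["POP1"]))

    def test_significance_flag_matches_q_and_alpha(self, small_cohorts):
        m1 = count_exchanges(small_cohorts.variants["POP1"])
        m2 = count_exchanges(small_cohorts.variants["POP2"])
        results, _ = compare_populations(m1, m2, alpha=0.05)
        for r in results:
            assert r.significant == (r.q < 0.05)
            assert r.q >= r.p - 1e-12

    def test_condition_on_ref_changes_denominator(self, small_cohorts):
        m1 = count_exchanges(small_cohorts.variants["POP1"])
        m2 = count_exchanges(small_cohorts.variants["POP2"])
        results, _ = compare_populations(m1, m2, condition_on_ref=True)
        for r in results:
            row_total = sum(
                m1.counts["ACDEFGHIKLMNPQRSTVWY".index(r.ref_aa)]
            )
            assert r.n_focal == row_total


class TestExclusiveIntersections:
    def test_disjoint_sets(self):
        rows = exclusive_intersections({"A": {"x"}, "B": {"y"}})
        assert [(r.members, set(r.elements)) for r in rows] == [
            (("A",), {"x"}),
            (("B",), {"y"}),
        ]

    def test_shared_element_single_row(self):
        rows = exclusive_intersections({"A": {"x"}, "B": {"x"}})
        assert len(rows) == 1
        assert rows[0].members == ("A", "B") and set(rows[0].elements) == {"x"}

    def test_rows_partition_union(self):
        rng = random.Random(11)
        sets = {
            name: {rng.randint(0, 9) for _ in range(rng.randint(0, 8))}
            for name in "ABCD"
        }
        rows = exclusive_intersections(sets)
        union = set().union(*sets.values())
        elements = [e for r in rows for e in r.elements]
        assert len(elements) == len(set(elements)) == len(union)

    def test_matches_brute_force_signature_grouping(self):
        """500 random instances against a brute-force membership grouping."""
        rng = random.Random(5)
        for _ in range(500):
            n_sets = rng.randint(1, 4)
            names = [f"S{i}" for i in range(n_sets)]
            sets = {
                name: {rng.randint(0, 9) for _ in range(rng.randint(0, 10))}
                for name in names
            }
            rows = exclusive_intersections(sets)
            brute = {}
            for el in set().union(*sets.values()):
                sig = tuple(sorted(n for n in names if el in sets[n]))
                brute.setdefault(sig, set()).add(el)
            assert {r.members: set(r.elements) for r in rows} == brute
            sizes = [r.size for r in rows]
            assert sizes == sorted(sizes, reverse=True)


def test_spiked_pair_dominates_and_is_detected():
    """A strongly spiked exchange pair is recovered as FDR-significant."""
    from kinvar.simulate import SimConfig, simulate_cohorts

    cfg = SimConfig(
        n_genes=15,
        protein_length_range=(150, 300),
        n_variants_per_population=3000,
        populations=("FOCAL", "REF"),
        spike_pairs=(("FOCAL", "A", "P", 10.0),),
        seed=3,
    )
    cohorts = simulate_cohorts(cfg)
    focal = count_exchanges(cohorts.variants["FOCAL"])
    ref = count_exchanges(cohorts.variants["REF"])
    results, _ = compare_populations(focal, ref)
    assert ("A", "P") in significant_pairs(results)
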