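"""Diversity and neutrality statistics, Phi_st, distances, MST."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdtkit import (
    Alignment,
    DistanceMatrix,
    TwoEpochModel,
    UndefinedStatisticError,
    collapse_haplotypes,
    fus_fs,
    haplotype_diversity,
    minimum_spanning_tree,
    neutrality_null,
    nucleotide_diversity,
    pairwise_phi_st,
    r2_statistic,
    simulate_coalescent,
    simulate_sequences,
    t92_gamma_distance,
    tajimas_d,
)
from cdtkit.popgen_stats import (
    _fs_from_summary,
    _mean_pairwise_diffs,
    _tajima_d_from_summary,
)


def aln(seqs, pops=None):
    return Alignment(list(seqs), [f"s{i}" for i in range(len(seqs))], pops)


class TestHaplotypes:
    def test_identical_sequences_collapse_to_one(self):
        t = collapse_haplotypes(aln(["ACGT"] * 5))
        assert t.n_haplotypes == 1 and t.segregating_sites == []

    def test_small_example(self):
        t = collapse_haplotypes(aln(["AAA", "AAT", "AAT"]))
        assert t.n_haplotypes == 2
        assert sorted(t.counts) == [1, 2]
        assert t.segregating_sites == [2]

    def test_missing_data_columns_excluded(self):
        # complete deletion: the N column is dropped, so all collapse together
        t = collapse_haplotypes(aln(["ANA", "AGA", "ACA"]))
        assert t.n_haplotypes == 1

    def test_counts_partition_input(self):
        sequences = ["AAAA", "AAAT", "AAAT", "TTTT", "AAAA"]
        t = collapse_haplotypes(aln(sequences))
        assert t.counts.sum() == len(sequences)
        assert sorted(i for mem in t.members for i in mem) == list(range(5))


class TestDiversity:
    def test_haplotype_diversity_toy(self):
        h, se = haplotype_diversity(collapse_haplotypes(aln(["AA", "AA", "AT", "AT"])))
        assert h == pytest.approx(4 / 3 * 0.5)
        assert se > 0

    def test_single_haplotype_zero_diversity(self):
        h, _ = haplotype_diversity(collapse_haplotypes(aln(["ACGT"] * 6)))
        assert h == 0.0

    def test_nucleotide_diversity_toys(self):
        pi, _ = nucleotide_diversity(aln(["A" * 100, "T" + "A" * 99]))
        assert pi == pytest.approx(0.01)
        assert nucleotide_diversity(aln(["ACGT"] * 4))[0] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.permutations(range(6)))
    def test_order_invariance(self, perm):
        seqs = ["AAAA", "AAAT", "AATT", "AAAA", "TAAA", "AAAT"]
        base = aln(seqs)
        shuffled = Alignment([seqs[i] for i in perm], [f"x{i}" for i in range(6)])
        assert nucleotide_diversity(base)[0] == pytest.approx(
            nucleotide_diversity(shuffled)[0]
        )
        assert haplotype_diversity(collapse_haplotypes(base))[0] == pytest.approx(
            haplotype_diversity(collapse_haplotypes(shuffled))[0]
        )


class TestTajimasD:
    def test_singleton_toy(self):
        # n=4, one singleton: hand evaluation gives -0.612
        assert tajimas_d(aln(["TAAA", "AAAA", "AAAA", "AAAA"])) == pytest.approx(
            -0.6124, abs=1e-4
        )

    def test_no_segregating_sites_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            tajimas_d(aln(["ACGT"] * 5))

    def test_mean_near_zero_under_constant_null(self):
        # fixed-S null replicates: mean D ~ 0, 5% rejection calibrated
        from cdtkit.synthetic_data import simulate_coalescent as sim

        const = TwoEpochModel("exponential", 1.0, 1.0, 1.0)
        rng = np.random.default_rng(0)
        n, s_sites = 50, 15

        def one(seed):
            g = sim(n, const, seed=seed)
            bl = g.branch_lengths()
            nodes = np.flatnonzero(bl > 0)
            hits = rng.choice(nodes, size=s_sites, p=bl[nodes] / bl[nodes].sum())
            tips = g.clade_tipsets()
            c = np.array([
                len(tips[h]) if h >= n else 1 for h in hits
            ])
            pi = float((c * (n - c)).sum()) / (n * (n - 1) / 2)
            return _tajima_d_from_summary(n, s_sites, pi)

        null = np.array([one(s) for s in range(2000)])
        data = np.array([one(10_000 + s) for s in range(500)])
        assert abs(data.mean()) < 4 * null.std() / np.sqrt(500)
        crit = np.quantile(null, 0.05)
        rej = (data <= crit).mean()
        assert 0.02 <= rej <= 0.08


class TestFusFs:
    def test_k1_signals_infinity(self):
        assert _fs_from_summary(3, 1, 0.7) == math.inf

    def test_zero_diversity_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fus_fs(aln(["ACGT"] * 3))

    @pytest.mark.parametrize("n,k,theta", [
        (5, 3, 1.0), (5, 2, 0.4), (8, 4, 2.5), (8, 8, 0.9), (7, 2, 3.0),
    ])
    def test_matches_direct_ewens_summation(self, n, k, theta):
        # oracle: Ewens probabilities from sympy Stirling numbers, summed directly
        from sympy.functions.combinatorial.numbers import stirling

        probs = []
        denom = math.prod(theta + i for i in range(n))
        for kk in range(1, n + 1):
            probs.append(float(stirling(n, kk, kind=1, signed=False)) * theta**kk / denom)
        s_prime = sum(probs[k - 1:])
        expect = math.log(s_prime / (1 - s_prime))
        assert _fs_from_summary(n, k, theta) == pytest.approx(expect, abs=1e-9)

    def test_on_alignment(self):
        value = fus_fs(aln(["AAAA", "AAAT", "AATT", "AAAA", "TAAA"]))
        assert np.isfinite(value)


class TestR2:
    def test_singleton_toy(self):
        # U=(1,0,0,0), pi=0.5: R2 = sqrt(0.75/4)/1
        assert r2_statistic(aln(["TAAA", "AAAA", "AAAA", "AAAA"])) == pytest.approx(
            math.sqrt(0.75 / 4), abs=1e-12
        )

    def test_no_variation_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r2_statistic(aln(["AC", "AC", "AC"]))


class TestNeutralityNull:
    def test_null_centred_data_has_middling_p(self, hky_gamma):
        const = TwoEpochModel("exponential", 0.01, 0.01, 1.0)
        g = simulate_coalescent(25, const, seed=42)
        data = simulate_sequences(g, hky_gamma, 608, seed=43)
        res = neutrality_null(data, "tajima_d", n_reps=400, seed=1)
        assert 0.05 < res.p_value < 0.95

    def test_expansion_detected_with_power(self, hky_gamma):
        model = TwoEpochModel("logistic", 0.02, 0.0002, 2.5e-4)
        hits = 0
        trials = 20
        for s in range(trials):
            g = simulate_coalescent(40, model, seed=300 + s)
            data = simulate_sequences(g, hky_gamma, 608, seed=400 + s)
            try:
                res = neutrality_null(data, "tajima_d", n_reps=200, seed=s)
            except (UndefinedStatisticError, ValueError):
                continue
            hits += res.p_value < 0.05
        assert hits >= 0.9 * trials

    def test_reproducible_and_validated(self, expansion_alignment):
        a = neutrality_null(expansion_alignment, "r2", n_reps=100, seed=7)
        b = neutrality_null(expansion_alignment, "r2", n_reps=100, seed=7)
        assert a.p_value == b.p_value
        with pytest.raises(ValueError):
            neutrality_null(expansion_alignment, "r2", n_reps=0, seed=7)
        with pytest.raises(ValueError):
            neutrality_null(expansion_alignment, "not_a_stat", n_reps=10, seed=7)


class TestPhiSt:
    def test_identical_compositions_give_zero(self):
        seqs = ["AAAA", "AATT"] * 4
        # each population holds two copies of each haplotype
        a = Alignment(seqs, [f"s{i}" for i in range(8)],
                      ["X", "X", "Y", "Y", "X", "X", "Y", "Y"])
        phi, p = pairwise_phi_st(a, "X", "Y", n_perms=200, seed=0)
        assert phi <= 1e-9
        assert p > 0.05

    def test_fixed_differences_give_one(self):
        a = aln(["AAAA"] * 4 + ["TTTT"] * 4, ["X"] * 4 + ["Y"] * 4)
        phi, p = pairwise_phi_st(a, "X", "Y", n_perms=300, seed=1)
        assert phi == pytest.approx(1.0)
        assert p < 0.05

    def test_label_swap_invariance_and_seeding(self):
        seqs = ["AAAA", "AAAT", "TTAA", "TTAT", "TTTT", "ATTT"]
        a = aln(seqs, ["X", "X", "X", "Y", "Y", "Y"])
        phi_xy, p_xy = pairwise_phi_st(a, "X", "Y", n_perms=300, seed=5)
        phi_yx, p_yx = pairwise_phi_st(a, "Y", "X", n_perms=300, seed=5)
        assert phi_xy == pytest.approx(phi_yx)
        assert p_xy == p_yx

    def test_small_population_rejected(self):
        a = aln(["AAAA", "TTTT", "TTTA"], ["X", "Y", "Y"])
        with pytest.raises(ValueError):
            pairwise_phi_st(a, "X", "Y")


def _t92_oracle(p, q, gc, alpha):
    h = 2 * gc * (1 - gc)
    if alpha is None:
        return -h * math.log(1 - p / h - q) - 0.5 * (1 - h) * math.log(1 - 2 * q)
    return alpha * (h * ((1 - p / h - q) ** (-1 / alpha) - 1)
                    + 0.5 * (1 - h) * ((1 - 2 * q) ** (-1 / alpha) - 1))


class TestT92:
    def test_identical_sequences_zero(self):
        d = t92_gamma_distance(aln(["ACGT" * 5] * 3), alpha=0.5)
        assert np.allclose(d.matrix, 0.0)

    def test_known_pair_matches_direct_formula(self):
        # seq pair engineered: length 20, 2 transitions (A<->G), 1 transversion (C<->A)
        s1 = "AAAAAAAAAACCCCCCCCCC"
        s2 = "GGAAAAAAAACCCCCCCCCA"
        a = aln([s1, s2])
        gc = (s1.count("G") + s1.count("C") + s2.count("G") + s2.count("C")) / 40
        expect = _t92_oracle(2 / 20, 1 / 20, gc, 0.5)
        d = t92_gamma_distance(a, alpha=0.5)
        assert d.matrix[0, 1] == pytest.approx(expect, abs=1e-9)
        expect_inf = _t92_oracle(2 / 20, 1 / 20, gc, None)
        d_big = t92_gamma_distance(a, alpha=1e9)
        assert d_big.matrix[0, 1] == pytest.approx(expect_inf, rel=1e-6)

    def test_saturated_pair_flagged_nan(self):
        a = aln(["AAAA", "GGGG"])  # P = 1 >> h
        d = t92_gamma_distance(a, alpha=1.0)
        assert math.isnan(d.matrix[0, 1])


def _brute_force_mst_weight(matrix):
    n = matrix.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(matrix[i, j] for i, j in combo))
    return best


class TestMST:
    def test_three_haplotype_example(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        d = DistanceMatrix(["H1", "H2", "H3"], m, "pairwise_diff_count")
        edges = minimum_spanning_tree(d)
        assert {(a, b) for a, b, _ in edges} == {("H1", "H2"), ("H1", "H3")}
        assert sum(w for *_, w in edges) == 3

    def test_two_haplotypes_single_edge(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 2.0], [2.0, 0]]), "p_distance")
        assert len(minimum_spanning_tree(d)) == 1

    def test_star_topology(self):
        n = 5
        m = np.full((n, n), 2.0)
        m[0, :] = m[:, 0] = 1.0
        np.fill_diagonal(m, 0.0)
        labels = [f"H{i}" for i in range(n)]
        edges = minimum_spanning_tree(DistanceMatrix(labels, m, "p_distance"))
        assert all("H0" in (a, b) for a, b, _ in edges)

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2)])
    def test_total_weight_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 10, size=(n, n)).astype(float)
        m = np.triu(m, 1)
        m = m + m.T
        d = DistanceMatrix([f"H{i}" for i in range(n)], m, "pairwise_diff_count")
        edges = minimum_spanning_tree(d)
        assert sum(w for *_, w in edges) == pytest.approx(_brute_force_mst_weight(m))

    def test_nan_distances_rejected(self):
        m = np.array([[0, np.nan], [np.nan, 0]])
        d = DistanceMatrix(["A", "B"], m, "t92_gamma")
        with pytest.raises(ValueError):
            minimum_spanning_tree(d)


class TestAlignmentValidation:
    def test_ragged_and_illegal_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment(["ACGT", "ACG"], ["a", "b"])
        with pytest.raises(ValueError, match="illegal character"):
            Alignment(["ACXT"], ["a"])
        with pytest.raises(ValueError, match="duplicate"):
            Alignment(["ACGT", "ACGT"], ["a", "a"])
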