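import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirconcord.de_io import DETable
from mirconcord.enrichment import (
    directional_overlap,
    fisher_exact_2x2,
    has_seed_site,
    intersection_distribution,
    multiset_exact_test,
    reverse_complement,
    scan_seed_sites,
    seed_enrichment,
)
from mirconcord.synthetic_data import simulate_gene_sets, simulate_utrs

MIR = "UAGCUUAUCAGACUGAUGUUGA"  # seed (positions 2-8) = AGCUUAU


def brute_scan(utr: str, mir: str) -> list[tuple[str, int]]:
    """Sliding-window re-derivation of the site taxonomy."""
    utr = utr.upper().replace("U", "T")
    mir = mir.upper().replace("U", "T")
    rc6 = reverse_complement(mir[1:7])
    m8 = reverse_complement(mir[7])
    out = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != rc6:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            out.append(("8mer", i - 1))
        elif has_m8:
            out.append(("7mer-m8", i - 1))
        elif has_a1:
            out.append(("7mer-A1", i))
        else:
            out.append(("6mer", i))
    return out


class TestScanSeedSites:
    def test_constructed_8mer(self):
        # ATAAGCTA = revcomp(seed 2-8) + A
        sites = scan_seed_sites("GGG" + "ATAAGCTA" + "GGG", MIR)
        assert [s.site_type for s in sites] == ["8mer"]
        assert (sites[0].start, sites[0].end) == (3, 11)

    @pytest.mark.parametrize(
        "insert, expected",
        [
            ("ATAAGCTC", "7mer-m8"),   # m8 match, no A1
            ("GTAAGCTA", "7mer-A1"),   # A1, no m8 match
            ("GTAAGCTC", "6mer"),      # core hexamer only
        ],
    )
    def test_site_taxonomy(self, insert, expected):
        sites = scan_seed_sites("CCC" + insert + "CCC", MIR)
        assert [s.site_type for s in sites] == [expected]

    def test_poly_a_utr_has_no_sites(self):
        assert scan_seed_sites("A" * 100, MIR) == []

    def test_counts_match_sliding_window_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            utr = "".join(bases[rng.integers(0, 4, size=300)])
            got = [(s.site_type, s.start) for s in scan_seed_sites(utr, MIR)]
            assert got == brute_scan(utr, MIR)

    def test_planted_sites_all_found(self):
        seqs, truth = simulate_utrs(20, 200, MIR, planted_sites_per_seq=3, seed=5)
        for uid, seq in seqs.items():
            n_8mer = sum(1 for s in scan_seed_sites(seq, MIR) if s.site_type == "8mer")
            assert n_8mer >= truth[uid]

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            scan_seed_sites("ACGTN", MIR)
        with pytest.raises(ValueError):
            scan_seed_sites("ACGT", "UAGCUUA")  # miRNA too short


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over the hypergeometric support."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    amin, amax = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        x: math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom
        for x in range(amin, amax + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisherExact2x2:
    def test_no_association(self):
        odds, p = fisher_exact_2x2(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_small_table(self):
        _, p = fisher_exact_2x2(3, 1, 1, 3)
        assert p == pytest.approx(0.4857, abs=1e-4)

    def test_extreme_table(self):
        odds, p = fisher_exact_2x2(10, 0, 0, 10)
        assert odds == np.inf
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)

    def test_symmetries(self):
        _, p = fisher_exact_2x2(7, 2, 3, 9)
        _, p_t = fisher_exact_2x2(7, 3, 2, 9)  # transpose
        _, p_s = fisher_exact_2x2(9, 3, 2, 7)  # row+column swap
        assert p == pytest.approx(p_t, rel=1e-12)
        assert p == pytest.approx(p_s, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 3, 4)


class TestSeedEnrichment:
    def test_paper_scale_proportions(self):
        res = seed_enrichment([True] * 23 + [False] * 44, 3590, 20988)
        assert res["proportion"] == pytest.approx(23 / 67)
        assert res["background_proportion"] == pytest.approx(3590 / 20988)
        assert res["p_value"] < 0.05

    def test_background_rate_gives_odds_near_one(self):
        res = seed_enrichment([True] * 20 + [False] * 80, 2000, 10000, disjoint_background=False)
        assert res["odds_ratio"] == pytest.approx(1.0, rel=0.05)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            seed_enrichment([], 10, 100)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            seed_enrichment([True] * 5, 3, 100)  # more flagged than background carries


def enumerate_intersections(N, sizes):
    """Exhaustive pmf of the m-way intersection by enumerating subsets.

    The first set is fixed to {0..s1-1} (exchangeability); remaining sets
    are enumerated exhaustively.
    """
    first = frozenset(range(sizes[0]))
    universe = range(N)
    counts = {}
    total = 0
    for others in itertools.product(
        *[itertools.combinations(universe, s) for s in sizes[1:]]
    ):
        inter = first
        for o in others:
            inter = inter & frozenset(o)
        counts[len(inter)] = counts.get(len(inter), 0) + 1
        total += 1
    pmf = np.zeros(min(sizes) + 1)
    for k, v in counts.items():
        pmf[k] = v / total
    return pmf


class TestMultisetExactTest:
    def test_degenerate_single_set(self):
        res = multiset_exact_test([4], 4, 10)
        assert res.fold_enrichment == 1.0 and res.p_value == 1.0

    def test_two_set_point_mass(self):
        res = multiset_exact_test((5, 5), 5, 10)
        assert res.expected == pytest.approx(2.5)
        assert res.fold_enrichment == pytest.approx(2.0)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_three_set_chain(self):
        res = multiset_exact_test((3, 3, 3), 3, 6)
        assert res.expected == pytest.approx(0.75)
        assert res.fold_enrichment == pytest.approx(4.0)
        assert res.p_value == pytest.approx(1 / 400, rel=1e-12)

    def test_distribution_sums_to_one(self):
        for sizes, N in [((10, 20, 30), 100), ((300, 250, 200), 1000)]:
            dist = intersection_distribution(sizes, N)
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_set_tail_equals_hypergeometric(self):
        N, s1, s2, obs = 200, 40, 60, 18
        res = multiset_exact_test((s1, s2), obs, N)
        assert res.p_value == pytest.approx(stats.hypergeom.sf(obs - 1, N, s1, s2), rel=1e-10)

    @pytest.mark.parametrize("N,sizes", [(6, (3, 3, 3)), (8, (4, 3, 5)), (10, (5, 4, 2))])
    def test_matches_exhaustive_enumeration(self, N, sizes):
        dist = intersection_distribution(sizes, N)
        np.testing.assert_allclose(dist, enumerate_intersections(N, sizes), atol=1e-12)

    def test_impossible_observed_rejected(self):
        with pytest.raises(ValueError):
            multiset_exact_test((3, 5), 4, 10)


class TestSimulatedGeneSets:
    def test_core_always_in_intersection(self):
        sets, core = simulate_gene_sets(100, (30, 40, 50), planted_core=10, seed=1)
        inter = set.intersection(*sets)
        assert core <= inter and len(inter) >= 10

    def test_full_sets_intersect_completely(self):
        sets, _ = simulate_gene_sets(20, (20, 20, 20), planted_core=0, seed=1)
        assert len(set.intersection(*sets)) == 20

    def test_null_intersection_matches_expectation(self):
        N, sizes = 50, (20, 20, 20)
        expected = N * np.prod([s / N for s in sizes])
        obs = []
        for seed in range(400):
            sets, _ = simulate_gene_sets(N, sizes, planted_core=0, seed=seed)
            obs.append(len(set.intersection(*sets)))
        dist = intersection_distribution(sizes, N)
        var = float(np.sum(np.arange(len(dist)) ** 2 * dist) - expected**2)
        se = math.sqrt(var / len(obs))
        assert abs(np.mean(obs) - expected) <= 3 * se

    def test_core_exceeding_min_size_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_sets(100, (5, 10), planted_core=6, seed=0)


def _called(contrast, genes_up, genes_down, genes_ns):
    rows = []
    for g in genes_up:
        rows.append((g, 2.0, 1e-8, 1e-6, True, True, "up"))
    for g in genes_down:
        rows.append((g, -2.0, 1e-8, 1e-6, True, True, "down"))
    for g in genes_ns:
        rows.append((g, 0.1, 0.8, 0.9, True, False, "none"))
    return DETable(
        contrast,
        pd.DataFrame(
            rows,
            columns=["feature_id", "log2FoldChange", "pvalue", "padj", "tested", "significant", "direction"],
        ),
    )


class TestDirectionalOverlap:
    def test_disjoint_significant_sets(self):
        x = _called("x", ["a"], [], ["b", "c", "d"])
        y = _called("y", ["b"], [], ["a", "c", "d"])
        res = directional_overlap(x, y)
        assert res.shared == 0 and res.up_up == res.down_down == res.discordant == 0

    def test_identical_tables_have_no_discordance(self):
        x = _called("x", ["a", "b"], ["c"], ["d", "e"])
        res = directional_overlap(x, x)
        assert res.discordant == 0
        assert res.up_up + res.down_down == 3

    def test_partition_sums_to_shared(self):
        x = _called("x", ["a", "b", "c"], ["d"], ["e", "f"])
        y = _called("y", ["a"], ["b", "d"], ["c", "e", "f"])
        res = directional_overlap(x, y)
        assert res.shared == 3  # a, b, d significant in both
        assert res.up_up + res.down_down + res.discordant == res.shared
        assert res.up_up == 1 and res.down_down == 1 and res.discordant == 1

    def test_empty_common_universe_rejected(self):
        x = _called("x", ["a"], [], [])
        y = _called("y", ["zz"], [], [])
        with pytest.raises(ValueError):
            directional_overlap(x, y)
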