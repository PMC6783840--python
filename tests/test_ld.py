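"""Two-locus LD estimation, D' confidence bounds and Gabriel blocks."""

import numpy as np
import pytest
from conftest import planted_panel
from hypothesis import given
from hypothesis import strategies as st

from hapgs import ld


def random_genotype_pair(rng, n=200):
    """Dosage pair drawn from a random two-locus haplotype distribution."""
    f = rng.dirichlet(np.ones(4))
    hapA = np.array([0, 0, 1, 1])
    hapB = np.array([0, 1, 0, 1])
    h1 = rng.choice(4, size=n, p=f)
    h2 = rng.choice(4, size=n, p=f)
    return hapA[h1] + hapA[h2], hapB[h1] + hapB[h2]


class TestEMTwoLocus:
    def test_unambiguous_sample_recovers_exact_frequencies(self):
        ga = np.array([0] * 50 + [2] * 50)
        gb = np.array([0] * 50 + [2] * 50)
        t = ld.em_two_locus(ga, gb)
        assert t.p_a1b1 == pytest.approx(0.5, abs=1e-9)
        assert t.p_a2b2 == pytest.approx(0.5, abs=1e-9)
        assert t.p_a1b2 == pytest.approx(0.0, abs=1e-9)

    def test_all_double_heterozygotes_stay_at_independence(self):
        ga = np.ones(40, dtype=int)
        gb = np.ones(40, dtype=int)
        t = ld.em_two_locus(ga, gb)
        assert ld.ld_stats(t).D == pytest.approx(0.0, abs=1e-9)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ld.LDUndefinedError):
            ld.em_two_locus(np.zeros(30, dtype=int), np.ones(30, dtype=int))

    def test_em_matches_bruteforce_profile_likelihood(self):
        """EM log-likelihood reaches the brute-force maximum over D."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            ga, gb = random_genotype_pair(rng)
            try:
                t = ld.em_two_locus(ga, gb)
            except ld.LDUndefinedError:
                continue
            counts = ld.genotype_counts(ga, gb)
            ll_em = ld.two_locus_loglik(counts, t.freqs())
            # allele-frequency MLEs are the sample frequencies; profile over D
            pa1, pb1 = t.p_a1, t.p_b1
            dmin = -min(pa1 * pb1, (1 - pa1) * (1 - pb1))
            dmax = min(pa1 * (1 - pb1), (1 - pa1) * pb1)
            best = -np.inf
            for d in np.linspace(dmin, dmax, 4001):
                f = np.array([pa1 * pb1 + d, pa1 * (1 - pb1) - d,
                              (1 - pa1) * pb1 - d, (1 - pa1) * (1 - pb1) + d])
                if f.min() < 0:
                    continue
                best = max(best, ld.two_locus_loglik(counts, f))
            assert ll_em >= best - 1e-6

    def test_em_equals_phased_counts_without_double_heterozygotes(self):
        rng = np.random.default_rng(7)
        # homozygous-only individuals: phase is observed
        hapA = np.array([0, 0, 1, 1])
        hapB = np.array([0, 1, 0, 1])
        h = rng.choice(4, size=150, p=[0.4, 0.1, 0.2, 0.3])
        ga, gb = 2 * hapA[h], 2 * hapB[h]
        t = ld.em_two_locus(ga, gb)
        direct = np.bincount(h, minlength=4) / len(h)
        assert np.allclose(t.freqs(), direct, atol=1e-9)


class TestLDStats:
    def test_independence_gives_zero(self):
        t = ld.TwoLocusTable(0.35, 0.35, 0.15, 0.15, 100)
        s = ld.ld_stats(t)
        assert s.D == pytest.approx(0.0, abs=1e-12)
        assert s.Dprime == pytest.approx(0.0, abs=1e-9)
        assert s.r2 == pytest.approx(0.0, abs=1e-9)

    def test_complete_symmetric_ld(self):
        s = ld.ld_stats(ld.TwoLocusTable(0.5, 0.0, 0.0, 0.5, 100))
        assert s.Dprime == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)

    def test_hand_case(self):
        s = ld.ld_stats(ld.TwoLocusTable(0.4, 0.1, 0.1, 0.4, 100))
        assert s.D == pytest.approx(0.15)
        assert s.DMAX == pytest.approx(0.25)
        assert s.Dprime == pytest.approx(0.6)
        assert s.r2 == pytest.approx(0.36)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ld.LDUndefinedError):
            ld.ld_stats(ld.TwoLocusTable(0.5, 0.5, 0.0, 0.0, 10))

    @given(st.integers(0, 2**32 - 1))
    def test_ranges_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        ga, gb = random_genotype_pair(rng, n=120)
        try:
            s = ld.ld_stats(ld.em_two_locus(ga, gb))
        except ld.LDUndefinedError:
            return
        assert 0.0 <= s.Dprime <= 1.0
        assert 0.0 <= s.r2 <= 1.0


class TestConfidenceBounds:
    def test_perfect_ld_sample(self):
        rng = np.random.default_rng(1)
        h = rng.random(400) < 0.4
        g = np.where(h[:200] | h[200:], 1, 0) + np.where(h[:200] & h[200:], 1, 0)
        lo, hi = ld.dprime_confidence_bounds(g, g)
        assert hi == pytest.approx(1.0)
        assert lo >= 0.7

    def test_independent_markers_bounded_upper(self):
        rng = np.random.default_rng(17)
        ga = rng.binomial(2, 0.5, size=200)
        gb = rng.binomial(2, 0.5, size=200)
        _, hi = ld.dprime_confidence_bounds(ga, gb)
        assert hi < 0.9

    def test_tiny_sample_gives_wide_bounds(self):
        lo, hi = ld.dprime_confidence_bounds([0, 1], [1, 0])
        assert lo <= 0.1
        assert hi >= 0.9


class TestGabrielBlocks:
    def test_recovers_single_planted_segment(self):
        dos, mm, spec = planted_panel(400, seed=13)
        blocks = ld.gabriel_blocks(dos, mm, compute_variants=True)
        assert len(blocks) == 1
        seg = spec.segments[0].marker_indices
        assert blocks[0].first == seg[0] and blocks[0].last == seg[-1]
        # two complementary founder variants dominate
        top = sorted(blocks[0].variants, key=lambda v: -v[1])[:2]
        assert sum(f for _, f in top) > 0.9

    def test_independent_markers_give_no_blocks(self):
        dos, mm, _ = planted_panel(400, seed=17, segment_bounds=())
        assert ld.gabriel_blocks(dos, mm, compute_variants=False) == []

    def test_blocks_disjoint_and_within_span(self):
        dos, mm, _ = planted_panel(
            400, seed=19, n_markers=40,
            segment_bounds=((5, 9), (25, 30)))
        blocks = ld.gabriel_blocks(dos, mm, compute_variants=False)
        covered = np.zeros(40, bool)
        for b in blocks:
            assert b.span_bp <= ld.GabrielParams().max_span_bp
            assert not covered[b.first:b.last + 1].any()
            covered[b.first:b.last + 1] = True

    def test_empty_marker_set(self):
        import pandas as pd

        mm = pd.DataFrame(columns=["marker_id", "chromosome", "position_bp"])
        assert ld.gabriel_blocks(np.zeros((10, 0)), mm) == []


class TestLDExtent:
    def test_critical_r2_constant_distribution(self):
        assert ld.critical_r2_from_values([0.09] * 50) == pytest.approx(0.09)

    def test_critical_r2_percentile_rule(self):
        vals = (np.arange(1, 11) / 10.0) ** 2  # sqrt(r2) = 0.1..1.0
        expected = float(np.quantile(np.arange(1, 11) / 10.0, 0.95) ** 2)
        assert ld.critical_r2_from_values(vals) == pytest.approx(expected)

    def test_single_chromosome_rejected(self):
        dos, mm, _ = planted_panel(50, seed=3, segment_bounds=())
        with pytest.raises(ValueError):
            ld.critical_r2(dos, mm)

    def test_unlinked_markers_have_low_critical_r2(self):
        dos, mm, _ = planted_panel(400, seed=23, segment_bounds=(),
                                   n_markers=30, n_chromosomes=3)
        crit = ld.critical_r2(dos, mm, seed=1)
        assert crit < 0.05

    def test_decay_crossing_with_planted_short_range_ld(self):
        dos, mm, spec = planted_panel(
            300, seed=29, n_markers=40, length=50_000,
            segment_bounds=((0, 5), (20, 26)))
        ext = ld.ld_decay_profile(dos, mm, bin_width_bp=2_000,
                                  max_dist_bp=30_000, critical=0.2)
        assert ext.crossing_distance_bp is not None

    def test_no_crossing_reported_as_absent(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        h = rng.random(100) < 0.5
        g = np.column_stack([h * 2, h * 2]).astype(int)
        mm = pd.DataFrame({"marker_id": ["a", "b"], "chromosome": [1, 1],
                           "position_bp": [100, 600]})
        ext = ld.ld_decay_profile(g, mm, 1000, 2000, critical=0.5)
        assert ext.crossing_distance_bp is None

    def test_zero_ld_crosses_at_first_bin(self):
        dos, mm, _ = planted_panel(400, seed=31, segment_bounds=(),
                                   n_markers=20, length=10_000)
        ext = ld.ld_decay_profile(dos, mm, 1_000, 10_000, critical=0.1)
        assert ext.crossing_distance_bp == pytest.approx(500.0)
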