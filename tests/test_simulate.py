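"""Synthetic-population generator: structure, Mendelian consistency,
heritability targeting and determinism."""

import numpy as np
import pandas as pd
import pytest

from hapgs import simulate as sm


class TestMarkerMap:
    def test_positions_strictly_increasing_within_chromosome(self):
        mm = sm.make_marker_map(1, 5, 1000, seed=1)
        pos = mm.position_bp.to_numpy()
        assert len(mm) == 5
        assert (np.diff(pos) > 0).all()
        assert pos.min() >= 1 and pos.max() <= 1000

    def test_equal_split_across_chromosomes(self):
        mm = sm.make_marker_map(11, 1100, 5 * 10**7, seed=7)
        counts = mm.chromosome.value_counts()
        assert (counts == 100).all()

    @pytest.mark.parametrize("args", [(2, 10, 5), (0, 5, 100), (3, 2, 100)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            sm.make_marker_map(*args, seed=0)


class TestPedigree:
    def test_full_sib_family_shares_both_parents(self):
        ped = sm.simulate_pedigree(1, 4, 0.0, 2, seed=3)
        prog = ped[ped.generation == 1]
        assert len(prog) == 4
        assert prog.sire_id.nunique() == 1 and prog.sire_id.iloc[0] != sm.UNKNOWN
        assert prog.dam_id.nunique() == 1

    def test_half_sib_fraction_and_totals(self):
        ped = sm.simulate_pedigree(65, 10, 0.5, 130, seed=9)
        prog = ped[ped.generation == 1]
        assert len(prog) == 650
        frac_unknown = (
            prog.groupby("family_id").sire_id.first() == sm.UNKNOWN
        ).mean()
        assert 0.35 < frac_unknown < 0.65

    def test_all_half_sib_when_fraction_one(self):
        ped = sm.simulate_pedigree(2, 3, 1.0, 4, seed=1)
        prog = ped[ped.generation == 1]
        assert (prog.sire_id == sm.UNKNOWN).all()
        assert len(prog) == 6

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError):
            sm.simulate_pedigree(2, 3, 0.5, 1, seed=1)


class TestGeneDrop:
    def test_no_recombination_copies_a_parental_haplotype(self):
        mm = sm.make_marker_map(1, 12, 10_000, seed=2)
        ped = sm.simulate_pedigree(2, 3, 0.0, 4, seed=2)
        spec = sm.make_founder_spec(mm, [(2, 5)], seed=2)
        ph = sm.drop_genotypes(ped, mm, spec, recomb_rate_per_bp=0.0, seed=5)
        idx = {iid: i for i, iid in enumerate(ph.ids)}
        for row in ped[ped.generation == 1].itertuples():
            child = ph.haplotypes[idx[row.individual_id]]
            sire = ph.haplotypes[idx[row.sire_id]]
            dam = ph.haplotypes[idx[row.dam_id]]
            assert any((child[0] == sire[k]).all() for k in range(2))
            assert any((child[1] == dam[k]).all() for k in range(2))

    def test_mendelian_consistency_all_trios(self):
        mm = sm.make_marker_map(2, 40, 100_000, seed=4)
        ped = sm.simulate_pedigree(6, 5, 0.0, 12, seed=4)
        spec = sm.make_founder_spec(mm, [(3, 7), (25, 28)], seed=4)
        ph = sm.drop_genotypes(ped, mm, spec, 1e-6, seed=6)
        dos = ph.dosage()
        idx = {iid: i for i, iid in enumerate(ph.ids)}
        for row in ped[ped.generation == 1].itertuples():
            c = dos[idx[row.individual_id]]
            s = dos[idx[row.sire_id]]
            d = dos[idx[row.dam_id]]
            # offspring dosage must be achievable from one allele per parent
            lo = (s > 1).astype(int) + (d > 1).astype(int)
            hi = 2 - ((s < 1).astype(int) + (d < 1).astype(int))
            assert ((c >= lo) & (c <= hi)).all()

    def test_planted_segment_has_founder_dprime_one(self):
        from conftest import planted_panel

        from hapgs import ld

        dos, mm, spec = planted_panel(200, seed=11)
        seg = spec.segments[0].marker_indices
        for a, b in [(seg[0], seg[1]), (seg[0], seg[-1])]:
            t = ld.em_two_locus(dos[:, a], dos[:, b])
            assert ld.ld_stats(t).Dprime == pytest.approx(1.0, abs=1e-6)

    def test_frequency_floor_enforced(self):
        mm = sm.make_marker_map(1, 10, 1000, seed=1)
        with pytest.raises(ValueError):
            sm.FounderHaplotypeSpec([], np.full(10, 0.01), mm)


class TestPhenotypes:
    def test_zero_heritability_rejected(self):
        mm = sm.make_marker_map(1, 10, 1000, seed=1)
        ped = sm.simulate_pedigree(2, 3, 0.0, 4, seed=1)
        spec = sm.make_founder_spec(mm, [], seed=1)
        ph = sm.drop_genotypes(ped, mm, spec, 0.0, seed=1)
        with pytest.raises(ValueError):
            sm.simulate_phenotypes(ph, ped, 5, 0.0, seed=1)

    def test_phenotype_regression_on_true_bv(self):
        sim = sm.simulate_study(n_markers=500, n_segments=0, n_qtl=100,
                                traits={"T": (0.4, None)}, seed=5)
        tr = sim["truth"].traits["T"]
        y = sim["phenotypes"]["T"].to_numpy(float)
        slope = np.polyfit(tr.true_breeding_values, y, 1)[0]
        assert 0.85 < slope < 1.15
        assert 0.3 < tr.realized_h2 < 0.5

    def test_heritability_targeting_over_replicates(self):
        realized = []
        for rep in range(20):
            sim = sm.simulate_study(
                n_markers=300, n_segments=0, n_qtl=60,
                traits={"T": (0.25, None)}, seed=300 + rep)
            realized.append(sim["truth"].traits["T"].realized_h2)
        assert abs(np.mean(realized) - 0.25) < 0.05

    def test_ordinal_categories_roughly_equiprobable(self):
        sim = sm.simulate_study(n_markers=300, n_segments=0, n_qtl=60,
                                traits={"ST": (0.3, 7)}, seed=6)
        counts = sim["phenotypes"]["ST"].value_counts(normalize=True)
        assert set(counts.index) <= set(range(7))
        assert counts.max() < 1 / 7 + 0.08

    def test_single_tree_plots(self):
        sim = sm.simulate_study(n_markers=200, n_segments=0, n_qtl=40,
                                traits={"T": (0.3, None)}, seed=8)
        phen = sim["phenotypes"].merge(sim["pedigree"], on="individual_id")
        dup = phen.groupby(["family_id", "design_block"]).size()
        assert (dup <= 1).all()


def test_seed_determinism_end_to_end():
    a = sm.simulate_study(n_markers=120, n_segments=4, n_qtl=20,
                          traits={"T": (0.3, None)}, seed=77)
    b = sm.simulate_study(n_markers=120, n_segments=4, n_qtl=20,
                          traits={"T": (0.3, None)}, seed=77)
    assert (a["phased"].haplotypes == b["phased"].haplotypes).all()
    pd.testing.assert_frame_equal(a["phenotypes"], b["phenotypes"])
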