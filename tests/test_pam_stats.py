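import numpy as np
import pytest

from genomepam import (
    CleavageSite,
    SiteTable,
    heatmap_matrix,
    pcv_table,
    weighted_pfm,
    wobble_comparison,
)
from genomepam.pam_stats import pam_window_slice
from genomepam.site_matching import FIVE_PRIME, THREE_PRIME

from .oracles import naive_chi_square


def site(start, flank3, reads=1, n_mm=0, flank5="A" * 10):
    return CleavageSite(
        chrom="c",
        start=start,
        end=start + 20,
        strand="+",
        aligned_seq="G" * 20,
        n_mismatch=n_mm,
        mismatch_positions=tuple(range(1, n_mm + 1)),
        flank5=flank5,
        flank3=flank3,
        read_count=reads,
    )


class TestWeightedPfm:
    def test_read_weighted_average(self):
        table = SiteTable([site(0, "AGG" + "C" * 7, reads=1), site(100, "TGG" + "C" * 7, reads=3)])
        pfm = weighted_pfm(table, "3p")
        # position 1: A weight 1, T weight 3
        assert pfm.matrix[0, 0] == pytest.approx(0.25)
        assert pfm.matrix[3, 0] == pytest.approx(0.75)
        assert np.allclose(pfm.matrix.sum(axis=0), 1.0)

    def test_site_mode_ignores_reads(self):
        table = SiteTable([site(0, "AGG" + "C" * 7, reads=1), site(100, "TGG" + "C" * 7, reads=99)])
        pfm = weighted_pfm(table, "3p", weight_mode="sites")
        assert pfm.matrix[0, 0] == pytest.approx(0.5)

    def test_equal_weights_match_unweighted(self):
        flanks = ["ACGTACGTAC", "TTGGCCAATT", "ACGTACGTAC"]
        table = SiteTable([site(i * 50, f, reads=7) for i, f in enumerate(flanks)])
        a = weighted_pfm(table, "3p", weight_mode="reads").matrix
        b = weighted_pfm(table, "3p", weight_mode="sites").matrix
        assert np.allclose(a, b)

    def test_identical_flanks_one_hot(self):
        table = SiteTable([site(0, "AGGTTTTTTT"), site(100, "AGGTTTTTTT", reads=4)])
        pfm = weighted_pfm(table, "3p")
        assert set(np.unique(pfm.matrix)) == {0.0, 1.0}
        assert pfm.information_content() == pytest.approx([2.0] * 10)

    def test_empty_stratum_error(self):
        table = SiteTable([site(0, "AGGTTTTTTT")])
        with pytest.raises(ValueError, match="mismatch"):
            weighted_pfm(table, "3p", stratum="mismatch")


class TestPcv:
    def test_identity_when_capture_equals_background(self):
        flanks = ["AAGGGGGGGG", "ACGGGGGGGG", "AGGGGGGGGG", "ATGGGGGGGG"]
        table = SiteTable([site(i * 40, f) for i, f in enumerate(flanks)])
        bg = [f[:2] for f in flanks]
        pcv = pcv_table(table, bg, L=2, orientation="3p")
        assert np.allclose(pcv.table["pcv"], 1.0)
        assert np.allclose(pcv.table["relative_pcv"], 0.0)

    def test_hand_arithmetic(self):
        # captured AG 75% / AA 25%; background uniform over {AA, AG, CA, GT}
        table = SiteTable(
            [site(0, "AG" + "G" * 8, reads=3), site(50, "AA" + "G" * 8, reads=1)]
        )
        bg = ["AA", "AG", "CA", "GT"]
        pcv = pcv_table(table, bg, L=2, orientation="3p")
        assert pcv.pcv("AG") == pytest.approx(3.0)
        assert pcv.pcv("AA") == pytest.approx(1.0)
        rel = pcv.table.set_index("pam")["relative_pcv"]
        assert rel["AG"] == pytest.approx(0.0)
        assert rel["AA"] == pytest.approx(np.log2(1 / 3))

    def test_relative_pcv_halving(self):
        table = SiteTable(
            [site(0, "AG" + "G" * 8, reads=2), site(50, "AA" + "G" * 8, reads=1)]
        )
        pcv = pcv_table(table, ["AG", "AA"], L=2)
        assert pcv.table.set_index("pam")["relative_pcv"]["AA"] == pytest.approx(-1.0)

    def test_normalization_invariants(self, ngg_run):
        _, _, _, sites, templates = ngg_run
        bg = [t.flank3[:3] for t in templates]
        pcv = pcv_table(sites, bg, L=3, orientation="3p")
        df = pcv.table
        assert df["captured_fraction"].sum() == pytest.approx(1.0)
        assert df["background_fraction"].sum() == pytest.approx(1.0)
        defined = df.dropna(subset=["pcv"])
        weighted_mean = (defined["background_fraction"] * defined["pcv"]).sum()
        assert weighted_mean == pytest.approx(1.0, abs=1e-6)
        assert defined["relative_pcv"].max() == pytest.approx(0.0)

    def test_scale_invariance_in_read_counts(self):
        flanks = ["AG" + "G" * 8, "AA" + "G" * 8, "CT" + "G" * 8]
        t1 = SiteTable([site(i * 40, f, reads=r) for i, (f, r) in enumerate(zip(flanks, [5, 2, 3]))])
        t2 = SiteTable([site(i * 40, f, reads=10 * r) for i, (f, r) in enumerate(zip(flanks, [5, 2, 3]))])
        bg = ["AG", "AA", "CT", "GG"]
        a = pcv_table(t1, bg, L=2).table["pcv"]
        b = pcv_table(t2, bg, L=2).table["pcv"]
        assert np.allclose(a.fillna(-1), b.fillna(-1))

    def test_background_absent_pam_undefined(self):
        table = SiteTable([site(0, "TT" + "G" * 8)])
        pcv = pcv_table(table, ["AA", "AG"], L=2)
        row = pcv.table.set_index("pam").loc["TT"]
        assert np.isnan(row["pcv"])

    def test_planted_model_recovery_top_pcv(self, ngg_run):
        # with planted NGG activity, the top 3-mer PCVs are exactly the NGG set
        _, _, _, sites, templates = ngg_run
        bg = [t.flank3[:3] for t in templates]
        pcv = pcv_table(sites, bg, L=3, orientation="3p")
        top4 = pcv.top_pams(4)
        assert sorted(top4) == ["AGG", "CGG", "GGG", "TGG"]

    def test_five_prime_window_slice(self):
        # 5' PAM positions count toward the spacer-proximal end of flank5
        flank = "ABCDEFGHIJ"
        assert pam_window_slice(flank, 4, 0, FIVE_PRIME) == "GHIJ"
        assert pam_window_slice(flank, 3, 2, FIVE_PRIME) == "FGH"
        assert pam_window_slice(flank, 4, 0, THREE_PRIME) == "ABCD"
        assert pam_window_slice(flank, 2, 3, THREE_PRIME) == "DE"


class TestHeatmap:
    def test_uniform_grid_zero(self):
        flanks = [a + b + c + d + "G" * 6 for a in "ACGT" for b in "A" for c in "A" for d in "A"]
        table = SiteTable([site(i * 40, f) for i, f in enumerate(flanks)])
        bg = [f[:4] for f in flanks]
        grid = heatmap_matrix(pcv_table(table, bg, L=4))
        vals = grid.to_numpy()
        assert np.allclose(vals[np.isfinite(vals)], 0.0)

    def test_dominant_pam_structure(self):
        sites_ = [site(0, "AGGT" + "G" * 6, reads=96)]
        sites_ += [site(40 * (i + 1), p + "G" * 6, reads=1)
                   for i, p in enumerate(["CCAA", "TTCC", "GACT"])]
        table = SiteTable(sites_)
        bg = ["AGGT", "CCAA", "TTCC", "GACT"]
        grid = heatmap_matrix(pcv_table(table, bg, L=4))
        assert grid.loc["AG", "GT"] == pytest.approx(0.0)
        finite = grid.stack()
        assert (finite[finite.index != ("AG", "GT")] < 0).all()

    def test_round_trips_flat_table(self):
        flanks = ["AGGT" + "G" * 6, "CCAA" + "G" * 6]
        table = SiteTable([site(i * 40, f, reads=i + 1) for i, f in enumerate(flanks)])
        pcv = pcv_table(table, [f[:4] for f in flanks], L=4)
        grid = heatmap_matrix(pcv)
        for row in pcv.table.dropna(subset=["pcv"]).itertuples(index=False):
            if np.isfinite(row.relative_pcv):
                assert grid.loc[row.pam[:2], row.pam[2:]] == pytest.approx(row.relative_pcv)

    def test_requires_len_four(self):
        table = SiteTable([site(0, "AG" + "G" * 8)])
        with pytest.raises(ValueError, match="4-base"):
            heatmap_matrix(pcv_table(table, ["AG"], L=2))


class TestWobble:
    def test_identical_strata_p_near_one(self):
        rows = [site(i * 40, "AGG" + "C" * 7, n_mm=0) for i in range(10)]
        rows += [site(1000 + i * 40, "AGG" + "C" * 7, n_mm=2) for i in range(10)]
        out = wobble_comparison(SiteTable(rows), position=2, base="G")
        assert out["perfect_frac"] == out["mismatch_frac"] == 1.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_enriched_base_detected_and_matches_oracle(self):
        rows = [site(i * 40, ("G" if i < 10 else "A") + "GG" + "C" * 7, n_mm=0)
                for i in range(100)]
        rows += [site(10_000 + i * 40, ("G" if i < 60 else "A") + "GG" + "C" * 7, n_mm=1)
                 for i in range(100)]
        out = wobble_comparison(SiteTable(rows), position=1, base="G")
        assert out["perfect_frac"] == pytest.approx(0.10)
        assert out["mismatch_frac"] == pytest.approx(0.60)
        assert out["p_value"] < 0.01
        stat, p, _ = naive_chi_square([[10, 90], [60, 40]])
        assert out["chi2"] == pytest.approx(stat)
        assert out["p_value"] == pytest.approx(p)

    def test_single_stratum_error(self):
        rows = [site(i * 40, "AGG" + "C" * 7, n_mm=0) for i in range(5)]
        with pytest.raises(ValueError, match="mismatch"):
            wobble_comparison(SiteTable(rows), position=2, base="G")
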