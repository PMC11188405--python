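"""The interval-mapping / CIM engine, permutation thresholds, peak calling."""

import numpy as np
import pandas as pd
import pytest

from sysgen import (PlantedTraitQTL, ScanProfile, SimConfig, build_grid,
                    call_peaks, cim_scan, interval_mapping_scan,
                    permutation_threshold, select_cofactors, simulate_study)
from sysgen.genmap import expected_genotype_matrix


def single_marker_lod(y, g):
    """Independent oracle: two-group regression LOD at one observed marker."""
    n = len(y)
    rss0 = np.sum((y - y.mean()) ** 2)
    resid = y.copy().astype(float)
    for cls in (0.0, 1.0):
        sel = g == cls
        resid[sel] = y[sel] - y[sel].mean()
    rss1 = np.sum(resid ** 2)
    return (n / 2.0) * np.log10(rss0 / rss1)


@pytest.fixture(scope="module")
def qtl_study():
    cfg = SimConfig(n_lines=200, n_transcripts=10, seed=21,
                    trait_qtl=(PlantedTraitQTL("A02_m025", 0.2),),
                    expression_scale="log2")
    geno, gmap, expr, traits, truth = simulate_study(cfg)
    grid = build_grid(gmap, step=1.0)
    return geno, gmap, traits["trait"].to_numpy(), grid


class TestIntervalMapping:
    def test_matches_single_marker_oracle_at_markers(self, qtl_study):
        geno, gmap, y, grid = qtl_study
        profile = interval_mapping_scan(y, geno, grid)
        markers = grid.positions[grid.positions["is_marker"]]
        for k in markers.index[::7]:
            j = markers.at[k, "left_idx"]
            oracle = single_marker_lod(y, geno.values[:, j])
            assert profile.table.at[k, "lod"] == pytest.approx(oracle, abs=1e-8)

    def test_lod_invariant_under_affine_trait_transform(self, qtl_study):
        geno, _, y, grid = qtl_study
        base = interval_mapping_scan(y, geno, grid).table["lod"]
        scaled = interval_mapping_scan(3.7 * y - 11.0, geno, grid).table["lod"]
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_perfectly_determined_trait_guarded(self, qtl_study):
        geno, _, _, grid = qtl_study
        y = geno.values[:, 30].copy()            # trait == marker code
        with pytest.warns(UserWarning, match="capped"):
            profile = interval_mapping_scan(y, geno, grid)
        assert profile.saturated
        k = int(profile.table["lod"].idxmax())
        assert profile.table.at[k, "r2"] == pytest.approx(1.0)
        assert np.isfinite(profile.table["lod"]).all()

    def test_zero_variance_trait_rejected(self, qtl_study):
        geno, _, _, grid = qtl_study
        with pytest.raises(ValueError, match="zero-variance"):
            interval_mapping_scan(np.ones(geno.n_lines), geno, grid)

    def test_additive_effect_sign_reports_allele_source(self, qtl_study):
        geno, gmap, y, grid = qtl_study
        profile = interval_mapping_scan(y, geno, grid)
        k = int(profile.table["lod"].idxmax())
        # planted driver raises the trait with the class-1 allele
        j = gmap.marker_index("A02_m025")
        g = geno.values[:, j]
        direction = np.sign(y[g == 1].mean() - y[g == 0].mean())
        assert np.sign(profile.table.at[k, "additive"]) == direction


class TestCofactorsAndCIM:
    def test_zero_max_cofactors_is_empty(self, qtl_study):
        geno, _, y, _ = qtl_study
        assert select_cofactors(y, geno, 0) == []

    def test_null_trait_selects_nothing_usually(self, qtl_study):
        geno, *_ = qtl_study
        rng = np.random.default_rng(5)
        empty = sum(len(select_cofactors(rng.standard_normal(geno.n_lines),
                                         geno, 5)) == 0 for _ in range(20))
        assert empty >= 18   # BIC admits no marker in >= 90% of null traits

    def test_planted_marker_recovered_first(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_lines=200, n_transcripts=5, seed=100 + seed,
                            trait_qtl=(PlantedTraitQTL("A01_m020", 0.5),),
                            expression_scale="log2")
            geno, gmap, _, traits, _ = simulate_study(cfg)
            cof = select_cofactors(traits["trait"].to_numpy(), geno, 5)
            assert cof, "selection returned nothing for a strong planted QTL"
            j = gmap.marker_index(cof[0])
            row = gmap.table.iloc[j]
            truth = gmap.table.iloc[gmap.marker_index("A01_m020")]
            if row["chrom"] == truth["chrom"] and abs(row["cM"] - truth["cM"]) <= 5:
                hits += 1
        assert hits >= 19    # first pick on/near the causal marker in >= 95%

    def test_empty_cofactors_reduces_to_im(self, qtl_study):
        geno, _, y, grid = qtl_study
        im = interval_mapping_scan(y, geno, grid).table
        cim = cim_scan(y, geno, grid, cofactors=(), window=10.0).table
        pd.testing.assert_frame_equal(im, cim)

    def test_window_protects_local_signal(self, qtl_study):
        geno, _, y, grid = qtl_study
        cof = ["A02_m025"]           # cofactor placed exactly on the QTL
        truth_pos = (grid.positions["chrom"] == "A02") & (grid.positions["cM"] == 50.0)
        k = grid.positions.index[truth_pos][0]
        with_window = cim_scan(y, geno, grid, cof, window=10.0).table.at[k, "lod"]
        without = cim_scan(y, geno, grid, cof, window=0.0).table.at[k, "lod"]
        assert with_window >= without
        assert with_window > 5.0     # planted R2=0.2, n=200: strong signal survives

    def test_cim_resolves_linked_qtl_pair(self):
        resolved = 0
        n_sims = 25
        for seed in range(n_sims):
            cfg = SimConfig(n_lines=200, n_transcripts=5, seed=300 + seed,
                            trait_qtl=(PlantedTraitQTL("A01_m010", 0.15),
                                       PlantedTraitQTL("A01_m040", 0.15)),
                            expression_scale="log2")
            geno, gmap, _, traits, _ = simulate_study(cfg)
            grid = build_grid(gmap, step=1.0)
            y = traits["trait"].to_numpy()
            cof = select_cofactors(y, geno, 5)
            profile = cim_scan(y, geno, grid, cof, window=10.0)
            thr = permutation_threshold(y, geno, grid, 100, 0.05, seed=seed,
                                        cofactors=cof, window=10.0)
            peaks = call_peaks(profile, thr.threshold, 10.0)
            found = {round(p.peak_cM / 10) for p in peaks if p.chrom == "A01"
                     if min(abs(p.peak_cM - 20), abs(p.peak_cM - 80)) <= 10}
            if len([p for p in peaks if p.chrom == "A01"
                    and abs(p.peak_cM - 20) <= 10]) >= 1 and \
               len([p for p in peaks if p.chrom == "A01"
                    and abs(p.peak_cM - 80) <= 10]) >= 1:
                resolved += 1
        assert resolved >= 0.8 * n_sims


class TestPermutationThreshold:
    def test_deterministic_under_seed(self, qtl_study):
        geno, _, y, grid = qtl_study
        a = permutation_threshold(y, geno, grid, 50, 0.05, seed=42)
        b = permutation_threshold(y, geno, grid, 50, 0.05, seed=42)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.maxima, b.maxima)

    def test_alpha_one_gives_min_of_maxima(self, qtl_study):
        geno, _, y, grid = qtl_study
        t = permutation_threshold(y, geno, grid, 50, 1.0, seed=1)
        assert t.threshold == pytest.approx(t.maxima.min())

    def test_refuses_unstable_quantile(self, qtl_study):
        geno, _, y, grid = qtl_study
        with pytest.raises(ValueError):
            permutation_threshold(y, geno, grid, 10, 0.05, seed=1)

    def test_threshold_monotone_in_alpha(self, qtl_study):
        geno, _, y, grid = qtl_study
        t10 = permutation_threshold(y, geno, grid, 100, 0.10, seed=3).threshold
        t05 = permutation_threshold(y, geno, grid, 100, 0.05, seed=3).threshold
        t01 = permutation_threshold(y, geno, grid, 100, 0.01, seed=3).threshold
        assert t10 <= t05 <= t01

    def test_maxima_grow_with_marker_count(self):
        """More independent tests -> stochastically larger genome-wide maxima."""
        meds = {}
        for spacing, key in ((8.0, "sparse"), (1.0, "dense")):
            cfg = SimConfig(n_lines=150, n_transcripts=5, seed=9,
                            marker_spacing_cM=spacing, expression_scale="log2")
            geno, gmap, _, traits, _ = simulate_study(cfg)
            grid = build_grid(gmap, step=2.0)
            t = permutation_threshold(traits["trait"].to_numpy(), geno, grid,
                                      200, 0.05, seed=4)
            meds[key] = np.median(t.maxima)
        assert meds["dense"] > meds["sparse"]


class TestCallPeaks:
    def _profile(self, chrom, cm, lod):
        tab = pd.DataFrame({"chrom": chrom, "cM": cm, "lod": lod,
                            "r2": 0.1, "additive": 0.5})
        return ScanProfile(tab, "t", 100)

    def test_flat_profile_below_threshold(self):
        p = self._profile(["1"] * 5, np.arange(5.0), np.full(5, 1.0))
        assert call_peaks(p, threshold=3.0) == []

    def test_two_maxima_within_radius_merge_to_higher(self):
        cm = np.arange(0.0, 21.0)
        lod = np.where(cm == 6, 5.0, np.where(cm == 14, 6.0, 3.5))
        p = self._profile(["1"] * len(cm), cm, lod)
        peaks = call_peaks(p, threshold=4.0, merge_radius=10.0)
        assert len(peaks) == 1
        assert peaks[0].peak_cM == 14.0

    def test_equal_lod_tie_breaks_to_lower_cM(self):
        cm = np.arange(0.0, 21.0)
        lod = np.where((cm == 6) | (cm == 14), 5.0, 3.0)
        peaks = call_peaks(self._profile(["1"] * len(cm), cm, lod),
                           threshold=4.0, merge_radius=10.0)
        assert [p.peak_cM for p in peaks] == [6.0]

    def test_support_interval_contains_peak_and_drop(self):
        cm = np.arange(0.0, 31.0)
        lod = 8.0 - 0.5 * np.abs(cm - 15)
        peaks = call_peaks(self._profile(["1"] * len(cm), cm, lod), threshold=4.0)
        (pk,) = peaks
        assert pk.ci_lo <= pk.peak_cM <= pk.ci_hi
        # 1.5-LOD drop at 0.5/cM slope: interval reaches just inside +-3 cM
        assert pk.ci_lo == 13.0 and pk.ci_hi == 17.0

    def test_planted_qtl_recovery_interval_covers_truth(self):
        covered = 0
        n_sims = 20
        for seed in range(n_sims):
            cfg = SimConfig(n_lines=200, n_transcripts=5, seed=500 + seed,
                            trait_qtl=(PlantedTraitQTL("A02_m025", 0.2),),
                            expression_scale="log2")
            geno, gmap, _, traits, _ = simulate_study(cfg)
            grid = build_grid(gmap, step=1.0)
            y = traits["trait"].to_numpy()
            cof = select_cofactors(y, geno, 5)
            profile = cim_scan(y, geno, grid, cof, window=10.0)
            thr = permutation_threshold(y, geno, grid, 100, 0.05, seed=seed,
                                        cofactors=cof, window=10.0)
            peaks = [p for p in call_peaks(profile, thr.threshold, 10.0)
                     if p.chrom == "A02"]
            if any(p.ci_lo - 2 <= 50.0 <= p.ci_hi + 2 for p in peaks):
                covered += 1
        assert covered >= 0.9 * n_sims

    def test_physical_interval_interpolated(self, toy_map):
        cm = np.arange(0.0, 41.0)
        lod = 8.0 - 0.5 * np.abs(cm - 10)
        peaks = call_peaks(self._profile(["A09"] * len(cm), cm, lod),
                           threshold=4.0, gmap=toy_map)
        (pk,) = peaks
        assert pk.bp_lo == toy_map.interpolate_bp("A09", pk.ci_lo)
        assert pk.bp_hi == toy_map.interpolate_bp("A09", pk.ci_hi)
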