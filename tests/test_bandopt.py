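import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lwcspec import indices as idx
from lwcspec.bandopt import (
    FEATURE_KINDS,
    FeatureComponents,
    MIN_VALID,
    assemble_features,
    corr_1d,
    corr_map_2d,
    corr_search_3d,
    critical_r,
    order_scan,
    pearson_r,
    permutation_screen,
)
from lwcspec.fod import fod_stack
from lwcspec.spectra import SpectraSet, SpectraError, TraitVector
from lwcspec.synth import SyntheticConfig, make_dataset


def _oracle_pearson(x, y):
    """From-scratch covariance/sigma definition with pairwise deletion."""
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = np.asarray(x, float)[keep], np.asarray(y, float)[keep]
    if x.size < MIN_VALID or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, x.size
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))), x.size


def _oracle_best_2d(s, t, form):
    best = None
    ws = s.wavelengths
    for i in range(ws.size):
        for j in range(ws.size):
            if i == j:
                continue
            iv = idx.two_band_index(s, form, ws[i], ws[j])
            vals = np.where(iv.valid, iv.values, np.nan)
            r, n = _oracle_pearson(vals, t.values)
            if np.isnan(r):
                continue
            if best is None or abs(r) > abs(best[2]) + 1e-12:
                best = ((ws[i], ws[j]), n, r)
    return best


def _oracle_best_3d(s, t, form):
    best = None
    ws = s.wavelengths
    for i in range(ws.size):
        for j in range(ws.size):
            for k in range(ws.size):
                if len({i, j, k}) != 3:
                    continue
                iv = idx.three_band_index(s, form, ws[i], ws[j], ws[k])
                vals = np.where(iv.valid, iv.values, np.nan)
                r, n = _oracle_pearson(vals, t.values)
                if np.isnan(r):
                    continue
                if best is None or abs(r) > abs(best[2]) + 1e-12:
                    best = ((ws[i], ws[j], ws[k]), n, r)
    return best


@pytest.fixture
def bench(rng):
    """12 samples on a 10-band grid plus a correlated trait."""
    wl = np.arange(800, 810)
    vals = 0.1 + 0.8 * rng.random((12, wl.size))
    s = SpectraSet(wl, vals, tuple(f"s{i}" for i in range(12)))
    t = TraitVector(s.sample_ids, 70 + 10 * rng.random(12))
    return s, t


class TestPearsonAndCritical:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 2, 4])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_critical_r_small_sample(self):
        assert critical_r(0.05, 4) == pytest.approx(0.950, abs=1e-3)

    def test_critical_r_limits(self):
        assert critical_r(0.999, 30) < 0.01
        assert critical_r(1e-6, 30) > 0.7

    def test_critical_r_consistent_with_t_test(self):
        # at the threshold, the two-sided t-test p-value equals alpha
        n, alpha = 154, 0.01
        r = critical_r(alpha, n)
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        assert 2 * stats.t.sf(tstat, n - 2) == pytest.approx(alpha, rel=1e-9)
        # reported critical value 0.201 corresponds to n ~ 165, not 154
        assert critical_r(0.01, 154) == pytest.approx(0.207, abs=1e-3)
        assert critical_r(0.01, 165) == pytest.approx(0.200, abs=1e-3)

    def test_critical_r_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            critical_r(0.01, 3)


class TestCorr1D:
    def test_self_correlation_peaks_at_own_band(self, toy_set):
        t = TraitVector(toy_set.sample_ids, toy_set.band(707))
        tab = corr_1d(toy_set, t)
        row = tab[tab.wavelength == 707].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.significant

    def test_screen_nested_across_levels(self, small_trimmed):
        s, t = small_trimmed
        sig01 = set(corr_1d(s, t, alpha=0.01).query("significant").wavelength)
        sig05 = set(corr_1d(s, t, alpha=0.05).query("significant").wavelength)
        assert sig01 <= sig05

    def test_planted_absorption_peak_recovered(self):
        cfg = SyntheticConfig(
            n=154,
            seed=11,
            absorption_centers=(970.0,),
            absorption_widths=(10.0,),
            absorption_base_depths=(0.10,),
            absorption_depth_slopes=(0.12,),
            amplitude_slope=0.0,
            structural_sd=0.0,
            noise_sd=0.008,
        )
        ds = make_dataset(cfg)
        tab = corr_1d(ds.spectra, ds.trait)
        peak = tab.loc[tab.r.abs().idxmax(), "wavelength"]
        assert abs(peak - 970) <= 5

    def test_order_scan_layout(self, small_trimmed):
        s, t = small_trimmed
        stack = fod_stack(s, [0.0, 0.8])
        tab = order_scan(stack, t)
        assert list(tab.columns) == ["order", "max_abs_r", "best_wavelength", "n_significant"]
        assert len(tab) == 2


class TestMap2D:
    @pytest.mark.parametrize("form", ["RVI", "NDVI", "DVI"])
    def test_matches_brute_force_oracle(self, bench, form):
        s, t = bench
        cmap, best = corr_map_2d(s, t, form)
        oracle = _oracle_best_2d(s, t, form)
        ws = s.wavelengths
        for i in range(ws.size):
            for j in range(ws.size):
                if i == j:
                    assert np.isnan(cmap.r[i, j])
                    continue
                iv = idx.two_band_index(s, form, ws[i], ws[j])
                r, n = _oracle_pearson(np.where(iv.valid, iv.values, np.nan), t.values)
                if np.isnan(r):
                    assert np.isnan(cmap.r[i, j])
                else:
                    assert cmap.r[i, j] == pytest.approx(r, abs=1e-12)
        assert best.wavelengths == oracle[0]
        assert best.r == pytest.approx(oracle[2], abs=1e-12)

    def test_dvi_map_antisymmetric(self, bench):
        s, t = bench
        cmap, _ = corr_map_2d(s, t, "DVI")
        off = ~np.eye(cmap.r.shape[0], dtype=bool)
        assert np.allclose(cmap.r[off], -cmap.r.T[off], atol=1e-12)

    def test_tie_break_prefers_lexicographic_pair(self, rng):
        # duplicated columns create exact |r| ties
        wl = np.arange(800, 806)
        base = 0.2 + 0.6 * rng.random((15, 3))
        vals = np.column_stack([base[:, 0], base[:, 1], base[:, 0], base[:, 2], base[:, 1], base[:, 2]])
        s = SpectraSet(wl, vals, tuple(f"s{i}" for i in range(15)))
        t = TraitVector(s.sample_ids, 70 + 10 * rng.random(15))
        for form in ("DVI", "NDVI", "RVI"):
            _, best = corr_map_2d(s, t, form)
            oracle = _oracle_best_2d(s, t, form)
            assert best.wavelengths == oracle[0]

    def test_invariance_to_sample_order_and_trait_scale(self, bench, rng):
        s, t = bench
        _, best = corr_map_2d(s, t, "DVI")
        perm = rng.permutation(s.n_samples)
        ids = tuple(s.sample_ids[i] for i in perm)
        s2 = s.subset(ids)
        t2 = TraitVector(ids, 3.0 * t.subset(ids).values - 40.0)
        _, best2 = corr_map_2d(s2, t2, "DVI")
        assert best2.wavelengths == best.wavelengths
        assert best2.r == pytest.approx(best.r, abs=1e-12)

    def test_stride_and_range_restrict_grid(self, bench):
        s, t = bench
        cmap, _ = corr_map_2d(s, t, "DVI", band_range=(800, 808), stride=2)
        assert np.array_equal(cmap.axes[0], [800, 802, 804, 806, 808])

    def test_map_long_export(self, bench):
        s, t = bench
        cmap, _ = corr_map_2d(s, t, "DVI")
        df = cmap.to_frame()
        assert set(df.columns) == {"lambda1", "lambda2", "r", "n_valid"}
        assert len(df) == s.n_bands * (s.n_bands - 1)


class TestSearch3D:
    @pytest.mark.parametrize("form", idx.THREE_BAND_FORMS)
    def test_matches_brute_force_oracle(self, rng, form):
        wl = np.arange(900, 908)
        vals = 0.1 + 0.8 * rng.random((14, wl.size))
        s = SpectraSet(wl, vals, tuple(f"s{i}" for i in range(14)))
        t = TraitVector(s.sample_ids, 70 + 10 * rng.random(14))
        best, _ = corr_search_3d(s, t, form, band_range=None, stride=1, refine=False)
        oracle = _oracle_best_3d(s, t, form)
        assert best.wavelengths == oracle[0]
        assert best.r == pytest.approx(oracle[2], abs=1e-12)

    def test_stride_larger_than_range_is_error(self, bench):
        s, t = bench
        with pytest.raises(SpectraError, match="no valid triples"):
            corr_search_3d(s, t, "3BI-7", band_range=(800, 809), stride=50)

    def test_kept_map_matches_best(self, bench):
        s, t = bench
        best, cmap = corr_search_3d(
            s, t, "3BI-7", band_range=None, stride=1, refine=False, keep_map=True
        )
        flat = np.nanmax(np.abs(cmap.r))
        assert abs(best.r) == pytest.approx(flat, abs=1e-12)


class TestPermutationScreen:
    def test_null_calibration_on_independent_bands(self):
        rng = np.random.default_rng(42)
        n, B, P = 120, 400, 250
        s = SpectraSet(
            np.arange(500, 500 + B),
            rng.standard_normal((n, B)),
            tuple(f"s{i}" for i in range(n)),
        )
        t = TraitVector(s.sample_ids, 70 + 5 * rng.standard_normal(n))
        alpha = 0.01
        fractions = permutation_screen(s, t, alpha=alpha, n_perm=P, seed=1)
        sigma = np.sqrt(alpha * (1 - alpha) / (P * B))
        assert abs(fractions.mean() - alpha) < 3 * sigma


class TestAssembleFeatures:
    @pytest.fixture
    def components(self, small_trimmed):
        from lwcspec.bandopt import BandCombo
        from lwcspec.fod import gl_derivative_set

        s, t = small_trimmed
        fod_s = gl_derivative_set(s, 0.8)
        return FeatureComponents(
            raw=s,
            fod=fod_s,
            fod_order=0.8,
            sensitive_raw=(800.0, 850.0, 900.0),
            sensitive_fod=(750.0, 800.0),
            best_2bi_raw={
                f: BandCombo(f, (700.0, 1200.0), 0.5, s.n_samples)
                for f in ("DVI", "RVI", "NDVI")
            },
            best_2bi_fod={
                f: BandCombo(f, (720.0, 1100.0), 0.4, s.n_samples)
                for f in ("DVI", "RVI", "NDVI")
            },
            best_3bi={
                f: BandCombo(f, (900.0, 850.0, 450.0), 0.3 + 0.01 * i, s.n_samples)
                for i, f in enumerate(idx.THREE_BAND_FORMS)
            },
        )

    def test_column_counts_per_kind(self, components):
        expected = {
            "Raw-sensitive-bands": 3,
            "R-FOD": 2,
            "MIs": 12,
            "2BI": 3,
            "FWBI-2BI": 2,
            "2BI-FOD": 3,
            "FWBI-2BI-FOD": 2,
            "3BI-0.8": 7,
            "FWBI-3BI-0.8": 2,
        }
        for kind in FEATURE_KINDS:
            X = assemble_features(kind, components)
            assert X.shape == (components.raw.n_samples, expected[kind]), kind
            assert list(X.index) == list(components.raw.sample_ids)

    def test_fwbi_3bi_uses_best_form(self, components):
        X = assemble_features("FWBI-3BI-0.8", components)
        # highest |r| was given to 3BI-7
        assert any("3BI-7" in c for c in X.columns)
        assert X.columns[0] == "FWBI"

    def test_missing_prerequisite_named(self, components):
        components.best_3bi = None
        with pytest.raises(ValueError, match="3-D search"):
            assemble_features("3BI-0.8", components)

    def test_unknown_kind_rejected(self, components):
        with pytest.raises(ValueError, match="unknown feature kind"):
            assemble_features("bogus", components)
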