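"""Correlation-based band optimization against a trait.

One-dimensional screening correlates every band with the trait and flags
bands whose |r| exceeds the two-tailed critical value at a chosen level.
Two- and three-dimensional searches exhaustively evaluate an index form over
all ordered wavelength tuples on a (possibly strided) grid and return the
combination maximizing |Pearson r|, with ties broken by the
lexicographically smallest wavelength tuple.  Invalid index values
(degenerate denominators) are handled by pairwise deletion; combinations
with fewer than MIN_VALID usable samples are excluded.

Three-dimensional maps are streamed: only the running best (and the full
map, if explicitly requested on a small grid) is retained.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectraSet, TraitVector, SpectraError, align
from . import indices as idx
from .indices import TWO_BAND_FORMS, THREE_BAND_FORMS
from .fod import FODStack

__all__ = [
    "MIN_VALID",
    "CorrelationMap",
    "BandCombo",
    "FeatureComponents",
    "FEATURE_KINDS",
    "pearson_r",
    "critical_r",
    "corr_1d",
    "order_scan",
    "corr_map_2d",
    "corr_search_3d",
    "permutation_screen",
    "assemble_features",
]

#: Minimum number of valid paired samples for a combination to count.
MIN_VALID = 10

#: |r| differences below this are treated as exact ties (resolved in favour
#: of the lexicographically smallest wavelength tuple).  Some forms have
#: structural ties: e.g. the fourth and seventh three-band forms are affine
#: in each other under swapping the last two bands, so |r| coincides exactly.
TIE_TOL = 1e-12

_VAR_FLOOR = 1e-300  # guards 0/0 for constant columns


class ConstantInputError(ValueError):
    """Correlation undefined because one input is constant."""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with pairwise deletion of non-finite pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired finite values, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom <= 0.0:
        raise ConstantInputError("correlation undefined for a constant input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def critical_r(alpha: float, n: int) -> float:
    """Two-tailed critical |r| at level ``alpha`` for sample size ``n``.

    Derived from the t distribution with n-2 degrees of freedom:
    r_crit = t / sqrt(t^2 + n - 2).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n = int(n)
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def _pearson_cols(
    M: np.ndarray, y: np.ndarray, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson r of matrix ``M`` (n, B) with vector ``y`` (n,).

    ``valid`` marks usable entries per column (pairwise deletion).  Columns
    with fewer than MIN_VALID valid samples or a constant input get NaN.
    Returns (r, n_valid).
    """
    n, B = M.shape
    if valid is None:
        valid = np.isfinite(M)
    elif valid.shape != M.shape:
        valid = np.broadcast_to(valid, M.shape)
    valid = valid & np.isfinite(M)
    if valid.all():
        nv = np.full(B, n)
        xc = M - M.mean(axis=0)
        yc = y - y.mean()
        sxy = yc @ xc
        sxx = np.einsum("ij,ij->j", xc, xc)
        syy = float(yc @ yc)
        denom = np.sqrt(sxx * syy)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > _VAR_FLOOR, sxy / np.maximum(denom, _VAR_FLOOR), np.nan)
    elif not valid.any():
        return np.full(B, np.nan), np.zeros(B, dtype=int)
    else:
        # Pre-centering by the global means keeps the one-pass column sums
        # well conditioned; Pearson r is shift-invariant so the result is
        # unchanged (per-column means of the shifted data are still removed).
        M = M - np.nanmean(np.where(valid, M, np.nan))
        y = y - y.mean()
        Mv = np.where(valid, M, 0.0)
        nv = valid.sum(axis=0)
        yv = valid * y[:, None]
        sx = Mv.sum(axis=0)
        sy = yv.sum(axis=0)
        sxx = np.einsum("ij,ij->j", Mv, Mv)
        syy = np.einsum("ij,ij->j", yv, yv)
        sxy = np.einsum("ij,ij->j", Mv, yv)
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.maximum(nv, 1)
            cxy = sxy - sx * sy / nn
            cxx = sxx - sx * sx / nn
            cyy = syy - sy * sy / nn
            denom = np.sqrt(np.maximum(cxx, 0.0) * np.maximum(cyy, 0.0))
            r = np.where(
                (nv >= MIN_VALID) & (denom > _VAR_FLOOR),
                cxy / np.maximum(denom, _VAR_FLOOR),
                np.nan,
            )
    r = np.clip(r, -1.0, 1.0)
    bad = nv < MIN_VALID
    if bad.any():
        r = np.where(bad, np.nan, r)
    return r, nv


@dataclass(frozen=True)
class CorrelationMap:
    """Correlation per band combination on a (strided) wavelength grid.

    ``r`` has one axis per free wavelength; undefined combinations are NaN.
    """

    form_id: str
    axes: tuple[np.ndarray, ...]
    r: np.ndarray
    n_valid: np.ndarray
    order: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long table lambda1, lambda2[, lambda3], r, n_valid (defined combos)."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        keep = np.isfinite(self.r)
        data = {f"lambda{i + 1}": m[keep] for i, m in enumerate(mesh)}
        data["r"] = self.r[keep]
        data["n_valid"] = self.n_valid[keep]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class BandCombo:
    """An index form, its wavelengths and the achieved trait correlation."""

    form_id: str
    wavelengths: tuple[float, ...]
    r: float
    n_valid: int
    significant: bool | None = None
    order: float | None = None

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def _strided_grid(
    s: SpectraSet, band_range: tuple[float, float] | None, stride: int
) -> np.ndarray:
    stride = int(stride)
    if stride < 1:
        raise ValueError(f"stride must be >= 1 nm, got {stride}")
    wl = s.wavelengths
    if band_range is not None:
        lo, hi = band_range
        wl = wl[(wl >= lo) & (wl <= hi)]
        if wl.size == 0:
            raise SpectraError(f"no grid wavelengths within {lo}-{hi} nm")
        anchor = lo
    else:
        anchor = wl[0]
    keep = np.isclose(np.mod(wl - anchor, stride), 0)
    return wl[keep]


def corr_1d(s: SpectraSet, t: TraitVector, alpha: float = 0.01) -> pd.DataFrame:
    """Per-band Pearson r with the trait, with a significance flag.

    Returns a table ``wavelength, r, n_valid, significant``; bands with an
    undefined correlation get NaN r and significant=False.
    """
    s, t = align(s, t)
    r, nv = _pearson_cols(s.values, t.values)
    sig = np.zeros(r.size, dtype=bool)
    ok = np.isfinite(r)
    if ok.any():
        cache = {int(k): (critical_r(alpha, int(k)) if k >= 4 else np.inf)
                 for k in np.unique(nv)}
        thresholds = np.array([cache[int(k)] for k in nv])
        sig = ok & (np.abs(r) >= thresholds)
    return pd.DataFrame(
        {"wavelength": s.wavelengths, "r": r, "n_valid": nv, "significant": sig}
    )


def order_scan(
    stack: FODStack, t: TraitVector, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-derivative-order summary of the 1-D screen.

    For each order: the maximum |r|, the wavelength achieving it, and the
    number of bands passing the significance screen.
    """
    rows = []
    for v in stack.orders:
        tab = corr_1d(stack[v], t, alpha=alpha)
        finite = tab.dropna(subset=["r"])
        if finite.empty:
            rows.append((v, np.nan, np.nan, 0))
            continue
        best = finite.loc[finite["r"].abs().idxmax()]
        rows.append(
            (v, float(abs(best["r"])), float(best["wavelength"]), int(tab["significant"].sum()))
        )
    return pd.DataFrame(
        rows, columns=["order", "max_abs_r", "best_wavelength", "n_significant"]
    )


def _update_best(best, form, wavelengths, r_val, nv):
    """Tolerance-aware improvement update.

    Combinations are visited in lexicographic order, so keeping the
    incumbent on a tie (|r| within TIE_TOL) yields the lexicographically
    smallest optimal tuple.
    """
    if not np.isfinite(r_val):
        return best
    if best is None or abs(r_val) > abs(best[2]) + TIE_TOL:
        return (form, wavelengths, float(r_val), int(nv))
    return best


def _row_argbest(absr: np.ndarray) -> int | None:
    """First index whose |r| is within TIE_TOL of the row maximum."""
    if np.all(np.isnan(absr)):
        return None
    top = np.nanmax(absr)
    return int(np.argmax(absr >= top - TIE_TOL))


def _finalize_best(best, alpha, order) -> BandCombo:
    form, wavelengths, r_val, nv = best
    sig = abs(r_val) >= critical_r(alpha, nv) if nv >= 4 else False
    return BandCombo(form, tuple(float(w) for w in wavelengths), r_val, nv, sig, order)


def corr_map_2d(
    s: SpectraSet,
    t: TraitVector,
    form: str,
    band_range: tuple[float, float] | None = None,
    stride: int = 1,
    alpha: float = 0.01,
    order: float | None = None,
) -> tuple[CorrelationMap, BandCombo]:
    """Exhaustive two-band search of RVI/NDVI/DVI over ordered pairs.

    Returns the full map (lambda1 x lambda2, diagonal NaN) and the best
    combination by |r| with lexicographic tie-breaking.
    """
    if form not in TWO_BAND_FORMS:
        raise ValueError(f"unknown two-band form {form!r}")
    s, t = align(s, t)
    ws = _strided_grid(s, band_range, stride)
    if ws.size < 2:
        raise SpectraError("need at least two bands to search pairs")
    X = s.bands(ws)
    y = t.values
    B = ws.size
    r_mat = np.full((B, B), np.nan)
    n_mat = np.zeros((B, B), dtype=int)
    best = None
    for i in range(B):
        vals, valid = idx._eval_two(form, X[:, i][:, None], X)
        r_row, nv = _pearson_cols(vals, y, valid)
        r_row[i] = np.nan
        r_mat[i] = r_row
        n_mat[i] = nv
        j = _row_argbest(np.abs(r_row))
        if j is None:
            continue
        best = _update_best(best, form, (ws[i], ws[j]), r_row[j], nv[j])
    if best is None:
        raise SpectraError("all band combinations are invalid")
    return (
        CorrelationMap(form, (ws.copy(), ws.copy()), r_mat, n_mat, order),
        _finalize_best(best, alpha, order),
    )


def _eval_triple_r(s_cols, y, form, i, j, K):
    """r for form at (i, j, all k in columns K); K is an (n, B) matrix."""
    vals, valid = idx._eval_three(form, s_cols[:, i][:, None], s_cols[:, j][:, None], K)
    return _pearson_cols(vals, y, valid)


def corr_search_3d(
    s: SpectraSet,
    t: TraitVector,
    form: str,
    band_range: tuple[float, float] | None = (400, 1300),
    stride: int = 5,
    refine: bool = True,
    alpha: float = 0.01,
    keep_map: bool = False,
    order: float | None = None,
) -> tuple[BandCombo, CorrelationMap | None]:
    """Exhaustive three-band search over ordered distinct triples.

    A coarse search on the strided grid is optionally refined on the 1 nm
    grid within +/- stride of the coarse optimum.  The map is only stored
    when ``keep_map`` is set and the strided grid is small (<= 60 bands).
    """
    if form not in THREE_BAND_FORMS:
        raise ValueError(f"unknown three-band form {form!r}")
    s, t = align(s, t)
    ws = _strided_grid(s, band_range, stride)
    if ws.size < 3:
        raise SpectraError("no valid triples: fewer than three bands on the strided grid")
    X = s.bands(ws)
    y = t.values
    B = ws.size
    store = keep_map and B <= 60
    r_cube = np.full((B, B, B), np.nan) if store else None
    n_cube = np.zeros((B, B, B), dtype=int) if store else None
    best = None
    for i in range(B):
        for j in range(B):
            if j == i:
                continue
            r_row, nv = _eval_triple_r(X, y, form, i, j, X)
            r_row[i] = np.nan
            r_row[j] = np.nan
            if store:
                r_cube[i, j] = r_row
                n_cube[i, j] = nv
            k = _row_argbest(np.abs(r_row))
            if k is None:
                continue
            best = _update_best(best, form, (ws[i], ws[j], ws[k]), r_row[k], nv[k])
    if best is None:
        raise SpectraError("all band combinations are invalid")

    if refine and stride > 1:
        best = _refine_triple(s, y, form, best, stride)

    cmap = (
        CorrelationMap(form, (ws.copy(), ws.copy(), ws.copy()), r_cube, n_cube, order)
        if store
        else None
    )
    return _finalize_best(best, alpha, order), cmap


def _refine_triple(s: SpectraSet, y: np.ndarray, form: str, best, stride: int):
    """Local 1 nm re-search within +/- stride of the coarse optimum."""
    grid = s.wavelengths
    windows = []
    for w in best[1]:
        cand = grid[(grid >= w - stride) & (grid <= w + stride)]
        windows.append(cand)
    for w1, w2, w3 in product(*windows):
        if len({w1, w2, w3}) != 3:
            continue
        vals, valid = idx._eval_three(
            form, s.band(w1), s.band(w2), s.band(w3)
        )
        r, nv = _pearson_cols(vals[:, None], y, valid[:, None])
        best = _update_best(best, form, (w1, w2, w3), r[0], nv[0])
    return best


def permutation_screen(
    s: SpectraSet,
    t: TraitVector,
    alpha: float = 0.01,
    n_perm: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Fraction of bands passing the 1-D screen under a permuted trait.

    Returns one fraction per permutation; under the null each should be
    close to ``alpha`` (exactly so, on average, for independent bands).
    """
    s, t = align(s, t)
    rng = np.random.default_rng(seed)
    n, B = s.values.shape
    thresh = critical_r(alpha, n)
    Xc = s.values - s.values.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    ok = norm > 0
    Xs = Xc[:, ok] / norm[ok]
    fractions = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(t.values)
        yc = yp - yp.mean()
        ynorm = np.sqrt(yc @ yc)
        r = (yc / ynorm) @ Xs
        fractions[p] = np.mean(np.abs(r) >= thresh)
    return fractions


# ---------------------------------------------------------------------------
# Feature assembly for the 9 data types of the model grid
# ---------------------------------------------------------------------------

FEATURE_KINDS = (
    "Raw-sensitive-bands",
    "R-FOD",
    "MIs",
    "2BI",
    "FWBI-2BI",
    "2BI-FOD",
    "FWBI-2BI-FOD",
    "3BI-0.8",
    "FWBI-3BI-0.8",
)


@dataclass
class FeatureComponents:
    """Everything assemble_features needs; populated by the fitting pipeline.

    All selections (sensitive bands, optimized combos) must come from the
    calibration subset only; the spectra here may cover all samples, since
    applying a fixed selection to validation samples is leakage-free.
    """

    raw: SpectraSet
    fod: SpectraSet | None = None
    fod_order: float | None = None
    sensitive_raw: tuple[float, ...] | None = None
    sensitive_fod: tuple[float, ...] | None = None
    best_2bi_raw: dict[str, BandCombo] | None = None
    best_2bi_fod: dict[str, BandCombo] | None = None
    best_3bi: dict[str, BandCombo] | None = None


def _need(value, what: str, step: str):
    if value is None:
        raise ValueError(f"feature kind needs {what}; run {step} first")
    return value


def _combo_columns(s: SpectraSet, combos: dict[str, BandCombo]) -> pd.DataFrame:
    cols = {}
    for form, combo in combos.items():
        if len(combo.wavelengths) == 2:
            iv = idx.two_band_index(s, form, *combo.wavelengths)
        else:
            iv = idx.three_band_index(s, form, *combo.wavelengths)
        cols[iv.name] = iv.as_series()
    return pd.DataFrame(cols)


def assemble_features(kind: str, comp: FeatureComponents) -> pd.DataFrame:
    """Samples x features table for one of the nine data-type labels.

    Invalid index values appear as NaN (imputed downstream); columns are
    named after their bands/forms.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}; choose from {FEATURE_KINDS}")
    raw = comp.raw
    ids = list(raw.sample_ids)

    if kind == "Raw-sensitive-bands":
        bands = _need(comp.sensitive_raw, "raw sensitive bands", "the 1-D screen on raw spectra")
        return pd.DataFrame(raw.bands(bands), index=ids,
                            columns=[f"R{w:g}" for w in bands])
    if kind == "R-FOD":
        fod = _need(comp.fod, "derivative spectra", "the derivative step")
        bands = _need(comp.sensitive_fod, "derivative sensitive bands",
                      "the 1-D screen on derivative spectra")
        return pd.DataFrame(fod.bands(bands), index=ids,
                            columns=[f"D{w:g}" for w in bands])
    if kind == "MIs":
        return idx.moisture_frame(raw)
    if kind == "2BI":
        combos = _need(comp.best_2bi_raw, "raw two-band optima", "the 2-D search on raw spectra")
        return _combo_columns(raw, combos)
    if kind == "FWBI-2BI":
        combos = _need(comp.best_2bi_raw, "raw two-band optima", "the 2-D search on raw spectra")
        rvi = {k: v for k, v in combos.items() if k == "RVI"}
        if not rvi:
            raise ValueError("feature kind needs the optimized RVI; run the 2-D search first")
        out = _combo_columns(raw, rvi)
        out.insert(0, "FWBI", idx.fwbi(raw).as_series())
        return out
    if kind == "2BI-FOD":
        fod = _need(comp.fod, "derivative spectra", "the derivative step")
        combos = _need(comp.best_2bi_fod, "derivative two-band optima",
                       "the 2-D search on derivative spectra")
        return _combo_columns(fod, combos)
    if kind == "FWBI-2BI-FOD":
        fod = _need(comp.fod, "derivative spectra", "the derivative step")
        combos = _need(comp.best_2bi_fod, "derivative two-band optima",
                       "the 2-D search on derivative spectra")
        rvi = {k: v for k, v in combos.items() if k == "RVI"}
        if not rvi:
            raise ValueError("feature kind needs the optimized RVI; run the 2-D search first")
        out = _combo_columns(fod, rvi)
        out.insert(0, "FWBI", idx.fwbi(raw).as_series())
        return out
    if kind == "3BI-0.8":
        fod = _need(comp.fod, "derivative spectra", "the derivative step")
        combos = _need(comp.best_3bi, "three-band optima", "the 3-D search")
        return _combo_columns(fod, combos)
    # FWBI-3BI-0.8: FWBI plus the single best three-band combo by |r|
    fod = _need(comp.fod, "derivative spectra", "the derivative step")
    combos = _need(comp.best_3bi, "three-band optima", "the 3-D search")
    best_form = max(combos, key=lambda k: combos[k].abs_r)
    out = _combo_columns(fod, {best_form: combos[best_form]})
    out.insert(0, "FWBI", idx.fwbi(raw).as_series())
    return out
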