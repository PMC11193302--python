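"""Spectral index catalogs and batch evaluation.

Two families:

* Twelve fixed-band moisture indices (WI, WBI, FWBI, SRWI-1/2, MSI, MSI-1,
  NDI-1, NDVI, NDWI, NDWI-Hyp, NDMI), always computed from the raw
  (order-0) reflectance.
* Free-wavelength optimization forms: the two-band RVI/NDVI/DVI and the
  three-band forms 3BI-1 .. 3BI-7, evaluated at any wavelengths on the grid
  (raw or derivative spectra).

Samples whose denominator falls within EPS of zero are flagged invalid, not
dropped, so downstream correlations can use pairwise deletion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectraSet, SpectraError

__all__ = [
    "EPS",
    "TWO_BAND_FORMS",
    "THREE_BAND_FORMS",
    "MOISTURE_INDEX_DEFS",
    "IndexDefinition",
    "IndexValues",
    "moisture_indices",
    "moisture_frame",
    "fwbi",
    "two_band_index",
    "three_band_index",
    "index_long_frame",
]

#: Degeneracy guard on denominators.
EPS = 1e-10

TWO_BAND_FORMS = ("RVI", "NDVI", "DVI")
THREE_BAND_FORMS = tuple(f"3BI-{i}" for i in range(1, 8))

#: name -> (kind, bands); "ratio" is R[a]/R[b], "nd" is (R[a]-R[b])/(R[a]+R[b]),
#: "fwbi" is R[a]/min(R over the inclusive window b).
MOISTURE_INDEX_DEFS: dict[str, tuple[str, tuple]] = {
    "WI": ("ratio", (900, 970)),
    "WBI": ("ratio", (970, 900)),
    "FWBI": ("fwbi", (900, (930, 980))),
    "SRWI-1": ("ratio", (858, 1240)),
    "SRWI-2": ("ratio", (1070, 1340)),
    "MSI": ("ratio", (1600, 820)),
    "MSI-1": ("ratio", (870, 1350)),
    "NDI-1": ("nd", (850, 1650)),
    "NDVI": ("nd", (858, 648)),
    "NDWI": ("nd", (858, 2130)),
    "NDWI-Hyp": ("nd", (1070, 1200)),
    "NDMI": ("nd", (1649, 1722)),
}


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    form_id: str
    bands: tuple

    @property
    def arity(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class IndexValues:
    """One index value per sample plus a validity flag per sample."""

    definition: IndexDefinition
    sample_ids: tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray

    @property
    def name(self) -> str:
        return self.definition.name

    def as_series(self) -> pd.Series:
        vals = np.where(self.valid, self.values, np.nan)
        return pd.Series(vals, index=list(self.sample_ids), name=self.name)


def _guarded_div(num, den) -> tuple[np.ndarray, np.ndarray]:
    num, den = np.broadcast_arrays(np.asarray(num, float), np.asarray(den, float))
    valid = np.abs(den) > EPS
    safe = np.where(valid, den, 1.0)
    return num / safe, valid


def _ratio(s: SpectraSet, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    return _guarded_div(s.band(a), s.band(b))


def _nd(s: SpectraSet, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    ra, rb = s.band(a), s.band(b)
    return _guarded_div(ra - rb, ra + rb)


def _fwbi(s: SpectraSet, a: float, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    sel = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not sel.any():
        raise SpectraError(f"no wavelengths in {lo}-{hi} nm for FWBI")
    return _guarded_div(s.band(a), s.values[:, sel].min(axis=1))


def _moisture_required(kind: str, bands: tuple) -> list[float]:
    if kind == "fwbi":
        return [bands[0], bands[1][0], bands[1][1]]
    return list(bands)


def moisture_indices(s: SpectraSet) -> dict[str, IndexValues]:
    """Evaluate the twelve fixed moisture indices on raw reflectance.

    Raises if the grid lacks any needed wavelength, listing the indices
    that cannot be computed.
    """
    grid = set(s.wavelengths.tolist())
    missing: dict[str, list[float]] = {}
    for name, (kind, bands) in MOISTURE_INDEX_DEFS.items():
        need = [w for w in _moisture_required(kind, bands) if w not in grid]
        if need:
            missing[name] = need
    if missing:
        raise SpectraError(
            "grid is missing wavelengths for moisture indices: "
            + "; ".join(f"{k} needs {v}" for k, v in missing.items())
        )
    out: dict[str, IndexValues] = {}
    for name, (kind, bands) in MOISTURE_INDEX_DEFS.items():
        if kind == "ratio":
            vals, valid = _ratio(s, *bands)
        elif kind == "nd":
            vals, valid = _nd(s, *bands)
        else:
            vals, valid = _fwbi(s, *bands)
        out[name] = IndexValues(
            IndexDefinition(name, name, bands), s.sample_ids, vals, valid
        )
    return out


def moisture_frame(s: SpectraSet) -> pd.DataFrame:
    """Samples x 12 table of moisture-index values (invalid -> NaN)."""
    cols = {name: iv.as_series() for name, iv in moisture_indices(s).items()}
    return pd.DataFrame(cols)


def fwbi(s: SpectraSet) -> IndexValues:
    """The floating-position water band index R900 / min(R930..980)."""
    return moisture_indices(s)["FWBI"]


def _eval_two(form: str, r1, r2) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a two-band form; arguments broadcast (e.g. (n,) vs (n, B))."""
    if form == "RVI":
        return _guarded_div(r1, r2)
    if form == "NDVI":
        return _guarded_div(r1 - r2, r1 + r2)
    if form == "DVI":
        vals = np.asarray(r1 - r2, float)
        return vals, np.ones(vals.shape, dtype=bool)
    raise ValueError(f"unknown two-band form {form!r}; choose from {TWO_BAND_FORMS}")


def _eval_three(form: str, r1, r2, r3) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a three-band form; any argument may broadcast."""
    if form == "3BI-1":
        return _guarded_div(r1, r2 * r3)
    if form == "3BI-2":
        return _guarded_div(r1, r2 + r3)
    if form == "3BI-3":
        return _guarded_div(r1 - r2, r2 + r3)
    if form == "3BI-4":
        return _guarded_div(r1 - r2, r2 - r3)
    if form == "3BI-5":
        return _guarded_div(r2 + r3, r1)
    if form == "3BI-6":
        # (R1-R2) / [(R1-R2) - (R2-R3)]; the denominator equals R1 - 2 R2 + R3
        return _guarded_div(r1 - r2, r1 - 2 * r2 + r3)
    if form == "3BI-7":
        vals = np.asarray(r1 - 2 * r2 + r3, float)
        return vals, np.ones(vals.shape, dtype=bool)
    raise ValueError(f"unknown three-band form {form!r}; choose from {THREE_BAND_FORMS}")


def two_band_index(
    s: SpectraSet, form: str, lambda1: float, lambda2: float
) -> IndexValues:
    """RVI = R1/R2, NDVI = (R1-R2)/(R1+R2) or DVI = R1-R2 at two wavelengths."""
    r1, r2 = s.band(lambda1), s.band(lambda2)
    vals, valid = _eval_two(form, r1, r2)
    definition = IndexDefinition(
        f"{form}({lambda1:g},{lambda2:g})", form, (lambda1, lambda2)
    )
    return IndexValues(definition, s.sample_ids, vals, valid)


def three_band_index(
    s: SpectraSet, form: str, lambda1: float, lambda2: float, lambda3: float
) -> IndexValues:
    """One of the seven three-band forms at pairwise-distinct wavelengths."""
    if len({lambda1, lambda2, lambda3}) != 3:
        raise SpectraError(
            f"three-band wavelengths must be pairwise distinct, got "
            f"({lambda1}, {lambda2}, {lambda3})"
        )
    r1, r2, r3 = s.band(lambda1), s.band(lambda2), s.band(lambda3)
    vals, valid = _eval_three(form, r1, r2, r3)
    definition = IndexDefinition(
        f"{form}({lambda1:g},{lambda2:g},{lambda3:g})",
        form,
        (lambda1, lambda2, lambda3),
    )
    return IndexValues(definition, s.sample_ids, vals, valid)


def index_long_frame(indices: list[IndexValues]) -> pd.DataFrame:
    """Long table ``sample_id, index_name, value, valid`` for export."""
    rows = []
    for iv in indices:
        for sid, v, ok in zip(iv.sample_ids, iv.values, iv.valid):
            rows.append((sid, iv.name, float(v) if ok else np.nan, bool(ok)))
    return pd.DataFrame(rows, columns=["sample_id", "index_name", "value", "valid"])
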