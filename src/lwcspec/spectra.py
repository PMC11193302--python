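"""Spectral containers, file I/O and preprocessing.

Reflectance spectra live on a shared integer-nanometre grid (ASD export
convention: 350-2500 nm resampled to 1 nm).  Removing noisy edge and
atmospheric-water windows leaves the grid split into contiguous segments;
every per-band operation downstream (smoothing, differentiation) is applied
segment by segment, never bridging a gap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectraSet",
    "TraitVector",
    "SpectraError",
    "ParseError",
    "DEFAULT_REMOVED_WINDOWS",
    "read_spectra",
    "read_spectra_table",
    "read_trait_table",
    "write_spectra",
    "write_trait",
    "resample_1nm",
    "trim_windows",
    "trim_default_windows",
    "morph_smooth",
    "mean_by_group",
    "align",
]


class SpectraError(ValueError):
    """Invalid spectral data or operation."""


class ParseError(SpectraError):
    """A spectra/trait text table could not be parsed."""


#: Windows removed by default (inclusive, nm): noisy instrument edges
#: 350-399 and 2401-2500, and the strong atmospheric water-vapour bands
#: 1355-1444 and 1777-1949.
DEFAULT_REMOVED_WINDOWS: tuple[tuple[int, int], ...] = (
    (350, 399),
    (1355, 1444),
    (1777, 1949),
    (2401, 2500),
)


def _segments(wavelengths: np.ndarray) -> tuple[slice, ...]:
    """Maximal runs of consecutive 1 nm-spaced wavelengths, as slices."""
    if wavelengths.size == 0:
        return ()
    breaks = np.flatnonzero(np.diff(wavelengths) != 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [wavelengths.size]))
    return tuple(slice(int(a), int(b)) for a, b in zip(starts, stops))


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths)
    if wl.ndim != 1 or wl.size == 0:
        raise SpectraError("wavelength grid must be a non-empty 1-D array")
    if np.any(np.diff(wl) <= 0):
        raise SpectraError("wavelengths must be strictly increasing")
    return wl


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on an integer-nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths)
        refl = np.asarray(self.reflectance, dtype=float)
        if refl.shape != wl.shape:
            raise SpectraError("reflectance and wavelengths must have equal length")
        if not np.all(np.isfinite(refl)):
            raise SpectraError("reflectance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    @property
    def segments(self) -> tuple[slice, ...]:
        return _segments(self.wavelengths)


@dataclass(frozen=True)
class SpectraSet:
    """Sample-by-wavelength reflectance matrix on a shared grid.

    ``values[i, j]`` is the reflectance of ``sample_ids[i]`` at
    ``wavelengths[j]``.  ``segments`` partitions the grid into maximal
    1 nm-spaced runs.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths)
        vals = np.asarray(self.values, dtype=float)
        ids = tuple(str(s) for s in self.sample_ids)
        if vals.ndim != 2 or vals.shape != (len(ids), wl.size):
            raise SpectraError(
                f"values must be (n_samples, n_bands) = ({len(ids)}, {wl.size}), "
                f"got {vals.shape}"
            )
        if len(set(ids)) != len(ids):
            raise SpectraError("duplicate sample ids")
        if not np.all(np.isfinite(vals)):
            raise SpectraError("reflectance values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", ids)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def segments(self) -> tuple[slice, ...]:
        return _segments(self.wavelengths)

    def band_index(self, nm: float) -> int:
        idx = np.searchsorted(self.wavelengths, nm)
        if idx >= self.wavelengths.size or self.wavelengths[idx] != nm:
            raise SpectraError(f"wavelength {nm} nm is not on the grid")
        return int(idx)

    def band(self, nm: float) -> np.ndarray:
        """Reflectance column at one wavelength (one value per sample)."""
        return self.values[:, self.band_index(nm)]

    def bands(self, nms: Iterable[float]) -> np.ndarray:
        cols = [self.band_index(nm) for nm in nms]
        return self.values[:, cols]

    def spectrum(self, sample_id: str) -> Spectrum:
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise SpectraError(f"unknown sample id {sample_id!r}") from None
        return Spectrum(self.wavelengths, self.values[i])

    def subset(self, sample_ids: Sequence[str]) -> "SpectraSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise SpectraError(f"unknown sample ids: {missing[:5]}")
        rows = [pos[s] for s in sample_ids]
        return SpectraSet(self.wavelengths, self.values[rows], tuple(sample_ids))

    def with_values(self, values: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.wavelengths, values, self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: first column wavelength_nm, one column per sample."""
        df = pd.DataFrame(self.values.T, columns=list(self.sample_ids))
        df.insert(0, "wavelength_nm", self.wavelengths)
        return df


@dataclass(frozen=True)
class TraitVector:
    """Per-sample trait values (leaf water content, %)."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    name: str = "lwc_percent"

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != len(ids):
            raise SpectraError("trait values must align 1:1 with sample ids")
        if len(set(ids)) != len(ids):
            raise SpectraError("duplicate sample ids in trait vector")
        if not np.all(np.isfinite(vals)):
            raise SpectraError("trait values must be finite")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", vals)

    def subset(self, sample_ids: Sequence[str]) -> "TraitVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise SpectraError(f"unknown sample ids: {missing[:5]}")
        rows = [pos[s] for s in sample_ids]
        return TraitVector(tuple(sample_ids), self.values[rows], self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, self.name: self.values})


def align(s: SpectraSet, t: TraitVector) -> tuple[SpectraSet, TraitVector]:
    """Restrict both to their common samples, in the spectra's order."""
    common = [sid for sid in s.sample_ids if sid in set(t.sample_ids)]
    if not common:
        raise SpectraError("spectra and trait share no samples")
    return s.subset(common), t.subset(common)


# ---------------------------------------------------------------------------
# I/O: wide spectra CSV (wavelength_nm + one column per sample) and a trait
# CSV (sample_id, lwc_percent).  Writers emit the same dialect.
# ---------------------------------------------------------------------------

def _read_numeric_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    names = [h.strip() for h in header[1:]]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ParseError(f"duplicate sample ids in {path}: {sorted(dupes)}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(bad.idxmax()) if bad.any() else int(df[col].isna().idxmax())
            raise ParseError(
                f"non-numeric cell in {path} at column {col!r}, data row {row}"
            )
    return df


def read_spectra_table(path) -> SpectraSet:
    df = _read_numeric_table(path)
    if df.columns[0] != "wavelength_nm":
        raise ParseError(
            f"first column of {path} must be 'wavelength_nm', got {df.columns[0]!r}"
        )
    wl = df["wavelength_nm"].to_numpy()
    sample_ids = tuple(df.columns[1:])
    if not sample_ids:
        raise ParseError(f"no sample columns in {path}")
    values = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectraSet(wl, values, sample_ids)


def read_trait_table(path, name: str = "lwc_percent") -> TraitVector:
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns or name not in df.columns:
        raise ParseError(f"{path} must have columns 'sample_id' and {name!r}")
    ids = [str(s) for s in df["sample_id"]]
    if len(set(ids)) != len(ids):
        raise ParseError(f"duplicate sample ids in {path}")
    vals = pd.to_numeric(df[name], errors="coerce")
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise ParseError(f"non-numeric cell in {path} at column {name!r}, data row {row}")
    return TraitVector(tuple(ids), vals.to_numpy(dtype=float), name)


def read_spectra(path, trait_path) -> tuple[SpectraSet, TraitVector]:
    """Read aligned spectra and trait tables.

    Samples present in only one of the two files are reported (warning log)
    and dropped; no overlap at all is an error.
    """
    s = read_spectra_table(path)
    t = read_trait_table(trait_path)
    only_s = [sid for sid in s.sample_ids if sid not in set(t.sample_ids)]
    only_t = [sid for sid in t.sample_ids if sid not in set(s.sample_ids)]
    if only_s:
        log.warning("dropping %d sample(s) without trait values: %s", len(only_s), only_s[:5])
    if only_t:
        log.warning("dropping %d trait sample(s) without spectra: %s", len(only_t), only_t[:5])
    return align(s, t)


def _full_precision(x: float) -> str:
    # 17 significant digits round-trip any float64 exactly
    return format(x, ".17g")


def write_spectra(s: SpectraSet, path) -> None:
    s.to_frame().to_csv(path, index=False, float_format=_full_precision)


def write_trait(t: TraitVector, path) -> None:
    t.to_frame().to_csv(path, index=False, float_format=_full_precision)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample_1nm(s: SpectraSet) -> SpectraSet:
    """Linearly interpolate each contiguous segment onto a 1 nm integer grid.

    Spectra already on an integer 1 nm grid are returned unchanged (copy-free
    semantics are not guaranteed; values are bit-identical).
    """
    wl = s.wavelengths
    if np.all(wl == np.round(wl)) and np.all(np.isin(np.diff(wl), [1])):
        return s
    segs = []
    lo = int(np.ceil(wl[0]))
    hi = int(np.floor(wl[-1]))
    if hi < lo:
        raise SpectraError("grid too narrow to resample to 1 nm")
    target = np.arange(lo, hi + 1)
    out = np.empty((s.n_samples, target.size))
    for i in range(s.n_samples):
        out[i] = np.interp(target, wl, s.values[i])
    return SpectraSet(target, out, s.sample_ids)


def trim_windows(
    s: SpectraSet, windows: Iterable[tuple[float, float]]
) -> SpectraSet:
    """Drop every wavelength inside any [start, end] window (inclusive)."""
    keep = np.ones(s.n_bands, dtype=bool)
    for start, end in windows:
        if start > end:
            raise SpectraError(f"invalid window ({start}, {end}): start > end")
        keep &= ~((s.wavelengths >= start) & (s.wavelengths <= end))
    if not keep.any():
        raise SpectraError("empty spectra: all wavelengths removed by trimming")
    return SpectraSet(s.wavelengths[keep], s.values[:, keep], s.sample_ids)


def trim_default_windows(s: SpectraSet) -> SpectraSet:
    """Remove the noisy edges (350-399, 2401-2500 nm) and the atmospheric
    water-vapour windows (1355-1444, 1777-1949 nm)."""
    return trim_windows(s, DEFAULT_REMOVED_WINDOWS)


def _smooth_block(block: np.ndarray, width: int) -> np.ndarray:
    """Mean of grey-scale morphological opening and closing, flat element."""
    size = (1, width)
    opened = ndimage.grey_opening(block, size=size, mode="reflect")
    closed = ndimage.grey_closing(block, size=size, mode="reflect")
    return 0.5 * (opened + closed)


def morph_smooth(obj, width: int = 7):
    """Morphological smoothing of a Spectrum or SpectraSet.

    The smoother is the average of the grey-scale opening and closing with a
    flat structuring element of ``width`` bands (odd, >= 3), applied
    independently to each contiguous segment with reflected edges.  The
    output is pointwise bounded by the input's rolling min/max over the
    structuring window.
    """
    if width % 2 == 0 or width < 3:
        raise SpectraError(f"smoothing width must be an odd integer >= 3, got {width}")
    if isinstance(obj, Spectrum):
        out = morph_smooth(
            SpectraSet(obj.wavelengths, obj.reflectance[None, :], ("_",)), width
        )
        return Spectrum(out.wavelengths, out.values[0])
    if not isinstance(obj, SpectraSet):
        raise TypeError("morph_smooth expects a Spectrum or SpectraSet")
    shortest = min(seg.stop - seg.start for seg in obj.segments)
    if width > shortest:
        raise SpectraError(
            f"smoothing width {width} exceeds shortest segment length {shortest}"
        )
    out = np.empty_like(obj.values)
    for seg in obj.segments:
        out[:, seg] = _smooth_block(obj.values[:, seg], width)
    return obj.with_values(out)


def mean_by_group(s: SpectraSet, groups: Mapping[str, str]) -> SpectraSet:
    """Average spectra sharing a group label (e.g. repeated scans per plot).

    ``groups`` maps sample id -> group id; samples without an entry are
    dropped.  Group order follows first appearance.
    """
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, sid in enumerate(s.sample_ids):
        g = groups.get(sid)
        if g is None:
            continue
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)
    if not order:
        raise SpectraError("no samples matched any group")
    vals = np.vstack([s.values[members[g]].mean(axis=0) for g in order])
    return SpectraSet(s.wavelengths, vals, tuple(order))
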