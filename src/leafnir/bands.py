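"""Correlation-driven quantification-band selection.

A per-wavenumber Pearson correlation spectrum between second-derivative
intensity and analyte concentration is thresholded at |r| >= tau
(default 0.8); the surviving points are intersected with the NIR
hotspots from the hetero-spectral 2D analysis and with the bands found
on the other hydration state (wet/dry common bands), then widened by
+-k grid points (default 1) so that very narrow bands contribute enough
data points to the PLS calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SpectraSet, SpectrumKind

__all__ = [
    "CorrelationSpectrum",
    "Band",
    "BandSet",
    "correlation_spectrum",
    "threshold_bands",
    "intersect_bands",
    "intersect_with_2d",
    "extend_bands",
    "extract_band_matrix",
]

FLAG_THRESHOLD = "from_threshold"
FLAG_2D = "from_2d"
FLAG_COMMON = "common_wet_dry"
FLAG_EXTENDED = "extended"


@dataclass(frozen=True)
class CorrelationSpectrum:
    """Pearson r between intensity and concentration, per wavenumber.

    Points with zero intensity variance across samples carry r = nan and
    ``defined`` = False; they can never be selected.
    """

    grid: np.ndarray
    r: np.ndarray
    defined: np.ndarray
    n: int
    analyte: str


@dataclass(frozen=True)
class Band:
    """One contiguous inclusive index interval [start, end] on a grid."""

    start: int
    end: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid band [{self.start}, {self.end}]")

    @property
    def n_points(self) -> int:
        return self.end - self.start + 1


@dataclass
class BandSet:
    """Disjoint, ascending index intervals with provenance flags."""

    grid: np.ndarray
    bands: list[Band]
    analyte: str

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: b.start)
        prev_end = -1
        for b in self.bands:
            if b.start <= prev_end:
                raise ValueError("bands overlap")
            if b.end >= self.grid.size:
                raise ValueError(f"band [{b.start}, {b.end}] exceeds grid bounds")
            prev_end = b.end

    def __len__(self) -> int:
        return len(self.bands)

    def covered_indices(self) -> np.ndarray:
        """All grid indices covered by any band, ascending."""
        if not self.bands:
            return np.array([], dtype=int)
        return np.concatenate(
            [np.arange(b.start, b.end + 1) for b in self.bands]
        )

    def covered_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.size, dtype=bool)
        mask[self.covered_indices()] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "analyte": self.analyte,
                "start_cm-1": self.grid[b.start],
                "end_cm-1": self.grid[b.end],
                "start_index": b.start,
                "end_index": b.end,
                "n_points": b.n_points,
                "flags": "|".join(sorted(b.flags)),
            }
            for b in self.bands
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "analyte", "start_cm-1", "end_cm-1",
                "start_index", "end_index", "n_points", "flags",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _mask_to_bands(mask: np.ndarray, flags: frozenset[str]) -> list[Band]:
    """Maximal contiguous True runs of a boolean mask as Band objects."""
    bands: list[Band] = []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    for s, e in zip(starts, ends):
        bands.append(Band(int(s), int(e), flags))
    return bands


def correlation_spectrum(
    spectra: SpectraSet, analyte: str, rel_var_floor: float = 1e-8
) -> CorrelationSpectrum:
    """Pearson correlation of each wavenumber's intensity with concentration.

    Wavenumbers whose intensity standard deviation falls below
    ``rel_var_floor`` times the largest column standard deviation are
    flagged undefined: variation that many orders of magnitude below
    the strongest signal is numerically meaningless (it would otherwise
    inherit a perfect correlation from far Gaussian tails in exact
    synthetic data) and cannot support a calibration.
    """
    if spectra.kind is not SpectrumKind.SECOND_DERIVATIVE:
        raise ValueError("correlation spectra are computed on second derivatives")
    n = spectra.n_samples
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    c = spectra.concentrations(analyte)
    if np.ptp(c) == 0:
        raise ValueError(f"all {analyte} concentrations are equal")
    x = spectra.matrix - spectra.matrix.mean(axis=0)
    cc = c - c.mean()
    sx = np.sqrt((x**2).sum(axis=0))
    sc = np.sqrt((cc**2).sum())
    defined = sx > rel_var_floor * sx.max()
    r = np.full(sx.shape, np.nan)
    np.divide(cc @ x, sx * sc, out=r, where=defined)
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationSpectrum(
        grid=spectra.grid.copy(), r=r, defined=defined, n=n, analyte=analyte
    )


def threshold_bands(cs: CorrelationSpectrum, tau: float = 0.8) -> BandSet:
    """Maximal runs of |r| >= tau (undefined points break runs)."""
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    mask = cs.defined & (np.abs(np.where(cs.defined, cs.r, 0.0)) >= tau)
    return BandSet(
        grid=cs.grid.copy(),
        bands=_mask_to_bands(mask, frozenset({FLAG_THRESHOLD})),
        analyte=cs.analyte,
    )


def _check_same_grid(a: BandSet, b_grid: np.ndarray) -> None:
    if a.grid.size != b_grid.size or not np.allclose(a.grid, b_grid):
        raise ValueError("band sets live on different grids")


def _union_flags(bs: BandSet, extra: str) -> frozenset[str]:
    flags: set[str] = {extra}
    for b in bs.bands:
        flags |= b.flags
    return frozenset(flags)


def intersect_bands(a: BandSet, b: BandSet) -> BandSet:
    """Pointwise intersection of covered indices (wet/dry common bands)."""
    _check_same_grid(a, b.grid)
    if a.analyte != b.analyte:
        raise ValueError(f"analyte mismatch: {a.analyte} vs {b.analyte}")
    mask = a.covered_mask() & b.covered_mask()
    return BandSet(
        grid=a.grid.copy(),
        bands=_mask_to_bands(mask, _union_flags(a, FLAG_COMMON)),
        analyte=a.analyte,
    )


def intersect_with_2d(bs: BandSet, hotspots: np.ndarray) -> BandSet:
    """Keep only band points confirmed by the 2D hotspot set."""
    hotspots = np.asarray(hotspots, dtype=int)
    if hotspots.size and hotspots.max() >= bs.grid.size:
        raise ValueError("hotspot index exceeds grid bounds")
    hot = np.zeros(bs.grid.size, dtype=bool)
    hot[hotspots] = True
    mask = bs.covered_mask() & hot
    return BandSet(
        grid=bs.grid.copy(),
        bands=_mask_to_bands(mask, _union_flags(bs, FLAG_2D)),
        analyte=bs.analyte,
    )


def extend_bands(bs: BandSet, k: int = 1) -> BandSet:
    """Widen every band by k grid points on each side, clip and merge."""
    if k < 0:
        raise ValueError(f"extension must be >= 0, got {k}")
    mask = np.zeros(bs.grid.size, dtype=bool)
    flags: set[str] = {FLAG_EXTENDED} if k > 0 else set()
    for b in bs.bands:
        mask[max(0, b.start - k) : min(bs.grid.size, b.end + k + 1)] = True
        flags |= b.flags
    return BandSet(
        grid=bs.grid.copy(),
        bands=_mask_to_bands(mask, frozenset(flags)),
        analyte=bs.analyte,
    )


def extract_band_matrix(
    spectra: SpectraSet, bs: BandSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample intensities at the covered indices.

    Returns ``(X, wavenumbers)`` where X is samples x selected-points in
    ascending wavenumber order and ``wavenumbers`` traces each column
    back to its grid position.
    """
    _check_same_grid(bs, spectra.grid)
    idx = bs.covered_indices()
    if idx.size == 0:
        raise ValueError(
            "empty band set: too few data points for a PLS calibration"
        )
    return spectra.matrix[:, idx], spectra.grid[idx]
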