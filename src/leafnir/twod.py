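"""Generalized two-dimensional correlation spectroscopy.

Implements Noda's synchronous and asynchronous correlation maps for a
perturbation-ordered spectral series, in both the homo-spectral case
(one spectral region against itself) and the hetero-spectral case
(NIR leaf-model spectra against MIR solution spectra of the same
concentration series).  The perturbation variable here is the analyte
concentration level.

For dynamic matrices ``A`` and ``B`` (levels x wavenumbers, per-level
mean-centered):

    sync  Phi(v1, v2) = (A^T B)_{v1 v2} / (m - 1)
    async Psi(v1, v2) = (A^T N B)_{v1 v2} / (m - 1)

with ``N`` the Hilbert-Noda matrix, N_jk = 0 if j == k else
1 / (pi (k - j)).  The synchronous map measures in-phase covariation of
intensities along the concentration series; the asynchronous map
measures out-of-phase (sequential) variation and vanishes identically
when the two series vary fully in phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectraSet, SpectrumKind

__all__ = [
    "PerturbationSeries",
    "TwoDMap",
    "make_series",
    "synchronous",
    "asynchronous",
    "correlate",
    "hilbert_noda_matrix",
    "split_nir_regions",
    "twod_hotspots",
    "NIR_REGION_BOUNDARIES",
]

# five-region split of the NIR working range, high to low wavenumber
NIR_REGION_BOUNDARIES = (7500.0, 6890.0, 5553.0, 5142.0, 4439.0, 4000.0)


@dataclass(frozen=True)
class PerturbationSeries:
    """A concentration-ordered spectral series, mean-centered.

    ``dynamic`` holds the levels x wavenumbers dynamic spectra (the
    per-wavenumber mean across levels removed), ``levels`` the analyte
    concentrations in ascending order and ``reference`` the subtracted
    mean spectrum.
    """

    grid: np.ndarray
    dynamic: np.ndarray
    levels: np.ndarray
    reference: np.ndarray
    analyte: str

    @property
    def m(self) -> int:
        return self.dynamic.shape[0]


@dataclass(frozen=True)
class TwoDMap:
    """Synchronous and asynchronous intensities over (axis1 x axis2)."""

    axis1: np.ndarray
    axis2: np.ndarray
    sync: np.ndarray
    async_: np.ndarray
    m: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (nu1, nu2) cell."""
        n1, n2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {
                "nu1_cm-1": n1.ravel(),
                "nu2_cm-1": n2.ravel(),
                "sync": self.sync.ravel(),
                "async": self.async_.ravel(),
            }
        )


def make_series(spectra: SpectraSet, analyte: str) -> PerturbationSeries:
    """Build the mean-centered perturbation series for one analyte.

    Expects one spectrum per concentration level (average replicates
    upstream); rows are re-ordered by ascending analyte concentration
    before centering.
    """
    if spectra.kind is not SpectrumKind.SECOND_DERIVATIVE:
        raise ValueError("perturbation series are built from second-derivative sets")
    level_ids = [m.level_id for m in spectra.samples]
    if len(set(level_ids)) != len(level_ids):
        raise ValueError("duplicate level_ids: average replicates first")
    if spectra.n_samples < 2:
        raise ValueError("need at least 2 concentration levels")
    conc = spectra.concentrations(analyte)
    order = np.argsort(conc, kind="stable")
    matrix = spectra.matrix[order]
    reference = matrix.mean(axis=0)
    return PerturbationSeries(
        grid=spectra.grid.copy(),
        dynamic=matrix - reference,
        levels=conc[order],
        reference=reference,
        analyte=analyte,
    )


def _check_aligned(a: PerturbationSeries, b: PerturbationSeries) -> None:
    if a.m != b.m:
        raise ValueError(f"level-count mismatch: {a.m} vs {b.m}")
    mismatch = np.nonzero(~np.isclose(a.levels, b.levels, rtol=1e-9, atol=0.0))[0]
    if mismatch.size:
        k = int(mismatch[0])
        raise ValueError(
            f"perturbation values differ at level {k}: "
            f"{a.levels[k]:g} vs {b.levels[k]:g}"
        )


def synchronous(a: PerturbationSeries, b: PerturbationSeries) -> np.ndarray:
    """Synchronous map Phi = A^T B / (m - 1) of two aligned series."""
    _check_aligned(a, b)
    return a.dynamic.T @ b.dynamic / (a.m - 1)


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """The m x m Hilbert-Noda transform matrix (discrete Hilbert kernel)."""
    j, k = np.indices((m, m))
    with np.errstate(divide="ignore"):
        n = 1.0 / (np.pi * (k - j))
    n[j == k] = 0.0
    return n


def asynchronous(a: PerturbationSeries, b: PerturbationSeries) -> np.ndarray:
    """Asynchronous map Psi = A^T N B / (m - 1) of two aligned series."""
    _check_aligned(a, b)
    if a.m < 3:
        import warnings

        warnings.warn(
            "asynchronous map with fewer than 3 levels is not meaningful",
            stacklevel=2,
        )
    noda = hilbert_noda_matrix(a.m)
    return a.dynamic.T @ noda @ b.dynamic / (a.m - 1)


def correlate(a: PerturbationSeries, b: PerturbationSeries) -> TwoDMap:
    """Full 2D correlation analysis: both maps in one TwoDMap."""
    return TwoDMap(
        axis1=a.grid.copy(),
        axis2=b.grid.copy(),
        sync=synchronous(a, b),
        async_=asynchronous(a, b),
        m=a.m,
    )


def split_nir_regions(
    grid: np.ndarray,
    boundaries: tuple[float, ...] = NIR_REGION_BOUNDARIES,
    tol: float | None = None,
) -> list[tuple[int, int]]:
    """Split an ascending NIR grid into the five working regions.

    Boundaries (descending cm-1) are snapped to nearest grid points;
    each interior boundary point belongs to the adjacent
    higher-wavenumber region.  Returns inclusive index intervals
    ``(start, end)`` ordered by descending wavenumber; their union is
    contiguous and pairwise disjoint.

    The grid must reach each outer boundary within ``tol`` cm-1
    (default 5 grid steps) — derivative filtering trims a few edge
    points off the measured span, so the lowest boundary may sit just
    outside the processed grid.
    """
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if tol is None:
        tol = 5.0 * float(np.median(np.diff(grid)))
    lo, hi = boundaries[-1], boundaries[0]
    if grid[0] > lo + tol or grid[-1] < hi - tol:
        raise ValueError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] does not cover the region "
            f"boundaries [{lo:g}, {hi:g}]"
        )
    snap = [int(np.argmin(np.abs(grid - b))) for b in boundaries]
    regions: list[tuple[int, int]] = []
    for k in range(len(boundaries) - 1):
        # interior boundary points belong to the higher-wavenumber region
        top = snap[k] if k == 0 else snap[k] - 1
        bottom = snap[k + 1]
        if bottom > top:
            raise ValueError("grid too coarse for the region boundaries")
        regions.append((bottom, top))
    return regions


def twod_hotspots(
    sync: np.ndarray,
    axis1: np.ndarray,
    mir_bands: list[tuple[float, float]],
    axis2: np.ndarray,
    q: float = 0.25,
    regions: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """NIR indices most strongly synchronized with the analyte's MIR bands.

    For each NIR index the statistic is the maximum |sync| over the MIR
    wavenumbers falling in ``mir_bands`` (cm-1 intervals covering the
    analyte's fundamentals).  Within each NIR region the indices whose
    statistic reaches the top ``q`` quantile are kept.  Returns a sorted
    integer index array on ``axis1``.
    """
    if not mir_bands:
        raise ValueError("mir_bands must list at least one MIR interval")
    if not 0 < q <= 1:
        raise ValueError(f"quantile fraction q must be in (0, 1], got {q}")
    mir_mask = np.zeros(axis2.size, dtype=bool)
    for lo, hi in mir_bands:
        mir_mask |= (axis2 >= min(lo, hi)) & (axis2 <= max(lo, hi))
    if not mir_mask.any():
        raise ValueError("no MIR grid points fall inside mir_bands")
    stat = np.abs(sync[:, mir_mask]).max(axis=1)
    if regions is None:
        regions = split_nir_regions(axis1)
    hits: list[int] = []
    for start, end in regions:
        seg = stat[start : end + 1]
        thresh = np.quantile(seg, 1.0 - q)
        hits.extend(start + np.nonzero(seg >= thresh)[0])
    return np.array(sorted(hits), dtype=int)
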