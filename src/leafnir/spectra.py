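"""Spectrum containers and single-series preprocessing.

Wavenumber-indexed spectra (NIR diffuse reflectance of leaf models,
MIR ATR absorbance of the corresponding solutions) are held on a shared
ascending grid.  Preprocessing covers the log10(1/R) absorbance
transform, Savitzky-Golay second differentiation, region restriction,
replicate statistics and per-level averaging.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SpectrumKind",
    "SampleState",
    "SampleMeta",
    "Spectrum",
    "SpectraSet",
    "VariabilitySpectrum",
    "to_absorbance",
    "second_derivative",
    "restrict_region",
    "replicate_variability",
    "average_replicates",
]


class SpectrumKind(str, enum.Enum):
    """Processing stage of the intensity axis."""

    REFLECTANCE = "reflectance"
    ABSORBANCE = "absorbance"
    SECOND_DERIVATIVE = "second_derivative"


class SampleState(str, enum.Enum):
    """Physical presentation of the sample."""

    WET = "wet"          # impregnated filter paper, water retained
    DRY = "dry"          # oven-dried filter paper, analytes concentrated
    SOLUTION = "solution"  # aqueous mixture measured by ATR


# legal kind transitions: raw reflectance -> absorbance -> second derivative
_KIND_ORDER = {
    SpectrumKind.REFLECTANCE: 0,
    SpectrumKind.ABSORBANCE: 1,
    SpectrumKind.SECOND_DERIVATIVE: 2,
}


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    Concentrations are expressed as %N (w/w) of the impregnating
    solution; ``level_id`` indexes the concentration design point and
    ``replicate_id`` the repeated acquisition of the same physical
    sample.  ``water_content`` (mass fraction) applies to wet models
    only.
    """

    sample_id: str
    level_id: int
    replicate_id: int
    state: SampleState
    casein_conc: float
    nitrate_conc: float
    water_content: float | None = None
    n_averaged: int = 1  # >1 once replicates have been averaged

    def __post_init__(self) -> None:
        if self.casein_conc < 0 or self.nitrate_conc < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: concentrations must be >= 0"
            )
        if self.water_content is not None and not 0 <= self.water_content <= 1:
            raise ValueError(
                f"sample {self.sample_id!r}: water_content must lie in [0, 1]"
            )
        if self.replicate_id < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate_id must be >= 1")

    def concentration(self, analyte: str) -> float:
        if analyte == "casein":
            return self.casein_conc
        if analyte == "nitrate":
            return self.nitrate_conc
        raise ValueError(f"unknown analyte {analyte!r}")


@dataclass(frozen=True)
class Spectrum:
    """A single wavenumber-indexed intensity trace."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    kind: SpectrumKind
    meta: SampleMeta

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or y.shape != wn.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)


@dataclass
class SpectraSet:
    """Aligned sample x wavenumber matrix on a shared ascending grid.

    Canonical row order is by ``(level_id, replicate_id)``; construction
    enforces it together with uniqueness of that pair.
    ``original_descending`` records whether the ingested axis ran
    high-to-low (FT instruments commonly export 9000 -> 4000).
    """

    grid: np.ndarray
    matrix: np.ndarray
    samples: list[SampleMeta]
    kind: SpectrumKind
    original_descending: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.grid.ndim != 1:
            raise ValueError("grid must be 1-D")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.matrix.ndim != 2 or self.matrix.shape != (
            len(self.samples),
            self.grid.size,
        ):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.samples)} samples x {self.grid.size} grid points"
            )
        keys = [(m.level_id, m.replicate_id) for m in self.samples]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate (level_id, replicate_id) = {dup}")
        order = np.argsort(
            np.array(keys, dtype=[("l", int), ("r", int)]), order=("l", "r")
        )
        self.samples = [self.samples[i] for i in order]
        self.matrix = self.matrix[order]

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def levels(self) -> list[int]:
        return sorted({m.level_id for m in self.samples})

    def __iter__(self) -> Iterable[Spectrum]:
        for row, meta in zip(self.matrix, self.samples):
            yield Spectrum(self.grid, row, self.kind, meta)

    def concentrations(self, analyte: str) -> np.ndarray:
        return np.array([m.concentration(analyte) for m in self.samples])

    def grid_step(self) -> float:
        return float(np.median(np.diff(self.grid)))


@dataclass(frozen=True)
class VariabilitySpectrum:
    """Replicate coefficient of variation of second-derivative values.

    ``cv`` is the sample standard deviation divided by the mean, per
    wavenumber; ``defined`` is False where the mean is numerically zero
    and the ratio is meaningless.
    """

    grid: np.ndarray
    cv: np.ndarray
    defined: np.ndarray
    n_replicates: int


# ---------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------

def to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Convert ratioed diffuse reflectance to apparent absorbance.

    Uses the standard log10(1/R) transform; every reflectance value must
    be strictly positive.
    """
    if spectra.kind is not SpectrumKind.REFLECTANCE:
        raise ValueError(f"expected reflectance input, got {spectra.kind.value}")
    bad = np.argwhere(spectra.matrix <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive reflectance at sample "
            f"{spectra.samples[i].sample_id!r}, wavenumber {spectra.grid[j]:g} cm-1 "
            f"({bad.shape[0]} offending points in total)"
        )
    return SpectraSet(
        grid=spectra.grid.copy(),
        matrix=-np.log10(spectra.matrix),
        samples=list(spectra.samples),
        kind=SpectrumKind.ABSORBANCE,
        original_descending=spectra.original_descending,
    )


def _check_uniform_grid(grid: np.ndarray, rel_tol: float = 0.01) -> float:
    steps = np.diff(grid)
    step = float(np.median(steps))
    if np.max(np.abs(steps - step)) > rel_tol * step:
        raise ValueError(
            "grid spacing deviates by more than "
            f"{rel_tol:.0%} from the median step ({step:g} cm-1); "
            "resample to a uniform grid first"
        )
    return step


def second_derivative(
    spectra: SpectraSet, window: int = 11, polyorder: int = 2
) -> SpectraSet:
    """Savitzky-Golay second derivative, in intensity / (cm-1)^2.

    Each point is the second-derivative coefficient of a local
    least-squares polynomial of order ``polyorder`` fitted over
    ``window`` grid points.  The (window-1)/2 edge points on each side
    have no full window and are dropped rather than padded.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder < 2 or window <= polyorder:
        raise ValueError(
            f"need window > polyorder >= 2, got window={window}, polyorder={polyorder}"
        )
    if window > spectra.grid.size:
        raise ValueError(
            f"window {window} exceeds grid length {spectra.grid.size}"
        )
    if _KIND_ORDER[spectra.kind] >= _KIND_ORDER[SpectrumKind.SECOND_DERIVATIVE]:
        raise ValueError("input is already a second-derivative set")
    step = _check_uniform_grid(spectra.grid)
    deriv = savgol_filter(
        spectra.matrix, window_length=window, polyorder=polyorder,
        deriv=2, delta=step, axis=1,
    )
    half = (window - 1) // 2
    sl = slice(half, spectra.grid.size - half)
    return SpectraSet(
        grid=spectra.grid[sl].copy(),
        matrix=deriv[:, sl],
        samples=list(spectra.samples),
        kind=SpectrumKind.SECOND_DERIVATIVE,
        original_descending=spectra.original_descending,
    )


def restrict_region(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep grid points in the closed interval [lo, hi] cm-1 (no resampling)."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (spectra.grid >= lo) & (spectra.grid <= hi)
    if not mask.any():
        raise ValueError(
            f"region [{lo}, {hi}] cm-1 does not overlap grid "
            f"[{spectra.grid[0]:g}, {spectra.grid[-1]:g}]"
        )
    return SpectraSet(
        grid=spectra.grid[mask].copy(),
        matrix=spectra.matrix[:, mask],
        samples=list(spectra.samples),
        kind=spectra.kind,
        original_descending=spectra.original_descending,
    )


def replicate_variability(
    spectra: SpectraSet, mean_floor: float = 1e-300
) -> VariabilitySpectrum:
    """Per-wavenumber sd/mean across repeated measurements.

    Standard deviation uses the n-1 denominator.  Points where the mean
    magnitude falls below ``mean_floor`` are flagged undefined.
    """
    n = spectra.n_samples
    if n < 2:
        raise ValueError("need at least 2 replicate spectra")
    mean = spectra.matrix.mean(axis=0)
    sd = spectra.matrix.std(axis=0, ddof=1)
    defined = np.abs(mean) > mean_floor
    cv = np.full(mean.shape, np.nan)
    np.divide(sd, mean, out=cv, where=defined)
    return VariabilitySpectrum(
        grid=spectra.grid.copy(), cv=cv, defined=defined, n_replicates=n
    )


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Collapse replicates to one mean spectrum per concentration level.

    The returned metadata keeps each level's concentrations and state,
    with ``replicate_id`` fixed to 1; level order is preserved.
    """
    if spectra.n_samples == 0:
        raise ValueError("empty SpectraSet")
    rows, metas = [], []
    for level in spectra.levels:
        idx = [i for i, m in enumerate(spectra.samples) if m.level_id == level]
        rows.append(spectra.matrix[idx].mean(axis=0))
        m0 = spectra.samples[idx[0]]
        metas.append(
            replace(
                m0,
                sample_id=f"L{level:02d}_mean",
                replicate_id=1,
                n_averaged=len(idx),
            )
        )
    return SpectraSet(
        grid=spectra.grid.copy(),
        matrix=np.vstack(rows),
        samples=metas,
        kind=spectra.kind,
        original_descending=spectra.original_descending,
    )
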