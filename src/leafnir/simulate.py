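"""Synthetic leaf-model spectra with known ground truth.

Emulates the study design the package targets: filter-paper "leaf
models" impregnated with casein / nitric-acid mixtures at nine
concentration levels, measured wet and oven-dried by diffuse-reflectance
NIR (9000-4000 cm-1, ~6 cm-1 step, six replicate acquisitions), plus
ATR MIR spectra (4000-800 cm-1, 4 cm-1 step) of the corresponding
aqueous solutions.

Spectra follow a Beer-Lambert mixture model: each component (casein,
nitrate, water, cellulose) contributes Gaussian absorbance bands scaled
by its effective concentration, on top of a low-order polynomial
baseline, a per-sample multiplicative gain and additive noise.
Noise-free generation is therefore exactly linear in each analyte's
concentration at every wavenumber, which is what makes full-pipeline
recovery testable.  Reflectance sets are emitted as R = 10^(-A).

The NIR band positions of water and cellulose follow the features
reported for wet filter-paper models (strong bands near 7150, 6900,
5200, 4750, 4400 and 4250 cm-1); the analyte NIR/MIR positions are
plausible stand-ins for protein N-H/C-H combination bands and nitrate
stretches, declared ground truth of the simulator rather than measured
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SampleMeta, SampleState, SpectraSet, SpectrumKind

__all__ = [
    "GaussianBand",
    "ComponentModel",
    "DesignSpec",
    "GroundTruth",
    "default_components",
    "default_design",
    "high_interference_wet_design",
    "generate_nir_set",
    "generate_mir_set",
    "paired_design",
]

NIR_GRID = (4000.0, 9000.0, 6.0)  # lo, hi, step (cm-1)
MIR_GRID = (800.0, 4000.0, 4.0)

# analytes are concentrated ~3x per volume when the wet model is oven-dried
DRY_CONCENTRATION_FACTOR = 3.0
# residual moisture scale of the dried paper relative to the wet model
DRY_WATER_SCALE = 0.05
WET_WATER_CONTENT = 0.80


@dataclass(frozen=True)
class GaussianBand:
    center: float   # cm-1
    sigma: float    # cm-1, Gaussian standard deviation
    intensity: float  # peak absorbance per unit concentration

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.intensity < 0:
            raise ValueError("band sigma must be > 0 and intensity >= 0")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.intensity * np.exp(-0.5 * ((grid - self.center) / self.sigma) ** 2)


@dataclass(frozen=True)
class ComponentModel:
    """Absorbing species: Gaussian bands in both spectral regions."""

    name: str
    nir_bands: tuple[GaussianBand, ...]
    mir_bands: tuple[GaussianBand, ...]

    def absorbance(
        self, grid: np.ndarray, region: str, shift: float = 0.0
    ) -> np.ndarray:
        """Summed band profiles; ``shift`` moves every center by that many cm-1."""
        bands = self.nir_bands if region == "nir" else self.mir_bands
        out = np.zeros_like(grid)
        for b in bands:
            out += b.profile(grid - shift)
        return out

    def centers(self, region: str) -> list[float]:
        bands = self.nir_bands if region == "nir" else self.mir_bands
        return [b.center for b in bands]


def default_components() -> dict[str, ComponentModel]:
    """The four-species mixture model used throughout the test suite."""
    return {
        "casein": ComponentModel(
            "casein",
            nir_bands=(
                GaussianBand(6510.0, 30.0, 0.060),  # N-H stretch 1st overtone
                GaussianBand(5780.0, 35.0, 0.050),  # C-H combination
                GaussianBand(4865.0, 28.0, 0.080),  # amide combination
                GaussianBand(4590.0, 25.0, 0.070),  # N-H/C=O combination
            ),
            mir_bands=(
                GaussianBand(1650.0, 25.0, 0.30),   # amide I
                GaussianBand(1545.0, 22.0, 0.22),   # amide II
                GaussianBand(1450.0, 18.0, 0.08),   # CH2/CH3 deformation
            ),
        ),
        "nitrate": ComponentModel(
            "nitrate",
            nir_bands=(
                GaussianBand(5900.0, 26.0, 0.045),
                GaussianBand(4330.0, 24.0, 0.065),
            ),
            mir_bands=(
                GaussianBand(1350.0, 30.0, 0.45),   # NO3 asymmetric stretch
                GaussianBand(1045.0, 15.0, 0.12),   # NO3 symmetric stretch
            ),
        ),
        "water": ComponentModel(
            "water",
            nir_bands=(
                GaussianBand(6900.0, 160.0, 0.55),  # O-H 1st overtone, broad
                GaussianBand(5200.0, 120.0, 0.70),  # O-H combination
                # narrower water / water-matrix features of the wet model
                GaussianBand(7150.0, 90.0, 0.20),
                GaussianBand(6300.0, 55.0, 0.10),
                GaussianBand(5800.0, 50.0, 0.12),
                GaussianBand(5600.0, 50.0, 0.10),
                GaussianBand(5250.0, 60.0, 0.12),
            ),
            mir_bands=(
                GaussianBand(3350.0, 180.0, 0.90),  # O-H stretch
                GaussianBand(1640.0, 45.0, 0.45),   # H-O-H bend
                GaussianBand(2120.0, 120.0, 0.08),  # association band
            ),
        ),
        "cellulose": ComponentModel(
            "cellulose",
            nir_bands=(
                GaussianBand(6700.0, 60.0, 0.12),
                GaussianBand(5200.0, 50.0, 0.18),
                GaussianBand(4750.0, 45.0, 0.20),
                GaussianBand(4400.0, 40.0, 0.22),
                GaussianBand(4250.0, 35.0, 0.18),
            ),
            mir_bands=(),  # solutions carry no paper matrix
        ),
    }


# fixed decorrelating order of the nitrate ladder across the nine levels:
# the design varies the nitrate : protein ratio, so the two concentration
# series must not be collinear (|r| ~= 0.17 for this permutation)
_NITRATE_LEVEL_ORDER = (2, 6, 0, 8, 4, 1, 7, 3, 5)


@dataclass(frozen=True)
class DesignSpec:
    """One acquisition campaign: levels x replicates under one state."""

    n_levels: int = 9
    casein_levels: tuple[float, ...] = ()    # %N per level
    nitrate_levels: tuple[float, ...] = ()   # %N per level
    n_replicates: int = 6
    mir_replicates: int = 1
    state: SampleState = SampleState.DRY
    noise_sd: float = 5e-5        # additive absorbance noise (AU)
    scatter_sd: float = 0.01      # multiplicative per-sample gain sd
    baseline_scale: float = 0.01  # sd of quadratic-baseline coefficients (AU)
    cellulose_gain_sd: float = 0.01   # per-filter matrix variation
    water_content_sd: float = 0.02    # per-sample moisture variation (wet)
    matrix_shift_sd: float = 0.0      # cm-1; per-sample rigid shift of the
                                      # water and cellulose bands (hydration /
                                      # swelling state), nonlinear interference
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.casein_levels:
            object.__setattr__(
                self,
                "casein_levels",
                tuple(np.linspace(0.2, 1.0, self.n_levels).round(6)),
            )
        if not self.nitrate_levels:
            base = np.linspace(0.05, 0.45, self.n_levels).round(6)
            if self.n_levels == len(_NITRATE_LEVEL_ORDER):
                base = base[list(_NITRATE_LEVEL_ORDER)]
            object.__setattr__(self, "nitrate_levels", tuple(base))
        if (
            len(self.casein_levels) != self.n_levels
            or len(self.nitrate_levels) != self.n_levels
        ):
            raise ValueError("concentration ladders must have n_levels entries")
        for name in ("noise_sd", "scatter_sd", "baseline_scale",
                     "cellulose_gain_sd", "water_content_sd", "matrix_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_design(state: SampleState = SampleState.DRY, seed: int = 0) -> DesignSpec:
    """The baseline nine-level, six-replicate campaign at moderate noise."""
    return DesignSpec(state=state, seed=seed)


def high_interference_wet_design(seed: int = 0) -> DesignSpec:
    """Wet models with strong, sample-to-sample variable water interference.

    Moisture varies by 10% (mass fraction sd) between samples, the gain
    scatter is 5%, the absorbance noise is fortyfold the baseline
    campaign, and the water / cellulose bands shift rigidly by a few
    cm-1 per sample with the hydration and swelling state of the paper.
    Second derivatives are highly shift-sensitive and the shift enters
    nonlinearly, so wavenumbers near the matrix bands carry
    sample-to-sample variance a linear latent-factor model cannot
    remove — the regime in which whole-spectrum calibration degrades
    while analyte-specific bands stay usable.
    """
    return DesignSpec(
        state=SampleState.WET,
        noise_sd=6e-3,
        scatter_sd=0.05,
        baseline_scale=0.02,
        water_content_sd=0.10,
        matrix_shift_sd=6.0,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator actually put into the spectra."""

    nir_band_centers: dict[str, list[float]]
    mir_band_centers: dict[str, list[float]]
    concentrations: list[dict]
    dry_concentration_factor: float
    design: DesignSpec

    def center_indices(
        self, grid: np.ndarray, component: str, region: str = "nir"
    ) -> np.ndarray:
        """Nearest grid index of each of a component's band centers.

        Centers falling outside the grid span are dropped (they cannot
        be recovered from a restricted region by construction).
        """
        centers = (
            self.nir_band_centers if region == "nir" else self.mir_band_centers
        )[component]
        idx = [
            int(np.argmin(np.abs(grid - c)))
            for c in centers
            if grid[0] <= c <= grid[-1]
        ]
        return np.array(sorted(set(idx)), dtype=int)


def _make_grid(spec: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = spec
    return np.arange(lo, hi + step / 2, step)


def _sample_absorbance(
    grid: np.ndarray,
    region: str,
    components: dict[str, ComponentModel],
    casein: float,
    nitrate: float,
    water_scale: float,
    cellulose_gain: float,
    design: DesignSpec,
    rng: np.random.Generator,
    matrix_shift: float = 0.0,
) -> np.ndarray:
    a = casein * components["casein"].absorbance(grid, region)
    a = a + nitrate * components["nitrate"].absorbance(grid, region)
    a = a + water_scale * components["water"].absorbance(grid, region, matrix_shift)
    if cellulose_gain > 0:
        a = a + cellulose_gain * components["cellulose"].absorbance(
            grid, region, matrix_shift
        )
    # low-order drift, annihilated by the second derivative by design
    x = (grid - grid.mean()) / (grid[-1] - grid[0]) * 2
    b0, b1, b2 = rng.normal(0.0, design.baseline_scale, size=3)
    a = a + b0 + b1 * x + b2 * x**2
    a = a * (1.0 + rng.normal(0.0, design.scatter_sd))
    a = a + rng.normal(0.0, design.noise_sd, size=grid.size)
    return a


def _truth(
    design: DesignSpec, components: dict[str, ComponentModel], samples: list[dict]
) -> GroundTruth:
    return GroundTruth(
        nir_band_centers={n: c.centers("nir") for n, c in components.items()},
        mir_band_centers={n: c.centers("mir") for n, c in components.items()},
        concentrations=samples,
        dry_concentration_factor=DRY_CONCENTRATION_FACTOR,
        design=design,
    )


def generate_nir_set(
    design: DesignSpec, components: dict[str, ComponentModel] | None = None
) -> tuple[SpectraSet, GroundTruth]:
    """Simulate a diffuse-reflectance NIR campaign for one leaf-model state.

    Returns the reflectance SpectraSet (levels x replicates rows) and
    the ground-truth record (band centers, per-sample effective
    concentrations).
    """
    if design.state not in (SampleState.WET, SampleState.DRY):
        raise ValueError("NIR leaf-model sets are generated wet or dry")
    components = components or default_components()
    rng = np.random.default_rng(design.seed)
    grid = _make_grid(NIR_GRID)
    dry = design.state is SampleState.DRY
    conc_factor = DRY_CONCENTRATION_FACTOR if dry else 1.0

    rows, metas, truth_rows = [], [], []
    for level in range(1, design.n_levels + 1):
        cas = design.casein_levels[level - 1]
        nit = design.nitrate_levels[level - 1]
        for rep in range(1, design.n_replicates + 1):
            if dry:
                water_scale = DRY_WATER_SCALE
                wc = None
            else:
                wc = float(
                    np.clip(
                        rng.normal(WET_WATER_CONTENT, design.water_content_sd),
                        0.5,
                        0.95,
                    )
                )
                water_scale = wc / WET_WATER_CONTENT
            cell_gain = 1.0 + rng.normal(0.0, design.cellulose_gain_sd)
            shift = (
                rng.normal(0.0, design.matrix_shift_sd)
                if design.matrix_shift_sd > 0
                else 0.0
            )
            a = _sample_absorbance(
                grid, "nir", components,
                cas * conc_factor, nit * conc_factor,
                water_scale, cell_gain, design, rng,
                matrix_shift=shift,
            )
            refl = np.power(10.0, -a)
            if not np.all(refl > 0):
                raise ValueError(
                    "generator parameters too extreme: non-positive reflectance"
                )
            sid = f"{design.state.value}_L{level:02d}_R{rep}"
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    level_id=level,
                    replicate_id=rep,
                    state=design.state,
                    casein_conc=cas,
                    nitrate_conc=nit,
                    water_content=wc,
                )
            )
            rows.append(refl)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "casein_conc": cas,
                    "nitrate_conc": nit,
                    "effective_casein": cas * conc_factor,
                    "effective_nitrate": nit * conc_factor,
                    "water_scale": water_scale,
                }
            )
    spectra = SpectraSet(
        grid=grid,
        matrix=np.vstack(rows),
        samples=metas,
        kind=SpectrumKind.REFLECTANCE,
    )
    return spectra, _truth(design, components, truth_rows)


def generate_mir_set(
    design: DesignSpec, components: dict[str, ComponentModel] | None = None
) -> tuple[SpectraSet, GroundTruth]:
    """Simulate ATR MIR absorbance spectra of the aqueous solutions.

    Solutions carry no cellulose matrix and the solvent (water) level is
    fixed across concentration levels.
    """
    components = components or default_components()
    # decouple the MIR noise stream from the NIR one under a shared design
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0x4D49)))
    grid = _make_grid(MIR_GRID)
    rows, metas, truth_rows = [], [], []
    for level in range(1, design.n_levels + 1):
        cas = design.casein_levels[level - 1]
        nit = design.nitrate_levels[level - 1]
        for rep in range(1, design.mir_replicates + 1):
            a = _sample_absorbance(
                grid, "mir", components, cas, nit,
                water_scale=1.0, cellulose_gain=0.0,
                design=design, rng=rng,
            )
            sid = f"solution_L{level:02d}_R{rep}"
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    level_id=level,
                    replicate_id=rep,
                    state=SampleState.SOLUTION,
                    casein_conc=cas,
                    nitrate_conc=nit,
                )
            )
            rows.append(a)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "casein_conc": cas,
                    "nitrate_conc": nit,
                    "effective_casein": cas,
                    "effective_nitrate": nit,
                    "water_scale": 1.0,
                }
            )
    spectra = SpectraSet(
        grid=grid,
        matrix=np.vstack(rows),
        samples=metas,
        kind=SpectrumKind.ABSORBANCE,
    )
    return spectra, _truth(design, components, truth_rows)


def paired_design(
    design: DesignSpec, components: dict[str, ComponentModel] | None = None
) -> tuple[SpectraSet, SpectraSet, GroundTruth]:
    """NIR leaf-model set plus the MIR solution set of the same ladder.

    Level i of the NIR set and level i of the MIR set share identical
    analyte concentrations, which is what lets the hetero-spectral 2D
    analysis use the concentration level as the common perturbation
    axis.
    """
    components = components or default_components()
    nir, truth = generate_nir_set(design, components)
    mir, _ = generate_mir_set(design, components)
    return nir, mir, truth
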