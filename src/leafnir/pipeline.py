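"""Config-driven end-to-end calibration runs.

One run covers the study's four quantification scenarios — casein and
nitrate, each in the dry and the wet leaf model — from raw (or
synthetic) spectra through preprocessing, hetero-spectral 2D
correlation, band selection and LOO-validated PLS calibration, with
every output written as diffable CSV/JSON plus a checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bands import (
    BandSet,
    correlation_spectrum,
    extend_bands,
    extract_band_matrix,
    intersect_bands,
    intersect_with_2d,
    threshold_bands,
)
from .pls import CalibrationResult, loo_cv
from .simulate import DesignSpec, default_components, generate_mir_set, generate_nir_set
from .spectra import (
    SampleState,
    SpectraSet,
    SpectrumKind,
    average_replicates,
    restrict_region,
    second_derivative,
    to_absorbance,
)
from .twod import correlate, make_series, split_nir_regions, twod_hotspots

__all__ = [
    "PreprocessConfig",
    "SelectionConfig",
    "PLSConfig",
    "PipelineConfig",
    "RunReport",
    "preprocess_nir",
    "preprocess_mir",
    "select_bands_for_state",
    "calibrate",
    "baseline_fullspectrum_run",
    "run_pipeline",
]

log = logging.getLogger("leafnir")

ANALYTES = ("casein", "nitrate")

# MIR intervals (cm-1) holding each analyte's fundamentals, used to pick
# the NIR hotspots out of the hetero-spectral synchronous map
DEFAULT_MIR_BANDS: dict[str, list[tuple[float, float]]] = {
    "casein": [(1500.0, 1700.0)],            # amide I / amide II
    "nitrate": [(1300.0, 1400.0), (1020.0, 1070.0)],  # NO3 stretches
}


@dataclass
class PreprocessConfig:
    nir_window: int = 11        # SG window for leaf-model NIR spectra
    mir_window: int = 17        # SG window for solution MIR spectra
    polyorder: int = 2
    region: tuple[float, float] = (4000.0, 7500.0)  # NIR working range, cm-1
    use_absorbance: bool = True  # log10(1/R) before differentiation


@dataclass
class SelectionConfig:
    tau: float = 0.8            # |r| threshold on the correlation spectrum
    hotspot_q: float = 0.25     # top quantile per NIR region in the 2D map
    extension: int = 1          # widen final bands by this many grid points
    mir_bands: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MIR_BANDS.items()}
    )
    common_wet_dry: bool = True  # intersect the wet and dry band sets


@dataclass
class PLSConfig:
    max_components: int = 10
    grouping: str = "per_sample"  # or "per_spectrum"
    average_replicates: bool = False  # calibrate on per-replicate spectra


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    analytes: tuple[str, ...] = ANALYTES
    design: DesignSpec | None = None   # synthetic source (None -> default)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    pls: PLSConfig = field(default_factory=PLSConfig)
    include_fullspectrum_baseline: bool = True
    write_twod_maps: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ValueError("analyte list must not be empty")
        unknown = set(self.analytes) - set(ANALYTES)
        if unknown:
            raise ValueError(f"unknown analytes {sorted(unknown)}")
        if self.pls.grouping not in ("per_sample", "per_spectrum"):
            raise ValueError(f"unknown grouping {self.pls.grouping!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "design" in kwargs and kwargs["design"] is not None:
            d = dict(kwargs["design"])
            if "state" in d:
                d["state"] = SampleState(d["state"])
            for key in ("casein_levels", "nitrate_levels"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = DesignSpec(**d)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("selection", SelectionConfig),
            ("pls", PLSConfig),
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = sub(**kwargs[key])
        if "analytes" in kwargs:
            kwargs["analytes"] = tuple(kwargs["analytes"])
        if "preprocess" in kwargs and isinstance(
            kwargs["preprocess"].region, list
        ):
            kwargs["preprocess"].region = tuple(kwargs["preprocess"].region)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["analytes"] = list(self.analytes)
        for enum_holder in ("design",):
            if out.get(enum_holder):
                out[enum_holder]["state"] = self.design.state.value
        return out


# ---------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------

def preprocess_nir(spectra: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """Reflectance -> (absorbance) -> SG second derivative -> working region."""
    if cfg.use_absorbance and spectra.kind is SpectrumKind.REFLECTANCE:
        spectra = to_absorbance(spectra)
    deriv = second_derivative(spectra, cfg.nir_window, cfg.polyorder)
    return restrict_region(deriv, *cfg.region)


def preprocess_mir(spectra: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """SG second derivative of the solution absorbance spectra."""
    return second_derivative(spectra, cfg.mir_window, cfg.polyorder)


def select_bands_for_state(
    nir_proc: SpectraSet,
    mir_proc: SpectraSet,
    analyte: str,
    cfg: SelectionConfig,
) -> tuple[BandSet, np.ndarray]:
    """Threshold bands intersected with the hetero-spectral 2D hotspots.

    Returns the (unextended) band set for one hydration state plus the
    hotspot index set for reporting.
    """
    cs = correlation_spectrum(nir_proc, analyte)
    bands = threshold_bands(cs, cfg.tau)

    nir_series = make_series(average_replicates(nir_proc), analyte)
    mir_series = make_series(average_replicates(mir_proc), analyte)
    twod = correlate(nir_series, mir_series)
    hotspots = twod_hotspots(
        twod.sync,
        twod.axis1,
        cfg.mir_bands[analyte],
        twod.axis2,
        q=cfg.hotspot_q,
        regions=split_nir_regions(twod.axis1),
    )
    return intersect_with_2d(bands, hotspots), hotspots


def calibrate(
    nir_proc: SpectraSet, bands: BandSet, analyte: str, cfg: PLSConfig
) -> CalibrationResult:
    """LOO-validated PLS1 on the selected band points of one state."""
    spectra = average_replicates(nir_proc) if cfg.average_replicates else nir_proc
    X, _ = extract_band_matrix(spectra, bands)
    y = spectra.concentrations(analyte)
    groups = (
        np.array([m.level_id for m in spectra.samples])
        if cfg.grouping == "per_sample"
        else np.arange(spectra.n_samples)
    )
    uniq = np.unique(groups).size
    max_c = min(cfg.max_components, uniq - 2, X.shape[1])
    return loo_cv(X, y, max_components=max_c, groups=groups)


def baseline_fullspectrum_run(
    nir_proc: SpectraSet, analyte: str, cfg: PLSConfig
) -> CalibrationResult:
    """Whole-working-region PLS calibration (no band selection).

    The negative control: every grid point of the restricted
    second-derivative spectra enters the regression.
    """
    spectra = average_replicates(nir_proc) if cfg.average_replicates else nir_proc
    y = spectra.concentrations(analyte)
    groups = (
        np.array([m.level_id for m in spectra.samples])
        if cfg.grouping == "per_sample"
        else np.arange(spectra.n_samples)
    )
    uniq = np.unique(groups).size
    max_c = min(cfg.max_components, uniq - 2, spectra.matrix.shape[1])
    return loo_cv(spectra.matrix, y, max_components=max_c, groups=groups)


# ---------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------

@dataclass
class RunReport:
    """Everything a pipeline run produced, in memory."""

    config: PipelineConfig
    band_sets: dict[str, BandSet]                       # analyte -> final bands
    state_band_sets: dict[tuple[str, str], BandSet]     # (analyte, state) -> pre-common
    calibrations: dict[tuple[str, str], CalibrationResult]  # (analyte, state)
    baselines: dict[tuple[str, str], CalibrationResult]
    manifest: dict

    def summary(self) -> str:
        lines = ["leafnir pipeline run", "=" * 40]
        for (analyte, state), cal in sorted(self.calibrations.items()):
            lines.append(
                f"{analyte:8s} {state:4s}: LOO R^2 = {cal.r2_validation:6.3f}  "
                f"RMSE = {cal.rmse:.4g}  factors = {cal.n_factors_chosen}  "
                f"band points = {cal.model.x_mean.size}"
            )
        for (analyte, state), cal in sorted(self.baselines.items()):
            lines.append(
                f"{analyte:8s} {state:4s} (full spectrum): "
                f"LOO R^2 = {cal.r2_validation:6.3f}"
            )
        return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_calibration(
    path: Path, spectra_ids: list[str], cal: CalibrationResult
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": spectra_ids,
            "y_true": cal.y_reference,
            "y_loo_pred": cal.loo_predictions,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full four-scenario calibration study.

    Synthetic wet and dry campaigns (plus the matching MIR solution
    series) are generated from ``config.design``; each analyte's bands
    are selected per state, intersected across states when configured,
    extended, and calibrated by LOO PLS in both states.
    """
    t0 = time.time()
    base = config.design or DesignSpec(seed=config.seed)
    dry_design = replace(base, state=SampleState.DRY, seed=config.seed)
    wet_design = replace(base, state=SampleState.WET, seed=config.seed + 1)
    components = default_components()

    def stage(name: str, fn, *args, **kwargs):
        t = time.time()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %-22s %.2fs", name, time.time() - t)
        return out

    nir_dry, truth = stage("generate dry NIR", generate_nir_set, dry_design, components)
    nir_wet, _ = stage("generate wet NIR", generate_nir_set, wet_design, components)
    mir, _ = stage("generate MIR", generate_mir_set, dry_design, components)

    proc = {
        "dry": stage("preprocess dry", preprocess_nir, nir_dry, config.preprocess),
        "wet": stage("preprocess wet", preprocess_nir, nir_wet, config.preprocess),
    }
    mir_proc = stage("preprocess MIR", preprocess_mir, mir, config.preprocess)

    band_sets: dict[str, BandSet] = {}
    state_band_sets: dict[tuple[str, str], BandSet] = {}
    calibrations: dict[tuple[str, str], CalibrationResult] = {}
    baselines: dict[tuple[str, str], CalibrationResult] = {}
    twod_maps = {}

    for analyte in config.analytes:
        per_state = {}
        for state in ("dry", "wet"):
            bs, _hot = stage(
                f"select {analyte}/{state}",
                select_bands_for_state,
                proc[state], mir_proc, analyte, config.selection,
            )
            per_state[state] = bs
            state_band_sets[(analyte, state)] = bs
        final = (
            intersect_bands(per_state["dry"], per_state["wet"])
            if config.selection.common_wet_dry
            else per_state["dry"]
        )
        final = extend_bands(final, config.selection.extension)
        band_sets[analyte] = final
        if config.write_twod_maps:
            for state in ("dry", "wet"):
                twod_maps[(analyte, state)] = correlate(
                    make_series(average_replicates(proc[state]), analyte),
                    make_series(average_replicates(mir_proc), analyte),
                )
        for state in ("dry", "wet"):
            calibrations[(analyte, state)] = stage(
                f"calibrate {analyte}/{state}",
                calibrate, proc[state], final, analyte, config.pls,
            )
            if config.include_fullspectrum_baseline:
                baselines[(analyte, state)] = stage(
                    f"baseline {analyte}/{state}",
                    baseline_fullspectrum_run, proc[state], analyte, config.pls,
                )

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_samples": {"dry": nir_dry.n_samples, "wet": nir_wet.n_samples},
        "results": {},
        "files": {},
    }
    for (analyte, state), cal in calibrations.items():
        entry = {"band_selected": cal.to_dict()}
        if (analyte, state) in baselines:
            entry["full_spectrum"] = baselines[(analyte, state)].to_dict()
        manifest["results"][f"{analyte}_{state}"] = entry

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for analyte, bs in band_sets.items():
            bs.to_csv(outdir / f"bands_{analyte}.csv")
        for (analyte, state), bs in state_band_sets.items():
            bs.to_csv(outdir / f"bands_{analyte}_{state}.csv")
        for (analyte, state), cal in calibrations.items():
            ids = [m.sample_id for m in proc[state].samples]
            _write_calibration(
                outdir / f"calibration_{analyte}_{state}.csv", ids, cal
            )
        if config.write_twod_maps:
            for (analyte, state), tm in twod_maps.items():
                tm.to_frame().to_csv(
                    outdir / f"twod_{analyte}_{state}.csv",
                    index=False,
                    float_format="%.6g",
                )
        for f in sorted(outdir.glob("*.csv")):
            manifest["files"][f.name] = _sha256(f)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    log.info("pipeline complete in %.2fs", time.time() - t0)
    return RunReport(
        config=config,
        band_sets=band_sets,
        state_band_sets=state_band_sets,
        calibrations=calibrations,
        baselines=baselines,
        manifest=manifest,
    )
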