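"""Reading and writing spectra.

CSV is the canonical interchange format: one wide table with a
``wavenumber_cm-1`` column plus one column per sample, and a metadata
sidecar keyed on ``sample_id``.  JCAMP-DX is supported read-only for
single-spectrum ``##XYDATA=(X++(Y..Y))`` blocks.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SampleMeta, SampleState, SpectraSet, Spectrum, SpectrumKind

__all__ = ["read_spectra", "write_spectra", "read_jcamp", "read_metadata"]

WAVENUMBER_COLUMN = "wavenumber_cm-1"

_META_COLUMNS = [
    "sample_id",
    "level_id",
    "replicate_id",
    "state",
    "casein_conc",
    "nitrate_conc",
    "water_content",
]


def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Load a metadata sidecar CSV into a sample_id -> SampleMeta map."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {missing}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        wc = row.get("water_content")
        out[str(row["sample_id"])] = SampleMeta(
            sample_id=str(row["sample_id"]),
            level_id=int(row["level_id"]),
            replicate_id=int(row["replicate_id"]),
            state=SampleState(str(row["state"])),
            casein_conc=float(row["casein_conc"]),
            nitrate_conc=float(row["nitrate_conc"]),
            water_content=None if pd.isna(wc) else float(wc),
        )
    return out


def read_spectra(
    path: str | Path,
    metadata: str | Path | dict[str, SampleMeta],
    kind: SpectrumKind = SpectrumKind.REFLECTANCE,
) -> SpectraSet:
    """Read a wide spectra CSV and join its metadata sidecar.

    The first column is the wavenumber axis (either direction); every
    other column is one sample whose header must resolve in the
    metadata.  The grid is normalised to ascending order and the
    original direction recorded.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavenumber column plus >= 1 sample")
    if df.columns[0] != WAVENUMBER_COLUMN:
        raise ValueError(
            f"{path}: first column must be {WAVENUMBER_COLUMN!r}, "
            f"got {df.columns[0]!r}"
        )
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values (ragged column lengths?)")
    diffs = np.diff(wn)
    if np.all(diffs < 0):
        descending = True
        wn = wn[::-1]
        body = df.iloc[::-1, 1:]
    elif np.all(diffs > 0):
        descending = False
        body = df.iloc[:, 1:]
    else:
        raise ValueError(f"{path}: wavenumber axis is not monotonic")

    meta_map = metadata if isinstance(metadata, dict) else read_metadata(metadata)
    samples = []
    for sid in body.columns:
        if sid not in meta_map:
            raise KeyError(f"sample id {sid!r} has no metadata entry")
        samples.append(meta_map[sid])
    return SpectraSet(
        grid=wn,
        matrix=body.to_numpy(dtype=float).T,
        samples=samples,
        kind=kind,
        original_descending=descending,
    )


def write_spectra(
    spectra: SpectraSet, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write a SpectraSet as wide CSV at full float precision.

    When ``metadata_path`` is given the sidecar is written alongside.
    The round trip through :func:`read_spectra` is lossless (repr-exact
    floats).
    """
    cols = {WAVENUMBER_COLUMN: spectra.grid}
    for meta, row in zip(spectra.samples, spectra.matrix):
        cols[meta.sample_id] = row
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if metadata_path is not None:
        rows = [
            {
                "sample_id": m.sample_id,
                "level_id": m.level_id,
                "replicate_id": m.replicate_id,
                "state": m.state.value,
                "casein_conc": m.casein_conc,
                "nitrate_conc": m.nitrate_conc,
                "water_content": "" if m.water_content is None else m.water_content,
            }
            for m in spectra.samples
        ]
        pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(
            metadata_path, index=False, float_format="%.17g"
        )


# ---------------------------------------------------------------------
# JCAMP-DX (read-only, single spectrum, XYDATA=(X++(Y..Y)))
# ---------------------------------------------------------------------

_NUM = re.compile(r"[+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?")


def read_jcamp(path: str | Path, meta: SampleMeta,
               kind: SpectrumKind = SpectrumKind.REFLECTANCE) -> Spectrum:
    """Read one spectrum from a JCAMP-DX file.

    Supports the tabular ``##XYDATA=(X++(Y..Y))`` form: each data line
    starts with an X value followed by consecutive Y values at XFACTOR/
    YFACTOR scaling.  Compressed (SQZ/DIF/DUP) encodings are not
    supported.
    """
    xfactor = yfactor = 1.0
    deltax: float | None = None
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if in_data and label in {"END", "ENDXYDATA"}:
                break
            if label == "XFACTOR":
                xfactor = float(value)
            elif label == "YFACTOR":
                yfactor = float(value)
            elif label == "DELTAX":
                deltax = float(value)
            elif label == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise ValueError(
                        f"{path}: unsupported XYDATA form {value!r}"
                    )
                in_data = True
            continue
        if in_data:
            nums = [float(t) for t in _NUM.findall(line)]
            if len(nums) < 2:
                raise ValueError(f"{path}: malformed XYDATA line {raw!r}")
            x0 = nums[0] * xfactor
            yvals = [v * yfactor for v in nums[1:]]
            if deltax is None and len(yvals) > 1:
                raise ValueError(f"{path}: multiple Y per line requires ##DELTAX")
            for k, y in enumerate(yvals):
                xs.append(x0 + k * (deltax or 0.0))
                ys.append(y)
    if not xs:
        raise ValueError(f"{path}: no XYDATA block found")
    wn = np.asarray(xs)
    inten = np.asarray(ys)
    order = np.argsort(wn)
    return Spectrum(wn[order], inten[order], kind, meta)
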