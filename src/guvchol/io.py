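"""File I/O: TIFF spectral stacks, CSV decay histograms and tables, JSON models.

Formats are deliberately plain: multi-page TIFF (one page per spectral
channel) with a JSON sidecar for channel centers; decays and IRFs as CSV with
``time_ns`` / ``counts`` columns; calibration tables and vesicle records as
CSV with units in the header; fitted models as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationResults
from .flim import DecayHistogram
from .spectral_gp import SpectralStack, VesicleRecord

DEFAULT_CHANNEL_GRID = [float(c) for c in range(565, 700, 10)]


class ParseError(ValueError):
    """A file did not match the expected layout; the message names the field."""


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def save_stack(stack: SpectralStack, path) -> Path:
    """Write a spectral stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.data))
    sidecar = {
        "channel_centers_nm": [float(c) for c in stack.channel_centers],
        "pixel_size_um": stack.pixel_size_um,
        "meta": _jsonable(stack.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_stack(path) -> SpectralStack:
    """Read a multi-page TIFF spectral stack and its JSON sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_file = _sidecar_path(path)
    pixel_size = None
    meta: dict = {}
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        centers = sidecar.get("channel_centers_nm")
        pixel_size = sidecar.get("pixel_size_um")
        meta = sidecar.get("meta", {})
        if centers is None:
            warnings.warn(
                f"{sidecar_file.name}: missing channel_centers_nm; "
                "defaulting to the 565-695 nm / 10 nm grid",
                stacklevel=2,
            )
            centers = DEFAULT_CHANNEL_GRID[: data.shape[0]]
    else:
        warnings.warn(
            f"no sidecar JSON for {path.name}; defaulting channel centers",
            stacklevel=2,
        )
        centers = DEFAULT_CHANNEL_GRID[: data.shape[0]]
    if len(centers) != data.shape[0]:
        raise ParseError(
            f"channel_centers_nm has {len(centers)} entries but the TIFF has "
            f"{data.shape[0]} pages"
        )
    return SpectralStack(
        data=data, channel_centers=np.asarray(centers, dtype=float),
        pixel_size_um=pixel_size, meta=meta,
    )


def save_decay(hist: DecayHistogram, path) -> Path:
    """Write a decay histogram (and IRF, if present) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_ns": hist.bin_centers, "counts": hist.counts})
    if hist.irf_counts is not None:
        df["irf_counts"] = hist.irf_counts
    header = f"# rep_period_ns={hist.rep_period}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def load_decay(path, rep_period: float | None = None) -> DecayHistogram:
    """Read a decay CSV (columns ``time_ns``, ``counts``, optional ``irf_counts``)."""
    path = Path(path)
    period = rep_period
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("#").split(","):
                key, _, value = token.strip().partition("=")
                if key == "rep_period_ns" and period is None:
                    period = float(value)
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    for col in ("time_ns", "counts"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column '{col}'")
    t = df["time_ns"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ParseError(f"{path.name}: column 'time_ns' must be strictly increasing")
    width = t[1] - t[0]
    edges = np.concatenate([t - width / 2.0, [t[-1] + width / 2.0]])
    if period is None:
        period = float(edges[-1])
    irf = df["irf_counts"].to_numpy(dtype=float) if "irf_counts" in df.columns else None
    return DecayHistogram(
        bin_edges=edges, counts=df["counts"].to_numpy(), irf_counts=irf,
        rep_period=float(period),
    )


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"table not found: {path}")
    return pd.read_csv(path)


def save_records(records: list[VesicleRecord], path) -> Path:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return save_table(df, path)


def save_model(model: CalibrationResults, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dataclasses.asdict(model), indent=1))
    return path


def load_model(path) -> CalibrationResults:
    payload = json.loads(Path(path).read_text())
    for key in ("intercept", "slope", "se_intercept", "se_slope"):
        if key not in payload:
            raise ParseError(f"model JSON missing field '{key}'")
    return CalibrationResults(**payload)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
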