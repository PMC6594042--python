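"""File formats: multi-page TIFF stacks with JSON sidecars, trace and
metrics CSVs, ROI JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import AreaTrace, RoiMask
from .synthetic import MovieSpec

__all__ = [
    "write_stack",
    "read_stack",
    "write_rois",
    "read_rois",
    "write_traces",
    "read_traces",
]


def write_stack(
    path: str | Path,
    stack: np.ndarray,
    spec: MovieSpec,
    extra_sidecar: dict | None = None,
) -> Path:
    """Write a (frames, channels, h, w) stack as a frame-major,
    channel-interleaved multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    n, c, h, w = stack.shape
    tifffile.imwrite(path, stack.reshape(n * c, h, w))
    sidecar = {"movie_spec": dataclasses.asdict(spec)}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, MovieSpec, dict]:
    """Read a stack written by :func:`write_stack`; returns
    (stack, spec, sidecar)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    sd = dict(sidecar["movie_spec"])
    sd["channel_order"] = tuple(sd["channel_order"])
    spec = MovieSpec(**sd)
    pages = tifffile.imread(path)
    stack = pages.reshape(
        spec.n_frames, spec.n_channels, spec.height_px, spec.width_px
    )
    return stack, spec, sidecar


def write_rois(path: str | Path, rois: dict[str, RoiMask] | list[RoiMask]) -> Path:
    path = Path(path)
    items = list(rois.values()) if isinstance(rois, dict) else list(rois)
    path.write_text(json.dumps([r.to_dict() for r in items]))
    return path


def read_rois(path: str | Path) -> dict[str, RoiMask]:
    items = json.loads(Path(path).read_text())
    rois = [RoiMask.from_dict(d) for d in items]
    return {r.label: r for r in rois}


def write_traces(path: str | Path, traces: list[AreaTrace]) -> Path:
    path = Path(path)
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_traces(path: str | Path) -> dict[str, AreaTrace]:
    """Traces keyed by (recording_id, label) -> AreaTrace; single-recording
    files are also reachable by label alone."""
    df = pd.read_csv(path, keep_default_na=False)
    out: dict[str, AreaTrace] = {}
    for (rid, label), g in df.groupby(["recording_id", "label"], sort=False):
        g = g.sort_values("frame")
        tr = AreaTrace(
            t_s=g["t_s"].to_numpy(),
            area_um2=g["area_um2"].to_numpy(),
            label=str(label),
            recording_id=str(rid),
        )
        out[f"{rid}/{label}" if rid else str(label)] = tr
    return out
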