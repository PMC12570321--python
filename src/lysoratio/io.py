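"""Readers/writers and run provenance.

Stacks travel as multi-page TIFF (ImageJ-flavored, axes ZCYX) with a
JSON sidecar carrying channel roles and voxel calibration; tabular
results are CSV with a JSON provenance sidecar (parameter values,
package version, seed, input hashes) so any output can be traced back
to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .imaging import PH_DEP, PH_INDEP, ImageStack

__all__ = ["read_stack", "write_stack", "write_results", "file_sha256"]

_DEFAULT_ORDER = (PH_DEP, PH_INDEP)


def write_stack(stack: ImageStack, path, channel_order=None) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a JSON sidecar.

    Channels are interleaved as ZCYX pages in ``channel_order`` (default:
    pH-dependent then pH-independent, then any extras). Values are
    rounded and clipped into the unsigned 16-bit range; the number of
    clipped pixels is recorded in the sidecar.
    """
    path = Path(path)
    order = list(channel_order or [r for r in _DEFAULT_ORDER if r in stack.channels])
    order += [r for r in stack.channels if r not in order]
    arrs = [stack.channels[r] for r in order]
    data = np.stack(arrs, axis=1)  # (Z, C, Y, X)
    clipped = int(np.sum((data < 0) | (data > 65535)))
    u16 = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    kwargs = {}
    if stack.pixel_size:
        kwargs["resolution"] = (1.0 / stack.pixel_size, 1.0 / stack.pixel_size)
    tifffile.imwrite(
        path, u16, imagej=True,
        metadata={"axes": "ZCYX", "unit": "um",
                  "spacing": stack.z_spacing or 1.0},
        **kwargs,
    )
    sidecar = {
        "channel_order": order,
        "pixel_size_um": stack.pixel_size,
        "z_spacing_um": stack.z_spacing,
        "bit_depth": 16,
        "clipped_pixels": clipped,
        "meta": _jsonable(stack.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(
    path,
    channel_map: dict | None = None,
    pixel_size: float | None = None,
    z_spacing: float | None = None,
    pixels_mode: bool = False,
) -> ImageStack:
    """Read a two-channel TIFF stack into an :class:`ImageStack`.

    Channel roles come from ``channel_map`` (role -> channel index) or
    from the JSON sidecar written by :func:`write_stack`. A missing
    pixel size is an error unless ``pixels_mode`` is set, because the
    morphometry filters are defined in calibrated units.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    # normalize to ZCYX; readers drop singleton Z or C axes
    if set(axes) <= set("ZCYXSQIT") and data.ndim == len(axes):
        axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
        axes = axes.replace("T", "Z")
        for missing in set("ZC") - set(axes):
            data = data[None]
            axes = missing + axes
        order = [axes.index(a) for a in "ZCYX"]
        data = np.transpose(data, order)
    elif data.ndim == 3:
        data = data[:, None, :, :]
    if data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as ZCYX")

    if channel_map is None:
        order = sidecar.get("channel_order")
        if order is None:
            raise ValueError(
                "no channel_map given and no sidecar channel order found; "
                "pass channel_map={'ph_dependent': 0, 'ph_independent': 1, ...}"
            )
        channel_map = {role: i for i, role in enumerate(order)}
    for role in (PH_DEP, PH_INDEP):
        if role not in channel_map:
            raise ValueError(f"channel_map is missing required role {role!r}")

    px = pixel_size or sidecar.get("pixel_size_um")
    zs = z_spacing or sidecar.get("z_spacing_um")
    if px is None and not pixels_mode:
        raise ValueError(
            "stack has no pixel size; pass pixel_size= or pixels_mode=True"
        )
    channels = {role: data[:, idx].astype(np.float64)
                for role, idx in channel_map.items()}
    return ImageStack(channels, pixel_size=px, z_spacing=zs,
                      meta={"source": str(path), **sidecar.get("meta", {})})


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(
    table: pd.DataFrame, path, provenance: dict | None = None
) -> Path:
    """Write a tidy CSV plus a JSON provenance sidecar.

    Floats are written at 9 significant digits; an empty table still
    produces a header-only CSV. The sidecar records the package version
    and whatever parameters/seeds/hashes the caller passes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "package": "lysoratio",
        "version": __version__,
        "n_rows": int(len(table)),
        "columns": list(table.columns),
        **_jsonable(provenance or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path
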