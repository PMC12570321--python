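"""Quantification of two-channel confocal stacks.

The pipeline mirrors standard ratiometric endolysosomal pH analysis:

1. per-plane background correction (subtract the 5th-percentile pixel
   value of each image in the stack),
2. sum projection across z,
3. intensity threshold on the pH-independent channel to mask labeled
   compartments,
4. per-field ratio = sum(pH-dependent) / sum(pH-independent) inside the
   mask, or per-object ratios after splitting touching puncta,
5. ratio -> pH interpolation through a calibration curve.

Per-object mode works plane by plane: connected components above the
threshold are split into individual organelles when the intensity saddle
between two local maxima is deep enough (see :func:`segment_objects`),
then filtered by area and outer radius before their per-channel
integrated intensities and ratios are measured.

Also here: color-coded ratio images, photobleaching F/F0 curves, and
nuclei counting for cytotoxicity assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .calibration import CalibrationCurve, interpolate_ph

__all__ = [
    "ImageStack",
    "MaskResult",
    "OrganelleRecord",
    "SegmentationResult",
    "ObjectFilters",
    "FieldResult",
    "PhotobleachSeries",
    "background_correct",
    "sum_project",
    "make_mask",
    "field_ratio",
    "segment_objects",
    "object_ratios",
    "ratio_image",
    "photobleach_curve",
    "count_nuclei",
]

PH_DEP = "ph_dependent"
PH_INDEP = "ph_independent"
NUCLEAR = "nuclear"

U16_MAX = 65535.0


@dataclass
class ImageStack:
    """Multi-channel z-stack with voxel calibration.

    ``channels`` maps a role (``ph_dependent``, ``ph_independent``,
    optionally ``nuclear``) to a float array of shape (planes, rows,
    cols). ``pixel_size`` (um/px) may be None for pixels-mode work, but
    calibrated morphometry then refuses to run.
    """

    channels: dict
    pixel_size: float | None = None  # um per pixel (x == y)
    z_spacing: float | None = None  # um between planes
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()
        }
        for arr in self.channels.values():
            if arr.ndim != 3:
                raise ValueError("channels must be (planes, rows, cols)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"stack has no channel with role {role!r}")
        return self.channels[role]


def background_correct(stack: ImageStack, percentile: float = 5.0) -> ImageStack:
    """Subtract the per-plane Nth-percentile value from every channel.

    Negative results are clipped to zero. The subtracted values are
    logged in the output's ``meta["background_subtracted"]``.
    """
    corrected, log = {}, {}
    for role, arr in stack.channels.items():
        if arr.size == 0:
            raise ValueError("empty stack")
        subs = np.percentile(arr, percentile, axis=(1, 2))
        corrected[role] = np.clip(arr - subs[:, None, None], 0.0, None)
        log[role] = [float(s) for s in subs]
    meta = dict(stack.meta)
    meta["background_subtracted"] = log
    meta["background_corrected"] = True
    return ImageStack(corrected, stack.pixel_size, stack.z_spacing,
                      stack.bit_depth, meta)


def sum_project(stack: ImageStack) -> ImageStack:
    """Pixel-wise sum across planes (float64 accumulation, no overflow)."""
    if not stack.meta.get("background_corrected", False):
        warnings.warn("sum-projecting a stack that was not background-corrected",
                      stacklevel=2)
    projected = {k: v.sum(axis=0, keepdims=True) for k, v in stack.channels.items()}
    meta = dict(stack.meta)
    meta["projected"] = True
    return ImageStack(projected, stack.pixel_size, stack.z_spacing,
                      stack.bit_depth, meta)


@dataclass(frozen=True)
class MaskResult:
    mask: np.ndarray  # bool
    threshold: float
    method: str

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def make_mask(reference_image: np.ndarray, method="otsu") -> MaskResult:
    """Threshold the pH-independent reference image into a binary mask.

    ``method`` is ``"otsu"``, ``("fixed", value)`` or ``("percentile", p)``.
    The mask selects pixels >= threshold; the threshold used is recorded.
    """
    img = np.asarray(reference_image, float)
    img2d = img[0] if img.ndim == 3 and img.shape[0] == 1 else img
    if isinstance(method, str) and method == "otsu":
        if np.ptp(img2d) == 0:
            raise ValueError("constant image: Otsu threshold undefined")
        thr = float(threshold_otsu(img2d))
        name = "otsu"
    else:
        kind, value = method
        if kind == "fixed":
            thr = float(value)
            name = f"fixed:{value:g}"
        elif kind == "percentile":
            thr = float(np.percentile(img2d, value))
            name = f"percentile:{value:g}"
        else:
            raise ValueError(f"unknown mask method {method!r}")
    mask = img2d >= thr
    if not mask.any():
        warnings.warn("mask is empty at the chosen threshold", stacklevel=2)
    return MaskResult(mask=mask, threshold=thr, method=name)


@dataclass
class FieldResult:
    """Per-field quantification summary."""

    ratio: float  # NaN when undefined (empty mask)
    n_mask_pixels: int
    intensity_ph_dep: float
    intensity_ph_indep: float
    threshold: float
    ph: float = np.nan
    ph_flag: str = ""
    n_objects: int | None = None
    ids: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ratio)


def field_ratio(
    projection: ImageStack,
    mask: MaskResult,
    calibration: CalibrationCurve | None = None,
    ids: dict | None = None,
) -> FieldResult:
    """Whole-field ratio of masked integrated intensities."""
    dep = projection.channel(PH_DEP)
    ref = projection.channel(PH_INDEP)
    dep2d = dep.sum(axis=0) if dep.ndim == 3 else dep
    ref2d = ref.sum(axis=0) if ref.ndim == 3 else ref
    if mask.mask.shape != dep2d.shape:
        raise ValueError("mask shape does not match the projection")
    s_dep = float(dep2d[mask.mask].sum())
    s_ref = float(ref2d[mask.mask].sum())
    if mask.empty or s_ref <= 0:
        return FieldResult(np.nan, int(mask.mask.sum()), s_dep, s_ref,
                           mask.threshold, ph_flag="empty_mask", ids=ids or {})
    ratio = s_dep / s_ref
    res = FieldResult(ratio, int(mask.mask.sum()), s_dep, s_ref,
                      mask.threshold, ids=ids or {})
    if calibration is not None:
        p = interpolate_ph(ratio, calibration)
        res.ph = p.ph
        if p.non_interpolatable:
            res.ph_flag = f"non_interpolatable_{p.side}"
        elif p.extrapolated:
            res.ph_flag = "extrapolated"
    return res


# ---------------------------------------------------------------------------
# per-object segmentation


@dataclass(frozen=True)
class ObjectFilters:
    """Morphometry filters in calibrated units (um^2 / um) or pixels."""

    area: tuple[float, float] = (10.0, 1500.0)
    outer_radius: tuple[float, float] = (0.0, 1000.0)
    units: str = "calibrated"  # "calibrated" | "pixel"


@dataclass
class OrganelleRecord:
    """One segmented compartment on one plane."""

    object_id: int
    plane: int
    rows: np.ndarray
    cols: np.ndarray
    centroid: tuple[float, float]  # (row, col), pixel centers, 0-based
    peak: float
    area: float  # calibrated units (or px^2 in pixel mode)
    outer_radius: float
    intensity_ph_dep: float = np.nan
    intensity_ph_indep: float = np.nan
    ratio: float = np.nan
    ph: float = np.nan
    flags: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)


@dataclass
class SegmentationResult:
    records: list
    discards: pd.DataFrame  # object_id, plane, area, outer_radius, reason
    threshold: float
    split_rule: str


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _flood_split(img: np.ndarray, mask: np.ndarray, split_rule: str,
                 saddle_fraction: float = 0.5):
    """Label above-threshold pixels into objects by descending flooding.

    Pixels are visited from brightest to dimmest (ties broken by index,
    so the result is deterministic). A pixel with no brighter neighbor
    seeds a new object at a local maximum; a pixel joining two existing
    objects sits at their saddle, whose value decides whether the two
    stay separate:

    * ``"saddle"`` (default): separate iff saddle <= saddle_fraction *
      lower peak (the valley between the two Gaussians is deep enough);
    * ``"peak_ratio"`` (literal reading of the 50% rule): separate iff
      the lower peak <= saddle_fraction * higher peak;
    * ``"none"``: plain connected components (always merge).

    Returns an int label image (0 = unlabeled) and a dict of root label
    -> peak value.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.zeros(img.shape, dtype=int), {}
    vals = img[rows, cols]
    order = np.lexsort((np.arange(rows.size), -vals))  # descending, stable

    labels = np.zeros(img.shape, dtype=int)
    parent: dict[int, int] = {}
    peak: dict[int, float] = {}
    nlab = 0
    h, w = img.shape

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        v = float(vals[idx])
        neighbor_roots: list[int] = []
        best_root, best_val = 0, -np.inf
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc]:
                root = find(labels[rr, cc])
                if root not in neighbor_roots:
                    neighbor_roots.append(root)
                nv = img[rr, cc]
                if nv > best_val:
                    best_val, best_root = nv, root
        if not neighbor_roots:
            nlab += 1
            labels[r, c] = nlab
            parent[nlab] = nlab
            peak[nlab] = v
            continue
        labels[r, c] = best_root
        for root in neighbor_roots:
            if root == best_root:
                continue
            a, b = find(best_root), find(root)
            if a == b:
                continue
            pa, pb = peak[a], peak[b]
            lo_peak, hi_peak = min(pa, pb), max(pa, pb)
            if split_rule == "saddle":
                separate = v <= saddle_fraction * lo_peak
            elif split_rule == "peak_ratio":
                separate = lo_peak <= saddle_fraction * hi_peak
            elif split_rule == "none":
                separate = False
            else:
                raise ValueError(f"unknown split_rule {split_rule!r}")
            if not separate:
                parent[b] = a
                peak[a] = hi_peak
    roots = {}
    flat = labels.ravel()
    nz = flat > 0
    lut = np.arange(nlab + 1)
    for lab in range(1, nlab + 1):
        lut[lab] = find(lab)
    flat[nz] = lut[flat[nz]]
    for lab in np.unique(flat[nz]):
        roots[int(lab)] = peak[int(lab)]
    return labels, roots


def segment_objects(
    plane: np.ndarray,
    threshold: float | MaskResult | None = None,
    split_rule: str = "saddle",
    filters: ObjectFilters = ObjectFilters(),
    pixel_size: float | None = None,
    plane_index: int = 0,
) -> SegmentationResult:
    """Segment one plane of the pH-independent channel into organelles.

    ``threshold`` may be a number, a precomputed :class:`MaskResult`, or
    None (Otsu on the plane). Touching objects are split per
    ``split_rule`` (see :func:`_flood_split`). Area and outer radius
    (max centroid-to-pixel distance) are computed in calibrated units
    from ``pixel_size`` unless ``filters.units == "pixel"``; records
    failing the filters go to the discard table with a reason.
    """
    img = np.asarray(plane, float)
    if img.ndim != 2:
        raise ValueError("segment_objects works on a single 2-D plane")
    if filters.units == "calibrated":
        if pixel_size is None:
            raise ValueError(
                "calibrated-unit filters need a pixel size; "
                "use ObjectFilters(units='pixel') for uncalibrated images"
            )
        scale = float(pixel_size)
    elif filters.units == "pixel":
        scale = 1.0
    else:
        raise ValueError(f"unknown filter units {filters.units!r}")

    if isinstance(threshold, MaskResult):
        mask_res = threshold
    elif threshold is None:
        mask_res = make_mask(img, "otsu")
    else:
        mask_res = make_mask(img, ("fixed", float(threshold)))

    labels, peaks = _flood_split(img, mask_res.mask, split_rule)

    records, discards = [], []
    next_id = 1
    for lab in sorted(peaks):
        rr, cc = np.nonzero(labels == lab)
        cy, cx = float(rr.mean()), float(cc.mean())
        area = rr.size * scale**2
        radius = float(np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2).max()) * scale
        rec = OrganelleRecord(
            object_id=next_id, plane=plane_index, rows=rr, cols=cc,
            centroid=(cy, cx), peak=peaks[lab], area=area, outer_radius=radius,
        )
        next_id += 1
        reason = None
        if not filters.area[0] <= area <= filters.area[1]:
            reason = "area"
        elif not filters.outer_radius[0] <= radius <= filters.outer_radius[1]:
            reason = "outer_radius"
        if reason is None:
            records.append(rec)
        else:
            discards.append(
                {"object_id": rec.object_id, "plane": plane_index,
                 "area": area, "outer_radius": radius,
                 "n_pixels": rr.size, "reason": reason}
            )
    discard_df = pd.DataFrame(
        discards,
        columns=["object_id", "plane", "area", "outer_radius", "n_pixels",
                 "reason"],
    )
    return SegmentationResult(records, discard_df, mask_res.threshold, split_rule)


def object_ratios(
    records: Sequence[OrganelleRecord],
    stack: ImageStack,
    calibration: CalibrationCurve | None = None,
) -> list:
    """Measure per-object integrated intensities, ratios and pH in place."""
    dep = stack.channel(PH_DEP)
    ref = stack.channel(PH_INDEP)
    for rec in records:
        d = float(dep[rec.plane, rec.rows, rec.cols].sum())
        r = float(ref[rec.plane, rec.rows, rec.cols].sum())
        rec.intensity_ph_dep = d
        rec.intensity_ph_indep = r
        rec.ratio = d / r if r > 0 else np.nan
        if calibration is not None and np.isfinite(rec.ratio):
            p = interpolate_ph(rec.ratio, calibration)
            rec.ph = p.ph
            if p.non_interpolatable:
                rec.flags["non_interpolatable"] = p.side
            if p.extrapolated:
                rec.flags["extrapolated"] = True
    return list(records)


def records_to_frame(records: Sequence[OrganelleRecord]) -> pd.DataFrame:
    """Tidy per-object table (documented schema, one row per object)."""
    rows = [
        {
            "object_id": r.object_id,
            "plane": r.plane,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "n_pixels": r.n_pixels,
            "area": r.area,
            "outer_radius": r.outer_radius,
            "intensity_ph_dep": r.intensity_ph_dep,
            "intensity_ph_indep": r.intensity_ph_indep,
            "ratio": r.ratio,
            "ph": r.ph,
            "flags": ";".join(
                f"{k}={v}" for k, v in sorted(r.flags.items())
            ),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["object_id", "plane", "centroid_row", "centroid_col",
                 "n_pixels", "area", "outer_radius", "intensity_ph_dep",
                 "intensity_ph_indep", "ratio", "ph", "flags"],
    )


# ---------------------------------------------------------------------------
# color-coded ratio images


def _build_lut() -> np.ndarray:
    """Versioned 256-entry blue -> green -> red LUT (v1).

    Blue encodes the least acidic end of the displayed ratio range; for
    an acid-bright probe larger ratios (more acidic) run toward red.
    """
    idx = np.arange(256)
    r = np.interp(idx, [0, 127.5, 255], [0, 0, 255])
    g = np.interp(idx, [0, 127.5, 255], [0, 255, 0])
    b = np.interp(idx, [0, 127.5, 255], [255, 0, 0])
    return np.stack([r, g, b], axis=1).round().astype(np.uint8)


RATIO_LUT_V1 = _build_lut()

#: 7x7 Gaussian smoothing kernel: sigma chosen so the kernel effectively
#: spans 7 pixels, then truncated to exactly a 7x7 footprint.
RATIO_FILTER_SIGMA = 7.0 / 6.0
_RATIO_FILTER_TRUNCATE = 3.0 / RATIO_FILTER_SIGMA


def ratio_image(
    projection: ImageStack,
    min_ratio: float,
    max_ratio: float,
    threshold_method="otsu",
) -> np.ndarray:
    """Color-coded per-pixel ratio image (8-bit RGB).

    The pH-independent channel is thresholded into a mask applied to both
    channels, each channel is smoothed with a 7x7 Gaussian, and the
    pixel-wise ratio inside the mask is clipped to [min_ratio, max_ratio]
    and mapped linearly through the blue->green->red LUT. Pixels outside
    the mask are black.
    """
    if not min_ratio < max_ratio:
        raise ValueError("require min_ratio < max_ratio")
    dep = projection.channel(PH_DEP)
    ref = projection.channel(PH_INDEP)
    dep2d = dep.sum(axis=0) if dep.ndim == 3 else dep
    ref2d = ref.sum(axis=0) if ref.ndim == 3 else ref
    mask = make_mask(ref2d, threshold_method).mask

    dep_f = ndimage.gaussian_filter(
        np.where(mask, dep2d, 0.0), RATIO_FILTER_SIGMA,
        truncate=_RATIO_FILTER_TRUNCATE,
    )
    ref_f = ndimage.gaussian_filter(
        np.where(mask, ref2d, 0.0), RATIO_FILTER_SIGMA,
        truncate=_RATIO_FILTER_TRUNCATE,
    )
    out = np.zeros(dep2d.shape + (3,), dtype=np.uint8)
    valid = mask & (ref_f > 0)
    ratio = np.zeros_like(dep_f)
    ratio[valid] = dep_f[valid] / ref_f[valid]
    clipped = np.clip(ratio[valid], min_ratio, max_ratio)
    idx = np.round(
        (clipped - min_ratio) / (max_ratio - min_ratio) * 255.0
    ).astype(int)
    out[valid] = RATIO_LUT_V1[idx]
    return out


# ---------------------------------------------------------------------------
# photobleaching


@dataclass
class PhotobleachSeries:
    """F/F0 per irradiation cycle for one field/well."""

    table: pd.DataFrame  # cycle, intensity, f_over_f0
    probe: str = ""
    ids: dict = field(default_factory=dict)

    @property
    def f_over_f0(self) -> np.ndarray:
        return self.table["f_over_f0"].to_numpy()

    @property
    def fraction_lost(self) -> float:
        return float(1.0 - self.f_over_f0[-1])


def photobleach_curve(
    intensities: Sequence[float], probe: str = "", ids: dict | None = None
) -> PhotobleachSeries:
    """Normalize per-cycle integrated field intensities to the first cycle."""
    f = np.asarray(intensities, float)
    if f.size < 2:
        raise ValueError("need >= 2 irradiation cycles")
    if f[0] <= 0:
        raise ValueError("first-cycle intensity must be positive")
    table = pd.DataFrame(
        {"cycle": np.arange(1, f.size + 1), "intensity": f, "f_over_f0": f / f[0]}
    )
    return PhotobleachSeries(table, probe=probe, ids=ids or {})


# ---------------------------------------------------------------------------
# nuclei counting


def count_nuclei(
    nuclear_image: np.ndarray,
    pixel_size: float,
    min_width: float = 5.0,
    max_width: float = 30.0,
    local_threshold: float = 100.0,
) -> int:
    """Count nuclei on a (sum-projected) nuclear-stain image.

    Local background is estimated by grey opening with a footprint wider
    than the largest nucleus, so blobs up to ``max_width`` are removed
    from the background estimate. Pixels >= ``local_threshold`` gray
    levels above that background are labeled, and components with an
    equivalent diameter between ``min_width`` and ``max_width`` (um) are
    counted.
    """
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("count_nuclei needs a calibrated image (pixel size)")
    img = np.asarray(nuclear_image, float)
    img2d = img.sum(axis=0) if img.ndim == 3 else img
    size = max(3, int(np.ceil(1.5 * max_width / pixel_size)) | 1)
    background = ndimage.grey_opening(img2d, size=(size, size))
    fg = (img2d - background) >= local_threshold
    labels, n = ndimage.label(fg)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    diam_um = 2.0 * np.sqrt(areas / np.pi) * pixel_size
    return int(np.sum((diam_um >= min_width) & (diam_um <= max_width)))
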