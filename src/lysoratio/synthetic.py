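"""Synthetic inputs for every pipeline stage.

No public microscope data accompanies the methodology this package
implements, so each stage is validated by parameter recovery on
simulated inputs with known ground truth:

* plate-reader titrations generated from a :class:`~lysoratio.probes.ProbeModel`
  with multiplicative replicate noise,
* two-channel confocal z-stacks of punctate organelles (late
  endosomes/lysosomes) with per-organelle true pH, diffuse background,
  PSF blur, Poisson shot noise and Gaussian read noise,
* photobleaching decay series, and
* treatment-induced pH shifts (e.g. methylamine alkalinization).

Organelles are rendered as isotropic 3-D Gaussians (sigma = radius / 2)
rather than hard spheres: that matches the blurred confocal appearance
of sub-resolution puncta and keeps every integral closed-form for test
oracles. The pH-independent channel carries each organelle's "load"
(probe amount); the pH-dependent channel shares the geometry with its
amplitude multiplied by sigmoid(probe, true pH) / reference_response, so
load cancels exactly in the noiseless per-organelle ratio.

All randomness flows from one seeded generator per call; identical seed
and config give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import PH_DEP, PH_INDEP, ImageStack, PhotobleachSeries, photobleach_curve
from .probes import APHID_LIKE, ProbeModel, sigmoid_value
from .spectroscopy import TitrationSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "simulate_titration",
    "sample_ground_truth",
    "render_stack",
    "simulate_stack",
    "simulate_photobleach",
    "apply_treatment",
]

PH_TRUNCATION = (3.0, 7.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated two-channel field.

    Distances are um; intensities arbitrary units (a.u.). ``photon_scale``
    is photons per a.u. for shot noise (``inf`` disables it);
    ``load_lognorm`` are the (mu, sigma) of log integrated pH-independent
    brightness per organelle.
    """

    shape: tuple[int, int, int] = (5, 256, 256)  # planes, rows, cols
    pixel_size: float = 0.2
    z_spacing: float = 1.5
    n_organelles: int = 50
    organelle_radius: tuple[float, float] = (0.5, 0.1)  # mean, sd (um)
    organelle_ph: tuple[float, float] = (5.1, 0.2)  # mean, sd (pH units)
    load_lognorm: tuple[float, float] = (9.9, 0.4)  # mu, sigma of log load
    background: float = 100.0
    background_gradient: float = 20.0  # ~20% flat-field nonuniformity
    psf_sigma: float = 0.2  # um, lateral
    psf_sigma_z: float = 0.6  # um, axial (confocal axial PSF is ~3x wider)
    read_noise_sd: float = 5.0
    photon_scale: float = 1.0  # photons per a.u.; inf = no shot noise
    seed: int = 0
    probe: ProbeModel = APHID_LIKE
    reference_response: float = 1.0

    def __post_init__(self) -> None:
        nums = (
            self.pixel_size, self.z_spacing, *self.organelle_radius,
            *self.organelle_ph, *self.load_lognorm, self.background,
            self.background_gradient, self.psf_sigma, self.psf_sigma_z,
            self.read_noise_sd,
            self.reference_response,
        )
        if not all(np.isfinite(nums)):
            raise ValueError("non-finite simulation parameter")
        if self.n_organelles < 0:
            raise ValueError("n_organelles must be >= 0")
        if self.reference_response <= 0:
            raise ValueError("reference_response must be positive")

    def without_noise(self) -> "SimulationConfig":
        """Same field with shot and read noise disabled."""
        return replace(self, read_noise_sd=0.0, photon_scale=np.inf)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions: 50 LE/Lys, pH ~ N(5.1, 0.2)."""
    return replace(SimulationConfig(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Per-organelle truth for one simulated field."""

    organelles: pd.DataFrame  # z, y, x (px), radius_um, ph, load
    treatment_shift: float = 0.0
    probe: ProbeModel = APHID_LIKE
    reference_response: float = 1.0

    @property
    def mean_ph(self) -> float:
        return float(self.organelles["ph"].mean()) if len(self.organelles) else np.nan

    def to_csv(self, path) -> None:
        self.organelles.to_csv(path, index=False)


def simulate_titration(
    probe: ProbeModel,
    ph_grid: Sequence[float],
    replicates: int = 2,
    noise_cv: float = 0.02,
    seed: int = 0,
    assay: str = "fluorescence",
) -> TitrationSeries:
    """Plate-reader titration: sigmoid(probe, pH) x (1 + eps) per replicate.

    ``eps ~ Normal(0, noise_cv)`` independently per well; deterministic
    for a fixed seed.
    """
    ph = np.asarray(ph_grid, float)
    if ph.size == 0 or not np.all(np.diff(ph) > 0):
        raise ValueError("ph_grid must be nonempty and strictly increasing")
    if replicates < 1 or noise_cv < 0:
        raise ValueError("need replicates >= 1 and noise_cv >= 0")
    rng = np.random.default_rng(seed)
    clean = sigmoid_value(probe, ph)
    rows = []
    for rep in range(replicates):
        eps = rng.normal(0.0, noise_cv, size=ph.size) if noise_cv > 0 else 0.0
        rows.append(
            pd.DataFrame({"ph": ph, "signal": clean * (1.0 + eps), "replicate": rep})
        )
    return TitrationSeries(
        probe.name, pd.concat(rows, ignore_index=True), assay=assay
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draws resampled into [lo, hi] (exact truncation by rejection)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw per-organelle geometry, pH and load for one field."""
    rng = np.random.default_rng(config.seed)
    planes, nrows, ncols = config.shape
    n = config.n_organelles
    if n == 0:
        df = pd.DataFrame(
            columns=["z", "y", "x", "radius_um", "ph", "load"], dtype=float
        )
        return GroundTruth(df, probe=config.probe,
                           reference_response=config.reference_response)
    radius = np.clip(
        rng.normal(*config.organelle_radius, n), 0.05, None
    )  # um; floor keeps degenerate draws renderable
    ph = _truncated_normal(rng, *config.organelle_ph, *PH_TRUNCATION, n)
    load = rng.lognormal(*config.load_lognorm, n)
    margin = np.clip(3.0 * radius / 2.0 / config.pixel_size, 1.0,
                     min(nrows, ncols) / 4.0)
    df = pd.DataFrame(
        {
            "z": rng.uniform(0, planes, n),
            "y": rng.uniform(margin, nrows - margin, n),
            "x": rng.uniform(margin, ncols - margin, n),
            "radius_um": radius,
            "ph": ph,
            "load": load,
        }
    )
    return GroundTruth(df, probe=config.probe,
                       reference_response=config.reference_response)


def render_stack(config: SimulationConfig, truth: GroundTruth) -> ImageStack:
    """Render the two channels for a given ground truth.

    pH-independent channel: background (+ linear gradient) plus one 3-D
    Gaussian per organelle whose integral is the organelle's load.
    pH-dependent channel: same geometry with each amplitude multiplied by
    sigmoid(probe, true pH) / reference_response. Both channels are then
    PSF-blurred, shot noise applied at ``photon_scale``, read noise
    added, and values clipped to the unsigned 16-bit range.

    Noise draws come from a generator derived from ``config.seed`` but
    independent of the ground-truth draws, so a treated (pH-shifted)
    field re-renders with identical geometry and noise stream.
    """
    planes, nrows, ncols = config.shape
    org = truth.organelles

    grad = (
        config.background_gradient * np.linspace(0.0, 1.0, ncols)[None, None, :]
        if config.background_gradient
        else 0.0
    )
    ref = np.full(config.shape, float(config.background)) + grad
    dep = ref.copy()

    for row in org.itertuples(index=False):
        sz = row.radius_um / 2.0 / config.z_spacing  # voxels
        sy = sx = row.radius_um / 2.0 / config.pixel_size
        # integral of the continuous 3-D Gaussian == load
        amp = row.load / ((2.0 * np.pi) ** 1.5 * sz * sy * sx)
        wy0 = max(0, int(row.y - 5 * sy))
        wy1 = min(nrows, int(row.y + 5 * sy) + 2)
        wx0 = max(0, int(row.x - 5 * sx))
        wx1 = min(ncols, int(row.x + 5 * sx) + 2)
        gz = np.exp(-((np.arange(planes) - row.z) ** 2) / (2 * sz**2))
        gy = np.exp(-((np.arange(wy0, wy1) - row.y) ** 2) / (2 * sy**2))
        gx = np.exp(-((np.arange(wx0, wx1) - row.x) ** 2) / (2 * sx**2))
        blob = amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        bright = float(sigmoid_value(truth.probe, row.ph))
        ref[:, wy0:wy1, wx0:wx1] += blob
        dep[:, wy0:wy1, wx0:wx1] += blob * (bright / truth.reference_response)

    if config.psf_sigma > 0 or config.psf_sigma_z > 0:
        sigmas = (
            config.psf_sigma_z / config.z_spacing,
            config.psf_sigma / config.pixel_size,
            config.psf_sigma / config.pixel_size,
        )
        ref = ndimage.gaussian_filter(ref, sigmas, mode="nearest")
        dep = ndimage.gaussian_filter(dep, sigmas, mode="nearest")

    noise_rng = np.random.default_rng([config.seed, 1])
    clipped = 0
    channels = {}
    for name, img in ((PH_INDEP, ref), (PH_DEP, dep)):
        if np.isfinite(config.photon_scale):
            img = noise_rng.poisson(img * config.photon_scale) / config.photon_scale
        if config.read_noise_sd > 0:
            img = img + noise_rng.normal(0.0, config.read_noise_sd, img.shape)
        clipped += int(np.sum((img < 0) | (img > 65535)))
        channels[name] = np.clip(img, 0.0, 65535.0)

    return ImageStack(
        channels,
        pixel_size=config.pixel_size,
        z_spacing=config.z_spacing,
        meta={"seed": config.seed, "clipped_pixels": clipped, "synthetic": True},
    )


def simulate_stack(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Draw a ground truth and render its two-channel stack."""
    truth = sample_ground_truth(config)
    return render_stack(config, truth), truth


def simulate_photobleach(
    f0: float,
    fraction_lost: float,
    n_cycles: int = 50,
    noise_cv: float = 0.0,
    seed: int = 0,
    probe: str = "",
) -> PhotobleachSeries:
    """Exponential photobleaching decay over irradiation cycles.

    The noiseless series decays geometrically from ``f0`` at cycle 1 to
    exactly ``(1 - fraction_lost) * f0`` at the final cycle; optional
    multiplicative Normal(0, noise_cv) noise is applied per cycle before
    F/F0 normalization.
    """
    if not 0.0 <= fraction_lost < 1.0:
        raise ValueError("fraction_lost must be in [0, 1)")
    if n_cycles < 2:
        raise ValueError("need >= 2 cycles")
    rng = np.random.default_rng(seed)
    cycles = np.arange(n_cycles)
    f = f0 * (1.0 - fraction_lost) ** (cycles / (n_cycles - 1))
    if noise_cv > 0:
        f = f * (1.0 + rng.normal(0.0, noise_cv, n_cycles))
    return photobleach_curve(f, probe=probe)


def match_objects(records, truth: GroundTruth, max_dist_px: float = 5.0):
    """Pair segmented objects with ground-truth organelles.

    Each record is matched to the nearest truth organelle whose center
    lies within ``max_dist_px`` in-plane and within half a plane in z;
    unmatched records get ``true_ph`` NaN. Returns a tidy frame with one
    row per record (object_id, plane, ph, true_ph, error).
    """
    org = truth.organelles
    rows = []
    for rec in records:
        true_ph = np.nan
        if len(org):
            cand = org[np.abs(org["z"] - rec.plane) <= 0.75]
            if len(cand):
                d = np.hypot(cand["y"] - rec.centroid[0],
                             cand["x"] - rec.centroid[1])
                j = d.idxmin()
                if d[j] <= max_dist_px:
                    true_ph = float(org.loc[j, "ph"])
        rows.append(
            {"object_id": rec.object_id, "plane": rec.plane,
             "ratio": rec.ratio, "ph": rec.ph, "true_ph": true_ph,
             "error": rec.ph - true_ph}
        )
    return pd.DataFrame(rows)


def apply_treatment(truth: GroundTruth, delta_ph: float) -> GroundTruth:
    """Shift every organelle's true pH by ``delta_ph`` (alkalinizing > 0).

    Shifted values are re-truncated to the physiological range
    [3.0, 7.5]; the applied shift is recorded cumulatively.
    """
    organelles = truth.organelles.copy()
    if len(organelles):
        organelles["ph"] = np.clip(organelles["ph"] + delta_ph, *PH_TRUNCATION)
    return GroundTruth(
        organelles,
        treatment_shift=truth.treatment_shift + delta_ph,
        probe=truth.probe,
        reference_response=truth.reference_response,
    )
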