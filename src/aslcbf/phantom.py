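"""Synthetic multi-tissue brain phantom and forward ASL signal simulation.

The phantom is three concentric ellipsoids — a CSF "ventricle" core, a
white-matter shell and an outer gray-matter shell — with smooth partial-volume
ramps (at least two voxels wide) between compartments.  Five azimuthal sectors
of the gray-matter shell stand in for the frontal, parietal, PRCPCC, temporal
and occipital cortical regions; the remaining brain tissue is labelled
"other".  Ground-truth perfusion follows the two-tissue mixing law

    true_cbf = pve_gm * c_GM(region) + pve_wm * c_WM

with CSF perfusion zero, so partial-volume correction has an exact target.

``simulate_asl`` inverts the single-compartment quantification equation to
produce a difference image whose noise-free quantification reproduces
``true_cbf`` to machine precision, then adds seeded Gaussian noise scaled to
the mean absolute difference signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParams, VolumeStack, quantification_factor
from .regions import OTHER_BRAIN_LABEL, REGION_LABELS

__all__ = ["PhantomConfig", "PhantomTruth", "build_phantom", "simulate_asl"]

# Regional gray-matter perfusion defaults (mL/100 g/min), calibrated so the
# uncorrected regional means of the default phantom land on the magnitudes
# typical of an Alzheimer's-dementia memory-clinic cohort.
DEFAULT_GM_CBF: dict[str, float] = {
    "frontal": 18.7,
    "parietal": 23.9,
    "prcpcc": 30.2,
    "temporal": 21.8,
    "occipital": 29.1,
    "other": 25.0,
}

# Ellipsoid radii as fractions of the brain semi-axes: CSF core, white-matter
# shell, gray-matter shell out to the brain surface.
_RHO_CSF = 0.22
_RHO_WM = 0.62
_RHO_BRAIN = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, ground-truth perfusion and noise level of the phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 1.7)
    true_gm_cbf_by_region: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GM_CBF)
    )
    true_wm_cbf: float = 20.0
    noise_sd_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be three axes, each >= 8 voxels")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive spacings")
        missing = set(REGION_LABELS) - set(self.true_gm_cbf_by_region)
        if missing:
            raise ValueError(f"true_gm_cbf_by_region missing regions: {sorted(missing)}")
        if any(v < 0 for v in self.true_gm_cbf_by_region.values()):
            raise ValueError("true gray-matter CBF values must be >= 0")
        if self.true_wm_cbf < 0:
            raise ValueError("true_wm_cbf must be >= 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")

    @property
    def gm_cbf_with_other(self) -> dict[str, float]:
        d = dict(self.true_gm_cbf_by_region)
        d.setdefault("other", DEFAULT_GM_CBF["other"])
        return d


@dataclass
class PhantomTruth:
    """Ground-truth tissue fractions, region labels and perfusion."""

    pve_gm: np.ndarray
    pve_wm: np.ndarray
    pve_csf: np.ndarray
    region_labels: np.ndarray
    true_cbf: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    config: PhantomConfig | None = None

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.pve_gm + self.pve_wm + self.pve_csf) > 0


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _ramp(rho: np.ndarray, edge: float, width: float) -> np.ndarray:
    """0 inside the edge, 1 outside, smooth over ``width`` (centred on edge)."""
    return _smoothstep((rho - (edge - width / 2.0)) / width)


def build_phantom(config: PhantomConfig) -> PhantomTruth:
    """Construct the concentric-ellipsoid phantom for a configuration.

    Deterministic: geometry depends only on the grid and spacings.  Raises if
    the grid is too small for three distinct compartments with smooth ramps.
    """
    shape = tuple(int(n) for n in config.grid_shape)
    voxel = tuple(float(v) for v in config.voxel_size_mm)

    coords = [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel)
    ]
    semi_axes = [0.92 * (n - 1) / 2.0 * v for n, v in zip(shape, voxel)]
    xs = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt(sum((x / a) ** 2 for x, a in zip(xs, semi_axes)))

    # Partial-volume ramps two voxels wide (in units of normalized radius).
    width = 2.0 * max(v / a for v, a in zip(voxel, semi_axes))
    if width >= (_RHO_WM - _RHO_CSF) or width >= (_RHO_BRAIN - _RHO_WM):
        raise ValueError(
            "grid too small: partial-volume ramps would merge the tissue "
            "compartments; enlarge grid_shape"
        )

    u_csf = _ramp(rho, _RHO_CSF, width)     # 0 in CSF core, 1 outside it
    u_wm = _ramp(rho, _RHO_WM, width)       # 0 inside WM shell, 1 in GM
    u_out = _ramp(rho, _RHO_BRAIN, width)   # 0 inside brain, 1 outside

    pve_csf = 1.0 - u_csf
    pve_wm = u_csf * (1.0 - u_wm)
    pve_gm = u_csf * u_wm * (1.0 - u_out)
    pve_sum = pve_csf + pve_wm + pve_gm
    brain = pve_sum > 0

    # Azimuthal sectors in the x-y plane carve the GM shell into the five
    # named regions; GM-dominant voxels (pve_gm >= 0.5) get sector labels.
    theta = np.arctan2(xs[1], xs[0])  # [-pi, pi)
    sector = np.floor((theta + np.pi) / (2.0 * np.pi) * 5.0).astype(int)
    sector = np.clip(sector, 0, 4) + 1
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = OTHER_BRAIN_LABEL
    gm_dominant = brain & (pve_gm >= 0.5)
    labels[gm_dominant] = sector[gm_dominant]

    for name, code in REGION_LABELS.items():
        if not np.any(labels == code):
            raise ValueError(
                f"grid too small: region {name!r} received no voxels"
            )

    gm_cbf = config.gm_cbf_with_other
    c_gm_by_code = np.zeros(OTHER_BRAIN_LABEL + 1)
    for name, code in REGION_LABELS.items():
        c_gm_by_code[code] = gm_cbf[name]
    c_gm_by_code[OTHER_BRAIN_LABEL] = gm_cbf["other"]

    true_cbf = pve_gm * c_gm_by_code[labels] + pve_wm * config.true_wm_cbf
    return PhantomTruth(
        pve_gm=pve_gm,
        pve_wm=pve_wm,
        pve_csf=pve_csf,
        region_labels=labels,
        true_cbf=true_cbf,
        voxel_size_mm=voxel,
        config=config,
    )


def simulate_asl(
    truth: PhantomTruth,
    params: KineticParams = KineticParams(),
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
    s0_brain: float = 1000.0,
) -> VolumeStack:
    """Forward-simulate the ASL difference and reference images.

    The noise-free difference image is ``true_cbf / f(params) * s0``, the exact
    inverse of quantification, so simulate -> quantify is the identity without
    noise.  Gaussian noise with standard deviation
    ``noise_sd_fraction * mean(|delta_s|)`` (mean over brain voxels) is added
    to the difference image only; the reference image stays noise-free.
    """
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    factor = quantification_factor(params)
    mask = truth.brain_mask
    s0 = np.where(mask, float(s0_brain), 0.0)
    delta_s = np.zeros_like(truth.true_cbf)
    delta_s[mask] = truth.true_cbf[mask] / factor * s0_brain
    if noise_sd_fraction > 0:
        sd = noise_sd_fraction * np.abs(delta_s[mask]).mean()
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sd, size=delta_s.shape)
        delta_s = np.where(mask, delta_s + noise, 0.0)
    return VolumeStack(
        delta_s=delta_s,
        s0=s0,
        voxel_size_mm=truth.voxel_size_mm,
        brain_mask=mask,
        pve_gm=truth.pve_gm,
        pve_wm=truth.pve_wm,
        pve_csf=truth.pve_csf,
        labels=truth.region_labels,
    )
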