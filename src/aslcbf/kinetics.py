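"""Single-compartment CBF quantification for pseudo-continuous ASL.

Perfusion is computed voxelwise from the labelled-minus-control difference
image ``delta_s`` and the proton-density reference ``s0`` as

    CBF = f(params) * delta_s / s0

where the scalar ``f`` collects the kinetic constants of the single-compartment
model: partition coefficient ``lam``, saturation-recovery correction of the PD
image (``t_sat``, ``t1gm``), post-label delay ``w`` decayed at the T1 of blood
``t1b``, labelling duration ``tau``, and labelling efficiency ``eps`` (label
efficiency folded together with background-suppression losses).  With times in
seconds and ``lam`` in mL/g the formula yields mL/g/s; ``unit_factor = 6000``
converts to the conventional mL/100 g/min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "VolumeStack",
    "CBFMap",
    "quantification_factor",
    "quantify_cbf",
]


@dataclass(frozen=True)
class KineticParams:
    """Constants of the single-compartment quantification equation.

    Parameters
    ----------
    w : float
        Post-label delay (s).
    tau : float
        Labelling duration (s).
    lam : float
        Blood-tissue water partition coefficient (mL/g).
    eps : float
        Labelling efficiency, including background-suppression losses
        (dimensionless, 0 < eps <= 1).
    t1b : float
        Longitudinal relaxation time of arterial blood (s).
    t_sat : float
        Saturation-recovery time of the proton-density image (s).
    t1gm : float
        T1 used for the saturation-recovery correction (s).
    unit_factor : float
        Scale from mL/g/s to output units; 6000 gives mL/100 g/min.
    """

    w: float = 2.0
    tau: float = 1.5
    lam: float = 0.9
    eps: float = 0.8 * 0.75
    t1b: float = 1.4
    t_sat: float = 2.0
    t1gm: float = 1.2
    unit_factor: float = 6000.0

    def __post_init__(self) -> None:
        for name in ("w", "tau", "lam", "eps", "t1b", "t_sat", "t1gm", "unit_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"KineticParams.{name} must be strictly positive")
        if self.eps > 1:
            raise ValueError("labelling efficiency eps cannot exceed 1")

    def replace(self, **kw) -> "KineticParams":
        return dataclasses.replace(self, **kw)


@dataclass
class VolumeStack:
    """Co-registered ASL volumes on a common grid.

    ``delta_s`` and ``s0`` are required; tissue partial-volume maps and the
    region label map are carried through when the stack originates from the
    phantom.  ``brain_mask`` defaults to ``s0 > 0``.
    """

    delta_s: np.ndarray
    s0: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    brain_mask: np.ndarray | None = None
    pve_gm: np.ndarray | None = None
    pve_wm: np.ndarray | None = None
    pve_csf: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_s = np.asarray(self.delta_s, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.delta_s.shape != self.s0.shape:
            raise ValueError(
                f"delta_s shape {self.delta_s.shape} != s0 shape {self.s0.shape}"
            )
        if len(self.voxel_size_mm) != self.delta_s.ndim:
            raise ValueError("voxel_size_mm must give one spacing per axis")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.brain_mask is None:
            self.brain_mask = self.s0 > 0
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.s0.shape:
                raise ValueError("brain_mask grid does not match volumes")


@dataclass
class CBFMap:
    """Voxelwise perfusion map in mL/100 g/min.

    ``kind`` records whether the map is raw quantification output
    (``"uncorrected"``) or a partial-volume-corrected cortical map
    (``"pvc_cortical"``).  Values outside ``mask`` are zero; negative values
    inside the mask (noise) are preserved.
    """

    values: np.ndarray
    kind: str
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("uncorrected", "pvc_cortical"):
            raise ValueError(f"unknown CBF map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask grids differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite CBF values inside the mask")


def quantification_factor(params: KineticParams) -> float:
    """Scalar multiplier of ``delta_s / s0`` in the quantification equation.

    Exposed separately so the inverse problem (simulating a difference image
    from a known perfusion map) and noise propagation are one multiplication.
    """
    sr_correction = 1.0 - np.exp(-params.t_sat / params.t1gm)
    decay = np.exp(params.w / params.t1b)
    denom = 2.0 * params.t1b * (1.0 - np.exp(-params.tau / params.t1b)) * params.eps
    return params.unit_factor * params.lam * sr_correction * decay / denom


def quantify_cbf(stack: VolumeStack, params: KineticParams) -> CBFMap:
    """Voxelwise single-compartment CBF quantification.

    Returns perfusion in mL/100 g/min (for the default ``unit_factor``) on the
    brain mask, zero outside.  Negative values are not clipped.

    Raises
    ------
    ValueError
        If the reference image is non-positive anywhere inside the mask.
    """
    mask = stack.brain_mask
    bad = int(np.count_nonzero(stack.s0[mask] <= 0))
    if bad:
        raise ValueError(
            f"invalid reference image: s0 <= 0 at {bad} voxel(s) inside the brain mask"
        )
    factor = quantification_factor(params)
    values = np.zeros_like(stack.delta_s)
    values[mask] = factor * stack.delta_s[mask] / stack.s0[mask]
    return CBFMap(values=values, kind="uncorrected", mask=mask,
                  voxel_size_mm=tuple(stack.voxel_size_mm))
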