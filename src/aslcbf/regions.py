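"""Regional and whole-brain perfusion extraction.

The five cortical regions mirror a standard atlas parcellation: frontal,
parietal, precuneus + posterior cingulate (PRCPCC), temporal and occipital.
Label integers are fixed package-wide; 6 marks brain tissue outside the named
regions and 0 background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import CBFMap
from .pvc import PVCResult, weighted_cortical_mean

__all__ = [
    "REGION_LABELS",
    "OTHER_BRAIN_LABEL",
    "RegionSummary",
    "whole_brain_mean",
    "regional_means",
]

REGION_LABELS: dict[str, int] = {
    "frontal": 1,
    "parietal": 2,
    "prcpcc": 3,
    "temporal": 4,
    "occipital": 5,
}
OTHER_BRAIN_LABEL = 6


@dataclass
class RegionSummary:
    """Per-region mean perfusion plus global summaries.

    ``uncorrected`` and ``pvc_cortical`` map region name to mean CBF in
    mL/100 g/min (``pvc_cortical`` entries are gray-matter-fraction weighted);
    a region absent from the label map is reported as missing (absent key),
    never as zero.  ``whole_brain_cbf`` is the unweighted mean over every
    brain-tissue voxel, CSF included.
    """

    uncorrected: dict[str, float] = field(default_factory=dict)
    pvc_cortical: dict[str, float] = field(default_factory=dict)
    whole_brain_cbf: float | None = None
    pvc_cortical_cbf: float | None = None
    voxel_counts: dict[str, int] = field(default_factory=dict)


def whole_brain_mean(cbf: CBFMap, brain_mask: np.ndarray) -> float:
    """Unweighted mean CBF over all voxels classified as brain tissue.

    CSF voxels are included, matching the convention that the whole-brain
    value averages everything inside the brain mask.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("whole-brain mask is empty")
    return float(cbf.values[brain_mask].mean())


def regional_means(
    cbf: CBFMap,
    labels: np.ndarray,
    pvc: PVCResult | None = None,
    pve_gm: np.ndarray | None = None,
) -> RegionSummary:
    """Mean uncorrected (and optionally PVC cortical) CBF per named region.

    Uncorrected regional means are unweighted over the region's voxels; PVC
    entries use the gray-matter-fraction-weighted cortical mean and require
    both ``pvc`` and ``pve_gm``.
    """
    labels = np.asarray(labels)
    if labels.shape != cbf.values.shape:
        raise ValueError("label map grid does not match the CBF map")
    summary = RegionSummary()
    for name, code in REGION_LABELS.items():
        roi = labels == code
        n = int(np.count_nonzero(roi))
        if n == 0:
            continue  # reported as missing, not zero
        summary.voxel_counts[name] = n
        summary.uncorrected[name] = float(cbf.values[roi].mean())
        if pvc is not None and pve_gm is not None:
            summary.pvc_cortical[name] = weighted_cortical_mean(pvc, pve_gm, roi)

    brain = labels > 0
    if brain.any():
        summary.whole_brain_cbf = whole_brain_mean(cbf, brain)
    if pvc is not None and pve_gm is not None and brain.any():
        summary.pvc_cortical_cbf = weighted_cortical_mean(pvc, pve_gm, brain)
    return summary
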