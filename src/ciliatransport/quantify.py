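"""Total ciliary fluorescence from confocal z-stacks.

The quantity reproduced here is the product of the volume of the
supra-threshold fluorescent region and its mean intensity — which is
algebraically the voxel volume times the summed supra-threshold
intensity — and the between-genotype percentage ratio of such totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import ZStack

__all__ = [
    "FluorescenceMeasure",
    "threshold_stack",
    "quantify_stack",
    "fluorescence_ratio",
]


@dataclass
class FluorescenceMeasure:
    """Supra-threshold volume, mean intensity, and their product."""

    volume_um3: float
    mean_intensity: float
    total_fluorescence: float
    threshold_used: float
    n_voxels: int


def threshold_stack(stack: ZStack, method: str | float = "otsu") -> tuple[np.ndarray, float]:
    """Binary voxel mask of the fluorescent region, with the threshold used.

    ``method`` is either ``"otsu"`` (threshold computed from the stack's
    global histogram) or a nonnegative absolute intensity value; voxels
    with intensity >= threshold are in the mask.  For paired-stack
    ratios a *common absolute* threshold avoids threshold-induced bias
    between the two stacks.
    """
    voxels = stack.voxels
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.all(voxels == voxels.flat[0]):
            raise ValueError("cannot compute an Otsu threshold on a constant stack")
        threshold = float(threshold_otsu(voxels))
    else:
        threshold = float(method)
        if threshold < 0:
            raise ValueError("absolute threshold must be nonnegative")
    return voxels >= threshold, threshold


def quantify_stack(stack: ZStack, mask: np.ndarray, threshold_used: float = float("nan")
                   ) -> FluorescenceMeasure:
    """Volume x mean intensity of the masked region.

    ``volume = voxel_volume * count(mask)``, ``mean`` is the arithmetic
    mean of masked intensities and ``total = volume * mean`` (exactly
    ``voxel_volume * sum(masked intensities)``).  An empty mask yields
    zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.voxels.shape:
        raise ValueError("mask shape must match stack shape")
    n = int(mask.sum())
    if n == 0:
        return FluorescenceMeasure(0.0, 0.0, 0.0, threshold_used, 0)
    volume = stack.voxel_volume_um3 * n
    mean = float(stack.voxels[mask].mean())
    return FluorescenceMeasure(volume, mean, volume * mean, threshold_used, n)


def fluorescence_ratio(
    measure_test: FluorescenceMeasure | list[FluorescenceMeasure],
    measure_reference: FluorescenceMeasure | list[FluorescenceMeasure],
) -> float:
    """Percentage ratio of total fluorescence, test over reference.

    Lists are reduced by the mean of their totals first (the ratio of
    group means, as when comparing genotype averages over animals).
    """

    def _total(m) -> float:
        if isinstance(m, FluorescenceMeasure):
            return m.total_fluorescence
        return float(np.mean([x.total_fluorescence for x in m]))

    ref = _total(measure_reference)
    if ref <= 0:
        raise ValueError("reference total fluorescence must be positive")
    return 100.0 * _total(measure_test) / ref
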