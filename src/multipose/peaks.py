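"""Peak detection and subpixel refinement on confidence maps.

Local peaks are pixels strictly greater than all eight neighbors
(plateaus yield no peak); grid borders are handled by -inf padding.
Global argmax ties break in raster (row, col) order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter

from .encode import ConfidenceMaps

__all__ = ["Peak", "find_global_peaks", "find_local_peaks", "refine_peaks"]

DEFAULT_PEAK_THRESHOLD = 0.2

# 3x3 neighborhood excluding the center pixel.
_NMS_FOOTPRINT = np.array(
    [[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool
)


@dataclass(frozen=True)
class Peak:
    channel: int
    grid_xy: tuple[int, int]  # (col, row) grid indices
    image_xy: tuple[float, float]  # refined image-space coordinates
    value: float


def _make_peak(channel: int, row: int, col: int, value: float, stride: int) -> Peak:
    return Peak(
        channel=channel,
        grid_xy=(int(col), int(row)),
        image_xy=(float(col * stride), float(row * stride)),
        value=float(value),
    )


def find_global_peaks(
    cms: ConfidenceMaps,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> list[Optional[Peak]]:
    """Per-channel argmax pixel, or None where the maximum is below threshold."""
    tensor = cms.tensor
    stride = cms.grid.output_stride
    out: list[Optional[Peak]] = []
    for ch in range(tensor.shape[2]):
        chan = tensor[:, :, ch]
        flat = int(np.argmax(chan))  # first occurrence = raster-order tie-break
        row, col = np.unravel_index(flat, chan.shape)
        val = chan[row, col]
        out.append(_make_peak(ch, row, col, val, stride) if val >= threshold else None)
    return out


def find_local_peaks(
    cms: ConfidenceMaps,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> list[Peak]:
    """All pixels strictly greater than their 8-neighborhood maximum and at
    least ``threshold``, via a grayscale dilation with the center excluded."""
    tensor = cms.tensor
    stride = cms.grid.output_stride
    out: list[Peak] = []
    for ch in range(tensor.shape[2]):
        chan = tensor[:, :, ch]
        dilated = maximum_filter(
            chan, footprint=_NMS_FOOTPRINT, mode="constant", cval=-np.inf
        )
        rows, cols = np.nonzero((chan > dilated) & (chan >= threshold))
        for row, col in zip(rows, cols):
            out.append(_make_peak(ch, row, col, chan[row, col], stride))
    return out


def refine_peaks(
    cms: ConfidenceMaps,
    peaks: Sequence[Peak],
    patch_size: int = 5,
) -> list[Peak]:
    """Integral-regression subpixel refinement.

    The offset applied to each grid-aligned peak is the confidence-weighted
    mean of the ``patch_size`` x ``patch_size`` patch coordinates relative
    to the peak pixel (patch clipped at borders; all-zero patch gives a
    zero offset).  Refined ``image_xy = (grid_xy + offset) * stride``.
    """
    if patch_size < 1 or patch_size % 2 != 1:
        raise ValueError("patch_size must be a positive odd integer")
    half = patch_size // 2
    tensor = cms.tensor
    gh, gw = tensor.shape[:2]
    stride = cms.grid.output_stride
    refined: list[Peak] = []
    for pk in peaks:
        col, row = pk.grid_xy
        r0, r1 = max(0, row - half), min(gh, row + half + 1)
        c0, c1 = max(0, col - half), min(gw, col + half + 1)
        patch = tensor[r0:r1, c0:c1, pk.channel]
        total = patch.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            dy = float((patch * (rr - row)).sum() / total)
            dx = float((patch * (cc - col)).sum() / total)
        else:
            dx = dy = 0.0
        refined.append(
            replace(pk, image_xy=((col + dx) * stride, (row + dy) * stride))
        )
    return refined
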