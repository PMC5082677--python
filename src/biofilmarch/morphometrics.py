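"""Per-slice particle analysis and box-counting fractal dimension.

The box-counting dimension D_B of a planar set F is the scaling exponent
of N(δ), the number of grid boxes of side δ that intersect F, as δ → 0:
estimated here as the slope of the ordinary least-squares line through
the points (−ln δ, ln N(δ)), with the coefficient of determination R² of
that fit as a quality measure.  The grid is anchored at the image origin
with a single offset, and box sizes default to powers of 2 from 2 up to a
quarter of the smaller image dimension.

Perimeter follows the border-pixel-center contour convention (the length
of a line through the centers of the 4-connected border pixels), under
which a solid w×h block measures 2(w−1) + 2(h−1).  The choice of
convention is immaterial downstream — every architecture quantity is a
ratio computed within one convention — but it is fixed and documented.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _sk_perimeter

from .types import BinaryMask, FractalEstimate, SliceMorphometry

# 8-connectivity: diagonal neighbors belong to the same particle
_STRUCT8 = np.ones((3, 3), dtype=int)


def particle_analysis(mask: BinaryMask | np.ndarray, min_particle_px: int = 1) -> SliceMorphometry:
    """Connected-component morphometrics of one binary slice.

    Components are 8-connected; those smaller than ``min_particle_px``
    pixels are discarded.  Area is the retained foreground pixel count,
    perimeter the total border-contour length of the retained particles.
    """
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(px, structure=_STRUCT8)
    if n and min_particle_px > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= min_particle_px) + 1
        retained = np.isin(labels, keep)
        labels, n = ndimage.label(retained, structure=_STRUCT8)
        px = retained
    elif n:
        pass
    else:
        px = np.zeros_like(px)
    area = int(px.sum())
    perim = float(_sk_perimeter(px, neighborhood=4)) if area else 0.0
    return SliceMorphometry(
        slice_index=0,
        area_px=float(area),
        perimeter_px=perim,
        particle_count=int(n),
        slice_area_px=float(px.size),
    )


def default_box_sizes(width: int, height: int) -> list[int]:
    """Powers of 2 from 1 up to a quarter of the smaller dimension.

    The single-pixel scale is included deliberately: at δ = 1 the count is
    the foreground area, and the fine-scale decade is where a curve-like
    reticulate network (local dimension ≈ 1) separates from a plane-filling
    blob (≈ 2).  Restricting to coarse scales makes both patterns look
    plane-filling and washes out the contrast.
    """
    limit = min(width, height) // 4
    sizes, d = [], 1
    while d <= limit:
        sizes.append(d)
        d *= 2
    return sizes or [1, 2]


def box_counts(mask: BinaryMask | np.ndarray, sizes: list[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Occupied-box counts N(δ) over an origin-anchored grid.

    For each box side δ the image is partitioned into δ×δ boxes anchored
    at (0, 0) (partial boxes at the far edges count); N(δ) is the number
    of boxes containing at least one foreground pixel.
    """
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    h, w = px.shape
    if sizes is None:
        sizes = default_box_sizes(w, h)
    sizes_arr = np.asarray(sizes, dtype=int)
    if np.any(sizes_arr < 1) or np.any(sizes_arr > min(h, w)):
        raise ValueError(f"box sizes must be in [1, {min(h, w)}]; got {sizes}")
    counts = np.empty(len(sizes_arr), dtype=int)
    for i, d in enumerate(sizes_arr):
        nh, nw = -(-h // d), -(-w // d)  # ceil
        padded = np.zeros((nh * d, nw * d), dtype=bool)
        padded[:h, :w] = px
        occ = padded.reshape(nh, d, nw, d).any(axis=(1, 3))
        counts[i] = int(occ.sum())
    return sizes_arr, counts


def fractal_dimension(sizes: np.ndarray, counts: np.ndarray) -> FractalEstimate:
    """OLS estimate of D_B from (δ, N(δ)) pairs.

    Fits ln N(δ) against −ln δ; the slope is D_B (clamped to [0, 2] for a
    planar set, raw slope retained) and R² measures the fit.  Fewer than
    two usable pairs (N > 0) leaves the estimate flagged undefined.
    """
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    usable = counts > 0
    if usable.sum() < 2:
        return FractalEstimate(
            d_b=0.0, r_squared=0.0, box_sizes=sizes, counts=counts, raw_slope=np.nan, defined=False
        )
    x = -np.log(sizes[usable])
    y = np.log(counts[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return FractalEstimate(
        d_b=float(np.clip(slope, 0.0, 2.0)),
        r_squared=float(r2),
        box_sizes=sizes,
        counts=counts,
        raw_slope=float(slope),
    )


def slice_morphometrics(
    binary_stack: list[BinaryMask],
    min_particle_px: int = 1,
    box_sizes: list[int] | None = None,
) -> list[SliceMorphometry]:
    """Full per-slice morphometrics of a harmonized, binarized stack.

    One record per slice, ordered bottom → top, each carrying particle
    area/perimeter/count and the fractal estimate of the slice pattern.
    """
    records = []
    for j, mask in enumerate(binary_stack, start=1):
        rec = particle_analysis(mask, min_particle_px=min_particle_px)
        rec.slice_index = j
        sizes, counts = box_counts(mask, sizes=box_sizes)
        rec.fractal = fractal_dimension(sizes, counts)
        if not rec.fractal.defined:
            rec.warnings.append("fractal estimate undefined (empty or near-empty slice)")
        records.append(rec)
    return records
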