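"""Raw images → binary masks and projections.

Mirrors a standard confocal image-analysis chain: 8-bit conversion,
global thresholding, maximum intensity projection, harmonization of slice
counts across replicate stacks, and color-rule segmentation of substrate
photographs.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_otsu

from .types import BinaryMask, ImageStack


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min–max rescale of an intensity grid to 8-bit (0–255).

    Rounding is half-up. A constant image maps to all zeros (with a
    warning) rather than raising, so batch runs survive empty slices.
    Images already of integer dtype within 0–255 pass through unchanged.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot convert an empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite intensities")
    if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 255:
        return image.astype(np.uint8)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        warnings.warn("constant image: 8-bit conversion maps to all zeros", stacklevel=2)
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (image - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half up


def threshold_mask(
    image: np.ndarray,
    method: str = "otsu",
    fixed_value: int | None = None,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Binarize an 8-bit image: foreground = intensity ≥ threshold.

    ``otsu`` picks the threshold maximizing between-class variance over
    the 256-bin histogram; ``fixed`` uses ``fixed_value`` directly.  A
    single-valued histogram yields an all-background mask with a warning.
    """
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer) or image.min() < 0 or image.max() > 255:
        raise ValueError("threshold_mask expects an 8-bit image; run to_8bit first")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        return BinaryMask(image >= fixed_value, pixel_size=pixel_size)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if image.min() == image.max():
        warnings.warn("single-valued histogram: returning all-background mask", stacklevel=2)
        return BinaryMask(np.zeros(image.shape, dtype=bool), pixel_size=pixel_size)
    t = threshold_otsu(image, nbins=256)
    # skimage's t separates classes as {<= t} / {> t}; with integer data the
    # equivalent >= convention uses t + 1.
    return BinaryMask(image >= int(t) + 1, pixel_size=pixel_size)


def max_intensity_projection(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the slices of a Z-stack (MIP)."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if voxels.ndim != 3 or voxels.shape[0] < 1:
        raise ValueError("MIP needs a non-empty 3-D stack")
    return voxels.max(axis=0)


def harmonization_indices(n_orig: int, n_target: int) -> np.ndarray:
    """1-based slice indices kept when reducing a stack from n_orig to n_target.

    Nearest selection on a linear index grid: ``round(linspace(1, n_orig,
    n_target))``.  Order-preserving and duplicate-free for n_target ≤ n_orig.
    """
    grid = np.linspace(1, n_orig, n_target)
    return np.floor(grid + 0.5).astype(int)  # round half up, no banker's rounding


def harmonize_slice_count(stacks: list[ImageStack]) -> list[ImageStack]:
    """Reduce every stack to the minimum slice count by index resampling.

    Replicate stacks of one tessera are acquired at slightly different
    thicknesses; downstream per-slice comparisons need equal N.  Slices
    are selected at evenly spaced ordinal positions; order is preserved
    and no slice is duplicated.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    n_target = min(s.n_slices for s in stacks)
    out = []
    for s in stacks:
        if s.n_slices == n_target:
            out.append(s)
            continue
        keep = harmonization_indices(s.n_slices, n_target) - 1
        out.append(
            ImageStack(
                voxels=s.voxels[keep],
                pixel_size=s.pixel_size,
                slice_thickness=s.slice_thickness,
                strain_id=s.strain_id,
                sampling_point=s.sampling_point,
            )
        )
    return out


def segment_tessera_photo(
    photo: np.ndarray,
    background_gray: tuple[float, float, float] = (200.0, 200.0, 200.0),
    chroma_tol: float = 60.0,
    green_margin: float = 10.0,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Color-rule segmentation of a substrate photograph.

    A pixel is classed colonized when its Euclidean RGB distance from the
    pale-gray background reference exceeds ``chroma_tol`` **and** its green
    channel exceeds red by ``green_margin`` (blue-green phototrophic
    biomass); everything else is background.  Defaults are tuned on the
    synthetic tessera generator.
    """
    photo = np.asarray(photo, dtype=float)
    if photo.ndim != 3 or photo.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    ref = np.asarray(background_gray, dtype=float)
    dist = np.linalg.norm(photo - ref, axis=-1)
    greenish = photo[..., 1] - photo[..., 0] > green_margin
    mask = (dist > chroma_tol) & greenish
    if mask.all() or not mask.any():
        warnings.warn("degenerate segmentation: mask is empty or full", stacklevel=2)
    return BinaryMask(mask, pixel_size=pixel_size)


def binarize_stack(
    stack: ImageStack,
    method: str = "otsu",
    fixed_value: int | None = None,
) -> list[BinaryMask]:
    """Convert a stack to per-slice binary masks with one global threshold.

    The threshold is computed once over the whole stack's histogram and
    applied to every slice.  A per-slice threshold would be unstable on
    nearly empty slices at the top and bottom of the biofilm, where the
    histogram is unimodal background noise and any split hallucinates
    foreground.
    """
    eight = to_8bit(stack.voxels)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        thr = int(fixed_value)
    elif method == "otsu":
        if eight.min() == eight.max():
            warnings.warn("single-valued stack: all-background masks", stacklevel=2)
            return [
                BinaryMask(np.zeros(eight.shape[1:], dtype=bool), pixel_size=stack.pixel_size)
                for _ in range(eight.shape[0])
            ]
        thr = int(threshold_otsu(eight, nbins=256)) + 1
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return [BinaryMask(sl >= thr, pixel_size=stack.pixel_size) for sl in eight]
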