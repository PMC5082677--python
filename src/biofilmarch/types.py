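"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A confocal Z-stack: slice-major 3-D intensity grid plus metadata.

    Slice index ``j`` runs 1..N from the bottom of the biofilm to the top
    (axis 0 of ``voxels``).  All slices share the same width × height.

    Parameters
    ----------
    voxels
        Array of shape ``(n_slices, height, width)``.
    pixel_size
        Lateral pixel size in μm/pixel.
    slice_thickness
        Optical-section thickness in μm (typically 5–6 μm).
    strain_id
        Label of the microbial strain the stack was acquired from.
    sampling_point
        Replicate index (1..3): three sampling points per tessera.
    """

    voxels: np.ndarray
    pixel_size: float = 1.0
    slice_thickness: float = 5.5
    strain_id: str = ""
    sampling_point: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"stack voxels must be 3-D (slices, height, width); got shape {self.voxels.shape}"
            )
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryMask:
    """2-D boolean foreground mask with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D; got shape {self.pixels.shape}")

    @property
    def coverage(self) -> float:
        """Fraction of pixels that are foreground."""
        return float(self.pixels.mean())


@dataclass
class FractalEstimate:
    """Box-counting fractal dimension from a log–log regression.

    ``d_b`` is the regression slope clamped to [0, 2] (the admissible range
    for a planar set); ``raw_slope`` keeps the unclamped value for
    diagnostics.  ``r_squared`` is the coefficient of determination of the
    fit of ln N(δ) against −ln δ.
    """

    d_b: float
    r_squared: float
    box_sizes: np.ndarray
    counts: np.ndarray
    raw_slope: float
    defined: bool = True


@dataclass
class SliceMorphometry:
    """Particle-analysis output for one slice of a binarized Z-stack."""

    slice_index: int
    area_px: float
    perimeter_px: float
    particle_count: int
    slice_area_px: float
    fractal: FractalEstimate | None = None
    warnings: list[str] = field(default_factory=list)
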