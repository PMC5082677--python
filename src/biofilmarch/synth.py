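"""Seeded synthetic inputs with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes, not biofilm physiology:

* **Z-stacks** whose per-slice substratum coverage follows a Gaussian
  profile along depth (high in the middle layers, low at the bottom and
  top of the biofilm), in two architecture regimes.  The *compact* regime
  is a thresholded smooth random field — few large blobs with smooth
  boundaries and a low perimeter-to-area ratio.  The *porous* regime is a
  union of narrow random-walk filaments forming a reticulate network with
  many voids and a high perimeter-to-area ratio.
* **Tessera photographs**: a pale-gray textured background with blue-green
  colonized patches occupying a controllable area fraction.
* **Roughness profiles**: zero-mean correlated random height series
  (1600 points by default, matching a palm rugosimeter acquisition).

Everything is deterministic given the spec/seed, so every pipeline stage
can be tested against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import ImageStack

ARCHITECTURES = ("compact", "porous")

# Near-binary autofluorescence model: dark background, bright foreground,
# slight additive noise on both.
_FG_MEAN, _FG_SD = 210.0, 12.0
_BG_MEAN, _BG_SD = 8.0, 4.0


@dataclass(frozen=True)
class SyntheticStackSpec:
    """Recipe for one synthetic confocal stack.

    ``peak_coverage`` is the target substratum coverage of the slice at
    ``profile_center``; coverage of slice j (1-based) decays as a Gaussian
    ``peak_coverage * exp(-(j - center)^2 / (2 * profile_width^2))``.
    ``profile_center`` defaults to the middle ordinal position (N+1)/2.
    """

    architecture: str
    n_slices: int = 9
    width: int = 64
    height: int = 64
    peak_coverage: float = 0.5
    profile_center: float | None = None
    profile_width: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"architecture must be one of {ARCHITECTURES}; got {self.architecture!r}"
            )
        if self.n_slices < 3:
            raise ValueError(f"n_slices must be >= 3; got {self.n_slices}")
        if self.width < 8 or self.height < 8:
            raise ValueError(
                f"stack dimensions must be >= 8 pixels; got {self.width}x{self.height}"
            )
        if not 0.0 < self.peak_coverage <= 1.0:
            raise ValueError(f"peak_coverage must be in (0, 1]; got {self.peak_coverage}")
        if self.profile_width <= 0:
            raise ValueError(f"profile_width must be > 0; got {self.profile_width}")

    @property
    def center(self) -> float:
        return (self.n_slices + 1) / 2 if self.profile_center is None else self.profile_center


@dataclass
class GroundTruth:
    """What the generator actually drew, for use as a test oracle."""

    architecture: str | None = None
    slice_targets: np.ndarray | None = None
    masks: np.ndarray | None = None  # boolean, (n_slices, h, w) or (h, w)
    photo_coverage: float | None = None

    def to_json(self) -> str:
        payload = {
            "architecture": self.architecture,
            "slice_targets": None
            if self.slice_targets is None
            else [float(t) for t in self.slice_targets],
            "photo_coverage": self.photo_coverage,
        }
        return json.dumps(payload, indent=2)


def gaussian_coverage_profile(spec: SyntheticStackSpec) -> np.ndarray:
    """Per-slice target coverage: Gaussian over the 1-based slice ordinal."""
    j = np.arange(1, spec.n_slices + 1, dtype=float)
    return spec.peak_coverage * np.exp(
        -((j - spec.center) ** 2) / (2.0 * spec.profile_width**2)
    )


def _threshold_field_to_count(fieldvals: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest entries of a 2-D field (exact count)."""
    if k <= 0:
        return np.zeros(fieldvals.shape, dtype=bool)
    flat = fieldvals.ravel()
    if k >= flat.size:
        return np.ones(fieldvals.shape, dtype=bool)
    # argpartition gives an exact pixel count, so realized coverage matches
    # the target to within 1/n_pixels.
    idx = np.argpartition(flat, flat.size - k)[flat.size - k :]
    mask = np.zeros(flat.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(fieldvals.shape)


def _compact_masks(spec: SyntheticStackSpec, targets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Thresholded smooth 3-D noise: large z-correlated blobs per slice."""
    noise = rng.standard_normal((spec.n_slices, spec.height, spec.width))
    sigma_xy = max(spec.width, spec.height) / 12.0
    smooth = ndimage.gaussian_filter(noise, sigma=(1.5, sigma_xy, sigma_xy), mode="wrap")
    n_px = spec.height * spec.width
    masks = np.zeros_like(smooth, dtype=bool)
    for j, target in enumerate(targets):
        masks[j] = _threshold_field_to_count(smooth[j], int(round(target * n_px)))
    return masks


def _random_walk_mask(
    shape: tuple[int, int], rng: np.random.Generator, n_steps: int, radius: int
) -> np.ndarray:
    """One 8-neighbor random-walk filament stamped with a small disk."""
    h, w = shape
    steps = rng.integers(-1, 2, size=(n_steps, 2))
    start = np.array([rng.integers(0, h), rng.integers(0, w)])
    pos = start + np.cumsum(steps, axis=0)
    # reflect at borders so filaments stay inside the frame
    pos[:, 0] = np.abs(pos[:, 0]) % (2 * h)
    pos[:, 0] = np.where(pos[:, 0] >= h, 2 * h - 1 - pos[:, 0], pos[:, 0])
    pos[:, 1] = np.abs(pos[:, 1]) % (2 * w)
    pos[:, 1] = np.where(pos[:, 1] >= w, 2 * w - 1 - pos[:, 1], pos[:, 1])
    mask = np.zeros(shape, dtype=bool)
    mask[pos[:, 0], pos[:, 1]] = True
    mask[start[0], start[1]] = True
    if radius > 0:
        mask = ndimage.binary_dilation(mask, structure=ndimage.generate_binary_structure(2, 1), iterations=radius)
    return mask


def _porous_masks(spec: SyntheticStackSpec, targets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reticulate filament networks from a shared walk pool.

    A pool of random-walk filaments is drawn once per stack; each slice
    accumulates walks from the pool (with a per-slice 1-pixel jitter) until
    its target pixel count is reached, so successive slices share most of
    their filaments — crude z-continuity of the network.
    """
    shape = (spec.height, spec.width)
    n_px = spec.height * spec.width
    pool: list[np.ndarray] = []

    def grow_pool() -> None:
        n_steps = int(rng.integers(18, 32))
        radius = int(rng.integers(0, 2))  # stroke width 1–3 px
        pool.append(_random_walk_mask(shape, rng, n_steps, radius))

    masks = np.zeros((spec.n_slices, spec.height, spec.width), dtype=bool)
    for j, target in enumerate(targets):
        k = int(round(target * n_px))
        if k <= 0:
            continue
        dy, dx = int(rng.integers(-1, 2)), int(rng.integers(-1, 2))
        acc = np.zeros(shape, dtype=bool)
        i = 0
        while acc.sum() < k:
            if i >= len(pool):
                grow_pool()
            acc |= np.roll(pool[i], (dy, dx), axis=(0, 1))
            i += 1
        masks[j] = acc
    return masks


def _render_intensities(masks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Near-binary 8-bit autofluorescence: dark background, bright signal."""
    fg = rng.normal(_FG_MEAN, _FG_SD, size=masks.shape)
    bg = rng.normal(_BG_MEAN, _BG_SD, size=masks.shape)
    out = np.where(masks, fg, bg)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_stack(spec: SyntheticStackSpec) -> tuple[ImageStack, GroundTruth]:
    """Generate one synthetic Z-stack plus its ground truth.

    Returns the stack as 8-bit intensities (bright biomass on a dark
    background) and a :class:`GroundTruth` holding the per-slice target
    coverages and the exact boolean masks that were rendered.
    """
    rng = np.random.default_rng(spec.seed)
    targets = gaussian_coverage_profile(spec)
    if spec.architecture == "compact":
        masks = _compact_masks(spec, targets, rng)
    else:
        masks = _porous_masks(spec, targets, rng)
    voxels = _render_intensities(masks, rng)
    stack = ImageStack(voxels=voxels, strain_id=f"synthetic-{spec.architecture}")
    truth = GroundTruth(architecture=spec.architecture, slice_targets=targets, masks=masks)
    return stack, truth


def generate_tessera_photo(
    coverage: float,
    width: int = 128,
    height: int = 128,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthetic photograph of a pale-gray tessera with blue-green patches.

    The colonized mask is a thresholded smooth random field whose pixel
    count matches ``coverage`` exactly (to within one pixel), recorded in
    the returned :class:`GroundTruth`.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1]; got {coverage}")
    rng = np.random.default_rng(seed)
    fieldvals = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=max(width, height) / 16.0, mode="wrap"
    )
    k = int(round(coverage * width * height))
    mask = _threshold_field_to_count(fieldvals, k)

    # pale-gray textured background
    base = 200.0 + ndimage.gaussian_filter(rng.normal(0, 12, (height, width)), 2.0)
    photo = np.stack([base, base, base], axis=-1) + rng.normal(0, 3, (height, width, 3))
    # blue-green biomass: green dominates red decisively, blue intermediate
    biom = np.stack(
        [
            rng.normal(55, 8, (height, width)),
            rng.normal(150, 10, (height, width)),
            rng.normal(125, 10, (height, width)),
        ],
        axis=-1,
    )
    photo = np.where(mask[..., None], biom, photo)
    photo = np.clip(np.rint(photo), 0, 255).astype(np.uint8)
    truth = GroundTruth(masks=mask, photo_coverage=float(mask.mean()))
    return photo, truth


def generate_roughness_profile(
    n: int = 1600,
    amplitude: float = 2.5,
    correlation_length: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Zero-mean correlated random height profile.

    ``n`` defaults to 1600 samples, the acquisition length of a palm
    rugosimeter pass over one tessera; ``amplitude`` sets the standard
    deviation of the heights (μm) and ``correlation_length`` the smoothing
    scale in samples.
    """
    if n < 2:
        raise ValueError(f"profile needs at least 2 points; got {n}")
    rng = np.random.default_rng(seed)
    z = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma=correlation_length, mode="wrap")
    z -= z.mean()
    sd = z.std()
    if sd > 0 and amplitude > 0:
        z *= amplitude / sd
    else:
        z = np.zeros(n)
    return z


@dataclass
class SyntheticStrain:
    """One synthetic strain: three replicate stacks plus a tessera photo."""

    strain_id: str
    architecture: str
    stacks: list[ImageStack]
    stack_truths: list[GroundTruth]
    photo: np.ndarray
    photo_truth: GroundTruth


def _subseed(master: int, i: int, k: int) -> int:
    # fixed arithmetic so replicates differ reproducibly
    return (master * 1_000_003 + i * 1_009 + k * 7) % (2**31 - 1)


def generate_strain_suite(
    n_strains: int,
    labels: list[str],
    seed: int = 0,
    n_slices: int = 9,
    width: int = 128,
    height: int = 128,
    compact_peak: tuple[float, float] = (0.55, 0.80),
    porous_peak: tuple[float, float] = (0.12, 0.35),
) -> list[SyntheticStrain]:
    """Generate a full study suite: per strain, 3 replicate stacks + photo.

    The three stacks share the strain's architecture and peak coverage but
    differ by derived sub-seeds (replicate sampling points on the same
    tessera).  The photo's coverage is tied to the coverage of the stack's
    ground-truth maximum-intensity projection, so substrate-scale and
    microscale coverage correlate across the suite as they do in real
    monospecific biofilms.

    Compact strains draw their peak slice coverage from ``compact_peak``
    and porous strains from ``porous_peak``: compact colonizers blanket
    the substrate densely while reticulate networks leave most of each
    slice empty.
    """
    if n_strains < 1:
        raise ValueError("suite must contain at least one strain")
    if len(labels) != n_strains:
        raise ValueError(f"need {n_strains} labels; got {len(labels)}")
    for lab in labels:
        if lab not in ARCHITECTURES:
            raise ValueError(f"unknown architecture label {lab!r}")

    rng = np.random.default_rng(seed)
    suite: list[SyntheticStrain] = []
    for i, label in enumerate(labels):
        lo, hi = compact_peak if label == "compact" else porous_peak
        peak = float(rng.uniform(lo, hi))
        stacks, truths = [], []
        for k in range(3):
            spec = SyntheticStackSpec(
                architecture=label,
                n_slices=n_slices,
                width=width,
                height=height,
                peak_coverage=peak,
                seed=_subseed(seed, i, k),
            )
            stack, truth = generate_stack(spec)
            stack.strain_id = f"strain{i + 1:02d}-{label}"
            stack.sampling_point = k + 1
            stacks.append(stack)
            truths.append(truth)
        mip_cov = float(truths[0].masks.any(axis=0).mean())
        photo_cov = float(np.clip(mip_cov + rng.normal(0, 0.01), 0.0, 1.0))
        photo, photo_truth = generate_tessera_photo(
            photo_cov, width=width, height=height, seed=_subseed(seed, i, 99)
        )
        suite.append(
            SyntheticStrain(
                strain_id=stacks[0].strain_id,
                architecture=label,
                stacks=stacks,
                stack_truths=truths,
                photo=photo,
                photo_truth=photo_truth,
            )
        )
    return suite


def write_suite(suite: list[SyntheticStrain], outdir: str | Path) -> None:
    """Write a suite to disk: TIFF stacks, PNG photos, JSON ground truth."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for strain in suite:
        sdir = outdir / strain.strain_id
        sdir.mkdir(exist_ok=True)
        for stack in strain.stacks:
            tifffile.imwrite(sdir / f"stack_sp{stack.sampling_point}.tif", stack.voxels)
        iio.imwrite(sdir / "tessera.png", strain.photo)
        (sdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "architecture": strain.architecture,
                    "slice_targets": [float(t) for t in strain.stack_truths[0].slice_targets],
                    "photo_coverage": strain.photo_truth.photo_coverage,
                },
                indent=2,
            )
        )
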