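"""Seeded synthetic head-MRI phantoms with exact ground-truth brain masks.

Each phantom is a head-like arrangement on an anisotropically spaced grid:

* a bright, smoothly perturbed ellipsoidal "brain" (the mask is exactly its
  support — labels carry no noise),
* a hollow ellipsoidal "skull/scalp" shell of intermediate intensity around
  it,
* two bright anterior "eye" spheres outside the brain,
* a multiplicative smooth bias field and additive Gaussian noise.

The phantom is deliberately simple — it exercises geometry handling,
learnability and the tri-planar pipeline, not anatomical realism.  A given
spec and seed reproduce the volume bitwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import MaskVolume, Volume, write_nifti

__all__ = ["PhantomSpec", "CohortJitter", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom.

    Geometry is expressed in voxels relative to ``grid_size``; intensities
    are arbitrary MR-like units (the pipeline min-max normalizes anyway).
    The default spacing mimics thick-slice anisotropic scanning.
    """

    grid_size: int = 64
    spacing: tuple[float, float, float] = (0.60, 1.20, 0.60)
    brain_semiaxes: tuple[float, float, float] = (0.30, 0.24, 0.27)  # x grid_size
    brain_center: tuple[float, float, float] = (0.50, 0.44, 0.50)  # x grid_size
    brain_intensity: float = 0.80
    texture_sd: float = 0.03
    perturb_amplitude: float = 0.08  # relative modulation of the ellipsoid boundary
    shell_scales: tuple[float, float] = (1.12, 1.30)
    shell_intensity: float = 0.45
    eye_radius: float = 0.05  # x grid_size
    eye_count: int = 2
    eye_anterior: float = 0.86  # axis-1 position, x grid_size
    eye_lateral_offset: float = 0.13  # axis-0 offset from center, x grid_size
    eye_intensity: float = 0.95
    background_intensity: float = 0.05
    noise_sd: float = 0.02
    bias_amplitude: float = 0.10
    bias_smoothness: float = 0.25  # gaussian sigma, x grid_size
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be at least 16")
        if min(self.brain_semiaxes) <= 0:
            raise ValueError("brain semi-axes must be positive")
        for inten in (self.brain_intensity, self.shell_intensity,
                      self.eye_intensity, self.background_intensity):
            if inten < 0:
                raise ValueError("intensities must be non-negative")
        g = self.grid_size
        outer = self.shell_scales[1]
        for c, a in zip(self.brain_center, self.brain_semiaxes):
            if c * g - a * outer * g < 1 or c * g + a * outer * g > g - 1:
                raise ValueError("brain plus shell exceeds the grid")


def _smooth_field(rng, shape, sigma):
    f = gaussian_filter(rng.standard_normal(shape).astype(np.float32), sigma)
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, MaskVolume]:
    """Render one phantom volume and its exact brain mask."""
    g = spec.grid_size
    rng = np.random.default_rng(spec.seed)
    shape = (g, g, g)

    ax = [np.arange(g, dtype=np.float32) for _ in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    center = [c * g for c in spec.brain_center]
    semi = [a * g for a in spec.brain_semiaxes]
    q = (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    )

    # fixed draw order keeps one seed -> one phantom, bitwise
    perturb = _smooth_field(rng, shape, g / 8)
    texture = rng.standard_normal(shape).astype(np.float32)
    bias = _smooth_field(rng, shape, spec.bias_smoothness * g)
    noise = rng.standard_normal(shape).astype(np.float32)

    brain = q <= 1.0 + spec.perturb_amplitude * perturb
    s1, s2 = spec.shell_scales
    shell = (q >= s1**2) & (q <= s2**2) & ~brain

    img = np.full(shape, spec.background_intensity, dtype=np.float32)
    img[brain] = spec.brain_intensity + spec.texture_sd * texture[brain]
    img[shell] = spec.shell_intensity

    eyes = np.zeros(shape, dtype=bool)
    r = spec.eye_radius * g
    offsets = np.linspace(-1.0, 1.0, spec.eye_count) if spec.eye_count > 1 else [0.0]
    for off in offsets[: spec.eye_count]:
        ec = (
            (0.5 + off * spec.eye_lateral_offset) * g,
            spec.eye_anterior * g,
            0.5 * g,
        )
        d2 = (xx - ec[0]) ** 2 + (yy - ec[1]) ** 2 + (zz - ec[2]) ** 2
        eyes |= d2 <= r**2
    eyes &= ~brain  # eyes are never brain; with default geometry already disjoint
    img[eyes] = spec.eye_intensity

    img *= 1.0 + spec.bias_amplitude * bias
    img += spec.noise_sd * noise
    np.maximum(img, 0.0, out=img)

    vol = Volume(img.astype(np.float32), spec.spacing)
    mask = MaskVolume(brain.astype(np.uint8), spec.spacing)
    return vol, mask


@dataclass(frozen=True)
class CohortJitter:
    """Relative/absolute per-phantom variation ranges for a cohort.

    ``noise_sd`` spans an absolute range (its default five-fold spread
    emulates acquisitions at different field strengths / SNR); the scale
    ranges multiply the base spec's value.
    """

    semiaxes_scale: tuple[float, float] = (0.90, 1.10)
    brain_intensity_scale: tuple[float, float] = (0.90, 1.10)
    shell_intensity_scale: tuple[float, float] = (0.85, 1.15)
    noise_sd: tuple[float, float] = (0.01, 0.05)
    bias_amplitude: tuple[float, float] = (0.05, 0.20)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: CohortJitter | None = None,
    seed: int = 0,
    out_dir=None,
    return_specs: bool = False,
):
    """Generate ``n`` jittered phantoms under one master seed.

    Returns a list of ``(Volume, MaskVolume)`` pairs (plus the per-phantom
    specs when ``return_specs``).  When ``out_dir`` is given, writes
    ``phantom_XXX.nii.gz`` / ``phantom_XXX_mask.nii.gz`` pairs there.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    base = base_spec or PhantomSpec()
    jit = jitter or CohortJitter()
    degenerate = all(
        lo == hi
        for lo, hi in (
            jit.semiaxes_scale, jit.brain_intensity_scale,
            jit.shell_intensity_scale, jit.noise_sd, jit.bias_amplitude,
        )
    )
    if degenerate:
        warnings.warn("all jitter ranges are degenerate: cohort phantoms differ only by seed")
    master = np.random.default_rng(seed)
    pairs = []
    specs = []
    for i in range(n):
        sc = master.uniform(*jit.semiaxes_scale)
        spec_i = replace(
            base,
            brain_semiaxes=tuple(a * sc for a in base.brain_semiaxes),
            brain_intensity=base.brain_intensity * master.uniform(*jit.brain_intensity_scale),
            shell_intensity=base.shell_intensity * master.uniform(*jit.shell_intensity_scale),
            noise_sd=master.uniform(*jit.noise_sd),
            bias_amplitude=master.uniform(*jit.bias_amplitude),
            seed=int(base.seed) + i,  # degenerate jitter with n=1 reproduces the base spec
        )
        vol, mask = generate_phantom(spec_i)
        pairs.append((vol, mask))
        specs.append(spec_i)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_nifti(vol, out / f"phantom_{i:03d}.nii.gz")
            write_nifti(mask, out / f"phantom_{i:03d}_mask.nii.gz")
    if return_specs:
        return pairs, specs
    return pairs
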