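"""Seeded brain-like phantoms with exact ground truth.

The generator emulates the difficulties of transaxial MR-T2 brain slices
that motivate the pipeline — piecewise-near-constant anatomical regions
with curved boundaries, smooth multiplicative intensity non-uniformity
(bias field), blurred edges, additive Gaussian noise and impulse
(salt-and-pepper) noise — while keeping the exact pre-degradation region
raster as ground truth.  It makes no claim to physical MR realism (no
k-space, no Rician noise, no relaxometry); its job is to give every stage
of the pipeline a target whose truth is known bit-exactly.

Construction order: nested offset ellipses are painted with the requested
region grays, edges are Gaussian-blurred, a seeded second-order polynomial
bias field of the requested relative amplitude multiplies the image,
Gaussian noise is added, and finally a fraction of pixels is replaced with
salt or pepper.  Degradations never touch the truth raster.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse

from ._util import to_uint8

__all__ = ["PhantomSpec", "generate_phantom", "phantom_suite", "SUITE_CASES"]


@dataclass
class PhantomSpec:
    """Recipe for one phantom.

    ``region_grays`` lists the intensity of each region, background first;
    they must be pairwise distinct.  ``bias_amplitude`` is the peak
    relative deviation of the multiplicative bias field (0.3 = +/-30%).
    ``blur_sigma`` (pixels) softens region edges; ``gaussian_sigma`` (gray
    levels) and ``impulse_fraction`` (probability in [0, 1)) add noise.
    """

    seed: int = 0
    shape: tuple[int, int] = (128, 128)
    n_regions: int = 2
    region_grays: tuple[int, ...] = (50, 200)
    bias_amplitude: float = 0.0
    blur_sigma: float = 0.0
    impulse_fraction: float = 0.0
    gaussian_sigma: float = 0.0

    def __post_init__(self) -> None:
        if len(self.region_grays) != self.n_regions:
            raise ValueError("need one gray per region")
        if len(set(self.region_grays)) != self.n_regions:
            raise ValueError("region grays must be pairwise distinct")
        if any(g < 0 or g > 255 for g in self.region_grays):
            raise ValueError("region grays must lie in [0, 255]")
        if not (0 <= self.impulse_fraction < 1):
            raise ValueError("impulse_fraction must lie in [0, 1)")
        if self.bias_amplitude < 0 or self.blur_sigma < 0 or self.gaussian_sigma < 0:
            raise ValueError("degradation magnitudes must be >= 0")
        if self.shape[0] < 3 or self.shape[1] < 3:
            raise ValueError("phantom must be at least 3x3")


def _region_raster(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Nested, slightly offset ellipses: label 0 is background, label j is
    the j-th ellipse from the outside in (head-like curved boundaries)."""
    h, w = spec.shape
    truth = np.zeros((h, w), dtype=np.int32)
    for j in range(1, spec.n_regions):
        scale = 0.82 * (spec.n_regions - j) / max(1, spec.n_regions - 1)
        # seeded sub-pixel-ish jitter keeps boundaries off the grid axes
        dr = rng.uniform(-0.04, 0.04) * h
        dc = rng.uniform(-0.04, 0.04) * w
        rot = rng.uniform(-np.pi / 6, np.pi / 6)
        rr, cc = ellipse(
            h / 2 + dr,
            w / 2 + dc,
            max(2.0, scale * h / 2),
            max(2.0, scale * w / 2 * 0.78),
            shape=(h, w),
            rotation=rot,
        )
        truth[rr, cc] = j
    return truth


def _bias_field(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field ``1 + b`` with ``max|b| = amplitude``.

    ``b`` is a random second-order polynomial over normalized coordinates,
    rescaled to the requested peak deviation — smooth and slowly varying
    the way MR coil inhomogeneity is.
    """
    h, w = shape
    y, x = np.meshgrid(
        np.linspace(-1.0, 1.0, h), np.linspace(-1.0, 1.0, w), indexing="ij"
    )
    coef = rng.normal(size=6)
    b = (
        coef[0] * x
        + coef[1] * y
        + coef[2] * x * y
        + coef[3] * x**2
        + coef[4] * y**2
        + coef[5]
    )
    lo, hi = b.min(), b.max()
    if hi > lo:
        b = (b - (hi + lo) / 2.0) / ((hi - lo) / 2.0) * amplitude
    else:
        b = np.zeros_like(b)
    return 1.0 + b


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build one phantom.

    Returns ``(image, truth, meta)``: the degraded uint8 image, the exact
    int32 region raster, and a metadata dict recording every parameter.
    Bit-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _region_raster(spec, rng)
    img = np.asarray(spec.region_grays, dtype=np.float64)[truth]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.bias_amplitude > 0:
        img = img * _bias_field(spec.shape, spec.bias_amplitude, rng)
    if spec.gaussian_sigma > 0:
        img = img + rng.normal(0.0, spec.gaussian_sigma, size=spec.shape)
    if spec.impulse_fraction > 0:
        n_pix = spec.shape[0] * spec.shape[1]
        n_hit = int(round(spec.impulse_fraction * n_pix))
        idx = rng.choice(n_pix, size=n_hit, replace=False)
        salt = rng.random(n_hit) < 0.5
        flat = img.ravel()
        flat[idx[salt]] = 255.0
        flat[idx[~salt]] = 0.0
        img = flat.reshape(spec.shape)
    meta = asdict(spec)
    meta["shape"] = list(spec.shape)
    meta["region_grays"] = list(spec.region_grays)
    return to_uint8(img), truth, meta


#: The fixed test battery: name -> spec overrides applied to the clean
#: two-region base phantom.
SUITE_CASES: dict[str, dict] = {
    "clean": {},
    "blurred": {"blur_sigma": 1.0},
    "biased": {"bias_amplitude": 0.2},
    "impulse": {"impulse_fraction": 0.02},
    "combined": {"bias_amplitude": 0.2, "impulse_fraction": 0.02, "blur_sigma": 1.0},
}


def phantom_suite(
    seed: int, shape: tuple[int, int] = (128, 128)
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """The fixed phantom battery used by the acceptance checks.

    Five two-region cases (grays 50/200): clean, blurred-edge, biased,
    impulse-noisy and combined.  Each case runs on its own child seed
    derived from ``seed``, so the battery is fully reproducible while the
    cases stay statistically independent.
    """
    out = []
    for i, (name, overrides) in enumerate(SUITE_CASES.items()):
        case_seed = (seed * 31 + i) % (2**31)
        spec = PhantomSpec(seed=case_seed, shape=shape, **overrides)
        img, truth, _ = generate_phantom(spec)
        out.append((img, truth, name))
    return out
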