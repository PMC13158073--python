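"""Reproducible 2-D brain-phantom image/mask pairs.

Each phantom is a brain-shaped ellipse on a dark field, carrying a smooth
intensity gradient plus a low-frequency texture, with up to three elliptical
lesions of configurable size and contrast.  Lesion intensity is blended
toward a bright (or dark) target so the image never saturates, the lesion
boundary is softened by a Gaussian blur of the lesion indicator, and pixel
noise is added last.  The ground-truth mask marks the *pre-blur* lesion
support, so masks stay crisp while image boundaries are ambiguous — the
regime that makes clinical tumor delineation hard.

Everything is a pure function of the spec (seed included): identical specs
give byte-identical images and masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "SegmentationSample",
    "make_phantom",
    "make_dataset",
    "write_dataset",
    "split_sizes",
]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a single phantom.

    ``lesion_radius_range`` is in fractions of the image side;
    ``contrast`` in (0, 1] scales the lesion-to-background intensity gap;
    ``boundary_blur_sigma`` (pixels) softens lesion edges in the image only;
    ``noise_sigma`` is the additive Gaussian pixel-noise level.
    """

    image_size: int = 256
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (0.05, 0.18)
    contrast: float = 0.6
    boundary_blur_sigma: float = 1.5
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.image_size, (int, np.integer)) and self.image_size >= 8):
            raise ValueError(f"image_size must be an int >= 8, got {self.image_size}")
        if not (0 <= self.n_lesions <= 3):
            raise ValueError(f"n_lesions must lie in [0, 3], got {self.n_lesions}")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < 0.4):
            raise ValueError(
                f"lesion_radius_range must satisfy 0 < lo <= hi < 0.4, "
                f"got {self.lesion_radius_range}"
            )
        if not (0 < self.contrast <= 1):
            raise ValueError(f"contrast must lie in (0, 1], got {self.contrast}")
        if self.boundary_blur_sigma < 0:
            raise ValueError(
                f"boundary_blur_sigma must be >= 0, got {self.boundary_blur_sigma}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class SegmentationSample:
    """A float image in [0, 1] with its aligned binary mask."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask must be binary, found values {vals[:5]}")


def _ellipse(yy, xx, cy, cx, ry, rx, theta=0.0):
    ct, st = np.cos(theta), np.sin(theta)
    dy, dx = yy - cy, xx - cx
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec, sample_id: str | None = None) -> SegmentationSample:
    """Generate one phantom image/mask pair from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n] / (n - 1.0)

    # brain support: slightly jittered tall ellipse around the image center
    cy = 0.5 + rng.uniform(-0.02, 0.02)
    cx = 0.5 + rng.uniform(-0.02, 0.02)
    ry = 0.44 + rng.uniform(-0.02, 0.02)
    rx = 0.38 + rng.uniform(-0.02, 0.02)
    support = _ellipse(yy, xx, cy, cx, ry, rx)

    # smooth background: radial falloff plus a heavy-blurred random field
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    texture = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8.0)
    texture = 0.05 * texture / (np.abs(texture).max() + 1e-12)
    bg = 0.40 + 0.10 * (1.0 - r2) + texture
    image = np.where(support, bg, 0.03)
    image = np.clip(image, 0.0, 0.9)

    mask = np.zeros((n, n), dtype=np.uint8)
    bump = np.zeros((n, n))
    for _ in range(spec.n_lesions):
        lo, hi = spec.lesion_radius_range
        lr_y = rng.uniform(lo, hi)
        lr_x = rng.uniform(lo, hi)
        rmax = max(lr_y, lr_x)
        # place so the lesion bounding circle stays inside the brain ellipse
        m_y = max(ry - rmax, 0.02)
        m_x = max(rx - rmax, 0.02)
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 1))
        lcy = cy + rad * m_y * np.sin(ang)
        lcx = cx + rad * m_x * np.cos(ang)
        theta = rng.uniform(0, np.pi)
        lesion = _ellipse(yy, xx, lcy, lcx, lr_y, lr_x, theta) & support
        mask[lesion] = 1
        sign = 1.0 if rng.uniform() < 0.7 else -1.0
        bump = np.maximum(bump, sign * lesion) if sign > 0 else np.minimum(
            bump, sign * lesion
        )

    if spec.boundary_blur_sigma > 0:
        bump = gaussian_filter(bump, sigma=spec.boundary_blur_sigma)
    # blend toward bright (0.97) or dark (0.03) targets: the gap scales
    # linearly with contrast and the image cannot saturate
    pos = np.clip(bump, 0, 1)
    neg = np.clip(-bump, 0, 1)
    image = image + spec.contrast * pos * (0.97 - image)
    image = image - spec.contrast * neg * (image - 0.03)

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(n, n))
    image = np.clip(image, 0.0, 1.0)
    return SegmentationSample(image=image, mask=mask,
                              id=sample_id or f"phantom_s{spec.seed}")


def split_sizes(n: int, fracs) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n samples over three fractions."""
    fracs = tuple(float(f) for f in fracs)
    if len(fracs) != 3 or any(f <= 0 for f in fracs):
        raise ValueError(f"need three positive split fractions, got {fracs}")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got sum {sum(fracs)}")
    raw = [f * n for f in fracs]
    base = [int(np.floor(x)) for x in raw]
    rem = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder
    for i in range(rem):
        base[order[i]] += 1
    return tuple(base)


def make_dataset(n: int, base_spec: PhantomSpec = PhantomSpec(),
                 split_fracs=(0.6, 0.2, 0.2), seed: int = 0):
    """Generate ``n`` phantoms with jittered difficulty plus a split map.

    Per-sample specs jitter radius, contrast and blur around ``base_spec``
    (multiplicative factors drawn from the dataset-level generator), and each
    sample gets its own derived seed.  Returns ``(samples, split)`` where
    ``split`` maps sample id -> one of train/val/test.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to populate three splits, got {n}")
    sizes = split_sizes(n, split_fracs)
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        r_fac = rng.uniform(0.7, 1.3)
        c_fac = rng.uniform(0.8, 1.2)
        b_fac = rng.uniform(0.5, 1.5)
        lo, hi = base_spec.lesion_radius_range
        spec = base_spec.replace(
            lesion_radius_range=(min(lo * r_fac, 0.39), min(hi * r_fac, 0.39)),
            contrast=float(np.clip(base_spec.contrast * c_fac, 0.05, 1.0)),
            boundary_blur_sigma=base_spec.boundary_blur_sigma * b_fac,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(make_phantom(spec, sample_id=f"phantom_{i:04d}"))
    split = {}
    bounds = np.cumsum((0,) + sizes)
    for name, lo_i, hi_i in zip(SPLITS, bounds[:-1], bounds[1:]):
        for s in samples[lo_i:hi_i]:
            split[s.id] = name
    return samples, split


def write_dataset(samples, split: dict, out_dir, overwrite: bool = False):
    """Write 8-bit grayscale PNG pairs plus a TSV manifest.

    Layout: ``<id>.png`` (image), ``<id>_mask.png`` (mask as 0/255), and
    ``manifest.tsv`` with lines ``id<TAB>split``.  Refuses to write into an
    existing non-empty directory unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite=True to replace its contents"
        )
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / f"{s.id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").save(
            out / f"{s.id}_mask.png"
        )
    with open(out / "manifest.tsv", "w") as fh:
        for s in samples:
            fh.write(f"{s.id}\t{split[s.id]}\n")
    return out
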