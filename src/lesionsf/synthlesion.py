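"""Synthetic dermoscopy-like lesion images with controllable asymmetry.

No public archive of the clinical images exists, so every pipeline stage
is exercised on generated data.  A lesion is a star-convex region with
polar boundary ``r(theta) = R (1 + sum a_m cos(m theta + phase_m))``
filled with a lesion color on a skin background, modulated by

* a linear intensity gradient of strength ``mass_asym`` along a random
  direction (asymmetric mass distribution),
* a dark Gaussian blob displaced from the center by
  ``color_asym * 0.8 R`` (asymmetric color distribution),

with odd boundary harmonics scaled by ``boundary_asym`` (asymmetric
shape), optional additive Gaussian pixel noise and optional dark cubic
hair strokes.  Generation is fully deterministic given the spec's seed,
and the exact ground-truth mask ``{|p - c| <= r(theta_p)}`` is returned
alongside the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import LabeledSet

__all__ = ["LesionSpec", "generate_lesion", "generate_cohort", "Cohort"]

# Dark blob: peak darkening per channel (red kept highest so the blob
# shifts hue, not just brightness).
_BLOB_DROP = np.array([60.0, 33.0, 24.0])
_HAIR_RGB = np.array([32.0, 26.0, 22.0])


@dataclass
class LesionSpec:
    """Parameters of one synthetic lesion; all asymmetry dials in [0, 1]."""

    image_size: int = 192
    base_radius: float = 55.0
    boundary_harmonics: list = field(default_factory=list)  # (order, amplitude, phase)
    boundary_asym: float = 0.0
    color_asym: float = 0.0
    mass_asym: float = 0.0
    skin_rgb: tuple = (205.0, 175.0, 155.0)
    lesion_rgb: tuple = (95.0, 65.0, 55.0)
    noise_sd: float = 0.0
    n_hairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.base_radius < 20:
            raise ValueError("base_radius must be >= 20 px")
        for a in (self.boundary_asym, self.color_asym, self.mass_asym):
            if not (0.0 <= a <= 1.0):
                raise ValueError("asymmetry parameters must lie in [0, 1]")
        if self.total_amplitude() >= 0.5:
            raise ValueError("harmonic amplitudes too large for a simple curve")
        if self.noise_sd < 0 or self.n_hairs < 0:
            raise ValueError("noise_sd and n_hairs must be non-negative")

    def effective_harmonics(self):
        """Harmonics with odd orders scaled by ``boundary_asym``."""
        out = []
        for m, a, ph in self.boundary_harmonics:
            amp = a * self.boundary_asym if m % 2 == 1 else a
            if amp > 0:
                out.append((int(m), float(amp), float(ph)))
        return out

    def total_amplitude(self):
        return sum(
            a * self.boundary_asym if m % 2 == 1 else a
            for m, a, _ in self.boundary_harmonics
        )


def _radius_profile(spec: LesionSpec, theta: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    for m, a, ph in spec.effective_harmonics():
        r = r + a * np.cos(m * theta + ph)
    return spec.base_radius * r


def _draw_hairs(img: np.ndarray, spec: LesionSpec, rng) -> None:
    h, w = img.shape[:2]
    for _ in range(spec.n_hairs):
        # Cubic Bezier across the frame, biased to cross the lesion.
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p3 = rng.uniform([0, 0], [h - 1, w - 1])
        mid = np.array([h / 2, w / 2]) + rng.normal(0, spec.base_radius / 2, 2)
        p1 = mid + rng.normal(0, 20, 2)
        p2 = mid + rng.normal(0, 20, 2)
        width = rng.uniform(0.5, 1.0)
        t = np.linspace(0, 1, 400)[:, None]
        pts = (
            (1 - t) ** 3 * p0
            + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t**2 * p2
            + t**3 * p3
        )
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr * dr + dc * dc > width * width + 1:
                    continue
                r2 = np.clip(rr + dr, 0, h - 1)
                c2 = np.clip(cc + dc, 0, w - 1)
                img[r2, c2] = _HAIR_RGB


def generate_lesion(spec: LesionSpec):
    """Render one lesion; returns ``(image uint8 HxWx3, mask bool HxW)``.

    The mask is the exact polar-inequality region; the rendered edge is
    anti-aliased over ~1 px so downstream sub-pixel contours are smooth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    c = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    dr, dc = rows - c[0], cols - c[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    rprof = _radius_profile(spec, theta)
    mask = dist <= rprof
    alpha = np.clip(rprof - dist + 0.5, 0.0, 1.0)  # anti-aliased coverage

    lesion = np.broadcast_to(
        np.asarray(spec.lesion_rgb, dtype=np.float64), (n, n, 3)
    ).copy()

    # Mass asymmetry: linear intensity gradient along a random direction.
    gdir = rng.uniform(0, 2 * math.pi)
    proj = (dr * math.sin(gdir) + dc * math.cos(gdir)) / spec.base_radius
    lesion *= (1.0 + 0.45 * spec.mass_asym * np.clip(proj, -1, 1))[..., None]

    # Color asymmetry: dark Gaussian blob displaced from the center.
    bdir = rng.uniform(0, 2 * math.pi)
    offset = spec.color_asym * 0.8 * spec.base_radius
    bc = c + offset * np.array([math.sin(bdir), math.cos(bdir)])
    sigma = spec.base_radius / 3.0
    blob = np.exp(-(((rows - bc[0]) ** 2 + (cols - bc[1]) ** 2) / (2 * sigma**2)))
    lesion -= blob[..., None] * _BLOB_DROP

    img = np.broadcast_to(
        np.asarray(spec.skin_rgb, dtype=np.float64), (n, n, 3)
    ).copy()
    img = img * (1 - alpha[..., None]) + lesion * alpha[..., None]

    if spec.n_hairs:
        _draw_hairs(img, spec, rng)
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


@dataclass
class Cohort:
    images: list
    masks: list
    labels: list
    ids: list
    specs: list

    def labeled_set(self, vectors) -> LabeledSet:
        return LabeledSet(vectors=vectors, labels=list(self.labels), ids=list(self.ids))


def _random_spec(rng, label: str, seed: int) -> LesionSpec:
    lo, hi = (0.0, 0.15) if label == "naevus" else (0.4, 0.9)
    harmonics = [
        (2, rng.uniform(0.0, 0.06), rng.uniform(0, 2 * math.pi)),
        (4, rng.uniform(0.0, 0.04), rng.uniform(0, 2 * math.pi)),
        (3, rng.uniform(0.10, 0.20), rng.uniform(0, 2 * math.pi)),
        (5, rng.uniform(0.06, 0.12), rng.uniform(0, 2 * math.pi)),
    ]
    return LesionSpec(
        image_size=192,
        base_radius=float(rng.uniform(40, 62)),
        boundary_harmonics=harmonics,
        boundary_asym=float(rng.uniform(lo, hi)),
        color_asym=float(rng.uniform(lo, hi)),
        mass_asym=float(rng.uniform(lo, hi)),
        skin_rgb=tuple(np.array([205.0, 175.0, 155.0]) + rng.normal(0, 6, 3)),
        lesion_rgb=tuple(np.array([95.0, 65.0, 55.0]) + rng.normal(0, 8, 3)),
        noise_sd=float(rng.uniform(1.0, 4.0)),
        n_hairs=int(rng.integers(0, 7)),
        seed=seed,
    )


def generate_cohort(n_benign: int, n_malignant: int, seed: int = 0) -> Cohort:
    """A labeled cohort: benign lesions draw every asymmetry dial from
    [0, 0.15], malignant from [0.4, 0.9]; all other parameters share one
    range.  The class gap is by construction — it makes classifier
    recovery a well-posed check, not a clinical claim."""
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one lesion per class")
    rng = np.random.default_rng(seed)
    images, masks, labels, ids, specs = [], [], [], [], []
    plan = [("naevus", i) for i in range(n_benign)] + [
        ("melanoma", i) for i in range(n_malignant)
    ]
    for label, i in plan:
        sub = int(rng.integers(0, 2**31 - 1))
        spec = _random_spec(rng, label, seed=sub)
        img, mask = generate_lesion(spec)
        images.append(img)
        masks.append(mask)
        labels.append(label)
        ids.append(f"{label[:3]}_{i:04d}")
        specs.append(spec)
    return Cohort(images=images, masks=masks, labels=labels, ids=ids, specs=specs)
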