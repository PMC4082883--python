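"""Synthetic mammogram-like lump phantoms with exact ground truth.

The phantom emulates the imaging situation the segmenter is built for: a
low-contrast lump plateau, a smooth "fuzzy halo" of intensity falloff beyond
the plateau, an oriented background texture grating, and additive Gaussian
noise.  The lump boundary is an ellipse whose radius is perturbed by a
low-order sinusoid so contours are irregular but star-shaped.

The halo model mirrors what makes real halos hard for gradient features: the
lesion signal drops sharply at the plateau rim to a faint skirt (half the
plateau contrast) that decays smoothly to zero across the halo, so the
strongest gradient in the lesion sits at the plateau rim — *inside* the true
extent — while the outer halo boundary carries almost no gradient at all.  A
gradient-driven tracker therefore locks onto the inner rim and excludes the
halo; texture features still see the halo because the lesion tissue
suppresses the background grating over its whole extent.

The exact ground-truth mask is the full lesion extent, plateau plus halo:
clinically the fuzzy transition zone belongs to the lump, and a segmenter
that stops at the substantial core under-segments.  With ``halo_width = 0``
the mask is exactly the perturbed ellipse.

The background grating is attenuated where the lump/halo signal is strong:
a dense mass locally obliterates background tissue texture, and a texture
grating passing unchanged under the lump would carry no lesion signature in
DC-free texture features.

``simulate_clicks`` stands in for the user: it samples ordered points at
equal arc-length spacing along the ground-truth boundary, optionally
perturbed by radial Gaussian jitter, mimicking a reader marking points on
the lump edge (ten by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import IntensityImage, ValidationError

#: Background mean intensity the lump plateau sits on.
BACKGROUND_LEVEL = 0.4

#: Fraction of the plateau contrast the halo skirt starts from.
HALO_SKIRT_LEVEL = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic lump phantom.

    boundary_irregularity is (amplitude_px, n_harmonics): the boundary radius
    is modulated by amplitude*cos(n_harmonics * angle).  background_texture is
    (orientation_deg, frequency_cyc_per_px, amplitude).
    """

    shape: tuple[int, int] = (96, 96)
    lump_center: tuple[float, float] = (48.0, 48.0)
    lump_radii: tuple[float, float] = (24.0, 24.0)
    boundary_irregularity: tuple[float, int] = (0.0, 0)
    lump_contrast: float = 0.5
    halo_width: float = 0.0
    background_texture: tuple[float, float, float] = (30.0, 0.2, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        cr, cc = self.lump_center
        r_row, r_col = self.lump_radii
        amp, _ = self.boundary_irregularity
        margin_r = r_row + amp + self.halo_width
        margin_c = r_col + amp + self.halo_width
        if (cr - margin_r < 0 or cr + margin_r >= rows
                or cc - margin_c < 0 or cc + margin_c >= cols):
            raise ValidationError(
                "lump plus halo margin does not fit inside the image"
            )
        if not (0.0 <= self.lump_contrast <= 1.0):
            raise ValidationError("lump_contrast must lie in [0, 1]")


def disk_spec(seed: int = 0) -> PhantomSpec:
    """High-contrast, noiseless circular lump — the easy control condition."""
    return PhantomSpec(seed=seed)


def textured_spec(seed: int = 0) -> PhantomSpec:
    """The hard condition: low contrast, fuzzy halo, background texture, noise."""
    return PhantomSpec(
        boundary_irregularity=(2.0, 3),
        lump_contrast=0.25,
        halo_width=6.0,
        background_texture=(30.0, 0.2, 0.12),
        noise_sigma=0.05,
        seed=seed,
    )


def make_lump_phantom(spec: PhantomSpec) -> tuple[IntensityImage, np.ndarray]:
    """Render the phantom image and its exact ground-truth mask.

    Deterministic given ``spec.seed``.  Returns ``(image, mask)`` with the
    mask a uint8 array, 1 inside the perturbed ellipse.
    """
    rows, cols = spec.shape
    cr, cc = spec.lump_center
    r_row, r_col = spec.lump_radii
    amp, harmonics = spec.boundary_irregularity
    r_mean = 0.5 * (r_row + r_col)

    rr, ccol = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dr = rr - cr
    dc = ccol - cc
    rho = np.hypot(dr / r_row, dc / r_col)  # normalized elliptical radius
    angle = np.arctan2(dr, dc)
    rho_b = 1.0 + (amp / r_mean) * np.cos(harmonics * angle)

    dist_px = (rho - rho_b) * r_mean  # approx. distance beyond the plateau

    # lesion extent: 1 on the plateau, cosine falloff to 0 across the halo
    if spec.halo_width > 0:
        ramp = 0.5 * (1.0 + np.cos(np.pi * dist_px / spec.halo_width))
        extent = np.where(
            dist_px <= 0, 1.0, np.where(dist_px <= spec.halo_width, ramp, 0.0)
        )
    else:
        extent = (dist_px <= 0).astype(np.float64)

    # intensity: full contrast on the plateau, a sharp drop to a faint skirt
    # (half contrast) that fades out with the extent across the halo, so the
    # outer halo boundary carries almost no gradient
    profile = np.where(dist_px <= 0, 1.0, HALO_SKIRT_LEVEL * extent)

    # ground truth = the whole lesion, plateau plus halo
    mask = (extent > 0).astype(np.uint8)

    theta_deg, freq, tex_amp = spec.background_texture
    th = np.deg2rad(theta_deg)
    grating = np.sin(2.0 * np.pi * freq * (dc * np.cos(th) + dr * np.sin(th)))
    image = (
        BACKGROUND_LEVEL
        + tex_amp * grating * (1.0 - extent)
        + spec.lump_contrast * profile
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return IntensityImage(np.clip(image, 0.0, 1.0)), mask


def _boundary_chain(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a star-shaped mask, ordered counterclockwise
    starting at the pixel with the smallest (row, col)."""
    mask = np.asarray(mask) > 0
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp == 0:
        raise ValidationError("mask is empty")
    if n_comp > 1:
        raise ValidationError(f"mask has {n_comp} connected components")
    interior = ndimage.binary_erosion(mask)
    boundary = np.argwhere(mask & ~interior)  # (k, 2) rows of (r, c)
    r0, c0 = boundary.mean(axis=0)
    # counterclockwise in conventional (x right, y up) orientation
    ang = np.arctan2(-(boundary[:, 0] - r0), boundary[:, 1] - c0)
    order = np.argsort(ang, kind="stable")
    chain = boundary[order]
    start = np.lexsort((chain[:, 1], chain[:, 0]))[0]
    return np.roll(chain, -start, axis=0)


def simulate_clicks(mask: np.ndarray, n_points: int = 10,
                    jitter_sigma: float = 0.0,
                    seed: int = 0) -> list[tuple[int, int]]:
    """Simulated user clicks on the lesion boundary.

    Samples ``n_points`` boundary pixels at equal arc-length spacing (in
    counterclockwise order, starting near the top-left-most boundary pixel)
    and perturbs each radially by seeded Gaussian jitter, clamped inside the
    image.
    """
    if n_points < 3:
        raise ValidationError(f"need at least 3 clicks, got {n_points}")
    chain = _boundary_chain(mask)
    diffs = np.diff(np.vstack([chain, chain[:1]]).astype(float), axis=0)
    seglen = np.hypot(diffs[:, 0], diffs[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    total = cum[-1] + seglen[-1]
    targets = np.arange(n_points) * total / n_points
    idx = np.searchsorted(cum, targets, side="right") - 1
    picks = chain[idx].astype(float)

    rng = np.random.default_rng(seed)
    if jitter_sigma > 0:
        r0, c0 = chain.mean(axis=0)
        radial = picks - np.array([r0, c0])
        norms = np.hypot(radial[:, 0], radial[:, 1])
        norms[norms == 0] = 1.0
        radial /= norms[:, None]
        picks = picks + radial * rng.normal(0.0, jitter_sigma, size=(n_points, 1))
    rows, cols = mask.shape
    picks = np.rint(picks).astype(int)
    picks[:, 0] = np.clip(picks[:, 0], 0, rows - 1)
    picks[:, 1] = np.clip(picks[:, 1], 0, cols - 1)
    return [tuple(p) for p in picks.tolist()]
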