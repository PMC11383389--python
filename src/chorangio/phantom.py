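"""Two-domain synthetic choroidal OCT phantom.

The generator emulates the acquisition gap the segmentation framework is built
for: a labeled "HD" domain (B-scans formed by averaging many speckle
realizations, sharp vessel boundaries, tuned focus) and an unlabeled
"low-quality" domain (2-realization averages with heavy residual speckle plus a
focus blur and a contrast/gamma shift).  Anatomy is a layered choroid under a
bright retinal band: a thin choriocapillaris band (no resolvable vessels),
Sattler's layer carrying small/medium vessels (SV) and Haller's layer carrying
large vessels (HV).  Every sample ships with exact vessel and sublayer masks.

Speckle follows fully developed multiplicative statistics: each realization
multiplies the clean reflectivity by unit-mean exponential noise, so averaging
n realizations keeps the expectation equal to the reflectivity and scales the
per-pixel variance exactly as 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "PhantomCube",
    "render_clean_scene",
    "apply_speckle_and_average",
    "make_domain_pair",
    "generate_sample",
    "generate_cube",
]

# piecewise-constant reflectivity levels (arbitrary backscatter units in [0,1])
REFLECTIVITY = {
    "retina": 0.80,
    "cc": 0.60,
    "stroma": 0.50,
    "vessel": 0.12,
    "sclera": 0.35,
}

PACKING_LIMIT = 0.6  # rejection sampling stalls beyond this union area fraction


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, optics and domain-shift knobs of the phantom.

    Spatial units: pixels unless suffixed; `axial_spacing` is um/pixel along
    depth, `lateral_spacing` and `slice_spacing` are mm/pixel in the en-face
    plane.  Vessel densities are target *area* fractions of the hosting band.
    """

    image_height: int = 96
    image_width: int = 128
    axial_spacing: float = 3.9
    lateral_spacing: float = 12.0 / 128
    slice_spacing: float = 12.0 / 64
    slice_count: int = 64
    rpe_depth: int = 20
    cc_thickness: int = 4
    sl_thickness: int = 24
    hl_thickness: int = 36
    sv_radius_range: tuple[float, float] = (1.5, 3.0)
    hv_radius_range: tuple[float, float] = (3.5, 7.0)
    vessel_density_sl: float = 0.40
    vessel_density_hl: float = 0.45
    n_averages_hd: int = 30
    n_averages_lq: int = 2
    focus_blur_sigma_lq: float = 1.2
    contrast_gamma_lq: float = 1.3
    surface_wave_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self):
        total = self.rpe_depth + self.cc_thickness + self.sl_thickness + self.hl_thickness
        if total > self.image_height:
            raise ValueError(
                f"layer stack ({total}px) exceeds image height ({self.image_height}px)"
            )
        if self.hv_radius_range[0] <= self.sv_radius_range[1]:
            raise ValueError("HV minimum radius must exceed SV maximum radius")
        if not (self.n_averages_hd > self.n_averages_lq >= 1):
            raise ValueError("need n_averages_hd > n_averages_lq >= 1")
        for name, d in (("vessel_density_sl", self.vessel_density_sl),
                        ("vessel_density_hl", self.vessel_density_hl)):
            if not 0.0 <= d <= PACKING_LIMIT:
                raise ValueError(
                    f"{name}={d} outside feasible range [0, {PACKING_LIMIT}] "
                    "(ellipse packing stalls above the limit)"
                )


@dataclass
class PhantomSample:
    """One B-scan with exact ground truth.

    `sublayer_mask` values: 0 outside the vascular choroid, 1 Sattler band,
    2 Haller band.  Vessel pixels always lie inside a band.
    """

    image: np.ndarray
    vessel_mask: np.ndarray
    sublayer_mask: np.ndarray
    domain_tag: str
    params: PhantomParams

    def __post_init__(self):
        inside = self.sublayer_mask[self.vessel_mask > 0]
        if inside.size and (inside == 0).any():
            raise ValueError("vessel pixel outside sublayer bands")


@dataclass
class PhantomCube:
    """Stack of geometrically continuous B-scans with a fovea landmark."""

    slices: list[PhantomSample]
    fovea_center: tuple[int, int]
    slice_spacing: float
    lateral_spacing: float

    def image_volume(self) -> np.ndarray:
        return np.stack([s.image for s in self.slices])

    def vessel_volume(self) -> np.ndarray:
        return np.stack([s.vessel_mask for s in self.slices])

    def sublayer_volume(self) -> np.ndarray:
        return np.stack([s.sublayer_mask for s in self.slices])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _surface(params: PhantomParams, rng: np.random.Generator, width: int) -> np.ndarray:
    """Smooth top-of-choroid depth profile (pixels) along the lateral axis."""
    x = np.arange(width) / max(width, 1)
    a = params.surface_wave_amplitude
    wave = (a * rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * (x + rng.uniform(0, 1)))
            + 0.5 * a * np.sin(4 * np.pi * (x + rng.uniform(0, 1))))
    return params.rpe_depth + wave


def _band_masks_2d(params: PhantomParams, top: np.ndarray) -> np.ndarray:
    """Sublayer mask (H, W) from the top surface profile; CC carries label 0."""
    h, w = params.image_height, len(top)
    rows = np.arange(h)[:, None]
    cc_top = top[None, :]
    sl_top = cc_top + params.cc_thickness
    hl_top = sl_top + params.sl_thickness
    hl_bot = hl_top + params.hl_thickness
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[(rows >= sl_top) & (rows < hl_top)] = 1
    mask[(rows >= hl_top) & (rows < hl_bot)] = 2
    return mask


def _fill_band_with_vessels(
    band: np.ndarray,
    radius_range: tuple[float, float],
    density: float,
    rng: np.random.Generator,
    max_attempts: int = 4000,
) -> np.ndarray:
    """Plant elliptical lumens until the band's vessel area fraction reaches
    `density` (rejection sampling; final fraction lands within +-10% relative)."""
    vessel = np.zeros_like(band, dtype=np.uint8)
    area = int(band.sum())
    if area == 0 or density <= 0:
        return vessel
    rows, cols = np.nonzero(band)
    r_lo, r_hi = rows.min(), rows.max()
    h, w = band.shape
    yy, xx = np.mgrid[0:h, 0:w]
    frac = 0.0
    for _ in range(max_attempts):
        if frac >= density:
            break
        r = rng.uniform(*radius_range)
        ax_lat = r * rng.uniform(1.0, 2.0)  # lumens slightly elongated laterally
        cy = rng.uniform(r_lo + r * 0.5, r_hi - r * 0.5) if r_hi - r * 0.5 > r_lo + r * 0.5 \
            else 0.5 * (r_lo + r_hi)
        # extend lateral sampling past the edges so coverage stays uniform
        cx = rng.uniform(-ax_lat, w + ax_lat)
        ell = ((yy - cy) / r) ** 2 + ((xx - cx) / ax_lat) ** 2 <= 1.0
        cand = vessel | (ell & (band > 0)).astype(np.uint8)
        new_frac = cand.sum() / area
        if new_frac <= density * 1.1:
            vessel = cand
            frac = new_frac
    if frac < density * 0.9:
        raise RuntimeError(
            f"vessel packing stalled at fraction {frac:.3f} (target {density})"
        )
    return vessel


def render_clean_scene(
    params: PhantomParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one noise-free B-scan scene.

    Returns (reflectivity, vessel_mask, sublayer_mask).  Reflectivity is
    piecewise constant: bright retinal band, medium choroidal stroma, dark
    vessel lumens, dimmer sclera below.
    """
    h, w = params.image_height, params.image_width
    top = _surface(params, rng, w)
    sublayer = _band_masks_2d(params, top)
    vessel = np.zeros((h, w), dtype=np.uint8)
    vessel |= _fill_band_with_vessels(sublayer == 1, params.sv_radius_range,
                                      params.vessel_density_sl, rng)
    vessel |= _fill_band_with_vessels(sublayer == 2, params.hv_radius_range,
                                      params.vessel_density_hl, rng)

    rows = np.arange(h)[:, None]
    refl = np.full((h, w), REFLECTIVITY["sclera"], dtype=np.float32)
    refl[rows < top[None, :]] = REFLECTIVITY["retina"]
    cc_zone = (rows >= top[None, :]) & (rows < top[None, :] + params.cc_thickness)
    refl[cc_zone] = REFLECTIVITY["cc"]
    refl[sublayer > 0] = REFLECTIVITY["stroma"]
    refl[vessel > 0] = REFLECTIVITY["vessel"]
    return refl, vessel, sublayer


def apply_speckle_and_average(
    reflectivity: np.ndarray, n_averages: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean of `n_averages` independent multiplicative-speckle realizations.

    Each realization is reflectivity x unit-mean exponential noise, so the
    output expectation equals the reflectivity and the per-pixel variance is
    reflectivity**2 / n_averages.
    """
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    acc = np.zeros_like(reflectivity, dtype=np.float64)
    for _ in range(int(n_averages)):
        acc += reflectivity * rng.exponential(1.0, size=reflectivity.shape)
    return (acc / n_averages).astype(np.float32)


def _lq_degrade(image: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Focus blur + gamma/contrast shift of the low-quality acquisition."""
    out = image
    if params.focus_blur_sigma_lq > 0:
        out = ndimage.gaussian_filter(out, params.focus_blur_sigma_lq)
    out = np.clip(out, 0.0, None)
    if params.contrast_gamma_lq != 1.0:
        out = out ** params.contrast_gamma_lq
    return out


def generate_sample(
    params: PhantomParams, rng: np.random.Generator, domain: str
) -> PhantomSample:
    """Render one sample of the requested domain ('hd' or 'lq')."""
    refl, vessel, sublayer = render_clean_scene(params, rng)
    if domain == "hd":
        img = apply_speckle_and_average(refl, params.n_averages_hd, rng)
    elif domain == "lq":
        img = apply_speckle_and_average(refl, params.n_averages_lq, rng)
        img = _lq_degrade(img, params)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return PhantomSample(img, vessel, sublayer, domain, params)


def make_domain_pair(
    params: PhantomParams, seed: int | None = None
) -> tuple[PhantomSample, PhantomSample]:
    """One HD and one low-quality sample from independently drawn geometry.

    The two domains differ in distribution (speckle level, focus, contrast),
    not pixel-wise; masks are exact for both.
    """
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_hd, rng_lq = (np.random.default_rng(c) for c in ss.spawn(2))
    return (generate_sample(params, rng_hd, "hd"),
            generate_sample(params, rng_lq, "lq"))


# ---------------------------------------------------------------------------
# cubes
# ---------------------------------------------------------------------------

def _surface_3d(params: PhantomParams, rng, t_count: int, width: int) -> np.ndarray:
    """Smooth top-of-choroid depth field over (slice, lateral)."""
    t = np.arange(t_count)[:, None] / max(t_count, 1)
    x = np.arange(width)[None, :] / max(width, 1)
    a = params.surface_wave_amplitude
    return (params.rpe_depth
            + a * rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * (x + rng.uniform(0, 1)))
            + 0.5 * a * np.sin(2 * np.pi * (t + rng.uniform(0, 1)))
            + 0.5 * a * np.sin(4 * np.pi * (x + t + rng.uniform(0, 1))))


def _fill_band_with_tubes(band: np.ndarray, radius_range, density, rng,
                          max_attempts: int = 8000) -> np.ndarray:
    """Plant ellipsoidal tubes (>= 2-slice extent) until the band's vessel
    volume fraction reaches `density` (within +-10% relative)."""
    t_n, h, w = band.shape
    vessel = np.zeros_like(band, dtype=np.uint8)
    volume = int(band.sum())
    if volume == 0 or density <= 0:
        return vessel
    occupied = 0
    frac = 0.0
    ts, rs, _ = np.nonzero(band)
    r_lo, r_hi = rs.min(), rs.max()
    for _ in range(max_attempts):
        if frac >= density:
            break
        r = rng.uniform(*radius_range)            # axial semi-axis
        ax_lat = r * rng.uniform(1.5, 3.0)        # lateral elongation
        ax_t = rng.uniform(1.5, 4.0)              # slice-direction semi-axis
        # centers may fall just outside the volume: clipping tubes at the
        # boundary keeps en-face coverage uniform out to the edges
        ct = rng.uniform(-ax_t, t_n + ax_t)
        cy = rng.uniform(r_lo, r_hi)
        cx = rng.uniform(-ax_lat, w + ax_lat)
        t0, t1 = max(0, int(ct - ax_t) - 1), min(t_n, int(ct + ax_t) + 2)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - ax_lat) - 1), min(w, int(cx + ax_lat) + 2)
        if t1 <= t0 or y1 <= y0 or x1 <= x0:
            continue
        tt, yy, xx = np.mgrid[t0:t1, y0:y1, x0:x1]
        ell = (((tt - ct) / ax_t) ** 2 + ((yy - cy) / r) ** 2
               + ((xx - cx) / ax_lat) ** 2) <= 1.0
        patch = ell & (band[t0:t1, y0:y1, x0:x1] > 0) & (vessel[t0:t1, y0:y1, x0:x1] == 0)
        gain = int(patch.sum())
        if gain == 0 or patch.any(axis=(1, 2)).sum() < 2:
            continue  # tubes must stay connected across >= 2 adjacent slices
        if (occupied + gain) / volume > density * 1.1:
            continue
        vessel[t0:t1, y0:y1, x0:x1][patch] = 1
        occupied += gain
        frac = occupied / volume
    if frac < density * 0.9:
        raise RuntimeError(
            f"tube packing stalled at fraction {frac:.3f} (target {density})"
        )
    # drop crumbs clipped off by band boundaries: every connected component
    # must span >= 2 adjacent slices (they are a negligible volume fraction)
    labeled, n_comp = ndimage.label(vessel)
    for i in range(1, n_comp + 1):
        comp = labeled == i
        if comp.any(axis=(1, 2)).sum() < 2:
            vessel[comp] = 0
    return vessel


def generate_cube(params: PhantomParams, seed: int | None = None,
                  domain: str = "lq") -> PhantomCube:
    """Generate a B-scan cube with 3-D vessel tubes and per-slice ground truth.

    Vessels are ellipsoids spanning at least two adjacent slices, so the
    en-face projection shows connected tubes.  The fovea landmark defaults to
    the cube center.
    """
    if params.slice_count < 2:
        raise ValueError("slice_count must be >= 2")
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_geo, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))

    t_n, h, w = params.slice_count, params.image_height, params.image_width
    top = _surface_3d(params, rng_geo, t_n, w)               # (T, W)
    rows = np.arange(h)[None, :, None]
    cc_top = top[:, None, :]
    sl_top = cc_top + params.cc_thickness
    hl_top = sl_top + params.sl_thickness
    hl_bot = hl_top + params.hl_thickness
    sublayer = np.zeros((t_n, h, w), dtype=np.uint8)
    sublayer[(rows >= sl_top) & (rows < hl_top)] = 1
    sublayer[(rows >= hl_top) & (rows < hl_bot)] = 2

    vessel = np.zeros_like(sublayer)
    vessel |= _fill_band_with_tubes(sublayer == 1, params.sv_radius_range,
                                    params.vessel_density_sl, rng_geo)
    vessel |= _fill_band_with_tubes(sublayer == 2, params.hv_radius_range,
                                    params.vessel_density_hl, rng_geo)

    refl = np.full((t_n, h, w), REFLECTIVITY["sclera"], dtype=np.float32)
    refl[rows < cc_top] = REFLECTIVITY["retina"]
    refl[(rows >= cc_top) & (rows < sl_top)] = REFLECTIVITY["cc"]
    refl[sublayer > 0] = REFLECTIVITY["stroma"]
    refl[vessel > 0] = REFLECTIVITY["vessel"]

    n_avg = params.n_averages_hd if domain == "hd" else params.n_averages_lq
    slices = []
    for t in range(t_n):
        img = apply_speckle_and_average(refl[t], n_avg, rng_noise)
        if domain == "lq":
            img = _lq_degrade(img, params)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        slices.append(PhantomSample(img, vessel[t], sublayer[t], domain, params))
    return PhantomCube(slices, (t_n // 2, w // 2),
                       params.slice_spacing, params.lateral_spacing)
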