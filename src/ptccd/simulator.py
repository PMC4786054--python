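"""Stochastic forward model of the p-t-CCD detector.

Converts tables of X-ray impact positions on the detector face into raw
16-bit images through three stages:

1. *Phosphor*: each X-ray is absorbed with probability ``q_abs``; an
   absorbed event emits a shower of light photons whose count follows a
   gamma distribution matched to the scintillation spectrum's mean and
   SD (stochastically rounded to an integer, preserving the mean); each
   photon is displaced by a radial PSF draw (Gaussian core +
   Gamma(2, scale) tail).
2. *Taper*: each light photon independently survives the optical chain
   and CCD quantum efficiency with probability ``transmission`` and is
   mapped face -> CCD through the radial distortion.
3. *CCD*: photoelectrons (one per detected photon) are binned into
   30 um pixels; Poisson dark charge and Gaussian read noise are added;
   the charge is digitized at ``g_adc`` ADU/electron with a constant
   bias, clipped to the 16-bit range.

Because photon survival is independent of position, thinning before the
PSF displacement is statistically identical to displacing every emitted
photon and thinning afterwards; :func:`simulate_image` uses the thinned
(fast) path while :func:`phosphor_stage`/:func:`taper_stage` expose the
literal stage-by-stage chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig, PhosphorModel
from .distortion import RadialMap

__all__ = [
    "PhotonTable", "LightTable", "CCDPhotons", "RawImage", "Window",
    "generate_spot_photons", "generate_flood_photons",
    "phosphor_stage", "taper_stage", "ccd_expose", "simulate_image",
]


@dataclass(frozen=True)
class PhotonTable:
    """X-ray impact positions (um) on the detector face for one exposure."""
    x_um: np.ndarray
    y_um: np.ndarray
    energy_kev: float = 12.0

    def __len__(self) -> int:
        return len(self.x_um)

    @staticmethod
    def concat(tables: list["PhotonTable"]) -> "PhotonTable":
        return PhotonTable(
            np.concatenate([t.x_um for t in tables]),
            np.concatenate([t.y_um for t in tables]),
            tables[0].energy_kev if tables else 12.0,
        )


@dataclass(frozen=True)
class LightTable:
    """Light photons leaving the phosphor: one row per photon, plus the
    per-absorbed-event emission counts."""
    x_um: np.ndarray
    y_um: np.ndarray
    event_counts: np.ndarray

    def __len__(self) -> int:
        return len(self.x_um)


@dataclass(frozen=True)
class CCDPhotons:
    """Photon arrival positions on the CCD plane (um); ``n_dropped``
    counts photons mapped outside the sensor."""
    x_um: np.ndarray
    y_um: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.x_um)


@dataclass(frozen=True)
class Window:
    """A rectangular CCD-pixel window [x0, x0+nx) x [y0, y0+ny)."""
    x0: int
    y0: int
    nx: int
    ny: int

    @staticmethod
    def full(cfg: DetectorConfig) -> "Window":
        return Window(0, 0, cfg.n_pixels, cfg.n_pixels)


@dataclass
class RawImage:
    """Integer pixel raster plus exposure metadata.  ``kind`` is one of
    raw | dark | flood; raw images carry the ADC bias."""
    data: np.ndarray
    window: Window
    exposure_s: float
    kind: str = "raw"
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Photon sources

def generate_spot_photons(
    center_um: tuple[float, float],
    sigma_um: float,
    mean_count: float,
    rng: np.random.Generator,
) -> PhotonTable:
    """A diffraction spot: Poisson total count, isotropic Gaussian profile."""
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    if mean_count < 0:
        raise ValueError("mean_count must be non-negative")
    n = rng.poisson(mean_count)
    return PhotonTable(
        center_um[0] + sigma_um * rng.standard_normal(n),
        center_um[1] + sigma_um * rng.standard_normal(n),
    )


def generate_flood_photons(
    mean_per_pixel: float,
    face_x0: int, face_y0: int, nfx: int, nfy: int,
    rng: np.random.Generator,
    face_pixel_um: float = 73.0,
) -> PhotonTable:
    """Uniform X-ray background over a face-pixel window, i.i.d. Poisson
    per 73 um pixel region and uniform within pixels."""
    if mean_per_pixel < 0:
        raise ValueError("mean_per_pixel must be non-negative")
    n = rng.poisson(mean_per_pixel * nfx * nfy)
    return PhotonTable(
        (face_x0 + nfx * rng.random(n)) * face_pixel_um,
        (face_y0 + nfy * rng.random(n)) * face_pixel_um,
    )


# ---------------------------------------------------------------------------
# Cascade stages

def _emission_counts(n_events: int, model: PhosphorModel,
                     rng: np.random.Generator) -> np.ndarray:
    """Integer light-photon yields per absorbed X-ray: gamma distribution
    matched to (gain_mean, gain_sd), stochastically rounded so the mean
    is preserved exactly."""
    if model.gain_sd == 0:
        return np.full(n_events, np.rint(model.gain_mean), dtype=np.int64)
    shape = (model.gain_mean / model.gain_sd) ** 2
    scale = model.gain_sd**2 / model.gain_mean
    g = rng.gamma(shape, scale, n_events)
    lo = np.floor(g)
    return (lo + (rng.random(n_events) < (g - lo))).astype(np.int64)


def _psf_displacement(n: int, model: PhosphorModel,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Radial PSF draws: Gaussian core with probability ``core_weight``,
    otherwise a Gamma(2, tail_scale) radial excursion at uniform angle."""
    core = rng.random(n) < model.psf_core_weight
    dx = np.empty(n)
    dy = np.empty(n)
    nc = int(core.sum())
    dx[core] = model.psf_core_sigma_um * rng.standard_normal(nc)
    dy[core] = model.psf_core_sigma_um * rng.standard_normal(nc)
    nt = n - nc
    r = rng.gamma(2.0, model.psf_tail_scale_um, nt)
    theta = rng.uniform(0.0, 2.0 * np.pi, nt)
    dx[~core] = r * np.cos(theta)
    dy[~core] = r * np.sin(theta)
    return dx, dy


def psf_radial_profile(r_um: np.ndarray, model: PhosphorModel) -> np.ndarray:
    """Radial intensity profile (2-D density at radius r) of the PSF
    mixture: ``w * N2(0, sigma) + (1-w) * Gamma(2, scale)`` where the
    gamma component's radial marginal is r*exp(-r/scale)/scale**2."""
    r = np.asarray(r_um, dtype=float)
    s, lam, w = model.psf_core_sigma_um, model.psf_tail_scale_um, \
        model.psf_core_weight
    core = np.exp(-0.5 * (r / s) ** 2) / (2.0 * np.pi * s * s)
    tail = np.exp(-r / lam) / (2.0 * np.pi * lam * lam)
    return w * core + (1.0 - w) * tail


def psf_widths(model: PhosphorModel) -> tuple[float, float]:
    """(FWHM, FW10%M) in um of the radial PSF intensity profile,
    evaluated numerically."""
    r = np.linspace(0.0, 2000.0, 200_001)
    prof = psf_radial_profile(r, model)
    peak = prof[0]
    fwhm = 2.0 * r[np.searchsorted(-prof, -0.5 * peak)]
    fw10 = 2.0 * r[np.searchsorted(-prof, -0.1 * peak)]
    return float(fwhm), float(fw10)


def phosphor_stage(photons: PhotonTable, model: PhosphorModel,
                   rng: np.random.Generator) -> LightTable:
    """Absorption, scintillation amplification and PSF displacement."""
    n = len(photons)
    absorbed = rng.random(n) < model.q_abs
    x0 = photons.x_um[absorbed]
    y0 = photons.y_um[absorbed]
    counts = _emission_counts(len(x0), model, rng)
    x = np.repeat(x0, counts)
    y = np.repeat(y0, counts)
    dx, dy = _psf_displacement(len(x), model, rng)
    return LightTable(x + dx, y + dy, counts)


def taper_stage(light: LightTable, radial: RadialMap,
                rng: np.random.Generator, transmission: float | None = None,
                ) -> CCDPhotons:
    """Binomial survival through the optical chain + CCD QE, then the
    face -> CCD distortion mapping.  Photons landing outside the sensor
    are dropped and counted."""
    t = radial.cfg.taper.transmission if transmission is None else transmission
    keep = rng.random(len(light)) < t
    xy = np.stack([light.x_um[keep], light.y_um[keep]], axis=-1)
    ccd = radial.face_to_ccd(xy)
    extent = radial.cfg.n_pixels * radial.cfg.taper.ccd_pixel_um
    inside = ((ccd[:, 0] >= 0) & (ccd[:, 0] < extent)
              & (ccd[:, 1] >= 0) & (ccd[:, 1] < extent))
    return CCDPhotons(ccd[inside, 0], ccd[inside, 1],
                      n_dropped=int((~inside).sum()))


def _survivor_face_positions(photons: PhotonTable, cfg: DetectorConfig,
                             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # Fast path: absorb, draw emission counts, binomially thin each shower
    # BEFORE displacing, then PSF-displace only the survivors.
    model = cfg.phosphor
    n = len(photons)
    absorbed = rng.random(n) < model.q_abs
    x0 = photons.x_um[absorbed]
    y0 = photons.y_um[absorbed]
    counts = _emission_counts(len(x0), model, rng)
    surv = rng.binomial(counts, cfg.taper.transmission)
    x = np.repeat(x0, surv)
    y = np.repeat(y0, surv)
    dx, dy = _psf_displacement(len(x), model, rng)
    return x + dx, y + dy


def ccd_expose(
    ccd_photons: CCDPhotons,
    exposure_s: float,
    cfg: DetectorConfig,
    rng: np.random.Generator,
    window: Window | None = None,
    kind: str = "raw",
) -> RawImage:
    """Bin photons into CCD pixels (unit photoelectron yield), accumulate
    dark charge and read noise, digitize and add the bias."""
    if exposure_s <= 0:
        raise ValueError("exposure_s must be positive")
    w = window or Window.full(cfg)
    pitch = cfg.taper.ccd_pixel_um
    ix = np.floor(ccd_photons.x_um / pitch).astype(np.int64) - w.x0
    iy = np.floor(ccd_photons.y_um / pitch).astype(np.int64) - w.y0
    ok = (ix >= 0) & (ix < w.nx) & (iy >= 0) & (iy < w.ny)
    electrons = np.bincount(iy[ok] * w.nx + ix[ok],
                            minlength=w.ny * w.nx).astype(float)
    electrons = electrons.reshape(w.ny, w.nx)
    electrons += rng.poisson(cfg.dark_e_per_s * exposure_s,
                             size=(w.ny, w.nx))
    electrons += cfg.read_noise_e * rng.standard_normal((w.ny, w.nx))
    adu = np.rint(cfg.g_adc * electrons) + cfg.bias_adu
    np.clip(adu, 0, cfg.adc_max, out=adu)
    return RawImage(adu.astype(np.uint16), w, exposure_s, kind=kind)


def simulate_image(
    photons: PhotonTable,
    cfg: DetectorConfig,
    seed_or_rng: int | np.random.Generator,
    window: Window | None = None,
    exposure_s: float = 1.0,
    kind: str = "raw",
    radial: RadialMap | None = None,
) -> RawImage:
    """Full forward simulation: phosphor + taper + CCD read-out.
    Deterministic for a given seed."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    radial = radial or RadialMap(cfg)
    fx, fy = _survivor_face_positions(photons, cfg, rng)
    ccd = radial.face_to_ccd(np.stack([fx, fy], axis=-1))
    img = ccd_expose(CCDPhotons(ccd[:, 0], ccd[:, 1]), exposure_s, cfg, rng,
                     window=window, kind=kind)
    if isinstance(seed_or_rng, (int, np.integer)):
        img.meta["seed"] = int(seed_or_rng)
    return img
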