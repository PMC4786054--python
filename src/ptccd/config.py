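"""Detector configuration.

A phosphor-taper-CCD (p-t-CCD) area detector converts X-rays to visible
light in a phosphor screen, demagnifies the light image through a
fibre-optic taper (FOT) and records it on a CCD.  All tunable parameters
of the simulated detector live in :class:`DetectorConfig`; the defaults
describe a 1024x1024-pixel module operated with monoenergetic 12 keV
X-rays at normal incidence.

Coordinate conventions (shared by every module):

* Detector-face pixels are 0-based squares of ``face_pixel_um`` (73 um);
  face pixel ``i`` spans ``[i*73, (i+1)*73)`` um, centre ``(i+0.5)*73``.
* CCD pixels are 0-based squares of ``ccd_pixel_um`` (30 um).
* The radial taper mapping is centred on the geometric centre of each
  grid (``n/2 * pitch``).
* Image arrays are indexed ``[iy, ix]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade import CascadeParams


@dataclass(frozen=True)
class PhosphorModel:
    """Phosphor screen: quantum absorption, scintillation gain and PSF.

    The scintillation spectrum (light photons per absorbed X-ray) is a
    gamma distribution matched to the stated mean and standard deviation;
    all cascade statistics depend on it only through those two moments.
    The point-spread function is a two-component radial mixture: an
    isotropic Gaussian core plus a Gamma(2, tail_scale) radial tail.
    The defaults describe the *full-system* PSF (phosphor plus the rest
    of the optical chain), sized at the envelope of the phosphor-alone
    constraints (radial intensity profile FWHM < 40 um, FW10%M <
    100 um): FWHM ~= 39 um, FW10%M ~= 76 um.  The PSF moves light
    between neighbouring pixels without changing totals, so it sets the
    inter-pixel correlation scale but none of the region-sum statistics.
    """

    q_abs: float = 0.85
    gain_mean: float = 281.5
    gain_sd: float = 163.3
    psf_core_sigma_um: float = 16.0
    psf_core_weight: float = 0.5
    psf_tail_scale_um: float = 35.0
    psf_fwhm_bound_um: float = 40.0
    psf_fw10m_bound_um: float = 100.0


@dataclass(frozen=True)
class TaperModel:
    """Fibre-optic taper: demagnification, losses and radial distortion.

    The face->CCD mapping is ``r_ccd = (r/demag) * (1 + k2 * r**2)`` with
    ``r`` the radial distance from the face centre in um; ``k2 > 0``
    gives a pincushion distortion.  The default ``k2`` displaces the grid
    by about three corrected pixels at the edge of the face.
    ``transmission`` folds FOT acceptance, FOT transmittance, stub
    acceptance and CCD quantum efficiency into one binomial survival
    probability per light photon.
    """

    demag: float = 2.7
    k2_per_um2: float = 4.1937e-12
    fot_acceptance: float = 0.50
    fot_transmittance: float = 0.14
    stub_acceptance: float = 0.70
    ccd_qe: float = 0.35
    ccd_pixel_um: float = 30.0

    @property
    def optical_transmittance(self) -> float:
        """Losses of the optical chain alone, excluding CCD QE (= 4.9%)."""
        return self.fot_acceptance * self.fot_transmittance * self.stub_acceptance

    @property
    def transmission(self) -> float:
        """Overall light survival probability, folding in the CCD QE (= 0.01715)."""
        return self.optical_transmittance * self.ccd_qe


@dataclass(frozen=True)
class DetectorConfig:
    """Full description of the simulated detector."""

    n_pixels: int = 1024              # per side, both face grid and CCD
    face_pixel_um: float = 73.0
    phosphor: PhosphorModel = field(default_factory=PhosphorModel)
    taper: TaperModel = field(default_factory=TaperModel)
    e_yield: float = 1.0              # photoelectrons per detected light photon
    g_adc: float = 0.2                # ADU per electron
    read_noise_e: float = 10.0
    dark_e_per_s: float = 0.01        # dark current, electrons/pixel/s
    bias_adu: int = 500               # raw-image pedestal
    corrected_pedestal_adu: int = 10  # pedestal re-added to stored corrected images
    adc_max: int = 65535
    energy_kev: float = 12.0

    @property
    def face_extent_um(self) -> float:
        return self.n_pixels * self.face_pixel_um

    @property
    def face_center_um(self) -> float:
        return 0.5 * self.n_pixels * self.face_pixel_um

    @property
    def ccd_center_um(self) -> float:
        return 0.5 * self.n_pixels * self.taper.ccd_pixel_um

    def cascade_params(self) -> CascadeParams:
        """Stage parameters of the stochastic detection cascade."""
        return CascadeParams(
            q_abs=self.phosphor.q_abs,
            gain_mean=self.phosphor.gain_mean,
            gain_sd=self.phosphor.gain_sd,
            transmission=self.taper.transmission,
            e_yield=self.e_yield,
            g_adc=self.g_adc,
            read_noise_e=self.read_noise_e,
        )


def _flatten(cfg: DetectorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    phos = d.pop("phosphor")
    taper = d.pop("taper")
    for k, v in phos.items():
        d[f"phosphor.{k}"] = v
    for k, v in taper.items():
        d[f"taper.{k}"] = v
    return d


def save_config(cfg: DetectorConfig, path: str | Path) -> None:
    """Write the configuration as a flat key-value YAML file."""
    Path(path).write_text(yaml.safe_dump(_flatten(cfg), sort_keys=True))


def load_config(path: str | Path, **overrides) -> DetectorConfig:
    """Read a flat key-value config file; keyword arguments override keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    phos_kwargs, taper_kwargs, top = {}, {}, {}
    for key, value in raw.items():
        if key.startswith("phosphor."):
            phos_kwargs[key.split(".", 1)[1]] = value
        elif key.startswith("taper."):
            taper_kwargs[key.split(".", 1)[1]] = value
        else:
            top[key] = value
    return DetectorConfig(
        phosphor=PhosphorModel(**phos_kwargs),
        taper=TaperModel(**taper_kwargs),
        **top,
    )
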