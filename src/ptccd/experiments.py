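"""Study drivers: simulated spot-ensemble statistics and the
real-detector cascade-factor estimation workflow.

The spot-ensemble driver reproduces the simulated-detector study design:
replicate raw images of a single Gaussian spot (Poisson total count) on
a uniform Poisson X-ray background, integrated by summation and by
profile fitting, on raw and on fully corrected images, in two detector
zones that sample different distortion registrations.

The real-detector workflow operates on small tabular inputs: a gain
measurement from simultaneous scintillation counting, the total
pixel-noise of a measurement box from no-beam exposures, and the
response variation of a repeatedly exposed signal after removal of the
beam-intensity trend, which together feed :func:`ptccd.cascade.estimate_gamma`.
A fixture generator synthesises such tables with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (build_dark, build_flat_field, correct_image,
                          simulate_floods, DarkImage, FlatField)
from .cascade import NoiseBudget, derive_noise_budget, estimate_gamma
from .config import DetectorConfig
from .distortion import DistortionMap, RadialMap, build_distortion_map
from .integration import (MeasurementBox, build_measurement_box,
                          build_reference_profile, empirical_pixel_covariance,
                          extract_box, profile_fit, summation_integrate,
                          variance_cascade, variance_poisson_mosflm)
from .simulator import (PhotonTable, Window, generate_flood_photons,
                        generate_spot_photons, simulate_image)

__all__ = [
    "EnsembleSpec", "ZoneGeometry", "PipelineEnsemble", "EnsembleResult",
    "build_zone_geometry", "run_spot_ensemble",
    "ResponseSeries", "GainEstimate", "TrendFit",
    "estimate_relative_factor", "gain_from_counting",
    "pixel_noise_from_darks", "trend_residual_variance",
    "make_response_fixture",
]

#: Central corrected-image pixel of the measurement box in each zone;
#: zone B is zone A shifted by six pixels in X and Y.
ZONE_CENTERS = {"A": (306, 306), "B": (300, 300)}


@dataclass(frozen=True)
class EnsembleSpec:
    """Study conditions for one spot-image ensemble."""

    n_replicates: int = 10_000
    spot_mean: float = 1.0e4          # Poisson mean of X-rays per spot
    spot_sigma_um: float = 90.0       # isotropic Gaussian spot width
    zone: str = "A"
    background_per_pixel: float = 20.0   # X-rays per 73 um face pixel
    box_params: tuple[int, int, int, int, int] = (23, 23, 5, 4, 11)
    n_profile_images: int = 20
    n_dark_images: int = 200
    n_flood_images: int = 100
    flood_mean_per_pixel: float = 100.0
    window_half: int = 17             # face pixels either side of the centre
    seed: int = 0

    @property
    def center_px(self) -> tuple[int, int]:
        if self.zone not in ZONE_CENTERS:
            raise ValueError(f"unknown zone {self.zone!r}")
        return ZONE_CENTERS[self.zone]


@dataclass
class ZoneGeometry:
    """Windowed geometry and calibration products for one detector zone."""
    cfg: DetectorConfig
    radial: RadialMap
    window: Window
    face_x0: int
    face_y0: int
    nf: int
    spot_center_um: tuple[float, float]
    dmap: DistortionMap
    dark: DarkImage
    flat: FlatField | None
    box_corrected: MeasurementBox
    box_raw: MeasurementBox


def build_zone_geometry(
    cfg: DetectorConfig,
    spec: EnsembleSpec,
    rng: np.random.Generator,
    with_flat: bool = True,
) -> ZoneGeometry:
    """Set up the simulation window around the zone centre, the
    distortion map, a 200-image dark and (optionally) the flat field."""
    cx, cy = spec.center_px
    face_x0, face_y0 = cx - spec.window_half, cy - spec.window_half
    nf = 2 * spec.window_half + 1
    radial = RadialMap(cfg)
    pitch = cfg.face_pixel_um

    # CCD window: bounding box of the mapped face-window boundary
    edge = np.linspace(0.0, nf * pitch, 81)
    pts = []
    for e in edge:
        pts += [(face_x0 * pitch + e, face_y0 * pitch),
                (face_x0 * pitch + e, (face_y0 + nf) * pitch),
                (face_x0 * pitch, face_y0 * pitch + e),
                ((face_x0 + nf) * pitch, face_y0 * pitch + e)]
    ccd = radial.face_to_ccd(np.asarray(pts))
    cpitch = cfg.taper.ccd_pixel_um
    cx0 = int(np.floor(ccd[:, 0].min() / cpitch)) - 2
    cy0 = int(np.floor(ccd[:, 1].min() / cpitch)) - 2
    ncx = int(np.ceil(ccd[:, 0].max() / cpitch)) + 2 - cx0
    ncy = int(np.ceil(ccd[:, 1].max() / cpitch)) + 2 - cy0
    window = Window(cx0, cy0, ncx, ncy)

    dmap = build_distortion_map(cfg, cx0, cy0, ncx, ncy,
                                face_x0, face_y0, nf, nf)
    dark = build_dark(cfg, rng, n_images=spec.n_dark_images, window=window)
    flat = None
    if with_flat:
        floods = simulate_floods(
            cfg, rng, spec.n_flood_images, spec.flood_mean_per_pixel,
            face_x0 - 4, face_y0 - 4, nf + 8, nf + 8, window, radial=radial)
        flat = build_flat_field(floods, dark, dmap)

    spot_center = ((cx + 0.5) * pitch, (cy + 0.5) * pitch)
    nx, ny, nrx, nry, nc = spec.box_params
    box_corr = build_measurement_box(
        (cx - face_x0, cy - face_y0), nx, ny, nrx, nry, nc)
    # The same physical box on the raw grid: parameters scaled by the
    # face-to-CCD pixel size ratio.
    sc = radial.face_to_ccd(np.asarray([spot_center]))[0]
    raw_center = (int(sc[0] // cpitch) - cx0, int(sc[1] // cpitch) - cy0)
    box_raw = box_corr.scaled(raw_center, pitch / (cpitch * cfg.taper.demag))
    return ZoneGeometry(cfg, radial, window, face_x0, face_y0, nf,
                        spot_center, dmap, dark, flat, box_corr, box_raw)


def _simulate_box_rasters(
    geom: ZoneGeometry, spec: EnsembleSpec, n: int,
    rng: np.random.Generator, corrected: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    cfg = geom.cfg
    raw = np.empty((n, geom.box_raw.ny, geom.box_raw.nx))
    corr = (np.empty((n, geom.box_corrected.ny, geom.box_corrected.nx))
            if corrected else None)
    for i in range(n):
        spot = generate_spot_photons(geom.spot_center_um, spec.spot_sigma_um,
                                     spec.spot_mean, rng)
        flood = generate_flood_photons(spec.background_per_pixel,
                                       geom.face_x0, geom.face_y0,
                                       geom.nf, geom.nf, rng,
                                       cfg.face_pixel_um)
        img = simulate_image(PhotonTable.concat([spot, flood]), cfg, rng,
                             window=geom.window, radial=geom.radial)
        raw[i] = extract_box(img.data.astype(float), geom.box_raw)
        if corrected:
            cimg = correct_image(img, geom.dark, geom.flat, geom.dmap,
                                 pedestal_adu=cfg.corrected_pedestal_adu)
            corr[i] = extract_box(cimg.quantized_values, geom.box_corrected)
    return raw, corr


@dataclass
class PipelineEnsemble:
    """Per-replicate integration results for one pipeline (raw or
    corrected images) plus ensemble summaries."""

    pipeline: str
    box: MeasurementBox
    i_s: np.ndarray                   # summation intensities
    var_poisson: np.ndarray           # per-replicate Poisson estimates
    var_cascade: np.ndarray           # per-replicate cascade estimates
    i_p: np.ndarray                   # diagonal-weighted profile intensities
    var_fit: np.ndarray               # per-replicate profile-fit estimates
    i_p_gls: np.ndarray | None = None
    var_gls: float | None = None
    profile: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.i_s)

    # --- summation summaries -------------------------------------------
    @property
    def mean_i_s(self) -> float:
        return float(self.i_s.mean())

    @property
    def se_mean_i_s(self) -> float:
        return float(self.i_s.std(ddof=1) / np.sqrt(self.n))

    @property
    def var_i_s(self) -> float:
        return float(self.i_s.var(ddof=1))

    @property
    def se_var_i_s(self) -> float:
        return self.var_i_s * np.sqrt(2.0 / (self.n - 1))

    def mean_se(self, arr: np.ndarray) -> tuple[float, float]:
        return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(self.n))

    # --- profile summaries ---------------------------------------------
    @property
    def var_i_p(self) -> float:
        return float(self.i_p.var(ddof=1))

    @property
    def profile_variance_ratio(self) -> float:
        """Observed var(I_P) over the mean diagonal-mode estimate: the
        factor by which fit-quality error estimates are optimistic."""
        return self.var_i_p / float(self.var_fit.mean())


@dataclass
class EnsembleResult:
    spec: EnsembleSpec
    geometry: ZoneGeometry
    raw: PipelineEnsemble
    corrected: PipelineEnsemble | None = None

    def summary(self) -> pd.DataFrame:
        """Tabulated ensemble statistics in the style of the study's
        summation/profile result tables (value, standard error)."""
        cols = {}
        for pipe in filter(None, (self.raw, self.corrected)):
            mp, sp = pipe.mean_se(pipe.var_poisson)
            mc, sc = pipe.mean_se(pipe.var_cascade)
            mf, sf = pipe.mean_se(pipe.var_fit)
            cols[pipe.pipeline] = {
                "mean(I_S) [ADU]": pipe.mean_i_s,
                "se mean(I_S)": pipe.se_mean_i_s,
                "var(I_S) [ADU^2]": pipe.var_i_s,
                "se var(I_S)": pipe.se_var_i_s,
                "mean poisson estimator [ADU^2]": mp,
                "se poisson estimator": sp,
                "mean cascade estimator [ADU^2]": mc,
                "se cascade estimator": sc,
                "mean(I_P) [ADU]": float(pipe.i_p.mean()),
                "var(I_P) [ADU^2]": pipe.var_i_p,
                "mean profile-fit estimator [ADU^2]": mf,
                "se profile-fit estimator": sf,
                "profile variance ratio": pipe.profile_variance_ratio,
                "GLS estimator [ADU^2]": pipe.var_gls,
                "var(I_P GLS) [ADU^2]": (float(pipe.i_p_gls.var(ddof=1))
                                         if pipe.i_p_gls is not None else None),
            }
        return pd.DataFrame(cols)


def _integrate_pipeline(
    name: str,
    rasters: np.ndarray,
    profile_rasters: np.ndarray,
    box: MeasurementBox,
    budget: NoiseBudget,
    pedestal: float,
    with_gls: bool,
    max_lag: int = 7,
) -> PipelineEnsemble:
    res = summation_integrate(rasters, box, pedestal=pedestal)
    vp = variance_poisson_mosflm(res, budget.gain_absorbed)
    vc = variance_cascade(res, budget)
    profile = build_reference_profile(profile_rasters, box, pedestal=pedestal)
    pf = profile_fit(rasters, box, profile, budget.gain_absorbed,
                     pedestal=pedestal)
    pe = PipelineEnsemble(name, box, res.intensity, vp, vc,
                          pf.intensity, pf.variance_fit, profile=profile)
    if with_gls:
        mf = empirical_pixel_covariance(rasters, box, max_lag=max_lag,
                                        pedestal=pedestal)
        g = profile_fit(rasters, box, profile, budget.gain_absorbed,
                        weights=mf, pedestal=pedestal)
        pe.i_p_gls = g.intensity
        pe.var_gls = float(g.variance_fit.mean())
    return pe


def run_spot_ensemble(
    spec: EnsembleSpec,
    pipeline: str = "both",
    cfg: DetectorConfig | None = None,
    with_gls: bool = True,
) -> EnsembleResult:
    """Generate a replicate spot-image ensemble and integrate it.

    ``pipeline`` selects "raw", "corrected" or "both" image chains.  All
    randomness derives from ``spec.seed``.
    """
    if pipeline not in ("raw", "corrected", "both"):
        raise ValueError("pipeline must be raw | corrected | both")
    cfg = cfg or DetectorConfig()
    rng = np.random.default_rng(spec.seed)
    corrected = pipeline in ("corrected", "both")
    geom = build_zone_geometry(cfg, spec, rng, with_flat=corrected)
    budget = derive_noise_budget(cfg.cascade_params())

    prof_raw, prof_corr = _simulate_box_rasters(
        geom, spec, spec.n_profile_images, rng, corrected)
    raw, corr = _simulate_box_rasters(
        geom, spec, spec.n_replicates, rng, corrected)

    raw_pe = _integrate_pipeline("raw", raw, prof_raw, geom.box_raw, budget,
                                 pedestal=cfg.bias_adu, with_gls=with_gls)
    corr_pe = None
    if corrected:
        corr_pe = _integrate_pipeline("corrected", corr, prof_corr,
                                      geom.box_corrected, budget,
                                      pedestal=0.0, with_gls=with_gls)
    return EnsembleResult(spec, geom, raw_pe, corr_pe)


# ===========================================================================
# Real-detector calibration workflow (tabular inputs)

@dataclass(frozen=True)
class ResponseSeries:
    """Per-exposure integrated intensity with a beam-monitor reading and
    a section id marking contiguous well-behaved segments of the time
    series (demarcated by abrupt changes such as top-up injections)."""
    intensity_adu: np.ndarray
    monitor: np.ndarray
    section_id: np.ndarray
    time_s: np.ndarray

    def __post_init__(self):
        n = len(self.intensity_adu)
        if not (len(self.monitor) == len(self.section_id)
                == len(self.time_s) == n):
            raise ValueError("series columns must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "monitor": self.monitor,
            "intensity_adu": self.intensity_adu, "section": self.section_id,
        })

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ResponseSeries":
        return ResponseSeries(
            intensity_adu=df["intensity_adu"].to_numpy(float),
            monitor=df["monitor"].to_numpy(float),
            section_id=df["section"].to_numpy(int),
            time_s=df["time_s"].to_numpy(float),
        )


@dataclass(frozen=True)
class GainEstimate:
    gain: float
    se: float


def estimate_relative_factor(intensity_upper: np.ndarray,
                             intensity_lower: np.ndarray) -> GainEstimate:
    """Relative intensity of two spots from simultaneous integrations:
    least-squares slope of upper vs lower through the origin."""
    x = np.asarray(intensity_lower, float)
    y = np.asarray(intensity_upper, float)
    if len(x) < 3:
        raise ValueError("need at least 3 simultaneous integrations")
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    se = np.sqrt(float(resid @ resid) / (len(x) - 1) / sxx)
    return GainEstimate(slope, se)


def gain_from_counting(
    intensity_sums: np.ndarray,
    photon_counts: np.ndarray,
    relative_factor: float | GainEstimate,
) -> GainEstimate:
    """Detector gain G' (ADU per incident photon) from images of one spot
    recorded simultaneously with scintillation counts of its partner.

    ``intensity_sums`` are the integrated intensities of the imaged
    (upper) spot; ``photon_counts`` the background-subtracted counts of
    the counted (lower) spot; ``relative_factor`` the upper/lower
    relative intensity (with its standard error if available).  The
    imaged intensities are converted to the counted spot's scale and a
    linear model is fitted; the standard error combines both stages.
    """
    i = np.asarray(intensity_sums, float)
    c = np.asarray(photon_counts, float)
    if len(i) != len(c):
        raise ValueError("series must have equal length")
    if len(i) < 3:
        raise ValueError("need at least 3 exposures")
    rf = (relative_factor.gain if isinstance(relative_factor, GainEstimate)
          else float(relative_factor))
    rf_se = (relative_factor.se if isinstance(relative_factor, GainEstimate)
             else 0.0)
    equiv = i / rf                    # inferred intensity of the counted spot
    a = np.stack([c, np.ones_like(c)], axis=1)
    coef, *_ = np.linalg.lstsq(a, equiv, rcond=None)
    slope = float(coef[0])
    resid = equiv - a @ coef
    s2 = float(resid @ resid) / (len(c) - 2)
    cxx = float(((c - c.mean()) ** 2).sum())
    slope_se = np.sqrt(s2 / cxx)
    se = abs(slope) * np.sqrt((slope_se / slope) ** 2 + (rf_se / rf) ** 2)
    return GainEstimate(slope, se)


def pixel_noise_from_darks(rasters: np.ndarray, box: MeasurementBox,
                           pedestal: float = 0.0) -> float:
    """Total pixel-noise variance N*psi (ADU^2) of a measurement box:
    sample variance of the box-region sum over a stack of no-beam
    images."""
    x = np.asarray(rasters, float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need at least two no-beam images")
    sums = extract_box(x - pedestal, box).reshape(x.shape[0], -1).sum(axis=1)
    return float(sums.var(ddof=1))


@dataclass(frozen=True)
class TrendFit:
    signal_mean: float            # mean of the trend values (ADU)
    residual_variance: float      # pooled variance about the trend (ADU^2)
    residual_variance_se: float
    trend_rel_sd: float           # SD of trend values over their mean
    section_scales: np.ndarray


def trend_residual_variance(series: ResponseSeries) -> TrendFit:
    """Remove the beam-intensity trend section by section and pool the
    residual variance.

    Within each section the integrated intensity is modelled as
    proportional to the monitor reading (a per-section linear scaling);
    residual variances are pooled unweighted with one degree of freedom
    per fitted scale.  The trend's relative SD is reported so the
    stationarity approximation can be checked.
    """
    sections = np.unique(series.section_id)
    if len(series.intensity_adu) < 2:
        raise ValueError("series too short")
    rss = 0.0
    trend_all = np.empty_like(series.intensity_adu, dtype=float)
    scales = []
    for s in sections:
        m = series.section_id == s
        if m.sum() < 3:
            raise ValueError(f"section {s} has fewer than 3 points")
        mon = series.monitor[m]
        inten = series.intensity_adu[m]
        if np.all(mon == 0):
            raise ValueError(f"section {s} has all-zero monitor readings")
        scale = float(mon @ inten) / float(mon @ mon)
        scales.append(scale)
        trend = scale * mon
        trend_all[m] = trend
        rss += float(((inten - trend) ** 2).sum())
    dof = len(series.intensity_adu) - len(sections)
    var = rss / dof
    return TrendFit(
        signal_mean=float(trend_all.mean()),
        residual_variance=var,
        residual_variance_se=var * np.sqrt(2.0 / dof),
        trend_rel_sd=float(trend_all.std(ddof=1) / trend_all.mean()),
        section_scales=np.asarray(scales),
    )


def make_response_fixture(
    gamma: float,
    gain_absorbed: float,
    n_psi: float,
    mean_signal_adu: float = 11_926.0,
    n_exposures: int = 400,
    n_sections: int = 8,
    trend_rel_sd: float = 0.013,
    exposure_s: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> ResponseSeries:
    """Synthetic stand-in for a beamline response time series.

    The monitor traces a sawtooth of top-up cycles (linear decay within
    each section, reset at section boundaries) whose relative SD matches
    ``trend_rel_sd``; intensities scatter about a monitor-proportional
    trend with the cascade-model variance ``gamma*G*signal + N*psi``.
    """
    if min(gamma, gain_absorbed, mean_signal_adu) <= 0 or n_psi < 0:
        raise ValueError("fixture parameters must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    per = n_exposures // n_sections
    n = per * n_sections
    # sawtooth with relative SD = trend_rel_sd: uniform over a range of
    # sqrt(12) * trend_rel_sd (relative)
    half_range = np.sqrt(3.0) * trend_rel_sd
    ramp = np.linspace(half_range, -half_range, per)
    monitor = 150.0 * (1.0 + np.tile(ramp, n_sections))
    scale = mean_signal_adu / monitor.mean()
    trend = scale * monitor
    sd = np.sqrt(gamma * gain_absorbed * trend + n_psi)
    intensity = trend + sd * rng.standard_normal(n)
    return ResponseSeries(
        intensity_adu=intensity,
        monitor=monitor,
        section_id=np.repeat(np.arange(n_sections), per),
        time_s=np.arange(n) * exposure_s,
    )
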