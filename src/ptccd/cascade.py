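"""Closed-form noise algebra of the p-t-CCD detection cascade.

A detection event passes through a chain of stochastic gain stages:
Poisson X-ray arrival, binomial absorption in the phosphor (probability
``q_abs``), scintillation amplification (mean ``gain_mean``, SD
``gain_sd`` light photons), binomial transmission of each light photon
to a stored photoelectron (probability ``transmission``), and a unit
photoelectron yield.  Summing the per-stage relative variances, each
normalised by the number of quanta entering that stage, gives the
relative variance of the stored charge::

    relvar = gamma / (n_mean * q_abs)

with the *cascade factor*::

    gamma = 1 + (gain_sd/gain_mean)**2 + (1/transmission - 1)/gain_mean

Read-out noise and digitization add a per-pixel *pixel factor*
``psi = (g_adc*read_noise_e)**2 + 1/12`` in ADU^2.  For a bias-corrected
region sum ``p`` (ADU) over ``N`` pixels the variance is then::

    Var(p) = gamma * G * p + N * psi

where ``G = gain_mean * transmission * e_yield * g_adc`` is the apparent
gain per *absorbed* X-ray and ``G' = q_abs * G`` the measurable gain per
*incident* X-ray.  An ideal photon counter has ``gamma = 1, psi = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CascadeParams",
    "NoiseBudget",
    "derive_noise_budget",
    "expected_signal_adu",
    "signal_variance_adu2",
    "signal_variance_counts",
    "estimate_gamma",
    "gain_incident_to_absorbed",
    "dqe",
]

#: Variance of the quantization error under the pseudo-quantization
#: model: uniform over 1 ADU.  Valid here because the read noise spans
#: g_adc * read_noise_e = 2 ADU > 1 ADU.
DIGITIZATION_VAR_ADU2 = 1.0 / 12.0


class ParameterError(ValueError):
    """A cascade parameter is outside its physical range."""


@dataclass(frozen=True)
class CascadeParams:
    """Stage parameters of the detection cascade (Table-style defaults
    live in :class:`ptccd.config.DetectorConfig`)."""

    q_abs: float
    gain_mean: float
    gain_sd: float
    transmission: float
    e_yield: float = 1.0
    g_adc: float = 0.2
    read_noise_e: float = 10.0
    digitization_var_adu2: float = DIGITIZATION_VAR_ADU2

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_abs <= 1.0:
            raise ParameterError(f"q_abs must be in [0, 1], got {self.q_abs}")
        if not 0.0 < self.transmission <= 1.0:
            raise ParameterError(
                f"transmission must be in (0, 1], got {self.transmission}"
            )
        if self.gain_mean <= 0:
            raise ParameterError("gain_mean must be positive")
        if self.gain_sd < 0:
            raise ParameterError("gain_sd must be non-negative")
        if self.g_adc <= 0:
            raise ParameterError("g_adc must be positive")
        if self.read_noise_e < 0:
            raise ParameterError("read_noise_e must be non-negative")
        if self.digitization_var_adu2 < 0:
            raise ParameterError("digitization_var_adu2 must be non-negative")


@dataclass(frozen=True)
class NoiseBudget:
    """Folded noise description of a detector: cascade factor, pixel
    factor and the two gains."""

    gamma: float
    psi: float
    gain_absorbed: float
    gain_incident: float


def derive_noise_budget(params: CascadeParams) -> NoiseBudget:
    """Fold the stage-by-stage relative-variance chain into (gamma, psi, G, G').

    The scintillation stage contributes ``(gain_sd/gain_mean)**2``; the
    binomial transmission contributes ``(1/transmission - 1)/gain_mean``
    (normalised by the light photons entering it); the unit photoelectron
    yield contributes nothing.
    """
    swank = (params.gain_sd / params.gain_mean) ** 2
    transfer = (1.0 / params.transmission - 1.0) / params.gain_mean
    gamma = 1.0 + swank + transfer
    psi = (params.g_adc * params.read_noise_e) ** 2 + params.digitization_var_adu2
    gain_absorbed = (
        params.gain_mean * params.transmission * params.e_yield * params.g_adc
    )
    return NoiseBudget(
        gamma=gamma,
        psi=psi,
        gain_absorbed=gain_absorbed,
        gain_incident=params.q_abs * gain_absorbed,
    )


def expected_signal_adu(n_incident_mean: float, params: CascadeParams) -> float:
    """Expected bias-corrected signal (ADU) for a mean incident photon count."""
    if n_incident_mean < 0:
        raise ParameterError("n_incident_mean must be non-negative")
    return n_incident_mean * derive_noise_budget(params).gain_incident


def signal_variance_adu2(
    signal_adu: float, n_pixels: float, budget: NoiseBudget
) -> float:
    """Variance (ADU^2) of a bias-corrected region sum estimated from a
    single observation ``signal_adu`` collected over ``n_pixels`` pixels:
    ``gamma * G * p + N * psi``."""
    if signal_adu < 0:
        raise ParameterError("signal_adu must be non-negative (bias-subtracted)")
    if n_pixels < 1:
        raise ParameterError("n_pixels must be >= 1")
    return budget.gamma * budget.gain_absorbed * signal_adu + n_pixels * budget.psi


def signal_variance_counts(
    counts: float, n_pixels: float, budget: NoiseBudget
) -> float:
    """The same variance expressed in detected-photon-count units: divide
    signal by G and variance by G^2, giving ``gamma*counts + N*psi/G**2``."""
    adu = counts * budget.gain_absorbed
    return signal_variance_adu2(adu, n_pixels, budget) / budget.gain_absorbed**2


def estimate_gamma(
    observed_variance: float,
    signal: float,
    pixel_noise_total: float,
    gain_absorbed: float,
) -> float:
    """Invert the region-sum variance model for the cascade factor:
    ``gamma = (Var - N*psi) / (G * p)``.

    ``pixel_noise_total`` is the total pixel-noise variance ``N*psi`` for
    the region, measurable from corrected dark frames.
    """
    if signal <= 0:
        raise ParameterError("signal must be positive")
    if gain_absorbed <= 0:
        raise ParameterError("gain_absorbed must be positive")
    if observed_variance < pixel_noise_total:
        raise ParameterError(
            "observed variance is below the pixel-noise floor "
            f"({observed_variance} < {pixel_noise_total}): non-physical input"
        )
    return (observed_variance - pixel_noise_total) / (gain_absorbed * signal)


def gain_incident_to_absorbed(g_incident: float, q_abs: float) -> float:
    """Convert the measurable per-incident-photon gain G' to the
    per-absorbed-photon gain G = G'/q_abs."""
    if not 0.0 < q_abs <= 1.0:
        raise ParameterError(f"q_abs must be in (0, 1], got {q_abs}")
    return g_incident / q_abs


def dqe(
    n_incident_mean: float,
    n_pixels: float,
    budget: NoiseBudget,
    q_abs: float,
) -> float:
    """Zero-frequency detective quantum efficiency for a region of interest.

    DQE = (S_o/sigma_o)^2 / (S_i/sigma_i)^2 with Poisson input
    (sigma_i^2 = n_mean) and the cascade output statistics, which reduces
    to ``q_abs / (gamma + N*psi / (G**2 * q_abs * n_mean))``.  Bounded by
    ``q_abs`` and tending to ``q_abs/gamma`` for strong signals.
    """
    if n_incident_mean <= 0:
        raise ParameterError("n_incident_mean must be positive")
    if n_pixels < 1:
        raise ParameterError("n_pixels must be >= 1")
    signal = n_incident_mean * budget.gain_incident
    variance = signal_variance_adu2(signal, n_pixels, budget)
    return (signal**2 / variance) / n_incident_mean


def dqe_table(
    n_incident: np.ndarray,
    n_pixels: np.ndarray,
    budget: NoiseBudget,
    q_abs: float,
) -> np.ndarray:
    """DQE evaluated over a grid: rows follow ``n_incident``, columns
    ``n_pixels``."""
    out = np.empty((len(n_incident), len(n_pixels)))
    for i, n in enumerate(n_incident):
        for j, npx in enumerate(n_pixels):
            out[i, j] = dqe(float(n), float(npx), budget, q_abs)
    return out
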