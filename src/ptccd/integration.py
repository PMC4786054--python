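"""Bragg-spot integration with cascade-aware error estimates.

A MOSFLM-style measurement box around a spot is split into a peak
region and a background rim; an unweighted least-squares plane fitted
to the background is interpolated under the peak.  Summation
integration subtracts the plane from the peak sum; its variance is
estimated either under the classical independent-Poisson-pixel
assumption or with the cascade + pixel-noise model::

    Var(I_S) = gamma*G*P_peak + M_raw*psi
             + (M/N)**2 * (gamma*G*P_bg + N_raw*psi)

where ``P_peak``/``P_bg`` are the pedestal-corrected region sums and
``M_raw``/``N_raw`` the numbers of raw-image pixels contributing to
each region (equal to M and N on raw images; approximated by the
corrected-box counts, or computed from the distortion map, on corrected
images).

Profile fitting scales a reference profile jointly with a background
plane by weighted least squares.  In the classical (diagonal) mode the
per-pixel weights assume independent Poisson pixels and the intensity
variance is the normal-equations variance scaled by the weighted
reduced chi-square of the fit — the estimate a fit-quality-based
integration program reports, which turns artificially optimistic when
pixel correlations smooth the data.  In the generalised (GLS) mode a
full pixel variance-covariance matrix is supplied instead and the
variance comes directly from the normal equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .cascade import NoiseBudget

__all__ = [
    "MeasurementBox", "BackgroundPlane", "IntegrationResult",
    "CovarianceModel", "build_measurement_box", "extract_box",
    "fit_background_plane", "summation_integrate",
    "variance_poisson_mosflm", "variance_cascade",
    "build_reference_profile", "profile_fit", "empirical_pixel_covariance",
]


class BoxError(ValueError):
    pass


@dataclass(frozen=True)
class MeasurementBox:
    """Measurement-box geometry: odd side lengths NX, NY; rim widths
    NRX, NRY separating background from peak; corner cut-off NC (pixels
    with |dx|+|dy| >= NC join the background).  The masks have mm
    symmetry."""

    center: tuple[int, int]      # (ix, iy) pixel indices of the central pixel
    nx: int
    ny: int
    nrx: int
    nry: int
    nc: int

    def __post_init__(self):
        if self.nx % 2 == 0 or self.ny % 2 == 0:
            raise BoxError("NX and NY must be odd")
        if self.nrx < 0 or self.nry < 0:
            raise BoxError("rim widths must be non-negative")
        if self.nrx > self.nx // 2 or self.nry > self.ny // 2:
            raise BoxError("rims must fit inside the box")

    @cached_property
    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel offsets (dx, dy) from the box centre, shape (NY, NX)."""
        dx = np.arange(self.nx) - self.nx // 2
        dy = np.arange(self.ny) - self.ny // 2
        return np.meshgrid(dx, dy)

    @cached_property
    def peak_mask(self) -> np.ndarray:
        dx, dy = self.offsets
        inner = ((np.abs(dx) <= self.nx // 2 - self.nrx)
                 & (np.abs(dy) <= self.ny // 2 - self.nry))
        return inner & (np.abs(dx) + np.abs(dy) < self.nc)

    @cached_property
    def bg_mask(self) -> np.ndarray:
        return ~self.peak_mask

    @property
    def m_peak(self) -> int:
        return int(self.peak_mask.sum())

    @property
    def n_bg(self) -> int:
        return int(self.bg_mask.sum())

    @cached_property
    def _bg_design(self) -> np.ndarray:
        dx, dy = self.offsets
        return np.stack([dx[self.bg_mask], dy[self.bg_mask],
                         np.ones(self.n_bg)], axis=1)

    @cached_property
    def _bg_pinv(self) -> np.ndarray:
        a = self._bg_design
        if self.n_bg < 3 or np.linalg.matrix_rank(a) < 3:
            raise BoxError("degenerate background geometry for plane fit")
        return np.linalg.pinv(a)

    def scaled(self, center: tuple[int, int], ratio: float) -> "MeasurementBox":
        """The same physical box expressed on a grid with a different
        pixel pitch: every parameter is scaled by ``ratio`` and rounded
        (side lengths to the nearest odd integer)."""
        def odd(v: float) -> int:
            return max(1, int(2 * round((v - 1) / 2) + 1))
        return MeasurementBox(
            center=center,
            nx=odd(self.nx * ratio), ny=odd(self.ny * ratio),
            nrx=round(self.nrx * ratio), nry=round(self.nry * ratio),
            nc=round(self.nc * ratio),
        )


def build_measurement_box(center: tuple[int, int], nx: int, ny: int,
                          nrx: int, nry: int, nc: int) -> MeasurementBox:
    return MeasurementBox(center, nx, ny, nrx, nry, nc)


def extract_box(image: np.ndarray, box: MeasurementBox) -> np.ndarray:
    """Cut the box raster (NY, NX) out of an image array indexed [iy, ix]."""
    cx, cy = box.center
    y0 = cy - box.ny // 2
    x0 = cx - box.nx // 2
    if y0 < 0 or x0 < 0 or y0 + box.ny > image.shape[-2] or \
            x0 + box.nx > image.shape[-1]:
        raise BoxError("measurement box extends outside the image")
    return np.asarray(image, dtype=float)[..., y0:y0 + box.ny, x0:x0 + box.nx]


@dataclass(frozen=True)
class BackgroundPlane:
    """rho_bg(p, q) = a*p + b*q + c in box-offset coordinates.  Fields
    are scalars for a single image or arrays for a stack."""
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def evaluate_sum_over_peak(self, box: MeasurementBox) -> np.ndarray:
        dx, dy = box.offsets
        return (self.a * dx[box.peak_mask].sum()
                + self.b * dy[box.peak_mask].sum()
                + self.c * box.m_peak)


@dataclass
class IntegrationResult:
    """Intensity and candidate variance estimates for one spot (or a
    stack of replicates: every field broadcasts)."""
    intensity: np.ndarray
    m_peak: int
    n_bg: int
    p_peak: np.ndarray           # pedestal-corrected peak-region sum
    p_bg: np.ndarray             # pedestal-corrected background-region sum
    method: str = "summation"
    variance_poisson: np.ndarray | None = None
    variance_cascade: np.ndarray | None = None
    variance_fit: np.ndarray | None = None

    @property
    def i_bg(self) -> np.ndarray:
        """Background interpolated under the peak: (M/N) * sum(bg)."""
        return self.p_bg * self.m_peak / self.n_bg


def fit_background_plane(raster: np.ndarray, box: MeasurementBox,
                         pedestal: float = 0.0) -> BackgroundPlane:
    """Unweighted least-squares plane through the background pixels of a
    pedestal-subtracted box raster (raster may be a stack)."""
    rho = np.asarray(raster, dtype=float) - pedestal
    bg = rho[..., box.bg_mask]
    coef = bg @ box._bg_pinv.T
    return BackgroundPlane(coef[..., 0], coef[..., 1], coef[..., 2])


def summation_integrate(raster: np.ndarray, box: MeasurementBox,
                        plane: BackgroundPlane | None = None,
                        pedestal: float = 0.0) -> IntegrationResult:
    """Summation intensity: peak sum minus the background plane
    interpolated under the peak."""
    rho = np.asarray(raster, dtype=float) - pedestal
    if plane is None:
        plane = fit_background_plane(raster, box, pedestal)
    p_peak = rho[..., box.peak_mask].sum(axis=-1)
    p_bg = rho[..., box.bg_mask].sum(axis=-1)
    return IntegrationResult(
        intensity=p_peak - plane.evaluate_sum_over_peak(box),
        m_peak=box.m_peak, n_bg=box.n_bg,
        p_peak=p_peak, p_bg=p_bg, method="summation",
    )


def variance_poisson_mosflm(result: IntegrationResult,
                            gain_absorbed: float) -> np.ndarray:
    """Classical independent-Poisson-pixel estimate:
    G * (I_S + I_bg * (1 + M/N))."""
    ratio = result.m_peak / result.n_bg
    var = gain_absorbed * (result.intensity + result.i_bg * (1.0 + ratio))
    result.variance_poisson = var
    return var


def variance_cascade(result: IntegrationResult, budget: NoiseBudget,
                     n_raw_pixels_peak: float | None = None,
                     n_raw_pixels_bg: float | None = None) -> np.ndarray:
    """Cascade + pixel-noise estimate applied to the peak and background
    region sums.  Raw-pixel counts default to the box-region counts (the
    documented approximation for corrected images, exact for raw)."""
    m_raw = result.m_peak if n_raw_pixels_peak is None else n_raw_pixels_peak
    n_raw = result.n_bg if n_raw_pixels_bg is None else n_raw_pixels_bg
    gg = budget.gamma * budget.gain_absorbed
    ratio2 = (result.m_peak / result.n_bg) ** 2
    var = (gg * result.p_peak + m_raw * budget.psi
           + ratio2 * (gg * result.p_bg + n_raw * budget.psi))
    result.variance_cascade = var
    return var


# ---------------------------------------------------------------------------
# Profile fitting

def build_reference_profile(rasters: np.ndarray, box: MeasurementBox,
                            pedestal: float = 0.0) -> np.ndarray:
    """Mean of background-plane- and pedestal-corrected box rasters,
    rounded to the nearest ADU."""
    rasters = np.asarray(rasters, dtype=float)
    if rasters.ndim == 2:
        rasters = rasters[None]
    if rasters.shape[-2:] != (box.ny, box.nx):
        raise BoxError("image rasters do not match the box size")
    plane = fit_background_plane(rasters, box, pedestal)
    dx, dy = box.offsets
    model_bg = (plane.a[..., None, None] * dx
                + plane.b[..., None, None] * dy
                + plane.c[..., None, None])
    resid = (rasters - pedestal) - model_bg
    return np.rint(resid.mean(axis=0))


@dataclass(frozen=True)
class CovarianceModel:
    """Banded empirical pixel variance-covariance matrix M_f for a box
    footprint: covariances kept up to ``max_lag`` pixels in X and Y,
    zero beyond; symmetric and projected to positive semi-definite."""
    matrix: np.ndarray
    max_lag: int


def empirical_pixel_covariance(rasters: np.ndarray, box: MeasurementBox,
                               max_lag: int = 7,
                               pedestal: float = 0.0) -> CovarianceModel:
    """Unbiased sample variances/covariances of box pixels across an
    image ensemble, banded at ``max_lag`` and PSD-projected if needed."""
    x = np.asarray(rasters, dtype=float) - pedestal
    if x.ndim != 3 or x.shape[0] < 2:
        raise BoxError("need a stack of at least two box rasters")
    flat = x.reshape(x.shape[0], -1)
    xc = flat - flat.mean(axis=0)
    cov = (xc.T @ xc) / (x.shape[0] - 1)
    dx, dy = box.offsets
    fdx, fdy = dx.ravel(), dy.ravel()
    band = ((np.abs(fdx[:, None] - fdx[None, :]) <= max_lag)
            & (np.abs(fdy[:, None] - fdy[None, :]) <= max_lag))
    cov = cov * band
    diag = np.diag(cov).copy()
    # Banding can break positive semi-definiteness, and near-linearly-
    # dependent pixels (e.g. after distortion correction) can leave
    # near-null directions that would dominate a GLS inverse.  Clip the
    # eigenvalues at a small fraction of the typical pixel variance and
    # restore the observed per-pixel variances by a diagonal congruence
    # (which keeps the matrix PSD).
    floor = 1e-2 * diag.mean()
    w, v = np.linalg.eigh(cov)
    if w[0] < floor:
        if w[0] < -1e-8 * w[-1]:
            warnings.warn("banded empirical covariance not PSD; "
                          "clipping negative eigenvalues")
        cov = (v * np.maximum(w, floor)) @ v.T
        d = np.diag(cov)
        scale = np.sqrt(diag / np.maximum(d, 1e-30 * diag.max()))
        cov = cov * np.outer(scale, scale)
    return CovarianceModel(matrix=cov, max_lag=max_lag)


def _profile_design(box: MeasurementBox, profile: np.ndarray) -> np.ndarray:
    dx, dy = box.offsets
    return np.stack([
        np.asarray(profile, dtype=float).ravel(),
        dx.ravel().astype(float),
        dy.ravel().astype(float),
        np.ones(box.nx * box.ny),
    ], axis=1)


def profile_fit(
    raster: np.ndarray,
    box: MeasurementBox,
    profile: np.ndarray,
    gain_absorbed: float,
    weights: str | CovarianceModel = "poisson",
    pedestal: float = 0.0,
) -> IntegrationResult:
    """Least-squares fit of scale x profile + background plane to the
    observed box; ``raster`` may be a replicate stack.

    ``weights="poisson"``: per-pixel variances ``G * rho`` (independent
    Poisson pixels); the intensity variance is the normal-equations
    variance scaled by the weighted reduced chi-square of the fit.
    ``weights=CovarianceModel``: generalised least squares with the full
    M_f; the variance comes from (A^T M_f^-1 A)^-1 directly.
    """
    rho = np.asarray(raster, dtype=float) - pedestal
    single = rho.ndim == 2
    if single:
        rho = rho[None]
    y = rho.reshape(rho.shape[0], -1)
    a = _profile_design(box, profile)
    f_sum = float(np.asarray(profile, dtype=float).sum())
    npx, npar = a.shape

    if isinstance(weights, CovarianceModel):
        mf = weights.matrix
        try:
            mf_inv_a = np.linalg.solve(mf, a)
        except np.linalg.LinAlgError as exc:
            raise BoxError("singular covariance model") from exc
        normal = a.T @ mf_inv_a
        cov_theta = np.linalg.inv(normal)
        theta = y @ (mf_inv_a @ cov_theta.T)
        var_k = np.full(rho.shape[0], cov_theta[0, 0])
        method = "profile_gls"
    else:
        w = 1.0 / (gain_absorbed * np.maximum(y, 1.0))
        # per-replicate 4x4 weighted normal equations, batched
        aw = w[:, :, None] * a[None, :, :]
        normal = np.einsum("pi,npj->nij", a, aw)
        rhs = np.einsum("np,npj->nj", y, aw)
        theta = np.linalg.solve(normal, rhs[..., None])[..., 0]
        cov00 = np.linalg.inv(normal)[:, 0, 0]
        resid = y - theta @ a.T
        s2 = np.einsum("np,np->n", w, resid**2) / (npx - npar)
        var_k = s2 * cov00
        method = "profile"

    intensity = theta[:, 0] * f_sum
    variance = var_k * f_sum**2
    p_peak = y[:, box.peak_mask.ravel()].sum(axis=-1)
    p_bg = y[:, box.bg_mask.ravel()].sum(axis=-1)
    if single:
        intensity, variance = intensity[0], variance[0]
        p_peak, p_bg = p_peak[0], p_bg[0]
    return IntegrationResult(
        intensity=intensity, m_peak=box.m_peak, n_bg=box.n_bg,
        p_peak=p_peak, p_bg=p_bg, method=method,
        variance_fit=variance,
    )
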