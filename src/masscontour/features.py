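"""Scalar roughness features of a 1D contour signature.

The signature ``h(i)`` is treated as a self-affine random profile, in the
spirit of surface metrology.  Four scalar descriptors are extracted:

* ``w`` — RMS roughness, the population standard deviation of the samples
  (vertical fluctuation scale);
* ``mu/sigma`` — mean over standard deviation, large for circular/regular
  contours;
* ``alpha`` — fractal (Hurst-type) exponent obtained from the small-lag
  power law of the height-height correlation function
  ``H(rho) = <[h(n) - h(n + rho)]^2> ~ rho^{2 alpha}``, with fractal
  dimension ``D = 2 - alpha`` for a planar profile;
* ``s`` — RMS slope, the root mean square of the first differences of the
  profile at unit sample spacing (how fast the boundary oscillates).

Statistical averages ``< . >`` use population moments (divide by N).  Lag
indexing is circular by default — a contour signature is a closed loop — with
a linear (truncated) mode for open segments such as signature subsections or
simulated fractional-Brownian profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateSignalError,
    FitError,
    InsufficientDataError,
    RegularSignatureWarning,
)
from .geometry import Signature

__all__ = [
    "CorrelationProfile",
    "rms_roughness",
    "mu_sigma_ratio",
    "height_height_correlation",
    "autocorrelation",
    "autocorrelation_length",
    "correlation_profile",
    "fractal_exponent",
    "rms_slope",
]

#: sigma = 0 fallback for the circularity ratio (perfectly regular contour).
MU_SIGMA_CAP = 1e6


def _values(sig) -> np.ndarray:
    if isinstance(sig, Signature):
        return sig.values
    return np.asarray(sig, dtype=float)


def rms_roughness(sig) -> float:
    """RMS roughness ``w = sqrt(<h^2> - <h>^2)`` (population moments)."""
    h = _values(sig)
    if len(h) < 2:
        raise InsufficientDataError("rms_roughness needs at least 2 samples")
    return float(np.sqrt(max(np.mean(h**2) - np.mean(h) ** 2, 0.0)))


def mu_sigma_ratio(sig, cap: float = MU_SIGMA_CAP) -> float:
    """Circularity ratio mean/std (population std).

    A perfectly regular signature has sigma = 0; the ratio is then capped at
    ``cap`` and a :class:`RegularSignatureWarning` is emitted so perfectly
    circular synthetic contours remain usable in feature tables.
    """
    h = _values(sig)
    if len(h) < 2:
        raise InsufficientDataError("mu_sigma_ratio needs at least 2 samples")
    sigma = rms_roughness(h)
    if sigma == 0.0:
        warnings.warn(
            "sigma = 0 (perfectly regular signature); ratio capped",
            RegularSignatureWarning,
            stacklevel=2,
        )
        return float(cap)
    return float(np.mean(h) / sigma)


def height_height_correlation(
    sig, rho_max: int | None = None, circular: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Height-height correlation ``H(rho) = <[h(n) - h(n + rho)]^2>``.

    Returns ``(rho, H)`` for ``rho = 1..rho_max`` (default ``N // 2``).
    Circular mode averages over all N wrap-around pairs; linear mode over the
    ``N - rho`` in-range pairs.
    """
    h = _values(sig)
    n = len(h)
    if rho_max is None:
        rho_max = n // 2
    if not 1 <= rho_max <= n // 2:
        raise ValueError(f"rho_max must be in [1, N/2]; got {rho_max} for N={n}")
    rho = np.arange(1, rho_max + 1)
    H = np.empty(rho_max)
    for k, r in enumerate(rho):
        if circular:
            d = h - np.roll(h, -r)
        else:
            d = h[r:] - h[:-r]
        H[k] = np.mean(d**2)
    return rho, H


def autocorrelation(sig, circular: bool = True) -> np.ndarray:
    """Normalized autocorrelation R(rho) for rho = 0..N//2, R(0) = 1.

    Computed on mean-subtracted samples and normalized by ``w^2``, so R decays
    toward 0 for a stationary signal.
    """
    h = _values(sig)
    n = len(h)
    w2 = np.mean(h**2) - np.mean(h) ** 2
    if w2 <= 0:
        raise DegenerateSignalError("autocorrelation undefined for w = 0")
    d = h - h.mean()
    k = n // 2
    if circular:
        # circular autocovariance via FFT
        f = np.fft.rfft(d, n=n)
        acov = np.fft.irfft(f * np.conj(f), n=n).real / n
        R = acov[: k + 1] / acov[0]
    else:
        R = np.empty(k + 1)
        R[0] = 1.0
        for r in range(1, k + 1):
            R[r] = np.mean(d[:-r] * d[r:]) / w2
    return R


def _first_crossing(R: np.ndarray, level: float) -> float | None:
    """Smallest (interpolated) lag where R first reaches ``level``."""
    below = np.flatnonzero(R <= level)
    if len(below) == 0:
        return None
    j = int(below[0])
    if j == 0:
        return 0.0
    r0, r1 = R[j - 1], R[j]
    # linear interpolation between integer lags j-1 and j
    return (j - 1) + (r0 - level) / (r0 - r1)


def autocorrelation_length(sig, circular: bool = True) -> tuple[np.ndarray, float]:
    """Correlation length xi: first (interpolated) lag where R reaches 1/e.

    If R never reaches 1/e within N/2 lags, xi = N/2 with a warning (the
    horizontal fluctuation scale exceeds the window).
    """
    h = _values(sig)
    R = autocorrelation(h, circular=circular)
    xi = _first_crossing(R, 1.0 / np.e)
    if xi is None:
        xi = len(h) / 2.0
        warnings.warn(
            "R(rho) never reaches 1/e within N/2 lags; xi set to N/2",
            stacklevel=2,
        )
    return R, float(xi)


@dataclass(frozen=True)
class CorrelationProfile:
    """Empirical correlation structure of a signature and the power-law fit.

    ``alpha`` is the fitted exponent clipped to [0, 1] (``alpha_raw`` keeps
    the unclipped slope/2); ``fractal_dimension = d - alpha`` with embedding
    dimension ``d = 2`` for a planar profile.
    """

    rho: np.ndarray
    H: np.ndarray
    R: np.ndarray
    xi: float
    alpha: float
    alpha_raw: float
    fractal_dimension: float
    fit_range: tuple[int, int]
    fit_r2: float


def _auto_fit_range(n: int, xi: float, rho_max: int) -> tuple[int, int]:
    """Small-lag fit window honoring rho << xi: [1, max(4, min(xi, N/10))]."""
    hi = max(4, min(int(xi), n // 10))
    return 1, min(hi, rho_max)


def correlation_profile(
    sig,
    fit_range: tuple[int, int] | None = None,
    circular: bool = True,
    rho_max: int | None = None,
) -> CorrelationProfile:
    """Compute H(rho), R(rho), xi and fit the fractal exponent alpha.

    ``alpha`` is half the slope of the ordinary least-squares line through
    ``(log rho, log H(rho))`` over the fit range; zero-valued H lags are
    excluded with a warning.  The automatic fit range is
    ``rho in [1, max(4, min(floor(xi), floor(N/10)))]``.
    """
    h = _values(sig)
    n = len(h)
    rho, H = height_height_correlation(h, rho_max=rho_max, circular=circular)
    R, xi = autocorrelation_length(h, circular=circular)
    if fit_range is None:
        fit_range = _auto_fit_range(n, xi, int(rho[-1]))
    lo, hi = int(fit_range[0]), int(fit_range[1])
    mask = (rho >= lo) & (rho <= hi) & (H > 0)
    if np.count_nonzero((rho >= lo) & (rho <= hi) & (H <= 0)):
        warnings.warn("zero H(rho) lags excluded from the log-log fit", stacklevel=2)
    if np.count_nonzero(mask) < 3:
        raise FitError(
            f"fewer than 3 usable lags in fit range [{lo}, {hi}]"
        )
    lx = np.log(rho[mask])
    ly = np.log(H[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    alpha_raw = float(slope / 2.0)
    alpha = float(np.clip(alpha_raw, 0.0, 1.0))
    return CorrelationProfile(
        rho=rho,
        H=H,
        R=R,
        xi=xi,
        alpha=alpha,
        alpha_raw=alpha_raw,
        fractal_dimension=2.0 - alpha,
        fit_range=(lo, hi),
        fit_r2=r2,
    )


def fractal_exponent(
    sig,
    fit_range: tuple[int, int] | None = None,
    circular: bool = True,
) -> tuple[float, float, float]:
    """Fractal exponent of a signature: ``(alpha, fractal_dimension, fit_r2)``."""
    prof = correlation_profile(sig, fit_range=fit_range, circular=circular)
    return prof.alpha, prof.fractal_dimension, prof.fit_r2


def rms_slope(sig, circular: bool = True, central: bool = False) -> float:
    """RMS slope ``s = sqrt(<(dh/drho)^2>)`` at unit sample spacing.

    Forward first differences by default (circular wrap for closed-loop
    signatures); ``central=True`` uses central differences instead.
    """
    h = _values(sig)
    if len(h) < 2:
        raise InsufficientDataError("rms_slope needs at least 2 samples")
    if central:
        if circular:
            d = (np.roll(h, -1) - np.roll(h, 1)) / 2.0
        else:
            d = (h[2:] - h[:-2]) / 2.0
            if len(d) == 0:
                raise InsufficientDataError("central differences need >= 3 samples")
    else:
        d = np.roll(h, -1) - h if circular else np.diff(h)
    return float(np.sqrt(np.mean(d**2)))
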