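"""Seeded synthetic inputs: benign/malignant phantom contours and fBm profiles.

Real mass boundaries are only available from mammography archives; this
module generates contours with the two geometric regimes the classification
method assumes:

* *benign-like*: near-elliptical, with a handful of low-order harmonic
  perturbations of small relative amplitude (smooth margin, regular shape);
* *malignant-like*: high-order harmonics of larger amplitude plus optional
  narrow Gaussian spicule spikes (microlobulated/spiculated margin).

Both are polar constructions ``r(theta) = r_e(theta) (1 + sum_k a_k
cos(k theta + phi_k))`` around a random reference ellipse, sampled at N_c
angles and rounded to the pixel grid so that synthetic contours carry the
same digitization noise as chain-code input.  The frequency-band split (low
orders for benign, high for malignant) makes class separation controllable
by a single amplitude knob.

1D fractional-Brownian-motion signatures of prescribed roughness exponent
alpha and RMS roughness w are generated by circulant embedding of
fractional Gaussian noise (exact covariance), for calibrating the fractal
exponent estimator.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmbeddingFallbackWarning, ParameterError
from .geometry import Contour, Signature

__all__ = [
    "CohortSpec",
    "make_benign_contour",
    "make_malignant_contour",
    "make_fbm_signature",
    "make_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic benign/malignant contour cohort.

    Semi-axes are in pixels; amplitudes are relative to the local ellipse
    radius.  Benign harmonics stay at or below ``benign_max_order`` while
    malignant orders are drawn from ``malignant_order_range``; the bands must
    not overlap so that the two classes differ in boundary frequency content
    as well as amplitude.
    """

    n_benign: int = 100
    n_malignant: int = 100
    seed: int = 0
    samples_per_contour: int = 256
    semi_axis_range: tuple[float, float] = (40.0, 80.0)
    benign_max_order: int = 4
    benign_amplitude_range: tuple[float, float] = (0.0, 0.03)
    malignant_order_range: tuple[int, int] = (8, 30)
    malignant_amplitude_range: tuple[float, float] = (0.10, 0.35)
    malignant_harmonics: tuple[int, int] = (4, 8)
    spicule_count_range: tuple[int, int] = (2, 6)
    spicule_amplitude_range: tuple[float, float] = (0.05, 0.15)
    spicule_width_rad: float = 0.05
    pixel_grid: bool = True
    center: tuple[float, float] = (150.0, 150.0)

    def __post_init__(self) -> None:
        for rng_ in (
            self.benign_amplitude_range,
            self.malignant_amplitude_range,
            self.spicule_amplitude_range,
        ):
            if not (0.0 <= rng_[0] <= rng_[1] <= 0.5):
                raise ParameterError(f"amplitude range {rng_} not within [0, 0.5]")
        if self.benign_max_order >= self.malignant_order_range[0]:
            raise ParameterError(
                "benign max harmonic order must be below the malignant minimum"
            )
        if self.samples_per_contour < 64:
            raise ParameterError("samples_per_contour must be >= 64")
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ParameterError("cohort counts must be nonnegative")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _polar_contour(
    spec: CohortSpec,
    rng: np.random.Generator,
    orders: np.ndarray,
    amps: np.ndarray,
    spicule_thetas: np.ndarray | None = None,
    spicule_amps: np.ndarray | None = None,
    contour_id: str | None = None,
) -> Contour:
    """Sample r(theta) = r_e(theta) * (1 + perturbation) on the pixel grid.

    The curve is polar (star-shaped about the center), so it self-intersects
    only if the radius reaches zero.  Spicule bumps point outward and cannot
    do that; the harmonic sum can, and its worst-case inward excursion is the
    total harmonic amplitude.
    """
    total = float(np.sum(amps))
    if total >= 1.0:
        raise ParameterError(
            f"total relative amplitude {total:.3f} >= 1 implies self-intersection"
        )
    a = rng.uniform(*spec.semi_axis_range)
    b = rng.uniform(*spec.semi_axis_range)
    n = spec.samples_per_contour
    theta = 2.0 * np.pi * np.arange(n) / n  # ascending -> anticlockwise
    r_e = a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))
    pert = np.zeros(n)
    phases = rng.uniform(0, 2 * np.pi, size=len(orders))
    for k, amp, phi in zip(orders, amps, phases):
        pert += amp * np.cos(k * theta + phi)
    if spicule_thetas is not None:
        for t0, g in zip(spicule_thetas, spicule_amps):
            d = np.angle(np.exp(1j * (theta - t0)))  # wrapped to (-pi, pi]
            pert += g * np.exp(-(d**2) / (2.0 * spec.spicule_width_rad**2))
    r = r_e * (1.0 + pert)
    if np.min(r) <= 0:
        raise ParameterError("perturbation drives the radius to zero")
    cx, cy = spec.center
    pts = np.column_stack((cx + r * np.cos(theta), cy + r * np.sin(theta)))
    if spec.pixel_grid:
        pts = np.rint(pts)
    return Contour.from_points(pts, contour_id=contour_id)


def make_benign_contour(
    spec: CohortSpec, seed, contour_id: str | None = None
) -> Contour:
    """Regular near-elliptical contour: low-order, low-amplitude harmonics."""
    rng = _as_rng(seed)
    orders = np.arange(1, spec.benign_max_order + 1)
    amps = rng.uniform(*spec.benign_amplitude_range, size=len(orders))
    return _polar_contour(spec, rng, orders, amps, contour_id=contour_id)


def make_malignant_contour(
    spec: CohortSpec, seed, contour_id: str | None = None
) -> Contour:
    """Irregular contour: high-order harmonics plus narrow spicule spikes."""
    rng = _as_rng(seed)
    n_harm = int(rng.integers(spec.malignant_harmonics[0], spec.malignant_harmonics[1] + 1))
    lo, hi = spec.malignant_order_range
    orders = rng.choice(np.arange(lo, hi + 1), size=min(n_harm, hi - lo + 1), replace=False)
    total_amp = rng.uniform(*spec.malignant_amplitude_range)
    weights = rng.dirichlet(np.ones(len(orders)))
    amps = total_amp * weights
    s_lo, s_hi = spec.spicule_count_range
    n_spic = int(rng.integers(s_lo, s_hi + 1))
    spic_thetas = rng.uniform(0, 2 * np.pi, size=n_spic)
    spic_amps = rng.uniform(*spec.spicule_amplitude_range, size=n_spic)
    return _polar_contour(
        spec, rng, orders, amps, spic_thetas, spic_amps, contour_id=contour_id
    )


def _fgn_circulant(alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise of Hurst exponent alpha, circulant embedding.

    Exact up to an overall scale factor (irrelevant here: the caller rescales
    the integrated profile to a target RMS roughness).
    """
    k = np.arange(n + 1, dtype=float)
    # autocovariance of unit-variance fGn increments
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * alpha)
        - 2 * np.abs(k) ** (2 * alpha)
        + np.abs(k - 1) ** (2 * alpha)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn(
            "circulant embedding not positive definite; using spectral synthesis",
            EmbeddingFallbackWarning,
            stacklevel=2,
        )
        return _fgn_spectral(alpha, n, rng)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(2 * n) + 1j * rng.standard_normal(2 * n)
    x = np.fft.fft(np.sqrt(lam) * z)
    return x.real[:n]


def _fgn_spectral(alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn via its power spectral density (fallback path)."""
    freqs = np.fft.rfftfreq(2 * n)
    psd = np.zeros_like(freqs)
    psd[1:] = freqs[1:] ** (1.0 - 2.0 * alpha)
    amp = np.sqrt(psd)
    phase = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n=2 * n)
    return x[:n]


def make_fbm_signature(
    alpha: float, w_target: float, N: int, seed, contour_id: str | None = None
) -> Signature:
    """Fractional-Brownian 1D profile with roughness exponent alpha.

    Fractional Gaussian noise with Hurst parameter ``alpha`` is generated by
    circulant embedding, cumulatively summed into an fBm path, mean-removed,
    and rescaled so that its RMS roughness equals ``w_target`` exactly.
    ``N`` must be a power of two >= 256 (exact embedding size).
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie strictly inside (0, 1)")
    if N < 256 or (N & (N - 1)) != 0:
        raise ParameterError("N must be a power of two >= 256")
    if w_target <= 0:
        raise ParameterError("w_target must be positive")
    rng = _as_rng(seed)
    fgn = _fgn_circulant(alpha, N, rng)
    h = np.cumsum(fgn)
    h -= h.mean()
    w = np.sqrt(np.mean(h**2))
    if w == 0:
        raise ParameterError("degenerate fBm draw (zero roughness)")
    h *= w_target / w
    return Signature(values=h, kind="fbm", source_contour_id=contour_id)


def make_cohort(spec: CohortSpec) -> tuple[list[Contour], list[str], list[dict]]:
    """Labeled synthetic cohort: contours, labels, and a per-contour manifest.

    Per-contour seeds are derived from the master seed so that any single
    contour can be regenerated independently.
    """
    ss = np.random.SeedSequence(spec.seed)
    n = spec.n_benign + spec.n_malignant
    child_seeds = ss.generate_state(n, dtype=np.uint32)
    contours: list[Contour] = []
    labels: list[str] = []
    manifest: list[dict] = []
    for i in range(n):
        label = "benign" if i < spec.n_benign else "malignant"
        cid = f"{label[0]}{i:04d}"
        seed_i = int(child_seeds[i])
        maker = make_benign_contour if label == "benign" else make_malignant_contour
        contours.append(maker(spec, seed_i, contour_id=cid))
        labels.append(label)
        manifest.append({"id": cid, "label": label, "seed": seed_i})
    return contours, labels, manifest
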