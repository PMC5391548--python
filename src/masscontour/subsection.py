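"""Subsection ranking: local features on contiguous signature blocks.

A whole-contour feature can miss localized irregularity (a boundary that is
smooth over two-thirds of its length but microlobulated on the rest).  The
signature is therefore split into C contiguous subsections, the feature is
computed on each, and the C values are sorted into a rank-ordered vector.
Sorting makes the vector independent of where the blocks start on the loop,
so classifiers see the distribution of local feature values rather than
their arrangement.  C sweeps the 11 values {1, 2, 4, ..., 20}; classifier
performance is averaged over the sweep.

Subsections are open segments, not closed loops, so lag-based features use
linear (truncated) indexing here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import features as F
from .exceptions import InsufficientDataError, SubsectionSkippedWarning
from .geometry import Signature

__all__ = [
    "DEFAULT_C_SET",
    "FEATURE_NAMES",
    "SubsectionVector",
    "SubsectionSweep",
    "segment",
    "subsection_feature",
    "subsection_feature_vector",
    "sweep_subsections",
]

DEFAULT_C_SET: tuple[int, ...] = (1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
FEATURE_NAMES: tuple[str, ...] = ("w", "mu_sigma", "alpha", "s")

# minimum subsection length per feature; alpha needs >= 3 fit lags, i.e.
# rho_max = len // 2 >= 3
_MIN_LEN = {"w": 2, "mu_sigma": 2, "s": 2, "alpha": 6}


def _values(sig) -> np.ndarray:
    return sig.values if isinstance(sig, Signature) else np.asarray(sig, float)


def segment(sig, C: int) -> list[np.ndarray]:
    """Split a signature into C contiguous blocks in signature order.

    Block sizes differ by at most one; the first ``N mod C`` blocks are one
    sample longer.  Concatenating the blocks reproduces the signature.
    """
    h = _values(sig)
    n = len(h)
    if C < 1:
        raise ValueError("C must be >= 1")
    if n < 2 * C:
        raise InsufficientDataError(
            f"signature of length {n} too short for C={C} (needs N >= 2C)"
        )
    base, extra = divmod(n, C)
    sizes = [base + 1] * extra + [base] * (C - extra)
    bounds = np.cumsum([0] + sizes)
    return [h[bounds[i] : bounds[i + 1]] for i in range(C)]


def subsection_feature(block: np.ndarray, feature: str) -> float:
    """One feature value on one open (non-circular) subsection."""
    if feature == "w":
        return F.rms_roughness(block)
    if feature == "mu_sigma":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cap rule handles sigma = 0
            return F.mu_sigma_ratio(block)
    if feature == "alpha":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short-block xi fallback is routine
            return F.fractal_exponent(block, circular=False)[0]
    if feature == "s":
        return F.rms_slope(block, circular=False)
    raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURE_NAMES}")


@dataclass(frozen=True)
class SubsectionVector:
    """Rank-ordered per-subsection feature values (ascending, length C)."""

    feature_name: str
    C: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != self.C:
            raise ValueError("vector length must equal C")
        if np.any(np.diff(v) < 0):
            raise ValueError("values must be nondecreasing")
        object.__setattr__(self, "values", v)


def subsection_feature_vector(sig, C: int, feature: str) -> SubsectionVector:
    """Compute ``feature`` on each of C subsections and sort ascending."""
    blocks = segment(sig, C)
    min_len = _MIN_LEN.get(feature, 2)
    if any(len(b) < min_len for b in blocks):
        raise InsufficientDataError(
            f"feature {feature!r} needs subsections of >= {min_len} samples"
        )
    vals = np.sort([subsection_feature(b, feature) for b in blocks])
    return SubsectionVector(feature_name=feature, C=C, values=vals)


@dataclass(frozen=True)
class SubsectionSweep:
    """Result of sweeping C: vectors keyed by C plus any skipped C values."""

    feature_name: str
    vectors: dict[int, SubsectionVector]
    skipped: dict[int, str] = field(default_factory=dict)


def sweep_subsections(
    sig, feature: str, C_set: tuple[int, ...] = DEFAULT_C_SET
) -> SubsectionSweep:
    """Subsection vectors for every C in the sweep set (default 11 values).

    C values infeasible for a short signature are skipped with a warning and
    recorded in ``skipped`` rather than failing the whole sweep.
    """
    vectors: dict[int, SubsectionVector] = {}
    skipped: dict[int, str] = {}
    for C in C_set:
        try:
            vectors[C] = subsection_feature_vector(sig, C, feature)
        except InsufficientDataError as exc:
            skipped[C] = str(exc)
            warnings.warn(
                f"C={C} skipped: {exc}", SubsectionSkippedWarning, stacklevel=2
            )
    return SubsectionSweep(feature_name=feature, vectors=vectors, skipped=skipped)
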