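"""Independent reference implementations used to cross-check the package.

Deliberately naive (double loops, dense search, scalar optimization) and
kept free of any masscontour internals so they stay independent of the code
paths they verify.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def naive_rms_roughness(h) -> float:
    h = list(map(float, h))
    n = len(h)
    mean = sum(h) / n
    mean_sq = sum(v * v for v in h) / n
    return math.sqrt(max(mean_sq - mean * mean, 0.0))


def naive_mu_sigma(h) -> float:
    h = list(map(float, h))
    mu = sum(h) / len(h)
    return mu / naive_rms_roughness(h)


def naive_height_height(h, rho_max, circular=True):
    h = list(map(float, h))
    n = len(h)
    out = []
    for rho in range(1, rho_max + 1):
        if circular:
            pairs = [(h[i] - h[(i + rho) % n]) ** 2 for i in range(n)]
        else:
            pairs = [(h[i] - h[i + rho]) ** 2 for i in range(n - rho)]
        out.append(sum(pairs) / len(pairs))
    return np.array(out)


def naive_autocorrelation(h, circular=True):
    h = list(map(float, h))
    n = len(h)
    mu = sum(h) / n
    d = [v - mu for v in h]
    w2 = sum(v * v for v in d) / n
    out = [1.0]
    for rho in range(1, n // 2 + 1):
        if circular:
            cov = sum(d[i] * d[(i + rho) % n] for i in range(n)) / n
        else:
            cov = sum(d[i] * d[i + rho] for i in range(n - rho)) / (n - rho)
        out.append(cov / w2)
    return np.array(out)


def naive_rms_slope(h, circular=True) -> float:
    h = list(map(float, h))
    n = len(h)
    if circular:
        diffs = [h[(i + 1) % n] - h[i] for i in range(n)]
    else:
        diffs = [h[i + 1] - h[i] for i in range(n - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def brute_force_ray_ellipse(a: float, b: float, theta: float, n_dense: int = 100_000) -> float:
    """Radius where the ray at angle ``theta`` crosses the ellipse x²/a²+y²/b²=1.

    Dense sampling of the parametric ellipse locates the crossing; the signed
    cross product of the ellipse point with the ray direction (which changes
    sign there) is then bracketed and solved by brentq.  Independent of the
    closed-form polar radius used by the implementation.
    """
    ux, uy = math.cos(theta), math.sin(theta)

    def cross(t: float) -> float:
        return a * math.cos(t) * uy - b * math.sin(t) * ux

    ts = np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
    forward = a * np.cos(ts) * ux + b * np.sin(ts) * uy > 0
    dists = np.abs(a * np.cos(ts) * uy - b * np.sin(ts) * ux)
    dists[~forward] = np.inf
    i0 = int(np.argmin(dists))
    span = 2.0 * np.pi / n_dense
    lo, hi = ts[i0] - span, ts[i0] + span
    if cross(lo) * cross(hi) > 0:  # widen until the sign change is bracketed
        lo, hi = ts[i0] - 3 * span, ts[i0] + 3 * span
    t = brentq(cross, lo, hi, xtol=1e-15)
    return math.hypot(a * math.cos(t), b * math.sin(t))
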