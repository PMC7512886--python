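"""Seeded synthetic inputs for exercising the diagnostics in isolation.

These generators build Poincaré-like point sets and closed-form linear
systems without integrating the love model, so period detection, peak
counting and the Lyapunov estimator can be tested against known answers.
All randomness is confined here and driven by an explicit seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .integrate import PoincareSection
from .model import LoveParams, classify_fixed_point

__all__ = [
    "periodic_points",
    "noisy_periodic_points",
    "random_points",
    "linear_system",
    "make_fixtures",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("periodic_points", "noisy_periodic_points", "random_points",
                 "linear_system")


def periodic_points(n_clusters: int = 4, n_points: int = 64,
                    jitter: float = 0.0, seed: int = 0,
                    scale: float = 1.0) -> PoincareSection:
    """A strobe-like cyclic sequence visiting ``n_clusters`` sites in order.

    Cluster centers sit on a circle of radius ``scale``; Gaussian jitter
    of standard deviation ``jitter`` (absolute units) is added per point.
    With jitter well below the inter-cluster spacing, detect_period
    returns ``n_clusters``.
    """
    if n_clusters < 1 or n_points < n_clusters:
        raise ValueError("need n_points >= n_clusters >= 1")
    rng = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(n_clusters) / n_clusters
    centers = scale * np.column_stack([np.cos(ang), np.sin(ang)])
    pts = centers[np.arange(n_points) % n_clusters].astype(float)
    if jitter > 0:
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    return PoincareSection(points=pts, period=2.0, phase=0.0)


def noisy_periodic_points(n_clusters: int = 4, n_points: int = 64,
                          seed: int = 0, scale: float = 1.0) -> PoincareSection:
    """Periodic points with jitter at 1e-4 of the circle radius — inside
    the default clustering radius, so the period is still resolved."""
    return periodic_points(n_clusters=n_clusters, n_points=n_points,
                           jitter=1e-4 * scale, seed=seed, scale=scale)


def random_points(n_points: int = 200, seed: int = 1) -> PoincareSection:
    """Uniform scatter on the unit square: no cyclic structure, so
    detect_period reports aperiodic."""
    rng = np.random.default_rng(seed)
    return PoincareSection(points=rng.random((n_points, 2)), period=2.0, phase=0.0)


def linear_system(a: float = -1.5, b: float = -2.0, c: float = 1.0,
                  d: float = 1.0) -> dict:
    """Closed-form eigen-oracle for a 2x2 linear system.

    Returns the coefficient matrix, its eigenvalues
    (trace ± sqrt(trace² - 4 det)) / 2 and the largest real part — the
    exact maximal Lyapunov exponent of the linear flow, used to check
    the Benettin estimator.
    """
    p = LoveParams(a=a, b=b, c=c, d=d)
    rep = classify_fixed_point(p)
    return {
        "a": a, "b": b, "c": c, "d": d,
        "eigenvalues": [[e.real, e.imag] for e in rep.eigenvalues],
        "max_real_eigenvalue": max(e.real for e in rep.eigenvalues),
        "determinant": rep.determinant,
        "trace": rep.trace,
    }


def make_fixtures(kind: str, seed: int, out_dir) -> Path:
    """Write one fixture file (CSV point set or JSON oracle); returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "periodic_points":
        sec = periodic_points(seed=seed)
    elif kind == "noisy_periodic_points":
        sec = noisy_periodic_points(seed=seed)
    elif kind == "random_points":
        sec = random_points(seed=seed)
    elif kind == "linear_system":
        path = out_dir / "linear_system.json"
        path.write_text(json.dumps(linear_system(), indent=2) + "\n")
        return path
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    path = out_dir / f"{kind}.csv"
    sec.to_csv(path)
    return path
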