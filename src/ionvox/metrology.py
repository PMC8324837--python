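"""SIMS image-quality and design calculators.

* 84-16% edge criterion for lateral resolution: the distance over which an
  edge profile rises from 16% to 84% of the plateau difference. For a
  Gaussian-blurred edge this equals 2 sigma (Phi(1) ~ 0.8413).
* Ion-yield vs resolution tradeoff: OLS fit with R^2, quantifying the cost
  of finer probes in collected counts.
* Axial sputter rate: thickness eroded per acquisition plane, from the
  number of planes needed to erode a sample of known thickness.
* Isotope barcode capacity: number of distinguishable probe identities when
  each probe carries an unordered combination of isotope labels.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from .io import LineScan

__all__ = [
    "edge_resolution_84_16",
    "yield_resolution_tradeoff",
    "sputter_rate",
    "breakthrough_plane",
    "barcode_capacity",
]


def edge_resolution_84_16(scan: LineScan, smooth: int = 0) -> float:
    """Lateral resolution of an edge profile by the 84-16% criterion.

    Plateaus are estimated as the medians of the outer 20% of samples on
    each side; the profile is normalised to them and the positions where it
    crosses 16% and 84% of the plateau difference are found by linear
    interpolation between samples. ``smooth`` (odd window length) applies a
    moving average first; off by default.
    """
    x = np.asarray(scan.position, dtype=float)
    y = np.asarray(scan.intensity, dtype=float)
    if len(x) < 4:
        raise ValueError("line scan too short for edge estimation")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(y, kernel, mode="same")
    n_edge = max(2, int(round(0.2 * len(y))))
    lo = np.median(y[:n_edge])
    hi = np.median(y[-n_edge:])
    span = hi - lo
    noise = max(y[:n_edge].std(), y[-n_edge:].std())
    if abs(span) <= 3 * noise or span == 0:
        raise ValueError(
            "no detectable edge: plateau difference below the noise floor"
        )
    norm = (y - lo) / span  # rising 0 -> 1 regardless of scan direction
    x16 = _first_crossing(x, norm, 0.16)
    x84 = _first_crossing(x, norm, 0.84)
    return float(abs(x84 - x16))


def _first_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    above = y >= level
    idx = np.nonzero(above[1:] != above[:-1])[0]
    if len(idx) == 0:
        # profile starts beyond the level: transition is sub-sample
        return float(x[np.argmax(above)])
    i = idx[0]
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(x[i])
    return float(x[i] + (level - y0) / (y1 - y0) * (x[i + 1] - x[i]))


def yield_resolution_tradeoff(points) -> dict:
    """OLS of total ion count against resolution across beam settings.

    ``points`` is a sequence of (current, resolution, total_ion_count) or a
    mapping/record array with those fields. Returns slope, intercept and
    R^2 of counts ~ resolution.
    """
    pts = np.asarray([(p["resolution"], p["total_ion_count"])
                      if isinstance(p, dict) else (p[1], p[2])
                      for p in points], dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for the tradeoff fit")
    x, y = pts[:, 0], pts[:, 1]
    if x.std() == 0:
        raise ValueError("resolution has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"slope": float(slope), "intercept": float(intercept),
            "r_squared": float(r2)}


def sputter_rate(known_thickness: float, planes_to_erode: int) -> float:
    """Thickness removed per acquisition plane (axial step)."""
    if known_thickness <= 0 or planes_to_erode < 1:
        raise ValueError("thickness must be > 0 and planes_to_erode >= 1")
    return known_thickness / planes_to_erode


def breakthrough_plane(depth_profile) -> int:
    """Plane index where a substrate/organic signal ratio first crosses half
    of its asymptotic (final-plateau) value — the erosion breakthrough.

    The asymptote is the median of the last 10% of planes (at least 3).
    """
    y = np.asarray(depth_profile, dtype=float)
    if len(y) < 4:
        raise ValueError("depth profile too short")
    tail = max(3, int(round(0.1 * len(y))))
    asymptote = np.median(y[-tail:])
    baseline = y[0]
    span = asymptote - baseline
    half = baseline + 0.5 * span
    tol = 1e-6 * abs(span)
    rising = span >= 0
    for i, v in enumerate(y):
        if (v >= half - tol) if rising else (v <= half + tol):
            return i
    raise ValueError("no breakthrough detected in depth profile")


def barcode_capacity(n_channels: int, labels_per_probe: int) -> int:
    """Distinguishable probe identities with unordered isotope combinations.

    Counted by exhaustive enumeration of label subsets and cross-checked
    against the closed-form binomial coefficient.
    """
    if n_channels < 1 or not 1 <= labels_per_probe <= n_channels:
        raise ValueError(
            f"need 1 <= labels_per_probe <= n_channels, got "
            f"({n_channels}, {labels_per_probe})"
        )
    enumerated = sum(1 for _ in combinations(range(n_channels),
                                             labels_per_probe))
    closed_form = comb(n_channels, labels_per_probe)
    assert enumerated == closed_form
    return enumerated
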