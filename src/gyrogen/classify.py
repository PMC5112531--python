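"""Fold-outcome classification for simulated cortical profiles.

After a growth run folds the bilayer, the region of interest (the special
area, at the plate center) ends up on top of a gyrus, inside a sulcus, or on
a bank -- the wall between them.  The rule used here operationalizes that
trichotomy: detrend the surface profile in a local window around the center
and rank the center height against the window; high percentile = gyrus, low
= sulcus, middle = bank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta

GYRUS_PERCENTILE = 75.0
SULCUS_PERCENTILE = 25.0

LABELS = ("gyrus", "sulcus", "bank")


@dataclass
class FoldOutcome:
    """Classification of one profile's center region."""

    label: str
    center_height_percentile: float
    local_slope: float
    window: float  # mm (half-width of the classification window)


class NoInstabilityError(RuntimeError):
    """Raised when a profile has not folded enough to classify."""


def classify_center(x: np.ndarray, height: np.ndarray, center: float,
                    window: float, min_amplitude: float = 0.2,
                    gyrus_percentile: float = GYRUS_PERCENTILE,
                    sulcus_percentile: float = SULCUS_PERCENTILE) -> FoldOutcome:
    """Classify the profile point at ``center`` as gyrus, sulcus, or bank.

    The profile inside ``[center - window, center + window]`` is linearly
    detrended; the center's height percentile within the window decides the
    label (>= 75 gyrus, <= 25 sulcus, else bank by default).  ``min_amplitude``
    (mm; default 10% of a 2 mm cortex) guards against classifying an
    unfolded profile.
    """
    x = np.asarray(x, dtype=np.float64)
    height = np.asarray(height, dtype=np.float64)
    if x.shape != height.shape or x.ndim != 1:
        raise ValueError("x and height must be 1-d arrays of equal length")
    if window <= 0:
        raise ValueError("window must be > 0")
    if center - window < x.min() - 1e-9 or center + window > x.max() + 1e-9:
        raise ValueError("profile does not cover [center - window, center + window]")
    sel = (x >= center - window) & (x <= center + window)
    xs, hs = x[sel], height[sel]
    if xs.size < 5:
        raise ValueError("too few profile samples inside the window")
    # remove constant + linear trend so the label only reflects local relief
    coef = np.polyfit(xs, hs, 1)
    resid = hs - np.polyval(coef, xs)
    amplitude = resid.max() - resid.min()
    if amplitude < min_amplitude:
        raise NoInstabilityError(
            f"no instability: detrended window amplitude {amplitude:.3g} mm "
            f"is below {min_amplitude:.3g} mm")
    i_center = int(np.argmin(np.abs(xs - center)))
    h0 = resid[i_center]
    # tie tolerance: samples at equal height (e.g. neighboring crests of a
    # periodic profile) must count as <= the center regardless of rounding
    tol = 1e-9 * max(amplitude, 1.0)
    percentile = 100.0 * np.mean(resid <= h0 + tol)
    # dimensionless local slope of the detrended relief at the center
    span = max(3, xs.size // 8)
    lo = max(0, i_center - span)
    hi = min(xs.size, i_center + span + 1)
    local_slope = float(np.polyfit(xs[lo:hi], resid[lo:hi], 1)[0])
    if percentile >= gyrus_percentile:
        label = "gyrus"
    elif percentile <= sulcus_percentile:
        label = "sulcus"
    else:
        label = "bank"
    return FoldOutcome(label=label, center_height_percentile=float(percentile),
                       local_slope=local_slope, window=float(window))


@dataclass
class OutcomeTable:
    """Outcome counts per simulation mode with exact binomial CIs."""

    counts: dict = field(default_factory=dict)   # mode -> {label: count}
    n_runs: dict = field(default_factory=dict)   # mode -> int
    gyrus_ci: dict = field(default_factory=dict)  # mode -> (lo, hi) proportion

    def proportion(self, mode: str, label: str) -> float:
        return self.counts[mode].get(label, 0) / self.n_runs[mode]

    def to_rows(self) -> list[dict]:
        rows = []
        for mode in self.counts:
            for label in LABELS:
                rows.append({"mode": mode, "label": label,
                             "count": self.counts[mode].get(label, 0),
                             "proportion": self.proportion(mode, label)})
        return rows


def exact_binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def tabulate_outcomes(outcomes, modes) -> OutcomeTable:
    """Count outcomes per mode; absent classes are listed with count 0.

    ``outcomes`` and ``modes`` are parallel sequences of ``FoldOutcome``
    (or labels) and mode names.  A Clopper-Pearson 95% CI is attached to
    each mode's gyrus proportion.
    """
    outcomes = list(outcomes)
    modes = list(modes)
    if not outcomes:
        raise ValueError("no outcomes to tabulate")
    if len(outcomes) != len(modes):
        raise ValueError("outcomes and modes must be parallel")
    labels = [o.label if isinstance(o, FoldOutcome) else str(o) for o in outcomes]
    bad = set(labels) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    table = OutcomeTable()
    for mode in dict.fromkeys(modes):
        sub = [l for l, m in zip(labels, modes) if m == mode]
        table.counts[mode] = dict(Counter(sub))
        table.n_runs[mode] = len(sub)
        table.gyrus_ci[mode] = exact_binomial_ci(table.counts[mode].get("gyrus", 0),
                                                 len(sub))
    return table
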