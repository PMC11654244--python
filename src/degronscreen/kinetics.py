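"""One-phase decay fits for protein degradation time courses.

Degradation is followed either by GFP fluorescence imaging or by immunoblot
band volumes (loading-control normalized); both are expressed as a fraction
of the time-zero signal and fitted with

    y(t) = plateau + (y0 - plateau) * exp(-k * t)

The half-life t50 = ln2 / k is the time at which the fitted curve crosses
halfway between y0 and the plateau.  A 95% confidence interval on t50 comes
from the parameter covariance by the delta method, with a replicate
bootstrap as fallback when the covariance is unusable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TimeCourse",
    "DecayFit",
    "Concordance",
    "normalize_timecourse",
    "wb_normalize",
    "fit_one_phase_decay",
    "compare_modalities",
]

MODALITY_MICROSCOPY = "microscopy"
MODALITY_WESTERN = "western"

#: sentinel half-life for series that do not decay
T50_NON_DEGRADING = float("inf")


@dataclass
class TimeCourse:
    """Replicate x time signals, normalized so each replicate starts at 1."""

    strain_id: str
    modality: str
    times: np.ndarray
    values: np.ndarray  # shape (n_replicates, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.times.size:
            raise ValueError("values must have one column per timepoint")
        if np.any(self.values < 0):
            raise ValueError("normalized signals must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]


@dataclass
class DecayFit:
    """One-phase decay parameters with a 95% CI on the half-life."""

    y0: float
    plateau: float
    k: float
    t50: float
    ci_low: float
    ci_high: float
    rss: float
    converged: bool
    non_degrading: bool = False
    ci_method: str = "delta"

    @property
    def t50_ln2_over_k(self) -> float:
        """Pure ln2/k half-life (identical to t50 for this parameterization)."""
        return math.log(2.0) / self.k if self.k > 0 else T50_NON_DEGRADING


@dataclass(frozen=True)
class Concordance:
    """Agreement between microscopy and immunoblot half-life estimates."""

    ratio: float  # t50 microscopy / t50 western
    ci_overlap: bool


def normalize_timecourse(
    times: Sequence[float],
    raw: Sequence[float] | np.ndarray,
    strain_id: str = "",
    modality: str = MODALITY_MICROSCOPY,
) -> TimeCourse:
    """Express each replicate as a fraction of its own time-zero signal."""
    t = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(raw, dtype=float))
    idx0 = np.flatnonzero(t == 0.0)
    if idx0.size == 0:
        raise ValueError("time course must include t = 0")
    y0 = y[:, idx0[0]]
    if np.any(y0 <= 0):
        raise ValueError("time-zero signal must be positive in every replicate")
    return TimeCourse(strain_id, modality, t, y / y0[:, None])


def wb_normalize(
    band_volumes: Sequence[float], loading_volumes: Sequence[float]
) -> np.ndarray:
    """Divide immunoblot band volumes by their loading-control (Act1) bands."""
    bands = np.asarray(band_volumes, dtype=float)
    loading = np.asarray(loading_volumes, dtype=float)
    if bands.shape != loading.shape:
        raise ValueError("band and loading-control vectors must match in shape")
    if np.any(loading <= 0):
        raise ValueError("loading-control volumes must be positive")
    return bands / loading


def _decay(t, y0, plateau, k):
    return plateau + (y0 - plateau) * np.exp(-k * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    plateau0 = float(np.clip(np.min(y), 0.0, 0.99))
    y00 = float(np.clip(y[np.argmin(t)], 0.8, 1.2))
    half = plateau0 + 0.5 * (y00 - plateau0)
    below = t[y <= half]
    tmax = float(np.max(t))
    thalf = float(np.min(below)) if below.size and np.min(below) > 0 else tmax / 2.0
    k0 = math.log(2.0) / max(thalf, 1e-6)
    return y00, plateau0, k0


def fit_one_phase_decay(
    tc: TimeCourse,
    min_amplitude: float = 0.1,
    bootstrap_draws: int = 1000,
    seed: int = 0,
) -> DecayFit:
    """Least-squares one-phase decay fit with a 95% CI on t50.

    Replicates are pooled into one residual vector.  Constraints:
    y0 in [0.8, 1.2] (absorbing normalization noise rather than pinning the
    start at 1), plateau in [0, 1], k > 0.  Series whose fitted amplitude
    (y0 - plateau) is below ``min_amplitude`` are flagged non-degrading and
    get an infinite-half-life sentinel.  The CI is asymptotic (delta method
    on ln2/k, t-quantile with N-3 dof); when the covariance is unusable and
    >= 3 replicates exist, a replicate bootstrap (``bootstrap_draws`` draws)
    is used instead.
    """
    if np.unique(tc.times).size < 3:
        raise ValueError("need at least three distinct timepoints")
    t = np.tile(tc.times, tc.n_replicates)
    y = tc.values.ravel()

    p0 = _initial_guess(tc.times, tc.values.mean(axis=0))
    bounds = ([0.8, 0.0, 1e-9], [1.2, 1.0, np.inf])
    try:
        popt, pcov = optimize.curve_fit(
            _decay, t, y, p0=p0, bounds=bounds, maxfev=10000
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((3, 3), np.nan)
        converged = False
    y0, plateau, k = (float(v) for v in popt)
    resid = y - _decay(t, *popt)
    rss = float(resid @ resid)

    if not converged or (y0 - plateau) < min_amplitude:
        return DecayFit(
            y0=y0, plateau=plateau, k=k,
            t50=T50_NON_DEGRADING, ci_low=float("nan"), ci_high=float("nan"),
            rss=rss, converged=converged, non_degrading=True, ci_method="none",
        )

    t50 = math.log(2.0) / k
    dof = max(y.size - 3, 1)
    var_k = float(pcov[2, 2]) if np.all(np.isfinite(pcov)) else float("nan")
    if np.isfinite(var_k) and var_k >= 0:
        se_t50 = math.log(2.0) / (k * k) * math.sqrt(var_k)
        q = float(stats.t.ppf(0.975, dof))
        lo, hi = max(t50 - q * se_t50, 0.0), t50 + q * se_t50
        method = "delta"
    elif tc.n_replicates >= 3:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(bootstrap_draws):
            pick = rng.integers(0, tc.n_replicates, tc.n_replicates)
            yb = tc.values[pick].ravel()
            try:
                pb, _ = optimize.curve_fit(_decay, t, yb, p0=popt, bounds=bounds, maxfev=5000)
                draws.append(math.log(2.0) / pb[2])
            except RuntimeError:
                continue
        if draws:
            lo, hi = (float(v) for v in np.percentile(draws, [2.5, 97.5]))
            lo, hi = min(lo, t50), max(hi, t50)
            method = "bootstrap"
        else:
            lo, hi, method = float("nan"), float("nan"), "none"
    else:
        lo, hi, method = float("nan"), float("nan"), "none"

    return DecayFit(
        y0=y0, plateau=plateau, k=k, t50=t50, ci_low=lo, ci_high=hi,
        rss=rss, converged=converged, non_degrading=False, ci_method=method,
    )


def compare_modalities(fit_m: DecayFit, fit_w: DecayFit) -> Concordance:
    """Half-life ratio (microscopy / immunoblot) and 95%-CI overlap flag."""
    for f, name in ((fit_m, "microscopy"), (fit_w, "western")):
        if not f.converged or f.non_degrading:
            raise ValueError(f"{name} fit is flagged; concordance undefined")
    overlap = (fit_m.ci_low <= fit_w.ci_high) and (fit_w.ci_low <= fit_m.ci_high)
    return Concordance(ratio=fit_m.t50 / fit_w.t50, ci_overlap=bool(overlap))
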