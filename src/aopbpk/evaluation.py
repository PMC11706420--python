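"""Prediction-accuracy metrics and DDI acceptance criteria.

GMFE (geometric mean fold error) measures precision on the log scale,
AFE (average fold error) measures bias, RMSE is on the untransformed
scale, and the within-k-fold fraction is the share of predictions inside
a k-fold envelope.  For DDI AUC ratios the Guest limits tighten as the
observed ratio approaches 1.  All metrics operate on the plasma scale as
reported clinically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AccuracyReport:
    n: int
    gmfe: float
    afe: float
    rmse: float
    fraction_within: float
    k: float
    fold_errors: list[float]  # per item, always >= 1


def accuracy(pred, obs, k: float = 2.0) -> AccuracyReport:
    """Fold-error metrics for paired positive predictions/observations.

    ``GMFE = 10^mean(|log10(pred/obs)|)``, ``AFE = 10^mean(log10(pred/obs))``,
    RMSE untransformed, and the fraction within ``k``-fold.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D and the same length")
    if len(pred) == 0:
        raise ValueError("empty input")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("all values must be positive")
    logr = np.log10(pred / obs)
    folds = np.power(10.0, np.abs(logr))
    return AccuracyReport(
        n=len(pred),
        gmfe=float(10.0 ** np.mean(np.abs(logr))),
        afe=float(10.0 ** np.mean(logr)),
        rmse=float(np.sqrt(np.mean((pred - obs) ** 2))),
        fraction_within=float(np.mean(folds <= k)),
        k=k,
        fold_errors=[float(f) for f in folds],
    )


@dataclass
class GuestVerdict:
    passed: bool
    limits: tuple[float, float]  # on the original (unmirrored) scale
    observed: float
    predicted: float


def guest_criterion(pred_ratio: float, obs_ratio: float, delta: float = 1.0) -> GuestVerdict:
    """Guest et al. acceptance limits for a predicted vs observed AUC ratio.

    Ratios below 1 (induction) are mirrored; the limit
    ``L = (delta + 2(R-1))/R`` shrinks toward ``delta`` as the observed
    ratio R approaches 1, and the prediction passes iff it lies within
    ``[R/L, R*L]`` (after mirroring).
    """
    if pred_ratio <= 0 or obs_ratio <= 0:
        raise ValueError("ratios must be positive")
    if delta < 1.0:
        raise ValueError("delta must be >= 1")
    mirrored = obs_ratio < 1.0
    r = 1.0 / obs_ratio if mirrored else obs_ratio
    p = 1.0 / pred_ratio if mirrored else pred_ratio
    limit = (delta + 2.0 * (r - 1.0)) / r
    lo, hi = r / limit, r * limit
    passed = lo <= p <= hi
    if mirrored:
        lo, hi = 1.0 / hi, 1.0 / lo
    return GuestVerdict(passed=passed, limits=(lo, hi), observed=obs_ratio, predicted=pred_ratio)


def twofold_check(pred: float, obs: float) -> bool:
    """True iff prediction is within twofold of the observation."""
    if pred <= 0 or obs <= 0:
        raise ValueError("values must be positive")
    ratio = pred / obs
    return 0.5 <= ratio <= 2.0


def fold_error(pred: float, obs: float) -> float:
    """Symmetric fold error max(pred/obs, obs/pred)."""
    if pred <= 0 or obs <= 0:
        raise ValueError("values must be positive")
    return max(pred / obs, obs / pred)
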