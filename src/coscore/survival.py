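"""Censored exponential survival models and the UP-vs-DOWN likelihood-ratio test.

The exponential model has constant hazard λ; with right-censoring the MLE is
closed form, λ̂ = d / T, where d is the number of observed events and
T = Σ tᵢ the total exposure time.  The maximized log-likelihood is
d·ln λ̂ − λ̂·T = d·(ln(d/T) − 1).  Two nested models are compared:

* two-rate model — separate rates for the UP and DOWN expression groups;
* one-rate model — a single pooled rate.

The likelihood-ratio statistic 2·(ℓ_UP + ℓ_DOWN − ℓ_pooled) is referred to
χ²(1); its upper tail is P_true, the significance of the observed UP/DOWN
survival difference.

A group with zero events gets λ̂ = 0 by convention; its log-likelihood
contribution is the supremum 0 (the limit of −λT as λ → 0), which keeps the
LRT finite for the tiny high-expression clusters real cohorts produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dichotomize import UP
from .errors import UnscorableError

logger = logging.getLogger(__name__)

_LRT_TOL = 1e-9


@dataclass(frozen=True)
class ExponentialFit:
    """Closed-form censored exponential MLE for one group."""

    rate: float
    n_events: int
    total_exposure: float
    loglik: float

    @property
    def degenerate(self) -> bool:
        """True when the group had no events (rate pinned at 0)."""
        return self.n_events == 0


@dataclass(frozen=True)
class GroupTest:
    """Two-rate vs pooled-rate comparison for one feature's UP/DOWN split."""

    fit_up: ExponentialFit
    fit_down: ExponentialFit
    fit_pooled: ExponentialFit
    lrt_stat: float
    p_true: float


def exp_loglik(n_events, total_exposure):
    """Maximized exponential log-likelihood d·(ln(d/T) − 1); 0 when d = 0."""
    d = np.asarray(n_events, dtype=float)
    T = np.asarray(total_exposure, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(d > 0, d * (np.log(np.where(d > 0, d, 1.0) / T) - 1.0), 0.0)
    return ll if ll.ndim else float(ll)


def fit_exponential(times, events) -> ExponentialFit:
    """Fit the censored exponential model by its closed-form MLE.

    Parameters
    ----------
    times : array-like of non-negative follow-up times (months).
    events : array-like of 0/1 indicators, 1 = endpoint occurred.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise UnscorableError("cannot fit an exponential model to an empty group")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise UnscorableError("follow-up times must be finite and non-negative")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise UnscorableError("event indicators must be 0 or 1")
    T = float(t.sum())
    if T <= 0:
        raise UnscorableError("total exposure is zero; no information in the group")
    d = int(e.sum())
    rate = d / T
    return ExponentialFit(rate=rate, n_events=d, total_exposure=T, loglik=exp_loglik(d, T))


def sanitize_times(times, events=None):
    """Replace zero follow-up times by half the smallest positive time.

    Exact zeros contribute no exposure and can empty the exposure sum of a
    small group; this declared convention keeps such records usable.  Returns
    the adjusted copy (``events`` is accepted for symmetry and not altered).
    """
    del events
    t = np.asarray(times, dtype=float).copy()
    zero = t == 0
    if zero.any():
        positive = t[t > 0]
        if positive.size == 0:
            raise UnscorableError("all follow-up times are zero")
        t[zero] = positive.min() / 2.0
        logger.info("replaced %d zero follow-up times by %g", zero.sum(), positive.min() / 2.0)
    return t


def compare_groups(times, events, labels) -> GroupTest:
    """LRT of separate UP/DOWN exponential rates against a pooled rate.

    ``labels`` holds "UP"/"DOWN" per sample (or a boolean mask, True = UP).
    Returns the two group fits, the pooled fit, the LRT statistic and its
    χ²(1) upper-tail probability P_true.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    lab = np.asarray(labels)
    up = lab if lab.dtype == bool else lab == UP
    if t.shape != e.shape or t.shape != up.shape:
        raise UnscorableError("times, events and labels must have equal length")
    if not up.any() or up.all():
        raise UnscorableError("both UP and DOWN groups must be non-empty")

    fit_up = fit_exponential(t[up], e[up])
    fit_down = fit_exponential(t[~up], e[~up])
    fit_pooled = fit_exponential(t, e)
    lrt = 2.0 * (fit_up.loglik + fit_down.loglik - fit_pooled.loglik)
    if lrt < -_LRT_TOL:  # nested models: can only be numerical noise
        raise AssertionError(f"negative LRT statistic {lrt}")
    lrt = max(lrt, 0.0)
    return GroupTest(
        fit_up=fit_up,
        fit_down=fit_down,
        fit_pooled=fit_pooled,
        lrt_stat=lrt,
        p_true=float(stats.chi2.sf(lrt, df=1)),
    )
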