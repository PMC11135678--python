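"""Inter-call intervals, bout-end-criterion estimation and bout statistics.

Animals that call in bouts produce two interleaved timescales of inter-call
intervals (ICIs): short within-bout gaps and long between-bout gaps. Both
are modeled as exponential processes, so the pooled ICIs follow the mixture

    f(t) = p * lf * exp(-lf t) + (1 - p) * ls * exp(-ls t),   lf > ls > 0,

with ``p`` the probability that a gap belongs to the fast (within-bout)
process. The bout-end criterion (BEC) is the interval at which the two
weighted process densities intersect,

    t* = ln( p lf / ((1 - p) ls) ) / (lf - ls),

the point past which a gap is more likely to come from the slow process.
Two estimators are provided: direct maximum likelihood on the untransformed
intervals (:class:`ExponentialMixtureBEC`, the default) and the classical
broken-stick fit to a histogram of log-intervals
(:class:`BrokenStickBEC`). Calls separated by gaps strictly below the BEC
are then segmented into bouts of at least two calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateIntervalError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "ICISeries",
    "BoutModelFit",
    "Bout",
    "ExponentialMixtureBEC",
    "BrokenStickBEC",
    "compute_icis",
    "fit_mixture_mle",
    "fit_broken_stick",
    "bec_from_params",
    "segment_bouts",
    "bout_statistics",
]

logger = logging.getLogger("calltag")


@dataclass
class ICISeries:
    """Ordered onset-to-onset gaps between one caller's consecutive calls."""

    caller_id: str
    intervals_s: np.ndarray

    def __post_init__(self):
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        if self.intervals_s.size and (
            np.any(self.intervals_s <= 0) or not np.all(np.isfinite(self.intervals_s))
        ):
            raise InvalidParameterError("intervals must be positive and finite")


@dataclass
class BoutModelFit:
    """Fitted bout model: mixture parameters (if any) plus the BEC."""

    bec_s: float
    method: str  # mixture_mle | broken_stick_hist
    n_intervals: int
    p_fast: float | None = None
    lambda_fast: float | None = None
    lambda_slow: float | None = None
    neg_log_lik: float | None = None
    degenerate: bool = False


@dataclass
class Bout:
    caller_id: str
    call_indices: list[int]
    t_start_s: float
    t_end_s: float

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def n_calls(self) -> int:
        return len(self.call_indices)


def compute_icis(calls, caller_id: str = "") -> ICISeries:
    """Onset-to-onset intervals for one individual's calls, sorted by onset.

    ``calls`` is a DataFrame with a t_start_s column or a 1-D onset array.
    A single call yields an empty series; duplicate onsets raise
    :class:`DegenerateIntervalError`.
    """
    if isinstance(calls, pd.DataFrame):
        onsets = calls["t_start_s"].to_numpy(dtype=float)
        if not caller_id and "caller_id" in calls.columns and len(calls):
            caller_id = str(calls["caller_id"].iloc[0])
    else:
        onsets = np.asarray(calls, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise InvalidParameterError("calls must be sorted by onset")
    gaps = np.diff(onsets)
    if np.any(gaps == 0):
        raise DegenerateIntervalError("duplicate onsets produce a zero interval")
    return ICISeries(caller_id=caller_id, intervals_s=gaps)


def bec_from_params(p_fast: float, lambda_fast: float, lambda_slow: float) -> float:
    """Closed-form density-intersection BEC of the two-process mixture."""
    if not (0 < p_fast < 1 and lambda_fast > lambda_slow > 0):
        raise InvalidParameterError("invalid mixture parameters")
    return float(
        np.log((p_fast * lambda_fast) / ((1 - p_fast) * lambda_slow))
        / (lambda_fast - lambda_slow)
    )


def _mixture_nll(theta: np.ndarray, t: np.ndarray) -> float:
    """Negative log-likelihood in (logit p, log l1, log l2) coordinates."""
    logit_p, log_l1, log_l2 = theta
    log_p = -np.logaddexp(0.0, -logit_p)
    log_q = -np.logaddexp(0.0, logit_p)
    l1, l2 = np.exp(log_l1), np.exp(log_l2)
    comp = np.stack(
        [log_p + log_l1 - l1 * t, log_q + log_l2 - l2 * t], axis=0
    )
    return -float(np.sum(logsumexp(comp, axis=0)))


class ExponentialMixtureBEC(BaseEstimator):
    """Bout-end criterion by exponential-mixture maximum likelihood.

    Fits the two-process mixture to untransformed intervals by L-BFGS-B in
    unconstrained coordinates (logit weight, log rates), from ``n_starts``
    deterministic multistarts, and keeps the best optimum. The BEC is the
    closed-form density intersection of the fitted processes.

    Fitted attributes: ``p_fast_``, ``lambda_fast_``, ``lambda_slow_``,
    ``bec_s_``, ``neg_log_lik_``, ``n_intervals_``, ``degenerate_``.
    A fit is flagged degenerate when the weight collapses to a boundary or
    the two rates are nearly equal (the data support a single process).
    """

    def __init__(self, min_intervals: int = 10, n_starts: int = 8,
                 random_state: int = 0):
        self.min_intervals = min_intervals
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).ravel()
        if t.size < self.min_intervals:
            raise InsufficientDataError(
                f"need >= {self.min_intervals} intervals, got {t.size}"
            )
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise InvalidParameterError("intervals must be positive and finite")
        rng = np.random.default_rng(self.random_state)
        starts = self._starts(t, rng)
        best, diagnostics = None, []
        for theta0 in starts:
            res = minimize(
                _mixture_nll, theta0, args=(t,), method="L-BFGS-B",
                bounds=[(-12, 12), (-20, 20), (-20, 20)],
            )
            diagnostics.append({"x0": list(theta0), "fun": float(res.fun),
                                "success": bool(res.success)})
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitFailureError(
                "mixture MLE failed to converge from every start",
                diagnostics={"starts": diagnostics},
            )
        p = float(expit(best.x[0]))
        l1, l2 = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
        if l1 >= l2:
            p_fast, lf, ls = p, l1, l2
        else:  # mixture labels are symmetric; order so fast > slow
            p_fast, lf, ls = 1.0 - p, l2, l1
        self.p_fast_, self.lambda_fast_, self.lambda_slow_ = p_fast, lf, ls
        self.neg_log_lik_ = float(best.fun)
        self.n_intervals_ = int(t.size)
        self.degenerate_ = bool(
            p_fast < 1e-3 or p_fast > 1 - 1e-3 or lf / ls < 1.05
            or p_fast * lf <= (1 - p_fast) * ls
        )
        if self.degenerate_:
            # no density crossing worth reporting; fall back to the slow-
            # process scale so downstream segmentation stays defined
            self.bec_s_ = float(np.quantile(t, 0.95))
            logger.warning(
                "mixture fit degenerate (p_fast=%.4f, rate ratio=%.3f); "
                "BEC fallback to the 95th interval percentile",
                p_fast, lf / ls,
            )
        else:
            self.bec_s_ = bec_from_params(p_fast, lf, ls)
        return self

    def _starts(self, t: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
        qs = np.quantile(t, [0.25, 0.5, 0.9])
        base = []
        for p0 in (0.5, 0.8):
            for fast_scale, slow_scale in ((qs[0], qs[2]), (qs[1], 4 * qs[2])):
                base.append(
                    np.array(
                        [np.log(p0 / (1 - p0)),
                         np.log(1.0 / max(fast_scale, 1e-9)),
                         np.log(1.0 / max(slow_scale, 1e-9))]
                    )
                )
        starts = list(base)
        while len(starts) < self.n_starts:
            starts.append(base[len(starts) % len(base)] + rng.normal(0, 0.5, 3))
        return starts[: self.n_starts]

    def predict(self, X):
        """Boolean array: interval is a within-bout (fast-process) gap."""
        if not hasattr(self, "bec_s_"):
            raise FitFailureError("estimator is not fitted")
        return np.asarray(X, dtype=float) < self.bec_s_

    def to_fit(self) -> BoutModelFit:
        return BoutModelFit(
            bec_s=self.bec_s_, method="mixture_mle", n_intervals=self.n_intervals_,
            p_fast=self.p_fast_, lambda_fast=self.lambda_fast_,
            lambda_slow=self.lambda_slow_, neg_log_lik=self.neg_log_lik_,
            degenerate=self.degenerate_,
        )


class BrokenStickBEC(BaseEstimator):
    """Bout-end criterion from a broken-stick fit to the log-ICI histogram.

    Intervals are histogrammed on a log10 axis (so both timescales get
    resolved bins), counts are converted to empirical densities per second,
    and for every candidate break with at least two nonempty bins on each
    side two least-squares lines are fitted to log10(density) against the
    bin center *in seconds* — the coordinates in which an exponential
    process is a straight line with slope ``-lambda log10 e``. The break
    minimizing the total squared error wins and the BEC is the abscissa
    where the two lines intersect, i.e. where the fast- and slow-process
    densities cross. Implied rates from the two slopes are exposed as
    ``lambda_fast_`` / ``lambda_slow_``.
    """

    def __init__(self, n_bins: int = 20, min_intervals: int = 10):
        self.n_bins = n_bins
        self.min_intervals = min_intervals

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).ravel()
        if t.size < self.min_intervals:
            raise InsufficientDataError(
                f"need >= {self.min_intervals} intervals, got {t.size}"
            )
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise InvalidParameterError("intervals must be positive and finite")
        if np.log10(t.max() / t.min()) < 0.5:
            # a single tight cluster cannot carry two timescales
            raise InsufficientDataError(
                "intervals span less than half a decade; no break to fit"
            )
        counts, edges = np.histogram(np.log10(t), bins=self.n_bins)
        lo, hi = 10.0 ** edges[:-1], 10.0 ** edges[1:]
        centers_s = np.sqrt(lo * hi)
        density = counts / (counts.sum() * (hi - lo))
        ok = counts > 0
        x, yv = centers_s[ok], np.log10(density[ok])
        if ok.sum() < 4 or np.unique(t).size < 4:
            raise InsufficientDataError(
                "too few distinct intervals for a broken-stick fit"
            )
        best = None
        for k in range(2, ok.sum() - 1):
            (m1, b1), res1 = _lsq_line(x[:k], yv[:k])
            (m2, b2), res2 = _lsq_line(x[k:], yv[k:])
            sse = res1 + res2
            if best is None or sse < best[0]:
                best = (sse, k, (m1, b1), (m2, b2))
        _, k, (m1, b1), (m2, b2) = best
        if abs(m1 - m2) > 1e-12:
            t_star = (b2 - b1) / (m1 - m2)
            if not x[0] <= t_star <= x[-1]:  # near-parallel lines: use break bin
                t_star = x[k]
        else:
            t_star = x[k]
        self.bec_s_ = float(t_star)
        self.slopes_ = (float(m1), float(m2))
        self.lambda_fast_ = float(-m1 * np.log(10.0))
        self.lambda_slow_ = float(-m2 * np.log(10.0))
        self.n_intervals_ = int(t.size)
        return self

    def to_fit(self) -> BoutModelFit:
        return BoutModelFit(
            bec_s=self.bec_s_, method="broken_stick_hist",
            n_intervals=self.n_intervals_,
            lambda_fast=self.lambda_fast_, lambda_slow=self.lambda_slow_,
        )


def _lsq_line(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], float]:
    """Least-squares line fit returning ((slope, intercept), SSE)."""
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return (float(coef[0]), float(coef[1])), float(np.sum(resid**2))


def fit_mixture_mle(intervals, **kwargs) -> BoutModelFit:
    """Functional wrapper over :class:`ExponentialMixtureBEC`."""
    return ExponentialMixtureBEC(**kwargs).fit(intervals).to_fit()


def fit_broken_stick(intervals, n_bins: int = 20, **kwargs) -> BoutModelFit:
    """Functional wrapper over :class:`BrokenStickBEC`."""
    return BrokenStickBEC(n_bins=n_bins, **kwargs).fit(intervals).to_fit()


def segment_bouts(
    calls: pd.DataFrame, bec_s: float, caller_id: str = ""
) -> tuple[list[Bout], list[int]]:
    """Partition one individual's calls into bouts and solitary calls.

    Maximal runs of consecutive calls whose onset-to-onset gaps are all
    strictly below ``bec_s``; runs of length >= 2 become bouts (spanning
    first call start to last call end), the rest are solitary. Returns
    ``(bouts, solitary_row_positions)``.
    """
    if bec_s <= 0:
        raise InvalidParameterError("bec_s must be positive")
    onsets = calls["t_start_s"].to_numpy(dtype=float)
    offsets = calls["t_end_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise InvalidParameterError("calls must be sorted by onset")
    if not caller_id and "caller_id" in calls.columns and len(calls):
        caller_id = str(calls["caller_id"].iloc[0])
    bouts: list[Bout] = []
    solitary: list[int] = []
    run = [0] if len(onsets) else []
    for i in range(1, len(onsets)):
        if onsets[i] - onsets[i - 1] < bec_s:
            run.append(i)
        else:
            _flush(run, onsets, offsets, caller_id, bouts, solitary)
            run = [i]
    _flush(run, onsets, offsets, caller_id, bouts, solitary)
    return bouts, solitary


def _flush(run, onsets, offsets, caller_id, bouts, solitary):
    if len(run) >= 2:
        bouts.append(
            Bout(
                caller_id=caller_id,
                call_indices=list(run),
                t_start_s=float(onsets[run[0]]),
                t_end_s=float(offsets[run[-1]]),
            )
        )
    elif run:
        solitary.extend(run)


def bout_statistics(
    call_table: pd.DataFrame,
    bec_s: float,
    by: str = "age_class",
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Per-group bout summaries from a caller-attributed call table.

    For each level of ``by`` (e.g. age class, or caller_id for
    per-individual rows): number of bouts, median and IQR of within-bout
    ICIs, coefficient of variation (sd/mean) over all of the group's ICIs,
    median bout duration and median calls per bout. Groups without bouts
    are omitted with a logged notice. Quantiles use the given numpy
    ``method`` (default linear interpolation).
    """
    rows = []
    for level, grp in call_table.groupby(by, sort=True):
        within, all_icis, durations, sizes = [], [], [], []
        for caller, calls in grp.groupby("caller_id"):
            calls = calls.sort_values("t_start_s")
            gaps = compute_icis(calls, str(caller)).intervals_s
            all_icis.append(gaps)
            bouts, _ = segment_bouts(calls, bec_s, str(caller))
            for b in bouts:
                idx = np.asarray(b.call_indices)
                within.append(gaps[idx[:-1]])
                durations.append(b.duration_s)
                sizes.append(b.n_calls)
        if not durations:
            logger.info("group %r=%r has no bouts; omitted from summary", by, level)
            continue
        w = np.concatenate(within) if within else np.array([])
        a = np.concatenate(all_icis) if all_icis else np.array([])
        q1, q3 = np.quantile(w, [0.25, 0.75], method=quantile_method)
        rows.append(
            {
                by: level,
                "n_bouts": len(durations),
                "n_calls": int(len(grp)),
                "median_ici_s": float(np.quantile(w, 0.5, method=quantile_method)),
                "iqr_ici_s": float(q3 - q1),
                "cv_ici": float(np.std(a, ddof=1) / np.mean(a)) if a.size > 1 else np.nan,
                "median_bout_duration_s": float(
                    np.quantile(durations, 0.5, method=quantile_method)
                ),
                "median_calls_per_bout": float(
                    np.quantile(sizes, 0.5, method=quantile_method)
                ),
            }
        )
    return pd.DataFrame(rows)
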