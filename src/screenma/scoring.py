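"""Negative-control normalization and MA-plot sgRNA scoring.

The method compares each induced sample with its paired pre-induction
sample on an MA plot: A = (lg C+ + lg C-)/2 is the mean log10 abundance
and M = lg C+ - lg C- the log10 fold change of a guide, where C+/C- are
counts normalized by the per-sample median of a stable subset of
negative-control sgRNAs.  Because count noise shrinks with abundance, the
null spread of M depends on A; it is estimated as the standard deviation
of M inside sliding windows over the control guides (each window holding
a fixed fraction of them) and smoothed with an exponential decay
sigma(A) = alpha * exp(-beta * A).  Each guide then gets Z = M / sigma(A)
and a one-sided upper-tail normal p-value, enrichment being the direction
of interest in a bypass screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .library import ScreenCountTable

__all__ = [
    "ControlSelection",
    "VarianceModel",
    "select_stable_controls",
    "control_median_normalize",
    "compute_ma",
    "fit_variance_model",
    "score_sgrnas",
    "score_pair",
]

logger = logging.getLogger(__name__)

DEFAULT_TRIM_FRACTION = 0.10
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_WINDOW_FRACTION = 0.02
DEFAULT_WINDOW_STEP = 1
MIN_WINDOW_SIZE = 20


@dataclass
class ControlSelection:
    """Stable negative-control guides kept for normalization and the variance fit.

    A control is removed when its count sits in the top or bottom
    ``trim_fraction`` tail (average-rank percentile) among controls in any
    sample.
    """

    retained_ids: list[str]
    removed: pd.DataFrame  # columns: sgrna_id, sample_id, reason

    @property
    def removed_ids(self) -> list[str]:
        return sorted(set(self.removed["sgrna_id"]))


@dataclass
class VarianceModel:
    """Fitted sigma_M|A = alpha * exp(-beta * A) plus its window summaries.

    ``windows`` has columns a_center (mean A of the window), sigma (sample
    SD of M, ddof=1) and n_members.  ``fit_mode`` is "nls" for the
    nonlinear least-squares fit or "loglinear_fallback" when that fails to
    converge and the closed-form OLS of ln(sigma) on A is used instead.
    """

    alpha: float
    beta: float
    windows: pd.DataFrame = field(repr=False)
    fit_mode: str = "nls"

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    def predict_sigma(self, a: np.ndarray | float) -> np.ndarray | float:
        return self.alpha * np.exp(-self.beta * np.asarray(a, dtype=float))


def _rank_percentiles(values: np.ndarray) -> np.ndarray:
    """Average-rank percentiles in (0, 1); all-tied inputs map to 0.5."""
    ranks = stats.rankdata(values, method="average")
    return (ranks - 0.5) / len(values)


def select_stable_controls(
    counts: ScreenCountTable,
    control_ids,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> ControlSelection:
    """Drop control guides whose raw count is extreme in any sample."""
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids is empty")
    missing = [c for c in control_ids if c not in counts.counts.index]
    if missing:
        raise ValueError(f"control ids absent from count table: {missing[:5]}")

    sub = counts.counts.loc[control_ids]
    removed_rows = []
    removed_set: set[str] = set()
    for sample in sub.columns:
        pct = _rank_percentiles(sub[sample].to_numpy(dtype=float))
        for sgid, p in zip(control_ids, pct):
            if p >= 1 - trim_fraction:
                removed_rows.append((sgid, sample, "top_tail"))
                removed_set.add(sgid)
            elif p <= trim_fraction:
                removed_rows.append((sgid, sample, "bottom_tail"))
                removed_set.add(sgid)
    retained = [c for c in control_ids if c not in removed_set]
    if not retained:
        raise ValueError(
            "all control sgRNAs removed by tail filtering; "
            "use a smaller trim_fraction"
        )
    removed = pd.DataFrame(removed_rows, columns=["sgrna_id", "sample_id", "reason"])
    logger.info(
        "control filtering: %d/%d controls retained (trim_fraction=%.2f)",
        len(retained), len(control_ids), trim_fraction,
    )
    return ControlSelection(retained_ids=retained, removed=removed)


def control_median_normalize(
    counts: ScreenCountTable, selection: ControlSelection
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample by its median over retained control guides.

    Returns the normalized real-valued table and the per-sample
    control-medians; after normalization the retained-control median is 1
    in every sample.
    """
    if not selection.retained_ids:
        raise ValueError("no retained controls")
    medians = counts.counts.loc[selection.retained_ids].median(axis=0)
    zero = medians[medians == 0]
    if len(zero):
        raise ValueError(
            f"control-median is zero in sample(s) {list(zero.index)}; "
            "cannot normalize"
        )
    normalized = counts.counts.astype(float) / medians
    return normalized, medians.rename("control_median")


def compute_ma(
    norm_induced: pd.Series,
    norm_control: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.Series, pd.Series]:
    """A and M (log10) for aligned normalized count vectors.

    A pseudocount on the normalized scale keeps both finite at zero counts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not norm_induced.index.equals(norm_control.index):
        norm_control = norm_control.reindex(norm_induced.index)
        if norm_control.isna().any():
            raise ValueError("induced and control vectors index different sgRNAs")
    if (norm_induced < 0).any() or (norm_control < 0).any():
        raise ValueError("normalized counts must be non-negative")
    c_plus = norm_induced.to_numpy(dtype=float) + pseudocount
    c_minus = norm_control.to_numpy(dtype=float) + pseudocount
    if np.any(c_plus <= 0) or np.any(c_minus <= 0):
        raise ValueError("zero counts require a positive pseudocount")
    lp, lm = np.log10(c_plus), np.log10(c_minus)
    a = pd.Series((lp + lm) / 2, index=norm_induced.index, name="A")
    m = pd.Series(lp - lm, index=norm_induced.index, name="M")
    return a, m


def _loglinear_fit(a_centers: np.ndarray, sigmas: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS of ln(sigma) on A: the log-linear exponential fit."""
    coef = np.polyfit(a_centers, np.log(sigmas), 1)
    return float(np.exp(coef[1])), float(-coef[0])


def fit_variance_model(
    a_controls,
    m_controls,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    window_step: int = DEFAULT_WINDOW_STEP,
    min_window_size: int = MIN_WINDOW_SIZE,
) -> VarianceModel:
    """Fit sigma_M|A = alpha*exp(-beta*A) to sliding-window SDs of control M.

    Controls are sorted by A; windows of w consecutive controls (w = the
    window fraction of the control count, floored at ``min_window_size``)
    advance by ``window_step``.  The exponential is fit to the
    (mean-A, SD-of-M) pairs by nonlinear least squares; if that fails to
    converge the log-linear closed form is used and flagged.
    """
    a = np.asarray(a_controls, dtype=float)
    m = np.asarray(m_controls, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("A and M must be aligned 1-d vectors")
    if not (np.isfinite(a).all() and np.isfinite(m).all()):
        raise ValueError("non-finite A or M among controls")
    n = len(a)
    w = max(math.ceil(window_fraction * n), min_window_size)
    if window_step < 1:
        raise ValueError("window_step must be >= 1")
    order = np.argsort(a, kind="stable")
    a_sorted, m_sorted = a[order], m[order]

    starts = range(0, n - w + 1, window_step)
    rows = []
    for s in starts:
        seg_m = m_sorted[s : s + w]
        sd = float(np.std(seg_m, ddof=1))
        if sd > 0:
            rows.append((float(np.mean(a_sorted[s : s + w])), sd, w))
    if len(rows) < 2:
        raise ValueError(
            f"fewer than 2 non-degenerate windows (n={n}, window={w}); "
            "cannot fit the variance model"
        )
    windows = pd.DataFrame(rows, columns=["a_center", "sigma", "n_members"])
    windows = windows.sort_values("a_center", kind="stable").reset_index(drop=True)

    ac = windows["a_center"].to_numpy()
    sg = windows["sigma"].to_numpy()
    alpha0, beta0 = _loglinear_fit(ac, sg)
    fit_mode = "nls"
    try:
        import warnings

        with warnings.catch_warnings():
            # two windows determine the curve exactly; the (undefined)
            # covariance is not used
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, alpha, beta: alpha * np.exp(-beta * x),
                ac, sg, p0=[alpha0, beta0], maxfev=10000,
            )
        alpha, beta = float(popt[0]), float(popt[1])
        if not (alpha > 0 and np.isfinite(alpha) and np.isfinite(beta)):
            raise RuntimeError("non-finite or non-positive NLS solution")
    except RuntimeError:
        alpha, beta = alpha0, beta0
        fit_mode = "loglinear_fallback"
        logger.warning("exponential NLS failed; using log-linear fallback fit")
    logger.info(
        "variance model: alpha=%.4g beta=%.4g (%d windows of %d, mode=%s)",
        alpha, beta, len(windows), w, fit_mode,
    )
    return VarianceModel(alpha=alpha, beta=beta, windows=windows, fit_mode=fit_mode)


def score_sgrnas(
    a: pd.Series,
    m: pd.Series,
    model: VarianceModel,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Z-scores and normal-tail p-values for every guide under the fitted model.

    sigma_hat is evaluated at each guide's A (extrapolation beyond the
    control range allowed); p is the upper-tail probability of Z, doubled
    and folded if ``two_sided``.
    """
    if not a.index.equals(m.index):
        raise ValueError("A and M index different sgRNAs")
    av, mv = a.to_numpy(dtype=float), m.to_numpy(dtype=float)
    if not (np.isfinite(av).all() and np.isfinite(mv).all()):
        raise ValueError("non-finite A or M; apply a pseudocount upstream")
    lo, hi = model.windows["a_center"].iloc[0], model.windows["a_center"].iloc[-1]
    n_extra = int(np.sum((av < lo) | (av > hi)))
    if n_extra:
        logger.info(
            "sigma extrapolated outside control window range for %d sgRNAs", n_extra
        )
    sigma = np.asarray(model.predict_sigma(av), dtype=float)
    z = mv / sigma
    p = stats.norm.sf(z)
    if two_sided:
        p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"A": av, "M": mv, "sigma_hat": sigma, "Z": z, "p": p}, index=a.index
    )


def score_pair(
    normalized: pd.DataFrame,
    induced_sample: str,
    control_sample: str,
    model: VarianceModel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Convenience: MA statistics + scores for one induced/control sample pair."""
    a, m = compute_ma(
        normalized[induced_sample], normalized[control_sample], pseudocount
    )
    scores = score_sgrnas(a, m, model, two_sided=two_sided)
    scores.insert(0, "C_minus", normalized[control_sample].to_numpy(dtype=float))
    scores.insert(0, "C_plus", normalized[induced_sample].to_numpy(dtype=float))
    return scores
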