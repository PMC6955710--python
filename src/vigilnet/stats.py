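"""Group statistics: pairwise t-tests with Holm correction, electrode
t-maps, and the one-vs-all Delta-degree / Delta-RT correlation.

Within-group time-on-task contrasts (level 1 vs 2 vs 3) are paired
t-tests, since the same subjects contribute all levels; vigilance-vs-
enhancement contrasts are Welch two-sample tests, since the groups are
different participants.  Families of p-values are corrected by the
Bonferroni-Holm step-down procedure.  Per-electrode t-maps flag
electrodes with |t| >= 2.5 by default.  The brain-behavior stage forms,
for each enhancement subject, a weighted one-vs-all contrast against the
vigilance cohort (uniform weights: subject value minus the vigilance
mean) for both the connectivity degree and the reaction time, and
correlates the two deltas (Pearson).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "pairwise_ttest",
    "holm_correct",
    "electrode_tmap",
    "delta_one_vs_all",
    "correlate",
    "TMAP_THRESHOLD",
]

TMAP_THRESHOLD = 2.5  # |t| criterion for electrode significance maps
DEFAULT_ALPHA = 0.05


@dataclass
class ComparisonResult:
    contrast: str
    t: float
    p: float
    df: float
    paired: bool


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance)."""


def pairwise_ttest(
    a: np.ndarray, b: np.ndarray, paired: bool, contrast: str = ""
) -> ComparisonResult:
    """Two-sided t-test between two sets of per-subject values.

    Paired for within-group level contrasts; Welch two-sample for
    between-group contrasts.  Identical paired samples give t = 0,
    p = 1; a constant nonzero paired shift with zero variance is flagged
    as degenerate (the t statistic is infinite).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal sample sizes")
        d = a - b
        if np.allclose(d, d[0]):
            if np.isclose(d[0], 0.0):
                return ComparisonResult(contrast, 0.0, 1.0, a.size - 1, True)
            raise DegenerateTestError(
                f"constant nonzero paired difference ({d[0]:g}): t is infinite"
            )
        with warnings.catch_warnings():
            # near-constant differences trip scipy's precision warning;
            # the exact-degenerate cases are handled above
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sst.ttest_rel(a, b)
        df = a.size - 1
    else:
        if np.allclose(a, a[0]) and np.allclose(b, b[0]):
            if np.isclose(a[0], b[0]):
                return ComparisonResult(contrast, 0.0, 1.0, a.size + b.size - 2, False)
            raise DegenerateTestError("both groups constant: t is infinite")
        res = sst.ttest_ind(a, b, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = float(res.df)
    return ComparisonResult(contrast, float(t), float(p), float(df), paired)


def holm_correct(p_values, alpha: float = DEFAULT_ALPHA):
    """Bonferroni-Holm step-down correction.

    Sorts p-values ascending and rejects while p_(k) <= alpha/(m-k+1);
    adjusted p-values follow the standard monotone max construction.
    Returns ``(reject, p_adjusted)`` in the input order.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="holm")
    return reject, p_adj


def electrode_tmap(
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    paired: bool = False,
    threshold: float = TMAP_THRESHOLD,
):
    """Per-electrode t-statistics between two groups of subjects.

    Parameters
    ----------
    metric_a, metric_b : ndarray, shape (n_subjects, n_electrodes)
        Per-subject nodal metric (degree, strength, ...) per electrode.
    paired : bool
        Paired test (level contrasts within a group) or Welch
        (between-group).
    threshold : float
        |t| criterion for the significance mask (default 2.5).

    Returns
    -------
    t : ndarray (n_electrodes,), mask : ndarray of bool, p : ndarray
    """
    metric_a = np.atleast_2d(np.asarray(metric_a, dtype=float))
    metric_b = np.atleast_2d(np.asarray(metric_b, dtype=float))
    if metric_a.shape[1] != metric_b.shape[1]:
        raise ValueError("electrode sets differ between groups")
    with warnings.catch_warnings():
        # electrodes with identical metric values (e.g. saturated degree
        # counts) trip scipy's precision warning; their t is reported as
        # nan and excluded from the mask
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            t, p = sst.ttest_rel(metric_a, metric_b, axis=0)
        else:
            t, p = sst.ttest_ind(metric_a, metric_b, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    ok = np.isfinite(t)
    mask[ok] = np.abs(t[ok]) >= threshold
    return t, mask, p


def delta_one_vs_all(
    enh_values: np.ndarray,
    vig_values: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted one-vs-all contrast of each enhancement subject.

    Delta(e) = sum_v weight_v * (value_e - value_v): every vigilance
    (control) subject is subtracted from each enhancement subject and
    the differences combined by a weighted sum.  Uniform weights (the
    default) reduce to value_e - mean(vigilance values).  Positive
    deltas mean the enhancement subject exceeds the vigilance reference.
    """
    enh_values = np.asarray(enh_values, dtype=float)
    vig_values = np.asarray(vig_values, dtype=float)
    if enh_values.size == 0 or vig_values.size == 0:
        raise ValueError("both groups must be nonempty")
    if weights is None:
        weights = np.full(vig_values.shape[0], 1.0 / vig_values.shape[0])
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != vig_values.shape[0]:
        raise ValueError("one weight per vigilance subject required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    reference = weights @ vig_values
    return enh_values - reference


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateTestError("zero variance input: correlation undefined")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)
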