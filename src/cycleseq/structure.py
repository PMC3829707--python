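"""Global structure of the expression distribution.

Power-law fit of expression levels (continuous maximum likelihood with a
KS-minimizing lower cutoff), LOESS smoothing of replicate CV against
expression, classification of genes into the three expression groups
(low-noisy <5x, bulk 5-1000x, highly expressed >1000x), and the relation of
expression to evolutionary gene persistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from cycleseq.coverage import ExpressionMatrix

LOW_CUT = 5.0
HIGH_CUT = 1000.0


@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    n_tail: int
    ks_distance: float


def _alpha_mle(tail: np.ndarray, xmin: float) -> float:
    return 1.0 + len(tail) / np.sum(np.log(tail / xmin))


def _ks_distance(tail: np.ndarray, xmin: float, alpha: float) -> float:
    x = np.sort(tail)
    cdf_fit = 1.0 - (x / xmin) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, len(x) + 1) / len(x)
    ecdf_lo = np.arange(0, len(x)) / len(x)
    return float(
        max(np.max(np.abs(ecdf_hi - cdf_fit)), np.max(np.abs(ecdf_lo - cdf_fit)))
    )


def fit_power_law(
    values: np.ndarray,
    xmin: float | None = None,
    max_xmin_candidates: int = 100,
) -> PowerLawFit:
    """Continuous power-law fit by maximum likelihood.

    The tail exponent is alpha = 1 + n / sum(ln(x_i/xmin)) over the points
    at or above ``xmin``.  When ``xmin`` is not given it is chosen, in the
    Clauset-Shalizi-Newman manner, to minimize the Kolmogorov-Smirnov
    distance between the tail data and the fitted law; candidate cutoffs are
    the unique data values (subsampled to at most ``max_xmin_candidates``).
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]

    def fit_at(xm: float) -> PowerLawFit:
        tail = values[values >= xm]
        if len(tail) < 2:
            raise ValueError("fewer than 2 tail points above xmin")
        logsum = np.sum(np.log(tail / xm))
        if logsum <= 0:
            raise ValueError("all tail values equal xmin; exponent undefined")
        a = _alpha_mle(tail, xm)
        return PowerLawFit(a, float(xm), len(tail), _ks_distance(tail, xm, a))

    if xmin is not None:
        return fit_at(xmin)

    cands = np.unique(values)[:-1]  # need at least 2 points in the tail
    if len(cands) > max_xmin_candidates:
        idx = np.linspace(0, len(cands) - 1, max_xmin_candidates).astype(int)
        cands = cands[idx]
    best: PowerLawFit | None = None
    for xm in cands:
        tail = values[values >= xm]
        if len(tail) < 10:
            continue
        if np.sum(np.log(tail / xm)) <= 0:
            continue
        fit = fit_at(xm)
        if best is None or fit.ks_distance < best.ks_distance:
            best = fit
    if best is None:
        raise ValueError("no viable xmin with >= 10 tail points")
    return best


def sample_power_law(
    alpha: float, xmin: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF samples from a continuous power law p(x) ~ x^-alpha."""
    return xmin * (1 - rng.random(size)) ** (-1.0 / (alpha - 1.0))


# ---------------------------------------------------------------------------
# CV vs expression smoothing
# ---------------------------------------------------------------------------


def smooth_cv_vs_expression(
    expression: np.ndarray, cv: np.ndarray, span: float = 0.3
):
    """Tricube-weighted local linear regression of CV on log expression.

    Returns a callable evaluating the smoothed curve at arbitrary expression
    values (monotone linear interpolation between fit points, constant
    extrapolation beyond the data range).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    expression = np.asarray(expression, dtype=float)
    cv = np.asarray(cv, dtype=float)
    ok = expression > 0
    if ok.sum() < 20:
        raise ValueError("need >= 20 genes with positive expression")
    x = np.log(expression[ok])
    fitted = lowess(cv[ok], x, frac=span, it=1, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]

    def curve(e):
        e = np.asarray(e, dtype=float)
        return np.interp(np.log(np.maximum(e, np.exp(xs[0]))), xs, ys)

    return curve


# ---------------------------------------------------------------------------
# three expression groups
# ---------------------------------------------------------------------------


@dataclass
class ExpressionGroups:
    labels: pd.Series  # low | bulk | high per gene
    group_mean_cv: pd.Series
    low_cut: float
    high_cut: float

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def per_gene_cv(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene CV pooled over time points: the mean of the five
    per-time-point replicate CVs."""
    vals = matrix.values
    cvs = []
    for t in sorted({c[0] for c in vals.columns}):
        sub = vals[t]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cvs.append(np.where(mean > 0, sd / mean, 0.0))
    return pd.Series(np.mean(cvs, axis=0), index=vals.index, name="cv")


def classify_groups(
    matrix: ExpressionMatrix,
    low_cut: float = LOW_CUT,
    high_cut: float = HIGH_CUT,
) -> ExpressionGroups:
    """Classify genes into low / bulk / high expression groups.

    low: maximal expression over the time-point means < ``low_cut``;
    high: pooled mean over all samples > ``high_cut``; bulk otherwise.
    """
    tmeans = matrix.timepoint_means
    peak = tmeans.max(axis=1)
    pooled = matrix.values.mean(axis=1)
    labels = pd.Series("bulk", index=tmeans.index, name="group")
    labels[peak < low_cut] = "low"
    labels[(pooled > high_cut) & (peak >= low_cut)] = "high"

    cv = per_gene_cv(matrix)
    group_mean_cv = cv.groupby(labels).mean()
    return ExpressionGroups(labels, group_mean_cv, low_cut, high_cut)


# ---------------------------------------------------------------------------
# expression vs persistence
# ---------------------------------------------------------------------------


def compare_expression_by_conservation(
    expression: pd.Series,
    persistence_index: pd.Series,
    low_pi: float = 50.0,
    high_pi: float = 150.0,
) -> dict:
    """Compare expression between persistent (PI > high_pi) and less
    conserved (PI < low_pi) genes: group medians, Welch t and chi-square
    statistics.  Pure reporting; empty partitions are flagged."""
    pi = persistence_index.reindex(expression.index)
    persistent = expression[pi > high_pi]
    less = expression[pi < low_pi]
    out = {
        "n_persistent": int(len(persistent)),
        "n_less_conserved": int(len(less)),
        "median_persistent": float(persistent.median()) if len(persistent) else None,
        "median_less_conserved": float(less.median()) if len(less) else None,
        "flagged": len(persistent) == 0 or len(less) == 0,
    }
    if not out["flagged"]:
        if persistent.var() == 0 and less.var() == 0 and (
            persistent.median() == less.median()
        ):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(persistent, less, equal_var=False)
        out["t_statistic"] = float(t)
        out["t_pvalue"] = float(p)
        grand_median = float(expression.median())
        table = np.array(
            [
                [(persistent > grand_median).sum(), (persistent <= grand_median).sum()],
                [(less > grand_median).sum(), (less <= grand_median).sum()],
            ]
        )
        if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            chi2, chi_p = stats.chi2_contingency(table)[:2]
            out["chi2_statistic"] = float(chi2)
            out["chi2_pvalue"] = float(chi_p)
    return out
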