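"""Validation statistics for score-vs-mass tables.

Pearson correlation (reported as r and R^2 with a two-tailed p value),
empirical ROC analysis with trapezoid AUC and a Youden-index optimal
cutoff, and intraclass correlation (two-way model, absolute agreement,
single measures) for intra-observer / inter-study reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .core import ValidationError

#: Score-table methods recognised by :func:`evaluate_scores`.
SCORE_METHODS = ("US", "CT", "cIB", "US_volume", "CT_volume")


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------

def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r, R^2 = r^2 and the t-based two-tailed p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_r2 needs two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC curve with AUC and the Youden-optimal cutoff.

    ``thresholds`` are candidate cutoffs in increasing order (midpoints
    between adjacent observed values plus open ends); a case is called
    positive when its value is >= the cutoff.  ``auc`` is the trapezoid
    area, identical to the Mann-Whitney concordance probability.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def roc(values: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC of a score against binary labels (positives are high values).

    The optimal cutoff maximizes Youden's J = sensitivity + specificity - 1;
    ties are broken towards the higher cutoff, i.e. the higher specificity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.size != labels.size or values.size == 0:
        raise ValidationError("roc needs equal-length, non-empty values and labels")
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("roc needs both classes present")

    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    # Mann-Whitney concordance == trapezoid AUC of the empirical curve
    auc = (
        (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    ) / (pos.size * neg.size)

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # later index = higher cutoff = higher specificity
    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        optimal_cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
    )


def tertile_labels(mass_mg: Sequence[float], boundary_mg: float = 10.0) -> np.ndarray:
    """Binary labels separating low masses (<= boundary) from higher ones (>)."""
    return (np.asarray(mass_mg, dtype=float) > boundary_mg).astype(int)


# --------------------------------------------------------------------------
# Intraclass correlation
# --------------------------------------------------------------------------

def icc(
    measurements: np.ndarray,
    model: str = "ICC2",
) -> tuple[float, float, float]:
    """Single-measures intraclass correlation with its F-based 95% CI.

    ``measurements`` is a complete (subjects x sessions) matrix.  The
    default ``ICC2`` is the two-way, absolute-agreement, single-measures
    coefficient (the usual choice for intra-observer and test-retest
    designs; the point estimate is the same under random- and mixed-effects
    interpretations of the session factor).  ``ICC1`` and ``ICC3`` select
    the one-way and the consistency variants.  Perfect agreement returns an
    ICC of exactly 1 with an undefined (NaN) interval.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("icc needs a (subjects x sessions) matrix with at least 2 of each")
    if np.isnan(m).any():
        raise ValidationError("icc requires a complete matrix (no missing cells)")
    if model not in ("ICC1", "ICC2", "ICC3"):
        raise ValidationError(f"unknown ICC model {model!r}")
    n, k = m.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "session": np.tile(np.arange(k), n),
            "value": m.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero residual variance etc.
        table = pg.intraclass_corr(
            df, targets="subject", raters="session", ratings="value"
        ).set_index("Type")
    row = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}[model]
    est = float(table.loc[row, "ICC"])
    lo, hi = (float(v) for v in table.loc[row, "CI95"])
    return est, lo, hi


# --------------------------------------------------------------------------
# Score-table evaluation
# --------------------------------------------------------------------------

def evaluate_scores(
    table: pd.DataFrame,
    method: str,
    mass_col: str = "mass_mg",
    roc_boundary_mg: float = 10.0,
) -> dict:
    """Correlation-with-mass and ROC summary for one scoring method.

    ``table`` is the tidy score table (columns ``speck_id, mass_mg, method,
    value``); returns ``{r2, p, auc, cutoff, sensitivity, specificity}``
    with sensitivity/specificity as fractions in [0, 1].
    """
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValidationError(f"no rows for method {method!r}")
    masses = sub[mass_col].to_numpy(dtype=float)
    values = sub["value"].to_numpy(dtype=float)
    _, r2, p = pearson_r2(masses, values)
    res = roc(values, tertile_labels(masses, roc_boundary_mg))
    return {
        "method": method,
        "n": int(len(sub)),
        "r2": r2,
        "p": p,
        "auc": res.auc,
        "cutoff": res.optimal_cutoff,
        "sensitivity": res.sens_at_cutoff,
        "specificity": res.spec_at_cutoff,
    }
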