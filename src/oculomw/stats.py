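"""Condition contrasts, correlations, and questionnaire-feature matrices.

The workhorse is a two-sided Wilcoxon rank-sum test with normal
approximation, tie correction, and continuity correction, signed by the
first sample's rank-sum deviation. Pearson correlations use the two-sided
t-based p-value. Raw (uncorrected) p-values are reported by default,
mirroring the star-tier convention (* <= .05, ** <= .01, *** <= .001); a
Benjamini-Hochberg option is available for users who want FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import FEATURE_COLUMNS, QUESTION_IDS


@dataclass(frozen=True)
class TestResult:
    """Rank-sum contrast for one variable: z, p, group sizes, direction."""

    variable: str
    statistic_z: float
    p_value: float
    n1: int
    n2: int
    direction: int           # sign of median(x) - median(y); 0 on ties
    degenerate: bool = False

    @property
    def df(self) -> int:
        """Degrees of freedom as conventionally reported: n1 + n2 - 2."""
        return self.n1 + self.n2 - 2


@dataclass(frozen=True)
class CorrelationCell:
    question: str
    feature: str
    pearson_r: float
    p_value: float
    tier: str                # "ns", "*", "**", "***", or "undefined"
    n: int


def significance_tier(p: float) -> str:
    if not np.isfinite(p):
        return "undefined"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

def ranksum(x: Sequence[float], y: Sequence[float], variable: str = "") -> TestResult:
    """Two-sided Wilcoxon rank-sum test (normal approximation).

    Uses the average-rank treatment of ties with the matching variance
    correction and a 0.5 continuity correction; z is signed by the deviation
    of x's rank sum from its null expectation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(np.sum(ranks[:n1]))
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    direction = int(np.sign(np.median(x) - np.median(y)))
    if var <= 0:
        return TestResult(variable, 0.0, 1.0, n1, n2, direction, degenerate=True)
    d = w - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var) if d != 0 else 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(variable, float(z), p, n1, n2, direction)


def condition_contrasts(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    variables: Sequence[str] | None = None,
    label_a: str = "MW",
    label_b: str = "F",
) -> tuple[list[TestResult], pd.DataFrame]:
    """One rank-sum test per oculometric variable plus a mean +/- SD summary.

    NaN cells (epochs without blinks, for mean blink duration) are dropped
    per variable before testing.
    """
    if variables is None:
        variables = [c for c in FEATURE_COLUMNS if c in features_a.columns]
    missing = [c for c in variables if c not in features_b.columns]
    if missing:
        raise ValidationError(f"feature tables do not share column(s) {missing}")
    results = []
    rows = []
    for var in variables:
        a = features_a[var].to_numpy(dtype=float)
        b = features_b[var].to_numpy(dtype=float)
        res = ranksum(a, b, variable=var)
        results.append(res)
        rows.append(
            {
                "variable": var,
                f"mean_{label_a}": float(np.nanmean(a)),
                f"sd_{label_a}": float(np.nanstd(a, ddof=1)),
                f"mean_{label_b}": float(np.nanmean(b)),
                f"sd_{label_b}": float(np.nanstd(b, ddof=1)),
                "z": res.statistic_z,
                "p": res.p_value,
                "df": res.df,
                "direction": res.direction,
            }
        )
    return results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with two-sided t-based p; (nan, nan) when a sample
    has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need at least 3 paired finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def questionnaire_correlations(
    mw_epochs: Sequence,
    questions: Sequence[str] = QUESTION_IDS,
    features: Sequence[str] = FEATURE_COLUMNS,
    fdr: bool = False,
) -> tuple[list[CorrelationCell], pd.DataFrame]:
    """Pearson r/p for every (question, feature) pair over MW epochs.

    Epochs must carry questionnaires and feature vectors. A question that is
    constant across epochs yields undefined cells. With ``fdr=True``,
    Benjamini-Hochberg-adjusted p-values drive the tiers instead of raw ones.
    """
    epochs = [
        ep for ep in mw_epochs
        if ep.questionnaire is not None and ep.features is not None
    ]
    if len(epochs) < 3:
        raise ValidationError("need at least 3 MW epochs with questionnaires and features")
    cells: list[CorrelationCell] = []
    raw = []
    for q in questions:
        answers = np.asarray(
            [ep.questionnaire.answers.get(q, np.nan) for ep in epochs], dtype=float
        )
        for feat in features:
            values = np.asarray([ep.features[feat] for ep in epochs], dtype=float)
            keep = np.isfinite(answers) & np.isfinite(values)
            if keep.sum() < 3 or np.std(answers[keep]) == 0 or np.std(values[keep]) == 0:
                cells.append(CorrelationCell(q, feat, float("nan"), float("nan"),
                                             "undefined", int(keep.sum())))
                raw.append(np.nan)
                continue
            r, p = pearson_corr(answers[keep], values[keep])
            cells.append(CorrelationCell(q, feat, r, p, significance_tier(p),
                                         int(keep.sum())))
            raw.append(p)
    if fdr:
        finite = [i for i, p in enumerate(raw) if np.isfinite(p)]
        if finite:
            adj = _benjamini_hochberg(np.asarray([raw[i] for i in finite]))
            for i, p_adj in zip(finite, adj):
                c = cells[i]
                cells[i] = CorrelationCell(c.question, c.feature, c.pearson_r,
                                           c.p_value, significance_tier(p_adj), c.n)
    df = pd.DataFrame(
        [
            {"question": c.question, "feature": c.feature, "pearson_r": c.pearson_r,
             "p": c.p_value, "tier": c.tier, "n": c.n}
            for c in cells
        ]
    )
    return cells, df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
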