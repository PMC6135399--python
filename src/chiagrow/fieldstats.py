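"""The trial's statistical layer: one-way ANOVA, Duncan's multiple range
test, and Pearson correlation matrices among growth indices.

The split-plot irrigation design is simplified to per-time-point one-way
comparisons of treatment means, which is how significance marks are
reported on the growth curves; no multiple-testing correction is applied
across time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaTable:
    """One-way ANOVA decomposition (treatment / residual / total)."""

    source: list[str]
    df: list[int]
    sum_sq: list[float]
    mean_sq: list[float]
    f: float
    p: float

    def to_frame(self) -> pd.DataFrame:
        n = len(self.source)
        return pd.DataFrame(
            {
                "source": self.source,
                "df": self.df,
                "sum_sq": self.sum_sq,
                "mean_sq": self.mean_sq,
                "F": [self.f] + [np.nan] * (n - 1),
                "p": [self.p] + [np.nan] * (n - 1),
            }
        )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Between/within sum-of-squares decomposition with an F test.

    ``groups`` is a list of replicate-value lists, one per treatment; at
    least two groups with two replicates each are required.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least 2 replicates")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_within = len(allv) - len(arrs)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaTable(
        source=["treatment", "residual", "total"],
        df=[df_between, df_within, df_between + df_within],
        sum_sq=[float(ss_between), float(ss_within), float(ss_between + ss_within)],
        mean_sq=[float(ms_between), float(ms_within), np.nan],
        f=float(f),
        p=p,
    )


@dataclass
class DuncanResult:
    """Duncan multiple-range grouping of treatment means.

    ``means`` are sorted descending with ``labels`` aligned; ``letters``
    assigns each mean a string of group letters — means sharing any letter
    are not significantly different at ``alpha``.
    """

    labels: list[str]
    means: np.ndarray
    letters: list[str]
    alpha: float
    ms_error: float
    df_error: int
    critical_ranges: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"treatment": self.labels, "mean": self.means, "letters": self.letters}
        )


def _duncan_q(alpha: float, span: int, df: int) -> float:
    # Duncan's protection level for a span of p means: 1 - (1-alpha)^(p-1)
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, span, df))


def duncan_mrt(
    groups: Sequence[Sequence[float]] | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> DuncanResult:
    """Duncan's multiple range test on (near-)balanced groups.

    The error mean square and degrees of freedom come from the one-way
    ANOVA of the same groups.  The critical range for a span of p sorted
    means is q_p * sqrt(MSE/n), with q_p the studentized-range quantile at
    Duncan's protection level 1 - (1-alpha)^(p-1); letters are assigned by
    the standard sweep from the largest mean, extending non-significance
    over whole spans.
    """
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        data = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        if labels is None:
            labels = [f"g{i + 1}" for i in range(len(data))]
    table = one_way_anova(data)
    mse = table.mean_sq[1]
    df_err = table.df[1]
    if df_err < 1:
        raise ValueError("error degrees of freedom < 1")
    n_h = len(data) / sum(1.0 / len(g) for g in data)  # harmonic mean group size
    k = len(data)
    means = np.array([g.mean() for g in data])
    order = np.argsort(-means)
    sm = means[order]
    slabels = [labels[i] for i in order]
    ranges = {p: _duncan_q(alpha, p, df_err) * np.sqrt(mse / n_h) for p in range(2, k + 1)}

    # non-significance matrix by the range sweep (largest spans first);
    # once a span's extremes fail to differ, everything inside it is NS
    ns = np.eye(k, dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if ns[i, j]:
                continue
            if sm[i] - sm[j] <= ranges[span]:
                ns[i : j + 1, i : j + 1] = True

    # letters from maximal NS intervals over the sorted means
    letters = [""] * k
    next_letter = 0
    prev_end = -1
    for i in range(k):
        j = i
        while j + 1 < k and ns[i, j + 1]:
            j += 1
        if j > prev_end or (i == 0):
            ch = chr(ord("a") + next_letter)
            next_letter += 1
            for m in range(i, j + 1):
                letters[m] += ch
            prev_end = j
    return DuncanResult(
        labels=slabels,
        means=sm,
        letters=letters,
        alpha=alpha,
        ms_error=float(mse),
        df_error=int(df_err),
        critical_ranges=ranges,
    )


def correlation_matrix(
    series: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with per-pair p values.

    Returns ``(r, p)`` DataFrames over the named vectors (all of equal
    length >= 3).  Zero-variance vectors give NaN entries with a warning
    rather than a silent 0.
    """
    if isinstance(series, pd.DataFrame):
        df = series.astype(float)
    else:
        df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in series.items()})
    n = len(df)
    if n < 3:
        raise ValueError("need vectors of length >= 3")
    names = list(df.columns)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    degenerate = [c for c in names if df[c].std(ddof=0) == 0]
    if degenerate:
        warnings.warn(f"zero-variance series: {degenerate}; correlations set to NaN")
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            if a in degenerate or b in degenerate:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(df[a], df[b])
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    for c in degenerate:
        r.loc[c, c] = np.nan
        p.loc[c, c] = np.nan
    return r, p
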