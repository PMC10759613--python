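"""Two-stage group screening: Welch ANOVA omnibus, Games-Howell post-hoc,
bias-corrected Hedges g, and Pearson chi-square for categorical demographics.

The omnibus test is Welch's heteroscedastic one-way ANOVA (precision weights
w_i = n_i / s_i^2 and a Welch-Satterthwaite-style denominator df), appropriate
for groups unbalanced in size with unequal variances. Pairwise contrasts for
significant omnibus tests use the Games-Howell procedure: a Welch t statistic
per pair referred to the studentized-range distribution at q = |t|*sqrt(2)
with k groups and Welch-Satterthwaite df. Effect sizes are the small-sample
bias-corrected Hedges g with pooled SD and the conventional interpretation
bins (negligible < 0.01 ... huge >= 2.00).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateGroupError",
    "OmnibusResult",
    "PairwiseResult",
    "welch_anova",
    "welch_anova_many",
    "games_howell",
    "hedges_g_corrected",
    "hedges_g_from_summary",
    "interpret_effect",
    "screen_measures",
    "chi_square_categorical",
    "EFFECT_BINS",
]


class DegenerateGroupError(ValueError):
    """A group with n < 2 or zero variance cannot enter the screen."""


@dataclass
class OmnibusResult:
    F: float
    df1: float
    df2: float
    p: float
    group_summaries: list[dict] = field(default_factory=list)
    measure: str | None = None
    timepoint: str | None = None


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    t: float
    df_welch: float
    q_stat: float
    p_gh: float
    g: float
    g_bin: str
    measure: str | None = None
    timepoint: str | None = None


def _validated_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise DegenerateGroupError(f"group {i} has n={a.size} < 2")
        if a.std(ddof=1) == 0:
            raise DegenerateGroupError(f"group {i} has zero variance")
    return arrays


def welch_anova(groups, labels=None) -> OmnibusResult:
    """Welch's heteroscedastic one-way ANOVA.

    F* = [sum_i w_i (m_i - m_w)^2 / (k-1)] /
         [1 + 2(k-2)/(k^2-1) * A],  A = sum_i (1 - w_i/W)^2 / (n_i - 1),
    with w_i = n_i/s_i^2, W = sum w_i, m_w the precision-weighted grand mean;
    the reference distribution is F(k-1, (k^2-1)/(3A)).
    """
    arrays = _validated_groups(groups)
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    A = (((1.0 - w / W) ** 2) / (n - 1.0)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * A
    F = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * A)
    p = float(stats.f.sf(F, df1, df2))
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    summaries = [
        {
            "group": lab,
            "n": int(ni),
            "mean": float(mi),
            "sem": float(math.sqrt(vi / ni)),
        }
        for lab, ni, mi, vi in zip(labels, n, m, v)
    ]
    return OmnibusResult(F=float(F), df1=df1, df2=float(df2), p=p,
                         group_summaries=summaries)


def welch_anova_many(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch ANOVA over many parallel measures.

    ``groups`` is a list of (n_i, m) arrays — one per group, columns are
    independent measures. Returns (F, p) arrays of length m. No missing
    values are handled here; intended for simulation studies.
    """
    k = len(groups)
    n = np.array([g.shape[0] for g in groups], dtype=float)[:, None]
    m = np.stack([g.mean(axis=0) for g in groups])
    v = np.stack([g.var(axis=0, ddof=1) for g in groups])
    w = n / v
    W = w.sum(axis=0)
    mw = (w * m).sum(axis=0) / W
    A = (((1.0 - w / W) ** 2) / (n - 1.0)).sum(axis=0)
    num = (w * (m - mw) ** 2).sum(axis=0) / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * A
    F = num / den
    df2 = (k**2 - 1.0) / (3.0 * A)
    p = stats.f.sf(F, k - 1.0, df2)
    return F, p


# effect-size interpretation bins on |g| (half-open on the left edge)
EFFECT_BINS = (
    (0.01, "negligible"),
    (0.20, "very small"),
    (0.50, "small"),
    (0.80, "medium"),
    (1.20, "large"),
    (2.00, "very large"),
    (math.inf, "huge"),
)


def interpret_effect(g: float) -> str:
    """Map |g| to its interpretation bin."""
    if not math.isfinite(g):
        raise ValueError("effect size must be finite")
    mag = abs(g)
    for upper, label in EFFECT_BINS:
        if mag < upper:
            return label
    return "huge"


def hedges_g_corrected(x1, x2) -> float:
    """Bias-corrected standardized mean difference.

    g = J * (m1 - m2) / s_pooled with the classical pooled SD over
    df = n1 + n2 - 2 and small-sample factor J = 1 - 3/(4*df - 1).
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateGroupError("need n >= 2 in both samples")
    return hedges_g_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def hedges_g_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Hedges g from group summary statistics (means, SDs, sizes)."""
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        raise DegenerateGroupError("pooled SD is zero; effect size undefined")
    d = (mean1 - mean2) / math.sqrt(pooled_var)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(J * d)


def games_howell(groups, labels=None) -> list[PairwiseResult]:
    """Games-Howell pairwise comparisons for unequal variances and sizes.

    For each pair: t = (m_i - m_j)/sqrt(s_i^2/n_i + s_j^2/n_j), with
    Welch-Satterthwaite df; the adjusted p is the studentized-range tail
    probability at q = |t|*sqrt(2) with k groups.
    """
    arrays = _validated_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            vi, vj = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            se = math.sqrt(vi + vj)
            diff = a.mean() - b.mean()
            t = diff / se
            df = (vi + vj) ** 2 / (
                vi**2 / (a.size - 1) + vj**2 / (b.size - 1)
            )
            q = abs(t) * math.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df))
            p = min(max(p, 0.0), 1.0)
            g = hedges_g_corrected(a, b)
            out.append(
                PairwiseResult(
                    pair=(labels[i], labels[j]),
                    mean_diff=float(diff),
                    se=float(se),
                    t=float(t),
                    df_welch=float(df),
                    q_stat=float(q),
                    p_gh=p,
                    g=g,
                    g_bin=interpret_effect(g),
                )
            )
    return out


def chi_square_categorical(contingency) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2-D counts table."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class ScreenResult:
    """Omnibus and gated pairwise tables for one timepoint."""

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)
    n_omnibus_tests: int = 0
    n_pairwise_tests: int = 0


def screen_measures(
    cohort,
    timepoint: str,
    alpha_omnibus: float = 0.05,
    alpha_pairwise: float = 0.05,
    measures=None,
    groups=("HC", "GWI_L", "GWI_H"),
) -> ScreenResult:
    """Per-measure Welch omnibus screen with gated Games-Howell follow-up.

    ``cohort`` is a :class:`~gwinet.cohort.CohortTable` (or any object with a
    compatible ``group_values``). Missing values are dropped per measure, so
    group sizes may differ across measures; measures with a degenerate group
    or absent at the timepoint are skipped with a log entry. Pairwise rows are
    produced only for omnibus p < ``alpha_omnibus`` (the gate), with a
    ``significant`` flag at ``alpha_pairwise``.
    """
    if measures is None:
        measures = list(dict.fromkeys(cohort.data["measure"]))
    omnibus_rows = []
    pairwise_rows = []
    skipped = []
    n_pairwise = 0
    for measure in measures:
        by_group = cohort.group_values(measure, timepoint)
        present = [g for g in groups if g in by_group and by_group[g].size > 0]
        if len(present) < 2:
            skipped.append(
                {"measure": measure, "timepoint": timepoint,
                 "reason": "fewer than 2 groups with data"}
            )
            continue
        vals = [by_group[g] for g in present]
        try:
            omni = welch_anova(vals, labels=present)
        except DegenerateGroupError as err:
            skipped.append(
                {"measure": measure, "timepoint": timepoint,
                 "reason": f"degenerate: {err}"}
            )
            continue
        row = {
            "measure": measure, "timepoint": timepoint,
            "F": omni.F, "df1": omni.df1, "df2": omni.df2, "p": omni.p,
        }
        for s in omni.group_summaries:
            row[f"n_{s['group']}"] = s["n"]
            row[f"mean_{s['group']}"] = s["mean"]
            row[f"sem_{s['group']}"] = s["sem"]
        omnibus_rows.append(row)
        if omni.p < alpha_omnibus:
            for pw in games_howell(vals, labels=present):
                n_pairwise += 1
                pairwise_rows.append(
                    {
                        "measure": measure, "timepoint": timepoint,
                        "group_i": pw.pair[0], "group_j": pw.pair[1],
                        "mean_diff": pw.mean_diff, "se": pw.se, "t": pw.t,
                        "df_welch": pw.df_welch, "p_gh": pw.p_gh,
                        "g": pw.g, "g_bin": pw.g_bin,
                        "significant": pw.p_gh < alpha_pairwise,
                    }
                )
    return ScreenResult(
        omnibus=pd.DataFrame(omnibus_rows),
        pairwise=pd.DataFrame(pairwise_rows),
        skipped=skipped,
        n_omnibus_tests=len(omnibus_rows),
        n_pairwise_tests=n_pairwise,
    )
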