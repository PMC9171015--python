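"""Statistical layer for the screening endpoints.

The assay's endpoint tables are compared across exposure groups with:

* Pearson chi-square on group x category contingency tables (nuclear
  maturation, cleavage categories, blastocyst outcomes), followed by post hoc
  Bonferroni-corrected two-proportion z-tests,
* one-way ANOVA + Tukey HSD for approximately normal endpoints (steroid
  concentrations, mitochondrial ratio, expansion fold),
* Kruskal–Wallis + Dunn's pairwise z procedure (tie-corrected, Bonferroni)
  for outlier-prone endpoints such as apoptotic/necrotic rates.

All tests are two-sided with significance at alpha = 0.05 by default.  The
post hoc z statistic uses the pooled proportion:
``z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))``.  When the pooled proportion
is degenerate (0 or 1) the z statistic is undefined and Fisher's exact test
is reported instead, flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ParameterError


@dataclass
class PairwiseResult:
    group_i: str
    group_j: str
    statistic: float
    raw_p: float
    adjusted_p: float
    significant: bool
    category: str | None = None
    method: str = "z"


@dataclass
class StatReport:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    alpha: float = 0.05
    pairwise: list[PairwiseResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "warnings": self.warnings,
            "pairwise": [
                {
                    "group_i": p.group_i,
                    "group_j": p.group_j,
                    "category": p.category,
                    "statistic": p.statistic,
                    "raw_p": p.raw_p,
                    "adjusted_p": p.adjusted_p,
                    "significant": p.significant,
                    "method": p.method,
                }
                for p in self.pairwise
            ],
        }


def _check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise ParameterError("counts must be nonnegative")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ParameterError("need at least 2 groups and 2 categories")
    if (counts.sum(axis=1) == 0).any():
        raise ParameterError("every group needs a nonzero total")
    return counts


def contingency_chi_square(counts: pd.DataFrame, alpha: float = 0.05) -> StatReport:
    """Pearson chi-square of independence on a group x category table.

    Expected counts come from the row/column marginals; cells with expected
    count < 5 are flagged in the report warnings.  No Yates correction is
    applied (R x C default of the assay's original software).
    """
    counts = _check_counts(counts)
    chi2, p, dof, expected = stats.chi2_contingency(counts.values, correction=False)
    warnings = []
    n_low = int((expected < 5).sum())
    if n_low:
        warnings.append(f"{n_low} cells have expected count < 5; chi-square approximate")
    return StatReport(
        test_name="chi_square", statistic=float(chi2), df=float(dof),
        p_value=float(p), alpha=alpha, warnings=warnings,
    )


def posthoc_proportion_ztests(
    counts: pd.DataFrame,
    category: str,
    comparisons: str = "all-pairs",
    reference: str | None = None,
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Bonferroni-corrected pooled two-proportion z-tests between groups.

    ``comparisons`` is ``"all-pairs"`` (every group pair; mirrors
    column-proportion post hoc behaviour) or ``"vs-reference"`` (each group
    against ``reference``).  The Bonferroni factor is the number of
    comparisons actually performed.
    """
    counts = _check_counts(counts)
    if category not in counts.columns:
        raise ParameterError(f"unknown category {category!r}")
    groups = list(counts.index)
    if comparisons == "all-pairs":
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    elif comparisons == "vs-reference":
        if reference is None or reference not in groups:
            raise ParameterError("vs-reference mode needs a valid reference group")
        pairs = [(reference, g) for g in groups if g != reference]
    else:
        raise ParameterError(f"unknown comparison family {comparisons!r}")

    m = len(pairs)
    results = []
    for a, b in pairs:
        x1, n1 = float(counts.loc[a, category]), float(counts.loc[a].sum())
        x2, n2 = float(counts.loc[b, category]), float(counts.loc[b].sum())
        pooled = (x1 + x2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            # z undefined; exact-test fallback on the 2x2 for this pair
            table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
            _, raw_p = stats.fisher_exact(table)
            z = float("nan")
            method = "fisher"
        else:
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            z = (x1 / n1 - x2 / n2) / se
            raw_p = 2 * stats.norm.sf(abs(z))
            method = "z"
        adj_p = min(1.0, raw_p * m)
        results.append(
            PairwiseResult(
                group_i=a, group_j=b, statistic=float(z), raw_p=float(raw_p),
                adjusted_p=float(adj_p), significant=bool(adj_p < alpha),
                category=category, method=method,
            )
        )
    return results


def _check_groups(groups: Mapping[str, Sequence[float]], min_n: int) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    out = {}
    for g, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < min_n:
            raise ParameterError(f"group {g!r} needs >= {min_n} observations")
        out[g] = arr
    return out


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> StatReport:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Tukey's p-values come from the studentized-range distribution; being a
    single-step family procedure they are reported as both raw and adjusted.
    All values identical in every group gives an undefined 0/0 F ratio,
    reported as no effect (p = 1).
    """
    data = _check_groups(groups, min_n=2)
    k = len(data)
    n_total = sum(len(v) for v in data.values())
    values = np.concatenate(list(data.values()))
    labels = np.concatenate([[g] * len(v) for g, v in data.items()])

    if np.ptp(values) == 0:
        report = StatReport(
            test_name="anova", statistic=float("nan"),
            df=(float(k - 1), float(n_total - k)), p_value=1.0, alpha=alpha,
            warnings=["zero variance everywhere: F undefined, reported as no effect"],
        )
        report.pairwise = [
            PairwiseResult(a, b, 0.0, 1.0, 1.0, False, method="tukey")
            for i, a in enumerate(data) for b in list(data)[i + 1 :]
        ]
        return report

    f_stat, p = stats.f_oneway(*data.values())
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    uniq = [str(g) for g in tukey.groupsunique]
    pair_order = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    pairwise = []
    for (g1, g2), meandiff, p_adj, reject in zip(
        pair_order, tukey.meandiffs, tukey.pvalues, tukey.reject
    ):
        pairwise.append(
            PairwiseResult(
                group_i=g1, group_j=g2, statistic=float(meandiff),
                raw_p=float(p_adj), adjusted_p=float(p_adj),
                significant=bool(reject), method="tukey",
            )
        )
    return StatReport(
        test_name="anova", statistic=float(f_stat),
        df=(float(k - 1), float(n_total - k)), p_value=float(p),
        alpha=alpha, pairwise=pairwise,
    )


def kruskal_dunn(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> StatReport:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise z comparisons.

    Dunn's z for groups i, j uses the mean ranks of the pooled sample and the
    tie-corrected variance ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)``
    with ``T = sum(t^3 - t)`` over tie groups; two-sided p-values are
    Bonferroni-adjusted over all pairs.
    """
    data = _check_groups(groups, min_n=1)
    n_total = sum(len(v) for v in data.values())
    if n_total < 3:
        raise ParameterError("need N >= 3 observations in total")
    values = np.concatenate(list(data.values()))

    if np.ptp(values) == 0:
        return StatReport(
            test_name="kruskal_wallis", statistic=0.0,
            df=float(len(data) - 1), p_value=1.0, alpha=alpha,
            warnings=["all values tied: H = 0"],
        )

    h_stat, p = stats.kruskal(*data.values())

    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for g, v in data.items():
        mean_ranks[g] = ranks[start : start + len(v)].mean()
        start += len(v)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    glist = list(data)
    pairs = [(a, b) for i, a in enumerate(glist) for b in glist[i + 1 :]]
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1 / len(data[a]) + 1 / len(data[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw_p = 2 * stats.norm.sf(abs(z))
        adj_p = min(1.0, raw_p * m)
        pairwise.append(
            PairwiseResult(
                group_i=a, group_j=b, statistic=float(z), raw_p=float(raw_p),
                adjusted_p=float(adj_p), significant=bool(adj_p < alpha),
                method="dunn",
            )
        )
    return StatReport(
        test_name="kruskal_wallis", statistic=float(h_stat),
        df=float(len(data) - 1), p_value=float(p), alpha=alpha, pairwise=pairwise,
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def derive_rates(counts: pd.DataFrame, kind: str = "meiotic") -> pd.DataFrame:
    """Per-group category percentages from a contingency table.

    Returns a long table with both the full-precision percentage and the
    integer percent (half-up rounding, the convention of the assay's printed
    tables).  For blastocyst tables the group total is the number of
    presumptive zygotes entering culture, so percent = blastocysts per
    fertilized oocyte.
    """
    if kind not in {"meiotic", "cleavage", "blastocyst"}:
        raise ParameterError(f"unknown endpoint kind {kind!r}")
    counts = _check_counts(counts)
    totals = counts.sum(axis=1)
    rows = []
    for g in counts.index:
        for cat in counts.columns:
            pct = 100.0 * counts.loc[g, cat] / totals[g]
            rows.append(
                {
                    "group": g,
                    "category": cat,
                    "count": int(counts.loc[g, cat]),
                    "group_total": int(totals[g]),
                    "percent": float(pct),
                    "percent_int": int(_round_half_up(np.array(pct))),
                }
            )
    return pd.DataFrame(rows)
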