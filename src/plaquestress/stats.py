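"""Two-group cohort comparisons in the study's publication style.

Continuous variables are summarised as median (IQR width) and compared
with the Mann-Whitney U test (the cohort's variables are non-normal by the
Shapiro-Wilk gate, so no parametric branch exists). Categorical variables
are summarised as counts (%) and compared with a chi-square test (Fisher's
exact on 2x2 tables with small expected counts); ordinal score variables
are compared with Mann-Whitney on the scores. Missing values are dropped
per variable with the per-variable group sizes reported. P < 0.05 flags
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def normality_gate(values) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality test: (W, p, is_normal at alpha = 0.05).

    Requires n >= 3 and a non-constant sample (a constant sample has no
    defined W statistic and is rejected).
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p >= ALPHA)


def compare_continuous(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U of the first group, p).

    Exact enumeration when both groups have n <= 8 and no ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_categorical(counts, ordinal_scores: tuple | None = None) -> tuple[float, str]:
    """P-value for a 2 x k contingency table: (p, test name).

    ``counts`` is a (2, k) array of non-negative integers (groups x
    levels). Binary/nominal variables use chi-square, falling back to
    Fisher's exact for 2x2 tables with any expected count < 5. For ordinal
    variables pass ``ordinal_scores = (scores_a, scores_b)`` to use
    Mann-Whitney on the scores instead.
    """
    if ordinal_scores is not None:
        _, p = compare_continuous(*ordinal_scores)
        return p, "mannwhitney"
    t = np.asarray(counts)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if np.any(t < 0) or t.sum() == 0:
        raise ValueError("table must be non-negative with a positive total")
    nonzero_cols = t.sum(axis=0) > 0
    t = t[:, nonzero_cols]
    if t.shape[1] < 2:
        raise ValueError("degenerate table: fewer than two observed categories")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and expected.min() < 5:
        _, p = sps.fisher_exact(t)
        return float(p), "fisher"
    _, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(p), "chi2"


def median_iqr(values) -> tuple[float, float]:
    """Median and IQR width (Q3 - Q1, linear interpolation between order stats)."""
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------


@dataclass
class VariableSpec:
    """One table row request: variable name and its statistical kind."""

    name: str
    kind: str  # "continuous" | "binary" | "ordinal"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown variable kind '{self.kind}'")


def build_comparison_table(
    data: pd.DataFrame,
    variables: list[VariableSpec],
    grouping: str = "group",
    group_levels: tuple[str, str] = ("vulnerable", "stable"),
) -> pd.DataFrame:
    """Publication-style two-group comparison table.

    One block of rows per variable: continuous variables get a single
    median (IQR) row; binary variables a count (%) row; ordinal variables
    one count (%) row per observed level (Mann-Whitney p shared across the
    block). Missing values are dropped per variable, with per-variable
    group sizes in ``n_vulnerable`` / ``n_stable`` columns.
    """
    ga, gb = group_levels
    da = data[data[grouping] == ga]
    db = data[data[grouping] == gb]
    if len(da) == 0 or len(db) == 0:
        raise ValueError(f"both groups must be non-empty ({ga}: {len(da)}, {gb}: {len(db)})")

    rows = []
    for spec in variables:
        if spec.name not in data.columns:
            raise KeyError(f"unknown variable '{spec.name}'")
        xa = da[spec.name].dropna()
        xb = db[spec.name].dropna()
        na, nb = len(xa), len(xb)
        if spec.kind == "continuous":
            if np.ptp(np.concatenate([xa.to_numpy(float), xb.to_numpy(float)])) == 0:
                p = 1.0  # identical constant data: no evidence of a difference
            else:
                _, p = compare_continuous(xa, xb)
            ma, ia = median_iqr(xa)
            mb, ib = median_iqr(xb)
            rows.append(
                {
                    "variable": spec.name,
                    "level": "",
                    "summary_vulnerable": f"{ma:.2f} ({ia:.2f})",
                    "summary_stable": f"{mb:.2f} ({ib:.2f})",
                    "median_vulnerable": ma,
                    "iqr_vulnerable": ia,
                    "median_stable": mb,
                    "iqr_stable": ib,
                    "n_vulnerable": na,
                    "n_stable": nb,
                    "p_value": p,
                    "significant": p < ALPHA,
                }
            )
        else:
            levels = sorted(set(xa.unique()) | set(xb.unique()))
            counts = np.array(
                [[int((xa == lv).sum()) for lv in levels], [int((xb == lv).sum()) for lv in levels]]
            )
            if spec.kind == "ordinal":
                if np.ptp(np.concatenate([xa.to_numpy(float), xb.to_numpy(float)])) == 0:
                    p, test = 1.0, "mannwhitney"
                else:
                    p, test = compare_categorical(counts, ordinal_scores=(xa.astype(float), xb.astype(float)))
            else:
                if counts.shape[1] < 2:
                    p, test = 1.0, "degenerate"
                else:
                    p, test = compare_categorical(counts)
            if spec.kind == "binary" and len(levels) == 2:
                # single row for the positive level
                lv = levels[-1]
                ca, cb = counts[0, -1], counts[1, -1]
                rows.append(
                    {
                        "variable": spec.name,
                        "level": str(lv),
                        "summary_vulnerable": f"{ca} ({100 * ca / na:.0f}%)" if na else "0",
                        "summary_stable": f"{cb} ({100 * cb / nb:.0f}%)" if nb else "0",
                        "count_vulnerable": int(ca),
                        "count_stable": int(cb),
                        "n_vulnerable": na,
                        "n_stable": nb,
                        "p_value": p,
                        "significant": p < ALPHA,
                    }
                )
            else:
                for j, lv in enumerate(levels):
                    ca, cb = counts[0, j], counts[1, j]
                    rows.append(
                        {
                            "variable": spec.name,
                            "level": str(lv),
                            "summary_vulnerable": f"{ca} ({100 * ca / na:.0f}%)" if na else "0",
                            "summary_stable": f"{cb} ({100 * cb / nb:.0f}%)" if nb else "0",
                            "count_vulnerable": int(ca),
                            "count_stable": int(cb),
                            "n_vulnerable": na,
                            "n_stable": nb,
                            "p_value": p,
                            "significant": p < ALPHA,
                        }
                    )
    return pd.DataFrame(rows)
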