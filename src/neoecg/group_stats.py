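"""pH grouping, descriptive statistics, Kruskal-Wallis and Dunn-Sidak post hoc.

The acid-base partition follows neonatal blood-gas convention: acidosis
pH < 7.20, normal 7.20 <= pH <= 7.45, alkalosis pH > 7.45 (boundary values
fall to normal; configurable).

The omnibus test is the tie-corrected Kruskal-Wallis statistic

    H = [12 / (N (N+1))] * sum_i n_i (rbar_i - (N+1)/2)^2  /  C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

referred to a chi-square with k-1 df.  Pairwise follow-up uses Dunn's rank
z-statistics with the tie-corrected standard error

    SE_ij = sqrt([N(N+1)/12 - sum_t(t^3 - t)/(12 (N-1))] (1/n_i + 1/n_j)),

Sidak-adjusted p = 1 - (1-p)^m over the m = k(k-1)/2 pairs, and simultaneous
comparison intervals estimate +/- z_{1-a*/2} SE with a* = 1 - (1-alpha)^(1/m);
by construction "adjusted p < alpha" and "interval excludes 0" coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import STAT_FEATURES

__all__ = [
    "PH_GROUP_ORDER",
    "assign_group",
    "describe",
    "KWResult",
    "DunnComparison",
    "kruskal_wallis",
    "dunn_sidak",
    "run_feature_tests",
]

PH_GROUP_ORDER = ("acidosis", "normal", "alkalosis")
_PH_BOUNDS = (6.5, 8.0)


def assign_group(
    ph: float, boundaries: tuple[float, float] = (7.20, 7.45), boundary_to_normal: bool = True
) -> str:
    """Map a pH value to acidosis / normal / alkalosis."""
    if not (_PH_BOUNDS[0] <= ph <= _PH_BOUNDS[1]):
        raise ValueError(f"pH {ph} outside plausibility bounds {_PH_BOUNDS}")
    lo, hi = boundaries
    if boundary_to_normal:
        if ph < lo:
            return "acidosis"
        if ph > hi:
            return "alkalosis"
        return "normal"
    if ph <= lo:
        return "acidosis"
    if ph >= hi:
        return "alkalosis"
    return "normal"


def describe(values, labels, groups=None) -> pd.DataFrame:
    """Per-group n, median, IQR (interpolated type-7 quartiles), mean, plus
    the [0, 1]-scaled values used for symmetric box plots.

    ``groups`` optionally fixes the reported groups; one named there with no
    observations is reported with n = 0 and missing summaries.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(labels)})
    span = df["value"].max() - df["value"].min()
    df["scaled"] = (df["value"] - df["value"].min()) / span if span > 0 else 0.5
    rows = []
    for g in (groups if groups is not None else _group_order(df["group"])):
        v = df.loc[df["group"] == g, "value"].to_numpy()
        if v.size == 0:
            rows.append({"group": g, "n": 0, "median": np.nan, "q1": np.nan,
                         "q3": np.nan, "iqr": np.nan, "mean": np.nan})
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": g, "n": int(v.size), "median": med, "q1": q1,
                     "q3": q3, "iqr": q3 - q1, "mean": float(v.mean())})
    out = pd.DataFrame(rows)
    out.attrs["scaled"] = df
    return out


def _group_order(labels) -> list:
    seen = list(dict.fromkeys(labels))
    known = [g for g in PH_GROUP_ORDER if g in seen]
    return known + [g for g in seen if g not in known]


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis omnibus result (chi-square scale)."""

    h: float
    df: int
    p: float
    groups: list[dict] = field(default_factory=list)  # label, n, mean_rank
    tie_correction: float = 1.0

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class DunnComparison:
    """One Dunn-Sidak pairwise record with its simultaneous interval."""

    group_i: str
    group_j: str
    estimate: float  # mean rank i - mean rank j
    lower: float
    upper: float
    z: float
    p_raw: float
    p_adj: float
    significant: bool


def _ranks_and_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(values)  # midranks
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, tie_sum


def kruskal_wallis(values, labels) -> KWResult:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(labels))
    order = _group_order(labels)
    groups = [g for g in order if np.sum(labels == g) > 0]
    k, n_total = len(groups), values.size
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    if n_total < 3:
        raise ValueError("need at least 3 observations")
    ranks, tie_sum = _ranks_and_ties(values)
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    group_rows = []
    h_num = 0.0
    for g in groups:
        r = ranks[labels == g]
        group_rows.append({"label": str(g), "n": int(r.size), "mean_rank": float(r.mean())})
        h_num += r.size * (r.mean() - (n_total + 1) / 2.0) ** 2
    h_raw = 12.0 / (n_total * (n_total + 1)) * h_num
    if correction <= 0:  # every value identical
        return KWResult(h=0.0, df=k - 1, p=1.0, groups=group_rows, tie_correction=0.0)
    h = h_raw / correction
    return KWResult(
        h=float(h), df=k - 1, p=float(stats.chi2.sf(h, k - 1)),
        groups=group_rows, tie_correction=float(correction),
    )


def dunn_sidak(values, labels, alpha: float = 0.05) -> list[DunnComparison]:
    """All-pairs Dunn comparisons with Sidak multiplicity adjustment."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(labels))
    groups = [g for g in _group_order(labels) if np.sum(labels == g) > 0]
    k, n_total = len(groups), values.size
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    ranks, tie_sum = _ranks_and_ties(values)
    m = k * (k - 1) // 2
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    alpha_star = 1.0 - (1.0 - alpha) ** (1.0 / m)
    z_crit = float(stats.norm.ppf(1.0 - alpha_star / 2.0))
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            ri = ranks[labels == groups[a]]
            rj = ranks[labels == groups[b]]
            est = float(ri.mean() - rj.mean())
            se = float(np.sqrt(var_term * (1.0 / ri.size + 1.0 / rj.size)))
            z = est / se if se > 0 else 0.0
            p_raw = float(2.0 * stats.norm.sf(abs(z)))
            p_adj = float(-np.expm1(m * np.log1p(-min(p_raw, 1.0)))) if p_raw < 1 else 1.0
            out.append(
                DunnComparison(
                    group_i=str(groups[a]), group_j=str(groups[b]), estimate=est,
                    lower=est - z_crit * se, upper=est + z_crit * se,
                    z=float(z), p_raw=p_raw, p_adj=min(p_adj, 1.0),
                    significant=bool(p_adj < alpha),
                )
            )
    return out


def run_feature_tests(
    features: pd.DataFrame,
    alpha: float = 0.05,
    feature_columns: list[str] | None = None,
    force_posthoc: bool = False,
) -> dict:
    """Omnibus + conditional post hoc for every feature column.

    Post hoc pairs are computed only when the omnibus Kruskal-Wallis p < alpha
    (set ``force_posthoc`` to compute all pairs regardless).  Features whose
    column is entirely missing are skipped with a note.
    """
    import warnings

    cols = feature_columns or [c for c in STAT_FEATURES if c in features.columns]
    report: dict = {"alpha": alpha, "features": {}}
    labels_all = features["group"]
    if labels_all.nunique() < 2:
        report["note"] = "fewer than 2 non-empty groups; tests skipped"
        return report
    for col in cols:
        sub = features[[col, "group"]].dropna()
        if sub.empty:
            warnings.warn(f"feature {col!r} entirely missing; skipped")
            continue
        if sub["group"].nunique() < 2 or len(sub) < 3:
            report["features"][col] = {"note": "too few groups or observations"}
            continue
        kw = kruskal_wallis(sub[col].to_numpy(), sub["group"])
        entry = {
            "chi_square": kw.h, "df": kw.df, "p": kw.p,
            "tie_correction": kw.tie_correction, "groups": kw.groups,
            "significant": bool(kw.p < alpha), "pairs": [],
        }
        if kw.p < alpha or force_posthoc:
            for c in dunn_sidak(sub[col].to_numpy(), sub["group"], alpha=alpha):
                entry["pairs"].append(
                    {"i": c.group_i, "j": c.group_j, "estimate": c.estimate,
                     "lower": c.lower, "upper": c.upper, "z": c.z,
                     "p_raw": c.p_raw, "p_adj": c.p_adj, "significant": c.significant}
                )
        report["features"][col] = entry
    return report
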