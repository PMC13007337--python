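"""Group-level statistics: count normalization, Holm-Sidak t-test families,
mixed repeated-measures ANOVA with Sidak post-hoc comparisons, and SEM.

These are the three inferential procedures used for group comparisons in
developmental imaging datasets of this kind:

* families of unpaired two-sided Student t-tests (pooled variance) with
  step-down Holm-Sidak correction across the family;
* two-way mixed-design (between-group x within-stimulus repeated-measures)
  ANOVA with Sidak-adjusted per-level group comparisons, falling back to a
  REML mixed model when the repeated-measures design is unbalanced;
* per-sample count/volume normalization where group summaries are means of
  per-sample ratios, never ratios of group totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "AnovaResult",
    "normalize_counts",
    "summarize_ratios",
    "holm_sidak_adjust",
    "holm_sidak_family",
    "rm_anova_sidak",
    "sem",
]

ALPHA = 0.05


def sem(values) -> float:
    """Standard error of the mean: sample SD (ddof=1) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM requires at least 2 values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def normalize_counts(table) -> pd.DataFrame:
    """Per-sample count/volume ratios (cells per µm³).

    Accepts a :class:`~odorbulb.protocol.CountVolumeTable` or a DataFrame with
    its columns; returns the table with an added ``ratio`` column.
    """
    df = table.table if hasattr(table, "table") else table
    df = df.copy()
    if (df["ob_volume"] <= 0).any():
        bad = df.loc[df["ob_volume"] <= 0, "sample_id"].tolist()
        raise ValueError(f"ob_volume must be > 0; offenders: {bad}")
    df["ratio"] = df["cell_count"] / df["ob_volume"]
    return df


def summarize_ratios(normalized: pd.DataFrame) -> pd.DataFrame:
    """Group x timepoint mean and SEM of per-sample ratios."""
    def _sem(v):
        return sem(v) if len(v) > 1 else float("nan")

    return (
        normalized.groupby(["group", "timepoint_dpf"], sort=False)["ratio"]
        .agg(mean_ratio="mean", sem_ratio=_sem, n="count")
        .reset_index()
    )


@dataclass
class ComparisonResult:
    """One two-group comparison inside a corrected family."""

    label: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    df: int
    p_raw: float
    p_adj: float
    significant: bool
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "t": self.t,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "significant": self.significant,
            "error": self.error,
        }


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values for a family of k tests.

    With raw p-values sorted ascending, ``p_adj(i) = max_{j<=i}
    1 - (1 - p(j))^(k - j + 1)``, capped at 1, reported in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D array")
    return multipletests(p, alpha=ALPHA, method="holm-sidak")[1]


def holm_sidak_family(comparisons: dict | list) -> list[ComparisonResult]:
    """Family of unpaired two-sided Student t-tests with Holm-Sidak correction.

    ``comparisons`` maps labels to ``(group_a_values, group_b_values)`` pairs
    (dict, or list of ``(label, a, b)`` tuples).  Tests use pooled variance
    (df = n_a + n_b - 2).  A degenerate comparison (either group with n < 2,
    or both groups with zero variance and unequal means) is reported with an
    error message and excluded from the correction; the rest of the family
    is adjusted with k = number of valid comparisons.
    """
    if isinstance(comparisons, dict):
        items = [(k, a, b) for k, (a, b) in comparisons.items()]
    else:
        items = list(comparisons)
    if not items:
        raise ValueError("family must contain at least one comparison")

    results: list[ComparisonResult] = []
    raw_p: list[float] = []
    valid_idx: list[int] = []
    for i, (label, a, b) in enumerate(items):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        err = None
        t = df = p = float("nan")
        if a.size < 2 or b.size < 2:
            err = "each group needs n >= 2"
        elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
                df = a.size + b.size - 2
            else:
                err = "zero variance in both groups with unequal means"
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
            df = a.size + b.size - 2
        results.append(
            ComparisonResult(
                label=label,
                mean_a=float(a.mean()) if a.size else float("nan"),
                mean_b=float(b.mean()) if b.size else float("nan"),
                n_a=int(a.size),
                n_b=int(b.size),
                t=float(t),
                df=int(df) if np.isfinite(df) else 0,
                p_raw=float(p),
                p_adj=float("nan"),
                significant=False,
                error=err,
            )
        )
        if err is None:
            raw_p.append(float(p))
            valid_idx.append(i)

    if raw_p:
        adj = holm_sidak_adjust(raw_p)
        for i, pa in zip(valid_idx, adj):
            results[i].p_adj = float(pa)
            results[i].significant = bool(pa < ALPHA)
    return results


@dataclass
class AnovaResult:
    """Mixed-design ANOVA effects plus Sidak-adjusted per-level comparisons.

    ``effects`` columns: effect, F, df1, df2, p.  ``posthoc`` holds one
    :class:`ComparisonResult` per within-factor level (group comparisons,
    Sidak-adjusted with k = number of levels); empty unless there are exactly
    two groups.  ``method`` records the fitting route
    (``mixed_anova``, ``rm_anova`` or ``reml``).
    """

    effects: pd.DataFrame
    posthoc: list[ComparisonResult] = field(default_factory=list)
    method: str = "mixed_anova"


def _sidak(p: float, k: int) -> float:
    return float(min(1.0, 1.0 - (1.0 - p) ** k))


def _posthoc_by_level(data: pd.DataFrame) -> list[ComparisonResult]:
    """Per-level unpaired group t-tests, Sidak-adjusted across levels."""
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        return []
    ga, gb = groups
    levels = list(dict.fromkeys(data["level"]))
    k = len(levels)
    out = []
    for lev in levels:
        sub = data[data["level"] == lev]
        a = sub.loc[sub["group"] == ga, "value"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == gb, "value"].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
        padj = _sidak(float(p), k)
        out.append(
            ComparisonResult(
                label=str(lev),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                n_a=int(a.size),
                n_b=int(b.size),
                t=float(t),
                df=int(a.size + b.size - 2),
                p_raw=float(p),
                p_adj=padj,
                significant=padj < ALPHA,
            )
        )
    return out


def rm_anova_sidak(data: pd.DataFrame) -> AnovaResult:
    """Two-way mixed repeated-measures ANOVA with Sidak post-hoc group tests.

    ``data`` is long-format with columns ``subject, group, level, value``:
    ``group`` is the between-subjects factor, ``level`` the repeated
    within-subject factor.  Balanced designs (every subject measured at every
    level) use the classical mixed-design ANOVA; unbalanced designs fall back
    to a REML linear mixed model with subject as the random blocking factor
    (Wald F tests, Kenward-Roger-like dfs are not attempted).  With a single
    group the within effect comes from a one-way repeated-measures ANOVA.
    """
    required = {"subject", "group", "level", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    data = data.copy()
    values = data["value"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")

    n_groups = data["group"].nunique()
    subjects_per_group = data.groupby("group")["subject"].nunique()
    if (subjects_per_group < 2).any():
        raise ValueError("each group needs at least 2 subjects")

    # degenerate input: no variance anywhere
    if np.ptp(values) == 0:
        effects = pd.DataFrame(
            {
                "effect": ["group", "level", "interaction"],
                "F": [0.0, 0.0, 0.0],
                "df1": [np.nan] * 3,
                "df2": [np.nan] * 3,
                "p": [1.0, 1.0, 1.0],
            }
        )
        return AnovaResult(effects=effects, posthoc=_posthoc_by_level(data), method="degenerate")

    counts = data.groupby(["subject", "level"]).size().unstack(fill_value=0)
    levels = list(dict.fromkeys(data["level"]))
    balanced = counts.shape[1] == len(levels) and (counts.to_numpy() == 1).all()

    import pingouin as pg

    if n_groups == 1:
        aov = pg.rm_anova(data=data, dv="value", within="level", subject="subject", detailed=True)
        row = aov[aov["Source"] == "level"].iloc[0]
        effects = pd.DataFrame(
            {
                "effect": ["level"],
                "F": [float(row["F"])],
                "df1": [float(row["DF"])],
                "df2": [float(aov[aov["Source"] == "Error"].iloc[0]["DF"])],
                "p": [float(row["p_unc"])],
            }
        )
        return AnovaResult(effects=effects, posthoc=[], method="rm_anova")

    if balanced:
        aov = pg.mixed_anova(
            data=data, dv="value", within="level", subject="subject", between="group"
        )
        name_map = {"group": "group", "level": "level", "Interaction": "interaction"}
        rows = []
        for src, eff in name_map.items():
            r = aov[aov["Source"] == src]
            if r.empty:
                continue
            r = r.iloc[0]
            rows.append(
                {
                    "effect": eff,
                    "F": float(r["F"]),
                    "df1": float(r["DF1"]),
                    "df2": float(r["DF2"]),
                    "p": float(r["p_unc"]),
                }
            )
        effects = pd.DataFrame(rows)
        method = "mixed_anova"
    else:
        effects = _reml_mixed_model(data)
        method = "reml"

    return AnovaResult(effects=effects, posthoc=_posthoc_by_level(data), method=method)


def _reml_mixed_model(data: pd.DataFrame) -> pd.DataFrame:
    """REML linear mixed model (random subject intercept) with Wald F tests.

    Used when the repeated-measures design has missing cells; approximate
    denominator dfs come from the residual df of the fixed-effects design.
    """
    import statsmodels.formula.api as smf

    df = data.rename(columns={"group": "grp", "level": "lev", "value": "val"}).copy()
    model = smf.mixedlm("val ~ C(grp) * C(lev)", df, groups=df["subject"])
    fit = model.fit(reml=True)
    wald = fit.wald_test_terms(scalar=True)
    table = wald.table
    rows = []
    resid_df = len(df) - fit.k_fe
    for term, eff in (("C(grp)", "group"), ("C(lev)", "level"), ("C(grp):C(lev)", "interaction")):
        if term not in table.index:
            continue
        r = table.loc[term]
        stat = float(r["statistic"])
        df1 = float(r["df_constraint"])
        rows.append(
            {
                "effect": eff,
                "F": stat / df1 if df1 > 0 else float("nan"),
                "df1": df1,
                "df2": float(resid_df),
                "p": float(sps.chi2.sf(stat, df1)) if df1 > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
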