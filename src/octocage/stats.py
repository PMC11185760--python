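"""Statistical screening of behavioral and gait parameters.

The screening layer mirrors common practice for this kind of assay:
a Shapiro-Wilk normality gate, unpaired two-sample Wilcoxon (rank-sum /
Mann-Whitney) screens per parameter and age timepoint, Kruskal-Wallis
with Dunn's two-sided post-hoc z-tests for syllable statistics, and
two-way ANOVA with Tukey HSD for gait parameters.  Raw p-values are
compared to alpha = 0.05 by default; a Benjamini-Hochberg option exists
but is off by default, matching the per-parameter screening convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------


def normality_gate(sample, alpha: float = ALPHA) -> dict:
    """Shapiro-Wilk normality check for one group.

    Returns {"p", "normal", "degenerate"}; with n < 3 both p and normal
    are the NaN sentinel, and a constant sample is flagged degenerate
    (not normal).
    """
    x = np.asarray(sample, float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        return {"p": np.nan, "normal": np.nan, "degenerate": False}
    if np.ptp(x) == 0:
        return {"p": 0.0, "normal": False, "degenerate": True}
    with np.errstate(all="ignore"):
        stat = sps.shapiro(x)
    return {"p": float(stat.pvalue), "normal": bool(stat.pvalue >= alpha),
            "degenerate": False}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    parameter: str
    timepoint: str
    statistic: float
    p: float
    direction: str           # increase/decrease in the test group vs control
    significant: bool
    n_test: int
    n_control: int


def rank_sum_test(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided unpaired two-sample Wilcoxon (Mann-Whitney U) test.

    The exact null distribution is used for small tie-free samples and
    the tie-corrected normal approximation otherwise (scipy's "auto"
    policy).  Returns (U statistic of the first sample, p).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_screen(
    table: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = ALPHA,
    test_group: str = "AD",
    control_group: str = "WT",
    treatment: str = "none",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-parameter, per-timepoint rank-sum screen of test vs control.

    ``labels`` carries genotype / age / treatment per mouse (same index
    as ``table``); only untreated animals enter the comparison by
    default.  NaN parameter values are dropped pairwise.  ``adjust``
    may be "bh" for Benjamini-Hochberg within each timepoint (off by
    default: raw p < alpha per parameter).
    """
    results = []
    for age in labels["age"].unique():
        sel = labels["age"] == age
        if "treatment" in labels:
            sel &= labels["treatment"] == treatment
        test_idx = labels.index[sel & (labels["genotype"] == test_group)]
        ctrl_idx = labels.index[sel & (labels["genotype"] == control_group)]
        if len(test_idx) == 0 or len(ctrl_idx) == 0:
            raise ValueError(f"empty group at timepoint {age!r}")
        rows = []
        for param in table.columns:
            a = table.loc[test_idx, param].dropna().to_numpy()
            b = table.loc[ctrl_idx, param].dropna().to_numpy()
            if len(a) == 0 or len(b) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0
                                              and a[0] == b[0]):
                rows.append((param, np.nan, np.nan, "none", len(a), len(b)))
                continue
            stat, p = rank_sum_test(a, b)
            diff = np.median(a) - np.median(b)
            direction = "increase" if diff > 0 else "decrease" if diff < 0 else "none"
            rows.append((param, stat, p, direction, len(a), len(b)))
        pvals = np.array([r[2] for r in rows], float)
        if adjust == "bh":
            from statsmodels.stats.multitest import multipletests

            ok = np.isfinite(pvals)
            adj = np.full_like(pvals, np.nan)
            if ok.any():
                adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            pvals = adj
        for (param, stat, p_raw, direction, na, nb), p_eff in zip(rows, pvals):
            results.append(
                ScreenResult(
                    parameter=param,
                    timepoint=str(age),
                    statistic=stat,
                    p=float(p_eff) if np.isfinite(p_eff) else np.nan,
                    direction=direction,
                    significant=bool(np.isfinite(p_eff) and p_eff < alpha),
                    n_test=na,
                    n_control=nb,
                )
            )
    return pd.DataFrame([vars(r) for r in results])


def screen_count(results: pd.DataFrame, parameters=None) -> int:
    """Number of parameters significant in at least one timepoint."""
    sel = results[results["significant"]]
    if parameters is not None:
        sel = sel[sel["parameter"].isin(set(parameters))]
    return int(sel["parameter"].nunique())


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def kruskal_dunn(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> dict:
    """Kruskal-Wallis omnibus test with Dunn's two-sided post-hoc tests.

    ``samples`` maps group name -> values.  Returns the tie-corrected
    omnibus statistic and p, and a DataFrame of pairwise Dunn z-tests
    on mean ranks (unadjusted two-sided p-values).  Degenerate input
    (all values identical) is flagged instead of tested.
    """
    names = list(samples)
    if len(names) < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 groups")
    arrays = []
    for name in names:
        x = np.asarray(samples[name], float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays.append(x)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"statistic": np.nan, "p": np.nan, "degenerate": True,
                "pairwise": None}
    stat, p = sps.kruskal(*arrays)

    # Dunn: z-tests on mean ranks with tie correction
    ranks = sps.rankdata(pooled)
    sizes = [len(x) for x in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {
        name: ranks[bounds[i] : bounds[i + 1]].mean() for i, name in enumerate(names)
    }
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_pair = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group_a": a, "group_b": b, "z": float(z), "p": float(p_pair),
             "significant": bool(p_pair < alpha)}
        )
    return {
        "statistic": float(stat),
        "p": float(p),
        "degenerate": False,
        "pairwise": pd.DataFrame(rows),
    }


# ---------------------------------------------------------------------------
# two-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------


def anova2_tukey(
    values,
    factor_a,
    factor_b,
    alpha: float = ALPHA,
    factor_names: tuple[str, str] = ("genotype", "age"),
) -> dict:
    """Two-way ANOVA (main effects + interaction) with conditional Tukey.

    Tukey's HSD on the crossed cell means is run when the interaction
    is significant at ``alpha`` and recorded as skipped otherwise.
    Returns {"anova": table, "interaction_p", "tukey", "tukey_run"}.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    na, nb = factor_names
    df = pd.DataFrame({"value": np.asarray(values, float),
                       na: list(factor_a), nb: list(factor_b)})
    df = df.dropna()
    cells = df.groupby([na, nb]).size()
    n_a = df[na].nunique()
    n_b = df[nb].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("both factors need at least 2 levels")
    if len(cells) < n_a * n_b or (cells == 0).any():
        raise ValueError("every factor-level cell must be non-empty")
    model = smf.ols(f"value ~ C({na}) * C({nb})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter_key = f"C({na}):C({nb})"
    interaction_p = float(table.loc[inter_key, "PR(>F)"])
    tukey = None
    run = interaction_p < alpha
    if run:
        cell = df[na].astype(str) + ":" + df[nb].astype(str)
        tukey = pairwise_tukeyhsd(df["value"].to_numpy(), cell.to_numpy(), alpha=alpha)
    return {
        "anova": table,
        "interaction_p": interaction_p,
        "tukey": tukey,
        "tukey_run": run,
    }
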