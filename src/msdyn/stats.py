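"""Two-group inference on microstate parameters.

Independent-sample t-tests (pooled, Welch, or Levene-gated automatic
choice) compare each temporal parameter and each transition cell between
groups; Bonferroni families divide alpha by the number of states (4) or
the number of ordered transitions (12). Effect sizes are Cohen's d from
the t statistic, with the small-sample (Hedges) correction available. A
summary-statistics mode computes the same tests directly from printed
group means, SDs and sizes, so published tables can be recomputed without
raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "two_sample_t",
    "t_from_summary",
    "effect_size",
    "bonferroni_family",
    "correlate",
    "compare_parameters",
    "compare_transitions",
    "correlate_with_scores",
]

FAMILY_ALPHA = 0.05
FAMILY_SIZES = {"params": 4, "transitions": 12, "single": 1}


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str  # "pooled" or "welch" (as actually used)
    mean1: float | None = None
    mean2: float | None = None
    n1: int | None = None
    n2: int | None = None

    def cohens_d(self, corrected: bool = False) -> float:
        return effect_size(self.t, self.n1, self.n2, corrected=corrected)


def _moments_t(m1, s1, n1, m2, s2, n2, variant) -> tuple[float, float]:
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        raise ZeroDivisionError("zero variance in both groups: t undefined")
    return (m1 - m2) / se, df


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Independent-sample t from group means, SDs and sizes.

    ``variant`` must be explicit here ("pooled" or "welch"): the automatic
    Levene gate needs raw values.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    t, df = _moments_t(m1, s1, n1, m2, s2, n2, variant)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), variant,
                       m1, m2, int(n1), int(n2))


def two_sample_t(
    x: np.ndarray, y: np.ndarray, variant: str = "auto",
    levene_alpha: float = 0.05,
) -> TTestResult:
    """Independent-sample t-test on raw values.

    ``variant="auto"`` runs Levene's test and switches to Welch when the
    equal-variance hypothesis is rejected at ``levene_alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    used = variant
    if variant == "auto":
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise ZeroDivisionError("zero variance in both groups: t undefined")
        _, p_lev = sps.levene(x, y)
        used = "welch" if p_lev < levene_alpha else "pooled"
    return t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size,
        variant=used,
    )


def effect_size(t: float, n1: int, n2: int, corrected: bool = False) -> float:
    """Cohen's d recovered from t: d = t * sqrt(1/n1 + 1/n2).

    ``corrected=True`` applies the small-sample (Hedges) factor
    ``1 - 3 / (4 * (n1 + n2 - 2) - 1)``.
    """
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    if corrected:
        df = n1 + n2 - 2
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(d)


def bonferroni_family(
    results: pd.DataFrame, family: str = "params", alpha: float = FAMILY_ALPHA
) -> pd.DataFrame:
    """Flag significance against the family-wise threshold alpha / m.

    ``family`` is "params" (m=4), "transitions" (m=12) or "single" (m=1);
    the comparison is a strict inequality p < alpha/m.
    """
    m = FAMILY_SIZES[family]
    out = results.copy()
    out["family"] = family
    out["alpha_threshold"] = alpha / m
    out["significant"] = out["p"] < alpha / m
    return out


def correlate(scores: np.ndarray, feature: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-tailed p (t-transform), n >= 3 required."""
    scores = np.asarray(scores, dtype=float)
    feature = np.asarray(feature, dtype=float)
    if scores.size != feature.size or scores.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if scores.std() == 0 or feature.std() == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    r, p = sps.pearsonr(scores, feature)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Table-level drivers


def _compare_rows(
    df: pd.DataFrame, value_col: str, by: list[str], design: pd.DataFrame,
    variant: str, family: str,
) -> pd.DataFrame:
    merged = df.merge(design[["subject_id", "group"]], on="subject_id")
    rows = []
    for keys, sub in merged.groupby(by, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        x = sub.loc[sub["group"] == "high", value_col].dropna().to_numpy()
        y = sub.loc[sub["group"] == "low", value_col].dropna().to_numpy()
        row = dict(zip(by, keys))
        row.update({"n_high": x.size, "n_low": y.size})
        if x.size < 2 or y.size < 2:
            row.update({"t": np.nan, "df": np.nan, "p": np.nan,
                        "variant": "insufficient-n", "low_n": True})
            rows.append(row)
            continue
        try:
            res = two_sample_t(x, y, variant=variant)
        except ZeroDivisionError:
            row.update({"t": np.nan, "df": np.nan, "p": np.nan,
                        "variant": "degenerate", "low_n": False})
            rows.append(row)
            continue
        row.update(
            {
                "mean_high": x.mean(), "sd_high": x.std(ddof=1),
                "mean_low": y.mean(), "sd_low": y.std(ddof=1),
                "t": res.t, "df": res.df, "p": res.p, "variant": res.variant,
                "cohens_d": res.cohens_d(corrected=False),
                "cohens_d_corrected": res.cohens_d(corrected=True),
                "low_n": x.size < 5 or y.size < 5,
            }
        )
        rows.append(row)
    return bonferroni_family(pd.DataFrame(rows), family=family)


def compare_parameters(
    params: pd.DataFrame, design: pd.DataFrame, variant: str = "auto"
) -> pd.DataFrame:
    """Per-state, per-measure group comparisons with the alpha/4 family.

    ``params`` is tidy: subject_id, state, duration_ms, occurrence_hz,
    coverage_pct, gev. Each measure is its own 4-comparison family (one
    test per state), matching the per-parameter Bonferroni convention.
    """
    blocks = []
    for measure in ("duration_ms", "occurrence_hz", "coverage_pct"):
        b = _compare_rows(params, measure, ["state"], design, variant, "params")
        b.insert(0, "measure", measure)
        blocks.append(b)
    gev_df = params[["subject_id", "gev"]].drop_duplicates("subject_id")
    gev_df = gev_df.assign(state="all")
    g = _compare_rows(gev_df, "gev", ["state"], design, variant, "single")
    g.insert(0, "measure", "gev")
    blocks.append(g)
    return pd.concat(blocks, ignore_index=True)


def compare_transitions(
    transitions: pd.DataFrame, design: pd.DataFrame, variant: str = "auto"
) -> pd.DataFrame:
    """Group comparison of the 12 ordered transition cells (alpha/12)."""
    return _compare_rows(
        transitions, "probability", ["from", "to"], design, variant,
        "transitions",
    )


def correlate_with_scores(
    features: pd.DataFrame,
    design: pd.DataFrame,
    feature_cols: list[str],
    score_cols: tuple[str, ...] = ("lsas_total", "lsas_fear", "lsas_avoidance"),
    fdr: bool = False,
) -> pd.DataFrame:
    """Within-group Pearson correlations of scale scores with features.

    Run separately inside each group (pooling the groups would inflate r
    through the group mean difference). Uncorrected by default, mirroring
    exploratory practice; ``fdr=True`` adds Benjamini-Hochberg q-values.
    """
    merged = features.merge(design, on="subject_id")
    rows = []
    for group, sub in merged.groupby("group", sort=False):
        for fc in feature_cols:
            for sc in score_cols:
                ok = sub[[fc, sc]].dropna()
                if len(ok) < 3:
                    continue
                try:
                    r, p = correlate(ok[sc].to_numpy(), ok[fc].to_numpy())
                except ZeroDivisionError:
                    continue
                rows.append(
                    {"group": group, "feature": fc, "score": sc,
                     "n": len(ok), "r": r, "p": p}
                )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
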