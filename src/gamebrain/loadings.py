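"""Canonical cross-loadings and their per-metric-class summaries.

A cross-loading is the Pearson correlation of an original residualized
variable with another set's canonical variate (in contrast to a loading,
which uses the variable's own set). Brain variables are loaded against the
games variate; game variables are loaded against each brain variate and
averaged across the three brain sets (the per-set values are retained).

Summaries per metric class report the mean loading across regions, a 95%
normal-approximation confidence interval (mean +/- 1.96 sd/sqrt(m)), and
the percentage of regions with positive and negative loadings (zeros count
as positive). Subcortical volumes are additionally split into ventricle and
corpus-callosum subclasses so those headline summaries can be read off
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureSet

__all__ = [
    "cross_loadings",
    "summarize_metric_class",
    "top_fraction_map",
    "loading_correlation",
    "CrossLoadingReport",
    "build_report",
]


def cross_loadings(variables: pd.DataFrame, variate: pd.Series | np.ndarray) -> pd.Series:
    """Pearson correlation of every column with the designated cross variate.

    Constant columns have no defined correlation and come back as NaN
    (flagged by the caller, excluded from summaries).
    """
    v = np.asarray(variate, dtype=float)
    if v.std() == 0:
        raise ValueError("variate is constant")
    X = variables.to_numpy(float)
    Xc = X - X.mean(axis=0)
    vc = v - v.mean()
    sd = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ vc) / (len(v) * sd * vc.std())
    r[sd == 0] = np.nan
    return pd.Series(np.clip(r, -1.0, 1.0), index=variables.columns)


@dataclass
class ClassSummary:
    metric_class: str
    mean: float
    ci_low: float
    ci_high: float
    pct_positive: float
    pct_negative: float
    n_regions: int

    def as_tuple(self):
        return (self.metric_class, self.mean, self.ci_low, self.ci_high,
                self.pct_positive, self.pct_negative, self.n_regions)


def summarize_metric_class(loadings: pd.Series | np.ndarray,
                           name: str = "") -> ClassSummary:
    """Mean, 95% CI (normal approximation over regions) and sign percentages
    for one metric class. Loadings >= 0 count as positive."""
    x = np.asarray(loadings, dtype=float)
    x = x[~np.isnan(x)]
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 regions to summarize")
    mean = float(x.mean())
    half = 1.96 * float(x.std(ddof=1)) / np.sqrt(m)
    return ClassSummary(
        metric_class=name,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        pct_positive=100.0 * float((x >= 0).mean()),
        pct_negative=100.0 * float((x < 0).mean()),
        n_regions=m,
    )


def top_fraction_map(loadings: pd.Series, fraction: float = 0.30) -> pd.Series:
    """Boolean mask of the regions ranking in the top ``fraction`` by loading
    magnitude in the class's dominant sign direction."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    x = loadings.dropna()
    dominant = 1.0 if float(x.mean()) >= 0 else -1.0
    k = ceil(fraction * len(x))
    ranked = (dominant * x).sort_values(ascending=False)
    top = set(ranked.index[:k])
    return pd.Series([i in top for i in loadings.index], index=loadings.index)


def loading_correlation(a: pd.Series | np.ndarray,
                        b: pd.Series | np.ndarray) -> tuple[float, tuple[float, float]]:
    """Pearson correlation between two loading vectors over the same regions,
    with a 95% Fisher-z confidence interval (m - 3 degrees)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("loading vectors must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant loading vector")
    r = float(stats.pearsonr(x, y).statistic)
    m = x.size
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = 1.96 / np.sqrt(m - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return r, (float(lo), float(hi))


# ---------------------------------------------------------------------------


def _volume_subclass(region: str) -> str:
    if "Vent" in region and "VentralDC" not in region:
        return "ventricle"
    if region.startswith("CC_"):
        return "corpus_callosum"
    return "subcortical_volume"


@dataclass
class CrossLoadingReport:
    """Per-variable cross-loadings plus class-level summaries and maps."""

    brain_loadings: pd.DataFrame  # columns: loading, metric_class, region, hemisphere
    game_loadings: pd.DataFrame  # per-variable mean + per-brain-set loadings
    class_summaries: pd.DataFrame
    top_maps: dict[str, pd.Series]
    myelin_thickness_r: float
    myelin_thickness_ci: tuple[float, float]

    def summary(self) -> str:
        lines = ["Canonical cross-loadings by metric class",
                 "=" * 72,
                 f"{'class':<24}{'mean':>8}{'95% CI':>18}{'% pos':>8}{'% neg':>8}"]
        for _, s in self.class_summaries.iterrows():
            lines.append(
                f"{s['metric_class']:<24}{s['mean']:>8.3f}"
                f"  [{s['ci_low']:+.3f}, {s['ci_high']:+.3f}]"
                f"{s['pct_positive']:>8.0f}{s['pct_negative']:>8.0f}"
            )
        lines.append(
            f"myelin-thickness loading correlation: r = "
            f"{self.myelin_thickness_r:+.3f} "
            f"[{self.myelin_thickness_ci[0]:+.3f}, {self.myelin_thickness_ci[1]:+.3f}]"
        )
        return "\n".join(lines)


def build_report(
    blocks: dict[str, FeatureSet],
    variates: pd.DataFrame,
    *,
    top_fraction: float = 0.30,
) -> CrossLoadingReport:
    """Assemble the full cross-loading report from the residualized blocks
    and the fitted canonical variates (one column per set)."""
    games_variate = variates["games"]
    brain_sets = [c for c in variates.columns if c != "games"]

    rows = []
    for name in ("structure", "functional_connectivity", "structural_connectivity"):
        fs = blocks[name]
        r = cross_loadings(fs.data, games_variate)
        meta = fs.metadata.copy()
        meta["loading"] = r
        # split volumes into ventricle / corpus-callosum subclasses
        vol = meta["metric_class"] == "subcortical_volume"
        meta.loc[vol, "metric_class"] = [
            _volume_subclass(rg) for rg in meta.loc[vol, "region"]
        ]
        rows.append(meta)
    brain = pd.concat(rows)

    games = blocks["games"]
    per_set = {bs: cross_loadings(games.data, variates[bs]) for bs in brain_sets}
    game_df = pd.DataFrame(per_set)
    game_df.insert(0, "loading", game_df.mean(axis=1))
    game_df["direction"] = games.metadata["direction"]

    summaries = []
    for cls, grp in brain.groupby("metric_class", sort=True):
        vals = grp["loading"].dropna()
        if len(vals) >= 2:
            summaries.append(summarize_metric_class(vals, cls).as_tuple())
    class_summaries = pd.DataFrame(
        summaries,
        columns=["metric_class", "mean", "ci_low", "ci_high",
                 "pct_positive", "pct_negative", "n_regions"],
    )

    top_maps = {}
    for cls, grp in brain.groupby("metric_class", sort=True):
        vals = grp.set_index("region")["loading"].dropna()
        if len(vals) >= 2:
            top_maps[cls] = top_fraction_map(vals, top_fraction)

    myelin = brain[brain["metric_class"] == "myelin"].set_index("region")["loading"]
    thick = brain[brain["metric_class"] == "thickness"].set_index("region")["loading"]
    common = myelin.index.intersection(thick.index)
    r, ci = loading_correlation(myelin.loc[common], thick.loc[common])

    return CrossLoadingReport(
        brain_loadings=brain,
        game_loadings=game_df,
        class_summaries=class_summaries,
        top_maps=top_maps,
        myelin_thickness_r=r,
        myelin_thickness_ci=ci,
    )
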