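"""Two-group and multi-group comparisons, regression and report assembly.

The comparison conventions follow the original analysis: an unpaired
t-test when both groups look normal (Shapiro-Wilk at alpha 0.05),
otherwise a two-tailed Mann-Whitney test; Kruskal-Wallis with Dunn
pairwise comparisons (Holm-adjusted) for three or more groups; ordinary
least squares with a two-sided slope test for regressions.  Summaries
are reported as mean +/- standard deviation, and the significance
criterion is p < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CentmorphError, InsufficientDataError

ALPHA = 0.05


@dataclass
class GroupSample:
    """A labelled vector of measurements from one condition."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)

    def summary(self) -> tuple[float, float, int]:
        """(mean, sd, n); sd uses ddof=1 (0 if n == 1)."""
        sd = float(self.values.std(ddof=1)) if self.n > 1 else 0.0
        return float(self.values.mean()), sd, self.n


@dataclass
class ComparisonResult:
    test: str  # unpaired_t | mann_whitney | kruskal_wallis
    statistic: float
    p: float
    summary: dict  # label -> (mean, sd, n)
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("p must be a probability")

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def _is_normal(values: np.ndarray) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return False  # Shapiro-Wilk undefined; fall back to the rank test
    return sps.shapiro(values).pvalue > ALPHA


def compare_two(a: GroupSample, b: GroupSample, test: str = "auto") -> ComparisonResult:
    """Two-group comparison with automatic parametric/non-parametric dispatch.

    ``auto`` runs Shapiro-Wilk on both groups (alpha 0.05): the unpaired
    t-test is used only when both pass, otherwise the two-tailed
    Mann-Whitney test.  Mann-Whitney uses the exact null distribution
    for combined n <= 20 without ties, the tie-corrected normal
    approximation otherwise; two identical groups give p = 1 by
    convention (every pooled value tied).
    """
    if a.n < 2 or b.n < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if test == "auto":
        test = "unpaired_t" if (_is_normal(a.values) and _is_normal(b.values)) \
            else "mann_whitney"
    summary = {a.label: a.summary(), b.label: b.summary()}
    if test == "unpaired_t":
        res = sps.ttest_ind(a.values, b.values)
        return ComparisonResult("unpaired_t", float(res.statistic),
                                float(res.pvalue), summary)
    if test == "mann_whitney":
        pooled = np.concatenate([a.values, b.values])
        if np.ptp(pooled) == 0:
            return ComparisonResult("mann_whitney", a.n * b.n / 2.0, 1.0, summary)
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (a.n + b.n <= 20 and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided",
                               method=method)
        return ComparisonResult("mann_whitney", float(res.statistic),
                                float(res.pvalue), summary)
    raise ValueError(f"unknown test {test!r}")


def _dunn_pairwise(groups: list[GroupSample]) -> pd.DataFrame:
    """Dunn z-tests on pooled ranks with tie correction, Holm-adjusted."""
    values = np.concatenate([g.values for g in groups])
    labels = np.concatenate([[i] * g.n for i, g in enumerate(groups)])
    N = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    mean_ranks = [ranks[labels == i].mean() for i in range(len(groups))]
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / groups[i].n + 1.0 / groups[j].n))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((groups[i].label, groups[j].label, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    df["p_adj"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def compare_many(groups: list[GroupSample],
                 correction: str = "holm") -> ComparisonResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons.

    Pairwise p-values are Holm-adjusted by default (the adjustment
    method is selectable but never less conservative than raw p).
    """
    if len(groups) < 3:
        raise InsufficientDataError(
            "compare_many needs >= 3 groups; use compare_two for two")
    for g in groups:
        if g.n < 2:
            raise InsufficientDataError(f"group {g.label!r} has n < 2")
    pooled = np.concatenate([g.values for g in groups])
    summary = {g.label: g.summary() for g in groups}
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
        pairwise = pd.DataFrame(
            [(a.label, b.label, 0.0, 1.0, 1.0)
             for a, b in itertools.combinations(groups, 2)],
            columns=["group_a", "group_b", "z", "p_raw", "p_adj"])
    else:
        stat, p = sps.kruskal(*[g.values for g in groups])
        pairwise = _dunn_pairwise(groups)
        if correction != "holm":
            pairwise["p_adj"] = multipletests(pairwise["p_raw"],
                                              method=correction)[1]
    return ComparisonResult("kruskal_wallis", float(stat), float(p), summary,
                            pairwise=pairwise)


def regress(x, y) -> RegressionResult:
    """Ordinary least squares with R^2 and a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need matched x, y with n >= 3")
    if np.ptp(x) == 0:
        raise CentmorphError("constant x: regression slope is undefined")
    if np.ptp(y) == 0:
        # flat response: zero slope explains nothing and there is nothing to explain
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, p_slope=1.0)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2,
                            p_slope=float(res.pvalue))


# --------------------------------------------------------------------------
# Report assembly

def comparison_table(comparisons: dict[str, ComparisonResult]) -> pd.DataFrame:
    rows = []
    for name, c in comparisons.items():
        for label, (mean, sd, n) in c.summary.items():
            rows.append({"comparison": name, "group": label, "mean": mean,
                         "sd": sd, "n": n, "test": c.test,
                         "statistic": c.statistic, "p": c.p})
    return pd.DataFrame(rows)


def distribution_table(distributions: dict[str, "BinnedDistribution"]) -> pd.DataFrame:
    frames = []
    for name, d in distributions.items():
        frames.append(pd.DataFrame({
            "panel": name, "bin": d.labels,
            "counts_percent": d.counts_percent,
            "area_percent": d.area_percent,
        }))
    return pd.concat(frames, ignore_index=True)


def build_report(out_dir, measurements: pd.DataFrame,
                 comparisons: dict | None = None,
                 distributions: dict | None = None,
                 plots: bool = True) -> dict:
    """Write the measurement tables (and plots) of one analysis run.

    ``measurements`` is one row per centrosome/panel/trace with every
    measured quantity.  Comparisons become a long-format test table and
    distributions a binned table on the standard nm^2 scheme.  Returns
    a dict of written paths; regenerating from the saved CSVs writes
    identical files.
    """
    from pathlib import Path

    if measurements is None or len(measurements) == 0:
        raise InsufficientDataError("a report needs at least one measurement row")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    mpath = out / "measurements.csv"
    measurements.to_csv(mpath, index=False)
    paths["measurements"] = mpath
    if comparisons:
        cpath = out / "comparisons.csv"
        comparison_table(comparisons).to_csv(cpath, index=False)
        paths["comparisons"] = cpath
    if distributions:
        dpath = out / "distributions.csv"
        distribution_table(distributions).to_csv(dpath, index=False)
        paths["distributions"] = dpath
    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        numeric = measurements.select_dtypes("number")
        if len(numeric.columns):
            fig, ax = plt.subplots(figsize=(4, 3))
            col = numeric.columns[0]
            vals = numeric[col].to_numpy()
            ax.scatter(np.random.default_rng(0).normal(0, 0.03, len(vals)), vals,
                       s=12, alpha=0.7)
            ax.errorbar([0], [vals.mean()], yerr=[vals.std(ddof=1) if len(vals) > 1 else 0],
                        fmt="_", color="k", capsize=6)
            ax.set_ylabel(col)
            ax.set_xticks([])
            fig.tight_layout()
            ppath = out / "measurements.png"
            fig.savefig(ppath, dpi=120)
            plt.close(fig)
            paths["scatter"] = ppath
        if distributions:
            fig, ax = plt.subplots(figsize=(5, 3))
            for name, d in distributions.items():
                ax.bar(range(len(d.labels)), d.counts_percent, alpha=0.5, label=name)
            ax.set_xticks(range(len(next(iter(distributions.values())).labels)))
            ax.set_xticklabels(next(iter(distributions.values())).labels,
                               rotation=60, fontsize=6)
            ax.set_ylabel("% of holes")
            ax.legend(fontsize=7)
            fig.tight_layout()
            bpath = out / "distributions.png"
            fig.savefig(bpath, dpi=120)
            plt.close(fig)
            paths["bars"] = bpath
    return paths
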