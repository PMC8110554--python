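"""Group-comparison and correlation layer shared by all modalities.

The experimental unit is the subject; per-subject summaries (ratios,
densities, counts) enter a common decision pipeline:

* Bartlett's test (alpha 0.05) gates variance homogeneity.
* Homogeneous variances: one-way ANOVA with two-sided Dunnett post hoc
  comparisons versus control.
* Heterogeneous variances: Welch ANOVA (or Kruskal-Wallis, configurable)
  with two-sided Dunn rank comparisons versus control
  (Bonferroni-adjusted).

Also provided: a two-way mixed (repeated-measures) ANOVA for group x
intensity-bin interactions, Pearson/Spearman correlations, and the
Wilcoxon/Mann-Whitney rank-sum test.  Every result carries its decision
trail so the chosen path is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "GroupSample",
    "TestResult",
    "compare_groups",
    "dunn_vs_control",
    "rm_anova_interaction",
    "correlate",
    "wilcoxon_ranksum",
]


@dataclass
class GroupSample:
    """Per-subject values with group labels; one value per subject."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape or self.values.ndim != 1:
            raise ValueError("values and labels must be matching 1D arrays")
        groups = pd.unique(self.labels)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        for g in groups:
            if (self.labels == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")

    def groups(self) -> dict[str, np.ndarray]:
        return {str(g): self.values[self.labels == g]
                for g in pd.unique(self.labels)}


@dataclass
class TestResult:
    test: str
    statistic: float
    df: tuple[float, float] | tuple[float] | None
    pvalue: float
    posthoc: dict[str, float] | None = None
    variance_homogeneous: bool | None = None
    trail: dict = field(default_factory=dict)


def _bartlett_gate(samples: list[np.ndarray], alpha: float) -> tuple[bool, float]:
    if all(np.ptp(s) == 0 for s in samples):
        return True, 1.0  # no variance anywhere: nothing to be unequal
    with np.errstate(all="ignore"):
        stat, p = stats.bartlett(*samples)
    if np.isnan(p):
        return True, 1.0
    return bool(p >= alpha), float(p)


def dunn_vs_control(samples: dict[str, np.ndarray], control: str,
                    adjust: bool = True) -> dict[str, float]:
    """Two-sided Dunn rank comparisons of each group versus control.

    Pools all observations, ranks them (midranks for ties), and compares
    mean ranks with the large-sample z statistic including the tie
    correction.  P-values are Bonferroni-adjusted over the number of
    comparisons versus control when ``adjust`` is True.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n_g = samples[g].size
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    comparisons = [g for g in names if g != control]
    out = {}
    for g in comparisons:
        se = np.sqrt(base_var * (1.0 / sizes[g] + 1.0 / sizes[control]))
        if se == 0:
            out[g] = 1.0
            continue
        z = (mean_ranks[g] - mean_ranks[control]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust:
            p = min(1.0, p * len(comparisons))
        out[g] = float(p)
    return out


def compare_groups(sample: GroupSample, control_label: str,
                   bartlett_alpha: float = 0.05,
                   hetero_method: str = "welch",
                   posthoc: bool = True) -> TestResult:
    """Omnibus group comparison with variance-gated test selection.

    Bartlett's test at ``bartlett_alpha`` decides the path: homogeneous
    variances lead to one-way ANOVA with two-sided Dunnett comparisons
    versus control; heterogeneous variances lead to Welch ANOVA (or
    Kruskal-Wallis when ``hetero_method='kruskal'``) with Dunn comparisons
    versus control.  The reported df are the design degrees of freedom
    (k - 1, N - k); the Welch-corrected denominator df appears in the
    trail.  All-identical data yield F = 0, p = 1.
    """
    groups = sample.groups()
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} not in sample")
    if hetero_method not in ("welch", "kruskal"):
        raise ValueError("hetero_method must be 'welch' or 'kruskal'")
    names = list(groups)
    arrays = [groups[g] for g in names]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_design = (float(k - 1), float(n_total - k))

    homogeneous, bartlett_p = _bartlett_gate(arrays, bartlett_alpha)
    trail = {"bartlett_p": bartlett_p, "variance_homogeneous": homogeneous,
             "groups": {g: int(groups[g].size) for g in names},
             "control": control_label}

    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:  # zero between- and within-group variance
        return TestResult(test="one-way ANOVA", statistic=0.0, df=df_design,
                          pvalue=1.0,
                          posthoc={g: 1.0 for g in names if g != control_label}
                          if posthoc else None,
                          variance_homogeneous=True, trail=trail)

    ph: dict[str, float] | None = None
    if homogeneous:
        stat, p = stats.f_oneway(*arrays)
        test_name = "one-way ANOVA"
        if posthoc:
            treatments = [groups[g] for g in names if g != control_label]
            res = stats.dunnett(*treatments, control=groups[control_label],
                                alternative="two-sided")
            ph = {g: float(pv) for g, pv in
                  zip([g for g in names if g != control_label], res.pvalue)}
            trail["posthoc_test"] = "Dunnett (two-sided) vs control"
    else:
        if hetero_method == "welch":
            long = pd.DataFrame({
                "value": sample.values,
                "group": sample.labels.astype(str),
            })
            welch = pg.welch_anova(data=long, dv="value", between="group")
            stat = float(welch.loc[0, "F"])
            p = float(welch.loc[0, "p_unc"])
            trail["welch_ddof2"] = float(welch.loc[0, "ddof2"])
            test_name = "Welch ANOVA"
        else:
            stat, p = stats.kruskal(*arrays)
            test_name = "Kruskal-Wallis"
        if posthoc:
            ph = dunn_vs_control(groups, control_label)
            trail["posthoc_test"] = "Dunn (two-sided, Bonferroni) vs control"
    return TestResult(test=test_name, statistic=float(stat), df=df_design,
                      pvalue=float(p), posthoc=ph,
                      variance_homogeneous=homogeneous, trail=trail)


def rm_anova_interaction(distributions: np.ndarray,
                         groups: np.ndarray) -> TestResult:
    """Two-way mixed ANOVA: group (between) x intensity bin (within).

    ``distributions`` is (subjects x bins), one repeated measure per bin per
    subject; ``groups`` labels the subjects.  Returns the interaction F and
    p (the signature of a group-specific distribution shape change).  When
    every subject shares one shape exactly the interaction carries no
    variance and F = 0, p = 1 by convention.
    """
    dist = np.asarray(distributions, dtype=float)
    groups = np.asarray(groups)
    if dist.ndim != 2 or dist.shape[0] != groups.shape[0]:
        raise ValueError("distributions must be (subjects x bins) matching groups")
    n_subj, n_bins = dist.shape
    long = pd.DataFrame({
        "value": dist.ravel(),
        "subject": np.repeat(np.arange(n_subj), n_bins),
        "bin": np.tile(np.arange(n_bins), n_subj),
        "group": np.repeat(groups.astype(str), n_bins),
    })
    df_int = (float((len(pd.unique(groups)) - 1) * (n_bins - 1)),
              float((n_subj - len(pd.unique(groups))) * (n_bins - 1)))
    # degenerate case: identical shapes leave no interaction variance
    centered = dist - dist.mean(axis=1, keepdims=True)
    if np.allclose(centered, centered.mean(axis=0, keepdims=True),
                   atol=1e-12 * max(1.0, np.abs(dist).max())):
        return TestResult(test="mixed RM-ANOVA interaction", statistic=0.0,
                          df=df_int, pvalue=1.0,
                          trail={"degenerate": "no interaction variance"})
    aov = pg.mixed_anova(data=long, dv="value", within="bin",
                         subject="subject", between="group", correction=False)
    row = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    return TestResult(test="mixed RM-ANOVA interaction",
                      statistic=float(row["F"]),
                      df=(float(row["DF1"]), float(row["DF2"])),
                      pvalue=float(row["p_unc"]),
                      trail={"anova_table": aov})


def correlate(x: np.ndarray, y: np.ndarray,
              method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Pearson results also report R^2 in the trail (the convention for linear
    fits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be matching 1D arrays with n >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        trail = {"r_squared": float(r ** 2), "df": int(x.size - 2)}
        name = "Pearson correlation"
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        trail = {"df": int(x.size - 2)}
        name = "Spearman correlation"
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestResult(test=name, statistic=float(r), df=(float(x.size - 2),),
                      pvalue=float(p), trail=trail)


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses the exact null distribution when both samples are small and free of
    ties, otherwise the normal approximation with tie correction and no
    continuity correction (so identical samples give p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="auto", use_continuity=False)
    return TestResult(test="Wilcoxon rank-sum", statistic=float(stat),
                      df=None, pvalue=float(p),
                      trail={"n": (int(a.size), int(b.size)),
                             "ties": bool(np.unique(np.concatenate([a, b])).size
                                          < a.size + b.size)})
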