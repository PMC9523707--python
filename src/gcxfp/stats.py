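"""Chemometrics on the UT feature table.

The statistical layer of the fingerprinting workflow: repeatability (%RSD),
Fisher-ratio sieving of class-discriminating features (one-way ANOVA F per
feature against the critical value, default F_crit(4, 8) = 3.84 at α = 0.05),
principal component analysis with mean-centering and unit-variance scaling,
Pearson correlation with hierarchical clustering and Z-score normalisation
for heatmaps, pairwise class response ratios (fold-changes of 2D peak
volumes), and the silage-characteristics two-way ANOVA
Y_ijk = μ + α_i + β_j + αβ_ij + ε_ijk with Bonferroni post hoc letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _SKPCA

from .align import FeatureTable


# ---------------------------------------------------------------------------
# Elementary indicators
# ---------------------------------------------------------------------------

def rsd(values) -> float:
    """Percent relative standard deviation: 100 · sample SD / mean.

    Returns NaN (undefined) when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("%RSD requires at least 2 values")
    m = v.mean()
    if m == 0:
        return math.nan
    return float(100.0 * v.std(ddof=1) / m)


def fisher_ratio(responses, classes) -> float:
    """One-way ANOVA F statistic (between-class MS / within-class MS).

    Returns inf when the class means differ but the within-class variance is
    zero, and NaN when the statistic is undefined (all values identical).
    """
    y = np.asarray(responses, dtype=float)
    labels = np.asarray(classes)
    groups = [y[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Fisher ratio requires >= 2 classes")
    n = y.size
    k = len(groups)
    grand = y.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if df2 <= 0:
        raise ValueError("no within-class degrees of freedom")
    if ss_within == 0:
        return math.nan if ss_between == 0 else math.inf
    return float((ss_between / df1) / (ss_within / df2))


def f_critical(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-tail critical value of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(sps.f.ppf(1.0 - alpha, df1, df2))


def t_test_unpaired(a, b) -> tuple[float, float]:
    """Two-sided unpaired t-test with pooled variance: (t, P).

    Returns (NaN, NaN) when the pooled variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        return math.nan, math.nan
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Feature-table statistics
# ---------------------------------------------------------------------------

def feature_fisher_ratios(table: FeatureTable,
                          exclude_classes: tuple[str, ...] = ("qc",),
                          exclude_missing: bool = False) -> pd.Series:
    """Per-feature Fisher ratio over the (non-QC) sample classes.

    Missing-flagged cells are included as 0 by default (absence below the
    S/N threshold is a real response of zero); ``exclude_missing`` drops
    them instead.
    """
    classes = table.classes()
    keep = ~classes.isin(exclude_classes)
    out = {}
    for fid, row in table.responses.iterrows():
        y = row[keep.index[keep]].to_numpy(dtype=float)
        labels = classes[keep].to_numpy()
        if exclude_missing:
            m = ~table.missing.loc[fid, keep.index[keep]].to_numpy(dtype=bool)
            y, labels = y[m], labels[m]
        out[fid] = fisher_ratio(y, labels)
    return pd.Series(out, name="F_calc")


def sieve(table: FeatureTable, threshold: float = 3.84,
          f_values: pd.Series | None = None,
          exclude_classes: tuple[str, ...] = ("qc",)) -> FeatureTable:
    """Retain features whose F_calc exceeds the critical threshold.

    Monotone: a larger threshold always yields a subset.  Features with an
    undefined (NaN) F are dropped; inf always passes a finite threshold.
    """
    f = f_values if f_values is not None else \
        feature_fisher_ratios(table, exclude_classes=exclude_classes)
    keep = f.index[f > threshold]
    return FeatureTable(
        features=table.features.loc[keep],
        responses=table.responses.loc[keep],
        normalized=table.normalized.loc[keep],
        missing=table.missing.loc[keep],
        meta=table.meta,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples × components
    loadings: pd.DataFrame          # features × components
    explained_variance_ratio: np.ndarray
    dropped_features: list = field(default_factory=list)


def pca(responses: pd.DataFrame, n_components: int | None = None,
        scale: bool = True) -> PCAResult:
    """PCA of a features × samples matrix with mean-centering and
    (by default) unit-variance scaling per feature.

    Constant feature rows are dropped with a warning; explained-variance
    fractions over all computable components sum to 1.
    """
    X = responses.to_numpy(dtype=float).T  # samples × features
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    dropped = list(responses.index[const])
    if dropped:
        import warnings
        warnings.warn(f"dropping {len(dropped)} constant feature(s)")
    X = X[:, ~const]
    feat_index = responses.index[~const]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / X.std(axis=0, ddof=1)
    max_comp = min(Xc.shape[0] - 1, Xc.shape[1])
    model = _SKPCA(n_components=max_comp, svd_solver="full")
    s = model.fit_transform(Xc)
    k = n_components or max_comp
    comp_names = [f"PC{i+1}" for i in range(max_comp)]
    return PCAResult(
        scores=pd.DataFrame(s[:, :k], index=responses.columns,
                            columns=comp_names[:k]),
        loadings=pd.DataFrame(model.components_[:k].T, index=feat_index,
                              columns=comp_names[:k]),
        explained_variance_ratio=model.explained_variance_ratio_,
        dropped_features=dropped,
    )


@dataclass
class CorrelationClustering:
    correlation: pd.DataFrame       # feature × feature Pearson r
    p_values: pd.DataFrame
    zscores: pd.DataFrame           # Z-scored responses (feature rows)
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    strong_pairs: pd.DataFrame      # pairs with r >= r_min and P < alpha


def correlation_clustered_heatmap(responses: pd.DataFrame,
                                  r_min: float = 0.900,
                                  alpha: float = 0.05) -> CorrelationClustering:
    """Pearson correlation matrix, average-linkage clustering on 1 − r, and
    Z-scored responses for heatmap rendering.

    Zero-variance feature rows are excluded with a warning.  Pairs with
    r ≥ ``r_min`` and two-sided P < ``alpha`` are flagged.
    """
    X = responses.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        import warnings
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance feature(s)")
    keep = sd > 0
    idx = responses.index[keep]
    X = X[keep]
    n = X.shape[1]
    if n < 3:
        raise ValueError("correlation clustering requires >= 3 samples")
    r = np.atleast_2d(np.corrcoef(X))
    r = np.clip(r, -1.0, 1.0)
    # two-sided P for Pearson r with n samples (t transform)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)

    if r.shape[0] >= 2:
        dist = 1.0 - r
        np.fill_diagonal(dist, 0.0)
        condensed = np.maximum(dist[np.triu_indices_from(dist, k=1)], 0.0)
        link = hierarchy.linkage(condensed, method="average")
    else:
        link = np.empty((0, 4))

    pairs = []
    iu = np.triu_indices_from(r, k=1)
    for a, b in zip(*iu):
        if r[a, b] >= r_min and p[a, b] < alpha:
            pairs.append((idx[a], idx[b], r[a, b], p[a, b]))
    strong = pd.DataFrame(pairs, columns=["feature_a", "feature_b", "r", "p"])

    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    zdf = pd.DataFrame(z, index=idx, columns=responses.columns)
    return CorrelationClustering(correlation=rdf, p_values=pdf, zscores=zdf,
                                 row_linkage=link, col_linkage=link,
                                 strong_pairs=strong)


def response_ratio(table: FeatureTable, class_a: str, class_b: str) -> pd.Series:
    """Per-feature fold-change: mean response in class_a / mean in class_b.

    inf where the denominator is zero but the numerator is not; NaN where
    both are zero.
    """
    classes = table.classes()
    for c in (class_a, class_b):
        if c not in set(classes):
            raise KeyError(f"class {c!r} not present in table")
    cols_a = classes.index[classes == class_a]
    cols_b = classes.index[classes == class_b]
    mean_a = table.responses[cols_a].mean(axis=1)
    mean_b = table.responses[cols_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    ratio[(mean_a == 0) & (mean_b == 0)] = np.nan
    return ratio.rename(f"{class_a}/{class_b}")


# ---------------------------------------------------------------------------
# Two-way ANOVA (completely randomized design) with Bonferroni letters
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Y_ijk = μ + α_i + β_j + (αβ)_ij + ε_ijk decomposition."""

    grand_mean: float
    ss: dict                    # D, L, DxL, error, total
    df: dict
    f: dict                     # per-effect F statistics
    p: dict                     # per-effect P-values
    factor_a_means: pd.Series   # DM-level means
    factor_b_means: pd.Series   # inoculum means
    letters: dict               # factor-b level -> letter group


def _letter_groups(levels, means: dict, differ) -> dict:
    """Compact letter display: levels sharing a letter do not differ."""
    order = sorted(levels, key=lambda l: -means[l])
    groups: list[set] = []
    for lv in order:
        placed = False
        for g in groups:
            if all(not differ(lv, other) for other in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    letters = {lv: "" for lv in levels}
    for g, letter in zip(groups, "abcdefghij"):
        for lv in g:
            letters[lv] += letter
    return {lv: "".join(sorted(letters[lv])) for lv in levels}


def two_way_anova(y, factor_a, factor_b, alpha: float = 0.05) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Factor A plays the dry-matter level, factor B the inoculum.  On balanced
    data the decomposition is exact: SS_total = SS_A + SS_B + SS_AB +
    SS_error.  Bonferroni pairwise pooled-variance t-tests on factor-B means
    (α divided by the number of comparisons) produce the letter groups.
    """
    y = np.asarray(y, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    a_levels = list(pd.unique(fa))
    b_levels = list(pd.unique(fb))
    cells = {}
    for ai in a_levels:
        for bj in b_levels:
            cell = y[(fa == ai) & (fb == bj)]
            if cell.size == 0:
                raise ValueError(f"empty cell ({ai}, {bj})")
            if cell.size < 2:
                raise ValueError(f"cell ({ai}, {bj}) needs >= 2 replicates")
            cells[(ai, bj)] = cell

    grand = y.mean()
    n = y.size
    a_means = {ai: y[fa == ai].mean() for ai in a_levels}
    b_means = {bj: y[fb == bj].mean() for bj in b_levels}

    ss_a = sum((y[fa == ai].size) * (a_means[ai] - grand) ** 2 for ai in a_levels)
    ss_b = sum((y[fb == bj].size) * (b_means[bj] - grand) ** 2 for bj in b_levels)
    ss_cells = sum(c.size * (c.mean() - grand) ** 2 for c in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    ss_tot = ((y - grand) ** 2).sum()

    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = n - len(a_levels) * len(b_levels)
    ms_err = ss_err / df_err if df_err > 0 else math.nan

    def _f(ss_eff, df_eff):
        if df_eff <= 0:
            return math.nan, math.nan
        if ms_err == 0 or not np.isfinite(ms_err):
            return math.nan, math.nan
        fval = (ss_eff / df_eff) / ms_err
        return float(fval), float(sps.f.sf(fval, df_eff, df_err))

    f_a, p_a = _f(ss_a, df_a)
    f_b, p_b = _f(ss_b, df_b)
    f_ab, p_ab = _f(ss_ab, df_ab)

    n_comp = len(b_levels) * (len(b_levels) - 1) // 2
    bonf_alpha = alpha / max(n_comp, 1)

    def _differ(l1, l2):
        g1, g2 = y[fb == l1], y[fb == l2]
        sp2 = (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()) \
            / (g1.size + g2.size - 2)
        if sp2 == 0:
            return g1.mean() != g2.mean()
        t = (g1.mean() - g2.mean()) / math.sqrt(sp2 * (1 / g1.size + 1 / g2.size))
        pval = 2.0 * sps.t.sf(abs(t), g1.size + g2.size - 2)
        return pval < bonf_alpha

    letters = _letter_groups(b_levels, b_means, _differ)

    return AnovaResult(
        grand_mean=float(grand),
        ss={"D": float(ss_a), "L": float(ss_b), "DxL": float(ss_ab),
            "error": float(ss_err), "total": float(ss_tot)},
        df={"D": df_a, "L": df_b, "DxL": df_ab, "error": df_err,
            "total": n - 1},
        f={"D": f_a, "L": f_b, "DxL": f_ab},
        p={"D": p_a, "L": p_b, "DxL": p_ab},
        factor_a_means=pd.Series(a_means),
        factor_b_means=pd.Series(b_means),
        letters=letters,
    )
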