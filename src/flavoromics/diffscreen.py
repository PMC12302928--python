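"""Differential-feature screening and heatmap ordering.

Markers are selected per pairwise group comparison by the combined rule
VIP > 1 (strict) and p < 0.05, with the pairwise p from Welch's t-test on
log intensities. The omnibus one-way ANOVA across all groups and its
Benjamini-Hochberg adjustment are computed alongside; the ``use_adjusted``
flag switches the selection to BH-adjusted p. Up/down direction follows the
sign of the log2 fold change of the first group over the second, computed
on unlogged group means.

Heatmap ordering mirrors the figure convention of the field: per-feature
z-scores, Euclidean distances, complete-linkage agglomeration. The
agglomeration is written here rather than delegated because the contract
fixes a deterministic tie-break (the cluster pair containing the lowest
original index merges first); scipy's linkage is the cross-check on
tie-free data in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chemometrics import fit_oplsda, log_intensities
from .tables_io import FeatureTable

# ---------------------------------------------------------------------------
# Univariate statistics
# ---------------------------------------------------------------------------


def anova_per_feature(X: pd.DataFrame, groups: Sequence[str]) -> pd.Series:
    """Classical one-way ANOVA F-test p-value per feature (column).

    ``X`` holds log intensities (samples x features, complete); ``groups``
    is the per-sample group label. Features with zero between-group *and*
    zero within-group variance (all samples identical) get p = 1 by
    convention; zero within-group variance with a real group difference
    gives p = 0.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least two groups")
    counts = np.array([(groups == g).sum() for g in uniq])
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    if X.isna().any().any():
        raise ValueError("ANOVA requires a complete matrix")
    Xn = X.to_numpy(dtype=float)
    grand = Xn.mean(axis=0)
    ssb = np.zeros(Xn.shape[1])
    ssw = np.zeros(Xn.shape[1])
    for g, n_g in zip(uniq, counts):
        block = Xn[groups == g]
        mean_g = block.mean(axis=0)
        ssb += n_g * (mean_g - grand) ** 2
        ssw += ((block - mean_g) ** 2).sum(axis=0)
    dfb = len(uniq) - 1
    dfw = len(groups) - len(uniq)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(ssb == 0, 1.0, p)          # no between-group signal at all
    p = np.where((ssw == 0) & (ssb > 0), 0.0, p)
    return pd.Series(p, index=X.columns, name="p_anova")


def welch_per_feature(
    X: pd.DataFrame, groups: Sequence[str], pair: tuple[str, str]
) -> pd.Series:
    """Welch's two-sample t-test p-value per feature for one group pair."""
    groups = np.asarray(groups)
    a = X.to_numpy(dtype=float)[groups == pair[0]]
    b = X.to_numpy(dtype=float)[groups == pair[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"both groups in {pair} need >= 2 samples")
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # near-identical imputed columns trigger a scipy precision warning
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    # identical constant columns in both groups -> no evidence of difference
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=X.columns, name="p_raw")


def bh_adjust(p_raw: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_raw, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    adjusted = multipletests(p, method="fdr_bh")[1]
    if isinstance(p_raw, pd.Series):
        return pd.Series(adjusted, index=p_raw.index, name="p_adjusted")
    return adjusted


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    """Per-feature screening result for one ordered group comparison.

    ``frame`` columns: p_raw, p_adjusted, p_anova, vip, log2_fold_change,
    selected, direction.
    """

    comparison: tuple[str, str]
    frame: pd.DataFrame
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted: bool = False

    @property
    def selected_features(self) -> list[str]:
        return list(self.frame.index[self.frame["selected"]])

    def summary(self) -> dict:
        sel = self.frame[self.frame["selected"]]
        return {
            "comparison": f"{self.comparison[0]} vs {self.comparison[1]}",
            "n_selected": int(len(sel)),
            "n_up": int((sel["direction"] == "up").sum()),
            "n_down": int((sel["direction"] == "down").sum()),
        }


def select_differential(
    vip: pd.Series,
    p: pd.Series,
    log2fc: pd.Series,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Apply the combined marker rule VIP > threshold (strict) and p < threshold.

    Returns a frame aligned with the inputs carrying ``selected`` flags and
    ``direction`` ("up" iff log2 fold change > 0).
    """
    if not (vip.index.equals(p.index) and vip.index.equals(log2fc.index)):
        raise ValueError("vip, p and log2fc must share one feature index")
    selected = (vip > vip_threshold) & (p < p_threshold)
    direction = np.where(log2fc > 0, "up", "down")
    return pd.DataFrame(
        {
            "vip": vip,
            "p": p,
            "log2_fold_change": log2fc,
            "selected": selected,
            "direction": direction,
        }
    )


def differential_analysis(
    table: FeatureTable,
    pair: tuple[str, str],
    n_ortho: int = 1,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
    cv: str | int | None = None,
) -> DifferentialResult:
    """Full screening for one pair: Welch p, BH, OPLS-DA VIP, fold change.

    ``table`` must be preprocessed (normalized, imputed). The model and the
    tests run on log2 intensities; fold changes on unlogged group means.
    """
    sub = table.subset_groups(pair)
    ordered = [g for g in pair]
    X = log_intensities(sub)
    p_raw = welch_per_feature(X, sub.group_labels, (ordered[0], ordered[1]))
    p_adj = bh_adjust(p_raw)
    p_omni = anova_per_feature(
        log_intensities(table), np.asarray(table.group_labels)
    ) if len(table.groups) > 2 else p_raw.rename("p_anova")
    model = fit_oplsda(X, list(sub.group_labels), n_ortho=n_ortho, cv=cv)
    means = sub.values.groupby(sub.group_labels).mean()
    log2fc = np.log2(means.loc[ordered[0]] / means.loc[ordered[1]]).rename(
        "log2_fold_change"
    )
    p_for_rule = p_adj if use_adjusted else p_raw
    sel = select_differential(
        model.vip, p_for_rule, log2fc, vip_threshold, p_threshold
    )
    frame = pd.DataFrame(
        {
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "p_anova": p_omni,
            "vip": model.vip,
            "log2_fold_change": log2fc,
            "selected": sel["selected"],
            "direction": sel["direction"],
        }
    )
    return DifferentialResult(
        comparison=(ordered[0], ordered[1]),
        frame=frame,
        vip_threshold=vip_threshold,
        p_threshold=p_threshold,
        use_adjusted=use_adjusted,
    )


# ---------------------------------------------------------------------------
# Heatmap ordering (z-score + complete linkage)
# ---------------------------------------------------------------------------


def zscore_features(values: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scores across samples; constant features map to zeros."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    z = (values - mean).div(sd.replace(0, np.nan), axis=1)
    return z.fillna(0.0)


@dataclass
class HeatmapOrder:
    """Complete-linkage dendrogram: scipy-style merge table and leaf order."""

    items: list[str]
    merges: np.ndarray  # (n-1) x 4: id_a, id_b, distance, cluster size
    leaves: list[int]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.items[i] for i in self.leaves]


def complete_linkage(D: np.ndarray, items: Sequence[str]) -> HeatmapOrder:
    """Agglomerate with complete linkage and a deterministic tie-break.

    Among pairs at the minimal distance, the pair whose clusters contain the
    lowest original indices merges first. Cluster ids follow the scipy
    convention (leaves 0..n-1, merges n, n+1, ...); within a merge the
    lower-id cluster is listed (and drawn) on the left.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items to cluster")
    D = np.asarray(D, dtype=float)
    active: dict[int, dict] = {
        i: {"min_idx": i, "size": 1} for i in range(n)
    }
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    children: dict[int, tuple[int, int]] = {}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), d in dist.items():
            key = (d, min(active[i]["min_idx"], active[j]["min_idx"]),
                   max(active[i]["min_idx"], active[j]["min_idx"]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, a, b = best
        d_ab = dist[(a, b)]
        size = active[a]["size"] + active[b]["size"]
        lo, hi = sorted((a, b))
        merges[step] = [lo, hi, d_ab, size]
        children[next_id] = (lo, hi)
        new_min = min(active[a]["min_idx"], active[b]["min_idx"])
        for other in list(active):
            if other in (a, b):
                continue
            d_new = max(
                dist[tuple(sorted((a, other)))], dist[tuple(sorted((b, other)))]
            )
            dist[tuple(sorted((next_id, other)))] = d_new
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        del active[a], active[b]
        active[next_id] = {"min_idx": new_min, "size": size}
        next_id += 1

    def expand(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return expand(left) + expand(right)

    leaves = expand(next_id - 1)
    return HeatmapOrder(items=list(items), merges=merges, leaves=leaves)


def heatmap_order(
    values: pd.DataFrame, axis: str = "features"
) -> HeatmapOrder:
    """Dendrogram order for a heatmap of a (samples x features) matrix.

    Features are z-scored across samples first (constant features become
    all-zero rows); distances are Euclidean; linkage is complete.
    ``axis="features"`` orders features, ``axis="samples"`` orders samples.
    """
    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    Z = zscore_features(values)
    M = Z.T if axis == "features" else Z
    items = list(M.index)
    X = M.to_numpy(dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return complete_linkage(D, items)
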