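"""Metabolite-VOC association: Spearman double matrix and pathway ORA.

The cross-platform integration computes pairwise Spearman rank correlations
between differential VOCs and non-volatile metabolites over the same
samples. Rho is the Pearson correlation of mid-ranks (average ranks on
ties); the p-value uses the t-approximation with n-2 degrees of freedom.
Significance flags default to raw p < 0.05 — matching the double-matrix
heatmap convention of marking asterisks at raw p — while BH-adjusted
p-values are always reported alongside.

Pathway analysis is an over-representation (upper-tail hypergeometric)
test: with N features in the universe, K in the pathway, and n selected,
the p-value is P(X >= k) for the observed overlap k.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffscreen import bh_adjust


@dataclass
class CorrelationMatrix:
    """Spearman rho/p between metabolites (rows) and VOCs (columns)."""

    rho: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    alpha: float = 0.05

    def to_long(self) -> pd.DataFrame:
        """Long-format edge table (metabolite, voc, rho, p, significant)."""
        rows = []
        for met in self.rho.index:
            for voc in self.rho.columns:
                rows.append(
                    {
                        "metabolite": met,
                        "voc": voc,
                        "rho": self.rho.loc[met, voc],
                        "p": self.p.loc[met, voc],
                        "p_adjusted": self.p_adjusted.loc[met, voc],
                        "significant": bool(self.significant.loc[met, voc]),
                    }
                )
        return pd.DataFrame(rows)


def spearman_matrix(
    X_met: pd.DataFrame, X_voc: pd.DataFrame, alpha: float = 0.05
) -> CorrelationMatrix:
    """Pairwise Spearman correlation between two sample-aligned tables.

    Both frames must share the same samples in the same order, with n >= 3.
    Zero-variance columns yield undefined correlations, reported as missing
    with a warning and never flagged significant.
    """
    if not X_met.index.equals(X_voc.index):
        raise ValueError("metabolite and VOC tables must share sample order")
    n = len(X_met)
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    constant = [
        c for c in X_met.columns if X_met[c].nunique() <= 1
    ] + [c for c in X_voc.columns if X_voc[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"zero-variance column(s), correlations undefined: {constant[:5]}...",
            stacklevel=2,
        )
    # Pearson on mid-ranks, computed blockwise so one constant column only
    # invalidates its own correlations (scipy's spearmanr NaNs everything)
    def center_ranks(df: pd.DataFrame) -> np.ndarray:
        R = np.apply_along_axis(stats.rankdata, 0, df.to_numpy(dtype=float))
        Rc = R - R.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.sqrt((Rc**2).sum(axis=0))
            return Rc / np.where(norm == 0, np.nan, norm)

    A = center_ranks(X_met)
    B = center_ranks(X_voc)
    rho_block = np.clip(A.T @ B, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = rho_block * np.sqrt((n - 2) / (1.0 - rho_block**2))
    p_block = 2.0 * stats.t.sf(np.abs(t_stat), n - 2)
    p_block = np.where(np.abs(rho_block) == 1.0, 0.0, p_block)
    rho = pd.DataFrame(rho_block, index=X_met.columns, columns=X_voc.columns)
    p = pd.DataFrame(p_block, index=X_met.columns, columns=X_voc.columns)
    flat = p.to_numpy().ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = bh_adjust(flat[ok])
    p_adj = pd.DataFrame(
        adj.reshape(p.shape), index=p.index, columns=p.columns
    )
    significant = p.notna() & (p < alpha)
    return CorrelationMatrix(
        rho=rho, p=p, p_adjusted=p_adj, significant=significant, alpha=alpha
    )


def spearman_exact_p(x: np.ndarray, y: np.ndarray, chunk: int = 40320) -> float:
    """Exact two-sided permutation p-value for Spearman rho (small n).

    Enumerates all n! permutations of one variable's ranks; intended as an
    option for n <= 10 where the t-approximation is coarse. Ties are
    handled through mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n > 10:
        raise ValueError("exact enumeration is limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    obs = abs(float(rx @ ry) / n)
    count = 0
    total = 0
    perm_iter = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(perm_iter, chunk))
        if not block:
            break
        perms = np.array(block)
        rhos = np.abs(ry[perms] @ rx) / n
        count += int((rhos >= obs - 1e-12).sum())
        total += len(block)
    return count / total


def ora_hypergeometric(
    selected: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per pathway.

    Pathway membership is intersected with the declared universe before
    testing; ``selected`` must be a subset of the universe. Returns a frame
    indexed by pathway id with columns ``hits`` (k), ``pathway_size`` (K),
    ``selected_size`` (n), ``universe_size`` (N), ``p`` and BH-adjusted
    ``p_adjusted``, sorted by p then pathway id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = set(selected) - universe
    if stray:
        raise ValueError(
            f"selected features outside the universe: {sorted(stray)[:5]}"
        )
    selected = set(selected)
    N, n = len(universe), len(selected)
    rows = []
    for pw in sorted(pathways):
        members = set(pathways[pw]) & universe
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "pathway_id": pw,
                "hits": k,
                "pathway_size": K,
                "selected_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows).set_index("pathway_id")
    frame["p_adjusted"] = bh_adjust(frame["p"])
    return frame.sort_values(["p", "pathway_id"])
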