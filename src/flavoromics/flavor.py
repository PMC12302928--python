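"""Aroma-contribution scoring and VOC-sensory networks.

A compound's odor activity value is its relative content divided by its
odor threshold in water, ``OAV_i = C_i / OT_i``; the relative odor activity
value rescales by the largest OAV in the set, ``ROAV_i = 100 * OAV_i /
OAV_max``, so the single most aroma-active compound scores exactly 100 and
every score is scale-invariant in the contents. ROAV > 1 marks a key
contributor, 0.1 <= ROAV <= 1 a moderate one, below 0.1 a minor one.

Each group is scored independently (its own OAV_max), with C_i the group
mean of internal-standard-normalized content. Compounds without a published
odor threshold are carried unscored and never define the reference maximum.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .tables_io import CHEMICAL_CLASSES, FeatureTable

CONTRIBUTION_KEY = "key"
CONTRIBUTION_MODERATE = "moderate"
CONTRIBUTION_MINOR = "minor"
CONTRIBUTION_UNSCORED = "unscored"


def classify_contribution(roav: pd.Series) -> pd.Series:
    """Contribution class per compound: key (>1), moderate ([0.1, 1]), minor.

    Boundaries read literally: exactly 1 is moderate (key requires the score
    to *exceed* one); exactly 0.1 is moderate (inclusive lower bound).
    Unscored compounds (NaN) are labelled ``unscored``.
    """
    out = pd.Series(CONTRIBUTION_UNSCORED, index=roav.index, dtype=object)
    out[roav.notna() & (roav > 1)] = CONTRIBUTION_KEY
    out[roav.notna() & (roav >= 0.1) & (roav <= 1)] = CONTRIBUTION_MODERATE
    out[roav.notna() & (roav < 0.1)] = CONTRIBUTION_MINOR
    out.name = "contribution_class"
    return out


def compute_roav(contents: pd.Series, annotations: pd.DataFrame) -> pd.DataFrame:
    """ROAV table for one group from mean relative contents.

    Parameters
    ----------
    contents
        Mean relative content ``C_i`` per compound (non-negative).
    annotations
        Validated annotation frame indexed by feature id with an
        ``odor_threshold`` column (same units as the contents).

    Returns a frame with columns ``content``, ``odor_threshold``, ``oav``,
    ``roav`` and ``contribution_class``; compounds lacking a threshold stay
    listed with NaN scores. All odor activity values zero is an error (no
    reference compound).
    """
    if (contents.dropna() < 0).any():
        raise ValueError("relative contents must be non-negative")
    ot = annotations["odor_threshold"].reindex(contents.index)
    oav = contents / ot
    scored = oav.dropna()
    if scored.empty or scored.max() <= 0:
        raise ValueError(
            "no compound with positive odor activity value; cannot normalize"
        )
    oav_max = scored.max()
    # divide first: the argmax becomes exactly 1.0, hence ROAV exactly 100
    roav = (oav / oav_max) * 100.0
    frame = pd.DataFrame(
        {
            "content": contents,
            "odor_threshold": ot,
            "oav": oav,
            "roav": roav,
            "contribution_class": classify_contribution(roav),
        }
    )
    frame.index.name = "feature_id"
    return frame


def group_mean_contents(
    table: FeatureTable, agg: str = "mean"
) -> pd.DataFrame:
    """Per-group aggregate relative content (groups x features).

    The aggregation of replicate contents into one ``C_i`` per breed is a
    modelling choice; the mean is the default, the median an option.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    grouped = table.values.groupby(table.group_labels)
    return grouped.mean() if agg == "mean" else grouped.median()


def roav_by_group(
    table: FeatureTable, annotations: pd.DataFrame, agg: str = "mean"
) -> dict[str, pd.DataFrame]:
    """Independent ROAV table per group (each with its own OAV_max)."""
    means = group_mean_contents(table, agg)
    return {g: compute_roav(means.loc[g], annotations) for g in means.index}


def class_composition(
    table: FeatureTable, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-group relative content (%) by chemical class (rows sum to 100).

    Features without a class annotation are pooled into ``others`` with a
    warning.
    """
    classes = annotations["chemical_class"].reindex(table.feature_ids)
    unannotated = classes.index[classes.isna()].tolist()
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} feature(s) without chemical class assigned "
            f"to 'others': {unannotated[:5]}...",
            stacklevel=2,
        )
        classes = classes.fillna("others")
    means = group_mean_contents(table)
    totals = means.T.groupby(classes.values).sum().T
    comp = totals.div(totals.sum(axis=1), axis=0) * 100.0
    return comp.reindex(columns=[c for c in CHEMICAL_CLASSES if c in comp.columns])


def venn_partition(
    presence: Mapping[str, Iterable[str]]
) -> dict[tuple[str, ...], set[str]]:
    """Exclusive 7-region partition for three named feature sets.

    Keys are sorted tuples of the group names owning each region, e.g.
    ``("GL",)`` for features unique to GL and ``("GL", "SN", "XZ")`` for
    the shared core. Regions are pairwise disjoint and cover the union.
    """
    if len(presence) != 3:
        raise ValueError(f"venn_partition expects exactly 3 sets, got {len(presence)}")
    names = sorted(presence)
    sets = {g: set(presence[g]) for g in names}
    regions: dict[tuple[str, ...], set[str]] = {}
    a, b, c = names
    for combo in (
        (a,), (b,), (c,), (a, b), (a, c), (b, c), (a, b, c)
    ):
        inside = set.intersection(*(sets[g] for g in combo))
        outside = set.union(
            *(sets[g] for g in names if g not in combo), set()
        )
        regions[combo] = inside - outside
    return regions


def presence_by_group(table: FeatureTable) -> dict[str, set[str]]:
    """Features observed (non-missing in at least one sample) per group."""
    out: dict[str, set[str]] = {}
    for g in table.groups:
        block = table.values[np.asarray(table.group_labels) == g]
        observed = block.columns[block.notna().any(axis=0)]
        out[g] = set(observed)
    return out


def build_sensory_network(
    selected_vocs: Sequence[str],
    annotations: pd.DataFrame,
    top_k: int = 10,
) -> nx.Graph:
    """Bipartite VOC-sensory-attribute network, pruned to top attributes.

    One edge per (VOC, descriptor) pair over the selected VOCs. Attributes
    are ranked by degree (number of connected VOCs), ties broken
    lexicographically; only the ``top_k`` attributes and their incident
    edges are retained. Node attributes: ``kind`` ("voc"/"attribute") and
    ``degree`` within the pruned network.
    """
    edges: list[tuple[str, str]] = []
    for voc in dict.fromkeys(selected_vocs):
        if voc not in annotations.index:
            continue
        for desc in annotations.loc[voc, "descriptors"]:
            edges.append((voc, desc))
    if not edges:
        warnings.warn("no sensory descriptors among selected VOCs; empty network",
                      stacklevel=2)
        return nx.Graph()
    degree: dict[str, int] = {}
    for _, desc in edges:
        degree[desc] = degree.get(desc, 0) + 1
    ranked = sorted(degree, key=lambda d: (-degree[d], d))
    kept = set(ranked[:top_k])
    g = nx.Graph()
    for voc, desc in edges:
        if desc in kept:
            g.add_node(voc, kind="voc")
            g.add_node(desc, kind="attribute")
            g.add_edge(voc, desc)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return g
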