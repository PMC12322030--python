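"""Weighted average gene family size and phylogenetically independent
contrasts.

The weighted average family size of species *s* over *n* families is

    WAS(s) = ( sum_i copy_is * w_i / n ) * mean_max,

where the weight w_i is the inverse of a per-family size denominator
(by default the family's maximum copy number over all species in the
matrix) and mean_max is the mean of those denominators.  Downweighting
each family by its maximum makes the statistic robust to a few huge
families; the mean_max factor restores the scale of a plain average, so
that when all families share the same maximum the statistic reduces
exactly to the species' mean copy number.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .io import CopyMatrix

__all__ = ["weighted_avg_size", "family_weights", "pic", "pic_correlation",
           "PICResult"]

WEIGHT_SCHEMES = ("inv_max", "inv_p95_max", "inv_mean", "inv_median")


def family_weights(matrix: CopyMatrix, scheme: str = "inv_max",
                   family_subset=None) -> tuple[pd.Series, float]:
    """Per-family weights w_i and the scale constant mean_max.

    Weights are always computed over the full species set of the matrix,
    not any later species subset.  Families whose denominator is zero
    despite nonzero counts (possible under ``inv_p95_max``/``inv_median``)
    are dropped with a warning; all-zero families are a hard error because
    they should have been removed by coverage filtering.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    counts = matrix.counts
    if family_subset is not None:
        subset = [f for f in counts.index if f in set(family_subset)]
        if not subset:
            raise ValueError("empty family subset")
        counts = counts.loc[subset]
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        bad = counts.index[arr.sum(axis=1) == 0][:5].tolist()
        raise ValueError(
            f"families with all-zero counts (filter first): {bad}")
    if scheme == "inv_max":
        denom = arr.max(axis=1)
    elif scheme == "inv_p95_max":
        n_drop = int(np.ceil(0.05 * arr.shape[1]))
        part = np.sort(arr, axis=1)
        denom = part[:, -(n_drop + 1)] if n_drop < arr.shape[1] else part[:, 0]
    elif scheme == "inv_mean":
        denom = arr.mean(axis=1)
    else:  # inv_median
        denom = np.median(arr, axis=1)
    keep = denom > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} families dropped: zero weighting denominator "
            f"under scheme {scheme!r}")
    denom = pd.Series(denom[keep], index=counts.index[keep])
    return 1.0 / denom, float(denom.mean())


def weighted_avg_size(matrix: CopyMatrix, scheme: str = "inv_max",
                      family_subset=None) -> pd.Series:
    """Weighted average gene family size per species."""
    weights, mean_max = family_weights(matrix, scheme, family_subset)
    counts = matrix.counts.loc[weights.index]
    n = len(weights)
    sizes = counts.mul(weights, axis=0).sum(axis=0) / n * mean_max
    zero_sp = sizes.index[counts.sum(axis=0) == 0]
    if len(zero_sp):
        warnings.warn(
            f"{len(zero_sp)} species have zero copies in every retained "
            f"family; reported as 0")
    return sizes


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts

@dataclass(frozen=True)
class PICResult:
    """Standardized contrasts, one per internal node in postorder."""

    contrasts: np.ndarray
    node_labels: list

    def __len__(self) -> int:
        return len(self.contrasts)


def pic(tree: dendropy.Tree, trait: dict) -> PICResult:
    """Felsenstein's phylogenetically independent contrasts.

    At each internal node of a strictly bifurcating tree the contrast is
    (x_L - x_R) / sqrt(b'_L + b'_R), where x are the pruned trait values of
    the two children and b' their branch lengths adjusted upward by
    b_L b_R / (b_L + b_R) at each pruning step.
    """
    values: dict = {}
    lengths: dict = {}
    contrasts: list[float] = []
    labels: list[str] = []
    for node in tree.postorder_node_iter():
        edge_len = node.edge.length if node.parent_node is not None else 0.0
        if edge_len is None:
            raise ValueError("contrasts require branch lengths on every edge")
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise ValueError(f"no trait value for tip {label!r}")
            values[node] = float(trait[label])
            lengths[node] = float(edge_len)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"tree must be strictly bifurcating (node with {len(children)} "
                f"children); resolve polytomies upstream")
        left, right = children
        bl, br = lengths[left], lengths[right]
        if bl + br <= 0:
            raise ValueError("zero-length cherry: contrasts undefined")
        contrasts.append((values[left] - values[right]) / np.sqrt(bl + br))
        labels.append(node.label or f"node{len(contrasts)}")
        values[node] = (values[left] / bl + values[right] / br) / (1 / bl + 1 / br) \
            if bl > 0 and br > 0 else (values[left] if br == 0 else values[right])
        lengths[node] = float(edge_len) + bl * br / (bl + br)
    return PICResult(contrasts=np.asarray(contrasts), node_labels=labels)


def pic_correlation(tree: dendropy.Tree, trait_x: dict, trait_y: dict,
                    *, method: str = "auto") -> dict:
    """Spearman correlation and through-origin slope of two traits' PICs.

    The slope is sum(c_x c_y) / sum(c_x^2): regression through the origin,
    as contrasts have arbitrary sign.  ``method`` is 'approx' (large-sample
    t approximation), 'exact' (full permutation enumeration, n <= 10), or
    'auto' (exact when n <= 7).
    """
    cx = pic(tree, trait_x).contrasts
    cy = pic(tree, trait_y).contrasts
    if len(cx) < 3:
        raise ValueError("need at least 3 contrast pairs")
    rho, p = stats.spearmanr(cx, cy)
    if method == "auto":
        method = "exact" if len(cx) <= 7 else "approx"
    if method == "exact":
        if len(cx) > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        p = _exact_spearman_p(cx, cy)
    denom = float(np.sum(cx ** 2))
    slope = float(np.sum(cx * cy)) / denom if denom > 0 else np.nan
    return {"rho": float(rho), "pvalue": float(p), "slope": slope,
            "n_contrasts": int(len(cx))}


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for Spearman's rho by full enumeration."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n_hit = total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        total += 1
        if r >= obs - 1e-12:
            n_hit += 1
    return n_hit / total
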