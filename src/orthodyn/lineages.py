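"""Detection of faster- and slower-evolving lineages, and tip-rate statistics.

Per-order workflow: the evolutionary rate of each tip is its summed branch
length back to the root (or to the order's most recent common ancestor —
the two give the same splits on clock-like backbones).  Orders whose rate
distribution rejects unimodality (Hartigan dip test, Monte-Carlo p) are
split by one-dimensional DBSCAN on the rates; the cluster with the higher
mean rate is the faster-evolving lineage (FEL), the remaining clustered
tips the slower-evolving lineage (SEL), unclustered tips noise.

Also here: the DR tip speciation-rate statistic (inverse equal-splits sum),
unpaired rank-based two-group comparison, and per-species intron summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

from .dip import dip_test
from .io import GroupMap

__all__ = ["root_to_tip_rates", "LineageSplit", "split_lineages",
           "dr_statistic", "compare_groups", "intron_summaries"]


def root_to_tip_rates(tree: dendropy.Tree, to_node: dendropy.Node | None = None
                      ) -> pd.Series:
    """Summed branch length from each tip to the root (or a given ancestor).

    With ``to_node`` set, rates are measured only for tips descending from
    that node, up to it — the per-order MRCA variant.
    """
    start = to_node if to_node is not None else tree.seed_node
    rates = {}
    for leaf in start.leaf_iter():
        d = 0.0
        node = leaf
        while node is not start:
            if node.edge.length is None:
                raise ValueError("missing branch length on the path to the root")
            d += node.edge.length
            node = node.parent_node
        rates[leaf.taxon.label] = d
    return pd.Series(rates).sort_index()


@dataclass
class GroupSplit:
    fel_tips: list = field(default_factory=list)
    sel_tips: list = field(default_factory=list)
    noise_tips: list = field(default_factory=list)
    dip_p_rates: float = np.nan
    dip_p_sizes: float = np.nan
    cluster_mean_rates: dict = field(default_factory=dict)


@dataclass
class LineageSplit:
    """Per-group FEL/SEL assignment; groups without a split have fel = []."""

    groups: dict  # group label -> GroupSplit

    @property
    def fel_tips(self) -> list:
        return sorted(t for g in self.groups.values() for t in g.fel_tips)

    @property
    def sel_tips(self) -> list:
        return sorted(t for g in self.groups.values() for t in g.sel_tips)

    def split_orders(self) -> list:
        return sorted(g for g, s in self.groups.items() if s.fel_tips)


def _default_eps(x: np.ndarray, min_pts: int) -> float:
    """DBSCAN radius: 3x the median k-nearest-neighbour distance (k=min_pts),
    with a fallback to 5% of the data range when the kNN distances collapse
    to zero (exactly repeated rates)."""
    xs = np.sort(x)
    n = len(xs)
    k = min(min_pts, n - 1)
    d = np.abs(xs[:, None] - xs[None, :])
    knn = np.sort(d, axis=1)[:, k]
    eps = 3.0 * float(np.median(knn))
    if eps <= 0:
        rng_ = float(xs[-1] - xs[0])
        eps = 0.05 * rng_ if rng_ > 0 else 1e-9
    return eps


def split_lineages(rates: pd.Series, sizes: pd.Series, groups: GroupMap,
                   *, alpha: float = 0.05, eps: float | None = None,
                   min_pts: int = 3, n_boot: int = 2000,
                   force_split: tuple = ()) -> LineageSplit:
    """Partition each group's tips into FEL / SEL / noise.

    A group is split only when the dip test on its rates has p <= ``alpha``
    (the dip p on its weighted sizes is recorded alongside), unless listed
    in ``force_split``.  DBSCAN runs on rates alone; if it finds fewer than
    two clusters the group stays unsplit.
    """
    out: dict = {}
    for group, members in sorted(groups.groups.items()):
        missing = [m for m in members if m not in rates.index or m not in sizes.index]
        if missing:
            raise ValueError(f"tips without rate/size values: {missing[:5]}")
        g = GroupSplit()
        out[group] = g
        r = rates[members].to_numpy()
        if len(members) < max(min_pts, 4):
            import warnings
            warnings.warn(f"group {group!r} smaller than min_pts/dip minimum; skipped")
            continue
        if np.ptp(r) <= 1e-9 * max(1.0, float(np.abs(r).max())):
            # effectively clock-like rates: unimodal by construction (the
            # dip is scale-invariant, so spacing-level float noise must not
            # be read as multimodality)
            g.dip_p_rates = 1.0
            g.dip_p_sizes = dip_test(sizes[members].to_numpy(), n_boot=n_boot).pvalue
            continue
        g.dip_p_rates = dip_test(r, n_boot=n_boot).pvalue
        g.dip_p_sizes = dip_test(sizes[members].to_numpy(), n_boot=n_boot).pvalue
        if g.dip_p_rates > alpha and group not in force_split:
            continue
        e = eps if eps is not None else _default_eps(r, min_pts)
        labels = DBSCAN(eps=e, min_samples=min_pts).fit_predict(r[:, None])
        clusters = sorted(set(labels) - {-1})
        if len(clusters) < 2:
            continue
        means = {c: float(r[labels == c].mean()) for c in clusters}
        fel_cluster = max(means, key=means.get)
        for m, lab in zip(members, labels):
            if lab == -1:
                g.noise_tips.append(m)
            elif lab == fel_cluster:
                g.fel_tips.append(m)
            else:
                g.sel_tips.append(m)
        g.cluster_mean_rates = means
        g.fel_tips.sort(), g.sel_tips.sort(), g.noise_tips.sort()
    return LineageSplit(groups=out)


# ---------------------------------------------------------------------------
# DR statistic

def dr_statistic(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip speciation rates by the inverse equal-splits method.

    For tip i with root-ward edge lengths l_1 (pendant), l_2, ... l_d,
    ES_i = sum_j l_j / 2^(j-1) and DR_i = 1 / ES_i.  Each edge's length is
    shared equally at every split above it, so old, sparsely divided tips
    accumulate a large ES and hence a low rate.
    """
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) > 2:
            raise ValueError("equal-splits requires a bifurcating tree")
    rows = {}
    for leaf in tree.leaf_node_iter():
        es = 0.0
        w = 1.0
        node = leaf
        while node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError("missing branch length")
            es += node.edge.length * w
            w *= 0.5
            node = node.parent_node
        if es <= 0:
            raise ValueError(f"tip {leaf.taxon.label!r} has zero path length")
        rows[leaf.taxon.label] = es
    df = pd.DataFrame({"ES": pd.Series(rows).sort_index()})
    df["DR"] = 1.0 / df["ES"]
    return df


# ---------------------------------------------------------------------------
# group comparisons

def compare_groups(values_a, values_b, *, paired: bool = False) -> dict:
    """Two-sided rank-based comparison of two samples with medians.

    Default is the unpaired Mann-Whitney rank-sum test (exact enumeration
    when both samples are tie-free and no larger than 20, normal
    approximation with tie correction otherwise).  ``paired`` switches to
    the Wilcoxon signed-rank test for equal-length paired samples.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = {"median_a": float(np.median(a)), "median_b": float(np.median(b)),
           "n_a": int(a.size), "n_b": int(b.size)}
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        import warnings
        warnings.warn("all pooled values identical; p = 1")
        res["pvalue"] = 1.0
        return res
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal sample sizes")
        res["pvalue"] = float(stats.wilcoxon(a, b).pvalue)
        return res
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not ties and max(a.size, b.size) <= 20) else "asymptotic"
    res["pvalue"] = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                             method=method).pvalue)
    return res


def intron_summaries(introns: pd.DataFrame, class_of: dict,
                     *, ani_denominator: str = "intron_containing") -> dict:
    """Per-species TNI/ANI and a rank-based comparison between two classes.

    TNI is the species' total intron count; ANI the mean intron count over
    intron-containing genes (``ani_denominator='all_genes'`` divides by all
    genes instead).  ``class_of`` maps species to one of exactly two class
    labels (e.g. 'fel'/'sel'); unmapped species are ignored.
    """
    need = {"gene", "species", "introns"}
    if not need <= set(introns.columns):
        raise ValueError(f"intron table must have columns {sorted(need)}")
    if (introns["introns"] < 0).any():
        raise ValueError("negative intron count")
    per_sp = []
    for sp, sub in introns.groupby("species"):
        if len(sub) == 0:
            raise ValueError(f"species {sp!r} has no genes")
        tni = int(sub["introns"].sum())
        if ani_denominator == "intron_containing":
            carriers = sub.loc[sub["introns"] > 0, "introns"]
            ani = float(carriers.mean()) if len(carriers) else np.nan
        else:
            ani = float(sub["introns"].mean())
        per_sp.append((sp, tni, ani, len(sub)))
    table = pd.DataFrame(per_sp, columns=["species", "TNI", "ANI", "n_genes"]
                         ).set_index("species").sort_index()
    classes = sorted({c for c in class_of.values()})
    comparisons = {}
    if len(classes) == 2:
        ca, cb = classes
        sel = table.index.map(lambda s: class_of.get(s))
        for col in ("TNI", "ANI"):
            va = table.loc[sel == ca, col].dropna()
            vb = table.loc[sel == cb, col].dropna()
            if len(va) and len(vb):
                comparisons[col] = {"class_a": ca, "class_b": cb,
                                    **compare_groups(va, vb)}
    return {"table": table, "comparisons": comparisons}
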