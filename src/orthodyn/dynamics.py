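"""Fold-change classification of family dynamics, net-change tallies, and
term enrichment.

Fold change compares per-family mean copy numbers between the
faster-evolving (FEL) and slower-evolving (SEL) tips of an order:
fc = mean_FEL / mean_SEL.  Categories: fc = 0 is a loss, fc < 0.67 a
contraction, fc > 1.5 an expansion, an infinite fc (SEL mean 0, FEL mean
positive) a gain, everything in between stable (the boundaries 0.67 and
1.5 themselves count as stable: the thresholds are strict).  Significance
per family is a two-sample Kolmogorov-Smirnov test between the per-species
copy-number samples of the two lineages, Bonferroni-adjusted over the
families actually tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationMap, CopyMatrix

__all__ = ["fold_change_table", "net_change_tally", "enrich"]

FC_CONTRACTION = 0.67
FC_EXPANSION = 1.5


def _category(mean_fel: float, mean_sel: float) -> str:
    if mean_fel == 0 and mean_sel == 0:
        return "undefined"
    if mean_fel == 0:
        return "loss"
    if mean_sel == 0:
        return "gain"
    fc = mean_fel / mean_sel
    if fc < FC_CONTRACTION:
        return "contraction"
    if fc > FC_EXPANSION:
        return "expansion"
    return "stable"


def fold_change_table(matrix: CopyMatrix, fel_tips, sel_tips,
                      family_subset=None, *, alpha: float = 0.05,
                      exact_max_n: int = 12) -> pd.DataFrame:
    """Per-family FEL/SEL means, fold change, category and KS significance.

    The KS statistic compares the family's per-species copy numbers in the
    FEL sample against the SEL sample (exact p for min(n, m) <=
    ``exact_max_n``, asymptotic otherwise).  Families with both means zero
    are reported as undefined and excluded from the multiple-testing
    correction.  ``significant`` requires adjusted p <= alpha and a
    non-stable, defined category.
    """
    fel = [t for t in fel_tips]
    sel = [t for t in sel_tips]
    if not fel or not sel:
        raise ValueError("both FEL and SEL tip sets must be nonempty")
    unknown = (set(fel) | set(sel)) - set(matrix.species_ids)
    if unknown:
        raise ValueError(f"tips not in matrix: {sorted(unknown)[:5]}")
    counts = matrix.counts
    if family_subset is not None:
        counts = counts.loc[[f for f in counts.index if f in set(family_subset)]]
    a = counts[fel].to_numpy(dtype=float)
    b = counts[sel].to_numpy(dtype=float)
    mean_fel = a.mean(axis=1)
    mean_sel = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_fel / mean_sel
    rows = []
    for i, fam in enumerate(counts.index):
        cat = _category(mean_fel[i], mean_sel[i])
        if cat == "undefined":
            p = np.nan
        else:
            method = "exact" if min(len(fel), len(sel)) <= exact_max_n else "asymp"
            p = stats.ks_2samp(a[i], b[i], method=method).pvalue
        rows.append((fam, mean_fel[i], mean_sel[i], fc[i], cat, p))
    df = pd.DataFrame(rows, columns=["family", "mean_fel", "mean_sel",
                                     "fold_change", "category", "p_raw"])
    tested = df["p_raw"].notna()
    m = int(tested.sum())
    df["p_adj"] = np.nan
    df.loc[tested, "p_adj"] = np.minimum(df.loc[tested, "p_raw"] * m, 1.0)
    df["significant"] = (df["p_adj"] <= alpha) & ~df["category"].isin(
        ["stable", "undefined"])
    return df


def net_change_tally(branch_deltas: pd.DataFrame) -> pd.DataFrame:
    """Sum per-branch copy-number changes into per-family net change.

    ``branch_deltas`` needs columns ``family`` and ``delta`` (integer change
    on one branch of the order's subtree); an optional ``order`` column is
    carried through and tallied within.  Net > 0 is an expansion, < 0 a
    contraction, = 0 no change.
    """
    need = {"family", "delta"}
    if not need <= set(branch_deltas.columns):
        raise ValueError(f"need columns {sorted(need)}")
    deltas = branch_deltas["delta"]
    if not np.issubdtype(np.asarray(deltas).dtype, np.integer):
        as_float = pd.to_numeric(deltas)
        if np.any(as_float != np.floor(as_float)):
            raise ValueError("branch deltas must be integers")
        branch_deltas = branch_deltas.assign(delta=as_float.astype(np.int64))
    keys = ["order", "family"] if "order" in branch_deltas.columns else ["family"]
    net = branch_deltas.groupby(keys, sort=True)["delta"].sum().reset_index()
    net = net.rename(columns={"delta": "net_change"})
    net["category"] = np.select(
        [net["net_change"] > 0, net["net_change"] < 0],
        ["expansion", "contraction"], default="no_change")
    return net


def enrich(target_families, background_families,
           annotations: AnnotationMap) -> pd.DataFrame:
    """One-sided hypergeometric (Fisher) term enrichment with BH adjustment.

    For each term annotating at least one target family: k = annotated
    targets, K = annotated background families, n = target size, N =
    background size; p = P[X >= k] for X ~ Hypergeom(N, K, n).  Terms
    absent from the background are not tested.  Results are sorted by p.
    """
    target = sorted(set(target_families))
    background = sorted(set(background_families))
    if not target:
        raise ValueError("empty target set")
    if not set(target) <= set(background):
        raise ValueError("target must be a subset of the background")
    N = len(background)
    n = len(target)
    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for fam in background:
        for t in annotations.terms_of(fam):
            term_bg[t] = term_bg.get(t, 0) + 1
    for fam in target:
        for t in annotations.terms_of(fam):
            term_tg[t] = term_tg.get(t, 0) + 1
    rows = []
    for term in sorted(term_tg):
        k = term_tg[term]
        K = term_bg[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p,
                     annotations.term_descriptions.get(term, "")))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p",
                                     "description"])
    if len(df):
        df["p_adj"] = stats.false_discovery_control(df["p"], method="bh")
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
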