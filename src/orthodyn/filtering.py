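"""Lineage-based coverage filtering, orphan families, and parsimony presence.

Coverage of a family in a group is the fraction of that group's species
carrying at least one copy; the family's overall coverage is the unweighted
mean over groups.  Families below a coverage threshold are treated as
species-specific and excluded from the weighted-size analyses; families
covering essentially all of exactly one order (and nothing else) are orphan
candidates whose evolutionary origin is then classified from staged
homology-hit thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import CopyMatrix, GroupMap

__all__ = ["compute_coverage", "filter_families", "fitch_state_sets",
           "fitch_presence_at_node", "cafe_inclusion_filter", "find_orphans",
           "classify_orphan_origin", "OrphanRecord"]

# in-dataset homology thresholds (e-value, bit score, percent identity) and
# external-database thresholds (e-value, bit score only)
EVALUE_MAX = 1e-5
BITSCORE_MIN = 50.0
PIDENT_MIN = 40.0


def compute_coverage(matrix: CopyMatrix, groups: GroupMap) -> pd.DataFrame:
    """Per-family coverage in each group plus the unweighted group average.

    Returns a DataFrame indexed by family with one column per group and an
    ``average`` column.
    """
    missing = set(matrix.species_ids) - set(groups.assignment)
    if missing:
        raise ValueError(f"species without group assignment: {sorted(missing)[:5]}")
    presence = matrix.presence()
    cols = {}
    for group, members in sorted(groups.groups.items()):
        members = [m for m in members if m in presence.columns]
        if not members:
            raise ValueError(f"group {group!r} has no species in the matrix")
        cols[group] = presence[members].mean(axis=1)
    cov = pd.DataFrame(cols)
    cov["average"] = cov.mean(axis=1)
    return cov


def filter_families(coverage: pd.DataFrame, threshold: float) -> list[str]:
    """Families whose average coverage reaches ``threshold`` (inclusive).

    The complement is the species-specific set.  Thresholds used in
    practice: 0.1 (relaxed, for the weighted-size and fold-change stages)
    and 0.5 (conserved families for the presence PCA).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return list(coverage.index[coverage["average"] >= threshold])


# ---------------------------------------------------------------------------
# Fitch parsimony

def fitch_state_sets(tree: dendropy.Tree, presence: dict) -> dict:
    """Bottom-up Fitch state sets for a binary presence character.

    Returns a mapping from every node to its state set (frozenset of 0/1):
    intersection of the child sets where nonempty, else their union.  The
    set at a node is computed from its subtree only.
    """
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in presence:
                raise ValueError(f"tip {label!r} has no presence state")
            state = int(presence[label])
            if state not in (0, 1):
                raise ValueError(f"tip {label!r} state {state!r} is not binary")
            sets[node] = frozenset({state})
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            sets[node] = inter if inter else frozenset.union(*child_sets)
    return sets


def fitch_presence_at_node(tree: dendropy.Tree, presence: dict,
                           node: dendropy.Node | None = None,
                           *, ambiguous_is_present: bool = True) -> bool:
    """Parsimony presence call at ``node`` (default: the root).

    An ambiguous state set {0, 1} counts as present under the default
    inclusive policy, which retains families conservatively.
    """
    sets = fitch_state_sets(tree, presence)
    node = node if node is not None else tree.seed_node
    s = sets[node]
    if s == frozenset({0, 1}):
        return ambiguous_is_present
    return 1 in s


def cafe_inclusion_filter(matrix: CopyMatrix, groups: GroupMap,
                          tree: dendropy.Tree, focal_order: str,
                          outgroup_species: list[str]) -> list[str]:
    """Families eligible for birth-death modelling of a focal order.

    A family is retained if it satisfies any of: (1) parsimony presence at
    the focal order's MRCA; (2) at least one copy in the focal order and in
    any other order; (3) at least one copy in the focal order and in the
    outgroup species.
    """
    focal_sp = groups.species_of(focal_order)
    unknown = set(outgroup_species) - set(matrix.species_ids)
    if unknown:
        raise ValueError(f"unknown outgroup species: {sorted(unknown)[:5]}")
    other_sp = [s for s in matrix.species_ids
                if s not in set(focal_sp) and s not in set(outgroup_species)
                and s in groups.assignment]
    taxa = [t for t in tree.taxon_namespace if t.label in set(focal_sp)]
    mrca = tree.mrca(taxa=taxa)
    presence = matrix.presence()
    focal = presence[[s for s in focal_sp if s in presence.columns]]
    kept = []
    for fam in matrix.family_ids:
        in_focal = bool(focal.loc[fam].any())
        crit2 = in_focal and bool(presence.loc[fam, other_sp].any()) if other_sp else False
        crit3 = in_focal and bool(presence.loc[fam, list(outgroup_species)].any()) \
            if outgroup_species else False
        if crit2 or crit3:
            kept.append(fam)
            continue
        states = {sp: int(presence.loc[fam, sp]) for sp in focal.columns}
        sub = {leaf.taxon.label: states.get(leaf.taxon.label, 0)
               for leaf in mrca.leaf_iter()}
        # bottom-up set at the order MRCA, over its subtree
        if _fitch_subtree_present(mrca, sub):
            kept.append(fam)
    return kept


def _fitch_subtree_present(node: dendropy.Node, presence: dict) -> bool:
    sets: dict = {}
    for nd in node.postorder_iter():
        if nd.is_leaf():
            sets[nd] = frozenset({int(presence[nd.taxon.label])})
        else:
            cs = [sets[c] for c in nd.child_nodes()]
            inter = frozenset.intersection(*cs)
            sets[nd] = inter if inter else frozenset.union(*cs)
    return 1 in sets[node]


# ---------------------------------------------------------------------------
# orphan families

@dataclass
class OrphanRecord:
    family: str
    host_order: str
    host_coverage: float
    origin: str | None = None          # family-level call (majority vote)
    gene_origins: dict | None = None   # per-gene calls


def find_orphans(coverage: pd.DataFrame, host_threshold: float = 0.98
                 ) -> list[OrphanRecord]:
    """Families covering >= ``host_threshold`` of exactly one order's
    species and completely absent from every other order."""
    group_cols = [c for c in coverage.columns if c != "average"]
    if len(group_cols) < 2:
        raise ValueError("orphan detection needs at least 2 groups")
    records = []
    vals = coverage[group_cols]
    for fam, row in vals.iterrows():
        nz = row[row > 0]
        if len(nz) == 1 and nz.iloc[0] >= host_threshold:
            records.append(OrphanRecord(family=fam, host_order=nz.index[0],
                                        host_coverage=float(nz.iloc[0])))
    return records


def classify_orphan_origin(orphans: list[OrphanRecord], hits: pd.DataFrame,
                           gene_to_family: dict, gene_to_species: dict,
                           groups: GroupMap) -> list[OrphanRecord]:
    """Assign an origin to each orphan family from its genes' homology hits.

    Per gene: an in-dataset hit to a species outside the host order passing
    e-value/bit-score/identity thresholds implies duplication or speciation
    followed by divergence; otherwise an external-database hit passing the
    e-value/bit-score thresholds implies putative horizontal transfer;
    otherwise the gene is putatively de novo.  The family-level origin is
    the majority vote over its genes, ties resolved to de novo; the
    per-gene calls are also retained.
    """
    fam_genes: dict[str, list[str]] = {}
    for gene, fam in gene_to_family.items():
        fam_genes.setdefault(fam, []).append(gene)
    hit_by_gene: dict[str, pd.DataFrame] = {
        str(g): sub for g, sub in hits.groupby("qseqid")}
    out = []
    for rec in orphans:
        gene_calls: dict[str, str] = {}
        for gene in sorted(fam_genes.get(rec.family, [])):
            rows = hit_by_gene.get(gene)
            gene_calls[gene] = _classify_gene(rows, rec.host_order,
                                              gene_to_species, groups)
        counts = pd.Series(gene_calls).value_counts() if gene_calls else pd.Series(dtype=int)
        if counts.empty:
            family_origin = "de_novo"
        else:
            top = counts[counts == counts.max()]
            family_origin = "de_novo" if len(top) > 1 else str(top.index[0])
        out.append(OrphanRecord(family=rec.family, host_order=rec.host_order,
                                host_coverage=rec.host_coverage,
                                origin=family_origin, gene_origins=gene_calls))
    return out


def _classify_gene(rows: pd.DataFrame | None, host_order: str,
                   gene_to_species: dict, groups: GroupMap) -> str:
    if rows is None or rows.empty:
        return "de_novo"
    in_ds = rows[rows["source"] == "in_dataset"]
    for r in in_ds.itertuples(index=False):
        subj_sp = gene_to_species.get(r.sseqid)
        if subj_sp is None:
            raise ValueError(f"cannot resolve hit subject {r.sseqid!r} to a species")
        if groups.assignment.get(subj_sp) == host_order:
            continue
        if (r.evalue < EVALUE_MAX and r.bitscore > BITSCORE_MIN
                and r.pident > PIDENT_MIN):
            return "duplication_speciation"
    ext = rows[rows["source"] == "external_db"]
    # the identity threshold applies only to the in-dataset comparison
    if ((ext["evalue"] < EVALUE_MAX) & (ext["bitscore"] > BITSCORE_MIN)).any():
        return "hgt"
    return "de_novo"
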