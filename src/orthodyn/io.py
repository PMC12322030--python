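"""Readers/writers for the external formats consumed by the pipeline.

All tabular formats are strict TSV: tab-separated, UTF-8, ``.`` decimal
separator, mandatory header row, no quoting.  This matches the conventions
of OrthoFinder's ``Orthogroups.GeneCount.tsv`` and BLAST ``-outfmt 6``
tables, from which the dialects here are derived.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CopyMatrix",
    "GroupMap",
    "AnnotationMap",
    "read_copy_matrix",
    "write_copy_matrix",
    "read_tree",
    "write_tree",
    "read_group_map",
    "write_group_map",
    "read_annotation_map",
    "read_hit_table",
    "write_table",
    "align_matrix_and_tree",
]

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "evalue", "bitscore", "source"]
HIT_SOURCES = frozenset({"in_dataset", "external_db"})


@dataclass(frozen=True)
class CopyMatrix:
    """Gene-family x species copy-number matrix.

    ``counts`` is a pandas DataFrame indexed by family id with one integer
    column per species.  Every downstream stage consumes this object.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate family ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
                raise ValueError("copy numbers must be integers")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative copy number at family {df.index[r]!r}, "
                f"species {df.columns[c]!r}"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def presence(self) -> pd.DataFrame:
        """Binary presence (1) / absence (0) view of the counts."""
        return (self.counts > 0).astype(np.int64)

    def subset(self, families: Iterable[str]) -> "CopyMatrix":
        fams = [f for f in self.counts.index if f in set(families)]
        return CopyMatrix(self.counts.loc[fams])


@dataclass(frozen=True)
class GroupMap:
    """Species -> group (taxonomic order) assignment."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty group map")
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sp, g in self.assignment.items():
            out.setdefault(g, []).append(sp)
        return out

    def species_of(self, group: str) -> list[str]:
        members = self.groups.get(group)
        if not members:
            raise KeyError(f"unknown or empty group {group!r}")
        return members


@dataclass(frozen=True)
class AnnotationMap:
    """Family -> functional-term sets plus term descriptions."""

    family_terms: Mapping[str, frozenset]
    term_descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "family_terms",
            {f: frozenset(ts) for f, ts in self.family_terms.items()},
        )
        object.__setattr__(self, "term_descriptions", dict(self.term_descriptions))

    def terms_of(self, family: str) -> frozenset:
        return self.family_terms.get(family, frozenset())


def read_copy_matrix(
    path, dialect: Literal["orthofinder_genecount", "plain_tsv"] = "orthofinder_genecount"
) -> CopyMatrix:
    """Read a family-by-species count table.

    The OrthoFinder ``Orthogroups.GeneCount.tsv`` dialect carries a trailing
    ``Total`` column, which is dropped; ``plain_tsv`` expects species columns
    only.  Row and column order are preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    if dialect == "orthofinder_genecount" and len(df.columns) and df.columns[-1] == "Total":
        df = df.iloc[:, :-1]
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    arr = numeric.to_numpy()
    bad = np.argwhere((arr != np.floor(arr)) | (arr < 0))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"invalid count {arr[r, c]!r} at family {df.index[r]!r}, "
            f"species {df.columns[c]!r} in {path}"
        )
    return CopyMatrix(numeric.astype(np.int64))


def write_copy_matrix(matrix: CopyMatrix, path, dialect: str = "plain_tsv") -> None:
    df = matrix.counts.copy()
    df.index.name = df.index.name or "Orthogroup"
    if dialect == "orthofinder_genecount":
        df = df.assign(Total=df.sum(axis=1))
    df.to_csv(path, sep="\t")


def read_tree(path_or_string, *, require_lengths: bool = True) -> dendropy.Tree:
    """Parse a rooted Newick tree, checking tip-label uniqueness.

    Missing branch lengths raise only when ``require_lengths`` is set;
    topology-only uses (e.g. Fitch parsimony) may pass ``False``.
    """
    src = str(path_or_string)
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, **kwargs)
        else:
            tree = dendropy.Tree.get(path=src, **kwargs)
    except Exception as exc:  # dendropy raises reader-specific errors
        msg = str(exc)
        if "uplicate" in msg or "multiple times" in msg:
            raise ValueError(f"duplicate tip labels in tree: {msg}") from exc
        raise ValueError(f"unparseable Newick: {msg}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dup}")
    if require_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has missing branch lengths")
            if edge.length < 0:
                raise ValueError("tree has negative branch lengths")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def read_group_map(path) -> GroupMap:
    df = _read_tsv(path, required=["species", "group"])
    dup = df["species"][df["species"].duplicated()]
    if len(dup):
        raise ValueError(f"species assigned to multiple groups: {dup.tolist()[:5]}")
    return GroupMap(dict(zip(df["species"], df["group"])))


def write_group_map(groups: GroupMap, path) -> None:
    df = pd.DataFrame(
        sorted(groups.assignment.items()), columns=["species", "group"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_map(path) -> AnnotationMap:
    """Read ``family<TAB>term[<TAB>description]`` rows (one term per row)."""
    df = _read_tsv(path, required=["family", "term"])
    fam_terms: dict[str, set] = {}
    desc: dict[str, str] = {}
    for row in df.itertuples(index=False):
        fam_terms.setdefault(row.family, set()).add(row.term)
        if hasattr(row, "description") and isinstance(row.description, str):
            desc[row.term] = row.description
    return AnnotationMap(
        {f: frozenset(ts) for f, ts in fam_terms.items()}, desc
    )


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-like homology hit table with a source tag.

    Columns: qseqid, sseqid, pident, evalue, bitscore, source; the source
    tag distinguishes hits against the in-dataset proteomes from hits
    against an external database.
    """
    df = _read_tsv(path, required=HIT_COLUMNS)
    for col in ("pident", "evalue", "bitscore"):
        df[col] = pd.to_numeric(df[col])
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        bad = df.loc[(df["pident"] < 0) | (df["pident"] > 100), "pident"].iloc[0]
        raise ValueError(f"percent identity {bad} outside [0, 100]")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-value")
    if (df["bitscore"] < 0).any():
        raise ValueError("negative bit score")
    unknown = set(df["source"]) - HIT_SOURCES
    if unknown:
        raise ValueError(f"unknown hit source tags: {sorted(unknown)}")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, *, sort_by: str | list[str] | None = None) -> None:
    """Write a results table deterministically (sorted rows, %.10g floats)."""
    out = df.copy()
    if sort_by is None and len(out.columns):
        sort_by = out.columns[0]
    if sort_by is not None:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def align_matrix_and_tree(
    matrix: CopyMatrix,
    tree: dendropy.Tree,
    policy: Literal["error", "intersect"] = "error",
) -> tuple[CopyMatrix, dendropy.Tree]:
    """Reconcile the species sets of a count matrix and a tree.

    ``error`` (default) refuses any mismatch — silent intersection hides
    upstream data bugs; ``intersect`` prunes both to the common species.
    """
    mat_sp = set(matrix.species_ids)
    tree_sp = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if mat_sp == tree_sp:
        return matrix, tree
    if policy == "error":
        raise ValueError(
            f"species mismatch: {sorted(mat_sp - tree_sp)[:5]} only in matrix, "
            f"{sorted(tree_sp - mat_sp)[:5]} only in tree"
        )
    common = mat_sp & tree_sp
    if not common:
        raise ValueError("no species in common between matrix and tree")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(common))
    cols = [s for s in matrix.species_ids if s in common]
    return CopyMatrix(matrix.counts[cols]), pruned


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("species", "group",
                     "family", "term", "qseqid", "sseqid", "source", "gene")})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df
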