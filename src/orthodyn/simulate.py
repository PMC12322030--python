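"""Synthetic orthogroup data with planted, recoverable structure.

The generator emulates the statistical shape of a large multi-order yeast
copy-number dataset: an ultrametric pure-birth species tree whose taxonomic
orders are monophyletic clades grafted onto a short ladder backbone, one
planted faster-evolving lineage (FEL) inside a designated order whose branch
lengths are inflated by a rate multiplier, and a family-by-species count
matrix built from labelled blocks:

* ``core``              — broadly present families, identical means everywhere;
* ``contracted_in_fel`` — mean reduced multiplicatively inside the FEL;
* ``lost_in_fel``       — structurally zero in FEL tips, positive elsewhere;
* ``gained_in_fel``     — positive only in FEL tips;
* ``driver``            — presence concentrated in a designated subset of
  orders, so that the first principal component of the presence matrix
  separates species by whether they carry the block;
* ``orphan``            — present in every tip of one host order, absent
  elsewhere, with simulated homology-hit tables encoding a planted origin
  (de novo / duplication-speciation / horizontal transfer) per family;
* ``rare_species_specific`` — present in a small fixed fraction of species,
  removed by the coverage filter.

Every random draw flows from one root seed through named substreams, so a
configuration is reproducible byte-for-byte.  The ground truth of all
planted labels is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .io import AnnotationMap, CopyMatrix, GroupMap

__all__ = ["CountModel", "SimConfig", "SimTruth", "SimBundle",
           "simulate_tree", "simulate_counts", "simulate_hit_tables",
           "simulate_introns", "simulate_all", "write_simulation"]

BLOCKS = ("core", "contracted_in_fel", "lost_in_fel", "gained_in_fel",
          "driver", "orphan", "rare_species_specific")
ORIGINS = ("de_novo", "duplication_speciation", "hgt")

# substream tags mixed into the seed sequence, one per generator stage
_STREAMS = {"tree": 11, "counts": 12, "hits": 13, "introns": 14}


@dataclass(frozen=True)
class CountModel:
    """Count noise model: per-cell distribution around the block mean.

    ``negative_binomial`` is parameterized by (mean, dispersion) with
    variance mean + mean^2/dispersion; ``fixed`` disables noise and rounds
    the mean (used for exact planted-block checks).
    """

    distribution: str = "poisson"
    dispersion: float = 5.0

    def draw(self, rng: np.random.Generator, mean: float, size) -> np.ndarray:
        if mean < 0:
            raise ValueError("negative mean")
        if self.distribution == "poisson":
            return rng.poisson(mean, size=size)
        if self.distribution == "negative_binomial":
            if mean == 0:
                return np.zeros(size, dtype=np.int64)
            th = self.dispersion
            return rng.negative_binomial(th, th / (th + mean), size=size)
        if self.distribution == "fixed":
            return np.full(size, int(round(mean)), dtype=np.int64)
        raise ValueError(f"unknown count distribution {self.distribution!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset (desk-scale defaults).

    Defaults mirror a 12-order clade with one faster-evolving lineage
    covering half of its order at twice the substitution rate, and a
    thousand gene families split across the planted blocks.
    """

    seed: int = 0
    n_orders: int = 12
    tips_per_order: int = 32
    fel_order: str = "O01"
    fel_fraction: float = 0.5
    rate_multiplier: float = 2.0
    block_sizes: dict = field(default_factory=lambda: {
        "core": 500, "contracted_in_fel": 60, "lost_in_fel": 40,
        "gained_in_fel": 30, "driver": 100, "orphan": 20,
        "rare_species_specific": 250})
    block_means: dict = field(default_factory=lambda: {
        "core": 2.0, "contracted_in_fel": 5.0, "lost_in_fel": 3.0,
        "gained_in_fel": 2.0, "driver": 1.0, "orphan": 2.0,
        "rare_species_specific": 1.0})
    count_model: CountModel = field(default_factory=CountModel)
    contraction_factor: float = 0.4
    driver_presence: float = 0.95
    driver_background: float = 0.02
    rare_fraction: float = 0.06
    annotation_terms_per_block: int = 2
    n_intron_genes: int = 100
    intron_mean_fel: float = 0.2
    intron_mean_sel: float = 0.5
    backbone_step: float = 0.02
    stem_length: float = 0.05

    def __post_init__(self) -> None:
        if self.n_orders < 2:
            raise ValueError("need at least 2 orders")
        if self.tips_per_order < 4:
            raise ValueError("dip testing downstream needs >=4 tips per order")
        if not 0 < self.fel_fraction <= 1:
            raise ValueError("fel_fraction must be in (0, 1]")
        if self.rate_multiplier < 1:
            raise ValueError("rate_multiplier must be >= 1")
        if set(self.block_sizes) - set(BLOCKS):
            raise ValueError(f"unknown blocks {set(self.block_sizes) - set(BLOCKS)}")
        if any(m <= 0 for m in self.block_means.values()):
            raise ValueError("block means must be positive")

    @property
    def order_labels(self) -> list[str]:
        return [f"O{i + 1:02d}" for i in range(self.n_orders)]

    @property
    def n_families(self) -> int:
        return sum(self.block_sizes.values())

    @property
    def driver_orders(self) -> list[str]:
        k = int(np.ceil(0.6 * self.n_orders))
        return self.order_labels[:k]

    @property
    def orphan_host_order(self) -> str:
        return self.order_labels[-1]

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stage]]))


@dataclass
class SimTruth:
    """Planted labels used as acceptance ground truth."""

    fel_tips: dict = field(default_factory=dict)          # order -> [tips]
    family_block: dict = field(default_factory=dict)      # family -> block
    orphan_host: dict = field(default_factory=dict)       # family -> order
    orphan_origin: dict = field(default_factory=dict)     # family -> origin
    driver_orders: list = field(default_factory=list)
    intron_means: dict = field(default_factory=dict)      # lineage class -> mean

    def families_of(self, block: str) -> list[str]:
        return [f for f, b in self.family_block.items() if b == block]


@dataclass
class SimBundle:
    config: SimConfig
    tree: dendropy.Tree
    groups: GroupMap
    matrix: CopyMatrix
    truth: SimTruth
    annotations: AnnotationMap
    hits: pd.DataFrame
    gene_to_family: dict
    gene_to_species: dict
    introns: pd.DataFrame


# ---------------------------------------------------------------------------
# tree

def _yule_clade(rng: np.random.Generator, n_tips: int, depth: float,
                labels: list[str], taxon_namespace) -> dendropy.Node:
    """Ultrametric pure-birth clade with ``n_tips`` extant tips.

    Split times follow a unit-rate Yule process (waiting time Exp(k) while k
    lineages exist) and are rescaled so every tip sits exactly at ``depth``
    below the returned clade root.
    """
    root = dendropy.Node()
    if n_tips == 1:
        leaf = root
        leaf.taxon = taxon_namespace.require_taxon(label=labels[0])
        root.depth_below = 0.0
        return root
    split_times = [0.0]
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    total = t + rng.exponential(1.0 / n_tips)
    scale = depth / total if total > 0 else 0.0
    # grow topology: each later split subdivides a uniformly chosen lineage
    root.sim_time = 0.0
    open_lineages = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        open_lineages.append(child)
    for st in split_times[1:]:
        idx = int(rng.integers(len(open_lineages)))
        node = open_lineages.pop(idx)
        node.sim_time = st
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            open_lineages.append(child)
    for i, leaf in enumerate(open_lineages):
        leaf.sim_time = total
        leaf.taxon = taxon_namespace.require_taxon(label=labels[i])
    for node in root.preorder_iter():
        if node is root:
            continue
        node.edge.length = (node.sim_time - node.parent_node.sim_time) * scale
    return root


def _pick_fel_clade(order_root: dendropy.Node, target: int) -> dendropy.Node:
    """Deterministically pick the planted FEL clade inside an order.

    Among internal nodes strictly below the order root, choose the one whose
    tip count is closest to the target; ties go to the earliest node in
    preorder (the first-branching candidate).
    """
    best, best_err = None, None
    for node in order_root.preorder_iter():
        if node is order_root or node.is_leaf():
            continue
        ntips = len(node.leaf_nodes())
        err = abs(ntips - target)
        if best is None or err < best_err:
            best, best_err = node, err
    if best is None:
        raise ValueError("order too small to hold a FEL clade")
    return best


def simulate_tree(config: SimConfig) -> tuple[dendropy.Tree, GroupMap, SimTruth]:
    """Simulate the species tree, order map and FEL assignment.

    The tree is ultrametric (total depth 1) when ``rate_multiplier`` is 1;
    otherwise every edge of the planted FEL clade, including its stem, is
    multiplied by the rate factor, making only that order non-clock-like.
    """
    rng = config.rng("tree")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    orders = config.order_labels
    assignment: dict[str, str] = {}
    order_roots: dict[str, dendropy.Node] = {}
    # pectinate spine: spine node i carries order clade i and the next spine
    # node; the last spine node carries the final two order clades
    spine = tree.seed_node
    spine_depth = 0.0
    for i, order in enumerate(orders):
        labels = [f"{order}_t{j + 1:02d}" for j in range(config.tips_per_order)]
        for lab in labels:
            assignment[lab] = order
        clade_depth = 1.0 - spine_depth - config.stem_length
        if clade_depth <= 0:
            raise ValueError("backbone too deep; reduce backbone_step")
        clade = _yule_clade(rng, config.tips_per_order, clade_depth, labels, tns)
        spine.add_child(clade)
        clade.edge.length = config.stem_length
        order_roots[order] = clade
        if i < len(orders) - 2:
            nxt = dendropy.Node()
            spine.add_child(nxt)
            nxt.edge.length = config.backbone_step
            spine = nxt
            spine_depth += config.backbone_step
    truth = SimTruth(driver_orders=list(config.driver_orders))

    if config.fel_order not in orders:
        raise ValueError(f"fel_order {config.fel_order!r} not among {orders}")
    target = max(2, int(round(config.fel_fraction * config.tips_per_order)))
    fel_root = _pick_fel_clade(order_roots[config.fel_order], target)
    for node in fel_root.preorder_iter():
        if node.edge.length is not None:
            node.edge.length *= config.rate_multiplier
    fel_tips = sorted(l.taxon.label for l in fel_root.leaf_iter())
    truth.fel_tips = {config.fel_order: fel_tips}
    truth.intron_means = {"fel": config.intron_mean_fel,
                          "sel": config.intron_mean_sel}
    return tree, GroupMap(assignment), truth


# ---------------------------------------------------------------------------
# counts

def simulate_counts(config: SimConfig, tree: dendropy.Tree, groups: GroupMap,
                    truth: SimTruth) -> tuple[CopyMatrix, SimTruth]:
    """Draw the family-by-species count matrix for every planted block."""
    rng = config.rng("counts")
    species = sorted(groups.assignment)
    tree_sp = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if tree_sp != species:
        raise ValueError("tree tips and group map species differ")
    n_sp = len(species)
    sp_order = np.array([groups.assignment[s] for s in species])
    fel = set(truth.fel_tips.get(config.fel_order, []))
    is_fel = np.array([s in fel for s in species])
    model = config.count_model
    cm = config.block_means

    def positive(mean: float, size) -> np.ndarray:
        """Strictly positive counts with the requested mean (>=1)."""
        if mean < 1:
            raise ValueError("means of structurally present blocks must be >= 1")
        return 1 + model.draw(rng, mean - 1.0, size)

    rows, fam_ids = [], []
    fam_counter = 0
    truth = replace_truth(truth)
    for block in BLOCKS:
        n_fam = config.block_sizes.get(block, 0)
        if n_fam == 0:
            continue
        for _ in range(n_fam):
            fam = f"F{fam_counter + 1:05d}"
            fam_counter += 1
            fam_ids.append(fam)
            truth.family_block[fam] = block
            if block == "core":
                row = model.draw(rng, cm[block], n_sp)
            elif block == "contracted_in_fel":
                row = model.draw(rng, cm[block], n_sp)
                row[is_fel] = model.draw(rng, cm[block] * config.contraction_factor,
                                         int(is_fel.sum()))
            elif block == "lost_in_fel":
                row = positive(cm[block], n_sp)
                row[is_fel] = 0
            elif block == "gained_in_fel":
                row = np.zeros(n_sp, dtype=np.int64)
                row[is_fel] = positive(cm[block], int(is_fel.sum()))
            elif block == "driver":
                p = np.where(np.isin(sp_order, config.driver_orders),
                             config.driver_presence, config.driver_background)
                if model.distribution == "fixed":
                    present = p >= 0.5
                else:
                    present = rng.random(n_sp) < p
                row = np.zeros(n_sp, dtype=np.int64)
                row[present] = positive(cm[block], int(present.sum()))
            elif block == "orphan":
                host = sp_order == config.orphan_host_order
                row = np.zeros(n_sp, dtype=np.int64)
                row[host] = positive(cm[block], int(host.sum()))
                truth.orphan_host[fam] = config.orphan_host_order
            elif block == "rare_species_specific":
                k = max(1, int(np.floor(config.rare_fraction * n_sp)))
                row = np.zeros(n_sp, dtype=np.int64)
                row[rng.choice(n_sp, size=k, replace=False)] = 1
            rows.append(np.asarray(row, dtype=np.int64))
    # planted origins cycle deterministically over the orphan families
    for i, fam in enumerate(sorted(truth.orphan_host)):
        truth.orphan_origin[fam] = ORIGINS[i % len(ORIGINS)]
    counts = pd.DataFrame(np.vstack(rows), index=fam_ids, columns=species)
    return CopyMatrix(counts), truth


def replace_truth(truth: SimTruth) -> SimTruth:
    return SimTruth(fel_tips=dict(truth.fel_tips),
                    family_block=dict(truth.family_block),
                    orphan_host=dict(truth.orphan_host),
                    orphan_origin=dict(truth.orphan_origin),
                    driver_orders=list(truth.driver_orders),
                    intron_means=dict(truth.intron_means))


def simulate_annotations(config: SimConfig, truth: SimTruth) -> AnnotationMap:
    """One dedicated term set per planted block, for enrichment checks."""
    fam_terms, desc = {}, {}
    for fam, block in truth.family_block.items():
        terms = {f"T:{block}:{j + 1}" for j in range(config.annotation_terms_per_block)}
        fam_terms[fam] = frozenset(terms)
        for t in terms:
            desc[t] = f"synthetic term for block {block}"
    return AnnotationMap(fam_terms, desc)


# ---------------------------------------------------------------------------
# homology hits and introns

def simulate_hit_tables(config: SimConfig, truth: SimTruth, groups: GroupMap
                        ) -> tuple[pd.DataFrame, dict, dict]:
    """Homology-hit rows realizing each orphan family's planted origin.

    de novo genes get no rows; duplication/speciation genes get one
    in-dataset hit outside the host order passing all three thresholds
    (e-value < 1e-5, bit score > 50, identity > 40%); HGT genes get an
    external-database hit passing the two-threshold rule plus an in-dataset
    decoy failing the identity cutoff.
    """
    rng = config.rng("hits")
    rows = []
    gene_to_family: dict[str, str] = {}
    gene_to_species: dict[str, str] = {}
    other_species = {order: [s for s, o in sorted(groups.assignment.items())
                             if o != order]
                     for order in {*truth.orphan_host.values()}}
    for fam in sorted(truth.orphan_host):
        host = truth.orphan_host[fam]
        origin = truth.orphan_origin[fam]
        host_tips = sorted(s for s, o in groups.assignment.items() if o == host)
        for sp in host_tips:
            gene = f"{fam}|{sp}"
            gene_to_family[gene] = fam
            gene_to_species[gene] = sp
            if origin == "de_novo":
                continue
            if origin == "duplication_speciation":
                subj_sp = other_species[host][int(rng.integers(len(other_species[host])))]
                rows.append((gene, f"{subj_sp}|g{int(rng.integers(1e6)):06d}",
                             round(45 + 40 * rng.random(), 1),
                             10 ** float(-6 - 14 * rng.random()),
                             round(60 + 100 * rng.random(), 1), "in_dataset"))
            elif origin == "hgt":
                rows.append((gene, f"NR_{int(rng.integers(1e8)):08d}",
                             round(25 + 10 * rng.random(), 1),
                             10 ** float(-6 - 6 * rng.random()),
                             round(55 + 40 * rng.random(), 1), "external_db"))
                # decoy within the dataset that fails the identity threshold
                subj_sp = other_species[host][int(rng.integers(len(other_species[host])))]
                rows.append((gene, f"{subj_sp}|g{int(rng.integers(1e6)):06d}",
                             round(20 + 15 * rng.random(), 1),
                             10 ** float(-6 - 2 * rng.random()),
                             round(52 + 10 * rng.random(), 1), "in_dataset"))
    hits = pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident",
                                       "evalue", "bitscore", "source"])
    # subject genes of in-dataset hits resolve to their species
    for r in hits.itertuples(index=False):
        if r.source == "in_dataset" and r.sseqid not in gene_to_species:
            gene_to_species[r.sseqid] = r.sseqid.split("|")[0]
    return hits, gene_to_family, gene_to_species


def simulate_introns(config: SimConfig, truth: SimTruth, groups: GroupMap
                     ) -> pd.DataFrame:
    """Per-gene intron counts; FEL tips draw from a lower Poisson mean."""
    rng = config.rng("introns")
    fel = {t for tips in truth.fel_tips.values() for t in tips}
    rows = []
    for sp in sorted(groups.assignment):
        mean = config.intron_mean_fel if sp in fel else config.intron_mean_sel
        counts = rng.poisson(mean, config.n_intron_genes)
        rows.extend((f"{sp}|ig{i + 1:04d}", sp, int(c))
                    for i, c in enumerate(counts))
    return pd.DataFrame(rows, columns=["gene", "species", "introns"])


# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator stage from one config and bundle the results."""
    tree, groups, truth = simulate_tree(config)
    matrix, truth = simulate_counts(config, tree, groups, truth)
    annotations = simulate_annotations(config, truth)
    hits, g2f, g2s = simulate_hit_tables(config, truth, groups)
    introns = simulate_introns(config, truth, groups)
    return SimBundle(config=config, tree=tree, groups=groups, matrix=matrix,
                     truth=truth, annotations=annotations, hits=hits,
                     gene_to_family=g2f, gene_to_species=g2s, introns=introns)


def write_simulation(bundle: SimBundle, out_dir) -> None:
    """Emit counts.tsv, tree.nwk, groups.tsv, annotations.tsv, hits.tsv,
    introns.tsv and truth.tsv under ``out_dir``."""
    import pathlib

    from .io import write_copy_matrix, write_group_map, write_table, write_tree

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_copy_matrix(bundle.matrix, out / "counts.tsv")
    write_tree(bundle.tree, out / "tree.nwk")
    write_group_map(bundle.groups, out / "groups.tsv")
    ann_rows = [(f, t, bundle.annotations.term_descriptions.get(t, ""))
                for f, ts in sorted(bundle.annotations.family_terms.items())
                for t in sorted(ts)]
    write_table(pd.DataFrame(ann_rows, columns=["family", "term", "description"]),
                out / "annotations.tsv", sort_by=["family", "term"])
    write_table(bundle.hits, out / "hits.tsv", sort_by=["qseqid", "sseqid"])
    write_table(bundle.introns, out / "introns.tsv", sort_by=["gene"])
    truth_rows = [("family_block", f, b) for f, b in sorted(bundle.truth.family_block.items())]
    truth_rows += [("fel_tip", o, t) for o, ts in sorted(bundle.truth.fel_tips.items())
                   for t in ts]
    truth_rows += [("orphan_origin", f, o) for f, o in sorted(bundle.truth.orphan_origin.items())]
    truth_rows += [("driver_order", o, "") for o in bundle.truth.driver_orders]
    write_table(pd.DataFrame(truth_rows, columns=["kind", "key", "value"]),
                out / "truth.tsv", sort_by=["kind", "key"])
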