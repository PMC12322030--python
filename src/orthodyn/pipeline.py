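"""End-to-end orchestration: simulate/load -> filter -> sizes -> lineages ->
fold change -> PCA/drivers -> orphans -> DR -> enrichment.

Every stage's parameters are echoed into the machine-readable report so
that no default stays silent, and all randomness flows from the single
root seed through the generator's named substreams; the same configuration
therefore reproduces every output file byte for byte.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import filtering, io, lineages, presence, sizes
from .dynamics import enrich, fold_change_table
from .simulate import SimBundle, SimConfig, simulate_all, write_simulation

__all__ = ["PipelineConfig", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """One structured configuration for a full analysis run."""

    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict = field(default_factory=dict)  # counts/tree/groups/... paths
    coverage_weighted: float = 0.1
    coverage_pca: float = 0.5
    orphan_threshold: float = 0.98
    alpha: float = 0.05
    weight_scheme: str = "inv_max"
    dbscan_eps: float | None = None
    dbscan_min_pts: int = 3
    dip_boot: int = 2000
    out_dir: str = "orthodyn_out"

    def __post_init__(self) -> None:
        for name in ("coverage_weighted", "coverage_pca", "orphan_threshold",
                     "alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.simulate is None and not self.inputs:
            raise ValueError("either a simulate block or input paths required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw) if sim is None else cls(
            **raw, simulate=SimConfig(**sim))
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = replace(config.simulate, seed=config.seed)
        return simulate_all(sim)
    paths = config.inputs
    for key in ("counts", "tree", "groups"):
        if key not in paths:
            raise ValueError(f"input path {key!r} missing")
        if not pathlib.Path(paths[key]).exists():
            raise FileNotFoundError(f"input file not found: {paths[key]}")
    matrix = io.read_copy_matrix(paths["counts"])
    tree = io.read_tree(paths["tree"])
    groups = io.read_group_map(paths["groups"])
    hits = io.read_hit_table(paths["hits"]) if "hits" in paths else None
    ann = io.read_annotation_map(paths["annotations"]) \
        if "annotations" in paths else None
    introns = pd.read_csv(paths["introns"], sep="\t") \
        if "introns" in paths else None
    return SimBundle(config=None, tree=tree, groups=groups, matrix=matrix,
                     truth=None, annotations=ann, hits=hits,
                     gene_to_family={}, gene_to_species={}, introns=introns)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the report dict.

    Output TSVs and ``report.json`` are written under ``config.out_dir``.
    Any stage failure aborts with the stage name attached.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(asdict(config)), "stages": {}}
    state: dict = {}
    for name, fn in _STAGES:
        try:
            fn(config, state, report, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# --------------------------------------------------------------------------
# stages

def _stage_inputs(config, state, report, out):
    bundle = _load_inputs(config)
    state["bundle"] = bundle
    if config.simulate is not None:
        write_simulation(bundle, out / "simulated")
    report["stages"]["inputs"] = {
        "n_families": bundle.matrix.shape[0],
        "n_species": bundle.matrix.shape[1],
        "n_groups": len(bundle.groups.groups),
        "simulated": config.simulate is not None,
    }


def _stage_coverage(config, state, report, out):
    b = state["bundle"]
    cov = filtering.compute_coverage(b.matrix, b.groups)
    retained_w = filtering.filter_families(cov, config.coverage_weighted)
    retained_p = filtering.filter_families(cov, config.coverage_pca)
    state.update(coverage=cov, retained_weighted=retained_w,
                 retained_pca=retained_p)
    io.write_table(cov.rename_axis("family").reset_index(), out / "coverage.tsv")
    (out / "retained.txt").write_text("\n".join(retained_w) + "\n")
    report["stages"]["coverage"] = {
        "threshold_weighted": config.coverage_weighted,
        "threshold_pca": config.coverage_pca,
        "n_retained_weighted": len(retained_w),
        "n_retained_pca": len(retained_p),
        "n_species_specific": b.matrix.shape[0] - len(retained_w),
    }


def _stage_sizes(config, state, report, out):
    b = state["bundle"]
    was = sizes.weighted_avg_size(b.matrix, config.weight_scheme,
                                  state["retained_weighted"])
    state["sizes"] = was
    io.write_table(was.rename("weighted_avg_size").rename_axis("species")
                   .reset_index(), out / "sizes.tsv")
    report["stages"]["sizes"] = {
        "scheme": config.weight_scheme,
        "n_families_used": len(state["retained_weighted"]),
        "median": float(was.median()),
    }


def _stage_lineages(config, state, report, out):
    b = state["bundle"]
    rates = lineages.root_to_tip_rates(b.tree)
    split = lineages.split_lineages(
        rates, state["sizes"], b.groups, alpha=config.alpha,
        eps=config.dbscan_eps, min_pts=config.dbscan_min_pts,
        n_boot=config.dip_boot)
    state.update(rates=rates, split=split)
    rows = [(g, t, lab) for g, s in sorted(split.groups.items())
            for lab, tips in (("fel", s.fel_tips), ("sel", s.sel_tips),
                              ("noise", s.noise_tips))
            for t in tips]
    io.write_table(pd.DataFrame(rows, columns=["group", "tip", "lineage"]),
                   out / "lineage_split.tsv", sort_by=["group", "tip"])
    report["stages"]["lineages"] = {
        "alpha": config.alpha,
        "split_orders": split.split_orders(),
        "dip_p_rates": {g: _r(s.dip_p_rates) for g, s in split.groups.items()},
        "n_fel_tips": len(split.fel_tips),
    }


def _stage_fold_change(config, state, report, out):
    split = state["split"]
    b = state["bundle"]
    tables = []
    for order in split.split_orders():
        g = split.groups[order]
        fc = fold_change_table(b.matrix, g.fel_tips, g.sel_tips,
                               state["retained_weighted"], alpha=config.alpha)
        fc.insert(0, "order", order)
        tables.append(fc)
    if tables:
        allfc = pd.concat(tables, ignore_index=True)
        io.write_table(allfc, out / "fold_change.tsv", sort_by=["order", "family"])
        cats = allfc.groupby("category")["family"].count().to_dict()
    else:
        allfc, cats = None, {}
    state["fold_change"] = allfc
    report["stages"]["fold_change"] = {"category_counts": cats}


def _stage_presence(config, state, report, out):
    b = state["bundle"]
    model = presence.presence_pca(b.matrix, state["retained_pca"])
    drivers = presence.find_drivers(model, component=1)
    state.update(pca=model, drivers=drivers)
    io.write_table(model.scores.rename_axis("species").reset_index(),
                   out / "pca_scores.tsv")
    io.write_table(model.loadings.rename_axis("family").reset_index(),
                   out / "pca_loadings.tsv")
    io.write_table(pd.DataFrame({"family": drivers.families,
                                 "rank": range(1, drivers.k + 1)}),
                   out / "drivers.tsv", sort_by="rank")
    pc1_cmp = presence.compare_component_coords(model, state["split"], 1)
    report["stages"]["presence"] = {
        "variance_fractions": [_r(v) for v in model.variance_fractions[:3]],
        "driver_k": drivers.k,
        "driver_rho": _r(drivers.rho),
        "driver_direction": drivers.direction,
        "pc1_fel_vs_sel": {g: _r(v["pvalue"]) for g, v in pc1_cmp.items()},
    }


def _stage_orphans(config, state, report, out):
    b = state["bundle"]
    orphans = filtering.find_orphans(state["coverage"], config.orphan_threshold)
    if b.hits is not None and len(orphans):
        orphans = filtering.classify_orphan_origin(
            orphans, b.hits, b.gene_to_family, b.gene_to_species, b.groups)
    state["orphans"] = orphans
    io.write_table(pd.DataFrame(
        [(r.family, r.host_order, r.host_coverage, r.origin or "")
         for r in orphans],
        columns=["family", "host_order", "host_coverage", "origin"]),
        out / "orphans.tsv")
    origins = pd.Series([r.origin for r in orphans if r.origin]).value_counts()
    report["stages"]["orphans"] = {
        "n_orphans": len(orphans),
        "origins": origins.to_dict(),
    }


def _stage_dr(config, state, report, out):
    b = state["bundle"]
    dr = lineages.dr_statistic(b.tree)
    state["dr"] = dr
    io.write_table(dr.rename_axis("species").reset_index(), out / "dr.tsv")
    split = state["split"]
    cmp = {}
    for order in split.split_orders():
        g = split.groups[order]
        cmp[order] = lineages.compare_groups(dr.loc[g.fel_tips, "DR"],
                                             dr.loc[g.sel_tips, "DR"])
    report["stages"]["dr"] = {
        "median_dr": _r(dr["DR"].median()),
        "fel_vs_sel": {g: {k: _r(v) for k, v in c.items()}
                       for g, c in cmp.items()},
    }


def _stage_introns(config, state, report, out):
    b = state["bundle"]
    if b.introns is None:
        report["stages"]["introns"] = {"skipped": True}
        return
    split = state["split"]
    fel = set(split.fel_tips)
    class_of = {sp: ("fel" if sp in fel else "sel")
                for sp in b.matrix.species_ids}
    res = lineages.intron_summaries(b.introns, class_of)
    io.write_table(res["table"].reset_index(), out / "introns_summary.tsv")
    report["stages"]["introns"] = {
        k: {kk: _r(vv) for kk, vv in v.items() if kk != "class_a" and kk != "class_b"}
        for k, v in res["comparisons"].items()}


def _stage_enrichment(config, state, report, out):
    b = state["bundle"]
    fc = state.get("fold_change")
    if b.annotations is None or fc is None or fc.empty:
        report["stages"]["enrichment"] = {"skipped": True}
        return
    target = sorted(set(fc.loc[fc["significant"]
                               & fc["category"].isin(["contraction", "loss"]),
                               "family"]))
    background = sorted(set(fc["family"]))
    if not target:
        report["stages"]["enrichment"] = {"n_terms": 0, "n_target": 0}
        return
    table = enrich(target, background, b.annotations)
    io.write_table(table, out / "enrichment.tsv", sort_by=["p", "term"])
    report["stages"]["enrichment"] = {
        "n_target": len(target),
        "n_terms": len(table),
        "top_terms": table.loc[table["p_adj"] <= config.alpha, "term"]
        .head(10).tolist(),
    }


_STAGES = [
    ("inputs", _stage_inputs),
    ("coverage", _stage_coverage),
    ("sizes", _stage_sizes),
    ("lineages", _stage_lineages),
    ("fold_change", _stage_fold_change),
    ("presence", _stage_presence),
    ("orphans", _stage_orphans),
    ("dr", _stage_dr),
    ("introns", _stage_introns),
    ("enrichment", _stage_enrichment),
]


def _r(x, nd: int = 10) -> float:
    """Round for stable JSON output."""
    return float(np.round(float(x), nd))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
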