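"""Presence/absence structure: PCA, score clustering, and driver families.

Species are points in a binary presence space (one coordinate per family).
Principal components of the column-centered presence matrix describe the
dominant axes of gene-content variation; density clustering of the first
two score dimensions groups species with similar repertoires; and a ranked
cumulative-presence scan identifies the "driver" families — the prefix of
loading-ranked families whose average presence best correlates (Spearman)
with the species' coordinates along a chosen component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN

from .io import CopyMatrix
from .lineages import LineageSplit, compare_groups

__all__ = ["PCModel", "presence_pca", "presence_pcoa", "cluster_scores",
           "find_drivers", "DriverResult", "compare_component_coords"]


@dataclass(frozen=True)
class PCModel:
    """Species scores, family loadings and explained-variance fractions."""

    scores: pd.DataFrame        # species x components
    loadings: pd.DataFrame      # families x components
    variance_fractions: np.ndarray
    presence: pd.DataFrame      # the (binary) data the model was fit to

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def presence_pca(matrix: CopyMatrix, family_subset=None, *,
                 binarize: bool = True, scale: bool = False,
                 n_components: int | None = None) -> PCModel:
    """PCA of the (binary) family profile matrix.

    Counts are binarized by default (>0 -> 1); ``binarize=False`` runs the
    copy-number variant used as a robustness check.  Family columns are
    centered; unit-variance scaling is off by default because scaling
    binary columns upweights rare families.  The SVD sign is fixed by
    making the largest-magnitude entry of each loading vector positive, so
    results are platform-stable.
    """
    data = matrix.counts
    if family_subset is not None:
        data = data.loc[[f for f in data.index if f in set(family_subset)]]
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 families and 2 species")
    X = (data > 0).astype(float) if binarize else data.astype(float)
    X = X.T  # species x families
    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    if scale:
        sd = Xc.std(axis=0, ddof=1).replace(0, np.nan)
        Xc = (Xc / sd).fillna(0.0)
    if np.allclose(Xc.to_numpy(), 0):
        raise ValueError("presence matrix is constant; PCA undefined")
    U, S, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    k = n_components or int(np.sum(S > S[0] * 1e-12))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest |entry| of each loading vector positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U * S, index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp)
    var = S ** 2 / float(np.sum(S ** 2))
    return PCModel(scores=scores, loadings=loadings, variance_fractions=var,
                   presence=X)


def presence_pcoa(matrix: CopyMatrix, family_subset=None, *,
                  metric: str = "jaccard", binarize: bool = True,
                  n_components: int = 2) -> pd.DataFrame:
    """Classical MDS (PCoA) on Jaccard or Hamming distances between species.

    A cross-check variant of :func:`presence_pca`: on strongly blocked data
    both place the blocks apart on their first axis.
    """
    if metric not in ("jaccard", "hamming"):
        raise ValueError("metric must be 'jaccard' or 'hamming'")
    data = matrix.counts
    if family_subset is not None:
        data = data.loc[[f for f in data.index if f in set(family_subset)]]
    X = (data > 0).astype(float) if binarize else data.astype(float)
    X = X.T
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    D = DistanceMatrix(squareform(pdist(X.to_numpy(), metric=metric)),
                       ids=[str(s) for s in X.index])
    ord_ = skbio_pcoa(D, number_of_dimensions=n_components)
    coords = ord_.samples.to_numpy()[:, :n_components].copy()
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return pd.DataFrame(coords, index=X.index,
                        columns=[f"Axis{j + 1}" for j in range(coords.shape[1])])


def cluster_scores(model: PCModel, *, eps: float, min_pts: int = 3) -> pd.Series:
    """DBSCAN labels on the (PC1, PC2) score plane; -1 marks noise."""
    if model.n_components < 2:
        raise ValueError("need at least 2 components to cluster scores")
    pts = model.scores.iloc[:, :2].to_numpy()
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    return pd.Series(labels, index=model.scores.index, name="cluster")


@dataclass(frozen=True)
class DriverResult:
    component: int
    direction: str          # 'ascending' or 'descending' loading order
    k: int                  # optimal prefix size
    rho: float              # signed Spearman rho at the optimum
    families: list          # the k driver families, in ranked order
    profile: pd.DataFrame   # per (direction, i): rho, for inspection


def find_drivers(model: PCModel, component: int = 1) -> DriverResult:
    """Driver families of one principal component.

    Families are ranked by their loading on the component, both ascending
    and descending.  For every prefix size i the per-species mean presence
    over the top-i families is correlated (Spearman) with the species'
    component coordinates; the prefix with the largest |rho| wins, ties
    going to the smaller i and then to the descending direction.  Prefixes
    whose cumulative presence is constant across species are skipped.
    """
    col = f"PC{component}"
    if col not in model.scores.columns:
        raise ValueError(f"component {component} not in model")
    coords = model.scores[col].to_numpy()
    if np.allclose(coords, coords[0]):
        raise ValueError("component coordinates are constant")
    coord_ranks = stats.rankdata(coords)
    presence = model.presence.to_numpy().T  # families x species
    families = np.asarray(model.presence.columns)
    load = model.loadings[col].to_numpy()
    best = None  # (|rho|, i, direction_priority, signed rho, order)
    profiles = []
    for direction in ("descending", "ascending"):
        order = np.argsort(load, kind="mergesort")
        if direction == "descending":
            order = order[::-1]
        cum = np.cumsum(presence[order], axis=0)
        denom = np.arange(1, len(order) + 1)[:, None]
        avg = cum / denom
        rhos = np.full(len(order), np.nan)
        for i in range(len(order)):
            row = avg[i]
            if np.all(row == row[0]):
                continue  # zero variance: rho undefined
            r = stats.rankdata(row)
            rhos[i] = np.corrcoef(r, coord_ranks)[0, 1]
        profiles.append(pd.DataFrame({"direction": direction,
                                      "i": np.arange(1, len(order) + 1),
                                      "rho": rhos}))
        for i, rho in enumerate(rhos):
            if np.isnan(rho):
                continue
            prio = 0 if direction == "descending" else 1
            key = (-abs(rho), i + 1, prio)
            if best is None or key < best[0]:
                best = (key, rho, direction, order[: i + 1])
    if best is None:
        raise ValueError("no prefix with non-constant cumulative presence")
    _, rho, direction, order_prefix = best
    return DriverResult(component=component, direction=direction,
                        k=len(order_prefix), rho=float(rho),
                        families=list(families[order_prefix]),
                        profile=pd.concat(profiles, ignore_index=True))


def compare_component_coords(model: PCModel, split: LineageSplit,
                             component: int = 1) -> dict:
    """Per-order rank-sum comparison of FEL vs SEL component coordinates."""
    col = f"PC{component}"
    out = {}
    for order, g in split.groups.items():
        if not g.fel_tips or not g.sel_tips:
            continue
        fel = model.scores.loc[[t for t in g.fel_tips
                                if t in model.scores.index], col]
        sel = model.scores.loc[[t for t in g.sel_tips
                                if t in model.scores.index], col]
        if len(fel) and len(sel):
            out[order] = compare_groups(fel, sel)
    return out
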