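"""Joint embedding, SNN clustering, and integration-quality scoring.

The evaluation suite mirrors the standard single-cell integration
benchmarks: batch-correction components (batch silhouette, graph
connectivity, principal-component regression comparison, kBET acceptance,
iLISI, cell-cycle conservation) are averaged into a *species mixing score*
(SMS); biology-preservation components (cLISI, isolated-label F1, cluster
silhouette rescaled to [0, 1]) into a *bioconservation score* (BCS); and the
overall quality is their equally weighted sum::

    total = 0.5 * SMS + 0.5 * BCS

Within each composite the components are averaged with equal weights.  All
components are oriented so that higher is better and live in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2
from sklearn.metrics import (
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError
from .expression_harmonization import CellMatrix

#: SNN edge weights below this Jaccard overlap are pruned.
SNN_PRUNE = 1.0 / 15.0

SMS_COMPONENTS = (
    "batch_asw",
    "graph_connectivity",
    "pcr_comparison",
    "kbet",
    "ilisi_norm",
    "cell_cycle_conservation",
)
BCS_COMPONENTS = ("clisi_norm", "isolated_label_f1", "silhouette_01")


@dataclass(frozen=True)
class Embedding:
    coordinates: np.ndarray
    basis: str = "pca"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or not np.all(np.isfinite(coords)):
            raise ConfigurationError("embedding must be a finite 2-D matrix")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# embedding and clustering


def scaled_hvg_matrix(
    m: CellMatrix, n_hvg: int = 2000, clip: float = 10.0
) -> np.ndarray:
    """Dense cells × genes matrix of the top-dispersion genes, z-scored.

    Gene selection uses scanpy's Seurat-flavour dispersion ranking on the
    log-normalised values; each selected gene is centred, scaled to unit
    variance and clipped at ``clip``.
    """
    import scanpy as sc

    adata = m.to_anndata()
    n_hvg = min(n_hvg, m.n_genes)
    if n_hvg < m.n_genes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip(X / sd, -clip, clip)
    return X


def pca_embed(
    m: CellMatrix, n_hvg: int = 2000, n_pcs: int = 30, seed: int = 0
) -> Embedding:
    """PCA of the scaled highly-variable-gene matrix."""
    if m.n_cells < 2 or m.n_genes < 2:
        raise ConfigurationError("need at least 2 cells and 2 genes")
    if n_pcs >= min(m.n_cells, m.n_genes):
        raise ConfigurationError(
            f"n_pcs={n_pcs} must be below min(cells, genes)="
            f"{min(m.n_cells, m.n_genes)}"
        )
    X = scaled_hvg_matrix(m, n_hvg=n_hvg)
    return pca_of_matrix(X, n_pcs=n_pcs, seed=seed)


def pca_of_matrix(X: np.ndarray, n_pcs: int = 30, seed: int = 0) -> Embedding:
    """PCA embedding of an already-scaled cells × features matrix."""
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="arpack", random_state=seed)
    coords = pca.fit_transform(X - X.mean(axis=0))
    # deterministic sign convention: largest-magnitude loading positive
    signs = np.sign(pca.components_[np.arange(n_pcs),
                                    np.argmax(np.abs(pca.components_), axis=1)])
    signs[signs == 0] = 1.0
    return Embedding(coordinates=coords * signs, basis="pca")


def knn_indices(e: Embedding, k: int) -> np.ndarray:
    """Indices (n × k) of the k nearest neighbours, self included."""
    if k <= 0:
        raise ConfigurationError("k must be positive")
    if k >= e.n_cells:
        raise ConfigurationError("k must be below the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(e.coordinates)
    _, idx = nn.kneighbors(e.coordinates)
    return idx


def knn_adjacency(e: Embedding, k: int) -> sp.csr_matrix:
    """Symmetrised unweighted kNN adjacency (no self loops)."""
    idx = knn_indices(e, k)
    n = e.n_cells
    rows = np.repeat(np.arange(n), idx.shape[1])
    cols = idx.ravel()
    keep = rows != cols
    A = sp.csr_matrix(
        (np.ones(keep.sum()), (rows[keep], cols[keep])), shape=(n, n)
    )
    A = ((A + A.T) > 0).astype(float)
    return A


def snn_graph(e: Embedding, k: int = 20, prune: float = SNN_PRUNE):
    """Jaccard-weighted shared-nearest-neighbour igraph graph."""
    import igraph as ig

    idx = knn_indices(e, k)
    n = e.n_cells
    incidence = sp.csr_matrix(
        (
            np.ones(idx.size),
            (np.repeat(np.arange(n), idx.shape[1]), idx.ravel()),
        ),
        shape=(n, n),
    )
    shared = (incidence @ incidence.T).tocoo()
    # neighbour sets all have size k, so |union| = 2k - |intersection|
    jaccard = shared.data / (2 * k - shared.data)
    keep = (jaccard >= prune) & (shared.row < shared.col)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    weights = jaccard[keep].tolist()
    g = ig.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    return g


def snn_cluster(
    e: Embedding,
    k: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
    prune: float = SNN_PRUNE,
) -> np.ndarray:
    """Modularity community detection on the SNN graph (Leiden, RB config)."""
    import leidenalg

    g = snn_graph(e, k=k, prune=prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"] if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# components


def silhouette_mean(e: Embedding, labels) -> float:
    """Mean silhouette coefficient over cells (Euclidean distances)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("silhouette requires at least 2 labels")
    return float(silhouette_samples(e.coordinates, labels).mean())


def batch_asw(e: Embedding, batch, group) -> float:
    """Batch mixing via 1 − |silhouette| w.r.t. batch, averaged per group."""
    batch = np.asarray(batch)
    group = np.asarray(group)
    scores = []
    for g in np.unique(group):
        mask = group == g
        sub_batch = batch[mask]
        if len(np.unique(sub_batch)) < 2:
            scores.append(1.0)  # a single-batch group is perfectly mixed
            continue
        s = silhouette_samples(e.coordinates[mask], sub_batch)
        scores.append(float(np.mean(1.0 - np.abs(s))))
    return float(np.mean(scores))


def graph_connectivity(adjacency: sp.spmatrix, group) -> float:
    """Mean over groups of (largest connected component / group size)."""
    group = np.asarray(group)
    scores = []
    for g in np.unique(group):
        idx = np.flatnonzero(group == g)
        if len(idx) == 1:
            scores.append(1.0)
            continue
        sub = adjacency[np.ix_(idx, idx)]
        _, labels = connected_components(sub, directed=False)
        largest = np.bincount(labels).max()
        scores.append(largest / len(idx))
    return float(np.mean(scores))


def _covariate_design(covariate) -> np.ndarray:
    """Design matrix for a covariate: one-hot for categorical, column otherwise."""
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUSb":
        cats = pd.get_dummies(pd.Series(cov)).to_numpy(dtype=float)
        return cats
    return cov.reshape(-1, 1).astype(float)


def variance_explained_by_covariate(
    X: np.ndarray, covariate, n_pcs: int = 50
) -> float:
    """Σ_i varexpl_i · R²(PC_i ~ covariate) over the top principal components."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    n_pcs = min(n_pcs, min(Xc.shape) - 1)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    varexpl = var[:n_pcs] / var.sum() if var.sum() > 0 else np.zeros(n_pcs)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    D = _covariate_design(covariate)
    D = np.column_stack([np.ones(len(D)), D - D.mean(axis=0)])
    total = 0.0
    for i in range(n_pcs):
        y = pcs[:, i]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            continue
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        total += varexpl[i] * max(r2, 0.0)
    return total


def pcr_comparison(
    pre: np.ndarray, post: np.ndarray, covariate, n_pcs: int = 50
) -> float:
    """Reduction in covariate-explained PCA variance, clipped to [0, 1]."""
    vc_pre = variance_explained_by_covariate(pre, covariate, n_pcs)
    if vc_pre < 1e-12:
        warnings.warn(
            "covariate explains no variance before correction; PCR score is 0"
        )
        return 0.0
    vc_post = variance_explained_by_covariate(post, covariate, n_pcs)
    return float(np.clip((vc_pre - vc_post) / vc_pre, 0.0, 1.0))


def cell_cycle_conservation(
    pre: np.ndarray, post: np.ndarray, cc_covariate, n_pcs: int = 50
) -> float:
    """1 − |ΔVar_cc| / Var_cc(pre), clipped to [0, 1]."""
    vc_pre = variance_explained_by_covariate(pre, cc_covariate, n_pcs)
    if vc_pre < 1e-12:
        warnings.warn(
            "cell-cycle covariate explains no variance before correction; "
            "conservation reported as 1"
        )
        return 1.0
    vc_post = variance_explained_by_covariate(post, cc_covariate, n_pcs)
    return float(np.clip(1.0 - abs(vc_post - vc_pre) / vc_pre, 0.0, 1.0))


def lisi(e: Embedding, labels, perplexity: float = 30.0) -> np.ndarray:
    """Per-cell local inverse Simpson index over *labels*.

    Neighbourhood probabilities use a Gaussian kernel calibrated per cell to
    the given perplexity (binary search on the kernel bandwidth, as in SNE).
    Values lie in [1, number of labels].
    """
    labels = np.asarray(labels)
    uniq, enc = np.unique(labels, return_inverse=True)
    n = e.n_cells
    if len(uniq) == 1:
        return np.ones(n)
    perplexity = max(1.0, min(perplexity, (n - 1) / 3.0))
    k = min(n - 1, max(int(np.ceil(3 * perplexity)), 5))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(e.coordinates)
    dist, idx = nn.kneighbors(e.coordinates)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    d2 = dist**2
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(60):
            w = np.exp(-d2[i] * beta)
            sw = w.sum()
            if sw <= 0:
                h = 0.0
            else:
                p = w / sw
                nzp = p[p > 0]
                h = -np.sum(nzp * np.log(nzp))
            if abs(h - target) < 1e-5:
                break
            if h > target:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        w = np.exp(-d2[i] * beta)
        sw = w.sum()
        if sw <= 0:
            out[i] = 1.0
            continue
        p = w / sw
        probs = np.bincount(enc[idx[i]], weights=p, minlength=len(uniq))
        out[i] = 1.0 / np.sum(probs**2)
    return out


def ilisi_norm(e: Embedding, batch, perplexity: float = 30.0) -> float:
    """(median LISI − 1) / (#batches − 1): 1 = perfectly mixed batches."""
    batch = np.asarray(batch)
    n_lab = len(np.unique(batch))
    if n_lab == 1:
        warnings.warn("single batch label; iLISI reported as 0")
        return 0.0
    med = float(np.median(lisi(e, batch, perplexity)))
    return float(np.clip((med - 1.0) / (n_lab - 1.0), 0.0, 1.0))


def clisi_norm(e: Embedding, labels, perplexity: float = 30.0) -> float:
    """(#labels − median LISI) / (#labels − 1): 1 = pure neighbourhoods."""
    labels = np.asarray(labels)
    n_lab = len(np.unique(labels))
    if n_lab == 1:
        return 1.0
    med = float(np.median(lisi(e, labels, perplexity)))
    return float(np.clip((n_lab - med) / (n_lab - 1.0), 0.0, 1.0))


def kbet_acceptance(
    knn_idx: np.ndarray,
    batch,
    n_samples: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of sampled neighbourhoods whose batch composition is not
    rejected by a chi-square goodness-of-fit test against the global one."""
    batch = np.asarray(batch)
    uniq, enc = np.unique(batch, return_inverse=True)
    if len(uniq) == 1:
        return 1.0
    n = len(batch)
    global_freq = np.bincount(enc, minlength=len(uniq)) / n
    rng = np.random.default_rng(seed)
    cells = (
        np.arange(n)
        if n_samples >= n
        else rng.choice(n, size=n_samples, replace=False)
    )
    k = knn_idx.shape[1]
    expected = global_freq * k
    dof = len(uniq) - 1
    accepted = 0
    for c in cells:
        observed = np.bincount(enc[knn_idx[c]], minlength=len(uniq))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.sum(
                np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
            )
        p = chi2.sf(stat, dof)
        if p >= alpha:
            accepted += 1
    return accepted / len(cells)


def isolated_label_f1(
    e: Embedding,
    labels,
    batch,
    seed: int = 0,
    resolutions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    k: int = 20,
) -> float:
    """Best-F1 recovery of isolated labels across clustering resolutions.

    Isolated labels are cell types present in the fewest batches; when every
    label spans every batch, all labels are isolated by this minimum rule
    (reported as such via a warning).
    """
    from sklearn.metrics import f1_score

    labels = np.asarray(labels)
    batch = np.asarray(batch)
    n_batches_per_label = {
        lab: len(np.unique(batch[labels == lab])) for lab in np.unique(labels)
    }
    min_batches = min(n_batches_per_label.values())
    isolated = [l for l, nb in n_batches_per_label.items() if nb == min_batches]
    if len(isolated) == len(n_batches_per_label):
        warnings.warn(
            "every label is present in the minimum number of batches; "
            "treating all labels as isolated"
        )
    k = min(k, e.n_cells - 1)
    best = {lab: 0.0 for lab in isolated}
    for res in resolutions:
        clusters = snn_cluster(e, k=k, resolution=res, seed=seed)
        for lab in isolated:
            y_true = (labels == lab).astype(int)
            for cl in np.unique(clusters):
                y_pred = (clusters == cl).astype(int)
                f1 = f1_score(y_true, y_pred, zero_division=0)
                if f1 > best[lab]:
                    best[lab] = float(f1)
    return float(np.mean(list(best.values())))


def nmi(labels_a, labels_b) -> float:
    """Normalised mutual information (arithmetic-mean normalisation)."""
    return float(
        normalized_mutual_info_score(
            np.asarray(labels_a), np.asarray(labels_b), average_method="arithmetic"
        )
    )


# ---------------------------------------------------------------------------
# baseline correction and composites


def species_center(m: CellMatrix, species) -> CellMatrix:
    """Per-gene centering baseline: within each species subtract the species
    mean and add the global mean.  Genes absent (all-zero) within a species
    are left untouched there."""
    species = np.asarray(species)
    X = m.dense().astype(float).copy()
    global_mean = X.mean(axis=1)
    for spc in np.unique(species):
        cols = np.flatnonzero(species == spc)
        sub = X[:, cols]
        present = np.asarray((np.abs(sub) > 0).sum(axis=1)).ravel() > 0
        offset = sub[present].mean(axis=1) - global_mean[present]
        sub[present] = sub[present] - offset[:, np.newaxis]
        X[:, cols] = sub
    return CellMatrix(
        counts=X,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_meta=m.cell_meta.copy(),
    )


@dataclass
class MetricReport:
    components: dict[str, float]
    species_mixing_score: float
    bioconservation_score: float
    total: float
    missing: list[str] = field(default_factory=list)
    #: per-cell cluster labels of the evaluated embedding (not serialised)
    cluster_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "components": dict(self.components),
            "species_mixing_score": self.species_mixing_score,
            "bioconservation_score": self.bioconservation_score,
            "total": self.total,
            "missing": list(self.missing),
        }


def composite_scores(components: dict[str, float]) -> MetricReport:
    """Combine named components into SMS, BCS and the weighted total.

    SMS averages the batch-correction components, BCS the bioconservation
    components (the silhouette coefficient is rescaled from [−1, 1] to
    [0, 1] first); absent components are skipped and flagged.
    """
    comps = dict(components)
    if "silhouette" in comps and "silhouette_01" not in comps:
        comps["silhouette_01"] = (comps["silhouette"] + 1.0) / 2.0
    missing = [
        name
        for name in SMS_COMPONENTS + BCS_COMPONENTS
        if name not in comps
    ]
    if missing:
        warnings.warn(f"composite computed without components: {missing}")
    sms_vals = [comps[c] for c in SMS_COMPONENTS if c in comps]
    bcs_vals = [comps[c] for c in BCS_COMPONENTS if c in comps]
    sms = float(np.mean(sms_vals)) if sms_vals else float("nan")
    bcs = float(np.mean(bcs_vals)) if bcs_vals else float("nan")
    total = 0.5 * sms + 0.5 * bcs
    return MetricReport(
        components=comps,
        species_mixing_score=sms,
        bioconservation_score=bcs,
        total=total,
        missing=missing,
    )


def evaluate_integration(
    merged: CellMatrix,
    *,
    batch_key: str = "species",
    label_key: str = "cell_type",
    cc_key: str | None = "cc_score",
    correct: bool = True,
    corrected_embedding: Embedding | None = None,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    k: int = 20,
    resolution: float = 0.3,
    perplexity: float = 30.0,
    kbet_samples: int = 500,
    seed: int = 0,
) -> MetricReport:
    """End-to-end metric evaluation of a merged, log-normalised matrix.

    The uncorrected scaled-HVG matrix is always the "pre" reference; the
    "post" state is the species-centred matrix (``correct=True``), an
    externally supplied corrected embedding, or the uncorrected data itself.
    Bioconservation components require a ``label_key`` column; without one
    they are skipped and flagged in the report.
    """
    meta = merged.cell_meta
    batch = meta[batch_key].to_numpy()
    have_labels = label_key is not None and label_key in meta.columns
    labels = meta[label_key].to_numpy() if have_labels else None

    pre_X = scaled_hvg_matrix(merged, n_hvg=n_hvg)
    if corrected_embedding is not None:
        post_X = corrected_embedding.coordinates
        embed = corrected_embedding
    elif correct:
        centered = species_center(merged, batch)
        post_X = scaled_hvg_matrix(centered, n_hvg=n_hvg)
        embed = pca_of_matrix(post_X, n_pcs=n_pcs, seed=seed)
    else:
        post_X = pre_X
        embed = pca_of_matrix(pre_X, n_pcs=n_pcs, seed=seed)

    k = min(k, merged.n_cells - 1)
    clusters = snn_cluster(embed, k=k, resolution=resolution, seed=seed)
    knn_idx = knn_indices(embed, k)
    adjacency = knn_adjacency(embed, k)
    groups = labels if have_labels else clusters

    components: dict[str, float] = {}
    components["batch_asw"] = batch_asw(embed, batch, groups)
    components["graph_connectivity"] = graph_connectivity(adjacency, groups)
    components["pcr_comparison"] = pcr_comparison(pre_X, post_X, batch)
    components["kbet"] = kbet_acceptance(
        knn_idx, batch, n_samples=kbet_samples, seed=seed
    )
    components["ilisi_norm"] = ilisi_norm(embed, batch, perplexity)
    if cc_key is not None and cc_key in meta.columns:
        cc = meta[cc_key].to_numpy(dtype=float)
        components["cell_cycle_conservation"] = cell_cycle_conservation(
            pre_X, post_X, cc
        )
    if len(np.unique(clusters)) > 1:
        components["silhouette"] = silhouette_mean(embed, clusters)
    if have_labels:
        components["clisi_norm"] = clisi_norm(embed, labels, perplexity)
        components["isolated_label_f1"] = isolated_label_f1(
            embed, labels, batch, seed=seed, k=k
        )
        components["nmi"] = nmi(clusters, labels)
    report = composite_scores(components)
    report.components["n_clusters"] = float(len(np.unique(clusters)))
    report.cluster_labels = clusters
    return report
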