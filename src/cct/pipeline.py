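"""Cell cycle trajectory reconstruction from raw count matrices.

Stages: neighbor pooling of raw counts, a two-pass trajectory-based library
size normalization (so that totals keep rising along the cycle and halve at
division instead of being flattened globally), principal-circle fitting and
pseudotime in PCA space, curvature-based segmentation into transcriptional
epochs, phase scores, epoch marker ranking and the effective-rank
dimensionality rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .principal_curve import PrincipalCurve, assign_pseudotime, fit_principal_curve

__all__ = [
    "CountMatrix",
    "InitialNormalization",
    "TrajectoryNormalization",
    "CurvatureProfile",
    "EpochSegmentation",
    "CCTResult",
    "pool_neighbor_counts",
    "initial_normalize",
    "trajectory_normalize",
    "curvature_profile",
    "segment_epochs",
    "phase_scores",
    "epoch_marker_genes",
    "effective_rank",
    "run_cct_pipeline",
]


@dataclass
class CountMatrix:
    """Genes x cells non-negative count matrix with identifiers.

    ``values`` may be dense or scipy-sparse; entries must be non-negative.
    Raw UMI counts are integers, but renormalized pseudocounts are allowed to
    be fractional, hence no integrality requirement here.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape must be (n_genes, n_cells)")
        if len(set(self.gene_ids)) != len(self.gene_ids) or len(set(self.cell_ids)) != len(
            self.cell_ids
        ):
            raise ValueError("gene and cell identifiers must be unique")
        if self.min() < 0:
            raise ValueError("counts must be non-negative")

    def min(self) -> float:
        return float(self.values.min()) if self.values.size else 0.0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def totals(self) -> np.ndarray:
        """Per-cell total counts (library sizes)."""
        t = self.values.sum(axis=0)
        return np.asarray(t).ravel()

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def to_anndata(self):
        import anndata as ad

        X = self.values.T.tocsr() if sp.issparse(self.values) else np.asarray(self.values).T
        return ad.AnnData(
            X=X.astype(np.float32),
            obs=pd.DataFrame(index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )

    def scaled_columns(self, factors: np.ndarray) -> "CountMatrix":
        """Multiply each cell column by its factor (preserves gene proportions)."""
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (self.n_cells,):
            raise ValueError("one factor per cell required")
        if sp.issparse(self.values):
            vals = self.values @ sp.diags(factors)
        else:
            vals = self.values * factors[None, :]
        return CountMatrix(vals, self.gene_ids, self.cell_ids)


def pool_neighbor_counts(counts: CountMatrix, knn: list[np.ndarray]) -> CountMatrix:
    """Pool raw reads from each cell and all its k nearest neighbours.

    ``pooled(g, c) = raw(g, c) + sum_{c' in knn(c)} raw(g, c')``.  The cell
    itself is added implicitly; a self-reference in a neighbor list is an
    error.  Empty neighbor lists leave the matrix unchanged.
    """
    n = counts.n_cells
    if len(knn) != n:
        raise ValueError("one neighbor list per cell required")
    rows, cols = [], []
    for c, nb in enumerate(knn):
        nb = np.asarray(nb, dtype=int)
        if np.any(nb == c):
            raise ValueError(f"cell {c} lists itself as a neighbor (self is added implicitly)")
        if nb.size and (nb.min() < 0 or nb.max() >= n):
            raise ValueError("neighbor index out of range")
        rows.extend(nb.tolist())
        cols.extend([c] * nb.size)
    A = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ) + sp.identity(n)
    vals = counts.values @ A.tocsc() if sp.issparse(counts.values) else counts.values @ A.toarray()
    if sp.issparse(vals):
        vals = vals.tocsr()
    return CountMatrix(vals, counts.gene_ids, counts.cell_ids)


@dataclass
class InitialNormalization:
    """Output of the first-pass normalization: log matrix, kNN graph, PCA."""

    lognorm: CountMatrix  # genes x cells, ln(1+x) of median-normalized counts
    knn: list[np.ndarray]
    pca: np.ndarray  # cells x n_pcs
    variable_genes: np.ndarray
    scale_factors: np.ndarray


def initial_normalize(
    counts: CountMatrix,
    n_top_genes: int = 10_000,
    n_pcs: int = 30,
    k: int = 10,
) -> InitialNormalization:
    """Median library-size normalization, ln(1+x), HVG selection, PCA and kNN.

    Each cell is scaled to the global median total; the ``n_top_genes`` most
    variable genes (capped at the gene count) feed a ``n_pcs``-component PCA,
    and a Euclidean kNN graph (k neighbors, self excluded) is built in the
    reduced space.  Standard steps are delegated to scanpy.
    """
    import scanpy as sc
    from sklearn.neighbors import NearestNeighbors

    if counts.n_cells < 2:
        raise ValueError("need at least 2 cells")
    totals = counts.totals()
    if np.any(totals == 0):
        bad = counts.cell_ids[totals == 0]
        raise ValueError(f"all-zero cells: {list(bad)}")
    median = float(np.median(totals))
    factors = median / totals

    adata = counts.to_anndata()
    sc.pp.normalize_total(adata, target_sum=median)
    sc.pp.log1p(adata)
    n_hvg = min(n_top_genes, counts.n_genes)
    if n_hvg < counts.n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        hvg_mask = adata.var["highly_variable"].to_numpy()
    else:
        hvg_mask = np.ones(counts.n_genes, dtype=bool)
    X = adata.X[:, hvg_mask]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X - X.mean(axis=0))

    k_eff = min(k, counts.n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pca)
    _, idx = nn.kneighbors(pca)
    knn = [row[row != c][:k_eff] for c, row in enumerate(idx)]

    lognorm_vals = adata.X.T.tocsr() if sp.issparse(adata.X) else np.asarray(adata.X).T
    lognorm = CountMatrix(lognorm_vals, counts.gene_ids, counts.cell_ids)
    return InitialNormalization(lognorm, knn, pca, counts.gene_ids[hvg_mask], factors)


@dataclass
class TrajectoryNormalization:
    """Output of the trajectory-based renormalization (second pass)."""

    normalized: CountMatrix  # raw counts rescaled per cell (pseudocounts)
    lognorm: CountMatrix  # pooled + ln(1+x) of the renormalized counts
    scale_factors: np.ndarray
    partition: np.ndarray  # corrected cell-to-node assignment
    smoothed_medians: np.ndarray  # per-cell target totals
    wide_partition: int | None
    split_threshold: float | None
    division_drop_ratio: float | None  # median(pre-division)/median(post-division)
    variable_genes: np.ndarray


def _split_wide_partition(
    totals: np.ndarray, partition: np.ndarray, q: int, iqr_factor: float = 3.0
):
    """Detect the anomalously wide partition and split it at the totals antimode.

    The division-moment partition mixes end-of-cycle cells (largest totals)
    with newborn cells (smallest); its spread of totals dwarfs the others.
    A 1-D 2-means on the totals locates the antimode; low-total cells join the
    neighboring partition with the smaller median (post-division side), high-
    total cells the other neighbor.
    """
    iqrs = np.full(q, np.nan)
    for i in range(q):
        vals = totals[partition == i]
        if vals.size >= 2:
            iqrs[i] = np.subtract(*np.percentile(vals, [75, 25]))
    med_iqr = np.nanmedian(iqrs)
    wide = int(np.nanargmax(iqrs))
    if not (iqrs[wide] > iqr_factor * med_iqr):
        return partition, None, None, None
    from sklearn.cluster import KMeans

    vals = totals[partition == wide]
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(np.log(vals + 1.0)[:, None])
    centers = km.cluster_centers_.ravel()
    threshold = float(np.exp(centers.mean()) - 1.0)
    lo_nb, hi_nb = (wide - 1) % q, (wide + 1) % q
    med_lo = np.median(totals[partition == lo_nb]) if np.any(partition == lo_nb) else np.inf
    med_hi = np.median(totals[partition == hi_nb]) if np.any(partition == hi_nb) else np.inf
    post_nb = lo_nb if med_lo <= med_hi else hi_nb
    pre_nb = hi_nb if post_nb == lo_nb else lo_nb
    newpart = partition.copy()
    in_wide = partition == wide
    newpart[in_wide & (totals <= threshold)] = post_nb
    newpart[in_wide & (totals > threshold)] = pre_nb
    lo_med = float(np.median(vals[vals <= threshold])) if np.any(vals <= threshold) else np.nan
    hi_med = float(np.median(vals[vals > threshold])) if np.any(vals > threshold) else np.nan
    ratio = hi_med / lo_med if np.isfinite(lo_med) and lo_med > 0 else None
    return newpart, wide, threshold, ratio


def _cyclic_linear_interp(node_pos: np.ndarray, node_vals: np.ndarray, s: np.ndarray, period: float):
    order = np.argsort(node_pos)
    xp = node_pos[order]
    fp = node_vals[order]
    xp_ext = np.concatenate([[xp[-1] - period], xp, [xp[0] + period]])
    fp_ext = np.concatenate([[fp[-1]], fp, [fp[0]]])
    return np.interp(np.mod(s, period), xp_ext, fp_ext)


def trajectory_normalize(
    counts: CountMatrix,
    partition: np.ndarray,
    pseudotime: np.ndarray,
    knn: list[np.ndarray] | None = None,
    n_top_genes: int = 10_000,
    smoothing: str = "linear",
    totals: np.ndarray | None = None,
) -> TrajectoryNormalization:
    """Normalize each cell's library size to the smoothed local median along the cycle.

    Steps: split the anomalously wide (division-moment) partition at the totals
    antimode; compute per-partition median totals; smooth them as a cyclic
    function of pseudotime (piecewise-linear by default, periodic cubic spline
    with ``smoothing='spline'``); rescale every cell to the smoothed median at
    its pseudotime; then re-pool with the provided kNN graph, ln(1+x) and
    re-select variable genes.  Column scaling preserves within-cell gene
    proportions by construction.

    ``totals`` are the per-cell library sizes used for wide-partition
    detection, the smoothed medians and the scale factors; they default to
    the column sums of ``counts`` but should be the *initial* (pre-pooling)
    totals when ``counts`` has been pooled, since pooling smears the division
    jump across the seam.
    """
    partition = np.asarray(partition, dtype=int)
    q = int(partition.max()) + 1
    if q < 3:
        raise ValueError("need at least 3 partitions along the trajectory")
    totals = counts.totals() if totals is None else np.asarray(totals, dtype=float)
    if totals.shape != (counts.n_cells,):
        raise ValueError("one total per cell required")
    newpart, wide, threshold, ratio = _split_wide_partition(totals, partition, q)

    # place each partition on the pseudotime axis at the circular mean of its
    # cells (node indices of a closed curve carry an arbitrary root/direction)
    ang = 2.0 * np.pi * np.asarray(pseudotime) / q
    medians = np.full(q, np.nan)
    node_pos = np.full(q, np.nan)
    for i in range(q):
        mask = newpart == i
        if not np.any(mask):
            continue
        medians[i] = np.median(totals[mask])
        mean_ang = np.arctan2(np.sin(ang[mask]).mean(), np.cos(ang[mask]).mean())
        node_pos[i] = (mean_ang / (2.0 * np.pi)) % 1.0 * q
    valid = ~np.isnan(medians)
    if smoothing == "spline" and valid.sum() >= 4:
        from scipy.interpolate import CubicSpline

        order = np.argsort(node_pos[valid])
        xp = node_pos[valid][order]
        fp = medians[valid][order]
        cs = CubicSpline(
            np.concatenate([xp, [xp[0] + q]]), np.concatenate([fp, [fp[0]]]), bc_type="periodic"
        )
        target = cs((np.asarray(pseudotime) - xp[0]) % q + xp[0])
    else:
        target = _cyclic_linear_interp(node_pos[valid], medians[valid], pseudotime, q)
    target = np.maximum(target, 1e-12)
    factors = target / totals
    normalized = counts.scaled_columns(factors)

    pooled = pool_neighbor_counts(normalized, knn) if knn is not None else normalized
    vals = pooled.values
    log_vals = vals.copy()
    if sp.issparse(log_vals):
        log_vals = log_vals.tocsr()
        log_vals.data = np.log1p(log_vals.data)
    else:
        log_vals = np.log1p(log_vals)
    lognorm = CountMatrix(log_vals, counts.gene_ids, counts.cell_ids)

    dense = lognorm.dense()
    var = dense.var(axis=1)
    n_hvg = min(n_top_genes, counts.n_genes)
    hvg = counts.gene_ids[np.argsort(var)[::-1][:n_hvg]]

    return TrajectoryNormalization(
        normalized=normalized,
        lognorm=lognorm,
        scale_factors=factors,
        partition=newpart,
        smoothed_medians=target,
        wide_partition=wide,
        split_threshold=threshold,
        division_drop_ratio=ratio,
        variable_genes=np.asarray(hvg, dtype=object),
    )


@dataclass
class CurvatureProfile:
    """Per-node curvature of the principal curve and its peaks."""

    values: np.ndarray  # (q,) non-negative
    peaks: np.ndarray  # node indices of curvature peaks, by decreasing prominence


def curvature_profile(
    curve: PrincipalCurve,
    prominence_fraction: float = 0.25,
    max_peaks: int = 5,
    normalize_speed: bool = False,
) -> CurvatureProfile:
    """Curvature along the curve: norm of the spline second derivative per node.

    Each coordinate of the node polyline is interpolated by a cubic spline in
    the natural (edge-unit) parameter; the curvature at node ``i`` is the
    Euclidean norm of the second-derivative vector there (nodes of an elastic
    curve are approximately equispaced, so the natural parameter is a good
    stand-in for arc length).  With ``normalize_speed`` the second derivative
    is divided by the squared local speed (Frenet-style normalization).  Peaks
    are local maxima with prominence at least ``prominence_fraction`` of the
    maximal curvature, capped at ``max_peaks`` by prominence.
    """
    from scipy.interpolate import CubicSpline
    from scipy.signal import find_peaks

    q = curve.n_nodes
    if q < 5:
        raise ValueError("need at least 5 nodes for curvature analysis")
    nodes = curve.nodes
    seg = nodes[1:] - nodes[:-1]
    if np.any(np.linalg.norm(seg, axis=1) == 0):
        raise ValueError("duplicate node positions")
    s = np.arange(q, dtype=float)
    if curve.closed:
        cs = CubicSpline(
            np.append(s, q), np.vstack([nodes, nodes[:1]]), bc_type="periodic", axis=0
        )
    else:
        cs = CubicSpline(s, nodes, bc_type="natural", axis=0)
    d2 = cs(s, 2)
    R = np.linalg.norm(d2, axis=1)
    if normalize_speed:
        speed2 = np.sum(cs(s, 1) ** 2, axis=1)
        R = R / np.maximum(speed2, 1e-12)

    if R.max() <= 0:
        return CurvatureProfile(values=R, peaks=np.array([], dtype=int))
    if curve.closed:
        # wrap the profile so peaks at the seam are found
        ext = np.concatenate([R, R, R])
        all_pk, props = find_peaks(ext, prominence=prominence_fraction * R.max())
        keep = (all_pk >= q) & (all_pk < 2 * q)
        pk = all_pk[keep] - q
        prom = props["prominences"][keep]
    else:
        pk, props = find_peaks(R, prominence=prominence_fraction * R.max())
        prom = props["prominences"]
    order = np.argsort(prom)[::-1][:max_peaks]
    peaks = np.sort(pk[order])
    return CurvatureProfile(values=R, peaks=peaks)


@dataclass
class EpochSegmentation:
    """Cyclic segmentation of pseudotime into transcriptional epochs."""

    boundaries: np.ndarray  # strictly increasing within [0, q)
    labels: list[str]  # one per segment
    cell_labels: np.ndarray

    @classmethod
    def from_peaks(
        cls, peaks: np.ndarray, pseudotime: np.ndarray, q: float
    ) -> "EpochSegmentation":
        """Segments between curvature peaks, the division point fixed at s = 0.

        Four segments map onto the canonical epochs T1, T1s, T2s, Tm; five
        segments carry an extra early-G1 label T1a before T1.
        """
        bounds = np.sort(np.asarray(peaks, dtype=float))
        bounds = bounds[(bounds > 0) & (bounds < q)]
        n_seg = len(bounds) + 1
        if n_seg == 4:
            labels = ["T1", "T1s", "T2s", "Tm"]
        elif n_seg == 5:
            labels = ["T1a", "T1", "T1s", "T2s", "Tm"]
        else:
            labels = [f"seg{i}" for i in range(n_seg)]
        edges = np.concatenate([[0.0], bounds, [q]])
        idx = np.clip(np.searchsorted(edges, pseudotime, side="right") - 1, 0, n_seg - 1)
        cell_labels = np.array([labels[i] for i in idx], dtype=object)
        return cls(boundaries=bounds, labels=labels, cell_labels=cell_labels)


def phase_scores(lognorm: CountMatrix, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-cell phase scores: mean log-scale expression over each marker set.

    The mean of logs corresponds (up to the +1 pseudocount) to the log of the
    geometric mean of the raw measures.  Raises when a set has no overlap with
    the matrix genes.
    """
    gene_index = {g: i for i, g in enumerate(lognorm.gene_ids)}
    dense = None
    out = {}
    for name, genes in gene_sets.items():
        rows = [gene_index[g] for g in genes if g in gene_index]
        if not rows:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if dense is None:
            dense = lognorm.dense()
        out[name] = dense[rows].mean(axis=0)
    return pd.DataFrame(out, index=lognorm.cell_ids.astype(str))


def epoch_marker_genes(
    lognorm: CountMatrix,
    epoch_labels: np.ndarray,
    variance_floor: float = 0.0,
    top_n: int = 20,
) -> dict[str, pd.DataFrame]:
    """Rank genes per epoch by log fold change of mean expression in vs outside.

    Genes whose total variance across cells falls below ``variance_floor`` are
    excluded; epochs with fewer than 2 cells are skipped with a warning.
    """
    epoch_labels = np.asarray(epoch_labels)
    epochs = [e for e in pd.unique(epoch_labels)]
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs")
    dense = lognorm.dense()
    var = dense.var(axis=1)
    keep = var >= variance_floor
    result: dict[str, pd.DataFrame] = {}
    for epoch in epochs:
        mask = epoch_labels == epoch
        if mask.sum() < 2:
            warnings.warn(f"epoch {epoch!r} has fewer than 2 cells; excluded", RuntimeWarning)
            continue
        lfc = dense[:, mask].mean(axis=1) - dense[:, ~mask].mean(axis=1)
        lfc = np.where(keep, lfc, -np.inf)
        order = np.argsort(lfc)[::-1][:top_n]
        order = order[np.isfinite(lfc[order]) & (lfc[order] != 0)]
        result[str(epoch)] = pd.DataFrame(
            {"gene": lognorm.gene_ids[order].astype(str), "log_fold_change": lfc[order]}
        ).reset_index(drop=True)
    return result


def effective_rank(matrix: np.ndarray, condition_bound: float = 10.0) -> int:
    """Largest r such that sigma_1 / sigma_r <= condition_bound.

    The number of leading singular values over which the matrix stays
    well-conditioned; 0 for an (effectively) zero matrix.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        return 0
    sv = np.linalg.svd(matrix, compute_uv=False)
    if sv[0] <= 0 or sv[0] < 1e-300:
        return 0
    return int(np.sum(sv >= sv[0] / condition_bound))


@dataclass
class CCTResult:
    """End-to-end pipeline output."""

    curve: PrincipalCurve
    pseudotime: np.ndarray
    root: int
    curvature: CurvatureProfile
    segmentation: EpochSegmentation
    cell_table: pd.DataFrame
    scores: pd.DataFrame
    markers: dict[str, pd.DataFrame]
    normalization: TrajectoryNormalization
    initial: InitialNormalization
    pca: np.ndarray


def run_cct_pipeline(
    counts: CountMatrix,
    gene_sets: dict[str, list[str]] | None = None,
    q: int = 50,
    n_top_genes: int = 10_000,
    n_pcs: int = 30,
    k: int = 10,
    seed: int = 0,
    stretch: float = 0.005,
    bend: float = 0.05,
    top_n_markers: int = 20,
) -> CCTResult:
    """Reconstruct the cell cycle trajectory from a raw count matrix.

    Orchestrates: first-pass normalization + kNN; pooling of raw counts;
    closed principal curve on the pooled, initially normalized data;
    trajectory-based renormalization; a second closed curve on the
    renormalized data; pseudotime rooted at the division gap; curvature
    segmentation; phase scores and epoch markers.
    """
    if gene_sets is None:
        from .io import default_gene_sets

        gene_sets = default_gene_sets()
    np.random.seed(seed)  # scanpy internals; the fitters themselves are deterministic

    init = initial_normalize(counts, n_top_genes=n_top_genes, n_pcs=n_pcs, k=k)
    pooled_raw = pool_neighbor_counts(counts, init.knn)
    pooled_init = initial_normalize(pooled_raw, n_top_genes=n_top_genes, n_pcs=n_pcs, k=k)

    initial_totals = counts.totals()
    curve0 = fit_principal_curve(
        pooled_init.pca, q=q, closed=True, stretch=stretch, bend=bend
    )
    pt0, _, _ = assign_pseudotime(curve0, pooled_init.pca, orientation_values=initial_totals)

    norm = trajectory_normalize(
        pooled_raw, curve0.partition, pt0, knn=init.knn, n_top_genes=n_top_genes,
        totals=initial_totals,
    )

    # second pass: embed the renormalized data and refit the curve
    gene_index = {g: i for i, g in enumerate(norm.lognorm.gene_ids)}
    hvg_rows = [gene_index[g] for g in norm.variable_genes]
    X = norm.lognorm.dense()[hvg_rows].T
    from sklearn.decomposition import PCA

    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full").fit_transform(X - X.mean(axis=0))
    curve = fit_principal_curve(pca, q=q, closed=True, stretch=stretch, bend=bend)
    pseudotime, root, rho = assign_pseudotime(curve, pca, orientation_values=initial_totals)

    # curvature on the root-aligned, direction-aware node order so that peak
    # indices live directly on the pseudotime axis
    order = _node_order(curve, root, pseudotime)
    aligned = PrincipalCurve(
        curve.nodes[order], True, curve.partition, curve.energy, curve.energy_trace
    )
    curv = curvature_profile(aligned)
    segmentation = EpochSegmentation.from_peaks(curv.peaks.astype(float), pseudotime, q)

    scores = phase_scores(norm.lognorm, gene_sets)
    markers = epoch_marker_genes(
        norm.lognorm,
        segmentation.cell_labels,
        variance_floor=float(np.median(norm.lognorm.dense().var(axis=1))),
        top_n=top_n_markers,
    )

    cell_table = pd.DataFrame(
        {
            "cell_id": counts.cell_ids.astype(str),
            "pseudotime": pseudotime,
            "partition": norm.partition,
            "epoch": segmentation.cell_labels,
            "total_counts": initial_totals,
        }
    )
    for col in scores.columns:
        cell_table[f"{col}_score"] = scores[col].to_numpy()

    return CCTResult(
        curve=curve,
        pseudotime=pseudotime,
        root=root,
        curvature=curv,
        segmentation=segmentation,
        cell_table=cell_table,
        scores=scores,
        markers=markers,
        normalization=norm,
        initial=init,
        pca=pca,
    )


def _node_order(curve: PrincipalCurve, root: int, pseudotime: np.ndarray) -> list[int]:
    """Order node indices so that index k sits at pseudotime ~k (direction-aware)."""
    q = curve.n_nodes
    forward = [(root + i) % q for i in range(q)]
    backward = [(root - i) % q for i in range(q)]
    # decide direction from the mean pseudotime of cells assigned to the next node
    nxt_f = np.mean(pseudotime[curve.partition == forward[1]]) if np.any(
        curve.partition == forward[1]
    ) else np.inf
    nxt_b = np.mean(pseudotime[curve.partition == backward[1]]) if np.any(
        curve.partition == backward[1]
    ) else np.inf
    return forward if nxt_f <= nxt_b else backward
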