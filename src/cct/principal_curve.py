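"""Elastic principal curves (open polylines and closed circles).

A principal curve is a polyline with nodes ``y_1..y_q`` fitted to a point
cloud by alternating (i) partition of the points to their nearest node and
(ii) a closed-form quadratic solve for the node positions minimizing

    U = MSE(points, assigned nodes) / N
        + lambda * sum_edges ||y_i - y_j||^2
        + mu * sum_nodes ||y_{i-1} - 2 y_i + y_{i+1}||^2

(the bending sum runs over interior nodes for open curves, cyclically for
closed ones).  Both half-steps decrease U, so the fitting loop is monotone.
Open curves are obtained by fitting a closed curve with q+1 nodes, deleting
the least-populated node (which for cyclic data sits in the division gap) and
refitting the remaining q-node path without the closing edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PrincipalCurve", "fit_principal_curve", "project_to_curve", "assign_pseudotime"]


@dataclass
class PrincipalCurve:
    """Fitted elastic polyline with the per-point partition."""

    nodes: np.ndarray  # (q, n)
    closed: bool
    partition: np.ndarray  # (N,) nearest-node index per point
    energy: float
    energy_trace: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        q = self.n_nodes
        e = [(i, i + 1) for i in range(q - 1)]
        if self.closed:
            e.append((q - 1, 0))
        return e

    def length(self) -> float:
        """Total polyline length (sum of edge lengths)."""
        return float(sum(np.linalg.norm(self.nodes[j] - self.nodes[i]) for i, j in self.edges()))


def _second_difference_matrix(q: int, closed: bool) -> np.ndarray:
    rows = []
    idx = range(q) if closed else range(1, q - 1)
    for i in idx:
        r = np.zeros(q)
        r[(i - 1) % q] = 1.0
        r[i] = -2.0
        r[(i + 1) % q] = 1.0
        rows.append(r)
    return np.array(rows) if rows else np.zeros((0, q))


def _edge_laplacian(q: int, closed: bool) -> np.ndarray:
    L = np.zeros((q, q))
    edges = [(i, i + 1) for i in range(q - 1)] + ([(q - 1, 0)] if closed else [])
    for i, j in edges:
        L[i, i] += 1.0
        L[j, j] += 1.0
        L[i, j] -= 1.0
        L[j, i] -= 1.0
    return L


def _energy(points, nodes, partition, closed, stretch, bend) -> float:
    mse = float(np.mean(np.sum((points - nodes[partition]) ** 2, axis=1)))
    edges = [(i, i + 1) for i in range(len(nodes) - 1)] + ([(len(nodes) - 1, 0)] if closed else [])
    u_e = sum(float(np.sum((nodes[j] - nodes[i]) ** 2)) for i, j in edges)
    D = _second_difference_matrix(len(nodes), closed)
    u_b = float(np.sum((D @ nodes) ** 2))
    return mse + stretch * u_e + bend * u_b


def _fit_topology(
    points: np.ndarray,
    nodes: np.ndarray,
    closed: bool,
    stretch: float,
    bend: float,
    max_iter: int,
    tol: float,
):
    """EM loop at fixed topology; returns (nodes, partition, energy trace)."""
    N = points.shape[0]
    q = nodes.shape[0]
    L = _edge_laplacian(q, closed)
    D = _second_difference_matrix(q, closed)
    B = D.T @ D
    trace = []
    partition = None
    for _ in range(max_iter):
        d2 = np.sum((points[:, None, :] - nodes[None, :, :]) ** 2, axis=2)
        partition = np.argmin(d2, axis=1)
        trace.append(_energy(points, nodes, partition, closed, stretch, bend))
        counts = np.bincount(partition, minlength=q).astype(float)
        sums = np.zeros_like(nodes)
        np.add.at(sums, partition, points)
        A = np.diag(counts / N) + stretch * L + bend * B
        new_nodes = np.linalg.solve(A, sums / N)
        shift = float(np.max(np.linalg.norm(new_nodes - nodes, axis=1)))
        nodes = new_nodes
        if shift < tol:
            break
    d2 = np.sum((points[:, None, :] - nodes[None, :, :]) ** 2, axis=2)
    partition = np.argmin(d2, axis=1)
    trace.append(_energy(points, nodes, partition, closed, stretch, bend))
    return nodes, partition, np.array(trace)


def _init_closed(points: np.ndarray, q: int) -> np.ndarray:
    """Deterministic initialization: an ellipse in the plane of the top 2 PCs."""
    center = points.mean(axis=0)
    X = points - center
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    n_pc = min(2, vt.shape[0])
    ang = 2 * np.pi * np.arange(q) / q
    radii = np.sqrt(2.0) * s[:n_pc] / np.sqrt(max(points.shape[0] - 1, 1))
    circ = np.zeros((q, 2))
    circ[:, 0] = np.cos(ang)
    circ[:, 1 % n_pc] = np.sin(ang) if n_pc > 1 else 0.0
    return center + (circ[:, :n_pc] * radii) @ vt[:n_pc]


def fit_principal_curve(
    points: np.ndarray,
    q: int = 30,
    closed: bool = True,
    stretch: float = 0.005,
    bend: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> PrincipalCurve:
    """Fit an elastic principal curve (closed circle or open polyline).

    Parameters
    ----------
    points
        (N, n) data; N must be >= q and the cloud must not be degenerate.
    q
        Number of nodes (>= 3).
    closed
        Closed principal circle if True, open polyline otherwise.
    stretch, bend
        Elastic penalty weights on squared edge lengths and squared second
        differences of consecutive nodes.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if q < 3:
        raise ValueError("q must be >= 3")
    if points.shape[0] < q:
        raise ValueError("need at least q data points")
    if np.allclose(points, points[0]):
        raise ValueError("degenerate input: all points identical")

    if closed:
        nodes0 = _init_closed(points, q)
        nodes, partition, trace = _fit_topology(
            points, nodes0, True, stretch, bend, max_iter, tol
        )
        return PrincipalCurve(nodes, True, partition, float(trace[-1]), trace)

    # open curve: fit closed with q+1 nodes, cut at the least-populated node
    nodes0 = _init_closed(points, q + 1)
    nodes_c, part_c, _ = _fit_topology(points, nodes0, True, stretch, bend, max_iter, tol)
    counts = np.bincount(part_c, minlength=q + 1)
    cut = int(np.argmin(counts))
    order = [(cut + 1 + i) % (q + 1) for i in range(q)]
    nodes, partition, trace = _fit_topology(
        points, nodes_c[order], False, stretch, bend, max_iter, tol
    )
    return PrincipalCurve(nodes, False, partition, float(trace[-1]), trace)


def project_to_curve(curve: PrincipalCurve, points: np.ndarray):
    """Project points onto the polyline; returns (s_raw, distances).

    ``s_raw = edge index + fractional position`` in node-index units, in
    ``[0, q-1]`` for open curves and ``[0, q)`` for closed ones.
    """
    points = np.asarray(points, dtype=float)
    edges = curve.edges()
    N = points.shape[0]
    best_d2 = np.full(N, np.inf)
    best_s = np.zeros(N)
    for k, (i, j) in enumerate(edges):
        a, b = curve.nodes[i], curve.nodes[j]
        ab = b - a
        denom = float(ab @ ab)
        frac = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(N)
        proj = a + frac[:, None] * ab
        d2 = np.sum((points - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_s[better] = k + frac[better]
    return best_s, np.sqrt(best_d2)


def assign_pseudotime(
    curve: PrincipalCurve,
    points: np.ndarray,
    root: int | None = None,
    orientation_values: np.ndarray | None = None,
):
    """Geodesic pseudotime from the root node, in edge units.

    For open curves the root must be an endpoint (0 or q-1).  For closed
    curves the root is any designated node; when ``root`` is None it is placed
    at the node just after the largest drop in the per-node median of
    ``orientation_values`` (the division gap).  The direction of traversal is
    chosen so that ``orientation_values`` (typically initial total counts)
    increase with pseudotime (positive rank correlation); if both orientations
    correlate negatively a warning is issued and the larger correlation wins.

    Returns ``(s, root, rho)`` with ``s`` in ``[0, q-1]`` (open) or ``[0, q)``
    (closed) and ``rho`` the Spearman correlation actually achieved.
    """
    from scipy.stats import spearmanr

    q = curve.n_nodes
    s_raw, _ = project_to_curve(curve, points)

    if not curve.closed:
        if root is None:
            root = 0
        if root not in (0, q - 1):
            raise ValueError("root of an open curve must be an endpoint node (0 or q-1)")
        s = s_raw if root == 0 else (q - 1) - s_raw
        rho = np.nan
        if orientation_values is not None:
            rho = float(spearmanr(s, orientation_values).statistic)
            if rho < 0:
                other = (q - 1) - s
                rho_other = float(spearmanr(other, orientation_values).statistic)
                if rho_other > rho:
                    s, rho = other, rho_other
                if rho < 0:
                    import warnings

                    warnings.warn(
                        "both orientations give negative correlation; keeping the larger",
                        RuntimeWarning,
                        stacklevel=2,
                    )
        return s, root, rho

    if root is None:
        if orientation_values is None:
            root = 0
        else:
            med = np.full(q, np.nan)
            for i in range(q):
                vals = np.asarray(orientation_values)[curve.partition == i]
                if vals.size:
                    med[i] = np.median(vals)
            med = np.where(np.isnan(med), np.nanmedian(med), med)
            drops = med - np.roll(med, 1)  # value minus predecessor's
            root = int(np.argmin(drops))
    forward = (s_raw - root) % q
    backward = (root - s_raw) % q
    if orientation_values is None:
        return forward, root, np.nan
    rho_f = float(spearmanr(forward, orientation_values).statistic)
    rho_b = float(spearmanr(backward, orientation_values).statistic)
    if max(rho_f, rho_b) < 0:
        import warnings

        warnings.warn(
            "both orientations give negative correlation; keeping the larger",
            RuntimeWarning,
            stacklevel=2,
        )
    return (forward, root, rho_f) if rho_f >= rho_b else (backward, root, rho_b)
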