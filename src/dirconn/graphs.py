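"""Density thresholding and directed graph measures.

Connectivity matrices are binarized by keeping the top ``floor(D * n(n-1))``
off-diagonal weights for each density D of a grid (default 1%..50% in 1%
steps); in weighted mode the surviving edges keep their original weights.
On each thresholded network the module computes the directed graph measures
used in whole-brain analyses: in/out degree (strength), directed shortest-path
distances and diameter, in/out global and local efficiency, the cycle-based
directed clustering coefficient

    C_i = (A^3)_ii / (d_in(i) d_out(i) - d<->(i)),   d<->(i) = (A^2)_ii,

the matching transitivity

    T = trace(A^3) / sum_i [ d_i (d_i - 1) - 2 (A^2)_ii ],

and Louvain modularity with the directed (Leicht-Newman) quality function.
Weighted generalizations follow the standard conventions: strengths for
degree, inverse-weight path lengths for efficiency, cube-root (Fagiolo-style)
weights for clustering/transitivity with weights normalized by the network
maximum, and weighted directed modularity.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConnectivityMatrix, ThresholdedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DensityThreshold",
    "GraphMeasures",
    "threshold_by_density",
    "degrees",
    "directed_distances",
    "global_efficiency",
    "local_efficiency",
    "directed_clustering",
    "transitivity",
    "modularity_louvain",
    "measures_over_densities",
    "auc_over_densities",
    "default_density_grid",
    "NODAL_MEASURES",
    "GLOBAL_MEASURES",
]

NODAL_MEASURES = (
    "in_degree",
    "out_degree",
    "degree",
    "in_global_eff",
    "out_global_eff",
    "global_eff",
    "in_local_eff",
    "out_local_eff",
    "local_eff",
    "clustering",
)

GLOBAL_MEASURES = (
    "E_in",
    "E_out",
    "E",
    "LE_in",
    "LE_out",
    "LE",
    "clustering_mean",
    "transitivity",
    "modularity",
    "diameter",
)


def default_density_grid(start: float = 0.01, stop: float = 0.50, step: float = 0.01) -> np.ndarray:
    """The standard density grid: 1% to 50% in 1% steps."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def _threshold_weights(w: np.ndarray, density: float, mode: str) -> np.ndarray:
    n = w.shape[0]
    m = n * (n - 1)
    if not 0 < density <= 0.5:
        raise ValueError("density must lie in (0, 0.5]")
    k = int(np.floor(density * m + 1e-9))
    if k < 1:
        raise ValueError(f"density {density} keeps no edges for n={n}")
    off = ~np.eye(n, dtype=bool)
    rows, cols = np.nonzero(off)
    vals = w[rows, cols]
    n_pos = int(np.count_nonzero(vals > 0))
    if k > n_pos:
        raise ValueError(
            f"requested density {density:.4f} exceeds the attainable maximum "
            f"{n_pos / m:.4f} (only {n_pos} positive off-diagonal entries)"
        )
    # deterministic tie-break: weight desc, then row, then col
    order = np.lexsort((cols, rows, -vals))
    keep = order[:k]
    adj = np.zeros_like(w)
    adj[rows[keep], cols[keep]] = 1.0 if mode == "binary" else vals[keep]
    return adj


def threshold_by_density(
    mat: ConnectivityMatrix | np.ndarray, density: float, mode: str = "binary"
) -> ThresholdedNetwork:
    """Keep the top ``floor(density * n(n-1))`` off-diagonal weights.

    Raises a ValueError naming the attainable maximum when the requested
    density exceeds the fraction of strictly positive entries (antisymmetric
    matrices have at most 50% of entries positive, hence the 50% cap on the
    density range).
    """
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    if isinstance(mat, ConnectivityMatrix):
        w = mat.weights
        meta = {"source_method": mat.method, "lag": mat.lag, "region_labels": mat.region_labels}
    else:
        w = np.asarray(mat, dtype=float)
        meta = {}
    if (w < 0).any():
        raise ValueError("thresholding expects a clipped (nonnegative) matrix")
    adj = _threshold_weights(w, density, mode)
    return ThresholdedNetwork(adjacency=adj, density=density, mode=mode, **meta)


def _adj(net) -> np.ndarray:
    return net.adjacency if isinstance(net, ThresholdedNetwork) else np.asarray(net, dtype=float)


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------


def degrees(net) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(in, out, total) degrees; weighted networks yield strengths."""
    a = _adj(net)
    d_in = a.sum(axis=0)
    d_out = a.sum(axis=1)
    return d_in, d_out, d_in + d_out


def _bfs_distances_small(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by boolean reachability powers; fast for the
    many small (sub)graphs the local-efficiency sweeps generate."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reach = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    for k in range(1, n):
        frontier = (frontier @ adj) & ~reach
        if not frontier.any():
            break
        D[frontier] = float(k)
        reach |= frontier
    return D


def directed_distances(net) -> tuple[np.ndarray, float, bool]:
    """All-pairs shortest directed path lengths.

    Returns ``(D, diameter, disconnected)``.  Binary networks use hop counts;
    weighted networks use inverse-weight edge lengths.  Unreachable pairs get
    ``inf``; the diameter is the largest finite off-diagonal distance (NaN for
    an edgeless network) and ``disconnected`` flags whether any pair was
    unreachable.
    """
    a = _adj(net)
    binary = bool(np.isin(a, (0.0, 1.0)).all())
    if binary:
        if a.shape[0] <= 64:
            D = _bfs_distances_small(a != 0)
        else:
            D = shortest_path(a != 0, method="D", unweighted=True)
    else:
        with np.errstate(divide="ignore"):
            lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
        D = shortest_path(lengths, method="D")
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(D[off])
    diameter = float(D[off][finite].max()) if finite.any() else float("nan")
    return D, diameter, bool(~finite.all())


def _efficiency_from_distances(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nodal (e_in, e_out): average inverse distance to/from each node."""
    n = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    if n < 2:
        return np.zeros(n), np.zeros(n)
    e_out = inv.sum(axis=1) / (n - 1)
    e_in = inv.sum(axis=0) / (n - 1)
    return e_in, e_out


def global_efficiency(net) -> dict:
    """Nodal and global in/out efficiency; E = (E_in + E_out)/2."""
    D, _, _ = directed_distances(net)
    e_in, e_out = _efficiency_from_distances(D)
    E_in = float(e_in.mean())
    E_out = float(e_out.mean())
    return {
        "e_in": e_in,
        "e_out": e_out,
        "E_in": E_in,
        "E_out": E_out,
        "E": 0.5 * (E_in + E_out),
    }


def local_efficiency(net) -> dict:
    """Global efficiency evaluated on each node's neighbor subgraph.

    A node's neighbors are the union of its in- and out-neighbors; nodes with
    fewer than two neighbors contribute 0.
    """
    a = _adj(net)
    n = a.shape[0]
    le_in = np.zeros(n)
    le_out = np.zeros(n)
    present = (a > 0) | (a.T > 0)
    binary = bool(np.isin(a, (0.0, 1.0)).all())
    for i in range(n):
        nbrs = np.nonzero(present[i])[0]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        if binary and len(nbrs) <= 64:
            D = _bfs_distances_small(sub != 0)
        else:
            D, _, _ = directed_distances(sub)
        e_in, e_out = _efficiency_from_distances(D)
        le_in[i] = e_in.mean()
        le_out[i] = e_out.mean()
    LE_in = float(le_in.mean())
    LE_out = float(le_out.mean())
    return {
        "le_in": le_in,
        "le_out": le_out,
        "LE_in": LE_in,
        "LE_out": LE_out,
        "LE": 0.5 * (LE_in + LE_out),
    }


def _cycle_weights(a: np.ndarray) -> np.ndarray:
    """Cube-root weights normalized by the network maximum (identity for
    binary networks)."""
    mx = a.max()
    if mx <= 0:
        return a
    return np.cbrt(a / mx)


def directed_clustering(net) -> np.ndarray:
    """Cycle clustering C_i = (A^3)_ii / (d_in d_out - d<->); triangles count
    only when the three edges form a directed cycle.  Degenerate denominators
    (<= 0) yield 0."""
    a = _adj(net)
    b = (a > 0).astype(float)
    w = _cycle_weights(a)
    cycles = np.diagonal(w @ w @ w)
    d_in, d_out, _ = degrees(b)
    recip = np.diagonal(b @ b)
    denom = d_in * d_out - recip
    c = np.zeros(a.shape[0])
    ok = denom > 0
    c[ok] = cycles[ok] / denom[ok]
    if (~ok & (cycles > 0)).any():  # pragma: no cover - defensive
        logger.warning("clustering denominator <= 0 with nonzero cycles; set to 0")
    return c


def transitivity(net) -> float:
    """T = trace(A^3) / sum_i [d_i(d_i - 1) - 2 (A^2)_ii]; 0 when the
    denominator is degenerate."""
    a = _adj(net)
    b = (a > 0).astype(float)
    w = _cycle_weights(a)
    num = float(np.trace(w @ w @ w))
    _, _, d_tot = degrees(b)
    recip = np.diagonal(b @ b)
    denom = float(np.sum(d_tot * (d_tot - 1) - 2 * recip))
    if denom <= 0:
        return 0.0
    return num / denom


def modularity_louvain(
    net, gamma: float = 1.0, n_restarts: int = 100, seed: int = 0
) -> tuple[float, list[set[int]]]:
    """Best-of-``n_restarts`` Louvain partition under the directed modularity
    quality function at resolution ``gamma``; returns (Q, partition)."""
    a = _adj(net)
    if not (a > 0).any():
        raise ValueError("modularity is undefined for an edgeless network")
    g = nx.from_numpy_array(a, create_using=nx.DiGraph)
    best_q = -np.inf
    best_part: list[set[int]] = []
    for r in range(max(1, int(n_restarts))):
        part = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=int(seed) + r
        )
        q = nx.community.modularity(g, part, weight="weight", resolution=gamma)
        if q > best_q:
            best_q = q
            best_part = part
    return float(best_q), best_part


# ---------------------------------------------------------------------------
# Density sweeps and AUC
# ---------------------------------------------------------------------------


def _measures_one_density(
    net: ThresholdedNetwork, measures: str | list, n_restarts: int, seed: int
) -> list[dict]:
    rows = []
    labels = net.region_labels
    want = set(NODAL_MEASURES) | set(GLOBAL_MEASURES) if measures == "all" else set(measures)

    def emit(measure, region, value):
        rows.append(
            {"density": net.density, "measure": measure, "region": region, "value": float(value)}
        )

    d_in, d_out, d_tot = degrees(net)
    ge = global_efficiency(net)
    need_le = want & {"in_local_eff", "out_local_eff", "local_eff", "LE_in", "LE_out", "LE"}
    le = local_efficiency(net) if need_le else None
    clust = directed_clustering(net) if want & {"clustering", "clustering_mean"} else None

    nodal = {
        "in_degree": d_in,
        "out_degree": d_out,
        "degree": d_tot,
        "in_global_eff": ge["e_in"],
        "out_global_eff": ge["e_out"],
        "global_eff": 0.5 * (ge["e_in"] + ge["e_out"]),
    }
    if le is not None:
        nodal.update(
            in_local_eff=le["le_in"],
            out_local_eff=le["le_out"],
            local_eff=0.5 * (le["le_in"] + le["le_out"]),
        )
    if clust is not None:
        nodal["clustering"] = clust
    for name, vec in nodal.items():
        if name in want:
            for lbl, v in zip(labels, vec):
                emit(name, lbl, v)

    glob = {"E_in": ge["E_in"], "E_out": ge["E_out"], "E": ge["E"]}
    if le is not None:
        glob.update(LE_in=le["LE_in"], LE_out=le["LE_out"], LE=le["LE"])
    if clust is not None:
        glob["clustering_mean"] = float(clust.mean())
    if "transitivity" in want:
        glob["transitivity"] = transitivity(net)
    if "diameter" in want:
        _, diam, _ = directed_distances(net)
        glob["diameter"] = diam
    if "modularity" in want:
        q, _ = modularity_louvain(net, n_restarts=n_restarts, seed=seed)
        glob["modularity"] = q
    for name, v in glob.items():
        if name in want:
            emit(name, "GLOBAL", v)
    return rows


def measures_over_densities(
    mat: ConnectivityMatrix | np.ndarray,
    densities: np.ndarray | None = None,
    mode: str = "binary",
    measures: str | list = "all",
    n_restarts: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format table of every requested measure at every density.

    Columns: ``density, measure, region, value`` with ``region='GLOBAL'`` for
    network-level measures.  Densities that exceed the attainable maximum are
    skipped with a warning.
    """
    if densities is None:
        densities = default_density_grid()
    rows: list[dict] = []
    for d in np.asarray(densities, dtype=float):
        try:
            net = threshold_by_density(mat, float(d), mode=mode)
        except ValueError as exc:
            logger.warning("skipping density %.3f: %s", d, exc)
            continue
        rows.extend(_measures_one_density(net, measures, n_restarts, seed))
    return pd.DataFrame(rows, columns=["density", "measure", "region", "value"])


def auc_over_densities(curves: pd.DataFrame) -> pd.DataFrame:
    """Trapezoidal integral of each (measure, region) curve over the density
    grid, yielding one threshold-robust value per measure and region."""
    required = {"density", "measure", "region", "value"}
    if not required.issubset(curves.columns):
        raise ValueError(f"curves must have columns {sorted(required)}")
    out = []
    for (measure, region), grp in curves.groupby(["measure", "region"], sort=False):
        d = grp["density"].to_numpy()
        if len(d) < 2:
            raise ValueError("AUC requires at least 2 densities")
        if (np.diff(d) <= 0).any():
            raise ValueError("density grid must be strictly increasing")
        out.append(
            {
                "measure": measure,
                "region": region,
                "auc": float(np.trapezoid(grp["value"].to_numpy(), d)),
                "density_lo": float(d[0]),
                "density_hi": float(d[-1]),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# scikit-learn surface
# ---------------------------------------------------------------------------


class DensityThreshold(BaseEstimator, TransformerMixin):
    """Transformer: stack of clipped matrices -> stack of thresholded
    adjacencies at one density."""

    def __init__(self, density: float = 0.2, mode: str = "binary"):
        self.density = density
        self.mode = mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_regions_ = X.shape[-1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.stack([_threshold_weights(w, self.density, self.mode) for w in X])


class GraphMeasures(BaseEstimator, TransformerMixin):
    """Transformer: stack of clipped connectivity matrices -> AUC feature
    matrix.

    ``transform`` thresholds each subject's matrix across the density grid,
    computes the requested measures at every density, and integrates each
    (measure, region) curve, producing one feature column per measure-region
    pair (``GLOBAL`` rows carry the network-level measures).  ``curves``
    returns the underlying long-format table instead.
    """

    def __init__(
        self,
        densities: np.ndarray | None = None,
        mode: str = "binary",
        measures: str | list = "all",
        n_restarts: int = 100,
        seed: int = 0,
    ):
        self.densities = densities
        self.mode = mode
        self.measures = measures
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_regions_ = X.shape[-1]
        first = self._auc_one(X[0])
        self.feature_names_out_ = [f"{m}:{r}" for m, r in zip(first["measure"], first["region"])]
        return self

    def _auc_one(self, w: np.ndarray) -> pd.DataFrame:
        curves = measures_over_densities(
            w,
            densities=self.densities,
            mode=self.mode,
            measures=self.measures,
            n_restarts=self.n_restarts,
            seed=self.seed,
        )
        return auc_over_densities(curves)

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.stack([self._auc_one(w)["auc"].to_numpy() for w in X])

    def curves(self, X, subject_ids=None) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        if subject_ids is None:
            subject_ids = [f"S{i:03d}" for i in range(X.shape[0])]
        frames = []
        for sid, w in zip(subject_ids, X):
            df = measures_over_densities(
                w,
                densities=self.densities,
                mode=self.mode,
                measures=self.measures,
                n_restarts=self.n_restarts,
                seed=self.seed,
            )
            df.insert(0, "subject", sid)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
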