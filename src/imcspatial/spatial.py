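"""Neighborhood graph and permutation interaction/avoidance testing.

For every ordered cell-type pair (A, B) the statistic is the mean number
of type-B neighbors per type-A cell within a fixed radius (the
histoCAT-style neighborhood statistic; directional, so (A, B) and (B, A)
differ).  The null is built by permuting lineage labels over the fixed
graph; one-sided empirical p-values with +1 smoothing test for
interaction (observed high) and avoidance (observed low), and
Benjamini-Hochberg correction is applied within an image, across ordered
pairs, separately for the interaction and avoidance families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

DEFAULT_RADIUS_UM = 15.0
DEFAULT_N_PERM = 1000
DEFAULT_MIN_CELLS = 10


@dataclass
class NeighborGraph:
    """Undirected proximity graph over cell centroids.

    Edges connect cells whose centroid distance is at most ``radius_um``
    (Euclidean, physical units).  Construction is independent of input
    row order.
    """

    cell_ids: np.ndarray          # (n,) original cell ids, sorted
    edges: np.ndarray             # (m, 2) index pairs i < j into cell_ids
    radius_um: float

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> csr_matrix:
        """Symmetric 0/1 adjacency in node-index space."""
        n = self.n_nodes
        if self.n_edges == 0:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def edge_id_set(self) -> set[tuple[int, int]]:
        """Edges as unordered pairs of original cell ids."""
        ids = self.cell_ids
        return {
            tuple(sorted((int(ids[i]), int(ids[j]))))
            for i, j in self.edges
        }


def build_graph(
    cells: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM,
    um_per_px: float = 1.0,
) -> NeighborGraph:
    """All centroid pairs within ``radius_um`` of each other.

    Cell coordinates are in pixels; distances are converted through
    ``um_per_px``.  No self-edges; the edge set is symmetric by
    construction.
    """
    if radius_um <= 0:
        raise ValidationError("radius_um must be positive")
    order = np.argsort(cells["cell_id"].to_numpy(), kind="stable")
    ids = cells["cell_id"].to_numpy()[order]
    xy = cells[["x", "y"]].to_numpy(dtype=float)[order] * um_per_px
    if len(ids) == 0:
        return NeighborGraph(ids, np.empty((0, 2), dtype=int), radius_um)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius_um, output_type="ndarray")
    pairs = np.sort(pairs, axis=1)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return NeighborGraph(ids, pairs, radius_um)


@dataclass
class InteractionResult:
    """Permutation-test outcome for one ordered cell-type pair."""

    type_a: str
    type_b: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_interaction: float
    p_avoidance: float
    q_interaction: float
    q_avoidance: float
    n_a: int
    n_b: int
    n_perm: int
    valid: bool


def _pair_stats(adj: csr_matrix, onehot: np.ndarray, counts: np.ndarray):
    """Mean B-neighbors per A-cell for every ordered (A, B) at once.

    ``onehot`` is the (n, L) lineage indicator; returns an (L, L) matrix
    whose (a, b) entry is (1_A' adj 1_B) / n_a, NaN where n_a = 0.
    """
    totals = onehot.T @ (adj @ onehot)
    with np.errstate(invalid="ignore", divide="ignore"):
        return totals / counts[:, None]


def interaction_test(
    graph: NeighborGraph,
    lineages: dict | pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    min_cells: int = DEFAULT_MIN_CELLS,
    seed: int = 0,
    check_null: bool = False,
) -> list[InteractionResult]:
    """Permutation interaction/avoidance test over all ordered type pairs.

    The graph is fixed; the null permutes the lineage labels over nodes
    ``n_perm`` times (seed-deterministic) and recomputes the neighbor
    statistic each time.  p_interaction = (1 + #{null >= obs}) /
    (1 + n_perm), p_avoidance likewise with <=.  Pairs where either type
    has fewer than ``min_cells`` members are emitted with valid=False,
    p = 1, z = 0.  With ``check_null`` the lineage multiset is asserted
    conserved on every permutation (test mode).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if isinstance(lineages, pd.Series):
        lineages = dict(lineages)
    labels = np.array([lineages.get(int(cid)) for cid in graph.cell_ids],
                      dtype=object)
    if any(l is None for l in labels):
        raise ValidationError("lineage undefined for some graph nodes")
    types, inverse = np.unique(labels.astype(str), return_inverse=True)
    L = len(types)
    n = graph.n_nodes
    counts = np.bincount(inverse, minlength=L)
    onehot = np.zeros((n, L))
    onehot[np.arange(n), inverse] = 1.0
    adj = graph.adjacency()

    observed = _pair_stats(adj, onehot, counts)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, L, L))
    base_sorted = np.sort(inverse)
    for t in range(n_perm):
        perm = rng.permutation(n)
        perm_inv = inverse[perm]
        if check_null:
            assert np.array_equal(np.sort(perm_inv), base_sorted)
        oh = np.zeros((n, L))
        oh[np.arange(n), perm_inv] = 1.0
        null[t] = _pair_stats(adj, oh, counts)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    results = []
    p_int_flat, p_avd_flat, meta = [], [], []
    for a in range(L):
        for b in range(L):
            valid = counts[a] >= min_cells and counts[b] >= min_cells
            if valid:
                obs = float(observed[a, b])
                nm, nsd = float(null_mean[a, b]), float(null_sd[a, b])
                z = (obs - nm) / nsd if nsd > 0 else 0.0
                p_int = (1 + int(np.sum(null[:, a, b] >= obs))) / (1 + n_perm)
                p_avd = (1 + int(np.sum(null[:, a, b] <= obs))) / (1 + n_perm)
            else:
                obs = float(observed[a, b]) if counts[a] > 0 else np.nan
                nm = nsd = z = 0.0
                p_int = p_avd = 1.0
            meta.append((a, b, obs, nm, nsd, z, valid))
            p_int_flat.append(p_int)
            p_avd_flat.append(p_avd)

    q_int = _bh_within_valid(p_int_flat, [m[6] for m in meta])
    q_avd = _bh_within_valid(p_avd_flat, [m[6] for m in meta])
    for k, (a, b, obs, nm, nsd, z, valid) in enumerate(meta):
        results.append(InteractionResult(
            type_a=str(types[a]), type_b=str(types[b]), observed=obs,
            null_mean=nm, null_sd=nsd, z=float(z),
            p_interaction=p_int_flat[k], p_avoidance=p_avd_flat[k],
            q_interaction=q_int[k], q_avoidance=q_avd[k],
            n_a=int(counts[a]), n_b=int(counts[b]),
            n_perm=n_perm, valid=bool(valid)))
    return results


def _bh_within_valid(pvals, valid_flags):
    """BH over the valid family; invalid entries keep q = 1."""
    q = np.ones(len(pvals))
    idx = [i for i, v in enumerate(valid_flags) if v]
    if idx:
        _, q_adj, _, _ = multipletests([pvals[i] for i in idx], method="fdr_bh")
        q[idx] = q_adj
    return q.tolist()


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def cohort_interaction_summary(
    results_by_sample: dict[str, pd.DataFrame],
    pairs: dict[str, tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired primary-vs-recurrent comparison of interaction z-scores.

    Per ordered cell-type pair: mean z per condition, the paired mean
    difference of z (recurrent minus primary), and how many images per
    condition are significant (q_interaction < alpha).  Descriptive only —
    no inferential claim is attached beyond the paired difference.
    """
    if not pairs:
        raise ValidationError("no matched pairs supplied")
    for pid, (prim, rec) in pairs.items():
        for sid in (prim, rec):
            if sid not in results_by_sample:
                raise ValidationError(
                    f"pair {pid!r}: no interaction results for sample {sid!r}")
    all_pairs = set()
    for df in results_by_sample.values():
        all_pairs |= set(zip(df["type_a"], df["type_b"]))

    def _z(df, a, b):
        sub = df[(df["type_a"] == a) & (df["type_b"] == b) & df["valid"]]
        return float(sub["z"].iloc[0]) if len(sub) else np.nan

    def _sig(df, a, b, alpha):
        sub = df[(df["type_a"] == a) & (df["type_b"] == b) & df["valid"]]
        return int(len(sub) and sub["q_interaction"].iloc[0] < alpha)

    rows = []
    for a, b in sorted(all_pairs):
        z_prim, z_rec, diffs = [], [], []
        sig_prim = sig_rec = 0
        for prim, rec in pairs.values():
            zp = _z(results_by_sample[prim], a, b)
            zr = _z(results_by_sample[rec], a, b)
            z_prim.append(zp)
            z_rec.append(zr)
            if np.isfinite(zp) and np.isfinite(zr):
                diffs.append(zr - zp)
            sig_prim += _sig(results_by_sample[prim], a, b, alpha)
            sig_rec += _sig(results_by_sample[rec], a, b, alpha)
        def _nanmean(v):
            v = [x for x in v if np.isfinite(x)]
            return float(np.mean(v)) if v else np.nan

        rows.append({
            "type_a": a, "type_b": b,
            "mean_z_primary": _nanmean(z_prim),
            "mean_z_recurrent": _nanmean(z_rec),
            "paired_z_diff": float(np.mean(diffs)) if diffs else np.nan,
            "n_pairs_used": len(diffs),
            "n_significant_primary": sig_prim,
            "n_significant_recurrent": sig_rec,
        })
    return pd.DataFrame(rows)
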