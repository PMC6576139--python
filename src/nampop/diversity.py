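"""Genetic distances, neighbor-joining phylogeny and PCA for founders and
RILs.

The distance is the allele-sharing dissimilarity d(i,j) = 1 - mean shared
allele fraction over pairwise-complete markers (AA vs AA -> 1, AA vs AB ->
0.5, AA vs BB -> 0), i.e. mean |dosage_i - dosage_j| / 2.  Trees are built
with the Saitou–Nei neighbor-joining algorithm with deterministic
lexicographic tie-breaking; negative branch lengths are clamped to zero and
logged.  PCA operates on per-marker mean-imputed, centered dosages via SVD.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import GenotypeMatrix

__all__ = ["DistanceMatrix", "allele_sharing_distance", "nj_tree", "pca",
           "flag_misassigned"]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: np.ndarray
    values: np.ndarray      # symmetric, zero diagonal, NaN when no shared calls
    n_shared: np.ndarray    # pairwise-complete marker counts
    low_confidence: np.ndarray  # pairs with < min_shared shared calls

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())


def allele_sharing_distance(G: GenotypeMatrix, min_shared: int = 50) -> DistanceMatrix:
    """1 - mean shared-allele fraction over pairwise-complete markers."""
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    c = G.calls
    valid = (c != -1)
    # sum |x_i - x_j| over complete markers via one-hot class products
    ind = [np.asarray((c == k) & valid, float) for k in (0, 1, 2)]
    n = np.asarray(valid, float) @ np.asarray(valid, float).T
    absdiff = (ind[0] @ ind[1].T + ind[1] @ ind[0].T
               + ind[1] @ ind[2].T + ind[2] @ ind[1].T
               + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n > 0, absdiff / (2.0 * n), np.nan)
    np.fill_diagonal(d, 0.0)
    low = (n < min_shared)
    np.fill_diagonal(low, False)
    return DistanceMatrix(G.sample_ids.copy(), d, n.astype(int), low)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with lexicographic tie-breaking.

    Ties in the Q criterion are resolved by the smallest (sorted) pair of
    cluster keys, where a cluster's key is its lexicographically smallest
    leaf id; negative branch lengths are clamped to 0 and logged.  Returns
    an unrooted (trifurcating root) :class:`skbio.TreeNode`.
    """
    if not D.is_complete():
        raise ValueError("distance matrix incomplete: NJ needs every pair defined")
    n = len(D.ids)
    if n < 3:
        raise ValueError("NJ needs at least three samples")

    d = D.values.astype(float).copy()
    # each active node: (newick fragment, sort key)
    nodes = [(str(t), str(t)) for t in D.ids]
    active = list(range(n))
    clamped = 0

    def _bl(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((nodes[idx[i]][1], nodes[idx[j]][1])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        gi, gj = idx[i], idx[j]
        dij = sub[i, j]
        bi = _bl(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        bj = _bl(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))))
        new_frag = (f"({nodes[gi][0]}:{bi:.10g},{nodes[gj][0]}:{bj:.10g})")
        new_key = min(nodes[gi][1], nodes[gj][1])
        # distances from the new node to the remaining actives
        dnew = 0.5 * (d[gi, idx] + d[gj, idx] - dij)
        gnew = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[gnew, idx] = dnew
        d[idx, gnew] = dnew
        nodes.append((new_frag, new_key))
        active = [g for g in active if g not in (gi, gj)] + [gnew]

    # closed-form three-point resolution
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    ba = _bl(0.5 * (dab + dac - dbc))
    bb = _bl(0.5 * (dab + dbc - dac))
    bc = _bl(0.5 * (dac + dbc - dab))
    trio = sorted([(nodes[a][1], nodes[a][0], ba), (nodes[b][1], nodes[b][0], bb),
                   (nodes[c][1], nodes[c][0], bc)])
    newick = "(" + ",".join(f"{frag}:{bl:.10g}" for _, frag, bl in trio) + ");"
    if clamped:
        log.info("nj_tree: clamped %d negative branch lengths to 0", clamped)
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


# ---------------------------------------------------------------------------
# PCA


def pca(G: GenotypeMatrix, n_components: int = 10):
    """Centered-dosage SVD.

    Missing calls are imputed with the per-marker mean.  Returns (scores
    DataFrame indexed by sample, explained-variance fractions).  Fractions
    are relative to the total dosage variance, so they sum to <= 1.
    """
    if G.n_samples < 2 or G.n_markers < 2:
        raise ValueError("need >= 2 samples and >= 2 markers")
    d = G.dosage()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    ii = np.where(np.isfinite(d), d, col_mean[None, :])
    x = ii - ii.mean(axis=0)
    total_var = float(np.sum(x ** 2))
    if total_var <= 1e-12:
        warnings.warn("all-constant genotype matrix: zero variance", stacklevel=2)
        return (pd.DataFrame(index=pd.Index(G.sample_ids, name="sample")),
                np.array([]))
    k = min(n_components, min(x.shape) - 1) or 1
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total_var
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=pd.Index(G.sample_ids, name="sample"),
                         columns=cols), explained)


# ---------------------------------------------------------------------------
# misassignment screen


def flag_misassigned(G: GenotypeMatrix, margin: float = 0.05) -> pd.DataFrame:
    """Reproducible replacement for visual outlier inspection on family
    trees: flag a sample whose mean allele-sharing distance to its own
    family exceeds its mean distance to some other family by ``margin``."""
    D = allele_sharing_distance(G)
    fams = pd.Series(G.families, index=np.arange(G.n_samples))
    rows = []
    ril = G.ril_mask()
    for i in np.flatnonzero(ril):
        fam = G.families[i]
        own = np.flatnonzero((G.families == fam) & ril)
        own = own[own != i]
        if len(own) == 0:
            warnings.warn(f"singleton family {fam}: sample {G.sample_ids[i]} skipped",
                          stacklevel=2)
            continue
        d_own = float(np.nanmean(D.values[i, own]))
        best_other, best_fam = np.inf, None
        for other in pd.unique(fams[ril]):
            if other == fam:
                continue
            oi = np.flatnonzero((G.families == other) & ril)
            if len(oi) == 0:
                continue
            m = float(np.nanmean(D.values[i, oi]))
            if m < best_other:
                best_other, best_fam = m, other
        if best_fam is not None and d_own > best_other + margin:
            rows.append({"sample": G.sample_ids[i], "family": fam,
                         "nearest_family": best_fam,
                         "own_mean_distance": d_own,
                         "nearest_mean_distance": best_other})
    return pd.DataFrame(rows, columns=["sample", "family", "nearest_family",
                                       "own_mean_distance", "nearest_mean_distance"])
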