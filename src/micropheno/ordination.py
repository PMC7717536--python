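"""Classical PCoA and agglomerative hierarchical clustering.

PCoA (classical multidimensional scaling) embeds a dissimilarity matrix via
eigendecomposition of the Gower double-centered squared-distance matrix.
Non-Euclidean inputs (e.g. Bray-Curtis) produce negative eigenvalues; these
are reported but excluded from the variance-explained denominator, which
sums positive eigenvalues only.

Clustering offers the three classical linkage rules — single (minimum),
complete (maximum) and average (UPGMA, unweighted mean over all cross
pairs) — with deterministic tie-breaking, and a leaf ordering used to sort
samples in composition bar charts and heat maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import DataError, DistanceMatrix

LINKAGES = ("single", "complete", "average")

#: eigenvalues below this (relative) magnitude count as zero
_EIG_TOL = 1e-9


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k, k = retained positive axes
    eigenvalues: np.ndarray  # full spectrum, descending (negatives included)
    variance_explained: np.ndarray  # fraction per retained axis

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(D: DistanceMatrix, k: int = 2, lingoes: bool = False) -> PCoAResult:
    """Principal coordinate analysis of a dissimilarity matrix.

    Double-centers B = -1/2 J D^2 J (J = I - 11'/n), eigendecomposes, and
    returns coordinates eigvec * sqrt(lambda) for up to `k` positive
    eigenvalues. Axis signs are fixed so each axis's largest-magnitude
    loading is positive, making output reproducible. ``lingoes=True``
    applies the Lingoes additive correction (adds the constant needed to
    make the off-diagonal squared distances Euclidean) before embedding.
    """
    D.check()
    n = len(D.sample_ids)
    if n < 3:
        raise DataError("too_few_samples", "PCoA needs at least 3 samples")
    d2 = D.values**2
    B = _double_center(d2)
    if lingoes:
        lam = np.linalg.eigvalsh(B)
        c = -lam.min()
        if c > _EIG_TOL * max(1.0, abs(lam).max()):
            d2 = d2 + 2 * c * (1 - np.eye(n))
            B = _double_center(d2)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = _EIG_TOL * max(1.0, abs(eigval).max())
    eigval = np.where(np.abs(eigval) <= tol, 0.0, eigval)
    n_pos = int((eigval > 0).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
    keep = min(k, n_pos)
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    for j in range(keep):  # deterministic sign: largest |loading| positive
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigval[eigval > 0].sum()
    ve = eigval[:keep] / pos_sum if pos_sum > 0 else np.zeros(keep)
    return PCoAResult(list(D.sample_ids), coords, eigval, ve)


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


# --------------------------------------------------------------------------
# Agglomerative clustering
# --------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    Leaves are numbered 0..n-1 in the order of ``leaf_ids``; each merge
    creates node ``n + step``. ``merges`` rows are (node_a, node_b, height,
    new_node) with node_a < node_b.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> list[float]:
        return [h for (_, _, h, _) in self.merges]

    def members(self) -> dict[int, frozenset[int]]:
        """Node id -> leaf indices under that node."""
        out = {i: frozenset([i]) for i in range(self.n_leaves)}
        for a, b, _, new in self.merges:
            out[new] = out[a] | out[b]
        return out


def hcluster(D: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Naive agglomerative clustering under single/complete/average linkage.

    At each step the pair of clusters at minimal linkage distance is merged;
    ties are broken by the lexicographically smallest (node_a, node_b) id
    pair so runs are bit-reproducible. Average linkage is UPGMA: the
    unweighted mean of all cross-pair distances.
    """
    if linkage not in LINKAGES:
        raise DataError("unknown_linkage", f"linkage must be one of {LINKAGES}, got {linkage!r}")
    D.check()
    n = len(D.sample_ids)
    if n < 2:
        raise DataError("too_few_samples", "clustering needs at least 2 samples")
    # active clusters: node id -> (leaf index set)
    active: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = len(active[a]), len(active[b])
        new = next_id
        next_id += 1
        merged = active[a] | active[b]
        del active[a], active[b]
        newdist: dict[int, float] = {}
        for c in active:
            dac = dist[_key(a, c)]
            dbc = dist[_key(b, c)]
            if linkage == "single":
                d = min(dac, dbc)
            elif linkage == "complete":
                d = max(dac, dbc)
            else:  # UPGMA
                d = (na * dac + nb * dbc) / (na + nb)
            newdist[c] = d
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, d in newdist.items():
            dist[_key(new, c)] = d
        active[new] = merged
        merges.append((a, b, h, new))
    return Dendrogram(list(D.sample_ids), merges, linkage)


def _key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def leaf_order(dend: Dendrogram) -> list[str]:
    """Sample ids in dendrogram display order.

    At each internal node the child cluster created earlier in the merge
    sequence is placed on the left; a leaf child (never itself the product
    of a merge) goes right of any merged cluster, and two leaf children are
    ordered by sample id. Deterministic and invariant to the input sample
    permutation when merge heights are distinct.
    """
    n = dend.n_leaves
    children = {new: (a, b) for a, b, _, new in dend.merges}
    creation = {new: step for step, (_, _, _, new) in enumerate(dend.merges)}

    def sort_key(node: int):
        if node < n:
            return (1, dend.leaf_ids[node], 0)
        return (0, "", creation[node])

    out: list[str] = []

    def walk(node: int) -> None:
        if node < n:
            out.append(dend.leaf_ids[node])
            return
        a, b = children[node]
        first, second = sorted((a, b), key=sort_key)
        walk(first)
        walk(second)

    root = dend.merges[-1][3] if dend.merges else 0
    walk(root)
    return out
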