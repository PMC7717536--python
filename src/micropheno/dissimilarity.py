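"""Beta-diversity: Bray-Curtis, Jaccard, UniFrac, and pairwise matrices.

Bray-Curtis and Jaccard are computed directly from their definitions on
per-sample abundance vectors. UniFrac (both variants) is computed natively on
a rooted phylogeny with branch lengths: each branch contributes according to
the abundance mass descending through it. The engine is self-contained
without a tree — UniFrac is optional, and precomputed square matrices can be
imported instead (see :func:`micropheno.io.read_distance_matrix`).
"""

from __future__ import annotations

import numpy as np

from .model import DataError, DistanceMatrix, Study, rank_index

METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("length_mismatch", "abundance vectors must be 1-D of equal length")
    if np.min(x) < 0 or np.min(y) < 0:
        raise DataError("negative_abundance", "negative abundance value")
    if not (np.any(x > 0) or np.any(y > 0)):
        raise DataError("empty_pair", "both vectors are all-zero")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum |x_i - y_i| / sum (x_i + y_i), in [0, 1]."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard(x, y) -> float:
    """Jaccard distance on presence/absence: 1 - |A and B| / |A or B|.

    Presence means strictly positive abundance; no detection-limit epsilon.
    """
    x, y = _check_pair(x, y)
    a = x > 0
    b = y > 0
    union = int(np.sum(a | b))
    inter = int(np.sum(a & b))
    return 1.0 - inter / union


def unifrac(tree, taxon_ids, x, y, weighted: bool = False) -> float:
    """UniFrac dissimilarity between two samples on a rooted phylogeny.

    `tree` is a scikit-bio ``TreeNode`` (or a Newick string); `taxon_ids`
    names the leaves corresponding to the entries of `x` and `y`. Every taxon
    with nonzero abundance in either sample must map to exactly one leaf.

    Unweighted: fraction of branch length leading to leaves present in
    exactly one of the two samples, over branch length present in either.
    Weighted (raw, unnormalized): sum over branches of
    length x |p_x(branch) - p_y(branch)| where p(branch) is the fraction of
    the sample's total abundance descending through the branch.
    """
    import skbio

    if isinstance(tree, str):
        tree = skbio.TreeNode.read([tree])
    x, y = _check_pair(x, y)
    if len(taxon_ids) != len(x):
        raise DataError("length_mismatch", "taxon_ids and abundance vectors differ in length")

    leaves = {t.name: t for t in tree.tips()}
    missing = [str(t) for t, xa, ya in zip(taxon_ids, x, y) if (xa > 0 or ya > 0) and t not in leaves]
    if missing:
        raise DataError("unmapped_taxa", f"taxa absent from tree: {', '.join(sorted(missing))}")

    xa = {t: v for t, v in zip(taxon_ids, x)}
    ya = {t: v for t, v in zip(taxon_ids, y)}
    xtot, ytot = x.sum(), y.sum()
    # postorder pass: abundance mass descending through each node's branch
    mass: dict[int, tuple[float, float]] = {}
    num = den = 0.0
    wsum = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mx, my = xa.get(node.name, 0.0), ya.get(node.name, 0.0)
        else:
            mx = sum(mass[id(c)][0] for c in node.children)
            my = sum(mass[id(c)][1] for c in node.children)
        mass[id(node)] = (mx, my)
        if node.is_root():
            continue
        b = node.length or 0.0
        if b < 0:
            raise DataError("negative_branch", f"negative branch length at {node.name!r}")
        if weighted:
            px = mx / xtot if xtot > 0 else 0.0
            py = my / ytot if ytot > 0 else 0.0
            wsum += b * abs(px - py)
        else:
            in_x, in_y = mx > 0, my > 0
            if in_x or in_y:
                den += b
                if in_x != in_y:
                    num += b
    if weighted:
        return float(wsum)
    return float(num / den) if den > 0 else 0.0


def pairwise_distances(
    study: Study,
    metric: str,
    rank: str = "genus",
    tree=None,
    cache: bool = True,
) -> DistanceMatrix:
    """Full symmetric dissimilarity matrix over the analyzable samples.

    The result is cached on the study under its metric name. UniFrac metrics
    require a Newick tree whose leaves are the taxon names at `rank`; without
    one, import a precomputed matrix via ``read_distance_matrix``.
    """
    if metric not in METRICS:
        raise DataError("unknown_metric", f"unknown metric {metric!r}; choose from {METRICS}")
    rank_index(rank)
    m = study.matrix(rank)
    ids = study.analyzable_samples()
    if len(ids) < 2:
        raise DataError("too_few_samples", "need at least 2 analyzable samples")
    rows = np.array([m.sample_row(sid) for sid in ids])
    n = len(ids)
    values = np.zeros((n, n))
    is_unifrac = metric.endswith("unifrac")
    if is_unifrac:
        if tree is None:
            raise DataError(
                "tree_required",
                f"{metric} needs a Newick tree; provide one or import a "
                "precomputed matrix with read_distance_matrix",
            )
        import skbio

        if isinstance(tree, str):
            tree = skbio.TreeNode.read([tree])
    names = m.taxon_names
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "bray_curtis":
                d = bray_curtis(rows[i], rows[j])
            elif metric == "jaccard":
                d = jaccard(rows[i], rows[j])
            else:
                d = unifrac(tree, names, rows[i], rows[j], weighted=(metric == "weighted_unifrac"))
            values[i, j] = values[j, i] = d
    dm = DistanceMatrix(metric, ids, values)
    dm.check()
    if cache:
        study.distances[metric] = dm
    return dm
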