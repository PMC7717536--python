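"""Pre-processing: rank rollup, dominant-taxon collapsing, alpha diversity.

These are the derived quantities computed once at import time so composition
views, bar charts and heat maps stay cheap: abundance matrices at every rank
above the input rank, a synthetic "others" taxon holding the low-abundance
tail, and per-sample Shannon / Gini-Simpson / Chao1 indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import RANKS, AbundanceMatrix, DataError, Study, Taxon, rank_index

OTHERS = "others"


@dataclass(frozen=True)
class DominanceConfig:
    """How to merge low-abundance taxa into the "others" category.

    threshold: the mean (global scope) or per-row (per_sample scope) relative
        abundance that the merged "others" mass must stay strictly below.
        Default 0.10.
    scope: "global" collapses one shared taxon set (all charts share a
        legend); "per_sample" applies the rule row by row.
    """

    threshold: float = 0.10
    scope: str = "global"

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise DataError("bad_threshold", f"threshold must be in (0, 1], got {self.threshold}")
        if self.scope not in ("global", "per_sample"):
            raise DataError("bad_scope", f"scope must be global or per_sample, got {self.scope!r}")


def rollup_rank(matrix: AbundanceMatrix, to_rank: str) -> AbundanceMatrix:
    """Sum abundances over all descendants of each taxon at `to_rank`.

    Row sums are preserved exactly (same-column addition only). Rolling a
    matrix up to its own rank returns an identical copy.
    """
    from_idx = rank_index(matrix.rank)
    to_idx = rank_index(to_rank)
    if to_idx > from_idx:
        raise DataError(
            "bad_rollup",
            f"cannot roll {matrix.rank} matrix down to {to_rank}; rollup only goes up",
        )
    ancestors: list[Taxon] = [t.ancestor(to_rank) for t in matrix.taxa]
    out_taxa: list[Taxon] = []
    index: dict[tuple, int] = {}
    for anc in ancestors:
        key = (anc.rank, anc.lineage())
        if key not in index:
            index[key] = len(out_taxa)
            out_taxa.append(anc)
    values = np.zeros((len(matrix.sample_ids), len(out_taxa)))
    counts = None
    if matrix.raw_counts is not None:
        counts = np.zeros_like(values)
    for j, anc in enumerate(ancestors):
        col = index[(anc.rank, anc.lineage())]
        values[:, col] += matrix.values[:, j]
        if counts is not None:
            counts[:, col] += matrix.raw_counts[:, j]
    return AbundanceMatrix(
        to_rank, list(matrix.sample_ids), out_taxa, values,
        source_kind=matrix.source_kind, raw_counts=counts,
    )


def build_rank_matrices(deepest: AbundanceMatrix) -> dict[str, AbundanceMatrix]:
    """Roll a matrix up through every higher rank; keys ordered phylum-first."""
    out: dict[str, AbundanceMatrix] = {}
    for rank in RANKS[: rank_index(deepest.rank) + 1]:
        out[rank] = deepest if rank == deepest.rank else rollup_rank(deepest, rank)
    return out


def collapse_minor_taxa(m: AbundanceMatrix, cfg: DominanceConfig = DominanceConfig()) -> AbundanceMatrix:
    """Merge the low-abundance tail into a synthetic "others" taxon.

    Global scope: taxa are taken from the smallest mean abundance upward and
    moved into "others" greedily for as long as the mean of "others" stays
    strictly below ``cfg.threshold``. Retained taxa keep their exact values
    and every row still sums to 1. Per-sample scope applies the same greedy
    rule to each row independently (the displayed legend then varies by
    sample). An "others" column is always appended, possibly all zero.
    """
    others = Taxon(m.rank, OTHERS)
    n, p = m.values.shape
    taxa = list(m.taxa) + [others]
    if cfg.scope == "global":
        means = m.values.mean(axis=0)
        order = sorted(range(p), key=lambda j: (means[j], m.taxa[j].name))
        merged: list[int] = []
        acc = 0.0
        for j in order:
            if len(merged) == p - 1:
                break  # never merge everything: keep at least one real taxon
            if acc + means[j] < cfg.threshold:
                acc += means[j]
                merged.append(j)
            else:
                break
        keep = [j for j in range(p) if j not in set(merged)]
        values = np.zeros((n, len(keep) + 1))
        values[:, : len(keep)] = m.values[:, keep]
        if merged:
            values[:, -1] = m.values[:, merged].sum(axis=1)
        taxa = [m.taxa[j] for j in keep] + [others]
        return AbundanceMatrix(m.rank, list(m.sample_ids), taxa, values,
                               source_kind=m.source_kind)
    # per_sample: keep all original columns, zeroing merged cells per row
    values = np.zeros((n, p + 1))
    values[:, :p] = m.values
    for i in range(n):
        row = m.values[i]
        order = sorted(range(p), key=lambda j: (row[j], m.taxa[j].name))
        acc = 0.0
        for idx, j in enumerate(order):
            if idx == p - 1:
                break
            if acc + row[j] < cfg.threshold:
                acc += row[j]
                values[i, j] = 0.0
                values[i, p] += row[j]
            else:
                break
    return AbundanceMatrix(m.rank, list(m.sample_ids), taxa, values,
                           source_kind=m.source_kind)


# --------------------------------------------------------------------------
# Alpha diversity
# --------------------------------------------------------------------------

ALPHA_INDICES = ("shannon", "simpson", "chao1")


def shannon(vec, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i over p_i > 0.

    Accepts counts or fractions (normalized internally). Natural log by
    default; pass ``base`` (e.g. 2 or 10) for other conventions.
    """
    p = _as_fractions(vec)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def simpson(vec, form: str = "gini") -> float:
    """Gini-Simpson diversity 1 - sum p_i^2 (higher = more diverse).

    ``form="dominance"`` returns the raw sum p_i^2 instead.
    """
    p = _as_fractions(vec)
    d = float((p * p).sum())
    if form == "dominance":
        return d
    if form != "gini":
        raise DataError("bad_form", f"simpson form must be gini or dominance, got {form!r}")
    return 1.0 - d


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from integer counts.

    Bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) by default, where
    F1 and F2 are singleton and doubleton counts; the classical form
    S_obs + F1^2 / (2 F2) is available and errors when F2 = 0.
    """
    c = np.asarray(counts, dtype=float)
    _check_nonempty(c)
    if np.any(np.abs(c - np.round(c)) > 1e-9):
        raise DataError("noninteger_counts", "chao1 requires integer counts")
    c = np.round(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise DataError("chao1_no_doubletons", "classical chao1 undefined when F2 = 0")
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(vec, index: str, **kwargs) -> float:
    """Dispatch to one alpha-diversity index by name."""
    if index == "shannon":
        return shannon(vec, **kwargs)
    if index == "simpson":
        return simpson(vec, **kwargs)
    if index == "chao1":
        return chao1(vec, **kwargs)
    raise DataError("unknown_index", f"unknown alpha diversity index {index!r}")


def _check_nonempty(v: np.ndarray) -> None:
    if v.size == 0 or not np.any(v > 0):
        raise DataError("empty_sample", "empty or all-zero abundance vector")
    if np.min(v) < 0:
        raise DataError("negative_abundance", "negative abundance value")


def _as_fractions(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    _check_nonempty(v)
    return v / v.sum()


def compute_diversity(study: Study, rank: str | None = None) -> None:
    """Fill the study's diversity cache from its deepest abundance matrix.

    Shannon and Simpson come from relative abundances; Chao1 only when raw
    counts were retained at import (it is undefined on fractions) and is
    simply absent from the cache otherwise.
    """
    if rank is None:
        rank = RANKS[max(rank_index(r) for r in study.abundance)]
    m = study.matrix(rank)
    for i, sid in enumerate(m.sample_ids):
        study.diversity[(sid, "shannon")] = shannon(m.values[i])
        study.diversity[(sid, "simpson")] = simpson(m.values[i])
        if m.raw_counts is not None:
            study.diversity[(sid, "chao1")] = chao1(m.raw_counts[i])
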