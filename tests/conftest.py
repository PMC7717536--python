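import numpy as np
import pytest

from micropheno.model import (
    AbundanceMatrix,
    DistanceMatrix,
    ParameterDef,
    ParameterSet,
    Sample,
    Study,
    Taxon,
)
from micropheno.preprocess import build_rank_matrices, compute_diversity


def lineage(*names):
    """Build a linked taxon chain phylum->...; returns the deepest taxon."""
    from micropheno.model import RANKS

    node = None
    for rank, name in zip(RANKS, names):
        node = Taxon(rank, name, parent=node)
    return node


def make_study(fractions, genus_lineages, sample_ids=None, params=None, counts=None):
    """Hand-built study from a fraction matrix and genus lineage tuples.

    `params` is a list of (name, vtype, {sample: value}).
    """
    fractions = np.asarray(fractions, dtype=float)
    n = fractions.shape[0]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    taxa = [lineage(*ln) for ln in genus_lineages]
    genus = AbundanceMatrix(
        taxa[0].rank, list(sample_ids), taxa, fractions,
        source_kind="counts" if counts is not None else "fractions",
        raw_counts=None if counts is None else np.asarray(counts, dtype=float),
    )
    pset = ParameterSet()
    extra_samples = []
    if params:
        defs = []
        for name, vtype, values in params:
            defs.append(ParameterDef(name, vtype))
        pset = ParameterSet(defs)
        for name, _, values in params:
            for sid, v in values.items():
                pset.add_record(sid, name, v)
                if sid not in sample_ids and sid not in extra_samples:
                    extra_samples.append(sid)
    study = Study(
        samples=[Sample(s) for s in list(sample_ids) + extra_samples],
        abundance=build_rank_matrices(genus),
        parameters=pset,
    )
    compute_diversity(study)
    return study


def random_euclidean_dm(rng, n, dim=3, metric_name="imported"):
    pts = rng.normal(size=(n, dim))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(metric_name, [f"s{i}" for i in range(n)], d), pts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_sample_study():
    """3 samples, 3 genera under 2 families (L holds g1+g2, R holds g3)."""
    return make_study(
        [[0.2, 0.3, 0.5], [0.1, 0.1, 0.8], [0.4, 0.4, 0.2]],
        [
            ("P1", "C1", "O1", "L", "g1"),
            ("P1", "C1", "O1", "L", "g2"),
            ("P1", "C1", "O2", "R", "g3"),
        ],
        params=[
            ("age", "continuous", {"s1": 30.0, "s2": 40.0, "s3": 25.0}),
            ("sex", "nominal", {"s1": "m", "s2": "f", "s3": "m"}),
            ("notes", "text", {"s1": "healthy"}),
        ],
    )
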