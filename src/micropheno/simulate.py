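"""Seeded generator of cohort-scale fixture studies with planted structure.

Emulates a small human gut-microbiome cohort (default 20 adult samples, 60
genera across 5 taxonomic ranks, a few dozen typed phenotype parameters in
Table-1-style categories): per-sample compositions are Dirichlet-multinomial
(so the sum-to-one constraint and integer counts the engine assumes both
hold), continuous parameters are Gaussian, and each *planted link* makes a
parameter a monotone function of a chosen taxon's relative abundance plus
Gaussian noise of scale sigma (in units of the signal's standard deviation,
which is 1 after standardization). An optional two-group split draws the two
halves from distinct Dirichlet concentrations, emulating a cohort separated
by diet.

The generator does not attempt realistic ecological dynamics or sequencing
error; it provides exactly the structure the analysis operations are
contracted to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .model import (
    DEFAULT_CATEGORY_SCHEME,
    AbundanceMatrix,
    DataError,
    ParameterDef,
    ParameterSet,
    Sample,
    Study,
    Taxon,
)
from .preprocess import build_rank_matrices, compute_diversity

#: Category/subgroup assignments cycled over generated continuous parameters.
_PARAM_GROUPS = [
    ("Body composition", "Body composition"),
    ("Blood profile", "Blood profile"),
    ("Diet", "Nutrients"),
    ("Diet", "Amount of food intake"),
    ("Physical activity (accelerometer)", "Physical activity"),
]


@dataclass(frozen=True)
class PlantedLink:
    """A parameter made monotone in one taxon's relative abundance."""

    taxon_index: int          # genus index, or index at `rank`
    parameter: str
    direction: int = 1        # +1 increasing, -1 decreasing
    sigma: float = 0.1        # Gaussian noise scale relative to unit signal
    rank: str = "genus"


@dataclass
class FixtureSpec:
    """Shape of a generated study; the seed fully determines the output."""

    n_samples: int = 20
    n_genera: int = 60
    n_continuous: int = 40
    n_nominal: int = 6
    n_ordinal: int = 4
    n_text: int = 2
    planted_links: tuple[PlantedLink, ...] = ()
    group_structure: bool = False
    sequencing_depth: int = 50_000
    n_no_microbiome: int = 0  # extra parameter-only samples (flagged, excluded)
    seed: int = 0


def _lineage_forest(rng: np.random.Generator, n_genera: int) -> list[Taxon]:
    """Random taxonomy: genera grouped under families/orders/classes/phyla."""
    n_phyla = max(2, n_genera // 15)
    n_classes = max(n_phyla, n_genera // 8)
    n_orders = max(n_classes, n_genera // 5)
    n_families = max(n_orders, n_genera // 3)
    phyla = [Taxon("phylum", f"Phylum{i:02d}") for i in range(n_phyla)]
    classes = [
        Taxon("class", f"Class{i:02d}", parent=phyla[rng.integers(n_phyla)])
        for i in range(n_classes)
    ]
    orders = [
        Taxon("order", f"Order{i:02d}", parent=classes[rng.integers(n_classes)])
        for i in range(n_orders)
    ]
    families = [
        Taxon("family", f"Family{i:02d}", parent=orders[rng.integers(n_orders)])
        for i in range(n_families)
    ]
    return [
        Taxon("genus", f"Genus{i:02d}", parent=families[rng.integers(n_families)])
        for i in range(n_genera)
    ]


def generate_study(spec: FixtureSpec = FixtureSpec(), compute_distances: bool = True) -> Study:
    """Generate a fully validated study from a fixture spec.

    Abundance counts are multinomial draws from per-sample Dirichlet
    compositions whose concentration decays across genera (a realistic
    dominance profile: a few dominant taxa, a long tail). Parameters follow
    their declared types; planted links overwrite the linked parameter with
    ``direction * z(abundance) + sigma * N(0,1)``.
    """
    rng = np.random.default_rng(spec.seed)
    genera = _lineage_forest(rng, spec.n_genera)
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]

    base = 50.0 / (1 + np.arange(spec.n_genera)) ** 1.2  # decaying concentration
    concentrations = [base]
    if spec.group_structure:
        alt = base.copy()
        perm = rng.permutation(spec.n_genera)
        alt = alt[perm] * rng.lognormal(0.0, 0.8, spec.n_genera)
        concentrations.append(alt)
    groups = (
        np.array([i % 2 for i in range(spec.n_samples)])
        if spec.group_structure
        else np.zeros(spec.n_samples, dtype=int)
    )
    counts = np.zeros((spec.n_samples, spec.n_genera))
    for i in range(spec.n_samples):
        comp = rng.dirichlet(concentrations[groups[i]])
        counts[i] = rng.multinomial(spec.sequencing_depth, comp)
    # a sample must not be all zero; redraw dominant taxon if degenerate
    for i in range(spec.n_samples):
        if counts[i].sum() == 0:  # pragma: no cover - vanishing probability
            counts[i, 0] = 1
    fractions = counts / counts.sum(axis=1, keepdims=True)
    genus_m = AbundanceMatrix(
        "genus", list(sample_ids), genera, fractions, source_kind="counts", raw_counts=counts
    )
    abundance = build_rank_matrices(genus_m)

    defs: list[ParameterDef] = []
    for i in range(spec.n_continuous):
        cat, sub = _PARAM_GROUPS[i % len(_PARAM_GROUPS)]
        defs.append(ParameterDef(f"param_c{i:02d}", "continuous", cat, sub))
    for i in range(spec.n_nominal):
        defs.append(ParameterDef(f"param_n{i:02d}", "nominal", "Basic information", "Basic information"))
    for i in range(spec.n_ordinal):
        defs.append(ParameterDef(f"param_o{i:02d}", "ordinal", "Other lifestyle", "Exercise habit"))
    for i in range(spec.n_text):
        defs.append(ParameterDef(f"param_t{i:02d}", "text", "Basic information", "Basic information"))
    if spec.group_structure:
        defs.append(ParameterDef("diet_group", "nominal", "Diet", "Amount of food intake"))
    pset = ParameterSet(defs)

    all_ids = list(sample_ids) + [
        f"X{i + 1:03d}" for i in range(spec.n_no_microbiome)
    ]
    nominal_levels = ["low", "mid", "high"]
    for sid in all_ids:
        for i in range(spec.n_continuous):
            pset.add_record(sid, f"param_c{i:02d}", float(rng.normal(50, 10)))
        for i in range(spec.n_nominal):
            pset.add_record(sid, f"param_n{i:02d}", nominal_levels[rng.integers(3)])
        for i in range(spec.n_ordinal):
            pset.add_record(sid, f"param_o{i:02d}", float(rng.integers(1, 6)))
        for i in range(spec.n_text):
            pset.add_record(sid, f"param_t{i:02d}", f"note-{rng.integers(1000)}")
    if spec.group_structure:
        for i, sid in enumerate(sample_ids):
            pset.add_record(sid, "diet_group", "high_fat" if groups[i] else "low_fat")

    link_rng = np.random.default_rng(spec.seed + 1)
    for link in spec.planted_links:
        m = abundance[link.rank]
        if not (0 <= link.taxon_index < len(m.taxa)):
            raise DataError(
                "bad_link", f"planted link taxon index {link.taxon_index} out of range at {link.rank}"
            )
        if link.parameter not in pset.by_name:
            raise DataError("bad_link", f"planted link parameter {link.parameter!r} not defined")
        x = m.values[:, link.taxon_index]
        z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        noise = link_rng.normal(0.0, 1.0, spec.n_samples)
        y = link.direction * z + link.sigma * noise
        for i, sid in enumerate(sample_ids):
            pset.add_record(sid, link.parameter, float(y[i]))

    study = Study(
        study_id=f"fixture-seed{spec.seed}",
        samples=[Sample(sid) for sid in all_ids],
        abundance=abundance,
        parameters=pset,
        category_scheme=DEFAULT_CATEGORY_SCHEME,
    )
    compute_diversity(study)
    if compute_distances and spec.n_samples >= 2:
        from .dissimilarity import pairwise_distances

        pairwise_distances(study, "jaccard")
        pairwise_distances(study, "bray_curtis")
    return study


def write_fixture(study: Study, outdir, ground_truth: Optional[dict] = None) -> dict[str, Path]:
    """Write the two-file TSV input pair (+ optional ground-truth JSON)."""
    import json

    from .io import write_abundance, write_parameters

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.tsv",
        "parameters": outdir / "parameters.tsv",
    }
    deepest = study.matrix("genus")
    write_abundance(deepest, paths["abundance"])
    write_parameters(study, paths["parameters"])
    if ground_truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
    return paths


def ground_truth(spec: FixtureSpec, study: Study) -> dict:
    """JSON-serializable record of the planted structure of a fixture."""
    out: dict = {"seed": spec.seed, "planted_links": []}
    for link in spec.planted_links:
        m = study.matrix(link.rank)
        out["planted_links"].append(
            {
                "taxon": m.taxa[link.taxon_index].name,
                "rank": link.rank,
                "parameter": link.parameter,
                "direction": link.direction,
                "sigma": link.sigma,
            }
        )
    if spec.group_structure:
        out["groups"] = {
            sid: ("high_fat" if i % 2 else "low_fat")
            for i, sid in enumerate(study.analyzable_samples())
        }
    return out
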