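"""In-memory domain model for an integrated microbiota--phenotype study.

A :class:`Study` bundles, for one cohort, rank-structured relative-abundance
matrices, a typed phenotype parameter set stored as name--value records, and
caches of per-sample alpha diversity and pairwise dissimilarity matrices.
Validation never raises: :func:`validate_study` reports every hard invariant
violation as an ERROR and every soft issue (samples without microbiome data,
unclassified taxa, unknown parameter groupings) as a WARN.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Taxonomic ranks handled by the engine, highest first.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Parameter value types. ``text`` parameters are browsable only and are
#: rejected by every correlation operation.
VTYPES = ("continuous", "nominal", "ordinal", "text")

UNCLASSIFIED = "unclassified"

#: Default category -> subgroups scheme for phenotype parameters, modelled on
#: the category/subgroup browsing hierarchy of human-cohort questionnaires
#: (basic information, health condition, physical characteristics, lifestyle).
DEFAULT_CATEGORY_SCHEME: dict[str, tuple[str, ...]] = {
    "Basic information": ("Basic information",),
    "Medical history": ("Medical history", "Family medical history", "Medication"),
    "Body composition": ("Body composition",),
    "Blood profile": ("Blood profile",),
    "Physical activity (accelerometer)": ("Physical activity",),
    "Diet": (
        "Food intake frequency",
        "Amount of food intake",
        "Nutrients",
        "Eating behaviour",
    ),
    "Other lifestyle": ("Smoking", "Exercise habit", "Sleep & rest"),
}


class DataError(ValueError):
    """Raised for malformed inputs or contract violations; carries a code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise DataError("unknown_rank", f"unknown taxonomic rank {rank!r}") from None


@dataclass(frozen=True)
class Taxon:
    """One taxon at a fixed rank, linked to its parent at the next higher rank.

    Names that cannot be resolved (empty lineage fields, unmapped labels) are
    kept, flagged ``is_unclassified``, and disambiguated by their lineage.
    """

    rank: str
    name: str
    parent: Optional["Taxon"] = None
    taxon_id: Optional[int] = None
    is_unclassified: bool = False

    def __post_init__(self):
        idx = rank_index(self.rank)
        if self.parent is not None:
            pidx = rank_index(self.parent.rank)
            if pidx != idx - 1:
                raise DataError(
                    "bad_parent_rank",
                    f"parent of {self.rank} {self.name!r} must be at rank "
                    f"{RANKS[idx - 1]!r}, got {self.parent.rank!r}",
                )

    def lineage(self) -> tuple[str, ...]:
        """Names from phylum down to this taxon's rank."""
        names: list[str] = []
        node: Optional[Taxon] = self
        while node is not None:
            names.append(node.name)
            node = node.parent
        return tuple(reversed(names))

    def ancestor(self, rank: str) -> "Taxon":
        """Return the ancestor at `rank` (self if rank equals own rank)."""
        target = rank_index(rank)
        node: Optional[Taxon] = self
        while node is not None and rank_index(node.rank) > target:
            node = node.parent
        if node is None or rank_index(node.rank) != target:
            raise DataError(
                "no_ancestor",
                f"taxon {self.name!r} ({self.rank}) has no ancestor at rank {rank!r}",
            )
        return node

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} ({self.rank})"


@dataclass
class AbundanceMatrix:
    """Samples x taxa relative abundances at a single taxonomic rank.

    ``values[i, j]`` is the fraction of sample ``sample_ids[i]`` assigned to
    ``taxa[j]``; each row sums to 1. When the source table held counts, the
    raw integer counts are retained in ``raw_counts`` (Chao1 needs them).
    """

    rank: str
    sample_ids: list[str]
    taxa: list[Taxon]
    values: np.ndarray
    source_kind: str = "fractions"  # "counts" or "fractions"
    raw_counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxa)):
            raise DataError(
                "shape_mismatch",
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa",
            )

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def column(self, taxon_name: str) -> np.ndarray:
        """Abundance vector of the named taxon across samples."""
        for j, t in enumerate(self.taxa):
            if t.name == taxon_name:
                return self.values[:, j]
        raise DataError("unknown_taxon", f"no taxon named {taxon_name!r} at rank {self.rank}")

    def sample_row(self, sample_id: str) -> np.ndarray:
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise DataError("unknown_sample", f"sample {sample_id!r} not in matrix") from None
        return self.values[i]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_names)


@dataclass(frozen=True)
class ParameterDef:
    name: str
    vtype: str
    category: str = ""
    subgroup: str = ""
    units: Optional[str] = None

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise DataError("unknown_vtype", f"unknown parameter type {self.vtype!r}")


@dataclass
class ParameterSet:
    """Typed parameter definitions plus (sample, parameter, value) records.

    Values are numeric for continuous/ordinal parameters and label strings for
    nominal/text ones. A missing (sample, parameter) pair means *not measured*;
    nothing is ever imputed.
    """

    defs: list[ParameterDef] = field(default_factory=list)
    records: dict[tuple[str, str], object] = field(default_factory=dict)

    def __post_init__(self):
        names = [d.name for d in self.defs]
        if len(names) != len(set(names)):
            raise DataError("duplicate_parameter", "duplicate parameter name in defs")

    @property
    def by_name(self) -> dict[str, ParameterDef]:
        return {d.name: d for d in self.defs}

    def add_record(self, sample_id: str, name: str, value) -> None:
        self.records[(sample_id, name)] = value

    def names(self, vtypes: Optional[tuple[str, ...]] = None) -> list[str]:
        if vtypes is None:
            return [d.name for d in self.defs]
        return [d.name for d in self.defs if d.vtype in vtypes]

    def values_for(self, name: str) -> dict[str, object]:
        """Sample -> value map for one parameter (missing samples absent)."""
        if name not in self.by_name:
            raise DataError("undefined_parameter", f"parameter {name!r} not defined")
        return {sid: v for (sid, pname), v in self.records.items() if pname == name}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities for one metric; zero diagonal."""

    metric: str
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DataError("shape_mismatch", "distance matrix is not square over sample_ids")

    def check(self) -> None:
        """Raise DataError on any invariant violation."""
        v = self.values
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise DataError("asymmetric", "distance matrix asymmetric beyond 1e-12")
        if np.max(np.abs(np.diag(v))) > 0:
            raise DataError("nonzero_diagonal", "distance matrix diagonal not exactly 0")
        if np.min(v) < 0:
            raise DataError("negative_distance", "negative dissimilarity entry")
        if self.metric in ("jaccard", "bray_curtis") and np.max(v) > 1 + 1e-12:
            raise DataError("out_of_range", f"{self.metric} entry exceeds 1")

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])


@dataclass
class Sample:
    sample_id: str
    metadata: dict = field(default_factory=dict)


@dataclass
class Study:
    """The integrated unit: samples, abundances per rank, typed parameters,
    and cached diversity / distance results.

    Samples that appear in the parameter table but in no abundance matrix are
    retained (browsable) but flagged ``no_microbiome`` and excluded from every
    analysis.
    """

    study_id: str = "study"
    samples: list[Sample] = field(default_factory=list)
    abundance: dict[str, AbundanceMatrix] = field(default_factory=dict)
    parameters: ParameterSet = field(default_factory=ParameterSet)
    diversity: dict[tuple[str, str], float] = field(default_factory=dict)
    distances: dict[str, DistanceMatrix] = field(default_factory=dict)
    category_scheme: Optional[dict[str, tuple[str, ...]]] = None

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def microbiome_sample_ids(self) -> set[str]:
        out: set[str] = set()
        for m in self.abundance.values():
            out.update(m.sample_ids)
        return out

    def analyzable_samples(self) -> list[str]:
        """Sample ids usable in analyses: those with microbiome data, in
        study order."""
        with_mb = self.microbiome_sample_ids()
        return [sid for sid in self.sample_ids if sid in with_mb]

    def no_microbiome_samples(self) -> list[str]:
        with_mb = self.microbiome_sample_ids()
        return [sid for sid in self.sample_ids if sid not in with_mb]

    def matrix(self, rank: str) -> AbundanceMatrix:
        rank_index(rank)
        if rank not in self.abundance:
            raise DataError("missing_rank", f"study has no abundance matrix at rank {rank!r}")
        return self.abundance[rank]


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "ERROR" | "WARN"
    code: str
    message: str
    subject: str = ""


class ValidationReport(list):
    """List of :class:`ValidationIssue` with convenience accessors."""

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self if i.level == "ERROR"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self if i.level == "WARN"]

    def ok(self) -> bool:
        return not self.errors


def validate_study(study: Study) -> ValidationReport:
    """Check every model invariant; report, never raise.

    Hard violations (rows not summing to 1, undefined parameter names,
    malformed distance caches) come back as ERROR; soft issues (samples
    lacking microbiome data, unclassified taxa, unknown category/subgroup
    pairs) as WARN. The study is not modified.
    """
    report = ValidationReport()
    err = lambda code, msg, subj="": report.append(ValidationIssue("ERROR", code, msg, subj))
    warn = lambda code, msg, subj="": report.append(ValidationIssue("WARN", code, msg, subj))

    ids = study.sample_ids
    if len(ids) != len(set(ids)):
        err("duplicate_sample", "duplicate sample ids in study")

    for rank, m in study.abundance.items():
        if m.rank != rank:
            err("rank_mismatch", f"matrix stored under {rank!r} claims rank {m.rank!r}", rank)
        if len(m.sample_ids) != len(set(m.sample_ids)):
            err("duplicate_sample", f"duplicate sample ids in {rank} matrix", rank)
        keys = [(t.rank, t.lineage()) for t in m.taxa]
        if len(keys) != len(set(keys)):
            err("duplicate_taxon", f"duplicate taxa in {rank} matrix", rank)
        if m.values.size:
            if np.min(m.values) < 0:
                err("negative_abundance", f"negative abundance at rank {rank}", rank)
            sums = m.values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            for i in bad:
                err(
                    "row_sum",
                    f"sample {m.sample_ids[i]!r} row sums to {sums[i]:.12g}, not 1",
                    m.sample_ids[i],
                )
        for t in m.taxa:
            if t.rank != rank:
                err("taxon_rank", f"taxon {t.name!r} has rank {t.rank}, matrix rank {rank}", t.name)
            if t.is_unclassified:
                warn("unclassified_taxon", f"unclassified taxon in {rank} matrix", t.name)

    # parameter records must reference defined parameters
    defined = set(study.parameters.by_name)
    for (sid, pname) in study.parameters.records:
        if pname not in defined:
            err("undefined_parameter", f"record for undefined parameter {pname!r}", pname)
    scheme = study.category_scheme
    if scheme is not None:
        for d in study.parameters.defs:
            if d.category and d.subgroup not in scheme.get(d.category, ()):
                warn(
                    "unknown_category_pair",
                    f"parameter {d.name!r} has unknown (category, subgroup) "
                    f"({d.category!r}, {d.subgroup!r})",
                    d.name,
                )

    for sid in study.no_microbiome_samples():
        warn("no_microbiome", f"sample {sid!r} has no microbiome data; excluded from analyses", sid)

    analyzable = set(study.analyzable_samples())
    for metric, dm in study.distances.items():
        try:
            dm.check()
        except DataError as e:
            err(e.code, f"cached {metric} distance matrix: {e}", metric)
        if set(dm.sample_ids) != analyzable:
            err(
                "distance_coverage",
                f"cached {metric} matrix does not cover exactly the analyzable samples",
                metric,
            )

    for (sid, index), value in study.diversity.items():
        if not math.isfinite(value) or value < 0:
            err("bad_diversity", f"{index} for {sid!r} is {value!r}", sid)

    return report


def copy_study(study: Study) -> Study:
    """Deep-enough copy for safe mutation in preprocessing steps."""
    return dataclasses.replace(
        study,
        samples=[Sample(s.sample_id, dict(s.metadata)) for s in study.samples],
        abundance={
            r: AbundanceMatrix(
                m.rank, list(m.sample_ids), list(m.taxa), m.values.copy(),
                m.source_kind,
                None if m.raw_counts is None else m.raw_counts.copy(),
            )
            for r, m in study.abundance.items()
        },
        parameters=ParameterSet(list(study.parameters.defs), dict(study.parameters.records)),
        diversity=dict(study.diversity),
        distances={
            k: DistanceMatrix(d.metric, list(d.sample_ids), d.values.copy())
            for k, d in study.distances.items()
        },
    )
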