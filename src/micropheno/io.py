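"""Readers/writers for the tab-delimited input contract and the embedded store.

Input contract (two tab-delimited files sharing sample ids by exact string
match):

* **abundance table** — samples as rows, one column per taxon; the column
  header is the full lineage ``phylum;class;order;family;genus`` (shorter
  prefixes for higher-rank files); values are counts or relative abundances
  (auto-detected unless declared). Empty lineage fields become
  "unclassified" placeholders, never dropped.
* **parameter table** — row 1: parameter names; row 2: value type per column
  (continuous / nominal / ordinal / text); row 3: category; row 4: subgroup;
  subsequent rows: sample id followed by values; an empty cell means *not
  measured*.

The persistent store is a single SQLite file with a name-value design:
tables ``samples``, ``taxa``, ``abundances``, ``parameter_defs``,
``parameter_values``, ``distances``, ``diversity`` (+ ``meta``). Floats
round-trip bit-exactly (REAL is an IEEE double).
"""

from __future__ import annotations

import json
import sqlite3
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    RANKS,
    UNCLASSIFIED,
    VTYPES,
    AbundanceMatrix,
    DataError,
    DistanceMatrix,
    ParameterDef,
    ParameterSet,
    Sample,
    Study,
    Taxon,
    validate_study,
)
from .preprocess import build_rank_matrices, compute_diversity

SCHEMA_VERSION = 1


class DataWarning(UserWarning):
    """Recoverable data-quality issue noticed while reading."""


# --------------------------------------------------------------------------
# Abundance table
# --------------------------------------------------------------------------

def parse_lineage(header: str, depth: Optional[int] = None) -> Taxon:
    """Build the linked taxon chain for one column header.

    ``"Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia"`` yields
    five linked taxa, family parent of genus; empty fields become
    "unclassified" placeholders at their rank, parented through the chain.
    """
    fields = [f.strip() for f in header.split(";")]
    if len(fields) > len(RANKS):
        raise DataError("bad_lineage", f"lineage {header!r} has more than {len(RANKS)} fields")
    if depth is not None:
        if len(fields) > depth:
            raise DataError("bad_lineage", f"lineage {header!r} deeper than table depth {depth}")
        fields = fields + [""] * (depth - len(fields))
    node: Optional[Taxon] = None
    for rank, name in zip(RANKS, fields):
        unclassified = name == "" or name.lower() == UNCLASSIFIED
        node = Taxon(
            rank=rank,
            name=name if name else UNCLASSIFIED,
            parent=node,
            is_unclassified=unclassified,
        )
    assert node is not None
    return node


def read_abundance(
    path, value_kind: str = "auto"
) -> dict[str, AbundanceMatrix]:
    """Read a samples x taxa table and return matrices at every derivable rank.

    ``value_kind`` is "counts", "fractions", or "auto" (rows all summing to
    1 +/- 0.01 are treated as fractions). Counts are normalized per sample to
    relative abundances; the original counts are retained on the deepest
    matrix for Chao1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise DataError("empty_table", f"{path}: need at least 1 sample row and 1 taxon column")
    sample_ids = [str(s) for s in df.index]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise DataError("duplicate_sample", f"{path}: duplicate sample id(s) {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise DataError("non_numeric", f"{path}: non-numeric abundance value ({e})") from None
    if np.any(~np.isfinite(values)):
        raise DataError("non_numeric", f"{path}: missing or non-finite abundance value")
    if np.min(values) < 0:
        raise DataError("negative_abundance", f"{path}: negative abundance value")
    sums = values.sum(axis=1)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise DataError(
            "all_zero_sample",
            f"{path}: sample(s) {[sample_ids[i] for i in zero]} have all-zero rows; "
            "no valid relative abundance",
        )
    depth = max(len(str(c).split(";")) for c in df.columns)
    taxa = [parse_lineage(str(c), depth) for c in df.columns]
    keys = [(t.rank, t.lineage()) for t in taxa]
    if len(keys) != len(set(keys)):
        raise DataError("duplicate_taxon", f"{path}: duplicate taxon lineage in header")
    if value_kind not in ("auto", "counts", "fractions"):
        raise DataError("bad_value_kind", f"value_kind must be auto/counts/fractions")
    if value_kind == "auto":
        value_kind = "fractions" if np.all(np.abs(sums - 1) <= 0.01) else "counts"
    raw = values.copy() if value_kind == "counts" else None
    fractions = values / sums[:, None]
    deepest = AbundanceMatrix(
        taxa[0].rank, sample_ids, taxa, fractions, source_kind=value_kind, raw_counts=raw
    )
    return build_rank_matrices(deepest)


def write_abundance(matrix: AbundanceMatrix, path, kind: str = "auto") -> None:
    """Write a matrix in the ingest dialect (lineage headers, samples as rows).

    ``kind="auto"`` writes raw counts when the matrix retained them,
    fractions otherwise.
    """
    if kind == "auto":
        kind = "counts" if matrix.raw_counts is not None else "fractions"
    if kind == "counts":
        if matrix.raw_counts is None:
            raise DataError("no_counts", "matrix has no raw counts to write")
        values = matrix.raw_counts
    else:
        values = matrix.values
    headers = [";".join(t.lineage()) for t in matrix.taxa]
    df = pd.DataFrame(values, index=matrix.sample_ids, columns=headers)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# --------------------------------------------------------------------------
# Parameter table
# --------------------------------------------------------------------------

def read_parameters(path) -> ParameterSet:
    """Read the typed parameter table into a ParameterSet.

    Header rows declare name / vtype / category / subgroup per column; each
    subsequent row is a sample. Continuous and ordinal cells must parse as
    numbers; empty cells are missing (never imputed).
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if raw.shape[0] < 4 or raw.shape[1] < 2:
        raise DataError("bad_header", f"{path}: need 4 header rows and at least 1 parameter column")
    names = [str(v).strip() for v in raw.iloc[0, 1:]]
    vtypes = [str(v).strip() for v in raw.iloc[1, 1:]]
    categories = [str(v).strip() for v in raw.iloc[2, 1:]]
    subgroups = [str(v).strip() for v in raw.iloc[3, 1:]]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DataError("duplicate_parameter", f"{path}: duplicate parameter name(s) {dupes}")
    for j, vt in enumerate(vtypes):
        if vt not in VTYPES:
            raise DataError(
                "unknown_vtype",
                f"{path}: column {names[j]!r} declares unknown vtype {vt!r} "
                f"(expected one of {VTYPES})",
            )
    defs = [
        ParameterDef(n, vt, cat, sub)
        for n, vt, cat, sub in zip(names, vtypes, categories, subgroups)
    ]
    pset = ParameterSet(defs)
    for i in range(4, raw.shape[0]):
        sid = str(raw.iloc[i, 0]).strip()
        if not sid:
            raise DataError("missing_sample_id", f"{path}: empty sample id at data row {i + 1}")
        for j, (name, vt) in enumerate(zip(names, vtypes)):
            cell = str(raw.iloc[i, j + 1]).strip()
            if cell == "":
                continue  # not measured
            if vt in ("continuous", "ordinal"):
                try:
                    value: object = float(cell)
                except ValueError:
                    raise DataError(
                        "non_numeric",
                        f"{path}: non-numeric value {cell!r} for {vt} parameter "
                        f"{name!r} at row {i + 1}, column {j + 2}",
                    ) from None
            else:
                value = cell
            pset.add_record(sid, name, value)
    return pset


def write_parameters(study: Study, path) -> None:
    """Write the study's parameters in the 4-header-row ingest dialect."""
    pset = study.parameters
    cols = [d.name for d in pset.defs]
    lines = [
        "sample_id\t" + "\t".join(cols),
        "vtype\t" + "\t".join(d.vtype for d in pset.defs),
        "category\t" + "\t".join(d.category for d in pset.defs),
        "subgroup\t" + "\t".join(d.subgroup for d in pset.defs),
    ]
    for sid in study.sample_ids:
        cells = []
        for d in pset.defs:
            v = pset.records.get((sid, d.name), "")
            if isinstance(v, float):
                cells.append(f"{v:.17g}")
            else:
                cells.append(str(v))
        lines.append(sid + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Distance matrix import/export
# --------------------------------------------------------------------------

def read_distance_matrix(path, metric: str = "imported") -> DistanceMatrix:
    """Load a precomputed square dissimilarity matrix from TSV.

    Row and column labels must match. Symmetry is enforced by averaging
    (D + D')/2, with a warning when the maximum asymmetry exceeds 1e-8.
    A negative entry or a nonzero diagonal (> 1e-12) is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise DataError("not_square", f"{path}: matrix is {df.shape[0]}x{df.shape[1]}")
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise DataError("label_mismatch", f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    if np.min(values) < 0:
        raise DataError("negative_distance", f"{path}: negative dissimilarity entry")
    if np.max(np.abs(np.diag(values))) > 1e-12:
        raise DataError("nonzero_diagonal", f"{path}: nonzero diagonal entry")
    asym = float(np.max(np.abs(values - values.T)))
    if asym > 1e-8:
        warnings.warn(
            f"{path}: max asymmetry {asym:.3g}; symmetrized by averaging", DataWarning
        )
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    dm = DistanceMatrix(metric, rows, values)
    dm.check()
    return dm


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# --------------------------------------------------------------------------
# Study assembly from files
# --------------------------------------------------------------------------

def load_study(
    abundance_path,
    parameters_path=None,
    study_id: str = "study",
    value_kind: str = "auto",
) -> Study:
    """Assemble a Study from the two-file contract and pre-compute the
    instant derivatives (rank rollups, alpha diversity, Jaccard and
    Bray-Curtis distances)."""
    from .dissimilarity import pairwise_distances

    abundance = read_abundance(abundance_path, value_kind=value_kind)
    deepest = abundance[RANKS[max(RANKS.index(r) for r in abundance)]]
    pset = read_parameters(parameters_path) if parameters_path else ParameterSet()
    sample_ids = list(deepest.sample_ids)
    for (sid, _pname) in pset.records:
        if sid not in sample_ids:
            sample_ids.append(sid)  # parameters-only sample: kept, flagged
    study = Study(
        study_id=study_id,
        samples=[Sample(sid) for sid in sample_ids],
        abundance=abundance,
        parameters=pset,
    )
    compute_diversity(study)
    if len(study.analyzable_samples()) >= 2:
        pairwise_distances(study, "jaccard", rank=deepest.rank)
        pairwise_distances(study, "bray_curtis", rank=deepest.rank)
    return study


# --------------------------------------------------------------------------
# SQLite store
# --------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE samples (
    ord INTEGER PRIMARY KEY, sample_id TEXT UNIQUE NOT NULL, metadata TEXT
);
CREATE TABLE taxa (
    taxon_key INTEGER PRIMARY KEY, rank TEXT NOT NULL, name TEXT NOT NULL,
    parent_key INTEGER, taxon_id INTEGER, is_unclassified INTEGER NOT NULL
);
CREATE TABLE abundances (
    rank TEXT NOT NULL, ord INTEGER NOT NULL, sample_id TEXT NOT NULL,
    taxon_key INTEGER NOT NULL, value REAL NOT NULL, raw_count REAL
);
CREATE TABLE parameter_defs (
    ord INTEGER PRIMARY KEY, name TEXT UNIQUE NOT NULL, vtype TEXT NOT NULL,
    category TEXT, subgroup TEXT, units TEXT
);
CREATE TABLE parameter_values (
    sample_id TEXT NOT NULL, name TEXT NOT NULL,
    value_num REAL, value_text TEXT,
    PRIMARY KEY (sample_id, name)
);
CREATE TABLE distances (
    metric TEXT NOT NULL, ord_i INTEGER NOT NULL, ord_j INTEGER NOT NULL,
    sample_i TEXT NOT NULL, sample_j TEXT NOT NULL, value REAL NOT NULL
);
CREATE TABLE diversity (
    sample_id TEXT NOT NULL, index_name TEXT NOT NULL, value REAL NOT NULL,
    PRIMARY KEY (sample_id, index_name)
);
"""


def save_store(study: Study, path) -> None:
    """Persist a validated study to a single-file SQLite store.

    Refuses to save a study whose validation report contains ERRORs.
    """
    report = validate_study(study)
    if not report.ok():
        first = report.errors[0]
        raise DataError(
            "invalid_study",
            f"refusing to save: {len(report.errors)} validation error(s); "
            f"first: [{first.code}] {first.message}",
        )
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.execute("INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),))
        con.execute("INSERT INTO meta VALUES ('study_id', ?)", (study.study_id,))
        con.execute(
            "INSERT INTO meta VALUES ('category_scheme', ?)",
            (json.dumps({k: list(v) for k, v in study.category_scheme.items()})
             if study.category_scheme is not None else None,),
        )
        for i, s in enumerate(study.samples):
            con.execute(
                "INSERT INTO samples VALUES (?, ?, ?)",
                (i, s.sample_id, json.dumps(s.metadata) if s.metadata else None),
            )
        # taxa: assign keys over the union of all matrices' lineage chains
        taxon_keys: dict[tuple, int] = {}

        def key_of(t: Taxon) -> int:
            k = (t.rank, t.lineage())
            if k not in taxon_keys:
                pkey = key_of(t.parent) if t.parent is not None else None
                taxon_keys[k] = len(taxon_keys) + 1
                con.execute(
                    "INSERT INTO taxa VALUES (?, ?, ?, ?, ?, ?)",
                    (taxon_keys[k], t.rank, t.name, pkey, t.taxon_id, int(t.is_unclassified)),
                )
            return taxon_keys[k]

        for rank, m in study.abundance.items():
            for j, t in enumerate(m.taxa):
                tk = key_of(t)
                for i, sid in enumerate(m.sample_ids):
                    raw = None if m.raw_counts is None else float(m.raw_counts[i, j])
                    con.execute(
                        "INSERT INTO abundances VALUES (?, ?, ?, ?, ?, ?)",
                        (rank, i, sid, tk, float(m.values[i, j]), raw),
                    )
            con.execute(
                "INSERT INTO meta VALUES (?, ?)",
                (f"source_kind:{rank}", m.source_kind),
            )
        for i, d in enumerate(study.parameters.defs):
            con.execute(
                "INSERT INTO parameter_defs VALUES (?, ?, ?, ?, ?, ?)",
                (i, d.name, d.vtype, d.category, d.subgroup, d.units),
            )
        by_name = study.parameters.by_name
        for (sid, name), v in study.parameters.records.items():
            numeric = by_name[name].vtype in ("continuous", "ordinal")
            con.execute(
                "INSERT INTO parameter_values VALUES (?, ?, ?, ?)",
                (sid, name, float(v) if numeric else None, None if numeric else str(v)),
            )
        for metric, dm in study.distances.items():
            for i in range(len(dm.sample_ids)):
                for j in range(i + 1, len(dm.sample_ids)):
                    con.execute(
                        "INSERT INTO distances VALUES (?, ?, ?, ?, ?, ?)",
                        (metric, i, j, dm.sample_ids[i], dm.sample_ids[j],
                         float(dm.values[i, j])),
                    )
        for (sid, index), v in study.diversity.items():
            con.execute("INSERT INTO diversity VALUES (?, ?, ?)", (sid, index, float(v)))
        con.commit()
    finally:
        con.close()


def load_store(path) -> Study:
    """Load a study from a SQLite store written by :func:`save_store`."""
    path = Path(path)
    if not path.exists():
        raise DataError("missing_store", f"store file {path} does not exist")
    con = sqlite3.connect(path)
    try:
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
        except sqlite3.DatabaseError as e:
            raise DataError("corrupt_store", f"{path}: not a valid store ({e})") from None
        version = int(meta.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise DataError(
                "schema_version",
                f"store schema version {version} != supported {SCHEMA_VERSION}",
            )
        samples = [
            Sample(sid, json.loads(mjson) if mjson else {})
            for _, sid, mjson in con.execute("SELECT ord, sample_id, metadata FROM samples ORDER BY ord")
        ]
        taxa_rows = {
            tk: (rank, name, pk, tid, bool(uc))
            for tk, rank, name, pk, tid, uc in con.execute(
                "SELECT taxon_key, rank, name, parent_key, taxon_id, is_unclassified FROM taxa"
            )
        }
        taxa_cache: dict[int, Taxon] = {}

        def taxon_of(tk: int) -> Taxon:
            if tk not in taxa_cache:
                rank, name, pk, tid, uc = taxa_rows[tk]
                taxa_cache[tk] = Taxon(
                    rank, name, taxon_of(pk) if pk is not None else None, tid, uc
                )
            return taxa_cache[tk]

        abundance: dict[str, AbundanceMatrix] = {}
        ranks = [r for (r,) in con.execute("SELECT DISTINCT rank FROM abundances")]
        for rank in sorted(ranks, key=RANKS.index):
            rows = list(
                con.execute(
                    "SELECT ord, sample_id, taxon_key, value, raw_count FROM abundances "
                    "WHERE rank = ? ORDER BY ord, rowid",
                    (rank,),
                )
            )
            sample_ids: list[str] = []
            for ordv, sid, *_ in rows:
                if sid not in sample_ids:
                    sample_ids.append(sid)
            tkeys: list[int] = []
            for _, _, tk, _, _ in rows:
                if tk not in tkeys:
                    tkeys.append(tk)
            values = np.zeros((len(sample_ids), len(tkeys)))
            raw = np.zeros_like(values)
            has_raw = True
            sidx = {s: i for i, s in enumerate(sample_ids)}
            tidx = {t: j for j, t in enumerate(tkeys)}
            for _, sid, tk, v, rc in rows:
                values[sidx[sid], tidx[tk]] = v
                if rc is None:
                    has_raw = False
                else:
                    raw[sidx[sid], tidx[tk]] = rc
            abundance[rank] = AbundanceMatrix(
                rank, sample_ids, [taxon_of(tk) for tk in tkeys], values,
                source_kind=meta.get(f"source_kind:{rank}", "fractions"),
                raw_counts=raw if has_raw else None,
            )
        defs = [
            ParameterDef(name, vtype, cat or "", sub or "", units)
            for _, name, vtype, cat, sub, units in con.execute(
                "SELECT ord, name, vtype, category, subgroup, units FROM parameter_defs ORDER BY ord"
            )
        ]
        pset = ParameterSet(defs)
        for sid, name, vn, vt in con.execute(
            "SELECT sample_id, name, value_num, value_text FROM parameter_values"
        ):
            pset.add_record(sid, name, vn if vn is not None else vt)
        distances: dict[str, DistanceMatrix] = {}
        metrics = [m for (m,) in con.execute("SELECT DISTINCT metric FROM distances")]
        for metric in metrics:
            rows = list(
                con.execute(
                    "SELECT ord_i, ord_j, sample_i, sample_j, value FROM distances "
                    "WHERE metric = ? ORDER BY ord_i, ord_j",
                    (metric,),
                )
            )
            ids: list[str] = []
            for oi, oj, si, sj, _ in rows:
                for o, s in ((oi, si), (oj, sj)):
                    while len(ids) <= o:
                        ids.append("")
                    ids[o] = s
            values = np.zeros((len(ids), len(ids)))
            for oi, oj, _, _, v in rows:
                values[oi, oj] = values[oj, oi] = v
            distances[metric] = DistanceMatrix(metric, ids, values)
        diversity = {
            (sid, index): v
            for sid, index, v in con.execute("SELECT sample_id, index_name, value FROM diversity")
        }
        scheme_json = meta.get("category_scheme")
        scheme = (
            {k: tuple(v) for k, v in json.loads(scheme_json).items()}
            if scheme_json else None
        )
        return Study(
            study_id=meta.get("study_id", "study"),
            samples=samples,
            abundance=abundance,
            parameters=pset,
            diversity=diversity,
            distances=distances,
            category_scheme=scheme,
        )
    finally:
        con.close()
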