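"""Ranked correlation search between taxon abundances and phenotype parameters.

The platform's core operation: Pearson's product-moment or Spearman's rank
correlation between any taxon's relative abundance and any continuous
parameter, over pairwise-complete samples (missing parameter values are
dropped per pair, never imputed). Three search modes:

* one pair (``correlate_pair``),
* one taxon against every continuous parameter
  (``correlate_taxon_vs_parameters``),
* one parameter against every taxon at a rank
  (``correlate_parameter_vs_taxa``),

each returning a table sorted by coefficient in descending order (the order
can be toggled). Text and nominal parameters are never correlation targets;
ordinal parameters may opt in under Spearman only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .model import DataError, Study, rank_index
from .preprocess import OTHERS

MIN_N = 3          # below this a coefficient is undefined
LOW_N = 10         # defined but flagged: too few pairs for a stable estimate


class UndefinedResult(DataError):
    pass


@dataclass
class CorrelationResult:
    x_id: str
    y_id: str
    method: str
    coefficient: float
    n: int
    p_value: Optional[float] = None
    adjusted_p: Optional[float] = None

    @property
    def low_n(self) -> bool:
        return self.n < LOW_N


@dataclass
class CorrelationTable:
    """Defined correlation rows sharing one fixed member, ranked by coefficient."""

    fixed_id: str
    method: str
    rows: list[CorrelationResult] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    descending: bool = True

    def sort(self) -> None:
        self.rows.sort(key=lambda r: (-r.coefficient if self.descending else r.coefficient, r.y_id))

    def toggle_order(self) -> None:
        self.descending = not self.descending
        self.sort()

    def top(self, n: int = 10) -> list[CorrelationResult]:
        """The n most positively correlated rows."""
        return sorted(self.rows, key=lambda r: (-r.coefficient, r.y_id))[:n]

    def bottom(self, n: int = 10) -> list[CorrelationResult]:
        """The n most negatively correlated rows."""
        return sorted(self.rows, key=lambda r: (r.coefficient, r.y_id))[:n]

    def add_bh_adjusted_p(self) -> None:
        """Attach Benjamini-Hochberg adjusted p-values across the table."""
        from statsmodels.stats.multitest import multipletests

        with_p = [r for r in self.rows if r.p_value is not None]
        if not with_p:
            return
        _, adj, _, _ = multipletests([r.p_value for r in with_p], method="fdr_bh")
        for r, q in zip(with_p, adj):
            r.adjusted_p = float(q)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "target": r.y_id,
                    "coefficient": r.coefficient,
                    "n": r.n,
                    "p_value": r.p_value,
                    "adjusted_p": r.adjusted_p,
                    "low_n": r.low_n,
                }
                for r in self.rows
            ]
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (full enumeration)."""
    n = len(x)
    if n > 10:
        raise DataError("too_large_for_exact", "exact permutation p limited to n <= 10")
    rx = _midranks(x)
    ry = _midranks(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        rho = _pearson(rx, ry[list(perm)])
        if abs(rho) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_pair(
    x: dict[str, float],
    y: dict[str, float],
    method: str = "spearman",
    x_id: str = "x",
    y_id: str = "y",
    compute_p: bool = True,
    exact_p: bool = False,
) -> CorrelationResult:
    """Correlate two per-sample numeric sources over pairwise-complete samples.

    `x` and `y` map sample id -> value; only samples present (and finite) in
    both enter the computation. Spearman is Pearson applied to average ranks
    (midranks on ties); p-values use the t approximation with n-2 degrees of
    freedom, or full permutation enumeration when ``exact_p`` (Spearman,
    n <= 10).
    """
    if method not in ("pearson", "spearman"):
        raise DataError("unknown_method", f"method must be pearson or spearman, got {method!r}")
    common = sorted(
        sid
        for sid in set(x) & set(y)
        if _finite(x[sid]) and _finite(y[sid])
    )
    n = len(common)
    if n < MIN_N:
        raise UndefinedResult(
            "undefined_result", f"only {n} pairwise-complete samples (need >= {MIN_N})"
        )
    xv = np.array([float(x[s]) for s in common])
    yv = np.array([float(y[s]) for s in common])
    for side, v in (("x", xv), ("y", yv)):
        if np.ptp(v) == 0:
            raise DataError("constant_input", f"{side} side ({x_id if side == 'x' else y_id}) is constant")
    if method == "spearman":
        rx, ry = _midranks(xv), _midranks(yv)
        r = _pearson(rx, ry)
    else:
        r = _pearson(xv, yv)
    r = min(1.0, max(-1.0, r))
    p = None
    if compute_p:
        if exact_p and method == "spearman":
            p = _exact_spearman_pvalue(xv, yv, r)
        else:
            p = _t_pvalue(r, n)
    return CorrelationResult(x_id, y_id, method, r, n, p)


def _finite(v) -> bool:
    try:
        return math.isfinite(float(v))
    except (TypeError, ValueError):
        return False


def _taxon_source(study: Study, taxon_name: str, rank: str) -> dict[str, float]:
    m = study.matrix(rank)
    col = m.column(taxon_name)  # raises unknown_taxon
    analyzable = set(study.analyzable_samples())
    return {
        sid: float(col[i]) for i, sid in enumerate(m.sample_ids) if sid in analyzable
    }


def _parameter_targets(study: Study, method: str, include_ordinal: bool) -> list[str]:
    vtypes = ("continuous",)
    if include_ordinal and method == "spearman":
        vtypes = ("continuous", "ordinal")
    return study.parameters.names(vtypes)


def correlate_taxon_vs_parameters(
    study: Study,
    taxon_name: str,
    rank: str,
    method: str = "spearman",
    include_ordinal: bool = False,
    compute_p: bool = True,
) -> CorrelationTable:
    """Rank every eligible parameter by its correlation with one taxon.

    Text and nominal parameters are never eligible; ordinal parameters join
    only under Spearman with ``include_ordinal``. Undefined results (too few
    pairs, constant inputs) are excluded from the rows and counted with
    their reason.
    """
    rank_index(rank)
    xsrc = _taxon_source(study, taxon_name, rank)
    table = CorrelationTable(fixed_id=f"{taxon_name}@{rank}", method=method)
    eligible = set(_parameter_targets(study, method, include_ordinal))
    for d in study.parameters.defs:
        if d.name not in eligible:
            table.excluded.append((d.name, f"vtype_{d.vtype}"))
            continue
        ysrc = {s: v for s, v in study.parameters.values_for(d.name).items() if s in xsrc}
        try:
            res = correlate_pair(
                xsrc, ysrc, method, x_id=table.fixed_id, y_id=d.name, compute_p=compute_p
            )
        except DataError as e:
            table.excluded.append((d.name, e.code))
            continue
        table.rows.append(res)
    table.sort()
    return table


def correlate_parameter_vs_taxa(
    study: Study,
    parameter: str,
    rank: str,
    method: str = "spearman",
    include_ordinal: bool = False,
    compute_p: bool = True,
) -> CorrelationTable:
    """Rank every taxon at a rank by its correlation with one parameter.

    Uses the pre-collapse matrix (minor taxa included; the synthetic
    "others" column, if present, excluded). The parameter must be
    continuous — or ordinal under Spearman with ``include_ordinal``.
    """
    rank_index(rank)
    pdef = study.parameters.by_name.get(parameter)
    if pdef is None:
        raise DataError("undefined_parameter", f"parameter {parameter!r} not defined")
    allowed = ("continuous", "ordinal") if (include_ordinal and method == "spearman") else ("continuous",)
    if pdef.vtype not in allowed:
        raise DataError(
            "vtype_not_continuous",
            f"parameter {parameter!r} has type {pdef.vtype}; correlation needs a continuous target",
        )
    ysrc = study.parameters.values_for(parameter)
    m = study.matrix(rank)
    table = CorrelationTable(fixed_id=parameter, method=method)
    for t in m.taxa:
        if t.name == OTHERS:
            continue
        xsrc = _taxon_source(study, t.name, rank)
        try:
            res = correlate_pair(
                xsrc, ysrc, method, x_id=f"{t.name}@{rank}", y_id=t.name, compute_p=compute_p
            )
        except DataError as e:
            table.excluded.append((t.name, e.code))
            continue
        res.x_id = parameter
        res.y_id = f"{t.name}@{rank}"
        table.rows.append(res)
    table.sort()
    return table
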