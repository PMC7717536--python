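"""Static views: composition table, pie drill-down, bar/heat/PCoA charts,
correlation scatter — assembled into a self-contained HTML report.

Every figure's underlying numbers are also written as TSV so charts are
testable (and reproducible) without image comparison; TSV output is
deterministic for a given study and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from html import escape
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .model import RANKS, DataError, Study, rank_index
from .ordination import hcluster, leaf_order, pcoa
from .preprocess import OTHERS, compute_diversity

_FLOAT_FMT = "%.12g"


@dataclass
class ViewConfig:
    """Display options shared by the composition views.

    max_taxa_displayed: the classic "top ten most abundant" rule — taxa
        ranked by global mean abundance (ties alphabetical), remaining mass
        shown as "others".
    sample_order: "by_id", or ("by_dendrogram", linkage, metric) to sort
        samples by hierarchical-clustering leaf order.
    color_parameter: continuous parameters color the PCoA scatter with a
        gradient, nominal ones with a categorical palette; text parameters
        are never drawable.
    """

    rank: str = "phylum"
    max_taxa_displayed: int = 10
    sample_order: object = "by_id"
    color_parameter: Optional[str] = None

    def __post_init__(self):
        rank_index(self.rank)
        if self.max_taxa_displayed < 1:
            raise DataError("bad_config", "max_taxa_displayed must be >= 1")


def _displayed_taxa(study: Study, cfg: ViewConfig) -> tuple[list[str], bool]:
    """Top-N taxon names by global mean abundance; True if an "others"
    residual column is needed."""
    m = study.matrix(cfg.rank)
    means = m.values.mean(axis=0)
    names = m.taxon_names
    order = sorted(range(len(names)), key=lambda j: (-means[j], names[j]))
    if len(order) <= cfg.max_taxa_displayed:
        return [names[j] for j in order], False
    top = order[: cfg.max_taxa_displayed]
    return [names[j] for j in top], True


def composition_table(study: Study, cfg: ViewConfig = ViewConfig()) -> pd.DataFrame:
    """Samples x (displayed taxa + "others" + diversity indices) table.

    Shows the ``max_taxa_displayed`` most abundant taxa (global mean, ties
    alphabetical); the remaining mass appears as "others". Every row carries
    the three alpha-diversity values (Chao1 blank when the input had no
    counts). Only analyzable samples appear.
    """
    m = study.matrix(cfg.rank)
    if not study.diversity:
        compute_diversity(study)
    names, need_others = _displayed_taxa(study, cfg)
    ids = study.analyzable_samples()
    rows = []
    for sid in ids:
        row = {"sample_id": sid}
        sample = m.sample_row(sid)
        shown = 0.0
        for name in names:
            v = float(m.column(name)[m.sample_ids.index(sid)])
            row[name] = v
            shown += v
        if need_others:
            row[OTHERS] = float(sample.sum() - shown)
        row["shannon"] = study.diversity.get((sid, "shannon"), float("nan"))
        row["simpson"] = study.diversity.get((sid, "simpson"), float("nan"))
        row["chao1"] = study.diversity.get((sid, "chao1"), float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def pie_drilldown(
    study: Study, sample_id: str, rank: str, taxon: Optional[str] = None
) -> tuple[list[str], np.ndarray]:
    """(labels, fractions) for a sample's pie chart.

    Without `taxon`: the sample's composition at `rank`. With `taxon`: the
    composition of that taxon's children at the next lower rank,
    renormalized to the taxon's mass; fractions sum to 1.
    """
    ridx = rank_index(rank)
    m = study.matrix(rank)
    if taxon is None:
        row = m.sample_row(sample_id)
        keep = row > 0
        labels = [t.name for t, k in zip(m.taxa, keep) if k]
        fracs = row[keep] / row[keep].sum()
        return labels, fracs
    if ridx + 1 >= len(RANKS):
        raise DataError("no_lower_rank", f"cannot drill below {RANKS[-1]}")
    parent = next((t for t in m.taxa if t.name == taxon), None)
    if parent is None:
        raise DataError("unknown_taxon", f"no taxon {taxon!r} at rank {rank}")
    child_rank = RANKS[ridx + 1]
    cm = study.matrix(child_rank)
    crow = cm.sample_row(sample_id)
    pkey = (parent.rank, parent.lineage())
    idx = [
        j for j, t in enumerate(cm.taxa)
        if t.parent is not None and (t.parent.rank, t.parent.lineage()) == pkey
    ]
    mass = crow[idx].sum()
    if mass <= 0:
        raise DataError("empty_slice", f"{taxon!r} has no abundance in sample {sample_id!r}")
    keep = [j for j in idx if crow[j] > 0]
    labels = [cm.taxa[j].name for j in keep]
    fracs = np.array([crow[j] for j in keep]) / mass
    return labels, fracs


def _resolve_sample_order(study: Study, cfg: ViewConfig) -> list[str]:
    if cfg.sample_order == "by_id":
        return sorted(study.analyzable_samples())
    try:
        tag, linkage, metric = cfg.sample_order
    except (TypeError, ValueError):
        raise DataError("bad_config", f"unrecognized sample_order {cfg.sample_order!r}") from None
    if tag != "by_dendrogram":
        raise DataError("bad_config", f"unrecognized sample_order {cfg.sample_order!r}")
    if metric not in study.distances:
        from .dissimilarity import pairwise_distances

        pairwise_distances(study, metric)
    return leaf_order(hcluster(study.distances[metric], linkage))


def _color_values(study: Study, parameter: str):
    pdef = study.parameters.by_name.get(parameter)
    if pdef is None:
        raise DataError("undefined_parameter", f"parameter {parameter!r} not defined")
    if pdef.vtype == "text":
        raise DataError("vtype_text", f"text parameter {parameter!r} cannot color a plot")
    return pdef, study.parameters.values_for(parameter)


def render_views(
    study: Study,
    cfg: ViewConfig = ViewConfig(),
    outdir="report",
    analyses: tuple[str, ...] = ("composition", "bar", "heatmap", "pcoa"),
    pcoa_metric: str = "bray_curtis",
    correlation_tables=(),
) -> Path:
    """Write report.html + figures/*.png + tables/*.tsv under `outdir`.

    Deterministic at the TSV level: rendering the same study twice yields
    byte-identical tables. Bar chart and heat map use dendrogram leaf order
    when ``cfg.sample_order`` requests it; the PCoA scatter is colored by
    ``cfg.color_parameter``.
    """
    outdir = Path(outdir)
    figdir = outdir / "figures"
    tabdir = outdir / "tables"
    figdir.mkdir(parents=True, exist_ok=True)
    tabdir.mkdir(parents=True, exist_ok=True)
    sections: list[str] = []

    order = _resolve_sample_order(study, cfg)
    comp = composition_table(study, cfg).loc[order]

    if "composition" in analyses:
        comp.to_csv(tabdir / "composition.tsv", sep="\t", float_format=_FLOAT_FMT)
        sections.append(
            "<h2>Microbiota composition</h2>"
            + f"<p>Rank: {escape(cfg.rank)}; displayed taxa capped at "
            + f"{cfg.max_taxa_displayed} by mean abundance.</p>"
            + comp.to_html(float_format=lambda v: f"{v:.4g}")
        )

    taxa_cols = [c for c in comp.columns if c not in ("shannon", "simpson", "chao1")]
    frac = comp[taxa_cols]

    if "bar" in analyses:
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(order)), 4))
        bottom = np.zeros(len(order))
        for col in taxa_cols:
            ax.bar(order, frac[col].to_numpy(), bottom=bottom, label=col)
            bottom += frac[col].to_numpy()
        ax.set_ylabel("relative abundance")
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=90, fontsize=7)
        ax.legend(fontsize=6, bbox_to_anchor=(1.02, 1), loc="upper left")
        fig.tight_layout()
        fig.savefig(figdir / "bar_chart.png", dpi=120)
        plt.close(fig)
        frac.to_csv(tabdir / "bar_chart.tsv", sep="\t", float_format=_FLOAT_FMT)
        sections.append("<h2>Bar chart</h2>" + _img("figures/bar_chart.png"))

    if "heatmap" in analyses:
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(order)), 4))
        im = ax.imshow(
            frac.to_numpy().T, aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0
        )
        ax.set_yticks(range(len(taxa_cols)))
        ax.set_yticklabels(taxa_cols, fontsize=7)
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=90, fontsize=7)
        fig.colorbar(im, ax=ax, label="relative abundance")
        fig.tight_layout()
        fig.savefig(figdir / "heatmap.png", dpi=120)
        plt.close(fig)
        frac.to_csv(tabdir / "heatmap.tsv", sep="\t", float_format=_FLOAT_FMT)
        sections.append("<h2>Heat map</h2>" + _img("figures/heatmap.png"))

    if "pcoa" in analyses:
        if pcoa_metric not in study.distances:
            from .dissimilarity import pairwise_distances

            pairwise_distances(study, pcoa_metric)
        res = pcoa(study.distances[pcoa_metric], k=2)
        coords = pd.DataFrame(
            res.coordinates,
            index=res.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(res.coordinates.shape[1])],
        )
        coords.index.name = "sample_id"
        coords.to_csv(tabdir / "pcoa_coordinates.tsv", sep="\t", float_format=_FLOAT_FMT)
        eig = pd.DataFrame({"eigenvalue": res.eigenvalues})
        ve_full = np.zeros(len(res.eigenvalues))
        ve_full[: len(res.variance_explained)] = res.variance_explained
        eig["variance_explained"] = ve_full
        eig.to_csv(tabdir / "pcoa_eigenvalues.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
        fig, ax = plt.subplots(figsize=(5, 4.5))
        xy = res.coordinates
        note = ""
        if cfg.color_parameter is not None:
            pdef, vals = _color_values(study, cfg.color_parameter)
            if pdef.vtype in ("continuous", "ordinal"):
                c = [vals.get(s, np.nan) for s in res.sample_ids]
                sc = ax.scatter(xy[:, 0], xy[:, 1], c=c, cmap="viridis")
                fig.colorbar(sc, ax=ax, label=cfg.color_parameter)
            else:  # nominal: one category per level
                levels = sorted({str(v) for v in vals.values()})
                cmap = plt.get_cmap("tab10")
                for li, level in enumerate(levels):
                    pts = [i for i, s in enumerate(res.sample_ids) if str(vals.get(s)) == level]
                    ax.scatter(xy[pts, 0], xy[pts, 1], color=cmap(li % 10), label=level)
                ax.legend(title=cfg.color_parameter, fontsize=7)
            note = f" colored by {escape(cfg.color_parameter)}"
        else:
            ax.scatter(xy[:, 0], xy[:, 1])
        pct = 100 * ve_full
        ax.set_xlabel(f"PCo1 ({pct[0]:.2f}%)")
        if xy.shape[1] > 1:
            ax.set_ylabel(f"PCo2 ({pct[1]:.2f}%)")
        fig.tight_layout()
        fig.savefig(figdir / "pcoa.png", dpi=120)
        plt.close(fig)
        neg = res.negative_eigenvalues
        neg_note = (
            f"<p>{len(neg)} negative eigenvalue(s) (non-Euclidean input) excluded "
            "from the variance-explained denominator.</p>" if len(neg) else ""
        )
        sections.append(
            f"<h2>PCoA ({escape(pcoa_metric)}){note}</h2>"
            + f"<p>PCo1 explains {pct[0]:.2f}% and PCo2 {pct[1] if len(pct) > 1 else 0:.2f}% "
            "of the variance.</p>" + neg_note + _img("figures/pcoa.png")
        )

    for ti, table in enumerate(correlation_tables):
        df = table.to_dataframe()
        stem = f"correlation_{ti}_{_slug(table.fixed_id)}_{table.method}"
        df.to_csv(tabdir / f"{stem}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        sections.append(
            f"<h2>Correlation search: {escape(table.fixed_id)} ({table.method})</h2>"
            + df.to_html(index=False, float_format=lambda v: f"{v:.4g}")
        )

    html = _page(study, sections)
    (outdir / "report.html").write_text(html)
    return outdir


def _slug(s: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in s)[:40]


def _img(rel: str) -> str:
    return f'<img src="{rel}" style="max-width:100%">'


def _page(study: Study, sections: list[str]) -> str:
    body = "\n".join(sections)
    n_flagged = len(study.no_microbiome_samples())
    flagged = (
        f"<p><em>{n_flagged} sample(s) without microbiome data are excluded "
        "from all analyses.</em></p>" if n_flagged else ""
    )
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{escape(study.study_id)}</title>"
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #ccc;padding:2px 6px;font-size:12px}</style></head><body>"
        f"<h1>Study report: {escape(study.study_id)}</h1>"
        f"<p>{len(study.samples)} samples; generated by micropheno {__version__}.</p>"
        + flagged + body + "</body></html>"
    )
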