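"""Figure rendering from on-disk result tables.

Figures are always rendered from the TSV tables written by the CLI, never
from in-memory state, so plotting stays decoupled and the tables themselves
are the testable artifacts.  Each figure is written as PNG and SVG with a
deterministic file name; missing tables cause a per-figure skip.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)


def _save(fig, outdir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = outdir / f"{stem}.{ext}"
        fig.savefig(p, dpi=100, metadata={"Date": None} if ext == "svg" else None)
        paths.append(p)
    plt.close(fig)
    return paths


def _read_scores(outputs_dir: Path) -> tuple[pd.DataFrame, list[str]] | None:
    path = outputs_dir / "scores.tsv"
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t", index_col=0)
    score_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
                  and c not in ("x", "y", "survival_time", "survival_event")]
    return df, score_cols


def render_report(outputs_dir: str | Path) -> list[Path]:
    """Render the figure set for whatever tables are present in a run directory.

    Distribution panels and a score heatmap come from ``scores.tsv``; the
    correlation heatmap (cluster-ordered when ``clusters.tsv`` exists) from
    ``corr.tsv``; the five-metric QC panel from ``qc.tsv``; KM curves when
    survival columns are present; spatial maps when x/y columns are present.
    """
    outputs_dir = Path(outputs_dir)
    written: list[Path] = []

    loaded = _read_scores(outputs_dir)
    if loaded is None:
        logger.info("render_report: scores.tsv missing; skipping score figures")
    else:
        df, score_cols = loaded
        if score_cols:
            written += _distribution_panels(df, score_cols, outputs_dir)
            written += _score_heatmap(df, score_cols, outputs_dir)
            if {"x", "y"}.issubset(df.columns):
                written += _spatial_maps(df, score_cols, outputs_dir)
            else:
                logger.info("render_report: no coordinates; spatial maps skipped")
            if {"survival_time", "survival_event"}.issubset(df.columns):
                written += _km_curves(df, score_cols, outputs_dir)

    corr_path = outputs_dir / "corr.tsv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, sep="\t", index_col=0)
        order = list(corr.index)
        clus_path = outputs_dir / "clusters.tsv"
        if clus_path.exists():
            clusters = pd.read_csv(clus_path, sep="\t", index_col=0)
            order = list(clusters.sort_values(["cluster", clusters.index.name or "signature"]).index)
        corr = corr.loc[order, order]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
        ax.set_yticks(range(len(order)), order, fontsize=6)
        fig.colorbar(im, ax=ax, label="correlation")
        ax.set_title("Signature score correlation")
        fig.tight_layout()
        written += _save(fig, outputs_dir, "fig_correlation_heatmap")
    else:
        logger.info("render_report: corr.tsv missing; correlation heatmap skipped")

    qc_path = outputs_dir / "qc.tsv"
    if qc_path.exists():
        written += _qc_panel(pd.read_csv(qc_path, sep="\t", index_col=0), outputs_dir)
    else:
        logger.info("render_report: qc.tsv missing; QC panel skipped")
    return written


def _distribution_panels(df, score_cols, outdir: Path) -> list[Path]:
    n = len(score_cols)
    fig, axes = plt.subplots(n, 1, figsize=(5, 1.6 * n), squeeze=False)
    for ax, col in zip(axes[:, 0], score_cols):
        vals = df[col].dropna()
        ax.hist(vals, bins=30, color="#4878a8")
        ax.set_ylabel(col, rotation=0, ha="right", fontsize=7)
    axes[-1, 0].set_xlabel("score")
    fig.suptitle("Score distributions")
    fig.tight_layout()
    return _save(fig, outdir, "fig_distributions")


def _score_heatmap(df, score_cols, outdir: Path) -> list[Path]:
    mat = df[score_cols].to_numpy(dtype=float).T
    # z-scale rows for comparability
    mu = np.nanmean(mat, axis=1, keepdims=True)
    sd = np.nanstd(mat, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(score_cols) + 2))
    im = ax.imshow((mat - mu) / sd, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(score_cols)), score_cols, fontsize=6)
    ax.set_xlabel("observations")
    fig.colorbar(im, ax=ax, label="z(score)")
    ax.set_title("Signature x observation scores")
    fig.tight_layout()
    return _save(fig, outdir, "fig_score_heatmap")


def _spatial_maps(df, score_cols, outdir: Path) -> list[Path]:
    written = []
    n = len(score_cols)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
    for ax, col in zip(axes[0], score_cols):
        sc = ax.scatter(df["x"], df["y"], c=df[col], s=25, cmap="magma")
        ax.set_title(col, fontsize=7)
        ax.set_aspect("equal")
        fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.suptitle("Spatial score maps")
    fig.tight_layout()
    written += _save(fig, outdir, "fig_spatial_maps")
    return written


def _km_curves(df, score_cols, outdir: Path) -> list[Path]:
    from lifelines import KaplanMeierFitter

    n = len(score_cols)
    fig, axes = plt.subplots(1, n, figsize=(3.5 * n, 3), squeeze=False)
    for ax, col in zip(axes[0], score_cols):
        med = df[col].median()
        for arm, mask in (("low", df[col] <= med), ("high", df[col] > med)):
            if mask.sum() == 0:
                continue
            km = KaplanMeierFitter(label=f"{col} {arm}")
            km.fit(df.loc[mask, "survival_time"], df.loc[mask, "survival_event"])
            km.plot_survival_function(ax=ax, ci_show=False)
        ax.set_title(col, fontsize=8)
    fig.suptitle("Kaplan-Meier by median score split")
    fig.tight_layout()
    return _save(fig, outdir, "fig_km_curves")


def _qc_panel(qc: pd.DataFrame, outdir: Path) -> list[Path]:
    metrics = [
        ("median_mean_expr", "median mean expression"),
        ("median_pct_zero", "median % zeros"),
        ("cor_score_totalcounts", "cor(score, total counts)"),
        ("cor_score_pctzero", "cor(score, % zeros)"),
        ("pct_genes_used", "% genes used"),
    ]
    fig, axes = plt.subplots(1, 5, figsize=(16, 0.35 * len(qc) + 2), squeeze=False)
    ypos = range(len(qc))
    for ax, (col, label) in zip(axes[0], metrics):
        ax.barh(list(ypos), qc[col].fillna(0.0), color="#5a9b6e")
        ax.set_yticks(list(ypos), list(qc.index), fontsize=6)
        ax.set_title(label, fontsize=8)
    fig.suptitle("Signature quality check")
    fig.tight_layout()
    return _save(fig, outdir, "fig_qc_panel")
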