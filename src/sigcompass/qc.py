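"""Signature reliability metrics and QC-based filtering.

Five metrics per (signature, dataset) pair: per-observation mean expression
of the signature genes, per-observation percentage of zeros among signature
genes, correlation of scores with total counts, correlation of scores with
the whole-matrix zero percentage, and the percentage of signature genes used
for the score.  Sparse data (single-cell/spatial) is where these matter:
signatures dominated by dropout are flagged and can be dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from sigcompass.catalog import Catalog, SignatureDefinition
from sigcompass.errors import SigcompassError
from sigcompass.expression import ExpressionDataset
from sigcompass.scoring import ScoreResult

DEFAULT_MAX_PCT_ZERO = 90.0
DEFAULT_MIN_PCT_GENES_USED = 30.0


@dataclass
class SignatureEvaluation:
    """The five reliability metrics for one signature on one dataset."""

    signature_name: str
    mean_expr_per_obs: pd.Series
    pct_zero_per_obs: pd.Series
    cor_score_totalcounts: float  # NaN when score variance is 0
    cor_score_pctzero: float
    pct_genes_used: float
    n_obs: int
    note: str = ""

    def as_row(self) -> dict:
        return {
            "signature": self.signature_name,
            "median_mean_expr": float(self.mean_expr_per_obs.median()),
            "median_pct_zero": float(self.pct_zero_per_obs.median()),
            "cor_score_totalcounts": self.cor_score_totalcounts,
            "cor_score_pctzero": self.cor_score_pctzero,
            "pct_genes_used": self.pct_genes_used,
            "n_obs": self.n_obs,
            "note": self.note,
        }


def _safe_pearson(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    if method == "spearman":
        return float(scipy.stats.spearmanr(x, y).statistic)
    return float(scipy.stats.pearsonr(x, y).statistic)


def _scalar_score(result: ScoreResult) -> pd.Series:
    """Reduce a ScoreResult to one numeric vector for correlation metrics."""
    v = result.values
    if isinstance(v, pd.Series):
        return v.astype(float)
    # composite results: use the final composite / first numeric column
    numeric = v.select_dtypes(include=[np.number])
    if result.signature_name in numeric.columns:
        return numeric[result.signature_name].astype(float)
    return numeric.iloc[:, 0].astype(float)


def evaluate_signature(
    ds: ExpressionDataset,
    sig: SignatureDefinition,
    result: ScoreResult,
    observations: list[str] | None = None,
    correlation: str = "pearson",
) -> SignatureEvaluation:
    """Compute the five reliability metrics for one scored signature.

    ``observations`` restricts the evaluation to a subset of observation ids
    (default: all).  Correlations are Pearson by default, Spearman by flag.
    """
    if ds.n_obs == 0:
        raise SigcompassError("cannot evaluate a signature on zero observations")
    obs = list(observations) if observations is not None else ds.obs_ids
    mat = ds.matrix[obs]
    upper = pd.Index([str(g).upper() for g in mat.index])
    mat = mat.set_axis(upper, axis=0)
    mat = mat[~mat.index.duplicated(keep="first")]
    present = [g for g in (s.upper() for s in sig.gene_symbols) if g in mat.index]
    if not present:
        raise SigcompassError(f"{sig.name}: no signature genes present in the data")
    sub = mat.loc[present]

    mean_expr = sub.mean(axis=0, skipna=True)
    pct_zero = (sub == 0).sum(axis=0) / len(present) * 100.0

    score = _scalar_score(result).reindex(obs)
    total_counts = mat.sum(axis=0, skipna=True)
    pct_zero_total = (mat == 0).sum(axis=0) / mat.shape[0] * 100.0

    cor_tc = _safe_pearson(score.to_numpy(), total_counts.to_numpy(), correlation)
    cor_pz = _safe_pearson(score.to_numpy(), pct_zero_total.to_numpy(), correlation)

    note = ""
    if ds.technology == "spatial":
        note = (
            "spatial data: per-spot totals reflect cell number/composition, so "
            "score-total correlations can be biologically driven"
        )
    return SignatureEvaluation(
        signature_name=sig.name,
        mean_expr_per_obs=mean_expr,
        pct_zero_per_obs=pct_zero,
        cor_score_totalcounts=cor_tc,
        cor_score_pctzero=cor_pz,
        pct_genes_used=100.0 * result.genes_used / result.genes_requested,
        n_obs=len(obs),
        note=note,
    )


def evaluate_all(
    ds: ExpressionDataset,
    results: dict[str, ScoreResult],
    catalog: Catalog,
    observations: list[str] | None = None,
    correlation: str = "pearson",
) -> tuple[pd.DataFrame, dict[str, SignatureEvaluation]]:
    """Evaluate every computed signature; returns a summary table plus details.

    One row per signature in deterministic (name) order; per-observation
    vectors are summarised by their median for the tabular export.
    """
    evals: dict[str, SignatureEvaluation] = {}
    rows = []
    for name in sorted(results):
        ev = evaluate_signature(
            ds, catalog.get(name), results[name], observations=observations,
            correlation=correlation,
        )
        evals[name] = ev
        rows.append(ev.as_row())
    cols = ["signature", "median_mean_expr", "median_pct_zero", "cor_score_totalcounts",
            "cor_score_pctzero", "pct_genes_used", "n_obs", "note"]
    table = pd.DataFrame(rows, columns=cols).set_index("signature")
    return table, evals


def filter_by_qc(
    evals: dict[str, SignatureEvaluation] | pd.DataFrame,
    max_pct_zero: float = DEFAULT_MAX_PCT_ZERO,
    min_pct_genes_used: float = DEFAULT_MIN_PCT_GENES_USED,
) -> tuple[list[str], pd.DataFrame]:
    """Drop signatures with excessive zeros AND low gene coverage.

    A signature is dropped iff its median per-observation zero percentage
    exceeds ``max_pct_zero`` and its percentage of genes used is below
    ``min_pct_genes_used`` (conjunction).  Returns the kept names and a table
    of all signatures with decisions and reasons.
    """
    if isinstance(evals, pd.DataFrame):
        table = evals
    else:
        if not evals:
            raise SigcompassError("filter_by_qc requires at least one evaluation")
        table = pd.DataFrame([e.as_row() for e in evals.values()]).set_index("signature")
    kept, rows = [], []
    for name, row in table.sort_index().iterrows():
        too_sparse = row["median_pct_zero"] > max_pct_zero
        low_cov = row["pct_genes_used"] < min_pct_genes_used
        dropped = bool(too_sparse and low_cov)
        if dropped:
            reason = (
                f"median zero fraction {row['median_pct_zero']:.1f}% > {max_pct_zero:g}% "
                f"and genes used {row['pct_genes_used']:.1f}% < {min_pct_genes_used:g}%"
            )
        else:
            reason = "kept"
        if not dropped:
            kept.append(name)
        rows.append({"signature": name, "dropped": dropped, "reason": reason})
    decisions = pd.DataFrame(rows).set_index("signature")
    if not kept:
        warnings.warn("filter_by_qc dropped every signature", stacklevel=2)
    return kept, decisions
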