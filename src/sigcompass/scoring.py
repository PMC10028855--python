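"""Per-observation signature scoring: six method families plus dispatch.

Every packaged signature is encoded as (method family, parameters).  The
families are:

``weighted_sum``
    linear combination of gene expression with per-gene weights.
``zscore_mean``
    per-gene z-score across observations, averaged over the gene list
    (down-regulated genes contribute with flipped sign).
``up_down_diff``
    mean expression of the up set minus mean expression of the down set.
``ssgsea``
    single-sample rank-based enrichment of the gene set against the full
    gene background (weighted in-set ECDF vs uniform out-of-set ECDF).
``ips_composite``
    four averaged, weighted z-score categories (EC/SC/MHC/CP) aggregated
    into a 0-10 composite.
``consensus_centroid``
    Pearson correlation of each observation against per-subtype centroids;
    argmax assigns the subtype label.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from sigcompass.catalog import Catalog, CatalogFilter, SignatureDefinition
from sigcompass.errors import (
    CoverageError,
    EmptySelectionError,
    GenesUnavailableError,
    SigcompassError,
)
from sigcompass.expression import ExpressionDataset, attach_scores, transform_metric

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.05
DEFAULT_SSGSEA_ALPHA = 0.25

IPS_CATEGORIES = ("EC", "SC", "MHC", "CP")


@dataclass
class ScoreResult:
    """Per-observation score(s) for one signature plus provenance."""

    signature_name: str
    values: pd.Series | pd.DataFrame
    genes_requested: int
    genes_used: int
    options_fingerprint: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return self.genes_used / self.genes_requested if self.genes_requested else 0.0


# ---------------------------------------------------------------------------
# method families (operate on already-intersected submatrices)
# ---------------------------------------------------------------------------

def score_weighted_sum(expr: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Sum over genes of weight * expression, per observation."""
    w = weights.reindex(expr.index)
    if w.isna().any() or not np.isfinite(w.to_numpy()).all():
        raise SigcompassError("weighted_sum requires a finite weight for every gene row")
    return pd.Series(w.to_numpy() @ expr.to_numpy(), index=expr.columns, dtype=float)


def _zscores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z across observations (sample sd); zero-variance genes get 0."""
    vals = expr.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def score_zscore_mean(expr: pd.DataFrame, directions: pd.Series) -> pd.Series:
    """Mean over genes of the per-gene z-score, sign-flipped for down genes."""
    if expr.shape[1] < 2:
        raise SigcompassError("zscore_mean requires at least 2 observations")
    z = _zscores(expr)
    signs = directions.reindex(expr.index).map({"up": 1.0, "none": 1.0, "down": -1.0})
    return z.mul(signs, axis=0).mean(axis=0, skipna=True)


def score_up_down(expr: pd.DataFrame, directions: pd.Series) -> pd.Series:
    """Mean of up-set expression minus mean of down-set expression."""
    d = directions.reindex(expr.index)
    up = expr.loc[d == "up"]
    down = expr.loc[d == "down"]
    if up.shape[0] == 0:
        raise CoverageError("up_down_diff: no up-regulated genes present in the data")
    vals = up.mean(axis=0, skipna=True)
    if down.shape[0]:
        vals = vals - down.mean(axis=0, skipna=True)
    return vals.astype(float)


def score_ssgsea(
    full_expr: pd.DataFrame,
    gene_set: list[str],
    alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> pd.Series:
    """Single-sample enrichment of ``gene_set`` against the full background.

    Per observation, all genes are ranked by expression ascending (mid-rank
    ties; the walk order breaks residual ties lexicographically by gene id).
    Walking the list from highest to lowest rank, the score is the summed
    difference between the rank-weighted in-set ECDF (weight ``rank**alpha``)
    and the uniform out-of-set ECDF.  Invariant under strictly monotone
    per-observation transforms.  With ``normalize``, scores are min-max
    scaled across observations.
    """
    genome = list(full_expr.index)
    in_set = np.array([g in set(gene_set) for g in genome])
    n_set = int(in_set.sum())
    if n_set < 2:
        raise CoverageError("ssgsea requires >=2 gene-set genes present in the background")
    if n_set == len(genome):
        raise SigcompassError(
            "ssgsea is undefined when the gene set covers the whole background "
            "(out-of-set ECDF has no mass)"
        )
    gene_ids = np.array(genome)
    vals = full_expr.to_numpy(dtype=float)
    n_genes, n_obs = vals.shape
    out = np.empty(n_obs)
    for j in range(n_obs):
        ranks = scipy.stats.rankdata(vals[:, j], method="average")
        order = np.lexsort((gene_ids, -ranks))  # descending rank, lexicographic ties
        inset_o = in_set[order]
        w = np.abs(ranks[order]) ** alpha * inset_o
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~inset_o) / (n_genes - n_set)
        out[j] = float(np.sum(p_in - p_out))
    scores = pd.Series(out, index=full_expr.columns, dtype=float)
    if normalize:
        rng = scores.max() - scores.min()
        scores = (scores - scores.min()) / (rng if rng else 1.0)
    return scores


def score_ips(
    expr: pd.DataFrame,
    class_labels: pd.Series,
    sub_classes: pd.Series,
    weights: pd.Series,
    signature_name: str = "IPS",
) -> pd.DataFrame:
    """Four averaged, weighted z-score categories plus the 0-10 composite.

    Sub-class score = weight * mean(z of its genes); category score = mean of
    its sub-class scores; AZ = mean of the four category scores; composite =
    0 if AZ <= 0 else min(10, 10*AZ/3).
    """
    z = _zscores(expr)
    cats: dict[str, pd.Series] = {}
    for cat in IPS_CATEGORIES:
        genes = class_labels.index[class_labels == cat]
        genes = [g for g in genes if g in z.index]
        if not genes:
            raise CoverageError(
                f"ips_composite: category {cat!r} has no genes present; composite refused"
            )
        sub_scores = []
        for sub in sorted(set(sub_classes.loc[genes])):
            sub_genes = [g for g in genes if sub_classes.loc[g] == sub]
            w = float(weights.loc[sub_genes[0]])
            sub_scores.append(w * z.loc[sub_genes].mean(axis=0))
        cats[cat] = pd.concat(sub_scores, axis=1).mean(axis=1)
    out = pd.DataFrame(
        {f"{signature_name}_{cat}": cats[cat] for cat in IPS_CATEGORIES}
    )
    az = out.mean(axis=1)
    ips = np.where(az <= 0, 0.0, np.minimum(10.0, 10.0 * az / 3.0))
    out[f"{signature_name}_AZ"] = az
    out[signature_name] = ips
    return out


def score_consensus_subtypes(
    expr: pd.DataFrame,
    centroids: pd.DataFrame,
    signature_name: str = "Consensus",
) -> pd.DataFrame:
    """Pearson correlation of each observation against each subtype centroid.

    Returns one score column per subtype plus a ``_label`` column holding the
    argmax subtype (ties resolved to the lexicographically first subtype,
    with a warning).  Zero-variance observations get missing scores.
    """
    shared = [g for g in expr.index if g in centroids.index]
    if len(shared) < 3:
        raise CoverageError("consensus_centroid requires >=3 genes shared with the centroids")
    sub = expr.loc[shared].to_numpy(dtype=float)
    cent = centroids.loc[shared].to_numpy(dtype=float)
    subtypes = list(centroids.columns)

    x = sub - sub.mean(axis=0, keepdims=True)
    c = cent - cent.mean(axis=0, keepdims=True)
    xn = np.sqrt((x**2).sum(axis=0))
    cn = np.sqrt((c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x.T @ c) / np.outer(xn, cn)
    corr[xn == 0, :] = np.nan
    out = pd.DataFrame(
        corr, index=expr.columns, columns=[f"{signature_name}_{s}" for s in subtypes]
    )
    # argmax with deterministic lexicographic tie-breaking
    order = np.argsort(subtypes, kind="stable")
    labels = []
    tie_seen = False
    for i in range(corr.shape[0]):
        row = corr[i]
        if np.isnan(row).all():
            labels.append(None)
            continue
        best = np.nanmax(row)
        winners = sorted(subtypes[k] for k in range(len(subtypes)) if row[k] == best)
        if len(winners) > 1:
            tie_seen = True
        labels.append(winners[0])
    if tie_seen:
        warnings.warn(
            f"{signature_name}: argmax ties resolved to lexicographically first subtype",
            stacklevel=2,
        )
    out[f"{signature_name}_label"] = labels
    return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _options_fingerprint(opts: dict) -> str:
    blob = json.dumps(opts, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _prepare_scale(ds: ExpressionDataset, sig: SignatureDefinition) -> ExpressionDataset:
    if ds.metric == sig.required_scale:
        return ds
    return transform_metric(ds, sig.required_scale)


def compute_signature(
    ds: ExpressionDataset,
    sig: SignatureDefinition | str,
    catalog: Catalog | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    ssgsea_alpha: float = DEFAULT_SSGSEA_ALPHA,
    ssgsea_normalize: bool = False,
) -> ScoreResult:
    """Score one signature on a dataset, converting the metric if needed.

    Genes are intersected case-insensitively.  If fewer than ``min_coverage``
    of the signature's genes are present, scoring is refused with a coverage
    report; partial coverage above the threshold proceeds with a warning.
    """
    if isinstance(sig, str):
        if catalog is None:
            raise SigcompassError("a catalog is required to resolve a signature by name")
        sig = catalog.get(sig)
    if not sig.genes_available:
        raise GenesUnavailableError(
            f"{sig.name}: gene list not packaged (metadata-only entry); cannot score"
        )
    opts = {
        "min_coverage": min_coverage,
        "ssgsea_alpha": ssgsea_alpha,
        "ssgsea_normalize": ssgsea_normalize,
        "required_scale": sig.required_scale,
    }
    warns: list[str] = []

    work = _prepare_scale(ds, sig)
    upper_index = pd.Index([str(g).upper() for g in work.matrix.index])
    mat = work.matrix.copy()
    mat.index = upper_index
    mat = mat[~mat.index.duplicated(keep="first")]

    requested = [s.upper() for s in sig.gene_symbols]
    present = [g for g in requested if g in mat.index]
    n_req, n_used = len(requested), len(present)
    coverage = n_used / n_req if n_req else 0.0
    if coverage < min_coverage:
        raise CoverageError(
            f"{sig.name}: only {n_used}/{n_req} signature genes present "
            f"({100 * coverage:.1f}% < {100 * min_coverage:.0f}% minimum)"
        )
    if n_used < n_req:
        warns.append(f"{n_req - n_used}/{n_req} signature genes absent from the data")

    sub = mat.loc[present]
    directions = pd.Series({g.symbol.upper(): g.direction for g in sig.genes})
    if sig.method == "weighted_sum":
        weights = pd.Series({g.symbol.upper(): g.weight for g in sig.genes})
        values: pd.Series | pd.DataFrame = score_weighted_sum(sub, weights)
        values.name = sig.name
    elif sig.method == "zscore_mean":
        values = score_zscore_mean(sub, directions)
        values.name = sig.name
    elif sig.method == "up_down_diff":
        values = score_up_down(sub, directions)
        values.name = sig.name
    elif sig.method == "ssgsea":
        values = score_ssgsea(mat, present, alpha=ssgsea_alpha, normalize=ssgsea_normalize)
        values.name = sig.name
    elif sig.method == "ips_composite":
        class_labels = pd.Series({g.symbol.upper(): g.class_label for g in sig.genes})
        sub_classes = pd.Series(
            {g.symbol.upper(): g.sub_class or g.symbol for g in sig.genes}
        )
        weights = pd.Series({g.symbol.upper(): g.weight for g in sig.genes})
        values = score_ips(sub, class_labels, sub_classes, weights, signature_name=sig.name)
    elif sig.method == "consensus_centroid":
        values = score_consensus_subtypes(sub, sig.centroids, signature_name=sig.name)
    else:  # pragma: no cover - catalog validation rejects unknown methods
        raise SigcompassError(f"unknown method {sig.method!r}")

    for w in warns:
        warnings.warn(f"{sig.name}: {w}", stacklevel=2)
    return ScoreResult(
        signature_name=sig.name,
        values=values,
        genes_requested=n_req,
        genes_used=n_used,
        options_fingerprint=_options_fingerprint(opts),
        warnings=warns,
    )


def compute_many(
    ds: ExpressionDataset,
    catalog: Catalog,
    filt: CatalogFilter | None = None,
    **opts,
) -> tuple[ExpressionDataset, pd.DataFrame, dict[str, ScoreResult]]:
    """Score every catalog signature matching a filter and attach the results.

    Per-signature failures (coverage, missing gene lists) are logged in the
    returned summary table rather than raised.  Returns the dataset with
    scores attached, the summary table, and the per-signature results.
    """
    table = catalog.available_signatures(filt)
    if table.empty:
        raise EmptySelectionError("catalog filter matched no signatures")
    rows = []
    results: dict[str, ScoreResult] = {}
    out = ds
    for name in table["name"]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = compute_signature(out, name, catalog=catalog, **opts)
                out = attach_scores(out, res)
            results[name] = res
            rows.append(
                {
                    "name": name,
                    "status": "ok",
                    "genes_used": res.genes_used,
                    "genes_requested": res.genes_requested,
                    "detail": "; ".join(res.warnings),
                }
            )
        except SigcompassError as exc:
            logger.info("compute_many: %s skipped: %s", name, exc)
            rows.append(
                {
                    "name": name,
                    "status": "failed",
                    "genes_used": 0,
                    "genes_requested": catalog.get(name).n_genes,
                    "detail": str(exc),
                }
            )
    if not results:
        raise EmptySelectionError("catalog filter matched no scoreable signatures")
    summary = pd.DataFrame(rows).set_index("name")
    return out, summary, results
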