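"""Simulators with planted signature signal for desk-scale testing.

Bulk counts are negative binomial with lognormal gene means; single-cell
adds per-entry logistic dropout; spatial lays spots on an integer grid with
region-structured signal.  A planted signal multiplies the expected counts
of a gene set by ``2**log2_fold_change`` in a subset of observations, and
every simulator returns a truth table holding the planted labels, so tests
never re-derive them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from sigcompass.catalog import Catalog, SignatureDefinition, SignatureGene
from sigcompass.errors import SigcompassError
from sigcompass.expression import ExpressionDataset

METHOD_FAMILIES = (
    "weighted_sum", "zscore_mean", "up_down_diff", "ssgsea", "ips_composite",
    "consensus_centroid",
)


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedSignal:
    """One planted perturbation: gene set x observation subset x effect size."""

    genes: tuple[str, ...]
    observations: tuple[int, ...] | str  # indices, or a region label (spatial)
    log2_fold_change: float
    name: str = "signal"

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if not isinstance(self.observations, str):
            object.__setattr__(self, "observations", tuple(self.observations))


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterization of one simulated dataset; seed determines output."""

    n_genes: int = 1000
    n_obs: int = 100
    technology: str = "bulk_rnaseq"
    nb_mean_log_mu: float = 1.0
    nb_mean_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    dropout_logit_intercept: float = 0.0
    dropout_logit_slope: float = -1.0
    grid_dims: tuple[int, int] | None = None
    region_map: tuple[str, ...] | None = None
    planted: tuple[PlantedSignal, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.region_map is not None:
            object.__setattr__(self, "region_map", tuple(self.region_map))

    def validate(self, obs_labels: list[str] | None = None) -> None:
        if self.n_genes < 1 or self.n_obs < 1:
            raise SigcompassError("n_genes and n_obs must be positive")
        universe = set(gene_names(self.n_genes))
        for p in self.planted:
            missing = set(p.genes) - universe
            if missing:
                raise SigcompassError(
                    f"planted gene set contains genes outside the universe: {sorted(missing)[:5]}"
                )
            if not isinstance(p.observations, str):
                bad = [i for i in p.observations if not (0 <= i < self.n_obs)]
                if bad:
                    raise SigcompassError(f"planted observation indices out of range: {bad[:5]}")


def _mean_matrix(design: SimulationDesign, rng: np.random.Generator,
                 region_of_obs: list[str] | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    genes = gene_names(design.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    mu = rng.lognormal(design.nb_mean_log_mu, design.nb_mean_log_sd, size=design.n_genes)
    mean = np.tile(mu[:, None], (1, design.n_obs))

    truth = pd.DataFrame(index=range(design.n_obs))
    for p in design.planted:
        if isinstance(p.observations, str):
            if region_of_obs is None:
                raise SigcompassError(
                    f"planted subset {p.observations!r} is a region label but the design "
                    "has no region map"
                )
            obs_idx = [i for i, r in enumerate(region_of_obs) if r == p.observations]
        else:
            obs_idx = list(p.observations)
        rows = [gene_pos[g] for g in p.genes]
        mean[np.ix_(rows, obs_idx)] *= 2.0 ** p.log2_fold_change
        flag = np.zeros(design.n_obs, dtype=bool)
        flag[obs_idx] = True
        truth[p.name] = flag
    return mean, truth


def _nb_draw(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_bulk(design: SimulationDesign) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Negative-binomial bulk counts with planted fold changes."""
    if design.technology != "bulk_rnaseq":
        raise SigcompassError("simulate_bulk requires technology='bulk_rnaseq'")
    design.validate()
    rng = np.random.default_rng(design.seed)
    mean, truth = _mean_matrix(design, rng)
    counts = _nb_draw(mean, design.nb_dispersion, rng)
    obs = [f"sample_{i:04d}" for i in range(design.n_obs)]
    truth.index = pd.Index(obs, name="observation_id")
    ds = ExpressionDataset(
        matrix=pd.DataFrame(counts, index=gene_names(design.n_genes), columns=obs),
        metric="counts",
        technology="bulk_rnaseq",
    )
    return ds, truth


def simulate_single_cell(design: SimulationDesign) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Bulk process plus per-entry dropout, logistic in the log expected mean.

    The dropout probability for an entry with expected mean m is
    ``expit(intercept + slope * log(m))``; the realized overall zero fraction
    is recorded in the truth table attributes.
    """
    if design.technology != "scrnaseq":
        raise SigcompassError("simulate_single_cell requires technology='scrnaseq'")
    design.validate()
    rng = np.random.default_rng(design.seed)
    mean, truth = _mean_matrix(design, rng)
    counts = _nb_draw(mean, design.nb_dispersion, rng)
    with np.errstate(divide="ignore"):
        p_drop = expit(design.dropout_logit_intercept
                       + design.dropout_logit_slope * np.log(mean))
    dropped = rng.random(counts.shape) < p_drop
    counts = np.where(dropped, 0.0, counts)
    obs = [f"cell_{i:04d}" for i in range(design.n_obs)]
    truth.index = pd.Index(obs, name="observation_id")
    truth.attrs["zero_fraction"] = float((counts == 0).mean())
    ds = ExpressionDataset(
        matrix=pd.DataFrame(counts, index=gene_names(design.n_genes), columns=obs),
        metric="counts",
        technology="scrnaseq",
    )
    return ds, truth


def expected_zero_fraction(design: SimulationDesign, n_draws: int = 200_000) -> float:
    """Closed-form-by-integration expectation of the single-cell zero fraction.

    Integrates dropout and NB zero mass over the lognormal gene-mean
    distribution by Monte Carlo on the means only (no count sampling), which
    is independent of the simulator's count-drawing path.
    """
    rng = np.random.default_rng(design.seed + 987654321)
    mu = rng.lognormal(design.nb_mean_log_mu, design.nb_mean_log_sd, size=n_draws)
    r = design.nb_dispersion
    p_nb_zero = (r / (r + mu)) ** r
    p_drop = expit(design.dropout_logit_intercept + design.dropout_logit_slope * np.log(mu))
    return float(np.mean(p_drop + (1 - p_drop) * p_nb_zero))


def simulate_spatial(design: SimulationDesign) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Spots on an integer grid with region-structured planted signal."""
    if design.technology != "spatial":
        raise SigcompassError("simulate_spatial requires technology='spatial'")
    if design.grid_dims is None:
        raise SigcompassError("simulate_spatial requires grid_dims")
    nr, nc = design.grid_dims
    n_spots = nr * nc
    if design.region_map is None or len(design.region_map) != n_spots:
        raise SigcompassError(
            f"region_map must assign a label to each of the {n_spots} spots"
        )
    if design.n_obs != n_spots:
        design = replace(design, n_obs=n_spots)
    design.validate()
    rng = np.random.default_rng(design.seed)
    regions = list(design.region_map)
    mean, truth = _mean_matrix(design, rng, region_of_obs=regions)
    counts = _nb_draw(mean, design.nb_dispersion, rng)
    obs = [f"spot_{i:04d}" for i in range(n_spots)]
    coords = pd.DataFrame(
        {"x": [i % nc for i in range(n_spots)], "y": [i // nc for i in range(n_spots)]},
        index=obs,
    )
    truth.index = pd.Index(obs, name="observation_id")
    truth["region"] = regions
    ds = ExpressionDataset(
        matrix=pd.DataFrame(counts, index=gene_names(design.n_genes), columns=obs),
        metric="counts",
        technology="spatial",
        obs_annotations=pd.DataFrame({"region": regions}, index=obs),
        coordinates=coords,
    )
    return ds, truth


def make_synthetic_catalog(
    n_sigs: int,
    gene_universe: list[str],
    size_range: tuple[int, int] = (5, 30),
    method_mix: tuple[str, ...] = METHOD_FAMILIES,
    seed: int = 0,
) -> Catalog:
    """Random valid signatures over a gene universe, cycling method families."""
    if size_range[0] < 2:
        raise SigcompassError("signature sizes must be >= 2")
    rng = np.random.default_rng(seed)
    cat = Catalog()
    for i in range(n_sigs):
        method = method_mix[i % len(method_mix)]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        picked = list(rng.choice(gene_universe, size=size, replace=False))
        centroids = None
        if method == "weighted_sum":
            genes = tuple(
                SignatureGene(g, "none", float(w))
                for g, w in zip(picked, rng.normal(0, 1, size))
            )
        elif method == "zscore_mean":
            genes = tuple(SignatureGene(g, "up") for g in picked)
        elif method == "up_down_diff":
            half = max(1, size // 2)
            genes = tuple(SignatureGene(g, "up") for g in picked[:half]) + tuple(
                SignatureGene(g, "down") for g in picked[half:]
            )
        elif method == "ssgsea":
            genes = tuple(SignatureGene(g, "none") for g in picked)
        elif method == "ips_composite":
            genes = tuple(
                SignatureGene(
                    g,
                    "none",
                    1.0 if k % 2 == 0 else -1.0,
                    ("EC", "SC", "MHC", "CP")[k % 4],
                    f"sub{k % 8}",
                )
                for k, g in enumerate(picked)
            )
            if size < 8:  # ensure every category is populated
                extra = [g for g in gene_universe if g not in picked][: 8 - size]
                genes = genes + tuple(
                    SignatureGene(
                        g, "none", 1.0, ("EC", "SC", "MHC", "CP")[(size + k) % 4],
                        f"sub{(size + k) % 8}",
                    )
                    for k, g in enumerate(extra)
                )
        else:  # consensus_centroid
            genes = tuple(SignatureGene(g, "none") for g in picked)
            centroids = pd.DataFrame(
                rng.normal(0, 1, (size, 3)),
                index=[g.upper() for g in picked],
                columns=["SubA", "SubB", "SubC"],
            )
        cat.register(
            SignatureDefinition(
                name=f"Syn{i:02d}_{_camel(method)}",
                topic="Synthetic activity",
                tumor_types=("synthetic",),
                first_author=_camel(method),
                reference_id="0",
                input_types=frozenset({"sequencing"}),
                required_scale="log",
                method=method,
                genes=genes,
                centroids=centroids,
            )
        )
    return cat


def _camel(method: str) -> str:
    return "".join(part.title() for part in method.split("_"))
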