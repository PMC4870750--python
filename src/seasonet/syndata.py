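"""Synthetic two-site, two-season expression studies with known ground truth.

The generator emulates the sampling design of a wild-fish seasonal
transcriptomics study: two contrasting sites, fish collected at the winter and
summer extremes (a balanced cell of ~9 individuals per site x season), a wide
and deliberately overlapping range of body lengths, and a ~10^4-gene
FPKM-scale matrix in which known fractions of genes are planted winter- or
summer-biased.  Co-expression structure is induced by latent per-sample
winter and summer factors: winter-biased genes load on the winter factor,
summer-biased genes on the summer factor, and a small set of "interface"
genes load on both, mimicking genes that bridge the two seasonal programmes.
Additional non-immune "organismal" modules (growth / metabolism / stress
analogues) get latent factors of their own.

Expression is generated in log2 space and exponentiated, which guarantees
non-negative abundances and matches the log2 transforms used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .study import ExpressionStudy, default_gene_annotation

__all__ = [
    "SynConfig",
    "GroundTruth",
    "generate_study",
    "generate_null_matrix",
    "write_truth_tsv",
    "planted_gene_sets",
]


@dataclass(frozen=True)
class SynConfig:
    """Parameters of the synthetic study design.

    All effect magnitudes are in log2 expression units.  ``factor_loading``
    is the target correlation between a module gene and its latent seasonal
    factor; interface genes carry that loading on their own season's factor
    and its negative on the opposite factor, so they covary with both
    seasonal programmes.
    """

    n_genes: int = 2000
    n_per_cell: int = 9              # samples per site x season cell
    sites: tuple[str, ...] = ("site1", "site2")
    frac_winter_biased: float = 0.05
    frac_summer_biased: float = 0.03
    effect_size_log2: float = 2.0    # seasonal shift beta
    site_effect_sd: float = 0.3
    sex_effect_sd: float = 0.1
    length_slope: float = 0.01       # SD of per-gene slope, log2 units / mm
    noise_sd: float = 0.4
    n_immune: int = 200
    n_core: int = 30                 # seasonally-biased core immune genes
    n_interface: int = 6             # core genes loading on both factors
    factor_loading: float = 0.9
    n_organismal_sets: int = 3
    organismal_set_size: int = 20
    n_stable: int = 50               # housekeeping-like reference candidates
    stable_noise_sd: float = 0.08
    dropout_prob: float = 0.0        # P(entry set undetectable)
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    length_range_mm: tuple[float, float] = (20.0, 60.0)
    seed: int = 0

    def validate(self) -> None:
        num = {
            k: v
            for k, v in asdict(self).items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for k, v in num.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite config value: {k}={v}")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if len(self.sites) < 1:
            raise ValueError("at least one site required")
        if not 0 <= self.frac_winter_biased + self.frac_summer_biased < 1:
            raise ValueError("biased fractions must sum to < 1")
        for k in ("site_effect_sd", "sex_effect_sd", "noise_sd",
                  "length_slope", "baseline_sd"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        if not 0 <= self.factor_loading < 1:
            raise ValueError("factor_loading must be in [0, 1)")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.n_stable < 0 or self.stable_noise_sd < 0:
            raise ValueError("stable-gene settings must be >= 0")
        n_w = int(self.frac_winter_biased * self.n_genes)
        n_s = int(self.frac_summer_biased * self.n_genes)
        if self.n_core > n_w + n_s:
            raise ValueError("n_core exceeds planted biased genes")
        if self.n_interface > self.n_core:
            raise ValueError("n_interface exceeds n_core")
        if self.n_interface > n_w + n_s:
            raise ValueError("n_interface exceeds planted biased genes")
        if self.n_immune < self.n_core:
            raise ValueError("n_immune must be >= n_core")


@dataclass
class GroundTruth:
    """What was planted: per-gene labels plus per-sample latent factors."""

    table: pd.DataFrame      # per gene: bias, interface, module, flags
    factors: pd.DataFrame    # per sample: F_winter, F_summer, F_<org>...
    config: SynConfig

    @property
    def winter_genes(self) -> list[str]:
        return list(self.table.index[self.table["bias"] == "winter"])

    @property
    def summer_genes(self) -> list[str]:
        return list(self.table.index[self.table["bias"] == "summer"])

    @property
    def interface_genes(self) -> list[str]:
        return list(self.table.index[self.table["interface_flag"]])

    @property
    def core_genes(self) -> list[str]:
        return list(self.table.index[self.table["core_flag"]])


def _sample_frame(config: SynConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.length_range_mm
    for site in config.sites:
        for season in ("winter", "summer"):
            for i in range(config.n_per_cell):
                rows.append(
                    {
                        "sample": f"{site}_{season}_{i + 1:02d}",
                        "site": site,
                        "season": season,
                        "sex": "M" if i % 2 == 0 else "F",
                        "length_mm": float(rng.uniform(lo, hi)),
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def generate_study(config: SynConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate one synthetic study and its ground truth.

    log2 abundance of gene *g* in sample *i* is::

        baseline_g + beta * 1[winter_i] * dir_g
        + site_offset(g, site_i) + sex_offset(g) * 1[male_i]
        + slope_g * (length_i - mean length)
        + loading_g . F_i   (winter, summer and/or organismal factors)
        + Normal(0, noise_sd)

    with ``dir_g`` = +1 for winter-biased genes and -1 for summer-biased
    genes, and the matrix returned as ``2**x`` on the linear FPKM scale.
    The same ``(config, seed)`` always produces byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _sample_frame(config, rng)
    n_samp = len(samples)
    gene_ids = pd.Index(
        [f"g{i:05d}" for i in range(config.n_genes)], name="gene"
    )

    # --- labels -----------------------------------------------------------
    n_w = int(config.frac_winter_biased * config.n_genes)
    n_s = int(config.frac_summer_biased * config.n_genes)
    order = rng.permutation(config.n_genes)
    winter_idx = order[:n_w]
    summer_idx = order[n_w : n_w + n_s]
    bias = np.array(["none"] * config.n_genes, dtype=object)
    bias[winter_idx] = "winter"
    bias[summer_idx] = "summer"

    # core genes: half from each biased pool (winter gets any remainder)
    n_core_w = min(config.n_core - config.n_core // 2, n_w)
    n_core_s = min(config.n_core - n_core_w, n_s)
    core_idx = np.concatenate(
        [winter_idx[:n_core_w], summer_idx[:n_core_s]]
    ).astype(int)
    core = np.zeros(config.n_genes, dtype=bool)
    core[core_idx] = True

    # interface genes: half winter-up, half summer-up, all core
    n_if_w = min(config.n_interface - config.n_interface // 2, n_core_w)
    n_if_s = min(config.n_interface - n_if_w, n_core_s)
    interface_idx = np.concatenate(
        [winter_idx[:n_if_w], summer_idx[:n_if_s]]
    ).astype(int)
    interface = np.zeros(config.n_genes, dtype=bool)
    interface[interface_idx] = True

    # immune genes: all core plus a random draw of the rest
    immune = core.copy()
    pool = np.flatnonzero(~core)
    extra = rng.choice(pool, size=config.n_immune - core.sum(), replace=False)
    immune[extra] = True

    # organismal modules drawn from unbiased, non-immune genes
    module = np.array(["none"] * config.n_genes, dtype=object)
    module[winter_idx] = "winter"
    module[summer_idx] = "summer"
    org_pool = np.flatnonzero((bias == "none") & ~immune)
    org_names = []
    for k in range(config.n_organismal_sets):
        name = ("growth", "metabolism", "stress")[k] if k < 3 else f"org{k+1}"
        org_names.append(name)
        pick = rng.choice(
            org_pool, size=config.organismal_set_size, replace=False
        )
        module[pick] = name
        org_pool = np.setdiff1d(org_pool, pick)

    # housekeeping-like stable genes: unbiased, low-noise, no covariate
    # effects, drawn with a floor on baseline so they stay well-expressed
    stable = np.zeros(config.n_genes, dtype=bool)
    if config.n_stable > 0:
        pick = rng.choice(
            org_pool, size=min(config.n_stable, org_pool.size), replace=False
        )
        stable[pick] = True
        module[pick] = "stable"

    # --- per-gene effects --------------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    baseline[stable] = np.maximum(baseline[stable], np.log2(20.0))
    site_off = rng.normal(
        0.0, config.site_effect_sd, (config.n_genes, len(config.sites))
    )
    sex_off = rng.normal(0.0, config.sex_effect_sd, config.n_genes)
    slope = rng.normal(0.0, config.length_slope, config.n_genes)
    site_off[stable] = 0.0
    sex_off[stable] = 0.0
    slope[stable] = 0.0
    direction = np.where(bias == "winter", 1.0, np.where(bias == "summer", -1.0, 0.0))

    # --- latent factors ----------------------------------------------------
    factor_names = ["winter", "summer"] + org_names
    F = rng.standard_normal((n_samp, len(factor_names)))
    rho = config.factor_loading
    if rho > 0 and config.noise_sd > 0:
        load_sd = config.noise_sd * rho / math.sqrt(1.0 - rho * rho)
    else:
        load_sd = 0.0
    loadings = np.zeros((config.n_genes, len(factor_names)))
    col = {name: j for j, name in enumerate(factor_names)}
    for g in range(config.n_genes):
        if interface[g]:
            # interface genes stay fully coupled to their own programme
            # (high within-set connectivity) and additionally couple,
            # negatively, to the opposite programme's residual variation
            # (so residual and seasonal-mean covariance reinforce rather
            # than cancel across the interface)
            own, opp = ("winter", "summer") if bias[g] == "winter" else ("summer", "winter")
            loadings[g, col[own]] = load_sd
            loadings[g, col[opp]] = -load_sd
        elif module[g] in col:
            loadings[g, col[module[g]]] = load_sd

    # --- assemble log2 matrix ----------------------------------------------
    is_winter = (samples["season"] == "winter").to_numpy(float)
    is_male = (samples["sex"] == "M").to_numpy(float)
    site_col = np.array(
        [list(config.sites).index(s) for s in samples["site"]], dtype=int
    )
    length_c = samples["length_mm"].to_numpy() - samples["length_mm"].mean()

    log2x = (
        baseline[:, None]
        + config.effect_size_log2 * direction[:, None] * is_winter[None, :]
        + site_off[:, site_col]
        + sex_off[:, None] * is_male[None, :]
        + slope[:, None] * length_c[None, :]
        + loadings @ F.T
        + rng.normal(0.0, 1.0, (config.n_genes, n_samp))
        * np.where(stable, config.stable_noise_sd, config.noise_sd)[:, None]
    )
    matrix = np.exp2(log2x)
    if config.dropout_prob > 0:
        drop = rng.random(matrix.shape) < config.dropout_prob
        matrix[drop] = 0.0

    genes = default_gene_annotation(gene_ids)
    genes["immune_flag"] = immune
    genes["core_flag"] = core
    genes["hub_flag"] = core  # core genes serve as network hubs
    study = ExpressionStudy(
        pd.DataFrame(matrix, index=gene_ids, columns=samples.index),
        samples,
        genes,
    )

    truth_table = pd.DataFrame(
        {
            "bias": bias,
            "interface_flag": interface,
            "module": module,
            "immune_flag": immune,
            "core_flag": core,
            "hub_flag": core,
        },
        index=gene_ids,
    )
    factors = pd.DataFrame(
        F, index=samples.index, columns=[f"F_{n}" for n in factor_names]
    )
    return study, GroundTruth(truth_table, factors, config)


def generate_null_matrix(
    n_genes: int,
    n_per_cell: int,
    sites: int | Sequence[str] = 2,
    seed: int = 0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
) -> ExpressionStudy:
    """Pure-noise study: i.i.d. Gaussian log2 expression, no effects at all.

    Suitable for estimating the false-positive rate of the seasonal-bias
    classifier.  Every gene's implied ground-truth label is "none".
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    site_labels = (
        tuple(f"site{i + 1}" for i in range(sites))
        if isinstance(sites, int)
        else tuple(sites)
    )
    cfg = SynConfig(
        n_genes=n_genes,
        n_per_cell=n_per_cell,
        sites=site_labels,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    samples = _sample_frame(cfg, rng)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    log2x = rng.normal(baseline_mean, baseline_sd, (n_genes, len(samples)))
    return ExpressionStudy(
        pd.DataFrame(np.exp2(log2x), index=gene_ids, columns=samples.index),
        samples,
        default_gene_annotation(gene_ids),
    )


def write_truth_tsv(truth: GroundTruth, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index_label="gene")


def planted_gene_sets(truth: GroundTruth, use_orthologues: bool = False) -> dict[str, list[str]]:
    """Planted modules as a gene-set collection (GMT-compatible dict)."""
    t = truth.table
    sets = {
        "winter_biased": list(t.index[t["bias"] == "winter"]),
        "summer_biased": list(t.index[t["bias"] == "summer"]),
        "core_immune": list(t.index[t["core_flag"]]),
        "interface": list(t.index[t["interface_flag"]]),
    }
    for name in sorted(set(t["module"]) - {"none", "winter", "summer"}):
        sets[f"organismal_{name}"] = list(t.index[t["module"] == name])
    if use_orthologues:
        sets = {k: [g.upper() for g in v] for k, v in sets.items()}
    return sets
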