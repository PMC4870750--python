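"""qPCR-side computations: endogenous-control screening, model-based
reference-gene stability (NormFinder-style) and relative expression.

Reference-gene candidates are screened from the RNAseq matrix by four
rules: no seasonal bias at either site, overall coefficient of variation
below 12 %, detectable expression in every sample, and mean FPKM above 5.
Stability then decomposes log expression into gene, group and gene x group
components; a gene's stability value combines the magnitude of its
intergroup deviation with the standard error contributed by its intragroup
variance, and the optimal control pair minimises the pair-combined
stability, preferring genes whose intergroup deviations cancel.

Relative expression follows the ddCt convention with an assumed doubling
per cycle: dCt = Ct_target - mean(Ct_controls), ddCt indexed to the
calibrator sample, RE = 2^-ddCt.  A second mode returns the per-gene
calibrator-referenced difference dCt^calibrator = Ct_calibrator - Ct_sample
(no control normalisation), the quantity used for between-tissue
comparisons where invariant controls are unrealistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import ExpressionStudy

__all__ = [
    "screen_control_candidates",
    "StabilityResult",
    "stability_rank",
    "relative_expression",
    "read_ct_csv",
]


def screen_control_candidates(
    study: ExpressionStudy,
    bias_table: pd.DataFrame,
    cv_max: float = 0.12,
    min_mean_fpkm: float = 5.0,
) -> tuple[list[str], pd.DataFrame]:
    """Candidate endogenous-control genes with a per-filter audit trail.

    Filters (all must pass): seasonal-bias class "none", coefficient of
    variation (SD/mean on the linear FPKM scale) < ``cv_max``, detectable
    (non-zero) expression in every sample, mean FPKM > ``min_mean_fpkm``.
    """
    missing = study.matrix.index.difference(bias_table.index)
    if len(missing):
        raise ValueError(
            f"bias table does not cover the gene universe ({len(missing)} missing)"
        )
    X = study.matrix.to_numpy()
    mean = X.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, X.std(axis=1, ddof=1) / mean, np.inf)
    audit = pd.DataFrame(
        {
            "pass_no_bias": (
                bias_table.loc[study.matrix.index, "class"] == "none"
            ).to_numpy(),
            "pass_cv": cv < cv_max,
            "pass_detected": (X > 0).all(axis=1),
            "pass_mean": mean > min_mean_fpkm,
            "cv": cv,
            "mean_fpkm": mean,
        },
        index=study.matrix.index,
    )
    audit["pass_all"] = audit[
        ["pass_no_bias", "pass_cv", "pass_detected", "pass_mean"]
    ].all(axis=1)
    candidates = list(audit.index[audit["pass_all"]])
    if not candidates:
        warnings.warn("no endogenous-control candidates passed", stacklevel=2)
    return candidates, audit


@dataclass
class StabilityResult:
    table: pd.DataFrame            # per gene: intergroup, se, stability, rank
    best_pair: tuple[str, str]
    best_pair_stability: float
    pair_table: pd.DataFrame       # all pairs with combined stability


def stability_rank(
    expr_subset: pd.DataFrame, group_labels: pd.Series | np.ndarray
) -> StabilityResult:
    """Model-based reference-gene stability over candidate genes.

    ``expr_subset`` is genes x samples (linear scale; log2 is taken
    internally with a pseudocount of 1).  For each gene, log expression
    decomposes into an overall gene level plus group-specific deviations;
    the intergroup deviation is the departure of the gene's group means
    from its own average (so a gene constant across samples scores
    exactly zero), and

        stability = |intergroup deviation| + SE(intragroup)

    The best pair minimises |mean pair deviation| + pooled SE over all
    gene pairs, which automatically prefers opposite-sign deviations.
    """
    groups = np.asarray(group_labels)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if expr_subset.shape[0] < 3:
        raise ValueError("need at least 3 candidate genes")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    L = np.log2(expr_subset.to_numpy(float) + 1.0)
    genes = list(expr_subset.index)
    n_g = len(genes)

    group_means = np.column_stack([L[:, groups == lv].mean(axis=1) for lv in levels])
    intra_var = np.column_stack(
        [L[:, groups == lv].var(axis=1, ddof=1) for lv in levels]
    )
    n_per = np.array([(groups == lv).sum() for lv in levels])

    # per-gene departure of group means from the gene's own average
    d = group_means - group_means.mean(axis=1, keepdims=True)
    inter = d[:, 0] if len(levels) == 2 else np.sqrt((d**2).mean(axis=1))
    se = np.sqrt((intra_var / n_per[None, :]).mean(axis=1))
    stability = np.abs(inter) + se

    table = pd.DataFrame(
        {"intergroup": inter, "se": se, "stability": stability},
        index=pd.Index(genes, name="gene"),
    )
    table["rank"] = table["stability"].rank(method="first").astype(int)
    table = table.sort_values(["stability", "rank"])

    pair_rows = []
    for i, j in itertools.combinations(range(n_g), 2):
        pair_dev = abs((inter[i] + inter[j]) / 2.0)
        pair_se = np.sqrt(se[i] ** 2 + se[j] ** 2) / 2.0
        pair_rows.append((genes[i], genes[j], pair_dev + pair_se))
    pair_table = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "stability"]
    ).sort_values(["stability", "gene_a", "gene_b"]).reset_index(drop=True)
    best = pair_table.iloc[0]
    return StabilityResult(
        table,
        (best["gene_a"], best["gene_b"]),
        float(best["stability"]),
        pair_table,
    )


def read_ct_csv(path: str) -> pd.DataFrame:
    """Long-format Ct table: columns sample, gene, well, Ct, role."""
    ct = pd.read_csv(path)
    required = {"sample", "gene", "Ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if "role" not in ct.columns:
        ct["role"] = "unknown"
    return ct


def _ct_means(ct: pd.DataFrame) -> pd.DataFrame:
    """Replicate wells averaged: one mean Ct per sample x gene."""
    if (ct["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct.groupby(["sample", "gene"])["Ct"].mean().unstack()  # samples x genes


def relative_expression(
    ct: pd.DataFrame,
    targets: list[str],
    controls: list[str] | None = None,
    mode: str = "ddct",
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Relative expression (mode "ddct") or dCt^calibrator (mode "dct_cal").

    The calibrator sample is taken from the ``role`` column (value
    "calibrator") unless named explicitly; it must be unique.  Samples
    with a missing Ct for a required gene are excluded from that gene's
    output (flagged by NaN).
    """
    wide = _ct_means(ct)
    if calibrator is None:
        cal_rows = ct.loc[ct.get("role", "") == "calibrator", "sample"].unique()
        if len(cal_rows) != 1:
            raise ValueError(
                f"expected exactly one calibrator sample, found {len(cal_rows)}"
            )
        calibrator = cal_rows[0]
    if calibrator not in wide.index:
        raise ValueError(f"calibrator sample {calibrator!r} has no Ct rows")
    missing_t = [g for g in targets if g not in wide.columns]
    if missing_t:
        raise ValueError(f"target genes without Ct data: {missing_t}")

    if mode == "dct_cal":
        out = wide[targets].rsub(wide.loc[calibrator, targets], axis=1)
        out.columns = [f"dCt_cal_{g}" for g in targets]
        return out
    if mode != "ddct":
        raise ValueError(f"unknown mode: {mode!r}")

    if not controls:
        raise ValueError("ddct mode requires control genes")
    missing_c = [g for g in controls if g not in wide.columns]
    if missing_c:
        raise ValueError(f"control genes without Ct data: {missing_c}")
    # arithmetic mean of control Ct = geometric mean of control quantities
    ctrl = wide[controls].mean(axis=1)
    out = {}
    for g in targets:
        dct = wide[g] - ctrl
        ddct = dct - (wide.loc[calibrator, g] - ctrl.loc[calibrator])
        out[f"RE_{g}"] = np.power(2.0, -ddct)
    return pd.DataFrame(out, index=wide.index)
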