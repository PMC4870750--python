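"""Expression filtering, per-site differential expression and the
cross-site seasonal-bias classifier, plus confounder-adjusted per-gene
linear models and effect-size ranking metrics.

The pipeline starts from an FPKM-scale matrix, so the per-site winter vs
summer test is a Welch two-sample t-test on log2(FPKM + pseudocount) - a
deliberate substitution for read-level negative-binomial testing that
preserves the decision rule (per-site p value and direction of change).
A gene is called seasonally biased only when it is significant, in the same
direction, at *both* sites at the individual error rate; with two-sided
per-site tests at alpha this bounds the per-gene null rate by alpha^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "filter_low_expression",
    "per_site_de",
    "classify_seasonal_bias",
    "fit_gene_lms",
    "ranking_metric",
]


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_low_mean: int
    n_undetected: int


def filter_low_expression(
    study: ExpressionStudy,
    mean_min: float = 0.5,
    max_undetected_frac: float = 0.5,
) -> tuple[ExpressionStudy, FilterReport]:
    """Drop genes with mean FPKM < ``mean_min`` or with more than
    ``max_undetected_frac`` of samples undetectable (expression exactly 0).

    Returns the restricted study and a report of counts removed per rule.
    An empty result is allowed (with a warning), not an error.
    """
    X = study.matrix.to_numpy()
    mean_ok = X.mean(axis=1) >= mean_min
    det_ok = (X == 0).mean(axis=1) <= max_undetected_frac
    keep = mean_ok & det_ok
    report = FilterReport(
        n_input=study.n_genes,
        n_kept=int(keep.sum()),
        n_low_mean=int((~mean_ok).sum()),
        n_undetected=int((~det_ok).sum()),
    )
    if report.n_kept == 0:
        warnings.warn("expression filter removed every gene", stacklevel=2)
    kept_ids = study.matrix.index[keep]
    return study.subset_genes(kept_ids), report


def _welch(
    w: np.ndarray, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test over gene rows; returns (t, p).

    Degenerate rows (zero variance in both groups) get p = 1 when the
    means agree and p = 0 when they differ, by convention.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(w, s, axis=1, equal_var=False)
    diff = w.mean(axis=1) - s.mean(axis=1)
    degen = (w.var(axis=1) == 0) & (s.var(axis=1) == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degen, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
        p = np.where(degen, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def per_site_de(
    study: ExpressionStudy, site: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Winter vs summer differential expression within one site.

    Welch two-sample t-test on log2(FPKM + pseudocount); log2FC is the
    winter mean minus the summer mean (positive = winter-up).  A BH false
    discovery rate column ``q`` is reported for context; the cross-site
    classifier uses the individual error rate.
    """
    sub = study.site_study(site)
    seasons = sub.samples["season"]
    n_w = int((seasons == "winter").sum())
    n_s = int((seasons == "summer").sum())
    if n_w < 2 or n_s < 2:
        raise ValueError(
            f"site {site!r} needs >= 2 samples per season (got {n_w}/{n_s})"
        )
    L = sub.log2(pseudocount).to_numpy()
    w = L[:, (seasons == "winter").to_numpy()]
    s = L[:, (seasons == "summer").to_numpy()]
    t, p = _welch(w, s)
    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0))
    return pd.DataFrame(
        {
            "mean_winter": w.mean(axis=1),
            "mean_summer": s.mean(axis=1),
            "log2fc": w.mean(axis=1) - s.mean(axis=1),
            "t": t,
            "p": p,
            "q": q,
        },
        index=sub.matrix.index,
    )


def classify_seasonal_bias(
    de_site_a: pd.DataFrame,
    de_site_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-site consistency classifier.

    ``winter`` if log2FC > 0 at both sites with both p < alpha; ``summer``
    if log2FC < 0 at both with both p < alpha; otherwise ``none``.  The
    returned table carries both sites' p and log2FC through and is
    symmetric in the order of the two inputs.
    """
    if not de_site_a.index.equals(de_site_b.index):
        if set(de_site_a.index) != set(de_site_b.index):
            raise ValueError("DE tables cover different gene universes")
        de_site_b = de_site_b.loc[de_site_a.index]
    sig = (de_site_a["p"] < alpha) & (de_site_b["p"] < alpha)
    both_up = (de_site_a["log2fc"] > 0) & (de_site_b["log2fc"] > 0)
    both_down = (de_site_a["log2fc"] < 0) & (de_site_b["log2fc"] < 0)
    cls = np.where(
        sig & both_up, "winter", np.where(sig & both_down, "summer", "none")
    )
    out = pd.DataFrame(
        {
            "class": cls,
            "p_a": de_site_a["p"],
            "p_b": de_site_b["p"],
            "log2fc_a": de_site_a["log2fc"],
            "log2fc_b": de_site_b["log2fc"],
        },
        index=de_site_a.index,
    )
    n_w = int((cls == "winter").sum())
    n_s = int((cls == "summer").sum())
    log.info("seasonal-bias classes: %d winter, %d summer", n_w, n_s)
    out.attrs["n_winter"] = n_w
    out.attrs["n_summer"] = n_s
    return out


# ---------------------------------------------------------------------------
# per-gene linear models
# ---------------------------------------------------------------------------

def _design(
    samples: pd.DataFrame,
    terms: tuple[str, ...],
    interactions_with_season: bool,
) -> tuple[np.ndarray, list[str]]:
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    base: dict[str, np.ndarray] = {}
    for t in terms:
        if t == "season":
            base[t] = (samples["season"] == "winter").to_numpy(float)
        elif t == "sex":
            base[t] = (samples["sex"] == "M").to_numpy(float)
        elif t == "site":
            lv = sorted(samples["site"].unique())
            if len(lv) > 2:
                raise ValueError("site terms support two levels")
            base[t] = (samples["site"] == lv[-1]).to_numpy(float)
        elif t == "length":
            x = samples["length_mm"].to_numpy(float)
            base[t] = x - x.mean()
        else:
            raise ValueError(f"unknown model term: {t}")
        cols.append(base[t])
        names.append(t)
    if interactions_with_season:
        for t in terms:
            if t == "season":
                continue
            cols.append(base["season"] * base[t])
            names.append(f"season:{t}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: some model terms are confounded "
            f"(terms={names})"
        )
    return X, names


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits of every column of Y on X."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)


def fit_gene_lms(
    study: ExpressionStudy,
    terms: tuple[str, ...] = ("season", "length", "sex", "site"),
    interactions_with_season: bool = False,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS of log2 expression on the design terms, fitted to every gene.

    For each gene and term the table reports the marginal (type II)
    F statistic, the effect size eta^2 = SS_term / SS_total, the sign of
    the fitted coefficient and F / F_crit(alpha = 0.05).  Main-effect
    statistics always come from the main-effects-only model; when
    ``interactions_with_season`` is set, season x term interactions are
    added and assessed by drop-one comparisons against the full model.

    Returns ``(per_gene, summary)`` where ``summary`` aggregates the mean
    F (with SE) per term across genes.
    """
    for col in ("season", "sex", "site", "length_mm"):
        if study.samples[col].isna().any():
            raise ValueError(f"sample metadata column {col!r} has missing values")
    Y = study.log2(pseudocount).to_numpy().T  # samples x genes
    Y = Y - Y.mean(axis=0)
    ss_total = np.einsum("ij,ij->j", Y, Y)
    ss_total = np.where(ss_total == 0, np.nan, ss_total)
    n = Y.shape[0]

    X_main, names_main = _design(study.samples, terms, False)
    X_full, names_full = (
        _design(study.samples, terms, True)
        if interactions_with_season
        else (X_main, names_main)
    )
    rss_full = _rss(X_full, Y)
    rss_main = _rss(X_main, Y) if interactions_with_season else rss_full
    df_res_full = n - X_full.shape[1]
    df_res_main = n - X_main.shape[1]

    beta_full, *_ = np.linalg.lstsq(X_full, Y, rcond=None)

    records = []
    for term in names_full[1:]:
        if term in names_main:
            Xr = X_main[:, [i for i, nm in enumerate(names_main) if nm != term]]
            delta = _rss(Xr, Y) - rss_main
            df_res = df_res_main
            rss_ref = rss_main
        else:  # interaction term: drop-one from the full model
            Xr = X_full[:, [i for i, nm in enumerate(names_full) if nm != term]]
            delta = _rss(Xr, Y) - rss_full
            df_res = df_res_full
            rss_ref = rss_full
        delta = np.clip(delta, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = delta / (rss_ref / df_res)
            eta2 = delta / ss_total
        # perfect fits: zero residual makes F infinite for contributing
        # terms and zero for the rest
        perfect = rss_ref <= 1e-12 * np.nan_to_num(ss_total, nan=1.0)
        F = np.where(
            perfect, np.where(delta > 1e-12 * np.nan_to_num(ss_total, nan=1.0),
                              np.inf, 0.0), F
        )
        eta2 = np.nan_to_num(np.clip(eta2, 0.0, 1.0))
        f_crit = stats.f.ppf(0.95, 1, df_res)
        sign = np.sign(beta_full[names_full.index(term)])
        for j, gene in enumerate(study.matrix.index):
            records.append(
                (gene, term, F[j], eta2[j], sign[j], F[j] / f_crit)
            )
    per_gene = pd.DataFrame.from_records(
        records, columns=["gene", "term", "F", "eta2", "coef_sign", "F_ratio"]
    )
    grp = per_gene.replace([np.inf, -np.inf], np.nan).groupby("term")["F"]
    summary = pd.DataFrame(
        {"mean_F": grp.mean(), "se_F": grp.sem(), "n_genes": grp.count()}
    )
    return per_gene, summary


def ranking_metric(
    source: pd.DataFrame,
    mode: str,
    term: str = "season",
) -> pd.Series:
    """Ranked gene list used by preranked enrichment.

    mode ``"fold"``: rank by a DE table's per-site log2 fold change.
    mode ``"adjusted"``: rank by sign(coefficient) * eta^2 for ``term`` of a
    per-gene LM table.  Ties break deterministically by gene identifier.
    """
    if mode == "fold":
        metric = source["log2fc"].copy()
    elif mode == "adjusted":
        sub = source[source["term"] == term]
        if sub.empty:
            raise ValueError(f"term {term!r} absent from LM table")
        metric = pd.Series(
            (sub["coef_sign"] * sub["eta2"]).to_numpy(), index=sub["gene"]
        )
    else:
        raise ValueError(f"unknown ranking mode: {mode!r}")
    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    return metric.loc[order]
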