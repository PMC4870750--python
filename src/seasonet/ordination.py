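"""Sample ordination (PCO), gene-set principal-component scores and the
three-variable path / mediation model for interface genes.

PCO here is classical scaling of Euclidean distances between samples in
log2 expression space, which for a Euclidean metric is equivalent to PCA
of the sample covariance structure.  PC1 scores summarise a gene set's
major axis of covariation via a correlation-matrix PCA, with the score
sign fixed so it correlates positively with the set's mean expression.

The mediation model asks whether an interface gene G carries the
association between the winter programme W and the summer programme S:
standardized OLS fits of S ~ W + G and G ~ W, a Sobel test for the
indirect path, and a "negation" flag raised when the univariate W -> S
association is significant but the direct effect is not once G enters the
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa

from .study import ExpressionStudy

__all__ = [
    "OrdinationResult",
    "pco_ordination",
    "pc1_scores",
    "PathFit",
    "path_mediation",
]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame       # samples x axes
    eigenvalues: np.ndarray    # non-increasing
    axis_tests: pd.DataFrame   # per axis: group p values and length corr


def pco_ordination(
    study: ExpressionStudy,
    gene_subset=None,
    k: int = 3,
    pseudocount: float = 1.0,
) -> OrdinationResult:
    """Principal co-ordinates analysis of samples.

    Euclidean distances between samples on log2 expression of the chosen
    genes, classical scaling via double-centering, and per-axis tests:
    two-sample t-tests on the axis scores for season, site and sex, plus a
    Pearson correlation with body length.
    """
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = study.subset_genes(gene_subset) if gene_subset is not None else study
    L = sub.log2(pseudocount).to_numpy().T  # samples x genes
    dm = DistanceMatrix(
        squareform(pdist(L, metric="euclidean")), ids=list(sub.samples.index)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        ord_res = pcoa(dm, number_of_dimensions=0)
    eig = ord_res.eigvals.to_numpy()
    n_pos = int((eig > 1e-9 * max(eig.max(), 1.0)).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    scores = ord_res.samples.iloc[:, :k].copy()
    scores.columns = [f"PCO{i + 1}" for i in range(k)]
    scores.index = sub.samples.index

    meta = sub.samples
    rows = []
    for i in range(k):
        ax = scores.iloc[:, i].to_numpy()
        row = {"axis": f"PCO{i + 1}"}
        for factor, positive in (("season", "winter"), ("sex", "M")):
            g1 = ax[(meta[factor] == positive).to_numpy()]
            g2 = ax[(meta[factor] != positive).to_numpy()]
            row[f"p_{factor}"] = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
        sites = sorted(meta["site"].unique())
        if len(sites) == 2:
            g1 = ax[(meta["site"] == sites[0]).to_numpy()]
            g2 = ax[(meta["site"] == sites[1]).to_numpy()]
            row["p_site"] = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
        else:
            row["p_site"] = np.nan
        r, p = stats.pearsonr(ax, meta["length_mm"].to_numpy())
        row["r_length"] = float(r)
        row["p_length"] = float(p)
        rows.append(row)
    axis_tests = pd.DataFrame(rows).set_index("axis")
    return OrdinationResult(scores, eig[:k], axis_tests)


def pc1_scores(
    study: ExpressionStudy, gene_subset, pseudocount: float = 1.0
) -> tuple[pd.Series, float]:
    """First principal component of the gene-gene correlation matrix.

    Returns per-sample scores (sign fixed to correlate positively with the
    subset's mean expression) and the fraction of variance PC1 explains.
    Constant genes are dropped with a warning.
    """
    sub = study.subset_genes(gene_subset)
    L = sub.log2(pseudocount).to_numpy()  # genes x samples
    sd = L.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"dropping {int((sd == 0).sum())} constant gene(s) from PC1",
            stacklevel=2,
        )
        L = L[sd > 0]
        sd = sd[sd > 0]
    if L.shape[0] < 2:
        raise ValueError("need at least 2 non-constant genes for PC1")
    Z = (L - L.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = np.corrcoef(Z)
    w, V = np.linalg.eigh(corr)
    v1 = V[:, -1]
    score = v1 @ Z
    mean_expr = L.mean(axis=0)
    if np.corrcoef(score, mean_expr)[0, 1] < 0:
        score = -score
    explained = float(w[-1] / w.sum())
    return pd.Series(score, index=sub.samples.index, name="PC1"), explained


# ---------------------------------------------------------------------------
# path / mediation model
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS with intercept prepended; returns (beta, se, p) for the slopes."""
    n = y.size
    X1 = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    df = n - X1.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X1.T @ X1)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta[1:], se[1:], p[1:]


def _standardize(v, name: str) -> np.ndarray:
    x = np.asarray(v, float).ravel()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name} is constant")
    return (x - x.mean()) / sd


@dataclass
class PathFit:
    """Standardized three-variable path model W -> G -> S with direct W -> S."""

    a: float                 # W -> G
    a_se: float
    a_p: float
    b: float                 # G -> S (given W)
    b_se: float
    b_p: float
    direct: float            # W -> S given G
    direct_se: float
    direct_p: float
    univariate: float        # W -> S alone
    univariate_se: float
    univariate_p: float
    sobel_z: float
    sobel_p: float
    negation: bool
    n: int
    small_sample: bool = False


def path_mediation(
    w_scores, s_scores, g_expression, alpha: float = 0.05
) -> PathFit:
    """Fit the three-variable path model for one interface gene.

    All variables are standardized before fitting.  The Sobel statistic is
    z = a b / sqrt(b^2 SE_a^2 + a^2 SE_b^2); the negation flag is true when
    the univariate W -> S slope is significant at ``alpha`` but the direct
    slope (with G in the model) is not.  Fits at n < 50 carry a
    small-sample caveat flag.
    """
    W = _standardize(w_scores, "W")
    S = _standardize(s_scores, "S")
    Gv = _standardize(g_expression, "G")
    if not (W.size == S.size == Gv.size):
        raise ValueError("W, S and G must have equal length")
    if abs(np.corrcoef(W, Gv)[0, 1]) > 0.999:
        raise ValueError("W and G are collinear (|r| > 0.999)")

    (a,), (a_se,), (a_p,) = _ols(Gv, W[:, None])
    (c,), (c_se,), (c_p,) = _ols(S, W[:, None])
    beta, se, p = _ols(S, np.column_stack([W, Gv]))
    direct, b = beta
    direct_se, b_se = se
    direct_p, b_p = p

    denom = np.sqrt(b * b * a_se * a_se + a * a * b_se * b_se)
    sobel_z = 0.0 if denom == 0 else float(a * b / denom)
    sobel_p = float(2.0 * stats.norm.sf(abs(sobel_z)))
    negation = bool(c_p < alpha and direct_p >= alpha)
    return PathFit(
        a=float(a), a_se=float(a_se), a_p=float(a_p),
        b=float(b), b_se=float(b_se), b_p=float(b_p),
        direct=float(direct), direct_se=float(direct_se), direct_p=float(direct_p),
        univariate=float(c), univariate_se=float(c_se), univariate_p=float(c_p),
        sobel_z=sobel_z, sobel_p=sobel_p, negation=negation,
        n=int(W.size), small_sample=bool(W.size < 50),
    )
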