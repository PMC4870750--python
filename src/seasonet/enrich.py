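"""Preranked gene-set enrichment, cross-site p-value combination and
set-overlap statistics.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranked list, hits increment the sum in proportion to
|metric|^weight (normalised over the set) and misses decrement it by
1/(N - N_set); the ES is the running sum's maximum deviation from zero.
Significance uses gene-tag permutations (random same-size sets drawn from
the ranked list), the appropriate null for a preranked analysis at small
sample size.

Per-site results are combined across the two localities with Fisher's
method.  Combining FDR-adjusted p values this way is statistically
unorthodox; it is provided because it mirrors the upstream analysis
convention, and combination of nominal p values is reported alongside as a
labelled alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "gsea_preranked",
    "fisher_combine",
    "combine_sites",
    "overlap_test",
    "OverlapResult",
]


# ---------------------------------------------------------------------------
# GMT IO
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file (name <TAB> description <TAB> members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name: {parts[0]}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(
    metric: pd.Series | np.ndarray,
    hit_mask: np.ndarray,
    weight: float = 1.0,
) -> float:
    """ES of one gene set along an already-ranked list.

    ``metric`` holds the ranking metric in list order (best to worst);
    ``hit_mask`` is a boolean membership vector of the same length.
    """
    r = np.abs(np.asarray(metric, float)) ** weight
    hit_mask = np.asarray(hit_mask, bool)
    n = r.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset")
    hit_w = np.where(hit_mask, r, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all member metrics are exactly zero: fall back to equal weights
        hit_w = hit_mask.astype(float)
        denom = float(n_hit)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit_mask) / (n - n_hit)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def _ranked_series(ranked: pd.Series) -> pd.Series:
    metric = ranked.astype(float)
    if metric.index.has_duplicates:
        raise ValueError("ranked list has duplicate genes")
    if not np.isfinite(metric.to_numpy()).all():
        raise ValueError("ranking metric contains non-finite values")
    if metric.nunique() == 1:
        raise ValueError("degenerate ranking: all metric values are equal")
    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    return metric.loc[order]


def gsea_preranked(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment over a collection of sets.

    The ranked list is (re)sorted by metric descending with deterministic
    gene-identifier tie-break.  For every set restricted to genes present:
    ES as above; NES = ES normalised by the mean same-sign permutation ES;
    nominal p from gene-tag permutations; BH FDR ``q`` across the reported
    sets.  Fully deterministic for a fixed seed.
    """
    metric = _ranked_series(ranked)
    genes = metric.index.to_numpy()
    pos = {g: i for i, g in enumerate(genes)}
    r = metric.to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    perms_by_size: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if len(idx) < min_size or len(idx) > max_size:
            log.info(
                "skipping set %s: %d genes after restriction", name, len(idx)
            )
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        es = enrichment_score(r, mask, weight)

        size = len(idx)
        if size not in perms_by_size:
            null = np.empty(n_perm)
            for b in range(n_perm):
                pmask = np.zeros(len(genes), dtype=bool)
                pmask[rng.choice(len(genes), size=size, replace=False)] = True
                null[b] = enrichment_score(r, pmask, weight)
            perms_by_size[size] = null
        null = perms_by_size[size]

        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
            nes = es / np.abs(same).mean()
        rows.append((name, size, es, nes, p))

    out = pd.DataFrame(
        rows, columns=["set", "size", "ES", "NES", "p"]
    ).set_index("set")
    if len(out):
        out["q"] = stats.false_discovery_control(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Fisher combination and cross-site results
# ---------------------------------------------------------------------------

def fisher_combine(p_values) -> float:
    """Fisher's method: X^2 = -2 sum(ln p), upper chi-square tail on 2k df."""
    p = np.asarray(list(np.atleast_1d(p_values)), dtype=float)
    if p.size == 0:
        raise ValueError("no p values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def combine_sites(
    result_a: pd.DataFrame,
    result_b: pd.DataFrame,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Merge two per-site enrichment tables and Fisher-combine p values.

    ``p_combined`` combines the per-site FDR q values (the upstream
    convention); ``p_combined_nominal`` combines the nominal p values and
    is the statistically conventional alternative.
    """
    merged = result_a.join(
        result_b, how="inner", lsuffix=suffixes[0], rsuffix=suffixes[1]
    )
    qa, qb = f"q{suffixes[0]}", f"q{suffixes[1]}"
    pa, pb = f"p{suffixes[0]}", f"p{suffixes[1]}"
    merged["p_combined"] = [
        fisher_combine([row[qa], row[qb]]) for _, row in merged.iterrows()
    ]
    merged["p_combined_nominal"] = [
        fisher_combine([row[pa], row[pb]]) for _, row in merged.iterrows()
    ]
    return merged


# ---------------------------------------------------------------------------
# set overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p: float          # one-sided hypergeometric enrichment P(X >= overlap)
    odds_ratio: float
    jaccard: float


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Hypergeometric enrichment test, odds ratio and Jaccard index.

    The odds ratio comes from the 2x2 membership table with a Haldane 0.5
    correction when any cell is zero.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a = set(set_a) & u
    b = set(set_b) & u
    k = len(a & b)
    # P(X >= k), X ~ Hypergeom(|U|, |A|, |B|)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    t11 = k
    t12 = len(a) - k
    t21 = len(b) - k
    t22 = len(u) - len(a) - len(b) + k
    cells = np.array([t11, t12, t21, t22], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    union = len(a | b)
    jac = k / union if union else 0.0
    return OverlapResult(len(u), len(a), len(b), k, min(p, 1.0), odds, jac)
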