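"""Filtering, per-site Welch DE, the cross-site bias classifier and
per-gene linear models, checked against independent statistics oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seasonet import de
from seasonet.syndata import SynConfig, generate_study, generate_null_matrix

from conftest import make_study, two_group_samples


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def test_filter_rules():
    samples = two_group_samples(5)
    M = np.full((3, 10), 5.0)
    M[0] = 0.4                       # low mean -> removed
    M[1, :6] = 0.0                   # 6/10 undetected -> removed
    M[1, 6:] = 7.5                   # mean 3.0 but 60% zeros
    study = make_study(M, samples)
    kept, report = de.filter_low_expression(study)
    assert list(kept.matrix.index) == ["g002"]
    assert report.n_low_mean == 1 and report.n_undetected == 1
    # identity case
    ident, rep2 = de.filter_low_expression(make_study(np.full((4, 10), 2.0), samples))
    assert ident.n_genes == 4 and rep2.n_kept == 4


def test_filter_empty_result_warns_not_raises():
    study = make_study(np.full((2, 10), 0.1), two_group_samples(5))
    with pytest.warns(UserWarning):
        kept, _ = de.filter_low_expression(study)
    assert kept.n_genes == 0


# ---------------------------------------------------------------------------
# per-site Welch test
# ---------------------------------------------------------------------------

def _welch_oracle(a, b):
    """Hand-rolled Welch t and p (Satterthwaite df) for one gene."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def test_per_site_de_matches_welch_oracle():
    rng = np.random.default_rng(1)
    samples = two_group_samples(9)
    M = 2.0 ** rng.normal(5, 1, (4, 18))
    study = make_study(M, samples)
    table = de.per_site_de(study, "site1", pseudocount=1.0)
    L = np.log2(M + 1.0)
    winter = (samples["season"] == "winter").to_numpy()
    for i, gene in enumerate(study.matrix.index):
        t, p = _welch_oracle(L[i, winter], L[i, ~winter])
        assert table.loc[gene, "t"] == pytest.approx(t, rel=1e-12)
        assert table.loc[gene, "p"] == pytest.approx(p, rel=1e-9)
        assert table.loc[gene, "log2fc"] == pytest.approx(
            L[i, winter].mean() - L[i, ~winter].mean()
        )


def test_per_site_de_degenerate_and_identity():
    samples = two_group_samples(3)
    M = np.vstack([
        np.full(6, 4.0),                       # constant: p = 1, fc = 0
        np.r_[np.full(3, 8.0), np.full(3, 2.0)],  # constant but shifted
    ])
    study = make_study(M, samples)
    tbl = de.per_site_de(study, "site1")
    assert tbl.iloc[0]["log2fc"] == 0 and tbl.iloc[0]["p"] == 1.0
    assert tbl.iloc[1]["p"] == 0.0 and tbl.iloc[1]["log2fc"] > 0
    with pytest.raises(KeyError):
        de.per_site_de(study, "nowhere")


def test_per_site_de_planted_effect_detected():
    cfg = SynConfig(n_genes=300, effect_size_log2=2.0, noise_sd=0.25,
                    factor_loading=0.0, n_immune=40, n_core=10, n_interface=2,
                    n_stable=0, seed=6)
    study, truth = generate_study(cfg)
    tbl = de.per_site_de(study, "site1")
    winter = truth.table["bias"] == "winter"
    assert (tbl.loc[winter, "p"] < 0.05).mean() > 0.95
    assert tbl.loc[winter, "log2fc"].mean() == pytest.approx(2.0, abs=0.15)


def test_per_site_type_one_error_calibrated():
    study = generate_null_matrix(10_000, n_per_cell=9, sites=1, seed=42)
    tbl = de.per_site_de(study, "site1")
    assert (tbl["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)


# ---------------------------------------------------------------------------
# cross-site classifier
# ---------------------------------------------------------------------------

def _de_frame(ps, fcs):
    genes = [f"g{i}" for i in range(len(ps))]
    return pd.DataFrame({"p": ps, "log2fc": fcs},
                        index=pd.Index(genes, name="gene"))


def test_classifier_rule_cases():
    a = _de_frame([0.01, 0.01, 0.01, 0.2], [+1.0, +1.0, +1.0, -1.0])
    b = _de_frame([0.01, 0.20, 0.01, 0.01], [+0.5, +1.0, -1.0, -1.0])
    out = de.classify_seasonal_bias(a, b)
    assert list(out["class"]) == ["winter", "none", "none", "none"]
    # summer case
    out2 = de.classify_seasonal_bias(
        _de_frame([0.001], [-2.0]), _de_frame([0.04], [-0.1])
    )
    assert out2["class"].iloc[0] == "summer"


def test_classifier_symmetric_in_site_order():
    rng = np.random.default_rng(0)
    a = _de_frame(rng.uniform(0, 0.2, 50), rng.normal(0, 1, 50))
    b = _de_frame(rng.uniform(0, 0.2, 50), rng.normal(0, 1, 50))
    ab = de.classify_seasonal_bias(a, b)
    ba = de.classify_seasonal_bias(b, a)
    assert (ab["class"] == ba["class"]).all()


def test_classifier_rejects_mismatched_universes():
    a = _de_frame([0.01], [1.0])
    b = _de_frame([0.01, 0.5], [1.0, 0.0])
    with pytest.raises(ValueError):
        de.classify_seasonal_bias(a, b)


def test_classifier_sensitivity_monotone_in_effect_size():
    sens = []
    for beta in (0.5, 1.0, 2.0):
        cfg = SynConfig(n_genes=800, effect_size_log2=beta, n_stable=0, seed=13)
        study, truth = generate_study(cfg)
        tables = [de.per_site_de(study, s) for s in study.sites]
        out = de.classify_seasonal_bias(*tables)
        planted = truth.table["bias"] != "none"
        sens.append(
            (out.loc[planted, "class"] == truth.table.loc[planted, "bias"]).mean()
        )
    assert sens[0] <= sens[1] + 0.02 and sens[1] <= sens[2] + 0.02
    assert sens[2] > 0.9


# ---------------------------------------------------------------------------
# per-gene linear models
# ---------------------------------------------------------------------------

def _lm_study(seed=0, n_genes=3):
    cfg = SynConfig(n_genes=max(n_genes, 200), n_immune=30, n_core=10,
                    n_interface=2, n_stable=0, seed=seed)
    study, _ = generate_study(cfg)
    return study.subset_genes(study.matrix.index[:n_genes])


def test_lm_perfect_length_fit():
    # lengths balanced across all factor cells so length is orthogonal to
    # season/sex/site and a perfect fit attributes all variance to length
    rows = []
    for site in ("site1", "site2"):
        for season in ("winter", "summer"):
            for i, (sex, ln) in enumerate(
                [("M", 25.0), ("F", 25.0), ("M", 55.0), ("F", 55.0)]
            ):
                rows.append({"sample": f"{site}_{season}_{i}", "site": site,
                             "season": season, "sex": sex, "length_mm": ln})
    samples = pd.DataFrame(rows).set_index("sample")
    length = samples["length_mm"].to_numpy()
    M = np.vstack([2.0 ** (0.1 * length + 2.0) - 1.0,  # log2(M+1) linear
                   np.full(len(samples), 3.0)])
    study = make_study(M, samples)
    per_gene, _ = de.fit_gene_lms(study)
    g0 = per_gene[per_gene["gene"] == "g000"].set_index("term")
    assert g0.loc["length", "eta2"] == pytest.approx(1.0, abs=1e-9)
    assert g0.loc["season", "eta2"] == pytest.approx(0.0, abs=1e-9)
    assert g0.loc["sex", "eta2"] == pytest.approx(0.0, abs=1e-9)
    assert g0.loc["length", "coef_sign"] == 1.0
    assert np.isinf(g0.loc["length", "F"])


def test_lm_matches_statsmodels_type2_anova():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    study = _lm_study(seed=8, n_genes=4)
    per_gene, _ = de.fit_gene_lms(study)
    L = study.log2(1.0)
    df_res_expected = 36 - 5
    for gene in study.matrix.index:
        data = study.samples.copy()
        data["y"] = L.loc[gene].to_numpy()
        data["length_c"] = data["length_mm"] - data["length_mm"].mean()
        fit = smf.ols("y ~ C(season) + length_c + C(sex) + C(site)", data).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        ss_total = ((data["y"] - data["y"].mean()) ** 2).sum()
        ours = per_gene[per_gene["gene"] == gene].set_index("term")
        for term, key in [("season", "C(season)"), ("length", "length_c"),
                          ("sex", "C(sex)"), ("site", "C(site)")]:
            assert ours.loc[term, "F"] == pytest.approx(an.loc[key, "F"], rel=1e-8)
            assert ours.loc[term, "eta2"] == pytest.approx(
                an.loc[key, "sum_sq"] / ss_total, rel=1e-8
            )
        f_crit = stats.f.ppf(0.95, 1, df_res_expected)
        assert ours["F_ratio"].to_numpy() == pytest.approx(
            ours["F"].to_numpy() / f_crit
        )


def test_lm_null_mean_f_near_expectation():
    study = generate_null_matrix(5000, n_per_cell=9, sites=2, seed=3)
    per_gene, summary = de.fit_gene_lms(study)
    expected = 31.0 / 29.0  # E[F(1, df2)] = df2 / (df2 - 2), df2 = 31
    for term in ("season", "length", "sex", "site"):
        assert summary.loc[term, "mean_F"] == pytest.approx(expected, abs=0.08)


def test_lm_interactions_and_rank_deficiency():
    study = _lm_study(seed=2)
    per_gene, _ = de.fit_gene_lms(study, interactions_with_season=True)
    assert set(per_gene["term"]) == {
        "season", "length", "sex", "site",
        "season:length", "season:sex", "season:site",
    }
    # confounded design: make sex == season
    samples = study.samples.copy()
    samples["sex"] = np.where(samples["season"] == "winter", "M", "F")
    broken = type(study)(study.matrix, samples, study.genes)
    with pytest.raises(ValueError, match="rank-deficient"):
        de.fit_gene_lms(broken)


# ---------------------------------------------------------------------------
# ranking metric
# ---------------------------------------------------------------------------

def test_ranking_modes_and_tie_break():
    lm = pd.DataFrame({
        "gene": ["g1", "g2", "g3"],
        "term": ["season"] * 3,
        "eta2": [0.5, 0.2, 0.2],
        "coef_sign": [1.0, -1.0, -1.0],
    })
    ranked = de.ranking_metric(lm, "adjusted", term="season")
    assert list(ranked.index) == ["g1", "g2", "g3"]  # ties by gene id
    det = pd.DataFrame({"log2fc": [0.5, -1.0, 2.0]},
                       index=pd.Index(["a", "b", "c"], name="gene"))
    assert list(de.ranking_metric(det, "fold").index) == ["c", "a", "b"]
    with pytest.raises(ValueError):
        de.ranking_metric(det, "nonsense")


def test_adjusted_ranking_places_planted_genes_at_extremes():
    cfg = SynConfig(n_genes=500, n_stable=0, seed=21)
    study, truth = generate_study(cfg)
    per_gene, _ = de.fit_gene_lms(study)
    ranked = de.ranking_metric(per_gene, "adjusted", term="season")
    pos = pd.Series(np.arange(len(ranked)), index=ranked.index)
    pct = pos / (len(ranked) - 1)
    planted = truth.table.index[truth.table["bias"] != "none"]
    extremity = (2 * pct.loc[planted] - 1).abs()
    assert extremity.median() > 0.9
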