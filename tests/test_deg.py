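"""Per-gene three-way ANOVA and the fold-change/p-value DEG filter."""

import numpy as np
import pandas as pd
import pytest

from omicshub import FactorialAnova, call_degs, fit_anova_per_gene
from omicshub.deg import (
    TERMS,
    DegenerateDesignError,
    get_deg_set,
    signed_fold_change,
)

from conftest import build_study, random_small_study


def _long_frame(study):
    rows = []
    for sid in study.matrix.columns:
        fac = study.samples.loc[sid]
        for gene in study.matrix.index:
            rows.append({
                "gene": gene, "expr": study.matrix.at[gene, sid],
                "genotype": fac["genotype"], "condition": fac["condition"],
                "tissue": fac["tissue"],
            })
    return pd.DataFrame(rows)


def test_f_statistics_match_statsmodels_oracle():
    """Vectorised sums-of-squares F values agree with an OLS anova_lm fit
    to 1e-8 relative error on a small random balanced study."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    study = random_small_study(n_genes=5, n_rep=3, seed=3)
    res = FactorialAnova(study).fit()
    long = _long_frame(study)
    name_map = {
        "genotype": "C(genotype)",
        "condition": "C(condition)",
        "tissue": "C(tissue)",
        "genotype:condition": "C(genotype):C(condition)",
        "genotype:tissue": "C(genotype):C(tissue)",
        "condition:tissue": "C(condition):C(tissue)",
        "genotype:condition:tissue": "C(genotype):C(condition):C(tissue)",
    }
    for gene in study.matrix.index:
        fit = smf.ols(
            "expr ~ C(genotype) * C(condition) * C(tissue)",
            data=long[long["gene"] == gene],
        ).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        for term in TERMS:
            expected = table.loc[name_map[term], "F"]
            got = res.f_values.at[gene, term]
            assert got == pytest.approx(expected, rel=1e-8)
            assert res.p_values.at[gene, term] == pytest.approx(
                table.loc[name_map[term], "PR(>F)"], rel=1e-6, abs=1e-12
            )


def test_contrast_matches_pooled_variance_recomputation():
    """The per-contrast condition test equals a from-scratch cell-means
    contrast with the pooled within-cell variance."""
    from scipy import stats

    study = random_small_study(n_genes=3, n_rep=3, seed=5)
    res = FactorialAnova(study).fit()
    samp = study.samples
    for gene in study.matrix.index:
        y = study.matrix.loc[gene]
        # pooled within-cell variance by explicit loop
        ss, df = 0.0, 0
        for _, grp in samp.groupby(["genotype", "condition", "tissue"], sort=False):
            vals = y[grp.index]
            ss += ((vals - vals.mean()) ** 2).sum()
            df += len(vals) - 1
        s2 = ss / df
        for geno in ("WT", "OX"):
            for tis in ("shoot", "root"):
                sel = (samp["genotype"] == geno) & (samp["tissue"] == tis)
                m_ref = y[samp.index[sel & (samp["condition"] == "nS")]].mean()
                m_str = y[samp.index[sel & (samp["condition"] == "-S")]].mean()
                t = (m_str - m_ref) / np.sqrt(s2 * (2 / 3))
                p = 2 * stats.t.sf(abs(t), df)
                row = res.contrasts[
                    (res.contrasts["gene_id"] == gene)
                    & (res.contrasts["genotype"] == geno)
                    & (res.contrasts["tissue"] == tis)
                ].iloc[0]
                assert row["p_value"] == pytest.approx(p, rel=1e-10)
                assert row["fold_change"] == pytest.approx(
                    float(signed_fold_change(m_str - m_ref)), rel=1e-10
                )


def test_constant_gene_reports_no_effect():
    cells = {
        (g, c, t): [8.0, 8.0, 8.0]
        for g in ("WT", "OX") for c in ("nS", "-S") for t in ("shoot", "root")
    }
    study = build_study({"flat": cells})
    res = fit_anova_per_gene(study)
    assert (res.p_values.loc["flat"] == 1.0).all()
    assert (res.contrasts["p_value"] == 1.0).all()
    assert (res.deg_records()["direction"] == "unchanged").all()


def test_separation_limit_gives_tiny_p_and_fold_change_four():
    """nS = 8, -S = 10 with infinitesimal jitter: condition p -> 0 and the
    linear fold change is 4."""
    eps = 1e-8
    cells = {}
    for i, (g, c, t) in enumerate(
        (g, c, t) for g in ("WT", "OX") for c in ("nS", "-S") for t in ("shoot", "root")
    ):
        base = 10.0 if c == "-S" else 8.0
        cells[(g, c, t)] = [base + eps * (i + j) for j in range(3)]
    study = build_study({"g": cells})
    res = fit_anova_per_gene(study)
    assert (res.contrasts["p_value"] < 1e-12).all()
    assert res.contrasts["fold_change"].to_numpy() == pytest.approx(4.0, rel=1e-6)


@pytest.mark.parametrize(
    "fc,p,expected",
    [
        (1.4, 1e-9, "unchanged"),   # FC filter dominates
        (3.0, 0.2, "unchanged"),    # p filter dominates
        (1.5, 1e-9, "up"),          # boundary FC 1.5 passes ("at least")
        (-1.5, 1e-9, "down"),
    ],
)
def test_deg_filter_boundaries(fc, p, expected):
    from omicshub.deg import FactorialAnovaResults

    contrasts = pd.DataFrame(
        {
            "gene_id": ["g"], "genotype": ["WT"], "tissue": ["shoot"],
            "contrast": ["WT:shoot"],
            "log2_fc": [np.log2(abs(fc)) * np.sign(fc)],
            "fold_change": [fc], "p_value": [p],
        }
    )
    res = FactorialAnovaResults(
        study=None,
        f_values=pd.DataFrame(index=["g"]),
        p_values=pd.DataFrame(index=["g"]),
        contrasts=contrasts,
        df_resid=16,
    )
    assert res.deg_records()["direction"].iloc[0] == expected


def test_up_down_sets_disjoint_and_threshold_monotone(planted_study):
    study, _ = planted_study
    res = FactorialAnova(study).fit()
    base = res.call_degs(fc_threshold=1.5, alpha=0.05)
    by_key = {(s.contrast, s.direction): s.gene_ids for s in base}
    for (contrast, direction), ids in by_key.items():
        other = by_key[(contrast, "down" if direction == "up" else "up")]
        assert not ids & other
    # raising fc or lowering alpha never adds a gene
    stricter_fc = {(s.contrast, s.direction): s.gene_ids
                   for s in res.call_degs(fc_threshold=2.0, alpha=0.05)}
    stricter_a = {(s.contrast, s.direction): s.gene_ids
                  for s in res.call_degs(fc_threshold=1.5, alpha=0.01)}
    for key, ids in by_key.items():
        assert stricter_fc[key] <= ids
        assert stricter_a[key] <= ids


def test_planted_recovery_rates(planted_study):
    """At planted log2FC=2, sd=0.25, n=3: >= 95% of planted DEGs recovered,
    <= 7% of calls are false positives (seeded regression)."""
    study, truth = planted_study
    sets = call_degs(study)
    planted = recovered = called = 0
    for s in sets:
        true_ids = truth.deg_ids(s.contrast, s.direction)
        planted += len(true_ids)
        recovered += len(true_ids & s.gene_ids)
        called += len(s.gene_ids)
    assert 100 * recovered / planted >= 95.0
    assert 100 * (called - recovered) / called <= 7.0


def test_null_type_one_error_calibrated(null_study):
    """With no planted effects, the condition-effect positive rate at
    p < 0.05 lies within 0.05 +/- 0.02 (1000 genes)."""
    study, truth = null_study
    assert all(not v for v in truth.deg_ids_by_contrast.values())
    res = fit_anova_per_gene(study)
    rate = float((res.p_values["condition"] < 0.05).mean())
    assert 0.03 <= rate <= 0.07


def test_single_level_factor_raises_naming_it():
    cells = {("WT", c, t): [8.0, 8.1, 7.9] for c in ("nS", "-S") for t in ("shoot", "root")}
    study = build_study({"g": cells})
    with pytest.raises(DegenerateDesignError, match="genotype"):
        fit_anova_per_gene(study)


def test_unknown_contrast_lists_available(planted_results):
    sets = planted_results.call_degs()
    with pytest.raises(KeyError, match="WT:shoot"):
        get_deg_set(sets, "nosuch:tissue", "up")
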