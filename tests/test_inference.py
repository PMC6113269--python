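"""Mixed models, FDR, and minimal-detectable-effect power analysis."""

import numpy as np
import pandas as pd
import pytest

from rsnet.datatypes import CostGrid
from rsnet.inference import (
    PowerSpec,
    fdr_bh,
    fit_mixed_model,
    mde_independent,
    mde_paired,
    nodewise_analysis,
)


def balanced_table(n_per_group=8, effect=0.0, noise=0.0, seed=0, covariates=False):
    rng = np.random.default_rng(seed)
    rows = []
    for g_idx, g in enumerate(("PDM", "CON")):
        for k in range(n_per_group):
            sid = f"{g}{k}"
            u = rng.normal() * noise
            for ph in ("MENS", "POV"):
                row = dict(
                    subject_id=sid,
                    group=g,
                    phase=ph,
                    value=effect * g_idx + u + rng.normal() * noise,
                )
                if covariates:
                    row.update(estradiol=rng.normal(50, 10), beck_anxiety=rng.normal(5, 2))
                rows.append(row)
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_group_indicator_outcome_matches_gls_oracle(self):
        # outcome = group indicator + tiny noise: the group estimate must
        # equal the group mean difference and the interaction vanish
        df = balanced_table(effect=1.0, noise=1e-3, seed=1)
        res = fit_mixed_model(df, covariates=[])
        group_key = next(k for k in res.params if k.startswith("group["))
        g2 = group_key[6:-1]
        cell = df.groupby(["group", "phase"])["value"].mean()
        g1 = next(g for g in df["group"].unique() if g != g2)
        # treatment coding: the group coefficient is the reference-phase
        # (MENS) contrast, which on balanced data GLS estimates exactly
        mens_diff = cell[(g2, "MENS")] - cell[(g1, "MENS")]
        assert res.params[group_key] == pytest.approx(mens_diff, abs=1e-6)
        assert abs(mens_diff - (-1.0)) < 1e-2  # and it is the planted shift
        assert res.params["group:phase"] == pytest.approx(0.0, abs=1e-2)
        assert res.converged

    def test_balanced_estimates_equal_closed_form_gls(self):
        # on complete balanced data with no covariates, GLS fixed effects
        # reduce to cell means; compare against the explicit contrast
        df = balanced_table(effect=0.7, noise=0.5, seed=3)
        res = fit_mixed_model(df, covariates=[])
        cell = df.groupby(["group", "phase"])["value"].mean()
        groups = sorted(df["group"].unique())
        g2 = groups[1]
        g1 = groups[0]
        expected_group = cell[(g2, "MENS")] - cell[(g1, "MENS")]
        expected_phase = cell[(g1, "POV")] - cell[(g1, "MENS")]
        expected_inter = (
            cell[(g2, "POV")] - cell[(g2, "MENS")] - expected_phase
        )
        group_key = next(k for k in res.params if k.startswith("group["))
        phase_key = next(k for k in res.params if k.startswith("phase["))
        assert res.params[group_key] == pytest.approx(expected_group, abs=1e-6)
        assert res.params[phase_key] == pytest.approx(expected_phase, abs=1e-6)
        assert res.params["group:phase"] == pytest.approx(expected_inter, abs=1e-6)

    def test_constant_outcome_all_effects_zero(self):
        df = balanced_table()
        df["value"] = 3.14
        res = fit_mixed_model(df, covariates=[])
        for name, val in res.params.items():
            expected = 3.14 if name == "intercept" else 0.0
            assert val == pytest.approx(expected, abs=1e-8)

    def test_incomplete_subjects_dropped(self):
        df = balanced_table(seed=5, noise=1.0)
        df = df[~((df.subject_id == "PDM0") & (df.phase == "POV"))]
        res = fit_mixed_model(df, covariates=[])
        assert res.n_subjects == 15

    def test_unstructured_covariance_recovered(self):
        # plant unequal phase variances and strong coupling; REML should
        # find them
        rng = np.random.default_rng(11)
        rows = []
        s1, s2, rho = 1.0, 2.0, 0.6
        cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
        chol = np.linalg.cholesky(cov)
        for g in ("PDM", "CON"):
            for k in range(150):
                e = chol @ rng.standard_normal(2)
                rows.append(dict(subject_id=f"{g}{k}", group=g, phase="MENS", value=e[0]))
                rows.append(dict(subject_id=f"{g}{k}", group=g, phase="POV", value=e[1]))
        res = fit_mixed_model(pd.DataFrame(rows), covariates=[])
        assert res.covariance["sd_MENS"] == pytest.approx(s1, rel=0.15)
        assert res.covariance["sd_POV"] == pytest.approx(s2, rel=0.15)
        assert res.covariance["cov"] == pytest.approx(rho * s1 * s2, rel=0.25)

    def test_type_one_error_calibrated(self):
        # null simulation: group effect rejections at alpha=0.05 should
        # land near the nominal rate
        n_sim = 200
        rej = 0
        for s in range(n_sim):
            df = balanced_table(n_per_group=15, effect=0.0, noise=1.0, seed=1000 + s)
            res = fit_mixed_model(df, covariates=[])
            key = next(k for k in res.pvalues if k.startswith("group["))
            rej += res.pvalues[key] < 0.05
        assert 0.02 <= rej / n_sim <= 0.09

    def test_singular_design_rejected(self):
        df = balanced_table()
        df["estradiol"] = 1.0  # constant covariate -> collinear with intercept
        with pytest.raises(ValueError, match="singular"):
            fit_mixed_model(df, covariates=["estradiol"])


class TestFDR:
    def test_all_rejected_when_under_stepup_line(self):
        reject, p_adj = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()
        assert np.all(np.diff(np.sort(p_adj)) >= -1e-15)

    def test_none_rejected_at_one(self):
        reject, _ = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_stepup_boundary(self):
        reject, _ = fdr_bh([0.001, 0.8, 0.9], q=0.05)
        assert list(reject) == [True, False, False]

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(30) ** 2
            reject_bh, _ = fdr_bh(p, q=0.05)
            bonf = p < 0.05 / p.size
            assert np.all(reject_bh[bonf])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestMDE:
    def test_study_design_values(self):
        assert mde_independent(PowerSpec("independent", n1=57, n2=62)) == 0.52
        assert mde_independent(PowerSpec("independent", n1=60, n2=60)) == 0.52
        assert mde_paired(PowerSpec("paired", n1=60)) == 0.37
        assert mde_paired(PowerSpec("paired", n1=57)) == 0.38

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestIndPower, TTestPower

        d = mde_independent(PowerSpec("independent", n1=40, n2=50), decimals=None)
        ref = TTestIndPower().solve_power(
            nobs1=40, ratio=50 / 40, alpha=0.05, power=0.8, alternative="two-sided"
        )
        assert d == pytest.approx(ref, abs=1e-6)
        dz = mde_paired(PowerSpec("paired", n1=35), decimals=None)
        ref_p = TTestPower().solve_power(nobs=35, alpha=0.05, power=0.8, alternative="two-sided")
        assert dz == pytest.approx(ref_p, abs=1e-6)

    def test_monotone_decreasing_in_n(self):
        vals = [
            mde_paired(PowerSpec("paired", n1=n), decimals=None)
            for n in (10, 20, 40, 80, 160)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        big = mde_independent(
            PowerSpec("independent", n1=10**6, n2=10**6), decimals=None
        )
        assert big < 0.01

    def test_normal_approximation_agreement(self):
        # z-based closed form within 0.02 of the noncentral-t solve for
        # moderately large df
        import scipy.stats

        for n1, n2 in ((30, 30), (57, 62), (100, 120)):
            z = scipy.stats.norm.ppf(1 - 0.05 / 2) + scipy.stats.norm.ppf(0.8)
            approx = z * np.sqrt(1 / n1 + 1 / n2)
            exact = mde_independent(PowerSpec("independent", n1=n1, n2=n2), decimals=None)
            assert abs(exact - approx) < 0.02

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec("independent", n1=57)  # missing n2
        with pytest.raises(ValueError):
            PowerSpec("paired", n1=1)
        with pytest.raises(ValueError):
            mde_paired(PowerSpec("independent", n1=5, n2=5))


class TestNodewise:
    def _nodal_table(self, n_nodes=4, costs=(0.03, 0.04), seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("PDM", "CON"):
            for k in range(10):
                sid = f"{g}{k}"
                u = rng.normal()
                for ph in ("MENS", "POV"):
                    for cost in costs:
                        for node in range(n_nodes):
                            shift = effect if (g == "PDM" and node == 0) else 0.0
                            rows.append(
                                dict(
                                    subject_id=sid,
                                    group=g,
                                    phase=ph,
                                    cost=cost,
                                    metric="degree",
                                    node=f"node{node}",
                                    value=shift + u + rng.normal(),
                                )
                            )
        return pd.DataFrame(rows)

    def test_row_bookkeeping(self):
        df = self._nodal_table()
        out = nodewise_analysis(df, CostGrid([0.03, 0.04]), metric_names=["degree"], covariates=[])
        # nodes x costs x effects rows for the one metric
        assert len(out) == 4 * 2 * 3
        assert set(out["effect"]) == {"group", "phase", "group:phase"}

    def test_null_table_mostly_clean_and_injected_effect_found(self):
        null = nodewise_analysis(
            self._nodal_table(seed=1), CostGrid([0.03, 0.04]),
            metric_names=["degree"], covariates=[],
        )
        assert null["significant_fdr"].sum() <= 1
        strong = nodewise_analysis(
            self._nodal_table(seed=2, effect=4.0), CostGrid([0.03, 0.04]),
            metric_names=["degree"], covariates=[],
        )
        hits = strong[(strong.effect == "group") & strong.significant_fdr]
        assert set(hits["node"]) == {"node0"}
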