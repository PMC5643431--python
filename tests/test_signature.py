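"""Gene correlation ranking, MDL gain filter, elastic-net risk models."""

import numpy as np
import pandas as pd
import pytest

from vasculomorph import prognosis, signature as G, synthetic


def _expr_from_latent(latent: np.ndarray, gene_ids, case_ids) -> pd.DataFrame:
    """Expression matrix whose log2(x+1) transform equals `latent`."""
    return pd.DataFrame(2.0**latent - 1.0, index=gene_ids, columns=case_ids)


class TestCorrelateGenes:
    def _tables(self, rng, n_cases=20):
        cases = [f"c{i}" for i in range(n_cases)]
        vf = pd.DataFrame({"f1": rng.normal(5, 1, n_cases)}, index=cases)
        latent = np.vstack(
            [
                3.0 + vf["f1"].to_numpy(),       # g_pos: exactly +VF
                13.0 - vf["f1"].to_numpy(),      # g_neg: exactly -VF
                np.full(n_cases, 4.0),           # g_const
            ]
        )
        expr = _expr_from_latent(latent, ["g_pos", "g_neg", "g_const"], cases)
        return expr, vf

    def test_exact_positive_and_negative_correlates(self, rng):
        expr, vf = self._tables(rng)
        r = G.correlate_genes(expr, vf, ["f1"])["f1"]
        assert r["g_pos"] == pytest.approx(1.0, abs=1e-12)
        assert r["g_neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_gene_gets_zero(self, rng):
        expr, vf = self._tables(rng)
        r = G.correlate_genes(expr, vf, ["f1"])["f1"]
        assert r["g_const"] == 0.0

    def test_planted_correlation_recovered_within_fisher_se(self):
        """Planted r=0.6 at n=64: the mean estimate over replicates lies
        within 3 SE (Fisher z) of the target."""
        zs = []
        for rep in range(10):
            c = synthetic.simulate_cohort(
                synthetic.SyntheticCohortSpec(
                    seed=5000 + rep, n_genes=50, n_signal_genes=1
                )
            )
            gene = c.signal_genes[0]
            feat = c.informative_features[0]
            r = G.correlate_genes(c.expression, c.features, [feat])[feat][gene]
            zs.append(np.arctanh(abs(r)))
        se = 1.0 / np.sqrt(64 - 3) / np.sqrt(len(zs))
        assert abs(np.mean(zs) - np.arctanh(0.6)) < 3 * se + 0.05

    def test_no_shared_cases_rejected(self, rng):
        expr, vf = self._tables(rng)
        vf.index = [f"other{i}" for i in range(len(vf))]
        with pytest.raises(ValueError):
            G.correlate_genes(expr, vf, ["f1"])


class TestSelectCandidates:
    def test_slice_size_ceil_rule(self, rng):
        genes = [f"G{i:05d}" for i in range(20000)]
        r = pd.Series(rng.normal(size=20000), index=genes)
        cands = G.select_candidates({"vf": r}, fraction=0.0005)
        assert len(cands) == 20  # 10 per direction, ceil(0.0005 * 20000)

    def test_nine_disjoint_slices_give_180(self, rng):
        genes = [f"G{i:05d}" for i in range(20000)]
        rankings = {}
        for v in range(9):
            r = pd.Series(rng.normal(0, 1e-6, 20000), index=genes)
            # plant disjoint extremes per vascular feature
            lo = slice(40 * v, 40 * v + 10)
            hi = slice(40 * v + 20, 40 * v + 30)
            r.iloc[lo] = -10 - np.arange(10)
            r.iloc[hi] = 10 + np.arange(10)
            rankings[f"vf{v}"] = r
        assert len(G.select_candidates(rankings, fraction=0.0005)) == 180

    def test_monotone_rank_preserving_transform_invariant(self, rng):
        genes = [f"g{i}" for i in range(200)]
        r = pd.Series(rng.normal(size=200), index=genes)
        a = G.select_candidates({"v": r}, fraction=0.05)
        b = G.select_candidates({"v": np.tanh(r) * 3 + r / 10}, fraction=0.05)
        assert a == b

    def test_fraction_bounds(self, rng):
        r = pd.Series(rng.normal(size=10), index=list("abcdefghij"))
        with pytest.raises(ValueError):
            G.select_candidates({"v": r}, fraction=0.6)


class TestInformationGain:
    def test_perfect_separator_gain_ratio_one(self):
        """A gene splitting balanced risk groups into two pure, equal bins:
        gain = H(risk) = 1 bit, split info = 1 bit, ratio exactly 1."""
        cases = [f"c{i}" for i in range(20)]
        labels = pd.Series([0] * 10 + [1] * 10, index=cases)
        latent = np.array([[2.0] * 10 + [6.0] * 10])
        expr = _expr_from_latent(latent, ["g"], cases)
        res = G.information_gain_filter(expr, ["g"], labels)
        assert res.gain["g"] == pytest.approx(1.0)
        assert res.final == ["g"]

    def test_label_independent_gene_rejected_by_mdl(self, rng):
        """Permuting labels: the MDL criterion accepts no cut for at least
        95% of 100 permutations."""
        cases = [f"c{i}" for i in range(40)]
        expr = _expr_from_latent(rng.normal(5, 1, (1, 40)), ["g"], cases)
        rejected = 0
        for seed in range(100):
            perm = np.random.default_rng(seed).permutation(40)
            labels = pd.Series(np.array([0] * 20 + [1] * 20)[perm], index=cases)
            res = G.information_gain_filter(expr, ["g"], labels)
            if res.gain["g"] == 0.0:
                rejected += 1
        assert rejected >= 95

    def test_empty_candidates_empty_final(self, cohort):
        lab = cohort.risk_groups
        res = G.information_gain_filter(cohort.expression, [], lab)
        assert res.final == []

    def test_gain_ratio_in_unit_interval(self, cohort):
        genes = list(cohort.expression.index[:30]) + cohort.signal_genes[:5]
        res = G.information_gain_filter(
            cohort.expression, genes, cohort.risk_groups
        )
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in res.gain.values())

    def test_single_class_labels_rejected(self, cohort):
        ones = pd.Series(1, index=cohort.expression.columns)
        with pytest.raises(ValueError):
            G.information_gain_filter(
                cohort.expression, cohort.signal_genes[:2], ones
            )


class TestRiskModel:
    def _single_gene_problem(self, rng, n=80, n_genes=30):
        cases = [f"c{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(n_genes)]
        latent = rng.normal(5, 1, (n_genes, n))
        labels = pd.Series((latent[0] > 5.0).astype(int), index=cases)
        return _expr_from_latent(latent, genes, cases), genes, labels

    def test_informative_gene_recovered(self, rng):
        expr, genes, labels = self._single_gene_problem(rng)
        train = expr.columns[:60]
        test = expr.columns[60:]
        m = G.train_risk_model(expr[train], genes, labels[train], seed=0)
        assert abs(m.coefficients["g0"]) > 1e-6
        pred = (G.predict_risk(m, expr[test]) >= 0.5).astype(int)
        assert (pred == labels[test]).mean() >= 0.95

    def test_infinite_penalty_zeroes_coefficients(self, rng):
        expr, genes, labels = self._single_gene_problem(rng)
        m = G.train_risk_model(
            expr, genes, labels, lambda_path=np.array([1e6]), seed=0
        )
        assert all(abs(c) < 1e-8 for c in m.coefficients.values())

    def test_same_seed_same_lambda(self, rng):
        expr, genes, labels = self._single_gene_problem(rng)
        a = G.train_risk_model(expr, genes, labels, seed=4)
        b = G.train_risk_model(expr, genes, labels, seed=4)
        assert a.chosen_lambda == b.chosen_lambda
        assert a.coefficients == b.coefficients

    def test_empty_gene_set_rejected(self, cohort):
        with pytest.raises(ValueError):
            G.train_risk_model(cohort.expression, [], cohort.risk_groups)


class TestGroundTruthLabels:
    def test_24_month_rule(self):
        surv = pd.DataFrame(
            {
                "dfs_months": [10.0, 30.0, 10.0, 25.0],
                "event": [1, 1, 0, 0],
            },
            index=list("abcd"),
        )
        lab = G.ground_truth_24mo_labels(surv)
        assert lab.to_dict() == {"a": 1, "b": 0, "d": 0}  # 'c' unknowable


class TestEvaluateRiskModel:
    def _oracle_model(self, cohort):
        """A risk model reading a synthetic indicator gene equal to the
        planted group."""
        ind = cohort.risk_groups.astype(float)
        expr = cohort.expression.copy()
        expr.loc["g_oracle"] = (2.0 ** (5.0 + 4.0 * ind) - 1.0).to_numpy()
        model = G.RiskModel(
            coefficients={"g_oracle": 10.0},
            intercept=-10.0 * 0.0,
            alpha=0.5,
            lambda_path=np.array([0.1]),
            chosen_lambda=0.1,
            training_target="vf_risk",
            n_folds=2,
            seed=0,
            gene_means={"g_oracle": float(np.log2(expr.loc["g_oracle"] + 1).mean())},
            gene_sds={"g_oracle": float(np.log2(expr.loc["g_oracle"] + 1).std())},
        )
        return model, expr

    def test_oracle_model_recovers_planted_hazard_ratio(self):
        """A model predicting the planted groups exactly evaluates to an
        HR consistent with the planted 2.4 (mean log-HR within 2 SE over
        replicates)."""
        logs = []
        for rep in range(12):
            c = synthetic.simulate_cohort(
                synthetic.SyntheticCohortSpec(
                    seed=7000 + rep, n_genes=30, n_signal_genes=2
                )
            )
            model, expr = self._oracle_model(c)
            rep_out = G.evaluate_risk_model(model, expr, c.survival)
            hr = rep_out.get("hazard_ratio")
            if hr and np.isfinite(hr) and hr > 0:
                logs.append(np.log(hr))
        se = np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert abs(np.mean(logs) - np.log(2.4)) < 2 * se + 0.1

    def test_oracle_predictions_match_planted_groups(self, cohort):
        model, expr = self._oracle_model(cohort)
        out = G.evaluate_risk_model(model, expr, cohort.survival)
        assert (out["risk_group"] == cohort.risk_groups).mean() == 1.0

    def test_random_scores_null_cindex(self, rng):
        """Random risk scores give concordance near 1/2."""
        from lifelines.utils import concordance_index

        cs = []
        for _ in range(30):
            t = rng.exponential(10, 50)
            cs.append(concordance_index(t, rng.normal(size=50), np.ones(50)))
        se = np.std(cs, ddof=1) / np.sqrt(len(cs))
        assert abs(np.mean(cs) - 0.5) < 3 * se + 0.01

    def test_added_informative_covariate_never_hurts_training_cindex(self, cohort):
        lab = prognosis.cluster_risk_groups(
            cohort.features, cohort.informative_features, survival=cohort.survival
        )
        surv = cohort.survival
        base = prognosis.cox_fit(
            surv["dfs_months"], surv["event"], surv[["stage_high"]]
        )
        both = prognosis.cox_fit(
            surv["dfs_months"],
            surv["event"],
            surv[["stage_high"]].assign(risk=lab),
        )
        assert both.c_index >= base.c_index - 1e-9
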