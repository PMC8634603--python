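"""Hierarchy estimation: beta/linear fits, classification, embedding."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

import connectoscope as cs


def beta_observations(h, rng, phi=20.0, reps=3, areas=None):
    """SLN drawn straight from the logit-link beta model."""
    n = len(h)
    if areas is None:
        areas = [f"A{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            mu = expit(h[i] - h[j])
            for _ in range(reps):
                rows.append((areas[i], areas[j], rng.beta(mu * phi, (1 - mu) * phi)))
    return pd.DataFrame(rows, columns=["target", "source", "sln"])


class TestHierarchyFit:
    def test_symmetric_two_area_case_equal_h(self):
        obs = pd.DataFrame(
            [("X", "Y", 0.5), ("Y", "X", 0.5)],
            columns=["target", "source", "sln"],
        )
        res = cs.fit_hierarchy_beta(obs, anchor="X")
        assert res.h_raw["X"] == pytest.approx(res.h_raw["Y"], abs=1e-6)

    def test_two_area_logit_inversion(self):
        obs = pd.DataFrame(
            [("X", "Y", 0.73), ("Y", "X", 0.27)],
            columns=["target", "source", "sln"],
        )
        res = cs.fit_hierarchy_beta(obs, anchor="Y")
        expected = logit(0.73)
        assert res.h_raw["X"] - res.h_raw["Y"] == pytest.approx(
            expected, abs=0.05
        )

    def test_parameter_recovery_from_beta_model(self, rng):
        h = rng.uniform(0, 1, 20)
        obs = beta_observations(h, rng, phi=20.0, reps=3)
        res = cs.fit_hierarchy_beta(obs)
        fitted = res.h[[f"A{i}" for i in range(20)]].to_numpy()
        assert spearmanr(h, fitted).statistic >= 0.95
        assert res.phi == pytest.approx(20.0, rel=0.25)
        assert res.pred_obs_correlation > 0.5

    def test_linear_and_beta_agree_on_model_data(self, rng):
        h = rng.uniform(0, 1, 15)
        obs = beta_observations(h, rng, phi=30.0, reps=2)
        b = cs.fit_hierarchy_beta(obs)
        l = cs.fit_hierarchy_linear(obs)
        assert spearmanr(b.h, l.h[b.h.index]).statistic >= 0.95
        assert np.isnan(l.phi)

    def test_anchor_choice_does_not_change_normalized_h(self, rng):
        h = rng.uniform(0, 1, 8)
        obs = beta_observations(h, rng, phi=50.0, reps=2)
        r1 = cs.fit_hierarchy_beta(obs, anchor="A0")
        r2 = cs.fit_hierarchy_beta(obs, anchor="A5")
        assert np.allclose(r1.h, r2.h[r1.h.index], atol=1e-3)

    def test_complementing_sln_reverses_ordering(self, rng):
        """SLN -> 1 - SLN flips every projection's direction of flow, so the
        fitted indices negate exactly."""
        h = rng.uniform(0, 1, 10)
        obs = beta_observations(h, rng, phi=30.0, reps=2)
        comp = obs.copy()
        comp["sln"] = 1.0 - comp["sln"]
        fwd = cs.fit_hierarchy_linear(obs, anchor="A0")
        bwd = cs.fit_hierarchy_linear(comp, anchor="A0")
        assert np.allclose(
            fwd.h_raw.to_numpy(), -bwd.h_raw[fwd.h_raw.index].to_numpy(),
            atol=1e-8,
        )

    def test_swap_plus_complement_is_identity(self, rng):
        """Recording a projection from the other end (swap target/source and
        complement SLN) carries the same information: the fit is unchanged."""
        h = rng.uniform(0, 1, 10)
        obs = beta_observations(h, rng, phi=30.0, reps=2)
        rev = obs.rename(columns={"target": "source", "source": "target"})
        rev["sln"] = 1.0 - rev["sln"]
        fwd = cs.fit_hierarchy_linear(obs, anchor="A0")
        bwd = cs.fit_hierarchy_linear(rev, anchor="A0")
        assert np.allclose(
            fwd.h_raw.to_numpy(), bwd.h_raw[fwd.h_raw.index].to_numpy(),
            atol=1e-8,
        )

    def test_matches_statsmodels_betamodel(self, rng):
        sm_beta = pytest.importorskip("statsmodels.othermod.betareg")
        h = rng.uniform(0, 1, 6)
        areas = [f"A{i}" for i in range(6)]
        obs = beta_observations(h, rng, phi=20.0, reps=4, areas=areas)
        res = cs.fit_hierarchy_beta(obs, anchor="A0")
        # independent route: statsmodels BetaModel with a signed incidence
        # design (anchor column dropped) and a logit mean link; the beta
        # draws are interior so no boundary handling applies on either route
        y = obs["sln"].to_numpy()
        x = np.zeros((len(obs), 5))
        for k, a in enumerate(areas[1:]):
            x[:, k] = (obs["target"] == a).astype(float) - (
                obs["source"] == a
            ).astype(float)
        mod = sm_beta.BetaModel(y, x)
        fit = mod.fit(disp=0)
        ref = np.concatenate([[0.0], fit.params[:5]])
        ours = res.h_raw[areas].to_numpy()
        assert np.allclose(ours, ref, atol=1e-3)

    def test_degenerate_flag_for_identical_sln(self):
        obs = pd.DataFrame(
            [("X", "Y", 0.5), ("Y", "Z", 0.5), ("Z", "X", 0.5)],
            columns=["target", "source", "sln"],
        )
        with pytest.warns(UserWarning):
            res = cs.fit_hierarchy_beta(obs)
        assert res.degenerate

    def test_disconnected_design_warns(self):
        obs = pd.DataFrame(
            [("A", "B", 0.6), ("C", "D", 0.4)],
            columns=["target", "source", "sln"],
        )
        with pytest.warns(UserWarning, match="components"):
            model = cs.HierarchyModel(obs)
        assert model.components is not None

    def test_from_injections_skips_agranular(self, gt_small, injections_small):
        model = cs.HierarchyModel.from_injections(injections_small)
        assert set(model.obs["target"]) <= set(gt_small.area_names)

    def test_summary_mentions_anchor_and_phi(self, rng):
        obs = beta_observations(rng.uniform(0, 1, 5), rng, phi=20, reps=2)
        res = cs.fit_hierarchy_beta(obs, anchor="A2")
        text = res.summary()
        assert "A2" in text and "phi" in text


class TestClassification:
    @pytest.mark.parametrize(
        "sln,expected", [(0.75, "FF"), (0.27, "FB"), (0.5, "unclassified")]
    )
    def test_rule(self, sln, expected):
        assert cs.classify_projections(sln) == expected

    def test_vectorized(self):
        out = cs.classify_projections([0.9, 0.1, 0.5])
        assert list(out) == ["FF", "FB", "unclassified"]


class TestEmbedding:
    def test_radius_extremes(self):
        h = pd.Series([1.0, 0.0, 0.5], index=["top", "bottom", "mid"])
        fln = pd.DataFrame(0.01, index=h.index, columns=h.index)
        np.fill_diagonal(fln.values, 0.0)
        emb = cs.circular_embedding(h, fln, anchor="top", n_restarts=5)
        coords = emb.to_frame()
        assert coords.loc["top", "R"] == 0.0
        assert coords.loc["bottom", "R"] == 1.0

    def test_equal_weights_give_equally_spaced_angles(self):
        h = pd.Series(0.5, index=["V1", "A", "B"])
        fln = pd.DataFrame(0.01, index=h.index, columns=h.index)
        np.fill_diagonal(fln.values, 0.0)
        emb = cs.circular_embedding(h, fln, anchor="V1", seed=0, n_restarts=20)
        assert emb.theta[0] == 0.0
        spacing = np.sort(np.degrees(emb.theta))
        assert np.allclose(spacing, [0.0, 120.0, 240.0], atol=1.0)

    def test_matches_one_degree_grid_oracle(self):
        h = pd.Series(0.5, index=["V1", "A", "B"])
        fln = pd.DataFrame(0.01, index=h.index, columns=h.index)
        np.fill_diagonal(fln.values, 0.0)
        emb = cs.circular_embedding(h, fln, anchor="V1", seed=0, n_restarts=20)
        # vectorized 1-degree grid search over the two free angles
        y = 2.0  # -log10(0.01)
        t = np.radians(np.arange(360))
        t2, t3 = np.meshgrid(t, t, indexing="ij")

        def circ(x):
            d = np.abs(x) % (2 * np.pi)
            return np.minimum(d, 2 * np.pi - d)

        c = np.stack([circ(t2), circ(t3), circ(t2 - t3)])
        sum_c = 2 * c.sum(axis=0)  # each unordered pair appears twice
        sum_c2 = 2 * (c ** 2).sum(axis=0)
        with np.errstate(invalid="ignore"):
            r = np.maximum(y * sum_c / sum_c2, 0.0)
            obj = 2 * ((y - r * c) ** 2).sum(axis=0)
        assert emb.objective_value <= np.nanmin(obj) * 1.01 + 1e-12

    def test_zero_fln_pairs_ignored(self):
        h = pd.Series(0.5, index=["V1", "A", "B", "C"])
        fln = pd.DataFrame(0.01, index=h.index, columns=h.index)
        np.fill_diagonal(fln.values, 0.0)
        fln.loc["C", :] = 0.0
        fln.loc[:, "C"] = 0.0
        emb = cs.circular_embedding(h, fln, anchor="V1", n_restarts=5)
        assert np.isfinite(emb.objective_value)

    def test_too_few_areas_raises(self):
        h = pd.Series([0.2, 0.8], index=["A", "B"])
        fln = pd.DataFrame(0.1, index=h.index, columns=h.index)
        with pytest.raises(ValueError):
            cs.circular_embedding(h, fln)
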