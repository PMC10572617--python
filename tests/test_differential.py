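"""Linear-model differential analysis, variance moderation and BH."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pathact.differential import (
    DesignSpec,
    bh_adjust,
    cross_contrast_intersection,
    differential_table,
    ebayes_moderate,
    fit_linear_model,
    fit_variance_prior,
)


def _design(n_case, n_control, batch=None, contrast=("case", "control")):
    samples = [f"s{i}" for i in range(n_case + n_control)]
    cond = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    b = pd.Series(batch, index=samples) if batch is not None else None
    return DesignSpec(condition=cond, contrast=contrast, batch=b)


class TestLinearFit:
    def test_contrast_is_difference_of_group_means(self):
        design = _design(3, 3)
        y = pd.DataFrame([[3.0, 3.2, 2.8, 1.1, 0.9, 1.0]], index=["f1"],
                         columns=design.condition.index)
        fit = fit_linear_model(y, design)
        assert fit.coef["f1"] == pytest.approx(y.iloc[0, :3].mean() - y.iloc[0, 3:].mean())

    def test_exact_group_means_fixture(self):
        design = _design(3, 3)
        y = pd.DataFrame([[3.0, 3.0, 3.0, 1.0, 1.0, 1.0]], index=["f1"],
                         columns=design.condition.index)
        fit = fit_linear_model(y, design)
        assert fit.coef["f1"] == pytest.approx(2.0, abs=1e-12)
        assert fit.s2["f1"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature(self):
        design = _design(3, 3)
        y = pd.DataFrame([[5.0] * 6], index=["f1"], columns=design.condition.index)
        fit = fit_linear_model(y, design)
        assert fit.coef["f1"] == pytest.approx(0.0, abs=1e-12)
        assert fit.s2["f1"] == pytest.approx(0.0, abs=1e-12)

    def test_batch_confounded_with_condition_raises(self):
        design_ok = _design(3, 3)
        design = DesignSpec(
            condition=design_ok.condition,
            contrast=("case", "control"),
            batch=design_ok.condition.copy(),
        )
        y = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 6)),
                         columns=design.condition.index)
        with pytest.raises(ValueError, match="aliased"):
            fit_linear_model(y, design)

    def test_batch_effect_removed_from_contrast(self):
        rng = np.random.default_rng(1)
        batch = ["b1", "b2"] * 5
        design = _design(5, 5, batch=batch)
        base = rng.normal(size=10)
        shift = np.where(np.array(batch) == "b2", 10.0, 0.0)
        y = pd.DataFrame([base + shift], index=["f1"], columns=design.condition.index)
        fit = fit_linear_model(y, design)
        no_batch = pd.DataFrame([base], index=["f1"], columns=design.condition.index)
        fit2 = fit_linear_model(no_batch, _design(5, 5, batch=batch))
        assert fit.coef["f1"] == pytest.approx(fit2.coef["f1"], abs=1e-10)


class TestModeration:
    def _fit(self, rng, n_features=200, n=6, sd=None):
        design = _design(n // 2, n - n // 2)
        sd = sd if sd is not None else np.ones(n_features)
        y = pd.DataFrame(rng.normal(scale=sd[:, None], size=(n_features, n)),
                         columns=design.condition.index)
        return fit_linear_model(y, design), design

    def test_infinite_prior_df_pins_variances_to_prior(self):
        fit, _ = self._fit(np.random.default_rng(2))
        mod = ebayes_moderate(fit, d0=np.inf)
        assert np.allclose(mod.s2_post, mod.s0_2)

    def test_zero_prior_df_reproduces_classical_t(self):
        rng = np.random.default_rng(3)
        fit, design = self._fit(rng, n_features=50)
        mod = ebayes_moderate(fit, d0=0)
        samples = design.condition.index
        case = samples[design.condition == "case"]
        ctrl = samples[design.condition == "control"]
        y = pd.DataFrame(rng.normal(size=(50, 6)), columns=samples)
        fit_y = fit_linear_model(y, design)
        mod_y = ebayes_moderate(fit_y, d0=0)
        t_ref, p_ref = stats.ttest_ind(y[case], y[ctrl], axis=1, equal_var=True)
        assert np.allclose(mod_y.t.to_numpy(), t_ref, atol=1e-10)
        assert np.allclose(mod_y.p.to_numpy(), p_ref, atol=1e-10)

    def test_prior_recovers_simulated_hyperparameters(self):
        """s2 drawn from the hierarchical model: MoM estimates are close."""
        rng = np.random.default_rng(4)
        d, d0_true, s0_true = 4, 8.0, 2.0
        s2 = s0_true * stats.f.rvs(d, d0_true, size=20000, random_state=rng)
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0_true, rel=0.15)
        assert s0_hat == pytest.approx(s0_true, rel=0.05)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R unavailable")
    def test_matches_limma_squeeze(self, tmp_path):
        """Independent oracle: limma::squeezeVar on the same variances."""
        rng = np.random.default_rng(5)
        d = 4
        s2 = 1.5 * stats.f.rvs(d, 10, size=500, random_state=rng)
        path = tmp_path / "s2.txt"
        np.savetxt(path, s2)
        script = (
            "suppressMessages(library(limma));"
            f"s2 <- scan('{path}', quiet=TRUE);"
            f"sq <- squeezeVar(s2, df={d});"
            "cat(sprintf('%.12f', c(sq$df.prior, sq$var.prior, sq$var.post[1:5])), sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        ref = [float(v) for v in out.stdout.split()]
        d0, s0 = fit_variance_prior(s2, d)
        assert d0 == pytest.approx(ref[0], rel=1e-4)
        assert s0 == pytest.approx(ref[1], rel=1e-4)
        post = (d0 * s0 + d * s2[:5]) / (d0 + d)
        assert np.allclose(post, ref[2:], rtol=1e-4)


class TestBH:
    def test_hand_checked_triple(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert np.allclose(bh_adjust([0.05]), [0.05])

    def test_capped_at_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_order_invariance_and_monotonicity(self, p, rnd):
        p = np.asarray(p)
        fdr = bh_adjust(p)
        assert np.all(fdr >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert np.allclose(bh_adjust(p[perm]), fdr[perm])


class TestTables:
    def test_planted_effects_recovered_single_run(self):
        rng = np.random.default_rng(6)
        design = _design(30, 30)
        y = rng.normal(size=(500, 60))
        y[:20, :30] += 1.5
        table, sig = differential_table(
            pd.DataFrame(y, index=[f"c{i}" for i in range(500)], columns=design.condition.index),
            design,
        )
        hits = {f for f in sig["feature_id"] if int(f[1:]) < 20}
        assert len(hits) >= 16
        assert (sig.set_index("feature_id").loc[sorted(hits), "direction"] == "up").all()

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(7)
        design = _design(4, 4)
        y = pd.DataFrame(rng.normal(size=(100, 8)), columns=design.condition.index)
        table, _ = differential_table(y, design)
        assert (table["fdr"] >= table["p"] - 1e-15).all()

    def test_cross_contrast_intersection_averages(self):
        t1 = pd.DataFrame(
            {"feature_id": ["a", "b"], "log2FC": [0.2, -1.0], "fdr": [0.01, 0.2],
             "direction": ["up", "down"]}
        )
        t2 = pd.DataFrame(
            {"feature_id": ["a", "b"], "log2FC": [0.4, -1.2], "fdr": [0.02, 0.01],
             "direction": ["up", "down"]}
        )
        out = cross_contrast_intersection({"c1": t1, "c2": t2})
        assert list(out["feature_id"]) == ["a"]  # b not significant in c1
        assert out.loc[0, "log2FC"] == pytest.approx(0.3)
        assert out.loc[0, "n_contrasts"] == 2

    def test_direction_disagreement_excluded(self):
        t1 = pd.DataFrame({"feature_id": ["a"], "log2FC": [0.2], "fdr": [0.01], "direction": ["up"]})
        t2 = pd.DataFrame({"feature_id": ["a"], "log2FC": [-0.2], "fdr": [0.01], "direction": ["down"]})
        assert cross_contrast_intersection({"c1": t1, "c2": t2}).empty
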