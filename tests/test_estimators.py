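import shutil
import subprocess
import textwrap
import warnings

import numpy as np
import pytest

import nmari as nm
from nmari.gls import q_het_total

from conftest import make_univariate, simulated_net
import oracles


class TestSolveMonotone:
    def test_truncation_at_zero(self):
        root, truncated = nm.solve_monotone(lambda t: 3.0 / (1.0 + t), 5.0)
        assert root == 0.0 and truncated

    def test_closed_form_pivot(self):
        # pivot(t) = 2*target/(1+t) crosses target at t = 1
        root, truncated = nm.solve_monotone(lambda t: 6.0 / (1.0 + t), 3.0)
        assert not truncated
        assert root == pytest.approx(1.0, abs=1e-10)

    def test_boundary_counts_as_truncated(self):
        root, truncated = nm.solve_monotone(lambda t: 2.0 / (1.0 + t), 2.0)
        assert root == 0.0 and truncated

    def test_univariate_grid_oracle(self):
        y, v = [0.0, 1.0, 3.0], [1.0, 1.0, 1.0]
        root, truncated = nm.solve_monotone(
            lambda t: oracles.uni_q(y, v, t), len(y) - 1
        )
        assert not truncated
        assert root == pytest.approx(oracles.uni_pm(y, v), abs=1e-6)

    def test_nonfinite_pivot_raises(self):
        with pytest.raises(nm.NumericalError):
            nm.solve_monotone(lambda t: np.nan, 1.0)


class TestPauleMandel:
    def test_noise_free_data_truncates(self, ab_ac_net):
        net = ab_ac_net.with_outcomes(ab_ac_net.X @ np.array([0.4, 0.1]))
        res = nm.estimate_pm_full(net)
        assert res.vc.tau_beta_sq == 0.0 and res.vc.tau_omega_sq == 0.0
        assert res.vc.truncated_beta and res.vc.truncated_omega

    @pytest.mark.parametrize("seed", range(4))
    def test_plug_back_satisfies_estimating_equations(self, seed):
        net = simulated_net(seed, n_treatments=5, design_mix={2: 9, 3: 3},
                            vc=(0.5, 0.3))
        res = nm.estimate_pm_full(net)
        tb, tw = res.vc.tau_beta_sq, res.vc.tau_omega_sq
        df_het = sum(d.df_het for d in net.designs)
        if not res.vc.truncated_beta:
            assert q_het_total(net, tb) == pytest.approx(df_het, abs=1e-10)
        if not res.vc.truncated_omega:
            assert nm.q_pivot_net(net, (tb, tw)).value == pytest.approx(
                net.n - net.c, abs=1e-10
            )

    def test_single_design_full_model_rejected(self):
        net = make_univariate([0.1, 0.5], [1.0, 1.0])
        with pytest.raises(nm.IdentifiabilityError):
            nm.estimate_pm_full(net)

    def test_all_singleton_designs_warn(self, ab_ac_blocks):
        net = nm.assemble_network(ab_ac_blocks[1:])  # one AB + one AC study
        with pytest.warns(UserWarning, match="not identifiable"):
            res = nm.estimate_pm_full(net)
        assert res.vc.tau_beta_sq == 0.0
        assert res.diagnostics["no_replication"]

    def test_consistency_matches_univariate_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.4, 0.8, 8)
        v = rng.uniform(0.05, 1.5, 8)
        net = make_univariate(y, v)
        res = nm.estimate_pm_consistency(net)
        assert res.vc.tau_beta_sq == pytest.approx(oracles.uni_pm(y, v), abs=1e-6)

    def test_consistency_zero_residual_truncates(self):
        net = make_univariate([0.5, 0.5, 0.5], [1.0, 2.0, 0.5])
        res = nm.estimate_pm_consistency(net)
        assert res.vc.tau_beta_sq == 0.0 and res.vc.truncated_beta


class TestDerSimonianLaird:
    def test_a0_is_residual_df(self, medium_net):
        coef = nm.dl_moment_coefficients(medium_net)
        # tr((W - WH) S) = n - rank(X), verified against the stored a0
        W = np.linalg.inv(medium_net.S)
        H = medium_net.X @ np.linalg.solve(
            medium_net.X.T @ W @ medium_net.X, medium_net.X.T @ W
        )
        assert coef.a0 == pytest.approx(float(np.trace((W - W @ H) @ medium_net.S)))
        assert coef.a2 >= 0

    def test_equal_variance_univariate_slope(self):
        v = 0.7
        net = make_univariate([0.0, 0.3, 0.9, 0.1], [v] * 4)
        coef = nm.dl_moment_coefficients(net)
        assert coef.a1 == pytest.approx((4 - 1) / v)

    def test_homogeneous_consistent_data(self, ab_ac_net):
        net = ab_ac_net.with_outcomes(ab_ac_net.X @ np.array([0.4, 0.1]))
        res = nm.estimate_dl(net)
        assert res.vc.tau_beta_sq == 0.0 and res.vc.tau_omega_sq == 0.0

    def test_consistency_model_matches_univariate_closed_form(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0.0, 1.0, 7)
        v = rng.uniform(0.1, 1.0, 7)
        net = make_univariate(y, v)
        res = nm.estimate_dl(net, model="consistency")
        assert res.vc.tau_beta_sq == pytest.approx(oracles.uni_dl(y, v), abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_moment_equations_hold_at_estimate(self, seed):
        net = simulated_net(seed + 20, n_treatments=5, design_mix={2: 9, 3: 3},
                            vc=(0.4, 0.4))
        res = nm.estimate_dl(net)
        coef = res.diagnostics["coefficients"]
        tb, tw = res.vc.tau_beta_sq, res.vc.tau_omega_sq
        if not res.vc.truncated_beta:
            assert coef.q_het0 == pytest.approx(coef.df_het + coef.b1 * tb, abs=1e-9)
        if not res.vc.truncated_omega:
            assert coef.q_net0 == pytest.approx(
                coef.a0 + coef.a1 * tb + coef.a2 * tw, abs=1e-9
            )

    def test_truncated_q_matches_pm_weights(self, ab_ac_net):
        """When both components truncate to zero, the PM pivot at the origin
        and the DL Q statistic are the same quadratic form."""
        net = ab_ac_net
        coef = nm.dl_moment_coefficients(net)
        assert nm.q_pivot_net(net, (0.0, 0.0)).value == pytest.approx(coef.q_net0)


class TestLikelihood:
    def test_location_invariance(self, medium_net):
        net = medium_net
        shift = net.X @ np.full(net.c, 2.5)
        shifted = net.with_outcomes(net.Y + shift)
        for vc in [(0.0, 0.0), (0.4, 0.2)]:
            assert nm.restricted_loglik(shifted, vc) == pytest.approx(
                nm.restricted_loglik(net, vc), rel=1e-12
            )

    def test_univariate_closed_form(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.2, 0.7, 6)
        v = rng.uniform(0.1, 0.9, 6)
        net = make_univariate(y, v)
        for t in (0.0, 0.3, 1.1):
            assert nm.restricted_loglik(net, (t, 0.0)) == pytest.approx(
                oracles.uni_restricted_loglik(y, v, t), rel=1e-12
            )

    def test_reml_univariate_matches_scan(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0.0, 1.0, 9)
        v = rng.uniform(0.05, 0.6, 9)
        net = make_univariate(y, v)
        res = nm.estimate_reml(net, "consistency")
        grid = np.linspace(0, 5, 20001)
        best = grid[np.argmax([oracles.uni_restricted_loglik(y, v, t) for t in grid])]
        assert res.vc.tau_beta_sq == pytest.approx(best, abs=5e-4)

    def test_reml_dominates_moment_estimates(self, medium_net):
        net = medium_net
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reml = nm.estimate_reml(net)
            pm = nm.estimate_pm_full(net)
            dl = nm.estimate_dl(net)
        ll_reml = nm.restricted_loglik(net, reml.vc)
        assert ll_reml >= nm.restricted_loglik(net, pm.vc) - 1e-6
        assert ll_reml >= nm.restricted_loglik(net, dl.vc) - 1e-6

    def test_parameter_recovery_large_network(self):
        truth = (0.5, 0.25)
        net = simulated_net(77, n_treatments=6, design_mix={2: 160, 3: 40},
                            vc=truth)
        res = nm.estimate_reml(net)
        assert res.vc.tau_beta_sq == pytest.approx(truth[0], abs=0.2)
        assert res.vc.tau_omega_sq == pytest.approx(truth[1], abs=0.25)

    def test_ml_maximizes_marginal_likelihood(self, medium_net):
        ml = nm.estimate_ml(medium_net)
        assert ml.diagnostics["converged"]
        at_opt = nm.marginal_loglik(medium_net, ml.vc)
        for perturbed in [(ml.vc.tau_beta_sq + 0.1, ml.vc.tau_omega_sq),
                          (ml.vc.tau_beta_sq, ml.vc.tau_omega_sq + 0.1)]:
            assert at_opt >= nm.marginal_loglik(medium_net, perturbed) - 1e-8


class TestReferenceInvariance:
    @pytest.mark.parametrize("method,model", [
        ("pm", "full"), ("dl", "full"), ("reml", "full"), ("pm", "consistency"),
    ])
    def test_variance_estimates_unchanged(self, medium_net, method, model):
        from conftest import blocks_from_net

        blocks = blocks_from_net(medium_net)
        other_ref = medium_net.treatments[1]
        net2 = nm.assemble_network(blocks, reference=other_ref)
        r1 = nm.estimate(medium_net, method, model)
        r2 = nm.estimate(net2, method, model)
        assert r2.vc.tau_beta_sq == pytest.approx(r1.vc.tau_beta_sq, abs=1e-8)
        assert r2.vc.tau_omega_sq == pytest.approx(r1.vc.tau_omega_sq, abs=1e-8)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_reml_matches_metafor(tmp_path, medium_net):
    """Cross-check REML against metafor's rma.mv with the matching
    compound-symmetry random-effects structure (an independent
    implementation of the same model)."""
    net = medium_net
    rows = "\n".join(
        f"{s},{':'.join(d)},{c[0]}{c[1]},{float(net.Y[i])!r}"
        for i, (s, d, c) in enumerate(net.row_map)
    )
    (tmp_path / "net.csv").write_text("study,design,comp,yi\n" + rows + "\n")
    np.savetxt(tmp_path / "V.csv", net.S, delimiter=",")
    np.savetxt(tmp_path / "X.csv", net.X, delimiter=",")
    script = textwrap.dedent(
        """
        suppressMessages(library(metafor))
        d <- read.csv("net.csv")
        V <- as.matrix(read.csv("V.csv", header=FALSE))
        X <- as.matrix(read.csv("X.csv", header=FALSE))
        f <- rma.mv(yi, V, mods=X, intercept=FALSE,
                    random=list(~comp|study, ~comp|design),
                    struct=c("CS","CS"), rho=0.5, phi=0.5, data=d,
                    method="REML")
        cat(f$tau2, f$gamma2, sep="\\n")
        """
    )
    (tmp_path / "check.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True,
        timeout=300,
    )
    assert out.returncode == 0, out.stderr
    r_tb, r_tw = (float(x) for x in out.stdout.split())
    ours = nm.estimate_reml(net).vc
    assert ours.tau_beta_sq == pytest.approx(r_tb, abs=2e-4)
    assert ours.tau_omega_sq == pytest.approx(r_tw, abs=2e-4)
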