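"""The mixed-model learner: quadrature accuracy, MLE quality, shrinkage.

The independent oracles here are (a) dense numerical integration of each
word's random-effect integral, (b) grid refinement of the marginal MLE on
toy data, and (c) R's lme4 (a separately authored mixed-model fitter)
invoked through Rscript on identical data.
"""

import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom as binom_dist
from scipy.stats import norm

import lexdrift as ld
from lexdrift.inference import conditional_modes, marginal_loglik

from conftest import make_state


def brute_force_loglik(theta, state, spec=ld.L1, transform="raw"):
    """Dense-quadrature oracle for the marginal log-likelihood."""
    b0, b_freq, sigma = theta
    total = 0.0
    t = np.log(state.freqs) if transform == "log" else state.freqs.astype(float)
    for i in range(state.lexicon.n_types):
        eta0 = (b0 if spec.estimate_intercept else 0.0) + (
            b_freq * t[i] if spec.estimate_freq_effect else 0.0
        )
        if sigma == 0:
            p = 1 / (1 + math.exp(-eta0))
            total += binom_dist.logpmf(state.n_red[i], state.freqs[i], p)
            continue

        def integrand(u, i=i, eta0=eta0):
            p = 1 / (1 + np.exp(-(eta0 + u)))
            return binom_dist.pmf(state.n_red[i], state.freqs[i], p) * norm.pdf(
                u, 0, sigma
            )

        val, _ = quad(
            integrand, -10 * sigma, 10 * sigma, limit=400,
            epsabs=1e-300, epsrel=1e-12,
        )
        total += math.log(val)
    return total


class TestMarginalLoglik:
    def test_closed_form_single_bernoulli(self):
        lex = ld.Lexicon([("a", 1), ("b", 1)])
        state = make_state(lex, [1, 0])
        # sigma = 0, b0 = 0: each word contributes log 0.5
        ll = marginal_loglik((0.0, 0.0, 0.0), state, ld.L1)
        assert ll == pytest.approx(2 * math.log(0.5), abs=1e-12)

    def test_closed_form_two_trials(self):
        lex = ld.Lexicon([("a", 2)])
        state = make_state(lex, [1])
        ll = marginal_loglik((0.0, 0.0, 0.0), state, ld.L1)
        assert ll == pytest.approx(math.log(2 * 0.25), abs=1e-12)

    def test_agq_matches_brute_force_on_random_instances(self):
        # sigma spans the word-effect range the generative model uses
        # (0.2-0.8); far larger spreads need more quadrature nodes
        rng = np.random.default_rng(31)
        for _ in range(50):
            k = rng.integers(2, 6)
            freqs = rng.integers(1, 11, size=k)
            lex = ld.Lexicon([(f"w{i}", int(f)) for i, f in enumerate(freqs)])
            n_red = rng.integers(0, freqs + 1)
            state = make_state(lex, n_red)
            theta = (
                float(rng.normal(0, 1.5)),
                0.0,
                float(rng.uniform(0.1, 1.0)),
            )
            agq = marginal_loglik(theta, state, ld.L1, n_quad=15)
            exact = brute_force_loglik(theta, state)
            assert agq == pytest.approx(exact, abs=1e-6)

    def test_quadrature_stable_between_15_and_25_nodes(self):
        rng = np.random.default_rng(5)
        freqs = rng.integers(1, 11, size=5)
        lex = ld.Lexicon([(f"w{i}", int(f)) for i, f in enumerate(freqs)])
        state = make_state(lex, rng.integers(0, freqs + 1))
        for theta in [(-1.0, 0.0, 0.5), (0.3, 0.0, 1.2), (-2.0, 0.0, 0.05)]:
            a = marginal_loglik(theta, state, ld.L1, n_quad=15)
            b = marginal_loglik(theta, state, ld.L1, n_quad=25)
            assert a == pytest.approx(b, abs=1e-6)

    def test_invalid_arguments_rejected(self, eth):
        state = make_state(eth, np.minimum(eth.freqs, 1))
        with pytest.raises(ValueError):
            marginal_loglik((0, 0, -0.5), state, ld.L1)
        with pytest.raises(ValueError):
            marginal_loglik((0, 0, 0.5), state, ld.L1, n_quad=0)


class TestFit:
    def test_homogeneous_large_counts_recover_flat_model(self):
        lex = ld.Lexicon([(f"w{i}", 2000) for i in range(8)])
        state = make_state(lex, [1000] * 8)
        fit = ld.fit(state, ld.L1)
        assert abs(fit.b0_hat) < 0.05
        assert fit.sigma_hat < 0.05

    def test_matches_grid_refined_oracle_on_toy_data(self):
        lex = ld.Lexicon([("a", 8), ("b", 6), ("c", 10)])
        state = make_state(lex, [2, 5, 3])
        fit = ld.fit(state, ld.L1, n_quad=15)
        # 2-D grid refinement over brute-force integrals
        b0s = np.linspace(-2, 2, 41)
        sigmas = np.linspace(0.0, 2.5, 26)
        grid = [
            (brute_force_loglik((b0, 0, s), state), b0, s)
            for b0 in b0s
            for s in sigmas
        ]
        best, b0_c, s_c = max(grid)
        for width in (0.2, 0.05, 0.0125):  # refine around the argmax
            b0s = np.linspace(b0_c - width, b0_c + width, 21)
            sigmas = np.linspace(max(0.0, s_c - width), s_c + width, 21)
            grid = [
                (brute_force_loglik((b0, 0, s), state), b0, s)
                for b0 in b0s
                for s in sigmas
            ]
            best, b0_c, s_c = max(grid)
        assert fit.b0_hat == pytest.approx(b0_c, abs=1e-2)
        assert fit.sigma_hat == pytest.approx(s_c, abs=1e-2)
        assert fit.loglik >= best - 1e-6

    def test_parameter_recovery_on_flap_scale_lexicon(self, flap_lexicon):
        params = ld.SeedParams(b0=-1.0, b_freq=0.0, b_w=0.4)
        b0s, sigmas = [], []
        for k in range(20):
            state = ld.seed_generation(flap_lexicon, params, np.random.default_rng(k))
            fit = ld.fit(state, ld.L1, n_quad=15)
            b0s.append(fit.b0_hat)
            sigmas.append(fit.sigma_hat)
        assert np.mean(b0s) == pytest.approx(-1.0, abs=0.1)
        assert np.mean(sigmas) == pytest.approx(0.4, abs=0.1)

    def test_sigma_zero_data_hits_boundary(self):
        lex = ld.Lexicon([(f"w{i}", 60) for i in range(12)])
        params = ld.SeedParams(b0=-0.5, b_freq=0.0, b_w=0.0)
        at_zero = 0
        for k in range(20):
            state = ld.seed_generation(lex, params, np.random.default_rng(100 + k))
            fit = ld.fit(state, ld.L1)
            at_zero += fit.sigma_hat < 0.05
        assert at_zero >= 18  # >= 90% of replicates

    def test_frequency_slope_recovered(self, flap_lexicon):
        params = ld.SeedParams(b0=-1.0, b_freq=0.02, b_w=0.2)
        slopes = []
        for k in range(5):
            state = ld.seed_generation(flap_lexicon, params, np.random.default_rng(k))
            fit = ld.fit(state, ld.L3, n_quad=5, generative_transform="raw")
            slopes.append(fit.b_freq_hat)
        assert np.mean(slopes) == pytest.approx(0.02, rel=0.3)

    def test_too_few_words_rejected(self):
        lex = ld.Lexicon([("a", 3)])
        with pytest.raises(ValueError):
            ld.fit(make_state(lex, [1]), ld.L1)


class TestConditionalModes:
    def test_sigma_zero_gives_all_zeros(self, eth):
        state = make_state(eth, np.minimum(eth.freqs, 2))
        u = conditional_modes(state, 0.0, 0.0)
        assert all(v == 0.0 for v in u.values())

    def test_symmetric_likelihood_has_zero_mode(self):
        lex = ld.Lexicon([("a", 4)])
        u = conditional_modes(make_state(lex, [2]), 0.0, 1.0)
        assert u["a"] == pytest.approx(0.0, abs=1e-8)

    def test_mode_matches_scalar_optimization(self):
        lex = ld.Lexicon([("a", 7)])
        state = make_state(lex, [6])
        sigma, eta0 = 0.8, -0.4
        u = conditional_modes(state, eta0, sigma)["a"]
        from scipy.optimize import minimize_scalar

        def neg(x):
            p = 1 / (1 + math.exp(-(eta0 + x)))
            return -(6 * math.log(p) + 1 * math.log(1 - p) - x**2 / (2 * sigma**2))

        ref = minimize_scalar(neg, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-12}).x
        assert u == pytest.approx(ref, abs=1e-6)

    def test_shrinkage_scales_with_evidence(self):
        # both words always reduced, below-mean fixed eta: the more frequent
        # word's effect is pulled less toward zero (radicalization direction)
        lex = ld.Lexicon([("rare", 2), ("freq", 50)])
        state = make_state(lex, [2, 50])
        u = conditional_modes(state, -1.0, 1.0)
        assert u["freq"] > u["rare"] > 0


@pytest.fixture(scope="module")
def rscript():
    path = shutil.which("Rscript")
    if path is None:
        pytest.fail("Rscript not on PATH; lme4 cross-check cannot run")
    return path


class TestLme4CrossCheck:
    def test_laplace_fit_matches_lme4(self, tmp_path_factory, rscript, eth):
        tmp = tmp_path_factory.mktemp("lme4")
        states, paths = [], []
        for k in range(3):
            st = ld.seed_generation(
                eth, ld.SeedParams(-1.5, 0.01, 0.6), np.random.default_rng(200 + k)
            )
            p = tmp / f"d{k}.tsv"
            st.to_frame().to_csv(p, sep="\t", index=False)
            states.append(st)
            paths.append(p)
        script = (
            "suppressMessages(library(lme4));"
            + ";".join(
                f"d<-read.delim('{p}');"
                "m<-suppressWarnings(glmer(cbind(n_red,freq-n_red)~1+(1|word),"
                "data=d,family=binomial));"
                "cat(sprintf('%.6f %.6f\\n',fixef(m)[1],sqrt(unlist(VarCorr(m))[1])))"
                for p in paths
            )
        )
        out = subprocess.run(
            [rscript, "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = [tuple(map(float, line.split())) for line in out.stdout.strip().splitlines()]
        for st, (b0_r, sig_r) in zip(states, ref):
            fit = ld.fit(st, ld.L1, n_quad=1)
            assert fit.b0_hat == pytest.approx(b0_r, abs=0.02)
            assert fit.sigma_hat == pytest.approx(sig_r, abs=0.02)
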