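"""Birth-death-gain model: transition probabilities, likelihood, posteriors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, poisson

import genomeflux as gf
from genomeflux.bdg_model import TruncationError, _Engine
from genomeflux.io_formats import ValidationError


def expm_series(Q: np.ndarray, t: float, tol: float = 1e-14) -> np.ndarray:
    """Independent oracle: uniformized power series for exp(Qt)."""
    q = np.abs(np.diag(Q)).max() or 1.0
    A = np.eye(len(Q)) + Q / q
    term = np.eye(len(Q))
    out = np.zeros_like(Q)
    log_weight = -q * t
    k = 0
    # Poisson-weighted sum of powers of the uniformized kernel
    while True:
        w = np.exp(log_weight)
        out += w * term
        if k > q * t and w < tol:
            break
        k += 1
        log_weight += np.log(q * t) - np.log(k)
        term = term @ A
        if k > 10_000:  # pragma: no cover
            raise RuntimeError("series did not converge")
    return out


def tridiagonal_generator(kappa, lam, mu, M):
    n = np.arange(M + 1, dtype=float)
    Q = np.zeros((M + 1, M + 1))
    up, down = kappa + n * lam, n * mu
    Q[np.arange(M), np.arange(1, M + 1)] = up[:-1]
    Q[np.arange(1, M + 1), np.arange(M)] = down[1:]
    Q[np.arange(M + 1), np.arange(M + 1)] = -(up + down)
    return Q


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = gf.transition_matrix(0.5, 0.2, 1.0, 0.0, 10)
        np.testing.assert_array_equal(P, np.eye(11))

    def test_pure_death_is_binomial(self):
        # kappa=lam=0, mu=1, t=ln2: each copy survives with prob 1/2
        P = gf.transition_matrix(0.0, 0.0, 1.0, np.log(2), 12)
        assert P[2, 0] == pytest.approx(0.25, abs=1e-12)
        for n in (1, 3, 5):
            np.testing.assert_allclose(P[n, :n + 1],
                                       binom.pmf(np.arange(n + 1), n, 0.5),
                                       atol=1e-12)

    @pytest.mark.parametrize("rates,t,M", [
        ((0.5, 0.3, 1.0), 1.0, 40),
        ((1.2, 0.0, 0.7), 0.5, 30),
        ((0.0, 0.4, 1.0), 2.0, 25),
    ])
    def test_matches_uniformization_series(self, rates, t, M):
        P = gf.transition_matrix(*rates, t, M)
        oracle = expm_series(tridiagonal_generator(*rates, M), t)
        assert np.abs(P - oracle).max() < 1e-10

    def test_chapman_kolmogorov(self):
        M = 60
        P1 = gf.transition_matrix(0.5, 0.2, 1.0, 0.4, M)
        P2 = gf.transition_matrix(0.5, 0.2, 1.0, 0.7, M)
        P12 = gf.transition_matrix(0.5, 0.2, 1.0, 1.1, M)
        # agreement within truncation tolerance on low rows
        assert np.abs((P1 @ P2 - P12)[:20]).max() < 1e-8

    def test_rows_substochastic_with_deficit(self):
        P = gf.transition_matrix(0.5, 0.3, 1.0, 1.0, 15)
        deficits = gf.truncation_deficit(P)
        assert (P >= 0).all() and (P <= 1).all()
        assert (deficits >= -1e-12).all()
        assert deficits[15] > deficits[0]  # top rows leak most

    def test_truncation_error_signals_increase_m(self):
        with pytest.raises(TruncationError):
            gf.transition_matrix(2.0, 0.5, 1.0, 3.0, 5, check_rows=[5],
                                 deficit_tol=1e-9)


class TestRootPrior:
    def test_poisson_when_no_duplication(self):
        prior = gf.root_prior(2.0, 0.0, 1.0, 60)
        assert prior[0] == pytest.approx(np.exp(-2.0), rel=1e-9)
        np.testing.assert_allclose(prior[:10], poisson.pmf(np.arange(10), 2.0),
                                   rtol=1e-9)

    def test_normalized_after_truncation(self):
        for rates in [(0.6, 0.3, 1.0), (2.0, 0.0, 0.5), (0.1, 0.05, 2.0)]:
            assert gf.root_prior(*rates, 30).sum() == pytest.approx(1.0)

    def test_negative_binomial_mean(self):
        prior = gf.root_prior(0.6, 0.3, 1.0, 300)
        mean = (prior * np.arange(301)).sum()
        assert mean == pytest.approx(0.6 / (1.0 - 0.3), rel=1e-9)

    def test_supercritical_rejected(self):
        with pytest.raises(ValidationError):
            gf.root_prior(0.5, 1.2, 1.0, 20)


class TestDiscreteGamma:
    @pytest.mark.parametrize("shape,K", [(0.5, 2), (1.0, 4), (5.0, 3)])
    def test_mean_one_and_ordered(self, shape, K):
        m = gf.discrete_gamma_multipliers(shape, K)
        assert len(m) == K
        assert m.mean() == pytest.approx(1.0)
        assert (np.diff(m) > 0).all()

    def test_large_shape_near_uniform(self):
        m = gf.discrete_gamma_multipliers(200.0, 4)
        assert np.abs(m - 1).max() < 0.1


class TestFamilyLogLikelihood:
    def test_zero_length_edge_tree_gives_prior(self):
        tree = gf.parse_tree("(A:0,B:0);")
        rates = gf.BDGRates(kappa=0.8, lam=0.2, mu=1.0)
        M = 30
        prior = gf.root_prior(0.8, 0.2, 1.0, M)
        for n in (0, 1, 3):
            ll = gf.family_log_likelihood(tree, {"A": n, "B": n}, rates, M=M,
                                          condition_on_observed=False)
            assert ll == pytest.approx(np.log(prior[n]), abs=1e-12)

    def test_two_leaf_brute_force(self, tree2):
        rates = gf.BDGRates(kappa=0.5, lam=0.2, mu=1.0)
        M = 25
        PA = gf.transition_matrix(0.5, 0.2, 1.0, 0.7, M)
        PB = gf.transition_matrix(0.5, 0.2, 1.0, 1.2, M)
        prior = gf.root_prior(0.5, 0.2, 1.0, M)
        for x1, x2 in [(0, 1), (2, 3), (1, 0), (4, 4)]:
            expected = np.log(sum(prior[a] * PA[a, x1] * PB[a, x2]
                                  for a in range(M + 1)))
            got = gf.family_log_likelihood(tree2, {"A": x1, "B": x2}, rates,
                                           M=M, condition_on_observed=False)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_conditioned_profiles_sum_to_one(self, tree2):
        # summing over enough profiles approaches 1 (truncation tolerance)
        rates = gf.BDGRates(kappa=0.4, lam=0.1, mu=1.2)
        M, top = 60, 12
        total = sum(
            np.exp(gf.family_log_likelihood(tree2, {"A": a, "B": b}, rates,
                                            M=M, condition_on_observed=True))
            for a, b in itertools.product(range(top + 1), repeat=2)
            if (a, b) != (0, 0)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_leaf_order_invariance(self, make_counts_fixture):
        ta = gf.parse_tree("((A:0.4,B:0.6):0.3,C:0.8);")
        tb = gf.parse_tree("((B:0.6,A:0.4):0.3,C:0.8);")
        rates = gf.BDGRates(kappa=0.6, lam=0.2, mu=1.0,
                            category_multipliers=(0.6, 1.4),
                            category_probs=(0.5, 0.5))
        prof = {"A": 2, "B": 0, "C": 1}
        la = gf.family_log_likelihood(ta, prof, rates, M=20)
        lb = gf.family_log_likelihood(tb, prof, rates, M=20)
        assert la == pytest.approx(lb, abs=1e-12)

    def test_m_below_max_count_rejected(self, tree2):
        with pytest.raises(ValidationError):
            gf.family_log_likelihood(tree2, {"A": 9, "B": 0},
                                     gf.BDGRates(0.5, 0.2, 1.0), M=5)


def enumerate_posteriors(prof, M=6, kappa=0.6, lam=0.25, mu=1.0,
                         cats=((1.0, 1.0),)):
    """Exhaustive oracle for the 3-leaf tree ((A,B):0.3,C) with branch
    lengths A=0.4, B=0.6, C=0.8: sums over all ancestral state pairs."""
    lengths = {"A": 0.4, "B": 0.6, "I": 0.3, "C": 0.8}
    total = 0.0
    joint = {e: np.zeros((M + 1, M + 1)) for e in lengths}
    for c, pi in cats:
        P = {n: gf.transition_matrix(kappa * c, lam * c, mu * c, t, M)
             for n, t in lengths.items()}
        prior = gf.root_prior(kappa * c, lam * c, mu * c, M)
        for r in range(M + 1):
            for i in range(M + 1):
                w = (pi * prior[r] * P["I"][r, i] * P["A"][i, prof["A"]]
                     * P["B"][i, prof["B"]] * P["C"][r, prof["C"]])
                total += w
                joint["I"][r, i] += w
                joint["A"][i, prof["A"]] += w
                joint["B"][i, prof["B"]] += w
                joint["C"][r, prof["C"]] += w

    def events(J):
        J = J / total
        S = M + 1
        return np.array([
            J[0, 1:].sum(),
            J[1:, 0].sum(),
            sum(J[s, m] for s in range(1, S) for m in range(s + 1, S)),
            sum(J[s, m] for s in range(2, S) for m in range(1, s)),
        ])

    return {e: events(j) for e, j in joint.items()}


class TestPosteriorEvents:
    @pytest.mark.parametrize("prof", [
        {"A": 1, "B": 0, "C": 2},
        {"A": 0, "B": 0, "C": 1},
        {"A": 3, "B": 2, "C": 0},
    ])
    def test_three_leaf_exhaustive_oracle(self, tree3, prof):
        cats = ((0.5, 0.5), (1.5, 0.5))
        rates = gf.BDGRates(kappa=0.6, lam=0.25, mu=1.0,
                            category_multipliers=(0.5, 1.5),
                            category_probs=(0.5, 0.5))
        cm = gf.CountMatrix(pd.DataFrame({k: [v] for k, v in prof.items()},
                                         index=["fam"]))
        model = gf.FittedModel(tree=tree3, rates=rates, log_likelihood=0.0,
                               M=6)
        post = gf.posterior_events(model, cm)
        oracle = enumerate_posteriors(prof, M=6, cats=cats)
        for e_i, name in enumerate(post.edge_names):
            key = name if name in "ABC" else "I"
            np.testing.assert_allclose(post.probs[0, e_i], oracle[key],
                                       atol=1e-6)

    def test_no_loss_when_mu_vanishes(self, tree3):
        # mu -> 0 with kappa/mu fixed: loss posterior shrinks like mu*t
        cm = gf.CountMatrix(pd.DataFrame({"A": [1], "B": [1], "C": [1]},
                                         index=["fam"]))
        p_loss = []
        for mu in (1e-1, 1e-2, 1e-3):
            rates = gf.BDGRates(kappa=mu, lam=0.0, mu=mu)
            model = gf.FittedModel(tree=tree3, rates=rates,
                                   log_likelihood=0.0, M=20)
            post = gf.posterior_events(model, cm)
            p_loss.append(post.probs[:, :, 1].max())
        assert p_loss[-1] < 1e-3
        assert p_loss[0] > p_loss[1] > p_loss[2]

    def test_probability_bounds(self, tree3, rng):
        rates = gf.BDGRates(kappa=0.6, lam=0.2, mu=1.0)
        frame = pd.DataFrame(rng.integers(0, 4, size=(50, 3)),
                             index=[f"f{i}" for i in range(50)],
                             columns=["A", "B", "C"])
        model = gf.FittedModel(tree=tree3, rates=rates, log_likelihood=0.0,
                               M=20)
        post = gf.posterior_events(model, gf.CountMatrix(frame))
        p = post.probs
        assert (p >= 0).all() and (p <= 1).all()
        # gain excludes loss and expansion on the same edge
        assert (p[:, :, 0] + p[:, :, 1] <= 1 + 1e-9).all()
        assert (p[:, :, 0] + p[:, :, 2] <= 1 + 1e-9).all()

    def test_missing_family_rejected(self, tree3, make_counts_fixture):
        cm = make_counts_fixture({"A": [1], "B": [0], "C": [1]}, ["f0"])
        model = gf.FittedModel(tree=tree3,
                               rates=gf.BDGRates(0.5, 0.1, 1.0),
                               log_likelihood=0.0, M=10)
        with pytest.raises(ValidationError):
            gf.posterior_events(model, cm, family_ids=["nope"])


class TestSummarizeEvents:
    def _posteriors(self):
        probs = np.zeros((2, 3, 4))
        probs[0, 0, 0] = 0.7
        probs[1, 2, 1] = 0.4
        probs[1, 1, 2] = 0.2
        return gf.EventPosteriors(["f1", "f2"], ["e1", "e2", "e3"], probs)

    def test_single_entry_sum(self):
        post = self._posteriors()
        s = gf.summarize_events(post, n_genomes=5, family_ids=["f1"])
        assert s.gains == pytest.approx(0.7)
        assert s.losses == 0 and s.n_families == 1

    def test_additivity_over_disjoint_sets(self):
        post = self._posteriors()
        s1 = gf.summarize_events(post, 5, ["f1"])
        s2 = gf.summarize_events(post, 5, ["f2"])
        both = gf.summarize_events(post, 5)
        merged = s1 + s2
        assert merged.total == pytest.approx(both.total)
        assert merged.n_families == both.n_families == 2

    def test_order_invariance(self):
        post = self._posteriors()
        a = gf.summarize_events(post, 5, ["f1", "f2"])
        b = gf.summarize_events(post, 5, ["f2", "f1"])
        assert a.as_dict() == b.as_dict()


@pytest.fixture(scope="module")
def fitted():
    tree = gf.simulate_tree(8, seed=3, depth=1.0)
    cfg = gf.SimConfig(n_leaves=8, n_families=800, defense_fraction=0.0,
                       kappa=0.4, lam=0.2, mu=1.0, tree_depth=1.0, seed=11)
    counts, _, _ = gf.simulate_families(tree, cfg)
    model = gf.fit_parameters(tree, counts,
                              gf.FitConfig(max_categories=2, seed=0))
    return tree, counts, model


class TestFitParameters:
    def test_mle_dominates_true_parameters(self, fitted):
        tree, counts, model = fitted
        true_ll = gf.matrix_log_likelihood(
            tree, counts.drop_all_zero(), gf.BDGRates(0.4, 0.2, 1.0)).sum()
        assert model.log_likelihood >= true_ll - 1e-6

    def test_trace_non_decreasing(self, fitted):
        _, _, model = fitted
        lls = [row["log_likelihood"] for row in model.trace]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_rate_recovery_ballpark(self, fitted):
        _, _, model = fitted
        # modest n: generous bands (the acceptance run uses 2000 families)
        assert model.rates.kappa == pytest.approx(0.4, rel=0.3)
        assert model.rates.mu == pytest.approx(1.0, rel=0.3)

    def test_empty_matrix_rejected(self, tree2):
        frame = pd.DataFrame({"A": [0], "B": [0]}, index=["f0"])
        with pytest.raises(ValidationError):
            gf.fit_parameters(tree2, gf.CountMatrix(frame))

    def test_model_round_trip(self, fitted, tmp_path):
        tree, _, model = fitted
        path = tmp_path / "model.txt"
        gf.write_model(model, path)
        back = gf.read_model(path, tree)
        assert back.rates.kappa == pytest.approx(model.rates.kappa)
        assert back.rates.category_multipliers == pytest.approx(
            model.rates.category_multipliers)
        assert back.log_likelihood == pytest.approx(model.log_likelihood)
        assert len(back.trace) == len(model.trace)


class TestRatesValidation:
    def test_supercritical_rejected(self):
        with pytest.raises(ValidationError):
            gf.BDGRates(kappa=0.5, lam=1.5, mu=1.0)

    def test_category_probs_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            gf.BDGRates(kappa=0.5, lam=0.1, mu=1.0,
                        category_multipliers=(0.5, 1.5),
                        category_probs=(0.3, 0.3))
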