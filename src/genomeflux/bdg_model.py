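"""Phylogenetic birth-death-gain model of gene-family content evolution.

A family of size ``n`` evolves along each tree edge as a continuous-time
Markov chain with up-rate ``kappa + n*lambda`` (gain + per-copy
duplication) and down-rate ``n*mu`` (per-copy loss). The module provides

* truncated transition matrices (dense matrix exponential of the
  tridiagonal generator, with the flow out of the top state dropped so
  the row-sum deficit measures the truncation error),
* the stationary root prior (negative binomial for ``lambda > 0``,
  Poisson for ``lambda = 0``),
* the family likelihood by pruning over size states, optionally
  conditioned on the family being observed (non-all-zero profile) and
  mixed over discrete-gamma rate categories,
* staged maximum-likelihood fitting of (kappa, lambda, mu), optional
  per-edge rate multipliers and up to four rate categories, and
* posterior decoding of gain / loss / expansion / reduction events per
  family per edge via an inside-outside pass.

Events are parent-to-child state patterns on an edge: gain = (0 -> >=1),
loss = (>=1 -> 0), expansion = (child > parent >= 1), reduction =
(parent > child >= 1). Expansion and reduction generalize single-copy
steps to any jump, mirroring the presence/absence logic of gain and loss;
a multi-copy jump counts as one event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats
from scipy.special import expit, logsumexp

from .io_formats import CountMatrix, SpeciesTree, ValidationError

logger = logging.getLogger("genomeflux")

__all__ = [
    "EVENT_TYPES",
    "NumericalError",
    "TruncationError",
    "BDGRates",
    "FitConfig",
    "FittedModel",
    "EventPosteriors",
    "EventSummary",
    "transition_matrix",
    "truncation_deficit",
    "root_prior",
    "discrete_gamma_multipliers",
    "family_log_likelihood",
    "matrix_log_likelihood",
    "fit_parameters",
    "posterior_events",
    "summarize_events",
    "default_truncation_bound",
    "write_model",
    "read_model",
]

EVENT_TYPES = ("gain", "loss", "expansion", "reduction")


class NumericalError(RuntimeError):
    """A numerical failure (non-convergence, truncation overflow)."""


class TruncationError(NumericalError):
    """Truncation mass exceeds tolerance: increase the state bound M."""


# --------------------------------------------------------------------------
# Rates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BDGRates:
    """Model parameters of the birth-death-gain process.

    Parameters
    ----------
    kappa
        Gain (immigration) rate per family per unit time.
    lam
        Duplication (birth) rate per gene copy per unit time.
    mu
        Loss (death) rate per gene copy per unit time.
    category_multipliers, category_probs
        Discrete rate categories; each multiplier scales all three rates
        jointly (so ``lam < mu`` is preserved within every category).
    edge_multipliers
        Optional per-edge positive scale factors, keyed by edge name
        (the child node's name); missing edges default to 1.
    gamma_shape
        Shape of the discrete-gamma category distribution, recorded for
        provenance when categories were derived from one.
    """

    kappa: float
    lam: float
    mu: float
    category_multipliers: tuple[float, ...] = (1.0,)
    category_probs: tuple[float, ...] = (1.0,)
    edge_multipliers: Mapping[str, float] | None = None
    gamma_shape: float | None = None

    def __post_init__(self):
        if min(self.kappa, self.lam, self.mu) < 0:
            raise ValidationError("rates must be >= 0")
        K = len(self.category_multipliers)
        if K != len(self.category_probs) or not (1 <= K <= 4):
            raise ValidationError("need 1..4 categories with matching probs")
        if any(m <= 0 for m in self.category_multipliers):
            raise ValidationError("category multipliers must be > 0")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValidationError("category probabilities must sum to 1")
        if self.edge_multipliers is not None:
            if any(m <= 0 for m in self.edge_multipliers.values()):
                raise ValidationError("edge multipliers must be > 0")
        if self.lam >= self.mu and self.lam > 0:
            raise ValidationError(
                "stationary root prior requires lambda < mu (or lambda = 0)"
            )

    @property
    def n_categories(self) -> int:
        return len(self.category_multipliers)

    def edge_multiplier_for(self, edge_name: str) -> float:
        if self.edge_multipliers is None:
            return 1.0
        return float(self.edge_multipliers.get(edge_name, 1.0))


# --------------------------------------------------------------------------
# Transition probabilities and root prior
# --------------------------------------------------------------------------

def _generator(kappa: float, lam: float, mu: float, M: int) -> np.ndarray:
    n = np.arange(M + 1, dtype=float)
    up = kappa + n * lam
    down = n * mu
    Q = np.zeros((M + 1, M + 1))
    Q[np.arange(M), np.arange(1, M + 1)] = up[:-1]
    Q[np.arange(1, M + 1), np.arange(M)] = down[1:]
    # diagonal keeps the FULL exit rate, including the up-flow out of state
    # M that leaves the truncated space, so rows are sub-stochastic and the
    # row-sum deficit equals the probability of ever escaping above M.
    Q[np.arange(M + 1), np.arange(M + 1)] = -(up + down)
    return Q


def transition_matrix(kappa: float, lam: float, mu: float, t: float, M: int,
                      *, check_rows: Sequence[int] | None = None,
                      deficit_tol: float = 1e-9) -> np.ndarray:
    """Transition probabilities P_t(n -> m) on the truncated space {0..M}.

    Computed as the matrix exponential of the truncated tridiagonal
    generator. If *check_rows* is given, the truncation deficit of those
    rows is required to stay below *deficit_tol*, otherwise a
    :class:`TruncationError` asks for a larger M.
    """
    if t < 0:
        raise ValidationError("branch length must be >= 0")
    if M < 1:
        raise ValidationError("truncation bound M must be >= 1")
    if min(kappa, lam, mu) < 0:
        raise ValidationError("rates must be >= 0")
    if t == 0:
        return np.eye(M + 1)
    P = scipy.linalg.expm(_generator(kappa, lam, mu, M) * t)
    np.clip(P, 0.0, 1.0, out=P)
    if check_rows is not None:
        deficit = truncation_deficit(P)[list(check_rows)]
        if deficit.max(initial=0.0) > deficit_tol:
            raise TruncationError(
                f"truncation mass {deficit.max():.3g} exceeds {deficit_tol:g}; "
                "increase M"
            )
    return P


def truncation_deficit(P: np.ndarray) -> np.ndarray:
    """Per-row probability mass lost to states above the truncation bound."""
    return 1.0 - P.sum(axis=1)


def root_prior(kappa: float, lam: float, mu: float, M: int) -> np.ndarray:
    """Stationary distribution of the chain, truncated to {0..M}.

    Negative binomial with size ``kappa/lam`` and success parameter
    ``lam/mu`` for ``lam > 0``; Poisson with mean ``kappa/mu`` for
    ``lam = 0``. Renormalized after truncation.
    """
    if mu <= 0:
        raise ValidationError("stationary prior requires mu > 0")
    states = np.arange(M + 1)
    if kappa == 0:
        prior = np.zeros(M + 1)
        prior[0] = 1.0  # no immigration: extinction is absorbing
        return prior
    if lam == 0:
        prior = scipy.stats.poisson.pmf(states, kappa / mu)
    else:
        if lam >= mu:
            raise ValidationError("no stationary distribution: lambda >= mu")
        prior = scipy.stats.nbinom.pmf(states, kappa / lam, 1.0 - lam / mu)
    total = prior.sum()
    if total <= 0:
        raise NumericalError("root prior vanished after truncation")
    return prior / total


def discrete_gamma_multipliers(shape: float, K: int) -> np.ndarray:
    """Mean-one rate multipliers of K equal-probability gamma slices.

    Each category takes the mean of its quantile slice of a
    Gamma(shape, scale=1/shape) distribution (mean-of-slice rule).
    """
    if shape <= 0:
        raise ValidationError("gamma shape must be > 0")
    if K == 1:
        return np.ones(1)
    edges = scipy.stats.gamma.ppf(np.linspace(0, 1, K + 1), a=shape,
                                  scale=1.0 / shape)
    upper = scipy.stats.gamma.cdf(edges, a=shape + 1, scale=1.0 / shape)
    means = K * np.diff(upper)
    return means / means.mean()  # exact mean 1 despite ppf round-off


def default_truncation_bound(max_count: int) -> int:
    return max(3 * max_count, 20)


# --------------------------------------------------------------------------
# Likelihood engine
# --------------------------------------------------------------------------

class _Engine:
    """Vectorized pruning over size states for a fixed tree and rates.

    Counts are an (n_families, n_leaves) integer array aligned to the
    tree's leaf order. All per-family quantities are computed in one
    sweep, with per-family rescaling to avoid underflow.
    """

    def __init__(self, tree: SpeciesTree, counts: np.ndarray, rates: BDGRates,
                 M: int, deficit_tol: float | None = None):
        if counts.max(initial=0) > M:
            raise ValidationError("M smaller than the maximum observed count")
        self.tree = tree
        self.counts = counts
        self.rates = rates
        self.M = M
        self.S = M + 1
        self._matrices: list[dict[int, np.ndarray]] = []
        self._priors: list[np.ndarray] = []
        check = range(int(counts.max(initial=0)) + 1) if deficit_tol else None
        cache: dict[float, np.ndarray] = {}
        for c in rates.category_multipliers:
            per_edge: dict[int, np.ndarray] = {}
            for e, child in enumerate(tree.edge_child_indices):
                m_e = rates.edge_multiplier_for(tree.edge_names[e])
                # joint scaling of all three rates == scaling elapsed time
                t_eff = tree.branch_lengths[child] * c * m_e
                if t_eff not in cache:
                    cache[t_eff] = transition_matrix(
                        rates.kappa, rates.lam, rates.mu, t_eff, M,
                        check_rows=check, deficit_tol=deficit_tol or 1e-9,
                    )
                per_edge[int(child)] = cache[t_eff]
            self._matrices.append(per_edge)
            self._priors.append(
                root_prior(rates.kappa * c, rates.lam * c, rates.mu * c, M)
            )

    # -- inside pass ------------------------------------------------------

    def _leaf_indicators(self) -> dict[int, np.ndarray]:
        out = {}
        lab2node = self.tree.leaf_index_map()
        # counts columns follow tree.leaf_labels order
        for col, label in enumerate(self.tree.leaf_labels):
            node = lab2node[label]
            L = np.zeros((self.counts.shape[0], self.S))
            L[np.arange(self.counts.shape[0]), self.counts[:, col]] = 1.0
            out[node] = L
        return out

    def inside(self, category: int, keep_messages: bool = False):
        """Partial likelihoods bottom-up; returns per-family log-likelihood.

        When *keep_messages* is set, also returns the scaled per-node
        conditional arrays and per-edge messages for the outside pass.
        """
        tree = self.tree
        n_fam = self.counts.shape[0]
        P = self._matrices[category]
        L: dict[int, np.ndarray] = self._leaf_indicators()
        msg: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_fam)
        for i in range(tree.n_nodes):
            if tree.is_leaf[i]:
                continue
            acc = np.ones((n_fam, self.S))
            for c in tree.children(i):
                m = L[int(c)] @ P[int(c)].T
                msg[int(c)] = m
                acc *= m
            scale = acc.max(axis=1)
            scale[scale == 0] = 1.0
            acc /= scale[:, None]
            logscale += np.log(scale)
            L[i] = acc
        lik = L[tree.root_index] @ self._priors[category]
        with np.errstate(divide="ignore"):
            loglik = np.log(lik) + logscale
        if keep_messages:
            return loglik, L, msg
        return loglik

    def log_zero_profile(self, category: int) -> float:
        """Log-probability of the all-zero leaf profile (for conditioning)."""
        tree = self.tree
        P = self._matrices[category]
        L: dict[int, np.ndarray] = {
            int(i): np.eye(self.S)[0:1] for i in tree.leaf_indices
        }
        logscale = 0.0
        for i in range(tree.n_nodes):
            if tree.is_leaf[i]:
                continue
            acc = np.ones((1, self.S))
            for c in tree.children(i):
                acc *= L[int(c)] @ P[int(c)].T
            s = acc.max()
            acc /= s
            logscale += np.log(s)
            L[i] = acc
        lik = (L[tree.root_index] @ self._priors[category])[0]
        return float(np.log(lik) + logscale)

    def mixture_log_likelihood(self, condition_on_observed: bool) -> np.ndarray:
        logpi = np.log(self.rates.category_probs)
        per_cat = np.stack([self.inside(k) for k in range(self.rates.n_categories)])
        ll = logsumexp(per_cat + logpi[:, None], axis=0)
        if condition_on_observed:
            logp0 = logsumexp(
                [self.log_zero_profile(k) + logpi[k]
                 for k in range(self.rates.n_categories)]
            )
            ll = ll - np.log1p(-np.exp(logp0))
        return ll

    # -- outside pass (posterior event decoding) --------------------------

    def edge_event_posteriors(self) -> np.ndarray:
        """Posterior P(event type) per (family, edge, type), mixed over
        categories with per-family posterior category weights."""
        tree = self.tree
        n_fam = self.counts.shape[0]
        n_edges = tree.n_edges
        edge_pos = {int(c): e for e, c in enumerate(tree.edge_child_indices)}
        logpi = np.log(self.rates.category_probs)

        per_cat_ll = []
        per_cat_events = []
        for k in range(self.rates.n_categories):
            loglik, L, msg = self.inside(k, keep_messages=True)
            per_cat_ll.append(loglik)
            P = self._matrices[k]
            S = self.S
            # event masks on the (parent s, child m) transition matrix
            sl = np.tril(np.ones((S, S)), -1)
            sl[:, 0] = 0.0  # parent > child >= 1
            su = np.triu(np.ones((S, S)), 1)
            su[0, :] = 0.0  # child > parent >= 1
            events = np.zeros((n_fam, n_edges, 4))
            # outside arrays, root downward (reverse postorder)
            O: dict[int, np.ndarray] = {
                tree.root_index: np.broadcast_to(
                    self._priors[k], (n_fam, S)).copy()
            }
            for i in range(tree.n_nodes - 1, -1, -1):
                if tree.is_leaf[i]:
                    continue
                kids = [int(c) for c in tree.children(i)]
                for c in kids:
                    T = O[i].copy()
                    for c2 in kids:
                        if c2 != c:
                            T *= msg[c2]
                    Pc = P[c]
                    Lc = L[c]
                    Z = np.einsum("fs,fs->f", T, msg[c])
                    Z[Z <= 0] = np.inf  # impossible data: posteriors -> 0
                    e = edge_pos[c]
                    gain = T[:, 0] * (Lc[:, 1:] @ Pc[0, 1:])
                    loss = (T[:, 1:] @ Pc[1:, 0]) * Lc[:, 0]
                    expn = np.einsum("fs,fs->f", T, Lc @ (Pc * su).T)
                    redn = np.einsum("fs,fs->f", T, Lc @ (Pc * sl).T)
                    events[:, e, 0] = gain / Z
                    events[:, e, 1] = loss / Z
                    events[:, e, 2] = expn / Z
                    events[:, e, 3] = redn / Z
                    if not tree.is_leaf[c]:
                        Oc = T @ Pc
                        scale = Oc.max(axis=1)
                        scale[scale == 0] = 1.0
                        O[c] = Oc / scale[:, None]
            per_cat_events.append(events)

        ll = np.stack(per_cat_ll) + logpi[:, None]          # (K, n_fam)
        w = np.exp(ll - logsumexp(ll, axis=0, keepdims=True))
        out = np.zeros((n_fam, n_edges, 4))
        for k in range(self.rates.n_categories):
            out += w[k][:, None, None] * per_cat_events[k]
        return np.clip(out, 0.0, 1.0)


def _counts_for_tree(tree: SpeciesTree, matrix: CountMatrix) -> np.ndarray:
    return matrix.aligned_to(tree).values


def _auto_engine(tree: SpeciesTree, counts: np.ndarray, rates: BDGRates,
                 M: int, deficit_tol: float = 1e-9,
                 max_doublings: int = 3) -> "_Engine":
    """Engine with automatic doubling of M while truncation mass exceeds
    tolerance on the rows the data can occupy."""
    for attempt in range(max_doublings + 1):
        try:
            return _Engine(tree, counts, rates, M, deficit_tol=deficit_tol)
        except TruncationError:
            if attempt == max_doublings:
                raise
            M *= 2
            logger.debug("truncation mass too high; retrying with M=%d", M)


def family_log_likelihood(tree: SpeciesTree,
                          profile: Mapping[str, int] | Sequence[int],
                          rates: BDGRates, M: int | None = None,
                          condition_on_observed: bool = True) -> float:
    """Log-likelihood of one family's leaf counts under the model."""
    if isinstance(profile, Mapping):
        counts = np.array([[int(profile[l]) for l in tree.leaf_labels]])
    else:
        counts = np.asarray(profile, dtype=int).reshape(1, -1)
        if counts.shape[1] != tree.n_leaves:
            raise ValidationError("profile length must equal the leaf count")
    if M is None:
        engine = _auto_engine(tree, counts, rates,
                              default_truncation_bound(int(counts.max())))
    else:
        engine = _Engine(tree, counts, rates, M)
    return float(engine.mixture_log_likelihood(condition_on_observed)[0])


def matrix_log_likelihood(tree: SpeciesTree, matrix: CountMatrix,
                          rates: BDGRates, M: int | None = None,
                          condition_on_observed: bool = True) -> np.ndarray:
    """Vector of per-family log-likelihoods for a whole count matrix."""
    counts = _counts_for_tree(tree, matrix)
    if M is None:
        engine = _auto_engine(
            tree, counts, rates,
            default_truncation_bound(int(counts.max(initial=0))))
    else:
        engine = _Engine(tree, counts, rates, M)
    return engine.mixture_log_likelihood(condition_on_observed)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Options of the staged maximum-likelihood fit."""

    max_categories: int = 4           # fit K = 1..max_categories in rounds
    edge_rates: bool = False          # per-edge rate multipliers round
    condition_on_observed: bool = True
    M: int | None = None              # truncation bound; None = automatic
    n_multistarts: int = 3            # seeded restarts in round 1
    seed: int = 0
    maxiter: int = 300
    rel_tol: float = 1e-6             # relative log-likelihood convergence

    def __post_init__(self):
        if not 1 <= self.max_categories <= 4:
            raise ValidationError("max_categories must be in 1..4")


@dataclass
class FittedModel:
    """Result of :func:`fit_parameters`."""

    tree: SpeciesTree
    rates: BDGRates
    log_likelihood: float
    trace: list[dict] = field(default_factory=list)
    converged: bool = True
    M: int = 20
    condition_on_observed: bool = True


def _rates_from_theta(theta: np.ndarray, K: int, edge_names: list[str] | None,
                      ) -> BDGRates:
    """Unpack optimizer parameters.

    Layout: (log kappa, log mu, logit(lambda/mu)) [+ log gamma shape if
    K > 1] [+ per-edge log multipliers, centered to product 1].
    """
    kappa = float(np.exp(theta[0]))
    mu = float(np.exp(theta[1]))
    lam = float(mu * expit(theta[2]))
    i = 3
    shape = None
    mult: tuple[float, ...] = (1.0,)
    if K > 1:
        shape = float(np.exp(theta[3]))
        mult = tuple(discrete_gamma_multipliers(shape, K))
        i = 4
    edge_multipliers = None
    if edge_names:
        logm = theta[i:i + len(edge_names)]
        logm = logm - logm.mean()  # fix the scale: geometric mean 1
        edge_multipliers = dict(zip(edge_names, np.exp(logm)))
    return BDGRates(kappa=kappa, lam=lam, mu=mu,
                    category_multipliers=mult,
                    category_probs=tuple([1.0 / K] * K),
                    edge_multipliers=edge_multipliers,
                    gamma_shape=shape)


def fit_parameters(tree: SpeciesTree, matrix: CountMatrix,
                   config: FitConfig | None = None) -> FittedModel:
    """Staged maximum-likelihood fit of the birth-death-gain model.

    Round 1 fits uniform rates from several seeded starts; later rounds
    warm-start and add per-edge multipliers (optional) and K = 2, 3, 4
    equal-probability discrete-gamma rate categories. The trace of
    (round, description, log-likelihood) is non-decreasing: a round that
    fails to improve keeps the best-so-far model.
    """
    config = config or FitConfig()
    if matrix.n_families == 0:
        raise ValidationError("empty count matrix")
    if config.condition_on_observed:
        matrix = matrix.drop_all_zero()
        if matrix.n_families == 0:
            raise ValidationError("no non-all-zero families to fit")
    counts = _counts_for_tree(tree, matrix)
    M = config.M or default_truncation_bound(int(counts.max(initial=0)))
    rng = np.random.default_rng(config.seed)

    def negloglik(theta: np.ndarray, K: int, edge_names) -> float:
        try:
            rates = _rates_from_theta(theta, K, edge_names)
            engine = _Engine(tree, counts, rates, M)
            ll = engine.mixture_log_likelihood(config.condition_on_observed)
        except (ValidationError, NumericalError, FloatingPointError):
            return 1e12
        total = float(ll.sum())
        return 1e12 if not np.isfinite(total) else -total

    def optimize(theta0, K, edge_names):
        res = scipy.optimize.minimize(
            negloglik, theta0, args=(K, edge_names), method="L-BFGS-B",
            options={"maxiter": config.maxiter, "ftol": config.rel_tol},
        )
        return res.x, -res.fun, bool(res.success)

    trace: list[dict] = []
    converged = True

    # round 1: uniform rates, multistart
    presence = (counts > 0).mean()
    base = np.array([np.log(max(presence, 0.05)), 0.0, -1.0])
    best = None
    for s in range(config.n_multistarts):
        theta0 = base + (rng.normal(0, 0.5, 3) if s else 0.0)
        x, ll, ok = optimize(theta0, 1, None)
        converged &= ok
        if best is None or ll > best[1]:
            best = (x, ll)
    theta, best_ll = best
    best_rates = _rates_from_theta(theta, 1, None)
    trace.append({"round": 1, "description": "uniform rates",
                  "log_likelihood": best_ll})

    edge_names = tree.edge_names if config.edge_rates else None
    rnd = 1
    if config.edge_rates:
        rnd += 1
        theta0 = np.concatenate([theta, np.zeros(tree.n_edges)])
        x, ll, ok = optimize(theta0, 1, edge_names)
        converged &= ok
        if ll >= best_ll:
            theta, best_ll = x, ll
            best_rates = _rates_from_theta(x, 1, edge_names)
        else:
            theta = np.concatenate([theta, np.zeros(tree.n_edges)])
        trace.append({"round": rnd, "description": "edge multipliers",
                      "log_likelihood": max(ll, best_ll)})

    for K in range(2, config.max_categories + 1):
        rnd += 1
        # warm start: previous base rates, near-uniform categories
        theta0 = np.concatenate([theta[:3], [np.log(20.0)], theta[3:]])
        x, ll, ok = optimize(theta0, K, edge_names)
        converged &= ok
        if ll >= best_ll:
            best_ll = ll
            best_rates = _rates_from_theta(x, K, edge_names)
            theta = np.concatenate([x[:3], x[4:]])
        trace.append({"round": rnd, "description": f"{K} gamma categories",
                      "log_likelihood": max(ll, best_ll)})

    if not converged:
        logger.warning("optimizer did not fully converge; best-so-far kept")
    # re-evaluate the winner with the truncation check, growing M if needed
    final = _auto_engine(tree, counts, best_rates, M)
    best_ll = float(
        final.mixture_log_likelihood(config.condition_on_observed).sum())
    return FittedModel(tree=tree, rates=best_rates, log_likelihood=best_ll,
                       trace=trace, converged=converged, M=final.M,
                       condition_on_observed=config.condition_on_observed)


# --------------------------------------------------------------------------
# Posterior event decoding and summaries
# --------------------------------------------------------------------------

@dataclass
class EventPosteriors:
    """Per-(family, edge) posterior probabilities of the four event types.

    ``probs`` has shape (n_families, n_edges, 4) with the last axis in
    :data:`EVENT_TYPES` order.
    """

    family_ids: list[str]
    edge_names: list[str]
    probs: np.ndarray

    def subset(self, family_ids: Iterable[str]) -> "EventPosteriors":
        ids = list(family_ids)
        pos = {f: i for i, f in enumerate(self.family_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise ValidationError(f"families absent from posteriors: {missing[:5]}")
        idx = [pos[f] for f in ids]
        return EventPosteriors(ids, self.edge_names, self.probs[idx])

    def totals(self) -> dict[str, float]:
        sums = self.probs.sum(axis=(0, 1))
        return dict(zip(EVENT_TYPES, map(float, sums)))

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        n_fam, n_edges, _ = self.probs.shape
        return pd.DataFrame({
            "family_id": np.repeat(self.family_ids, n_edges),
            "edge": np.tile(self.edge_names, n_fam),
            "p_gain": self.probs[:, :, 0].ravel(),
            "p_loss": self.probs[:, :, 1].ravel(),
            "p_expansion": self.probs[:, :, 2].ravel(),
            "p_reduction": self.probs[:, :, 3].ravel(),
        })


@dataclass
class EventSummary:
    """Expected event totals over a family set (sum of posteriors)."""

    gains: float
    losses: float
    expansions: float
    reductions: float
    n_families: int
    n_genomes: int

    @property
    def total(self) -> float:
        return self.gains + self.losses + self.expansions + self.reductions

    def as_dict(self) -> dict[str, float]:
        return {"gain": self.gains, "loss": self.losses,
                "expansion": self.expansions, "reduction": self.reductions}

    def __add__(self, other: "EventSummary") -> "EventSummary":
        if self.n_genomes != other.n_genomes:
            raise ValidationError("cannot add summaries over different genome sets")
        return EventSummary(
            self.gains + other.gains, self.losses + other.losses,
            self.expansions + other.expansions,
            self.reductions + other.reductions,
            self.n_families + other.n_families, self.n_genomes,
        )


def posterior_events(model: FittedModel, matrix: CountMatrix,
                     family_ids: Iterable[str] | None = None) -> EventPosteriors:
    """Posterior gain/loss/expansion/reduction probabilities per edge.

    An inside-outside pass computes, for every family and edge, the joint
    posterior of the (parent, child) states given all leaf counts; the
    four event probabilities are sums over the corresponding state
    patterns, mixed over rate categories by their per-family posterior
    weights.
    """
    if family_ids is not None:
        matrix = matrix.subset(family_ids)
    counts = _counts_for_tree(model.tree, matrix)
    M = model.M
    if counts.max(initial=0) > M:
        M = default_truncation_bound(int(counts.max(initial=0)))
        logger.warning("model M too small for these counts; using M=%d", M)
    engine = _Engine(model.tree, counts, model.rates, M)
    probs = engine.edge_event_posteriors()
    return EventPosteriors(matrix.family_ids, model.tree.edge_names, probs)


def summarize_events(posteriors: EventPosteriors, n_genomes: int,
                     family_ids: Iterable[str] | None = None) -> EventSummary:
    """Total expected events per type over edges and a family set."""
    if family_ids is not None:
        posteriors = posteriors.subset(family_ids)
    if posteriors.probs.size == 0:
        raise ValidationError("empty posteriors")
    t = posteriors.totals()
    return EventSummary(t["gain"], t["loss"], t["expansion"], t["reduction"],
                        n_families=len(posteriors.family_ids),
                        n_genomes=int(n_genomes))


# --------------------------------------------------------------------------
# Model serialization (key-value text)
# --------------------------------------------------------------------------

def write_model(model: FittedModel, path: str | Path) -> None:
    """Serialize fitted parameters as a flat key=value text file."""
    lines = [
        "# genomeflux fitted birth-death-gain model",
        f"kappa={model.rates.kappa!r}",
        f"lambda={model.rates.lam!r}",
        f"mu={model.rates.mu!r}",
        f"category_multipliers={','.join(map(repr, model.rates.category_multipliers))}",
        f"category_probs={','.join(map(repr, model.rates.category_probs))}",
        f"gamma_shape={model.rates.gamma_shape!r}",
        f"log_likelihood={model.log_likelihood!r}",
        f"M={model.M}",
        f"condition_on_observed={model.condition_on_observed}",
        f"converged={model.converged}",
    ]
    if model.rates.edge_multipliers:
        kv = ";".join(f"{k}:{v!r}" for k, v in model.rates.edge_multipliers.items())
        lines.append(f"edge_multipliers={kv}")
    for row in model.trace:
        lines.append(
            f"trace={row['round']},{row['description']},{row['log_likelihood']!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model(path: str | Path, tree: SpeciesTree) -> FittedModel:
    kv: dict[str, str] = {}
    trace = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        if key == "trace":
            rnd, desc, ll = value.split(",", 2)
            trace.append({"round": int(rnd), "description": desc,
                          "log_likelihood": float(ll)})
        else:
            kv[key] = value
    edge_multipliers = None
    if "edge_multipliers" in kv:
        edge_multipliers = {
            part.split(":")[0]: float(part.split(":")[1])
            for part in kv["edge_multipliers"].split(";")
        }
    shape = None if kv.get("gamma_shape", "None") == "None" else float(kv["gamma_shape"])
    rates = BDGRates(
        kappa=float(kv["kappa"]), lam=float(kv["lambda"]), mu=float(kv["mu"]),
        category_multipliers=tuple(float(x) for x in kv["category_multipliers"].split(",")),
        category_probs=tuple(float(x) for x in kv["category_probs"].split(",")),
        edge_multipliers=edge_multipliers, gamma_shape=shape,
    )
    return FittedModel(
        tree=tree, rates=rates, log_likelihood=float(kv["log_likelihood"]),
        trace=trace, converged=kv.get("converged", "True") == "True",
        M=int(kv["M"]),
        condition_on_observed=kv.get("condition_on_observed", "True") == "True",
    )
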