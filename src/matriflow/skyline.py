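"""Genealogy-point-estimate skyline demography for a matriline.

A full Bayesian skyline samples genealogies by MCMC; here the genealogy
is a UPGMA tree on pairwise HKY maximum-likelihood distances, and the
classic / generalized skyline of Pybus & Rambaut is read off its
coalescent intervals: an interval with i lineages and length gamma_i
estimates Ne*tau as gamma_i * i(i-1)/2 (time in substitutions/site).
The generalized variant pools short adjacent intervals, with the pooling
threshold epsilon chosen by small-sample AIC when not supplied.  This
trades posterior uncertainty for a desk-scale point estimate; the
qualitative growth-phase signal is what downstream interpretation uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .core import Alignment

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 generator normalised to one expected substitution per unit time."""
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = freqs[j] * (kappa if (i, j) in transitions else 1.0)
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(freqs * np.diag(Q))
    return Q / mu


class _HKYTransition:
    """Spectral form of the HKY chain for fast P(t) evaluation."""

    def __init__(self, kappa: float, freqs: np.ndarray):
        freqs = np.clip(np.asarray(freqs, dtype=float), 1e-9, None)
        freqs = freqs / freqs.sum()
        self.freqs = freqs
        Q = _hky_rate_matrix(kappa, freqs)
        s = np.sqrt(freqs)
        B = (Q * s[None, :]) / s[:, None]       # symmetric similarity
        lam, U = eigh((B + B.T) / 2)
        self._lam = lam
        self._left = U / s[:, None]
        self._right = (U * s[:, None]).T

    def probability(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(P, 1e-300, None)


def hky_distance(
    aln: Alignment,
    kappa: float = 2.0,
    p_inv: float = 0.0,
    gamma_alpha: float | None = None,
    gamma_categories: int = 4,
) -> np.ndarray:
    """Pairwise HKY maximum-likelihood distances (substitutions/site).

    kappa is fixed from configuration; base frequencies are empirical
    over the whole alignment.  Optional among-site rate variation uses a
    discrete gamma (mean-per-quantile) and/or a proportion of invariant
    sites, mixed into the transition probability.
    """
    n = aln.n
    seqs = [np.array([_BASE_IDX[b] for b in s]) for s in aln.seqs]
    flat = np.concatenate(seqs)
    freqs = np.bincount(flat, minlength=4).astype(float)
    model = _HKYTransition(kappa, freqs)

    if gamma_alpha is not None:
        from scipy.stats import gamma as gamma_dist

        qs = (np.arange(gamma_categories) + 0.5) / gamma_categories
        rates = gamma_dist.ppf(qs, a=gamma_alpha, scale=1.0 / gamma_alpha)
        rates = rates / rates.mean()
    else:
        rates = np.array([1.0])
    weights = np.full(rates.size, 1.0 / rates.size)

    def transition(t):
        P = sum(w * model.probability(t * r) for w, r in zip(weights, rates))
        if p_inv > 0:
            P = p_inv * np.eye(4) + (1 - p_inv) * P
        return P

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = np.zeros((4, 4))
            np.add.at(counts, (seqs[i], seqs[j]), 1.0)
            if np.trace(counts) == counts.sum():
                continue

            def nll(t):
                return -np.sum(counts * np.log(model.freqs[:, None] * transition(t)))

            res = minimize_scalar(nll, bounds=(1e-8, 10.0), method="bounded")
            D[i, j] = D[j, i] = float(res.x)
    return D


# ------------------------------------------------------------------ UPGMA


@dataclass
class UltrametricTree:
    """UPGMA genealogy: linkage matrix, tip labels, node heights."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def coalescent_times(self) -> np.ndarray:
        """Node heights (merge distance / 2), ascending; n-1 values."""
        return np.sort(self.linkage[:, 2] / 2.0)

    def newick(self) -> str:
        root, _ = hierarchy.to_tree(self.linkage, rd=True)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            h = node.dist / 2.0
            parts = []
            for ch in (node.left, node.right):
                bl = h - (0.0 if ch.is_leaf() else ch.dist / 2.0)
                parts.append(f"{rec(ch)}:{bl:.8g}")
            return "(" + ",".join(parts) + ")"

        return rec(root) + ";"


def upgma(D: np.ndarray, labels: list[str] | None = None) -> UltrametricTree:
    """Average-linkage (UPGMA) tree; ultrametric with heights = d/2."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    iu = np.triu_indices(n, 1)
    Z = hierarchy.linkage(D[iu], method="average")
    return UltrametricTree(linkage=Z, labels=list(labels))


# ---------------------------------------------------------------- skyline


@dataclass
class SkylineProfile:
    """Piecewise-constant Ne*tau through time (substitutions/site units)."""

    boundaries: np.ndarray   # group boundary times, ascending, len = k+1
    estimates: np.ndarray    # per-group Ne*tau, len = k
    epsilon: float
    aicc: float

    def __post_init__(self):
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("interval boundaries must strictly increase")
        if np.any(self.estimates <= 0):
            raise ValueError("Ne estimates must be positive")

    def at(self, t: float) -> float:
        k = np.searchsorted(self.boundaries, t, side="right") - 1
        k = min(max(k, 0), len(self.estimates) - 1)
        return float(self.estimates[k])

    def harmonic_mean(self) -> float:
        """Time-weighted harmonic-mean Ne*tau over the profile."""
        spans = np.diff(self.boundaries)
        return float(spans.sum() / np.sum(spans / self.estimates))

    def times_in_years(self, rate_per_site_per_my: float) -> np.ndarray:
        """Convert boundaries to years given a rate in subs/site/My."""
        return self.boundaries / rate_per_site_per_my * 1e6


def _intervals(coal_times: np.ndarray, n: int):
    """(k lineages, gamma length) for each inter-coalescent interval."""
    t = np.concatenate([[0.0], np.sort(coal_times)])
    ks = np.arange(n, 1, -1)
    gammas = np.diff(t)
    return ks, gammas


def _grouped_profile(ks, gammas, eps):
    """Pool adjacent intervals (tipward first) until each spans >= eps."""
    groups = []
    cur_k, cur_g = [], []
    for k, g in zip(ks, gammas):
        cur_k.append(k)
        cur_g.append(g)
        if sum(cur_g) >= eps:
            groups.append((list(cur_k), list(cur_g)))
            cur_k, cur_g = [], []
    if cur_k:
        if groups:
            pk, pg = groups[-1]
            groups[-1] = (pk + cur_k, pg + cur_g)
        else:
            groups.append((cur_k, cur_g))
    bounds = [0.0]
    est = []
    for gk, gg in groups:
        m = len(gk)
        ne = sum(g * k * (k - 1) / 2.0 for k, g in zip(gk, gg)) / m
        est.append(max(ne, 1e-12))
        bounds.append(bounds[-1] + sum(gg))
    return np.array(bounds), np.array(est), groups


def _profile_loglik(groups):
    ll = 0.0
    for gk, gg in groups:
        m = len(gk)
        ne = sum(g * k * (k - 1) / 2.0 for k, g in zip(gk, gg)) / m
        ne = max(ne, 1e-12)
        for k, g in zip(gk, gg):
            rate = k * (k - 1) / 2.0 / ne
            ll += np.log(rate) - rate * g
    return ll


def classic_skyline(
    tree: UltrametricTree | np.ndarray,
    group_eps: float | None = 0.0,
    n_tips: int | None = None,
) -> SkylineProfile:
    """Classic (eps=0) or generalized (eps>0) skyline of a genealogy.

    ``tree`` may be an :class:`UltrametricTree` or a raw vector of
    coalescent times (then ``n_tips`` is required).  ``group_eps=None``
    selects the pooling threshold by AICc over a grid spanning the
    interval lengths.
    """
    if isinstance(tree, UltrametricTree):
        times, n = tree.coalescent_times, tree.n
    else:
        times = np.sort(np.asarray(tree, dtype=float))
        if n_tips is None:
            raise ValueError("n_tips required when passing raw times")
        n = n_tips
    if times.size != n - 1:
        raise ValueError("need n-1 coalescent times for n tips")
    ks, gammas = _intervals(times, n)
    # guard against zero-length intervals from exact ties
    gammas = np.maximum(gammas, 1e-12)

    def evaluate(eps):
        bounds, est, groups = _grouped_profile(ks, gammas, eps)
        K = len(groups)
        n_int = len(gammas)
        ll = _profile_loglik(groups)
        denom = max(n_int - K - 1, 1)
        aicc = -2 * ll + 2 * K + 2 * K * (K + 1) / denom
        return bounds, est, aicc

    if group_eps is not None:
        bounds, est, aicc = evaluate(group_eps)
        return SkylineProfile(bounds, est, float(group_eps), aicc)

    grid = np.unique(
        np.concatenate([[0.0], np.quantile(gammas, [0.25, 0.5, 0.75, 0.9]),
                        [gammas.sum() / 4, gammas.sum() / 2]])
    )
    best = None
    for eps in grid:
        bounds, est, aicc = evaluate(eps)
        if best is None or aicc < best[2] - 1e-12:
            best = (bounds, est, aicc, eps)
    bounds, est, aicc, eps = best
    return SkylineProfile(bounds, est, float(eps), aicc)


def matriline_skyline(
    aln: Alignment,
    kappa: float = 2.0,
    group_eps: float | None = None,
    **hky_kwargs,
) -> tuple[UltrametricTree, SkylineProfile]:
    """Distance matrix -> UPGMA genealogy -> skyline, in one call."""
    D = hky_distance(aln, kappa=kappa, **hky_kwargs)
    tree = upgma(D, labels=list(aln.ids))
    return tree, classic_skyline(tree, group_eps=group_eps)
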