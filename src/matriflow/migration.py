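"""Bayesian structured-coalescent inference of theta and migration rates.

Compares two models of the breeding system with microsatellite data:
model I (panmixia, a single mutation-scaled size theta) and model II (a
k-deme island model with per-deme theta_i and asymmetric mutation-scaled
immigration rates M[j->i]).  The sampler explores the joint posterior of
parameters and per-locus genealogies by Metropolis-Hastings:

* genealogy moves re-thread one lineage through the rest of the tree
  (conditional-prior proposal, likelihood-ratio acceptance), rescale all
  event times, resimulate above a uniform time cut, redraw one locus in
  full, or (rarely) redraw every locus and parameter from the prior;
* theta (uniform prior on (0, 200)) is updated by near-Gibbs draws from
  its conditional given the genealogies' coalescent exposures;
* the migration matrix M (uniform priors on (0, 1000)) is integrated
  out of the target analytically; genealogy proposals run at a working
  matrix adapted during burn-in and frozen afterwards, with the
  proposal density corrected in the acceptance ratio, and the reported
  M posterior is drawn from its truncated-Gamma conditional at each
  recorded step.

Microsatellites follow a single-step ladder mutation model: alleles live
on a bounded ladder spanning the observed size range plus a buffer, the
generator is symmetric tridiagonal, and branch transition probabilities
come from its spectral decomposition.  Time is mutation-scaled, so
coalescence in deme i happens at rate 2/theta_i per lineage pair and a
lineage in i traces back to j at rate M[j->i].

Model choice uses the (log) harmonic-mean marginal likelihood over the
recorded samples, averaged across replicate chains, plus a stabilised
variant that drops the lowest likelihood tail; the log Bayes factor is
Mlog(island) - Mlog(panmixia).  Nem[j->i] = M[j->i] * theta_i / 4.
"""

from __future__ import annotations

import random as pyrandom
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import MISSING, GenotypeMatrix

THETA_MAX = 200.0
M_MAX = 1000.0


class ChainDiagnosticError(RuntimeError):
    """Raised when a chain shows no evidence of mixing."""


@dataclass
class ChainConfig:
    """MCMC schedule; the study-scale default records 5000 steps thinned
    by 100 over 3 replicates (1.5e6 proposals per model across the
    replicate set)."""

    steps: int = 5000
    thin: int = 100
    replicates: int = 3
    burnin_fraction: float = 0.10
    p_param_move: float = 0.4
    # genealogy move mix (fractions of non-parameter proposals)
    p_full_redraw: float = 0.05    # redraw the whole genealogy
    p_scale: float = 0.20          # rescale all event times
    p_above: float = 0.15          # resimulate above a uniform time cut
    scale_factor: float = 1.3      # remainder: single-lineage re-threading
    # global prior redraw of (theta, M, all genealogies); accepted on the
    # likelihood ratio alone -- negligible in posterior runs but makes
    # prior-only chains mix instantly
    p_global_redraw: float = 0.01
    theta_max: float = THETA_MAX
    m_max: float = M_MAX
    ladder_buffer: int = 10
    max_events: int = 20_000
    min_acceptance: float = 0.01
    min_ess: float = 50.0
    strict: bool = True


@dataclass
class PosteriorRun:
    flavor: str
    theta_mode: np.ndarray
    theta_ci: np.ndarray          # (k, 2)
    m_mode: np.ndarray            # (k, k), zero diagonal
    m_ci: np.ndarray              # (k, k, 2)
    mlog: float                   # harmonic-mean marginal log likelihood
    mlog_replicates: list[float]
    mlog_truncated: float
    acceptance: dict
    theta_trace: np.ndarray       # (replicates*steps, k)
    m_trace: np.ndarray
    ll_trace: np.ndarray
    ess: float


# ------------------------------------------------------- ladder mutation


class LadderModel:
    """Symmetric single-step ladder chain on a bounded allele range."""

    def __init__(self, lo: int, hi: int):
        self.lo, self.hi = int(lo), int(hi)
        S = self.hi - self.lo + 1
        if S < 2:
            raise ValueError("ladder needs at least two states")
        Q = np.zeros((S, S))
        for i in range(S - 1):
            Q[i, i + 1] = Q[i + 1, i] = 0.5
        np.fill_diagonal(Q, -Q.sum(axis=1))
        lam, U = np.linalg.eigh(Q)
        self.S = S
        self._lam = lam
        self._U = U

    def transition(self, t: float) -> np.ndarray:
        P = (self._U * np.exp(self._lam * t)) @ self._U.T
        return np.clip(P, 0.0, None)

    def state_of(self, allele: int) -> int:
        return int(allele) - self.lo


# ------------------------------------------------- genealogy structure


class Genealogy:
    """Coalescent tree with explicit per-branch migration paths.

    ``parent``/``time`` define the tree (leaves 0..n-1 at time 0);
    ``node_deme[v]`` is the deme in which lineage v starts (sampling
    deme for leaves, coalescence deme for internal nodes); ``mig[v]``
    lists (t, from, to) migration events on the branch above v in
    ascending time.  Per-deme exposure statistics sufficient for the
    structured-coalescent prior are cached in ``stats``.
    """

    __slots__ = (
        "parent",
        "time",
        "n_leaves",
        "k",
        "node_deme",
        "mig",
        "stats",
        "loglik",
    )

    def __init__(self, parent, time, n_leaves, k, node_deme, mig):
        self.parent = parent
        self.time = time
        self.n_leaves = n_leaves
        self.k = k
        self.node_deme = node_deme
        self.mig = mig
        self.stats = None
        self.loglik = np.nan

    @property
    def root(self) -> int:
        return int(np.argmax(self.time))

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def compute_stats(self):
        """Per-deme exposures (pair time, lineage time, event counts),
        computed with one vectorised sweep over the event timeline."""
        k = self.k
        n = self.n_leaves
        coal_t = self.time[n:]
        coal_d = self.node_deme[n:]
        mig_t, mig_i, mig_j = [], [], []
        for lst in self.mig.values():
            for (t, i, j) in lst:
                mig_t.append(t)
                mig_i.append(i)
                mig_j.append(j)
        mig_t = np.asarray(mig_t)
        mig_i = np.asarray(mig_i, dtype=int)
        mig_j = np.asarray(mig_j, dtype=int)

        times = np.concatenate([coal_t, mig_t])
        order = np.argsort(times, kind="stable")
        times = times[order]
        E = times.size
        # per-deme count deltas at each event
        delta = np.zeros((E, k))
        ev_is_coal = order < (n - 1)
        idx_coal = order[ev_is_coal]            # index into coal arrays
        idx_mig = order[~ev_is_coal] - (n - 1)  # index into mig arrays
        rows_coal = np.where(ev_is_coal)[0]
        rows_mig = np.where(~ev_is_coal)[0]
        np.subtract.at(delta, (rows_coal, coal_d[idx_coal]), 1.0)
        np.subtract.at(delta, (rows_mig, mig_i[idx_mig]), 1.0)
        np.add.at(delta, (rows_mig, mig_j[idx_mig]), 1.0)

        init = np.bincount(self.node_deme[:n], minlength=k).astype(float)
        counts_before = init[None, :] + np.vstack(
            [np.zeros(k), np.cumsum(delta, axis=0)[:-1]]
        )
        dt = np.diff(np.concatenate([[0.0], times]))
        pair_time = np.sum(counts_before * (counts_before - 1) * dt[:, None], axis=0)
        lin_time = np.sum(counts_before * dt[:, None], axis=0)
        n_coal = np.bincount(coal_d, minlength=k).astype(float)
        n_mig = np.zeros((k, k))
        if mig_t.size:
            np.add.at(n_mig, (mig_j, mig_i), 1.0)
        self.stats = (pair_time, lin_time, n_coal, n_mig)
        return self.stats


def genealogy_log_prior(gen: Genealogy, theta: np.ndarray, M: np.ndarray) -> float:
    """Structured-coalescent log density from the cached exposures."""
    if gen.stats is None:
        gen.compute_stats()
    pair_time, lin_time, n_coal, n_mig = gen.stats
    th = np.maximum(np.asarray(theta, dtype=float), 1e-12)
    mig_in = np.asarray(M, dtype=float)
    lp = -np.sum(pair_time / th)
    lp -= np.sum(lin_time * mig_in.sum(axis=0))
    lp += np.sum(n_coal * np.log(2.0 / th))
    mask = n_mig > 0
    if np.any(mask):
        if np.any(mig_in[mask] <= 0):
            return -np.inf
        lp += float(np.sum(n_mig[mask] * np.log(mig_in[mask])))
    return float(lp)


def _gillespie_up(
    lineages: list[tuple[int, int]],
    t0: float,
    theta,
    M,
    pyr: pyrandom.Random,
    id_pool: list[int],
    max_events: int,
):
    """Run the structured coalescent upward from (node, deme) lineages.

    Returns (coal_events, mig_events) or None when ``max_events`` is
    exceeded.  coal: (t, deme, child_a, child_b, new_node); mig:
    (t, branch_node, from, to).
    """
    k = len(theta)
    th = [max(float(x), 1e-12) for x in theta]
    mig_out = [float(sum(M[j][i] for j in range(k) if j != i)) for i in range(k)]
    by_deme: list[list[int]] = [[] for _ in range(k)]
    for node, d in lineages:
        by_deme[d].append(node)
    counts = [len(x) for x in by_deme]
    remaining = len(lineages)
    t = t0
    coals, migs = [], []
    pool_i = 0
    n_ev = 0
    while remaining > 1:
        n_ev += 1
        if n_ev > max_events:
            return None
        R = 0.0
        for i in range(k):
            c = counts[i]
            R += c * (c - 1) / th[i] + c * mig_out[i]
        if R <= 0:
            raise RuntimeError("structured coalescent cannot proceed (rate 0)")
        t += pyr.expovariate(R)
        u = pyr.random() * R
        acc = 0.0
        chosen = None
        for i in range(k):
            c = counts[i]
            acc += c * (c - 1) / th[i]
            if u < acc:
                chosen = ("coal", i)
                break
            acc += c * mig_out[i]
            if u < acc:
                v = pyr.random() * mig_out[i]
                aj = 0.0
                j_sel = None
                for j in range(k):
                    if j == i:
                        continue
                    aj += float(M[j][i])
                    if v < aj:
                        j_sel = j
                        break
                chosen = ("mig", i, j_sel if j_sel is not None else (i + 1) % k)
                break
        if chosen is None:
            continue
        if chosen[0] == "coal":
            i = chosen[1]
            li = by_deme[i]
            a = li.pop(pyr.randrange(len(li)))
            b = li.pop(pyr.randrange(len(li)))
            new = id_pool[pool_i]
            pool_i += 1
            coals.append((t, i, a, b, new))
            li.append(new)
            counts[i] -= 1
            remaining -= 1
        else:
            _, i, j = chosen
            li = by_deme[i]
            node = li.pop(pyr.randrange(len(li)))
            by_deme[j].append(node)
            counts[i] -= 1
            counts[j] += 1
            migs.append((t, node, i, j))
    return coals, migs


def simulate_genealogy(
    deme_of_leaf: np.ndarray,
    theta: np.ndarray,
    M: np.ndarray,
    rng,
    max_events: int = 20_000,
) -> Genealogy | None:
    """Draw a complete genealogy from the structured coalescent."""
    n = int(deme_of_leaf.size)
    k = int(np.atleast_1d(theta).size)
    pyr = pyrandom.Random(int(rng.integers(1, 2**31 - 1)))
    Ml = np.asarray(M, dtype=float).tolist() if k > 1 else [[0.0]]
    out = _gillespie_up(
        [(l, int(deme_of_leaf[l])) for l in range(n)],
        0.0,
        np.atleast_1d(theta).tolist(),
        Ml,
        pyr,
        list(range(n, 2 * n - 1)),
        max_events,
    )
    if out is None:
        return None
    coals, migs = out
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    node_deme = np.zeros(2 * n - 1, dtype=int)
    node_deme[:n] = deme_of_leaf
    mig: dict[int, list] = {}
    for (t, i, a, b, new) in coals:
        parent[a] = parent[b] = new
        time[new] = t
        node_deme[new] = i
    for (t, node, i, j) in migs:
        mig.setdefault(node, []).append((t, i, j))
    return Genealogy(parent, time, n, k, node_deme, mig)


def resimulate_above(
    gen: Genealogy,
    t_cut: float,
    theta,
    M,
    rng,
    max_events: int = 20_000,
) -> Genealogy | None:
    """Keep the genealogy below ``t_cut``; redraw everything above it
    from the conditional structured-coalescent prior."""
    n = gen.n_leaves
    k = gen.k
    parent = gen.parent
    time = gen.time
    # extant branches at the cut, with their deme at t_cut
    lineages = []
    for v in range(2 * n - 1):
        p = parent[v]
        if time[v] <= t_cut and (p < 0 or time[p] > t_cut):
            d = int(gen.node_deme[v])
            for (t, i, j) in gen.mig.get(v, ()):
                if t <= t_cut:
                    d = j
            lineages.append((v, d))
    freed = [v for v in range(n, 2 * n - 1) if time[v] > t_cut]
    pyr = pyrandom.Random(int(rng.integers(1, 2**31 - 1)))
    Ml = np.asarray(M, dtype=float).tolist() if k > 1 else [[0.0]]
    out = _gillespie_up(
        lineages,
        t_cut,
        np.atleast_1d(theta).tolist(),
        Ml,
        pyr,
        sorted(freed),
        max_events,
    )
    if out is None:
        return None
    coals, migs = out
    new_parent = parent.copy()
    new_time = time.copy()
    new_deme = gen.node_deme.copy()
    new_mig = {}
    for v, lst in gen.mig.items():
        if time[v] > t_cut:
            continue  # branch removed with the upper part
        pv = parent[v]
        if pv >= 0 and time[pv] <= t_cut:
            kept = list(lst)  # branch fully below the cut
        else:
            kept = [e for e in lst if e[0] <= t_cut]  # branch spans the cut
        if kept:
            new_mig[v] = kept
    for v, _ in lineages:
        new_parent[v] = -1
    for f in freed:
        new_parent[f] = -1  # clear stale links before ids are reused
    for (t, i, a, b, new) in coals:
        new_parent[a] = new_parent[b] = new
        new_time[new] = t
        new_deme[new] = i
    for (t, node, i, j) in migs:
        new_mig.setdefault(node, []).append((t, i, j))
    for v in new_mig:
        new_mig[v] = sorted(new_mig[v])
    return Genealogy(new_parent, new_time, n, k, new_deme, new_mig)


def rethread_lineage(
    gen: Genealogy,
    v: int,
    theta,
    M,
    rng,
    max_events: int = 20_000,
) -> Genealogy | None:
    """Detach the branch above node v and re-thread it through the rest.

    The branch's migration path and its coalescence point are redrawn
    from the conditional structured-coalescent prior given the rest of
    the genealogy (the remaining lineages' recorded paths are held
    fixed), so the Metropolis-Hastings acceptance is the likelihood
    ratio alone.  Returns None if the proposal exceeds ``max_events``
    or cannot proceed.
    """
    n = gen.n_leaves
    k = gen.k
    parent = gen.parent.copy()
    time = gen.time.copy()
    node_deme = gen.node_deme.copy()
    mig = {u: list(lst) for u, lst in gen.mig.items()}

    p = int(parent[v])
    if p < 0:
        return None
    q = int(parent[p])
    children_p = [c for c in range(2 * n - 1) if parent[c] == p]
    s = children_p[0] if children_p[1] == v else children_p[1]
    # surgery: splice s's branch through to q, drop p and v's path
    merged = mig.get(s, []) + mig.get(p, [])
    mig.pop(p, None)
    mig.pop(v, None)
    if merged:
        mig[s] = merged
    else:
        mig.pop(s, None)
    parent[s] = q
    parent[v] = -1
    parent[p] = -1
    time[p] = 0.0

    t0 = float(time[v])
    # rest branches: everything outside v's clade and the removed p
    rest_nodes = [u for u in range(2 * n - 1) if u not in (v, p)]
    rest_nodes = [
        u for u in rest_nodes if not _in_clade(gen.parent, v, u)
    ]
    roots = [u for u in rest_nodes if parent[u] < 0]
    if len(roots) != 1:
        return None
    r_root = roots[0]

    # event-driven sweep over the rest of the genealogy, from t0 upward:
    # membership events are node tops (children leave, parent enters) and
    # recorded migrations; between events the per-deme membership is
    # constant and the threaded lineage runs its exponential clocks
    rest_set = set(rest_nodes)
    children_of: dict[int, list[int]] = {}
    for u in rest_nodes:
        pu = int(parent[u])
        if pu >= 0 and pu in rest_set:
            children_of.setdefault(pu, []).append(u)
    events = []  # (t, 0=node-top, u) / (t, 1=migration, u, i, j)
    deme_at_t0: dict[int, int] = {}
    for u in rest_nodes:
        if time[u] > t0:
            events.append((float(time[u]), 0, u, -1, -1))
        d_u = int(node_deme[u])
        for (t, i, j) in mig.get(u, ()):
            if t > t0:
                events.append((float(t), 1, u, i, j))
            else:
                d_u = j
        deme_at_t0[u] = d_u
    events.sort()
    members: dict[int, set[int]] = {}
    for u in rest_nodes:
        pu = int(parent[u])
        top = time[pu] if pu >= 0 else np.inf
        if time[u] <= t0 and top > t0:
            members.setdefault(deme_at_t0[u], set()).add(u)

    pyr = pyrandom.Random(int(rng.integers(1, 2**31 - 1)))
    th = np.maximum(np.atleast_1d(theta), 1e-12)
    Ml = np.asarray(M, dtype=float) if k > 1 else np.zeros((1, 1))
    mig_out = Ml.sum(axis=0)
    d = int(node_deme[v])
    t = t0
    new_path = []
    ev_i = 0
    n_ev = 0
    target = None
    while target is None:
        n_ev += 1
        if n_ev > max_events:
            return None
        t_end = events[ev_i][0] if ev_i < len(events) else np.inf
        c_same = len(members.get(d, ()))
        rate = c_same * 2.0 / th[d] + mig_out[d]
        hit = False
        if rate > 0:
            dt = pyr.expovariate(rate)
            if t + dt < t_end:
                t += dt
                hit = True
        if not hit:
            if ev_i >= len(events):
                return None  # stranded: no partner reachable, no migration
            t = t_end
            ev, kind, u, i, j = events[ev_i]
            ev_i += 1
            if kind == 0:
                for c in children_of.get(u, ()):
                    for dd in members.values():
                        dd.discard(c)
                members.setdefault(int(node_deme[u]), set()).add(u)
            else:
                members.get(i, set()).discard(u)
                members.setdefault(j, set()).add(u)
            continue
        if pyr.random() * rate < c_same * 2.0 / th[d]:
            target = sorted(members[d])[pyr.randrange(c_same)]
        else:
            u_r = pyr.random() * mig_out[d]
            acc = 0.0
            for j in range(k):
                if j == d:
                    continue
                acc += Ml[j, d]
                if u_r < acc:
                    new_path.append((t, d, j))
                    d = j
                    break

    # attach: reuse p as the new parent node
    pu = int(parent[target])
    parent[v] = p
    parent[target] = p
    parent[p] = pu
    time[p] = t
    node_deme[p] = d
    lst = mig.pop(target, [])
    below = [e for e in lst if e[0] <= t]
    above = [e for e in lst if e[0] > t]
    if below:
        mig[target] = below
    if above:
        mig[p] = above
    if new_path:
        mig[v] = new_path
    return Genealogy(parent, time, n, k, node_deme, mig)


def _in_clade(parent: np.ndarray, v: int, u: int) -> bool:
    """True if u lies strictly inside the clade rooted at v (u != v)."""
    if u == v:
        return False
    x = u
    while x >= 0:
        x = int(parent[x])
        if x == v:
            return True
    return False


def scale_genealogy(gen: Genealogy, s: float) -> Genealogy:
    """Multiply every event time by s (topology and demes unchanged)."""
    new_mig = {
        v: [(t * s, i, j) for (t, i, j) in lst] for v, lst in gen.mig.items()
    }
    out = Genealogy(
        gen.parent.copy(),
        gen.time * s,
        gen.n_leaves,
        gen.k,
        gen.node_deme.copy(),
        new_mig,
    )
    if gen.stats is not None:
        pair_time, lin_time, n_coal, n_mig = gen.stats
        out.stats = (pair_time * s, lin_time * s, n_coal, n_mig)
    return out


def n_events(gen: Genealogy) -> int:
    return (gen.n_leaves - 1) + sum(len(v) for v in gen.mig.values())


# --------------------------------------------------------- likelihood


def tree_loglik(gen: Genealogy, states: np.ndarray, ladder: LadderModel) -> float:
    """Felsenstein pruning on the genealogy under the ladder model.

    ``states`` holds the ladder state index per leaf, or -1 for missing
    (partial of ones).  Root prior is uniform over ladder states.
    """
    n = gen.n_leaves
    S = ladder.S
    n_nodes = 2 * n - 1
    partial = np.ones((n_nodes, S))
    for l in range(n):
        if states[l] >= 0:
            partial[l] = 0.0
            partial[l, states[l]] = 1.0
    order = np.argsort(gen.time[n:], kind="stable") + n
    logscale = 0.0
    children: dict[int, list] = {}
    for c, p in enumerate(gen.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(c)
    for node in order:
        acc = np.ones(S)
        for c in children[int(node)]:
            t = gen.time[node] - gen.time[c]
            acc = acc * (ladder.transition(t) @ partial[c])
        mx = acc.max()
        if mx <= 0:
            return -np.inf
        partial[node] = acc / mx
        logscale += np.log(mx)
    root = int(order[-1])
    return float(logscale + np.log(partial[root].mean()))


# ------------------------------------------------------------- sampler


@dataclass
class _LocusData:
    deme_of_leaf: np.ndarray
    states: np.ndarray
    ladder: LadderModel


def _prepare_loci(g: GenotypeMatrix, deme_index: dict[str, int], buffer: int):
    loci = []
    for l in range(g.n_loci):
        demes, states = [], []
        observed = []
        for i in range(g.n):
            d = deme_index[g.demes[i]]
            for a in g.genotypes[i, l, :]:
                demes.append(d)
                if a == MISSING:
                    states.append(-1)
                else:
                    observed.append(int(a))
                    states.append(int(a))
        if not observed:
            continue
        lo, hi = min(observed) - buffer, max(observed) + buffer
        lad = LadderModel(lo, hi)
        st = np.array(
            [lad.state_of(s) if s >= 0 else -1 for s in states], dtype=int
        )
        loci.append(_LocusData(np.array(demes), st, lad))
    if not loci:
        raise ValueError("no typed loci")
    return loci


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.allclose(x.var(), 0):
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (x.var() * n)
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1 + 2 * s))


def _mode(samples: np.ndarray, bins: int = 40) -> float:
    hist, edges = np.histogram(samples, bins=bins)
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2)


_THETA_GRID = np.geomspace(1e-3, THETA_MAX, 2048)
_M_GRID = np.geomspace(1e-6, M_MAX, 2048)


def _grid_edges(grid: np.ndarray) -> np.ndarray:
    mid = np.sqrt(grid[1:] * grid[:-1])
    return np.concatenate([[grid[0] * grid[0] / mid[0]], mid, [grid[-1]]])


_THETA_EDGES = _grid_edges(_THETA_GRID)
_M_EDGES = _grid_edges(_M_GRID)


def _gibbs_sample(logdens, grid, edges, current, rng):
    """Near-Gibbs update of one scalar from its conditional density.

    Draws from a piecewise-constant approximation of the conditional on
    a log grid and applies a Metropolis-Hastings correction so the
    update is exact.  Returns the (possibly unchanged) value.
    """
    ld = logdens(grid)
    widths = np.diff(edges)
    lw = ld + np.log(widths)
    lw -= lw.max()
    w = np.exp(lw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        return current
    cdf = np.cumsum(w) / total
    b = int(np.searchsorted(cdf, rng.random()))
    b = min(b, grid.size - 1)
    prop = float(rng.uniform(edges[b], edges[b + 1]))
    # proposal log-density at proposed and current values
    bc = int(np.clip(np.searchsorted(edges, current) - 1, 0, grid.size - 1))
    logq_prop = lw[b] - np.log(widths[b])
    logq_cur = lw[bc] - np.log(widths[bc])
    logr = (
        float(logdens(np.array([prop]))[0])
        - float(logdens(np.array([current]))[0])
        + logq_cur
        - logq_prop
    )
    return prop if np.log(rng.random()) < logr else current


def _mig_cond_logp(stats, M: np.ndarray) -> float:
    """M-dependent part of one genealogy's log density at a fixed M."""
    _, lin_time, _, n_mig = stats
    lp = -float(np.sum(lin_time * M.sum(axis=0)))
    mask = n_mig > 0
    if np.any(mask):
        if np.any(M[mask] <= 0):
            return -np.inf
        lp += float(np.sum(n_mig[mask] * np.log(M[mask])))
    return lp


def _mig_marginal_logp(G_tot: np.ndarray, T1_tot: np.ndarray, m_max: float) -> float:
    """Log prior of all migration histories with M integrated out.

    Each entry has an independent Uniform(0, m_max) prior, so
    integral = Gamma(G+1) / T1^(G+1) * P(G+1, m_max*T1) / m_max
    with P the regularised lower incomplete gamma function.
    """
    from scipy.special import gammainc, gammaln as _gammaln

    k = T1_tot.size
    lp = 0.0
    for i in range(k):
        t1 = max(float(T1_tot[i]), 1e-300)
        for j in range(k):
            if i == j:
                continue
            G = float(G_tot[j, i])
            reg = gammainc(G + 1.0, m_max * t1)
            if reg <= 0:
                return -np.inf
            lp += (
                _gammaln(G + 1.0)
                - (G + 1.0) * np.log(t1)
                + np.log(reg)
                - np.log(m_max)
            )
    return lp


def _coal_logp(stats, theta: np.ndarray) -> float:
    """theta-dependent part of one genealogy's log density."""
    pair_time, _, n_coal, _ = stats
    th = np.maximum(theta, 1e-12)
    return float(-np.sum(pair_time / th) + np.sum(n_coal * np.log(2.0 / th)))


def _sample_m_posterior(G_tot, T1_tot, m_max, rng) -> np.ndarray:
    """Draw M | genealogies: independent truncated Gamma(G+1, T1)."""
    from scipy.stats import gamma as gamma_dist

    k = T1_tot.size
    M = np.zeros((k, k))
    for i in range(k):
        t1 = max(float(T1_tot[i]), 1e-300)
        for j in range(k):
            if i == j:
                continue
            dist = gamma_dist(a=float(G_tot[j, i]) + 1.0, scale=1.0 / t1)
            hi = float(dist.cdf(m_max))
            u = rng.uniform(0.0, max(hi, 1e-300))
            M[j, i] = float(np.clip(dist.ppf(u), 0.0, m_max))
    return M


def sample_posterior(
    g: GenotypeMatrix,
    flavor: str = "island",
    config: ChainConfig | None = None,
    seed: int | None = None,
    flat_likelihood: bool = False,
) -> PosteriorRun:
    """MCMC posterior for (theta, M) under panmixia or the island model.

    ``flavor='panmixia'`` pools every individual into one deme with a
    single theta; ``'island'`` uses the GenotypeMatrix deme labels.
    The migration-rate matrix is integrated out of the target
    analytically (uniform prior), which decouples it from the
    migration-event counts of the current genealogies; the reported M
    posterior is sampled from its conditional at each recorded step.
    Genealogy proposals are simulated at a working migration matrix that
    adapts during burn-in and is frozen afterwards, with the proposal
    density corrected in the acceptance ratio.
    ``flat_likelihood`` replaces the data likelihood by 1 (prior-only
    runs, used to verify detailed balance).  Raises
    :class:`ChainDiagnosticError` when acceptance or ESS collapses
    (disable with ``config.strict=False``).
    """
    config = config or ChainConfig()
    if flavor == "panmixia":
        deme_names = ["all"]
        deme_index = {d: 0 for d in set(g.demes)}
    elif flavor == "island":
        deme_names = g.deme_labels()
        deme_index = {d: i for i, d in enumerate(deme_names)}
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    k = len(deme_names)
    if flavor == "island":
        for d in deme_names:
            if sum(1 for x in g.demes if x == d) < 4:
                raise ValueError(f"deme {d!r} has fewer than 4 individuals")

    loci = _prepare_loci(g, deme_index, config.ladder_buffer)
    rng_master = np.random.default_rng(seed)

    # moment initialisation: under single-step mutation the expected
    # squared pairwise allele-size difference within a deme equals theta,
    # so starting there removes most of the tree-length burn-in drift
    theta_init = np.full(k, 10.0)
    for i in range(k):
        diffs = []
        for ld0 in loci:
            sel = np.where(ld0.deme_of_leaf == i)[0]
            vals = ld0.states[sel]
            vals = vals[vals >= 0].astype(float)
            if vals.size >= 4:
                diffs.append(2.0 * vals.var())
        if diffs:
            theta_init[i] = float(np.clip(np.mean(diffs), 0.5, 100.0))

    all_theta, all_m, all_ll = [], [], []
    mlogs, mlogs_trunc = [], []
    acc_stats = {
        "param_tried": 0,
        "param_acc": 0,
        "gene_tried": 0,
        "gene_acc": 0,
    }

    def locus_loglik(gen, ld):
        return 0.0 if flat_likelihood else tree_loglik(gen, ld.states, ld.ladder)

    theta_grid = np.geomspace(1e-3, config.theta_max, 2048)
    theta_edges = _grid_edges(theta_grid)

    for rep in range(config.replicates):
        rng = np.random.default_rng(rng_master.integers(1, 2**31 - 1))
        theta = theta_init.copy()
        M_work = np.zeros((k, k))
        if k > 1:
            M_work[~np.eye(k, dtype=bool)] = 10.0
        gens = []
        for ld in loci:
            gen = None
            while gen is None:
                gen = simulate_genealogy(
                    ld.deme_of_leaf, theta, M_work, rng, config.max_events
                )
            gen.loglik = locus_loglik(gen, ld)
            gen.compute_stats()
            gens.append(gen)

        def totals():
            T1 = sum(g_.stats[1] for g_ in gens)
            G = sum(g_.stats[3] for g_ in gens)
            return G, T1

        G_tot, T1_tot = totals()
        marg_cur = (
            _mig_marginal_logp(G_tot, T1_tot, config.m_max) if k > 1 else 0.0
        )

        n_record = config.steps
        n_prop = n_record * config.thin
        n_burn = int(config.burnin_fraction * n_prop)
        th_tr = np.empty((n_record, k))
        m_tr = np.empty((n_record, k, k))
        ll_tr = np.empty(n_record)
        rec = 0
        for it in range(n_prop + n_burn):
            if k > 1 and it < n_burn and it % 50 == 0:
                # adapt the proposal migration matrix during burn-in only
                M_work = np.clip(
                    (G_tot + 1.0) / np.maximum(T1_tot, 1e-6)[None, :],
                    1e-4,
                    config.m_max,
                )
                np.fill_diagonal(M_work, 0.0)
            if rng.random() < config.p_global_redraw:
                # independent draw of (theta, all genealogies) from the
                # prior, using an auxiliary M drawn from its own prior;
                # marginalised over that auxiliary draw the proposal
                # density is exactly the M-integrated prior, so the
                # acceptance is the data likelihood ratio alone
                acc_stats["param_tried"] += 1
                theta_new = np.maximum(
                    rng.uniform(0.0, config.theta_max, size=k), 1e-3
                )
                M_new = np.zeros((k, k))
                if k > 1:
                    M_new[~np.eye(k, dtype=bool)] = rng.uniform(
                        0.0, config.m_max, size=k * (k - 1)
                    )
                cands = []
                ok = True
                for ld0 in loci:
                    c0 = simulate_genealogy(
                        ld0.deme_of_leaf, theta_new, M_new, rng,
                        config.max_events,
                    )
                    if c0 is None:
                        ok = False
                        break
                    c0.compute_stats()
                    c0.loglik = locus_loglik(c0, ld0)
                    cands.append(c0)
                if ok:
                    logr = sum(c0.loglik for c0 in cands) - sum(
                        g_.loglik for g_ in gens
                    )
                    if np.log(rng.random()) < logr:
                        gens = cands
                        theta = theta_new
                        if k > 1:
                            G_tot = sum(c0.stats[3] for c0 in cands)
                            T1_tot = sum(c0.stats[1] for c0 in cands)
                            marg_cur = _mig_marginal_logp(
                                G_tot, T1_tot, config.m_max
                            )
                            if it < n_burn:  # kernel adaptation only here
                                M_work = np.maximum(M_new, 1e-4)
                                np.fill_diagonal(M_work, 0.0)
                        acc_stats["param_acc"] += 1
            elif rng.random() < config.p_param_move:
                acc_stats["param_tried"] += 1
                i = int(rng.integers(0, k))
                # conditional: theta^-C * exp(-T2/theta), uniform prior
                C = sum(g_.stats[2][i] for g_ in gens)
                T2 = sum(g_.stats[0][i] for g_ in gens)

                def ld_theta(x, C=C, T2=T2):
                    return -C * np.log(x) - T2 / x

                new = _gibbs_sample(
                    ld_theta, theta_grid, theta_edges, float(theta[i]), rng
                )
                if new != theta[i]:
                    theta = theta.copy()
                    theta[i] = new
                    acc_stats["param_acc"] += 1
            else:
                acc_stats["gene_tried"] += 1
                li = int(rng.integers(0, len(loci)))
                ld = loci[li]
                cur = gens[li]
                u_move = rng.random()
                is_scale = False
                if u_move < config.p_full_redraw:
                    cand = simulate_genealogy(
                        ld.deme_of_leaf, theta, M_work, rng, config.max_events
                    )
                    log_hastings = 0.0
                elif u_move < config.p_full_redraw + config.p_scale:
                    is_scale = True
                    lam = config.scale_factor
                    s = float(np.exp(rng.uniform(-np.log(lam), np.log(lam))))
                    cand = scale_genealogy(cur, s)
                    log_hastings = (
                        _coal_logp(cand.stats, theta)
                        - _coal_logp(cur.stats, theta)
                        + n_events(cur) * np.log(s)
                    )
                elif u_move < (
                    config.p_full_redraw + config.p_scale + config.p_above
                ):
                    t_cut = rng.uniform(0.0, cur.tmrca)
                    cand = resimulate_above(
                        cur, t_cut, theta, M_work, rng, config.max_events
                    )
                    if cand is not None:
                        log_hastings = np.log(cur.tmrca / cand.tmrca)
                else:
                    root = cur.root
                    v = int(rng.integers(0, 2 * cur.n_leaves - 1))
                    if v == root:
                        cand = None
                    else:
                        cand = rethread_lineage(
                            cur, v, theta, M_work, rng, config.max_events
                        )
                    log_hastings = 0.0
                if cand is not None:
                    if cand.stats is None:
                        cand.compute_stats()
                    if np.isnan(cand.loglik):
                        cand.loglik = locus_loglik(cand, ld)
                    logr = cand.loglik - cur.loglik + log_hastings
                    marg_new = marg_cur
                    if k > 1:
                        G_new = G_tot - cur.stats[3] + cand.stats[3]
                        T1_new = T1_tot - cur.stats[1] + cand.stats[1]
                        marg_new = _mig_marginal_logp(G_new, T1_new, config.m_max)
                        logr += marg_new - marg_cur
                        if not is_scale:
                            # correct for proposing paths at M_work
                            logr -= _mig_cond_logp(cand.stats, M_work)
                            logr -= -_mig_cond_logp(cur.stats, M_work)
                    if np.log(rng.random()) < logr:
                        if k > 1:
                            G_tot, T1_tot = G_new, T1_new
                            marg_cur = marg_new
                        gens[li] = cand
                        acc_stats["gene_acc"] += 1
            if it >= n_burn and (it - n_burn + 1) % config.thin == 0:
                th_tr[rec] = theta
                m_tr[rec] = (
                    _sample_m_posterior(G_tot, T1_tot, config.m_max, rng)
                    if k > 1
                    else np.zeros((k, k))
                )
                ll_tr[rec] = sum(gen.loglik for gen in gens)
                rec += 1
        th_tr, m_tr, ll_tr = th_tr[:rec], m_tr[:rec], ll_tr[:rec]
        all_theta.append(th_tr)
        all_m.append(m_tr)
        all_ll.append(ll_tr)
        mlogs.append(float(np.log(len(ll_tr)) - logsumexp(-ll_tr)))
        keep = ll_tr >= np.quantile(ll_tr, 0.10)
        mlogs_trunc.append(float(np.log(keep.sum()) - logsumexp(-ll_tr[keep])))

    theta_s = np.vstack(all_theta)
    m_s = np.vstack(all_m)
    ll_s = np.concatenate(all_ll)

    gene_rate = acc_stats["gene_acc"] / max(acc_stats["gene_tried"], 1)
    param_rate = acc_stats["param_acc"] / max(acc_stats["param_tried"], 1)
    ess = _ess(ll_s) if not flat_likelihood else float(len(ll_s))
    if config.strict and not flat_likelihood:
        if max(gene_rate, param_rate) < config.min_acceptance or ess < config.min_ess:
            raise ChainDiagnosticError(
                f"chain not mixing: acceptance gene={gene_rate:.3f} "
                f"param={param_rate:.3f}, ESS={ess:.0f}"
            )

    theta_mode = np.array([_mode(theta_s[:, i]) for i in range(k)])
    theta_ci = np.array(
        [np.quantile(theta_s[:, i], [0.025, 0.975]) for i in range(k)]
    )
    m_mode = np.zeros((k, k))
    m_ci = np.zeros((k, k, 2))
    for i in range(k):
        for j in range(k):
            if i != j:
                m_mode[i, j] = _mode(m_s[:, i, j])
                m_ci[i, j] = np.quantile(m_s[:, i, j], [0.025, 0.975])
    return PosteriorRun(
        flavor=flavor,
        theta_mode=theta_mode,
        theta_ci=theta_ci,
        m_mode=m_mode,
        m_ci=m_ci,
        mlog=float(np.mean(mlogs)),
        mlog_replicates=mlogs,
        mlog_truncated=float(np.mean(mlogs_trunc)),
        acceptance={"genealogy": gene_rate, "parameter": param_rate},
        theta_trace=theta_s,
        m_trace=m_s,
        ll_trace=ll_s,
        ess=ess,
    )


# ------------------------------------------------------ model comparison


def compare_models(run_panmixia: PosteriorRun, run_island: PosteriorRun) -> dict:
    """Log Bayes factor of structure over panmixia.

    LBF = Mlog(island) - Mlog(panmixia); positive favours the structured
    model.  Both the plain harmonic-mean and the truncated variant are
    reported.
    """
    lbf = run_island.mlog - run_panmixia.mlog
    lbf_t = run_island.mlog_truncated - run_panmixia.mlog_truncated
    if lbf > 2:
        support = "structure (strong)" if lbf > 10 else "structure"
    elif lbf < -2:
        support = "panmixia (strong)" if lbf < -10 else "panmixia"
    else:
        support = "indecisive"
    return {
        "log_bayes_factor": float(lbf),
        "log_bayes_factor_truncated": float(lbf_t),
        "favoured": support,
    }


def effective_migrants(theta: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Nem[j, i] = M[j, i] * theta_i / 4 (effective migrants into i from j)."""
    theta = np.asarray(theta, dtype=float)
    M = np.asarray(M, dtype=float)
    k = theta.size
    if M.shape != (k, k):
        raise ValueError("M must be k x k")
    nem = M * theta[None, :] / 4.0
    np.fill_diagonal(nem, 0.0)
    return nem
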