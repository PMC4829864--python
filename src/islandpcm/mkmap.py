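"""Mk models and stochastic character mapping.

A continuous-time Markov chain on a small discrete alphabet (island vs
continent occupancy) runs along the tree.  The likelihood is Felsenstein's
pruning algorithm with per-branch transition matrices P(t) = expm(Q t).
Stochastic maps are drawn by backward pruning / forward node-state sampling,
then endpoint-conditioned branch histories are sampled exactly by
uniformization.  Ambiguous tips may be coded "?" (uniform likelihood).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .treeio import Phylogeny, RegimePainting, _merge_segments

__all__ = [
    "MkModel",
    "mk_loglik",
    "fit_mk",
    "stochastic_map",
    "transition_summary",
    "transition_probabilities",
    "node_marginals",
    "sim_history",
    "read_tip_states",
]

UNIFORMIZATION_CAP = 10_000


@dataclass
class MkModel:
    states: tuple[str, ...]
    Q: np.ndarray
    root_prior: np.ndarray
    logL: float | None = None
    at_bounds: bool = False

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match state alphabet")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("negative off-diagonal rate in Q")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(self.Q).max())):
            raise ValueError("Q rows must sum to zero")
        if abs(self.root_prior.sum() - 1.0) > 1e-9 or np.any(self.root_prior < 0):
            raise ValueError("root prior must be a probability vector")

    def to_dict(self):
        return {
            "states": list(self.states),
            "Q": self.Q.tolist(),
            "root_prior": self.root_prior.tolist(),
            "logL": self.logL,
            "at_bounds": self.at_bounds,
        }


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q, normalized; uniform for the zero matrix."""
    k = Q.shape[0]
    if np.allclose(Q, 0):
        return np.full(k, 1.0 / k)
    w, vl = np.linalg.eig(Q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(vl[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


class _Propagator:
    """Per-branch transition matrices, eigendecomposition-based with an expm
    fallback for defective Q."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._use_eig = False
        try:
            w, U = np.linalg.eig(Q)
            Ui = np.linalg.inv(U)
            if np.linalg.cond(U) < 1e8:
                self.w, self.U, self.Ui = w, U, Ui
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if self._use_eig:
            P = np.real(self.U @ (np.exp(self.w * t)[:, None] * self.Ui))
        else:
            P = linalg.expm(self.Q * t)
        np.clip(P, 0.0, 1.0, out=P)
        rows = P.sum(axis=1, keepdims=True)
        return P / rows


def _tip_likelihoods(tree: Phylogeny, tip_states, states: tuple[str, ...]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    L = np.zeros((tree.n_tips, len(states)))
    for i, label in enumerate(tree.tip_labels):
        if label not in tip_states:
            raise KeyError(f"no state for tip {label!r}")
        s = str(tip_states[label])
        if s == "?":
            L[i, :] = 1.0
        elif s in idx:
            L[i, idx[s]] = 1.0
        else:
            raise ValueError(f"tip {label!r} has unknown state {s!r}")
    return L


def _pruning(tree: Phylogeny, tipL: np.ndarray, prop: _Propagator):
    """Partial conditional likelihoods with per-node log scalers.

    Returns (L (n_nodes, k) scaled, logscale per node cumulative over the
    subtree, P per non-root branch)."""
    k = tipL.shape[1]
    L = np.zeros((tree.n_nodes, k))
    logscale = np.zeros(tree.n_nodes)
    P = {}
    for v in range(tree.n_nodes):
        if v != tree.root:
            P[v] = prop(tree.branch_length[v])
    for v in tree.postorder():
        if tree.is_tip(v):
            L[v] = tipL[v]
        else:
            acc = np.ones(k)
            sc = 0.0
            for c in tree.children(v):
                acc = acc * (P[c] @ L[c])
                sc += logscale[c]
            m = acc.max()
            if m <= 0:
                raise ValueError(f"zero likelihood at node {v}: data impossible under Q")
            L[v] = acc / m
            logscale[v] = sc + math.log(m)
    return L, logscale, P


def mk_loglik(tree: Phylogeny, tip_states, Q, root_prior=None, *, states=None) -> float:
    """Pruning-algorithm log-likelihood of discrete tip states under Q.

    ``states`` fixes the alphabet (and its mapping to rows of Q); by default
    it is inferred from the observed tip states, which requires every state
    to be observed at least once.
    """
    Q = np.asarray(Q, dtype=float)
    if states is None:
        states = _infer_states(tip_states, Q)
    else:
        states = tuple(states)
    if root_prior is None:
        root_prior = stationary_distribution(Q)
    tipL = _tip_likelihoods(tree, tip_states, states)
    L, logscale, _ = _pruning(tree, tipL, _Propagator(Q))
    lik = float(np.asarray(root_prior) @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return math.log(lik) + logscale[tree.root]


def _infer_states(tip_states, Q) -> tuple[str, ...]:
    k = Q.shape[0]
    vals = tip_states.values() if isinstance(tip_states, dict) else tip_states
    observed = sorted({str(s) for s in vals if str(s) != "?"})
    if len(observed) > k:
        raise ValueError(f"{len(observed)} observed states but Q is {k}x{k}")
    if len(observed) == k:
        return tuple(observed)
    raise ValueError(
        "state alphabet cannot be inferred (fewer observed states than Q "
        "dimensions); pass states explicitly via MkModel"
    )


def fit_mk(
    tree: Phylogeny,
    tip_states,
    model: str = "ARD",
    *,
    root_prior: str = "stationary",
    states: tuple[str, ...] | None = None,
) -> MkModel:
    """ML fit of an Mk model ("ARD" all-rates-different, "SYM", or "ER").

    Rates are optimized in log space by L-BFGS-B from three starts around a
    parsimony-flavored heuristic rate; rates pinned at the box bounds are
    flagged on the returned model.
    """
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    observed = sorted({str(s) for s in tip_states.values() if str(s) != "?"})
    if states is None:
        states = tuple(observed)
    if len(observed) < 2:
        raise ValueError("need at least 2 distinct observed states to fit rates")
    k = len(states)
    tipL = _tip_likelihoods(tree, tip_states, states)

    if model == "ARD":
        n_par = k * (k - 1)
    elif model == "SYM":
        n_par = k * (k - 1) // 2
    elif model == "ER":
        n_par = 1
    else:
        raise ValueError(f"unknown model {model!r}")

    def build_Q(rates: np.ndarray) -> np.ndarray:
        Q = np.zeros((k, k))
        if model == "ARD":
            Q[~np.eye(k, dtype=bool)] = rates
        elif model == "SYM":
            iu = np.triu_indices(k, 1)
            Q[iu] = rates
            Q[(iu[1], iu[0])] = rates
        else:
            Q[~np.eye(k, dtype=bool)] = rates[0]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def prior_for(Q):
        if root_prior == "stationary":
            return stationary_distribution(Q)
        if root_prior == "uniform":
            return np.full(k, 1.0 / k)
        raise ValueError(f"unknown root prior {root_prior!r}")

    def nll(log_rates: np.ndarray) -> float:
        Q = build_Q(np.exp(log_rates))
        try:
            L, logscale, _ = _pruning(tree, tipL, _Propagator(Q))
        except ValueError:
            return np.inf
        lik = float(prior_for(Q) @ L[tree.root])
        if not np.isfinite(lik) or lik <= 0:
            return np.inf
        return -(math.log(lik) + logscale[tree.root])

    depth = max(tree.depth, np.finfo(float).tiny)
    base = math.log(1.0 / depth)
    lo, hi = base + math.log(1e-6), base + math.log(1e4)
    bounds = [(lo, hi)] * n_par
    best = None
    for mult in (1.0, 0.1, 10.0):
        x0 = np.full(n_par, base + math.log(mult))
        sol = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or sol.fun < best.fun:
            best = sol
    if not np.isfinite(best.fun):
        raise ValueError("Mk likelihood is non-finite everywhere searched")
    rates = np.exp(best.x)
    Q = build_Q(rates)
    at_bounds = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    return MkModel(
        states=tuple(states),
        Q=Q,
        root_prior=prior_for(Q),
        logL=-float(best.fun),
        at_bounds=at_bounds,
    )


def transition_probabilities(Q, t: float) -> np.ndarray:
    """P(t) = expm(Q t): state transition probabilities over duration t."""
    return _Propagator(np.asarray(Q, dtype=float))(t)


def node_marginals(
    tree: Phylogeny, tip_states, Q, root_prior=None, *, states=None
) -> np.ndarray:
    """Marginal posterior state probabilities at every node (n_nodes, k).

    Standard up-pass (pruning) plus down-pass message passing; rows sum to 1.
    """
    Q = np.asarray(Q, dtype=float)
    if states is None:
        states = _infer_states(tip_states, Q)
    if root_prior is None:
        root_prior = stationary_distribution(Q)
    root_prior = np.asarray(root_prior, dtype=float)
    tipL = _tip_likelihoods(tree, tip_states, states)
    prop = _Propagator(Q)
    L, _, P = _pruning(tree, tipL, prop)
    k = len(states)
    down = np.zeros((tree.n_nodes, k))
    down[tree.root] = root_prior
    for v in tree.preorder():
        for c in tree.children(v):
            sib_msg = np.ones(k)
            for s in tree.children(v):
                if s != c:
                    sib_msg = sib_msg * (P[s] @ L[s])
            down[c] = P[c].T @ (down[v] * sib_msg)
    post = down * L
    totals = post.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero posterior mass: data impossible under Q")
    return post / totals


def sim_history(
    tree: Phylogeny,
    Q,
    states,
    seed: int | np.random.Generator,
    *,
    root_prior=None,
) -> RegimePainting:
    """Unconditioned forward simulation of the Markov chain along the tree.

    Useful as a ground-truth generator for recovery and count-expectation
    checks; the returned painting's tip-end states are the simulated data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    states = tuple(states)
    k = len(states)
    if root_prior is None:
        root_prior = stationary_distribution(Q)
    node_state = np.empty(tree.n_nodes, dtype=int)
    node_state[tree.root] = rng.choice(k, p=np.asarray(root_prior))
    segments: dict[int, list[tuple[str, float]]] = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = int(node_state[tree.parent[v]])
        remaining = float(tree.branch_length[v])
        segs: list[tuple[str, float]] = []
        if remaining == 0.0:
            segments[v] = [(states[s], 0.0)]
            node_state[v] = s
            continue
        while True:
            rate = -Q[s, s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if wait >= remaining:
                segs.append((states[s], remaining))
                break
            segs.append((states[s], wait))
            remaining -= wait
            w = Q[s].clip(min=0.0)
            w[s] = 0.0
            s = int(rng.choice(k, p=w / w.sum()))
        segments[v] = _merge_segments(segs)
        node_state[v] = s
    return RegimePainting(segments=segments, alphabet=states)


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------


def _sample_branch_path(
    rng: np.random.Generator,
    Q: np.ndarray,
    prop: _Propagator,
    t: float,
    a: int,
    b: int,
    states: tuple[str, ...],
    branch_id,
) -> list[tuple[str, float]]:
    """Endpoint-conditioned CTMC path on [0, t] from state a to state b,
    sampled exactly by uniformization."""
    k = Q.shape[0]
    omega = float(np.max(-np.diag(Q)))
    if omega <= 0.0:
        if a != b:
            raise RuntimeError(f"branch {branch_id}: endpoints differ under zero Q")
        return [(states[a], t)]
    Rm = np.eye(k) + Q / omega
    Pab = float(prop(t)[a, b])
    if Pab <= 0:
        raise RuntimeError(
            f"branch {branch_id}: endpoint pair ({states[a]},{states[b]}) has "
            "zero transition probability"
        )
    # N | endpoints: p(n) ~ Poisson(omega t; n) * (R^n)[a,b] / Pab
    u = rng.random()
    log_pois = -omega * t
    Rn = np.eye(k)
    cum = 0.0
    n_jumps = None
    for n in range(UNIFORMIZATION_CAP + 1):
        if n > 0:
            Rn = Rn @ Rm
            log_pois += math.log(omega * t) - math.log(n)
        term = math.exp(log_pois) * Rn[a, b] / Pab
        cum += term
        if u <= cum:
            n_jumps = n
            break
    if n_jumps is None:
        raise RuntimeError(
            f"branch {branch_id}: uniformization failed to terminate within "
            f"{UNIFORMIZATION_CAP} candidate jumps"
        )
    if n_jumps == 0:
        return [(states[a], t)]
    # powers of R needed for bridge sampling of the jump chain
    Rpow = [np.eye(k)]
    for _ in range(n_jumps):
        Rpow.append(Rpow[-1] @ Rm)
    seq = [a]
    for j in range(1, n_jumps):
        prev = seq[-1]
        w = Rm[prev, :] * Rpow[n_jumps - j][:, b]
        tot = w.sum()
        if tot <= 0:
            raise RuntimeError(f"branch {branch_id}: bridge sampling dead end")
        seq.append(int(rng.choice(k, p=w / tot)))
    seq.append(b)
    times = np.sort(rng.random(n_jumps)) * t
    # convert the (possibly virtual) jump sequence to dwell segments:
    # state seq[i] holds from jump i to jump i+1 (the last until t)
    segs: list[tuple[str, float]] = []
    prev_t = 0.0
    for s, jt in zip(seq, np.append(times, t)):
        segs.append((states[s], float(jt - prev_t)))
        prev_t = float(jt)
    segs = [(s, d) for s, d in segs if d > 0]
    merged = _merge_segments(segs)
    # guard against float drift
    total = sum(d for _, d in merged)
    if merged and abs(total - t) > 1e-9 * max(t, 1.0):
        s_last, d_last = merged[-1]
        merged[-1] = (s_last, d_last + (t - total))
    return merged


def stochastic_map(
    tree: Phylogeny,
    tip_states,
    Q,
    n_maps: int,
    seed: int | np.random.Generator,
    *,
    root_prior=None,
    states: tuple[str, ...] | None = None,
) -> list[RegimePainting]:
    """Sample complete character histories conditional on the tip states.

    Node states come from the joint conditional distribution (backward
    pruning, forward sampling); branch interiors from exact
    endpoint-conditioned uniformization.  Tip-end states of every painting
    equal the observed tip states.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    if states is None:
        states = _infer_states(tip_states, Q)
    if root_prior is None:
        root_prior = stationary_distribution(Q)
    root_prior = np.asarray(root_prior, dtype=float)
    tipL = _tip_likelihoods(tree, tip_states, states)
    prop = _Propagator(Q)
    L, logscale, P = _pruning(tree, tipL, prop)

    maps: list[RegimePainting] = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        w = root_prior * L[tree.root]
        if w.sum() <= 0:
            raise ValueError("zero root likelihood: data impossible under Q")
        node_state[tree.root] = rng.choice(len(states), p=w / w.sum())
        for v in tree.preorder():
            if v == tree.root:
                continue
            a = node_state[tree.parent[v]]
            w = P[v][a, :] * L[v]
            node_state[v] = rng.choice(len(states), p=w / w.sum())
        segments = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            bl = float(tree.branch_length[v])
            a, b = int(node_state[tree.parent[v]]), int(node_state[v])
            if bl == 0.0:
                # zero-length branches (resolved polytomies) cannot change state
                if a != b:
                    raise RuntimeError(f"state change across zero-length branch {v}")
                segments[v] = [(states[b], 0.0)]
                continue
            segments[v] = _sample_branch_path(rng, Q, prop, bl, a, b, states, v)
        maps.append(RegimePainting(segments=segments, alphabet=tuple(states)))
    return maps


def transition_summary(paintings) -> dict:
    """Mean per-pair transition counts and per-state dwell times over maps."""
    if not paintings:
        raise ValueError("need at least one painting")
    alphabet = paintings[0].alphabet
    counts = sum(p.transition_counts() for p in paintings) / len(paintings)
    dwell = {s: 0.0 for s in alphabet}
    for p in paintings:
        for s, d in p.dwell_times().items():
            dwell[s] += d
    dwell = {s: d / len(paintings) for s, d in dwell.items()}
    return {"mean_transition_counts": counts, "mean_dwell_times": dwell,
            "n_maps": len(paintings)}


def read_tip_states(path_or_buf) -> pd.Series:
    """Tip-state CSV ``species,state`` -> Series indexed by species."""
    df = pd.read_csv(path_or_buf, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "state" not in cols:
        raise ValueError("tip-state CSV must have columns species,state")
    return df.set_index(cols["species"])[cols["state"]].rename("state")
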