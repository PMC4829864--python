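"""Synthetic trees, paintings, and traits for calibration and power studies.

The centerpiece is :func:`study_fixture`: a 48-tip ultrametric pure-birth
tree (depth normalized to 1) carrying a 2-tip island clade ("AbdAlKuri") and
a disjoint 5-tip island clade ("Socotra").  Body size evolves under
regime-specific Brownian rates -- continent 1.0, Socotra 2.0, Abd al Kuri
20.0, mirroring the roughly 2x and >20x island accelerations the analyses
are designed to detect -- and three head dimensions evolve as single-rate
Brownian traits whose per-branch increments correlate 0.8 with the size
increments.

All generators take a mandatory seed and are deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pcm
from .treeio import Phylogeny, RegimePainting

__all__ = [
    "SimConfig",
    "yule_tree",
    "paint_clades",
    "study_fixture",
    "simulate_dataset",
    "FIXTURE_RATES",
]

FIXTURE_RATES = {"continent": 1.0, "Socotra": 2.0, "AbdAlKuri": 20.0}
FIXTURE_CLADES = (("AbdAlKuri", 2), ("Socotra", 5))
HEAD_SIZE_CORRELATION = 0.8


def yule_tree(n_tips: int, seed: int | np.random.Generator) -> Phylogeny:
    """Pure-birth tree with ``n_tips`` tips, rescaled to depth 1.

    Simulated forward in time: exponential waiting times with rate equal to
    the number of extant lineages, a uniformly chosen lineage splitting at
    each event.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lengths = np.zeros(n_nodes)
    root = n_tips  # internal ids follow tip ids
    next_internal = n_tips + 1
    t = 0.0
    # active lineages: (parent node id, birth time of the lineage)
    active: list[tuple[int, float]] = [(root, 0.0), (root, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        par, birth = active.pop(i)
        node = next_internal
        next_internal += 1
        parent[node] = par
        lengths[node] = t - birth
        active.append((node, t))
        active.append((node, t))
    T = t + rng.exponential(1.0 / n_tips)
    for tip, (par, birth) in enumerate(active):
        parent[tip] = par
        lengths[tip] = T - birth
    lengths /= T  # normalize depth to 1
    labels = [f"t{i+1}" for i in range(n_tips)]
    return Phylogeny(parent, lengths, labels)


def clade_tip_sets(tree: Phylogeny) -> dict[int, frozenset[str]]:
    """Tip-label set below each internal node."""
    below: dict[int, frozenset[str]] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            below[v] = frozenset([tree.tip_labels[v]])
        else:
            s = frozenset()
            for c in tree.children(v):
                s |= below[c]
            below[v] = s
    return {v: s for v, s in below.items() if not tree.is_tip(v)}


def paint_clades(
    tree: Phylogeny,
    clade_specs: list[tuple[frozenset | set | list, str]],
    *,
    background: str = "continent",
    stem_fraction: float = 0.5,
) -> RegimePainting:
    """Paint named clades onto a background regime.

    Each spec is (tip label set, regime label); the tips must be monophyletic.
    The clade's stem branch switches from background to the clade regime at
    ``stem_fraction`` of its length (measured from the parent end); all crown
    branches carry the clade regime.
    """
    sets = clade_tip_sets(tree)
    by_set = {s: v for v, s in sets.items()}
    alphabet = [background] + [lab for _, lab in clade_specs]
    segments: dict[int, list[tuple[str, float]]] = {}
    for v in range(tree.n_nodes):
        if v != tree.root:
            bl = float(tree.branch_length[v])
            segments[v] = [(background, bl)] if bl > 0 else [(background, 0.0)]
    for tips, label in clade_specs:
        tips = frozenset(tips)
        if len(tips) == 1:
            # single-tip "clade": paint part of its terminal branch
            mrca = tree.label_index[next(iter(tips))]
            crown: list[int] = []
        else:
            if tips not in by_set:
                raise ValueError(f"tips {sorted(tips)} are not monophyletic")
            mrca = by_set[tips]
            crown = _descendant_branches(tree, mrca)
        for b in crown:
            bl = float(tree.branch_length[b])
            segments[b] = [(label, bl)] if bl > 0 else [(label, 0.0)]
        stem_len = float(tree.branch_length[mrca])
        if stem_len > 0:
            cut = stem_fraction * stem_len
            segs = []
            if cut > 0:
                segs.append((background, cut))
            segs.append((label, stem_len - cut))
            segments[mrca] = segs
        else:
            segments[mrca] = [(label, 0.0)]
    painting = RegimePainting(segments=segments, alphabet=tuple(alphabet))
    painting.validate(tree)
    return painting


def _descendant_branches(tree: Phylogeny, node: int) -> list[int]:
    out, stack = [], list(tree.children(node))
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(tree.children(v))
    return out


def find_disjoint_clades(tree: Phylogeny, sizes: list[int]) -> list[frozenset[str]] | None:
    """First clades of the requested sizes in postorder, pairwise disjoint.

    Returns None when the tree lacks such a combination.
    """
    sets = clade_tip_sets(tree)
    order = [v for v in tree.postorder() if not tree.is_tip(v)]
    chosen: list[frozenset[str]] = []
    for size in sizes:
        pick = None
        for v in order:
            s = sets[v]
            if len(s) == size and all(not (s & c) for c in chosen):
                pick = s
                break
        if pick is None:
            return None
        chosen.append(pick)
    return chosen


def study_fixture(seed: int):
    """Deterministic stand-in for the unavailable specimen data.

    Returns (tree, painting, TraitTable, groups Series).  48-tip Yule tree of
    depth 1 with a 2-tip "AbdAlKuri" clade and a disjoint 5-tip "Socotra"
    clade; log-scale body size (svl) under multi-rate BM with rates
    (continent, Socotra, AbdAlKuri) = (1, 2, 20); head traits hl/hw/hd under
    rate-1 BM with branch increments correlated 0.8 with size.  Trees drawn
    from the seed are redrawn (deterministically) until the required clade
    sizes exist.
    """
    rng = np.random.default_rng(seed)
    sizes = [n for _, n in FIXTURE_CLADES]
    for _ in range(1000):
        tree = yule_tree(48, rng)
        clades = find_disjoint_clades(tree, sizes)
        if clades is not None:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a tree containing the island clades")
    specs = [(clade, label) for clade, (label, _) in zip(clades, FIXTURE_CLADES)]
    painting = paint_clades(tree, specs, background="continent")
    traits = _fixture_traits(tree, painting, rng)
    groups = pd.Series("continent", index=tree.tip_labels, name="group")
    for clade, (label, _) in zip(clades, FIXTURE_CLADES):
        groups.loc[sorted(clade)] = label
    return tree, painting, traits, groups


def _fixture_traits(
    tree: Phylogeny,
    painting: RegimePainting,
    rng: np.random.Generator,
    *,
    rates: dict[str, float] | None = None,
    head_rate: float = 1.0,
    rho: float = HEAD_SIZE_CORRELATION,
) -> pcm.TraitTable:
    """Simulate svl under the painted rates and correlated head traits.

    Head increments on each branch: rho * (scaled size increment) +
    sqrt(1-rho^2) * independent Brownian noise, so each head trait is
    marginally BM(head_rate) while correlating rho with size per branch.
    """
    rates = dict(FIXTURE_RATES) if rates is None else rates
    n = tree.n_nodes
    var_s = np.zeros(n)
    for v, segs in painting.segments.items():
        var_s[v] = sum(rates[s] * d for s, d in segs)
    var_h = head_rate * np.where(np.arange(n) == tree.root, 0.0, tree.branch_length)
    vals = np.zeros((n, 4))  # svl, hl, hw, hd
    eps = rng.standard_normal((n, 4))
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = tree.parent[v]
        ds = math.sqrt(var_s[v]) * eps[v, 0]
        vals[v, 0] = vals[p, 0] + ds
        sh = math.sqrt(var_h[v])
        zs = eps[v, 0]  # standardized size increment
        for j in (1, 2, 3):
            vals[v, j] = vals[p, j] + sh * (rho * zs + math.sqrt(1 - rho**2) * eps[v, j])
    df = pd.DataFrame(
        vals[: tree.n_tips], index=tree.tip_labels, columns=["svl", "hl", "hw", "hd"]
    )
    df.index.name = "species"
    return pcm.TraitTable(data=df, scale="log10")


@dataclass
class SimConfig:
    """Declarative recipe for replicate simulation bundles."""

    n_tips: int = 48
    seed: int = 0
    n_reps: int = 1
    clade_specs: tuple[tuple[str, int], ...] = ()  # (regime label, clade size)
    rates: dict[str, float] = field(default_factory=lambda: {"continent": 1.0})
    background: str = "continent"
    ou_alpha: float | None = None
    ou_theta: float = 0.0
    root_state: float = 0.0
    fixed_tree: Phylogeny | None = None

    def validate(self) -> None:
        problems = []
        if self.n_tips < 2:
            problems.append("n_tips must be >= 2")
        if self.n_reps < 1:
            problems.append("n_reps must be >= 1")
        if any(r < 0 for r in self.rates.values()):
            problems.append("rates must be non-negative")
        if sum(n for _, n in self.clade_specs) > self.n_tips:
            problems.append("clade sizes exceed n_tips")
        for label, _ in self.clade_specs:
            if label not in self.rates:
                problems.append(f"no rate for regime {label!r}")
        if self.background not in self.rates:
            problems.append(f"no rate for background regime {self.background!r}")
        if self.ou_alpha is not None and self.ou_alpha < 0:
            problems.append("ou_alpha must be >= 0")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimBundle:
    tree: Phylogeny
    painting: RegimePainting
    traits: np.ndarray  # (n_tips,) body-size values in tip order
    groups: pd.Series


def simulate_dataset(config: SimConfig) -> list[SimBundle]:
    """Generate ``config.n_reps`` (tree, painting, trait, groups) bundles."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = [n for _, n in config.clade_specs]
    out = []
    for _ in range(config.n_reps):
        if config.fixed_tree is not None:
            tree = config.fixed_tree
            clades = find_disjoint_clades(tree, sizes)
            if clades is None:
                raise ValueError("fixed tree lacks the requested clade sizes")
        else:
            for _ in range(1000):
                tree = yule_tree(config.n_tips, rng)
                clades = find_disjoint_clades(tree, sizes)
                if clades is not None:
                    break
            else:  # pragma: no cover
                raise RuntimeError("no tree with the requested clades")
        specs = [
            (clade, label)
            for clade, (label, _) in zip(clades, config.clade_specs)
        ]
        painting = paint_clades(tree, specs, background=config.background)
        if config.ou_alpha is not None and config.ou_alpha > 0:
            x = _sim_ou(tree, config.ou_alpha, config.rates[config.background],
                        config.ou_theta, rng)
        else:
            x = pcm.sim_bm(
                tree,
                painting=painting,
                rates=config.rates,
                root_state=config.root_state,
                n_reps=1,
                seed=rng,
            )[0]
        groups = pd.Series(config.background, index=tree.tip_labels, name="group")
        for clade, (label, _) in zip(clades, config.clade_specs):
            groups.loc[sorted(clade)] = label
        out.append(SimBundle(tree=tree, painting=painting, traits=x, groups=groups))
    return out


def _sim_ou(tree, alpha, sigma2, theta, rng):
    """OU simulation with a stationary root, branch by branch."""
    n = tree.n_nodes
    vals = np.zeros(n)
    stat_var = sigma2 / (2.0 * alpha)
    vals[tree.root] = theta + math.sqrt(stat_var) * rng.standard_normal()
    for v in tree.preorder():
        if v == tree.root:
            continue
        t = tree.branch_length[v]
        m = theta + (vals[tree.parent[v]] - theta) * math.exp(-alpha * t)
        var = stat_var * -math.expm1(-2.0 * alpha * t)
        vals[v] = m + math.sqrt(var) * rng.standard_normal()
    return vals[: tree.n_tips]
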