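"""Disparity analyses: island/continent disparity ratios against a Brownian
null, pseudo-community range resampling, and contrasts-through-time
envelopes.

Disparity of a species group is the average squared Euclidean distance
between the trait values of all unordered pairs of species in the group.
The disparity-ratio test asks whether island/continent disparity ratios
exceed what single-process Brownian evolution on the same tree produces; the
pseudo-community test asks whether random continental assemblages of the
island community's size reproduce the island trait ranges; the
contrasts-through-time envelope flags nodes whose standardized contrast
magnitude exceeds a simulated single-rate quantile band.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pcm
from .hypotests import mc_pvalue
from .treeio import Phylogeny

__all__ = [
    "DisparityTest",
    "RangeTest",
    "group_disparity",
    "disparity_ratio_test",
    "pseudo_community_test",
    "contrasts_through_time",
]


def group_disparity(values) -> float:
    """Average squared Euclidean distance over all unordered pairs.

    ``values`` is (m,) for one trait or (m, p) for several.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    m = arr.shape[0]
    if m < 2:
        raise ValueError("disparity needs at least 2 members")
    # sum_{i<j} ||xi-xj||^2 = m * sum_i ||xi - xbar||^2
    centered = arr - arr.mean(axis=0)
    return float(m * (centered**2).sum() / (m * (m - 1) / 2))


def _disparity_many(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Group disparity for a stack of datasets.

    X is (m_sims, n, p); idx selects the group members.  Returns (m_sims,).
    """
    sub = X[:, idx, :]
    m = sub.shape[1]
    centered = sub - sub.mean(axis=1, keepdims=True)
    return m * (centered**2).sum(axis=(1, 2)) / (m * (m - 1) / 2)


@dataclass
class DisparityTest:
    disparity_island: float
    disparity_continent: float
    ratio: float
    null_ratios: np.ndarray
    p_value: float
    n_sims: int
    seed: int
    mode: str

    def to_dict(self, *, include_null: bool = False):
        d = {
            "statistic": "disparity_ratio",
            "disparity_island": self.disparity_island,
            "disparity_continent": self.disparity_continent,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "mode": self.mode,
        }
        if include_null:
            d["null"] = np.asarray(self.null_ratios).tolist()
        return d


@dataclass
class RangeTest:
    island_range: np.ndarray      # per trait
    p_values: np.ndarray          # per trait
    k: int
    n_resamples: int
    exhaustive: bool
    seed: int | None
    trait_names: list[str]

    def to_dict(self):
        return {
            "statistic": "range",
            "island_range": np.asarray(self.island_range).tolist(),
            "p_values": np.asarray(self.p_values).tolist(),
            "k": self.k,
            "n_resamples": self.n_resamples,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "traits": list(self.trait_names),
        }


def disparity_ratio_test(
    tree: Phylogeny,
    X,
    island_members,
    continent_members,
    n_sims: int = 10_000,
    seed: int = 0,
    mode: str = "univariate",
) -> DisparityTest:
    """Island/continent disparity ratio against a Brownian null.

    Univariate mode simulates single-rate BM at the ML rate of the observed
    trait; multivariate mode simulates correlated BM at the ML evolutionary
    rate matrix.  Group memberships are held fixed; the p-value is the
    add-one upper tail over simulated ratios.
    """
    island = list(island_members)
    continent = list(continent_members)
    if set(island) & set(continent):
        raise ValueError("island and continent groups overlap")
    if len(island) < 2 or len(continent) < 2:
        raise ValueError("each group needs at least 2 members")
    lab = tree.label_index
    idx_i = np.array([lab[s] for s in island])
    idx_c = np.array([lab[s] for s in continent])

    if mode == "univariate":
        xv = pcm.align_traits(tree, X)
        arr = xv[:, None]
        fit = pcm.fit_bm1(tree, xv)
        sims = pcm.sim_bm(
            tree, sigma2=fit.sigma2, root_state=fit.root_state,
            n_reps=n_sims, seed=seed,
        )[:, :, None]
    elif mode == "multivariate":
        if isinstance(X, pd.DataFrame):
            arr = np.column_stack([pcm.align_traits(tree, X[c]) for c in X.columns])
        else:
            arr = np.asarray(X, dtype=float)
        R = pcm.evol_vcv(tree, arr).to_numpy()
        roots = [pcm.fit_bm1(tree, arr[:, j]).root_state for j in range(arr.shape[1])]
        sims = pcm.sim_mvbm(tree, R, roots, n_reps=n_sims, seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    d_i = group_disparity(arr[idx_i])
    d_c = group_disparity(arr[idx_c])
    if d_c == 0:
        raise ValueError("continental disparity is zero; ratio undefined")
    obs = d_i / d_c
    null_c = _disparity_many(sims, idx_c)
    null_i = _disparity_many(sims, idx_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        null = null_i / null_c
    null = null[np.isfinite(null)]
    return DisparityTest(
        disparity_island=d_i,
        disparity_continent=d_c,
        ratio=obs,
        null_ratios=null,
        p_value=mc_pvalue(obs, null, tail="upper"),
        n_sims=n_sims,
        seed=seed,
        mode=mode,
    )


def pseudo_community_test(
    continental_values,
    island_values,
    k: int | None = None,
    n_resamples: int = 10_000,
    seed: int | None = 0,
) -> RangeTest:
    """Compare island trait ranges with random continental assemblages.

    Draws size-k subsets of the continental pool without replacement and
    computes, per trait, the proportion of pseudo-communities whose range
    (max - min) is at least the island range.  When the number of distinct
    subsets C(n, k) is at most ``n_resamples`` the enumeration is exhaustive
    and the p-value exact; otherwise Monte-Carlo sampling with the add-one
    correction is used.  Ties count as reaching the island range.
    """
    cont, names = _as_matrix(continental_values)
    isl, names_i = _as_matrix(island_values)
    if names_i and names and names_i != names:
        raise ValueError("trait columns differ between island and continent")
    if k is None:
        k = isl.shape[0]
    if isl.shape[0] != k:
        raise ValueError(f"island community has {isl.shape[0]} species, expected k={k}")
    n = cont.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds continental pool of {n}")
    if k < 2:
        raise ValueError("community size must be >= 2 for a range")
    obs_range = isl.max(axis=0) - isl.min(axis=0)
    n_total = math.comb(n, k)
    if n_total <= n_resamples:
        ranges = np.empty((n_total, cont.shape[1]))
        for i, combo in enumerate(itertools.combinations(range(n), k)):
            sub = cont[list(combo)]
            ranges[i] = sub.max(axis=0) - sub.min(axis=0)
        p = (ranges >= obs_range).mean(axis=0)
        return RangeTest(
            island_range=obs_range,
            p_values=p,
            k=k,
            n_resamples=n_total,
            exhaustive=True,
            seed=None,
            trait_names=names or [f"trait{i}" for i in range(cont.shape[1])],
        )
    rng = np.random.default_rng(seed)
    ranges = np.empty((n_resamples, cont.shape[1]))
    for i in range(n_resamples):
        sub = cont[rng.choice(n, size=k, replace=False)]
        ranges[i] = sub.max(axis=0) - sub.min(axis=0)
    p = (1 + (ranges >= obs_range).sum(axis=0)) / (1 + n_resamples)
    return RangeTest(
        island_range=obs_range,
        p_values=p,
        k=k,
        n_resamples=n_resamples,
        exhaustive=False,
        seed=seed,
        trait_names=names or [f"trait{i}" for i in range(cont.shape[1])],
    )


def _as_matrix(values) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float), list(values.columns)
    if isinstance(values, pd.Series):
        return values.to_numpy(dtype=float)[:, None], None
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def contrasts_through_time(
    tree: Phylogeny,
    x,
    n_sims: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    *,
    envelope: str = "pointwise",
) -> pd.DataFrame:
    """Observed |standardized contrasts| against a simulated quantile band.

    The null band comes from ``n_sims`` single-rate BM simulations at the ML
    rate of the observed trait.  ``envelope='pointwise'`` gives per-node
    (1-level)/2 and (1+level)/2 quantiles of |contrast| (contrasts map
    one-to-one to nodes on a fixed tree); ``'pooled'`` pools |contrasts|
    across nodes into a single band.  A node is flagged when its observed
    |contrast| exceeds the upper bound.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    xv = pcm.align_traits(tree, x)
    obs = pcm.pic(tree, xv)
    fit = pcm.fit_bm1(tree, xv)
    sims = pcm.sim_bm(
        tree, sigma2=fit.sigma2, root_state=fit.root_state, n_reps=n_sims, seed=seed
    )
    sim_contrasts, node_ids = pcm.pic_matrix(tree, sims)
    abs_sim = np.abs(sim_contrasts)
    qlo, qhi = (1 - level) / 2, (1 + level) / 2
    if envelope == "pointwise":
        lower = np.quantile(abs_sim, qlo, axis=0)
        upper = np.quantile(abs_sim, qhi, axis=0)
    elif envelope == "pooled":
        lower = np.full(abs_sim.shape[1], np.quantile(abs_sim, qlo))
        upper = np.full(abs_sim.shape[1], np.quantile(abs_sim, qhi))
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    abs_obs = np.abs(obs.contrasts)
    return pd.DataFrame(
        {
            "node": obs.node_ids,
            "height": obs.heights,
            "abs_contrast": abs_obs,
            "lower": lower,
            "upper": upper,
            "flagged": abs_obs > upper,
        }
    )
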