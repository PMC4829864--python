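"""Simulation-null hypothesis tests.

Phylogenetic ANOVA and MANOVA compare island and mainland trait values: the
classical F statistic (or Wilks' lambda) is computed on the data, then on
many datasets simulated under Brownian motion on the same tree with the
group labels held fixed, and the p-value is the add-one-corrected tail
proportion (1 + #{null at least as extreme}) / (1 + n_sims) -- so p can
never be 0 and floors at 1/(n_sims + 1).

The parametric bootstrap contrasts multi-rate (BMS) against single-rate
(BM1) Brownian motion: the statistic is the log-likelihood difference, its
null distribution comes from refitting both models to data simulated under
the fitted BM1, and power is estimated by simulating under the fitted BMS
and counting exceedances of the null's 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pcm
from .treeio import Phylogeny, RegimePainting

__all__ = [
    "MonteCarloTest",
    "BootstrapResult",
    "anova_f",
    "wilks_lambda",
    "phylo_anova",
    "phylo_manova",
    "parametric_bootstrap_bms",
    "mc_pvalue",
]


def mc_pvalue(observed: float, null: np.ndarray, *, tail: str = "upper") -> float:
    """Add-one Monte-Carlo p-value: (1 + #extreme) / (1 + N)."""
    null = np.asarray(null, dtype=float)
    if tail == "upper":
        extreme = int(np.sum(null >= observed))
    elif tail == "lower":
        extreme = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + extreme) / (1 + len(null))


@dataclass
class MonteCarloTest:
    statistic: str
    observed: float
    null: np.ndarray
    p_value: float
    n_sims: int
    seed: int
    tail: str = "upper"

    def to_dict(self, *, include_null: bool = False):
        d = {
            "statistic": self.statistic,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "tail": self.tail,
        }
        if include_null:
            d["null"] = np.asarray(self.null).tolist()
        return d


@dataclass
class BootstrapResult:
    observed_lr: float
    null_lr: np.ndarray
    p_value: float
    power: float
    n_boot: int
    seed: int
    n_failures: int = 0

    def to_dict(self, *, include_null: bool = False):
        d = {
            "statistic": "LRdiff",
            "observed_lr": self.observed_lr,
            "p_value": self.p_value,
            "power": self.power,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failures": self.n_failures,
        }
        if include_null:
            d["null"] = np.asarray(self.null_lr).tolist()
        return d


# ---------------------------------------------------------------------------
# Classical statistics (vectorized over leading axes)
# ---------------------------------------------------------------------------


def _group_indices(groups) -> tuple[list[np.ndarray], list]:
    g = pd.Series(groups)
    labels = sorted(g.unique().tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    pos = [np.flatnonzero((g == lab).to_numpy()) for lab in labels]
    if any(len(p) == 0 for p in pos):
        raise ValueError("empty group")
    return pos, labels


def anova_f(x, groups) -> float:
    """Classical one-way ANOVA F = (SSB/df_B) / (SSW/df_W)."""
    return float(_anova_f_many(np.atleast_2d(np.asarray(x, dtype=float)), groups)[0])


def _anova_f_many(X: np.ndarray, groups) -> np.ndarray:
    """F statistics for rows of X (m, n)."""
    pos, _ = _group_indices(groups)
    n = X.shape[1]
    k = len(pos)
    if n - k <= 0:
        raise ValueError("no within-group degrees of freedom")
    grand = X.mean(axis=1, keepdims=True)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for p in pos:
        sub = X[:, p]
        m = sub.mean(axis=1, keepdims=True)
        ssb += len(p) * (m[:, 0] - grand[:, 0]) ** 2
        ssw += ((sub - m) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / dfb) / (ssw / dfw)


def wilks_lambda(X, groups) -> float:
    """Wilks' lambda = det(W) / det(W + B) for one-way MANOVA."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D (observations x traits)")
    return float(_wilks_many(arr[None, :, :], groups)[0])


def _wilks_many(X: np.ndarray, groups) -> np.ndarray:
    """Wilks' lambda for a stack of datasets X (m, n, p)."""
    pos, _ = _group_indices(groups)
    m, n, p = X.shape
    grand = X.mean(axis=1, keepdims=True)
    T = np.einsum("mni,mnj->mij", X - grand, X - grand)
    W = np.zeros((m, p, p))
    for idx in pos:
        sub = X[:, idx, :]
        gm = sub.mean(axis=1, keepdims=True)
        W += np.einsum("mni,mnj->mij", sub - gm, sub - gm)
    detW = np.linalg.det(W)
    detT = np.linalg.det(T)
    if np.any(detT <= 0) or np.any(detW < 0):
        bad = detW < 0
        detW = np.where(bad, np.nan, detW)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = detW / detT
    if not np.all(np.isfinite(lam)):
        raise ValueError("singular scatter matrix in Wilks' lambda")
    return lam


# ---------------------------------------------------------------------------
# Phylogenetic simulation-null tests
# ---------------------------------------------------------------------------


def phylo_anova(
    tree: Phylogeny, x, groups, n_sims: int = 10_000, seed: int = 0
) -> MonteCarloTest:
    """Phylogenetic ANOVA: F's null distribution from single-rate BM
    simulations at the ML rate fitted to the observed data."""
    if n_sims < 99:
        raise ValueError("n_sims must be >= 99")
    xv = pcm.align_traits(tree, x)
    groups = _align_groups(tree, groups)
    obs = anova_f(xv, groups)
    fit = pcm.fit_bm1(tree, xv)
    sims = pcm.sim_bm(
        tree, sigma2=fit.sigma2, root_state=fit.root_state, n_reps=n_sims, seed=seed
    )
    null = _anova_f_many(sims, groups)
    return MonteCarloTest(
        statistic="F",
        observed=obs,
        null=null,
        p_value=mc_pvalue(obs, null, tail="upper"),
        n_sims=n_sims,
        seed=seed,
        tail="upper",
    )


def phylo_manova(
    tree: Phylogeny, X, groups, n_sims: int = 10_000, seed: int = 0
) -> MonteCarloTest:
    """Phylogenetic MANOVA: Wilks' lambda against multivariate BM
    simulations at the ML evolutionary rate matrix (smaller lambda = more
    extreme, so the lower tail is used)."""
    if n_sims < 99:
        raise ValueError("n_sims must be >= 99")
    if isinstance(X, pd.DataFrame):
        arr = np.column_stack([pcm.align_traits(tree, X[c]) for c in X.columns])
    else:
        arr = np.asarray(X, dtype=float)
    groups = _align_groups(tree, groups)
    obs = wilks_lambda(arr, groups)
    R = pcm.evol_vcv(tree, arr).to_numpy()
    roots = _gls_roots(tree, arr)
    sims = pcm.sim_mvbm(tree, R, roots, n_reps=n_sims, seed=seed)
    null = _wilks_many(sims, groups)
    return MonteCarloTest(
        statistic="WilksLambda",
        observed=obs,
        null=null,
        p_value=mc_pvalue(obs, null, tail="lower"),
        n_sims=n_sims,
        seed=seed,
        tail="lower",
    )


def _gls_roots(tree: Phylogeny, arr: np.ndarray) -> np.ndarray:
    return np.array([pcm.fit_bm1(tree, arr[:, j]).root_state for j in range(arr.shape[1])])


def _align_groups(tree: Phylogeny, groups) -> pd.Series:
    if isinstance(groups, pd.Series):
        return groups.loc[tree.tip_labels]
    g = pd.Series(list(groups))
    if len(g) != tree.n_tips:
        raise ValueError("groups length does not match tips")
    g.index = tree.tip_labels
    return g


def parametric_bootstrap_bms(
    tree: Phylogeny,
    painting: RegimePainting,
    x,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    n_power: int | None = None,
    confidence: float = 0.95,
    max_failure_rate: float = 0.05,
    compute_power: bool = True,
) -> BootstrapResult:
    """Parametric bootstrap of BMS vs BM1 with power.

    Observed statistic: logL(BMS) - logL(BM1) on the data.  Null sample: the
    same statistic on ``n_boot`` datasets simulated under the fitted BM1.
    Power: fraction of ``n_power`` datasets simulated under the fitted BMS
    whose statistic exceeds the null's ``confidence`` quantile.  Replicates
    whose optimizer fails are dropped and counted; more than
    ``max_failure_rate`` failures aborts.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    if n_power is None:
        n_power = n_boot
    xv = pcm.align_traits(tree, x)
    rng = np.random.default_rng(seed)
    fit1 = pcm.fit_bm1(tree, xv)
    fits = pcm.fit_bms(tree, painting, xv)
    obs = max(fits.logL - fit1.logL, 0.0)

    def lr_of(data: np.ndarray) -> float:
        f1 = pcm.fit_bm1(tree, data)
        fs = pcm.fit_bms(tree, painting, data)
        return max(fs.logL - f1.logL, 0.0)

    failures = 0

    def lr_sample(sims: np.ndarray) -> np.ndarray:
        nonlocal failures
        vals = []
        for row in sims:
            try:
                vals.append(lr_of(row))
            except (np.linalg.LinAlgError, ValueError):
                failures += 1
        return np.asarray(vals)

    null_sims = pcm.sim_bm(
        tree, sigma2=fit1.sigma2, root_state=fit1.root_state, n_reps=n_boot, seed=rng
    )
    null_lr = lr_sample(null_sims)
    if compute_power:
        power_sims = pcm.sim_bm(
            tree,
            painting=painting,
            rates=fits.sigma2_by_regime,
            root_state=fits.root_state,
            n_reps=n_power,
            seed=rng,
        )
        power_lr = lr_sample(power_sims)
    else:
        n_power = 0
        power_lr = np.empty(0)
    if failures > max_failure_rate * (n_boot + n_power):
        raise RuntimeError(
            f"{failures} optimizer failures out of {n_boot + n_power} replicates"
        )
    threshold = float(np.quantile(null_lr, confidence))
    power = float(np.mean(power_lr > threshold)) if compute_power else float("nan")
    return BootstrapResult(
        observed_lr=obs,
        null_lr=null_lr,
        p_value=mc_pvalue(obs, null_lr, tail="upper"),
        power=power,
        n_boot=n_boot,
        seed=seed,
        n_failures=failures,
    )
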