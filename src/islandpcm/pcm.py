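"""Continuous-trait models on phylogenies.

Likelihoods and ML fits for single-rate Brownian motion (BM1), multi-rate
Brownian motion with regime-specific rates (BMS), and single-optimum
Ornstein-Uhlenbeck (OU1); small-sample AIC; Felsenstein's independent
contrasts; GLS ancestral states; phylogenetic regression residuals; and
seeded Brownian trait simulators (single-rate, regime-painted, and
multivariate).

All Gaussian computation runs through a Cholesky factorization of the
phylogenetic covariance; a single diagonal jitter of 1e-10 x max(diag) is
attempted on failure, after which the matrix is declared singular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .treeio import Phylogeny, RegimePainting, regime_vcv_arrays, vcv_array

__all__ = [
    "BMFit",
    "BMSFit",
    "OUFit",
    "ContrastSet",
    "TraitTable",
    "bm_loglik",
    "fit_bm1",
    "fit_bms",
    "fit_ou1",
    "ou_loglik",
    "aicc",
    "compare_models",
    "pic",
    "asr_bm",
    "pgls_residuals",
    "head_residuals",
    "sim_bm",
    "sim_mvbm",
    "evol_vcv",
    "align_traits",
]

LOG2PI = math.log(2.0 * math.pi)
ALPHA_FLOOR = 1e-8


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def _cho(C: np.ndarray):
    """Cholesky with the package's jitter policy: one retry with
    1e-10 * max(diag) added to the diagonal, then failure."""
    try:
        return linalg.cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * float(np.max(np.diag(C)))
    try:
        return linalg.cho_factor(
            C + jitter * np.eye(C.shape[0]), lower=True, check_finite=False
        )
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "phylogenetic covariance is singular even after diagonal jitter"
        ) from exc


def _cho_solve(cf, b):
    return linalg.cho_solve(cf, b, check_finite=False)


def _logdet(cf) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(cf[0]))))


def align_traits(tree: Phylogeny, x) -> np.ndarray:
    """Return trait values ordered like ``tree.tip_labels``.

    Accepts a pandas Series/DataFrame indexed by species, a mapping, or an
    array already in tip order.
    """
    if isinstance(x, (pd.Series, pd.DataFrame)):
        missing = [l for l in tree.tip_labels if l not in x.index]
        if missing:
            raise KeyError(f"traits missing for tips: {missing}")
        arr = x.loc[tree.tip_labels].to_numpy(dtype=float)
    elif isinstance(x, dict):
        arr = np.array([float(x[l]) for l in tree.tip_labels])
    else:
        arr = np.asarray(x, dtype=float)
        if arr.shape[0] != tree.n_tips:
            raise ValueError(
                f"trait vector length {arr.shape[0]} != {tree.n_tips} tips"
            )
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite trait values")
    return arr


# ---------------------------------------------------------------------------
# Fit records
# ---------------------------------------------------------------------------


@dataclass
class BMFit:
    sigma2: float
    root_state: float
    logL: float
    k: int
    n: int
    aicc: float
    model: str = "BM1"

    def to_dict(self):
        return {
            "model": self.model,
            "params": {"sigma2": self.sigma2, "root_state": self.root_state},
            "logL": self.logL,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
        }


@dataclass
class BMSFit:
    sigma2_by_regime: dict[str, float]
    root_state: float
    logL: float
    k: int
    n: int
    aicc: float
    model: str = "BMS"

    def to_dict(self):
        return {
            "model": self.model,
            "params": {
                "sigma2_by_regime": dict(self.sigma2_by_regime),
                "root_state": self.root_state,
            },
            "logL": self.logL,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
        }


@dataclass
class OUFit:
    alpha: float
    theta: float
    sigma2: float
    logL: float
    k: int
    n: int
    aicc: float
    alpha_at_bound: bool = False
    model: str = "OU1"

    def to_dict(self):
        return {
            "model": self.model,
            "params": {
                "alpha": self.alpha,
                "theta": self.theta,
                "sigma2": self.sigma2,
            },
            "logL": self.logL,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "alpha_at_bound": self.alpha_at_bound,
        }


@dataclass
class ContrastSet:
    """Standardized independent contrasts with the height of the node that
    produced each one."""

    node_ids: np.ndarray
    contrasts: np.ndarray
    heights: np.ndarray

    def __len__(self):
        return len(self.node_ids)

    def reml_rate(self) -> float:
        """Mean squared contrast: the REML Brownian rate estimate."""
        return float(np.mean(self.contrasts**2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.node_ids,
                "contrast": self.contrasts,
                "height": self.heights,
            }
        )


@dataclass
class TraitTable:
    """Species-by-trait table; values are log10-transformed at ingestion."""

    data: pd.DataFrame
    scale: str = "log10"

    COLUMNS = ("svl", "hl", "hw", "hd")

    @classmethod
    def read_csv(cls, path_or_buf, *, log10: bool = True) -> "TraitTable":
        df = pd.read_csv(path_or_buf)
        cols = {c.lower(): c for c in df.columns}
        if "species" not in cols:
            raise ValueError("trait CSV must have a 'species' column")
        df = df.rename(columns={v: k for k, v in cols.items()}).set_index("species")
        keep = [c for c in cls.COLUMNS if c in df.columns]
        if not keep:
            raise ValueError(f"no trait columns among {cls.COLUMNS}")
        df = df[keep].astype(float)
        if log10:
            if (df <= 0).any().any():
                raise ValueError("non-positive trait values cannot be log10-transformed")
            df = np.log10(df)
            scale = "log10"
        else:
            scale = "raw"
        return cls(data=df, scale=scale)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species")

    def column(self, name: str, *, dropna: bool = True) -> pd.Series:
        s = self.data[name]
        return s.dropna() if dropna else s

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# Likelihoods and fits
# ---------------------------------------------------------------------------


def _mvn_loglik(C: np.ndarray, resid: np.ndarray) -> float:
    cf = _cho(C)
    q = float(resid @ _cho_solve(cf, resid))
    n = len(resid)
    return -0.5 * (n * LOG2PI + _logdet(cf) + q)


def bm_loglik(tree: Phylogeny, x, sigma2: float, root_state: float) -> float:
    """Log-likelihood of single-rate Brownian motion at fixed parameters."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    xv = align_traits(tree, x)
    C = sigma2 * vcv_array(tree)
    return _mvn_loglik(C, xv - root_state)


def _gls_profile(C0: np.ndarray, xv: np.ndarray, *, denom: str = "ml"):
    """GLS mean and profiled scale for covariance ``s * C0``.

    Returns (mu, s_hat, concentrated logL at ML scale)."""
    cf = _cho(C0)
    n = len(xv)
    rhs = np.empty((n, 2))
    rhs[:, 0] = 1.0
    rhs[:, 1] = xv
    B = _cho_solve(cf, rhs)
    s11 = float(B[:, 0].sum())
    s1x = float(B[:, 1].sum())
    sxx = float(xv @ B[:, 1])
    mu = s1x / s11
    q = sxx - s1x * s1x / s11
    s_ml = q / n
    if s_ml <= 0:
        raise ValueError("degenerate data: zero phylogenetic variance")
    logL = -0.5 * (n * LOG2PI + _logdet(cf) + n * math.log(s_ml) + n)
    s = q / (n - 1) if denom == "reml" else s_ml
    return mu, s, logL


def fit_bm1(tree: Phylogeny, x, *, denom: str = "ml") -> BMFit:
    """ML fit of single-rate Brownian motion.

    ``denom='reml'`` reports the (n-1)-denominator rate instead of the ML
    rate; the log-likelihood and AICc always refer to the ML fit.
    """
    xv = align_traits(tree, x)
    n = len(xv)
    if n < 2:
        raise ValueError("need at least 2 tips")
    mu, s, logL = _gls_profile(vcv_array(tree), xv, denom=denom)
    k = 2
    return BMFit(sigma2=s, root_state=mu, logL=logL, k=k, n=n, aicc=_fit_aicc(logL, k, n))


def fit_bms(tree: Phylogeny, painting: RegimePainting, x) -> BMSFit:
    """ML fit of multi-rate Brownian motion over a regime painting.

    The covariance is sum_r sigma2_r V_r with V_r the per-regime shared-time
    matrices.  One rate is profiled out analytically along with the root
    state; the remaining R-1 log rate ratios are optimized by Nelder-Mead
    from three starts (equal rates, x0.1, x10).  Starting at equal rates
    makes the fit's likelihood at least BM1's.
    """
    xv = align_traits(tree, x)
    n = len(xv)
    mats = regime_vcv_arrays(tree, painting)
    regimes = list(painting.alphabet)
    dwell = painting.dwell_times()
    absent = [r for r in regimes if dwell[r] <= 0]
    if absent:
        raise ValueError(f"regimes absent from the painting: {absent}")
    V = np.stack([mats[r] for r in regimes])
    R = len(regimes)
    rhs = np.empty((n, 2))
    rhs[:, 0] = 1.0
    rhs[:, 1] = xv
    BIG = 1e10  # finite penalty keeps L-BFGS-B line searches sane

    def objective(log_ratios) -> float:
        ratios = np.concatenate([[1.0], np.exp(np.asarray(log_ratios, dtype=float))])
        C0 = np.tensordot(ratios, V, axes=1)
        try:
            L = np.linalg.cholesky(C0)
        except np.linalg.LinAlgError:
            return BIG
        B = linalg.solve_triangular(L, rhs, lower=True, check_finite=False)
        s11 = float(B[:, 0] @ B[:, 0])
        s1x = float(B[:, 0] @ B[:, 1])
        sxx = float(B[:, 1] @ B[:, 1])
        q = sxx - s1x * s1x / s11
        if q <= 0:
            return BIG
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        return 0.5 * (n * LOG2PI + logdet + n * math.log(q / n) + n)

    def concentrated(log_ratios: np.ndarray):
        ratios = np.concatenate([[1.0], np.exp(log_ratios)])
        C0 = np.tensordot(ratios, V, axes=1)
        mu, s, logL = _gls_profile(C0, xv)
        return mu, s * ratios, logL

    bound = math.log(1e8)
    best = None
    for start in (np.zeros(R - 1), np.full(R - 1, math.log(0.1)),
                  np.full(R - 1, math.log(10.0))):
        if R == 1:
            best = (objective(np.zeros(0)), np.zeros(0))
            break
        sol = optimize.minimize(
            objective, start, method="L-BFGS-B",
            bounds=[(-bound, bound)] * (R - 1),
        )
        cand = (float(sol.fun), np.asarray(sol.x, dtype=float))
        if best is None or cand[0] < best[0]:
            best = cand
    if best[0] >= BIG:
        raise SingularCovarianceError("BMS covariance singular at every start")
    mu, sig2, logL = concentrated(best[1])
    k = 1 + R
    return BMSFit(
        sigma2_by_regime={r: float(s) for r, s in zip(regimes, sig2)},
        root_state=mu,
        logL=logL,
        k=k,
        n=n,
        aicc=_fit_aicc(logL, k, n),
    )


def _ou_structure(tree: Phylogeny, alpha: float) -> np.ndarray:
    """Stationary-root OU covariance divided by sigma2:
    exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)) / (2 alpha)."""
    C = vcv_array(tree)  # t_ij = shared time
    depths = np.diag(C)
    d = depths[:, None] + depths[None, :] - 2.0 * C  # patristic distances
    return np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)


def ou_loglik(tree: Phylogeny, x, alpha: float, sigma2: float, theta: float) -> float:
    """OU1 log-likelihood at fixed parameters (stationary root at theta)."""
    if alpha <= 0 or sigma2 <= 0:
        raise ValueError("alpha and sigma2 must be positive")
    if not tree.is_ultrametric():
        raise ValueError("OU1 requires an ultrametric tree")
    xv = align_traits(tree, x)
    V = sigma2 * _ou_structure(tree, alpha)
    return _mvn_loglik(V, xv - theta)


def fit_ou1(
    tree: Phylogeny, x, *, alpha_bounds: tuple[float, float] | None = None
) -> OUFit:
    """ML fit of single-optimum OU with the root drawn from the stationary
    distribution around the optimum.  Requires an ultrametric tree.

    sigma2 and theta are profiled analytically; alpha is optimized on a log
    grid refined by bounded scalar minimization over
    [1e-8, 50 / tree depth].
    """
    if not tree.is_ultrametric():
        raise ValueError("OU1 requires an ultrametric tree")
    xv = align_traits(tree, x)
    n = len(xv)
    if alpha_bounds is None:
        alpha_bounds = (ALPHA_FLOOR, 50.0 / tree.depth)
    lo, hi = alpha_bounds

    def profiled(alpha: float):
        V0 = _ou_structure(tree, alpha)
        return _gls_profile(V0, xv)

    def objective(log_alpha: float) -> float:
        try:
            return -profiled(math.exp(log_alpha))[2]
        except (SingularCovarianceError, ValueError):
            return np.inf

    grid = np.linspace(math.log(lo), math.log(hi), 25)
    vals = [objective(g) for g in grid]
    gbest = int(np.argmin(vals))
    glo = grid[max(gbest - 1, 0)]
    ghi = grid[min(gbest + 1, len(grid) - 1)]
    sol = optimize.minimize_scalar(
        objective, bounds=(glo, ghi), method="bounded",
        options={"xatol": 1e-10},
    )
    cands = [(vals[gbest], grid[gbest]), (float(sol.fun), float(sol.x))]
    fbest, labest = min(cands)
    alpha = math.exp(labest)
    theta, sigma2, logL = profiled(alpha)
    k = 3
    return OUFit(
        alpha=alpha,
        theta=theta,
        sigma2=sigma2,
        logL=logL,
        k=k,
        n=n,
        aicc=_fit_aicc(logL, k, n),
        alpha_at_bound=alpha >= 0.99 * hi,
    )


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_aicc(logL: float, k: int, n: int) -> float:
    """AICc for fit records: NaN (not an error) when n <= k + 1, so tiny
    worked examples can still be fitted."""
    return aicc(logL, k, n) if n - k - 1 > 0 else math.nan


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted models by AICc (ascending) with delta-AICc."""
    rows = [
        {"model": f.model, "logL": f.logL, "k": f.k, "n": f.n, "aicc": f.aicc}
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# Contrasts, ancestral states, regression
# ---------------------------------------------------------------------------


def pic(tree: Phylogeny, x) -> ContrastSet:
    """Felsenstein's standardized independent contrasts.

    At each internal node with children values x_i, x_j on (augmented)
    branches v_i, v_j the contrast is (x_i - x_j)/sqrt(v_i + v_j); the node
    receives the inverse-variance-weighted mean and its branch is augmented
    by v_i v_j / (v_i + v_j).  Returns one contrast per internal node with
    the node's height.  Vectorized over trailing axes of ``x``.
    """
    contrasts, _, node_ids = _pic_engine(tree, x)
    if contrasts.ndim != 1:
        raise ValueError("pic expects a single trait vector; use pic_matrix")
    h = tree.heights()
    return ContrastSet(node_ids=node_ids, contrasts=contrasts, heights=h[node_ids])


def _pic_engine(tree: Phylogeny, x):
    """Shared pruning pass.  ``x`` may be shape (n_tips,) or (m, n_tips)."""
    arr = np.asarray(x, dtype=float)
    series_like = isinstance(x, (pd.Series, dict))
    if series_like or arr.ndim == 1:
        arr = align_traits(tree, x)[None, :]
        squeeze = True
    else:
        if arr.shape[-1] != tree.n_tips:
            raise ValueError("last axis must match the number of tips")
        squeeze = False
    m = arr.shape[0]
    n = tree.n_nodes
    vals = np.zeros((m, n))
    vals[:, : tree.n_tips] = arr
    vlen = tree.branch_length.astype(float).copy()
    node_ids = []
    contrasts = np.zeros((m, tree.n_tips - 1))
    ci = 0
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        a, b = tree.children(v)
        va, vb = vlen[a], vlen[b]
        pooled = va + vb
        if pooled <= 0:
            raise ZeroDivisionError(
                f"zero pooled branch length at node {v}: contrasts undefined"
            )
        contrasts[:, ci] = (vals[:, a] - vals[:, b]) / math.sqrt(pooled)
        node_ids.append(v)
        vals[:, v] = (vb * vals[:, a] + va * vals[:, b]) / pooled
        vlen[v] += va * vb / pooled
        ci += 1
    out = contrasts[0] if squeeze else contrasts
    return out, vals, np.array(node_ids, dtype=np.int64)


def pic_matrix(tree: Phylogeny, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Contrasts for many datasets at once: X is (m, n_tips); returns
    (contrasts (m, n_tips-1), node ids)."""
    contrasts, _, node_ids = _pic_engine(tree, np.atleast_2d(X))
    return contrasts, node_ids


def asr_bm(tree: Phylogeny, x) -> dict[int, float]:
    """GLS/ML ancestral states under Brownian motion, keyed by internal node
    id.  The root equals the BM1 GLS root state."""
    xv = align_traits(tree, x)
    C = vcv_array(tree)
    cf = _cho(C)
    one = np.ones(tree.n_tips)
    mu = float(one @ _cho_solve(cf, xv)) / float(one @ _cho_solve(cf, one))
    w = _cho_solve(cf, xv - mu)
    shared = tree.mrca_heights()  # (n_nodes, n_tips)
    out: dict[int, float] = {}
    for v in range(tree.n_tips, tree.n_nodes):
        out[v] = mu + float(shared[v] @ w)
    return out


def pgls_residuals(tree: Phylogeny, y, x) -> pd.Series:
    """Residuals of a phylogenetic (GLS) regression of y on x.

    beta = (X' C^-1 X)^-1 X' C^-1 y with an intercept column; the returned
    residuals are the raw response residuals y - X beta (not re-whitened),
    usable directly as species-level size-corrected trait values.
    """
    yv = align_traits(tree, y)
    xv = align_traits(tree, x)
    C = vcv_array(tree)
    cf = _cho(C)
    X = np.column_stack([np.ones_like(xv), xv])
    CiX = _cho_solve(cf, X)
    XtCiX = X.T @ CiX
    if np.linalg.cond(XtCiX) > 1e12:
        raise ValueError("collinear design: covariate is (nearly) constant")
    beta = np.linalg.solve(XtCiX, X.T @ _cho_solve(cf, yv))
    return pd.Series(yv - X @ beta, index=tree.tip_labels)


def head_residuals(tree: Phylogeny, traits: TraitTable) -> pd.DataFrame:
    """Size-corrected head dimensions: phylogenetic-regression residuals of
    each of hl/hw/hd on svl, computed on species present for both traits."""
    cols = [c for c in ("hl", "hw", "hd") if c in traits.data.columns]
    if "svl" not in traits.data.columns or not cols:
        raise ValueError("need svl and at least one head trait")
    out = {}
    svl = traits.data["svl"]
    for c in cols:
        out[c] = pgls_residuals(tree, traits.data[c], svl)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


def _branch_variances(
    tree: Phylogeny,
    sigma2: float | None,
    painting: RegimePainting | None,
    rates: dict[str, float] | None,
) -> np.ndarray:
    var = np.zeros(tree.n_nodes)
    if painting is not None:
        if rates is None:
            raise ValueError("painting given without per-regime rates")
        painting.validate(tree)
        missing = [r for r in {s for segs in painting.segments.values() for s, _ in segs} if r not in rates]
        if missing:
            raise ValueError(f"no rate supplied for regimes {missing}")
        if any(r < 0 for r in rates.values()):
            raise ValueError("negative rate")
        for v, segs in painting.segments.items():
            var[v] = sum(rates[s] * d for s, d in segs)
    else:
        if sigma2 is None or sigma2 < 0:
            raise ValueError("sigma2 must be given and non-negative")
        var = sigma2 * tree.branch_length.copy()
        var[tree.root] = 0.0
    return var


def sim_bm(
    tree: Phylogeny,
    *,
    sigma2: float | None = None,
    painting: RegimePainting | None = None,
    rates: dict[str, float] | None = None,
    root_state: float = 0.0,
    n_reps: int = 1,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate Brownian traits tip-ward along branches.

    Either a single ``sigma2`` or a ``painting`` plus per-regime ``rates``.
    Returns an (n_reps, n_tips) array in ``tree.tip_labels`` order.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    var = _branch_variances(tree, sigma2, painting, rates)
    sd = np.sqrt(var)
    vals = np.empty((n_reps, tree.n_nodes))
    eps = rng.standard_normal((n_reps, tree.n_nodes))
    vals[:, tree.root] = root_state
    for v in tree.preorder():
        if v == tree.root:
            continue
        vals[:, v] = vals[:, tree.parent[v]] + sd[v] * eps[:, v]
    return vals[:, : tree.n_tips]


def sim_mvbm(
    tree: Phylogeny,
    R: np.ndarray,
    roots,
    *,
    n_reps: int = 1,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate correlated traits under multivariate Brownian motion.

    ``R`` is the (p, p) evolutionary rate matrix (per-unit-time increment
    covariance, must be positive definite); returns
    (n_reps, n_tips, p) in tip order.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T):
        raise ValueError("R must be square symmetric")
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait rate matrix R is not positive definite") from exc
    roots = np.broadcast_to(np.asarray(roots, dtype=float), (p,))
    sd = np.sqrt(np.maximum(tree.branch_length, 0.0))
    sd[tree.root] = 0.0
    vals = np.empty((n_reps, tree.n_nodes, p))
    vals[:, tree.root, :] = roots
    eps = rng.standard_normal((n_reps, tree.n_nodes, p)) @ L.T
    for v in tree.preorder():
        if v == tree.root:
            continue
        vals[:, v, :] = vals[:, tree.parent[v], :] + sd[v] * eps[:, v, :]
    return vals[:, : tree.n_tips, :]


def evol_vcv(tree: Phylogeny, X) -> pd.DataFrame:
    """ML evolutionary rate (variance-covariance) matrix of several traits.

    R = (X - 1 mu')' C^-1 (X - 1 mu') / n with per-trait GLS means mu.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        arr = np.column_stack([align_traits(tree, X[c]) for c in cols])
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D (tips x traits)")
        cols = [f"trait{i}" for i in range(arr.shape[1])]
    n, p = arr.shape
    if p < 1:
        raise ValueError("need at least one trait")
    if p > n:
        raise ValueError(f"more traits ({p}) than species ({n})")
    C = vcv_array(tree)
    cf = _cho(C)
    one = np.ones(n)
    Ci1 = _cho_solve(cf, one)
    denom = float(one @ Ci1)
    mus = (Ci1 @ arr) / denom
    D = arr - mus
    R = D.T @ _cho_solve(cf, D) / n
    R = (R + R.T) / 2.0
    return pd.DataFrame(R, index=cols, columns=cols)
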