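"""Maximum-likelihood models of continuous trait evolution on a phylogeny.

Implements the three classic single-trait models — Brownian motion (BM),
Ornstein-Uhlenbeck (OU, stabilizing selection toward an optimum) and
Early-Burst (EB, exponentially decaying rate) — with per-species measurement
error folded into the tip covariance, plus Pagel's lambda/delta/kappa
transformation tests, GLS ancestral-state reconstruction, Felsenstein's
independent contrasts and a contrast-based rate comparison.

The tip covariance of each model is a deterministic function of the shared
root-to-MRCA times ``t_a`` and tip depths:

* BM:  ``sigma2 * t_a``
* EB:  ``sigma2 * (exp(r t_a) - 1) / r``  (-> BM as r -> 0)
* OU (root fixed at z0): ``sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_a))``

with ``d_ij`` the patristic distance.  The likelihood is the multivariate
normal density of the observed tip means around ``z0`` with covariance
``V_model + diag(SE^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloCovariance, phylo_covariance, tip_labels, transform_tree

__all__ = [
    "TraitObservations",
    "EvoModelFit",
    "AncestralStates",
    "PagelResult",
    "ContrastSet",
    "RateComparison",
    "fit_trait_model",
    "akaike_weights",
    "reconstruct_ancestral",
    "fit_pagel",
    "pagel_lrt",
    "compute_pics",
    "compare_clade_rates",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class TraitObservations:
    """Per-species trait means (ln scale) with standard errors of the mean."""

    species: list[str]
    mean: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len(self.species) != len(set(self.species)):
            raise ValueError("duplicated species in observations")
        if np.any(self.se < 0):
            raise ValueError("standard errors must be >= 0")

    @classmethod
    def from_replicates(cls, table: pd.DataFrame, species_col: str = "species",
                        value_col: str = "value", ln: bool = True) -> "TraitObservations":
        """Summarize replicate measurements: mean and SE computed on the ln scale.

        Species with a single record get SE = 0.
        """
        vals = table[[species_col, value_col]].dropna()
        if ln:
            if (vals[value_col] <= 0).any():
                bad = vals.loc[vals[value_col] <= 0, species_col].unique().tolist()
                raise ValueError(f"non-positive values under ln transform: {bad}")
            vals = vals.assign(**{value_col: np.log(vals[value_col])})
        grp = vals.groupby(species_col)[value_col]
        mean = grp.mean()
        n = grp.count()
        sd = grp.std(ddof=1).fillna(0.0)
        se = (sd / np.sqrt(n)).where(n > 1, 0.0)
        return cls(list(mean.index), mean.to_numpy(), se.to_numpy())

    def subset(self, species: list[str]) -> "TraitObservations":
        idx = [self.species.index(s) for s in species]
        return TraitObservations(list(species), self.mean[idx], self.se[idx])


@dataclass
class EvoModelFit:
    model: str
    params: dict
    lnl: float
    aic: float
    n_params: int
    aicw: float | None = None
    converged: bool = True
    n_restarts: int = 0
    # cached geometry so ancestral reconstruction can reuse the fit
    species: list[str] = field(default_factory=list, repr=False)
    se: np.ndarray | None = field(default=None, repr=False)


@dataclass
class AncestralStates:
    node_ids: list[str]
    estimate_ln: np.ndarray
    variance: np.ndarray
    estimate_pg: np.ndarray
    root_id: str

    @property
    def root_estimate_pg(self) -> float:
        return float(self.estimate_pg[self.node_ids.index(self.root_id)])


@dataclass
class PagelResult:
    parameter: str
    estimate: float
    lnl: float
    null_lnl: dict
    p_values: dict
    boundary: bool = False


@dataclass
class ContrastSet:
    contrasts: np.ndarray
    node_ids: list[str]
    clade: str = ""


@dataclass
class RateComparison:
    statistic: float
    p_value: float
    mean_abs: tuple[float, float]
    sd_abs: tuple[float, float]
    n: tuple[int, int]


# ---------------------------------------------------------------------------
# model covariances


def _model_cov(model: str, C: np.ndarray, params: dict) -> np.ndarray:
    sigma2 = params["sigma2"]
    if model == "BM":
        return sigma2 * C
    if model == "EB":
        r = params["r"]
        if abs(r) < 1e-12:
            return sigma2 * C
        return sigma2 * np.expm1(r * C) / r
    if model == "OU":
        alpha = params["alpha"]
        if alpha < 1e-12:
            return sigma2 * C
        depths = np.diag(C)
        d = depths[:, None] + depths[None, :] - 2.0 * C
        return sigma2 / (2.0 * alpha) * np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * C))
    raise ValueError(f"unknown model {model!r}")


def _profiled_loglik(V: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Log-likelihood with the root state z0 profiled out by GLS; returns (lnL, z0)."""
    n = len(y)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.nan
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    one = np.ones(n)
    Vi_y = linalg.cho_solve(cho, y)
    Vi_1 = linalg.cho_solve(cho, one)
    z0 = float(one @ Vi_y) / float(one @ Vi_1)
    r = y - z0
    quad = float(r @ linalg.cho_solve(cho, r))
    return -0.5 * (n * _LOG2PI + logdet + quad), z0


def _align(tree, obs: TraitObservations) -> tuple[PhyloCovariance, np.ndarray, np.ndarray]:
    tips = set(tip_labels(tree))
    missing = sorted(set(obs.species) - tips)
    if missing:
        raise ValueError(f"observed species not on tree: {missing}")
    cov = phylo_covariance(tree, order=obs.species)
    return cov, obs.mean, obs.se


def fit_trait_model(tree, obs: TraitObservations, model: str,
                    n_restarts: int = 50, seed: int = 0) -> EvoModelFit:
    """ML fit of BM / OU / EB to tip means with SE, restarting the optimizer."""
    model = model.upper()
    if model not in ("BM", "OU", "EB"):
        raise ValueError(f"unknown model {model!r}")
    cov, y, se = _align(tree, obs)
    if len(y) < 2:
        raise ValueError("need at least 2 species")
    C = cov.matrix
    D = np.diag(se ** 2)
    T = float(np.max(np.diag(C)))
    vy = float(np.var(y)) or 1e-4

    lo_s2, hi_s2 = 1e-8, 100.0 * vy
    lo_a, hi_a = 1e-8, 50.0 / T
    lo_r, hi_r = -10.0 / T, 0.0

    def unpack(theta):
        p = {"sigma2": float(np.exp(theta[0]))}
        if model == "OU":
            p["alpha"] = float(np.exp(theta[1]))
        elif model == "EB":
            p["r"] = float(theta[1])
        return p

    def nll(theta):
        p = unpack(theta)
        V = _model_cov(model, C, p) + D
        lnl, _ = _profiled_loglik(V, y)
        return -lnl if np.isfinite(lnl) else 1e10

    bounds = [(np.log(lo_s2), np.log(hi_s2))]
    if model == "OU":
        bounds.append((np.log(lo_a), np.log(hi_a)))
    elif model == "EB":
        bounds.append((lo_r, hi_r))

    rng = np.random.default_rng(seed)
    starts = [np.array([np.log(max(vy / T, lo_s2))] + ([np.log(1.0 / T)] if model == "OU" else [])
                       + ([-1.0 / T] if model == "EB" else []))]
    for _ in range(max(0, n_restarts - 1)):
        s = [rng.uniform(np.log(lo_s2), np.log(hi_s2))]
        if model == "OU":
            s.append(rng.uniform(np.log(lo_a), np.log(hi_a)))
        elif model == "EB":
            s.append(rng.uniform(lo_r, hi_r))
        starts.append(np.array(s))

    best = None
    converged = False
    for s in starts:
        res = optimize.minimize(nll, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    params = unpack(best.x)
    V = _model_cov(model, C, params) + D
    lnl, z0 = _profiled_loglik(V, y)
    params["z0"] = z0
    k = 2 if model == "BM" else 3
    fit = EvoModelFit(model=model, params=params, lnl=float(lnl), aic=2.0 * k - 2.0 * lnl,
                      n_params=k, converged=converged, n_restarts=len(starts),
                      species=list(obs.species), se=se.copy())
    return fit


def akaike_weights(fits: list[EvoModelFit]) -> list[EvoModelFit]:
    """Attach Akaike weights exp(-delta/2)/sum to a compared set of fits."""
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.aicw = float(wi)
    return fits


# ---------------------------------------------------------------------------
# ancestral reconstruction


def _node_ids(tree) -> None:
    """Assign stable ids: tip label for leaves, 'nd<k>' (preorder) for internals."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node._spid = node.taxon.label
        else:
            node._spid = f"nd{k}"
            k += 1


def _all_node_mrca_depths(tree, order: list[str]):
    """Shared-path matrix over tips (in ``order``) and all internal nodes."""
    _node_ids(tree)
    depth = {}
    for node in tree.preorder_node_iter():
        p = node.parent_node
        depth[node] = 0.0 if p is None else depth[p] + (node.edge.length or 0.0)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    tipmap = {n.taxon.label: n for n in tree.leaf_node_iter()}
    nodes = [tipmap[s] for s in order] + internals
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    M = np.zeros((m, m))
    sub: dict = {}
    for node in tree.postorder_node_iter():
        mine = [node] if node in idx else []
        groups = []
        for child in node.child_nodes():
            groups.append(sub[child])
        d = depth[node]
        # pairs across different child subtrees share this node as MRCA
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for u in groups[a]:
                    for v in groups[b]:
                        M[idx[u], idx[v]] = M[idx[v], idx[u]] = d
        # this node vs every descendant
        for g in groups:
            for u in g:
                if mine:
                    M[idx[mine[0]], idx[u]] = M[idx[u], idx[mine[0]]] = d
        if mine:
            M[idx[mine[0]], idx[mine[0]]] = d
        sub[node] = mine + [u for g in groups for u in g]
    ids = [getattr(n, "_spid") for n in nodes]
    root_id = internals[0]._spid
    return M, ids, len(order), root_id


def reconstruct_ancestral(tree, obs: TraitObservations, fit: EvoModelFit) -> AncestralStates:
    """Conditional-expectation (GLS) ancestral states under a fitted model.

    Internal-node estimates are the conditional means of the joint multivariate
    normal implied by the fitted model given the observed tip means (with their
    SE); back-transformed values are reported as exp(estimate) in pg.
    """
    if not fit.converged:
        raise ValueError("model fit did not converge")
    if fit.params.get("z0") is None:
        raise ValueError("unfitted model")
    M, ids, n_tips, root_id = _all_node_mrca_depths(tree, list(obs.species))
    V_all = _model_cov(fit.model, M, fit.params)
    tt = slice(0, n_tips)
    aa = slice(n_tips, None)
    V_tt = V_all[tt, tt] + np.diag(obs.se ** 2)
    V_at = V_all[aa, tt]
    V_aa = V_all[aa, aa]
    z0 = fit.params["z0"]
    cho = linalg.cho_factor(V_tt, lower=True)
    w = linalg.cho_solve(cho, obs.mean - z0)
    est = z0 + V_at @ w
    covred = V_aa - V_at @ linalg.cho_solve(cho, V_at.T)
    var = np.maximum(np.diag(covred), 0.0)
    anc_ids = ids[n_tips:]
    return AncestralStates(node_ids=anc_ids, estimate_ln=est, variance=var,
                           estimate_pg=np.exp(est), root_id=root_id)


# ---------------------------------------------------------------------------
# Pagel transformation tests


def _pagel_cov(tree, parameter: str, value: float, order: list[str]) -> np.ndarray:
    if parameter == "lambda":
        cov = transform_tree(phylo_covariance(tree, order=order), "lambda", value)
        return cov.matrix
    t = transform_tree(tree, parameter, value)
    return phylo_covariance(t, order=order).matrix


_PAGEL_BOUNDS = {"lambda": (0.0, 1.0), "delta": (1e-3, 3.0), "kappa": (0.0, 3.0)}
_PAGEL_NULLS = {"lambda": (1.0, 0.0), "delta": (1.0,), "kappa": (1.0, 0.0)}


def pagel_lrt(lnl_alt: float, lnl_null: float) -> float:
    """Likelihood-ratio p-value on chi2 with 1 df (negative deltas clipped to 0)."""
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return float(stats.chi2.sf(stat, df=1))


def fit_pagel(tree, obs: TraitObservations, parameter: str,
              n_grid: int = 21) -> PagelResult:
    """ML estimate of one Pagel transform parameter on the BM likelihood.

    SE enters as diag(SE^2) added after transforming the phylogenetic part.
    LRT p-values are reported against the supported null values
    (lambda: 1 and 0; delta: 1; kappa: 1 and 0).
    """
    parameter = parameter.lower()
    if parameter not in _PAGEL_BOUNDS:
        raise ValueError(f"unknown Pagel parameter {parameter!r}")
    _, y, se = _align(tree, obs)
    D = np.diag(se ** 2)
    order = list(obs.species)

    def best_lnl_at(value: float) -> float:
        Cv = _pagel_cov(tree, parameter, value, order)
        vy = float(np.var(y)) or 1e-4
        T = float(np.max(np.diag(Cv))) or 1.0

        def nll(ls2):
            V = np.exp(ls2[0]) * Cv + D
            lnl, _ = _profiled_loglik(V, y)
            return -lnl if np.isfinite(lnl) else 1e10

        res = optimize.minimize_scalar(
            lambda v: nll([v]), bounds=(np.log(1e-10), np.log(1e4 * vy / T + 1e-8)),
            method="bounded", options={"xatol": 1e-8})
        return -res.fun

    lo, hi = _PAGEL_BOUNDS[parameter]
    grid = np.linspace(lo, hi, n_grid)
    lnls = np.array([best_lnl_at(v) for v in grid])
    i = int(np.argmax(lnls))
    a = grid[max(0, i - 1)]
    b = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(lambda v: -best_lnl_at(v), bounds=(a, b),
                                   method="bounded", options={"xatol": 1e-5})
    est = float(res.x)
    lnl = float(-res.fun)
    if lnls.max() > lnl:  # grid end-point was the optimum
        est, lnl = float(grid[i]), float(lnls.max())

    boundary = False
    if np.ptp(lnls) < 1e-6:
        warnings.warn(f"flat likelihood surface for {parameter}; estimate at boundary")
        boundary = True

    null_lnl = {v: best_lnl_at(v) for v in _PAGEL_NULLS[parameter]}
    p_values = {v: pagel_lrt(lnl, l0) for v, l0 in null_lnl.items()}
    return PagelResult(parameter=parameter, estimate=est, lnl=lnl,
                       null_lnl=null_lnl, p_values=p_values, boundary=boundary)


# ---------------------------------------------------------------------------
# independent contrasts


def compute_pics(tree, values: dict | pd.Series, clade: str = "") -> ContrastSet:
    """Felsenstein's standardized independent contrasts on a binary tree.

    Contrast at an internal node = (x_i - x_j) / sqrt(b_i + b_j); the node's
    working value is the 1/b-weighted mean and its parent branch is extended by
    b_i b_j / (b_i + b_j).  Zero-length sister pairs with equal values give a
    contrast of 0 by convention; with differing values they are an error.
    """
    if isinstance(values, pd.Series):
        values = values.dropna().to_dict()
    tips = tip_labels(tree)
    missing = sorted(set(tips) - set(values))
    if missing:
        raise ValueError(f"no trait value for tips: {missing}")
    _node_ids(tree)
    work: dict = {}
    blen: dict = {}
    contrasts: list[float] = []
    ids: list[str] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            work[node] = float(values[node.taxon.label])
            blen[node] = float(node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        if len(children) == 1:  # unifurcate root stem left by pruning
            child = children[0]
            work[node] = work[child]
            blen[node] = float(node.edge.length or 0.0) + blen[child]
            continue
        if len(children) != 2:
            raise ValueError("tree must be strictly binary (resolve polytomies first)")
        ci, cj = children
        xi, xj = work[ci], work[cj]
        bi, bj = blen[ci], blen[cj]
        if bi + bj == 0:
            if xi != xj:
                raise ValueError(f"zero-length sister pair with differing values at {node._spid}")
            contrasts.append(0.0)
            work[node] = xi
            extension = 0.0
        else:
            contrasts.append((xi - xj) / np.sqrt(bi + bj))
            work[node] = (xi / bi + xj / bj) / (1.0 / bi + 1.0 / bj) if bi > 0 and bj > 0 \
                else (xi if bj > 0 else xj)
            extension = bi * bj / (bi + bj)
        ids.append(node._spid)
        blen[node] = float(node.edge.length or 0.0) + extension
    return ContrastSet(contrasts=np.array(contrasts), node_ids=ids, clade=clade)


def compare_clade_rates(contrasts_a: ContrastSet | np.ndarray,
                        contrasts_b: ContrastSet | np.ndarray) -> RateComparison:
    """Two-sided Mann-Whitney U on |contrasts|, first group as reference.

    Exact p for small tie-free samples; mid-rank normal approximation with
    continuity and tie correction otherwise.
    """
    a = np.abs(contrasts_a.contrasts if isinstance(contrasts_a, ContrastSet) else np.asarray(contrasts_a, float))
    b = np.abs(contrasts_b.contrasts if isinstance(contrasts_b, ContrastSet) else np.asarray(contrasts_b, float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both contrast sets must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "asymptotic" if (has_ties or len(a) * len(b) > 400) else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return RateComparison(statistic=float(res.statistic), p_value=float(res.pvalue),
                          mean_abs=(float(a.mean()), float(b.mean())),
                          sd_abs=(float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                                  float(b.std(ddof=1)) if len(b) > 1 else 0.0),
                          n=(len(a), len(b)))
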