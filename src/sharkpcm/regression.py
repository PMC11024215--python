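"""Phylogenetic generalized least squares with ML lambda, and model selection.

The error covariance is ``sigma2 * C(lambda)`` where C is the shared-path
matrix of the phylogeny and lambda scales its off-diagonal entries.  lambda is
profiled on a grid of step 0.01 refined by bounded search, and the full
profile curve is kept with each fit so multimodal surfaces are visible.
Ordinary least squares is the lambda = 0 special case.

Also here: type-II F tests (each term dropped from the full model at the full
model's lambda and case set), re-leveling post-hoc pairwise contrasts with
Benjamini-Hochberg adjustment, partial correlation on PGLS residuals, GVIF
collinearity screening, and all-subsets AICc model selection with conditional
averaging.  The AICc parameter count k is the number of fixed-effect
coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .trees import PhyloCovariance, phylo_covariance

__all__ = [
    "Term",
    "DesignSpec",
    "RegressionFit",
    "DredgeResult",
    "fit_pgls",
    "type2_anova",
    "posthoc_pairwise",
    "partial_correlation",
    "gvif",
    "aicc_penalty",
    "dredge_aicc",
]


@dataclass(frozen=True)
class Term:
    name: str
    ln: bool = False
    categorical: bool = False
    reference: str | None = None
    squared: bool = False

    @property
    def label(self) -> str:
        base = f"ln_{self.name}" if self.ln else self.name
        return f"{base}^2" if self.squared else base


@dataclass(frozen=True)
class DesignSpec:
    response: str
    terms: tuple[Term, ...]
    response_ln: bool = False

    def __post_init__(self):
        labels = [t.label for t in self.terms]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicated terms in design")

    def with_terms(self, terms) -> "DesignSpec":
        return replace(self, terms=tuple(terms))

    def relevel(self, factor: str, reference: str) -> "DesignSpec":
        terms = tuple(replace(t, reference=reference) if t.name == factor else t
                      for t in self.terms)
        return replace(self, terms=terms)


def build_design(data: pd.DataFrame, design: DesignSpec):
    """Complete-case design matrix; returns (X, y, column names, term->cols map, cases)."""
    cols = [design.response] + [t.name for t in design.terms]
    missing = sorted(set(cols) - set(data.columns))
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    sub = data[cols].dropna()
    if sub.empty:
        raise ValueError("no complete cases")
    y = sub[design.response].to_numpy(float)
    if design.response_ln:
        if (y <= 0).any():
            raise ValueError("non-positive response under ln transform")
        y = np.log(y)
    X_cols = [np.ones(len(sub))]
    names = ["Intercept"]
    term_cols: dict = {}
    for t in design.terms:
        start = len(names)
        col = sub[t.name]
        if t.categorical:
            levels = [str(l) for l in (col.cat.categories if isinstance(col.dtype, pd.CategoricalDtype)
                                       else sorted(col.unique()))]
            levels = [l for l in levels if l in set(col.astype(str))]
            ref = t.reference if t.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed for {t.name}")
            for lev in levels:
                if lev == ref:
                    continue
                X_cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{t.label}[{lev}]")
        else:
            v = col.to_numpy(float)
            if t.ln:
                if (v <= 0).any():
                    raise ValueError(f"non-positive values under ln transform in {t.name}")
                v = np.log(v)
            if t.squared:
                v = v ** 2
            X_cols.append(v)
            names.append(t.label)
        term_cols[t.label] = list(range(start, len(names)))
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"singular design; aliased columns: {aliased}")
    return X, y, names, term_cols, list(sub.index)


def _aliased_columns(X, names):
    keep = [0]
    aliased = []
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            aliased.append(names[j])
        else:
            keep.append(j)
    return aliased


@dataclass
class RegressionFit:
    params: pd.DataFrame
    lambda_: float
    lnl: float
    sigma2: float
    n: int
    df_resid: int
    aicc: float
    profile: pd.DataFrame | None
    zresid: pd.Series
    residuals: pd.Series
    cases: list[str]
    term_cols: dict = field(repr=False, default_factory=dict)
    _context: dict = field(repr=False, default_factory=dict)

    @property
    def outliers(self) -> list[str]:
        return list(self.zresid.index[np.abs(self.zresid) > 3])


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls(X, y, V):
    cho = linalg.cho_factor(V, lower=True)
    Xw = linalg.solve_triangular(cho[0], X, lower=True)
    yw = linalg.solve_triangular(cho[0], y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return beta, rss, logdet, Xw, yw, resid_w


def _ml_loglik(n, rss, logdet):
    s2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)


def aicc_penalty(k: int, n: int) -> float:
    """Small-sample correction added to AIC: 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return 2.0 * k * (k + 1) / (n - k - 1)


def fit_pgls(tree_or_cov, data: pd.DataFrame, design: DesignSpec,
             lambda_mode="ml", grid_step: float = 0.01) -> RegressionFit:
    """lambda-PGLS fit.  ``lambda_mode`` is "ml" or a fixed value (0 gives OLS).

    The profile-likelihood curve over the lambda grid is returned with the fit;
    its maximizer is the reported lambda.  Cases with |standardized residual|
    > 3 are exposed via ``fit.outliers``.
    """
    X, y, names, term_cols, cases = build_design(data, design)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"too few complete cases ({n}) for design of rank {p}")
    if isinstance(tree_or_cov, PhyloCovariance):
        cov = tree_or_cov.subset(cases)
    else:
        cov = phylo_covariance(tree_or_cov, order=cases)
    C = cov.matrix

    def negll(lam):
        _, rss, logdet, *_ = _gls(X, y, _lambda_cov(C, lam))
        return -_ml_loglik(n, rss, logdet)

    profile = None
    if lambda_mode == "ml":
        grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
        lnls = np.array([-negll(l) for l in grid])
        i = int(np.argmax(lnls))
        lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
        res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        lam = float(res.x) if -res.fun >= lnls[i] else float(grid[i])
        profile = pd.DataFrame({"lambda": grid, "lnl": lnls})
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("fixed lambda must be in [0, 1]")

    V = _lambda_cov(C, lam)
    beta, rss, logdet, Xw, yw, resid_w = _gls(X, y, V)
    lnl = _ml_loglik(n, rss, logdet)
    df_resid = n - p
    s2 = rss / df_resid
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    params = pd.DataFrame({"coef": beta, "se": se, "t": tvals, "p": pvals}, index=names)
    z = resid_w / np.sqrt(s2)
    raw_resid = y - X @ beta
    aicc = (2 * p - 2 * lnl) + aicc_penalty(p, n)
    return RegressionFit(params=params, lambda_=lam, lnl=float(lnl), sigma2=float(s2),
                         n=n, df_resid=df_resid, aicc=float(aicc), profile=profile,
                         zresid=pd.Series(z, index=cases),
                         residuals=pd.Series(raw_resid, index=cases), cases=cases,
                         term_cols=term_cols,
                         _context={"X": X, "y": y, "V": V, "rss": rss, "names": names,
                                   "design": design})


def type2_anova(fit: RegressionFit) -> pd.DataFrame:
    """Type-II F test of each term: full model vs. the model dropping that term,
    at the full model's lambda and case set."""
    ctx = fit._context
    X, y, V = ctx["X"], ctx["y"], ctx["V"]
    n, p = X.shape
    rss_full = ctx["rss"]
    rows = []
    for label, cols in fit.term_cols.items():
        keep = [j for j in range(p) if j not in cols]
        _, rss_r, *_ = _gls(X[:, keep], y, V)
        q = len(cols)
        F = ((rss_r - rss_full) / q) / (rss_full / (n - p))
        pval = stats.f.sf(F, q, n - p)
        rows.append((label, float(F), q, n - p, float(pval)))
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"]).set_index("term")


def posthoc_pairwise(tree_or_cov, data: pd.DataFrame, design: DesignSpec,
                     factor: str, lambda_mode="ml") -> pd.DataFrame:
    """All level pairs of a factor via reference re-leveling, BH-adjusted.

    Each pair's contrast is the coefficient of level b in the refit with level
    a as the reference (intercept)."""
    fterm = next((t for t in design.terms if t.name == factor and t.categorical), None)
    if fterm is None:
        raise ValueError(f"{factor!r} is not a categorical term of the design")
    col = data[factor].dropna().astype(str)
    levels = [str(l) for l in (data[factor].cat.categories
                               if isinstance(data[factor].dtype, pd.CategoricalDtype)
                               else sorted(col.unique()))]
    levels = [l for l in levels if (col == l).sum() >= 1]
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 observed levels")
    rows = []
    for a_i, a in enumerate(levels):
        refit = fit_pgls(tree_or_cov, data, design.relevel(factor, a), lambda_mode=lambda_mode)
        for b in levels[a_i + 1:]:
            row = refit.params.loc[f"{fterm.label}[{b}]"]
            rows.append((a, b, float(row["coef"]), float(row["se"]), float(row["p"])))
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "estimate", "se", "p_raw"])
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def partial_correlation(tree_or_cov, data: pd.DataFrame, response: str,
                        predictor: str, covariate: str,
                        lambda_mode="ml", first_stage="pgls") -> RegressionFit:
    """PGLS of response residuals on predictor residuals, covariate factored out.

    Both residual sets come from lambda-PGLS first-stage fits by default
    (``first_stage="ols"`` switches to OLS residuals)."""
    if predictor == covariate:
        raise ValueError("covariate identical to predictor")
    mode = lambda_mode if first_stage == "pgls" else 0.0
    sub = data[[response, predictor, covariate]].dropna()
    d1 = DesignSpec(response=response, terms=(Term(covariate),))
    d2 = DesignSpec(response=predictor, terms=(Term(covariate),))
    f1 = fit_pgls(tree_or_cov, sub, d1, lambda_mode=mode)
    f2 = fit_pgls(tree_or_cov, sub, d2, lambda_mode=mode)
    resid = pd.DataFrame({"resid_y": f1.residuals, "resid_x": f2.residuals}).dropna()
    d3 = DesignSpec(response="resid_y", terms=(Term("resid_x"),))
    return fit_pgls(tree_or_cov, resid, d3, lambda_mode=lambda_mode)


def gvif(data: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Generalized variance inflation factors, reported as GVIF^(1/(2 df)).

    Determinant-ratio form on the correlation matrix of the non-intercept
    design columns: GVIF_term = det(R11) det(R22) / det(R)."""
    X, _, names, term_cols, _ = build_design(data, design)
    Z = X[:, 1:]
    cols = {lbl: [c - 1 for c in cc] for lbl, cc in term_cols.items()}
    R = np.corrcoef(Z, rowvar=False)
    detR = np.linalg.det(R)
    rows = []
    for label, cc in cols.items():
        other = [j for j in range(Z.shape[1]) if j not in cc]
        if not other:
            rows.append((label, 1.0, len(cc), 1.0))
            continue
        d1 = np.linalg.det(R[np.ix_(cc, cc)])
        d2 = np.linalg.det(R[np.ix_(other, other)])
        g = d1 * d2 / detR
        df = len(cc)
        rows.append((label, float(g), df, float(g ** (1.0 / (2 * df)))))
    return pd.DataFrame(rows, columns=["term", "gvif", "df", "gvif_scaled"]).set_index("term")


@dataclass
class DredgeResult:
    models: pd.DataFrame
    fits: list
    best: pd.DataFrame
    averaged: pd.DataFrame
    gvif_report: pd.DataFrame
    constraints: list
    cases: list[str]


def dredge_aicc(tree_or_cov, data: pd.DataFrame, full_design: DesignSpec,
                fixed: tuple[str, ...] = (), forbidden_pairs=(),
                lambda_mode="ml") -> DredgeResult:
    """All-subsets AICc model selection with co-occurrence constraints.

    Every candidate model contains the fixed covariates and no forbidden pair;
    all models are fitted on the cases complete for the full predictor pool so
    their AICc values are comparable.  The best set is Delta_i < 2; conditional
    averaging weights each coefficient by the Akaike weights of the models
    containing its term."""
    labels = {t.name: t for t in full_design.terms}
    for f in fixed:
        if f not in labels:
            raise ValueError(f"fixed covariate {f!r} not in the design")
    forbidden = [frozenset(p) for p in forbidden_pairs]
    for pair in forbidden:
        if set(fixed) >= pair:
            raise ValueError(f"fixed covariates violate constraint {sorted(pair)}")
    optional = [t.name for t in full_design.terms if t.name not in fixed]
    # complete cases for the full pool define the common case set
    _, _, _, _, cases = build_design(data, full_design)
    sub = data.loc[cases]
    gvif_report = gvif(sub, full_design) if len(full_design.terms) > 1 else pd.DataFrame()

    combos = []
    for r in range(len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            chosen = set(fixed) | set(combo)
            if any(pair <= chosen for pair in forbidden):
                continue
            combos.append(tuple(t.name for t in full_design.terms if t.name in chosen))
    if len(combos) < 2:
        raise ValueError("fewer than 2 candidate models after constraints")

    fits, rows = [], []
    for combo in combos:
        spec = full_design.with_terms([labels[nm] for nm in combo])
        fit = fit_pgls(tree_or_cov, sub, spec, lambda_mode=lambda_mode)
        fits.append(fit)
        rows.append({"terms": combo, "k": len(fit.params), "n": fit.n,
                     "lnl": fit.lnl, "lambda": fit.lambda_, "aicc": fit.aicc})
    models = pd.DataFrame(rows)
    models["delta"] = models["aicc"] - models["aicc"].min()
    w = np.exp(-models["delta"] / 2.0)
    models["weight"] = w / w.sum()
    order = models.sort_values("aicc").index
    models = models.loc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    best = models[models["delta"] < 2.0]

    # conditional model averaging over the full enumerated set
    coef_rows = {}
    for (_, row), fit in zip(models.iterrows(), fits):
        for name, prow in fit.params.iterrows():
            coef_rows.setdefault(name, []).append((row["weight"], prow["coef"]))
    avg = []
    for name, pairs in coef_rows.items():
        wsum = sum(wgt for wgt, _ in pairs)
        est = sum(wgt * c for wgt, c in pairs) / wsum if wsum > 0 else np.nan
        avg.append((name, est, wsum))
    averaged = pd.DataFrame(avg, columns=["coef_name", "estimate", "weight_sum"]).set_index("coef_name")
    return DredgeResult(models=models, fits=fits, best=best, averaged=averaged,
                        gvif_report=gvif_report, constraints=list(forbidden_pairs),
                        cases=cases)
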