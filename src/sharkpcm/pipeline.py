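"""End-to-end orchestration: trait preparation, group tests, model fits, report.

``run_full_analysis`` strings together the stages of a genome-size
comparative study — summary statistics by clade, BM/OU/EB fits with Akaike
weights, ancestral reconstruction, Pagel transformation tests, independent
contrasts with a clade rate comparison, chromosome-number CTMC selection with
stochastic mapping, lambda-PGLS tables, and AICc dredging — and emits a plain
dict report.  Stage failures are recorded and do not stop independent stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import chromevol, regression, traitmodels
from .trees import phylo_covariance, prune, tip_labels, transform_tree

__all__ = [
    "StudyConfig",
    "prepare_traits",
    "pca1_scores",
    "q10_correct",
    "anova_tukey",
    "summary_by_group",
    "run_full_analysis",
    "robustness_across_trees",
]


@dataclass
class StudyConfig:
    alpha: float = 0.05
    q10: float = 1.65
    reference_temp_c: float = 20.0
    n_restarts: int = 50
    n_sims: int = 2000
    seed: int = 0
    outlier_policy: str = "report"  # or "remove"
    robustness_trees: int = 100

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def q10_correct(rate: float | np.ndarray, measured_temp_c: float | np.ndarray,
                q10: float = 1.65, reference_temp_c: float = 20.0):
    """Temperature-standardize a metabolic rate: rate * Q10^((T_ref - T)/10)."""
    return rate * q10 ** ((reference_temp_c - np.asarray(measured_temp_c)) / 10.0)


def pca1_scores(table: pd.DataFrame, sign_anchor: str | None = None):
    """First principal component of centered (unscaled) columns.

    Returns (scores Series, percent variance explained).  The sign is fixed so
    PCA1 correlates positively with ``sign_anchor`` (default: the first column).
    """
    X = table.dropna()
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc.to_numpy(float), full_matrices=False)
    scores = Xc.to_numpy(float) @ vt[0]
    pct = 100.0 * s[0] ** 2 / np.sum(s ** 2)
    anchor = X[sign_anchor] if sign_anchor else X.iloc[:, 0]
    if np.corrcoef(scores, anchor.to_numpy(float))[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=X.index), float(pct)


@dataclass
class PreparedTraits:
    table: pd.DataFrame
    observations: traitmodels.TraitObservations
    pca_variance: dict = field(default_factory=dict)


def prepare_traits(records: pd.DataFrame, config: StudyConfig | None = None,
                   length_cols: list[str] | None = None,
                   age_cols: list[str] | None = None,
                   smr_temp_col: str | None = None) -> PreparedTraits:
    """Collapse replicate records to per-species means with ln-scale SEs.

    ``records`` is long: columns species, variable, value.  Genome-size rows
    (variable == "genome_size") are averaged on the pg scale for summaries,
    with SE computed after ln transformation.  Optional PCA summaries for body
    length / age variables and Q10 temperature correction for SMR.
    """
    config = config or StudyConfig()
    needed = {"species", "variable", "value"}
    if not needed <= set(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    gs = records[records["variable"] == "genome_size"]
    if (gs["value"] <= 0).any():
        bad = gs.loc[gs["value"] <= 0, "species"].unique().tolist()
        raise ValueError(f"non-positive genome sizes under ln transform: {bad}")
    obs = traitmodels.TraitObservations.from_replicates(
        gs.rename(columns={"value": "value"}), value_col="value", ln=True)
    wide = records.pivot_table(index="species", columns="variable", values="value",
                               aggfunc="mean")
    wide = wide.rename(columns={"genome_size": "genome_size_pg"})
    if "genome_size_pg" in wide:
        wide["ln_genome_size"] = np.log(wide["genome_size_pg"])
    pca_variance = {}
    if length_cols:
        scores, pct = pca1_scores(wide[length_cols], sign_anchor=length_cols[0])
        wide["L_PCA1"] = scores
        pca_variance["length"] = pct
    if age_cols:
        scores, pct = pca1_scores(wide[age_cols], sign_anchor=age_cols[0])
        wide["T_PCA1"] = scores
        pca_variance["age"] = pct
    if smr_temp_col and "SMR" in wide and smr_temp_col in wide:
        wide["SMR_20C"] = q10_correct(wide["SMR"], wide[smr_temp_col],
                                      config.q10, config.reference_temp_c)
    return PreparedTraits(table=wide, observations=obs, pca_variance=pca_variance)


@dataclass
class AnovaResult:
    f: float
    df: tuple[int, int]
    p: float
    tukey: pd.DataFrame
    letters: dict


def _letter_display(groups: list[str], sig_pairs: set, order: dict) -> dict:
    """Compact letter display: groups sharing no letter differ at alpha."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    for a in groups:
        for b in groups:
            if a < b and frozenset((a, b)) not in sig_pairs:
                g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: min(order[x] for x in c))
    letters: dict = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for grp in clique:
            letters[grp] += letter
    return letters


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letter grouping."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    by = [values[groups == g] for g in names]
    if sum(len(b) for b in by) - len(names) < 1:
        raise ValueError("not enough residual degrees of freedom")
    for g, b in zip(names, by):
        if len(b) == 1 and len(names) == sum(len(x) == 1 for x in by):
            raise ValueError("all groups are singletons")
    F, p = stats.f_oneway(*by)
    df = (len(names) - 1, len(values) - len(names))
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    sig = {frozenset((str(r["group1"]), str(r["group2"])))
           for _, r in tukey.iterrows() if bool(r["reject"])}
    order = {g: float(np.mean(b)) for g, b in zip(names, by)}
    letters = _letter_display(names, sig, order)
    return AnovaResult(f=float(F), df=df, p=float(p), tukey=tukey, letters=letters)


def summary_by_group(table: pd.DataFrame, value_col: str, group_col: str) -> pd.DataFrame:
    """Count, range, mean ± SD and CV% (100·SD/mean, raw scale) per group."""
    rows = []
    for grp, sub in table.groupby(group_col, observed=True):
        v = sub[value_col].dropna()
        if v.empty:
            continue
        mean, sd = float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0
        rows.append({group_col: grp, "n": len(v), "min": float(v.min()),
                     "max": float(v.max()), "mean": mean, "sd": sd,
                     "cv": 100.0 * sd / mean if mean else np.nan})
    return pd.DataFrame(rows).set_index(group_col)


def run_full_analysis(dataset, config: StudyConfig | None = None,
                      stages: tuple[str, ...] = ("summary", "trait_models", "ancestral",
                                                 "pagel", "pics", "chromosomes",
                                                 "pgls", "dredge")) -> dict:
    """Run the study pipeline on a dataset bundle and return a structured report.

    ``dataset`` needs attributes tree, trait_table (wide, indexed by species,
    with columns ln_genome_size / genome_size_pg / clade and covariates),
    replicates (long pg-scale measurements) and chromosomes (count specs).
    Failed stages are reported under ``report["errors"]``; independent stages
    still run.
    """
    config = config or StudyConfig()
    report: dict = {"config": config, "errors": {}, "seed": config.seed}
    tree = dataset.tree
    table = dataset.trait_table
    species = tip_labels(tree)
    ingroup = [s for s in species if dataset.clades.get(s) != "Outgroup"]
    obs_all = traitmodels.TraitObservations.from_replicates(dataset.replicates)
    obs_in = obs_all.subset([s for s in obs_all.species if s in set(ingroup)])
    tree_in = prune(tree, ingroup)

    def stage(name, fn):
        if name not in stages:
            return
        try:
            report[name] = fn()
        except Exception as exc:  # stage isolation: record and continue
            report["errors"][name] = repr(exc)

    def _summary():
        out = {"by_clade": summary_by_group(table, "genome_size_pg", "clade")}
        ing = table.loc[table["clade"] != "Outgroup", "genome_size_pg"].dropna()
        out["ingroup"] = {"n": int(len(ing)), "mean": float(ing.mean()),
                          "sd": float(ing.std(ddof=1)),
                          "cv": float(100 * ing.std(ddof=1) / ing.mean()),
                          "range": (float(ing.min()), float(ing.max()))}
        lnv = np.log(table["genome_size_pg"].dropna())
        grp = table.loc[lnv.index, "clade"].astype(str)
        out["clade_anova"] = anova_tukey(lnv.to_numpy(), grp.to_numpy(), config.alpha)
        return out

    def _trait_models():
        out = {}
        for label, (t, o) in {"with_outgroup": (tree, obs_all),
                              "ingroup_only": (tree_in, obs_in)}.items():
            fits = [traitmodels.fit_trait_model(t, o, m, n_restarts=config.n_restarts,
                                                seed=config.seed)
                    for m in ("BM", "OU", "EB")]
            fits = traitmodels.akaike_weights(fits)
            best = max(fits, key=lambda f: f.aicw)
            out[label] = {"fits": fits, "best": best.model, "best_aicw": best.aicw}
        return out

    def _ancestral():
        fits = report.get("trait_models") or _trait_models()
        best_name = fits["with_outgroup"]["best"]
        best = next(f for f in fits["with_outgroup"]["fits"] if f.model == best_name)
        anc = traitmodels.reconstruct_ancestral(tree, obs_all, best)
        best_in_name = fits["ingroup_only"]["best"]
        best_in = next(f for f in fits["ingroup_only"]["fits"] if f.model == best_in_name)
        anc_in = traitmodels.reconstruct_ancestral(tree_in, obs_in, best_in)
        return {"all": anc, "ingroup": anc_in,
                "root_all_pg": anc.root_estimate_pg,
                "root_ingroup_pg": anc_in.root_estimate_pg}

    def _pagel():
        out = {}
        for label, (t, o) in {"with_outgroup": (tree, obs_all),
                              "ingroup_only": (tree_in, obs_in)}.items():
            out[label] = {p: traitmodels.fit_pagel(t, o, p)
                          for p in ("lambda", "delta", "kappa")}
        return out

    def _pics():
        raw = table["genome_size_pg"]
        out = {}
        sets = []
        for clade in ("Squalomorphii", "Galeomorphii"):
            members = [s for s in ingroup if dataset.clades[s] == clade]
            sub = prune(tree, members)
            cs = traitmodels.compute_pics(sub, raw.loc[members], clade=clade)
            sets.append(cs)
            out[clade] = {"mean_abs": float(np.abs(cs.contrasts).mean()),
                          "sd_abs": float(np.abs(cs.contrasts).std(ddof=1)),
                          "n": len(cs.contrasts)}
        out["comparison"] = traitmodels.compare_clade_rates(sets[0], sets[1])
        return out

    def _chromosomes():
        chrom_obs = chromevol.ChromObservations.from_counts(dataset.chromosomes)
        bounds = chrom_obs.bounds
        norm = transform_tree(tree, "normalize_length", 0.0)
        fits = [chromevol.fit_chrom_model(norm, chrom_obs, m, seed=config.seed)
                for m in chromevol.default_model_family(bounds)]
        best = chromevol.select_chrom_model(fits)
        anc = chromevol.ancestral_chrom_probs(norm, chrom_obs, best)
        root_modal = anc.modal_state(anc.node_ids[0])
        expct = chromevol.expected_transitions(norm, chrom_obs, best,
                                               n_sims=config.n_sims, seed=config.seed)
        return {"fits": fits, "best": best, "ancestral": anc,
                "root_modal_state": root_modal, "expectations": expct,
                "totals": expct.totals, "bounds": bounds}

    def _pgls():
        cov = phylo_covariance(tree, order=list(table.index))
        rows = {}
        specs = {
            "ln_Na": regression.DesignSpec("ln_genome_size", (regression.Term("ln_Na"),)),
            "ln_Ca": regression.DesignSpec("ln_genome_size", (regression.Term("ln_Ca"),)),
            "ln_SMR": regression.DesignSpec("ln_genome_size", (regression.Term("ln_SMR"),)),
            "Sal": regression.DesignSpec(
                "ln_genome_size", (regression.Term("ln_Depth"), regression.Term("Sal", categorical=True))),
        }
        sub = table.loc[[s for s in table.index if dataset.clades.get(s) != "Outgroup"]]
        for name, spec in specs.items():
            try:
                fit = regression.fit_pgls(cov, sub, spec)
                entry = {"fit": fit, "lambda": fit.lambda_, "df": fit.df_resid}
                if name in ("ln_Na", "ln_Ca", "ln_SMR"):
                    row = fit.params.loc[name]
                    entry.update(slope=float(row["coef"]), se=float(row["se"]),
                                 t=float(row["t"]), p=float(row["p"]))
                else:
                    an = regression.type2_anova(fit)
                    entry["anova"] = an
                    if an.loc["Sal", "p"] < config.alpha:
                        entry["posthoc"] = regression.posthoc_pairwise(cov, sub, spec, "Sal")
                rows[name] = entry
            except Exception as exc:
                rows[name] = {"error": repr(exc)}
        return rows

    def _dredge():
        cov = phylo_covariance(tree, order=list(table.index))
        sub = table.loc[[s for s in table.index if dataset.clades.get(s) != "Outgroup"]]
        spec = regression.DesignSpec("ln_genome_size", (
            regression.Term("L_PCA1"),
            regression.Term("PBS", categorical=True),
            regression.Term("RM", categorical=True),
            regression.Term("ln_Ls"),
            regression.Term("ln_Depth"),
            regression.Term("Sal", categorical=True),
        ))
        return regression.dredge_aicc(cov, sub, spec, fixed=("L_PCA1",),
                                      forbidden_pairs=())

    stage("summary", _summary)
    stage("trait_models", _trait_models)
    stage("ancestral", _ancestral)
    stage("pagel", _pagel)
    stage("pics", _pics)
    stage("chromosomes", _chromosomes)
    stage("pgls", _pgls)
    stage("dredge", _dredge)
    return report


@dataclass
class RobustnessSummary:
    table: pd.DataFrame
    n_trees: int
    n_failed: int


def robustness_across_trees(trees, analysis_fn, mcc_result: dict,
                            alpha: float = 0.05) -> RobustnessSummary:
    """Re-run an analysis across a tree sample and summarize concordance.

    ``analysis_fn(tree)`` returns {statistic: (value, p or None)};
    ``mcc_result`` is the same mapping computed on the backbone tree.  Reports
    the median of each statistic and the percentage of trees whose p-value
    falls on the same side of alpha as the backbone result.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    per_tree: dict = {k: [] for k in mcc_result}
    failures = 0
    for t in trees:
        try:
            res = analysis_fn(t)
        except Exception:
            failures += 1
            continue
        for k, v in res.items():
            per_tree[k].append(v)
    rows = []
    for k, (mcc_val, mcc_p) in mcc_result.items():
        vals = [v for v, _ in per_tree[k]]
        ps = [p for _, p in per_tree[k] if p is not None]
        median = float(np.median(vals)) if vals else np.nan
        if mcc_p is not None and ps:
            side = mcc_p < alpha
            pct = 100.0 * np.mean([(p < alpha) == side for p in ps])
        else:
            pct = np.nan
        rows.append({"statistic": k, "mcc_value": mcc_val, "median": median,
                     "mcc_p": mcc_p, "pct_same_side": pct})
    return RobustnessSummary(table=pd.DataFrame(rows).set_index("statistic"),
                             n_trees=len(trees), n_failed=failures)
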