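"""Synthetic trees, traits, karyotypes and regression datasets with known truth.

Every generator takes an explicit seed and is byte-reproducible.  The
shark-like dataset bundles all of them into a 76-taxon study design: 71
ingroup species split into two labeled superorder-like clades plus 5 outgroup
taxa, replicate genome-size measurements on a subset of species, bounded
chromosome counts with missing and polymorphic entries, phylogenetically
clustered categorical covariates, and the scattered availability of the
physiological/life-history predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import chromevol
from .traitmodels import TraitObservations, _model_cov
from .trees import phylo_covariance, tip_labels, transform_tree

__all__ = [
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_continuous_trait",
    "simulate_chromosome_numbers",
    "simulate_pgls_dataset",
    "make_sharklike_dataset",
]


@dataclass
class SyntheticDataset:
    tree: dendropy.Tree
    trait_table: pd.DataFrame          # wide, per species
    replicates: pd.DataFrame           # long: species, value (pg)
    chromosomes: dict                  # species -> count spec string or "X"
    clades: dict                       # species -> clade label
    truth: dict = field(default_factory=dict)


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int = 0,
                       prefix: str = "t") -> dendropy.Tree:
    """Pure-birth ultrametric tree with ``n_tips`` tips.

    Lineage splits arrive at rate ``k * birth_rate`` with ``k`` extant
    lineages; after the n-th lineage appears the process runs one final
    exponential waiting time so that no tip branch is zero.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        node = dendropy.Node()
        root.add_child(node)
        active.append((node, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    for i, (node, birth) in enumerate(active):
        node.edge.length = t - birth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"{prefix}{i + 1}")
    return tree


def _scale_depth(tree: dendropy.Tree, depth: float) -> dendropy.Tree:
    from .trees import tree_depth

    d = tree_depth(tree)
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node and e.length is not None:
            e.length *= depth / d
    return tree


def simulate_continuous_trait(tree, model: str, params: dict,
                              measurement_sd: float = 0.0, n_replicates: int = 1,
                              seed: int = 0) -> pd.DataFrame:
    """Simulate tip values from the model's multivariate normal, plus noisy replicates.

    Returns a long table (species, replicate, value); the latent species value
    is the replicate mean's expectation.  Noise is on the same (ln) scale as
    the trait.
    """
    model = model.upper()
    sigma2 = params.get("sigma2", 1.0)
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if model == "OU" and params.get("alpha", 0.0) < 0:
        raise ValueError("alpha must be >= 0")
    if model == "EB" and params.get("r", 0.0) > 0:
        raise ValueError("r must be <= 0")
    rng = np.random.default_rng(seed)
    species = tip_labels(tree)
    C = phylo_covariance(tree, order=species).matrix
    V = _model_cov(model, C, params)
    z0 = params.get("z0", 0.0)
    if sigma2 == 0:
        latent = np.full(len(species), z0)
    else:
        latent = rng.multivariate_normal(np.full(len(species), z0), V, method="cholesky"
                                         if _pd_ok(V) else "eigh")
    rows = []
    for sp, z in zip(species, latent):
        for r in range(n_replicates):
            rows.append((sp, r + 1, z + rng.normal(0.0, measurement_sd)))
    return pd.DataFrame(rows, columns=["species", "replicate", "value"])


def _pd_ok(V: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
        return True
    except np.linalg.LinAlgError:
        return False


def simulate_chromosome_numbers(tree, rates: dict, root_state: int,
                                bounds: tuple[int, int], seed: int = 0,
                                model: chromevol.ChromModel | None = None):
    """Gillespie simulation of the bounded chromosome-number CTMC along each branch.

    Returns (counts dict species -> int, event log DataFrame).  Events that
    would exit [s_min, s_max] never fire (their rate is zero at the boundary).
    """
    s_min, s_max = bounds
    if not (s_min <= root_state <= s_max):
        raise ValueError("root_state outside bounds")
    if model is None:
        model = chromevol.ChromModel(
            "simulation", gain="gain" in rates, loss="loss" in rates,
            duplication="duplication" in rates, demi="demi" in rates,
            linear=any(k.endswith("_slope") for k in rates), bounds=bounds)
    else:
        model = model.with_bounds(bounds)
    Q = chromevol.build_rate_matrix(model, rates)
    rng = np.random.default_rng(seed)
    from .traitmodels import _node_ids

    _node_ids(tree)
    state: dict = {}
    counts: dict = {}
    log = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = root_state
        else:
            s = state[node.parent_node]
            t = float(node.edge.length or 0.0)
            tau = 0.0
            while True:
                i = s - s_min
                rate = -Q[i, i]
                if rate <= 0:
                    break
                tau += rng.exponential(1.0 / rate)
                if tau >= t:
                    break
                targets = np.where(Q[i] > 0)[0]
                probs = Q[i, targets] / Q[i, targets].sum()
                j = int(rng.choice(targets, p=probs))
                new = j + s_min
                comp = chromevol._classify_rates(model, rates, s_min, s, new)
                types = list(comp)
                weights = np.array([comp[k] for k in types])
                typ = types[int(rng.choice(len(types), p=weights / weights.sum()))]
                branch_id = node.taxon.label if node.is_leaf() else node._spid
                log.append((branch_id, typ, tau, s, new))
                s = new
            state[node] = s
        if node.is_leaf():
            counts[node.taxon.label] = state[node]
    event_log = pd.DataFrame(log, columns=["branch", "type", "time", "from_state", "to_state"])
    return counts, event_log


def simulate_pgls_dataset(tree, true_beta: dict, lambda_true: float, sigma2: float,
                          predictor_spec: dict, seed: int = 0,
                          response: str = "y") -> pd.DataFrame:
    """Simulate a regression dataset with phylogenetically structured residuals.

    ``predictor_spec`` maps predictor name to one of ``"bm"`` (Brownian
    predictor), ``"iid"`` (independent normal), or ``("categorical", levels,
    frequencies)`` — a latent Brownian trait thresholded at the frequency
    quantiles, which induces phylogenetic clustering of the levels.  The
    response is ``design @ beta + eps`` with ``eps ~ N(0, sigma2 * C(lambda))``.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = tip_labels(tree)
    n = len(species)
    C = phylo_covariance(tree, order=species)
    data = pd.DataFrame(index=pd.Index(species, name="species"))
    Cm = C.matrix
    for name, kind in predictor_spec.items():
        if kind == "bm":
            data[name] = rng.multivariate_normal(np.zeros(n), Cm)
        elif kind == "iid":
            data[name] = rng.normal(size=n)
        elif isinstance(kind, tuple) and kind[0] == "categorical":
            _, levels, freqs = kind
            latent = rng.multivariate_normal(np.zeros(n), Cm)
            q = np.cumsum(freqs)[:-1]
            cuts = np.quantile(latent, q)
            data[name] = pd.Categorical.from_codes(
                np.searchsorted(cuts, latent).astype(int), categories=list(levels))
        else:
            raise ValueError(f"unknown predictor kind {kind!r}")
    X = [np.ones(n)]
    names = ["Intercept"]
    for name in predictor_spec:
        col = data[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            for lev in col.cat.categories[1:]:
                X.append((col == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
        else:
            X.append(col.to_numpy(float))
            names.append(name)
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    beta = np.array([true_beta.get(nm, 0.0) for nm in names])
    Vl = transform_tree(C, "lambda", lambda_true).matrix
    eps = rng.multivariate_normal(np.zeros(n), sigma2 * Vl)
    data[response] = X @ beta + eps
    return data


# ---------------------------------------------------------------------------
# the shark-like study design


def _graft(subtrees, stem_depths, total_depth):
    """Join ultrametric subtrees under a common root at the given stem depths."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    for sub, stem in zip(subtrees, stem_depths):
        _scale_depth(sub, total_depth - stem)
        node = sub.seed_node
        node.parent_node = None
        root.add_child(node)
        node.edge.length = stem
        for leaf in sub.leaf_node_iter():
            leaf.taxon = taxa.new_taxon(label=leaf.taxon.label)
    return tree


def make_sharklike_dataset(seed: int = 0) -> SyntheticDataset:
    """A 76-taxon synthetic analogue of the shark genome-size study design.

    The tree carries 48 + 23 ingroup species in two labeled clades
    ("Galeomorphii", "Squalomorphii") and 5 outgroup taxa; genome sizes evolve
    under an Early-Burst process on the ln scale and are affinely calibrated so
    the ingroup C-values span the published range (2.86-17.05 pg), with
    replicate measurements for 18 species.  Chromosome counts evolve under a
    loss-dominated gain/loss CTMC inside [28, 64] with missing tips and a few
    polymorphic reports.  Covariates are generated with known coefficients and
    the study's missingness pattern (SMR, CFAR, k, T, r_max sparsely observed).
    """
    rng = np.random.default_rng(seed)
    galeo = simulate_yule_tree(48, 1.0, seed=int(rng.integers(2**31)), prefix="galeo_")
    squalo = simulate_yule_tree(23, 1.0, seed=int(rng.integers(2**31)), prefix="squalo_")
    outg = simulate_yule_tree(5, 1.0, seed=int(rng.integers(2**31)), prefix="outg_")
    ingroup = _graft([galeo, squalo], [0.10, 0.10], 0.75)
    # re-label grafting: ingroup root then outgroup under the global root
    tree = _graft([ingroup, outg], [0.25, 0.30], 1.0)
    species = tip_labels(tree)
    clades = {s: ("Galeomorphii" if s.startswith("galeo_") else
                  "Squalomorphii" if s.startswith("squalo_") else "Outgroup")
              for s in species}
    ingroup_sp = [s for s in species if clades[s] != "Outgroup"]

    # --- genome size: EB on the ln scale, calibrated to the study's range
    r_true = -2.5
    sim = simulate_continuous_trait(tree, "EB", {"sigma2": 2.0, "z0": np.log(6.0), "r": r_true},
                                    measurement_sd=0.0, n_replicates=1,
                                    seed=int(rng.integers(2**31)))
    latent = sim.set_index("species")["value"]
    outg_sp0 = [s for s in species if clades[s] == "Outgroup"]
    # ingroup calibrated to the printed C-value range; outgroup placed in a
    # lower band, emulating the smaller chimaera/batoid genomes that make the
    # stem leading to the ingroup carry a burst of size change
    lo, hi = latent[ingroup_sp].min(), latent[ingroup_sp].max()
    a = (np.log(17.05) - np.log(2.86)) / (hi - lo)
    b = np.log(2.86) - a * lo
    ln_c = a * latent + b
    shift = float(ln_c[outg_sp0].mean()) - np.log(3.2)
    ln_c[outg_sp0] = np.clip(ln_c[outg_sp0] - shift, np.log(2.55), np.log(4.6))
    # measurement replicates for 18 species (ln-scale noise)
    multi = list(rng.choice(ingroup_sp, size=18, replace=False))
    rows = []
    for sp in species:
        n_rep = int(rng.integers(2, 5)) if sp in multi else 1
        for rep in range(n_rep):
            noise = rng.normal(0.0, 0.06) if n_rep > 1 else 0.0
            rows.append((sp, rep + 1, float(np.exp(ln_c[sp] + noise))))
    replicates = pd.DataFrame(rows, columns=["species", "replicate", "value"])

    # --- chromosome numbers: loss-dominated dysploidy on the normalized tree
    norm_tree = transform_tree(tree, "normalize_length", 0.0)
    chrom_rates = {"gain": 23.0, "loss": 42.0}
    counts, events = simulate_chromosome_numbers(
        norm_tree, chrom_rates, root_state=57, bounds=(28, 64),
        seed=int(rng.integers(2**31)))
    known = list(rng.choice(ingroup_sp, size=36, replace=False)) + \
        [s for s in species if clades[s] == "Outgroup"][:3]
    chromosomes: dict = {}
    poly = set(rng.choice(known, size=4, replace=False))
    for sp in species:
        if sp not in known:
            chromosomes[sp] = "X"
        elif sp in poly:
            c = counts[sp]
            alt = min(64, max(28, c + int(rng.choice([-1, 1]))))
            chromosomes[sp] = f"{c}:2;{alt}:1"
        else:
            chromosomes[sp] = str(counts[sp])

    # --- covariates with known coefficients relative to ln genome size
    table = pd.DataFrame(index=pd.Index(species, name="species"))
    table["clade"] = [clades[s] for s in species]
    obs = TraitObservations.from_replicates(replicates)
    ln_gs = pd.Series(obs.mean, index=obs.species).reindex(species)
    table["genome_size_pg"] = replicates.groupby("species")["value"].mean().reindex(species)
    table["ln_genome_size"] = ln_gs
    truth_beta = {"ln_Na": 0.78, "ln_Ca": 0.52, "ln_SMR": -0.69, "CFAR": -0.12}
    n = len(species)
    C = phylo_covariance(tree, order=species).matrix
    Ccorr = C / np.max(np.diag(C))  # unit tip variance, tree-shaped correlation

    def predictor(center, beta, noise_sd):
        # x carries the trait signal at slope beta plus tree-structured noise,
        # so the PGLS of ln genome size on x recovers ~beta
        noise = rng.multivariate_normal(np.zeros(n), (noise_sd ** 2) * Ccorr)
        return center + (ln_gs - ln_gs.mean()).to_numpy() / beta + noise

    table["ln_Na"] = predictor(1.5, truth_beta["ln_Na"], 0.10)
    table["ln_Ca"] = predictor(3.0, truth_beta["ln_Ca"], 0.20)
    table["ln_SMR"] = predictor(4.0, truth_beta["ln_SMR"], 0.15)
    table["CFAR"] = predictor(1.0, truth_beta["CFAR"], 0.8)
    table["L_PCA1"] = rng.multivariate_normal(np.zeros(n), C)
    table["ln_Ls"] = 0.3 * table["L_PCA1"] + rng.normal(1.0, 0.5, n)
    table["k_growth"] = rng.normal(0.15, 0.05, n)
    table["T_PCA1"] = rng.multivariate_normal(np.zeros(n), C)
    table["r_max"] = rng.normal(0.3, 0.1, n)
    table["ln_Depth"] = rng.multivariate_normal(np.full(n, 5.0), 0.5 * C)
    # phylogenetically clustered categoricals via thresholded latent BM traits
    def categorical(levels, freqs, effect=0.0):
        latentc = rng.multivariate_normal(np.zeros(n), C) + effect * (ln_gs - ln_gs.mean()).to_numpy()
        cuts = np.quantile(latentc, np.cumsum(freqs)[:-1])
        return pd.Categorical.from_codes(np.searchsorted(cuts, latentc).astype(int),
                                         categories=levels)

    table["RM"] = categorical(["oviparous", "aplacental", "placental"], [0.4, 0.35, 0.25],
                              effect=-0.6)
    table["Sal"] = categorical(["marine", "marine-brackish", "amphidromous"],
                               [0.75, 0.15, 0.10], effect=-0.8)
    table["PBS"] = categorical(["type1", "type2", "type3", "type4", "type5"],
                               [0.15, 0.3, 0.25, 0.2, 0.1], effect=0.5)
    table["TS"] = categorical(["type1", "type2", "type3", "type4"],
                              [0.2, 0.3, 0.3, 0.2], effect=0.5)
    table["Clim"] = categorical(["tropical", "subtropical", "temperate"], [0.4, 0.35, 0.25])
    table["Occ"] = categorical(["pelagic", "benthopelagic", "epibenthic"], [0.3, 0.4, 0.3])

    # the study's missingness pattern: sparse physiological/life-history data
    def mask_except(col, n_obs):
        keep = set(rng.choice(ingroup_sp, size=n_obs, replace=False))
        table.loc[[s for s in species if s not in keep], col] = np.nan

    mask_except("ln_Na", 25)
    mask_except("ln_Ca", 34)
    mask_except("ln_SMR", 17)
    mask_except("CFAR", 62)
    mask_except("k_growth", 57)
    mask_except("T_PCA1", 56)
    mask_except("r_max", 33)
    outg_sp = [s for s in species if clades[s] == "Outgroup"]
    table.loc[outg_sp, ["ln_Ls", "L_PCA1", "ln_Depth"]] = np.nan

    truth = {
        "trait_model": "EB", "trait_r": r_true, "trait_scale": (float(a), float(b)),
        "chrom_rates": chrom_rates, "chrom_root": 57, "chrom_bounds": (28, 64),
        "beta": truth_beta, "n_ingroup": 71, "n_outgroup": 5,
        "n_chrom_known": len(known), "seed": seed,
    }
    return SyntheticDataset(tree=tree, trait_table=table, replicates=replicates,
                            chromosomes=chromosomes, clades=clades, truth=truth)
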