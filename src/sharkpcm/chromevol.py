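"""Chromosome-number evolution under a bounded continuous-time Markov chain.

The state space is the integer interval [s_min, s_max].  Four mechanisms move
the chain: single-chromosome gains (ascending dysploidy, s -> s+1), losses
(descending dysploidy, s -> s-1), duplications (polyploidy, s -> 2s) and
demi-duplications (s -> 1.5s, split across floor/ceil when fractional).  Rates
may be constant or linear in the state.  Events whose target leaves the state
space are suppressed (their rate is zeroed), a reflecting-boundary convention.

Tip data are probability vectors over states: a point count is a unit mass,
polymorphic reports weight states by their report frequencies, and a missing
karyotype is the all-ones vector.  The likelihood is computed by Felsenstein
pruning with per-branch transition matrices expm(Q t); the root state is
integrated over the normalized root conditional likelihoods (no free root
parameters).  Marginal ancestral probabilities come from an analytic up-down
pass, and expected per-branch transition counts from stochastic mapping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import total_branch_length

__all__ = [
    "ChromModel",
    "ChromObservations",
    "ChromFit",
    "NodeStateProbs",
    "TransitionExpectations",
    "EVENT_TYPES",
    "build_rate_matrix",
    "chrom_likelihood",
    "fit_chrom_model",
    "select_chrom_model",
    "default_model_family",
    "ancestral_chrom_probs",
    "expected_transitions",
]

EVENT_TYPES = ("gain", "loss", "duplication", "demi")


@dataclass(frozen=True)
class ChromModel:
    """Structure of a chromosome-number rate model (which mechanisms, constant/linear)."""

    name: str
    gain: bool = True
    loss: bool = True
    duplication: bool = False
    demi: bool = False
    linear: bool = False  # gain/loss rates linear in (state - s_min)
    bounds: tuple[int, int] = (1, 50)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = []
        if self.gain:
            names.append("gain")
            if self.linear:
                names.append("gain_slope")
        if self.loss:
            names.append("loss")
            if self.linear:
                names.append("loss_slope")
        if self.duplication:
            names.append("duplication")
        if self.demi:
            names.append("demi")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def with_bounds(self, bounds: tuple[int, int]) -> "ChromModel":
        return ChromModel(self.name, self.gain, self.loss, self.duplication,
                          self.demi, self.linear, tuple(bounds))


def default_model_family(bounds: tuple[int, int]) -> list[ChromModel]:
    """The eight-model candidate family: {constant, linear} x {±duplication} x {±demi}."""
    fam = []
    for linear in (False, True):
        tag = "Linear Rate" if linear else "Constant Rate"
        fam.append(ChromModel(f"{tag} with No Duplication", linear=linear, bounds=bounds))
        fam.append(ChromModel(f"{tag}", duplication=True, linear=linear, bounds=bounds))
        fam.append(ChromModel(f"{tag} with Demi-duplication", duplication=True, demi=True,
                              linear=linear, bounds=bounds))
        fam.append(ChromModel(f"{tag} with Demi-duplication only", demi=True,
                              linear=linear, bounds=bounds))
    return fam


def build_rate_matrix(model: ChromModel, rates: dict) -> np.ndarray:
    """Assemble the CTMC generator Q on states [s_min, s_max].

    Boundary-exiting events are suppressed; rows sum to zero.
    """
    s_min, s_max = model.bounds
    if s_max - s_min < 1:
        raise ValueError("state space must span at least 2 states")
    m = s_max - s_min + 1
    states = np.arange(s_min, s_max + 1)
    Q = np.zeros((m, m))
    for i, s in enumerate(states):
        if model.gain and s + 1 <= s_max:
            r = rates.get("gain", 0.0) + rates.get("gain_slope", 0.0) * (s - s_min)
            Q[i, i + 1] += max(r, 0.0)
        if model.loss and s - 1 >= s_min:
            r = rates.get("loss", 0.0) + rates.get("loss_slope", 0.0) * (s - s_min)
            Q[i, i - 1] += max(r, 0.0)
        if model.duplication:
            t = 2 * s
            if s_min <= t <= s_max:
                Q[i, t - s_min] += rates.get("duplication", 0.0)
        if model.demi:
            mu = rates.get("demi", 0.0)
            lo_t, hi_t = math.floor(1.5 * s), math.ceil(1.5 * s)
            if lo_t == hi_t:
                if s_min <= lo_t <= s_max and lo_t != s:
                    Q[i, lo_t - s_min] += mu
            else:
                for t in (lo_t, hi_t):
                    if s_min <= t <= s_max and t != s:
                        Q[i, t - s_min] += mu / 2.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if np.allclose(Q, 0.0) and m > 1:
        warnings.warn("all rates zero: absorbing rate matrix")
    return Q


@dataclass
class ChromObservations:
    """Per-species probability vectors over the chromosome-number state space."""

    species: list[str]
    probs: np.ndarray  # (n_species, n_states)
    bounds: tuple[int, int]

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.bounds[0], self.bounds[1] + 1)

    @classmethod
    def from_counts(cls, counts: dict, bounds: tuple[int, int] | None = None,
                    pad_low: int = 1, pad_high: int = 10) -> "ChromObservations":
        """Build observation vectors from raw count specs.

        ``counts[species]`` may be an int, the string ``"X"`` (missing), a
        string like ``"40"`` or ``"40:2;41:1"`` (polymorphic with report
        frequencies), or a list of (count, weight) pairs.  When ``bounds`` is
        None it is set to [min observed - pad_low, max observed + pad_high].
        """
        parsed: dict = {}
        observed: list[int] = []
        for sp, spec in counts.items():
            if spec is None or (isinstance(spec, str) and spec.strip().upper() == "X") \
                    or (isinstance(spec, float) and np.isnan(spec)):
                parsed[sp] = None
                continue
            if isinstance(spec, str):
                pairs = []
                for part in spec.split(";"):
                    if ":" in part:
                        c, w = part.split(":")
                        pairs.append((int(c), float(w)))
                    else:
                        pairs.append((int(part), 1.0))
            elif isinstance(spec, (int, np.integer)):
                pairs = [(int(spec), 1.0)]
            else:
                pairs = [(int(c), float(w)) for c, w in spec]
            parsed[sp] = pairs
            observed.extend(c for c, _ in pairs)
        if bounds is None:
            if not observed:
                raise ValueError("no informative counts to set bounds from")
            bounds = (min(observed) - pad_low, max(observed) + pad_high)
        s_min, s_max = bounds
        m = s_max - s_min + 1
        species = list(parsed)
        probs = np.zeros((len(species), m))
        for i, sp in enumerate(species):
            if parsed[sp] is None:
                probs[i] = 1.0  # missing: all states allowed
            else:
                for c, w in parsed[sp]:
                    if not (s_min <= c <= s_max):
                        raise ValueError(f"count {c} for {sp} outside bounds {bounds}")
                    probs[i, c - s_min] += w
                probs[i] /= probs[i].sum()
        return cls(species, probs, (s_min, s_max))

    def pad(self, bounds: tuple[int, int]) -> "ChromObservations":
        """Embed the vectors in a wider state space (missing stays all-ones)."""
        s_min, s_max = bounds
        if s_min > self.bounds[0] or s_max < self.bounds[1]:
            raise ValueError("padded bounds must contain current bounds")
        m = s_max - s_min + 1
        off = self.bounds[0] - s_min
        probs = np.zeros((len(self.species), m))
        for i in range(len(self.species)):
            if np.all(self.probs[i] == 1.0):
                probs[i] = 1.0
            else:
                probs[i, off:off + self.probs.shape[1]] = self.probs[i]
        return ChromObservations(list(self.species), probs, (s_min, s_max))


@dataclass
class ChromFit:
    model: ChromModel
    rates: dict
    lnl: float
    aic: float
    converged: bool = True
    root_distribution: np.ndarray | None = field(default=None, repr=False)


@dataclass
class NodeStateProbs:
    node_ids: list[str]
    states: np.ndarray
    probs: np.ndarray  # (n_nodes, n_states)

    def modal_state(self, node_id: str) -> int:
        i = self.node_ids.index(node_id)
        return int(self.states[np.argmax(self.probs[i])])


@dataclass
class TransitionExpectations:
    branch_ids: list[str]
    expected: pd.DataFrame  # index branch id, columns event types
    totals: dict
    n_sims: int
    node_state_samples: pd.DataFrame | None = None  # states (not indices), if requested


# ---------------------------------------------------------------------------
# pruning likelihood


def _tree_arrays(tree):
    """Postorder node list with parent indices, branch lengths, tip labels, ids."""
    from .traitmodels import _node_ids

    _node_ids(tree)
    nodes = list(tree.postorder_node_iter())
    index = {n: i for i, n in enumerate(nodes)}
    parent = np.array([index[n.parent_node] if n.parent_node is not None else -1
                       for n in nodes])
    blen = np.array([float(n.edge.length or 0.0) for n in nodes])
    is_leaf = np.array([n.is_leaf() for n in nodes])
    labels = [n.taxon.label if n.is_leaf() else n._spid for n in nodes]
    return nodes, parent, blen, is_leaf, labels


def _check_normalized(tree, enforce: bool):
    total = total_branch_length(tree)
    if abs(total - 1.0) > 1e-6:
        if enforce:
            from .trees import transform_tree

            return transform_tree(tree, "normalize_length", 0.0)
        raise ValueError(f"tree total branch length is {total:.4g}, expected 1 "
                         "(normalize first or pass normalize=True)")
    return tree


def _pruning(tree, obs: ChromObservations, Q: np.ndarray):
    """Return per-node partial likelihoods, log-scalers and transition matrices."""
    nodes, parent, blen, is_leaf, labels = _tree_arrays(tree)
    m = Q.shape[0]
    sp_index = {sp: i for i, sp in enumerate(obs.species)}
    P = [None] * len(nodes)
    L = np.zeros((len(nodes), m))
    logscale = np.zeros(len(nodes))
    for i, node in enumerate(nodes):
        if parent[i] >= 0:
            P[i] = expm(Q * blen[i])
        if is_leaf[i]:
            lab = labels[i]
            if lab not in sp_index:
                raise ValueError(f"no chromosome observation for tip {lab!r}")
            L[i] = obs.probs[sp_index[lab]]
        else:
            vec = np.ones(m)
            sc = 0.0
            for j in np.where(parent == i)[0]:
                vec = vec * (P[j] @ L[j])
                sc += logscale[j]
            top = vec.max()
            if top <= 0:
                raise ValueError("zero likelihood (incompatible observations)")
            L[i] = vec / top
            logscale[i] = sc + np.log(top)
    return nodes, parent, blen, is_leaf, labels, P, L, logscale


def chrom_likelihood(tree, obs: ChromObservations, model: ChromModel,
                     rates: dict, normalize: bool = False) -> float:
    """Pruning log-likelihood with the normalized-conditional root distribution."""
    extra = sorted(set(obs.species) - {l.taxon.label for l in tree.leaf_node_iter()})
    if extra:
        raise ValueError(f"observed species not on tree: {extra}")
    tree = _check_normalized(tree, enforce=normalize)
    Q = build_rate_matrix(model, rates)
    *_, L, logscale = _pruning(tree, obs, Q)
    root_L = L[-1]
    pi = root_L / root_L.sum()
    return float(np.log(root_L @ pi) + logscale[-1])


def fit_chrom_model(tree, obs: ChromObservations, model: ChromModel,
                    seed: int = 0, n_restarts: int = 3,
                    normalize: bool = False) -> ChromFit:
    """ML rates by bounded optimization on log scale with restarts, AIC = 2k - 2lnL."""
    informative = np.sum(~np.all(obs.probs == 1.0, axis=1))
    if informative < 3:
        raise ValueError("need at least 3 species with informative chromosome states")
    tree = _check_normalized(tree, enforce=normalize)
    names = model.param_names
    if not names:
        raise ValueError("model has no free parameters")
    slope_mask = np.array([n.endswith("_slope") for n in names])

    def unpack(theta):
        vals = np.exp(theta)
        return {n: float(v) for n, v in zip(names, vals)}

    def nll(theta):
        try:
            return -chrom_likelihood(tree, obs, model, unpack(theta))
        except (ValueError, FloatingPointError):
            return 1e10

    rng = np.random.default_rng(seed)
    lo, hi = np.log(1e-4), np.log(500.0)
    starts = [np.where(slope_mask, np.log(0.1), np.log(10.0))]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(np.log(0.01), np.log(100.0), size=len(names)))
    best, converged = None, False
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", bounds=[(lo, hi)] * len(names))
        if best is None or res.fun < best.fun:
            best, converged = res, bool(res.success)
    rates = unpack(best.x)
    lnl = -float(best.fun)
    k = model.n_params
    Q = build_rate_matrix(model, rates)
    *_, L, logscale = _pruning(tree, obs, Q)
    root = L[-1] / L[-1].sum()
    return ChromFit(model=model, rates=rates, lnl=lnl, aic=2.0 * k - 2.0 * lnl,
                    converged=converged, root_distribution=root)


def select_chrom_model(fits: list[ChromFit]) -> ChromFit:
    if not fits:
        raise ValueError("no fitted models")
    return min(fits, key=lambda f: f.aic)


# ---------------------------------------------------------------------------
# marginal ancestral probabilities (up-down pass)


def ancestral_chrom_probs(tree, obs: ChromObservations, fit: ChromFit,
                          normalize: bool = False) -> NodeStateProbs:
    """Marginal posterior state probabilities at every internal node."""
    if fit.rates is None:
        raise ValueError("unfitted model")
    if normalize:
        tree = _check_normalized(tree, enforce=True)
    Q = build_rate_matrix(fit.model, fit.rates)
    nodes, parent, blen, is_leaf, labels, P, L, logscale = _pruning(tree, obs, Q)
    m = Q.shape[0]
    n = len(nodes)
    root = n - 1
    pi = L[root] / L[root].sum()
    out = np.zeros((n, m))
    out[root] = pi
    # children of i: down-pass in reverse postorder (root first)
    children = [np.where(parent == i)[0] for i in range(n)]
    for i in reversed(range(n)):
        for c in children[i]:
            sib_msg = np.ones(m)
            for s in children[i]:
                if s != c:
                    sib_msg = sib_msg * (P[s] @ L[s])
            pre = out[i] * sib_msg
            out[c] = pre @ P[c]
            t = out[c].max()
            if t > 0:
                out[c] /= t
    post = out * L
    post /= post.sum(axis=1, keepdims=True)
    internal = [i for i in range(n) if not is_leaf[i]]
    return NodeStateProbs(node_ids=[labels[i] for i in internal],
                          states=np.arange(fit.model.bounds[0], fit.model.bounds[1] + 1),
                          probs=post[internal])


# ---------------------------------------------------------------------------
# stochastic mapping


def _classify_rates(model: ChromModel, rates: dict, s_min: int, s: int, t: int) -> dict:
    """Component rates contributing to a jump s -> t (types may overlap on a target)."""
    comp = {}
    if model.gain and t == s + 1:
        comp["gain"] = max(rates.get("gain", 0.0) + rates.get("gain_slope", 0.0) * (s - s_min), 0.0)
    if model.loss and t == s - 1:
        comp["loss"] = max(rates.get("loss", 0.0) + rates.get("loss_slope", 0.0) * (s - s_min), 0.0)
    if model.duplication and t == 2 * s:
        comp["duplication"] = rates.get("duplication", 0.0)
    if model.demi:
        lo_t, hi_t = math.floor(1.5 * s), math.ceil(1.5 * s)
        if t in (lo_t, hi_t) and t != s:
            comp["demi"] = rates.get("demi", 0.0) if lo_t == hi_t else rates.get("demi", 0.0) / 2.0
    return comp


def _sample_branch_history(rng, Q, R_powers, lam, a, b, t, type_frac,
                           n_draws, max_reject=20):
    """Event-type counts (fractional assignment) for n_draws endpoint-conditioned paths.

    Rejection sampling from the unconditional chain, with a uniformization
    bridge fallback when the endpoint acceptance rate is poor.
    """
    m = Q.shape[0]
    counts = np.zeros((len(EVENT_TYPES),))
    targets = [np.where(Q[i] > 0)[0] for i in range(m)]
    target_p = [Q[i, tg] / Q[i, tg].sum() if len(tg) else None for i, tg in enumerate(targets)]
    exit_rate = -np.diag(Q)

    done = 0
    attempts = 0
    budget = max_reject * n_draws
    while done < n_draws and attempts < budget:
        attempts += 1
        s = a
        tau = 0.0
        path = []
        while True:
            rate = exit_rate[s]
            if rate <= 0:
                break
            tau += rng.exponential(1.0 / rate)
            if tau >= t:
                break
            nxt = rng.choice(targets[s], p=target_p[s])
            path.append((s, int(nxt)))
            s = int(nxt)
        if s == b:
            for (u, v) in path:
                counts += type_frac[(u, v)]
            done += 1
    if done < n_draws:
        counts += _uniformization_counts(rng, R_powers, lam, a, b, t, type_frac,
                                         n_draws - done)
    return counts


def _uniformization_counts(rng, R_powers, lam, a, b, t, type_frac, n_draws):
    """Bridge sampling of jump chains via uniformization; returns summed type counts."""
    counts = np.zeros(len(EVENT_TYPES))
    lt = lam * t
    n_max = len(R_powers) - 1
    logpois = -lt + np.arange(n_max + 1) * np.log(lt + 1e-300) - \
        np.array([math.lgamma(k + 1) for k in range(n_max + 1)])
    w = np.exp(logpois) * np.array([R_powers[k][a, b] for k in range(n_max + 1)])
    if w.sum() <= 0:
        raise ValueError("endpoint-conditioned branch has probability 0")
    w /= w.sum()
    R = R_powers[1]
    for _ in range(n_draws):
        n = int(rng.choice(n_max + 1, p=w))
        s = a
        for k in range(n):
            steps_left = n - k - 1
            probs = R[s] * R_powers[steps_left][:, b]
            tot = probs.sum()
            if tot <= 0:
                break
            nxt = int(rng.choice(len(probs), p=probs / tot))
            if nxt != s:
                counts += type_frac[(s, nxt)]
            s = nxt
    return counts


def expected_transitions(tree, obs: ChromObservations, fit: ChromFit,
                         n_sims: int = 2000, seed: int = 0,
                         normalize: bool = False,
                         return_states: bool = False) -> TransitionExpectations:
    """Expected per-branch counts of each event type via stochastic mapping.

    Node states are sampled from the joint posterior; branch histories are
    sampled conditional on endpoints; expectations are means over ``n_sims``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if normalize:
        tree = _check_normalized(tree, enforce=True)
    Q = build_rate_matrix(fit.model, fit.rates)
    nodes, parent, blen, is_leaf, labels, P, L, logscale = _pruning(tree, obs, Q)
    m = Q.shape[0]
    n = len(nodes)
    root = n - 1
    rng = np.random.default_rng(seed)
    s_min = fit.model.bounds[0]

    # fractional type assignment for each possible jump
    type_frac: dict = {}
    for i in range(m):
        for j in np.where(Q[i] > 0)[0]:
            comp = _classify_rates(fit.model, fit.rates, s_min, i + s_min, j + s_min)
            tot = sum(comp.values())
            vec = np.zeros(len(EVENT_TYPES))
            for k, typ in enumerate(EVENT_TYPES):
                vec[k] = comp.get(typ, 0.0) / tot if tot > 0 else 0.0
            type_frac[(i, int(j))] = vec

    lam = float(np.max(-np.diag(Q)))
    if lam <= 0:
        expectations = pd.DataFrame(0.0, index=[labels[i] for i in range(n) if parent[i] >= 0],
                                    columns=list(EVENT_TYPES))
        totals = {t: 0.0 for t in EVENT_TYPES}
        return TransitionExpectations(list(expectations.index), expectations, totals, n_sims)
    t_max = float(blen.max())
    # enough uniformization terms to cover the Poisson tail on the longest branch
    n_max = max(8, int(lam * t_max + 10.0 * math.sqrt(lam * t_max + 1.0)))
    R = np.eye(m) + Q / lam
    R_powers = [np.eye(m)]
    for _ in range(n_max):
        R_powers.append(R_powers[-1] @ R)

    # joint posterior sampling of node states, vectorized over simulations
    state = np.zeros((n, n_sims), dtype=int)
    pi = L[root] / L[root].sum()
    post_root = pi * L[root]
    post_root /= post_root.sum()
    state[root] = rng.choice(m, size=n_sims, p=post_root)
    children = [np.where(parent == i)[0] for i in range(n)]
    for i in reversed(range(n)):
        for c in children[i]:
            cond = P[c] * L[c][None, :]  # rows: parent state
            rowsum = cond.sum(axis=1, keepdims=True)
            rowsum[rowsum == 0] = 1.0  # unreachable parent states, never sampled
            cond = cond / rowsum
            for ps in np.unique(state[i]):
                mask = state[i] == ps
                state[c][mask] = rng.choice(m, size=int(mask.sum()), p=cond[ps])

    branch_ids = [labels[i] for i in range(n) if parent[i] >= 0]
    expected = np.zeros((len(branch_ids), len(EVENT_TYPES)))
    bi = 0
    for i in range(n):
        if parent[i] < 0:
            continue
        a_states = state[parent[i]]
        b_states = state[i]
        pairs, counts = np.unique(np.stack([a_states, b_states]), axis=1, return_counts=True)
        acc = np.zeros(len(EVENT_TYPES))
        for (a, b), cnt in zip(pairs.T, counts):
            acc += _sample_branch_history(rng, Q, R_powers, lam, int(a), int(b),
                                          float(blen[i]), type_frac, int(cnt))
        expected[bi] = acc / n_sims
        bi += 1
    df = pd.DataFrame(expected, index=branch_ids, columns=list(EVENT_TYPES))
    totals = {t: float(df[t].sum()) for t in EVENT_TYPES}
    samples = None
    if return_states:
        samples = pd.DataFrame(state.T + s_min, columns=labels)
    return TransitionExpectations(branch_ids, df, totals, n_sims, samples)
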