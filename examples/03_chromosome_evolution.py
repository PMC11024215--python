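"""Chromosome-number evolution: CTMC fitting, ancestral states, stochastic mapping.

Simulates loss-dominated dysploidy (chromosome fusions outpacing fissions) on
a tree normalized to total length 1, fits the candidate model family, and maps
expected numbers of gain/loss events onto the branches.  Loss totals should
exceed gain totals, mirroring the simulated asymmetry.
"""

import sharkpcm as sp
from sharkpcm.chromevol import (ChromModel, ChromObservations, ancestral_chrom_probs,
                                default_model_family, expected_transitions,
                                fit_chrom_model, select_chrom_model)

tree = sp.transform_tree(sp.simulate_yule_tree(50, 1.0, seed=11), "normalize_length", 0.0)
counts, events = sp.simulate_chromosome_numbers(
    tree, {"gain": 20.0, "loss": 45.0}, root_state=50, bounds=(28, 64), seed=11)
print(f"simulated {len(events)} events "
      f"({(events['type'] == 'loss').sum()} losses, {(events['type'] == 'gain').sum()} gains)")

obs = ChromObservations.from_counts(counts)  # bounds: [min-1, max+10]
print(f"state space from data: {obs.bounds}")

fits = [fit_chrom_model(tree, obs, m, seed=0, n_restarts=2)
        for m in default_model_family(obs.bounds)[:4]]  # constant-rate family
best = select_chrom_model(fits)
print(f"\nbest model: {best.model.name} (AIC {best.aic:.2f})")
print({k: round(v, 2) for k, v in best.rates.items()})

anc = ancestral_chrom_probs(tree, obs, best)
root = anc.node_ids[0]
print(f"\nmodal root chromosome number: n = {anc.modal_state(root)} (simulated root: 50)")

ex = expected_transitions(tree, obs, best, n_sims=2000, seed=1)
print("\nexpected event totals over the tree (stochastic mapping, 2000 draws):")
for typ, tot in ex.totals.items():
    print(f"  {typ:12s} {tot:8.2f}")
print("losses should exceed gains, matching the simulated 45 vs 20 rate asymmetry")
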