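"""Independent test oracles.

The isotopomer oracle simulates steady-state labeling by balancing full
positional isotopomer distributions (2**n states per n-carbon metabolite)
with fixed-point iteration.  It shares no code with the production EMU
engine beyond the network data structures, so agreement between the two
is a meaningful correctness check.
"""

from __future__ import annotations

import itertools

import numpy as np


def _substrate_distribution(model, metabolite: str, tracer) -> np.ndarray:
    """Isotopomer distribution of a substrate under one tracer (no noise)."""
    n = model.metabolites[metabolite].n_carbons
    dist = np.zeros(2 ** n)
    if metabolite == tracer.metabolite:
        idx = 0
        for i, ch in enumerate(tracer.pattern):
            if ch == "1":
                idx |= 1 << i
        dist[idx] = 1.0
    else:
        dist[0] = 1.0  # unlabeled
    return dist


def isotopomer_mids(model, v, tracer, n_iter: int = 20000, tol: float = 1e-14):
    """{metabolite: MID} for all balanced metabolites by brute force.

    Isotopomer index bit i (LSB first) is carbon position i+1.  Reactions
    map substrate letters to product letters; multi-substrate reactions
    assume independently mixed pools.  Steady state is found by damped
    fixed-point iteration of  x_met = inflow(x) / consumption_rate.
    """
    v = np.asarray(v, float)
    state = {}
    for name, met in model.metabolites.items():
        if met.role == "balanced":
            d = np.zeros(2 ** met.n_carbons)
            d[0] = 1.0
            state[name] = d

    consumption = {}
    for name in state:
        total = 0.0
        for j, c in model.consumption(name):
            total += float(c) * v[j]
        consumption[name] = total

    def dist_of(term_met):
        met = model.metabolites[term_met]
        if met.role == "substrate":
            return _substrate_distribution(model, term_met, tracer)
        return state[term_met]

    # Precompute per-reaction structure: substrate terms with letters and
    # product terms with letters.
    rxns = []
    for j, r in enumerate(model.reactions):
        subs = [(t.metabolite, t.atoms) for t in r.reactants if t.atoms]
        prods = [(t.metabolite, float(t.coeff), t.atoms)
                 for t in r.products
                 if t.atoms and model.metabolites[t.metabolite].role == "balanced"]
        if prods:
            rxns.append((j, subs, prods))

    for _ in range(n_iter):
        inflow = {name: np.zeros_like(d) for name, d in state.items()}
        for j, subs, prods in rxns:
            if v[j] == 0.0:
                continue
            dists = [dist_of(m) for m, _ in subs]
            sizes = [len(a) for _, a in subs]
            # joint over substrate isotopomers (independent pools)
            for combo in itertools.product(*[range(2 ** s) for s in sizes]):
                prob = 1.0
                for d, idx in zip(dists, combo):
                    prob *= d[idx]
                if prob == 0.0:
                    continue
                labeled = {}
                for (m, atoms), idx in zip(subs, combo):
                    for pos, letter in enumerate(atoms):
                        labeled[letter] = (idx >> pos) & 1
                for pm, w, patoms in prods:
                    pidx = 0
                    for pos, letter in enumerate(patoms):
                        if labeled[letter]:
                            pidx |= 1 << pos
                    inflow[pm][pidx] += w * v[j] * prob
        max_delta = 0.0
        for name in state:
            new = inflow[name] / consumption[name]
            max_delta = max(max_delta, np.abs(new - state[name]).max())
            state[name] = new
        if max_delta < tol:
            break

    out = {}
    for name, dist in state.items():
        n = model.metabolites[name].n_carbons
        mid = np.zeros(n + 1)
        for idx, p in enumerate(dist):
            mid[bin(idx).count("1")] += p
        out[name] = mid
    return out
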