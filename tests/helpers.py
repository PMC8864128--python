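"""Independent brute-force oracles used to cross-check exact inference."""

from itertools import product

import numpy as np


def full_joint(structure, cpts):
    """Explicit joint table: {assignment tuple -> probability}.

    Built by brute-force multiplication over all complete assignments, in
    the order of ``structure.names``; independent of the package's
    factorized evaluation and enumeration-based inference.
    """
    names = structure.names
    cat_lists = [structure.categories(n) for n in names]
    table = {}
    for combo in product(*cat_lists):
        assignment = dict(zip(names, combo))
        p = 1.0
        for n in names:
            p *= cpts.prob(n, assignment[n], assignment)
        table[combo] = p
    return table


def brute_posterior(structure, cpts, target, evidence):
    """Posterior of ``target`` by summation over the explicit joint table."""
    names = structure.names
    t_idx = names.index(target)
    cats = structure.categories(target)
    joint = full_joint(structure, cpts)
    out = np.zeros(len(cats))
    for combo, p in joint.items():
        if all(combo[names.index(v)] == val for v, val in evidence.items()):
            out[cats.index(combo[t_idx])] += p
    total = out.sum()
    if total <= 0:
        raise ZeroDivisionError("evidence has zero probability")
    return out / total


def naive_loo_posteriors(structure, data, alpha):
    """Leave-one-out posteriors by literal refitting on n - 1 records."""
    import pandas as pd

    from framingnet.network import CategoricalDataset, estimate_cpts, posterior_target

    evidence_vars = list(structure.t1_variables)
    if structure.message is not None:
        evidence_vars.append(structure.message)
    rows = []
    for i in range(len(data)):
        rest = CategoricalDataset(structure, data.frame.drop(data.frame.index[i]))
        cpts = estimate_cpts(structure, rest, alpha=alpha)
        obs = {v: data.frame.iloc[i][v] for v in evidence_vars}
        rows.append(posterior_target(structure, cpts, obs))
    return np.asarray(rows)
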