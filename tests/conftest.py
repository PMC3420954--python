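import itertools
import math

import numpy as np
import pytest

from eyespot_origins import mk2, synthetic_data, trees


@pytest.fixture
def three_tip_tree():
    return trees.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(n_tips: int, seed: int, depth: float = 10.0) -> trees.Chronogram:
    return synthetic_data.simulate_chronogram(n_tips, depth=depth, seed=seed)


def random_character(tree: trees.Chronogram, seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {label: int(rng.integers(0, 2)) for label in tree.tip_labels}


def brute_force_lnL(tree, char, rates, constraints=None, root_prior="stationary"):
    """Exhaustive sum over every internal-node state assignment.

    Independent of the pruning implementation: multiplies closed-form
    transition probabilities edge by edge and sums over all assignments.
    """
    constraints = constraints or {}
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    if root_prior == "stationary":
        prior = rates.stationary
    elif root_prior == "equal":
        prior = (0.5, 0.5)
    else:
        prior = root_prior
    tip_state = {v: char.get(tree.labels[v]) for v in tree.tip_ids}
    edge_P = {
        v: mk2.transition_matrix(rates, float(tree.branch_length[v]))
        for v in range(tree.n_nodes - 1)
    }
    total = 0.0
    tips_with_data = [v for v, s in tip_state.items() if s is not None]
    missing_tips = [v for v, s in tip_state.items() if s is None]
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(internals, assign))
        if any(states[n] != s for n, s in constraints.items() if n in states):
            continue
        for m_assign in itertools.product((0, 1), repeat=len(missing_tips)):
            states.update(zip(missing_tips, m_assign))
            states.update({v: tip_state[v] for v in tips_with_data})
            if any(states[n] != s for n, s in constraints.items()):
                continue
            p = prior[states[tree.root]]
            for v in range(tree.n_nodes - 1):
                p *= edge_P[v][states[int(tree.parent[v])], states[v]]
            total += p
    return math.log(total)
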