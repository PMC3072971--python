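"""Independent oracles for the test suite.

Enumeration over internal-node state assignments with expm-based transition
probabilities; shares no code with the pruning implementation.
"""

import itertools

import numpy as np
from scipy.linalg import expm



def mk_rate_matrix(k: int, rate: float) -> np.ndarray:
    Q = np.full((k, k), rate, dtype=float)
    np.fill_diagonal(Q, -(k - 1) * rate)
    return Q


def brute_force_mk(tree, states: dict, k: int, rate: float):
    """(log-likelihood, {internal node id: posterior vector}) by enumeration.

    ``states`` maps tip label to state or None for missing (summed over).
    """
    Q = mk_rate_matrix(k, rate)
    nodes = list(tree.postorder())
    P = {nd.index: expm(Q * nd.edge.length) for nd in nodes}
    internals = [nd for nd in nodes if not nd.is_leaf()]
    tips = [nd for nd in nodes if nd.is_leaf()]

    def tip_states(nd):
        s = states[tree.tip_label(nd)]
        return range(k) if s is None else [s]

    total = 0.0
    marg = {nd.index: np.zeros(k) for nd in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        a = {nd.index: s for nd, s in zip(internals, assign)}
        p = 1.0 / k  # uniform root prior
        for nd in internals:
            if nd is not tree.root:
                p *= P[nd.index][a[nd.parent_node.index], a[nd.index]]
        for nd in tips:  # tip states factorize given the parent state
            p *= sum(P[nd.index][a[nd.parent_node.index], s] for s in tip_states(nd))
        total += p
        for nd in internals:
            marg[nd.index][a[nd.index]] += p
    post = {i: v / total for i, v in marg.items()}
    return float(np.log(total)), post
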