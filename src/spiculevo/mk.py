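"""Symmetric Mk likelihood and marginal ancestral-state reconstruction.

The Mk model (Lewis's one-rate "Mk1" flavour) is a continuous-time Markov
chain on k states in which every state flips to every other state at the
same instantaneous rate alpha, so the stationary distribution is uniform.
For a branch of length t (expected substitutions per site of the molecular
tree, used directly as the character time axis) the transition probabilities
have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k * alpha * t)
    P_ij(t) = 1/k -   1/k   * exp(-k * alpha * t)     (i != j)

The column likelihood is computed by Felsenstein's pruning algorithm with
per-node rescaling (no underflow for trees of hundreds of tips), the rate is
estimated per character by bounded 1-D maximum likelihood on log(alpha), and
marginal posterior state probabilities at every node come from a second,
root-to-tip (outside) pass — equivalent to re-rooting the tree at each node.

The public surface follows the Model/Results convention:
:class:`MkCharacterModel` is built from a tree and a character column;
``fit()`` returns :class:`MkCharacterResults` carrying the rate MLE, its
standard error, the log-likelihood, node posteriors and ``summary()``.
Thin functional wrappers (:func:`column_log_likelihood`, :func:`fit_rate`,
:func:`marginal_asr`) cover scripting use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .characters import MISSING, CharacterColumn
from .trees import Phylogeny

__all__ = [
    "MkModel",
    "mk_transition_matrix",
    "MkCharacterModel",
    "MkCharacterResults",
    "AncestralReconstruction",
    "column_log_likelihood",
    "fit_rate",
    "marginal_asr",
    "pooled_rate_fit",
    "RATE_BOUNDS",
]

RATE_BOUNDS = (1e-8, 100.0)


@dataclass(frozen=True)
class MkModel:
    """Mk parameterization: state count, flip rate, root prior (uniform by default)."""

    k: int = 2
    rate: float = 1.0
    root_prior: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.root_prior is not None:
            p = np.asarray(self.root_prior, dtype=float)
            if p.shape != (self.k,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("root_prior must be a length-k probability vector")

    def prior_vector(self) -> np.ndarray:
        if self.root_prior is None:
            return np.full(self.k, 1.0 / self.k)
        return np.asarray(self.root_prior, dtype=float)


def mk_transition_matrix(model_or_rate, t: float, k: int | None = None) -> np.ndarray:
    """k x k transition probability matrix of the symmetric Mk chain over time t.

    Accepts either an :class:`MkModel` or a raw rate (with ``k`` given).
    """
    if isinstance(model_or_rate, MkModel):
        rate, k = model_or_rate.rate, model_or_rate.k
    else:
        rate = float(model_or_rate)
        if k is None:
            raise ValueError("k is required when passing a raw rate")
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = math.exp(-k * rate * t)
    off = (1.0 - e) / k
    diag = 1.0 / k + (k - 1.0) / k * e
    P = np.full((k, k), off)
    np.fill_diagonal(P, diag)
    return P


# ---------------------------------------------------------------------------
# pruning internals (vectorized over characters)
# ---------------------------------------------------------------------------


class _TreeArrays:
    """Postorder child/edge-length arrays extracted once per tree."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.n = tree.n_nodes
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.edge_len = np.zeros(self.n)
        self.is_tip = np.zeros(self.n, dtype=bool)
        self.tip_label: dict[int, str] = {}
        self.order: list[int] = []
        for nd in tree.postorder():
            i = nd.index
            self.order.append(i)
            self.edge_len[i] = nd.edge.length
            if nd.is_leaf():
                self.is_tip[i] = True
                self.tip_label[i] = nd.taxon.label
            else:
                self.children[i] = [c.index for c in nd.child_nodes()]
        self.root = tree.root.index


def _tip_partials(ta: _TreeArrays, cols: list[CharacterColumn], k: int) -> np.ndarray:
    """(n_nodes, n_cols, k) array; tip rows are indicators, all-ones when missing."""
    C = len(cols)
    L = np.ones((ta.n, C, k))
    for j, col in enumerate(cols):
        for i, label in ta.tip_label.items():
            try:
                s = col.states[label]
            except KeyError:
                raise ValueError(
                    f"character {col.name!r} has no state for tip {label!r}"
                ) from None
            if s == MISSING:
                continue
            if not (0 <= s < k):
                raise ValueError(
                    f"state {s} of tip {label!r} out of range for k={k}"
                )
            L[i, j, :] = 0.0
            L[i, j, s] = 1.0
    return L


def _edge_message(down: np.ndarray, e: float, k: int) -> np.ndarray:
    """Propagate child partials through the closed-form symmetric P(t).

    ``msg[s] = sum_j P_sj * down[j] = (1-e)/k * sum_j down[j] + e * down[s]``.
    """
    S = down.sum(axis=-1, keepdims=True)
    return (1.0 - e) / k * S + e * down


def _down_pass(ta: _TreeArrays, tipL: np.ndarray, rate: float, k: int):
    """Return (partials, log_scalers, messages) of the pruning pass.

    partials[i] is the scaled conditional likelihood of the data below node
    i given its state; messages[i] is node i's contribution to its parent
    (already propagated across i's edge).
    """
    n, C = tipL.shape[0], tipL.shape[1]
    partial = np.empty_like(tipL)
    msg = [None] * n
    logscale = np.zeros(C)
    exp_e = np.exp(-k * rate * ta.edge_len)
    for i in ta.order:
        if ta.is_tip[i]:
            partial[i] = tipL[i]
        else:
            prod = np.ones((C, k))
            for c in ta.children[i]:
                prod = prod * msg[c]
            mx = prod.max(axis=-1, keepdims=True)
            mx = np.where(mx > 0, mx, 1.0)
            logscale += np.log(mx[:, 0])
            partial[i] = prod / mx
        if i != ta.root:
            msg[i] = _edge_message(partial[i], exp_e[i], k)
    return partial, logscale, msg


def _loglike_cols(ta: _TreeArrays, tipL: np.ndarray, rate: float, k: int,
                  prior: np.ndarray) -> np.ndarray:
    partial, logscale, _ = _down_pass(ta, tipL, rate, k)
    root = partial[ta.root] @ prior
    with np.errstate(divide="ignore"):
        return np.log(root) + logscale


def _marginals(ta: _TreeArrays, tipL: np.ndarray, rate: float, k: int,
               prior: np.ndarray) -> np.ndarray:
    """Marginal posterior state probabilities at every node (outside pass)."""
    partial, _, msg = _down_pass(ta, tipL, rate, k)
    C = tipL.shape[1]
    exp_e = np.exp(-k * rate * ta.edge_len)
    up = np.empty_like(tipL)
    up[ta.root] = np.broadcast_to(prior, (C, k))
    for i in reversed(ta.order):
        if ta.is_tip[i]:
            continue
        kids = ta.children[i]
        for c in kids:
            sib = up[i].copy()
            for c2 in kids:
                if c2 is not c:
                    sib = sib * msg[c2]
            u = _edge_message(sib, exp_e[c], k)  # P symmetric: same propagation
            tot = u.sum(axis=-1, keepdims=True)
            up[c] = u / np.where(tot > 0, tot, 1.0)
    post = up * partial
    tot = post.sum(axis=-1, keepdims=True)
    return post / np.where(tot > 0, tot, 1.0)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class MkCharacterModel:
    """Mk likelihood for one discrete character on a fixed rooted tree.

    Parameters
    ----------
    tree
        The phylogeny; branch lengths are the character's time axis.
    column
        A :class:`~spiculevo.characters.CharacterColumn` (or a plain mapping
        taxon -> state) covering every tip; missing states allowed.
    k
        Number of states (2 for presence/absence spicule characters).
    root_prior
        Probability vector over root states; uniform (the Mk assumption)
        when omitted.
    """

    def __init__(self, tree: Phylogeny, column, k: int = 2, root_prior=None):
        if not isinstance(column, CharacterColumn):
            column = CharacterColumn(name="character", states=dict(column))
        self.tree = tree
        self.column = column
        self.k = int(k)
        self._prior = MkModel(k=self.k, rate=1.0, root_prior=root_prior).prior_vector()
        self._ta = _TreeArrays(tree)
        self._tipL = _tip_partials(self._ta, [column], self.k)

    def loglike(self, rate: float) -> float:
        """Pruning log-likelihood of the column at the given flip rate."""
        if rate < 0:
            raise ValueError("rate must be >= 0")
        return float(_loglike_cols(self._ta, self._tipL, rate, self.k, self._prior)[0])

    def is_constant(self) -> bool:
        return len({s for s in self.column.states.values() if s != MISSING}) <= 1

    def fit(self, bounds: tuple[float, float] = RATE_BOUNDS,
            tol: float = 1e-8) -> "MkCharacterResults":
        """Maximize the likelihood over the rate by bounded search on log(alpha).

        A constant character has its likelihood maximized as alpha -> 0; it
        is returned at the lower bound with ``constant_character=True``.
        """
        lo, hi = bounds
        if self.is_constant():
            rate = lo
            return self._results(rate, self.loglike(rate), constant=True)
        res = minimize_scalar(
            lambda lg: -self.loglike(math.exp(lg)),
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": tol},
        )
        rate = math.exp(res.x)
        return self._results(rate, -res.fun, constant=False)

    def marginal_posteriors(self, rate: float) -> np.ndarray:
        """(n_nodes, k) marginal posteriors, rows indexed by postorder node id."""
        return _marginals(self._ta, self._tipL, rate, self.k, self._prior)[:, 0, :]

    def _rate_se(self, rate: float) -> float:
        # observed-information SE from a central second difference of the
        # log-likelihood in rate; nan at the bounds or under flat curvature
        lo, hi = RATE_BOUNDS
        h = max(1e-5, 1e-4 * rate)
        if rate - h <= lo or rate + h >= hi:
            return float("nan")
        d2 = (self.loglike(rate + h) - 2 * self.loglike(rate) + self.loglike(rate - h)) / h**2
        if d2 >= 0:
            return float("nan")
        return 1.0 / math.sqrt(-d2)

    def _results(self, rate: float, llf: float, constant: bool) -> "MkCharacterResults":
        bse = float("nan") if constant else self._rate_se(rate)
        return MkCharacterResults(model=self, rate=rate, llf=llf,
                                  constant_character=constant, rate_se=bse)


@dataclass
class AncestralReconstruction:
    """Per-node posterior state probabilities for one character.

    ``posteriors`` rows are indexed by the tree's postorder node ids.  Tip
    rows are indicators of the observed state (uniform when missing), per
    the reconstruction's reporting convention.
    """

    character: str
    char_class: str | None
    k: int
    rate: float
    log_likelihood: float
    posteriors: np.ndarray

    def node_posterior(self, node_id: int) -> np.ndarray:
        return self.posteriors[node_id]


@dataclass
class MkCharacterResults:
    """Fitted Mk character model: rate MLE, uncertainty, posteriors, summary."""

    model: MkCharacterModel
    rate: float
    llf: float
    constant_character: bool
    rate_se: float
    _post: np.ndarray | None = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {"rate": self.rate}

    @property
    def bse(self) -> dict[str, float]:
        return {"rate": self.rate_se}

    def node_posteriors(self) -> np.ndarray:
        if self._post is None:
            self._post = self.model.marginal_posteriors(self.rate)
        return self._post

    def reconstruction(self) -> AncestralReconstruction:
        post = self.node_posteriors().copy()
        # reporting convention: tips are indicators (uniform when missing)
        ta = self.model._ta
        k = self.model.k
        for i, label in ta.tip_label.items():
            s = self.model.column.states[label]
            if s == MISSING:
                post[i, :] = 1.0 / k
            else:
                post[i, :] = 0.0
                post[i, s] = 1.0
        return AncestralReconstruction(
            character=self.model.column.name,
            char_class=self.model.column.char_class,
            k=k,
            rate=self.rate,
            log_likelihood=self.llf,
            posteriors=post,
        )

    def posteriors_frame(self) -> pd.DataFrame:
        """Reconstruction table: node id, tip label, per-state probabilities."""
        rec = self.reconstruction()
        ta = self.model._ta
        rows = []
        for i in ta.order:
            rows.append(
                {
                    "node": i,
                    "tip": ta.tip_label.get(i, ""),
                    **{f"p_state{s}": rec.posteriors[i, s] for s in range(self.model.k)},
                }
            )
        df = pd.DataFrame(rows).sort_values("node").reset_index(drop=True)
        df["character"] = self.model.column.name
        df["rate"] = self.rate
        df["logL"] = self.llf
        return df

    def summary(self) -> str:
        lines = [
            "Mk character model results",
            "=" * 42,
            f"character:        {self.model.column.name}",
            f"states (k):       {self.model.k}",
            f"tips:             {self.model.tree.n_tips}",
            f"rate MLE:         {self.rate:.6g}",
            f"rate SE:          {self.rate_se:.3g}",
            f"log-likelihood:   {self.llf:.6f}",
            f"constant char:    {self.constant_character}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Posterior probability of state 1 against node depth (quick look)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tree = self.model.tree
        depth = {}
        for nd in tree.preorder():
            depth[nd.index] = (
                0.0 if nd is tree.root else depth[nd.parent_node.index] + nd.edge.length
            )
        post = self.node_posteriors()
        xs = [depth[i] for i in range(tree.n_nodes)]
        ys = post[:, min(1, self.model.k - 1)]
        ax.scatter(xs, ys, s=12)
        ax.set_xlabel("node depth (subs/site)")
        ax.set_ylabel("posterior P(state 1)")
        ax.set_title(self.model.column.name)
        return ax


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def column_log_likelihood(tree: Phylogeny, col: CharacterColumn, model: MkModel) -> float:
    """Felsenstein pruning log-likelihood of one column under an Mk model."""
    return MkCharacterModel(tree, col, k=model.k, root_prior=model.root_prior).loglike(
        model.rate
    )


def fit_rate(tree: Phylogeny, col: CharacterColumn, k: int = 2) -> MkCharacterResults:
    """Per-character rate MLE (bounded search on log rate)."""
    return MkCharacterModel(tree, col, k=k).fit()


def marginal_asr(tree: Phylogeny, col: CharacterColumn, model: MkModel) -> AncestralReconstruction:
    """Marginal ancestral-state reconstruction at a fixed rate."""
    m = MkCharacterModel(tree, col, k=model.k, root_prior=model.root_prior)
    res = MkCharacterResults(
        model=m,
        rate=model.rate,
        llf=m.loglike(model.rate),
        constant_character=m.is_constant(),
        rate_se=float("nan"),
    )
    return res.reconstruction()


def pooled_rate_fit(tree: Phylogeny, columns: list[CharacterColumn], k: int = 2,
                    bounds: tuple[float, float] = RATE_BOUNDS, tol: float = 1e-8):
    """One shared rate maximizing the summed log-likelihood of many columns.

    Returns ``(rate, total_loglike)``.  Used for pooled parameter-recovery
    checks; the per-character analyses fit rates independently.
    """
    ta = _TreeArrays(tree)
    tipL = _tip_partials(ta, columns, k)
    prior = np.full(k, 1.0 / k)

    def neg(lg: float) -> float:
        return -float(_loglike_cols(ta, tipL, math.exp(lg), k, prior).sum())

    res = minimize_scalar(
        neg, bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded", options={"xatol": tol},
    )
    return math.exp(res.x), -res.fun
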