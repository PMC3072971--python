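"""Synthetic data with the statistical structure the analyses assume.

Generates birth–death trees, binary characters evolved under the symmetric
Mk chain, planted irreversible-loss characters with known ground truth,
bathymetric habit labels, and nucleotide alignments under HKY with a
proportion of invariant sites and discrete-gamma rate variation — everything
needed to exercise the pipeline end to end at desk scale without external
downloads.

The default :class:`SimulationConfig` emulates the shape of the study
system: ~89 species, a 13-character binary spicule matrix, depth labels in
proportion 43 shallow : 46 deep with two dual-zone species, and two marker
partitions of 660 and 864 sites with pinv = 0.367474 and gamma shape
0.557592.  All generators are driven by numpy's PCG64 streams (dendropy's
birth–death sampler uses Python's Mersenne Twister) and are bit-reproducible
given (seed, config).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist
from dendropy.simulate import treesim

from .characters import MISSING, CharacterColumn, CharacterMatrix, DepthMetadata
from .mk import mk_transition_matrix
from .seqmat import AlignedSequenceMatrix
from .trees import Phylogeny

__all__ = [
    "SequenceSpec",
    "SimulationConfig",
    "simulate_tree",
    "yule_tip_count",
    "simulate_mk_character",
    "simulate_loss_scenario",
    "assign_depth",
    "discrete_gamma_rates",
    "simulate_alignment",
    "make_fixture",
    "Fixture",
]

# printed parameter estimates for the combined two-marker analysis, reused
# as simulation defaults
DEFAULT_BASE_FREQS = (0.191611, 0.247736, 0.290797, 0.269856)  # A C G T
DEFAULT_PINV = 0.367474
DEFAULT_GAMMA_SHAPE = 0.557592


@dataclass
class SequenceSpec:
    """One marker partition: length, HKY parameters, rate heterogeneity."""

    length: int = 660
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    pinv: float = DEFAULT_PINV
    gamma_shape: float | None = DEFAULT_GAMMA_SHAPE
    n_categories: int = 4
    name: str = "marker"

    def validate(self) -> None:
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or (f <= 0).any() or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        if not (0.0 <= self.pinv <= 1.0):
            raise ValueError("pinv must be in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class SimulationConfig:
    """Everything a full synthetic dataset needs; defaults sized to the study."""

    seed: int = 0
    n_tips: int = 89
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_height: float | None = 0.3  # subs/site; None keeps raw time units
    n_characters: int = 13
    mk_rate: float = 1.0
    n_losses: int = 2
    min_clade: int = 3
    depth_proportions: tuple[float, float] = (43 / 89, 46 / 89)
    n_both_habit: int = 2
    sequences: tuple[SequenceSpec, ...] = (
        SequenceSpec(length=660, name="coi"),
        SequenceSpec(length=864, name="r28s"),
    )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        seqs = raw.pop("sequences", None)
        if "depth_proportions" in raw:
            raw["depth_proportions"] = tuple(raw["depth_proportions"])
        cfg = cls(**raw)
        if seqs is not None:
            for s in seqs:
                if "base_freqs" in s:
                    s["base_freqs"] = tuple(s["base_freqs"])
            cfg.sequences = tuple(SequenceSpec(**s) for s in seqs)
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["sequences"] = [asdict(s) for s in self.sequences]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    seed: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    height: float | None = None,
) -> Phylogeny:
    """Birth–death tree conditioned on the number of extant tips.

    The process runs until n_tips extant lineages exist (stop-at-n, not
    uniform over labeled histories); extinct lineages are pruned, so the
    result is ultrametric.  Tips are relabeled ``T0001``... in leaf order.
    Optionally rescaled so the root-to-tip height equals ``height``.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if death_rate >= birth_rate:
        raise ValueError("death rate must be below birth rate")
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=random.Random(int(seed)),
    )
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i:0{width}d}"
    tree = Phylogeny(dtree)
    if height is not None:
        tree = tree.scale_to_height(height)
    return tree


def yule_tip_count(t: float, birth_rate: float, rng: np.random.Generator) -> int:
    """Lineage count of an unconditioned pure-birth process at time t.

    Gillespie simulation; the expectation is exp(birth_rate * t).
    """
    n, clock = 1, 0.0
    while True:
        clock += rng.exponential(1.0 / (birth_rate * n))
        if clock > t:
            return n
        n += 1


# ---------------------------------------------------------------------------
# discrete characters
# ---------------------------------------------------------------------------


def simulate_mk_character(
    tree: Phylogeny, k: int, rate: float, seed_or_rng, name: str = "char",
    char_class: str | None = None,
) -> CharacterColumn:
    """Evolve one k-state character along the tree under the symmetric Mk chain."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = _as_rng(seed_or_rng)
    state: dict[int, int] = {}
    states = {}
    for nd in tree.preorder():
        if nd is tree.root:
            state[nd.index] = int(rng.integers(k))
        else:
            P = mk_transition_matrix(rate, nd.edge.length, k)
            state[nd.index] = int(rng.choice(k, p=P[state[nd.parent_node.index]]))
        if nd.is_leaf():
            states[tree.tip_label(nd)] = state[nd.index]
    return CharacterColumn(name=name, states=states, char_class=char_class)


def _mp_score_and_count(tree: Phylogeny, states: dict[str, int]) -> tuple[int, int]:
    """Sankoff parsimony score of a binary column and the number of
    most-parsimonious internal labelings (tips fixed)."""
    INF = 10**9
    cost: dict[int, list[int]] = {}
    count: dict[int, list[int]] = {}
    for nd in tree.postorder():
        if nd.is_leaf():
            s = states[tree.tip_label(nd)]
            cost[nd.index] = [0 if t == s else INF for t in (0, 1)]
            count[nd.index] = [1, 1]
            continue
        c = [0, 0]
        n = [1, 1]
        for ch in nd.child_nodes():
            cc, cn = cost[ch.index], count[ch.index]
            for s in (0, 1):
                opts = [cc[t] + (0 if t == s else 1) for t in (0, 1)]
                best = min(opts)
                c[s] += best
                n[s] *= sum(cn[t] for t in (0, 1) if opts[t] == best)
        cost[nd.index], count[nd.index] = c, n
    rc, rn = cost[tree.root.index], count[tree.root.index]
    best = min(rc)
    return best, sum(rn[s] for s in (0, 1) if rc[s] == best)


def simulate_loss_scenario(
    tree: Phylogeny, n_losses: int, min_clade: int, seed_or_rng,
    name: str = "char", char_class: str | None = None,
):
    """Plant irreversible losses: present everywhere except n disjoint clades.

    Losses are modeled as rare irreversible transitions: a loss event lands
    on an internal edge with probability proportional to its branch length
    (the placement distribution of a rare Poisson event on the tree),
    restricted to edges subtending at least ``min_clade`` tips and subject
    to disjointness and to the constraint that every chosen clade's parent
    keeps at least one present descendant.

    A selection is accepted only when the planted events are the *unique*
    most-parsimonious explanation of the resulting column (Sankoff check):
    without this, two losses separated by a small present clade are
    indistinguishable from one loss plus one gain, and the planted count
    would not be a well-defined ground truth.  Returns
    ``(column, planted_child_node_ids)``.
    """
    rng = _as_rng(seed_or_rng)
    tips = set(tree.tip_labels)
    if n_losses == 0:
        return CharacterColumn(name, {t: 1 for t in tips}, char_class), []
    candidates = [
        nd for nd in tree.postorder()
        if not nd.is_leaf() and nd is not tree.root
        and len(tree.leafset_below(nd)) >= min_clade
    ]
    weights = np.array([max(nd.edge.length, 1e-12) for nd in candidates])

    def feasible(nd, lost):
        below = tree.leafset_below(nd)
        if below & lost:
            return False
        if not (tree.leafset_below(nd.parent_node) - below - lost):
            return False  # parent would keep no present descendant
        return len(tips - lost - below) >= 1

    chosen: list = []
    for _attempt in range(500):
        chosen, lost = [], set()
        while len(chosen) < n_losses:
            idxs = [i for i, nd in enumerate(candidates) if feasible(nd, lost)]
            if not idxs:
                break
            w = weights[idxs]
            pick = candidates[int(rng.choice(idxs, p=w / w.sum()))]
            chosen.append(pick)
            lost |= tree.leafset_below(pick)
        if len(chosen) != n_losses:
            continue
        states = {t: 0 if t in lost else 1 for t in tips}
        score, nmp = _mp_score_and_count(tree, states)
        if score == n_losses and nmp == 1:
            break
        chosen = []
    if len(chosen) < n_losses:
        raise ValueError(
            f"tree does not admit {n_losses} identifiable disjoint clades "
            f"of >= {min_clade} tips"
        )
    lost = set()
    for nd in chosen:
        lost |= tree.leafset_below(nd)
    states = {t: 0 if t in lost else 1 for t in tips}
    return (
        CharacterColumn(name, states, char_class),
        sorted(nd.index for nd in chosen),
    )


def assign_depth(
    taxa,
    seed_or_rng,
    proportions: tuple[float, float] = (43 / 89, 46 / 89),
    clustered: bool = False,
    tree: Phylogeny | None = None,
    flip_rate: float = 0.5,
    n_both: int = 0,
    depth_threshold_m: float = 100.0,
) -> DepthMetadata:
    """Draw shallow/deep habit labels, i.i.d. or phylogenetically clustered.

    Clustered mode evolves a slow binary Mk character on the tree (state 0
    -> shallow, 1 -> deep); ``flip_rate == 0`` gives a habit constant across
    the tree.  ``n_both`` taxa are then relabeled as dual-zone species.
    """
    rng = _as_rng(seed_or_rng)
    taxa = list(taxa)
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid proportions")
    p = p / p.sum()
    if clustered:
        if tree is None:
            raise ValueError("clustered mode needs the tree")
        col = simulate_mk_character(tree, 2, flip_rate, rng)
        habits = {t: ("shallow" if col.states[t] == 0 else "deep") for t in taxa}
    else:
        draws = rng.choice(["shallow", "deep"], size=len(taxa), p=p)
        habits = dict(zip(taxa, draws))
    if n_both:
        for t in rng.choice(taxa, size=n_both, replace=False):
            habits[str(t)] = "both"
    return DepthMetadata(habits, depth_threshold_m)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def discrete_gamma_rates(shape: float, m: int) -> np.ndarray:
    """Mean rates of m equal-probability categories of a mean-1 gamma.

    Category boundaries are quantiles of Gamma(shape, scale=1/shape); the
    category rate is the conditional mean within the category, renormalized
    to mean exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    probs = np.arange(1, m) / m
    bounds = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    upper = gammainc(shape + 1, shape * bounds[1:])
    lower = gammainc(shape + 1, shape * bounds[:-1])
    rates = m * (upper - lower)
    return rates / rates.mean()


def _hky_q(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix (A C G T order), scaled to mean rate 1."""
    ti = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if (i, j) in ti else 1.0) * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def simulate_alignment(
    tree: Phylogeny, spec: SequenceSpec, seed_or_rng
) -> AlignedSequenceMatrix:
    """Evolve an alignment under HKY + invariant sites + discrete gamma.

    A site is invariant with probability pinv; variable sites draw one of
    the gamma categories, whose rates are scaled by 1/(1-pinv) so the
    overall expected rate is 1 and branch lengths keep their
    substitutions-per-site meaning.
    """
    spec.validate()
    rng = _as_rng(seed_or_rng)
    freqs = np.asarray(spec.base_freqs, dtype=float)
    Q = _hky_q(spec.kappa, freqs)
    if spec.gamma_shape is None:
        cat_rates = np.array([1.0])
    else:
        cat_rates = discrete_gamma_rates(spec.gamma_shape, spec.n_categories)
    if spec.pinv < 1.0:
        var_rates = cat_rates / (1.0 - spec.pinv)
    else:
        var_rates = cat_rates * 0.0
    # per-site rate assignment
    L = spec.length
    invariant = rng.random(L) < spec.pinv
    cat = rng.integers(len(cat_rates), size=L)
    site_rate_index = np.where(invariant, len(var_rates), cat)  # last index = rate 0
    all_rates = np.concatenate([var_rates, [0.0]])

    # precompute per-edge, per-rate transition matrices
    nucs = np.array(list("ACGT"))
    seqs: dict[int, np.ndarray] = {}
    for nd in tree.preorder():
        if nd is tree.root:
            seqs[nd.index] = rng.choice(4, size=L, p=freqs)
            continue
        parent = seqs[nd.parent_node.index]
        child = parent.copy()
        for ri, r in enumerate(all_rates):
            mask = site_rate_index == ri
            if not mask.any() or r == 0.0 or nd.edge.length == 0.0:
                continue
            P = expm(Q * nd.edge.length * r)
            P = np.clip(P, 0.0, None)
            P = P / P.sum(axis=1, keepdims=True)
            sub = parent[mask]
            u = rng.random(sub.shape[0])
            cum = np.cumsum(P[sub], axis=1)
            child[mask] = (u[:, None] > cum).sum(axis=1)
        seqs[nd.index] = child

    taxa, rows = [], []
    for nd in tree.postorder():
        if nd.is_leaf():
            taxa.append(tree.tip_label(nd))
            rows.append("".join(nucs[seqs[nd.index]]))
    return AlignedSequenceMatrix(taxa, rows, name=spec.name)


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------

# 13 spicule presence/absence characters emulating the study matrix's shape:
# (name, class, planted loss count or None for free Mk evolution)
FIXTURE_CHARACTERS = [
    ("triaenes", "megasclere", 2),
    ("long_shafted_triaenes", "megasclere", None),
    ("anatriaenes", "megasclere", None),
    ("calthrops", "megasclere", None),
    ("desmas", "megasclere", 3),
    ("euasters", "microsclere", 2),
    ("sterrasters", "microsclere", 3),
    ("aspidasters", "microsclere", None),
    ("amphiasters", "microsclere", None),
    ("spirasters", "microsclere", None),
    ("sanidasters", "microsclere", 2),
    ("microrhabds", "microsclere", None),
    ("toxas", "microsclere", 2),
]


@dataclass
class Fixture:
    """A complete synthetic dataset plus its planted ground truth."""

    config: SimulationConfig
    tree: Phylogeny
    matrix: CharacterMatrix
    meta: DepthMetadata
    alignments: list[AlignedSequenceMatrix]
    planted: dict[str, list[int]]  # character -> planted loss child-node ids
    paths: dict[str, Path] = field(default_factory=dict)


def make_fixture(cfg: SimulationConfig, outdir=None) -> Fixture:
    """Generate the packaged desk-scale dataset (optionally written to disk).

    Characters listed with a planted loss count get irreversible planted
    losses (known ground truth); the rest evolve freely at ``cfg.mk_rate``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    tree_seed = int(ss.generate_state(1)[0] % (2**31))
    tree = simulate_tree(
        cfg.n_tips, tree_seed, cfg.birth_rate, cfg.death_rate, cfg.tree_height
    )
    streams = [np.random.default_rng(s) for s in ss.spawn(cfg.n_characters + 2 + len(cfg.sequences))]

    chars = FIXTURE_CHARACTERS[: cfg.n_characters]
    columns, planted = [], {}
    for (name, klass, n_loss), rng in zip(chars, streams):
        if n_loss is None:
            col = simulate_mk_character(tree, 2, cfg.mk_rate, rng, name, klass)
            planted[name] = []
        else:
            try:
                col, edges = simulate_loss_scenario(
                    tree, n_loss, cfg.min_clade, rng, name, klass
                )
            except ValueError:
                col, edges = simulate_loss_scenario(tree, 1, cfg.min_clade, rng, name, klass)
            planted[name] = edges
        columns.append(col)
    matrix = CharacterMatrix.from_columns(columns)

    meta = assign_depth(
        tree.tip_labels,
        streams[cfg.n_characters],
        proportions=cfg.depth_proportions,
        n_both=cfg.n_both_habit,
    )
    alignments = [
        simulate_alignment(tree, spec, rng)
        for spec, rng in zip(cfg.sequences, streams[cfg.n_characters + 2:])
    ]

    fx = Fixture(cfg, tree, matrix, meta, alignments, planted)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "matrix": outdir / "characters.tsv",
            "matrix_nexus": outdir / "characters.nex",
            "meta": outdir / "depth.tsv",
            "config": outdir / "config.yaml",
        }
        paths["tree"].write_text(tree.to_newick() + "\n", encoding="utf-8")
        matrix.to_tsv(paths["matrix"])
        matrix.to_nexus(paths["matrix_nexus"])
        meta.to_tsv(paths["meta"])
        cfg.to_yaml(paths["config"])
        for aln in alignments:
            p = outdir / f"{aln.name}.fasta"
            aln.write_fasta(p)
            paths[aln.name] = p
        fx.paths = paths
    return fx


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
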