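"""From node posteriors to homoplasy counts.

Reconstruction posteriors are turned into tiered state calls — HIGH when a
state's posterior exceeds 0.95, MODERATE when it exceeds 0.65 (up to 0.95),
ambiguous otherwise — and confident calls into counts of independent
secondary losses and convergent gains per character, stratified by the
bathymetric habit (shallow vs deep) of the descendant species.

Event semantics (binary presence/absence characters): a LOSS at tier t is an
edge whose parent is called present and whose child is called absent, both
at tier t or better; a GAIN is the reverse.  Events are maximal — an edge
deeper inside an already-absent (already-present) clade cannot qualify
because its parent is absent (present) — and ambiguous nodes break event
chains: no event is counted through them.  The root's state is reported but
never counted as a gain or loss; a state confidently present at the root
counts as a "root origin" when tallying independent origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characters import DepthMetadata
from .mk import AncestralReconstruction
from .trees import Phylogeny

__all__ = [
    "Call",
    "call_states",
    "count_events",
    "independent_origins",
    "stratify_by_depth",
    "homoplasy_report",
    "HomoplasyReport",
    "HIGH",
    "MODERATE",
]

HIGH = "HIGH"
MODERATE = "MODERATE"
_TIER_RANK = {None: 0, MODERATE: 1, HIGH: 2}

PRESENT, ABSENT = 1, 0


@dataclass(frozen=True)
class Call:
    """Tiered state call at one node; ``state is None`` means ambiguous."""

    state: int | None
    tier: str | None

    @property
    def ambiguous(self) -> bool:
        return self.state is None

    def at_least(self, state: int, tier: str) -> bool:
        return self.state == state and _TIER_RANK[self.tier] >= _TIER_RANK[tier]


def call_states(
    recon: AncestralReconstruction, high: float = 0.95, moderate: float = 0.65
) -> dict[int, Call]:
    """Per-node tiered calls from marginal posteriors.

    Thresholds must satisfy 0.5 < moderate < high <= 1 so at most one state
    can qualify.  Tips carry posterior 1 on their observed state and are
    called HIGH; missing tips (uniform posterior) are ambiguous.
    """
    if not (0.5 < moderate < high <= 1.0):
        raise ValueError("need 0.5 < moderate < high <= 1")
    calls: dict[int, Call] = {}
    for node_id, p in enumerate(recon.posteriors):
        s = int(np.argmax(p))
        pmax = float(p[s])
        if pmax > high:
            calls[node_id] = Call(s, HIGH)
        elif pmax > moderate:
            calls[node_id] = Call(s, MODERATE)
        else:
            calls[node_id] = Call(None, None)
    return calls


def _event_rows(calls: dict[int, Call], tree: Phylogeny, character: str, tier: str):
    """Scan every edge for qualifying loss/gain transitions at the given tier."""
    rows = []
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        pc, cc = calls[nd.parent_node.index], calls[nd.index]
        for event, pstate, cstate in (("loss", PRESENT, ABSENT), ("gain", ABSENT, PRESENT)):
            if pc.at_least(pstate, tier) and cc.at_least(cstate, tier):
                own = HIGH if (pc.tier == HIGH and cc.tier == HIGH) else MODERATE
                rows.append(
                    {
                        "character": character,
                        "parent": nd.parent_node.index,
                        "child": nd.index,
                        "event": event,
                        "tier": own,
                    }
                )
    return rows


def count_events(
    calls: dict[int, Call], tree: Phylogeny, character: str = "character",
    tier: str = HIGH,
) -> pd.DataFrame:
    """Event table of independent losses and gains at the given tier.

    Columns: character, parent, child, event, tier (the event's own tier,
    i.e. the weaker of its two endpoint calls).
    """
    if tier not in (HIGH, MODERATE):
        raise ValueError(f"unknown tier {tier!r}")
    return pd.DataFrame(
        _event_rows(calls, tree, character, tier),
        columns=["character", "parent", "child", "event", "tier"],
    )


def independent_origins(
    calls: dict[int, Call], tree: Phylogeny, character: str = "character",
    state: int = PRESENT, tier: str = HIGH,
) -> int:
    """Number of independent origins of *state* at the given tier.

    Counts maximal gain edges into the state, plus one "root origin" when
    the root itself is confidently in the state.
    """
    n = 0
    if calls[tree.root.index].at_least(state, tier):
        n += 1
    other = 1 - state
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        if calls[nd.parent_node.index].at_least(other, tier) and calls[nd.index].at_least(state, tier):
            n += 1
    return n


def event_habitat(tree: Phylogeny, child_id: int, meta: DepthMetadata) -> str:
    """Habitat attribution of an event edge: consensus of descendant tips.

    Species recorded in both depth zones are excluded; ``mixed`` when the
    remaining tips disagree, ``unknown`` when none remain.
    """
    node = tree.node(child_id)
    habits = set()
    for label in tree.leafset_below(node) if not node.is_leaf() else {tree.tip_label(node)}:
        h = meta.habit(label)
        if h != "both":
            habits.add(h)
    if not habits:
        return "unknown"
    if len(habits) > 1:
        return "mixed"
    return habits.pop()


def stratify_by_depth(
    events: pd.DataFrame, meta: DepthMetadata, tree: Phylogeny
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach a habitat to each event and aggregate counts.

    Returns ``(events_with_habitat, summary)`` where the summary counts
    events per (character class when available, else character) x event
    type x habitat.
    """
    meta.validate_tips(tree.tip_labels)
    ev = events.copy()
    ev["habitat"] = [event_habitat(tree, int(c), meta) for c in ev["child"]] if len(ev) else []
    group_col = "char_class" if "char_class" in ev.columns else "character"
    if len(ev):
        summary = (
            ev.groupby([group_col, "event", "habitat"]).size().rename("count").reset_index()
        )
    else:
        summary = pd.DataFrame(columns=[group_col, "event", "habitat", "count"])
    return ev, summary


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class HomoplasyReport:
    """Per-character and aggregate homoplasy tallies.

    ``events`` holds every event qualifying at the MODERATE tier, with the
    event's own tier, habitat, and the tip set below the event edge;
    HIGH-tier counts are the subset with ``tier == "HIGH"``.
    ``coincident_edges`` flags edges where one character's loss coincides
    with another character's gain (candidate spicule replacements); no
    conclusion is drawn from it.
    """

    per_character: pd.DataFrame
    events: pd.DataFrame
    class_totals: pd.DataFrame
    coincident_edges: pd.DataFrame

    def summary_text(self) -> str:
        lines = ["Homoplasy report", "=" * 60]
        for _, r in self.per_character.iterrows():
            lines.append(
                f"{r['character']:<24s} class={r['char_class'] or '-':<12s} "
                f"rate={r['rate']:.4g} logL={r['logL']:.3f} "
                f"losses HIGH={r['losses_high']} (mod+ {r['losses_moderate']}) "
                f"gains HIGH={r['gains_high']} (mod+ {r['gains_moderate']}) "
                f"HIGH losses shallow/deep/mixed={r['losses_high_shallow']}/"
                f"{r['losses_high_deep']}/{r['losses_high_mixed']}"
            )
        lines.append("-" * 60)
        for _, r in self.class_totals.iterrows():
            lines.append(
                f"TOTAL {r['char_class'] or '-':<12s} "
                f"losses HIGH={r['losses_high']} gains HIGH={r['gains_high']} "
                f"HIGH losses shallow/deep/mixed={r['losses_high_shallow']}/"
                f"{r['losses_high_deep']}/{r['losses_high_mixed']}"
            )
        if len(self.coincident_edges):
            lines.append(f"{len(self.coincident_edges)} edge(s) with coincident loss+gain "
                         f"of different characters (possible spicule replacement)")
        return "\n".join(lines)

    def to_tsv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_character.to_csv(outdir / "per_character.tsv", sep="\t", index=False)
        self.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
        self.class_totals.to_csv(outdir / "class_totals.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(self.summary_text() + "\n", encoding="utf-8")


def homoplasy_report(
    recons: dict[str, AncestralReconstruction],
    meta: DepthMetadata,
    tree: Phylogeny,
    high: float = 0.95,
    moderate: float = 0.65,
) -> HomoplasyReport:
    """Count losses/gains for every reconstructed character and stratify by depth."""
    meta.validate_tips(tree.tip_labels)
    all_events = []
    rows = []
    for name, rec in recons.items():
        calls = call_states(rec, high=high, moderate=moderate)
        ev = count_events(calls, tree, character=name, tier=MODERATE)
        ev["char_class"] = rec.char_class
        ev, _ = stratify_by_depth(ev, meta, tree)
        ev["tips_below"] = [
            ";".join(sorted(tree.leafset_below(tree.node(int(c)))))
            if not tree.node(int(c)).is_leaf()
            else tree.tip_label(tree.node(int(c)))
            for c in ev["child"]
        ]
        all_events.append(ev)
        hi = ev[ev["tier"] == HIGH]
        root_p = rec.posteriors[tree.root.index]
        rows.append(
            {
                "character": name,
                "char_class": rec.char_class,
                "rate": rec.rate,
                "logL": rec.log_likelihood,
                "losses_high": int((hi["event"] == "loss").sum()),
                "losses_moderate": int((ev["event"] == "loss").sum()),
                "gains_high": int((hi["event"] == "gain").sum()),
                "gains_moderate": int((ev["event"] == "gain").sum()),
                "losses_high_shallow": int(((hi["event"] == "loss") & (hi["habitat"] == "shallow")).sum()),
                "losses_high_deep": int(((hi["event"] == "loss") & (hi["habitat"] == "deep")).sum()),
                "losses_high_mixed": int(((hi["event"] == "loss") & (hi["habitat"] == "mixed")).sum()),
                "root_state": int(np.argmax(root_p)),
                "root_posterior": float(np.max(root_p)),
            }
        )
    per_character = pd.DataFrame(rows)
    events = (
        pd.concat(all_events, ignore_index=True)
        if all_events
        else pd.DataFrame(
            columns=["character", "parent", "child", "event", "tier", "char_class",
                     "habitat", "tips_below"]
        )
    )
    agg_cols = ["losses_high", "losses_moderate", "gains_high", "gains_moderate",
                "losses_high_shallow", "losses_high_deep", "losses_high_mixed"]
    if len(per_character):
        class_totals = (
            per_character.fillna({"char_class": ""})
            .groupby("char_class", as_index=False)[agg_cols]
            .sum()
        )
    else:
        class_totals = pd.DataFrame(columns=["char_class"] + agg_cols)

    if len(events):
        losses = events[events["event"] == "loss"][["child", "character"]]
        gains = events[events["event"] == "gain"][["child", "character"]]
        merged = losses.merge(gains, on="child", suffixes=("_lost", "_gained"))
        coincident = merged[merged["character_lost"] != merged["character_gained"]]
    else:
        coincident = pd.DataFrame(columns=["child", "character_lost", "character_gained"])
    return HomoplasyReport(per_character, events, class_totals, coincident.reset_index(drop=True))
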