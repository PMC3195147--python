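"""Single-gain / multiple-loss ancestral reconstruction.

Each component is assumed to have been gained exactly once on the tree
(horizontal transfer between the sampled groups is taken to be negligible)
and subsequently lost independently on branches, never regained.  Under
that model the most parsimonious history places the gain at the most recent
common ancestor of all presence tips and reads losses off the maximal
absence-only subtrees inside the gain clade.

Ancestor-at-the-root ("LECA") classification comes in two modes:

* ``MRCA`` — present iff the gain lands on the root, i.e. presence spans
  both sides of the root bipartition;
* ``CONSERVATIVE`` — present iff at least ``k`` major lineages on *each*
  side of the root carry the component (default ``k=2``).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from leca_trace.formats import (
    EventReport,
    LecaStatus,
    LineageProfile,
    ReferenceTree,
    Side,
    TaxonMap,
    TreeNode,
    ValidationError,
)
from leca_trace.lineage_summary import binarize

Edge = tuple[str, str]


@dataclass(frozen=True)
class EventHistory:
    """Reconstructed history of one component on a reference tree.

    ``gain_node`` is ``None`` when the component is absent from every tip.
    ``node_states`` maps every node label to reconstructed presence.
    """

    component: str
    gain_node: str | None
    loss_edges: frozenset[Edge]
    node_states: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "loss_edges", frozenset(self.loss_edges))
        object.__setattr__(self, "node_states", dict(self.node_states))

    def gain_edge(self, tree: ReferenceTree) -> tuple[str | None, str] | None:
        """The edge above the gain node; ``(None, root)`` for a root gain."""
        if self.gain_node is None:
            return None
        node = tree.node(self.gain_node)
        return (node.parent.label if node.parent is not None else None, self.gain_node)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


@dataclass(frozen=True)
class LecaRule:
    """Root-presence criterion: mode plus the per-side lineage minimum."""

    mode: str = "MRCA"
    k: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("MRCA", "CONSERVATIVE"):
            raise ValidationError(f"unknown rule mode {self.mode!r}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")


def mrca(tree: ReferenceTree, tips: Iterable[str]) -> TreeNode:
    """Most recent common ancestor of a non-empty set of tips."""
    labels = list(tips)
    if not labels:
        raise ValidationError("mrca of an empty tip set is undefined")
    nodes = [tree.node(t) for t in labels]
    common: set[int] | None = None
    order: list[TreeNode] = []
    for node in nodes:
        path = node.ancestors(include_self=True)
        ids = {id(n) for n in path}
        if common is None:
            common = ids
            order = path  # nearest-first path of the first tip
        else:
            common &= ids
    assert common is not None
    for node in order:
        if id(node) in common:
            return node
    raise ValidationError("tips do not share an ancestor (disconnected tree?)")


def dollo_infer(
    tree: ReferenceTree, presence: Mapping[str, int], component: str = ""
) -> EventHistory:
    """Most parsimonious single-gain history explaining the tip presences.

    The gain is placed at the MRCA of the present tips; every node inside
    the gain clade with at least one present descendant tip is reconstructed
    PRESENT; losses are the edges subtending maximal all-absent subtrees
    inside the gain clade.
    """
    tip_set = set(tree.tip_labels)
    if set(presence) != tip_set:
        missing = tip_set - set(presence)
        extra = set(presence) - tip_set
        raise ValidationError(
            f"presence vector does not match tree tips "
            f"(missing={sorted(missing)}, extra={sorted(extra)})"
        )
    present_tips = [t for t in tree.tip_labels if presence[t]]
    if not present_tips:
        states = {n.label: False for n in tree.root.preorder()}
        return EventHistory(component, None, frozenset(), states)

    gain = mrca(tree, present_tips)

    has_present: dict[str, bool] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            has_present[node.label] = bool(presence[node.label])
        else:
            has_present[node.label] = any(has_present[c.label] for c in node.children)

    in_gain_clade: dict[str, bool] = {}
    for node in tree.root.preorder():
        if node is gain:
            in_gain_clade[node.label] = True
        elif node.parent is not None and in_gain_clade.get(node.parent.label, False):
            in_gain_clade[node.label] = True
        else:
            in_gain_clade[node.label] = False

    states = {
        n.label: in_gain_clade[n.label] and has_present[n.label]
        for n in tree.root.preorder()
    }
    losses = frozenset(
        (n.parent.label, n.label)
        for n in tree.root.preorder()
        if n.parent is not None
        and states[n.parent.label]
        and in_gain_clade[n.label]
        and not has_present[n.label]
    )
    return EventHistory(component, gain.label, losses, states)


def dollo_oracle(
    tree: ReferenceTree, presence: Mapping[str, int]
) -> tuple[int, frozenset[str]]:
    """Exhaustive check of the single-gain minimum (small trees only).

    Tries every candidate gain node ancestral to all present tips, counts
    the maximal all-absent subtrees below it, and returns the minimal loss
    count with the set of optimal gain labels.
    """
    present_tips = [t for t in tree.tip_labels if presence.get(t)]
    if not present_tips:
        return 0, frozenset()
    anchor = mrca(tree, present_tips)
    candidates = anchor.ancestors(include_self=True)

    def count_losses(node: TreeNode) -> int:
        sub_tips = {leaf.label for leaf in node.leaves()}
        if not sub_tips & set(present_tips):
            return 1  # whole subtree absent: one maximal loss
        if node.is_leaf:
            return 0
        return sum(count_losses(c) for c in node.children)

    scores = {cand.label: sum(count_losses(c) for c in cand.children) if not cand.is_leaf else 0
              for cand in candidates}
    best = min(scores.values())
    return best, frozenset(label for label, s in scores.items() if s == best)


def classify_leca(
    history: EventHistory,
    profile_presence: Mapping[str, int],
    taxa: TaxonMap,
    rule: LecaRule = LecaRule(),
) -> LecaStatus:
    """Classify a component's presence in the root ancestor.

    ``profile_presence`` maps each major lineage to 0/1 presence; the taxon
    map supplies each lineage's side of the root bipartition.
    """
    if history.gain_node is None or not any(profile_presence.values()):
        return LecaStatus.NO_DATA
    tallies = {Side.UNIKONT: 0, Side.BIKONT: 0}
    for lineage, present in profile_presence.items():
        if present:
            tallies[taxa.side_of_lineage(lineage)] += 1
    needed = 1 if rule.mode == "MRCA" else rule.k
    if tallies[Side.UNIKONT] >= needed and tallies[Side.BIKONT] >= needed:
        return LecaStatus.PRESENT
    return LecaStatus.ABSENT


def tentative_losses(
    history: EventHistory, tree: ReferenceTree, taxa: TaxonMap
) -> frozenset[Edge]:
    """Losses whose entire subtree consists of ongoing ('P') genomes.

    Such losses may reflect incomplete sequencing rather than true absence.
    """
    out = set()
    for parent, child in history.loss_edges:
        leaves = tree.node(child).leaves()
        if leaves and all(taxa.status_of(leaf.label) == "P" for leaf in leaves):
            out.add((parent, child))
    return frozenset(out)


def map_events(
    histories: Sequence[EventHistory],
    tree: ReferenceTree,
    taxa: TaxonMap | None = None,
) -> dict[tuple[str | None, str], dict[str, int]]:
    """Aggregate per-edge gain/loss tallies across component histories.

    The key ``(None, root)`` collects gains on the root itself.  When a
    taxon map is given, losses whose subtrees hold only status-P genomes
    are additionally counted as tentative.
    """
    labels = {n.label for n in tree.root.preorder()}
    counts: dict[tuple[str | None, str], dict[str, int]] = {}

    def bucket(edge: tuple[str | None, str]) -> dict[str, int]:
        return counts.setdefault(edge, {"gains": 0, "losses": 0, "tentative_losses": 0})

    for hist in histories:
        if set(hist.node_states) != labels:
            raise ValidationError(
                f"history for {hist.component!r} was built on a different tree"
            )
        if hist.gain_node is not None:
            bucket(hist.gain_edge(tree))["gains"] += 1
        tentative = tentative_losses(hist, tree, taxa) if taxa is not None else frozenset()
        for edge in hist.loss_edges:
            b = bucket(edge)
            b["losses"] += 1
            if edge in tentative:
                b["tentative_losses"] += 1
    return counts


def build_reports(
    profile: LineageProfile,
    tree: ReferenceTree,
    taxa: TaxonMap,
    rule: LecaRule = LecaRule(),
    inventory: Sequence[str] | None = None,
) -> tuple[list[EventReport], list[EventHistory]]:
    """Run the full per-component pipeline on a lineage-level profile.

    Components named in ``inventory`` but missing from the profile are
    reported ``NO_DATA`` with no events.  Returns the final reports plus
    the underlying histories (for event mapping).
    """
    matrix = binarize(profile)
    if set(matrix.taxa) != set(tree.tip_labels):
        raise ValidationError(
            "profile lineages do not match the tree tips: "
            f"profile={sorted(matrix.taxa)}, tree={sorted(tree.tip_labels)}"
        )
    reports: list[EventReport] = []
    histories: list[EventHistory] = []
    for comp in matrix.components:
        presence = matrix.presence_of(comp)
        hist = dollo_infer(tree, presence, component=comp)
        status = classify_leca(hist, presence, taxa, rule)
        reports.append(
            EventReport(
                component=comp,
                gain_edge=hist.gain_edge(tree),
                loss_edges=hist.loss_edges,
                leca_status=status,
                tentative_losses=tentative_losses(hist, tree, taxa),
            )
        )
        histories.append(hist)
    if inventory is not None:
        known = set(matrix.components)
        for comp in inventory:
            if comp not in known:
                reports.append(
                    EventReport(comp, None, frozenset(), LecaStatus.NO_DATA, frozenset())
                )
    return reports, histories


def leca_counts(reports: Iterable[EventReport]) -> dict[LecaStatus, int]:
    """Tally reports by LECA status."""
    out = {s: 0 for s in LecaStatus}
    for rep in reports:
        out[rep.leca_status] += 1
    return out
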