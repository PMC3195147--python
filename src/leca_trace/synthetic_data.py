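"""Simulator for single-gain / multiple-loss gene-content evolution.

Each component is gained once (at the root with probability ``p_root``,
otherwise on a uniformly chosen edge) and then lost along branches as a
Poisson process with rate ``loss_rate`` per unit branch length; a loss
removes the component from the entire subtree and it is never regained.
Status-P ("ongoing") genomes can additionally censor true presences,
modelling incomplete assemblies.

All randomness flows from the single ``seed`` in :class:`SimConfig`; the
same seed replays the same histories regardless of the censoring level
(censoring reuses a common uniform draw), so censoring sweeps are paired.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from leca_trace.ancestral import EventHistory
from leca_trace.formats import (
    PresenceMatrix,
    ReferenceTree,
    TaxonMap,
    ValidationError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    tree: ReferenceTree
    n_components: int
    seed: int
    p_root: float = 1.0
    loss_rate: float = 0.0
    censor_missing: float = 0.0
    default_branch_length: float = 1.0
    component_prefix: str = "comp"

    def __post_init__(self) -> None:
        if self.n_components < 0:
            raise ValidationError("n_components must be >= 0")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("p_root", "censor_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.loss_rate < 0:
            raise ValidationError(f"loss_rate must be >= 0, got {self.loss_rate}")


@dataclass(frozen=True)
class ComponentTruth:
    """Ground-truth events for one simulated component."""

    gain_edge: tuple[str | None, str]
    loss_edges: frozenset[tuple[str, str]]
    tip_presence: Mapping[str, int]  # pre-censoring

    def __post_init__(self) -> None:
        object.__setattr__(self, "loss_edges", frozenset(self.loss_edges))
        object.__setattr__(self, "tip_presence", dict(self.tip_presence))


@dataclass(frozen=True)
class SimTruth:
    tree: ReferenceTree
    components: Mapping[str, ComponentTruth] = field(default_factory=dict)

    def verify(self) -> None:
        """Check that tip presences are reproducible from the event sets."""
        for name, truth in self.components.items():
            gain_label = truth.gain_edge[1]
            gain = self.tree.node(gain_label)
            in_clade = {leaf.label for leaf in gain.leaves()}
            lost = set()
            for _, child in truth.loss_edges:
                lost |= {leaf.label for leaf in self.tree.node(child).leaves()}
            for tip in self.tree.tip_labels:
                expect = int(tip in in_clade and tip not in lost)
                if truth.tip_presence[tip] != expect:
                    raise ValidationError(
                        f"{name}: tip {tip!r} presence inconsistent with events"
                    )


def _edge_length(node, default: float) -> float:
    return node.length if node.length is not None else default


def simulate_content(
    cfg: SimConfig, taxa: TaxonMap | None = None
) -> tuple[PresenceMatrix, SimTruth]:
    """Draw a presence/absence matrix plus its ground-truth histories.

    Censoring applies only to genomes whose status in ``taxa`` is ``P``;
    with no taxon map (or no P genomes) the observed matrix equals the true
    tip presences.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree
    tips = tree.tip_labels
    nodes = list(tree.root.preorder())
    non_root = [n for n in nodes if n.parent is not None]
    names = [f"{cfg.component_prefix}{i:04d}" for i in range(cfg.n_components)]

    truths: dict[str, ComponentTruth] = {}
    true_presence = np.zeros((len(tips), cfg.n_components), dtype=np.int8)
    tip_index = {t: i for i, t in enumerate(tips)}

    for j, name in enumerate(names):
        if rng.random() < cfg.p_root:
            gain = tree.root
            gain_edge: tuple[str | None, str] = (None, tree.root.label)
        else:
            node = non_root[rng.integers(len(non_root))]
            gain = node
            gain_edge = (node.parent.label, node.label)

        # Raw loss events per edge strictly below the gain; nested events
        # collapse onto the rootmost lost edge (presence is binary).
        raw_lost: set[str] = set()
        stack = list(gain.children)
        while stack:
            node = stack.pop()
            n_events = rng.poisson(cfg.loss_rate * _edge_length(node, cfg.default_branch_length))
            if n_events > 0:
                raw_lost.add(node.label)
            stack.extend(node.children)
        loss_edges = set()
        for label in raw_lost:
            node = tree.node(label)
            if not any(a.label in raw_lost for a in node.ancestors()):
                loss_edges.add((node.parent.label, label))

        lost_tips: set[str] = set()
        for _, child in loss_edges:
            lost_tips |= {leaf.label for leaf in tree.node(child).leaves()}
        presence = {
            t: int(t in {leaf.label for leaf in gain.leaves()} and t not in lost_tips)
            for t in tips
        }
        for t, v in presence.items():
            true_presence[tip_index[t], j] = v
        truths[name] = ComponentTruth(gain_edge, frozenset(loss_edges), presence)

    # Common uniform draw so censor levels are paired under a fixed seed.
    censor_draw = rng.random(size=true_presence.shape)
    observed = true_presence.copy()
    if cfg.censor_missing > 0 and taxa is not None:
        for i, tip in enumerate(tips):
            if taxa.status_of(tip) == "P":
                hit = censor_draw[i, :] < cfg.censor_missing
                observed[i, hit] = 0

    matrix = PresenceMatrix(tuple(tips), tuple(names), observed)
    truth = SimTruth(tree, truths)
    truth.verify()
    return matrix, truth


def simulate_alignments(
    matrix: PresenceMatrix,
    lengths: Mapping[str, int] | int,
    seed: int,
) -> dict[str, dict[str, str]]:
    """Random-residue alignments matching a presence matrix's occupancy.

    Components present in no taxon are omitted.  These alignments carry no
    phylogenetic signal; they exist to exercise supermatrix assembly.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    for comp in matrix.components:
        length = lengths if isinstance(lengths, int) else lengths[comp]
        if length < 1:
            raise ValidationError(f"alignment length for {comp!r} must be >= 1")
        presence = matrix.presence_of(comp)
        taxa = [t for t in matrix.taxa if presence[t]]
        if not taxa:
            continue
        out[comp] = {
            t: "".join(AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=length))
            for t in taxa
        }
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Per-component comparison of inferred histories against the truth."""

    table: pd.DataFrame
    gain_recovery_rate: float
    mean_loss_diff: float


def recovery_report(truth: SimTruth, inferred: Sequence[EventHistory]) -> RecoveryReport:
    """Score inferred histories against simulated ground truth.

    ``loss_diff`` is inferred minus true loss count; with no censoring it is
    never positive (parsimony is a lower bound on the true event count).
    """
    by_name = {h.component: h for h in inferred}
    if set(by_name) != set(truth.components):
        raise ValidationError(
            "inferred histories do not match the simulated component set"
        )
    rows = []
    for name, t in truth.components.items():
        h = by_name[name]
        rows.append(
            {
                "component": name,
                "true_gain": t.gain_edge[1],
                "inferred_gain": h.gain_node,
                "gain_recovered": h.gain_node == t.gain_edge[1],
                "true_losses": len(t.loss_edges),
                "inferred_losses": len(h.loss_edges),
                "loss_diff": len(h.loss_edges) - len(t.loss_edges),
            }
        )
    table = pd.DataFrame(rows)
    return RecoveryReport(
        table=table,
        gain_recovery_rate=float(table["gain_recovered"].mean()) if rows else float("nan"),
        mean_loss_diff=float(table["loss_diff"].mean()) if rows else float("nan"),
    )
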