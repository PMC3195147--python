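"""Domain types and file formats.

Everything the pipeline reads or writes lives here: rooted Newick trees with
a declared root bipartition, binary presence/absence matrices, categorical
lineage profiles, taxon maps, and gain/loss event reports.  All writers are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml


class LecaTraceError(Exception):
    """Base class for all package errors."""


class ValidationError(LecaTraceError):
    """Raised when an input file or in-memory object violates its contract."""


class Side(str, Enum):
    """Which side of the root bipartition a lineage belongs to."""

    UNIKONT = "UNIKONT"
    BIKONT = "BIKONT"


class Category(str, Enum):
    """Categorical presence level of a component within one lineage."""

    ALL = "ALL"
    GEQ_HALF = "GEQ_HALF"
    LT_HALF = "LT_HALF"
    ABSENT = "ABSENT"


class LecaStatus(str, Enum):
    """Verdict on a component's presence in the ancestor at the root."""

    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    NO_DATA = "NO_DATA"


#: Genome sequencing statuses: complete, draft assembly, ongoing.
GENOME_STATUSES = frozenset({"C", "A", "P"})


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of a rooted (possibly multifurcating) tree."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str, length: float | None = None) -> None:
        self.label = label
        self.length = length
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []

    def add_child(self, child: TreeNode) -> TreeNode:
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def ancestors(self, include_self: bool = False) -> list[TreeNode]:
        """Path from this node to the root, nearest first."""
        out = [self] if include_self else []
        node = self.parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r})"


class ReferenceTree:
    """A rooted species/lineage tree with an optional root bipartition.

    Parameters
    ----------
    root:
        Root node of a fully labelled tree (every node carries a unique
        label; use :func:`parse_tree` to auto-label internal nodes).
    root_sides:
        Mapping from each root-child label to its :class:`Side`.  Required
        for LECA classification; may be ``None`` for purely topological use.
    """

    def __init__(self, root: TreeNode, root_sides: Mapping[str, Side] | None = None):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        for node in root.preorder():
            if node.label is None or node.label == "":
                raise ValidationError("every tree node must carry a label")
            if node.label in self._index:
                raise ValidationError(f"duplicate node label {node.label!r}")
            self._index[node.label] = node
        self.root_sides: dict[str, Side] | None = None
        if root_sides is not None:
            child_labels = {c.label for c in root.children}
            sides = {k: Side(v) for k, v in root_sides.items()}
            if set(sides) != child_labels:
                raise ValidationError(
                    "root_sides must cover exactly the root's children: "
                    f"expected {sorted(child_labels)}, got {sorted(sides)}"
                )
            self.root_sides = sides
        # tip -> side, resolved through the containing root-child subtree
        self._tip_side: dict[str, Side] = {}
        if self.root_sides is not None:
            for child in root.children:
                side = self.root_sides[child.label]
                for leaf in child.leaves():
                    self._tip_side[leaf.label] = side

    # -- basic queries ------------------------------------------------------

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise ValidationError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def tips(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def edges(self) -> list[tuple[str, str]]:
        """All (parent, child) label pairs, in preorder."""
        return [
            (n.parent.label, n.label) for n in self.root.preorder() if n.parent is not None
        ]

    def side_of_tip(self, tip_label: str) -> Side:
        if tip_label not in self._tip_side:
            raise ValidationError(f"tip {tip_label!r} has no root side (root_sides unset?)")
        return self._tip_side[tip_label]

    def total_length(self, default_length: float = 1.0) -> float:
        return sum(
            n.length if n.length is not None else default_length
            for n in self.root.preorder()
            if n.parent is not None
        )

    # -- serialization ------------------------------------------------------

    def to_newick(self, annotations: Mapping[str, Mapping[str, int]] | None = None) -> str:
        """Render as Newick; ``annotations`` adds NHX tags to named nodes."""

        def render(node: TreeNode) -> str:
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                s = f"({inner}){node.label}"
            else:
                s = node.label
            if node.length is not None:
                s += f":{node.length:g}"
            tags = (annotations or {}).get(node.label)
            if tags:
                body = ":".join(f"{k}={v}" for k, v in sorted(tags.items()))
                s += f"[&&NHX:{body}]"
            return s

        return render(self.root) + ";"


def _resolve_side_entry(tree_root: TreeNode, entry: str) -> str:
    """Resolve a sides-config entry (root-child label or any tip label)
    to the label of the root child whose subtree contains it."""
    for child in tree_root.children:
        if entry == child.label:
            return child.label
        if any(leaf.label == entry for leaf in child.leaves()):
            return child.label
    raise ValidationError(f"sides entry {entry!r} matches no root child subtree")


def parse_tree(newick: str, sides: Mapping[str, Sequence[str]] | None = None) -> ReferenceTree:
    """Parse a rooted Newick string into a :class:`ReferenceTree`.

    Unlabelled internal nodes are auto-labelled ``N<i>`` by preorder index,
    deterministically.  ``sides`` maps side names (``UNIKONT``/``BIKONT``)
    to lists of root-child labels (or representative tip labels).
    """
    if "[&U]" in newick.upper().replace(" ", ""):
        raise ValidationError("tree is declared unrooted ([&U]); a rooted tree is required")
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValidationError(f"could not parse Newick input: {exc}") from exc
    if dtree.seed_node is None or len(dtree.seed_node.child_nodes()) < 2:
        raise ValidationError("tree root must have at least two children")

    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            label = dnode.label
        node = TreeNode(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    for i, node in enumerate(root.preorder()):
        if not node.is_leaf and (node.label is None or node.label == ""):
            node.label = f"N{i}"
        if node.is_leaf and (node.label is None or node.label == ""):
            raise ValidationError("tree contains an unlabelled tip")

    root_sides: dict[str, Side] | None = None
    if sides is not None:
        root_sides = {}
        for side_name, entries in sides.items():
            side = Side(side_name)
            for entry in entries:
                child_label = _resolve_side_entry(root, entry)
                if child_label in root_sides and root_sides[child_label] != side:
                    raise ValidationError(
                        f"root child {child_label!r} assigned to both sides"
                    )
                root_sides[child_label] = side
    return ReferenceTree(root, root_sides)


def read_tree(path: str | Path, sides: Mapping[str, Sequence[str]] | None = None) -> ReferenceTree:
    return parse_tree(Path(path).read_text(encoding="utf-8"), sides=sides)


def write_tree(tree: ReferenceTree, path: str | Path | None = None) -> str:
    text = tree.to_newick() + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Presence matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary taxa x components matrix (1 = at least one orthologue found)."""

    taxa: tuple[str, ...]
    components: tuple[str, ...]
    values: np.ndarray  # shape (n_taxa, n_components), dtype int8

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.taxa), len(self.components)):
            raise ValidationError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.components)} components"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon in presence matrix")
        if len(set(self.components)) != len(self.components):
            raise ValidationError("duplicate component in presence matrix")
        if not np.isin(vals, (0, 1)).all():
            i, j = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at taxon {self.taxa[i]!r}, "
                f"component {self.components[j]!r}"
            )

    def presence_of(self, component: str) -> dict[str, int]:
        j = self.components.index(component)
        return {t: int(self.values[i, j]) for i, t in enumerate(self.taxa)}

    def select_components(self, names: Sequence[str]) -> "PresenceMatrix":
        idx = [self.components.index(n) for n in names]
        return PresenceMatrix(self.taxa, tuple(names), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.taxa), columns=list(self.components))


def read_matrix(path: str | Path) -> PresenceMatrix:
    """Read a tab-delimited binary presence matrix (first column = taxon)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty presence matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate taxon {dup!r}")
    values = np.empty(df.shape, dtype=np.int8)
    for i, taxon in enumerate(df.index):
        for j, comp in enumerate(df.columns):
            cell = str(df.iat[i, j]).strip()
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"{path}: non-binary cell {cell!r} at taxon {taxon!r}, "
                    f"component {comp!r}"
                )
            values[i, j] = int(cell)
    return PresenceMatrix(tuple(df.index), tuple(df.columns), values)


def write_matrix(matrix: PresenceMatrix, path: str | Path | None = None, index_name: str = "taxon") -> str:
    buf = io.StringIO()
    buf.write(index_name + "\t" + "\t".join(matrix.components) + "\n")
    for i, taxon in enumerate(matrix.taxa):
        buf.write(taxon + "\t" + "\t".join(str(int(v)) for v in matrix.values[i]) + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Categorical lineage profiles
# ---------------------------------------------------------------------------

#: Tokens as printed, normalised by stripping all whitespace and lowercasing.
_TOKEN_MAP = {
    "100": Category.ALL,
    "≥50": Category.GEQ_HALF,
    ">=50": Category.GEQ_HALF,
    ">50": Category.GEQ_HALF,
    "half": Category.GEQ_HALF,
    "50": Category.GEQ_HALF,
    "<50": Category.LT_HALF,
    "": Category.ABSENT,
}

_CANONICAL_TOKEN = {
    Category.ALL: "100",
    Category.GEQ_HALF: ">=50",
    Category.LT_HALF: "<50",
    Category.ABSENT: "",
}


def normalize_token(token: str) -> Category:
    """Map one printed profile cell to its :class:`Category`.

    Accepts the full printed dialect: ``100``, ``≥50``/``>=50``/``>50``,
    ``< 50``/``<50``, ``Half``, ``50`` and blank; whitespace-insensitive.
    """
    key = "".join(str(token).split()).lower()
    try:
        return _TOKEN_MAP[key]
    except KeyError:
        raise ValidationError(f"unknown profile token {token!r}") from None


@dataclass(frozen=True)
class LineageProfile:
    """Categorical lineage x component presence profile."""

    lineages: tuple[str, ...]
    components: tuple[str, ...]
    cells: tuple[tuple[Category, ...], ...]  # row-major, one row per lineage

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineages", tuple(self.lineages))
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "cells", tuple(tuple(r) for r in self.cells))
        if len(set(self.lineages)) != len(self.lineages):
            raise ValidationError("duplicate lineage in profile")
        if len(set(self.components)) != len(self.components):
            raise ValidationError("duplicate component in profile")
        if len(self.cells) != len(self.lineages) or any(
            len(r) != len(self.components) for r in self.cells
        ):
            raise ValidationError("profile is not rectangular")
        for row in self.cells:
            for c in row:
                if not isinstance(c, Category):
                    raise ValidationError(f"profile cell {c!r} is not a Category")

    def cell(self, lineage: str, component: str) -> Category:
        return self.cells[self.lineages.index(lineage)][self.components.index(component)]

    def column(self, component: str) -> dict[str, Category]:
        j = self.components.index(component)
        return {lin: self.cells[i][j] for i, lin in enumerate(self.lineages)}

    def select_components(self, names: Sequence[str]) -> "LineageProfile":
        idx = [self.components.index(n) for n in names]
        return LineageProfile(
            self.lineages,
            tuple(names),
            tuple(tuple(row[j] for j in idx) for row in self.cells),
        )


def read_profile(path: str | Path) -> LineageProfile:
    """Read a tab-delimited categorical profile (first column = lineage)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty profile")
    rows: list[tuple[Category, ...]] = []
    for i, lineage in enumerate(df.index):
        row = []
        for j, comp in enumerate(df.columns):
            try:
                row.append(normalize_token(df.iat[i, j]))
            except ValidationError as exc:
                raise ValidationError(
                    f"{path}: {exc} at lineage {lineage!r}, component {comp!r}"
                ) from None
        rows.append(tuple(row))
    return LineageProfile(tuple(df.index), tuple(df.columns), tuple(rows))


def write_profile(profile: LineageProfile, path: str | Path | None = None, index_name: str = "lineage") -> str:
    buf = io.StringIO()
    buf.write(index_name + "\t" + "\t".join(profile.components) + "\n")
    for lineage, row in zip(profile.lineages, profile.cells):
        buf.write(lineage + "\t" + "\t".join(_CANONICAL_TOKEN[c] for c in row) + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Taxon map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonMap:
    """Species -> lineage -> root-side bookkeeping, plus genome statuses."""

    species_lineage: Mapping[str, str] = field(default_factory=dict)
    lineage_side: Mapping[str, Side] = field(default_factory=dict)
    genome_status: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_lineage", dict(self.species_lineage))
        object.__setattr__(
            self, "lineage_side", {k: Side(v) for k, v in self.lineage_side.items()}
        )
        statuses = dict(self.genome_status)
        for sp, st in statuses.items():
            if st not in GENOME_STATUSES:
                raise ValidationError(
                    f"genome status for {sp!r} must be one of C/A/P, got {st!r}"
                )
        object.__setattr__(self, "genome_status", statuses)

    def lineage_of(self, species: str) -> str:
        try:
            return self.species_lineage[species]
        except KeyError:
            raise ValidationError(f"species {species!r} has no lineage mapping") from None

    def side_of_lineage(self, lineage: str) -> Side:
        try:
            return self.lineage_side[lineage]
        except KeyError:
            raise ValidationError(f"lineage {lineage!r} has no root side") from None

    def status_of(self, species: str, default: str = "C") -> str:
        return self.genome_status.get(species, default)


def read_taxon_map(path: str | Path) -> TaxonMap:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: taxon map must be a mapping")
    return TaxonMap(
        species_lineage=raw.get("species_lineage", {}) or {},
        lineage_side=raw.get("lineage_side", {}) or {},
        genome_status=raw.get("genome_status", {}) or {},
    )


def write_taxon_map(taxa: TaxonMap, path: str | Path | None = None) -> str:
    doc = {
        "species_lineage": dict(sorted(taxa.species_lineage.items())),
        "lineage_side": {k: v.value for k, v in sorted(taxa.lineage_side.items())},
        "genome_status": dict(sorted(taxa.genome_status.items())),
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Event reports
# ---------------------------------------------------------------------------

#: Pseudo-parent label marking a gain on the root itself.
ROOT_PARENT = None


@dataclass(frozen=True)
class EventReport:
    """Final per-component verdict: gain edge, losses, LECA status."""

    component: str
    gain_edge: tuple[str | None, str] | None
    loss_edges: frozenset[tuple[str, str]]
    leca_status: LecaStatus
    tentative_losses: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "loss_edges", frozenset(self.loss_edges))
        object.__setattr__(self, "tentative_losses", frozenset(self.tentative_losses))
        if not self.tentative_losses <= self.loss_edges:
            raise ValidationError(
                f"{self.component}: tentative losses must be a subset of losses"
            )


def _format_edge(edge: tuple[str | None, str] | None) -> str:
    if edge is None:
        return "NONE"
    parent, child = edge
    if parent is ROOT_PARENT:
        return "ROOT"
    return f"{parent}->{child}"


def write_report(
    reports: Iterable[EventReport],
    tree: ReferenceTree,
    tsv_path: str | Path | None = None,
    newick_path: str | Path | None = None,
) -> tuple[str, str]:
    """Render event reports as a sorted TSV and an NHX-annotated Newick.

    Returns ``(tsv_text, newick_text)``; both are deterministic for a given
    input set regardless of report ordering.
    """
    reports = sorted(reports, key=lambda r: r.component)
    tree_edges = set(tree.edges())

    def check_edge(comp: str, edge: tuple[str | None, str]) -> None:
        if edge[0] is ROOT_PARENT:
            if edge[1] != tree.root.label:
                raise ValidationError(f"{comp}: root gain names {edge[1]!r}, not the root")
        elif edge not in tree_edges:
            raise ValidationError(f"{comp}: edge {edge!r} not in tree")

    buf = io.StringIO()
    buf.write("component\tleca_status\tgain_edge\tn_losses\tloss_edges\ttentative_losses\n")
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    tentative: dict[str, int] = {}
    for rep in reports:
        if rep.gain_edge is not None:
            check_edge(rep.component, rep.gain_edge)
            gains[rep.gain_edge[1]] = gains.get(rep.gain_edge[1], 0) + 1
        for edge in rep.loss_edges:
            check_edge(rep.component, edge)
            losses[edge[1]] = losses.get(edge[1], 0) + 1
        for edge in rep.tentative_losses:
            tentative[edge[1]] = tentative.get(edge[1], 0) + 1
        loss_str = ",".join(sorted(_format_edge(e) for e in rep.loss_edges))
        tent_str = ",".join(sorted(_format_edge(e) for e in rep.tentative_losses))
        buf.write(
            f"{rep.component}\t{rep.leca_status.value}\t{_format_edge(rep.gain_edge)}"
            f"\t{len(rep.loss_edges)}\t{loss_str}\t{tent_str}\n"
        )
    tsv_text = buf.getvalue()

    annotations: dict[str, dict[str, int]] = {}
    for label in set(gains) | set(losses) | set(tentative):
        tags: dict[str, int] = {}
        if gains.get(label):
            tags["gains"] = gains[label]
        if losses.get(label):
            tags["losses"] = losses[label]
        if tentative.get(label):
            tags["tentative"] = tentative[label]
        annotations[label] = tags
    newick_text = tree.to_newick(annotations) + "\n"

    if tsv_path is not None:
        Path(tsv_path).write_text(tsv_text, encoding="utf-8")
    if newick_path is not None:
        Path(newick_path).write_text(newick_text, encoding="utf-8")
    return tsv_text, newick_text
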