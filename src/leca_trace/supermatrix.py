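"""Partitioned supermatrix assembly and taxon-occupancy filtering.

Per-component FASTA alignments are concatenated over the union of their
taxa; a taxon absent from a component contributes a block of ``?`` for that
partition.  Missing-data fractions count whole-partition absence (a taxon's
share of columns in partitions where it has no sequence), which is the
quantity the occupancy filter thresholds; gap-inclusive accounting is
available as an option.
"""

from __future__ import annotations

import io
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from leca_trace.formats import ValidationError

MISSING_CHAR = "?"


@dataclass(frozen=True)
class Partition:
    """One component's column span, 1-based inclusive."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Supermatrix:
    taxa: tuple[str, ...]
    partitions: tuple[Partition, ...]
    rows: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "partitions", tuple(self.partitions))
        object.__setattr__(self, "rows", dict(self.rows))
        if set(self.rows) != set(self.taxa):
            raise ValidationError("supermatrix rows do not match taxa")
        total = self.total_length
        pos = 1
        for part in self.partitions:
            if part.start != pos or part.end < part.start:
                raise ValidationError(f"partition {part.name!r} does not tile the matrix")
            pos = part.end + 1
        if pos != total + 1:
            raise ValidationError("partitions do not span the full alignment")
        for taxon, row in self.rows.items():
            if len(row) != total:
                raise ValidationError(
                    f"row for {taxon!r} has length {len(row)}, expected {total}"
                )

    @property
    def total_length(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    def block(self, taxon: str, partition: Partition) -> str:
        return self.rows[taxon][partition.start - 1 : partition.end]

    def has_sequence(self, taxon: str, partition: Partition) -> bool:
        """True unless the taxon's block for this partition is all missing."""
        return any(ch != MISSING_CHAR for ch in self.block(taxon, partition))


@dataclass(frozen=True)
class OccupancyReport:
    missing_fraction: Mapping[str, float]
    partition_taxa: Mapping[str, int]


def _normalize_label(label: str) -> str:
    return " ".join(label.split())


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read one rectangular FASTA alignment into an ordered taxon->row map."""
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        label = _normalize_label(record.description or record.id)
        if label in rows:
            raise ValidationError(f"{path}: duplicate taxon {label!r}")
        rows[label] = str(record.seq)
    if not rows:
        raise ValidationError(f"{path}: empty alignment")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValidationError(f"{path}: ragged alignment (row lengths {sorted(lengths)})")
    return rows


def concatenate(alignments: Mapping[str, Mapping[str, str]]) -> Supermatrix:
    """Concatenate component alignments into one supermatrix.

    ``alignments`` maps component name to a taxon->row mapping; partition
    order follows the mapping order, taxon order is first appearance.
    """
    if not alignments:
        raise ValidationError("no alignments to concatenate")
    taxa: list[str] = []
    lengths: dict[str, int] = {}
    for name, aln in alignments.items():
        if not aln:
            raise ValidationError(f"alignment {name!r} is empty")
        row_lengths = {len(s) for s in aln.values()}
        if len(row_lengths) != 1:
            raise ValidationError(
                f"alignment {name!r} is ragged (row lengths {sorted(row_lengths)})"
            )
        lengths[name] = row_lengths.pop()
        for taxon in aln:
            label = _normalize_label(taxon)
            if label not in taxa:
                taxa.append(label)

    partitions: list[Partition] = []
    pos = 1
    for name in alignments:
        partitions.append(Partition(name, pos, pos + lengths[name] - 1))
        pos += lengths[name]

    rows = {t: [] for t in taxa}
    for name, aln in alignments.items():
        normalized = {_normalize_label(t): s for t, s in aln.items()}
        filler = MISSING_CHAR * lengths[name]
        for taxon in taxa:
            rows[taxon].append(normalized.get(taxon, filler))
    return Supermatrix(
        tuple(taxa), tuple(partitions), {t: "".join(parts) for t, parts in rows.items()}
    )


def occupancy(sm: Supermatrix, count_gaps: bool = False) -> OccupancyReport:
    """Per-taxon missing fraction and per-partition taxon counts.

    With ``count_gaps`` the fraction counts every ``?``/``-`` character;
    by default only whole-partition absence counts as missing.
    """
    total = sm.total_length
    fractions: dict[str, float] = {}
    part_counts = {p.name: 0 for p in sm.partitions}
    for taxon in sm.taxa:
        if count_gaps:
            row = sm.rows[taxon]
            missing = sum(1 for ch in row if ch in (MISSING_CHAR, "-"))
        else:
            missing = sum(
                p.length for p in sm.partitions if not sm.has_sequence(taxon, p)
            )
        fractions[taxon] = missing / total if total else 0.0
    for part in sm.partitions:
        part_counts[part.name] = sum(1 for t in sm.taxa if sm.has_sequence(t, part))
    return OccupancyReport(fractions, part_counts)


def filter_taxa(
    sm: Supermatrix,
    max_missing: float = 0.60,
    exclude: Sequence[str] = (),
    count_gaps: bool = False,
) -> Supermatrix:
    """Drop taxa whose missing fraction exceeds ``max_missing`` (plus any
    named exclusions); partitions are left untouched."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValidationError(f"max_missing must lie in [0, 1], got {max_missing}")
    report = occupancy(sm, count_gaps=count_gaps)
    excluded = {_normalize_label(t) for t in exclude}
    keep = [
        t
        for t in sm.taxa
        if report.missing_fraction[t] <= max_missing and t not in excluded
    ]
    if not keep:
        detail = ", ".join(f"{t}={report.missing_fraction[t]:.3f}" for t in sm.taxa)
        raise ValidationError(f"occupancy filter removed every taxon ({detail})")
    return Supermatrix(tuple(keep), sm.partitions, {t: sm.rows[t] for t in keep})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_supermatrix_fasta(sm: Supermatrix, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    for taxon in sm.taxa:
        buf.write(f">{taxon}\n{sm.rows[taxon]}\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_partitions(sm: Supermatrix, path: str | Path | None = None) -> str:
    """RAxML-style partition table: ``PROT, name = start-end``."""
    text = "".join(f"PROT, {p.name} = {p.start}-{p.end}\n" for p in sm.partitions)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_nexus_sets(sm: Supermatrix, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    buf.write("#NEXUS\nbegin sets;\n")
    for p in sm.partitions:
        buf.write(f"    charset {p.name} = {p.start}-{p.end};\n")
    buf.write("end;\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_occupancy(report: OccupancyReport, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    buf.write("taxon\tmissing_fraction\n")
    for taxon, frac in report.missing_fraction.items():
        buf.write(f"{taxon}\t{frac:.6f}\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_supermatrix(fasta_path: str | Path, partition_path: str | Path) -> Supermatrix:
    rows = read_fasta_alignment(fasta_path)
    partitions: list[Partition] = []
    for line in Path(partition_path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            start, end = span.split("-")
            partitions.append(Partition(name.strip(), int(start), int(end)))
        except ValueError:
            raise ValidationError(f"{partition_path}: malformed partition line {line!r}") from None
    return Supermatrix(tuple(rows), tuple(partitions), rows)
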