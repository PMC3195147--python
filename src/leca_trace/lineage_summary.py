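"""Collapse species-level presence matrices into lineage-level categories.

The categorical scheme mirrors the published summary tables: a component is
``ALL`` when found in every sampled species of a lineage, ``GEQ_HALF`` at a
presence fraction in [0.5, 1), ``LT_HALF`` in (0, 0.5), and ``ABSENT`` at 0.
"""

from __future__ import annotations

import numpy as np

from leca_trace.formats import (
    Category,
    LineageProfile,
    PresenceMatrix,
    TaxonMap,
    ValidationError,
)


def category_for_fraction(present: int, sampled: int) -> Category:
    """Apply the summary thresholds to ``present`` of ``sampled`` species."""
    if sampled <= 0:
        raise ValidationError("lineage with zero sampled species has no category")
    if not 0 <= present <= sampled:
        raise ValidationError(f"present count {present} outside [0, {sampled}]")
    if present == 0:
        return Category.ABSENT
    if present == sampled:
        return Category.ALL
    if 2 * present >= sampled:  # f >= 0.5, exact in integers
        return Category.GEQ_HALF
    return Category.LT_HALF


def summarize(matrix: PresenceMatrix, taxa: TaxonMap) -> LineageProfile:
    """Collapse a species x component matrix into a lineage profile.

    Lineages appear in order of first occurrence among the matrix taxa;
    lineages with no sampled species are omitted.  Unmapped taxa are an
    error.
    """
    lineage_rows: dict[str, list[int]] = {}
    for i, species in enumerate(matrix.taxa):
        lineage = taxa.lineage_of(species)
        lineage_rows.setdefault(lineage, []).append(i)
    cells = []
    for lineage, rows in lineage_rows.items():
        block = matrix.values[rows, :]
        n = len(rows)
        cells.append(
            tuple(category_for_fraction(int(block[:, j].sum()), n) for j in range(block.shape[1]))
        )
    return LineageProfile(tuple(lineage_rows), matrix.components, tuple(cells))


def binarize(profile: LineageProfile) -> PresenceMatrix:
    """Collapse categories to presence: any printed category counts as 1.

    Even a below-half fraction attests that at least one genome of the
    lineage carries the component, which is what ancestral inference needs.
    """
    values = np.array(
        [[0 if c is Category.ABSENT else 1 for c in row] for row in profile.cells],
        dtype=np.int8,
    )
    return PresenceMatrix(profile.lineages, profile.components, values)
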