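"""Loaders for the packaged lineage-level fixtures.

The fixtures transcribe the published lineage-by-component presence
categories onto the packaged 15-lineage reference tree rooted between the
unikont and bikont clades.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from leca_trace.formats import (
    LineageProfile,
    ReferenceTree,
    Side,
    TaxonMap,
    read_profile,
    read_taxon_map,
    read_tree,
)

#: Component groupings used in the published summary tables.
APC_SUBUNITS = (
    "Apc10", "Apc11", "Apc2", "Apc1", "Apc4", "Apc5", "Apc8", "Apc6",
    "Apc3", "Apc7", "Apc12", "Apc13", "Apc16", "Apc9", "Apc15", "Apc14",
)
ADAPTORS = ("Cdc20", "Cdh1", "Ama1", "Rap", "Cortex")
COHESIN = (
    "Smc1", "Smc3", "Scc1", "Scc3", "Scc2", "Scc4", "Eco1", "Pds5", "Wpl1/Rad61",
)
TARGETS = COHESIN + ("Separase", "Securin")
UNPROFILED = ("Mfr1", "CyclinA", "CyclinB", "Cdk1", "Cdk2")


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(str(resources.files("leca_trace") / "data" / name))


def load_taxon_map() -> TaxonMap:
    return read_taxon_map(fixture_path("taxon_map.yaml"))


def sides_config(taxa: TaxonMap) -> dict[str, list[str]]:
    """Build a read_tree ``sides`` config from a taxon map's lineage sides."""
    out: dict[str, list[str]] = {Side.UNIKONT.value: [], Side.BIKONT.value: []}
    for lineage, side in sorted(taxa.lineage_side.items()):
        out[side.value].append(lineage)
    return out


def load_reference_tree(taxa: TaxonMap | None = None) -> ReferenceTree:
    taxa = taxa if taxa is not None else load_taxon_map()
    return read_tree(fixture_path("fig2.nwk"), sides=sides_config(taxa))


def load_table1_profile() -> LineageProfile:
    """21 components (16 subunits + 5 adaptors) x 15 lineages."""
    return read_profile(fixture_path("table1_lineage.tsv"))


def load_table2_profile() -> LineageProfile:
    """11 target components (9 cohesin + separase + securin) x 15 lineages."""
    return read_profile(fixture_path("table2_lineage.tsv"))


def load_inventory() -> list[str]:
    """The full 37-component inventory, in file order."""
    lines = fixture_path("inventory.txt").read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def load_combined_profile() -> LineageProfile:
    """Tables 1 and 2 merged into one 32-component profile."""
    p1, p2 = load_table1_profile(), load_table2_profile()
    if p1.lineages != p2.lineages:
        raise ValueError("fixture profiles disagree on lineage set/order")
    return LineageProfile(
        p1.lineages,
        p1.components + p2.components,
        tuple(r1 + r2 for r1, r2 in zip(p1.cells, p2.cells)),
    )
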