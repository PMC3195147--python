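# leca-trace

Ancestral gene-content reconstruction on a rooted eukaryote reference tree.

Given a binary presence/absence matrix of gene-complex components across
genomes (or a lineage-level categorical profile), a rooted species/lineage
tree, and a taxon map declaring each lineage's side of the root bipartition,
`leca-trace`:

- collapses species-level matrices into lineage-level categorical profiles
  (`ALL` / `GEQ_HALF` / `LT_HALF` / `ABSENT`);
- infers each component's history under single-gain/multiple-loss (Dollo)
  parsimony: the gain node is the MRCA of all presence tips, losses are the
  maximal absence-only subtrees inside the gain clade;
- classifies each component's presence in the root ancestor under two rules
  (`MRCA`: presence spans both root sides; `CONSERVATIVE`: at least *k*
  lineages on each side, default k=2) and aggregates gains/losses per branch;
- builds partitioned supermatrices from per-component FASTA alignments,
  reports per-taxon missing-data fractions, and filters taxa above a
  missing-data threshold (default 60%);
- simulates the assumed generative process (one gain, Poisson losses along
  branches, optional censoring of incomplete genomes) with ground truth, to
  validate the inference end to end.

Packaged fixtures (`src/leca_trace/data/`) provide a 15-lineage reference
tree rooted between the unikont and bikont clades, two transcribed
lineage-level component profiles (21 + 11 components), a taxon map, and the
full 37-component inventory. Running inference on them with defaults
reproduces the headline result: 24 of 37 components present at the root.

## CLI

```sh
# lineage summary from a species-level binary matrix
leca-trace summarize --matrix species.tsv --taxon-map map.yaml --out-dir out/

# gain/loss inference + LECA inventory on the packaged fixtures
python - <<'EOF'
from leca_trace.fixtures import fixture_path
print(fixture_path("fig2.nwk"))
EOF
leca-trace infer --tree <fig2.nwk> --profile <profile.tsv> \
    --taxon-map <taxon_map.yaml> --inventory <inventory.txt> \
    --mode MRCA --out-dir out/
# -> out/events.tsv, out/annotated.nwk (NHX gain/loss tags), out/edge_events.tsv

# supermatrix assembly + occupancy filter
leca-trace concat --alignments alns/ --max-missing 0.60 --out-dir out/

# simulation with ground truth
leca-trace simulate --tree tree.nwk --n-components 100 --seed 1 \
    --p-root 0.5 --loss-rate 0.3 --out-dir out/
```

Exit codes: 0 success, 2 validation error, 1 internal error. All outputs are
deterministic; reruns are byte-identical. Existing outputs are never
overwritten without `--force`.

## Layout

| Module | Role |
| --- | --- |
| `leca_trace.formats` | trees, matrices, profiles, taxon maps, event reports; all I/O |
| `leca_trace.lineage_summary` | species→lineage categorical collapse, binarization |
| `leca_trace.ancestral` | Dollo inference, exhaustive oracle, LECA rules, event mapping |
| `leca_trace.supermatrix` | concatenation, occupancy, missing-data filter |
| `leca_trace.synthetic_data` | seeded gain/loss simulator + recovery scoring |
| `leca_trace.cli` | `leca-trace summarize\|infer\|concat\|simulate` |
| `leca_trace.fixtures` | loaders for the packaged reference data |
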