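# Lineage-level taxon map for the packaged reference tree.  At this
# granularity each "species" is a major lineage, so the species -> lineage
# mapping is the identity.  Genome statuses are species-level information
# that is not available at lineage resolution, so none are declared here
# (absent statuses default to "C", i.e. losses are not flagged tentative).
species_lineage:
  Capsaspora: Capsaspora
  Choanoflagellata: Choanoflagellata
  Metazoa: Metazoa
  Dikarya: Dikarya
  Chytridiomycota: Chytridiomycota
  Microsporidia: Microsporidia
  Apusozoa: Apusozoa
  Amoebozoa: Amoebozoa
  Excavata: Excavata
  Apicomplexa: Apicomplexa
  Ciliata: Ciliata
  Heterokonta: Heterokonta
  Haptophyta: Haptophyta
  Viridiplantae: Viridiplantae
  Rhodophyta: Rhodophyta
lineage_side:
  Capsaspora: UNIKONT
  Choanoflagellata: UNIKONT
  Metazoa: UNIKONT
  Dikarya: UNIKONT
  Chytridiomycota: UNIKONT
  Microsporidia: UNIKONT
  Apusozoa: UNIKONT
  Amoebozoa: UNIKONT
  Excavata: BIKONT
  Apicomplexa: BIKONT
  Ciliata: BIKONT
  Heterokonta: BIKONT
  Haptophyta: BIKONT
  Viridiplantae: BIKONT
  Rhodophyta: BIKONT
genome_status: {}
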