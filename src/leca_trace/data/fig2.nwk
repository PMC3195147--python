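((((Capsaspora,Choanoflagellata,Metazoa)Holozoa,(Dikarya,Chytridiomycota,Microsporidia)Fungi)Opisthokonta,Apusozoa,Amoebozoa)Unikonta,(Excavata,(((Viridiplantae,Rhodophyta)Plantae,Haptophyta),Heterokonta,(Apicomplexa,Ciliata)Alveolata))Bikonta)LECA;
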