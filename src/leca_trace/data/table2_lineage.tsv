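lineage	Smc1	Smc3	Scc1	Scc3	Scc2	Scc4	Eco1	Pds5	Wpl1/Rad61	Separase	Securin
Choanoflagellata	100	100	100	100	100		Half	100	Half	100
Metazoa	>50	>50	>50	100	100	100	100	100	100	>50	< 50
Capsaspora	100	100	100	100	100	100	100	100	100	100
Dikarya	100	100	100	100	100	>50	>50	100	100	100	< 50
Microsporidia	>50	>50		>50						>50
Chytridiomycota	100	100	100	100	100	50	100	100	100	100
Apusozoa	100	100	100	100	100		100			100
Amoebozoa	100	100	100	>50	>50		>50	>50		100
Excavata	100	100	>50	>50	< 50		>50	>50		100
Ciliata	100	< 50	< 50							>50
Apicomplexa	100	>50	< 50	>50						>50
Heterokonta	100	>50	>50	>50	>50		>50	>50		>50
Viridiplantae	100	100	100	100	>50	>50	>50	100	>50	>50
Rhodophyta	100	100	100	100	>50		100	>50		100
Haptophyta	100	100	100	100	100		100	100		100
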