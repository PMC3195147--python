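lineage	Apc10	Apc11	Apc2	Apc1	Apc4	Apc5	Apc8	Apc6	Apc3	Apc7	Apc12	Apc13	Apc16	Apc9	Apc15	Apc14	Cdc20	Cdh1	Ama1	Rap	Cortex
Choanoflagellata	100		100	100	≥50		100	100	100	≥50							100	100
Metazoa	100	100	100	100	100	100	100	100	100	100	≥50	≥50	< 50				100	100		< 50	< 50
Capsaspora	100	100	100	100	100	100	100		100	100							100	100
Dikarya	100	100	100	100	100	100	100	100	100		≥50	≥50		< 50	< 50	< 50	100	100	≥50
Microsporidia	100	< 50		100			≥50	100	100								100	100
Chytridiomycota	≥50	100	100	100	≥50	≥50	100	100	100	100							100	100
Apusozoa	100	100	100	100	100	100	100	100	100								100	100
Amoebozoa	100	100	≥50	100	≥50	≥50	≥50	≥50	≥50	≥50	≥50	≥50					≥50	100
Excavata	≥50	≥50	≥50	≥50			≥50	≥50	≥50	< 50							≥50	< 50
Ciliata	100	100	100	100	100		100	100	100								≥50	100
Apicomplexa	≥50	≥50		< 50			< 50	< 50	< 50	≥50								≥50
Heterokonta	100	≥50	≥50	50	< 50	≥50	100	≥50	≥50	≥50	≥50	≥50					100	≥50
Viridiplantae	100	100	100	100	100	≥50	100	100	100	≥50	< 50	≥50					100	≥50
Rhodophyta	100	100	100	100			100	100	100								100	100
Haptophyta	100	100	100	100	100		100	100	100								100	100
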