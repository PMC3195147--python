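# Full 37-component inventory.  Components listed here but missing from a
# profile are reported NO_DATA by the inference stage.
Apc10
Apc11
Apc2
Apc1
Apc4
Apc5
Apc8
Apc6
Apc3
Apc7
Apc12
Apc13
Apc16
Apc9
Apc15
Apc14
Cdc20
Cdh1
Ama1
Rap
Cortex
Smc1
Smc3
Scc1
Scc3
Scc2
Scc4
Eco1
Pds5
Wpl1/Rad61
Separase
Securin
Mfr1
CyclinA
CyclinB
Cdk1
Cdk2
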