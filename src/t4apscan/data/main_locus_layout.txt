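# Main T4aP locus gene order (transcription order, pilB-proximal end first).
# One slot per line; pilS*/pilR* slots belong to the combined two-component
# family pilRS and are resolved positionally into pilR1S1/pilR2S2 pairs.
# Edit this file to change the planted locus architecture.
pilB
pilT
pilC
pilA
pilS1
pilR1
pilS2
pilR2
pilG
pilH
pilI
tsaP
pilM
pilN
pilO
pilP
pilQ
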