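# 18-node sub-network of the T-LGL survival signaling model: the nodes
# whose state does not stabilize under logical steady state analysis of
# the full 60-node network with its six inputs clamped (stimulation, IL15
# and PDGF ON; secondary stimuli, CD45 and TAX OFF).  Rules are the full
# model's rules with the stabilized node values substituted; the
# "AND NOT Apoptosis" death clauses are retained.
# Top component: receptor negative-feedback oscillator.
CTLA4* = TCR AND NOT Apoptosis
TCR* = NOT (CTLA4 OR Apoptosis)
# Bottom component: apoptotic switch.
S1P* = NOT (Ceramide OR Apoptosis)
sFas* = S1P AND NOT Apoptosis
Fas* = NOT (sFas OR Apoptosis)
Ceramide* = Fas AND NOT (S1P OR Apoptosis)
DISC* = (Ceramide OR (Fas AND NOT FLIP)) AND NOT Apoptosis
Caspase* = ((BID AND NOT IAP) OR DISC) AND NOT Apoptosis
FLIP* = NOT (DISC OR Apoptosis)
BID* = NOT (MCL1 OR Apoptosis)
IAP* = NOT (BID OR Apoptosis)
MCL1* = NOT (DISC OR Apoptosis)
GPCR* = S1P AND NOT Apoptosis
SMAD* = GPCR AND NOT Apoptosis
CREB* = IFNG AND NOT Apoptosis
IFNG* = NOT (SMAD OR P2 OR Apoptosis)
P2* = (IFNG OR P2) AND NOT Apoptosis
Apoptosis* = Caspase OR Apoptosis
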