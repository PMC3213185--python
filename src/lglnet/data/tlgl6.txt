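# 6-node apoptotic core of the T-LGL survival signaling network.
# Obtained from the 18-node sub-network by separating the TCR/CTLA4
# oscillator and merging simple mediator nodes.  Node order defines the
# bit order of printed states (leftmost digit = S1P).
S1P* = NOT (Ceramide OR Apoptosis)
FLIP* = NOT (DISC OR Apoptosis)
Fas* = NOT (S1P OR Apoptosis)
Ceramide* = Fas AND NOT (S1P OR Apoptosis)
DISC* = (Ceramide OR (Fas AND NOT FLIP)) AND NOT Apoptosis
Apoptosis* = DISC OR Apoptosis
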