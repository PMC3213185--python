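# Full 60-node T-LGL survival signaling network (T cell large granular
# lymphocyte leukemia; activation-induced cell death circuitry of
# cytotoxic T lymphocytes).
#
# Six source nodes model the external condition: antigen stimulation
# (Stimuli), IL15 and PDGF over-abundance clamped ON; secondary antigen
# encounter (Stimuli2), the phosphatase CD45 and the viral protein TAX
# clamped OFF.  Every non-output rule carries an "AND NOT Apoptosis"
# clause: once programmed cell death commits, all signaling activity
# ceases.
#
# External inputs (default clamping = disease condition).
#@ source Stimuli = 1
#@ source IL15 = 1
#@ source PDGF = 1
#@ source Stimuli2 = 0
#@ source CD45 = 0
#@ source TAX = 0
# Proximal TCR signaling and cytoskeleton branch.
CTLA4* = TCR AND NOT Apoptosis
TCR* = (Stimuli AND NOT CTLA4) AND NOT Apoptosis
PDGFR* = (S1P OR PDGF) AND NOT Apoptosis
FYN* = (TCR OR IL2RB) AND NOT Apoptosis
Cytoskeleton_signaling* = FYN AND NOT Apoptosis
LCK* = (CD45 OR ((TCR OR IL2RB) AND NOT ZAP70)) AND NOT Apoptosis
ZAP70* = (LCK AND NOT FYN) AND NOT Apoptosis
GRB2* = (IL2RB OR ZAP70) AND NOT Apoptosis
PLCG1* = (GRB2 OR PDGFR) AND NOT Apoptosis
# MAPK / PI3K growth branch.
RAS* = ((GRB2 OR PLCG1) AND NOT GAP) AND NOT Apoptosis
GAP* = ((RAS OR (PDGFR AND GAP)) AND NOT (IL15 OR IL2)) AND NOT Apoptosis
MEK* = RAS AND NOT Apoptosis
ERK* = (MEK AND PI3K) AND NOT Apoptosis
PI3K* = (PDGFR OR RAS) AND NOT Apoptosis
NFKB* = (TPL2 OR PI3K OR (FLIP AND TRADD AND IAP)) AND NOT Apoptosis
NFAT* = PI3K AND NOT Apoptosis
RANTES* = NFKB AND NOT Apoptosis
# Cytokine signaling (IL2 / JAK-STAT).
IL2* = ((NFKB OR STAT3 OR NFAT) AND NOT TBET) AND NOT Apoptosis
IL2RBT* = (ERK AND TBET) AND NOT Apoptosis
IL2RB* = (IL2RBT AND (IL2 OR IL15)) AND NOT Apoptosis
IL2RAT* = (IL2 AND (STAT3 OR NFKB)) AND NOT Apoptosis
IL2RA* = ((IL2 AND IL2RAT) AND NOT IL2RA) AND NOT Apoptosis
JAK* = ((IL2RA OR IL2RB OR RANTES OR IFNG) AND NOT (SOCS OR CD45)) AND NOT Apoptosis
SOCS* = (JAK AND NOT (IL2 OR IL15)) AND NOT Apoptosis
STAT3* = JAK AND NOT Apoptosis
P27* = STAT3 AND NOT Apoptosis
Proliferation* = (STAT3 AND NOT P27) AND NOT Apoptosis
TBET* = (JAK OR TBET) AND NOT Apoptosis
# Interferon-gamma module.
CREB* = (ERK AND IFNG) AND NOT Apoptosis
IFNGT* = (TBET OR STAT3 OR NFAT) AND NOT Apoptosis
IFNG* = (((IL2 OR IL15 OR Stimuli) AND IFNGT) AND NOT (SMAD OR P2)) AND NOT Apoptosis
P2* = ((IFNG OR P2) AND NOT Stimuli2) AND NOT Apoptosis
GZMB* = ((CREB AND IFNG) OR TBET) AND NOT Apoptosis
# TNF / NF-kB survival module.
TPL2* = (TAX OR (PI3K AND TNF)) AND NOT Apoptosis
TNF* = NFKB AND NOT Apoptosis
TRADD* = (TNF AND NOT (IAP OR A20)) AND NOT Apoptosis
A20* = NFKB AND NOT Apoptosis
# Fas / ceramide death-receptor module.
FasL* = (STAT3 OR NFKB OR NFAT OR ERK) AND NOT Apoptosis
FasT* = NFKB AND NOT Apoptosis
Fas* = ((FasT AND FasL) AND NOT sFas) AND NOT Apoptosis
sFas* = (FasT AND S1P) AND NOT Apoptosis
Ceramide* = (Fas AND NOT S1P) AND NOT Apoptosis
DISC* = (FasT AND ((Fas AND IL2) OR Ceramide OR (Fas AND NOT FLIP))) AND NOT Apoptosis
Caspase* = ((((TRADD OR GZMB) AND BID) AND NOT IAP) OR DISC) AND NOT Apoptosis
FLIP* = ((NFKB OR (CREB AND IFNG)) AND NOT DISC) AND NOT Apoptosis
BID* = ((Caspase OR GZMB) AND NOT (BclxL OR MCL1)) AND NOT Apoptosis
IAP* = (NFKB AND NOT BID) AND NOT Apoptosis
BclxL* = ((NFKB OR STAT3) AND NOT (BID OR GZMB OR DISC)) AND NOT Apoptosis
MCL1* = ((IL2RB AND STAT3 AND NFKB AND PI3K) AND NOT DISC) AND NOT Apoptosis
# Sphingolipid rheostat.
GPCR* = S1P AND NOT Apoptosis
SMAD* = GPCR AND NOT Apoptosis
SPHK1* = PDGFR AND NOT Apoptosis
S1P* = (SPHK1 AND NOT Ceramide) AND NOT Apoptosis
# Output: programmed cell death is self-sustaining once committed.
Apoptosis* = Caspase OR Apoptosis
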