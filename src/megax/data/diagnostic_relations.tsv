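source	target	polarity	kind	provenance
PPARG	XIAP	-	regulation	literature-curated: PPARG represses XIAP
PPARG	UBE2D1	-	regulation	literature-curated: PPARG represses UBE2D1
PPARG	SKP2	-	regulation	literature-curated: PPARG represses SKP2
PPARG	ACKR3	-	regulation	literature-curated: PPARG represses ACKR3
PPARG	MI21	-	regulation	literature-curated: PPARG represses MI21 (printed symbol; likely MIR21)
PPARG	HOXA10	-	regulation	literature-curated: PPARG represses HOXA10
PPARG	STAT1	-	regulation	literature-curated: PPARG represses STAT1
PPARG	PDPN	-	regulation	literature-curated: PPARG represses PDPN
PPARG	MIR223	+	regulation	literature-curated: PPARG activates MIR223
PPARG	ANGPT1	+	regulation	literature-curated: PPARG activates ANGPT1
PPARG	CYP2A6	+	regulation	literature-curated: PPARG activates CYP2A6
PPARG	FOXA2	+	regulation	literature-curated: PPARG activates FOXA2
LSCC	XIAP	+	disease_association	literature-curated: XIAP up in LSCC
LSCC	UBE2D1	+	disease_association	literature-curated: UBE2D1 up in LSCC
LSCC	SKP2	+	disease_association	literature-curated: SKP2 up in LSCC
LSCC	ACKR3	+	disease_association	literature-curated: ACKR3 up in LSCC
LSCC	MI21	+	disease_association	literature-curated: MI21 up in LSCC (printed symbol; likely MIR21)
LSCC	HOXA10	+	disease_association	literature-curated: HOXA10 up in LSCC
LSCC	STAT1	+	disease_association	literature-curated: STAT1 up in LSCC
LSCC	PDPN	+	disease_association	literature-curated: PDPN up in LSCC
LSCC	MIR223	-	disease_association	literature-curated: MIR223 down in LSCC
LSCC	ANGPT1	-	disease_association	literature-curated: ANGPT1 down in LSCC
LSCC	CYP2A6	-	disease_association	literature-curated: CYP2A6 down in LSCC
LSCC	FOXA2	-	disease_association	literature-curated: FOXA2 down in LSCC
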