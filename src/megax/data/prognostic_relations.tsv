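source	target	polarity	kind	provenance
PPARG	TNF	-	regulation	literature-curated: PPARG deactivates TNF
PPARG	NOS2	-	regulation	literature-curated: PPARG deactivates NOS2
PPARG	ACE	-	regulation	literature-curated: PPARG deactivates ACE
PPARG	STK11	+	regulation	literature-curated: PPARG activates STK11
TNF	LSCC	+	disease_association	literature-curated: TNF promotes LSCC
NOS2	LSCC	+	disease_association	literature-curated: NOS2 promotes LSCC
ACE	LSCC	+	disease_association	literature-curated: ACE promotes LSCC
STK11	LSCC	-	disease_association	literature-curated: STK11 inhibits LSCC
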