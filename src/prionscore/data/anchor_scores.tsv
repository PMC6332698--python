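# Published combined aggregation-propensity scores for human hnRNP
# prion-like protein variants, used as calibration/validation anchors.
# Sequences are NOT bundled: fetch by accession (scripts/fetch_anchors.py)
# into a sequence directory, then resolve with prionscore.anchors.
# mutation "-" marks the wild-type row; positions are 1-based on the
# canonical (or stated isoform) UniProt sequence.
id	accession	mutation	published_score
hnRNPA1_wt	P09651	-	0.34
hnRNPA1_Q277K	P09651	Q277K	0.34
hnRNPA1_G283R	P09651	G283R	0.34
hnRNPA1_P340S	P09651	P340S	0.36
hnRNPA1_D314V	P09651	D314V	0.59
hnRNPA1_D314N	P09651	D314N	0.53
hnRNPDL_wt	O14979	-	1.18
hnRNPDL_D378H	O14979	D378H	1.26
hnRNPDL_D378N	O14979	D378N	1.30
hnRNPD0_wt	Q14103	-	1.13
hnRNPD0_F225L	Q14103	F225L	1.13
hnRNPD0_D319V	Q14103	D319V	1.33
hnRNPD0_iso2_D300V	Q14103-2	D300V	1.33
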