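# Per-residue prion propensity scale derived from saturation mutagenesis of
# the Sup35 yeast prion domain (the scale used by the PAPA composition
# predictor). Dimensionless; higher = more prion-promoting.
# provenance: published PAPA distribution (papa.py propensity table)
# columns: residue	value
A	-0.396490246
C	0.415164505
D	-1.276997939
E	-0.605023827
F	0.838732498
G	-0.039220713
H	-0.278573356
I	0.813697862
K	-1.576748587
L	-0.040005335
M	0.673729095
N	0.080295334
P	-1.197447496
Q	0.069168387
R	-0.405858577
S	0.133912418
T	-0.11457038
V	0.813697862
W	0.666735081
Y	0.77865336
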