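# Synthetic hexapeptide position-specific scoring matrix for amyloid-core
# detection: 6 hexapeptide positions x 20 residues, higher = more
# amyloidogenic. Constructed for this package (NOT the published WALTZ
# matrix): per-residue amyloid propensities modulated by asymmetric
# per-position factors so that scores are position-sensitive.
# provenance: synthetic, generated for prionscore
residue	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
pos1	0.240	0.720	-1.040	-0.960	1.520	-0.400	-0.160	1.440	-1.120	1.120	0.800	0.280	-1.600	0.240	-0.800	0.040	0.160	1.360	1.280	1.200
pos2	0.315	0.945	-1.365	-1.260	1.995	-0.525	-0.210	1.890	-1.470	1.470	1.050	0.367	-2.100	0.315	-1.050	0.053	0.210	1.785	1.680	1.575
pos3	0.390	1.170	-1.690	-1.560	2.470	-0.650	-0.260	2.340	-1.820	1.820	1.300	0.455	-2.600	0.390	-1.300	0.065	0.260	2.210	2.080	1.950
pos4	0.360	1.080	-1.560	-1.440	2.280	-0.600	-0.240	2.160	-1.680	1.680	1.200	0.420	-2.400	0.360	-1.200	0.060	0.240	2.040	1.920	1.800
pos5	0.330	0.990	-1.430	-1.320	2.090	-0.550	-0.220	1.980	-1.540	1.540	1.100	0.385	-2.200	0.330	-1.100	0.055	0.220	1.870	1.760	1.650
pos6	0.270	0.810	-1.170	-1.080	1.710	-0.450	-0.180	1.620	-1.260	1.260	0.900	0.315	-1.800	0.270	-0.900	0.045	0.180	1.530	1.440	1.350
anchors	-12.7	12.065
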