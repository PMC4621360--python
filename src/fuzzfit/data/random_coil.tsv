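# Default random-coil 13C chemical-shift reference ("wishart1995").
# Mean Calpha/Cbeta shifts (ppm, DSS scale) follow the widely used random-coil
# compilation of Wishart et al. (1995, J Biomol NMR 5:67) for short unstructured
# peptides. The sd column carries representative per-nucleus dispersions
# (0.30 ppm for CA, 0.40 ppm for CB) standing in for the residue-specific
# scatter of the underlying compilation; users may supply their own table with
# measured dispersions via secondary_shifts.load_random_coil(path=...).
# Glycine has no Cbeta; its CB row is NA and disorder profiling for Gly falls
# back to the Calpha deviation alone.
residue	nucleus	mean_ppm	sd_ppm
A	CA	52.5	0.30
A	CB	19.1	0.40
R	CA	56.0	0.30
R	CB	30.9	0.40
N	CA	53.1	0.30
N	CB	38.9	0.40
D	CA	54.2	0.30
D	CB	41.1	0.40
C	CA	58.2	0.30
C	CB	28.0	0.40
E	CA	56.6	0.30
E	CB	29.9	0.40
Q	CA	55.7	0.30
Q	CB	29.4	0.40
G	CA	45.1	0.30
G	CB	NA	NA
H	CA	55.0	0.30
H	CB	29.0	0.40
I	CA	61.1	0.30
I	CB	38.8	0.40
L	CA	55.1	0.30
L	CB	42.4	0.40
K	CA	56.2	0.30
K	CB	33.1	0.40
M	CA	55.4	0.30
M	CB	32.9	0.40
F	CA	57.7	0.30
F	CB	39.6	0.40
P	CA	63.3	0.30
P	CB	32.1	0.40
S	CA	58.3	0.30
S	CB	63.8	0.40
T	CA	61.8	0.30
T	CB	69.8	0.40
W	CA	57.5	0.30
W	CB	29.6	0.40
Y	CA	57.9	0.30
Y	CB	38.8	0.40
V	CA	62.2	0.30
V	CB	32.9	0.40
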