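# Background amino-acid frequencies resembling the reviewed human proteome,
# used by the synthetic proteome generator. Values are normalized at load.
residue	frequency
A	0.0701
R	0.0564
N	0.0358
D	0.0473
C	0.0230
Q	0.0477
E	0.0710
G	0.0657
H	0.0263
I	0.0434
L	0.0996
K	0.0573
M	0.0213
F	0.0365
P	0.0631
S	0.0833
T	0.0536
W	0.0122
Y	0.0267
V	0.0597
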