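# Average residue masses (Da) of amino-acid residues in a polypeptide chain
# (i.e. amino-acid mass minus one water). One water (18.0153 Da) is added
# per chain when computing molecular weight.
residue	mass_da
G	57.0519
A	71.0788
S	87.0782
P	97.1167
V	99.1326
T	101.1051
C	103.1388
L	113.1594
I	113.1594
N	114.1038
D	115.0886
Q	128.1307
K	128.1741
E	129.1155
M	131.1926
H	137.1411
F	147.1766
R	156.1875
Y	163.1760
W	186.2132
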