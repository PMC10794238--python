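# Binary residue hydrophobicity classification (1 = hydrophobic).
# The nine strongly hydrophobic types of the contact-potential literature's
# classification (C M F I L V W Y A); overridable via config.
A	1
C	1
D	0
E	0
F	1
G	0
H	0
I	1
K	0
L	1
M	1
N	0
P	0
Q	0
R	0
S	0
T	0
V	1
W	1
Y	1
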