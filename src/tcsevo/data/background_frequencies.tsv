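# Background amino-acid frequencies q^a: average occurrence over a large
# non-redundant protein database (Robinson & Robinson composition, as used by
# standard sequence-comparison tools). Stand-in for the family pipeline's
# database-average background; overridable via config.
A	0.07805
C	0.01925
D	0.05364
E	0.06295
F	0.03856
G	0.07377
H	0.02199
I	0.05142
K	0.05744
L	0.09019
M	0.02243
N	0.04487
P	0.05203
Q	0.04264
R	0.05129
S	0.07120
T	0.05841
V	0.06441
W	0.01330
Y	0.03216
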