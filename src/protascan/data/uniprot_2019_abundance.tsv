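# Natural amino-acid abundance, UniProt knowledgebase (release 2019_05 scale).
# symbol	frequency
A	0.0911
R	0.0569
N	0.0390
D	0.0546
C	0.0123
Q	0.0379
E	0.0622
G	0.0730
H	0.0220
I	0.0558
L	0.0989
K	0.0495
M	0.0238
F	0.0391
P	0.0485
S	0.0675
T	0.0561
W	0.0129
Y	0.0293
V	0.0687
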