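scheme_id: default
A: [aliphatic, small]
C: [polar, small]
D: [negative]
E: [negative]
F: [aromatic]
G: [aliphatic, small]
H: [aromatic, positive]
I: [aliphatic]
K: [positive]
L: [aliphatic]
M: [aliphatic]
N: [polar]
P: [aliphatic]
Q: [polar]
R: [positive]
S: [polar, small]
T: [polar, small]
V: [aliphatic]
W: [aromatic]
Y: [aromatic]
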