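# li10 reduced amino-acid alphabet (Li, Kim & Helman 2003), 10 groups.
# Format: one group per line; first letter is the group representative,
# remaining letters are members mapped onto it.  Lines after the 10 canonical
# groups assign the rare/ambiguous aa27 letters:
#   B (Asn/Asp)  -> group of N,  Z (Gln/Glu) -> group of Q,
#   J (Leu/Ile)  -> group of L,  U (Sec)     -> group of C,
#   O (Pyl)      -> group of K,  X and *     -> dedicated wildcard/stop ranks.
C C U
F F Y W
M M L J
I I V
G G
P P
A A T S
N N H B
Q Q E D Z
R R K O
X X
* *
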