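# mu10 reduced amino-acid alphabet (Murphy, Wallqvist & Levy 2000), 10 groups.
# Same format as li10.txt; rare-letter assignments follow the most common
# resolution of each ambiguity code.
L L V I M J
C C U
A A
G G
S S T
P P
F F Y W
E E D N Q B Z
K K R O
H H
X X
* *
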