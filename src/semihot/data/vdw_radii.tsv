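# Van der Waals radii by element, A (Chothia-style united-atom values
# for protein heavy atoms; 'default' covers anything not listed).
element	radius
C	1.87
N	1.65
O	1.4
S	1.85
P	1.9
default	1.8
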