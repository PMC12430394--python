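[Molden Format]
[Atoms] Angs
H 1 1 0.0000000000 0.0000000000 0.0000000000
[GTO]
1 0
 s 1 1.00
  1.0000000000e+00 1.0000000000e+00

[5D]
[7F]
[MO]
 Sym= A
 Ene= -0.5000000000
 Spin= Alpha
 Occup= 1.0000000000
   1  1.000000000000e+00
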