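VV  rxnet synthetic matrix library
XX
//
ID  RAX_SYNTH
XX
BF  synthetic consensus-derived stand-in for the RAX homeodomain motif
XX
P0      A      C      G      T
01     10     70     10     10      C
02     10     10     10     70      T
03     10     10     10     70      T
04      1      1      1     97      T
05     97      1      1      1      A
06     97      1      1      1      A
07      1      1      1     97      T
08      1      1      1     97      T
09     97      1      1      1      A
10     10     10     70     10      G
11     10     70     10     10      C
12     70     10     10     10      A
XX
CC  Synthetic stand-in: the published core consensus TAATTA (positions
CC  4-9, strongly conserved) flanked by weakly informative positions.
CC  Constructed because the MatInspector RAX matrix is proprietary.
XX
//
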