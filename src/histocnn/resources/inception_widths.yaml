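# Per-module inception branch widths.
# Keys: n1 (1x1), n3r (3x3 reduce), n3 (3x3), n5r (5x5 reduce), n5 (5x5),
# pool (pool projection).  `total` is the module output channel count and
# must equal n1 + n3 + n5 + pool at width multiplier 1.
# Modules 3a-4d use the canonical GoogLeNet allocations; 4e is the canonical
# allocation rescaled proportionally (largest-remainder rounding) so the four
# output branches total 1856.
"3a": {n1: 64,  n3r: 96,  n3: 128, n5r: 16, n5: 32,  pool: 32,  total: 256}
"3b": {n1: 128, n3r: 128, n3: 192, n5r: 32, n5: 96,  pool: 64,  total: 480}
"4a": {n1: 192, n3r: 96,  n3: 208, n5r: 16, n5: 48,  pool: 64,  total: 512}
"4b": {n1: 160, n3r: 112, n3: 224, n5r: 24, n5: 64,  pool: 64,  total: 512}
"4c": {n1: 128, n3r: 128, n3: 256, n5r: 24, n5: 64,  pool: 64,  total: 512}
"4d": {n1: 112, n3r: 144, n3: 288, n5r: 32, n5: 64,  pool: 64,  total: 528}
"4e": {n1: 571, n3r: 357, n3: 714, n5r: 71, n5: 286, pool: 285, total: 1856}
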