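# Allometric length -> mass relationships, mass_g = a * size_cm ** b.
# Editable defaults; the most specific matching taxon group wins, the
# fallback entry is always present.  Coefficients are order-of-magnitude
# values for typical wetland taxa, not literature fits.
groups:
  - {rank: class, name: Aves, a: 0.009, b: 3.0}
  - {rank: class, name: Mammalia, a: 0.02, b: 3.0}
  - {rank: class, name: Actinopterygii, a: 0.01, b: 3.0}
  - {rank: class, name: Amphibia, a: 0.015, b: 3.0}
  - {rank: class, name: Reptilia, a: 0.012, b: 3.0}
  - {rank: class, name: Insecta, a: 0.03, b: 2.6}
  - {rank: class, name: Magnoliopsida, a: 0.005, b: 2.5}
fallback: {a: 0.01, b: 3.0}
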