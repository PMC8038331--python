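# Pairing rules for the packaged library.
# Ten linkers by default; a seven-linker subset for Ar13-Ar16; the
# supplementary linkers L11-L18 additionally for Ar9 variants d, e, h, j.
default_linkers: [L1, L2, L3, L4, L5, L6, L7, L8, L9, L10]
group_overrides:
  Ar13: [L1, L2, L3, L6, L7, L8, L10]
  Ar14: [L1, L2, L3, L6, L7, L8, L10]
  Ar15: [L1, L2, L3, L6, L7, L8, L10]
  Ar16: [L1, L2, L3, L6, L7, L8, L10]
extra_pairs:
  Ar9d: [L11, L12, L13, L14, L15, L16, L17, L18]
  Ar9e: [L11, L12, L13, L14, L15, L16, L17, L18]
  Ar9h: [L11, L12, L13, L14, L15, L16, L17, L18]
  Ar9j: [L11, L12, L13, L14, L15, L16, L17, L18]
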