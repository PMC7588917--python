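# Wobble recognition rules and selective constraints S_ij for W_i computation.
#
# Watson-Crick pairing always contributes with S = 0 (the anticodon is the
# reverse complement of the codon). Each generic rule adds one wobble
# isoacceptor keyed by the codon's third base: the recognizing anticodon has
# the listed wobble base at position 34 and the remaining two bases Watson-
# Crick paired. Constraints follow dos Reis-style eukaryotic defaults:
#   G34:U3 pairing      S = 0.41
#   I34:C3 (A34 read as inosine)  S = 0.28
#   I34:A3                        S = 0.9999
#   U34:G3 pairing      S = 0.68
# Special cases: ATA gains the lysidine/agmatidine-style CAT recognizer
# (S = 0.89); ATG and TGG take no wobble partner (their U34 wobble anticodon
# belongs to a different amino acid or reads a stop).
generic:
  T: {wobble_base: G, s: 0.41, label: "G:U"}
  C: {wobble_base: A, s: 0.28, label: "I:C"}
  A: {wobble_base: A, s: 0.9999, label: "I:A"}
  G: {wobble_base: T, s: 0.68, label: "U:G"}
special:
  ATA:
    extra:
      - {anticodon: CAT, s: 0.89, label: "k2C/agm:A"}
  ATG:
    drop_wobble: true
  TGG:
    drop_wobble: true
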