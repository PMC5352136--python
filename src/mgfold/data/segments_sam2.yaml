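# Secondary-structure segment map for the 52-nt SAM-II riboswitch.
# Inclusive 1-based author-residue ranges; edit to match your numbering.
# The five primary elements must not overlap; contacts joining L1 with P2b
# are classified as the triplex, L3 with P1 as the pseudoknot.
segments:
  P1:
  - [1, 7]
  - [20, 26]
  L1:
  - [8, 19]
  P2a:
  - [27, 32]
  - [39, 44]
  P2b:
  - [33, 38]
  L3:
  - [45, 52]
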