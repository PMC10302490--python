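# Synthetic reconstruction of the mixed-resolution PC lipid representation
# (representation 1): tails mapped with regular beads covering exactly four
# heavy atoms and small beads covering exactly three, at most one
# unsaturation per bead, regular beads stacked at the tail start.  Bead
# assignments are this package's own engineered reconstruction (the original
# per-lipid assignments are not published in the main text); they reproduce
# the representation's building-block accounting: 16 bond types, 27 angle
# types, 9 angle types pinned at 180 degrees = 77 free parameters.
# Angle terms are enumerated as all connected bead triples.
name: representation1-synthetic
lipids:
  DLPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C1}
    - {name: C1B, type: C1}
    - {name: C2B, type: C1}
    - {name: C3B, type: C1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [3, 7]
    - [7, 8]
    - [8, 9]
  DMPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C1}
    - {name: C3A, type: SC1}
    - {name: C4A, type: SC1}
    - {name: C1B, type: C1}
    - {name: C2B, type: C1}
    - {name: C3B, type: SC1}
    - {name: C4B, type: SC1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [3, 8]
    - [8, 9]
    - [9, 10]
    - [10, 11]
  DPPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C1}
    - {name: C4A, type: C1}
    - {name: C1B, type: C1}
    - {name: C2B, type: C1}
    - {name: C3B, type: C1}
    - {name: C4B, type: C1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [3, 8]
    - [8, 9]
    - [9, 10]
    - [10, 11]
  DSPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C1}
    - {name: C4A, type: SC1}
    - {name: C5A, type: SC1}
    - {name: C1B, type: C1}
    - {name: C2B, type: C1}
    - {name: C3B, type: C1}
    - {name: C4B, type: SC1}
    - {name: C5B, type: SC1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [7, 8]
    - [3, 9]
    - [9, 10]
    - [10, 11]
    - [11, 12]
    - [12, 13]
  POPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C4h}
    - {name: C3A, type: C1}
    - {name: C4A, type: SC1}
    - {name: C5A, type: SC1}
    - {name: C1B, type: C1}
    - {name: C2B, type: C1}
    - {name: C3B, type: C1}
    - {name: C4B, type: C1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [7, 8]
    - [3, 9]
    - [9, 10]
    - [10, 11]
    - [11, 12]
  DOPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C4h}
    - {name: C3A, type: C1}
    - {name: C4A, type: SC1}
    - {name: C5A, type: SC1}
    - {name: C1B, type: C1}
    - {name: C2B, type: C4h}
    - {name: C3B, type: C1}
    - {name: C4B, type: SC1}
    - {name: C5B, type: SC1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [7, 8]
    - [3, 9]
    - [9, 10]
    - [10, 11]
    - [11, 12]
    - [12, 13]
  SDPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C5h}
    - {name: C2A, type: C4h}
    - {name: C3A, type: C4h}
    - {name: C4A, type: C4h}
    - {name: C5A, type: SC4h}
    - {name: C6A, type: SC2}
    - {name: C1B, type: C1}
    - {name: C2B, type: C1}
    - {name: C3B, type: C1}
    - {name: C4B, type: C1}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [7, 8]
    - [8, 9]
    - [3, 10]
    - [10, 11]
    - [11, 12]
    - [12, 13]
  PDPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C1}
    - {name: C4A, type: SC1}
    - {name: C5A, type: SC1}
    - {name: C1B, type: C5h}
    - {name: C2B, type: C4h}
    - {name: C3B, type: SC4h}
    - {name: C4B, type: SC4h}
    - {name: C5B, type: SC4h}
    - {name: C6B, type: SC2}
    bonds:
    - [0, 1]
    - [1, 2]
    - [2, 3]
    - [2, 4]
    - [4, 5]
    - [5, 6]
    - [6, 7]
    - [7, 8]
    - [3, 9]
    - [9, 10]
    - [10, 11]
    - [11, 12]
    - [12, 13]
    - [13, 14]
fixed_angles:
- [C1, C1, C1]
- [C1, C1, SC1]
- [C1, SC1, SC1]
- [SN4a, C1, C1]
- [N4a, C1, C1]
- [C4h, C1, SC1]
- [C4h, C1, SN4a]
- [C4h, C1, N4a]
- [SC4h, SC4h, SC4h]
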