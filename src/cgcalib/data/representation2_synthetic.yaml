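# Synthetic reconstruction of the homogeneous-tail PC lipid representation
# (representation 2): the bulk of every saturated tail uses regular beads
# only; the next-to-ester group is either a small bead (3-to-1) or a regular
# bead (5-to-1), which makes every lipid's model unique; PUFA tails are
# mapped at slightly lower resolution.  Bead assignments are this package's
# own engineered reconstruction; they reproduce the representation's
# accounting: 13 bond types, 12 angle types, 2 angle types pinned at 180
# degrees = 48 free parameters.  Angle terms are restricted to the glycerol
# backbone and the tail chains (listed explicitly per lipid).
name: representation2-synthetic
lipids:
  DLPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: SC1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C1}
    - {name: C1B, type: SC1}
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [3, 7, 8]
    - [7, 8, 9]
  DMPC:
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [3, 7, 8]
    - [7, 8, 9]
  DPPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: SC1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C1}
    - {name: C4A, type: C1}
    - {name: C1B, type: SC1}
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [5, 6, 7]
    - [3, 8, 9]
    - [8, 9, 10]
    - [9, 10, 11]
  DSPC:
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [5, 6, 7]
    - [3, 8, 9]
    - [8, 9, 10]
    - [9, 10, 11]
  POPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: SC1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C4h}
    - {name: C4A, type: C1}
    - {name: C1B, type: SC1}
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [5, 6, 7]
    - [3, 8, 9]
    - [8, 9, 10]
    - [9, 10, 11]
  DOPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: SC1}
    - {name: C2A, type: C1}
    - {name: C3A, type: C4h}
    - {name: C4A, type: C1}
    - {name: C1B, type: SC1}
    - {name: C2B, type: C1}
    - {name: C3B, type: C4h}
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [5, 6, 7]
    - [3, 8, 9]
    - [8, 9, 10]
    - [9, 10, 11]
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
    - {name: C5A, type: C4h}
    - {name: C1B, type: SC1}
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [5, 6, 7]
    - [6, 7, 8]
    - [3, 9, 10]
    - [9, 10, 11]
    - [10, 11, 12]
  PDPC:
    beads:
    - {name: NC3, type: Q1}
    - {name: PO4, type: Q5}
    - {name: GL1, type: SN4a}
    - {name: GL2, type: N4a}
    - {name: C1A, type: C5h}
    - {name: C2A, type: C4h}
    - {name: C3A, type: C4h}
    - {name: C4A, type: C4h}
    - {name: C5A, type: C4h}
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
    angles:
    - [1, 2, 3]
    - [2, 4, 5]
    - [4, 5, 6]
    - [5, 6, 7]
    - [6, 7, 8]
    - [3, 9, 10]
    - [9, 10, 11]
    - [10, 11, 12]
fixed_angles:
- [C1, C1, C1]
- [SC1, C1, C1]
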