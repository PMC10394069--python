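# Default mitochondrial diagnostic panels for the synthetic bovine mitogenome.
#
# SYNTHETIC: apart from the T1b pair of transitions at 7542 and 16022, which
# are published diagnostic sites of that sub-clade, every position and allele
# below is an invented stand-in chosen only to give each clade a distinct,
# internally consistent signature on the simulator's reference frame
# (16,338 bp, circular, 1-based).  Do not use for real specimens; supply a
# curated panel file with the same schema instead.
#
# Schema:
#   panels:
#     - haplogroup: <label>
#       parent: <label or null>        # ancestral clade; acyclic
#       variants:
#         - {position: <1-based>, ref: <base>, alt: <base>, class: transition|transversion|insertion|deletion}
reference: synthetic_bovine_mt
panels:
  - haplogroup: T123
    parent: null
    variants:
      - {position: 2001, ref: A, alt: G, class: transition}
      - {position: 4002, ref: C, alt: T, class: transition}
  - haplogroup: T1
    parent: T123
    variants:
      - {position: 3003, ref: G, alt: A, class: transition}
      - {position: 5004, ref: T, alt: C, class: transition}
      - {position: 9005, ref: C, alt: T, class: transition}
  - haplogroup: T3
    parent: T123
    variants:
      - {position: 3504, ref: A, alt: G, class: transition}
      - {position: 6006, ref: C, alt: A, class: transversion}
      - {position: 10007, ref: T, alt: C, class: transition}
  - haplogroup: T1a
    parent: T1
    variants:
      - {position: 8008, ref: G, alt: A, class: transition}
      - {position: 12009, ref: C, alt: T, class: transition}
  - haplogroup: T1b
    parent: T1
    variants:
      - {position: 7542, ref: C, alt: T, class: transition}
      - {position: 16022, ref: T, alt: C, class: transition}
  - haplogroup: T1d
    parent: T1
    variants:
      - {position: 8510, ref: T, alt: C, class: transition}
      - {position: 12511, ref: G, alt: A, class: transition}
  - haplogroup: I
    parent: null
    variants:
      - {position: 1500, ref: C, alt: T, class: transition}
      - {position: 6500, ref: A, alt: G, class: transition}
      - {position: 11500, ref: G, alt: T, class: transversion}
      - {position: 14500, ref: T, alt: C, class: transition}
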