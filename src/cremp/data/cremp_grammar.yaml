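# Default module grammar: a/b cysteine-spacing templates and the conserved
# diagnostic-residue catalogue (positions 1-based from the module's first
# cysteine).  Edit or copy to define other cysteine-anchored grammars.
modules:
  - label: a
    internal_gaps: [4, 5, 8]
    tail: 6
    gap_tolerance: 1
    max_tail_insert: 64
  - label: b
    internal_gaps: [4, 5, 8]
    tail: 11
    gap_tolerance: 1
    max_tail_insert: 64
catalogue:
  shared:
    - [3, D]
    - [8, K]
    - [9, G]
    - [17, G]
    - [19, P]
  type_specific:
    a:
      - [7, P]
      - [26, P]
    b:
      - [25, K]
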