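# Reference amino-acid compositions for Euclidean ranking.
#
# Keys are the 17 pooled components (A C DN EQ F G H I K L M P R S T V Y);
# HYL/HYP entries from acid-hydrolysis literature are folded into K/P at
# load.  Only values printed in accessible text are pre-filled; the
# eggshell-membrane entry is therefore PARTIAL (two checked components) and
# is excluded from ranking until a user supplies the full literature
# vector.  Collagen/keratin/elastin vectors are user-supplied: compute them
# offline from their accessions (e.g. chicken collagens XP_422615,
# NP_990121, AAA48736; feather keratins NP_001095202, NP_001095201,
# NP_001075171) and add entries of the form:
#
#   collagen_avg:
#     components: {A: ..., C: ..., DN: ..., ...}   # must sum to 100
#
eggshell_membrane:
  partial: true
  provenance: >
    Literature acid-hydrolysis averages for chicken eggshell membrane;
    only the glycine and cysteine contents are pinned here.
  components:
    G: 9.5
    C: 10.1
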