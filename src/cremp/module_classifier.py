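"""Module-type assignment from tail length and diagnostic residues.

The two module types share their cysteine spacing and differ in tail
length (6 vs 11 residues) and in a handful of diagnostic residues: prolines
at positions 7 and 26 occur only in a-type modules, a lysine at position 25
only in b-type modules.  Canonical-spacing hits are typed directly by their
tail; deviant hits fall back on a diagnostic-residue vote, then on tail
proximity.  Diagnostic positions are read in the module's canonical
coordinate frame, shifted by the cumulative gap offset when an internal
gap deviates (positions are anchored to cysteines, not absolute offsets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .motif_model import (
    ConservedCatalogue,
    DEFAULT_CATALOGUE,
    DEFAULT_SPECS,
    ModuleSpec,
    map_canonical_position,
)
from .motif_scanner import ModuleHit
from .seqio import ProteinSequence

TAIL_MATCH = "tail_match"
TAIL_PROXIMITY = "tail_proximity"
CONFLICTS = "conflicts"


@dataclass(frozen=True)
class ClassificationResult:
    label: str  # a, b, a_variant, b_variant, unknown
    evidence: tuple[str, ...]


def _diagnostics_present(
    hit: ModuleHit, seq: ProteinSequence, spec: ModuleSpec, catalogue: ConservedCatalogue
) -> list[str]:
    """Type-specific diagnostic residues observed in the hit, e.g. ['P7']."""
    found = []
    for pos, res in sorted(catalogue.type_specific.get(spec.label, frozenset())):
        actual = map_canonical_position(spec, hit.observed_gaps, pos)
        idx = hit.start + actual - 1
        if hit.start <= idx < hit.end and seq.residues[idx] == res:
            found.append(f"{res}{pos}")
    return found


def classify_module(
    hit: ModuleHit,
    seq: ProteinSequence,
    specs: Sequence[ModuleSpec] = DEFAULT_SPECS,
    catalogue: ConservedCatalogue = DEFAULT_CATALOGUE,
) -> ClassificationResult:
    """Assign a final type to one module hit.

    Rule cascade: (1) canonical gaps and a tail exactly matching one spec
    type the hit directly; (2) otherwise diagnostic residues vote (each
    observed P7/P26 for a, K25 for b) and the majority yields a variant
    label; (3) with no or tied votes, the tail — net of any insert — breaks
    the tie by proximity to the canonical tail lengths, equidistance giving
    ``unknown``.  Evidence lists the fired rules consistent with the label,
    plus ``conflicts`` when both types had support.
    """
    if hit.start < 0 or hit.end > len(seq):
        raise ValueError("hit coordinates out of sequence bounds")
    by_label = {s.label: s for s in specs}
    a_spec, b_spec = by_label["a"], by_label["b"]
    evidence_a = _diagnostics_present(hit, seq, a_spec, catalogue)
    evidence_b = _diagnostics_present(hit, seq, b_spec, catalogue)

    # rule 1: canonical spacing and exact tail
    for spec in (a_spec, b_spec):
        if hit.observed_gaps == spec.internal_gaps and hit.observed_tail == spec.tail:
            own = evidence_a if spec.label == "a" else evidence_b
            return ClassificationResult(spec.label, (TAIL_MATCH, *own))

    # rule 2: diagnostic-residue majority
    conflict = bool(evidence_a) and bool(evidence_b)
    if len(evidence_a) != len(evidence_b):
        if len(evidence_a) > len(evidence_b):
            label, own = "a_variant", evidence_a
        else:
            label, own = "b_variant", evidence_b
        ev = (*own, CONFLICTS) if conflict else tuple(own)
        return ClassificationResult(label, ev)

    # rule 3: tail proximity, excluding the insert
    effective_tail = hit.observed_tail - hit.insert_length
    da, db = abs(effective_tail - a_spec.tail), abs(effective_tail - b_spec.tail)
    extra = (CONFLICTS,) if conflict else ()
    if da < db:
        return ClassificationResult("a_variant", (TAIL_PROXIMITY, *extra))
    if db < da:
        return ClassificationResult("b_variant", (TAIL_PROXIMITY, *extra))
    return ClassificationResult("unknown", (TAIL_PROXIMITY, *extra))


def classify_hits(
    hits: Sequence[ModuleHit],
    seqs: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
    specs: Sequence[ModuleSpec] = DEFAULT_SPECS,
    catalogue: ConservedCatalogue = DEFAULT_CATALOGUE,
) -> list[ClassificationResult]:
    """Classify hits in place (updating ``hit.label``) and return the results."""
    if not isinstance(seqs, Mapping):
        seqs = {s.id: s for s in seqs}
    results = []
    for hit in hits:
        res = classify_module(hit, seqs[hit.seq_id], specs, catalogue)
        hit.label = res.label
        results.append(res)
    return results
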