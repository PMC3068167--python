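"""Cysteine-anchored module detection and chaining.

Candidate modules are generated at every window of four *consecutive*
cysteines (consecutive because inter-cysteine spacers may not contain a
cysteine, so the four anchors of a module are necessarily adjacent in the
sequence's cysteine list).  A candidate matches a spec when each observed
gap lies within ``gap_tolerance`` of the canonical spacing and its tail —
delimited by the next cysteine, or capped at the canonical length at the
end of a cysteine-free stretch — is cysteine-free and no longer than
``tail + max_tail_insert``.

Overlapping candidates are resolved by weighted-interval-scheduling dynamic
programming that maximizes, in order: total residues covered, number of
modules, fewest deviations.  Runs of adjacent selected modules become
:class:`RepeatRegion` objects carrying the module-architecture string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .motif_model import ModuleSpec, DEFAULT_SPECS
from .seqio import ProteinSequence

GAP_SHRUNK = "gap_shrunk"
GAP_GROWN = "gap_grown"
TAIL_INSERT = "tail_insert"


@dataclass
class ModuleHit:
    """One detected module occurrence.

    ``label`` starts as the provisional scanner assignment (the spec label
    on an exact spacing match, else ``"variant"``) and is refined by the
    classifier.  ``insert_length`` is the observed tail minus the canonical
    tail of the generating spec (0 when none).
    """

    seq_id: str
    start: int
    end: int
    label: str
    observed_gaps: tuple[int, ...]
    observed_tail: int
    deviations: tuple[str, ...] = ()
    insert_length: int = 0
    spec_label: str = ""

    def __post_init__(self) -> None:
        n_cys = len(self.observed_gaps) + 1
        if self.end - self.start != n_cys + sum(self.observed_gaps) + self.observed_tail:
            raise ValueError("hit span inconsistent with observed gaps and tail")
        if self.insert_length < 0:
            raise ValueError("insert_length must be non-negative")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def type_letter(self) -> str:
        """One-letter architecture symbol: the module type, or 'v' if unknown."""
        base = self.label.split("_")[0]
        return base if len(base) == 1 and base not in ("v", "u") else "v"


@dataclass
class RepeatRegion:
    """A maximal run of adjacent selected modules on one sequence."""

    seq_id: str
    start: int
    end: int
    hits: list[ModuleHit] = field(default_factory=list)

    @property
    def architecture(self) -> str:
        return architecture_string(self)


def find_candidate_modules(
    seq: ProteinSequence, specs: Sequence[ModuleSpec] = DEFAULT_SPECS
) -> list[ModuleHit]:
    """Enumerate all module candidates in *seq* under the given grammar.

    Every cysteine is tried as a module start; a candidate is emitted for
    each spec whose spacing template the following cysteines satisfy within
    tolerance.  One cysteine window can legitimately yield candidates for
    several specs (an exact b match doubles as an a match with a 5-residue
    tail insert); the chaining step arbitrates.
    """
    residues = seq.residues
    cys = [i for i, ch in enumerate(residues) if ch == "C"]
    hits: list[ModuleHit] = []
    for j in range(len(cys)):
        for spec in specs:
            n_gaps = len(spec.internal_gaps)
            if j + n_gaps >= len(cys):
                continue
            anchors = cys[j : j + n_gaps + 1]
            gaps = tuple(anchors[k + 1] - anchors[k] - 1 for k in range(n_gaps))
            deviations = []
            ok = True
            for g, canon in zip(gaps, spec.internal_gaps):
                if abs(g - canon) > spec.gap_tolerance:
                    ok = False
                    break
                if g < canon:
                    deviations.append(GAP_SHRUNK)
                elif g > canon:
                    deviations.append(GAP_GROWN)
            if not ok:
                continue
            last = anchors[-1]
            next_cys = cys[j + n_gaps + 1] if j + n_gaps + 1 < len(cys) else None
            if next_cys is not None:
                avail = next_cys - last - 1
                if avail < spec.tail or avail > spec.tail + spec.max_tail_insert:
                    continue
                tail = avail
            else:
                # no downstream cysteine: inserts are unobservable, cap the
                # tail at canonical length; too little room kills the match
                if len(residues) - last - 1 < spec.tail:
                    continue
                tail = spec.tail
            insert = tail - spec.tail
            if insert > 0:
                deviations.append(TAIL_INSERT)
            exact = gaps == spec.internal_gaps and insert == 0
            hits.append(
                ModuleHit(
                    seq_id=seq.id,
                    start=anchors[0],
                    end=last + 1 + tail,
                    label=spec.label if exact else "variant",
                    observed_gaps=gaps,
                    observed_tail=tail,
                    deviations=tuple(deviations),
                    insert_length=insert,
                    spec_label=spec.label,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.spec_label))
    return hits


def chain_modules(
    candidates: Sequence[ModuleHit], max_gap_between_modules: int = 0
) -> list[RepeatRegion]:
    """Select a non-overlapping candidate subset and group it into regions.

    Dynamic programming over candidates sorted by end position maximizes
    (total residues covered, module count, −deviations); remaining ties are
    resolved toward smaller start positions, then spec label, making the
    result deterministic.  Selected modules separated by at most
    ``max_gap_between_modules`` non-module residues form one region.
    """
    if not candidates:
        return []
    cands = sorted(
        candidates, key=lambda h: (h.end, h.start, len(h.deviations), h.spec_label)
    )
    n = len(cands)
    # best[i]: best chain score using candidates[0..i] ending at or before cands[i].end
    NEG = (0, 0, 0)
    best_ending: list[tuple] = [NEG] * n  # score of best chain ending exactly with i
    prev: list[int] = [-1] * n
    best_prefix: list[tuple] = [NEG] * n  # best chain among cands[0..i]
    best_prefix_idx: list[int] = [-1] * n
    for i, h in enumerate(cands):
        own = (h.span, 1, -len(h.deviations))
        # find best chain ending before h.start (linear scan; candidate counts
        # per sequence are modest)
        base, base_idx = NEG, -1
        for j in range(i):
            if cands[j].end <= h.start and best_ending[j] > base:
                base, base_idx = best_ending[j], j
        best_ending[i] = tuple(a + b for a, b in zip(base, own))
        prev[i] = base_idx
        if i == 0 or best_ending[i] > best_prefix[i - 1]:
            best_prefix[i] = best_ending[i]
            best_prefix_idx[i] = i
        else:
            best_prefix[i] = best_prefix[i - 1]
            best_prefix_idx[i] = best_prefix_idx[i - 1]
    # reconstruct
    chain: list[ModuleHit] = []
    i = best_prefix_idx[n - 1]
    while i >= 0:
        chain.append(cands[i])
        i = prev[i]
    chain.reverse()
    # group into regions
    regions: list[RepeatRegion] = []
    for hit in chain:
        if (
            regions
            and hit.seq_id == regions[-1].seq_id
            and hit.start - regions[-1].end <= max_gap_between_modules
        ):
            regions[-1].hits.append(hit)
            regions[-1].end = hit.end
        else:
            regions.append(
                RepeatRegion(seq_id=hit.seq_id, start=hit.start, end=hit.end, hits=[hit])
            )
    return regions


def architecture_string(region: RepeatRegion) -> str:
    """Concatenated one-letter module labels, in order; variants render 'v'."""
    letters = []
    for h in region.hits:
        if h.label in ("variant", "unknown"):
            letters.append("v")
        else:
            letters.append(h.type_letter)
    return "".join(letters)


def compress_pattern(arch: str) -> str:
    """Compress an architecture string to its smallest repeating unit.

    Returns ``"(unit)k"`` for the smallest period dividing the length, e.g.
    ``"abab"`` → ``"(ab)2"``; an aperiodic string compresses trivially to
    ``"(arch)1"``.
    """
    if not arch:
        return ""
    n = len(arch)
    for p in range(1, n):
        if n % p == 0 and arch == arch[:p] * (n // p):
            return f"({arch[:p]}){n // p}"
    return f"({arch})1"


def scan(
    seq: ProteinSequence,
    specs: Sequence[ModuleSpec] = DEFAULT_SPECS,
    max_gap_between_modules: int = 0,
) -> list[RepeatRegion]:
    """Convenience: candidate generation followed by chaining."""
    return chain_modules(
        find_candidate_modules(seq, specs), max_gap_between_modules
    )
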