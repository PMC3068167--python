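"""Synthetic module-repeat proteins with known ground truth.

The generator emulates the documented repeat biology: proteins are
concatenations of canonical a/b modules (optionally between cysteine-free
flanks), with point substitutions at a per-position rate, scheduled
single-residue spacing deviations (the documented gap shrink/growth
cases), and scheduled proline/alanine-rich C-terminal tail inserts (the
progressive lengthening seen in lizard modules, up to 59 residues).
Cysteine anchors and diagnostic residues can be protected so that
substitution noise never destroys the grammar itself.

All randomness flows from one seeded numpy generator, so a run is fully
reproduced by (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .motif_model import (
    AMINO_ACIDS,
    ConservedCatalogue,
    DEFAULT_CATALOGUE,
    DEFAULT_SPECS,
    ModuleSpec,
    map_canonical_position,
)
from .motif_scanner import GAP_GROWN, GAP_SHRUNK, TAIL_INSERT, ModuleHit
from .seqio import ProteinSequence

NON_CYS = tuple(ch for ch in AMINO_ACIDS if ch != "C")

#: stylized Pro/Ala-rich insert alphabet: 45% A, 45% P, 10% spread uniformly
DEFAULT_INSERT_ALPHABET: tuple[tuple[str, float], ...] = tuple(
    [("A", 0.45), ("P", 0.45)]
    + [(ch, 0.10 / 17) for ch in NON_CYS if ch not in "AP"]
)


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth plan for one simulated protein.

    ``grammar`` is the ordered module-type plan (e.g. ``"ab" * 4`` or
    ``["a"] * 21``); ``deviation_schedule`` entries are
    ``(module_index, gap_index, ±1)`` spacing edits and
    ``insert_schedule`` entries ``(module_index, insert_length)`` tail
    extensions, both 0-based on the grammar.  Flanks are cysteine-free.
    """

    grammar: Sequence[str] = ("a", "b", "a", "b")
    substitution_rate: float = 0.0
    protect_cys: bool = True
    protect_diagnostics: bool = True
    deviation_schedule: tuple[tuple[int, int, int], ...] = ()
    insert_schedule: tuple[tuple[int, int], ...] = ()
    insert_alphabet: tuple[tuple[str, float], ...] = DEFAULT_INSERT_ALPHABET
    flank_lengths: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        n = len(self.grammar)
        for idx, gap, delta in self.deviation_schedule:
            if not 0 <= idx < n:
                raise ValueError(f"deviation schedule references module {idx} of {n}")
        for idx, length in self.insert_schedule:
            if not 0 <= idx < n:
                raise ValueError(f"insert schedule references module {idx} of {n}")
            if length < 0:
                raise ValueError("insert lengths must be non-negative")
        object.__setattr__(self, "grammar", tuple(self.grammar))


@dataclass(frozen=True)
class TruthRecord:
    start: int
    end: int
    type: str
    deviations: tuple[str, ...]
    insert_length: int


@dataclass(frozen=True)
class GroundTruth:
    sequence: ProteinSequence
    records: tuple[TruthRecord, ...]
    region_start: int
    region_end: int


def _build_module(
    spec: ModuleSpec,
    catalogue: ConservedCatalogue,
    observed_gaps: Sequence[int],
) -> tuple[list[str], set[int], set[int]]:
    """Module residues (no insert yet) plus 0-based anchor/diagnostic indices."""
    filler = "A"
    segments: list[str] = []
    positions = catalogue.positions_for(spec.label)
    canon_cys = spec.cys_positions
    residues: list[str] = []
    anchor_idx: set[int] = set()
    diag_idx: set[int] = set()
    # cysteines and gap segments
    for k in range(spec.n_cys):
        anchor_idx.add(len(residues))
        residues.append("C")
        seg_len = observed_gaps[k] if k < len(observed_gaps) else spec.tail
        canon_len = spec.internal_gaps[k] if k < len(spec.internal_gaps) else spec.tail
        gap_start_canon = canon_cys[k] + 1  # first canonical position of the segment
        for o in range(seg_len):
            canon_pos = gap_start_canon + o if o < canon_len else None
            res = positions.get(canon_pos, filler) if canon_pos else filler
            if canon_pos in positions:
                diag_idx.add(len(residues))
            residues.append(res)
    return residues, anchor_idx, diag_idx


def _draw_insert(rng: np.random.Generator, length: int, alphabet) -> str:
    letters = [a for a, _ in alphabet]
    probs = np.array([p for _, p in alphabet], dtype=float)
    probs /= probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def simulate_protein(
    params: SimulationParams,
    specs: Sequence[ModuleSpec] = DEFAULT_SPECS,
    catalogue: ConservedCatalogue = DEFAULT_CATALOGUE,
    seq_id: str = "sim",
) -> tuple[ProteinSequence, GroundTruth]:
    """Generate one protein and its ground-truth module records.

    Each planned module starts from its canonical sequence, applies
    scheduled gap edits and tail inserts, then substitutes unprotected
    positions at ``substitution_rate`` (substitutions never introduce a
    cysteine while ``protect_cys`` holds).
    """
    rng = np.random.default_rng(params.seed)
    by_label = {s.label: s for s in specs}
    gap_edits: dict[int, dict[int, int]] = {}
    for idx, gap, delta in params.deviation_schedule:
        gap_edits.setdefault(idx, {})[gap] = gap_edits.setdefault(idx, {}).get(gap, 0) + delta
    inserts = {idx: length for idx, length in params.insert_schedule}

    chunks: list[str] = []
    records: list[TruthRecord] = []
    n_flank, c_flank = params.flank_lengths
    if n_flank:
        chunks.append("".join(rng.choice(list(NON_CYS), size=n_flank)))
    offset = n_flank
    for m, label in enumerate(params.grammar):
        spec = by_label[label]
        observed_gaps = list(spec.internal_gaps)
        deviations: list[str] = []
        for gap, delta in sorted(gap_edits.get(m, {}).items()):
            observed_gaps[gap] += delta
            if observed_gaps[gap] < 0:
                raise ValueError(
                    f"gap edit on module {m} gap {gap} collides two cysteines"
                )
            deviations.append(GAP_SHRUNK if delta < 0 else GAP_GROWN)
        residues, anchor_idx, diag_idx = _build_module(spec, catalogue, observed_gaps)
        insert_len = inserts.get(m, 0)
        if insert_len:
            residues.extend(_draw_insert(rng, insert_len, params.insert_alphabet))
            deviations.append(TAIL_INSERT)
        # substitution pass
        if params.substitution_rate > 0:
            for i in range(len(residues)):
                if params.protect_cys and i in anchor_idx:
                    continue
                if params.protect_diagnostics and i in diag_idx:
                    continue
                if rng.random() < params.substitution_rate:
                    pool = NON_CYS if params.protect_cys else tuple(AMINO_ACIDS)
                    choices = [ch for ch in pool if ch != residues[i]]
                    residues[i] = rng.choice(choices)
        module_seq = "".join(residues)
        records.append(
            TruthRecord(
                start=offset,
                end=offset + len(module_seq),
                type=label,
                deviations=tuple(deviations),
                insert_length=insert_len,
            )
        )
        chunks.append(module_seq)
        offset += len(module_seq)
    region_end = offset
    if c_flank:
        chunks.append("".join(rng.choice(list(NON_CYS), size=c_flank)))
    seq = ProteinSequence(id=seq_id, residues="".join(chunks))
    truth = GroundTruth(
        sequence=seq,
        records=tuple(records),
        region_start=n_flank,
        region_end=region_end,
    )
    return seq, truth


@dataclass(frozen=True)
class RecoveryReport:
    precision: float
    recall: float
    exact_boundary_rate: float
    type_accuracy: float
    n_truth: int
    n_predicted: int
    n_matched: int


def recovery_report(
    truth: GroundTruth, predicted: Sequence[ModuleHit], slack: int = 0
) -> RecoveryReport:
    """Score predicted modules against planted ones.

    A prediction matches a truth record when both boundaries agree within
    ``slack`` residues (one-to-one, in coordinate order).  Type accuracy is
    scored over matched pairs using the prediction's type letter.
    """
    preds = sorted(predicted, key=lambda h: (h.start, h.end))
    used = [False] * len(preds)
    matched = 0
    exact = 0
    correct_type = 0
    for rec in truth.records:
        for i, hit in enumerate(preds):
            if used[i]:
                continue
            if abs(hit.start - rec.start) <= slack and abs(hit.end - rec.end) <= slack:
                used[i] = True
                matched += 1
                exact += hit.start == rec.start and hit.end == rec.end
                correct_type += hit.type_letter == rec.type
                break
    n_truth, n_pred = len(truth.records), len(preds)
    return RecoveryReport(
        precision=matched / n_pred if n_pred else 0.0,
        recall=matched / n_truth if n_truth else 0.0,
        exact_boundary_rate=exact / matched if matched else 0.0,
        type_accuracy=correct_type / matched if matched else 0.0,
        n_truth=n_truth,
        n_predicted=n_pred,
        n_matched=matched,
    )
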