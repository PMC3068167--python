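"""Position-frequency matrices and information content over module stacks.

Same-type modules align without gaps once gap-deviant hits are excluded,
so a stack is simply a list of equal-length rows.  Information content per
column follows the WebLogo protein convention: log2(20) minus the Shannon
entropy of the column's residue distribution, in bits, without small-sample
correction.  For cross-type comparison, b-type rows are trimmed by exactly
5 residues from the C-terminus so every row is 27 long — the same
equal-length device used to compare a and b modules directly.

The unknown residue X is kept as a 21st symbol in the frequency table and
contributes to the entropy as its own (maximally uninformative) symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .motif_model import DEFAULT_SPECS, ModuleSpec, module_length
from .motif_scanner import GAP_GROWN, GAP_SHRUNK, ModuleHit
from .seqio import ProteinSequence

MAX_BITS = float(np.log2(20.0))
B_TRIM = 5  # residues trimmed from the b-module C-terminus for cross-type rows


@dataclass
class ModuleStack:
    """Equal-length module rows with provenance and per-row type letters."""

    context: str  # module type, or "cross"
    rows: list[str]
    source: list[tuple[str, int]] = field(default_factory=list)
    row_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("a module stack needs at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("stack rows must be of equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass
class PositionProfile:
    """Per-position residue fractions and information content (bits)."""

    length: int
    frequencies: list[dict[str, float]]
    information: list[float]


def stack_modules(
    hits: Sequence[ModuleHit],
    seqs: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
    type_filter: str | None = None,
    cross_type: bool = False,
    specs: Sequence[ModuleSpec] = DEFAULT_SPECS,
) -> ModuleStack:
    """Stack classified module hits into equal-length rows.

    Gap-deviant modules are excluded (they cannot be stacked without an
    alignment); tail-inserted modules contribute their canonical-length
    prefix, inserts being C-terminal extensions.  ``type_filter`` keeps one
    type; ``cross_type`` keeps both and trims b rows to a-module length.
    """
    if not isinstance(seqs, Mapping):
        seqs = {s.id: s for s in seqs}
    lengths = {s.label: module_length(s) for s in specs}
    rows, source, row_types = [], [], []
    for hit in hits:
        t = hit.type_letter
        if t not in lengths:
            continue
        if type_filter is not None and not cross_type and t != type_filter:
            continue
        if GAP_SHRUNK in hit.deviations or GAP_GROWN in hit.deviations:
            continue
        row = seqs[hit.seq_id].residues[hit.start : hit.start + lengths[t]]
        if len(row) < lengths[t]:
            continue
        if cross_type and t == "b":
            row = row[: lengths["b"] - B_TRIM]
        rows.append(row)
        source.append((hit.seq_id, hit.start))
        row_types.append(t)
    if not rows:
        raise ValueError("no modules left to stack after filtering")
    context = "cross" if cross_type else (type_filter or "all")
    return ModuleStack(context=context, rows=rows, source=source, row_types=row_types)


def position_profile(stack: ModuleStack) -> PositionProfile:
    """Empirical residue fractions and information content per column."""
    n = len(stack.rows)
    frequencies: list[dict[str, float]] = []
    information: list[float] = []
    for i in range(stack.width):
        column = [r[i] for r in stack.rows]
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        freqs = {ch: c / n for ch, c in sorted(counts.items())}
        h_bits = float(_shannon_entropy(list(freqs.values()), base=2))
        frequencies.append(freqs)
        information.append(max(0.0, MAX_BITS - h_bits))
    return PositionProfile(length=stack.width, frequencies=frequencies, information=information)


def _top_residue(freqs: dict[str, float]) -> tuple[str, float]:
    best = max(freqs.values())
    residue = min(ch for ch, f in freqs.items() if f == best)  # lexicographic tie-break
    return residue, best


def conserved_positions(
    profile: PositionProfile, min_fraction: float = 1.0
) -> list[tuple[int, str]]:
    """1-based positions whose top residue reaches ``min_fraction``."""
    out = []
    for i, freqs in enumerate(profile.frequencies):
        residue, frac = _top_residue(freqs)
        if frac >= min_fraction:
            out.append((i + 1, residue))
    return out


def consensus(profile: PositionProfile) -> str:
    """Per-position top residue; ties broken lexicographically."""
    return "".join(_top_residue(f)[0] for f in profile.frequencies)


def write_profile_tsv(profile: PositionProfile, path) -> None:
    """Profile table: position, per-residue fractions, information in bits."""
    residues = sorted({ch for f in profile.frequencies for ch in f})
    lines = ["\t".join(["position", *residues, "information_bits"])]
    for i, freqs in enumerate(profile.frequencies):
        row = [str(i + 1)]
        row += [f"{freqs.get(ch, 0.0):.6g}" for ch in residues]
        row.append(f"{profile.information[i]:.6g}")
        lines.append("\t".join(row))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
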