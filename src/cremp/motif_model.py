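"""Module grammar for cysteine-anchored repeat proteins.

A *module* is four cysteines with fixed inter-cysteine spacing plus a
C-terminal tail: the a-type module is C-X4-C-X5-C-X8-C-X6 (27 residues),
the b-type module shares the cysteine spacing but carries an 11-residue
tail (32 residues).  One a followed by one b forms the 59-residue repeat
unit of CREMP (cysteine-rich eggshell membrane protein).

This module defines the spacing templates (:class:`ModuleSpec`), the
catalogue of conserved diagnostic residues (:class:`ConservedCatalogue`),
and canonical-sequence construction.  Everything downstream — scanning,
classification, conservation profiling, simulation — consumes these
definitions.

Position numbering convention: module positions are 1-based with position
1 = the first cysteine.  This is the only origin under which all eight
catalogued residues (D3, P7, K8, G9, G17, P19, K25, P26) fall between the
correct cysteine anchors (C at 1, 6, 12, 21); see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet accepted on input; X marks unknowns from contig translations
ALPHABET = AMINO_ACIDS + "X"


@dataclass(frozen=True)
class ModuleSpec:
    """A cysteine-spacing template defining one module type.

    Parameters
    ----------
    label:
        One-letter module-type token, e.g. ``"a"`` or ``"b"``.
    internal_gaps:
        Residues between consecutive cysteines (canonical ``(4, 5, 8)``).
    tail:
        Residues after the last cysteine (canonical 6 for a, 11 for b).
    gap_tolerance:
        Allowed deviation, per gap, from the canonical spacing.
    max_tail_insert:
        Longest accepted C-terminal extension beyond the canonical tail
        (the largest documented insert is 59 residues).
    """

    label: str
    internal_gaps: tuple[int, ...]
    tail: int
    gap_tolerance: int = 1
    max_tail_insert: int = 64

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("ModuleSpec label must be a non-empty token")
        if any(g < 0 for g in self.internal_gaps):
            raise ValueError("internal gaps must be non-negative")
        if self.tail < 0 or self.gap_tolerance < 0 or self.max_tail_insert < 0:
            raise ValueError("tail, gap_tolerance and max_tail_insert must be non-negative")
        object.__setattr__(self, "internal_gaps", tuple(self.internal_gaps))

    @property
    def n_cys(self) -> int:
        return len(self.internal_gaps) + 1

    @property
    def cys_positions(self) -> tuple[int, ...]:
        """1-based positions of the cysteine anchors within the module."""
        pos = [1]
        for g in self.internal_gaps:
            pos.append(pos[-1] + g + 1)
        return tuple(pos)


@dataclass(frozen=True)
class ConservedCatalogue:
    """Conserved diagnostic residues, keyed 1-based from the first cysteine.

    ``shared`` positions hold in every module type; ``type_specific`` maps a
    module label to the residues found only in that type (P7/P26 for a,
    K25 for b).
    """

    shared: frozenset[tuple[int, str]] = frozenset()
    type_specific: Mapping[str, frozenset[tuple[int, str]]] = field(default_factory=dict)

    def positions_for(self, label: str) -> dict[int, str]:
        """All catalogued (position → residue) entries applying to *label*."""
        entries = dict()
        for pos, res in self.shared:
            entries[pos] = res
        for pos, res in self.type_specific.get(label, frozenset()):
            entries[pos] = res
        return entries


#: shared conserved residues: D3, K8, G9, G17, P19
DEFAULT_CATALOGUE = ConservedCatalogue(
    shared=frozenset({(3, "D"), (8, "K"), (9, "G"), (17, "G"), (19, "P")}),
    type_specific={
        "a": frozenset({(7, "P"), (26, "P")}),
        "b": frozenset({(25, "K")}),
    },
)

A_SPEC = ModuleSpec(label="a", internal_gaps=(4, 5, 8), tail=6)
B_SPEC = ModuleSpec(label="b", internal_gaps=(4, 5, 8), tail=11)
DEFAULT_SPECS: tuple[ModuleSpec, ...] = (A_SPEC, B_SPEC)


def module_length(spec: ModuleSpec) -> int:
    """Total residue length of one canonical module (cysteines + gaps + tail)."""
    return spec.n_cys + sum(spec.internal_gaps) + spec.tail


def repeat_length(specs: Sequence[ModuleSpec]) -> int:
    """Length of a repeat formed by concatenating the given module templates."""
    if not specs:
        raise ValueError("repeat_length requires a non-empty spec list")
    return sum(module_length(s) for s in specs)


def build_canonical_sequence(
    spec: ModuleSpec,
    catalogue: ConservedCatalogue = DEFAULT_CATALOGUE,
    filler: str = "A",
) -> str:
    """Construct the idealized module sequence for *spec*.

    Cysteines sit at the anchor positions, catalogued residues (shared plus
    the label's type-specific set) at theirs, and *filler* everywhere else.
    """
    if len(filler) != 1 or filler not in AMINO_ACIDS or filler == "C":
        raise ValueError("filler must be a single standard residue other than C")
    length = module_length(spec)
    cys = set(spec.cys_positions)
    residues = [filler] * length
    for p in cys:
        residues[p - 1] = "C"
    for pos, res in catalogue.positions_for(spec.label).items():
        if pos in cys:
            raise ValueError(f"catalogued position {pos} collides with a cysteine anchor")
        if pos <= length:
            residues[pos - 1] = res
    return "".join(residues)


def map_canonical_position(
    spec: ModuleSpec, observed_gaps: Sequence[int], position: int
) -> int:
    """Map a canonical 1-based module position onto a gap-deviant module.

    Positions are anchored to the cysteine that precedes them: a position
    downstream of a shrunk or grown gap shifts by the cumulative gap offset,
    positions within a gap keep the offset accumulated before that gap.
    """
    offset = 0
    for k, canon_gap in enumerate(spec.internal_gaps):
        closing_cys = spec.cys_positions[k + 1]
        if position >= closing_cys:
            offset += observed_gaps[k] - canon_gap
        else:
            break
    return position + offset


def _catalogue_from_config(raw: Mapping) -> ConservedCatalogue:
    shared = frozenset((int(p), str(r)) for p, r in raw.get("shared", []))
    type_specific = {
        label: frozenset((int(p), str(r)) for p, r in entries)
        for label, entries in raw.get("type_specific", {}).items()
    }
    return ConservedCatalogue(shared=shared, type_specific=type_specific)


def load_grammar(path: str | Path) -> tuple[list[ModuleSpec], ConservedCatalogue]:
    """Load module specs and a conserved catalogue from a YAML/JSON config.

    The shipped default (``cremp/data/cremp_grammar.yaml``) encodes the a/b
    grammar; users may define other cysteine-spacing grammars, e.g. the
    slime-mold C-X4-C-X5-C-X6..10-C spacing via a tolerant third gap.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [
        ModuleSpec(
            label=str(m["label"]),
            internal_gaps=tuple(int(g) for g in m["internal_gaps"]),
            tail=int(m["tail"]),
            gap_tolerance=int(m.get("gap_tolerance", 1)),
            max_tail_insert=int(m.get("max_tail_insert", 64)),
        )
        for m in raw["modules"]
    ]
    catalogue = _catalogue_from_config(raw.get("catalogue", {}))
    return specs, catalogue


def default_grammar_path() -> Path:
    return Path(__file__).parent / "data" / "cremp_grammar.yaml"
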