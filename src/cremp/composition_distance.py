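"""Aggregated amino-acid composition vectors and Euclidean distances.

Compositions are expressed the way acid-hydrolysis literature reports
them, so that sequence-derived and hydrolysis-derived vectors are
comparable: tryptophan is excluded entirely (hydrolysis destroys it and
analyses omit it), Asp+Asn are pooled as "DN" and Glu+Gln as "EQ"
(hydrolysis deamidates the amides), leaving 17 components summing to
100%.  Hydroxylysine and hydroxyproline in literature reference tables
are folded into Lys and Pro at config load.  Unknown residues (X) carry
no compositional information and are excluded like W.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .seqio import ProteinSequence

#: the 17 composition keys: 20 standard residues minus W, with D/N and E/Q pooled
COMPOSITION_KEYS: tuple[str, ...] = (
    "A", "C", "DN", "EQ", "F", "G", "H", "I", "K",
    "L", "M", "P", "R", "S", "T", "V", "Y",
)

_RESIDUE_TO_KEY = {
    **{k: k for k in COMPOSITION_KEYS if len(k) == 1},
    "D": "DN", "N": "DN", "E": "EQ", "Q": "EQ",
}


@dataclass(frozen=True)
class CompositionVector:
    """Percentages over the 17 pooled components; sums to 100."""

    components: Mapping[str, float]
    total_residues: int

    def __post_init__(self) -> None:
        if set(self.components) != set(COMPOSITION_KEYS):
            raise ValueError("composition vector must cover exactly the 17 pooled keys")
        if any(v < 0 for v in self.components.values()):
            raise ValueError("composition percentages must be non-negative")
        if abs(sum(self.components.values()) - 100.0) > 1e-6:
            raise ValueError("composition percentages must sum to 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.components[k] for k in COMPOSITION_KEYS], dtype=float)


def composition_vector(seqs: Sequence[ProteinSequence]) -> CompositionVector:
    """Pool residue counts across sequences into one percentage vector.

    W and X are dropped from numerator and denominator alike.
    """
    counts = {k: 0 for k in COMPOSITION_KEYS}
    total = 0
    for seq in seqs:
        for ch in seq.residues:
            key = _RESIDUE_TO_KEY.get(ch)
            if key is None:  # W or X
                continue
            counts[key] += 1
            total += 1
    if total == 0:
        raise ValueError("no residues left after excluding W and X")
    components = {k: 100.0 * c / total for k, c in counts.items()}
    return CompositionVector(components=components, total_residues=total)


def euclidean_distance(v1: CompositionVector, v2: CompositionVector) -> float:
    """Euclidean distance between two percentage vectors."""
    if set(v1.components) != set(v2.components):
        raise ValueError("composition vectors have mismatched key sets")
    return float(np.linalg.norm(v1.as_array() - v2.as_array()))


def rank_references(
    query: CompositionVector, refs: Mapping[str, CompositionVector]
) -> list[tuple[str, float]]:
    """References ordered by ascending distance to *query* (ties by label)."""
    if not refs:
        raise ValueError("at least one reference composition is required")
    ranked = [(label, euclidean_distance(query, v)) for label, v in refs.items()]
    ranked.sort(key=lambda item: (item[1], item[0]))
    return ranked


def _default_refs_path() -> Path:
    return Path(__file__).parent / "data" / "reference_compositions.yaml"


def load_reference_compositions(
    path: str | Path | None = None,
) -> dict[str, CompositionVector]:
    """Load labeled full reference compositions from YAML.

    Each entry maps the 17 pooled keys (optionally plus ``HYL``/``HYP``,
    folded into K/P at load) to percentages summing to 100.  Entries
    flagged ``partial: true`` document known components without a complete
    vector; they are skipped here (see :func:`load_partial_compositions`)
    because they cannot participate in distance ranking.
    """
    with open(path or _default_refs_path()) as fh:
        raw = yaml.safe_load(fh) or {}
    refs: dict[str, CompositionVector] = {}
    for label, entry in raw.items():
        if entry.get("partial", False):
            continue
        values = dict(entry.get("components", {}))
        values["K"] = values.get("K", 0.0) + values.pop("HYL", 0.0)
        values["P"] = values.get("P", 0.0) + values.pop("HYP", 0.0)
        components = {k: float(values.get(k, 0.0)) for k in COMPOSITION_KEYS}
        total = sum(components.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"reference {label!r} percentages sum to {total}, not 100")
        refs[label] = CompositionVector(
            components=components, total_residues=int(entry.get("total_residues", 0))
        )
    return refs


def load_partial_compositions(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Raw component maps of entries flagged ``partial: true`` (no pooling)."""
    with open(path or _default_refs_path()) as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        label: {k: float(v) for k, v in entry.get("components", {}).items()}
        for label, entry in raw.items()
        if entry.get("partial", False)
    }
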