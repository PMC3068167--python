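"""Sequence and annotation I/O: FASTA in, module tables / intervals / trees out.

Coordinates are 0-based half-open internally and in BED output; the
human-readable TSV additionally reports 1-based inclusive columns to match
conventional residue numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_model import ALPHABET

TSV_HEADER = [
    "seq_id",
    "start",
    "end",
    "start_1based",
    "end_1based",
    "label",
    "observed_gaps",
    "observed_tail",
    "insert_length",
    "deviations",
]


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus an amino-acid string (20 standard residues + X)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be a non-empty token")
        residues = self.residues.upper()
        if len(residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {i + 1}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file, preserving record order.

    Lower-case input is normalized to upper-case; residues outside the
    20-letter alphabet plus X raise a ``ValueError`` naming the record and
    offending position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        seqs.append(ProteinSequence(id=rec.id, residues=str(rec.seq), description=desc))
    return seqs


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path) -> None:
    """Write 60-column wrapped FASTA; round-trips through :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def _hit_row(hit) -> dict:
    return {
        "seq_id": hit.seq_id,
        "start": hit.start,
        "end": hit.end,
        "label": hit.label,
        "observed_gaps": list(hit.observed_gaps),
        "observed_tail": hit.observed_tail,
        "insert_length": hit.insert_length,
        "deviations": list(hit.deviations),
    }


def write_annotations(hits: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write module hits as ``tsv``, ``bed`` or ``json``.

    All three encode identical information: TSV has a fixed header and one
    row per hit; BED uses 0-based half-open protein coordinates with the
    label in the name column; JSON is a list of objects mirroring the hit
    fields.
    """
    if format == "tsv":
        lines = ["\t".join(TSV_HEADER)]
        for h in hits:
            lines.append(
                "\t".join(
                    [
                        h.seq_id,
                        str(h.start),
                        str(h.end),
                        str(h.start + 1),
                        str(h.end),
                        h.label,
                        ",".join(map(str, h.observed_gaps)),
                        str(h.observed_tail),
                        str(h.insert_length),
                        ",".join(h.deviations) or ".",
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "bed":
        lines = []
        for h in hits:
            name = (
                f"{h.label}|gaps={','.join(map(str, h.observed_gaps))}"
                f"|tail={h.observed_tail}|insert={h.insert_length}"
                f"|dev={','.join(h.deviations) or '.'}"
            )
            lines.append("\t".join([h.seq_id, str(h.start), str(h.end), name, "0", "+"]))
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "json":
        Path(path).write_text(json.dumps([_hit_row(h) for h in hits], indent=1) + "\n")
    else:
        raise ValueError(f"unknown annotation format: {format!r}")


def read_annotations_json(path: str | Path) -> list:
    """Re-load a JSON annotation dump as :class:`~cremp.motif_scanner.ModuleHit`."""
    from .motif_scanner import ModuleHit

    with open(path) as fh:
        raw = json.load(fh)
    return [
        ModuleHit(
            seq_id=r["seq_id"],
            start=int(r["start"]),
            end=int(r["end"]),
            label=r["label"],
            observed_gaps=tuple(int(g) for g in r["observed_gaps"]),
            observed_tail=int(r["observed_tail"]),
            deviations=tuple(r["deviations"]),
            insert_length=int(r["insert_length"]),
        )
        for r in raw
    ]


def write_newick(newick: str, path: str | Path) -> None:
    """Serialize a Newick string produced by :mod:`cremp.module_phylogeny`."""
    text = newick if newick.endswith(";") else newick + ";"
    Path(path).write_text(text + "\n")
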