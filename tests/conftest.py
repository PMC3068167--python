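import pytest

from cremp import (
    A_SPEC,
    B_SPEC,
    DEFAULT_CATALOGUE,
    ProteinSequence,
    build_canonical_sequence,
    classify_hits,
    scan,
)

CANONICAL_A = "CADAACPKGAACAAAAGAPACAAAAPA"
CANONICAL_B = "CADAACAKGAACAAAAGAPACAAAKAAAAAAA"


@pytest.fixture
def canonical_a():
    return build_canonical_sequence(A_SPEC, DEFAULT_CATALOGUE)


@pytest.fixture
def canonical_b():
    return build_canonical_sequence(B_SPEC, DEFAULT_CATALOGUE)


@pytest.fixture
def abab_sequence(canonical_a, canonical_b):
    return ProteinSequence(id="abab", residues=(canonical_a + canonical_b) * 2)


def scan_and_classify(seq, specs=None):
    """Full detection pipeline: scan, chain, classify; returns flat hit list."""
    kwargs = {} if specs is None else {"specs": specs}
    regions = scan(seq, **kwargs)
    hits = [h for r in regions for h in r.hits]
    if specs is None:
        classify_hits(hits, {seq.id: seq})
    else:
        classify_hits(hits, {seq.id: seq}, specs)
    return hits
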