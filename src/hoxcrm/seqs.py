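"""Small DNA-string helpers shared across the package.

All sequences are plus-strand uppercase strings over A, C, G, T; coordinates
are 0-based, half-open throughout.
"""

from __future__ import annotations

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised on malformed DNA input (bad alphabet, bad length)."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a plus-strand sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, name: str = "sequence") -> str:
    """Validate and return an uppercase ACGT string."""
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise SequenceError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return seq


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise SequenceError(f"hamming distance needs equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))
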