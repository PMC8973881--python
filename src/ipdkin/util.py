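"""Shared sequence utilities: IUPAC degenerate codes and strand arithmetic."""

from __future__ import annotations

import numpy as np

#: IUPAC nucleotide codes mapped to the set of concrete bases they allow.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement, accepting IUPAC degenerate symbols."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(motif: str) -> None:
    """Raise ValueError naming the first character outside the IUPAC alphabet."""
    if not motif:
        raise ValueError("empty motif")
    for ch in motif:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")


def iupac_regex(motif: str) -> str:
    """Translate an IUPAC motif into a character-class regular expression."""
    validate_iupac(motif)
    parts = []
    for ch in motif:
        allowed = IUPAC_CODES[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return "".join(parts)


def spawn_seed(seed: int, *salt: int) -> int:
    """Derive a child seed below 2**31 from a parent seed and integer salt."""
    ss = np.random.SeedSequence([int(seed), *map(int, salt)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
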