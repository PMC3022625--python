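"""Low-level DNA helpers shared by every stage of the pipeline."""

from __future__ import annotations

BAMHI_SITE = "GGATCC"  # cut G^GATCC, leaves 5' overhang GATC
HINDIII_SITE = "AAGCTT"  # cut A^AGCTT, leaves 5' overhang AGCT

BAMHI_OVERHANG = "GATC"
HINDIII_OVERHANG = "AGCT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ACGT = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains characters outside the strict ACGT alphabet."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, name: str = "sequence", min_len: int = 1) -> str:
    """Uppercase ``seq`` and reject anything outside ACGT or shorter than ``min_len``."""
    seq = seq.upper()
    if len(seq) < min_len:
        raise ValueError(f"{name} must be at least {min_len} nt, got {len(seq)}")
    bad = set(seq) - _ACGT
    if bad:
        raise AlphabetError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return seq


def find_all(haystack: str, needle: str) -> list[int]:
    """0-based start positions of every exact occurrence of ``needle``."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)
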