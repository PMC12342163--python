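"""Canonical chromosome ordering shared by annotation IO and gene ordering.

Rank: chr1..chr22 numerically, then chrX, chrY, chrM; every other contig
name sorts after those, lexicographically. A leading "chr" prefix is
ignored, case-insensitively, so "1", "Chr1" and "chr1" rank the same.
"""

from __future__ import annotations

_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}

# Rank assigned to non-canonical contigs; ties among them are broken by the
# normalized name, so the overall key is still a total order.
OTHER_RANK = 26


def normalize_chromosome(name: str) -> str:
    """Strip an optional "chr" prefix and surrounding whitespace."""
    s = name.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def chromosome_sort_key(name: str) -> tuple[int, str]:
    """Sort key ``(rank, normalized_name)`` implementing the canonical order."""
    s = normalize_chromosome(name)
    if s.isdigit():
        n = int(s)
        if 1 <= n <= 22:
            return (n, "")
    upper = s.upper()
    if upper in _SPECIAL:
        return (_SPECIAL[upper], "")
    return (OTHER_RANK, s)
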