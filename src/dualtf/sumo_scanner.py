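"""Degenerate consensus-motif scanning over protein sequences.

Patterns are short ordered lists of allowed-residue sets; a window matches
when every residue lies in its position's set. Matching is case-insensitive,
overlapping matches all count, and only the given orientation is scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ConsensusPattern:
    """Ordered allowed-residue sets; a full-alphabet set is a wildcard."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError("pattern must span at least 2 positions")
        for i, allowed in enumerate(self.positions):
            if not allowed:
                raise ValueError(f"position {i}: empty residue set")
            illegal = set(allowed) - AA_ALPHABET
            if illegal:
                raise ValueError(f"position {i}: illegal residues {sorted(illegal)}")

    @property
    def length(self) -> int:
        return len(self.positions)


def _pos(chars: str) -> frozenset[str]:
    return frozenset(chars)


_ANY = frozenset(AA_ALPHABET)

#: SUMOylation acceptor consensus: aliphatic, K, anything, E.
PSI_KXE = ConsensusPattern("psi-k-x-e", (_pos("ILV"), _pos("K"), _ANY, _pos("E")))

#: Companion consensus with the printed residue classes: {K,L,Y}, C, anything, I.
PHI_CXI = ConsensusPattern("phi-c-x-i", (_pos("KLY"), _pos("C"), _ANY, _pos("I")))

PATTERNS = {PSI_KXE.name: PSI_KXE, PHI_CXI.name: PHI_CXI}


@dataclass(frozen=True)
class MotifMatch:
    protein: str
    start: int
    matched: str


def scan_consensus(seq: str, pattern: ConsensusPattern, protein_id: str = "") -> list[MotifMatch]:
    """All (possibly overlapping) windows of ``seq`` matching ``pattern``.

    Residues are validated against the 20-letter alphabet; an illegal residue
    raises with its position.
    """
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in AA_ALPHABET:
            raise ValueError(f"illegal residue {ch!r} at position {i}")
    w = pattern.length
    matches = []
    for start in range(len(s) - w + 1):
        window = s[start : start + w]
        if all(ch in allowed for ch, allowed in zip(window, pattern.positions)):
            matches.append(MotifMatch(protein_id, start, window))
    return matches


def count_sumo_sites(
    proteins: Iterable[tuple[str, str]] | "SequenceSetLike",
    pattern: ConsensusPattern = PSI_KXE,
) -> dict[str, int]:
    """Per-protein count of consensus matches."""
    records = proteins.records if hasattr(proteins, "records") else proteins
    return {
        rec_id: len(scan_consensus(seq, pattern, rec_id)) for rec_id, seq in records
    }


def sumo_table(counts: Mapping[str, int]) -> list[tuple[str, int, bool]]:
    """Rows of (protein id, match count, presence flag)."""
    return [(tf, n, n > 0) for tf, n in counts.items()]
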