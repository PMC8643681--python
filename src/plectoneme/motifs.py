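"""IUPAC consensus motif scanning on both strands.

Scans a nucleotide sequence for windows matching a degenerate consensus
(e.g. the 23 bp promoter motif TTTGTGTABSTGBTTATGTAGGT found upstream of
the most highly upregulated supercoiling-responsive genes), allowing up to
a fixed number of mismatches.  A position matches when the sequence base is
a member of the IUPAC class at that consensus position; ``N`` in the
sequence matches nothing but ``N`` in the consensus.

Coordinates are 1-based and windows inclusive.  Reverse-strand hits test
the reverse complement of the window against the consensus and are reported
at the forward coordinate of the window start.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IUPAC", "MotifHit", "scan_consensus", "reverse_complement"]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# full IUPAC complement: R<->Y, K<->M, B<->V, D<->H; S, W, N self-complementary
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement, defined for all IUPAC nucleotide codes."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 1-based window start (forward coordinates),
    strand, mismatch count."""

    position: int
    strand: str  # "+" or "-"
    mismatches: int


def _validate(sequence: str, consensus: str) -> tuple[str, str]:
    sequence = sequence.upper()
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) in consensus: {sorted(bad)}")
    bad_seq = set(sequence) - set("ACGTN")
    if bad_seq:
        raise ValueError(f"invalid sequence character(s): {sorted(bad_seq)}")
    return sequence, consensus


def scan_consensus(
    sequence: str,
    consensus: str,
    max_mismatches: int = 0,
) -> list[MotifHit]:
    """All windows matching the consensus with at most ``max_mismatches``.

    Both strands are scanned; hits are sorted by position, forward strand
    first at equal positions.  An empty or too-short sequence yields an
    empty list.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    sequence, consensus = _validate(sequence, consensus)
    k = len(consensus)
    if k == 0:
        raise ValueError("consensus must be non-empty")
    n = len(sequence)
    if n < k:
        return []

    classes = [IUPAC[c] for c in consensus]
    rc_classes = [IUPAC[reverse_complement(c)] for c in consensus][::-1]

    hits: list[MotifHit] = []
    for start in range(n - k + 1):
        window = sequence[start : start + k]
        mm_fwd = 0
        for base, cls in zip(window, classes):
            if base not in cls:
                mm_fwd += 1
                if mm_fwd > max_mismatches:
                    break
        if mm_fwd <= max_mismatches:
            hits.append(MotifHit(position=start + 1, strand="+", mismatches=mm_fwd))
        # reverse strand: revcomp(window) vs consensus, equivalently window
        # vs the reverse-complemented consensus classes
        mm_rev = 0
        for base, cls in zip(window, rc_classes):
            if base not in cls:
                mm_rev += 1
                if mm_rev > max_mismatches:
                    break
        if mm_rev <= max_mismatches:
            hits.append(MotifHit(position=start + 1, strand="-", mismatches=mm_rev))
    return hits
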