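"""Shared sequence and coordinate helpers.

Internal coordinate convention throughout the package: 0-based, half-open
[start, end) on the plus strand of the reference (the convention of BED and
of rMATS ``*Start_0base`` / ``*End`` column pairs). GTF I/O converts to/from
1-based inclusive at the boundary.
"""
from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returns DNA letters)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G+C; strand-invariant. Empty sequence -> ValueError."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def get_chrom_seq(genome, chrom: str) -> str:
    """Plus-strand sequence of a chromosome.

    Accepts a plain ``{name: sequence}`` mapping (e.g. ``ToyGenome``
    ``chrom_sequences``), an object exposing such a mapping, or a
    ``pyfaidx.Fasta`` handle.
    """
    if hasattr(genome, "chrom_sequences"):
        genome = genome.chrom_sequences
    if isinstance(genome, dict):
        try:
            return genome[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None
    # pyfaidx.Fasta and friends
    try:
        rec = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not in genome") from None
    return str(rec[:])


def fetch(genome, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Sequence of [start, end) on ``strand`` (transcript orientation)."""
    if start < 0 or end < start:
        raise ValueError(f"bad interval [{start}, {end})")
    seq = get_chrom_seq(genome, chrom)
    if end > len(seq):
        raise ValueError(
            f"interval [{start}, {end}) outside chromosome {chrom!r} "
            f"(length {len(seq)})"
        )
    sub = seq[start:end]
    return sub if strand == "+" else revcomp(sub)
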