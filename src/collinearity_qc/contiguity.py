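"""Assembly contiguity statistics: sequence counts, Nx/Lx, cumulative curve.

Nx is the length of the shortest sequence among the largest sequences
that jointly cover at least x of the total assembly length; Lx is how
many sequences that takes.  The threshold comparison is ``>=`` on the
exact (unrounded) value of ``x * total_length``, the convention used by
published assembly-statistics tools.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigError, InputError


@dataclass(frozen=True)
class SequenceLengths:
    """Sequence lengths of one assembly (a multiset, order-irrelevant)."""

    assembly_label: str
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.lengths):
            raise InputError(f"all sequence lengths must be >= 1 ({self.assembly_label})")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class ContiguityStats:
    assembly_label: str
    n_sequences: int
    total_length: int
    n50: int
    n90: int
    l50: int
    l90: int

    def as_dict(self) -> dict:
        return {
            "assembly": self.assembly_label,
            "n_sequences": self.n_sequences,
            "total_length": self.total_length,
            "n50": self.n50,
            "n90": self.n90,
            "l50": self.l50,
            "l90": self.l90,
        }


def read_lengths(fasta_path: str | Path, assembly_label: str | None = None) -> SequenceLengths:
    """Sequence lengths from a FASTA file (plain or gzip).

    Length is the count of residue characters per record.  Empty files,
    zero-length records and duplicate sequence names are rejected.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"FASTA file not found: {fasta_path}")
    opener = gzip.open if fasta_path.suffix == ".gz" else open
    lengths: list[int] = []
    seen: set[str] = set()
    with opener(fasta_path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise InputError(f"duplicate sequence name {rec.id!r} in {fasta_path}")
            seen.add(rec.id)
            if len(rec.seq) == 0:
                raise InputError(f"zero-length record {rec.id!r} in {fasta_path}")
            lengths.append(len(rec.seq))
    if not lengths:
        raise InputError(f"no sequences in {fasta_path}")
    return SequenceLengths(assembly_label or fasta_path.stem, tuple(lengths))


def nx_lx(lengths: SequenceLengths, x: float) -> tuple[int, int]:
    """(Nx, Lx) for a fraction x in (0, 1).

    With lengths sorted descending, Lx is the smallest k whose top-k sum
    reaches ``x * total_length`` and Nx is the k-th length.
    """
    if not 0 < x < 1:
        raise ConfigError(f"x must be in (0, 1): {x}")
    if len(lengths) == 0:
        raise InputError("empty length set")
    desc = np.sort(np.asarray(lengths.lengths, dtype=np.int64))[::-1]
    cum = np.cumsum(desc)
    # smallest k (0-based) with cum[k] >= x * total; equality counts as
    # reached, so the threshold is formed exactly (float 0.9 * total can
    # overshoot an integer boundary by one ulp)
    thr = Fraction(str(x)) * lengths.total_length
    k = int(np.searchsorted(cum, float(thr), side="left"))
    while k > 0 and int(cum[k - 1]) >= thr:
        k -= 1
    while int(cum[k]) < thr:
        k += 1
    return int(desc[k]), k + 1


def contiguity_stats(lengths: SequenceLengths) -> ContiguityStats:
    n50, l50 = nx_lx(lengths, 0.5)
    n90, l90 = nx_lx(lengths, 0.9)
    return ContiguityStats(
        assembly_label=lengths.assembly_label,
        n_sequences=len(lengths),
        total_length=lengths.total_length,
        n50=n50, n90=n90, l50=l50, l90=l90,
    )


def cumulative_curve(lengths: SequenceLengths) -> list[tuple[int, int]]:
    """(k, cumulative bp of the k largest sequences) for k = 1..n."""
    if len(lengths) == 0:
        raise InputError("empty length set")
    desc = sorted(lengths.lengths, reverse=True)
    out: list[tuple[int, int]] = []
    total = 0
    for k, l in enumerate(desc, start=1):
        total += l
        out.append((k, total))
    return out


def write_curve_tsv(curve: Sequence[tuple[int, int]], path: str | Path) -> Path:
    """Write the cumulative curve as a 2-column TSV for plotting."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("k\tcumulative_bp\n")
        for k, bp in curve:
            fh.write(f"{k}\t{bp}\n")
    return path
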