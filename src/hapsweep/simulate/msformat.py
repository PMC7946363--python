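"""ms-format text import/export.

The classic coalescent-simulator dialect: a command/header line, one blank
line, then per replicate a ``//`` separator, ``segsites: <k>``, a
``positions: <f1> <f2> ...`` line (fractions of the segment on [0, 1]),
and one 0/1 row per sampled chromosome. Fractional positions convert to
strictly increasing integer bp by rounding against the segment length and
bumping collisions upward by one bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import numpy as np

from ..hapstats import HaplotypeMatrix

__all__ = ["MsReplicate", "read_ms", "write_ms", "ms_to_matrix", "matrix_to_ms"]


@dataclass(frozen=True)
class MsReplicate:
    positions: tuple[float, ...]  # fractional, sorted
    haplotypes: np.ndarray  # n x segsites int8
    index: int = 0

    def __post_init__(self):
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.size and hap.ndim != 2:
            raise ValueError("haplotype rows must form a matrix")
        if hap.size and hap.shape[1] != len(self.positions):
            raise ValueError("row length must equal segsites")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("positions must be sorted")
        object.__setattr__(self, "haplotypes", hap)

    @property
    def segsites(self) -> int:
        return len(self.positions)


def read_ms(stream: TextIO | Iterable[str]) -> Iterator[MsReplicate]:
    """Parse an ms-format stream into replicates.

    Malformed blocks raise ``ValueError`` carrying the offending line
    number.
    """
    lines = list(stream)
    i, n = 0, len(lines)
    index = 0

    def err(lineno: int, msg: str):
        return ValueError(f"ms parse error at line {lineno}: {msg}")

    while i < n:
        if not lines[i].strip().startswith("//"):
            i += 1
            continue
        i += 1
        while i < n and not lines[i].strip():
            i += 1
        if i >= n or not lines[i].strip().startswith("segsites:"):
            raise err(i + 1, "expected 'segsites:' after '//'")
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise err(i + 1, f"bad segsites count in {lines[i]!r}") from None
        i += 1
        if segsites == 0:
            yield MsReplicate((), np.zeros((0, 0), np.int8), index)
            index += 1
            continue
        while i < n and not lines[i].strip():
            i += 1
        if i >= n or not lines[i].strip().startswith("positions:"):
            raise err(i + 1, "expected 'positions:' line")
        positions = tuple(float(x) for x in lines[i].split(":", 1)[1].split())
        if len(positions) != segsites:
            raise err(i + 1, f"{len(positions)} positions for {segsites} segsites")
        i += 1
        rows = []
        while i < n:
            text = lines[i].strip()
            if not text or text.startswith("//"):
                break
            if len(text) != segsites or not set(text) <= {"0", "1"}:
                raise err(i + 1, f"bad haplotype row {text!r}")
            rows.append([int(c) for c in text])
            i += 1
        yield MsReplicate(positions, np.array(rows, np.int8), index)
        index += 1


def write_ms(reps: Iterable[MsReplicate], stream: TextIO, header: str = "ms") -> None:
    """Write replicates in ms format (read_ms . write_ms is the identity
    on replicate content, modulo float formatting)."""
    stream.write(header.rstrip("\n") + "\n\n")
    for rep in reps:
        stream.write("//\n")
        stream.write(f"segsites: {rep.segsites}\n")
        if rep.segsites:
            stream.write(
                "positions: " + " ".join(f"{p:.8f}" for p in rep.positions) + "\n"
            )
            for row in rep.haplotypes:
                stream.write("".join(str(int(a)) for a in row) + "\n")
        stream.write("\n")


def ms_to_matrix(
    rep: MsReplicate, seq_length: int, chrom: str | None = None
) -> HaplotypeMatrix:
    """Convert fractional positions to strictly increasing integer bp.

    bp = round(fraction * seq_length); collisions (and any non-increase)
    are bumped upward by 1 bp, deterministically.
    """
    out = []
    prev = 0
    for p in rep.positions:
        b = max(int(round(p * seq_length)), prev + 1)
        out.append(b)
        prev = b
    return HaplotypeMatrix(
        alleles=rep.haplotypes,
        positions=np.array(out, dtype=np.int64),
        chrom=chrom or f"rep{rep.index}",
    )


def matrix_to_ms(matrix: HaplotypeMatrix, seq_length: int, index: int = 0) -> MsReplicate:
    return MsReplicate(
        positions=tuple(float(p) / seq_length for p in matrix.positions),
        haplotypes=matrix.alleles,
        index=index,
    )
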