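"""Detection of stable local secondary-structure domains.

A sequence of length L is divided into consecutive blocks (default 10 nt;
a short trailing block keeps coverage total), and every run of successive
blocks is a domain candidate D.  Each candidate is scored by two normalized
sums of base-pairing probabilities:

    p_inside(D)  = sum_{i<j, i,j in D} p_ij / |D|^2
    p_io(D)      = sum_{i<j, exactly one of i,j in D} p_ij / ((L - |D|) |D|)

A region that pairs densely within itself (high p_inside) while pairing
negligibly with the rest of the molecule (low p_io) folds as a
self-contained local structure — a structural domain.  The default
extraction rule is p_inside > 0.003 and p_io < 0.0003 (strict), with the
cross sum taken over unordered pairs counted once; a ``symmetric_double_count``
flag reproduces the alternative reading in which each cross pair is counted
in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .bpp import BasePairProbabilityMatrix

__all__ = [
    "BlockDecomposition",
    "DomainCandidate",
    "DomainScore",
    "ExtractionPolicy",
    "decompose_blocks",
    "enumerate_candidates",
    "score_candidate",
    "extract_domains",
    "scan_report",
    "write_bed",
]

DEFAULT_BLOCK_SIZE = 10
DEFAULT_THRESHOLD_INSIDE = 0.003
DEFAULT_THRESHOLD_IO = 0.0003


@dataclass(frozen=True)
class BlockDecomposition:
    """Division of positions 1..L into consecutive fixed-size blocks.

    All blocks have exactly ``block_size`` positions except possibly the
    last, which holds the remainder so that no position is dropped.
    """

    sequence_length: int
    block_size: int = DEFAULT_BLOCK_SIZE

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError(f"sequence_length must be >= 1, got {self.sequence_length}")
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")

    @property
    def n_blocks(self) -> int:
        return -(-self.sequence_length // self.block_size)

    def block_range(self, index: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of block ``index`` (0-based)."""
        if not (0 <= index < self.n_blocks):
            raise IndexError(f"block index {index} outside 0..{self.n_blocks - 1}")
        start = index * self.block_size + 1
        end = min(start + self.block_size - 1, self.sequence_length)
        return start, end

    @property
    def blocks(self) -> list[tuple[int, int]]:
        return [self.block_range(b) for b in range(self.n_blocks)]


@dataclass(frozen=True)
class DomainCandidate:
    """A contiguous run of blocks: positions start..end, 1-based inclusive."""

    first_block: int
    last_block: int
    start: int
    end: int
    sequence_length: int

    @property
    def size(self) -> int:
        """|D|, the number of positions inside the candidate."""
        return self.end - self.start + 1

    def contains(self, other: "DomainCandidate") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "DomainCandidate") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class DomainScore:
    """The two block statistics of a candidate."""

    p_inside: float
    p_inside_outside: float


@dataclass(frozen=True)
class ExtractionPolicy:
    """Thresholds and reporting mode for domain extraction.

    ``all_passing`` reports every candidate satisfying both strict
    inequalities; ``maximal_passing`` (default) drops passing candidates
    strictly contained in another passing candidate; ``best_nonoverlapping``
    greedily keeps candidates by descending p_inside, excluding overlaps.
    """

    threshold_inside: float = DEFAULT_THRESHOLD_INSIDE
    threshold_io: float = DEFAULT_THRESHOLD_IO
    report_mode: Literal["all_passing", "maximal_passing", "best_nonoverlapping"] = (
        "maximal_passing"
    )
    symmetric_double_count: bool = False

    def __post_init__(self) -> None:
        if self.threshold_inside < 0 or self.threshold_io < 0:
            raise ValueError("thresholds must be >= 0")
        if self.report_mode not in ("all_passing", "maximal_passing", "best_nonoverlapping"):
            raise ValueError(f"unknown report_mode {self.report_mode!r}")

    def passes(self, score: DomainScore) -> bool:
        return (
            score.p_inside > self.threshold_inside
            and score.p_inside_outside < self.threshold_io
        )


def decompose_blocks(length: int, block_size: int = DEFAULT_BLOCK_SIZE) -> BlockDecomposition:
    """Divide 1..length into ceil(length / block_size) consecutive blocks."""
    return BlockDecomposition(sequence_length=length, block_size=block_size)


def enumerate_candidates(decomp: BlockDecomposition) -> list[DomainCandidate]:
    """Every run of successive blocks, in lexicographic (first, last) order.

    For B blocks there are exactly B(B+1)/2 candidates.
    """
    out: list[DomainCandidate] = []
    for first in range(decomp.n_blocks):
        start = decomp.block_range(first)[0]
        for last in range(first, decomp.n_blocks):
            end = decomp.block_range(last)[1]
            out.append(
                DomainCandidate(
                    first_block=first,
                    last_block=last,
                    start=start,
                    end=end,
                    sequence_length=decomp.sequence_length,
                )
            )
    return out


def _prefix(matrix: BasePairProbabilityMatrix) -> np.ndarray:
    """2-D inclusive prefix sums of the symmetric matrix, padded by one."""
    S = matrix.symmetric
    C = np.zeros((matrix.length + 1, matrix.length + 1))
    C[1:, 1:] = S.cumsum(axis=0).cumsum(axis=1)
    return C

def _block_sum(C: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    # sum of S[a..b, c..d], 1-based inclusive
    return float(C[b, d] - C[a - 1, d] - C[b, c - 1] + C[a - 1, c - 1])


def _score_from_prefix(
    C: np.ndarray, cand: DomainCandidate, symmetric_double_count: bool
) -> DomainScore:
    L = cand.sequence_length
    a, b = cand.start, cand.end
    d = cand.size
    inside = _block_sum(C, a, b, a, b) / 2.0  # symmetric block counts each pair twice
    row_mass = _block_sum(C, a, b, 1, L)
    cross = row_mass - 2.0 * inside
    if symmetric_double_count:
        cross *= 2.0
    p_inside = inside / (d * d)
    p_io = 0.0 if d == L else cross / ((L - d) * d)
    return DomainScore(p_inside=p_inside, p_inside_outside=p_io)


def score_candidate(
    cand: DomainCandidate,
    matrix: BasePairProbabilityMatrix,
    symmetric_double_count: bool = False,
) -> DomainScore:
    """Score one candidate.

    p_inside sums p_ij over unordered pairs with both ends in D, divided by
    |D|^2.  p_inside_outside sums p_ij over unordered pairs with exactly one
    end in D, divided by (L - |D|)|D|; for the whole-sequence candidate the
    cross set is empty and the statistic is defined as 0.  With
    ``symmetric_double_count`` each cross pair is counted twice (the
    (D^c x D) and (D x D^c) directions separately).
    """
    if cand.sequence_length != matrix.length:
        raise ValueError(
            f"candidate length {cand.sequence_length} != matrix length {matrix.length}"
        )
    return _score_from_prefix(_prefix(matrix), cand, symmetric_double_count)


def _select(
    scored: list[tuple[DomainCandidate, DomainScore]],
    policy: ExtractionPolicy,
) -> list[tuple[DomainCandidate, DomainScore]]:
    passing = [(c, s) for c, s in scored if policy.passes(s)]
    if policy.report_mode == "all_passing":
        chosen = passing
    elif policy.report_mode == "maximal_passing":
        chosen = [
            (c, s)
            for c, s in passing
            if not any(o.contains(c) and o != c for o, _ in passing)
        ]
    else:  # best_nonoverlapping
        chosen = []
        for c, s in sorted(passing, key=lambda cs: (-cs[1].p_inside, cs[0].start, cs[0].end)):
            if not any(c.overlaps(o) for o, _ in chosen):
                chosen.append((c, s))
    return sorted(chosen, key=lambda cs: (cs[0].start, cs[0].end))


def extract_domains(
    matrix: BasePairProbabilityMatrix,
    policy: ExtractionPolicy | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> list[tuple[DomainCandidate, DomainScore]]:
    """Scan every candidate and return those passing the extraction policy,
    sorted by start position.  Fully deterministic."""
    policy = policy or ExtractionPolicy()
    decomp = decompose_blocks(matrix.length, block_size)
    C = _prefix(matrix)
    scored = [
        (cand, _score_from_prefix(C, cand, policy.symmetric_double_count))
        for cand in enumerate_candidates(decomp)
    ]
    return _select(scored, policy)


def scan_report(
    matrix: BasePairProbabilityMatrix,
    policy: ExtractionPolicy | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """One row per candidate: start, end, size, p_inside, p_io, passes.

    Coordinates are 1-based inclusive; rows are in candidate enumeration
    order (lexicographic by block run).
    """
    policy = policy or ExtractionPolicy()
    decomp = decompose_blocks(matrix.length, block_size)
    C = _prefix(matrix)
    rows = []
    for cand in enumerate_candidates(decomp):
        score = _score_from_prefix(C, cand, policy.symmetric_double_count)
        rows.append(
            {
                "start": cand.start,
                "end": cand.end,
                "size": cand.size,
                "p_inside": score.p_inside,
                "p_io": score.p_inside_outside,
                "passes": policy.passes(score),
            }
        )
    return pd.DataFrame(rows, columns=["start", "end", "size", "p_inside", "p_io", "passes"])


def write_bed(
    domains: list[tuple[DomainCandidate, DomainScore]],
    path: str | Path,
    chrom: str = "seq",
) -> None:
    """Export extracted domains as BED (0-based half-open); the score column
    is p_inside scaled by 1000 and clamped to [0, 1000]."""
    with Path(path).open("w") as handle:
        for k, (cand, score) in enumerate(domains, start=1):
            bed_score = int(min(max(score.p_inside * 1000.0, 0.0), 1000.0))
            handle.write(
                f"{chrom}\t{cand.start - 1}\t{cand.end}\tdomain_{k}\t{bed_score}\t+\n"
            )
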