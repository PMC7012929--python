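"""Gamma-centroid secondary-structure prediction from a probability matrix.

The gamma-centroid estimator predicts the nested structure S maximizing

    gain(S) = sum over (i, j) in S of [(gamma + 1) * p_ij - 1]

so only pairs with p_ij > 1/(gamma + 1) can contribute positively.  Larger
gamma trades specificity for sensitivity; gamma = 4 (threshold 0.2) is the
conventional working point for locating well-supported local helices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .bpp import BasePairProbabilityMatrix

__all__ = [
    "SecondaryStructure",
    "CentroidParams",
    "gamma_centroid",
    "expected_gain",
    "to_dot_bracket",
    "from_dot_bracket",
]


class DotBracketError(ValueError):
    """Raised on malformed dot-bracket text."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs on positions 1..length."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i}, {j}) violates 1 <= i < j <= {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position reused by pair ({i}, {j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1 :]:
                if k > j:
                    break
                if k > i and l > j:  # i < k <= j < l
                    raise ValueError(
                        f"crossing pairs ({i}, {j}) and ({k}, {l}): structure is not nested"
                    )

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls, length: int) -> "SecondaryStructure":
        return cls(length=length, pairs=frozenset())


@dataclass(frozen=True)
class CentroidParams:
    """Estimator parameter: gamma > 0, default 4 (pair threshold 1/(gamma+1) = 0.2)."""

    gamma: float = 4.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @property
    def threshold(self) -> float:
        return 1.0 / (self.gamma + 1.0)


def expected_gain(
    structure: SecondaryStructure,
    matrix: BasePairProbabilityMatrix,
    params: CentroidParams | None = None,
) -> float:
    """The estimator's objective: sum of (gamma+1)*p_ij - 1 over the pairs.

    Additive over disjoint pair sets; the empty structure scores 0.
    """
    params = params or CentroidParams()
    if structure.length != matrix.length:
        raise ValueError(
            f"structure length {structure.length} != matrix length {matrix.length}"
        )
    g1 = params.gamma + 1.0
    return sum(g1 * matrix[i, j] - 1.0 for i, j in structure.pairs)


def gamma_centroid(
    matrix: BasePairProbabilityMatrix, params: CentroidParams | None = None
) -> SecondaryStructure:
    """Maximum-gain nested structure by interval dynamic programming.

    Only pairs with p_ij strictly above 1/(gamma+1) may appear: a pair at
    exactly the threshold has zero gain and is excluded, so the reported
    structure is the canonical minimum-pair argmax.  Ties between equal-gain
    decompositions are broken toward fewer pairs, then toward the
    lexicographically smallest pair set.
    """
    params = params or CentroidParams()
    L = matrix.length
    g1 = params.gamma + 1.0
    P = matrix.symmetric
    gain = g1 * np.triu(P, k=1) - 1.0
    eligible = gain > 0.0
    if not eligible.any():
        return SecondaryStructure.empty(L)
    gain = np.where(eligible, gain, -np.inf)

    # G[i, j+1]: best gain on closed 0-based interval i..j; Np: its pair count
    # under the fewest-pairs tie-break.  Padded so empty intervals read 0.
    G = np.zeros((L, L + 1))
    Np = np.zeros((L, L + 1), dtype=np.int64)
    for span in range(2, L + 1):
        for i in range(L - span + 1):
            j = i + span - 1
            best_g = G[i, j]  # j unpaired
            best_n = Np[i, j]
            if eligible[i : j + 1, j].any():
                ks = np.nonzero(eligible[i : j + 1, j])[0] + i
                left_g = G[i, ks]  # interval i..k-1
                left_n = Np[i, ks]
                inner_g = np.where(ks + 1 < L, G[np.minimum(ks + 1, L - 1), j], 0.0)
                inner_n = np.where(ks + 1 < L, Np[np.minimum(ks + 1, L - 1), j], 0)
                cand_g = left_g + inner_g + gain[ks, j]
                cand_n = left_n + inner_n + 1
                order = np.lexsort((cand_n, -cand_g))
                top = order[0]
                if cand_g[top] > best_g or (
                    cand_g[top] == best_g and cand_n[top] < best_n
                ):
                    best_g = cand_g[top]
                    best_n = cand_n[top]
            G[i, j + 1] = best_g
            Np[i, j + 1] = best_n

    pairs: set[tuple[int, int]] = set()

    def trace(i: int, j: int) -> None:
        while j > i:
            if G[i, j + 1] == G[i, j] and Np[i, j + 1] == Np[i, j]:
                j -= 1  # j unpaired; preferred on ties (fewer pairs / smaller indices)
                continue
            for k in range(i, j):
                if not eligible[k, j]:
                    continue
                lg, ln = G[i, k], Np[i, k]
                ig = G[k + 1, j] if k + 1 < L else 0.0
                inn = Np[k + 1, j] if k + 1 < L else 0
                if (
                    lg + ig + gain[k, j] == G[i, j + 1]
                    and ln + inn + 1 == Np[i, j + 1]
                ):
                    pairs.add((k + 1, j + 1))
                    trace(k + 1, j - 1)
                    j = k - 1
                    break
            else:  # pragma: no cover - DP and traceback disagree
                raise AssertionError("traceback failed to reproduce the DP optimum")

    trace(0, L - 1)
    return SecondaryStructure(length=L, pairs=frozenset(pairs))


def to_dot_bracket(structure: SecondaryStructure) -> str:
    """Render as dot-bracket: '(' and ')' at paired positions, '.' elsewhere."""
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def from_dot_bracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket text; raises :class:`DotBracketError` with the
    offending 1-based position on unbalanced input."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise DotBracketError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise DotBracketError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs))
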