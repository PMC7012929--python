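"""Base-pairing probability matrices from an inside-outside partition function.

The folding model is deliberately simple: each allowed base pair carries a
positive Boltzmann weight (optionally per pair type), adjacent nested pairs
may receive a multiplicative stacking bonus, and a hairpin loop must enclose
at least ``min_loop`` unpaired nucleotides.  The ensemble is the set of all
pseudoknot-free structures.  The algorithmic structure (O(L^3) inside and
outside dynamic programming over an unambiguous decomposition) is exactly
that of the standard McCaskill computation; only the per-structure weight is
simplified.  Matrices computed under a full nearest-neighbour model by an
external folder can be imported via :func:`read_bpp` and flow through the
downstream machinery unchanged, because everything downstream consumes only
the matrix.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .constructs import AlphabetError, RnaSequence

__all__ = [
    "FoldingModel",
    "BasePairProbabilityMatrix",
    "StructureEnsemble",
    "partition_function",
    "base_pair_probabilities",
    "enumerate_structures",
    "structure_weight",
    "read_bpp",
    "write_bpp",
]

#: Default per-pair-type Boltzmann weights.  Ordered to reflect relative
#: stability: a G-C pair (three hydrogen bonds) outweighs A-U, which
#: outweighs the wobble G-U.  Magnitudes are order-one so that partition
#: values stay well scaled for typical lengths.
DEFAULT_PAIR_WEIGHTS: Mapping[str, float] = {"GC": 3.0, "AU": 2.0, "GU": 1.0}

ROW_SUM_TOL = 1e-9


def _pair_key(a: str, b: str) -> str:
    """Canonical unordered key for a residue pair, e.g. ('U','A') -> 'AU'."""
    return a + b if a <= b else b + a


@dataclass(frozen=True)
class FoldingModel:
    """A weight-per-pair Boltzmann model of RNA secondary structure.

    Parameters
    ----------
    allowed_pairs
        Unordered residue pairs that may form, as canonical two-letter keys.
    pair_weight
        Either a single positive weight for every allowed pair, or a mapping
        from canonical pair key to weight.
    min_loop
        Minimum number of unpaired nucleotides enclosed by a pair
        (the steric hairpin-loop constraint; pair (i, j) requires
        j - i > min_loop).
    stacking_bonus
        Multiplicative weight applied once for every pair (i, j) whose
        inner neighbour (i+1, j-1) is also paired; 1.0 disables stacking.
    """

    allowed_pairs: frozenset[str] = frozenset(DEFAULT_PAIR_WEIGHTS)
    pair_weight: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    min_loop: int = 3
    stacking_bonus: float = 1.0

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError(f"min_loop must be >= 0, got {self.min_loop}")
        if self.stacking_bonus <= 0:
            raise ValueError(f"stacking_bonus must be > 0, got {self.stacking_bonus}")
        normalized = set()
        for key in self.allowed_pairs:
            if len(key) != 2 or set(key) - set("ACGU"):
                raise ValueError(f"allowed pair {key!r} is not a two-letter RNA pair key")
            normalized.add(_pair_key(*key))
        object.__setattr__(self, "allowed_pairs", frozenset(normalized))
        if isinstance(self.pair_weight, Mapping):
            weights = {}
            for k, w in self.pair_weight.items():
                if w <= 0:
                    raise ValueError(f"pair weight for {k} must be > 0, got {w}")
                weights[_pair_key(*k)] = float(w)
            object.__setattr__(self, "pair_weight", weights)
        elif self.pair_weight <= 0:
            raise ValueError(f"pair_weight must be > 0, got {self.pair_weight}")

    def weight(self, a: str, b: str) -> float:
        """Boltzmann weight of the residue pair (a, b); 0 if disallowed."""
        key = _pair_key(a, b)
        if key not in self.allowed_pairs:
            return 0.0
        if isinstance(self.pair_weight, Mapping):
            return float(self.pair_weight.get(key, 0.0))
        return float(self.pair_weight)

    def weight_matrix(self, residues: str) -> np.ndarray:
        """(L, L) array of pair weights w[i, j] (0-based; 0 where disallowed
        or closer than the minimum loop)."""
        L = len(residues)
        w = np.zeros((L, L))
        for i in range(L):
            for j in range(i + self.min_loop + 1, L):
                w[i, j] = self.weight(residues[i], residues[j])
        return w


class BppFormatError(ValueError):
    """Raised on malformed probability-matrix files."""


class BasePairProbabilityMatrix:
    """Probabilities p_ij that positions i and j (1-based, i < j) are paired.

    Stored as a symmetric (L, L) array with zero diagonal.  The accessor is
    unordered: ``m[i, j] == m[j, i]``.  Each position pairs with at most one
    partner, so every row sum is bounded by 1.
    """

    def __init__(self, length: int, entries: np.ndarray | Mapping[tuple[int, int], float]):
        if length < 1:
            raise ValueError(f"length must be >= 1, got {length}")
        self.length = int(length)
        if isinstance(entries, np.ndarray):
            if entries.shape != (length, length):
                raise ValueError(
                    f"entries shape {entries.shape} does not match length {length}"
                )
            mat = np.asarray(entries, dtype=float)
            mat = np.triu(mat, k=1)
        else:
            mat = np.zeros((length, length))
            for (i, j), p in entries.items():
                if not (1 <= i < j <= length):
                    raise ValueError(f"entry ({i}, {j}) violates 1 <= i < j <= {length}")
                mat[i - 1, j - 1] = p
        self._upper = mat
        self._validate()

    def _validate(self) -> None:
        m = self._upper
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-9):
            bad = np.argwhere((m < -1e-12) | (m > 1 + 1e-9))[0]
            raise ValueError(
                f"probability out of [0, 1] at ({bad[0] + 1}, {bad[1] + 1}): "
                f"{m[bad[0], bad[1]]}"
            )
        np.clip(m, 0.0, 1.0, out=m)
        rows = self.row_sums()
        if np.any(rows > 1 + ROW_SUM_TOL):
            i = int(np.argmax(rows))
            raise ValueError(
                f"row sum at position {i + 1} is {rows[i]:.6g} > 1: a base "
                "can pair with at most one partner"
            )

    @property
    def symmetric(self) -> np.ndarray:
        """Full symmetric (L, L) array (copy-free view is not guaranteed)."""
        return self._upper + self._upper.T

    def row_sums(self) -> np.ndarray:
        """Total pairing probability per position, sum_j p_ij."""
        return self._upper.sum(axis=0) + self._upper.sum(axis=1)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        if not (1 <= i < j <= self.length):
            raise IndexError(f"({ij[0]}, {ij[1]}) outside 1..{self.length}")
        return float(self._upper[i - 1, j - 1])

    def entries(self, floor: float = 0.0) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, p) for entries with p > floor, 1-based, sorted by (i, j)."""
        ii, jj = np.nonzero(self._upper > floor)
        order = np.lexsort((jj, ii))
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            yield i + 1, j + 1, float(self._upper[i, j])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BasePairProbabilityMatrix):
            return NotImplemented
        return self.length == other.length and np.array_equal(self._upper, other._upper)


@dataclass(frozen=True)
class StructureEnsemble:
    """An explicitly enumerated Boltzmann ensemble (testing/oracle use only)."""

    length: int
    structures: list[tuple[frozenset[tuple[int, int]], float]]

    @property
    def partition_value(self) -> float:
        return sum(w for _, w in self.structures)

    def pair_probability(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        z = self.partition_value
        return sum(w for pairs, w in self.structures if (i, j) in pairs) / z


def _seq_residues(seq: RnaSequence | str) -> str:
    if isinstance(seq, RnaSequence):
        return seq.residues
    return RnaSequence(id="", residues=seq).residues


def _inside(w: np.ndarray, stack: float, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Inside DP over the unambiguous rightmost-pair decomposition.

    ``A[i, j+1]`` holds the (scaled) partition value of the closed interval
    i..j; ``B[i, j]`` the value restricted to structures in which (i, j) is
    paired.  Scaling multiplies each nucleotide by 1/scale, so the true
    partition value is ``A[0, L] * scale**L``.
    """
    L = w.shape[0]
    q = 1.0 / scale
    q2 = q * q
    A = np.ones((L, L + 1))
    B = np.zeros((L, L))
    s1 = stack - 1.0
    for span in range(1, L + 1):
        for i in range(L - span + 1):
            j = i + span - 1
            if w[i, j] > 0.0:
                interior = A[i + 1, j] if i + 1 < L else 1.0
                stacked = B[i + 1, j - 1] if s1 != 0.0 and i + 1 <= j - 1 else 0.0
                B[i, j] = w[i, j] * q2 * (interior + s1 * stacked)
            # j unpaired, or paired with some k in i..j-1
            A[i, j + 1] = A[i, j] * q + float(np.dot(A[i, i : j + 1], B[i : j + 1, j]))
    return A, B


def _outside(A: np.ndarray, B: np.ndarray, w: np.ndarray, stack: float, scale: float) -> np.ndarray:
    """Outside pass mirroring :func:`_inside`; returns OB with
    p[i, j] = B[i, j] * OB[i, j] / A[0, L]."""
    L = w.shape[0]
    q = 1.0 / scale
    q2 = q * q
    s1 = stack - 1.0
    OA = np.zeros((L, L + 1))
    OB = np.zeros((L, L))
    OA[0, L] = 1.0
    for span in range(L, 0, -1):
        # interval decompositions first: they feed OB cells of the same span
        for i in range(L - span + 1):
            j = i + span - 1
            o = OA[i, j + 1]
            if o != 0.0:
                OA[i, j] += o * q
                OA[i, i : j + 1] += o * B[i : j + 1, j]
                OB[i : j + 1, j] += o * A[i, i : j + 1]
        for i in range(L - span + 1):
            j = i + span - 1
            ob = OB[i, j]
            if ob != 0.0 and w[i, j] > 0.0:
                c = w[i, j] * q2 * ob
                if i + 1 < L:
                    OA[i + 1, j] += c
                if s1 != 0.0 and i + 1 <= j - 1:
                    OB[i + 1, j - 1] += s1 * c
    return OB


def _run_scaled(w: np.ndarray, stack: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Run the inside DP, adapting the per-nucleotide scale until all cell
    magnitudes are representable in double precision."""
    L = w.shape[0]
    scale = 1.0
    for _ in range(12):
        with np.errstate(over="ignore", invalid="ignore"):
            A, B = _inside(w, stack, scale)
        finite = bool(np.isfinite(A).all() and np.isfinite(B).all())
        z = A[0, L]
        if finite and z > 0.0:
            return A, B, scale, z
        if not finite:
            scale *= math.exp(600.0 / L)  # push magnitudes down by ~e^600 overall
        else:  # underflow: scale chosen too aggressively on a sparse ensemble
            scale *= math.exp(-600.0 / L)
    raise ArithmeticError("partition function could not be scaled into range")


def partition_function(seq: RnaSequence | str, model: FoldingModel | None = None) -> float:
    """Boltzmann partition value Z over all nested structures of ``seq``.

    Z is the sum over every pseudoknot-free structure of the product of its
    pair weights (times stacking bonuses).  The empty structure contributes
    1, so Z = 1 exactly when no pair is possible.  Returns ``inf`` if the
    unscaled value exceeds double range (the scaled computation used for
    probabilities is unaffected; see :func:`base_pair_probabilities`).
    """
    model = model or FoldingModel()
    residues = _seq_residues(seq)
    w = model.weight_matrix(residues)
    L = len(residues)
    A, _, scale, z = _run_scaled(w, model.stacking_bonus)
    return z * scale**L


def base_pair_probabilities(
    seq: RnaSequence | str, model: FoldingModel | None = None
) -> BasePairProbabilityMatrix:
    """The base-pairing probability matrix {p_ij} of ``seq`` under ``model``.

    p_ij is the Boltzmann-ensemble probability that positions i and j form a
    base pair, computed by the inside-outside recursions in O(L^3) time.
    """
    model = model or FoldingModel()
    residues = _seq_residues(seq)
    w = model.weight_matrix(residues)
    A, B, scale, z = _run_scaled(w, model.stacking_bonus)
    OB = _outside(A, B, w, model.stacking_bonus, scale)
    p = B * OB / z
    np.clip(p, 0.0, 1.0, out=p)
    return BasePairProbabilityMatrix(len(residues), p)


ENUMERATION_CAP = 20


def structure_weight(
    pairs: frozenset[tuple[int, int]], residues: str, model: FoldingModel
) -> float:
    """Boltzmann weight of one explicit structure: the product of its pair
    weights times a stacking bonus for every directly nested adjacent pair.

    Computed from the pair set alone, independently of any recursion.
    """
    weight = 1.0
    for i, j in pairs:
        weight *= model.weight(residues[i - 1], residues[j - 1])
    if model.stacking_bonus != 1.0:
        for i, j in pairs:
            if (i + 1, j - 1) in pairs:
                weight *= model.stacking_bonus
    return weight


def enumerate_structures(
    seq: RnaSequence | str, model: FoldingModel | None = None, cap: int = ENUMERATION_CAP
) -> StructureEnsemble:
    """Exhaustively enumerate every nested structure of a short sequence.

    Intended as a brute-force oracle; refuses sequences longer than ``cap``
    nucleotides because the ensemble grows exponentially.
    """
    model = model or FoldingModel()
    residues = _seq_residues(seq)
    L = len(residues)
    if L > cap:
        raise ValueError(
            f"sequence of length {L} exceeds the enumeration cap of {cap} nt; "
            "exhaustive enumeration is only for oracle-scale inputs"
        )

    def recurse(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        # all nested pair sets on closed 1-based interval i..j
        if j - i < model.min_loop + 1:
            return [frozenset()]
        out = list(recurse(i, j - 1))  # j unpaired
        for k in range(i, j - model.min_loop):
            if model.weight(residues[k - 1], residues[j - 1]) > 0.0:
                for left in recurse(i, k - 1):
                    for inner in recurse(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        return out

    structures = [
        (pairs, structure_weight(pairs, residues, model)) for pairs in recurse(1, L)
    ]
    return StructureEnsemble(length=L, structures=structures)


# --- matrix I/O -------------------------------------------------------------

_UBOX_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s+([0-9.eE+-]+)\s+ubox\s*$")
_SEQUENCE_RE = re.compile(r"/sequence\s*\{?\s*\((.*?)\)\s*\}?\s*def", re.DOTALL)

WRITE_FLOOR = 1e-6


def read_bpp(
    path: str | Path, dialect: str = "tsv", length: int | None = None
) -> BasePairProbabilityMatrix:
    """Read a base-pairing probability matrix.

    ``tsv``: tab-separated ``i<TAB>j<TAB>p`` with 1-based i < j and a
    ``# length=L`` header line.  ``vienna_ubox``: the PostScript dot-plot
    dialect in which each ``i j v ubox`` line stores v = sqrt(p); the
    sequence length is taken from the embedded ``/sequence`` block, or from
    the ``length`` argument.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path, length)
    if dialect == "vienna_ubox":
        return _read_ubox(path, length)
    raise ValueError(f"unknown matrix dialect {dialect!r}")


def _read_tsv(path: Path, length: int | None) -> BasePairProbabilityMatrix:
    entries: dict[tuple[int, int], float] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"length\s*=\s*(\d+)", line)
                if m:
                    length = int(m.group(1))
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise BppFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            try:
                i, j, p = int(fields[0]), int(fields[1]), float(fields[2])
            except ValueError as exc:
                raise BppFormatError(f"{path}:{lineno}: {exc}") from exc
            if i >= j:
                raise BppFormatError(f"{path}:{lineno}: requires i < j, got i={i}, j={j}")
            if not (0.0 <= p <= 1.0):
                raise BppFormatError(f"{path}:{lineno}: probability {p} outside [0, 1]")
            entries[(i, j)] = p
    if length is None:
        raise BppFormatError(f"{path}: no '# length=L' header and no length given")
    for (i, j) in entries:
        if j > length:
            raise BppFormatError(f"{path}: entry ({i}, {j}) exceeds declared length {length}")
    return BasePairProbabilityMatrix(length, entries)


def _read_ubox(path: Path, length: int | None) -> BasePairProbabilityMatrix:
    text = Path(path).read_text()
    if length is None:
        m = _SEQUENCE_RE.search(text)
        if m:
            seq = re.sub(r"[\s\\]", "", m.group(1))
            length = len(seq)
    entries: dict[tuple[int, int], float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _UBOX_RE.match(line)
        if not m:
            continue
        i, j, v = int(m.group(1)), int(m.group(2)), float(m.group(3))
        if i >= j:
            raise BppFormatError(f"{path}:{lineno}: ubox entry requires i < j")
        p = v * v  # dot-plot files store sqrt(p)
        if p > 1.0 + 1e-9:
            raise BppFormatError(f"{path}:{lineno}: implied probability {p} > 1")
        entries[(i, j)] = min(p, 1.0)
    if length is None:
        raise BppFormatError(
            f"{path}: sequence length not found in dot plot; pass length= explicitly"
        )
    return BasePairProbabilityMatrix(length, entries)


def write_bpp(
    matrix: BasePairProbabilityMatrix, path: str | Path, floor: float = WRITE_FLOOR
) -> None:
    """Write the TSV dialect: a ``# length=L`` header, then ``i<TAB>j<TAB>p``
    for every entry above ``floor``, sorted by (i, j)."""
    with Path(path).open("w") as handle:
        handle.write(f"# length={matrix.length}\n")
        for i, j, p in matrix.entries(floor=floor):
            handle.write(f"{i}\t{j}\t{p:.10g}\n")
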