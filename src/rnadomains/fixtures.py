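"""Seeded synthetic fixtures: matrices or sequences with planted domains.

``matrix_only`` mode writes an ideal hairpin signature directly into a
probability matrix: an anti-diagonal stem inside each planted interval plus
sparse uniform cross-noise elsewhere.  ``sequence_with_hairpins`` mode emits
a sequence whose planted intervals are G/C-rich inverted repeats closed by
A-rich loops, embedded in a non-pairing A/C background, so that folding the
sequence reproduces the planted signal.  Identical specs (including the
seed) produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .bpp import BasePairProbabilityMatrix
from .constructs import RnaSequence
from .domains import DEFAULT_THRESHOLD_IO

__all__ = ["FixtureSpec", "PlantedDomain", "generate_fixture", "detectable_stem_probability"]


class FixtureSpecError(ValueError):
    """Raised when a fixture specification cannot guarantee its contract."""


@dataclass(frozen=True)
class PlantedDomain:
    """Ground truth for one planted hairpin: interval and stem pairing level."""

    start: int
    end: int
    stem_probability: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"domain end {self.end} < start {self.start}")
        if not (0.0 < self.stem_probability <= 1.0):
            raise ValueError(
                f"stem_probability must be in (0, 1], got {self.stem_probability}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FixtureSpec:
    """Specification for one synthetic fixture.

    ``background_noise`` bounds every off-domain matrix entry.  It must stay
    strictly below the inside-outside extraction threshold: the worst-case
    cross statistic of any candidate is then below threshold by
    construction, so planted domains cannot be masked by noise.
    """

    seed: int
    length: int
    planted_domains: tuple[PlantedDomain, ...]
    background_noise: float = 2e-4
    mode: Literal["matrix_only", "sequence_with_hairpins"] = "matrix_only"
    io_threshold_guard: float = DEFAULT_THRESHOLD_IO

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.background_noise < 0:
            raise ValueError(f"background_noise must be >= 0, got {self.background_noise}")
        if self.mode not in ("matrix_only", "sequence_with_hairpins"):
            raise ValueError(f"unknown fixture mode {self.mode!r}")
        doms = sorted(self.planted_domains, key=lambda d: d.start)
        for d in doms:
            if d.start < 1 or d.end > self.length:
                raise FixtureSpecError(
                    f"planted domain {d.start}-{d.end} outside 1..{self.length}"
                )
        for a, b in zip(doms, doms[1:]):
            if b.start <= a.end:
                raise FixtureSpecError(
                    f"planted domains {a.start}-{a.end} and {b.start}-{b.end} overlap"
                )
        if self.mode == "matrix_only" and self.background_noise >= self.io_threshold_guard:
            raise FixtureSpecError(
                f"background_noise {self.background_noise} >= inside-outside "
                f"threshold {self.io_threshold_guard}: worst-case cross noise could "
                "exceed the extraction guarantee"
            )


def _stem_pairs(dom: PlantedDomain) -> list[tuple[int, int]]:
    """Anti-diagonal stem entries of a planted hairpin.

    The stem occupies the outer two-thirds of the interval (span // 3 pairs),
    leaving an unpaired loop of at least a third of the span, mimicking a
    simple hairpin geometry.
    """
    n_stem = max(1, dom.span // 3)
    return [(dom.start + k, dom.end - k) for k in range(n_stem)]


def detectable_stem_probability(
    span: int,
    block_size: int = 10,
    threshold_inside: float = 0.003,
) -> float:
    """Stem probability at which a planted hairpin of ``span`` nt is a
    *sharp* domain: the planted candidate passes the inside threshold while
    any candidate extended by one block fails it.

    The inside statistic of the planted interval is stem_sum / span^2 and of
    a one-block extension stem_sum / (span + block)^2, so any target inside
    value c with threshold < c < threshold * ((span + block)/span)^2 works;
    the geometric midpoint of that window is used.
    """
    upper = threshold_inside * ((span + block_size) / span) ** 2
    target_inside = float(np.sqrt(threshold_inside * upper))
    n_stem = max(1, span // 3)
    p = target_inside * span * span / n_stem
    if p > 1.0:
        raise FixtureSpecError(
            f"span {span} too long for a sharply detectable stem "
            f"(would need stem probability {p:.3g} > 1)"
        )
    return p


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[BasePairProbabilityMatrix | RnaSequence, list[PlantedDomain]]:
    """Generate the fixture and return it with its ground-truth domain table."""
    rng = np.random.default_rng(spec.seed)
    truth = sorted(spec.planted_domains, key=lambda d: d.start)
    if spec.mode == "matrix_only":
        return _matrix_fixture(spec, rng, truth), truth
    return _sequence_fixture(spec, rng, truth), truth


def _matrix_fixture(
    spec: FixtureSpec, rng: np.random.Generator, truth: list[PlantedDomain]
) -> BasePairProbabilityMatrix:
    L = spec.length
    m = np.zeros((L, L))
    in_domain = np.zeros(L + 1, dtype=int)  # position -> 1-based domain id, 0 = none
    for did, dom in enumerate(truth, start=1):
        in_domain[dom.start : dom.end + 1] = did
        for i, j in _stem_pairs(dom):
            m[i - 1, j - 1] = dom.stem_probability
    if spec.background_noise > 0 and L > 1:
        n_noise = L  # sparse: about one extra entry per position
        ii = rng.integers(1, L, size=3 * n_noise)
        jj = rng.integers(1, L + 1, size=3 * n_noise)
        placed = 0
        for i, j in zip(ii, jj):
            if placed >= n_noise:
                break
            if i >= j:
                continue
            if in_domain[i] != 0 and in_domain[i] == in_domain[j]:
                continue  # keep planted intervals clean inside
            m[i - 1, j - 1] += rng.uniform(0.0, spec.background_noise)
            placed += 1
    row_sums = m.sum(axis=0) + m.sum(axis=1)
    if np.any(row_sums > 1.0):
        pos = int(np.argmax(row_sums))
        raise FixtureSpecError(
            f"row sum {row_sums[pos]:.4g} > 1 at position {pos + 1}: planted stems "
            "plus noise violate the one-partner-per-base bound"
        )
    return BasePairProbabilityMatrix(L, m)


# The background and loops are adenosine-only: A pairs with neither itself
# nor the G/C stem arms under the AU/GC/GU rules, so all pairing probability
# concentrates on the planted inverted repeats.
_STEM = np.array(list("GC"))


def _sequence_fixture(
    spec: FixtureSpec, rng: np.random.Generator, truth: list[PlantedDomain]
) -> RnaSequence:
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    chars = ["A"] * spec.length
    for dom in truth:
        n_stem = max(1, dom.span // 3)
        arm = rng.choice(_STEM, size=n_stem).tolist()
        for k in range(n_stem):
            chars[dom.start - 1 + k] = arm[k]
            chars[dom.end - 1 - k] = comp[arm[k]]
        for pos in range(dom.start - 1 + n_stem, dom.end - n_stem):
            chars[pos] = "A"  # A-rich loop between the arms
    return RnaSequence(id=f"fixture_seed{spec.seed}", residues="".join(chars))
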