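"""Karyotype state space and the whole-chromosome missegregation kernel.

A karyotype is a vector of non-negative integer autosome copy numbers,
canonically of length 22 (autosomes 1-22, genomic order, no sex
chromosomes).  Karyotypes are represented as plain tuples of ints so they
hash and compare by value.  Most functions accept vectors of any length so
that small toy spaces (2-4 chromosomes) can be enumerated exhaustively in
tests; the :func:`parse_karyotype` / :func:`validate_karyotype` entry
points enforce the canonical 22-chromosome form.

Missegregation model
--------------------
During one division each of the parent's ``N_tot = sum(copies)`` chromosome
copies missegregates independently with probability ``p``; a missegregating
copy ends up in one daughter (that daughter gains a copy, the other loses
one), with the direction uniform.  Copy number is therefore conserved:
``daughter1 + daughter2 == 2 * parent`` chromosome-wise on every draw.
Cells with any chromosome at 0 copies, or above ``max_copy``, are
non-viable.  This per-copy Bernoulli kernel is the single place to swap in
alternative missegregation mechanics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

N_AUTOSOMES = 22

Karyotype = Tuple[int, ...]

DIPLOID: Karyotype = (2,) * N_AUTOSOMES


class KaryotypeError(ValueError):
    """Raised on malformed karyotype vectors or invalid kernel parameters."""


@dataclass(frozen=True)
class TransitionKernel:
    """Per-chromosome-copy missegregation model.

    Parameters
    ----------
    p
        Probability that a single chromosome copy missegregates during one
        division.  Dimensionless, ``0 <= p < 1``.
    max_copy
        Viability cap on the copy number of any single chromosome.
    """

    p: float = 1e-3
    max_copy: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise KaryotypeError(f"missegregation rate p must be in [0, 1), got {self.p}")
        if self.max_copy < 1:
            raise KaryotypeError(f"max_copy must be >= 1, got {self.max_copy}")


def parse_karyotype(s: str) -> Karyotype:
    """Parse a dot-separated copy-number string, e.g. ``"2.2.2.....2"``."""
    try:
        k = tuple(int(x) for x in s.strip().split("."))
    except ValueError as e:
        raise KaryotypeError(f"cannot parse karyotype string {s!r}") from e
    return validate_karyotype(k)


def format_karyotype(k: Sequence[int]) -> str:
    """Serialize to the dot-separated string form; round-trips bit-exactly."""
    return ".".join(str(int(x)) for x in k)


def validate_karyotype(k: Sequence[int], n_chrom: int = N_AUTOSOMES) -> Karyotype:
    k = tuple(int(x) for x in k)
    if len(k) != n_chrom:
        raise KaryotypeError(f"karyotype must have {n_chrom} entries, got {len(k)}")
    if any(x < 0 for x in k):
        raise KaryotypeError(f"copy numbers must be >= 0, got {k}")
    return k


def is_viable(k: Sequence[int], max_copy: int = 8) -> bool:
    """A cell is viable iff every chromosome has between 1 and ``max_copy`` copies."""
    return all(1 <= x <= max_copy for x in k)


def manhattan_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Total number of single-chromosome copy changes separating two karyotypes."""
    if len(a) != len(b):
        raise KaryotypeError(f"dimension mismatch: {len(a)} vs {len(b)}")
    return int(sum(abs(int(x) - int(y)) for x, y in zip(a, b)))


def one_step_neighbors(
    k: Sequence[int], max_copy: int = 8, include_nonviable: bool = True
) -> Set[Karyotype]:
    """All karyotypes one missegregation away (+-1 on one chromosome).

    Moves below 0 or above ``max_copy`` are blocked.  Neighbors with a
    chromosome at 0 are non-viable; pass ``include_nonviable=False`` to
    drop them (e.g. when growing the charted region).  An interior
    karyotype (all copies in ``[1, max_copy - 1]``) has exactly
    ``2 * len(k)`` neighbors — 44 in the canonical 22-autosome space.
    """
    k = tuple(int(x) for x in k)
    out: Set[Karyotype] = set()
    for c in range(len(k)):
        for step in (-1, +1):
            new = k[c] + step
            if new < 0 or new > max_copy:
                continue
            nb = k[:c] + (new,) + k[c + 1 :]
            if include_nonviable or is_viable(nb, max_copy):
                out.add(nb)
    return out


def charted_region(
    frequent: Iterable[Sequence[int]], radius: int = 2, max_copy: int = 8
) -> Set[Karyotype]:
    """Viable karyotypes within ``radius`` missegregations of the frequent set.

    The union of closed Manhattan balls around each frequent karyotype,
    restricted to viable states.  Grown by breadth-first expansion through
    viable one-step neighbors; since viability is a per-chromosome box
    constraint, every viable state within the ball is reachable this way.
    """
    if radius < 0:
        raise KaryotypeError(f"radius must be >= 0, got {radius}")
    seeds = [tuple(int(x) for x in k) for k in frequent]
    if not seeds:
        raise KaryotypeError("frequent set is empty")
    region: Set[Karyotype] = {k for k in seeds if is_viable(k, max_copy)}
    frontier = set(region)
    for _ in range(radius):
        nxt: Set[Karyotype] = set()
        for k in frontier:
            for nb in one_step_neighbors(k, max_copy, include_nonviable=False):
                if nb not in region:
                    nxt.add(nb)
        region |= nxt
        frontier = nxt
    return region


def single_ms_probability(
    parent: Sequence[int], child: Sequence[int], kernel: TransitionKernel
) -> float:
    """P(exactly one missegregation during division of *parent* turns the
    focal daughter into *child*).

    With ``n_c`` parental copies of the altered chromosome and ``N_tot``
    total copies, the exactly-one-event probability directed at the focal
    daughter is ``n_c * p * (1 - p)**(N_tot - 1) / 2`` — any one of the
    ``n_c`` copies missegregates, all other copies segregate faithfully,
    and the gained copy lands in the focal daughter with probability 1/2
    (a loss, symmetrically, means it landed in the sister).  Returns 0 for
    parent/child pairs not at Manhattan distance 1.
    """
    d = manhattan_distance(parent, child)
    if d != 1:
        return 0.0
    p = kernel.p
    diff = [int(c) - int(q) for q, c in zip(parent, child)]
    c = next(i for i, x in enumerate(diff) if x != 0)
    n_c = int(parent[c])
    if n_c == 0:
        return 0.0
    n_tot = int(sum(parent))
    return n_c * p * (1.0 - p) ** (n_tot - 1) / 2.0


def _per_copy_delta_dist(p: float) -> Dict[int, float]:
    # Change to the focal daughter's count contributed by one parental copy.
    return {0: 1.0 - p, +1: p / 2.0, -1: p / 2.0}


def _chromosome_delta_dist(n_copies: int, p: float) -> Dict[int, float]:
    """Distribution of the focal daughter's net copy change on one chromosome,
    convolving the independent per-copy outcomes."""
    dist: Dict[int, float] = {0: 1.0}
    single = _per_copy_delta_dist(p)
    for _ in range(n_copies):
        nxt: Dict[int, float] = {}
        for d0, q0 in dist.items():
            for d1, q1 in single.items():
                nxt[d0 + d1] = nxt.get(d0 + d1, 0.0) + q0 * q1
        dist = nxt
    return dist


def exact_daughter_distribution(
    parent: Sequence[int], kernel: TransitionKernel
) -> Dict[Karyotype, float]:
    """Exact distribution of one daughter's karyotype after division.

    Product over chromosomes of the per-chromosome net-change convolution.
    Support grows exponentially with the number of chromosomes, so this is
    intended for small toy karyotypes and for validating the stochastic
    :func:`division_kernel`; viability is *not* applied (non-viable
    daughters carry their probability mass explicitly).
    """
    parent = tuple(int(x) for x in parent)
    per_chrom = [_chromosome_delta_dist(n, kernel.p) for n in parent]
    out: Dict[Karyotype, float] = {}
    for deltas in itertools.product(*(d.items() for d in per_chrom)):
        prob = 1.0
        child = []
        for n, (d, q) in zip(parent, deltas):
            prob *= q
            child.append(n + d)
        child_t = tuple(child)
        out[child_t] = out.get(child_t, 0.0) + prob
    return out


def division_kernel(
    parent: Sequence[int], kernel: TransitionKernel, rng: np.random.Generator
) -> Tuple[Karyotype, Karyotype]:
    """Stochastic division: returns the two daughter karyotypes.

    Each of the parent's copies missegregates independently with
    probability ``p``; a missegregating copy goes wholly to one daughter,
    direction uniform.  Copy number is conserved chromosome-wise.
    """
    parent = tuple(int(x) for x in parent)
    d1 = list(parent)
    d2 = list(parent)
    for c, n in enumerate(parent):
        if n == 0:
            continue
        n_events = rng.binomial(n, kernel.p)
        for _ in range(n_events):
            if rng.random() < 0.5:
                d1[c] += 1
                d2[c] -= 1
            else:
                d1[c] -= 1
                d2[c] += 1
    return tuple(d1), tuple(d2)


def count_states(n_chrom: int = N_AUTOSOMES, max_copy: int = 8) -> int:
    """Number of viable karyotypes: ``max_copy ** n_chrom`` vectors with every
    chromosome between 1 and ``max_copy`` copies (exceeds 10^19 for the
    canonical 22-autosome, 8-copy space)."""
    return max_copy**n_chrom


def enumerate_ball(
    center: Sequence[int], radius: int, max_copy: int = 8
) -> Set[Karyotype]:
    """Brute-force enumeration of viable states within a Manhattan ball.

    Exhaustive over signed per-chromosome changes; exponential in radius
    and vector length, used as an oracle for :func:`charted_region`.
    """
    center = tuple(int(x) for x in center)
    n = len(center)
    out: Set[Karyotype] = set()

    def rec(i: int, budget: int, acc: List[int]) -> None:
        if i == n:
            k = tuple(acc)
            if is_viable(k, max_copy):
                out.add(k)
            return
        for delta in range(-budget, budget + 1):
            v = center[i] + delta
            if v < 1 or v > max_copy:
                continue
            acc.append(v)
            rec(i + 1, budget - abs(delta), acc)
            acc.pop()

    rec(0, radius, [])
    return out
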