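"""Conditional-independence union information and its synergy.

The measure treats each source A_i (a subset of the predictor variables) as an
agent that knows the target prior p(t) and its own conditional p(A_i | t).
Agents may pool conditionals but, lacking joint observations, must assume
their blocks are conditionally independent given T.  The set Q of
distributions they can construct consists of the compositions

    q(t, a) = p(t) * prod_blocks p(block | t)

over all partitions of A = union(A_i) whose blocks are each contained in some
source.  Union information is

    I_union_CI(A_1, ..., A_m -> T) = min{ I(A;T), max_{q in Q} I_q(A;T) },

clipped at I(A;T) so that an agent coalition can never claim more information
than the true joint provides; synergy is S_CI = I(Y;T) - I_union_CI, where Y
is the full set of declared predictor variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .discrete import (
    JointPMF,
    compose_ci,
    conditional_mutual_information,
    entropy,
    mutual_information,
)

__all__ = [
    "SourceCollection",
    "CIFamily",
    "BivariateAtoms",
    "DecompositionResult",
    "normalize_sources",
    "admissible_partitions",
    "union_information_ci",
    "synergy_ci",
    "bivariate_atoms_ci",
]

#: Conditional-entropy threshold (bits) below which a source counts as a
#: deterministic function of the remaining sources.
DETERMINISTIC_TOL = 1e-9


@dataclass(frozen=True)
class SourceCollection:
    """Ordered antichain of variable subsets A1..Am (the sources)."""

    sources: tuple[frozenset, ...]

    def __post_init__(self):
        srcs = tuple(frozenset(s) for s in self.sources)
        if not srcs:
            raise ValueError("empty source collection")
        if any(not s for s in srcs):
            raise ValueError("sources must be nonempty")
        object.__setattr__(self, "sources", srcs)

    @classmethod
    def of(cls, *sources: Iterable[str] | str) -> "SourceCollection":
        return cls(tuple(
            frozenset((s,)) if isinstance(s, str) else frozenset(s)
            for s in sources
        ))

    @property
    def union(self) -> frozenset:
        return frozenset().union(*self.sources)

    def __iter__(self):
        return iter(self.sources)

    def __len__(self):
        return len(self.sources)


@dataclass(frozen=True)
class CIFamily:
    """The admissible partitions of A and their composed distributions."""

    partitions: tuple[tuple[frozenset, ...], ...]
    composed: tuple[JointPMF, ...] = ()
    scores: tuple[float, ...] = ()


@dataclass(frozen=True)
class BivariateAtoms:
    """Redundant, unique and synergistic atoms of a bivariate decomposition."""

    R: float
    U1: float
    U2: float
    S: float

    @property
    def total(self) -> float:
        return self.R + self.U1 + self.U2 + self.S


@dataclass(frozen=True)
class DecompositionResult:
    """A measure value in bits plus solver/argmax diagnostics."""

    value: float
    status: str = "optimal"
    argmax_partition: tuple[frozenset, ...] | None = None
    clipped: bool = False
    certificate: object = None
    atoms: BivariateAtoms | None = None
    diagnostics: dict = field(default_factory=dict)


# -- source normalization ------------------------------------------------------


def normalize_sources(
    pmf: JointPMF, collection: SourceCollection
) -> SourceCollection:
    """Drop subset-dominated sources, then deterministic sources.

    A source contained in another contributes nothing to the admissible
    family; a source that is a deterministic function of the union of the
    others (conditional entropy below ``DETERMINISTIC_TOL`` bits) is removed
    iteratively, scanning in reverse declaration order so that exactly one of
    a mutually-determining pair survives and the survivor set is
    declaration-order stable.
    """
    for s in collection:
        for v in s:
            if v not in pmf.variables:
                raise KeyError(f"unknown variable {v!r}")
    srcs = [s for s in collection.sources]
    # subset removal (also removes exact duplicates, keeping the first)
    kept: list[frozenset] = []
    for i, s in enumerate(srcs):
        dominated = any(
            (s < t) or (s == t and j < i) for j, t in enumerate(srcs) if j != i
        )
        if not dominated:
            kept.append(s)
    # Deterministic-function removal, reverse declaration order, re-tested
    # after each removal.  A source is removed when it is a deterministic
    # function of a SINGLE other source (a generalized subvector, e.g. a
    # duplicated variable Y3 = Y2) or is itself constant.  Determinism given a
    # whole coalition of other sources does not trigger removal: a source that
    # only the coalition can reconstruct (e.g. Y3 = Y1 xor Y2) genuinely adds
    # a channel of its own.
    changed = True
    while changed and len(kept) > 1:
        changed = False
        for i in range(len(kept) - 1, -1, -1):
            if entropy(pmf, tuple(kept[i])) < DETERMINISTIC_TOL:
                del kept[i]
                changed = True
                break
            deterministic = False
            for j in range(len(kept)):
                if j == i:
                    continue
                other = kept[j] - kept[i]
                if not other:
                    continue
                h = (entropy(pmf, tuple(other | kept[i]))
                     - entropy(pmf, tuple(other)))
                if h < DETERMINISTIC_TOL:
                    deterministic = True
                    break
            if deterministic:
                del kept[i]
                changed = True
                break
    if not kept:
        raise ValueError("no sources left after normalization")
    return SourceCollection(tuple(kept))


# -- admissible partitions -----------------------------------------------------


def _set_partitions(items: Sequence):
    """Yield all set partitions of ``items`` (restricted growth strings)."""
    items = list(items)
    n = len(items)
    if n == 0:
        return
    a = [0] * n
    b = [1] * n  # b[i] = 1 + max(a[:i])
    while True:
        blocks: dict[int, list] = {}
        for x, lab in zip(items, a):
            blocks.setdefault(lab, []).append(x)
        yield [tuple(blocks[k]) for k in sorted(blocks)]
        # next RGS
        i = n - 1
        while i > 0 and a[i] == b[i]:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = max(b[i], a[i] + 1) if j == i + 1 else max(b[j - 1], a[j - 1] + 1)


def admissible_partitions(collection: SourceCollection) -> CIFamily:
    """Partitions of A = union(A_i) whose blocks each fit inside a source."""
    union = sorted(collection.union)
    parts = []
    for part in _set_partitions(union):
        if all(
            any(frozenset(block) <= s for s in collection) for block in part
        ):
            parts.append(tuple(frozenset(b) for b in part))
    return CIFamily(partitions=tuple(parts))


def _canonical_key(pmf: JointPMF) -> tuple:
    """Hashable fingerprint of a composed distribution (dedup under symmetry)."""
    return tuple(np.round(pmf.probs.ravel(), 12))


# -- the measure ---------------------------------------------------------------


def union_information_ci(
    pmf: JointPMF,
    collection: SourceCollection,
    target: str | None = None,
) -> DecompositionResult:
    """I_union_CI(A1,...,Am -> T) = min{I(A;T), max_q I_q(A;T)}."""
    target = target if target is not None else pmf.target
    if target is None:
        raise ValueError("no target designated")
    norm = normalize_sources(pmf, collection)
    family = admissible_partitions(norm)
    union = sorted(norm.union)
    i_true = mutual_information(pmf, union, target)

    best = -np.inf
    best_part = None
    seen: set = set()
    scores = []
    composed = []
    for part in family.partitions:
        blocks = [tuple(sorted(b)) for b in part]
        q = compose_ci(pmf, blocks, target=target)
        key = _canonical_key(q)
        if key in seen:
            continue
        seen.add(key)
        score = mutual_information(q, union, target)
        composed.append(q)
        scores.append(score)
        if score > best + 1e-15:
            best = score
            best_part = part
    clipped = best > i_true
    value = min(i_true, best)
    return DecompositionResult(
        value=float(value),
        argmax_partition=best_part,
        clipped=bool(clipped),
        diagnostics={
            "normalized_sources": norm,
            "family": CIFamily(family.partitions, tuple(composed), tuple(scores)),
            "i_true": i_true,
            "max_iq": best,
        },
    )


def synergy_ci(
    pmf: JointPMF,
    collection: SourceCollection | None = None,
    target: str | None = None,
) -> float:
    """S_CI = I(Y;T) - I_union_CI, with Y the full declared source set.

    The mutual-information term always uses every declared predictor variable
    (not just the union of the collection); this is what makes the synergy of
    a single source A1 equal I(Y \\ A1; T | A1).
    """
    target = target if target is not None else pmf.target
    if target is None:
        raise ValueError("no target designated")
    all_sources = tuple(v for v in pmf.variables if v != target)
    if collection is None:
        collection = SourceCollection.of(*all_sources)
    i_full = mutual_information(pmf, all_sources, target)
    return float(i_full - union_information_ci(pmf, collection, target).value)


def bivariate_atoms_ci(pmf: JointPMF, target: str | None = None) -> BivariateAtoms:
    """(R, U1, U2, S) from I_union_CI for a two-source system.

    Solves  S = I(Y;T) - I_u,  U1 = I_u - I(Y2;T),  U2 = I_u - I(Y1;T),
    R = I(Y1;T) - U1, with I_u = I_union_CI(Y1, Y2 -> T).
    """
    target = target if target is not None else pmf.target
    srcs = tuple(v for v in pmf.variables if v != target)
    if len(srcs) != 2:
        raise ValueError("bivariate decomposition needs exactly two sources")
    y1, y2 = srcs
    i_u = union_information_ci(pmf, SourceCollection.of(y1, y2), target).value
    i = mutual_information(pmf, srcs, target)
    i1 = mutual_information(pmf, y1, target)
    i2 = mutual_information(pmf, y2, target)
    s = i - i_u
    u1 = i_u - i2
    u2 = i_u - i1
    r = i1 - u1
    return BivariateAtoms(R=r, U1=u1, U2=u2, S=s)
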