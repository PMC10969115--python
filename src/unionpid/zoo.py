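"""Canonical distributions used in the PID synergy literature, plus random
fixtures for property tests.

Every construction returns a :class:`~unionpid.discrete.JointPMF` whose target
is the variable ``"T"`` (for COPYXOR_CHAIN the caller picks ``T1`` or ``T2``).
Composite symbols (e.g. the COPY target ``T = (Y1, Y2)``) are tuples.

The parameterized families (``ADAPTED_REDUCEDOR``, ``ADAPTED_XOR``,
``ADAPTED_XOR_V2``) take a parameter ``r`` in [0, 1].
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

from .discrete import JointPMF

__all__ = ["ZOO_NAMES", "make_distribution", "random_joint"]


def _pmf(variables, outcomes, target="T"):
    outcomes = {k: float(v) for k, v in outcomes.items()}
    return JointPMF.from_outcomes(variables, outcomes, target=target)


def _xor():
    return _pmf(
        ("T", "Y1", "Y2"),
        {(a ^ b, a, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _and():
    return _pmf(
        ("T", "Y1", "Y2"),
        {(a & b, a, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _copy():
    return _pmf(
        ("T", "Y1", "Y2"),
        {((a, b), a, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _tweaked_copy():
    # COPY with the outcome T=(1,1) removed and the rest kept equiprobable
    return _pmf(
        ("T", "Y1", "Y2"),
        {((a, b), a, b): Fraction(1, 3) for a, b in [(0, 0), (0, 1), (1, 0)]},
    )


def _t_eq_y1():
    return _pmf(
        ("T", "Y1", "Y2"),
        {(a, a, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _boom():
    rows = [(0, 0, 2), (1, 0, 0), (1, 1, 2), (2, 0, 0), (2, 2, 0), (2, 2, 1)]
    return _pmf(("T", "Y1", "Y2"), {r: Fraction(1, 6) for r in rows})


def _adapted_reducedor(r):
    return _pmf(
        ("T", "Y1", "Y2"),
        {
            (0, 0, 0): Fraction(1, 2),
            (1, 0, 0): r / 4,
            (1, 1, 0): (1 - r) / 4,
            (1, 0, 1): (1 - r) / 4,
            (1, 1, 1): r / 4,
        },
    )


def _targetmono_a():
    # T = Y1 AND Y2 with Z = (Y1, Y2) alongside
    return _pmf(
        ("T", "Z", "Y1", "Y2"),
        {(a & b, (a, b), a, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _targetmono_b():
    rows = {
        (0, 0, 1, 0): 0.419,
        (1, 1, 2, 1): 0.203,
        (2, 1, 3, 0): 0.007,
        (0, 0, 3, 1): 0.346,
        (2, 2, 4, 4): 0.025,
    }
    return _pmf(("T", "Z", "Y1", "Y2"), rows)


def _copyxor_chain():
    # T1 a relabeled COPY of (Y1, Y2); T2 = Y1 xor Y2; Y - T1 - T2 Markov
    rows = {
        (0, 0, 0, 0): Fraction(1, 4),
        (1, 1, 0, 1): Fraction(1, 4),
        (1, 2, 1, 0): Fraction(1, 4),
        (0, 3, 1, 1): Fraction(1, 4),
    }
    return JointPMF.from_outcomes(("T2", "T1", "Y1", "Y2"),
                                  {k: float(v) for k, v in rows.items()})


def _adapted_xor(r):
    return _pmf(
        ("T", "Y1", "Y2"),
        {
            (0, 0, 0): r / 4,
            (1, 0, 0): (1 - r) / 4,
            (1, 1, 0): Fraction(1, 4),
            (1, 0, 1): Fraction(1, 4),
            (0, 1, 1): Fraction(1, 4),
        },
    )


def _adapted_xor_v2(r):
    return _pmf(
        ("T", "Y1", "Y2"),
        {
            (0, 0, 0): r / 10,
            (1, 0, 0): (1 - r) / 10,
            (1, 1, 0): Fraction(4, 10),
            (1, 0, 1): Fraction(4, 10),
            (0, 1, 1): Fraction(1, 10),
        },
    )


def _rdnxor():
    # two parallel XOR blocks; both sources carry the shared block label b
    outcomes = {}
    for b in (0, 1):
        for x1 in (0, 1):
            for x2 in (0, 1):
                outcomes[((b, x1 ^ x2), (b, x1), (b, x2))] = Fraction(1, 8)
    return _pmf(("T", "Y1", "Y2"), outcomes)


def _rdnunqxor():
    # RDNXOR plus one private (unique) bit per source, both visible in T
    outcomes = {}
    for b, x1, x2, u1, u2 in itertools.product((0, 1), repeat=5):
        outcomes[
            ((b, x1 ^ x2, u1, u2), (b, x1, u1), (b, x2, u2))
        ] = Fraction(1, 32)
    return _pmf(("T", "Y1", "Y2"), outcomes)


def _xorduplicate():
    return _pmf(
        ("T", "Y1", "Y2", "Y3"),
        {(a ^ b, a, b, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _andduplicate():
    return _pmf(
        ("T", "Y1", "Y2", "Y3"),
        {(a & b, a, b, b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _xorloses():
    # XOR plus a third source that copies the target
    return _pmf(
        ("T", "Y1", "Y2", "Y3"),
        {(a ^ b, a, b, a ^ b): Fraction(1, 4) for a in (0, 1) for b in (0, 1)},
    )


def _xormulticoal():
    # three iid bits; every pair of sources determines T = a xor b xor c
    outcomes = {}
    for a, b, c in itertools.product((0, 1), repeat=3):
        outcomes[(a ^ b ^ c, (a, b), (b, c), (c, a))] = Fraction(1, 8)
    return _pmf(("T", "Y1", "Y2", "Y3"), outcomes)


_PARAMETRIC = {
    "ADAPTED_REDUCEDOR": _adapted_reducedor,
    "ADAPTED_XOR": _adapted_xor,
    "ADAPTED_XOR_V2": _adapted_xor_v2,
}

_FIXED = {
    "XOR": _xor,
    "AND": _and,
    "COPY": _copy,
    "TWEAKED_COPY": _tweaked_copy,
    "T_EQ_Y1": _t_eq_y1,
    "BOOM": _boom,
    "TARGETMONO_A": _targetmono_a,
    "TARGETMONO_B": _targetmono_b,
    "COPYXOR_CHAIN": _copyxor_chain,
    "RDNXOR": _rdnxor,
    "RDNUNQXOR": _rdnunqxor,
    "XORDUPLICATE": _xorduplicate,
    "ANDDUPLICATE": _andduplicate,
    "XORLOSES": _xorloses,
    "XORMULTICOAL": _xormulticoal,
}

ZOO_NAMES = tuple(sorted(_FIXED) + sorted(_PARAMETRIC))


def make_distribution(name: str, r: float | None = None) -> JointPMF:
    """Construct a registered distribution by name.

    Parameters
    ----------
    name
        One of :data:`ZOO_NAMES` (case-insensitive).
    r
        Parameter in [0, 1] for the parameterized families; rejected for the
        fixed distributions.
    """
    key = name.upper()
    if key in _FIXED:
        if r is not None:
            raise ValueError(f"{key} takes no parameter")
        return _FIXED[key]()
    if key in _PARAMETRIC:
        if r is None:
            raise ValueError(f"{key} requires parameter r")
        r = Fraction(r).limit_denominator(10**9)
        if not 0 <= r <= 1:
            raise ValueError("r must be in [0, 1]")
        return _PARAMETRIC[key](r)
    raise KeyError(f"unknown distribution {name!r}")


def random_joint(
    alphabet_sizes: list[int],
    seed: int,
    concentration: float = 1.0,
    sparsity: float = 0.0,
) -> JointPMF:
    """Dirichlet-random joint pmf over a full outcome grid.

    The first variable is the target ``T``; the rest are ``Y1, Y2, ...``.
    ``sparsity`` is the probability of zeroing each cell before renormalizing
    (used to exercise zero-mass support handling); the draw is re-tried if
    everything is zeroed.
    """
    sizes = [int(s) for s in alphabet_sizes]
    if any(s <= 0 for s in sizes):
        raise ValueError("alphabet sizes must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.prod(sizes))
    while True:
        mass = rng.dirichlet([concentration] * n)
        if sparsity > 0:
            mass = mass * (rng.random(n) >= sparsity)
        if mass.sum() > 0:
            break
    mass = mass / mass.sum()
    names = ("T",) + tuple(f"Y{i}" for i in range(1, len(sizes)))
    alphabets = {v: tuple(range(s)) for v, s in zip(names, sizes)}
    return JointPMF(names, alphabets, mass.reshape(sizes), target="T")
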