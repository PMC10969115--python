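"""Exact finite-alphabet probability objects and information functionals.

Everything downstream (the union-information measure, the Blackwell-order
machinery, the legacy synergy measures) consumes the two containers defined
here: :class:`JointPMF`, a joint probability mass function over a designated
target variable and a set of source variables, and :class:`ChannelMatrix`, a
row-stochastic conditional distribution ``p(output | target)`` viewed as a
discrete memoryless channel.

All information quantities are in bits (base-2 logarithms).  Probabilities are
floats; masses must be non-negative and sum to one within ``MASS_TOL``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MASS_TOL",
    "JointPMF",
    "ChannelMatrix",
    "marginalize",
    "conditional_channel",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "compose_ci",
    "merge_variables",
]

#: Tolerance for mass normalization and informational identities.
MASS_TOL = 1e-9


def _as_varset(vars: str | Iterable[str]) -> tuple[str, ...]:
    if isinstance(vars, str):
        return (vars,)
    return tuple(vars)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    """Elementwise p*log2(p) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


@dataclass(frozen=True)
class JointPMF:
    """Finite joint distribution over one target and several source variables.

    Parameters
    ----------
    variables
        Ordered variable names; the axis order of ``probs``.
    alphabets
        Mapping from variable name to its finite symbol tuple.  Symbols are
        arbitrary hashables (small ints, strings, or tuples for composite
        variables such as ``T = (Y1, Y2)``).
    probs
        Array of joint probabilities with ``probs.shape[i] ==
        len(alphabets[variables[i]])``.
    target
        Name of the designated target variable (optional; measures that need
        a target accept it explicitly as well).
    """

    variables: tuple[str, ...]
    alphabets: Mapping[str, tuple]
    probs: np.ndarray
    target: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(
            self, "alphabets", {v: tuple(a) for v, a in self.alphabets.items()}
        )
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        for v in self.variables:
            if v not in self.alphabets:
                raise ValueError(f"no alphabet for variable {v!r}")
        expected = tuple(len(self.alphabets[v]) for v in self.variables)
        if p.shape != expected:
            raise ValueError(f"probs shape {p.shape} != alphabet sizes {expected}")
        if np.any(p < -MASS_TOL):
            raise ValueError("negative probability mass")
        total = float(p.sum())
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"masses sum to {total}, not 1")
        if self.target is not None and self.target not in self.variables:
            raise ValueError(f"target {self.target!r} not among variables")

    # -- convenience accessors -------------------------------------------------

    def axis(self, var: str) -> int:
        try:
            return self.variables.index(var)
        except ValueError:
            raise KeyError(f"unknown variable {var!r}") from None

    def alphabet(self, var: str) -> tuple:
        return self.alphabets[var]

    @property
    def sources(self) -> tuple[str, ...]:
        """All variables other than the target, in declaration order."""
        return tuple(v for v in self.variables if v != self.target)

    def outcomes(self):
        """Iterate ``(outcome_tuple, probability)`` over positive-mass cells."""
        for idx in np.argwhere(self.probs > 0):
            sym = tuple(
                self.alphabets[v][i] for v, i in zip(self.variables, idx)
            )
            yield sym, float(self.probs[tuple(idx)])

    def with_target(self, target: str) -> "JointPMF":
        return JointPMF(self.variables, self.alphabets, self.probs, target)

    @classmethod
    def from_outcomes(
        cls,
        variables: Sequence[str],
        outcomes: Mapping[tuple, float],
        target: str | None = None,
        alphabets: Mapping[str, Sequence] | None = None,
    ) -> "JointPMF":
        """Build a pmf from a sparse ``{outcome tuple: mass}`` map.

        Alphabets default to the sorted set of symbols seen per variable;
        duplicate outcome tuples are rejected.
        """
        variables = tuple(variables)
        if alphabets is None:
            cols: list[set] = [set() for _ in variables]
            for out in outcomes:
                if len(out) != len(variables):
                    raise ValueError(f"outcome {out} arity != {len(variables)}")
                for c, s in zip(cols, out):
                    c.add(s)
            alphabets = {v: tuple(sorted(c, key=repr)) for v, c in zip(variables, cols)}
        else:
            alphabets = {v: tuple(a) for v, a in alphabets.items()}
        shape = tuple(len(alphabets[v]) for v in variables)
        probs = np.zeros(shape)
        index = {v: {s: i for i, s in enumerate(alphabets[v])} for v in variables}
        for out, mass in outcomes.items():
            idx = tuple(index[v][s] for v, s in zip(variables, out))
            if probs[idx] != 0.0:
                raise ValueError(f"duplicate outcome {out}")
            probs[idx] = mass
        return cls(variables, alphabets, probs, target)


@dataclass(frozen=True)
class ChannelMatrix:
    """Row-stochastic conditional distribution p(output | input symbol)."""

    row_labels: tuple
    col_labels: tuple
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if np.any(m < -MASS_TOL) or np.any(m > 1 + MASS_TOL):
            raise ValueError("channel entries outside [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > MASS_TOL):
            raise ValueError("channel rows must sum to 1")


# -- marginalization and channels ---------------------------------------------


def marginalize(pmf: JointPMF, keep: str | Iterable[str]) -> JointPMF:
    """Sum out every variable not in ``keep``, preserving declaration order."""
    keep_set = set(_as_varset(keep))
    if not keep_set:
        raise ValueError("keep must be nonempty")
    for v in keep_set:
        if v not in pmf.variables:
            raise KeyError(f"unknown variable {v!r}")
    kept = tuple(v for v in pmf.variables if v in keep_set)
    drop_axes = tuple(i for i, v in enumerate(pmf.variables) if v not in keep_set)
    probs = pmf.probs.sum(axis=drop_axes) if drop_axes else pmf.probs
    target = pmf.target if pmf.target in kept else None
    return JointPMF(kept, {v: pmf.alphabets[v] for v in kept}, probs, target)


def _marginal_array(pmf: JointPMF, vars: tuple[str, ...]) -> np.ndarray:
    """Marginal prob array with axes ordered as in ``vars``."""
    drop = tuple(i for i, v in enumerate(pmf.variables) if v not in vars)
    arr = pmf.probs.sum(axis=drop) if drop else pmf.probs
    order = tuple(v for v in pmf.variables if v in vars)
    perm = tuple(order.index(v) for v in vars)
    return arr.transpose(perm)


def conditional_channel(
    pmf: JointPMF, given: str | Iterable[str], outputs: str | Iterable[str]
) -> ChannelMatrix:
    """Channel matrix K with ``K[t, y] = p(y | t)``.

    ``given`` may be a set of variables, in which case rows are indexed by
    joint symbol tuples.  Rows for zero-probability conditioning symbols are
    excluded (the conditional is undefined there and the symbol contributes to
    no expectation).
    """
    given_t = _as_varset(given)
    out_t = _as_varset(outputs)
    if set(given_t) & set(out_t):
        raise ValueError("outputs must be disjoint from the conditioning set")
    joint = _marginal_array(pmf, given_t + out_t)
    n_given = int(np.prod([len(pmf.alphabets[v]) for v in given_t]))
    flat = joint.reshape(n_given, -1)
    row_mass = flat.sum(axis=1)
    rows = row_mass > 0
    matrix = flat[rows] / row_mass[rows, None]
    given_syms = list(itertools.product(*(pmf.alphabets[v] for v in given_t)))
    out_syms = list(itertools.product(*(pmf.alphabets[v] for v in out_t)))
    if len(given_t) == 1:
        given_syms = [s[0] for s in given_syms]
    if len(out_t) == 1:
        out_syms = [s[0] for s in out_syms]
    row_labels = tuple(s for s, ok in zip(given_syms, rows) if ok)
    return ChannelMatrix(row_labels, tuple(out_syms), matrix)


# -- information functionals ---------------------------------------------------


def entropy(pmf: JointPMF, vars: str | Iterable[str]) -> float:
    """Shannon entropy H(vars) in bits."""
    vars_t = _as_varset(vars)
    if not vars_t:
        raise ValueError("vars must be nonempty")
    arr = _marginal_array(pmf, vars_t)
    return float(-_xlog2x(arr).sum())


def mutual_information(
    pmf: JointPMF, A: str | Iterable[str], B: str | Iterable[str]
) -> float:
    """Mutual information I(A;B) in bits; A and B must be disjoint."""
    A_t, B_t = _as_varset(A), _as_varset(B)
    if set(A_t) & set(B_t):
        raise ValueError("argument sets overlap")
    return entropy(pmf, A_t) + entropy(pmf, B_t) - entropy(pmf, A_t + B_t)


def conditional_mutual_information(
    pmf: JointPMF,
    A: str | Iterable[str],
    B: str | Iterable[str],
    C: str | Iterable[str] = (),
) -> float:
    """Conditional mutual information I(A;B|C) in bits.

    With empty ``C`` this reduces to :func:`mutual_information`.  Satisfies
    the chain rule I(A,B;T) = I(A;T) + I(B;T|A).
    """
    A_t, B_t, C_t = _as_varset(A), _as_varset(B), _as_varset(C)
    sets = [set(A_t), set(B_t), set(C_t)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError("argument sets overlap")
    if not C_t:
        return mutual_information(pmf, A_t, B_t)
    # I(A;B|C) = H(A,C) + H(B,C) - H(A,B,C) - H(C)
    return (
        entropy(pmf, A_t + C_t)
        + entropy(pmf, B_t + C_t)
        - entropy(pmf, A_t + B_t + C_t)
        - entropy(pmf, C_t)
    )


# -- conditional-independence composition --------------------------------------


def compose_ci(
    pmf: JointPMF,
    partition: Sequence[Iterable[str]],
    target: str | None = None,
) -> JointPMF:
    """Compose q(t, a) = p(t) * prod_blocks p(block | t).

    ``partition`` is a list of disjoint variable blocks; their union A must
    not contain the target.  The returned pmf ranges over {target} followed by
    the variables of A in the parent's declaration order, with Q assigning
    zero mass to zero-probability target symbols.
    """
    target = target if target is not None else pmf.target
    if target is None:
        raise ValueError("no target designated")
    blocks = [tuple(_as_varset(b)) for b in partition]
    seen: set[str] = set()
    for b in blocks:
        if not b:
            raise ValueError("empty block")
        for v in b:
            if v == target:
                raise ValueError("target may not appear in a block")
            if v in seen:
                raise ValueError(f"variable {v!r} in more than one block")
            if v not in pmf.variables:
                raise KeyError(f"unknown variable {v!r}")
            seen.add(v)
    union = tuple(v for v in pmf.variables if v in seen)
    out_vars = (target,) + union
    shape = tuple(len(pmf.alphabets[v]) for v in out_vars)

    p_t = _marginal_array(pmf, (target,))
    q = np.zeros(shape)
    pos = p_t > 0
    # start from p(t) broadcast over all source axes
    q += p_t.reshape((-1,) + (1,) * len(union))
    for b in blocks:
        joint = _marginal_array(pmf, (target,) + b)  # axes (t, *b)
        cond = np.zeros_like(joint)
        cond[pos] = joint[pos] / p_t[pos].reshape((-1,) + (1,) * len(b))
        # align cond onto (t, *union)
        expand = [0] + [1 + union.index(v) for v in b]
        full_shape = [1] * len(out_vars)
        for ax_out, ax_in in zip(expand, range(cond.ndim)):
            full_shape[ax_out] = cond.shape[ax_in]
        perm = np.argsort(expand)  # cond axes are already in (t, *b) order
        # reorder cond axes to ascending output-axis order, then reshape
        cond_sorted = cond.transpose(tuple(perm))
        insert_axes = sorted(expand)
        view_shape = [1] * len(out_vars)
        for ax, size in zip(insert_axes, cond_sorted.shape):
            view_shape[ax] = size
        q *= cond_sorted.reshape(view_shape)
    return JointPMF(out_vars, {v: pmf.alphabets[v] for v in out_vars}, q, target)


def merge_variables(
    pmf: JointPMF, members: Iterable[str], new_name: str
) -> JointPMF:
    """Replace several variables by a single composite (tuple-valued) one.

    The composite takes the position of the first member in declaration order
    and its symbols are tuples of member symbols.  Useful for multi-variable
    targets such as (T, Z).
    """
    members = tuple(_as_varset(members))
    if len(members) == 1 and members[0] == new_name:
        return pmf
    for v in members:
        if v not in pmf.variables:
            raise KeyError(f"unknown variable {v!r}")
    if new_name in set(pmf.variables) - set(members):
        raise ValueError(f"name {new_name!r} already in use")
    rest = [v for v in pmf.variables if v not in members]
    new_vars = []
    inserted = False
    for v in pmf.variables:
        if v in members:
            if not inserted:
                new_vars.append(new_name)
                inserted = True
            continue
        new_vars.append(v)
    # move member axes to the front, flatten them into one composite axis,
    # then permute the composite into the first member's slot
    arr = _marginal_array(pmf, members + tuple(rest))  # reorder only
    m_size = int(np.prod([len(pmf.alphabets[v]) for v in members]))
    arr = arr.reshape((m_size,) + tuple(len(pmf.alphabets[v]) for v in rest))
    cur_vars = [new_name] + rest
    perm = [cur_vars.index(v) for v in new_vars]
    arr = arr.transpose(perm)
    alphabets = {v: pmf.alphabets[v] for v in rest}
    alphabets[new_name] = tuple(
        itertools.product(*(pmf.alphabets[v] for v in members))
    )
    target = pmf.target
    if target in members:
        target = new_name
    elif target not in new_vars:
        target = None
    return JointPMF(tuple(new_vars), alphabets, arr, target)
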