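"""Maximum-entropy distributions with fixed marginals via iterative
proportional fitting (IPF).

Given a joint pmf p and a list of variable subsets, IPF computes the
maximum-entropy joint whose marginals on those subsets match p's.  The
iteration starts from the uniform distribution on the support of the product
of the constraint supports and cyclically rescales each constrained marginal
onto its target; convergence is measured in total variation per constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .discrete import JointPMF, _as_varset, _marginal_array, _xlog2x

__all__ = ["MaxEntResult", "maxent_ipf"]


@dataclass(frozen=True)
class MaxEntResult:
    distribution: JointPMF
    iterations: int
    constraint_residual: float
    converged: bool
    entropy_trace: tuple[float, ...] = ()


def maxent_ipf(
    pmf: JointPMF,
    constraint_marginals: Sequence[Iterable[str] | str],
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> MaxEntResult:
    """Fit the maximum-entropy joint preserving the listed marginals of p.

    Returns a :class:`MaxEntResult`; non-convergence within ``max_sweeps``
    sweeps is reported via ``converged=False`` (no exception), with the final
    total-variation residual recorded.
    """
    constraints = [tuple(_as_varset(c)) for c in constraint_marginals]
    if not constraints:
        raise ValueError("need at least one constraint marginal")
    for c in constraints:
        for v in c:
            if v not in pmf.variables:
                raise KeyError(f"unknown variable {v!r}")
    targets = []
    axes_per = []
    for c in constraints:
        targets.append(_marginal_array(pmf, tuple(v for v in pmf.variables if v in c)))
        axes_per.append(tuple(i for i, v in enumerate(pmf.variables) if v not in c))

    # init: uniform over the support of the product of constraint supports
    support = np.ones_like(pmf.probs, dtype=bool)
    for tgt, axes in zip(targets, axes_per):
        mask = tgt > 0
        support &= np.expand_dims(mask, axes) if axes else mask
    r = support.astype(float)
    r /= r.sum()

    entropy_trace = [float(-_xlog2x(r).sum())]
    residual = np.inf
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        for tgt, axes in zip(targets, axes_per):
            cur = r.sum(axis=axes) if axes else r
            ratio = np.ones_like(cur)
            pos = cur > 0
            ratio[pos] = tgt[pos] / cur[pos]
            r = r * (np.expand_dims(ratio, axes) if axes else ratio)
        residual = 0.0
        for tgt, axes in zip(targets, axes_per):
            cur = r.sum(axis=axes) if axes else r
            residual = max(residual, 0.5 * float(np.abs(cur - tgt).sum()))
        entropy_trace.append(float(-_xlog2x(r).sum()))
        if residual < tol:
            break
    dist = JointPMF(pmf.variables, pmf.alphabets, r / r.sum(), pmf.target)
    return MaxEntResult(
        distribution=dist,
        iterations=sweeps,
        constraint_residual=float(residual),
        converged=residual < tol,
        entropy_trace=tuple(entropy_trace),
    )
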