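"""Degradation-order (Blackwell) machinery for PID.

A channel KQ is degraded from K (written KQ <=_d K) when KQ = K @ W for some
row-stochastic garbling W: observing Q is never better than observing the
output of K and post-processing it.  This module provides

* :func:`blackwell_le` — LP feasibility test with an explicit garbling witness;
* :func:`redundancy_degradation` — the degradation-order redundancy: the
  largest I(Q;T) over channels dominated by every source channel K(i),
  maximized exactly by enumerating the vertices of the lifted garbling
  polytope (mutual information is convex in KQ for fixed p(t), so the max is
  attained at a vertex);
* :func:`union_vk` — the fixed-marginal union information: the convex
  minimization of I(union(A_i); T) over joints that preserve every p(A_i, T);
* :func:`synergy_d` — the synergy derived from it, I(Y;T) minus the minimum;
* :func:`degradation_decomposition_bivariate` — the (R, U1, U2, S) atoms
  implied by the degradation redundancy; S may be negative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .discrete import (
    ChannelMatrix,
    JointPMF,
    _as_varset,
    _marginal_array,
    conditional_channel,
    mutual_information,
)
from .maxent import maxent_ipf
from .union_ci import (
    BivariateAtoms,
    DecompositionResult,
    SourceCollection,
    normalize_sources,
)

__all__ = [
    "DegradationWitness",
    "blackwell_le",
    "redundancy_degradation",
    "union_vk",
    "synergy_d",
    "degradation_decomposition_bivariate",
]

#: Reconstruction tolerance for a degradation witness, max-norm.
WITNESS_TOL = 1e-7

#: Largest number of candidate bases enumerated exactly before falling back
#: to sampled bases (the fallback value is flagged as a lower bound).
MAX_BASES = 2_000_000

#: Batch size for the vectorized basis solves (memory control).
_BASIS_CHUNK = 100_000


@dataclass(frozen=True)
class DegradationWitness:
    feasible: bool
    garbling: ChannelMatrix | None = None
    residual: float = float("inf")


def blackwell_le(KQ: ChannelMatrix, K: ChannelMatrix) -> DegradationWitness:
    """Test KQ <=_d K: is there a row-stochastic W with K @ W = KQ?"""
    if set(KQ.row_labels) != set(K.row_labels):
        raise ValueError("channels must share the same input (target) alphabet")
    # align KQ rows to K's row order
    perm = [KQ.row_labels.index(lab) for lab in K.row_labels]
    B = KQ.matrix[perm]
    A = K.matrix
    n_in, n_y = A.shape
    n_q = B.shape[1]
    # variables: W flattened (n_y, n_q)
    n_vars = n_y * n_q
    rows = []
    rhs = []
    for t in range(n_in):
        for q in range(n_q):
            coef = np.zeros(n_vars)
            coef[q::n_q] = A[t]
            rows.append(coef)
            rhs.append(B[t, q])
    for y in range(n_y):
        coef = np.zeros(n_vars)
        coef[y * n_q:(y + 1) * n_q] = 1.0
        rows.append(coef)
        rhs.append(1.0)
    res = linprog(
        c=np.zeros(n_vars),
        A_eq=np.array(rows),
        b_eq=np.array(rhs),
        bounds=(0, 1),
        method="highs",
    )
    if res.status != 0:
        return DegradationWitness(feasible=False)
    W = res.x.reshape(n_y, n_q)
    # clean tiny negatives and renormalize rows before validating
    W = np.clip(W, 0.0, None)
    W /= W.sum(axis=1, keepdims=True)
    residual = float(np.max(np.abs(A @ W - B)))
    if residual > WITNESS_TOL:
        return DegradationWitness(feasible=False, residual=residual)
    return DegradationWitness(
        feasible=True,
        garbling=ChannelMatrix(K.col_labels, KQ.col_labels, W),
        residual=residual,
    )


# -- exact maximization of I(Q;T) over the degradation polytope ----------------


def _mi_from_channel(p_t: np.ndarray, KQ: np.ndarray) -> float:
    joint = p_t[:, None] * KQ
    return _mi_from_joint_batch(joint[None])[0]


def _mi_from_joint_batch(joint: np.ndarray) -> np.ndarray:
    """I between the two axes of each (n, a, b) joint table, in bits."""
    pa = joint.sum(axis=2, keepdims=True)
    pb = joint.sum(axis=1, keepdims=True)
    denom = pa * pb
    ratio = np.ones_like(joint)
    pos = joint > 1e-15
    ratio[pos] = joint[pos] / denom[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pos, joint * np.log2(ratio), 0.0)
    return terms.sum(axis=(1, 2))


def _nullspace(A: np.ndarray, rtol: float = 1e-10):
    u, s, vh = np.linalg.svd(A, full_matrices=True)
    tol = (s.max() if s.size else 0.0) * rtol + 1e-13
    rank = int((s > tol).sum())
    return vh[rank:].T, rank


def _polytope_vertices(Aeq, beq, n_vars, rng=None):
    """Vertices of {x >= 0 : Aeq x = beq} by active-set enumeration.

    Parametrizes the affine solution set as x = x0 + Z u and enumerates bases
    of d = dim(null) nonnegativity constraints.  Returns (vertices, exact)
    where ``exact`` is False when the basis count exceeded MAX_BASES and a
    seeded random sample of bases was used instead.
    """
    x0, *_ = np.linalg.lstsq(Aeq, beq, rcond=None)
    if np.max(np.abs(Aeq @ x0 - beq)) > 1e-8:
        raise RuntimeError("equality system inconsistent")
    Z, rank = _nullspace(Aeq)
    d = Z.shape[1]
    if d == 0:
        return x0[None, :], True
    n_bases = math.comb(n_vars, d)
    exact = n_bases <= MAX_BASES
    if exact:
        combo_iter = itertools.combinations(range(n_vars), d)
    else:
        rng = np.random.default_rng(0 if rng is None else rng)
        combo_iter = (
            tuple(rng.choice(n_vars, size=d, replace=False))
            for _ in range(MAX_BASES)
        )
    pieces = []
    while True:
        chunk = list(itertools.islice(combo_iter, _BASIS_CHUNK))
        if not chunk:
            break
        combos = np.array(chunk, dtype=int)
        A_b = Z[combos]                      # (n, d, d)
        b_b = -x0[combos]                    # (n, d)
        dets = np.abs(np.linalg.det(A_b))
        scale = np.abs(A_b).max(axis=(1, 2)) + 1e-30
        ok = dets > 1e-10 * scale**A_b.shape[1]
        if not ok.any():
            continue
        u = np.linalg.solve(A_b[ok], b_b[ok][..., None])[..., 0]
        x = x0[None, :] + u @ Z.T
        feas = (x >= -1e-9).all(axis=1)
        if feas.any():
            pieces.append(np.clip(x[feas], 0.0, None))
    if not pieces:
        return np.empty((0, n_vars)), exact
    verts = np.unique(np.round(np.concatenate(pieces), 9), axis=0)
    return verts, exact


def _source_channels(pmf, collection, target):
    Ks = []
    for src in collection:
        outs = tuple(v for v in pmf.variables if v in src)
        Ks.append(conditional_channel(pmf, target, outs))
    return Ks


def redundancy_degradation(
    pmf: JointPMF,
    collection: SourceCollection,
    target: str | None = None,
    q_size: int | None = None,
    auto_escalate: bool = True,
) -> DecompositionResult:
    """Degradation-order redundancy: max I(Q;T) s.t. KQ <=_d K(i) for all i.

    The feasible set {(KQ, W1..Wm) : KQ = K(i) Wi, Wi row-stochastic} is a
    polytope and the objective is convex in KQ, so the exact maximum sits at
    a vertex.  ``q_size`` is the output alphabet of Q (default |T|); with
    ``auto_escalate`` it grows until the optimum stops increasing, capped at
    the product of the source output alphabet sizes.
    """
    target = target if target is not None else pmf.target
    if target is None:
        raise ValueError("no target designated")
    Ks = _source_channels(pmf, collection, target)
    p_t_full = _marginal_array(pmf, (target,))
    p_t = p_t_full[p_t_full > 0]
    n_t = len(p_t)
    cap = int(np.prod([K.matrix.shape[1] for K in Ks]))
    q = q_size if q_size is not None else n_t
    q = min(q, cap) if auto_escalate else q
    if q < 2:
        q = min(2, cap) if cap >= 2 else cap

    history = []
    best_val, best_kq, exact_all = -np.inf, None, True
    while True:
        val, kq, exact = _redundancy_at_q(Ks, p_t, q)
        history.append((q, val))
        exact_all = exact_all and exact
        if val > best_val + 1e-12:
            best_val, best_kq = val, kq
        if not auto_escalate:
            break
        if q >= cap or (len(history) >= 2 and history[-1][1] <= history[-2][1] + 1e-9):
            break
        q += 1
    status = "optimal" if exact_all else "lower_bound"
    cert = ChannelMatrix(
        Ks[0].row_labels, tuple(range(best_kq.shape[1])), best_kq
    )
    return DecompositionResult(
        value=float(max(best_val, 0.0)),
        status=status,
        certificate=cert,
        diagnostics={"q_size_history": history, "channels": Ks},
    )


def _redundancy_at_q(Ks, p_t, q):
    n_t = len(p_t)
    sizes = [K.matrix.shape[1] for K in Ks]
    n_vars = sum(s * q for s in sizes)
    offs = np.cumsum([0] + [s * q for s in sizes])
    rows, rhs = [], []
    # K(1) W1 = K(i) Wi  for i >= 2
    K1 = Ks[0].matrix
    for i in range(1, len(Ks)):
        Ki = Ks[i].matrix
        for t in range(n_t):
            for c in range(q):
                coef = np.zeros(n_vars)
                coef[offs[0] + c:offs[1]:q] = K1[t]
                coef[offs[i] + c:offs[i + 1]:q] -= Ki[t]
                rows.append(coef)
                rhs.append(0.0)
    # row-stochasticity of every Wi
    for i, s in enumerate(sizes):
        for y in range(s):
            coef = np.zeros(n_vars)
            start = offs[i] + y * q
            coef[start:start + q] = 1.0
            rows.append(coef)
            rhs.append(1.0)
    verts, exact = _polytope_vertices(np.array(rows), np.array(rhs), n_vars)
    if verts.shape[0] == 0:
        raise RuntimeError("degradation polytope vertex enumeration failed")
    W1 = verts[:, offs[0]:offs[1]].reshape(-1, sizes[0], q)
    KQs = np.einsum("ty,nyq->ntq", K1, W1)
    joints = p_t[None, :, None] * KQs
    vals = _mi_from_joint_batch(joints)
    i_best = int(np.argmax(vals))
    return float(vals[i_best]), KQs[i_best], exact


# -- fixed-marginal union information (convex program) -------------------------


def union_vk(
    pmf: JointPMF,
    collection: SourceCollection,
    target: str | None = None,
    tol: float = 1e-10,
) -> DecompositionResult:
    """min I(union(A_i); T) over joints p* with p*(A_i, T) = p(A_i, T).

    Solved as a convex program with linear equality constraints using a
    trust-region interior method with analytic gradient.  Variables are the
    joint cells compatible with every constrained marginal's support (cells
    projecting onto a zero marginal are forced to zero and dropped).  The
    start point is the maximum-entropy (IPF) distribution with the same
    marginals, which is feasible and interior.
    """
    target = target if target is not None else pmf.target
    if target is None:
        raise ValueError("no target designated")
    union_vars = tuple(v for v in pmf.variables if v in collection.union)
    grid_vars = union_vars + (target,)
    p_grid = _marginal_array(pmf, grid_vars)
    shape = p_grid.shape
    n_cells = p_grid.size

    marg_axes, marg_targets = [], []
    for src in collection.sources:
        keep = [i for i, v in enumerate(grid_vars) if v in src or v == target]
        drop = tuple(i for i in range(len(grid_vars)) if i not in keep)
        marg_axes.append((keep, drop))
        marg_targets.append(p_grid.sum(axis=drop) if drop else p_grid)

    allowed = np.ones(shape, dtype=bool)
    for (keep, drop), tgt in zip(marg_axes, marg_targets):
        mask = tgt > 0
        allowed &= np.expand_dims(mask, drop) if drop else mask
    idx_allowed = np.flatnonzero(allowed.ravel())
    n = idx_allowed.size

    # linear constraint matrix: one row per positive marginal cell
    cell_multi = np.array(np.unravel_index(idx_allowed, shape)).T  # (n, ndim)
    A_rows, b_vals = [], []
    for (keep, drop), tgt in zip(marg_axes, marg_targets):
        tgt_flat = tgt.ravel()
        tgt_shape = tgt.shape
        proj = np.ravel_multi_index(
            tuple(cell_multi[:, k] for k in keep), tgt_shape
        )
        for cell in np.flatnonzero(tgt_flat > 0):
            row = np.zeros(n)
            row[proj == cell] = 1.0
            A_rows.append(row)
            b_vals.append(tgt_flat[cell])
    A = np.array(A_rows)
    b = np.array(b_vals)
    # keep an independent subset of the (redundant) marginal constraints
    from scipy.linalg import qr as _qr

    _, R, piv = _qr(A.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > (diag.max() if diag.size else 0) * 1e-12).sum())
    A, b = A[piv[:rank]], b[piv[:rank]]

    start = maxent_ipf(
        pmf_from_grid(grid_vars, pmf, p_grid),
        [tuple(sorted(src | {target})) for src in collection.sources],
    ).distribution.probs
    x0 = np.clip(start.ravel()[idx_allowed], 1e-12, None)

    axis_t = len(grid_vars) - 1
    t_of_cell = cell_multi[:, axis_t]
    a_of_cell = np.ravel_multi_index(
        tuple(cell_multi[:, k] for k in range(axis_t)), shape[:-1]
    )
    n_a = int(np.prod(shape[:-1]))
    p_t = p_grid.sum(axis=tuple(range(axis_t)))
    h_t_nats = float(-np.sum(p_t[p_t > 0] * np.log(p_t[p_t > 0])))
    ln2 = np.log(2.0)

    def split_objective(x):
        xc = np.clip(x, 1e-15, None)
        pa = np.bincount(a_of_cell, weights=x, minlength=n_a)
        pac = np.clip(pa, 1e-15, None)
        f_nats = float(np.sum(x * np.log(xc)) - np.sum(pa * np.log(pac)))
        g = np.log(xc) - np.log(pac[a_of_cell])
        return (f_nats + h_t_nats) / ln2, g / ln2

    if rank >= n:
        # constraints pin the joint: p* = p restricted to the allowed cells
        x_opt = p_grid.ravel()[idx_allowed]
        res = None
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="delta_grad == 0.0", category=UserWarning
            )
            res = minimize(
                lambda x: split_objective(x)[0],
                x0,
                jac=lambda x: split_objective(x)[1],
                method="trust-constr",
                constraints=[LinearConstraint(A, b, b)],
                bounds=Bounds(np.zeros(n), np.ones(n)),
                options={"gtol": tol, "xtol": 1e-12, "maxiter": 2000, "verbose": 0},
            )
        x_opt = np.clip(res.x, 0.0, None)
    full = np.zeros(n_cells)
    full[idx_allowed] = x_opt
    full /= full.sum()
    p_star = pmf_from_grid(grid_vars, pmf, full.reshape(shape))
    value = mutual_information(p_star, union_vars, target)
    if res is None:
        status, diag = "optimal", {"niter": 0, "constr_violation": 0.0}
    else:
        status = "optimal" if res.status in (1, 2) else f"solver_status_{res.status}"
        diag = {"niter": res.niter, "constr_violation": float(res.constr_violation)}
    return DecompositionResult(
        value=float(value), status=status, certificate=p_star, diagnostics=diag
    )


def pmf_from_grid(grid_vars, parent: JointPMF, probs: np.ndarray) -> JointPMF:
    alphabets = {v: parent.alphabets[v] for v in grid_vars}
    target = parent.target if parent.target in grid_vars else None
    return JointPMF(tuple(grid_vars), alphabets, probs, target)


def synergy_d(
    pmf: JointPMF,
    collection: SourceCollection | None = None,
    target: str | None = None,
) -> float:
    """S_d = I(Y;T) - I_union_VK(collection -> T); non-negative."""
    target = target if target is not None else pmf.target
    if target is None:
        raise ValueError("no target designated")
    all_sources = tuple(v for v in pmf.variables if v != target)
    if collection is None:
        collection = SourceCollection.of(*all_sources)
    norm = normalize_sources(pmf, collection)
    i_full = mutual_information(pmf, all_sources, target)
    val = i_full - union_vk(pmf, norm, target).value
    return float(max(val, 0.0))


def degradation_decomposition_bivariate(
    pmf: JointPMF, target: str | None = None, q_size: int | None = None
) -> BivariateAtoms:
    """(R, U1, U2, S) with R the degradation redundancy; S may be negative."""
    target = target if target is not None else pmf.target
    srcs = tuple(v for v in pmf.variables if v != target)
    if len(srcs) != 2:
        raise ValueError("bivariate decomposition needs exactly two sources")
    y1, y2 = srcs
    r = redundancy_degradation(
        pmf, SourceCollection.of(y1, y2), target, q_size=q_size
    ).value
    i = mutual_information(pmf, srcs, target)
    i1 = mutual_information(pmf, y1, target)
    i2 = mutual_information(pmf, y2, target)
    return BivariateAtoms(R=r, U1=i1 - r, U2=i2 - r, S=i + r - i1 - i2)
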