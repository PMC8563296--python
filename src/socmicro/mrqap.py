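"""Dyadic matrix regression with quadratic-assignment permutation inference.

Dyadic observations (one per unordered pair of individuals) violate the
independence assumptions of ordinary regression because every individual
appears in many dyads. The quadratic assignment procedure (QAP) builds the
null distribution by jointly permuting the rows and columns of a matrix by
one node relabeling, which preserves that dependence structure exactly.

For multiple predictors this module implements the double-semi-partialing
variant (MRQAP-DSP): for each predictor X_k, the residual matrix E_k of
X_k regressed on the remaining predictors is node-permuted and substituted
for X_k, and the pivotal OLS t-statistic of the substituted column is
compared with the observed t of X_k in the full model. The t (not the raw
coefficient) is compared across permutations because it is pivotal under
heteroskedasticity. p-values use the add-one Monte-Carlo rule
(1 + #as-extreme) / (1 + N); with ``exhaustive=True`` the full symmetric
group is enumerated and the p-value is the exact tail proportion
(the identity permutation is part of the group, so p >= 1/n!).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dyad import DyadMatrix

__all__ = [
    "DyadDesign",
    "MRQAPResult",
    "vectorize_dyads",
    "devectorize_dyads",
    "ols_dyadic",
    "node_permute",
    "mrqap_dsp",
    "qap_single",
]

_T_TOL = 1e-9  # permuted |t| within this of observed |t| counts as a tie


# ---------------------------------------------------------------------------
# Design container
# ---------------------------------------------------------------------------

class DyadDesign:
    """Response and named predictor dyad matrices over one set of nodes.

    The effective mask marks usable dyads: off-diagonal, finite in the
    response and in every predictor, and (optionally) allowed by a
    user-supplied symmetric boolean *mask*.
    """

    def __init__(self, response: DyadMatrix, predictors: dict,
                 mask: Optional[np.ndarray] = None):
        self.response = response
        self.predictors = {
            str(name): (m if m.ids == response.ids else m.reorder(response.ids))
            for name, m in predictors.items()
        }
        if not self.predictors:
            raise ValueError("need at least one predictor")
        n = response.n
        eff = ~np.eye(n, dtype=bool)
        eff &= np.isfinite(response.values)
        for m in self.predictors.values():
            eff &= np.isfinite(m.values)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n, n):
                raise ValueError("mask shape mismatch")
            if not np.array_equal(mask, mask.T):
                raise ValueError("mask must be symmetric")
            eff &= mask
        self.mask = eff

    @property
    def names(self) -> list[str]:
        return list(self.predictors)


@dataclass
class VectorizedDesign:
    """Dyad-vectorized design: one row per unordered masked-in dyad."""

    ids: list  # node ids in the canonical (lexicographic) order
    iu: np.ndarray  # node index of the first member of each dyad
    ju: np.ndarray
    y: np.ndarray  # (n_dyads,)
    X: np.ndarray  # (n_dyads, p)
    names: list
    complete: bool  # True if every i<j pair of the retained nodes is masked in


def vectorize_dyads(design: DyadDesign) -> VectorizedDesign:
    """Flatten the design to one row per masked-in unordered dyad.

    Nodes are placed in lexicographic id order and nodes with no usable
    dyad are dropped, so the dyad ordering is deterministic. Requires at
    least 3 usable nodes.
    """
    order = sorted(design.response.ids)
    resp = design.response.reorder(order)
    mask_full = design.mask
    perm = np.array([design.response.ids.index(u) for u in order])
    mask = mask_full[np.ix_(perm, perm)]
    preds = {k: m.reorder(order) for k, m in design.predictors.items()}
    used = mask.any(axis=1)
    if used.sum() < 3:
        raise ValueError(
            f"only {int(used.sum())} nodes have usable dyads; need >= 3"
        )
    keep = [u for u, flag in zip(order, used) if flag]
    resp = resp.subset(keep)
    preds = {k: m.subset(keep) for k, m in preds.items()}
    mask = mask[np.ix_(used, used)]
    n = len(keep)
    iu, ju = np.triu_indices(n, k=1)
    sel = mask[iu, ju]
    iu, ju = iu[sel], ju[sel]
    y = resp.values[iu, ju]
    X = np.column_stack([preds[k].values[iu, ju] for k in preds])
    return VectorizedDesign(
        ids=keep, iu=iu, ju=ju, y=y, X=X, names=list(preds),
        complete=bool(sel.all()),
    )


def devectorize_dyads(values: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                      n: int) -> np.ndarray:
    """Re-assemble a dyad vector into a symmetric matrix (NaN elsewhere)."""
    out = np.full((n, n), np.nan)
    out[iu, ju] = values
    out[ju, iu] = values
    return out


# ---------------------------------------------------------------------------
# OLS plumbing
# ---------------------------------------------------------------------------

def _safe_t(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """t = beta / se with the degenerate se = 0 cases pinned: an exactly
    zero coefficient with zero standard error is t = 0 (perfectly flat
    data), a nonzero one is signed infinity (perfect fit)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
        zero_se = se == 0
        t = np.where(zero_se & (beta == 0), 0.0, t)
        t = np.where(zero_se & (beta != 0), np.sign(beta) * np.inf, t)
    return t


def _ols(y: np.ndarray, X: np.ndarray):
    """Plain OLS: returns (beta, t). X must include any intercept column."""
    n, k = X.shape
    G = X.T @ X
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular design matrix") from None
    beta = Ginv @ (X.T @ y)
    resid = y - X @ beta
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(Ginv), 0.0))
    return beta, _safe_t(beta, se)


def _batched_column_t(Z: np.ndarray, y: np.ndarray, col: int) -> np.ndarray:
    """t-statistic of column *col* for a batch of OLS fits.

    Z has shape (B, n, k); y is (n,) shared across the batch. Uses batched
    normal equations; singular members fall back to the pseudo-inverse.
    """
    B, n, k = Z.shape
    G = np.einsum("bnk,bnl->bkl", Z, Z)
    r = np.einsum("bnk,n->bk", Z, y)
    try:
        beta = np.linalg.solve(G, r[..., None])[..., 0]
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
        beta = np.einsum("bkl,bl->bk", Ginv, r)
    yy = float(y @ y)
    rss = np.maximum(yy - np.einsum("bk,bk->b", beta, r), 0.0)
    sigma2 = rss / max(n - k, 1)
    se = np.sqrt(np.maximum(sigma2 * Ginv[:, col, col], 0.0))
    return _safe_t(beta[:, col], se)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the predictor columns involved in a rank deficiency."""
    flagged = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        scale = max(float(np.abs(X[:, j]).max()), 1.0)
        if np.abs(resid).max() < 1e-8 * scale:
            flagged.append(names[j])
    return flagged or list(names)


def ols_dyadic(y: np.ndarray, X: np.ndarray,
               names: Optional[Sequence[str]] = None,
               add_intercept: bool = True):
    """OLS over dyad rows: returns (coefficients, t-statistics), intercept
    first when *add_intercept*. The t values are used only as pivotal
    permutation statistics, never for parametric p-values.

    Raises on rank deficiency, naming the collinear predictors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(names) if names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    full = np.column_stack([np.ones(len(y)), X]) if add_intercept else X
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = _collinear_columns(X, names)
        raise np.linalg.LinAlgError(
            f"rank-deficient dyadic design; collinear predictor(s): {bad}"
        )
    return _ols(y, full)


# ---------------------------------------------------------------------------
# Node permutation
# ---------------------------------------------------------------------------

def node_permute(M: DyadMatrix, perm) -> DyadMatrix:
    """Jointly permute rows and columns: M'[i, j] = M[perm(i), perm(j)].

    *perm* is either a dict mapping each id to an id (a bijection) or an
    integer index array of length n forming a permutation of range(n).
    """
    n = M.n
    if isinstance(perm, dict):
        if sorted(perm) != sorted(M.ids) or sorted(perm.values()) != sorted(M.ids):
            raise ValueError("perm is not a bijection of the matrix ids")
        q = np.array([M.index_of(perm[u]) for u in M.ids])
    else:
        q = np.asarray(perm, dtype=int)
        if q.shape != (n,) or sorted(q.tolist()) != list(range(n)):
            raise ValueError("perm is not a permutation of range(n)")
    return M._like(M.ids, M.values[np.ix_(q, q)])


def _draw_permutations(n: int, n_permutations: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(B, n) array of uniform node permutations (with replacement)."""
    return np.argsort(rng.random((n_permutations, n)), axis=1)


def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=int)


# ---------------------------------------------------------------------------
# QAP engines
# ---------------------------------------------------------------------------

@dataclass
class MRQAPResult:
    """Coefficients and permutation inference for one dyadic regression."""

    predictor_names: list
    beta: dict
    intercept: float
    tstat: dict
    pvalue: dict
    n_as_extreme: dict  # permutations at least as extreme as observed
    n_permutations: int
    seed: Optional[int]
    n_nodes: int
    n_dyads: int
    sided: str
    exhaustive: bool
    method: str

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sided": self.sided,
            "exhaustive": self.exhaustive,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_nodes": self.n_nodes,
            "n_dyads": self.n_dyads,
            "intercept": self.intercept,
            "predictors": {
                name: {
                    "beta": self.beta[name],
                    "t": self.tstat[name],
                    "p": self.pvalue[name],
                    "n_as_extreme": self.n_as_extreme[name],
                    "n_perm": self.n_permutations,
                    "seed": self.seed,
                }
                for name in self.predictor_names
            },
        }


def _count_as_extreme(t_perm: np.ndarray, t_obs: float, sided: str) -> int:
    if sided == "two":
        return int(np.sum(np.abs(t_perm) >= abs(t_obs) - _T_TOL))
    if sided == "greater":
        return int(np.sum(t_perm >= t_obs - _T_TOL))
    if sided == "less":
        return int(np.sum(t_perm <= t_obs + _T_TOL))
    raise ValueError(f"sided must be 'two', 'greater' or 'less', got {sided!r}")


def _perm_t_stream(E: np.ndarray, perms: np.ndarray, iu: np.ndarray,
                   ju: np.ndarray, Xc: np.ndarray, y: np.ndarray,
                   complete: bool) -> np.ndarray:
    """t of the node-permuted residual column in y ~ [Xc, E_perm].

    Node permutation is applied to the full residual matrix before the
    dyad mask is re-applied; with an incomplete mask a permutation can map
    a usable dyad onto a missing entry, in which case that permutation is
    refit on its finite dyad subset.
    """
    vals = E[perms[:, iu], perms[:, ju]]  # (B, n_dyads)
    B, nd = vals.shape
    k0 = Xc.shape[1]
    if complete or not np.isnan(vals).any():
        Z = np.concatenate(
            [np.broadcast_to(Xc, (B, nd, k0)).copy(), vals[:, :, None]], axis=2
        )
        return _batched_column_t(Z, y, k0)
    out = np.empty(B)
    for b in range(B):
        ok = np.isfinite(vals[b])
        if ok.sum() <= k0 + 1:
            out[b] = np.nan
            continue
        Z = np.column_stack([Xc[ok], vals[b, ok]])[None, :, :]
        out[b] = _batched_column_t(Z, y[ok], k0)[0]
    return out


def _qap_engine(design: DyadDesign, n_permutations: int, seed, sided: str,
                exhaustive: bool, residualize: bool, method: str) -> MRQAPResult:
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    vd = vectorize_dyads(design)
    n = len(vd.ids)
    p = vd.X.shape[1]
    full = np.column_stack([np.ones(len(vd.y)), vd.X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = _collinear_columns(vd.X, vd.names)
        raise np.linalg.LinAlgError(
            f"rank-deficient dyadic design; collinear predictor(s): {bad}"
        )
    beta_full, _ = _ols(vd.y, full)

    if exhaustive:
        perms = _all_permutations(n)
    else:
        rng = np.random.default_rng(seed)
        perms = _draw_permutations(n, n_permutations, rng)
    B = len(perms)

    tstat, pval, nextr = {}, {}, {}
    ones = np.ones((len(vd.y), 1))
    for k, name in enumerate(vd.names):
        others = np.delete(vd.X, k, axis=1)
        Xc = np.column_stack([ones, others]) if others.size else ones
        xk = vd.X[:, k]
        if residualize and p > 1:
            coef, *_ = np.linalg.lstsq(Xc, xk, rcond=None)
            e = xk - Xc @ coef
        else:
            e = xk
        E = devectorize_dyads(e, vd.iu, vd.ju, n)
        # observed t through the same route as the permutations, so the
        # identity permutation reproduces it exactly
        t_obs = float(
            _batched_column_t(
                np.column_stack([Xc, e])[None, :, :], vd.y, Xc.shape[1]
            )[0]
        )
        t_perm = _perm_t_stream(E, perms, vd.iu, vd.ju, Xc, vd.y, vd.complete)
        valid = np.isfinite(t_perm) | np.isinf(t_perm)
        t_valid = t_perm[valid]
        count = _count_as_extreme(t_valid, t_obs, sided)
        if exhaustive:
            pval[name] = count / len(t_valid)
        else:
            pval[name] = (1 + count) / (1 + len(t_valid))
        tstat[name] = t_obs
        nextr[name] = count
    return MRQAPResult(
        predictor_names=vd.names,
        beta={name: float(beta_full[1 + k]) for k, name in enumerate(vd.names)},
        intercept=float(beta_full[0]),
        tstat=tstat,
        pvalue=pval,
        n_as_extreme=nextr,
        n_permutations=B,
        seed=None if exhaustive else seed,
        n_nodes=n,
        n_dyads=len(vd.y),
        sided=sided,
        exhaustive=exhaustive,
        method=method,
    )


def mrqap_dsp(design: DyadDesign, n_permutations: int = 1000,
              seed: Optional[int] = None, sided: str = "two",
              exhaustive: bool = False) -> MRQAPResult:
    """MRQAP with double semi-partialing.

    For each predictor: the residual matrix of that predictor on the
    others is node-permuted, substituted into the model, and the pivotal t
    of the substituted column forms the permutation distribution compared
    against the observed full-model t. Coefficients are reported from the
    unpermuted full model.
    """
    return _qap_engine(design, n_permutations, seed, sided, exhaustive,
                       residualize=True, method="mrqap_dsp")


def qap_single(design: DyadDesign, n_permutations: int = 1000,
               seed: Optional[int] = None, sided: str = "two",
               exhaustive: bool = False) -> MRQAPResult:
    """Single-predictor QAP: node-permute the predictor matrix itself.

    Equivalent to permuting the response under a one-predictor model; with
    one predictor the DSP residual is just the centered predictor, whose
    permutation stream yields the identical t sequence, so this is the
    no-partialing special case of :func:`mrqap_dsp`.
    """
    if len(design.predictors) != 1:
        raise ValueError(
            f"qap_single requires exactly one predictor, got "
            f"{len(design.predictors)}"
        )
    return _qap_engine(design, n_permutations, seed, sided, exhaustive,
                       residualize=False, method="qap_single")
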