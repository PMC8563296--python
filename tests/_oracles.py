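"""Independent brute-force oracles used to validate the permutation
machinery. Deliberately naive: explicit loops, pseudo-inverse OLS, and
full enumeration of the symmetric group — sharing no code with the
package's vectorized implementations."""

from __future__ import annotations

import itertools

import numpy as np

T_TIE_TOL = 1e-9  # same tie rule as the implementation: >= |t_obs| - tol


def ols_t_oracle(y, X):
    """Closed-form OLS coefficients and t-statistics via the normal
    equations, computed with the pseudo-inverse."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se,
                     np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    return beta, t


def _dyad_vector(mat, n):
    return np.array([mat[i][j] for i in range(n) for j in range(i + 1, n)])


def exhaustive_qap_counts(y_mat, pred_mats, residualize, sided="two"):
    """Exact QAP/MRQAP-DSP tail counts over the full permutation group.

    Returns (counts, n_perms, t_obs) with one entry per predictor:
    counts[k] = number of node permutations whose substituted-column
    |t| is at least |t_obs| (two-sided; the identity is included).
    """
    n = len(y_mat)
    y = _dyad_vector(np.asarray(y_mat, float), n)
    Xcols = [_dyad_vector(np.asarray(m, float), n) for m in pred_mats]
    nd = len(y)
    Xfull = np.column_stack([np.ones(nd)] + Xcols)
    _, t_full = ols_t_oracle(y, Xfull)
    t_obs = t_full[1:]

    counts = []
    all_perms = list(itertools.permutations(range(n)))
    for k in range(len(Xcols)):
        others = [c for j, c in enumerate(Xcols) if j != k]
        Xo = np.column_stack([np.ones(nd)] + others)
        if residualize and others:
            bo, _ = ols_t_oracle(Xcols[k], Xo)
            e = Xcols[k] - Xo @ bo
        else:
            e = Xcols[k]
        # rebuild the residual as a symmetric matrix
        E = np.zeros((n, n))
        pos = 0
        for i in range(n):
            for j in range(i + 1, n):
                E[i][j] = e[pos]
                E[j][i] = e[pos]
                pos += 1
        count = 0
        for perm in all_perms:
            Ep = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    Ep[i][j] = E[perm[i]][perm[j]]
            ep = _dyad_vector(Ep, n)
            Z = np.column_stack([Xo, ep])
            _, tz = ols_t_oracle(y, Z)
            tp = tz[-1]
            if sided == "two":
                hit = abs(tp) >= abs(t_obs[k]) - T_TIE_TOL
            elif sided == "greater":
                hit = tp >= t_obs[k] - T_TIE_TOL
            else:
                hit = tp <= t_obs[k] + T_TIE_TOL
            count += bool(hit)
        counts.append(count)
    return counts, len(all_perms), t_obs


def random_symmetric(rng, n, diag=np.nan):
    """Random symmetric matrix with the given diagonal."""
    a = rng.normal(size=(n, n))
    a = np.triu(a, 1)
    a = a + a.T
    np.fill_diagonal(a, diag)
    return a
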