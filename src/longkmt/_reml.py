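"""Fast REML for the null linear mixed model with random intercept + slope.

The null model of the longitudinal score test is

    y_i = X_i beta + Z_i b_i + eps_i,   b_i ~ N(0, D),  eps_i ~ N(0, s2e I)

with ``Z_i = [1, t_i]`` (random intercept and random time slope) and iid
within-subject error.  Because every subject's covariance block is a
function of its *observation-time pattern* only, subjects are grouped by
pattern and all per-subject sums collapse into per-pattern cross-product
tensors; one REML objective evaluation then costs a few hundred flops per
pattern regardless of n.  This is what makes refitting the null model tens
of thousands of times in the simulation study affordable.

D is parameterized through its Cholesky factor with log-diagonal, so the
optimizer is unconstrained; a singular (boundary) D shows up as a very
negative log-diagonal and is flagged rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["RemlResult", "reml_fit"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class _Pattern:
    times: np.ndarray  # (m_o,)
    rows: np.ndarray  # (n_pat, m_o) original row indices
    Z: np.ndarray  # (m_o, 2)
    SXX: np.ndarray  # (m_o, m_o, p, p)
    SXy: np.ndarray  # (m_o, m_o, p)
    Syy: np.ndarray  # (m_o, m_o)
    X: np.ndarray  # (n_pat, m_o, p)
    y: np.ndarray  # (n_pat, m_o)


@dataclass
class RemlResult:
    beta: np.ndarray
    D: np.ndarray
    sigma_eps2: float
    loglik: float
    converged: bool
    boundary: bool
    n_subjects: int
    n_obs: int
    patterns: list[_Pattern] = field(repr=False)
    _sigma_inv: dict = field(default_factory=dict, repr=False)

    # -- block operations -------------------------------------------------
    def _pattern_inverses(self):
        if not self._sigma_inv:
            for k, pat in enumerate(self.patterns):
                S = pat.Z @ self.D @ pat.Z.T + self.sigma_eps2 * np.eye(len(pat.times))
                self._sigma_inv[k] = np.linalg.inv(S)
        return self._sigma_inv

    def apply_sigma_inv(self, arr: np.ndarray) -> np.ndarray:
        """``Sigma0^{-1} @ arr`` via per-subject block solves.

        ``arr`` is (n_obs,) or (n_obs, k) in the original row order.
        """
        arr = np.asarray(arr, dtype=float)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr[:, None]
        out = np.empty_like(arr)
        inv = self._pattern_inverses()
        for k, pat in enumerate(self.patterns):
            block = arr[pat.rows]  # (n_pat, m_o, k)
            out[pat.rows] = np.einsum("ab,ibk->iak", inv[k], block)
        return out[:, 0] if squeeze else out

    def sigma0_dense(self) -> np.ndarray:
        """Dense marginal covariance (tests / small data only)."""
        n_obs = sum(p.rows.size for p in self.patterns)
        S = np.zeros((n_obs, n_obs))
        for pat in self.patterns:
            blk = pat.Z @ self.D @ pat.Z.T + self.sigma_eps2 * np.eye(len(pat.times))
            for rows in pat.rows:
                S[np.ix_(rows, rows)] = blk
        return S


def _build_patterns(subject, time, y, X):
    order = np.lexsort((time, subject))
    subject, time = subject[order], time[order]
    # split into per-subject slices
    starts = np.flatnonzero(np.r_[True, subject[1:] != subject[:-1]])
    ends = np.r_[starts[1:], subject.size]
    groups: dict[tuple, list] = {}
    for s, e in zip(starts, ends):
        key = tuple(time[s:e])
        groups.setdefault(key, []).append(order[s:e])
    patterns = []
    for key, row_lists in groups.items():
        rows = np.asarray(row_lists)
        t = np.asarray(key, dtype=float)
        Xi = X[rows]  # (n_pat, m_o, p)
        yi = y[rows]
        patterns.append(
            _Pattern(
                times=t,
                rows=rows,
                Z=np.column_stack([np.ones_like(t), t]),
                SXX=np.einsum("iap,ibq->abpq", Xi, Xi, optimize=True),
                SXy=np.einsum("iap,ib->abp", Xi, yi, optimize=True),
                Syy=np.einsum("ia,ib->ab", yi, yi),
                X=Xi,
                y=yi,
            )
        )
    return patterns


def _theta_to_vc(theta):
    s2e = np.exp(theta[0])
    L = np.array([[np.exp(theta[1]), 0.0], [theta[2], np.exp(theta[3])]])
    return s2e, L @ L.T


def _neg2_reml(theta, patterns, p):
    s2e, D = _theta_to_vc(theta)
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    logdet = 0.0
    for pat in patterns:
        m = len(pat.times)
        S = pat.Z @ D @ pat.Z.T + s2e * np.eye(m)
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            return 1e12
        W = np.linalg.inv(S)
        n_pat = pat.rows.shape[0]
        logdet += n_pat * ld
        XtWX += np.einsum("ab,abpq->pq", W, pat.SXX)
        XtWy += np.einsum("ab,abp->p", W, pat.SXy)
        ytWy += float(np.einsum("ab,ab->", W, pat.Syy))
    try:
        c = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return 1e12
    beta = np.linalg.solve(XtWX, XtWy)
    quad = ytWy - beta @ XtWy
    logdet_xwx = 2.0 * np.log(np.diag(c)).sum()
    return logdet + logdet_xwx + quad


def reml_fit(subject, time, y, X, start=None) -> RemlResult:
    """REML estimation of (beta, D, s2e) for the random intercept+slope LMM.

    ``subject`` is an integer code per observation; ``X`` the fixed-effect
    design including the intercept and time columns.  Raises on a
    rank-deficient design; a boundary (near-singular) D is retained and
    flagged.
    """
    subject = np.asarray(subject)
    time = np.asarray(time, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_obs, p = X.shape
    if np.unique(time).size < 2:
        raise ValueError(
            "all observations share one time point; the longitudinal fit "
            "needs m >= 2 -- use the cross-sectional (ANCOVA) mode instead"
        )
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns for the error message
        _, R = np.linalg.qr(X)
        bad = [str(j) for j in np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * n_obs)]
        raise ValueError(f"design matrix is rank deficient (columns {bad})")
    patterns = _build_patterns(subject, time, y, X)
    n_subjects = sum(pat.rows.shape[0] for pat in patterns)

    if start is None:
        v = float(np.var(y))
        start = np.array([np.log(v / 2 + 1e-6), np.log(v / 4 + 1e-6) / 2, 0.0, -1.0])
    res = optimize.minimize(
        _neg2_reml,
        start,
        args=(patterns, p),
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise RuntimeError(f"REML fit failed to converge: {res.message}")
    s2e, D = _theta_to_vc(res.x)
    # recompute beta at the optimum
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    for pat in patterns:
        W = np.linalg.inv(pat.Z @ D @ pat.Z.T + s2e * np.eye(len(pat.times)))
        XtWX += np.einsum("ab,abpq->pq", W, pat.SXX)
        XtWy += np.einsum("ab,abp->p", W, pat.SXy)
    beta = np.linalg.solve(XtWX, XtWy)
    ev = np.linalg.eigvalsh(D)
    boundary = ev[0] < 1e-6 * max(ev[-1], s2e)
    loglik = -0.5 * (res.fun + (n_obs - p) * _LOG2PI)
    return RemlResult(
        beta=beta,
        D=D,
        sigma_eps2=float(s2e),
        loglik=float(loglik),
        converged=bool(res.success),
        boundary=bool(boundary),
        n_subjects=n_subjects,
        n_obs=n_obs,
        patterns=patterns,
    )
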