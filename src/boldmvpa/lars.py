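"""Least angle regression with the LASSO modification (coefficient path).

Traces the piecewise-linear path of solutions to

    min_b  1/2 ||y - X b||^2 + lam ||b||_1

from ``lam = max_j |x_j' y|`` (all coefficients zero) down to the
least-squares end.  At each breakpoint a covariate either joins the active
set (its absolute correlation with the residual reaches the shared maximum)
or leaves it (its coefficient crosses zero: the LASSO drop modification).
Between breakpoints the active coefficients move along the equiangular
direction, so every absolute active correlation decreases at the same unit
rate in the step parameter and the breakpoint penalty is the current maximal
absolute correlation.

The caller is expected to center (and, if desired, scale) the columns of
``X`` and to center ``y``; the decoder estimator wraps this with
standardization and intercept handling.  The path can also be run purely
from Gram-form inputs (``X'X`` and ``X'y``), which the permutation control
uses to avoid recomputing fold Gram matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["LarsPath", "lars_lasso_path"]

_EPS = 1e-12


@dataclass
class LarsPath:
    """Breakpoints of the LASSO coefficient path.

    lambdas[k] is the L1 penalty at breakpoint k (descending, starting at
    lambda_max with the all-zero solution); coefs[k] the full coefficient
    vector; active_sets[k] the active covariate indices in entry order.
    """

    lambdas: np.ndarray          # (n_breakpoints,)
    coefs: np.ndarray            # (n_breakpoints, p)
    active_sets: list            # list of tuples

    @property
    def n_breakpoints(self) -> int:
        return len(self.lambdas)

    def coef_with_max_active(self, max_active: int) -> tuple[np.ndarray, float]:
        """Last breakpoint whose active set has at most ``max_active`` members."""
        for k in range(self.n_breakpoints - 1, -1, -1):
            if len(self.active_sets[k]) <= max_active:
                return self.coefs[k], self.lambdas[k]
        return self.coefs[0], self.lambdas[0]


def lars_lasso_path(X: np.ndarray | None = None, y: np.ndarray | None = None,
                    max_active: int | None = None, *,
                    gram: np.ndarray | None = None,
                    Xty: np.ndarray | None = None,
                    n_samples: int | None = None,
                    tol: float = 1e-10) -> LarsPath:
    """Compute the LARS-LASSO breakpoint path.

    Parameters
    ----------
    X, y : centered design (m x p) and centered response. May be omitted when
        ``gram`` (= X'X) and ``Xty`` (= X'y) are supplied.
    max_active : stop once the active set holds this many covariates (the
        recorded final breakpoint is the solution at which the next covariate
        would enter). None runs to the least-squares end.
    n_samples : number of rows of the (centered) design; inferred from ``X``
        when given. The active set is additionally capped at
        ``n_samples - 1`` — the rank of a centered design — past which the
        equiangular direction is undefined.
    tol : numerical tolerance for correlation ties and zero crossings.

    Notes
    -----
    Constant (zero-variance) columns are excluded with a warning.  Exact
    duplicate columns can never co-enter: their entry step is undefined
    (zero denominator) and is skipped, so the lower index wins; ties in the
    entry correlation are likewise broken toward the lowest index.
    """
    if gram is None or Xty is None:
        if X is None or y is None:
            raise ValueError("provide either (X, y) or (gram, Xty)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        gram = X.T @ X
        Xty = X.T @ y
        n_samples = X.shape[0]
    else:
        gram = np.asarray(gram, dtype=float)
        Xty = np.asarray(Xty, dtype=float)
    p = len(Xty)
    valid = np.diag(gram) > _EPS
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} constant column(s) excluded "
                      "from the LARS-LASSO path")
    if max_active is None:
        max_active = p
    max_active = int(max_active)
    if n_samples is not None:
        max_active = min(max_active, n_samples - 1)

    beta = np.zeros(p)
    active: list[int] = []
    lambdas = []
    coefs = []
    sets = []

    def record(lam):
        lambdas.append(max(lam, 0.0))
        coefs.append(beta.copy())
        sets.append(tuple(active))

    c0 = np.where(valid, np.abs(Xty), -np.inf)
    C = float(np.max(c0)) if valid.any() else 0.0
    record(C)
    if max_active == 0 or C < tol:
        return LarsPath(np.array(lambdas), np.array(coefs), sets)

    # the entering covariate is decided by the step computation (never by
    # re-scanning correlations, which would readmit exact duplicates)
    pending_entry: int | None = int(np.flatnonzero(c0 >= C - tol * max(1.0, C)).min())
    just_dropped = -1
    for _ in range(8 * p + 10):
        if pending_entry is not None:
            if len(active) >= max_active:
                break
            active.append(pending_entry)
            pending_entry = None
        if not active:
            break
        c = Xty - gram[:, active] @ beta[active]
        A = np.asarray(active)
        C = float(np.max(np.abs(c[A])))
        if C < tol * max(1.0, lambdas[0]):
            break
        entry_tol = tol * max(1.0, C)

        s = np.sign(c[A])
        s[s == 0] = 1.0
        G = gram[np.ix_(A, A)]
        try:
            d = np.linalg.solve(G, s)
        except np.linalg.LinAlgError:
            d = np.linalg.lstsq(G, s, rcond=None)[0]
        a = gram[:, A] @ d  # rate of correlation change, all covariates

        # candidate steps: inactive entry, zero crossing, active-set OLS end
        is_active = np.zeros(p, dtype=bool)
        is_active[A] = True
        gamma = C  # gamma == C zeroes every active correlation (OLS end)
        entry_j = -1
        inact = np.where(~is_active & valid)[0]
        inact = inact[inact != just_dropped]
        if inact.size:
            with np.errstate(divide="ignore", invalid="ignore"):
                g1 = (C - c[inact]) / (1.0 - a[inact])
                g2 = (C + c[inact]) / (1.0 + a[inact])
            for g in (g1, g2):
                pos = np.isfinite(g) & (g > entry_tol)
                if pos.any():
                    gmin = float(g[pos].min())
                    if gmin < gamma - entry_tol:
                        gamma = gmin
                        entry_j = int(inact[pos & (g <= gmin + entry_tol)].min())
                    elif gmin <= gamma + entry_tol and entry_j >= 0:
                        entry_j = min(entry_j,
                                      int(inact[pos & (g <= gmin + entry_tol)].min()))
        drop_idx = -1
        with np.errstate(divide="ignore", invalid="ignore"):
            gd = -beta[A] / d
        ok = np.isfinite(gd) & (gd > entry_tol)
        if ok.any():
            gmin = float(gd[ok].min())
            if gmin < gamma - entry_tol:
                gamma = gmin
                entry_j = -1
                drop_idx = int(A[np.flatnonzero(ok & (gd <= gmin + entry_tol))[0]])

        beta[A] += gamma * d
        just_dropped = -1
        if drop_idx >= 0:
            beta[drop_idx] = 0.0
            active.remove(drop_idx)
            just_dropped = drop_idx
        elif entry_j >= 0:
            pending_entry = entry_j
        record(C - gamma)
        if C - gamma < tol or (drop_idx < 0 and entry_j < 0):
            break
    return LarsPath(np.array(lambdas), np.array(coefs), sets)
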