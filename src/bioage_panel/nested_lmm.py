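"""Gaussian linear mixed model with nested random intercepts (pair / individual).

This is the model behind biological-age residualization in a twin cohort:

    y_ijk = x_ijk' beta + u_i + u_ij + e_ijk

with ``u_i ~ N(0, sigma2_pair)`` a twin-pair intercept, ``u_ij ~ N(0,
sigma2_individual)`` an individual intercept nested in the pair, and i.i.d.
residual ``e_ijk ~ N(0, sigma2_resid)``.

The fitter profiles out ``beta`` and the residual variance and optimizes the
(restricted) likelihood over the two variance ratios ``lambda_p =
sigma2_pair/sigma2_resid`` and ``lambda_i = sigma2_individual/sigma2_resid``.
For this covariance structure the marginal precision has a closed Woodbury
form, so every likelihood evaluation reduces to per-individual and per-pair
weighted sums — O(n) with small dense algebra, no per-group matrix factorization.
Empirical-Bayes (BLUP) predictions of both random intercepts come from the
same quantities.

General-purpose mixed-model software fits the identical model; this dedicated
routine exists because the package's calibration studies refit it thousands of
times.  Its estimates are cross-checked against an independent general solver
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["NestedLMM", "NestedLMMResult"]

_TWO_PI = 2.0 * np.pi


class _Workspace:
    """Precomputed, variance-independent sufficient statistics."""

    def __init__(self, y, X, pair_ids, individual_ids):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("y and X have different lengths")
        pair_ids = np.asarray(pair_ids)
        individual_ids = np.asarray(individual_ids)

        # sort rows by (pair, individual) so reduceat segments are contiguous
        order = np.lexsort((individual_ids, pair_ids))
        self.order = order
        y, X = y[order], X[order]
        pair_ids, individual_ids = pair_ids[order], individual_ids[order]

        _, ind_codes = np.unique(individual_ids, return_inverse=True)
        _, pair_codes = np.unique(pair_ids, return_inverse=True)
        # each individual must belong to exactly one pair
        ind_first = np.concatenate(([True], ind_codes[1:] != ind_codes[:-1]))
        self.ind_starts = np.flatnonzero(ind_first)
        ind_of_rows = np.cumsum(ind_first) - 1
        if np.any(pair_codes[self.ind_starts][ind_of_rows] != pair_codes):
            raise ValueError("individual_ids must be nested within pair_ids")

        self.n, self.p = n, p
        self.y, self.X = y, X
        self.ind_row = ind_of_rows                       # row -> individual index
        self.pair_of_ind = pair_codes[self.ind_starts]   # individual -> pair index
        pair_first = np.concatenate(
            ([True], self.pair_of_ind[1:] != self.pair_of_ind[:-1])
        )
        self.pair_starts_ind = np.flatnonzero(pair_first)  # segments in individual axis
        self.n_ind = self.ind_starts.size
        self.n_pair = self.pair_starts_ind.size
        self.pair_row = self.pair_of_ind[self.ind_row]

        M = np.column_stack([X, y])                      # (n, p+1)
        self.C = M.T @ M                                 # total cross-products
        self.S = np.add.reduceat(M, self.ind_starts, axis=0)   # per-individual sums
        self.n_k = np.diff(np.append(self.ind_starts, n)).astype(float)

    def wls_pieces(self, lam_p, lam_i):
        """Return (C_W, logdet, aux) where C_W = [X y]' W^-1 [X y]."""
        d_i = 1.0 + lam_i * self.n_k                     # (n_ind,)
        w_k = lam_i / d_i
        T = self.S / d_i[:, None]                        # per-individual, shrunk
        C_A = self.C - (self.S * w_k[:, None]).T @ self.S
        P = np.add.reduceat(T, self.pair_starts_ind, axis=0)   # (n_pair, p+1)
        c_g = np.add.reduceat(self.n_k / d_i, self.pair_starts_ind)
        d_p = 1.0 + lam_p * c_g
        v_g = lam_p / d_p
        C_W = C_A - (P * v_g[:, None]).T @ P
        logdet = float(np.sum(np.log(d_i)) + np.sum(np.log(d_p)))
        return C_W, logdet, (d_i, v_g, c_g, d_p)

    def quad_form(self, r, lam_p, lam_i):
        """r' W^-1 r computed on the residual vector (cancellation-safe)."""
        d_i = 1.0 + lam_i * self.n_k
        Sr = np.add.reduceat(r, self.ind_starts)
        Pr = np.add.reduceat(Sr / d_i, self.pair_starts_ind)
        c_g = np.add.reduceat(self.n_k / d_i, self.pair_starts_ind)
        v_g = lam_p / (1.0 + lam_p * c_g)
        return float(r @ r - (lam_i / d_i) @ Sr ** 2 - v_g @ Pr ** 2)


def _neg2loglik(ws: _Workspace, lam_p, lam_i, reml):
    if lam_p < 0 or lam_i < 0:
        return np.inf, None
    C_W, logdet, _ = ws.wls_pieces(lam_p, lam_i)
    p = ws.p
    Xx, Xy, yy = C_W[:p, :p], C_W[:p, p], C_W[p, p]
    try:
        beta = np.linalg.solve(Xx, Xy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = ws.quad_form(ws.y - ws.X @ beta, lam_p, lam_i)
    if rss <= 0:
        rss = np.finfo(float).tiny
    if reml:
        dof = ws.n - p
        sign, ld_xx = np.linalg.slogdet(Xx)
        if sign <= 0:
            return np.inf, None
        crit = dof * np.log(_TWO_PI * rss / dof) + logdet + ld_xx + dof
    else:
        crit = ws.n * np.log(_TWO_PI * rss / ws.n) + logdet + ws.n
    return crit, (beta, rss, Xx)


@dataclass
class NestedLMMResult:
    """Fitted nested random-intercept model."""

    fe_params: np.ndarray
    cov_fe: np.ndarray
    sigma2_pair: float
    sigma2_individual: float
    sigma2_resid: float
    llf: float
    reml: bool
    converged: bool
    n_obs: int
    n_individuals: int
    n_pairs: int
    _ws: _Workspace = None
    _lam: tuple = None

    @property
    def fe_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_fe))

    def random_effects(self):
        """Empirical-Bayes (BLUP) predictions.

        Returns
        -------
        u_pair : array (n_pairs,)
        u_individual : array (n_individuals,)
        """
        ws, (lam_p, lam_i) = self._ws, self._lam
        r = ws.y - ws.X @ self.fe_params
        d_i = 1.0 + lam_i * ws.n_k
        Sr = np.add.reduceat(r, ws.ind_starts) / d_i          # Z_i' A^-1 r
        Pr = np.add.reduceat(Sr, ws.pair_starts_ind)          # 1' A^-1 r per pair
        c_g = np.add.reduceat(ws.n_k / d_i, ws.pair_starts_ind)
        d_p = 1.0 + lam_p * c_g
        u_pair = lam_p * Pr / d_p
        v_g = lam_p / d_p
        u_ind = lam_i * (Sr - (v_g * Pr)[ws.pair_of_ind] * (ws.n_k / d_i))
        return u_pair, u_ind

    def vc_se(self) -> np.ndarray:
        """Asymptotic standard errors of (sigma2_pair, sigma2_individual,
        sigma2_resid) from the numerical Hessian of the (restricted)
        likelihood in the variance parameters."""
        ws = self._ws
        p = ws.p if self.reml else 0

        def crit(v):
            s2p, s2i, s2e = v
            if s2e <= 0 or s2p < 0 or s2i < 0:
                return np.inf
            C_W, logdet_w, _ = ws.wls_pieces(s2p / s2e, s2i / s2e)
            Xx, Xy = C_W[:ws.p, :ws.p], C_W[:ws.p, ws.p]
            beta = np.linalg.solve(Xx, Xy)
            rss = ws.quad_form(ws.y - ws.X @ beta, s2p / s2e, s2i / s2e)
            out = ws.n * np.log(s2e) + logdet_w + rss / s2e
            if self.reml:
                sign, ld = np.linalg.slogdet(Xx)
                out += ld - ws.p * np.log(s2e)
            return out

        theta = np.array([max(self.sigma2_pair, 1e-10 * self.sigma2_resid),
                          max(self.sigma2_individual, 1e-10 * self.sigma2_resid),
                          self.sigma2_resid])
        h = np.maximum(1e-4 * theta, 1e-10)
        H = np.empty((3, 3))
        f0 = crit(theta)
        for a in range(3):
            for b in range(a, 3):
                ea, eb = np.zeros(3), np.zeros(3)
                ea[a], eb[b] = h[a], h[b]
                if a == b:
                    H[a, a] = (crit(theta + ea) - 2 * f0 + crit(theta - ea)) / h[a] ** 2
                else:
                    H[a, b] = H[b, a] = (
                        crit(theta + ea + eb) - crit(theta + ea - eb)
                        - crit(theta - ea + eb) + crit(theta - ea - eb)
                    ) / (4 * h[a] * h[b])
        try:
            cov = 2.0 * np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return se

    def resid(self, kind: str = "eb") -> np.ndarray:
        """Row-level residuals in the original row order.

        kind="eb": observation - fixed effects - BLUPs of both intercepts.
        kind="marginal": observation - fixed effects only.
        """
        ws = self._ws
        r = ws.y - ws.X @ self.fe_params
        if kind == "marginal":
            out_sorted = r
        elif kind == "eb":
            u_pair, u_ind = self.random_effects()
            out_sorted = r - u_pair[ws.pair_row] - u_ind[ws.ind_row]
        else:
            raise ValueError("kind must be 'eb' or 'marginal'")
        out = np.empty_like(out_sorted)
        out[ws.order] = out_sorted
        return out


class NestedLMM:
    """Two-level nested random-intercept Gaussian mixed model.

    Parameters
    ----------
    reml : bool
        Restricted maximum likelihood (default) or full ML (required for
        likelihood-ratio tests of fixed effects).
    """

    _STARTS = ((0.5, 0.5), (0.05, 0.5), (0.5, 0.05), (1e-6, 1e-6), (2.0, 2.0))

    def __init__(self, reml: bool = True):
        self.reml = reml

    def fit(self, y, X, pair_ids, individual_ids) -> NestedLMMResult:
        ws = _Workspace(y, X, pair_ids, individual_ids)
        if ws.n_pair < 2 or ws.n < ws.p + 2:
            raise ValueError("need at least 2 pairs and more observations than parameters")

        best = None
        for x0 in self._STARTS:
            res = minimize(
                lambda v: _neg2loglik(ws, v[0], v[1], self.reml)[0],
                x0=np.asarray(x0, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, None), (0.0, None)],
                options={"ftol": 1e-13, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if not np.isfinite(best.fun):
            raise RuntimeError(
                f"mixed-model fit failed to converge: {best.message} "
                f"(gradient {getattr(best, 'jac', None)})"
            )
        lam_p, lam_i = float(best.x[0]), float(best.x[1])
        crit, (beta, rss, Xx) = _neg2loglik(ws, lam_p, lam_i, self.reml)
        dof = ws.n - ws.p if self.reml else ws.n
        sigma2 = rss / dof
        cov_fe = sigma2 * np.linalg.inv(Xx)
        return NestedLMMResult(
            fe_params=beta,
            cov_fe=cov_fe,
            sigma2_pair=lam_p * sigma2,
            sigma2_individual=lam_i * sigma2,
            sigma2_resid=sigma2,
            llf=-0.5 * crit,
            reml=self.reml,
            converged=bool(best.success or np.isfinite(crit)),
            n_obs=ws.n,
            n_individuals=ws.n_ind,
            n_pairs=ws.n_pair,
            _ws=ws,
            _lam=(lam_p, lam_i),
        )
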