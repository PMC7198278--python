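"""Restricted maximum likelihood for the single-random-effect mixed model.

The model is

    y = X b + Z g + e,   g ~ N(0, Va * K),   e ~ N(0, Ve * I),

with K a known kinship matrix over entries and Z an incidence matrix mapping
observations to entries (identity when y is already one value per entry).
Writing lambda = Va / Ve, the covariance is V = Ve * (I + lambda * Z K Z').
A single eigendecomposition reduces every restricted-likelihood evaluation
to O(n) diagonal work, so the one-dimensional profile over lambda can be
maximized by a coarse log-spaced grid followed by bounded refinement.

For Z = I this is the classic spectral (EMMA-style) trick on eig(K).  For a
thin incidence Z (records to entries) the same trick runs on the q x q
matrix K^{1/2} Z'Z K^{1/2}, with q the number of entries, so record-level
trial data with thousands of plots stays cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .genotypes import KinshipMatrix

__all__ = ["KinshipMixedLM", "KinshipMixedLMResults", "drop_aliased_columns"]

_LOG2PI = np.log(2.0 * np.pi)


def drop_aliased_columns(
    X: np.ndarray, names: list[str] | None = None, tol: float = 1e-8
) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns of a design matrix.

    Columns are scanned left to right (modified Gram-Schmidt): a column is
    kept when its residual against the span of already-kept columns is
    non-negligible.  Earlier columns therefore take precedence — the
    intercept and main effects survive, aliased interaction cells drop.
    Returns the reduced matrix, the kept names and the dropped names.
    """
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] == 0:
        return X, [], []
    n = X.shape[0]
    Q = np.empty((n, 0))
    keep: list[int] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        scale = np.linalg.norm(v)
        if scale == 0.0:
            continue
        r = v - Q @ (Q.T @ v)
        r = r - Q @ (Q.T @ r)  # re-orthogonalize for stability
        nr = np.linalg.norm(r)
        if nr > tol * scale:
            Q = np.column_stack([Q, r / nr])
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep)]
    return X[:, keep], [names[j] for j in keep], dropped


class KinshipMixedLM:
    """Mixed linear model with one kinship-structured random effect.

    Parameters
    ----------
    endog : array (n_obs,)
        Response vector.
    exog : array (n_obs, p)
        Fixed-effect design; must have full column rank (use
        :func:`drop_aliased_columns` first for trial designs with aliased
        location x year cells).
    kinship : KinshipMatrix over entries.
    incidence : optional (n_obs, n_entries) 0/1 matrix mapping observations
        to entries.  Identity (one observation per entry, in kinship order)
        when omitted.
    """

    def __init__(self, endog, exog, kinship: KinshipMatrix, incidence=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if not isinstance(kinship, KinshipMatrix):
            kinship = KinshipMatrix(np.asarray(kinship))
        self.kinship = kinship
        n = self.endog.shape[0]
        if incidence is None:
            if kinship.n != n:
                raise ValueError(
                    "without an incidence matrix, y must have one value per "
                    "kinship entry"
                )
            self.incidence = None
        else:
            incidence = np.asarray(incidence, dtype=float)
            if incidence.shape != (n, kinship.n):
                raise ValueError("incidence must be (n_obs, n_entries)")
            self.incidence = incidence
        p = self.exog.shape[1]
        if p >= n:
            raise ValueError("more fixed-effect columns than observations")
        if np.linalg.matrix_rank(self.exog) < p:
            raise ValueError("fixed-effect design is rank deficient")
        self._prepare()

    # -- spectral preparation ------------------------------------------------
    def _prepare(self) -> None:
        y, X = self.endog, self.exog
        if self.incidence is None:
            d, U = self.kinship.eig()
            self._mu = np.clip(d, 0.0, None)          # eigenvalues of Z K Z'
            self._ty = U.T @ y                        # rotated responses
            self._tX = U.T @ X
            self._full_rotation = True
        else:
            A = self.kinship.sqrt()
            T = self.incidence @ A                    # (n, q)
            B = T.T @ T                               # = A Z'Z A, symmetric
            mu, Q = np.linalg.eigh(B)
            self._mu = np.clip(mu, 0.0, None)
            Tt = T @ Q                                # (n, q), orthonormal cols scaled
            self._Tt_y = Tt.T @ y
            self._Tt_X = Tt.T @ X
            self._yty = float(y @ y)
            self._Xty = X.T @ y
            self._XtX = X.T @ X
            self._full_rotation = False
        sign, logdet = np.linalg.slogdet(self.exog.T @ self.exog)
        self._logdet_XtX = logdet

    # -- restricted likelihood ----------------------------------------------
    def _profile(self, lam: float):
        """Profiled REML pieces at ratio lambda = Va/Ve.

        Returns (restricted log-likelihood, Ve_hat, beta_hat, XVX_inv).
        """
        n, p = self.endog.shape[0], self.exog.shape[1]
        mu = self._mu
        if self._full_rotation:
            w = lam * mu + 1.0                       # diag of V0 in eigenbasis
            sw = 1.0 / w
            tX, ty = self._tX, self._ty
            XVX = (tX * sw[:, None]).T @ tX
            XVy = (tX * sw[:, None]).T @ ty
            yVy = float(ty @ (ty * sw))
            logdet_V0 = float(np.sum(np.log(w)))
        else:
            a = lam / (1.0 + lam * mu)               # Woodbury coefficients
            TtX, Tty = self._Tt_X, self._Tt_y
            XVX = self._XtX - (TtX * a[:, None]).T @ TtX
            XVy = self._Xty - TtX.T @ (a * Tty)
            yVy = self._yty - float(Tty @ (a * Tty))
            logdet_V0 = float(np.sum(np.log1p(lam * mu)))
        beta = np.linalg.solve(XVX, XVy)
        yPy = yVy - float(XVy @ beta)
        yPy = max(yPy, 1e-300)
        ve = yPy / (n - p)
        sign, logdet_XVX = np.linalg.slogdet(XVX)
        llf = -0.5 * (
            (n - p) * (_LOG2PI + np.log(ve) + 1.0)
            + logdet_V0
            + logdet_XVX
            - self._logdet_XtX
        )
        return llf, ve, beta, XVX

    def loglike_restricted(self, lam: float) -> float:
        """Restricted log-likelihood profiled over beta and Ve at given lambda."""
        return self._profile(lam)[0]

    def fit(self, grid: np.ndarray | None = None) -> "KinshipMixedLMResults":
        """Maximize the restricted likelihood over lambda = Va/Ve.

        A 41-point log grid on [1e-5, 1e5] (plus the Va = 0 boundary) is
        scanned, then the bracketing interval is refined by bounded
        minimization in log(lambda).
        """
        if grid is None:
            grid = np.logspace(-5, 5, 41)
        lams = np.concatenate(([0.0], grid))
        lls = np.array([self.loglike_restricted(l) for l in lams])
        i = int(np.argmax(lls))
        best_lam, best_ll = lams[i], lls[i]
        if 0 < i < len(lams) - 1 and best_lam > 0.0:
            lo = np.log(lams[i - 1]) if lams[i - 1] > 0 else np.log(lams[i]) - 4.0
            hi = np.log(lams[i + 1])
            res = minimize_scalar(
                lambda t: -self.loglike_restricted(np.exp(t)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if -res.fun >= best_ll:
                best_lam, best_ll = float(np.exp(res.x)), float(-res.fun)
        # explicit boundary comparison: Va clamped at zero
        if lls[0] >= best_ll:
            best_lam, best_ll = 0.0, float(lls[0])
        llf, ve, beta, XVX = self._profile(best_lam)
        va = best_lam * ve
        return KinshipMixedLMResults(self, best_lam, va, ve, beta, llf, XVX)


class KinshipMixedLMResults:
    """REML estimates for :class:`KinshipMixedLM`.

    Attributes
    ----------
    va, ve : additive-genetic and residual variance components (trait units^2)
    params : GLS fixed-effect estimates at the REML variances
    llf : restricted log-likelihood at the optimum
    bic : -2 llf + p log(n)
    """

    def __init__(self, model, lam, va, ve, params, llf, XVX):
        self.model = model
        self.lam = float(lam)
        self.va = float(va)
        self.ve = float(ve)
        self.params = params
        self.llf = float(llf)
        self._XVX = XVX
        n, p = model.endog.shape[0], model.exog.shape[1]
        self.nobs = n
        self.df_model = p
        self.bic = -2.0 * self.llf + p * np.log(n)

    @property
    def h2(self) -> float:
        """Narrow-sense heritability Va / (Va + Ve)."""
        return self.va / (self.va + self.ve)

    def cov_params(self) -> np.ndarray:
        return self.ve * np.linalg.inv(self._XVX)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    def blup(self) -> np.ndarray:
        """Empirical BLUP of the entry effects g at the REML variances.

        g_hat = Va K Z' V^{-1} (y - X beta_hat), evaluated through the
        cached spectral quantities.
        """
        m = self.model
        resid = m.endog - m.exog @ self.params
        K = m.kinship.values
        if m.incidence is None:
            Vinv_r = self._vinv(resid)
            return self.va * (K @ Vinv_r)
        Vinv_r = self._vinv(resid)
        return self.va * (K @ (m.incidence.T @ Vinv_r))

    def _vinv(self, x: np.ndarray) -> np.ndarray:
        m, lam = self.model, self.lam
        if m.incidence is None:
            d, U = m.kinship.eig()
            w = lam * np.clip(d, 0, None) + 1.0
            return (U @ ((U.T @ x) / w)) / self.ve
        A = m.kinship.sqrt()
        T = m.incidence @ A
        B = T.T @ T
        mu, Q = np.linalg.eigh(B)
        mu = np.clip(mu, 0.0, None)
        Tt = T @ Q
        a = lam / (1.0 + lam * mu)
        return (x - Tt @ (a * (Tt.T @ x))) / self.ve

    def summary(self) -> str:
        lines = [
            "Kinship mixed model (REML)",
            "=" * 44,
            f"nobs: {self.nobs:>8d}    fixed effects: {self.df_model}",
            f"Va:   {self.va:>12.6g}  Ve: {self.ve:>12.6g}",
            f"h2:   {self.h2:>12.4f}  lambda: {self.lam:.6g}",
            f"restricted llf: {self.llf:.6f}   BIC: {self.bic:.3f}",
            "-" * 44,
            f"{'coef':>12s} {'se':>12s}",
        ]
        bse = self.bse
        for b, s in zip(self.params, bse):
            lines.append(f"{b:>12.5g} {s:>12.5g}")
        return "\n".join(lines)
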