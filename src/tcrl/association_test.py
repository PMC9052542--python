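"""Score tests linking a repertoire to a phenotype under a mixed model.

The phenotype follows a generalized linear mixed model

    E(y_i) = pi( beta' X_i + eta' W' f(R_i) + h(R_i) ),    h ~ N(0, tau^2 S),

with identity link for continuous traits and logit link for binary
traits. Two score tests are performed:

* fixed effect: H0: eta = 0, tau^2 = 0. The score U_eta of the
  property-weighted composition features, evaluated at the confounder-only
  null fit, is compared to a chi-square with r degrees of freedom.
* random effect: H0': tau^2 = 0 with eta unconstrained. A quadratic-form
  score in the kernel S, centered and scaled by projection-matrix traces,
  is asymptotically standard normal. For binary traits the statistic is
  built on the working response of the iteratively reweighted least
  squares (IRLS) linearization of the logistic fit.

The two scores are independent under the null, so their p-values are
combined with Fisher's method (chi-square with 4 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import default_weight_matrix, feature_matrix, weighted_features
from .homology_kernel import HomologyKernel, SubstitutionScheme, build_kernel, psd_project
from .repertoire_io import CovariateTable, PhenotypeVector, RepertoireSet

_MU_CLAMP = 1e-10
_COND_LIMIT = 1e12


class ModelFitError(RuntimeError):
    """Raised when a null-model fit fails (rank deficiency, separation, ...)."""


@dataclass
class NullFitH0:
    """Null fit under H0 (confounders only): eta = 0, tau^2 = 0."""

    beta_tilde: np.ndarray
    mu_tilde: np.ndarray
    omega_diag: np.ndarray      # diagonal of the weight matrix Omega~
    Gamma: np.ndarray           # Omega~ - Omega~ X (X'Omega~X)^-1 X'Omega~
    X: np.ndarray
    trait_type: str


@dataclass
class NullFitH0prime:
    """Null fit under H0' (confounders + fixed features): tau^2 = 0."""

    gamma_hat: np.ndarray
    Z: np.ndarray               # [X | G], n x d
    mu_hat: np.ndarray
    resid: np.ndarray           # continuous: y - mu; binary: weighted working resid
    P0: np.ndarray              # residual projection (weighted for binary)
    sigma2: np.ndarray | float  # residual variance estimate, denominator n - d
    trait_type: str

    @property
    def dim_d(self) -> int:
        return self.Z.shape[1]


@dataclass
class TestResult:
    """P-values and statistics from the fixed, random, and combined tests."""

    mode: str
    trait_type: str
    n: int
    scheme: str | None = None
    stat_eta: float | None = None
    p_eta: float | None = None
    df_eta: int | None = None
    Q_tau2: float | None = None
    p_tau2: float | None = None
    fisher_stat: float | None = None
    p_combined: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def p_value(self) -> float:
        """The headline p-value for the requested mode."""
        if self.mode == "fixed":
            return self.p_eta
        if self.mode == "random":
            return self.p_tau2
        return self.p_combined

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "trait_type": self.trait_type,
            "n": self.n,
            "scheme": self.scheme,
            "stat_eta": self.stat_eta,
            "p_eta": self.p_eta,
            "df_eta": self.df_eta,
            "Q_tau2": self.Q_tau2,
            "p_tau2": self.p_tau2,
            "fisher_stat": self.fisher_stat,
            "p_combined": self.p_combined,
            "p_value": self.p_value,
        }
        out.update(self.diagnostics)
        return out


def _check_full_rank(M: np.ndarray, name: str) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ModelFitError(f"design matrix {name} is rank deficient")


def _fit_logistic(Z: np.ndarray, y: np.ndarray, *, tol: float = 1e-10,
                  max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Logistic MLE by IRLS; returns (coefficients, fitted probabilities)."""
    n, d = Z.shape
    gamma = np.zeros(d)
    loglik = -np.inf
    for _ in range(max_iter):
        lp = Z @ gamma
        mu = 1.0 / (1.0 + np.exp(-lp))
        mu = np.clip(mu, _MU_CLAMP, 1.0 - _MU_CLAMP)
        w = mu * (1.0 - mu)
        # working response update (Newton-Raphson = IRLS for logistic)
        zw = lp + (y - mu) / w
        WZ = Z * w[:, None]
        try:
            gamma_new = np.linalg.solve(Z.T @ WZ, Z.T @ (w * zw))
        except np.linalg.LinAlgError as exc:
            raise ModelFitError(f"IRLS normal equations singular: {exc}") from exc
        lp_new = Z @ gamma_new
        ll_new = float(np.sum(y * lp_new - np.log1p(np.exp(lp_new))))
        if np.isfinite(loglik) and abs(ll_new - loglik) <= tol * (abs(loglik) + tol):
            gamma = gamma_new
            loglik = ll_new
            break
        gamma, loglik = gamma_new, ll_new
    else:
        raise ModelFitError(
            "logistic IRLS did not converge in "
            f"{max_iter} iterations (possible separation)"
        )
    mu = 1.0 / (1.0 + np.exp(-(Z @ gamma)))
    mu = np.clip(mu, _MU_CLAMP, 1.0 - _MU_CLAMP)
    return gamma, mu


def fit_null_h0(X: np.ndarray, y: np.ndarray, trait_type: str) -> NullFitH0:
    """Fit the confounder-only null model and assemble the score ingredients.

    Continuous traits use ordinary least squares with the MLE residual
    variance (denominator n); binary traits use logistic IRLS. The
    projection Gamma annihilates X (Gamma X = 0), which removes the
    uncertainty of the nuisance fit from the score covariance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    _check_full_rank(X, "X")
    if trait_type == "continuous":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = X @ beta
        sigma2_mle = float(np.mean((y - mu) ** 2))
        omega_diag = np.full(n, sigma2_mle)
    elif trait_type == "binary":
        if len(np.unique(y)) < 2:
            raise ModelFitError("binary trait has only one class")
        beta, mu = _fit_logistic(X, y)
        omega_diag = mu * (1.0 - mu)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    OX = X * omega_diag[:, None]
    Gamma = np.diag(omega_diag) - OX @ np.linalg.solve(X.T @ OX, OX.T)
    return NullFitH0(
        beta_tilde=beta, mu_tilde=mu, omega_diag=omega_diag,
        Gamma=Gamma, X=X, trait_type=trait_type,
    )


def score_fixed(fit: NullFitH0, G: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fixed-effect score test of eta = 0.

    ``U_eta = G'(y - mu~)`` with covariance ``Sigma~ = G' Gamma~ G``; the
    statistic ``U'Sigma^-1 U`` is chi-square with r = G.shape[1] df.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(y, dtype=float)
    U = G.T @ (y - fit.mu_tilde)
    Sigma = G.T @ fit.Gamma @ G
    Sigma = (Sigma + Sigma.T) / 2.0
    eig = np.linalg.eigvalsh(Sigma)
    # a feature with no variance left after projecting out X gives a
    # (near-)zero eigenvalue regardless of the condition number's scale
    if eig[0] <= max(eig[-1], 1.0) / _COND_LIMIT:
        raise ModelFitError(
            "score covariance is (near-)singular; check for constant or "
            "collinear weighted features"
        )
    stat = float(U @ np.linalg.solve(Sigma, U))
    r = G.shape[1]
    p = float(stats.chi2.sf(stat, df=r))
    return stat, max(p, np.finfo(float).tiny)


def fit_null_h0prime(
    X: np.ndarray, G: np.ndarray | None, y: np.ndarray, trait_type: str,
) -> NullFitH0prime:
    """Fit the null model with confounders and fixed features (tau^2 = 0).

    For continuous traits this is OLS of y on Z = [X | G] with the
    unbiased residual variance (denominator n - d). For binary traits
    the logistic fit is linearized through its IRLS working response:
    with weights omega = mu(1 - mu), the weighted design is
    ``Zdag = Omega^{1/2} Z`` and the weighted working residual equals
    ``(y - mu) / sqrt(omega)``; the stored projection and variance refer
    to this weighted regression.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if G is None or (hasattr(G, "shape") and np.size(G) == 0):
        Z = X
    else:
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        Z = np.hstack([X, G])
    n, d = Z.shape
    if n <= d:
        raise ModelFitError(f"n = {n} must exceed the design dimension d = {d}")
    _check_full_rank(Z, "Z = [X | G]")
    if trait_type == "continuous":
        gamma, *_ = np.linalg.lstsq(Z, y, rcond=None)
        mu = Z @ gamma
        resid = y - mu
        P0 = np.eye(n) - Z @ np.linalg.solve(Z.T @ Z, Z.T)
        sigma2 = float(resid @ resid / (n - d))
    elif trait_type == "binary":
        gamma, mu = _fit_logistic(Z, y)
        omega = mu * (1.0 - mu)
        sqrt_w = np.sqrt(omega)
        Zd = Z * sqrt_w[:, None]
        # weighted working residual: Omega^{1/2} y_w - Zdag gamma = (y-mu)/sqrt(omega)
        resid = (y - mu) / sqrt_w
        P0 = np.eye(n) - Zd @ np.linalg.solve(Zd.T @ Zd, Zd.T)
        sigma2 = float(resid @ resid / (n - d))
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    return NullFitH0prime(
        gamma_hat=gamma, Z=Z, mu_hat=mu, resid=resid,
        P0=P0, sigma2=sigma2, trait_type=trait_type,
    )


def _score_random(fit: NullFitH0prime, S: np.ndarray, *,
                  two_sided: bool = False) -> tuple[float, float]:
    n = len(fit.resid)
    d = fit.dim_d
    U = float(fit.resid @ S @ fit.resid)
    SP0 = S @ fit.P0
    tr1 = float(np.trace(SP0))
    tr2 = float(np.sum(SP0 * SP0.T))   # tr(SP0 SP0)
    sigma2 = fit.sigma2
    var = 2.0 * sigma2 ** 2 * (tr2 - tr1 ** 2 / (n - d))
    numer = U - tr1 * sigma2
    if var <= 1e-10 * max(1.0, 2.0 * sigma2 ** 2 * abs(tr2)):
        # S = I (or S in the projection's null direction) makes both the
        # numerator and the variance vanish identically: no information
        # about tau^2, so the test is exactly null.
        if abs(numer) <= 1e-8 * max(1.0, abs(U)):
            return 0.0, 1.0 if two_sided else 0.5
        raise ModelFitError(
            "variance of the random-effect score is non-positive; the kernel "
            "is degenerate with respect to the null design"
        )
    Q = numer / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(Q))) if two_sided else float(stats.norm.sf(Q))
    return Q, max(min(p, 1.0), np.finfo(float).tiny)


def score_random_continuous(
    fit: NullFitH0prime, kernel: HomologyKernel | np.ndarray, y=None, *,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Variance-component score test of tau^2 = 0 for a continuous trait.

    ``U = (y - mu)' S (y - mu)`` is centered at ``tr(S P0) sigma^2`` and
    scaled by ``sqrt(2 sigma^4 [tr(SP0 SP0) - tr(SP0)^2/(n-d)])``; the
    standardized Q is asymptotically N(0,1) under the null. The p-value
    is upper-tail by default: tau^2 >= 0, so only inflation of U above
    its null mean is evidence against H0'.
    """
    if fit.trait_type != "continuous":
        raise ValueError("fit is not for a continuous trait")
    S = kernel.S if isinstance(kernel, HomologyKernel) else np.asarray(kernel, float)
    return _score_random(fit, S, two_sided=two_sided)


def score_random_binary(
    fit: NullFitH0prime, kernel: HomologyKernel | np.ndarray, y=None, *,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Variance-component score test of tau^2 = 0 for a binary trait.

    Identical in structure to the continuous case, with the quadratic
    form taken in the IRLS weighted working residual and the projection
    and variance from the weighted working regression.
    """
    if fit.trait_type != "binary":
        raise ValueError("fit is not for a binary trait")
    S = kernel.S if isinstance(kernel, HomologyKernel) else np.asarray(kernel, float)
    return _score_random(fit, S, two_sided=two_sided)


def score_random(fit: NullFitH0prime, kernel, **kw) -> tuple[float, float]:
    """Dispatch to the continuous or binary variance-component test."""
    if fit.trait_type == "continuous":
        return score_random_continuous(fit, kernel, **kw)
    return score_random_binary(fit, kernel, **kw)


def fisher_combine(p_eta: float, p_tau2: float) -> tuple[float, float]:
    """Combine two independent p-values: -2(ln p1 + ln p2) ~ chi-square, 4 df."""
    ps = []
    for p in (p_eta, p_tau2):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            import warnings
            warnings.warn("p-value of 0 clamped to smallest positive float")
            p = np.finfo(float).tiny
        ps.append(p)
    stat = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stat), float(stats.chi2.sf(stat, df=4))


def tcrl_test(
    rs: RepertoireSet,
    cov: CovariateTable,
    phe: PhenotypeVector,
    W: np.ndarray | None = None,
    scheme: SubstitutionScheme | None = None,
    mode: str = "combined",
    kernel: HomologyKernel | None = None,
    two_sided: bool = False,
) -> TestResult:
    """End-to-end repertoire-phenotype association test.

    Parameters
    ----------
    rs, cov, phe
        Aligned repertoires, covariates, and phenotype (same subject order).
    W : array, optional
        p x r biochemical property weights; Kyte-Doolittle hydropathy by
        default.
    scheme : SubstitutionScheme, optional
        Alignment scheme for the kernel (BLOSUM62, EMBOSS default gaps,
        if omitted). Ignored if ``kernel`` is supplied.
    mode : {"combined", "fixed", "random"}
        "fixed" tests only the extracted features; "random" tests only
        the repertoire-homology random effect (no composition features
        in the null design); "combined" runs both and Fisher-combines.
    kernel : HomologyKernel, optional
        Precomputed kernel (will be PSD-projected if not already).
    """
    if mode not in ("combined", "fixed", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (rs.n == cov.n == phe.n):
        raise ValueError("repertoires, covariates, and phenotype sizes differ")
    if rs.subject_ids != cov.subject_ids or rs.subject_ids != phe.subject_ids:
        raise ValueError("subject order differs between inputs; use align_tables")
    X, y, trait = cov.X, phe.y, phe.trait_type

    if W is None:
        W = default_weight_matrix()
    F = feature_matrix(rs)
    G = weighted_features(F, W)
    r = G.shape[1]

    result = TestResult(mode=mode, trait_type=trait, n=rs.n)

    if mode in ("fixed", "combined"):
        fit0 = fit_null_h0(X, y, trait)
        result.stat_eta, result.p_eta = score_fixed(fit0, G, y)
        result.df_eta = r

    if mode in ("random", "combined"):
        if kernel is None:
            if scheme is None:
                scheme = SubstitutionScheme()
            kernel = psd_project(build_kernel(rs, scheme))
        else:
            kernel = psd_project(kernel)
        result.scheme = kernel.scheme.matrix_name
        G_null = G if mode == "combined" else None
        fit1 = fit_null_h0prime(X, G_null, y, trait)
        result.Q_tau2, result.p_tau2 = score_random(fit1, kernel, two_sided=two_sided)
        result.diagnostics["dim_d"] = fit1.dim_d

    if mode == "combined":
        result.fisher_stat, result.p_combined = fisher_combine(
            result.p_eta, result.p_tau2
        )
    return result
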