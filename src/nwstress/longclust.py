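"""Model-based clustering of 5-point longitudinal expression profiles.

Each entity contributes one ordered vector of log2 expression over the
five water conditions. Profiles are modelled as a finite mixture of
multivariate Gaussians whose component precision matrices are
parameterized by the modified Cholesky decomposition

    Sigma_g^{-1} = T_g' D_g^{-1} T_g,

with T_g unit lower-triangular (generalized autoregressive coefficients:
row k regresses condition k on the preceding conditions) and D_g a
positive diagonal of innovation variances. The decomposition reflects
the longitudinal reading of the design — mild stress sits between
optimal and severe, the two rewatering points follow severe stress — and
gives a numerically stable density: the quadratic form is
||D^{-1/2} T (x - mu)||^2 and log|Sigma| = sum(log D_kk) since |T| = 1.

Fitting is by EM with log-sum-exp responsibilities, multiple seeded
k-means-style restarts, and an Aitken-accelerated convergence check; the
number of components is chosen by BIC (convention 2*loglik - k*log n,
larger is better) over a small range, G = 1..8 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

log = logging.getLogger(__name__)

LOG_2PI = np.log(2.0 * np.pi)

#: Floor on innovation variances (log2-units squared).
D_FLOOR = 1e-6


def modified_cholesky(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Factor a covariance as Sigma^{-1} = T' D^{-1} T.

    Returns (T, d) with T unit lower-triangular and d the diagonal of D.
    Computed from the lower Cholesky factor L of Sigma: T = diag(L) L^{-1}
    and d = diag(L)^2.
    """
    sigma = np.asarray(sigma, dtype=float)
    L = np.linalg.cholesky(sigma)
    diag = np.diag(L)
    Linv = solve_triangular(L, np.eye(len(L)), lower=True)
    T = diag[:, None] * Linv
    d = diag**2
    return T, d


def reconstruct_sigma(T: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Invert the modified Cholesky factorization back to Sigma."""
    prec = T.T @ np.diag(1.0 / d) @ T
    return np.linalg.inv(prec)


def gaussian_logdensity_cholesky(
    X: np.ndarray, mu: np.ndarray, T: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Log N(x; mu, Sigma) with Sigma^{-1} = T' D^{-1} T, no inversion.

    ``X`` may be a single d-vector or an (n, d) array.
    """
    d = np.asarray(d, dtype=float)
    if (d <= 0).any():
        raise ValueError("innovation variances must be positive")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    z = (X2 - mu) @ T.T
    quad = (z**2 / d).sum(axis=1)
    k = X2.shape[1]
    out = -0.5 * (k * LOG_2PI + np.log(d).sum() + quad)
    return float(out[0]) if single else out


def gaussian_density_cholesky(x, mu, T, d) -> float | np.ndarray:
    """Density counterpart of :func:`gaussian_logdensity_cholesky`."""
    return np.exp(gaussian_logdensity_cholesky(x, mu, T, d))


def n_params(G: int, dim: int = 5, covariance: str = "full") -> int:
    """Free-parameter count of a G-component mixture in ``dim`` dimensions."""
    if covariance == "full":
        cov = G * (dim * (dim + 1) // 2)
    elif covariance == "tied":
        cov = dim * (dim + 1) // 2
    elif covariance == "diagonal":
        cov = G * dim
    else:
        raise ValueError(f"unknown covariance family {covariance!r}")
    return (G - 1) + G * dim + cov


@dataclass
class MixtureModel:
    """A fitted longitudinal Gaussian mixture."""

    G: int
    weights: np.ndarray
    means: np.ndarray  # G x d
    T: np.ndarray  # G x d x d unit lower-triangular
    D: np.ndarray  # G x d innovation variances
    loglik: float
    n_params: int
    bic: float
    n_obs: int
    converged: bool
    n_iter: int
    seed: int
    restart: int
    loglik_trace: np.ndarray = field(repr=False, default=None)
    covariance: str = "full"

    def covariances(self) -> np.ndarray:
        return np.stack([reconstruct_sigma(self.T[g], self.D[g]) for g in range(self.G)])

    def log_component_densities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.stack(
            [
                gaussian_logdensity_cholesky(X, self.means[g], self.T[g], self.D[g])
                for g in range(self.G)
            ],
            axis=1,
        )

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        logr = np.log(self.weights) + self.log_component_densities(X)
        logr -= logsumexp_rows(logr)[:, None]
        return np.exp(logr)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """MAP component labels, 1-based."""
        return self.responsibilities(X).argmax(axis=1) + 1


def logsumexp_rows(A: np.ndarray) -> np.ndarray:
    m = A.max(axis=1)
    return m + np.log(np.exp(A - m[:, None]).sum(axis=1))


def _kmeans_labels(X: np.ndarray, G: int, rng: np.random.Generator, n_iter: int = 10):
    """Small seeded Lloyd iteration used only for EM initialization."""
    n = len(X)
    centers = X[rng.choice(n, size=G, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = dist.argmin(axis=1)
        for g in range(G):
            mask = labels == g
            if mask.any():
                centers[g] = X[mask].mean(axis=0)
            else:
                centers[g] = X[rng.integers(n)]
    return labels


def _m_step(X, resp, covariance: str, ridge: float = 0.0):
    n, dim = X.shape
    Nk = resp.sum(axis=0)
    weights = Nk / n
    means = (resp.T @ X) / Nk[:, None]
    G = resp.shape[1]
    sigmas = np.empty((G, dim, dim))
    for g in range(G):
        diff = X - means[g]
        sigmas[g] = (resp[:, g][:, None] * diff).T @ diff / Nk[g]
    if covariance == "tied":
        pooled = np.einsum("g,gij->ij", Nk, sigmas) / n
        sigmas[:] = pooled
    if covariance == "diagonal":
        for g in range(G):
            sigmas[g] = np.diag(np.diag(sigmas[g]))
    Ts = np.empty_like(sigmas)
    Ds = np.empty((G, dim))
    for g in range(G):
        sg = sigmas[g] + ridge * np.eye(dim)
        for boost in (0.0, 1e-8, 1e-6, 1e-4):
            try:
                T, d = modified_cholesky(sg + boost * np.eye(dim))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise np.linalg.LinAlgError("component covariance not positive definite")
        Ts[g] = T
        Ds[g] = np.maximum(d, D_FLOOR)
    return weights, means, Ts, Ds


def _e_step(X, weights, means, Ts, Ds):
    G = len(weights)
    logd = np.stack(
        [gaussian_logdensity_cholesky(X, means[g], Ts[g], Ds[g]) for g in range(G)],
        axis=1,
    )
    logr = np.log(weights) + logd
    norm = logsumexp_rows(logr)
    resp = np.exp(logr - norm[:, None])
    return resp, norm.sum()


def _fit_once(X, G, rng, tol, max_iter, covariance):
    n = len(X)
    labels = _kmeans_labels(X, G, rng)
    resp = np.zeros((n, G))
    resp[np.arange(n), labels] = 1.0
    resp = 0.9 * resp + 0.1 / G  # soften hard init so no component starts empty
    params = _m_step(X, resp, covariance)
    trace = []
    loglik = -np.inf
    converged = False
    for it in range(max_iter):
        resp, loglik = _e_step(X, *params)
        trace.append(loglik)
        if params[0].min() < 1.0 / n:
            return None, np.array(trace)  # component collapse -> restart
        params = _m_step(X, resp, covariance)
        if len(trace) >= 3:
            # Aitken acceleration on the loglik sequence
            l0, l1, l2 = trace[-3], trace[-2], trace[-1]
            denom = l1 - l0
            a = (l2 - l1) / denom if denom != 0 else 0.0
            l_inf = l1 + (l2 - l1) / (1.0 - a) if a < 1.0 else l2
            if abs(l_inf - l2) < tol * (abs(l2) + 1.0):
                converged = True
                break
        elif len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * (
            abs(trace[-1]) + 1.0
        ):
            converged = True
            break
    resp, loglik = _e_step(X, *params)
    trace.append(loglik)
    return (params, resp, loglik, converged, len(trace)), np.array(trace)


def fit_em(
    profiles,
    G: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    covariance: str = "full",
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit a G-component Gaussian mixture by EM; return the best restart.

    ``profiles`` is an (n, d) array or a DataFrame (index = entity ids).
    Each restart initializes from a seeded k-means-style hard partition
    followed by one M-step. Restarts whose smallest component weight
    falls below 1/n are discarded as degenerate. The second return value
    holds per-entity responsibilities and 1-based MAP labels.
    """
    index = profiles.index if isinstance(profiles, pd.DataFrame) else None
    X = np.asarray(profiles, dtype=float)
    n = len(X)
    if G < 1:
        raise ValueError("G must be >= 1")
    if G > n:
        raise ValueError(f"G={G} exceeds the number of profiles ({n})")
    ss = np.random.SeedSequence([seed, G])
    best = None
    n_failed = 0
    for r, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        fit, trace = _fit_once(X, G, rng, tol, max_iter, covariance)
        if fit is None:
            n_failed += 1
            log.debug("restart %d collapsed (G=%d); discarded", r, G)
            continue
        params, resp, loglik, converged, n_iter = fit
        if best is None or loglik > best[2]:
            best = (params, resp, loglik, converged, n_iter, r, trace)
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} restarts degenerate for G={G} on n={n} profiles"
        )
    if n_failed:
        log.info("fit_em(G=%d): %d of %d restarts collapsed", G, n_failed, n_restarts)
    (weights, means, Ts, Ds), resp, loglik, converged, n_iter, r, trace = best
    k = n_params(G, X.shape[1], covariance)
    model = MixtureModel(
        G=G,
        weights=weights,
        means=means,
        T=Ts,
        D=Ds,
        loglik=float(loglik),
        n_params=k,
        bic=2.0 * float(loglik) - k * np.log(n),
        n_obs=n,
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        restart=r,
        loglik_trace=trace,
        covariance=covariance,
    )
    assign = pd.DataFrame(
        resp, columns=[f"z{g + 1}" for g in range(G)], index=index
    )
    assign["map_group"] = resp.argmax(axis=1) + 1
    return model, assign


def select_G(
    profiles,
    G_range=range(1, 9),
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    covariance: str = "full",
) -> tuple[MixtureModel, pd.DataFrame, pd.DataFrame]:
    """Fit every G in ``G_range`` and keep the model with maximal BIC.

    Returns (best model, its assignments, per-G BIC table). Gs that fail
    on every restart are recorded in the table with NaN scores.
    """
    rows = []
    best = None
    for G in G_range:
        try:
            model, assign = fit_em(
                profiles, G, n_restarts=n_restarts, seed=seed, tol=tol,
                max_iter=max_iter, covariance=covariance,
            )
        except (RuntimeError, ValueError) as exc:
            rows.append({"G": G, "loglik": np.nan, "bic": np.nan, "error": str(exc)})
            continue
        rows.append(
            {"G": G, "loglik": model.loglik, "bic": model.bic,
             "n_params": model.n_params, "converged": model.converged}
        )
        if best is None or model.bic > best[0].bic:
            best = (model, assign)
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(f"every fit failed; diagnostics:\n{table}")
    return best[0], best[1], table


def prescreen_profiles(profiles: pd.DataFrame, fc_threshold: float) -> list:
    """Entities whose mild- or severe-stress response clears the fold
    change threshold relative to optimal water (|W2-W1| or |W3-W1| on the
    log2 scale)."""
    P = profiles.to_numpy()
    keep = (np.abs(P[:, 1] - P[:, 0]) >= np.log2(fc_threshold)) | (
        np.abs(P[:, 2] - P[:, 0]) >= np.log2(fc_threshold)
    )
    return list(profiles.index[keep])


def split_up_down(
    assignment: pd.DataFrame, profiles: pd.DataFrame, split_pair: tuple[int, int] = (2, 1)
) -> pd.Series:
    """A-posteriori up/down subgrouping within each MAP group.

    The mixture is symmetric — mirrored trajectories land in the same
    component — so for display each group is split on whether the profile
    at condition ``split_pair[0]`` exceeds that at ``split_pair[1]``
    (1-based water-condition indices). Ties go down.
    """
    i, j = split_pair
    if not (1 <= i <= 5 and 1 <= j <= 5 and i != j):
        raise ValueError(f"invalid split pair {split_pair}")
    P = profiles.loc[assignment.index] if assignment.index is not None else profiles
    up = P.iloc[:, i - 1].to_numpy() > P.iloc[:, j - 1].to_numpy()
    n_tie = int((P.iloc[:, i - 1].to_numpy() == P.iloc[:, j - 1].to_numpy()).sum())
    if n_tie:
        log.info("split_up_down: %d tie(s) assigned to 'down'", n_tie)
    return pd.Series(np.where(up, "up", "down"), index=P.index, name="subgroup")
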