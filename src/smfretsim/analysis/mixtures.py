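"""Gaussian and skew-Gaussian mixture models fitted by EM.

The Gaussian mixture is the classic latent-class model for apparent-efficiency
histograms; the skew-Gaussian mixture replaces each component density with

    f(x) = (2/omega) phi((x - xi)/omega) Phi(alpha (x - xi)/omega),

where xi is a location, omega a scale and alpha a shape parameter (alpha = 0
recovers the Gaussian).  Skewed components matter for peaks pressed against
the edges of the unit interval, e.g. the donor-only peak near E = 0.

Both fitters are plain EM with a per-iteration log-likelihood trace (the
trace is monotone non-decreasing; the skew fit uses ECM updates, which share
that guarantee).  Initialisation: k-means for the Gaussian mixture,
quantile blocks with moment-matched skewness for the skew mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

__all__ = ["MixtureFit", "fit_gaussian_mixture", "fit_skew_mixture",
           "skew_normal_pdf", "DegenerateMixtureError"]

_VAR_FLOOR = 1e-12


class DegenerateMixtureError(RuntimeError):
    pass


@dataclass
class MixtureFit:
    """Fitted mixture parameters, components sorted by ascending location.

    For ``kind="gaussian"`` the locations are component means and the shapes
    are all zero; for ``kind="skew"`` they are the skew-normal (xi, omega,
    alpha) parameters.
    """

    kind: str
    weights: np.ndarray
    locations: np.ndarray
    scales: np.ndarray
    shapes: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def K(self) -> int:
        return self.weights.size

    @property
    def means(self) -> np.ndarray:
        """Component means (equal to locations for the Gaussian kind)."""
        if self.kind == "gaussian":
            return self.locations
        delta = self.shapes / np.sqrt(1.0 + self.shapes**2)
        return self.locations + self.scales * delta * math.sqrt(2.0 / math.pi)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, xi, om, al in zip(self.weights, self.locations, self.scales, self.shapes):
            out += w * skew_normal_pdf(x, xi, om, al)
        return out


def skew_normal_pdf(x, xi: float, omega: float, alpha: float):
    """Density (2/omega) phi(z) Phi(alpha z), z = (x - xi)/omega.

    alpha = 0 reduces exactly to the N(xi, omega^2) density.
    """
    z = (np.asarray(x, dtype=float) - xi) / omega
    return 2.0 / omega * norm.pdf(z) * ndtr(alpha * z)


def _logsumexp_rows(logp: np.ndarray) -> np.ndarray:
    m = logp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(logp - m).sum(axis=1, keepdims=True))).ravel()


def _responsibilities(log_comp: np.ndarray):
    tot = _logsumexp_rows(log_comp)
    resp = np.exp(log_comp - tot[:, None])
    return resp, float(tot.sum())


def _check_values(values, K) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if np.unique(x).size < K:
        raise ValueError(f"need at least {K} distinct values to fit {K} components")
    return x


def fit_gaussian_mixture(values, K: int, seed: int | None = 0, tol: float = 1e-6,
                         max_iter: int = 1000, n_restarts: int = 5) -> MixtureFit:
    """Maximum-likelihood K-component Gaussian mixture via EM.

    k-means initialisation with ``n_restarts`` seeds; the best (highest
    log-likelihood) converged solution is returned, components sorted by mean.
    Convergence: log-likelihood change below ``tol``.
    """
    x = _check_values(values, K)
    n = x.size
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    failures: list[str] = []
    for restart in range(n_restarts):
        try:
            mu, sd, w = _kmeans_init(x, K, rng)
            fit = _em_gaussian(x, K, mu, sd, w, tol, max_iter)
        except DegenerateMixtureError as exc:
            failures.append(str(exc))
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise DegenerateMixtureError(
            f"all {n_restarts} EM restarts degenerated: {failures[-1]}")
    return best


def _kmeans_init(x, K, rng):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=3,
                random_state=int(rng.integers(0, 2**31 - 1))).fit(x[:, None])
    labels = km.labels_
    mu = km.cluster_centers_.ravel().astype(float)
    sd = np.empty(K)
    w = np.empty(K)
    overall_sd = max(x.std(), 1e-3)
    for k in range(K):
        sel = labels == k
        w[k] = max(sel.mean(), 1.0 / x.size)
        sd[k] = x[sel].std() if sel.sum() > 1 else overall_sd
        if sd[k] <= 0:
            sd[k] = overall_sd / K
    w /= w.sum()
    return mu, sd, w


def _em_gaussian(x, K, mu, sd, w, tol, max_iter) -> MixtureFit:
    n = x.size
    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        log_comp = (np.log(w)[None, :]
                    - np.log(sd)[None, :] - 0.5 * math.log(2 * math.pi)
                    - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2)
        resp, ll = _responsibilities(log_comp)
        trace.append(ll)
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise DegenerateMixtureError("component weight collapsed to 0")
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < _VAR_FLOOR):
            raise DegenerateMixtureError("component variance collapsed to 0")
        sd = np.sqrt(var)
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll
    order = np.argsort(mu)
    return MixtureFit(kind="gaussian", weights=w[order], locations=mu[order],
                      scales=sd[order], shapes=np.zeros(K),
                      loglik=trace[-1], loglik_trace=np.asarray(trace),
                      n_iter=len(trace), converged=converged)


# ---------------------------------------------------------------------------
# skew-normal mixture
# ---------------------------------------------------------------------------

def _skew_moment_init(x, K, rng):
    """Quantile-block initialisation with moment-matched skewness per block."""
    xs = np.sort(x)
    blocks = np.array_split(xs, K)
    xi = np.empty(K)
    omega = np.empty(K)
    alpha = np.empty(K)
    w = np.array([len(b) for b in blocks], dtype=float)
    w /= w.sum()
    b_max = 0.995  # |delta| cap
    for k, b in enumerate(blocks):
        m, s = b.mean(), max(b.std(), 1e-4)
        g1 = 0.0
        if b.size > 8 and s > 0:
            g1 = float(np.mean(((b - m) / s) ** 3))
        g1 = float(np.clip(g1, -0.99, 0.99))
        a23 = abs(g1) ** (2.0 / 3.0)
        denom = a23 + ((4.0 - math.pi) / 2.0) ** (2.0 / 3.0)
        delta = math.copysign(math.sqrt(math.pi / 2.0 * a23 / denom), g1) if denom > 0 else 0.0
        delta = max(min(delta, b_max), -b_max)
        omega[k] = s / math.sqrt(max(1.0 - 2.0 * delta**2 / math.pi, 1e-3))
        xi[k] = m - omega[k] * delta * math.sqrt(2.0 / math.pi)
        alpha[k] = delta / math.sqrt(max(1.0 - delta**2, 1e-6))
        # nudge symmetric blocks off the alpha = 0 stationary point
        if abs(alpha[k]) < 0.2:
            alpha[k] = 0.5 if rng.random() < 0.5 else -0.5
    return xi, omega, alpha, w


def _skew_log_pdf(x, xi, omega, alpha):
    z = (x[:, None] - xi[None, :]) / omega[None, :]
    return (math.log(2.0) - np.log(omega)[None, :]
            - 0.5 * math.log(2 * math.pi) - 0.5 * z * z
            + log_ndtr(alpha[None, :] * z))


def fit_skew_mixture(values, K: int, seed: int | None = 0, tol: float = 1e-6,
                     max_iter: int = 1000, n_restarts: int = 5) -> MixtureFit:
    """Maximum-likelihood K-component skew-normal mixture via ECM.

    Uses the stochastic representation X = xi + Delta t + e with t a standard
    half-normal and e ~ N(0, Gamma): the E-step needs only the truncated-normal
    moments of t given x, the CM-steps update (xi, Delta, Gamma) in closed
    form.  omega^2 = Gamma + Delta^2 and alpha = Delta / sqrt(Gamma).
    """
    x = _check_values(values, K)
    n = x.size
    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for restart in range(n_restarts):
        try:
            xi, omega, alpha, w = _skew_moment_init(x, K, rng)
            fit = _em_skew(x, K, xi, omega, alpha, w, tol, max_iter)
        except DegenerateMixtureError as exc:
            failures.append(str(exc))
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise DegenerateMixtureError(
            f"all {n_restarts} ECM restarts degenerated: {failures[-1]}")
    return best


def _em_skew(x, K, xi, omega, alpha, w, tol, max_iter) -> MixtureFit:
    n = x.size
    delta = alpha / np.sqrt(1.0 + alpha**2)
    Delta = omega * delta
    Gamma = omega**2 * (1.0 - delta**2)
    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        omega = np.sqrt(Gamma + Delta**2)
        alpha = Delta / np.sqrt(Gamma)
        log_comp = np.log(w)[None, :] + _skew_log_pdf(x, xi, omega, alpha)
        resp, ll = _responsibilities(log_comp)
        trace.append(ll)

        # E-step: truncated-normal moments of the latent half-normal factor
        denom = Gamma + Delta**2
        mu_t = Delta[None, :] * (x[:, None] - xi[None, :]) / denom[None, :]
        s_t = np.sqrt(Gamma / denom)[None, :]
        h = mu_t / s_t
        # phi(h)/Phi(h), computed stably in log space
        ratio = np.exp(norm.logpdf(h) - log_ndtr(h))
        e_t = mu_t + s_t * ratio
        e_t2 = mu_t**2 + s_t**2 + mu_t * s_t * ratio

        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise DegenerateMixtureError("component weight collapsed to 0")
        w = nk / n
        # CM-steps
        xi = (resp * (x[:, None] - Delta[None, :] * e_t)).sum(axis=0) / nk
        dx = x[:, None] - xi[None, :]
        Delta = (resp * e_t * dx).sum(axis=0) / np.maximum((resp * e_t2).sum(axis=0), 1e-300)
        Gamma = (resp * (dx**2 - 2.0 * Delta[None, :] * e_t * dx
                         + Delta[None, :] ** 2 * e_t2)).sum(axis=0) / nk
        if np.any(Gamma < _VAR_FLOOR):
            raise DegenerateMixtureError("component scale collapsed to 0")
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll
    omega = np.sqrt(Gamma + Delta**2)
    alpha = Delta / np.sqrt(Gamma)
    order = np.argsort(xi)
    return MixtureFit(kind="skew", weights=w[order], locations=xi[order],
                      scales=omega[order], shapes=alpha[order],
                      loglik=trace[-1], loglik_trace=np.asarray(trace),
                      n_iter=len(trace), converged=converged)
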