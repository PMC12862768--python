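"""Multi-sequence Gaussian hidden Markov model over burst regions.

Each burst region contributes one short apparent-efficiency sequence; the
sequences are treated as independent realisations of a single K-state HMM
with Gaussian emissions and shared parameters, fitted by Baum–Welch
(hmmlearn's GaussianHMM).  States are reported sorted by ascending mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMMFit", "fit_hmm", "compare_transition_matrices"]


@dataclass
class HMMFit:
    transmat: np.ndarray        # K x K, rows sum to 1, states sorted by mean
    means: np.ndarray           # state emission means
    variances: np.ndarray       # state emission variances
    startprob: np.ndarray
    n_sequences: int
    mean_sequence_length: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        T = np.asarray(self.transmat, dtype=float)
        if np.abs(T.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("rows of the transition matrix must sum to 1")
        if np.any(np.asarray(self.variances) <= 0):
            raise ValueError("state variances must be > 0")


def fit_hmm(sequences, K: int = 2, seed: int | None = 0, tol: float = 1e-4,
            max_iter: int = 200, min_covar: float = 1e-4) -> HMMFit:
    """Fit a K-state Gaussian HMM jointly across independent sequences.

    ``sequences`` is an iterable of 1D apparent-efficiency arrays (one per
    burst region); empty or NaN-containing sequences are dropped.  State means
    are initialised at the interior quantiles of the pooled values, the
    transition matrix sticky-uniform.  A fit that stops at ``max_iter``
    without meeting ``tol`` is returned with ``converged=False``.
    """
    seqs = [np.asarray(s, dtype=float).ravel() for s in sequences]
    seqs = [s[np.isfinite(s)] for s in seqs]
    seqs = [s for s in seqs if s.size > 0]
    if len(seqs) < 2:
        raise ValueError("need at least 2 non-empty sequences")
    lengths = np.array([s.size for s in seqs])
    x = np.concatenate(seqs)
    if x.size <= K:
        raise ValueError("total sequence length must exceed the state count")

    if np.ptp(x) < 1e-12:
        # degenerate: a single occupied state is the only identifiable model
        transmat = np.eye(K)
        means = np.full(K, x[0])
        variances = np.full(K, min_covar)
        start = np.zeros(K)
        start[0] = 1.0
        return HMMFit(transmat=transmat, means=means, variances=variances,
                      startprob=start, n_sequences=len(seqs),
                      mean_sequence_length=float(lengths.mean()),
                      loglik=float("nan"), converged=True)

    from hmmlearn.hmm import GaussianHMM

    model = GaussianHMM(n_components=K, covariance_type="diag", n_iter=max_iter,
                        tol=tol, min_covar=min_covar, init_params="",
                        params="stmc",
                        random_state=None if seed is None else int(seed))
    q = np.quantile(x, (np.arange(K) + 0.5) / K)
    model.startprob_ = np.full(K, 1.0 / K)
    model.transmat_ = np.full((K, K), 0.1 / max(K - 1, 1)) + np.eye(K) * (0.9 - 0.1 / max(K - 1, 1))
    model.transmat_ /= model.transmat_.sum(axis=1, keepdims=True)
    model.means_ = q[:, None]
    model.covars_ = np.full((K, 1), max(x.var() / (K * K), 4 * min_covar))
    model.fit(x[:, None], lengths=lengths)

    means = model.means_.ravel()
    variances = model.covars_.reshape(K, -1)[:, 0]
    order = np.argsort(means)
    transmat = model.transmat_[np.ix_(order, order)]
    transmat = transmat / transmat.sum(axis=1, keepdims=True)
    return HMMFit(transmat=transmat, means=means[order],
                  variances=variances[order],
                  startprob=model.startprob_[order],
                  n_sequences=len(seqs),
                  mean_sequence_length=float(lengths.mean()),
                  loglik=float(model.monitor_.history[-1]),
                  converged=bool(model.monitor_.converged))


def compare_transition_matrices(T_est, T_ref) -> dict:
    """Elementwise deviation summary between two stochastic matrices."""
    A = np.asarray(T_est, dtype=float)
    B = np.asarray(T_ref, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("transition matrices must have equal 2D shapes")
    for M, name in ((A, "T_est"), (B, "T_ref")):
        if np.abs(M.sum(axis=1) - 1.0).max() > 1e-6 or M.min() < -1e-12 or M.max() > 1 + 1e-12:
            raise ValueError(f"{name} is not a stochastic matrix")
    dev = np.abs(A - B)
    return {"max_abs_deviation": float(dev.max()),
            "mean_abs_deviation": float(dev.mean())}
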