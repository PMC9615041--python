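"""Mixture-of-Gaussian-processes clustering of dynamic time courses.

Loose-dynamic peaks are grouped into temporal-behavior categories with a
truncated mixture of hierarchical GPs: each component k has a latent mean
curve m_k ~ GP(0, K_f) (RBF kernel over days), and a member profile
deviates from its component mean with within-cluster covariance
Sigma = sigma_y^2 * RBF + sigma_n^2 * I.

Fitting is MAP-EM on (weights, component mean curves) at fixed
hyperparameters: the E-step computes responsibilities against
N(y; m_k, Sigma), the M-step updates weights and the GP-regression MAP of
each m_k, and this monotonically increases the penalized log-likelihood

    J = sum_i log sum_k pi_k N(y_i; m_k, Sigma) + sum_k log N(m_k; 0, K_f).

Hyperparameters are re-optimized by bounded L-BFGS-B every few iterations
(the objective is re-based there). Because plug-in means can split one
population across two components, a merge phase follows: pairs of
components are merged greedily whenever the exact integrated marginal
likelihood of the hard partition (component means integrated out) plus the
assignment term improves, which removes duplicated components but never
merges genuinely separated ones. Components with total responsibility
below ``min_occupancy`` are pruned. Cluster labels are arbitrary;
comparisons across runs should use a permutation-invariant index.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_JITTER = 1e-6


def _rbf(t1: np.ndarray, t2: np.ndarray, variance: float, lengthscale: float) -> np.ndarray:
    d2 = (t1[:, None] - t2[None, :]) ** 2
    return variance * np.exp(-0.5 * d2 / lengthscale**2)


class GPMixtureClusterer(BaseEstimator, ClusterMixin):
    """Truncated mixture of hierarchical GPs for shared-grid time courses.

    Parameters
    ----------
    times : array-like
        Observation days, one per column of X (replicates repeat a day).
    K_max : int
        Truncation level; surplus components are merged/pruned.
    min_occupancy : float
        Total responsibility below which a component counts as empty.
    signal_variance, lengthscale : float
        Cluster-mean GP kernel K_f (standardized scale; days).
    within_variance, noise_variance : float
        Within-cluster RBF variance and white-noise variance of Sigma.
    optimize_hypers : bool
        Re-optimize hyperparameters every ``hyper_every`` EM iterations.
    n_restarts : int
        Independent seeded restarts; the best penalized likelihood wins.

    Attributes (after fit)
    ----------------------
    labels_ : argmax-responsibility component per profile
    responsibilities_ : (n, K) matrix, rows sum to 1
    weights_ : mixing weights
    means_ : (K, T) component MAP mean curves at the observation times
    n_clusters_ : number of non-empty components
    lower_bound_segments_ : list of per-segment objective trajectories
        (each non-decreasing; a new segment starts at each hyper update)
    """

    def __init__(
        self,
        times=None,
        K_max: int = 12,
        min_occupancy: float = 1.0,
        signal_variance: float = 1.0,
        lengthscale: float = 8.0,
        within_variance: float = 0.1,
        noise_variance: float = 0.2,
        optimize_hypers: bool = True,
        hyper_every: int = 5,
        merge: bool = True,
        n_restarts: int = 5,
        max_iter: int = 200,
        tol: float = 1e-4,
        random_state: int = 0,
    ):
        self.times = times
        self.K_max = K_max
        self.min_occupancy = min_occupancy
        self.signal_variance = signal_variance
        self.lengthscale = lengthscale
        self.within_variance = within_variance
        self.noise_variance = noise_variance
        self.optimize_hypers = optimize_hypers
        self.hyper_every = hyper_every
        self.merge = merge
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ---- kernel/likelihood helpers -------------------------------------

    def _kernels(self, theta):
        sf2, ell, sy2, sn2 = theta
        t = self._t
        Kf = _rbf(t, t, sf2, ell) + _JITTER * np.eye(len(t))
        Sigma = _rbf(t, t, sy2, ell) + (sn2 + _JITTER) * np.eye(len(t))
        return Kf, Sigma

    @staticmethod
    def _log_gauss(Y: np.ndarray, mean: np.ndarray, L: np.ndarray) -> np.ndarray:
        diff = (Y - mean[None, :]).T
        sol = np.linalg.solve(L, diff)
        quad = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return -0.5 * (quad + logdet + Y.shape[1] * _LOG2PI)

    def _m_step_means(self, Y, R, Rk, Kf, Sigma):
        K = R.shape[1]
        T = Y.shape[1]
        means = np.zeros((K, T))
        for k in range(K):
            if Rk[k] < 1e-8:
                continue
            ybar = (R[:, k] @ Y) / Rk[k]
            x = np.linalg.solve(Kf + Sigma / Rk[k], ybar)
            means[k] = Kf @ x
        return means

    def _objective(self, Y, R, pi, means, Kf, Sigma):
        L = np.linalg.cholesky(Sigma)
        logp = np.stack([self._log_gauss(Y, means[k], L) for k in range(len(pi))], axis=1)
        with np.errstate(divide="ignore"):
            mix = logsumexp(logp + np.log(np.maximum(pi, 1e-300))[None, :], axis=1)
        Lf = np.linalg.cholesky(Kf)
        prior = 0.0
        for k in range(len(pi)):
            sol = np.linalg.solve(Lf, means[k])
            prior += -0.5 * (sol @ sol) - np.log(np.diag(Lf)).sum() - 0.5 * len(means[k]) * _LOG2PI
        return float(mix.sum() + prior), logp

    # ---- EM ------------------------------------------------------------

    def _em(self, Y, R, theta, max_iter, record):
        n, K = R.shape
        Kf, Sigma = self._kernels(theta)
        pi = R.sum(axis=0) / n
        means = self._m_step_means(Y, R, R.sum(axis=0), Kf, Sigma)
        segment: list[float] = []
        prev = -np.inf
        for it in range(max_iter):
            if self.optimize_hypers and it > 0 and it % self.hyper_every == 0:
                theta = self._update_hypers(Y, R, theta)
                Kf, Sigma = self._kernels(theta)
                means = self._m_step_means(Y, R, R.sum(axis=0), Kf, Sigma)
                if segment:
                    record.append(segment)
                segment = []
                prev = -np.inf
            # E-step
            obj, logp = self._objective(Y, R, pi, means, Kf, Sigma)
            with np.errstate(divide="ignore"):
                logr = logp + np.log(np.maximum(pi, 1e-300))[None, :]
            logr -= logsumexp(logr, axis=1, keepdims=True)
            R = np.exp(logr)
            # M-step
            Rk = R.sum(axis=0)
            pi = Rk / n
            means = self._m_step_means(Y, R, Rk, Kf, Sigma)
            segment.append(obj)
            if np.isfinite(prev) and obj - prev < self.tol:
                prev = obj
                break
            prev = obj
        if segment:
            record.append(segment)
        return R, pi, means, theta, prev

    def _update_hypers(self, Y, R, theta):
        Rk = R.sum(axis=0)
        pi = Rk / len(Y)

        def neg(log_theta):
            th = np.exp(log_theta)
            try:
                Kf, Sigma = self._kernels(th)
                means = self._m_step_means(Y, R, Rk, Kf, Sigma)
                obj, _ = self._objective(Y, R, pi, means, Kf, Sigma)
            except np.linalg.LinAlgError:
                return 1e12
            return -obj

        bounds = [
            (np.log(1e-3), np.log(10.0)),
            (np.log(1.0), np.log(56.0)),
            (np.log(1e-4), np.log(5.0)),
            (np.log(1e-4), np.log(5.0)),
        ]
        res = optimize.minimize(
            neg, np.log(theta), method="L-BFGS-B", bounds=bounds, options={"maxiter": 15}
        )
        return np.exp(res.x) if np.isfinite(res.fun) else theta

    # ---- integrated marginal + merging ---------------------------------

    def _integrated_marginal(self, Ysub, Kf, Sigma):
        nC = len(Ysub)
        L = np.linalg.cholesky(Sigma)
        base = self._log_gauss(Ysub, np.zeros(Ysub.shape[1]), L).sum()
        Sinv = np.linalg.inv(Sigma)
        b = Sinv @ Ysub.sum(axis=0)
        P = np.linalg.inv(Kf) + nC * Sinv
        mu = np.linalg.solve(P, b)
        sign, logdet = np.linalg.slogdet(np.eye(len(Kf)) + nC * Kf @ Sinv)
        return float(base + 0.5 * b @ mu - 0.5 * logdet)

    def _merge_pass(self, Y, labels, pi, Kf, Sigma):
        labels = labels.copy()
        active = sorted(set(labels))
        marg = {
            k: self._integrated_marginal(Y[labels == k], Kf, Sigma) for k in active
        }
        nk = {k: int((labels == k).sum()) for k in active}
        wk = {k: max(pi[k], 1e-300) for k in active}
        improved = True
        while improved and len(active) > 1:
            improved = False
            best = (0.0, None)
            for a_i, ka in enumerate(active):
                for kb in active[a_i + 1 :]:
                    merged = self._integrated_marginal(
                        Y[(labels == ka) | (labels == kb)], Kf, Sigma
                    )
                    assign = (
                        (nk[ka] + nk[kb]) * np.log(wk[ka] + wk[kb])
                        - nk[ka] * np.log(wk[ka])
                        - nk[kb] * np.log(wk[kb])
                    )
                    delta = merged - marg[ka] - marg[kb] + assign
                    if delta > best[0]:
                        best = (delta, (ka, kb, merged))
            if best[1] is not None:
                ka, kb, merged = best[1]
                labels[labels == kb] = ka
                marg[ka] = merged
                nk[ka] += nk[kb]
                wk[ka] += wk[kb]
                active.remove(kb)
                del marg[kb], nk[kb], wk[kb]
                improved = True
        return labels

    # ---- public API ----------------------------------------------------

    def fit(self, X, y=None):
        Y = np.asarray(X, dtype=float)
        if Y.ndim != 2:
            raise ValueError("X must be 2-D (profiles x observations)")
        if self.times is None:
            raise ValueError("observation times must be provided")
        self._t = np.asarray(self.times, dtype=float)
        if len(self._t) != Y.shape[1]:
            raise ValueError("times length must match the number of columns")
        n = len(Y)
        K = self.K_max
        if n < K:
            logger.warning("fewer profiles (%d) than K_max (%d); reducing", n, K)
            K = max(n, 1)

        theta0 = np.array(
            [self.signal_variance, self.lengthscale, self.within_variance, self.noise_variance]
        )
        best = None
        for restart in range(self.n_restarts):
            seed = self.random_state + 1000 * restart
            km = KMeans(n_clusters=K, n_init=4, random_state=seed).fit(Y)
            R = np.zeros((n, K))
            R[np.arange(n), km.labels_] = 1.0
            record: list[list[float]] = []
            R, pi, means, theta, obj = self._em(Y, R, theta0.copy(), self.max_iter, record)

            if self.merge:
                Kf, Sigma = self._kernels(theta)
                labels = R.argmax(axis=1)
                labels = self._merge_pass(Y, labels, pi, Kf, Sigma)
                keep = sorted(set(labels))
                if len(keep) < R.shape[1]:
                    R2 = np.zeros((n, len(keep)))
                    for j, k in enumerate(keep):
                        R2[labels == k, j] = 1.0
                    R, pi, means, theta, obj = self._em(Y, R2, theta, 25, record)

            if best is None or obj > best["obj"]:
                best = {
                    "obj": obj, "R": R, "pi": pi, "means": means,
                    "theta": theta, "record": record,
                }

        R, pi, means, theta = best["R"], best["pi"], best["means"], best["theta"]
        occupancy = R.sum(axis=0)
        keep = occupancy >= min(self.min_occupancy, occupancy.max())
        R = R[:, keep]
        R = R / R.sum(axis=1, keepdims=True)
        self.weights_ = R.sum(axis=0) / n
        self.means_ = means[keep]
        self.theta_ = theta
        self.responsibilities_ = R
        self.labels_ = R.argmax(axis=1)
        self.occupancy_ = R.sum(axis=0)
        self.n_clusters_ = int((self.occupancy_ >= self.min_occupancy).sum())
        self.lower_bound_segments_ = best["record"]
        self.lower_bound_ = best["obj"]
        self.times_ = self._t
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        Y = np.asarray(X, dtype=float)
        Kf, Sigma = self._kernels(self.theta_)
        L = np.linalg.cholesky(Sigma)
        logp = np.stack(
            [self._log_gauss(Y, m, L) for m in self.means_], axis=1
        ) + np.log(np.maximum(self.weights_, 1e-300))[None, :]
        return logp.argmax(axis=1)

    def posterior_curves(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Posterior mean and pointwise SD of each cluster curve on a grid.

        The SD combines the posterior uncertainty of the cluster mean with
        the within-cluster GP variance (the band that covers member
        curves, noise excluded).
        """
        if grid is None:
            grid = np.linspace(self.times_.min(), self.times_.max(), 101)
        grid = np.asarray(grid, dtype=float)
        sf2, ell, sy2, sn2 = self.theta_
        t = self.times_
        Kf, Sigma = self._kernels(self.theta_)
        Ks = _rbf(grid, t, sf2, ell)
        Kss = _rbf(grid, grid, sf2, ell)
        rows = []
        for k in range(len(self.means_)):
            Rk = max(self.occupancy_[k], 1e-8)
            A = Kf + Sigma / Rk
            # means_ stores Kf @ solve(A, ybar); recover the dual weights
            x0 = np.linalg.solve(Kf, self.means_[k])
            mean = Ks @ x0
            cov = Kss - Ks @ np.linalg.solve(A, Ks.T)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None) + sy2)
            for g, mval, sval in zip(grid, mean, sd):
                rows.append({"cluster": k, "t": g, "mean": mval, "sd": sval})
        return pd.DataFrame(rows)


def fit_gp_mixture(
    profiles: np.ndarray,
    times: np.ndarray,
    K_max: int = 12,
    min_occupancy: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> GPMixtureClusterer:
    """Functional wrapper: fit the mixture and return the fitted clusterer."""
    model = GPMixtureClusterer(
        times=times, K_max=K_max, min_occupancy=min_occupancy, random_state=seed, **kwargs
    )
    return model.fit(profiles)


def cluster_summary(model: GPMixtureClusterer) -> pd.DataFrame:
    """Per-cluster size and mean-curve values at the observation days."""
    days = np.unique(model.times_)
    curves = model.posterior_curves(days)
    rows = []
    for k in range(len(model.means_)):
        sub = curves[curves["cluster"] == k]
        row = {"cluster": k, "size": int((model.labels_ == k).sum())}
        for _, r in sub.iterrows():
            row[f"mean_d{r['t']:g}"] = r["mean"]
        rows.append(row)
    return pd.DataFrame(rows)
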