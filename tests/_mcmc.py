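"""Independent MCMC reference for the decontamination model.

A Metropolis-within-Gibbs sampler written directly against the model's
joint density (Poisson likelihood, truncated-normal contamination
priors via scipy.stats.truncnorm, flat Dirichlet on the native
profiles) — sharing no code with the package's variational engine. Used
as a long-run oracle for posterior summaries on small instances.

Blocks per sweep: per-entry random-walk updates of theta and beta
(vectorized accept/reject; entries are conditionally independent),
per-droplet delta and per-ADT mu random walks, a joint (delta_i,
theta_i.) shift move and a joint (mu_j, beta_.j) shift move (which keep
mixing healthy when the prior scales are small), and per-cluster
random-walk updates of phi in additive-log-ratio coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm


def _tn_logpdf(val, mean, sd, lo, hi):
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.logpdf(val, a, b, loc=mean, scale=sd)


def _softmax0(y):
    full = np.concatenate([np.zeros((y.shape[0], 1)), y], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


class ModelSampler:
    def __init__(self, x, labels, eta, tau1, tau2, beta_upper=0.5, seed=None):
        self.x = np.asarray(x, dtype=float)
        self.I, self.J = self.x.shape
        self.labels = np.asarray(labels, dtype=int)
        self.K = int(self.labels.max()) + 1
        self.eta = np.asarray(eta, dtype=float)
        self.tau1, self.tau2, self.B = tau1, tau2, beta_upper
        self.L = self.x.sum(axis=1)
        self.rng = np.random.default_rng(seed)

        self.theta = np.full((self.I, self.J), 0.05)
        self.beta = np.full((self.I, self.J), 0.02)
        self.delta = np.full(self.I, 0.05)
        self.mu = np.full(self.J, 0.02)
        phi0 = np.vstack(
            [
                (self.x[self.labels == k].sum(axis=0) + 1.0)
                / (self.x[self.labels == k].sum() + self.J)
                for k in range(self.K)
            ]
        )
        self.phi_alr = np.log(phi0[:, 1:]) - np.log(phi0[:, :1])
        # proposal scales, adapted during burn-in
        self.s = {"theta": 0.02, "beta": 0.02, "delta": 0.05, "mu": 0.02,
                  "shift_d": 0.02, "shift_m": 0.01, "phi": 0.05}

    # ---- densities -------------------------------------------------
    def _lam(self, theta=None, beta=None, phi=None):
        theta = self.theta if theta is None else theta
        beta = self.beta if beta is None else beta
        phi = _softmax0(self.phi_alr) if phi is None else phi
        pc = phi[self.labels]
        return (1 - beta) * (theta * self.eta[None, :] + (1 - theta) * pc) + beta

    def _loglik_entries(self, lam):
        return self.x * np.log(lam) - lam * self.L[:, None]

    # ---- moves -----------------------------------------------------
    def _entrywise(self, name, cur, lo, hi, prior_mean, tau, other_args):
        prop = cur + self.rng.normal(0, self.s[name], cur.shape)
        ok = (prop > lo) & (prop < hi)
        prop = np.where(ok, prop, cur)
        if name == "theta":
            lam_new = self._lam(theta=prop)
            lam_old = self._lam()
        else:
            lam_new = self._lam(beta=prop)
            lam_old = self._lam()
        dlp = (
            self._loglik_entries(lam_new)
            - self._loglik_entries(lam_old)
            + _tn_logpdf(prop, prior_mean, tau, lo, hi)
            - _tn_logpdf(cur, prior_mean, tau, lo, hi)
        )
        acc = ok & (np.log(self.rng.uniform(size=cur.shape)) < dlp)
        return np.where(acc, prop, cur), acc.mean()

    def _hyper(self, name, cur, lo, hi, vals, tau, axis):
        prop = cur + self.rng.normal(0, self.s[name], cur.shape)
        ok = (prop > lo) & (prop < hi)
        prop = np.where(ok, prop, cur)
        if axis == 1:  # delta: mean over ADTs of each droplet's thetas
            dlp = (
                _tn_logpdf(vals, prop[:, None], tau, lo, hi)
                - _tn_logpdf(vals, cur[:, None], tau, lo, hi)
            ).sum(axis=1)
        else:  # mu
            dlp = (
                _tn_logpdf(vals, prop[None, :], tau, lo, hi)
                - _tn_logpdf(vals, cur[None, :], tau, lo, hi)
            ).sum(axis=0)
        acc = ok & (np.log(self.rng.uniform(size=cur.shape)) < dlp)
        return np.where(acc, prop, cur), acc.mean()

    def _shift_delta(self):
        """Joint shift of (delta_i, theta_i.) — the slow direction when
        tau1 is small."""
        sh = self.rng.normal(0, self.s["shift_d"], self.I)
        prop_d = self.delta + sh
        prop_t = self.theta + sh[:, None]
        ok = (
            (prop_d > 0) & (prop_d < 1)
            & (prop_t > 0).all(axis=1) & (prop_t < 1).all(axis=1)
        )
        sh = np.where(ok, sh, 0.0)
        prop_d = self.delta + sh
        prop_t = self.theta + sh[:, None]
        lam_new = self._lam(theta=prop_t)
        lam_old = self._lam()
        dlp = (self._loglik_entries(lam_new) - self._loglik_entries(lam_old)).sum(
            axis=1
        ) + (
            _tn_logpdf(prop_t, prop_d[:, None], self.tau1, 0.0, 1.0)
            - _tn_logpdf(self.theta, self.delta[:, None], self.tau1, 0.0, 1.0)
        ).sum(axis=1)
        acc = ok & (np.log(self.rng.uniform(size=self.I)) < dlp)
        self.delta = np.where(acc, prop_d, self.delta)
        self.theta = np.where(acc[:, None], prop_t, self.theta)
        return acc.mean()

    def _shift_mu(self):
        sh = self.rng.normal(0, self.s["shift_m"], self.J)
        prop_m = self.mu + sh
        prop_b = self.beta + sh[None, :]
        ok = (
            (prop_m > 0) & (prop_m < self.B)
            & (prop_b > 0).all(axis=0) & (prop_b < self.B).all(axis=0)
        )
        sh = np.where(ok, sh, 0.0)
        prop_m = self.mu + sh
        prop_b = self.beta + sh[None, :]
        lam_new = self._lam(beta=prop_b)
        lam_old = self._lam()
        dlp = (self._loglik_entries(lam_new) - self._loglik_entries(lam_old)).sum(
            axis=0
        ) + (
            _tn_logpdf(prop_b, prop_m[None, :], self.tau2, 0.0, self.B)
            - _tn_logpdf(self.beta, self.mu[None, :], self.tau2, 0.0, self.B)
        ).sum(axis=0)
        acc = ok & (np.log(self.rng.uniform(size=self.J)) < dlp)
        self.mu = np.where(acc, prop_m, self.mu)
        self.beta = np.where(acc[None, :], prop_b, self.beta)
        return acc.mean()

    def _update_phi(self):
        accs = []
        for k in range(self.K):
            prop_alr = self.phi_alr.copy()
            prop_alr[k] += self.rng.normal(0, self.s["phi"], self.J - 1)
            phi_old = _softmax0(self.phi_alr)
            phi_new = _softmax0(prop_alr)
            rows = self.labels == k
            lam_old = self._lam(phi=phi_old)[rows]
            lam_new = self._lam(phi=phi_new)[rows]
            dlp = (
                self.x[rows] * (np.log(lam_new) - np.log(lam_old))
                - (lam_new - lam_old) * self.L[rows, None]
            ).sum()
            # flat Dirichlet prior; ALR jacobian = sum log phi
            dlp += np.log(phi_new[k]).sum() - np.log(phi_old[k]).sum()
            if np.log(self.rng.uniform()) < dlp:
                self.phi_alr = prop_alr
                accs.append(1.0)
            else:
                accs.append(0.0)
        return float(np.mean(accs))

    def _adapt(self, rates):
        for name, rate in rates.items():
            self.s[name] *= float(np.exp(0.5 * (rate - 0.3)))

    # ---- driver ----------------------------------------------------
    def sweep(self):
        rates = {}
        self.theta, rates["theta"] = self._entrywise(
            "theta", self.theta, 0.0, 1.0, self.delta[:, None], self.tau1, None
        )
        self.beta, rates["beta"] = self._entrywise(
            "beta", self.beta, 0.0, self.B, self.mu[None, :], self.tau2, None
        )
        self.delta, rates["delta"] = self._hyper(
            "delta", self.delta, 0.0, 1.0, self.theta, self.tau1, axis=1
        )
        self.mu, rates["mu"] = self._hyper(
            "mu", self.mu, 0.0, self.B, self.beta, self.tau2, axis=0
        )
        rates["shift_d"] = self._shift_delta()
        rates["shift_m"] = self._shift_mu()
        rates["phi"] = self._update_phi()
        return rates

    def native_fraction(self):
        phi = _softmax0(self.phi_alr)
        pc = phi[self.labels]
        w_nat = (1 - self.beta) * (1 - self.theta) * pc
        lam = self._lam()
        nat = (self.x * w_nat / lam).sum(axis=1)
        return nat / self.L

    def run(self, n_sweeps, burn_in, thin=5):
        draws = []
        for t in range(n_sweeps):
            rates = self.sweep()
            if t < burn_in and (t + 1) % 50 == 0:
                self._adapt(rates)
            if t >= burn_in and (t - burn_in) % thin == 0:
                draws.append(self.native_fraction())
        return np.array(draws)


def posterior_native_fraction(
    x, labels, eta, tau1, tau2, n_sweeps=30000, burn_in=5000, seed=None
):
    """Posterior-mean per-droplet native fraction by long-run MCMC."""
    sampler = ModelSampler(x, labels, eta, tau1, tau2, seed=seed)
    draws = sampler.run(n_sweeps, burn_in)
    return draws.mean(axis=0)
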