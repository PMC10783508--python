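"""Mean-field stochastic variational inference for the decontamination model.

The model, for droplet i (cluster k_i, library size L_i) and ADT j:

    x_ij | L ~ Poisson(lambda_ij * L_i)
    lambda_ij = (1-beta_ij)*theta_ij*eta_j
              + (1-beta_ij)*(1-theta_ij)*phi[k_i, j]
              + beta_ij
    theta_ij ~ TruncNormal(delta_i, tau1) on (0, 1)
    beta_ij  ~ TruncNormal(mu_j,  tau2) on (0, beta_upper)
    phi_k    ~ Dirichlet(1)            (simplex per cluster)
    delta_i, mu_j ~ flat on their supports

tau1 and tau2 are the scales (standard deviations) of the parent
normals, following the (mean, scale) convention.

eta (the ambient profile) is a fixed plug-in estimated upstream.

Inference maximizes the evidence lower bound with a fully factorized
Gaussian over unconstrained parameters: logit-type bijections map
bounded scalars to the real line and an additive-log-ratio bijection
maps each phi row to R^{J-1}. The ELBO gradient is split by smoothness:
the Poisson log-likelihood term is estimated with single-sample
reparameterized draws, while the truncated-normal coupling terms —
whose 1/tau^2 curvature would otherwise amplify sampling noise and
saturate the optimizer's step normalization — are integrated
analytically at the variational means (a delta-method Rao-
Blackwellization). Adam follows the combined gradient. Posterior means
of the constrained parameters are Monte-Carlo averages over the fitted
variational distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class DivergenceError(RuntimeError):
    """The ELBO became non-finite during optimization."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite ELBO at iteration {iteration}")
        self.iteration = iteration


def _npdf(z):
    return np.exp(-0.5 * z * z - _LOG_SQRT_2PI)


def _trunc_logZ_and_dlogZ(mean, sd, lo, hi):
    """log normalizer of TruncNormal(mean, sd) on (lo, hi) and its
    derivative w.r.t. the mean; stable for sd << hi - lo."""
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    Z = np.maximum(ndtr(b) - ndtr(a), 1e-300)
    dlogZ = (_npdf(a) - _npdf(b)) / (sd * Z)
    return np.log(Z), dlogZ


def _softmax0(z):
    """ALR inverse: rows of [0, z] through softmax."""
    full = np.concatenate([np.zeros((z.shape[0], 1)), z], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _ljac_sigmoid(z):
    """Sum of log|d sigmoid(z)/dz|, stable for |z| >> 1."""
    return -np.sum(np.logaddexp(0.0, z) + np.logaddexp(0.0, -z))


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        # lr may be a scalar or one value per parameter block
        self.lr = [lr] * len(shapes) if np.isscalar(lr) else list(lr)
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads, lr_scale=1.0):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v, lr in zip(params, grads, self.m, self.v, self.lr):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p += (lr * lr_scale) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _collapsed_map(x, labels, eta, B, init_delta, init_beta, phi0, maxiter=500):
    """Maximum-likelihood fit of the tied limit of the model.

    As tau1, tau2 -> 0 the per-entry rates collapse to their prior
    means (theta_ij = delta_i, beta_ij = mu_j); that likelihood is
    low-dimensional and smooth, so L-BFGS converges quickly. Optional
    warm start for the variational fit; note the tied maximum
    likelihood folds mean-level contamination into the native profiles
    (see the fit docstring), so it is not the default.
    """
    from scipy.optimize import minimize

    I, J = x.shape
    K = phi0.shape[0]
    L = x.sum(axis=1)
    onehot = np.zeros((I, K))
    onehot[np.arange(I), labels] = 1.0

    def logit(p):
        return np.log(p) - np.log1p(-p)

    z0 = np.concatenate(
        [
            np.full(I, logit(init_delta)),
            np.full(J, logit(init_beta / B)),
            (np.log(phi0[:, 1:]) - np.log(phi0[:, :1])).ravel(),
        ]
    )

    def unpack(z):
        delta = expit(z[:I])
        mu = B * expit(z[I : I + J])
        phi = _softmax0(z[I + J :].reshape(K, J - 1))
        return delta, mu, phi

    def negloglik(z):
        delta, mu, phi = unpack(z)
        phi_cells = phi[labels]
        lam = (1.0 - mu[None, :]) * (
            delta[:, None] * eta[None, :] + (1.0 - delta[:, None]) * phi_cells
        ) + mu[None, :]
        lam = np.maximum(lam, 1e-300)
        ll = np.sum(x * np.log(lam)) - np.sum(lam * L[:, None])
        g = x / lam - L[:, None]
        d_delta = ((g * (1.0 - mu[None, :])) * (eta[None, :] - phi_cells)).sum(axis=1)
        d_mu = (
            g
            * (
                1.0
                - delta[:, None] * eta[None, :]
                - (1.0 - delta[:, None]) * phi_cells
            )
        ).sum(axis=0)
        d_phi = onehot.T @ (g * (1.0 - mu[None, :]) * (1.0 - delta[:, None]))
        g_de = d_delta * delta * (1.0 - delta)
        g_mu = d_mu * mu * (1.0 - expit(z[I : I + J]))
        inner = (d_phi * phi).sum(axis=1, keepdims=True)
        g_ph = (phi * (d_phi - inner))[:, 1:]
        grad = np.concatenate([g_de, g_mu, g_ph.ravel()])
        return -ll, -grad

    res = minimize(
        negloglik, z0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter}
    )
    return unpack(res.x)


def _fit_saa(
    x, labels, eta, *, tau1, tau2, B, means, lsds, shapes, onehot,
    n_draws, max_lbfgs_iter, rng,
):
    """Deterministically optimize a fixed-draw (sample average) ELBO.

    The reparameterization noise is frozen: ``n_draws`` standard-normal
    draws per variational coordinate are sampled once and the ELBO
    becomes a smooth deterministic function of the variational means
    and log-scales, which L-BFGS can drive to an actual optimum. The
    likelihood term is averaged over the fixed draws; the
    truncated-normal coupling, jacobian and entropy terms are
    integrated analytically at the means (delta method), which keeps
    the 1/tau^2 curvature out of the sampled part entirely.
    """
    from scipy.optimize import minimize

    I, J = x.shape
    L = x.sum(axis=1)
    sd1 = tau1  # prior scales (standard deviations)
    sd2 = tau2
    inv_t1sq = 1.0 / tau1**2
    inv_t2sq = 1.0 / tau2**2
    eps_draws = [
        [rng.standard_normal(s) for s in shapes] for _ in range(n_draws)
    ]
    sizes = [int(np.prod(s)) for s in shapes]

    def pack(blocks):
        return np.concatenate([np.ravel(b) for b in blocks])

    def unpack(flat):
        out = []
        ofs = 0
        for s, n in zip(shapes + shapes, sizes + sizes):
            out.append(flat[ofs : ofs + n].reshape(s))
            ofs += n
        return out[:5], out[5:]

    def negelbo(flat):
        # optimizer coordinates are non-centered: the per-entry mean
        # blocks are residuals from their hyper-mean block, which
        # separates the 1/tau^2 curvature (carried by the residuals)
        # from the likelihood curvature (carried by the hyper-means)
        # and keeps L-BFGS line searches healthy
        (w_th, v_be, m_de, m_mu, m_ph), lsds_c = unpack(flat)
        m_th = m_de[:, None] + w_th
        m_be = m_mu[None, :] + v_be
        sig = [np.exp(np.clip(s, -20.0, 3.0)) for s in lsds_c]

        # analytic (deterministic) part at the means
        th0 = expit(m_th)
        dth0 = th0 * (1.0 - th0)
        sbe0 = expit(m_be)
        be0 = B * sbe0
        dbe0 = be0 * (1.0 - sbe0)
        de0 = expit(m_de)
        dde0 = de0 * (1.0 - de0)
        smu0 = expit(m_mu)
        mu0 = B * smu0
        dmu0 = mu0 * (1.0 - smu0)
        phi0m = _softmax0(m_ph)
        logZ1, dlogZ1 = _trunc_logZ_and_dlogZ(de0, sd1, 0.0, 1.0)
        logZ2, dlogZ2 = _trunc_logZ_and_dlogZ(mu0, sd2, 0.0, B)
        resid_th = th0 - de0[:, None]
        resid_be = be0 - mu0[None, :]

        lp = (
            -0.5
            * inv_t1sq
            * (
                np.sum(resid_th**2)
                + np.sum((sig[0] * dth0) ** 2)
                + J * np.sum((sig[2] * dde0) ** 2)
            )
            - J * np.sum(logZ1)
            - 0.5
            * inv_t2sq
            * (
                np.sum(resid_be**2)
                + np.sum((sig[1] * dbe0) ** 2)
                + I * np.sum((sig[3] * dmu0) ** 2)
            )
            - I * np.sum(logZ2)
        )
        ljac = (
            _ljac_sigmoid(m_th)
            + _ljac_sigmoid(m_be)
            + _ljac_sigmoid(m_de)
            + _ljac_sigmoid(m_mu)
            + np.sum(np.log(np.maximum(phi0m, 1e-300)))
        )
        entropy = sum(np.sum(s) for s in lsds_c)

        gp_th = -resid_th * inv_t1sq * dth0 + (1.0 - 2.0 * th0)
        gp_be = -resid_be * inv_t2sq * dbe0 + (1.0 - 2.0 * sbe0)
        gp_de = (resid_th.sum(axis=1) * inv_t1sq - J * dlogZ1) * dde0 + (
            1.0 - 2.0 * de0
        )
        gp_mu = (resid_be.sum(axis=0) * inv_t2sq - I * dlogZ2) * dmu0 + (
            1.0 - 2.0 * smu0
        )
        gp_ph = (1.0 - J * phi0m)[:, 1:]
        gs_prior = [
            -(sig[0] ** 2) * dth0**2 * inv_t1sq + 1.0,
            -(sig[1] ** 2) * dbe0**2 * inv_t2sq + 1.0,
            -(sig[2] ** 2) * J * dde0**2 * inv_t1sq + 1.0,
            -(sig[3] ** 2) * I * dmu0**2 * inv_t2sq + 1.0,
            np.ones(shapes[4]),
        ]

        ll_acc = 0.0
        gl_means = [np.zeros(s) for s in shapes]
        gl_lsds = [np.zeros(s) for s in shapes]
        for eps in eps_draws:
            z_th = m_th + sig[0] * eps[0]
            z_be = m_be + sig[1] * eps[1]
            z_ph = m_ph + sig[4] * eps[4]
            theta = expit(z_th)
            s_be = expit(z_be)
            beta = B * s_be
            phi = _softmax0(z_ph)
            phi_cells = phi[labels]
            lam = (
                (1.0 - beta) * (theta * eta[None, :] + (1.0 - theta) * phi_cells)
                + beta
            )
            lam = np.maximum(lam, 1e-300)
            ll_acc += np.sum(x * np.log(lam)) - np.sum(lam * L[:, None])
            g_lam = x / lam - L[:, None]
            gl_th = (
                g_lam
                * (1.0 - beta)
                * (eta[None, :] - phi_cells)
                * theta
                * (1.0 - theta)
            )
            gl_be = (
                g_lam
                * (1.0 - theta * eta[None, :] - (1.0 - theta) * phi_cells)
                * beta
                * (1.0 - s_be)
            )
            d_phi = onehot.T @ (g_lam * (1.0 - beta) * (1.0 - theta))
            inner = (d_phi * phi).sum(axis=1, keepdims=True)
            gl_ph = (phi * (d_phi - inner))[:, 1:]
            gl_means[0] += gl_th
            gl_means[1] += gl_be
            gl_means[4] += gl_ph
            gl_lsds[0] += gl_th * sig[0] * eps[0]
            gl_lsds[1] += gl_be * sig[1] * eps[1]
            gl_lsds[4] += gl_ph * sig[4] * eps[4]
        inv_n = 1.0 / n_draws
        elbo = ll_acc * inv_n + lp + ljac + entropy
        g_th_full = gl_means[0] * inv_n + gp_th
        g_be_full = gl_means[1] * inv_n + gp_be
        g_means = [
            g_th_full,
            g_be_full,
            gp_de + g_th_full.sum(axis=1),
            gp_mu + g_be_full.sum(axis=0),
            gl_means[4] * inv_n + gp_ph,
        ]
        g_lsds = [g * inv_n + gp for g, gp in zip(gl_lsds, gs_prior)]
        if not np.isfinite(elbo):
            return 1e300, np.zeros_like(flat)
        return -elbo, -pack(g_means + g_lsds)

    m_th0, m_be0, m_de0, m_mu0, m_ph0 = means
    x0 = pack(
        [
            m_th0 - m_de0[:, None],
            m_be0 - m_mu0[None, :],
            m_de0,
            m_mu0,
            m_ph0,
        ]
        + lsds
    )
    res = minimize(
        negelbo,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_lbfgs_iter, "maxcor": 20},
    )
    (w_th, v_be, m_de, m_mu, m_ph), lsds_c = unpack(res.x)
    means_c = [m_de[:, None] + w_th, m_mu[None, :] + v_be, m_de, m_mu, m_ph]
    return means_c, [np.clip(s, -20.0, 3.0) for s in lsds_c], res


def _posterior_summaries(
    full_means, lsds, shapes, B, eta, trace, converged, n_iter, centered,
    rng, posterior_draws,
):
    """Monte-Carlo posterior means over the fitted variational law."""
    acc = {"theta": 0.0, "beta": 0.0, "delta": 0.0, "mu": 0.0, "phi": 0.0}
    sig = [np.exp(s) for s in lsds]
    for _ in range(posterior_draws):
        z = [
            m + sg * rng.standard_normal(sh)
            for m, sg, sh in zip(full_means, sig, shapes)
        ]
        acc["theta"] += expit(z[0])
        acc["beta"] += B * expit(z[1])
        acc["delta"] += expit(z[2])
        acc["mu"] += B * expit(z[3])
        acc["phi"] += _softmax0(z[4])
    post = {k: v / posterior_draws for k, v in acc.items()}
    post["phi"] /= post["phi"].sum(axis=1, keepdims=True)
    return {
        **post,
        "eta": eta,
        "elbo_trace": trace,
        "converged": converged,
        "n_iter": n_iter,
        "variational": {
            "means": {
                "theta": full_means[0], "beta": full_means[1],
                "delta": full_means[2], "mu": full_means[3],
                "phi": full_means[4],
            },
            "log_sds": {
                "theta": lsds[0], "beta": lsds[1], "delta": lsds[2],
                "mu": lsds[3], "phi": lsds[4],
            },
        },
    }


def fit_advi(
    x,
    labels,
    eta,
    *,
    tau1: float = 2e-5,
    tau2: float = 2e-6,
    beta_upper: float = 0.5,
    init_theta: float = 1e-4,
    init_beta: float = 1e-2,
    init_delta: float = 0.01,
    init_mu: float = 0.01,
    max_iter: int = 50000,
    elbo_rel_tol: float = 1e-4,
    elbo_window: int = 100,
    learning_rate: float = 0.05,
    lr_decay_iter: int = 2000,
    lr_decay_power: float = 0.5,
    init_sigma: float = 0.1,
    posterior_draws: int = 256,
    warm_start: bool = False,
    centered: bool = True,
    optimizer: str = "adam",
    rao_blackwell: bool = False,
    n_saa_draws: int = 4,
    seed=None,
):
    """Fit the decontamination model by SVI; return posterior summaries.

    ``x`` is the dense I x J count matrix, ``labels`` 0-based cluster
    indices, ``eta`` the fixed ambient profile. Optimization uses Adam
    at ``learning_rate`` (decaying as 1/sqrt after ``lr_decay_iter``
    iterations) and stops early when the windowed mean ELBO changes by
    less than ``elbo_rel_tol`` relatively, or at ``max_iter``.

    A note on identifiability: with flat hyperpriors the posterior has
    a ridge — mean-level contamination can be traded between the
    native profiles ``phi`` and the contamination channels with little
    likelihood cost, and the truncation normalizers mildly favor the
    degenerate all-native end. The stated initial values (small
    ``theta``, ``beta`` at the expected background scale) anchor the
    fit on that ridge; running unrelated optimizers (e.g. the tied
    maximum likelihood, ``warm_start=True``) to full convergence lands
    on the all-native end instead. Droplet-level contamination
    *variation* is identified regardless; the mean-level split is a
    convention set by this initialization, which real marker structure
    in the data sharpens into genuine identification.

    Returns a dict with posterior-mean parameter arrays (``phi``,
    ``theta``, ``beta``, ``delta``, ``mu``), the ``elbo_trace``,
    ``converged`` flag and ``n_iter``.
    """
    x = np.asarray(x, dtype=float)
    I, J = x.shape
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max()) + 1
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (J,) or not np.isclose(eta.sum(), 1.0):
        raise ValueError("eta must be a length-J simplex")
    L = x.sum(axis=1)
    if (L <= 0).any():
        raise ValueError("droplets with zero total counts; filter them first")
    for k in range(K):
        if x[labels == k].sum() <= 0:
            raise ValueError(f"cluster {k} has zero total counts")
    rng = np.random.default_rng(seed)
    B = beta_upper
    sd1 = tau1  # prior scales (standard deviations)
    sd2 = tau2
    inv_t1sq = 1.0 / tau1**2
    inv_t2sq = 1.0 / tau2**2

    def logit(p):
        return np.log(p) - np.log1p(-p)

    # phi initialized at per-cluster empirical profiles (ALR coordinates)
    phi0 = np.vstack(
        [
            (x[labels == k].sum(axis=0) + 1.0) / (x[labels == k].sum() + J)
            for k in range(K)
        ]
    )
    if warm_start:
        delta0, mu0, phi0 = _collapsed_map(
            x, labels, eta, B, init_delta, init_beta, phi0
        )
        delta0 = np.clip(delta0, 1e-8, 1.0 - 1e-8)
        mu0 = np.clip(mu0, 1e-8 * B, (1.0 - 1e-8) * B)
        m_th = np.tile(logit(delta0)[:, None], (1, J))
        m_be = np.tile(logit(mu0 / B)[None, :], (I, 1))
        m_de = logit(delta0)
        m_mu = logit(mu0 / B)
    else:
        m_th = np.full((I, J), logit(init_theta))
        m_be = np.full((I, J), logit(init_beta / B))
        m_de = np.full(I, logit(init_delta))
        m_mu = np.full(J, logit(init_mu / B))
    m_ph = np.log(np.maximum(phi0[:, 1:], 1e-300)) - np.log(
        np.maximum(phi0[:, :1], 1e-300)
    )
    if not centered:
        # store the per-entry mean blocks as residuals from their
        # hyper-mean block; the hyper-means then receive the summed
        # gradients directly and travel freely (non-centered
        # optimizer coordinates; the variational family is unchanged)
        m_th = m_th - m_de[:, None]
        m_be = m_be - m_mu[None, :]
    means = [m_th, m_be, m_de, m_mu, m_ph]
    lsds = [np.full(m.shape, np.log(init_sigma)) for m in means]
    shapes = [m.shape for m in means]
    opt = _Adam(shapes + shapes, learning_rate)

    onehot = np.zeros((I, K))
    onehot[np.arange(I), labels] = 1.0

    if optimizer == "saa":
        means, lsds, res = _fit_saa(
            x, labels, eta, tau1=tau1, tau2=tau2, B=B,
            means=means, lsds=lsds, shapes=shapes, onehot=onehot,
            n_draws=n_saa_draws, max_lbfgs_iter=max_iter, rng=rng,
        )
        m_th, m_be, m_de, m_mu, m_ph = means
        trace = np.array([-res.fun])
        converged = bool(res.success)
        n_iter = int(res.nit)
        return _posterior_summaries(
            means, lsds, shapes, B, eta, trace, converged, n_iter,
            centered, rng, posterior_draws,
        )
    if optimizer != "adam":
        raise ValueError(f"unknown optimizer {optimizer!r}")

    trace = np.empty(max_iter)
    converged = False
    n_iter = max_iter
    prev_window_mean = None

    def _full_means():
        if centered:
            return m_th, m_be
        return m_de[:, None] + m_th, m_mu[None, :] + m_be

    for it in range(max_iter):
        sig = [np.exp(s) for s in lsds]
        eps = [rng.standard_normal(s) for s in shapes]
        f_th, f_be = _full_means()
        z_th = f_th + sig[0] * eps[0]
        z_be = f_be + sig[1] * eps[1]
        z_de = m_de + sig[2] * eps[2]
        z_mu = m_mu + sig[3] * eps[3]
        z_ph = m_ph + sig[4] * eps[4]

        # ---- sampled likelihood part (theta, beta, phi only) ----
        theta = expit(z_th)
        s_be = expit(z_be)
        beta = B * s_be
        phi = _softmax0(z_ph)
        phi_cells = phi[labels]
        lam = (1.0 - beta) * (theta * eta[None, :] + (1.0 - theta) * phi_cells) + beta
        lam = np.maximum(lam, 1e-300)
        g_lam = x / lam - L[:, None]

        gl_th = g_lam * (1.0 - beta) * (eta[None, :] - phi_cells) * theta * (1.0 - theta)
        gl_be = (
            g_lam
            * (1.0 - theta * eta[None, :] - (1.0 - theta) * phi_cells)
            * beta
            * (1.0 - s_be)
        )
        d_phi = onehot.T @ (g_lam * (1.0 - beta) * (1.0 - theta))
        inner = (d_phi * phi).sum(axis=1, keepdims=True)
        gl_ph = (phi * (d_phi - inner))[:, 1:]

        # ---- prior + jacobian part ----
        # Default: evaluated at the sampled values (plain single-sample
        # reparameterized gradients). With rao_blackwell=True they are
        # instead integrated at the variational means (delta method),
        # which removes the 1/tau^2-amplified gradient noise but also
        # the noise-assisted travel of the coupled pairs.
        if rao_blackwell:
            th0 = expit(f_th)
            sbe0 = expit(f_be)
            de0 = expit(m_de)
            smu0 = expit(m_mu)
            phi0m = _softmax0(m_ph)
        else:
            th0 = theta
            sbe0 = s_be
            de0 = expit(z_de)
            smu0 = expit(z_mu)
            phi0m = phi
        dth0 = th0 * (1.0 - th0)
        be0 = B * sbe0
        dbe0 = be0 * (1.0 - sbe0)
        dde0 = de0 * (1.0 - de0)
        mu0 = B * smu0
        dmu0 = mu0 * (1.0 - smu0)
        logZ1, dlogZ1 = _trunc_logZ_and_dlogZ(de0, sd1, 0.0, 1.0)
        logZ2, dlogZ2 = _trunc_logZ_and_dlogZ(mu0, sd2, 0.0, B)

        resid_th = th0 - de0[:, None]
        resid_be = be0 - mu0[None, :]
        gp_th = -resid_th * inv_t1sq * dth0 + (1.0 - 2.0 * th0)
        gp_be = -resid_be * inv_t2sq * dbe0 + (1.0 - 2.0 * sbe0)
        gp_de = (resid_th.sum(axis=1) * inv_t1sq - J * dlogZ1) * dde0 + (
            1.0 - 2.0 * de0
        )
        gp_mu = (resid_be.sum(axis=0) * inv_t2sq - I * dlogZ2) * dmu0 + (
            1.0 - 2.0 * smu0
        )
        gp_ph = (1.0 - J * phi0m)[:, 1:]

        g_full_th = gl_th + gp_th
        g_full_be = gl_be + gp_be
        if centered:
            g_means = [g_full_th, g_full_be, gp_de, gp_mu, gl_ph + gp_ph]
        else:
            g_means = [
                g_full_th,
                g_full_be,
                gp_de + g_full_th.sum(axis=1),
                gp_mu + g_full_be.sum(axis=0),
                gl_ph + gp_ph,
            ]

        # ---- scale gradients (entropy term + pathwise) ----
        if rao_blackwell:
            g_lsds = [
                gl_th * sig[0] * eps[0] + 1.0 - sig[0] ** 2 * dth0**2 * inv_t1sq,
                gl_be * sig[1] * eps[1] + 1.0 - sig[1] ** 2 * dbe0**2 * inv_t2sq,
                1.0 - sig[2] ** 2 * J * dde0**2 * inv_t1sq,
                1.0 - sig[3] ** 2 * I * dmu0**2 * inv_t2sq,
                gl_ph * sig[4] * eps[4] + 1.0,
            ]
        else:
            g_lsds = [
                g_full_th * sig[0] * eps[0] + 1.0,
                g_full_be * sig[1] * eps[1] + 1.0,
                g_means[2] * sig[2] * eps[2] + 1.0,
                g_means[3] * sig[3] * eps[3] + 1.0,
                (gl_ph + gp_ph) * sig[4] * eps[4] + 1.0,
            ]

        # ---- ELBO estimate (additive constants dropped) ----
        ll = np.sum(x * np.log(lam)) - np.sum(lam * L[:, None])
        lp = (
            -0.5 * inv_t1sq * np.sum(resid_th**2)
            - J * np.sum(logZ1)
            - 0.5 * inv_t2sq * np.sum(resid_be**2)
            - I * np.sum(logZ2)
        )
        if rao_blackwell:
            lp -= 0.5 * inv_t1sq * (
                np.sum((sig[0] * dth0) ** 2) + J * np.sum((sig[2] * dde0) ** 2)
            ) + 0.5 * inv_t2sq * (
                np.sum((sig[1] * dbe0) ** 2) + I * np.sum((sig[3] * dmu0) ** 2)
            )
        ljac = (
            _ljac_sigmoid(z_th if not rao_blackwell else f_th)
            + _ljac_sigmoid(z_be if not rao_blackwell else f_be)
            + _ljac_sigmoid(z_de if not rao_blackwell else m_de)
            + _ljac_sigmoid(z_mu if not rao_blackwell else m_mu)
            + np.sum(np.log(np.maximum(phi0m, 1e-300)))
        )
        entropy = sum(np.sum(s) for s in lsds)
        elbo = ll + lp + ljac + entropy
        if not np.isfinite(elbo):
            raise DivergenceError(it)
        trace[it] = elbo

        lr_scale = (
            1.0
            if it < lr_decay_iter
            else (lr_decay_iter / (it + 1.0)) ** lr_decay_power
        )
        opt.step(means + lsds, g_means + g_lsds, lr_scale)

        if (it + 1) % elbo_window == 0:
            wmean = trace[it + 1 - elbo_window : it + 1].mean()
            if prev_window_mean is not None:
                rel = abs(wmean - prev_window_mean) / (abs(prev_window_mean) + 1.0)
                if rel < elbo_rel_tol:
                    converged = True
                    n_iter = it + 1
                    break
            prev_window_mean = wmean

    trace = trace[:n_iter].copy()
    f_th, f_be = _full_means()
    return _posterior_summaries(
        [f_th, f_be, m_de, m_mu, m_ph], lsds, shapes, B, eta,
        trace, converged, n_iter, centered, rng, posterior_draws,
    )
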