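"""Adaptive MCMC machinery for the hierarchical diffusion model.

The posterior is sampled with an adaptive Metropolis-within-Gibbs scheme on a
non-centered parameterization: each person-level parameter is
``raw_ik = mu_k + sigma_k * z_ik`` with ``z_ik ~ N(0,1)`` a priori, where
``raw`` lives on an unconstrained scale (log for boundary separation and
non-decision time, logit for the starting point, identity for drifts and
effect slopes).  One sweep updates, component by component,

* every person's ``z`` in column ``k`` jointly (the likelihood factorizes
  over persons given the group level, so proposals are accepted or rejected
  per person from a single vectorized likelihood pass),
* each group mean ``mu_k``,
* each group log-SD ``log sigma_k`` (half-normal prior on ``sigma_k`` plus
  the log-scale Jacobian).

Proposal scales adapt in batches during warmup toward a 0.44 acceptance rate
(the standard componentwise target) and are frozen afterwards.  Distributional
correctness is the contract and is checked by the parameter-recovery and
conjugate-oracle tests, not by appeal to a named algorithm.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .wfpt import _log_density

# column layout of the person-parameter matrix (natural scales)
PARAM_COLS = ["a", "w", "v_living", "v_nonliving", "t0",
              "v_a", "v_c", "v_int", "t0_a", "t0_c", "t0_int", "w_c"]
_IDX = {n: i for i, n in enumerate(PARAM_COLS)}

#: sampling-scale transform per column: 0 identity, 1 log, 2 logit
TRANSFORM = {"a": 1, "w": 2, "t0": 1}

_T0_FLOOR = 1e-3


@njit(cache=True)
def _loglik_kernel(rt, up, pidx, A, C, living, prime, P, use_wc, per_trial, out):
    """Total log likelihood, accumulated per person (and optionally per trial).

    ``P`` is (n_person, 12) on natural scales; ``out`` is (n_person,) and is
    overwritten.  ``per_trial`` is filled when its size matches the trials.
    """
    out[:] = 0.0
    n = rt.size
    store = per_trial.size == n
    for j in range(n):
        i = pidx[j]
        a = P[i, 0]
        w = P[i, 1]
        e = P[i, 5] * A[j] + P[i, 6] * C[j] + P[i, 7] * A[j] * C[j]
        if living[j] == 1:
            v = P[i, 2] + e
        else:
            v = P[i, 3] - e
        t0 = P[i, 4] + P[i, 8] * A[j] + P[i, 9] * C[j] + P[i, 10] * A[j] * C[j]
        if t0 < _T0_FLOOR:
            t0 = _T0_FLOOR
        if use_wc == 1:
            lw = math.log(w) - math.log(1.0 - w) + P[i, 11] * prime[j]
            w = 1.0 / (1.0 + math.exp(-lw))
        ll = _log_density(rt[j], up[j] == 1, a, w, v, t0)
        if store:
            per_trial[j] = ll
        out[i] += ll
    return out


def _natural(raw: np.ndarray, kind: int) -> np.ndarray:
    if kind == 1:
        return np.exp(raw)
    if kind == 2:
        return 1.0 / (1.0 + np.exp(-raw))
    return raw


class TrialData:
    """Kept trials flattened into the arrays the likelihood kernel consumes."""

    def __init__(self, df):
        kept = df[df["kept"]] if "kept" in df.columns else df
        pids = kept["participant_id"].astype(str).to_numpy()
        self.person_labels = np.unique(pids)
        lookup = {p: i for i, p in enumerate(self.person_labels)}
        self.pidx = np.array([lookup[p] for p in pids], dtype=np.int64)
        self.rt = kept["rt_s"].to_numpy(dtype=np.float64)
        self.up = (kept["response"].to_numpy() == "living").astype(np.uint8)
        self.A = kept["association"].to_numpy(dtype=np.float64)
        self.C = kept["congruence"].to_numpy(dtype=np.float64)
        self.living = (kept["target_type"].to_numpy() == "living").astype(np.uint8)
        if "prime_category" in kept.columns:
            prime_living = kept["prime_category"].to_numpy() == "living"
        else:
            prime_living = np.where(self.C == 1, self.living == 1, self.living == 0)
        self.prime = np.where(prime_living, 1.0, -1.0)
        self.index = kept.index.to_numpy()
        self.n_person = len(self.person_labels)
        self.n_trials = len(kept)

    def loglik(self, P, use_wc, per_trial=None):
        out = np.empty(self.n_person)
        pt = per_trial if per_trial is not None else np.empty(0)
        _loglik_kernel(self.rt, self.up, self.pidx, self.A, self.C, self.living,
                       self.prime, P, 1 if use_wc else 0, pt, out)
        return out


class AMWGChain:
    """One chain of the adaptive Metropolis-within-Gibbs sampler."""

    def __init__(self, data: TrialData, cols, transforms, mu_prior, sd_prior,
                 init_mu, init_ls, init_z, rng, use_wc):
        self.data = data
        self.cols = list(cols)                      # active PARAM_COLS names
        self.cidx = np.array([_IDX[c] for c in cols])
        self.kind = np.array(transforms)            # per active column
        self.mu_m = np.array([mu_prior[c][0] for c in cols])
        self.mu_s = np.array([mu_prior[c][1] for c in cols])
        self.sd_scale = np.array([sd_prior[c] for c in cols])
        self.rng = rng
        self.use_wc = use_wc
        K, n_p = len(cols), data.n_person

        self.mu = init_mu.copy()
        self.ls = init_ls.copy()
        self.z = init_z.copy()
        self.P = np.zeros((n_p, len(PARAM_COLS)))
        # keep inactive base columns at safe neutral values (never used unless
        # the column is active, except w which always enters the kernel)
        self.P[:, _IDX["w"]] = 0.5
        for k in range(K):
            self._set_col(k)
        self.person_ll = self.data.loglik(self.P, self.use_wc)

        self.step_z = np.full((n_p, K), 0.4)
        self.step_mu = np.full(K, 0.1)
        self.step_ls = np.full(K, 0.4)
        self.step_ils = np.full(K, 0.4)
        self.acc_z = np.zeros((n_p, K))
        self.acc_mu = np.zeros(K)
        self.acc_ls = np.zeros(K)
        self.acc_ils = np.zeros(K)
        self.n_batch = 0

    # -- state helpers -------------------------------------------------
    def _set_col(self, k, z_col=None, mu=None, ls=None):
        z = self.z[:, k] if z_col is None else z_col
        m = self.mu[k] if mu is None else mu
        s = math.exp(self.ls[k] if ls is None else ls)
        self.P[:, self.cidx[k]] = _natural(m + s * z, self.kind[k])

    def total_logpost(self):
        lp = float(np.sum(self.person_ll))
        lp += float(np.sum(-0.5 * ((self.mu - self.mu_m) / self.mu_s) ** 2))
        sig = np.exp(self.ls)
        lp += float(np.sum(-0.5 * (sig / self.sd_scale) ** 2 + self.ls))
        lp += float(np.sum(-0.5 * self.z ** 2))
        return lp

    # -- updates -------------------------------------------------------
    def _update_z(self, k):
        n_p = self.data.n_person
        z_new = self.z[:, k] + self.step_z[:, k] * self.rng.standard_normal(n_p)
        old_col = self.P[:, self.cidx[k]].copy()
        self._set_col(k, z_col=z_new)
        ll_new = self.data.loglik(self.P, self.use_wc)
        log_alpha = (ll_new - self.person_ll) + 0.5 * (self.z[:, k] ** 2 - z_new ** 2)
        accept = np.log(self.rng.random(n_p)) < log_alpha
        self.z[accept, k] = z_new[accept]
        self.person_ll[accept] = ll_new[accept]
        self.P[~accept, self.cidx[k]] = old_col[~accept]
        self.acc_z[:, k] += accept

    def _update_scalar(self, k, which):
        if which == "mu":
            cur, step = self.mu[k], self.step_mu[k]
            prop = cur + step * self.rng.standard_normal()
            dprior = (-0.5 * ((prop - self.mu_m[k]) / self.mu_s[k]) ** 2
                      + 0.5 * ((cur - self.mu_m[k]) / self.mu_s[k]) ** 2)
            kw = {"mu": prop}
        else:
            cur, step = self.ls[k], self.step_ls[k]
            prop = cur + step * self.rng.standard_normal()
            s_new, s_old = math.exp(prop), math.exp(cur)
            c = self.sd_scale[k]
            dprior = (-0.5 * (s_new / c) ** 2 + prop) - (-0.5 * (s_old / c) ** 2 + cur)
            kw = {"ls": prop}
        old_col = self.P[:, self.cidx[k]].copy()
        self._set_col(k, **kw)
        ll_new = self.data.loglik(self.P, self.use_wc)
        log_alpha = float(np.sum(ll_new - self.person_ll)) + dprior
        if math.log(self.rng.random()) < log_alpha:
            if which == "mu":
                self.mu[k] = prop
                self.acc_mu[k] += 1
            else:
                self.ls[k] = prop
                self.acc_ls[k] += 1
            self.person_ll = ll_new
        else:
            self.P[:, self.cidx[k]] = old_col

    def _interweave(self, k):
        """Centered-frame update of (mu_k, sigma_k) at fixed person values.

        The non-centered frame mixes poorly for parameters the data pin down
        tightly (the group mean and its SD become strongly coupled to the
        z's).  Holding the person-level raw values fixed, the group mean is
        conjugate-normal and the SD needs only a cheap Metropolis step — no
        trial-likelihood evaluation — after which z is recomputed.  The
        person parameters (and the cached likelihood) are unchanged.
        """
        sig = math.exp(self.ls[k])
        raw = self.mu[k] + sig * self.z[:, k]
        n_p = raw.size
        prec = 1.0 / self.mu_s[k] ** 2 + n_p / sig ** 2
        mean = (self.mu_m[k] / self.mu_s[k] ** 2 + raw.sum() / sig ** 2) / prec
        self.mu[k] = mean + math.sqrt(1.0 / prec) * self.rng.standard_normal()

        cur = self.ls[k]
        prop = cur + self.step_ils[k] * self.rng.standard_normal()
        s_old, s_new = math.exp(cur), math.exp(prop)
        ss = float(np.sum((raw - self.mu[k]) ** 2))
        c = self.sd_scale[k]
        log_alpha = ((-n_p * prop - 0.5 * ss / s_new ** 2 - 0.5 * (s_new / c) ** 2 + prop)
                     - (-n_p * cur - 0.5 * ss / s_old ** 2 - 0.5 * (s_old / c) ** 2 + cur))
        if math.log(self.rng.random()) < log_alpha:
            self.ls[k] = prop
            self.acc_ils[k] += 1
        self.z[:, k] = (raw - self.mu[k]) / math.exp(self.ls[k])

    def sweep(self):
        K = len(self.cols)
        for k in range(K):
            self._update_z(k)
        for k in range(K):
            self._update_scalar(k, "mu")
        for k in range(K):
            self._update_scalar(k, "ls")
        for k in range(K):
            self._interweave(k)

    def adapt(self, batch_size):
        """Batch adaptation of proposal scales toward 0.44 acceptance."""
        self.n_batch += 1
        delta = min(0.25, self.n_batch ** -0.5)
        self.step_z *= np.exp(np.where(self.acc_z / batch_size > 0.44, delta, -delta))
        self.step_mu *= np.exp(np.where(self.acc_mu / batch_size > 0.44, delta, -delta))
        self.step_ls *= np.exp(np.where(self.acc_ls / batch_size > 0.44, delta, -delta))
        self.step_ils *= np.exp(np.where(self.acc_ils / batch_size > 0.44, delta, -delta))
        np.clip(self.step_z, 1e-3, 10.0, out=self.step_z)
        np.clip(self.step_mu, 1e-4, 5.0, out=self.step_mu)
        np.clip(self.step_ls, 1e-3, 5.0, out=self.step_ls)
        np.clip(self.step_ils, 1e-3, 5.0, out=self.step_ils)
        self.acc_z[:] = 0
        self.acc_mu[:] = 0
        self.acc_ls[:] = 0
        self.acc_ils[:] = 0

    def acceptance_rates(self):
        return {"z": self.step_z.mean(), "mu": self.step_mu.mean(),
                "ls": self.step_ls.mean()}


def run_chain(data: TrialData, cols, transforms, mu_prior, sd_prior,
              init_mu, init_ls, init_z, n_iter, n_warmup, seed, use_wc,
              store_loglik=True, batch_size=50, init_retries=5):
    """Run one chain; returns dict of post-warmup draws.

    Raises ``RuntimeError`` if the likelihood is non-finite at initialization
    after ``init_retries`` jittered restarts.
    """
    rng = np.random.default_rng(seed)
    chain = None
    for attempt in range(init_retries + 1):
        jitter = 0.0 if attempt == 0 else 0.1 * attempt
        mu0 = init_mu + jitter * rng.standard_normal(init_mu.size)
        z0 = init_z + jitter * rng.standard_normal(init_z.shape)
        chain = AMWGChain(data, cols, transforms, mu_prior, sd_prior,
                          mu0, init_ls, z0, rng, use_wc)
        if np.all(np.isfinite(chain.person_ll)):
            break
    else:
        bad = np.where(~np.isfinite(chain.person_ll))[0]
        raise RuntimeError(
            f"non-finite initial likelihood for persons {bad.tolist()} after "
            f"{init_retries} jittered re-initializations")

    K, n_p = len(cols), data.n_person
    n_keep = n_iter - n_warmup
    draws_mu = np.empty((n_keep, K), dtype=np.float64)
    draws_ls = np.empty((n_keep, K), dtype=np.float64)
    draws_P = np.empty((n_keep, n_p, K), dtype=np.float32)
    draws_ll = (np.empty((n_keep, data.n_trials), dtype=np.float32)
                if store_loglik else None)
    per_trial = np.empty(data.n_trials) if store_loglik else None

    for it in range(n_iter):
        chain.sweep()
        if it < n_warmup:
            if (it + 1) % batch_size == 0:
                chain.adapt(batch_size)
        else:
            j = it - n_warmup
            draws_mu[j] = chain.mu
            draws_ls[j] = chain.ls
            draws_P[j] = chain.P[:, chain.cidx]
            if store_loglik:
                chain.data.loglik(chain.P, use_wc, per_trial=per_trial)
                draws_ll[j] = per_trial
    return {"mu": draws_mu, "log_sigma": draws_ls, "person": draws_P,
            "loglik": draws_ll, "steps": chain.acceptance_rates()}
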