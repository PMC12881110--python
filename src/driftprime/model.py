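"""Hierarchical Bayesian diffusion model: model and results classes.

``HierarchicalDDM`` is built from a (pre-treated) trial table and a model
variant; ``fit()`` runs MCMC and returns a ``DDMResults`` object carrying the
posterior draws, convergence diagnostics, a Table-style ``summary()`` of the
fixed effects, the pointwise log-likelihood matrix for LOO-CV, and posterior
predictive checks.

Likelihood: every kept trial contributes the Wiener first-passage density of
its (response boundary, RT) under the per-trial parameters assembled by the
trial-level regression (response coding, living = upper boundary).  Person
parameters are modelled hierarchically with uncorrelated random intercepts
and slopes; group means and SDs carry weakly informative priors (see
``default_priors``).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compare as _compare
from .design import GROUP_FIELDS, ModelSpec, PersonParams, get_model, validate_trials
from .sampler import PARAM_COLS, TRANSFORM, TrialData, run_chain
from .wfpt import WienerParams, simulate as simulate_wiener

__all__ = ["FitConfig", "HierarchicalDDM", "DDMResults", "default_priors",
           "convergence_table"]

_FLAG_TO_COL = {
    "drift_assoc": "v_a", "drift_cong": "v_c", "drift_interaction": "v_int",
    "t0_assoc": "t0_a", "t0_cong": "t0_c", "t0_interaction": "t0_int",
    "start_cong": "w_c",
}

#: display names for group-level fixed effects, in summary-table row order
REPORT_NAMES = {
    "a": "mu_a", "w": "mu_w", "v_nonliving": "mu_v_nonliving",
    "v_living": "mu_v_living", "t0": "mu_t0", "v_a": "mu_v_assoc",
    "v_c": "mu_v_cong", "v_int": "mu_v_inter", "t0_a": "mu_t0_assoc",
    "t0_c": "mu_t0_cong", "t0_int": "mu_t0_inter", "w_c": "mu_w_cong",
}


def default_priors() -> dict:
    """Weakly informative default priors (sampling scales).

    Group means: boundary separation on the log scale ~ N(log 1.5, 0.6)
    (approximating a truncated N(1.5, 1) on the natural scale); starting
    point on the logit scale ~ N(0, 0.5); baseline drifts ~ N(0, 5);
    non-decision time on the log scale ~ N(log 0.3, 0.5) (approximating a
    truncated N(0.3 s, 0.2 s)); all effect means ~ N(0, 0.5).  Group SDs:
    half-normal(0.5), except all non-decision-time SDs, half-normal(0.1).
    """
    mu = {"a": (np.log(1.5), 0.6), "w": (0.0, 0.5),
          "v_living": (0.0, 5.0), "v_nonliving": (0.0, 5.0),
          "t0": (np.log(0.3), 0.5)}
    for c in ("v_a", "v_c", "v_int", "t0_a", "t0_c", "t0_int", "w_c"):
        mu[c] = (0.0, 0.5)
    sd = {c: 0.5 for c in PARAM_COLS}
    for c in ("t0", "t0_a", "t0_c", "t0_int"):
        sd[c] = 0.1
    return {"mu": mu, "sd": sd}


@dataclass
class FitConfig:
    """MCMC settings; defaults follow the original analysis (4 chains of
    5000 iterations, first half discarded as warmup -> 10,000 kept draws)."""

    n_chains: int = 4
    n_iter: int = 5000
    warmup_frac: float = 0.5
    seed: int = 0
    store_loglik: bool = True
    priors: dict | None = None

    @property
    def n_warmup(self) -> int:
        return int(self.n_iter * self.warmup_frac)

    @property
    def n_draws_total(self) -> int:
        return self.n_chains * (self.n_iter - self.n_warmup)


def convergence_table(draws: dict, rhat_max: float = 1.01,
                      ess_min: float = 400.0) -> pd.DataFrame:
    """Split-chain R-hat and bulk/tail ESS for a dict of (chain, draw) arrays,
    flagged against the given thresholds."""
    import arviz as az
    idata = az.from_dict(posterior=dict(draws))
    rhat = az.rhat(idata)
    ess_b = az.ess(idata, method="bulk")
    ess_t = az.ess(idata, method="tail")
    rows = [(name, float(rhat[name].values), float(ess_b[name].values),
             float(ess_t[name].values)) for name in draws]
    df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk", "ess_tail"])
    df["rhat_ok"] = df["rhat"] < rhat_max
    df["ess_ok"] = np.minimum(df["ess_bulk"], df["ess_tail"]) > ess_min
    return df.set_index("parameter")


def _ez_moments(p_correct, rt_var, rt_mean, n):
    """Closed-form moment (EZ-style) diffusion estimates used only to
    initialize chains near the data."""
    pc = min(max(p_correct, 0.5 + 1.0 / (2 * max(n, 2))), 1.0 - 1.0 / (2 * max(n, 2)))
    L = np.log(pc / (1 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / max(rt_var, 1e-4)
    v = float(np.clip(x ** 0.25, 0.5, 5.0))
    a = float(np.clip(L / v, 0.6, 3.0))
    mdt = (a / (2 * v)) * (1 - np.exp(-v * a)) / (1 + np.exp(-v * a))
    return v, a, float(rt_mean - mdt)


class HierarchicalDDM:
    """Hierarchical drift-diffusion model for the 2x2 priming design.

    Parameters
    ----------
    trials : DataFrame
        Canonical trial table (pre-treated; only ``kept`` rows are used).
    spec : ModelSpec or str
        Which priming effects are free (e.g. ``"Model 8"``).
    priors : dict, optional
        Overrides merged into :func:`default_priors`.
    """

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec | str = "Model 8",
                 priors: dict | None = None):
        self.trials = validate_trials(trials)
        self.spec = get_model(spec) if isinstance(spec, str) else spec
        self.data = TrialData(self.trials)
        if self.data.n_trials == 0:
            raise ValueError("no kept trials to fit")
        all_pids = set(self.trials["participant_id"].astype(str))
        kept_pids = set(self.data.person_labels)
        if all_pids - kept_pids:
            raise ValueError("every participant must have at least one kept trial; "
                             f"none left for {sorted(all_pids - kept_pids)}")
        self.cols = ["a", "w", "v_living", "v_nonliving", "t0"] + \
            [c for f, c in _FLAG_TO_COL.items() if getattr(self.spec, f)]
        self.transforms = [TRANSFORM.get(c, 0) for c in self.cols]
        pri = default_priors()
        if priors:
            pri["mu"].update(priors.get("mu", {}))
            pri["sd"].update(priors.get("sd", {}))
        self.priors = pri

    @classmethod
    def from_dataframe(cls, trials, spec="Model 8", **kwargs) -> "HierarchicalDDM":
        return cls(trials, spec=spec, **kwargs)

    # -- initialization ------------------------------------------------
    def _initial_state(self):
        d = self.data
        K, n_p = len(self.cols), d.n_person
        raw = np.zeros((n_p, K))
        correct = (d.up == 1) == (d.living == 1)
        for i in range(n_p):
            sel = d.pidx == i
            vs, av, t0s = [], [], []
            for liv in (1, 0):
                s = sel & (d.living == liv)
                if s.sum() < 4:
                    continue
                rts = d.rt[s & correct]
                if rts.size < 3:
                    rts = d.rt[s]
                v, a, t0 = _ez_moments(correct[s].mean(), rts.var(), rts.mean(),
                                       int(s.sum()))
                vs.append(v if liv else -v)
                av.append(a)
                t0s.append(t0)
            a_i = np.mean(av) if av else 1.4
            v_liv = vs[0] if len(vs) > 0 else 2.0
            v_non = vs[1] if len(vs) > 1 else -2.0
            t0_i = min(0.9 * d.rt[sel].min(), np.mean(t0s) if t0s else 0.3)
            t0_i = float(np.clip(t0_i, 0.05, 1.0))
            for k, c in enumerate(self.cols):
                if c == "a":
                    raw[i, k] = np.log(a_i)
                elif c == "w":
                    raw[i, k] = 0.0
                elif c == "v_living":
                    raw[i, k] = v_liv
                elif c == "v_nonliving":
                    raw[i, k] = v_non
                elif c == "t0":
                    raw[i, k] = np.log(t0_i)
        init_mu = raw.mean(axis=0)
        sig0 = {"a": 0.15, "w": 0.15, "v_living": 0.4, "v_nonliving": 0.4,
                "t0": 0.1, "v_a": 0.05, "v_c": 0.1, "v_int": 0.05,
                "t0_a": 0.005, "t0_c": 0.005, "t0_int": 0.005, "w_c": 0.05}
        init_ls = np.log([sig0[c] for c in self.cols])
        init_z = np.clip((raw - init_mu) / np.exp(init_ls), -2.0, 2.0)
        for k, c in enumerate(self.cols):
            if c == "t0":
                # exact (unclipped): initial t0 must stay below each person's
                # fastest response or the likelihood is -inf at the start
                init_z[:, k] = (raw[:, k] - init_mu[k]) / np.exp(init_ls[k])
            elif c not in ("a", "w", "v_living", "v_nonliving"):
                init_z[:, k] = 0.0
        return init_mu, init_ls, init_z

    # -- likelihood surface (used by invariance tests and PPC) ---------
    def total_loglik(self, persons: list[PersonParams]) -> float:
        """Total log likelihood of the kept trials at fixed person values."""
        P = np.zeros((len(persons), len(PARAM_COLS)))
        for i, p in enumerate(persons):
            for j, c in enumerate(PARAM_COLS):
                P[i, j] = getattr(p, c if c != "v_int" else "v_int")
        return float(self.data.loglik(P, self.spec.start_cong).sum())

    # -- fitting -------------------------------------------------------
    def fit(self, config: FitConfig | None = None, **kwargs) -> "DDMResults":
        config = config if config is not None else FitConfig(**kwargs)
        init_mu, init_ls, init_z = self._initial_state()
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = []
        t_start = time.perf_counter()
        for c, ss in enumerate(seeds):
            chains.append(run_chain(
                self.data, self.cols, self.transforms,
                self.priors["mu"], self.priors["sd"],
                init_mu, init_ls, init_z,
                config.n_iter, config.n_warmup, ss,
                use_wc=self.spec.start_cong, store_loglik=config.store_loglik))
        wall = time.perf_counter() - t_start
        return DDMResults(self, config, chains, wall)


class DDMResults:
    """Posterior draws, diagnostics and predictive machinery for one fit."""

    def __init__(self, model: HierarchicalDDM, config: FitConfig, chains, wall_time):
        self.model = model
        self.spec = model.spec
        self.config = config
        self.wall_time = wall_time
        self.cols = model.cols
        # stack to (chain, draw, ...)
        self._mu = np.stack([c["mu"] for c in chains])
        self._ls = np.stack([c["log_sigma"] for c in chains])
        self._person = np.stack([c["person"] for c in chains])
        if chains[0]["loglik"] is not None:
            self._loglik = np.stack([c["loglik"] for c in chains])
        else:
            self._loglik = None
        self.draws = self._report_draws()

    # -- draws on reporting scales ------------------------------------
    def _report_draws(self) -> dict:
        out = {}
        for k, c in enumerate(self.cols):
            mu = self._mu[:, :, k]
            kind = self.model.transforms[k]
            if kind == 1:
                mu = np.exp(mu)
            elif kind == 2:
                mu = 1.0 / (1.0 + np.exp(-mu))
            out[REPORT_NAMES[c]] = mu
            out["sigma_" + c] = np.exp(self._ls[:, :, k])
        return out

    @property
    def log_likelihood(self) -> np.ndarray:
        """Pointwise log likelihood, shape (total draws, kept trials)."""
        if self._loglik is None:
            raise ValueError("fit was run with store_loglik=False")
        return self._loglik.reshape(-1, self._loglik.shape[-1])

    def person_draws(self, flat: bool = False) -> np.ndarray:
        """Person-parameter draws, (chain, draw, person, column) on natural
        scales (or flattened over chains)."""
        return self._person.reshape(-1, *self._person.shape[2:]) if flat else self._person

    def to_draws_frame(self) -> pd.DataFrame:
        """Tabular draws: one row per draw with chain/iteration indices."""
        n_chain, n_draw = self._mu.shape[:2]
        recs = {"chain": np.repeat(np.arange(n_chain), n_draw),
                "iteration": np.tile(np.arange(n_draw), n_chain)}
        for name, arr in self.draws.items():
            recs[name] = arr.reshape(-1)
        return pd.DataFrame(recs)

    # -- summaries -----------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and central 95% credible interval per fixed
        effect, rows in the canonical report order."""
        rows = []
        order = [REPORT_NAMES[c] for c in GROUP_FIELDS if c in self.cols]
        for name in order:
            x = self.draws[name].reshape(-1)
            rows.append((name, x.mean(), x.std(ddof=1),
                         np.quantile(x, 0.025), np.quantile(x, 0.975)))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "ci_2.5%", "ci_97.5%"]).set_index("parameter")

    def diagnostics(self, rhat_max: float = 1.01, ess_min: float = 400.0) -> pd.DataFrame:
        """Split-chain R-hat and bulk/tail ESS per group-level parameter,
        with pass/fail flags against the stated thresholds."""
        return convergence_table(self.draws, rhat_max=rhat_max, ess_min=ess_min)

    def loo(self) -> "_compare.LooResult":
        """PSIS leave-one-out cross-validation of this fit."""
        return _compare.psis_loo(self.log_likelihood)

    # -- posterior predictive ------------------------------------------
    def posterior_predictive(self, n_replicates: int = 100, rng=None,
                             quantiles=(0.1, 0.5, 0.9)) -> pd.DataFrame:
        """Observed vs. predicted accuracy and RT quantiles per design cell.

        Each replicate takes one posterior draw, simulates every kept trial
        from the diffusion process at that draw's person parameters, and
        accumulates per-cell statistics; the report gives the observed value,
        the predictive mean and a central 95% predictive interval, and flags
        cells whose observed statistic falls outside the interval.
        """
        if n_replicates == 0:
            return pd.DataFrame(columns=["target_type", "congruence", "association",
                                         "stat", "observed", "pred_mean",
                                         "pred_2.5%", "pred_97.5%", "flagged"])
        rng = np.random.default_rng(rng)
        d = self.model.data
        P_flat = self.person_draws(flat=True)
        picks = rng.integers(0, P_flat.shape[0], n_replicates)

        cells = list({(int(l), int(a), int(c)) for l, a, c in
                      zip(d.living, d.A, d.C)})
        cell_of_trial = {j: (int(d.living[j]), int(d.A[j]), int(d.C[j]))
                         for j in range(d.n_trials)}
        stats_names = ["accuracy"] + [f"rt_q{q:g}" for q in quantiles]

        def cell_stats(up, rt):
            correct = up if liv else ~up
            return [float(np.mean(correct))] + [float(np.quantile(rt, q)) for q in quantiles]

        # observed
        observed = {}
        for cell in cells:
            liv, A, C = cell
            sel = (d.living == liv) & (d.A == A) & (d.C == C)
            observed[cell] = cell_stats(d.up[sel] == 1, d.rt[sel])

        # predicted
        pred = {cell: [] for cell in cells}
        col_idx = {c: k for k, c in enumerate(self.cols)}
        for r in picks:
            P = P_flat[r]
            sim_up = np.empty(d.n_trials, dtype=bool)
            sim_rt = np.empty(d.n_trials)
            for i in range(d.n_person):
                psel = d.pidx == i
                for cell in cells:
                    liv, A, C = cell
                    sel = psel & (d.living == liv) & (d.A == A) & (d.C == C)
                    n = int(sel.sum())
                    if n == 0:
                        continue
                    wp = self._wiener_at(P[i], col_idx, liv, A, C)
                    up, rt, _ = simulate_wiener(wp, n, method="fast", rng=rng)
                    sim_up[sel] = up
                    sim_rt[sel] = rt
            for cell in cells:
                liv, A, C = cell
                sel = (d.living == liv) & (d.A == A) & (d.C == C)
                pred[cell].append(cell_stats(sim_up[sel], sim_rt[sel]))

        rows = []
        for cell in sorted(cells, reverse=True):
            liv, A, C = cell
            arr = np.array(pred[cell])
            for s, name in enumerate(stats_names):
                lo, hi = np.quantile(arr[:, s], [0.025, 0.975])
                obs = observed[cell][s]
                rows.append(("living" if liv else "nonliving",
                             "congruent" if C == 1 else "incongruent",
                             "associated" if A == 1 else "non-associated",
                             name, obs, arr[:, s].mean(), lo, hi,
                             not (lo <= obs <= hi)))
        return pd.DataFrame(rows, columns=["target_type", "congruence", "association",
                                           "stat", "observed", "pred_mean",
                                           "pred_2.5%", "pred_97.5%", "flagged"])

    def _wiener_at(self, P_i, col_idx, liv, A, C) -> WienerParams:
        """Per-trial Wiener parameters from one person-draw row."""
        def get(c, default=0.0):
            return float(P_i[col_idx[c]]) if c in col_idx else default
        e = get("v_a") * A + get("v_c") * C + get("v_int") * A * C
        v = get("v_living") + e if liv else get("v_nonliving") - e
        t0 = max(get("t0") + get("t0_a") * A + get("t0_c") * C + get("t0_int") * A * C,
                 1e-3)
        w = get("w", 0.5)
        if self.spec.start_cong:
            prime_living = bool(liv) if C == 1 else not bool(liv)
            lw = np.log(w / (1 - w)) + get("w_c") * (1.0 if prime_living else -1.0)
            w = float(1.0 / (1.0 + np.exp(-lw)))
        return WienerParams(a=get("a", 1.0), w=w, v=v, t0=t0)
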