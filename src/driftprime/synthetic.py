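"""Synthetic priming datasets with known ground truth.

Emulates the study design end to end: ``n_participants`` (default 44), each
seeing ``n_items`` target pictures (default 40, half living) four times, once
per (association x congruence) prime condition — 160 trials per participant.
Person-level parameters are drawn from group distributions (positive
parameters on the log scale, the starting point on the logit scale), each
trial's effective diffusion parameters follow the trial-level regression of
:mod:`driftprime.design`, and responses/RTs are generated from the Wiener
first-passage process.  The returned truth record carries the seed, the
group-level truth and every person-level value, so parameter-recovery tests
can score any fit against it.

Default group means are the posterior means reported for the winning model
of the original study (a = 1.398, w = 0.514, v_nonliving = -2.909,
v_living = 3.030, t0 = 0.296 s, drift effects v_a = 0.049, v_c = 0.264,
v_int = -0.018, non-decision-time effects -0.003 / 0.000 / -0.003 s).
Between-person SDs are configurable stand-ins (the study's random-effect
table lives in supplementary material): log/logit-scale SDs chosen to give
natural-scale spreads of roughly SD(a) ~ 0.28, SD(t0) ~ 0.05 s, drift
baseline SD 0.5, drift-slope SDs 0.05 except the congruence-on-drift slope
(0.3 — that effect showed large between-person variability), t0-slope SDs
0.01 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import (GROUP_FIELDS, GroupParams, ModelSpec, PersonParams,
                     T0_FLOOR, get_model, trial_params, validate_trials)
from .wfpt import WienerParams, simulate as simulate_wiener

__all__ = ["GeneratorConfig", "default_truth", "generate_dataset", "describe"]

_STUDY_MEANS = {
    "a": 1.398, "w": 0.514, "v_nonliving": -2.909, "v_living": 3.030,
    "t0": 0.296, "v_a": 0.049, "v_c": 0.264, "v_int": -0.018,
    "t0_a": -0.003, "t0_c": 0.000, "t0_int": -0.003, "w_c": 0.0,
}

_DEFAULT_SDS = {
    "a": 0.2,            # log scale  -> SD(a) ~ 0.28 around 1.4
    "w": 0.3,            # logit scale
    "v_nonliving": 0.5, "v_living": 0.5,
    "t0": 0.17,          # log scale  -> SD(t0) ~ 0.05 s around 0.3
    "v_a": 0.05, "v_c": 0.3, "v_int": 0.05,
    "t0_a": 0.01, "t0_c": 0.01, "t0_int": 0.01,
    "w_c": 0.05,         # logit scale
}


def default_truth() -> GroupParams:
    """Study-condition group truth (winning-model posterior means)."""
    return GroupParams(mean=dict(_STUDY_MEANS), sd=dict(_DEFAULT_SDS))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_participants: int = 44
    n_items: int = 40           # 40 items x 4 prime conditions = 160 trials
    spec: ModelSpec | str = "Model 8"
    truth: GroupParams = field(default_factory=default_truth)
    seed: int = 0
    p_fast_guess: float = 0.0   # contamination: uniform guesses on [0.05, 0.19] s
    p_lapse: float = 0.0        # contamination: lapses on [3.05, 8] s

    def __post_init__(self):
        if isinstance(self.spec, str):
            self.spec = get_model(self.spec)
        if self.n_items % 2:
            raise ValueError("n_items must be even (half living, half non-living)")


def _draw_person_params(cfg: GeneratorConfig, rng: np.random.Generator) -> list[PersonParams]:
    m, s = cfg.truth.mean, cfg.truth.sd
    n = cfg.n_participants
    loga = rng.normal(np.log(m["a"]), s.get("a", 0.0), n)
    lw = rng.normal(np.log(m["w"] / (1 - m["w"])), s.get("w", 0.0), n)
    logt0 = rng.normal(np.log(m["t0"]), s.get("t0", 0.0), n)
    cols = {"a": np.exp(loga), "w": 1 / (1 + np.exp(-lw)), "t0": np.exp(logt0)}
    for name in ("v_living", "v_nonliving", "v_a", "v_c", "v_int",
                 "t0_a", "t0_c", "t0_int", "w_c"):
        cols[name] = rng.normal(m.get(name, 0.0), s.get(name, 0.0), n)
    persons = [PersonParams(**{k: float(cols[k][i]) for k in cols}) for i in range(n)]
    # feasibility: effects must not drive any design cell's t0 to the floor
    for i, p in enumerate(persons):
        worst = p.t0 - abs(p.t0_a) - abs(p.t0_c) - abs(p.t0_int)
        if cfg.spec.t0_assoc or cfg.spec.t0_cong or cfg.spec.t0_interaction:
            if worst <= T0_FLOOR:
                raise ValueError(
                    f"infeasible truth: participant {i} has min per-trial t0 "
                    f"{worst:.4f} s <= floor (t0={p.t0:.4f}, effects too large)")
    return persons


def _design_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Balanced design: each item once per (A, C) cell, half the items living."""
    items = np.arange(cfg.n_items)
    target = np.where(items < cfg.n_items // 2, "living", "nonliving")
    rows = []
    for item, ttype in zip(items, target):
        for A in (-1, 1):
            for C in (-1, 1):
                rows.append((f"item{item:03d}", ttype, A, C))
    return pd.DataFrame(rows, columns=["item_id", "target_type", "association", "congruence"])


def generate_dataset(config: GeneratorConfig | None = None, **kwargs):
    """Generate one complete trial table plus its ground-truth record.

    Returns ``(trials, truth)``: a canonical trial table (one row per trial)
    and a dict with the seed, the generating model, group-level truth and a
    per-person parameter table.
    """
    cfg = config if config is not None else GeneratorConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    persons = _draw_person_params(cfg, rng)
    design = _design_table(cfg)

    frames = []
    for i, person in enumerate(persons):
        pid = f"p{i:03d}"
        df = design.copy()
        df.insert(0, "participant_id", pid)
        # trials within a (target type, A, C) cell share parameters: simulate per cell
        rts = np.empty(len(df))
        resp = np.empty(len(df), dtype=object)
        for (ttype, A, C), grp in df.groupby(["target_type", "association", "congruence"],
                                             sort=False):
            wp = trial_params({"target_type": ttype, "association": A, "congruence": C},
                              person, cfg.spec)
            up, rt, _ = simulate_wiener(wp, len(grp), method="fast", rng=rng)
            rts[grp.index] = rt
            resp[grp.index] = np.where(up, "living", "nonliving")
        df["response"] = resp
        df["rt_s"] = rts
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)

    # optional contamination, to exercise the pre-treatment stage
    n = len(trials)
    if cfg.p_fast_guess > 0:
        hit = rng.random(n) < cfg.p_fast_guess
        trials.loc[hit, "rt_s"] = rng.uniform(0.05, 0.19, int(hit.sum()))
        trials.loc[hit, "response"] = rng.choice(["living", "nonliving"], int(hit.sum()))
    if cfg.p_lapse > 0:
        hit = rng.random(n) < cfg.p_lapse
        trials.loc[hit, "rt_s"] = rng.uniform(3.05, 8.0, int(hit.sum()))

    trials = validate_trials(trials)
    truth = {
        "seed": cfg.seed,
        "model": cfg.spec.name,
        "n_participants": cfg.n_participants,
        "n_items": cfg.n_items,
        "group_mean": dict(cfg.truth.mean),
        "group_sd": dict(cfg.truth.sd),
        "persons": pd.DataFrame([asdict(p) for p in persons],
                                index=[f"p{i:03d}" for i in range(len(persons))]),
    }
    return trials, truth


def describe(trials: pd.DataFrame) -> pd.DataFrame:
    """Condition descriptives: accuracy % and RT mean/SD (ms) per cell.

    Accuracy is computed over kept trials; RT statistics over kept *correct*
    trials, displayed in milliseconds.  One row per (target type x congruence
    x association) cell, mirroring the layout of standard priming reports.
    """
    df = trials.copy()
    if "kept" in df.columns:
        df = df[df["kept"]]
    df["correct"] = df["response"] == df["target_type"]
    rows = []
    for ttype in ("living", "nonliving"):
        for C, cname in ((-1, "incongruent"), (1, "congruent")):
            for A, aname in ((1, "associated"), (-1, "non-associated")):
                cell = df[(df["target_type"] == ttype) & (df["congruence"] == C)
                          & (df["association"] == A)]
                if len(cell) == 0:
                    import warnings
                    warnings.warn(f"empty design cell {ttype}/{cname}/{aname}", stacklevel=2)
                    rows.append((ttype, cname, aname, np.nan, np.nan, np.nan))
                    continue
                acc = 100.0 * cell["correct"].mean()
                rt = cell.loc[cell["correct"], "rt_s"] * 1000.0
                rows.append((ttype, cname, aname, acc,
                             rt.mean() if len(rt) else np.nan,
                             rt.std(ddof=1) if len(rt) > 1 else np.nan))
    return pd.DataFrame(rows, columns=["target_type", "congruence", "association",
                                       "accuracy_pct", "rt_mean_ms", "rt_sd_ms"])
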