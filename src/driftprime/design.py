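"""Experimental design and trial-level parameter equations.

The experiment is a 2 (prime-target association, effect-coded A in {-1, +1})
x 2 (category congruence, C in {-1, +1}) x 2 (target type: living vs.
non-living) word-picture priming design with a living/non-living
categorization response.  Response coding is used throughout: the upper
diffusion boundary is the "living" response, the lower one "non-living".

Per-trial diffusion parameters for person ``i`` on trial ``j`` follow the
trial-level regression

    v_living(ij)     = v_living(i)     + e(ij)
    v_nonliving(ij)  = v_nonliving(i)  - e(ij)
    with  e(ij) = v_a(i) A(j) + v_c(i) C(j) + v_int(i) A(j) C(j)

    t0(ij) = t0(i) + t0a(i) A(j) + t0c(i) C(j) + t0int(i) A(j) C(j)

so that association and congruence always push the drift toward the correct
boundary (up for living, down for non-living targets).  A model variant
(ModelSpec) switches individual effects on or off; the canonical family of
ten variants ranges from the 5-parameter baseline (Model 0) to the full model
with starting-point bias (Model 9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .wfpt import WienerParams

__all__ = [
    "ModelSpec",
    "PersonParams",
    "GroupParams",
    "model_family",
    "get_model",
    "trial_params",
    "validate_trials",
    "TRIAL_COLUMNS",
    "T0_FLOOR",
]

#: canonical trial-table columns (delimited text interface)
TRIAL_COLUMNS = ["participant_id", "item_id", "target_type", "association",
                 "congruence", "response", "rt_s"]

#: per-trial non-decision time is clamped here if effects drive it negative
T0_FLOOR = 1e-3


@dataclass(frozen=True)
class ModelSpec:
    """Which priming effects a model variant allows."""

    name: str
    drift_assoc: bool = False
    drift_cong: bool = False
    drift_interaction: bool = False
    t0_assoc: bool = False
    t0_cong: bool = False
    t0_interaction: bool = False
    start_cong: bool = False

    @property
    def flags(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "name"}


def model_family() -> list[ModelSpec]:
    """The canonical ordered family of ten model variants.

    Model 0 is the baseline (no priming effects); Models 1-5 allow a single
    effect (association or congruence on drift, non-decision time, or
    starting point); Model 6 combines the best single-effect accounts; Model
    7 has all four main effects; Model 8 adds both interactions; Model 9
    additionally frees the starting point.
    """
    return [
        ModelSpec("Model 0"),
        ModelSpec("Model 1", drift_assoc=True),
        ModelSpec("Model 2", t0_assoc=True),
        ModelSpec("Model 3", drift_cong=True),
        ModelSpec("Model 4", t0_cong=True),
        ModelSpec("Model 5", start_cong=True),
        ModelSpec("Model 6", drift_cong=True, t0_assoc=True),
        ModelSpec("Model 7", drift_assoc=True, drift_cong=True,
                  t0_assoc=True, t0_cong=True),
        ModelSpec("Model 8", drift_assoc=True, drift_cong=True, drift_interaction=True,
                  t0_assoc=True, t0_cong=True, t0_interaction=True),
        ModelSpec("Model 9", drift_assoc=True, drift_cong=True, drift_interaction=True,
                  t0_assoc=True, t0_cong=True, t0_interaction=True, start_cong=True),
    ]


def get_model(name: str) -> ModelSpec:
    """Look up a family member by name ("Model 8") or short alias ("m8")."""
    fam = model_family()
    key = name.strip().lower().replace(" ", "")
    for spec in fam:
        if key in (spec.name.lower().replace(" ", ""), f"m{spec.name.split()[-1]}"):
            return spec
    raise KeyError(f"unknown model {name!r}; family: {[s.name for s in fam]}")


@dataclass
class PersonParams:
    """Person-level diffusion parameters (natural scales)."""

    a: float
    w: float
    v_living: float
    v_nonliving: float
    t0: float
    v_a: float = 0.0
    v_c: float = 0.0
    v_int: float = 0.0
    t0_a: float = 0.0
    t0_c: float = 0.0
    t0_int: float = 0.0
    w_c: float = 0.0  # starting-point shift on the logit scale (Models 5/9)


#: order of the fixed-effect (group mean) rows in summary tables
GROUP_FIELDS = ["a", "w", "v_nonliving", "v_living", "t0",
                "v_a", "v_c", "v_int", "t0_a", "t0_c", "t0_int", "w_c"]


@dataclass
class GroupParams:
    """Group means and between-person SDs of every person-level parameter.

    Means for ``a``, ``w`` and ``t0`` are on their natural scales; person
    values are generated/modelled on the log (a, t0) and logit (w) scales, so
    the matching SDs in ``sd`` are log/logit-scale SDs.
    """

    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self):
        for k in self.mean:
            if k not in GROUP_FIELDS:
                raise KeyError(f"unknown group parameter {k!r}")
        for k, s in self.sd.items():
            if s < 0:
                raise ValueError(f"group SD for {k!r} must be >= 0, got {s}")
        m = self.mean
        if "a" in m and m["a"] <= 0:
            raise ValueError("group mean a must be > 0")
        if "w" in m and not (0 < m["w"] < 1):
            raise ValueError("group mean w must be in (0,1)")
        if "t0" in m and m["t0"] < 0:
            raise ValueError("group mean t0 must be >= 0")


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def trial_params(trial, person: PersonParams, spec: ModelSpec) -> WienerParams:
    """Per-trial diffusion parameters for one trial (scalar reference path).

    ``trial`` is a mapping (e.g. a DataFrame row) with ``target_type``,
    ``association``, ``congruence``.  Effects whose flag is off in ``spec``
    are exactly 0.  The starting-point effect (Models 5/9) is coded by prime
    category: a living prime shifts ``w`` toward the living (upper) boundary
    on the logit scale.
    """
    A = float(trial["association"])
    C = float(trial["congruence"])
    if A not in (-1.0, 1.0) or C not in (-1.0, 1.0):
        raise ValueError(f"effect codes must be -1/+1, got A={A}, C={C}")
    living = trial["target_type"] == "living"

    e = 0.0
    if spec.drift_assoc:
        e += person.v_a * A
    if spec.drift_cong:
        e += person.v_c * C
    if spec.drift_interaction:
        e += person.v_int * A * C
    v = (person.v_living + e) if living else (person.v_nonliving - e)

    t0 = person.t0
    if spec.t0_assoc:
        t0 += person.t0_a * A
    if spec.t0_cong:
        t0 += person.t0_c * C
    if spec.t0_interaction:
        t0 += person.t0_int * A * C
    if t0 < T0_FLOOR:
        warnings.warn(f"per-trial t0 clamped to {T0_FLOOR} s", stacklevel=2)
        t0 = T0_FLOOR

    w = person.w
    if spec.start_cong:
        # prime category: equals target type iff congruent
        prime_living = living if C == 1.0 else not living
        P = 1.0 if prime_living else -1.0
        w = float(_expit(_logit(w) + person.w_c * P))

    try:
        return WienerParams(a=person.a, w=w, v=v, t0=t0)
    except ValueError as err:
        raise ValueError(f"invalid diffusion parameters for trial {dict(trial)}: {err}") from err


def validate_trials(df: pd.DataFrame, require_response: bool = True) -> pd.DataFrame:
    """Validate and normalize a canonical trial table.

    Checks column presence, effect codes, positive RTs and the consistency of
    target type with the congruence code; adds a ``kept`` flag column if
    missing and a ``prime_category`` convenience column.
    """
    required = [c for c in TRIAL_COLUMNS if require_response or c != "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    df = df.copy()
    df["association"] = df["association"].astype(int)
    df["congruence"] = df["congruence"].astype(int)
    for col in ("association", "congruence"):
        bad = ~df[col].isin([-1, 1])
        if bad.any():
            raise ValueError(f"{col} codes must be -1/+1; offending rows {df.index[bad][:5].tolist()}")
    if (df["rt_s"] <= 0).any():
        raise ValueError("rt_s must be > 0 for all trials")
    bad_type = ~df["target_type"].isin(["living", "nonliving"])
    if bad_type.any():
        raise ValueError("target_type must be 'living' or 'nonliving'")
    if require_response:
        bad_resp = ~df["response"].isin(["living", "nonliving"])
        if bad_resp.any():
            raise ValueError("response must be 'living' or 'nonliving'")
    other = {"living": "nonliving", "nonliving": "living"}
    df["prime_category"] = np.where(df["congruence"] == 1, df["target_type"],
                                    df["target_type"].map(other))
    if "kept" not in df.columns:
        df["kept"] = True
    # warn (not fail) on participants missing design cells
    cells = df.groupby("participant_id").apply(
        lambda g: g.groupby(["association", "congruence"]).size().shape[0],
        include_groups=False)
    degenerate = cells[cells < 4]
    if len(degenerate):
        warnings.warn(f"participants missing design cells: {list(degenerate.index)}",
                      stacklevel=2)
    return df
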