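"""Response-time pre-treatment.

Two filters, applied in a fixed order before any model fitting:

1. absolute bounds — trials faster than 200 ms or slower than 3 s are
   discarded (boundary values inclusive, i.e. kept);
2. per-participant Tukey fences on log RT — among the surviving trials of
   each participant, log RTs more than ``k = 1.5`` interquartile ranges below
   the first or above the third quartile are discarded (strict comparison:
   values exactly on a fence are kept).

Both filters flag trials via the ``kept`` column rather than dropping rows,
and return a :class:`FilterReport` whose counts are exactly reconstructible
from the flagged table.  The Tukey step runs once (no cascading re-passes);
its removal percentage is reported relative to the trials that survived the
bounds step, while the bounds percentage is relative to all input trials.
Quartiles use linear interpolation between order statistics; the log base is
irrelevant to fence membership (an affine change on the log scale) and the
natural log is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterReport", "filter_rt_bounds", "tukey_log_filter", "preprocess"]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Counts and percentages of removed trials for one filtering step."""

    step: str
    n_input: int
    n_removed: int
    fences: dict = field(default_factory=dict)  # participant -> (lo, hi), Tukey only

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {"step": self.step, "n_input": self.n_input,
                "n_removed": self.n_removed, "pct_removed": self.pct_removed,
                "fences": {str(k): list(v) for k, v in self.fences.items()}}


def filter_rt_bounds(trials: pd.DataFrame, lo: float = 0.2, hi: float = 3.0):
    """Flag trials with RT outside ``[lo, hi]`` seconds as not kept."""
    trials = trials.copy()
    if "kept" not in trials.columns:
        trials["kept"] = True
    n_input = len(trials)
    ok = trials["rt_s"].between(lo, hi, inclusive="both")
    removed = int((trials["kept"] & ~ok).sum())
    trials["kept"] = trials["kept"] & ok
    report = FilterReport("rt_bounds", n_input, removed)
    logger.info("rt bounds [%g, %g] s removed %d of %d trials (%.2f%%)",
                lo, hi, removed, n_input, report.pct_removed)
    return trials, report


def tukey_log_filter(trials: pd.DataFrame, k: float = 1.5, min_trials: int = 4,
                     correct_only: bool = False):
    """Flag per-participant log-RT outliers beyond the Tukey fences.

    Operates on currently kept trials only (apply after
    :func:`filter_rt_bounds`); participants with fewer than ``min_trials``
    kept trials are left unfiltered with a warning.  With ``correct_only``
    the filter is restricted to correct-response trials (requires
    ``response`` and ``target_type`` columns); by default all trials enter.
    """
    trials = trials.copy()
    if "kept" not in trials.columns:
        trials["kept"] = True
    eligible = trials["kept"].copy()
    if correct_only:
        eligible &= trials["response"] == trials["target_type"]
    n_input = int(eligible.sum())
    fences: dict = {}
    remove_idx = []
    for pid, grp in trials[eligible].groupby("participant_id"):
        if len(grp) < min_trials:
            warnings.warn(f"participant {pid!r}: only {len(grp)} kept trials, "
                          "Tukey filter skipped", stacklevel=2)
            continue
        logrt = np.log(grp["rt_s"].to_numpy())
        q1, q3 = np.quantile(logrt, [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        fences[pid] = (float(lo), float(hi))
        out = (logrt < lo) | (logrt > hi)  # strict: values on a fence are kept
        remove_idx.extend(grp.index[out])
    trials.loc[remove_idx, "kept"] = False
    report = FilterReport("tukey_log", n_input, len(remove_idx), fences=fences)
    logger.info("Tukey log-RT fences (k=%g) removed %d of %d trials (%.2f%%)",
                k, len(remove_idx), n_input, report.pct_removed)
    return trials, report


def preprocess(trials: pd.DataFrame, lo: float = 0.2, hi: float = 3.0,
               k: float = 1.5, exclude_participants=()) -> tuple[pd.DataFrame, list[FilterReport]]:
    """Full pre-treatment: drop excluded participants, bounds, then Tukey."""
    if len(exclude_participants):
        trials = trials[~trials["participant_id"].isin(exclude_participants)].copy()
    trials, rep1 = filter_rt_bounds(trials, lo=lo, hi=hi)
    trials, rep2 = tukey_log_filter(trials, k=k)
    return trials, [rep1, rep2]
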