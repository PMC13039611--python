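"""Reaction-time preprocessing: censoring, fast-guess removal, block pooling,
medians, and App-vs-Laptop technical-delay alignment.

Reaction times are measured from modulation onset.  Values above the 2.5 s
ceiling and non-responses are coded at exactly 2.5 s and flagged censored;
responses faster than 140 ms are removed as anticipatory (the floor is
exclusive: exactly 140 ms is retained).  Blocks are pooled after a
two-sample Kolmogorov-Smirnov homogeneity check, and the per-stimulus median
is taken over the pooled coded values.  The App implementation carries a
technical delay (audio streaming + touchscreen readout); it is estimated as
the group-level mean App-minus-Laptop difference of median RTs over three
well-perceived reference stimuli and subtracted from raw App RTs before the
censoring rules are re-applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .trial_sim import DELAY_REFERENCE_STIMULI

__all__ = [
    "preprocess",
    "block_homogeneity",
    "block_homogeneity_table",
    "pool_and_median",
    "estimate_delay",
    "DelayEstimate",
    "CEILING_S",
    "FLOOR_S",
]

CEILING_S = 2.5
FLOOR_S = 0.140

KEY = ["participant", "implementation", "stimulus_id"]


def preprocess(
    records: pd.DataFrame,
    ceiling_s: float = CEILING_S,
    floor_s: float = FLOOR_S,
    delay_s: float = 0.0,
    delay_implementation: str = "App",
) -> pd.DataFrame:
    """Apply the censoring and fast-guess rules to a trial table.

    Returns a clean long table with columns ``participant, implementation,
    stimulus_id, block, rt_s, censored``.  Rules:

    * ``delay_s`` is first subtracted from raw RTs of ``delay_implementation``
      (delay correction precedes the censor/floor re-check, so a corrected RT
      that falls below the floor is removed);
    * RTs above ``ceiling_s`` and non-responses are coded at the ceiling and
      flagged censored;
    * RTs strictly below ``floor_s`` are removed and counted (per-key counts
      in ``result.attrs["n_removed_fast"]``).

    Accepts either a raw trial table (``rt_raw_s``/``responded``) or its own
    output (the operation is idempotent).
    """
    df = records.copy()
    rt_col = "rt_s" if "rt_s" in df.columns else "rt_raw_s"
    rt = df[rt_col].to_numpy(dtype=float)
    if "responded" in df.columns:
        responded = df["responded"].to_numpy(dtype=bool)
    elif "censored" in df.columns:  # re-entrant: keep earlier censoring
        responded = ~df["censored"].to_numpy(dtype=bool)
    else:
        responded = ~np.isnan(rt)
    if np.any(rt[responded] < 0):
        raise ValueError("negative reaction times in input")
    if delay_s != 0.0:
        is_delayed = (df["implementation"] == delay_implementation).to_numpy()
        rt = np.where(is_delayed & responded, rt - delay_s, rt)
    censored = ~responded | (rt > ceiling_s)
    out = df[[c for c in KEY + ["block", "onset_s"] if c in df.columns]].copy()
    out["rt_s"] = np.where(censored, ceiling_s, rt)
    out["censored"] = censored
    fast = responded & ~censored & (rt < floor_s)
    removed = out[fast]
    out = out[~fast].reset_index(drop=True)
    out.attrs["n_removed_fast"] = (
        removed.groupby(KEY).size() if len(removed) else pd.Series(dtype=int)
    )
    out.attrs["n_removed_fast_total"] = int(fast.sum())
    return out


def block_homogeneity(rts_block1, rts_block2) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov check that two blocks share a distribution.

    Returns (D, asymptotic p).  The caller pools the blocks regardless of the
    outcome; the check flags stimuli whose blocks differ (e.g. procedural
    learning between blocks).
    """
    x = np.asarray(rts_block1, float)
    y = np.asarray(rts_block2, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both blocks need at least one response")
    res = ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def block_homogeneity_table(clean: pd.DataFrame) -> pd.DataFrame:
    """KS block check for every (participant, implementation, stimulus)."""
    rows = []
    for key, grp in clean.groupby(KEY):
        b1 = grp.loc[grp["block"] == 1, "rt_s"].to_numpy()
        b2 = grp.loc[grp["block"] == 2, "rt_s"].to_numpy()
        if len(b1) == 0 or len(b2) == 0:
            rows.append((*key, np.nan, np.nan))
            continue
        d, p = block_homogeneity(b1, b2)
        rows.append((*key, d, p))
    return pd.DataFrame(rows, columns=KEY + ["ks_d", "ks_p"])


def pool_and_median(clean: pd.DataFrame) -> pd.DataFrame:
    """Median RT per (participant, implementation, stimulus), blocks pooled.

    The median is computed over all pooled coded values, censored codes
    included (a censored code can therefore pull the median up to the
    ceiling, which is flagged rather than dropped).  Returns per key:
    ``median_rt_s``, ``median_promptness`` (1/median RT), trial counts, and a
    ``fully_censored`` flag.  A key with zero retained trials yields a
    missing value, not an error.
    """
    rows = []
    for key, grp in clean.groupby(KEY):
        rts = grp["rt_s"].to_numpy()
        if len(rts) == 0:
            rows.append((*key, np.nan, np.nan, 0, 0, False))
            continue
        med = float(np.median(rts))
        rows.append(
            (
                *key,
                med,
                1.0 / med if med > 0 else np.nan,
                len(rts),
                int(grp["censored"].sum()),
                bool(grp["censored"].all()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=KEY
        + ["median_rt_s", "median_promptness", "n_trials", "n_censored", "fully_censored"],
    )


@dataclass
class DelayEstimate:
    """Group-level technical delay with its per-participant breakdown."""

    delay_s: float
    per_difference: pd.DataFrame  # one row per (participant, reference stimulus)
    excluded_participants: list[str]

    def __float__(self) -> float:
        return self.delay_s


def estimate_delay(
    medians: pd.DataFrame,
    ref_stimuli: tuple[str, ...] = DELAY_REFERENCE_STIMULI,
    implementations: tuple[str, str] = ("App", "Laptop"),
) -> DelayEstimate:
    """Group-level App-minus-Laptop technical delay (s).

    For every participant and each of the three well-perceived reference
    stimuli, the difference of median RTs (first implementation minus second)
    is formed; the estimate is the mean over all such differences.
    Participants missing any reference median in either implementation are
    excluded from the estimate and listed.
    """
    wide = medians.pivot_table(
        index=["participant", "stimulus_id"],
        columns="implementation",
        values="median_rt_s",
    )
    a, b = implementations
    rows, excluded = [], []
    for participant, sub in wide.groupby(level="participant"):
        sub = sub.droplevel("participant")
        missing = [
            s
            for s in ref_stimuli
            if s not in sub.index
            or a not in sub.columns
            or b not in sub.columns
            or np.isnan(sub.loc[s, a])
            or np.isnan(sub.loc[s, b])
        ]
        if missing:
            excluded.append(participant)
            continue
        for s in ref_stimuli:
            rows.append((participant, s, float(sub.loc[s, a] - sub.loc[s, b])))
    diffs = pd.DataFrame(rows, columns=["participant", "stimulus_id", "difference_s"])
    if len(diffs) == 0:
        raise ValueError("no participant has all reference stimuli in both implementations")
    return DelayEstimate(
        delay_s=float(diffs["difference_s"].mean()),
        per_difference=diffs,
        excluded_participants=excluded,
    )
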