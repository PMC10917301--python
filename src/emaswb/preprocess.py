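"""Raw EMA rows -> analyzable day records.

Implements the standard reductions used in daily-diary alcohol studies:
first-report-of-day drink counts, a minimum-days inclusion rule, the
Anscombe variance-stabilizing transform of counts, next-day ("tonight")
lagging of the drinking outcome, and the per-person fraction of drinking
days spent drinking alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "anscombe",
    "build_day_records",
    "apply_exclusions",
    "lag_tonight",
    "alone_fraction",
    "moments",
    "Moments",
]

_DAY_KEY = ["participant_id", "wave", "day_index"]


def anscombe(x):
    """Anscombe transform ``2 * sqrt(x + 3/8)`` of a count (array-friendly).

    Strictly increasing on ``x >= 0``; negative input raises.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("anscombe requires nonnegative counts")
    out = 2.0 * np.sqrt(arr + 0.375)
    return out if arr.shape else float(out)


def build_day_records(ema: pd.DataFrame) -> pd.DataFrame:
    """Collapse prompt-level EMA rows into one record per participant-day.

    Drinks: the first non-missing report of the day (prompt order).
    Ratings: averaged over the day's answered prompts.  Texts: concatenated
    in prompt order.  The drinking-alone flag is the first non-missing
    answer.  Duplicate ``(participant, wave, day, prompt)`` keys raise.
    """
    key = _DAY_KEY + ["prompt_index"]
    if ema.duplicated(key).any():
        dupes = ema[ema.duplicated(key, keep=False)][key].head()
        raise ValueError(f"duplicate prompt keys in EMA table:\n{dupes}")
    ema = ema.sort_values(key, kind="mergesort")

    def first_valid(s: pd.Series):
        s = s.dropna()
        if "NA" in getattr(s, "values", []):
            s = s[s != "NA"]
        return s.iloc[0] if len(s) else np.nan

    grouped = ema.groupby(_DAY_KEY, sort=True)
    days = grouped.agg(
        drinks_yesterday=("drinks_24h", first_valid),
        alone=("alone", first_valid),
        valence=("valence", "mean"),
        stress=("stress", "mean"),
        burnout=("burnout", "mean"),
        n_prompts=("prompt_index", "size"),
        text=("text", lambda s: " ".join(t for t in s.dropna() if t)),
    ).reset_index()
    days["alone"] = days["alone"].fillna("NA")
    days["anscombe_drinks"] = anscombe(days["drinks_yesterday"].to_numpy(float))
    return days


def apply_exclusions(days: pd.DataFrame, min_ema_days: int = 4
                     ) -> tuple[pd.DataFrame, dict]:
    """Drop participants with fewer than ``min_ema_days`` recorded days.

    Returns the filtered table and a report of participants/days before and
    after.  Idempotent: re-applying to its own output changes nothing.
    """
    n_days = days.groupby("participant_id")["day_index"].size()
    keep = n_days[n_days >= min_ema_days].index
    out = days[days["participant_id"].isin(keep)].reset_index(drop=True)
    report = {
        "min_ema_days": int(min_ema_days),
        "participants_before": int(n_days.size),
        "participants_after": int(len(keep)),
        "participants_excluded": int(n_days.size - len(keep)),
        "days_before": int(len(days)),
        "days_after": int(len(out)),
    }
    return out, report


def lag_tonight(days: pd.DataFrame) -> pd.DataFrame:
    """Pair day-n features with day-(n+1) reported drinks ("tonight").

    Because drinks are reported for the past 24 hours, the drinks a person
    reports on day n+1 were consumed on the evening of day n; pairing day-n
    affect and language with them captures drinking *tonight*.  Pairs are
    only formed for consecutive day indices within the same participant and
    wave; the last observed day of a wave yields no pair.
    """
    nxt = days[_DAY_KEY + ["drinks_yesterday", "anscombe_drinks", "alone"]].copy()
    nxt["day_index"] = nxt["day_index"] - 1
    nxt = nxt.rename(columns={
        "drinks_yesterday": "drinks_tonight",
        "anscombe_drinks": "anscombe_tonight",
        "alone": "alone_tonight",
    })
    out = days.merge(nxt, on=_DAY_KEY, how="inner")
    return out.reset_index(drop=True)


def alone_fraction(days: pd.DataFrame, min_drinking_days: int = 3) -> pd.DataFrame:
    """Per-person fraction of drinking days spent drinking alone.

    Only days with an observed alone flag count (waves where the question
    was asked and drinks >= 1).  Persons with fewer than
    ``min_drinking_days`` observed drinking days are flagged ``included =
    False``; persons with zero drinking days are excluded, never 0/0.
    """
    flagged = days[days["alone"].isin(["alone", "others"])]
    grp = flagged.groupby("participant_id")["alone"]
    n_drink = grp.size()
    n_alone = grp.apply(lambda s: int((s == "alone").sum()))
    out = pd.DataFrame({
        "participant_id": n_drink.index,
        "n_drinking_days": n_drink.to_numpy(),
        "n_alone_days": n_alone.to_numpy(),
    })
    out["alone_fraction"] = out["n_alone_days"] / out["n_drinking_days"]
    out["included"] = out["n_drinking_days"] >= min_drinking_days
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class Moments:
    mean: float
    sd: float
    median: float
    skewness: float
    kurtosis: float
    n: int


def moments(values) -> Moments:
    """Sample moments: mean, sd (n-1), median, Fisher skewness g1 and excess
    kurtosis g2.

    A constant vector returns skewness/kurtosis 0 by convention.  Fewer than
    3 observations raise, as the higher moments are undefined.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("moments requires at least 3 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        sk = ku = 0.0
    else:
        sk = float(stats.skew(x, bias=True))
        ku = float(stats.kurtosis(x, bias=True))
    return Moments(mean=float(np.mean(x)), sd=sd, median=float(np.median(x)),
                   skewness=sk, kurtosis=ku, n=int(x.size))
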