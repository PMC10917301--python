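"""Composite subjective well-being scores and reliability statistics.

The composite SWB score combines a momentary, affective component (EMA
valence minus the average of stress and burnout) with a baseline component
(positive affect and Cantril ladder minus negative affect and depression),
all inputs z-transformed first:

    momentary SWB = z(valence) - mean(z(stress), z(burnout))
    baseline SWB  = mean(z(PA), z(Cantril)) - mean(z(NA), z(PHQ-9))
    SWB           = mean(momentary SWB, baseline SWB)

Missing elements are simply dropped from the enclosing mean, so the score
degrades gracefully down to a single available input; only a fully missing
profile is undefined.

Reliability helpers: Cronbach's alpha, McDonald's omega (one-factor fit),
the one-way random-effects intraclass correlation ICC(1), and test-retest
correlation across waves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "zscore",
    "momentary_swb",
    "baseline_swb",
    "composite_swb",
    "CompositeSwb",
    "score_persons",
    "cronbach_alpha",
    "mcdonald_omega",
    "icc_1",
    "test_retest",
]


def zscore(values, ddof: int = 0):
    """Standardize to mean 0, sd 1 over the scoring population.

    Uses the population sd (``ddof=0``) by default so that a three-point
    grid like [1, 2, 3] maps to [-1.2247, 0, 1.2247]; pass ``ddof=1`` for
    the sample-sd variant.  NaNs pass through; zero variance raises.
    """
    x = np.asarray(values, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=ddof)
    if not np.isfinite(s) or s == 0.0:
        raise ValueError("zscore undefined for zero-variance input")
    return (x - m) / s


def _nanmean_parts(*parts):
    vals = [p for p in parts if p is not None and np.isfinite(p)]
    return float(np.mean(vals)) if vals else np.nan


def momentary_swb(z_valence, z_stress=None, z_burnout=None) -> float:
    """``z_valence - mean(z_stress, z_burnout)``, missing parts dropped."""
    if z_valence is None or not np.isfinite(z_valence):
        return np.nan
    neg = _nanmean_parts(z_stress, z_burnout)
    return float(z_valence) - (neg if np.isfinite(neg) else 0.0)


def baseline_swb(z_pa=None, z_cantril=None, z_na=None, z_phq9=None) -> float:
    """``mean(z_pa, z_cantril) - mean(z_na, z_phq9)``, missing parts dropped."""
    pos = _nanmean_parts(z_pa, z_cantril)
    neg = _nanmean_parts(z_na, z_phq9)
    if not np.isfinite(pos) and not np.isfinite(neg):
        return np.nan
    return (pos if np.isfinite(pos) else 0.0) - (neg if np.isfinite(neg) else 0.0)


@dataclass(frozen=True)
class CompositeSwb:
    momentary: float
    baseline: float
    swb: float


def composite_swb(z_valence=None, z_stress=None, z_burnout=None,
                  z_pa=None, z_cantril=None, z_na=None, z_phq9=None
                  ) -> CompositeSwb:
    """Full composite from (standardized) parts; missing-tolerant.

    Raises if all seven inputs are missing.
    """
    mom = momentary_swb(z_valence, z_stress, z_burnout) \
        if z_valence is not None and np.isfinite(z_valence) else np.nan
    base = baseline_swb(z_pa, z_cantril, z_na, z_phq9)
    swb = _nanmean_parts(mom if np.isfinite(mom) else None,
                         base if np.isfinite(base) else None)
    if not np.isfinite(swb):
        raise ValueError("composite SWB undefined: all components missing")
    return CompositeSwb(momentary=mom, baseline=base, swb=swb)


def score_days(days: pd.DataFrame) -> pd.DataFrame:
    """Add a day-level momentary SWB column to a day-record table.

    Valence, stress and burnout day means are z-scored across all
    person-days, then combined as ``z_valence - mean(z_stress, z_burnout)``
    with missing parts dropped.
    """
    out = days.copy()
    z = {}
    for col in ("valence", "stress", "burnout"):
        x = out[col].to_numpy(float)
        m, s = np.nanmean(x), np.nanstd(x, ddof=0)
        z[col] = (x - m) / s if s > 0 else np.full_like(x, np.nan)
    neg = pd.DataFrame({"s": z["stress"], "b": z["burnout"]}).mean(axis=1).to_numpy()
    mom = z["valence"] - np.where(np.isfinite(neg), neg, 0.0)
    out["momentary_swb"] = np.where(np.isfinite(z["valence"]), mom, np.nan)
    return out


def score_persons(days: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Person-level SWB table from day records and baseline surveys.

    Momentary ratings are averaged per person, then z-scored across
    persons; baseline scales are averaged across a person's waves, then
    z-scored.  Stress/burnout and the depression/negative-affect block
    enter negatively per the composite definition.
    """
    pm = days.groupby("participant_id")[["valence", "stress", "burnout"]].mean()
    bm = baseline.groupby("participant_id")[
        ["panas_pos", "panas_neg", "cantril", "phq9", "ucla3", "audit", "age"]
    ].mean()
    gender = baseline.groupby("participant_id")["gender"].first()
    df = pm.join(bm, how="outer")

    z = {}
    for col in ("valence", "stress", "burnout", "panas_pos", "panas_neg",
                "cantril", "phq9"):
        x = df[col].to_numpy(float)
        m, s = np.nanmean(x), np.nanstd(x, ddof=0)
        z[col] = (x - m) / s if s > 0 else np.full_like(x, np.nan)

    def _pairmean(a, b):
        return pd.DataFrame({"a": a, "b": b}).mean(axis=1).to_numpy()

    neg_mom = _pairmean(z["stress"], z["burnout"])
    mom = z["valence"] - np.where(np.isfinite(neg_mom), neg_mom, 0.0)
    mom = np.where(np.isfinite(z["valence"]), mom, np.nan)
    pos = _pairmean(z["panas_pos"], z["cantril"])
    neg = _pairmean(z["panas_neg"], z["phq9"])
    base = np.where(np.isfinite(pos), pos, 0.0) - np.where(np.isfinite(neg), neg, 0.0)
    base = np.where(np.isfinite(pos) | np.isfinite(neg), base, np.nan)
    swb = np.nanmean(np.column_stack([mom, base]), axis=1)

    out = pd.DataFrame({
        "participant_id": df.index,
        "momentary_swb": mom,
        "baseline_swb": base,
        "swb": swb,
        "audit": df["audit"].to_numpy(float),
        "ucla3": df["ucla3"].to_numpy(float),
        "age": df["age"].to_numpy(float),
    })
    out["gender"] = out["participant_id"].map(gender)
    return out.reset_index(drop=True)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an (observations x items) matrix."""
    X = np.asarray(items, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("alpha needs >= 2 items and >= 3 observations")
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total variance")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def mcdonald_omega(items: np.ndarray) -> float:
    """McDonald's omega-total from a single-factor ML fit.

    Items are standardized, a one-factor model is fit by maximum
    likelihood, and ``omega = (sum lambda)^2 / ((sum lambda)^2 +
    sum(1 - lambda^2))``.  Heywood loadings (|lambda| > 1) are clipped.
    """
    from sklearn.decomposition import FactorAnalysis

    X = np.asarray(items, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("omega needs >= 2 items and >= 3 observations")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("omega undefined: zero-variance item")
    Z = (X - X.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=1, random_state=0)
    fa.fit(Z)
    lam = fa.components_[0]
    if lam.sum() < 0:          # sign indeterminacy of the factor
        lam = -lam
    lam = np.clip(lam, -1.0, 1.0)
    num = lam.sum() ** 2
    return float(num / (num + np.sum(1.0 - lam ** 2)))


def icc_1(values, groups) -> float:
    """One-way random-effects intraclass correlation ICC(1).

    ``(MSB - MSW) / (MSB + (k0 - 1) MSW)`` with the unbalanced-design
    ``k0 = (N - sum(n_i^2)/N) / (G - 1)``.  Requires >= 2 groups and at
    least one group with >= 2 observations.
    """
    df = pd.DataFrame({"g": np.asarray(groups), "y": np.asarray(values, float)})
    df = df.dropna()
    sizes = df.groupby("g")["y"].size()
    G, N = sizes.size, int(sizes.sum())
    if G < 2 or N - G < 1:
        raise ValueError("ICC(1) needs >= 2 groups and within-group replicates")
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (G - 1)
    msw = ssw / (N - G)
    k0 = (N - float((sizes ** 2).sum()) / N) / (G - 1)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return float(max(icc, -1.0))


def test_retest(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation over the participant intersection of two waves."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("test-retest needs >= 3 matched pairs")
    return float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
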