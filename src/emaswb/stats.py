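"""Within/between-person inference.

Within-person analyses center every variable on the person's own mean and
pool the centered deviations; the Pearson correlation of pooled centered
pairs equals the standardized fixed-effect slope of the corresponding
stage-wise multilevel model.  Significance of within-person correlations
comes from a permutation distribution that shuffles the outcome within each
person's own days, preserving the within-person design.  Dependent
correlations sharing one variable are compared with Steiger's Z, group
deviations from the grand mean with one-sample t tests, and multiple
comparisons across topic families with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "within_center",
    "fixed_effect_r",
    "permutation_p",
    "steiger_test",
    "compare_dependent_accuracies",
    "group_deviation_test",
    "std_multiple_regression",
    "bh_correct",
]


def within_center(df: pd.DataFrame, cols, group: str = "participant_id"
                  ) -> pd.DataFrame:
    """Subtract each person's own mean from the listed columns.

    Persons with a single observation contribute zeros (flagged in the
    ``_single_obs`` column).  Centered columns keep their names.
    """
    counts = df.groupby(group)[group].transform("size")
    means = df.groupby(group)[list(cols)].transform("mean")
    out = df.copy()
    out[list(cols)] = df[list(cols)] - means
    flag = pd.Series((counts == 1).to_numpy(), index=out.index,
                     name="_single_obs")
    return pd.concat([out, flag], axis=1)


def fixed_effect_r(x, y) -> float:
    """Pearson r of pooled (centered) pairs; NaN-pairs dropped.

    Equals the standardized slope of pooled OLS of y on x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a correlated variable")
    return float(np.corrcoef(x, y)[0, 1])


def permutation_p(x, y, groups, n_perm: int = 20000, seed: int = 0,
                  chunk: int = 500) -> float:
    """Two-tailed permutation p-value for the pooled within-person r.

    The outcome is shuffled within each person's own observations, which
    leaves person means (and hence the centering) intact, so only the
    cross-products change.  ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    g = np.asarray(groups)
    if not (x.shape == y.shape == g.shape):
        raise ValueError("x, y and groups must be aligned")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, g = x[ok], y[ok], g[ok]
    order = np.argsort(g, kind="stable")
    x, y, g = x[order], y[order], g[order]
    # within-group centering so the dot product is the only moving part
    df = pd.DataFrame({"g": g})
    for name, v in (("x", x), ("y", y)):
        df[name] = v
        df[name] -= df.groupby("g")[name].transform("mean")
    xc = df["x"].to_numpy()
    yc = df["y"].to_numpy()
    obs = abs(float(xc @ yc))

    gid = pd.factorize(g)[0].astype(np.float64)
    rng = np.random.default_rng(seed)
    n = xc.size
    hits = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = gid[None, :] * 2.0 + rng.random((m, n))
        perm = np.argsort(keys, axis=1, kind="stable")
        stat = np.abs(yc[perm] @ xc)
        hits += int((stat >= obs - 1e-12).sum())
        done += m
    return (1 + hits) / (n_perm + 1)


@dataclass(frozen=True)
class SteigerResult:
    z: float
    p: float


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> SteigerResult:
    """Steiger's Z for two dependent correlations sharing variable j.

    Uses Fisher z-transforms with the pooled-r covariance term; two-tailed
    normal p.  The implied 3x3 correlation matrix must be positive
    definite.
    """
    R = np.array([[1, r_jk, r_jh], [r_jk, 1, r_kh], [r_jh, r_kh, 1]])
    if np.any(np.abs([r_jk, r_jh, r_kh]) >= 1):
        raise ValueError("correlations must lie in (-1, 1)")
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError("correlation triple is not positive definite")
    if n < 4:
        raise ValueError("need n >= 4")
    zjk = np.arctanh(r_jk)
    zjh = np.arctanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    psi = r_kh * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * \
        (1 - 2 * rbar ** 2 - r_kh ** 2)
    sbar = psi / (1 - rbar ** 2) ** 2
    z = (zjk - zjh) * np.sqrt((n - 3) / (2.0 * (1 - sbar)))
    p = 2 * sps.norm.sf(abs(z))
    return SteigerResult(z=float(z), p=float(max(p, np.finfo(float).tiny)))


def compare_dependent_accuracies(r_jk: float, r_jh: float, r_kh: float,
                                 n_jk: int, n_jh: int) -> SteigerResult:
    """Compare two predictive accuracies (|r|) of the same outcome.

    Accuracies enter as magnitudes and the effective n is the floor of the
    mean of the two analyses' sample sizes.
    """
    n_eff = int(np.floor((n_jk + n_jh) / 2.0))
    return steiger_test(abs(r_jk), abs(r_jh), r_kh, n_eff)


@dataclass(frozen=True)
class GroupDeviation:
    mean: float
    se: float
    t: float
    p: float
    n: int


def group_deviation_test(group_scores, grand_mean: float) -> GroupDeviation:
    """One-sample t test of a group's scores against the grand mean."""
    x = np.asarray(group_scores, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("group deviation test needs n >= 2")
    se = x.std(ddof=1) / np.sqrt(x.size)
    t, p = sps.ttest_1samp(x, grand_mean)
    return GroupDeviation(mean=float(x.mean()), se=float(se), t=float(t),
                          p=float(p), n=int(x.size))


def std_multiple_regression(y, X: pd.DataFrame) -> dict:
    """Standardized multiple regression via the correlation-matrix solve.

    Returns standardized betas, their p-values, adjusted R-squared and the
    multiple correlation r.  Predictor matrix must be full rank.
    """
    Xd = pd.DataFrame(X).astype(float)
    yv = np.asarray(y, float)
    ok = np.isfinite(yv) & np.isfinite(Xd.to_numpy()).all(axis=1)
    Xd, yv = Xd[ok], yv[ok]
    n, p = Xd.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    Z = (Xd - Xd.mean()) / Xd.std(ddof=1)
    zy = (yv - yv.mean()) / yv.std(ddof=1)
    Rxx = np.corrcoef(Z.to_numpy(), rowvar=False)
    if p > 1 and np.linalg.cond(Rxx) > 1e10:
        raise ValueError("predictor matrix is (near-)singular")
    rxy = np.array([np.corrcoef(Z[c], zy)[0, 1] for c in Z.columns])
    Rxx = np.atleast_2d(Rxx)
    betas = np.linalg.solve(Rxx, rxy)
    r2 = float(rxy @ betas)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    # standardized-coefficient t tests
    mse = (1.0 - r2) / (n - p - 1)
    inv = np.linalg.inv(Rxx)
    se = np.sqrt(mse * np.diag(inv))
    tvals = betas / se
    pvals = 2 * sps.t.sf(np.abs(tvals), df=n - p - 1)
    return {
        "betas": dict(zip(Xd.columns, betas.tolist())),
        "p_values": dict(zip(Xd.columns, pvals.tolist())),
        "r2": r2,
        "r2_adj": float(r2_adj),
        "r": float(np.sqrt(max(r2, 0.0))),
        "n": int(n),
    }


def bh_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    flags = np.zeros(m, dtype=bool)
    if below.size:
        flags[order[: below[-1] + 1]] = True
    return flags
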