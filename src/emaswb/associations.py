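"""Differential language analysis: topic-outcome associations.

Each LDA topic's usage is correlated with a drinking outcome at the
between-person level (partial correlation controlling for age and gender)
or the within-person level (person-mean-centered usage and outcome; the
demographic covariates are constants within person and drop out of the
centering).  Benjamini-Hochberg correction is applied per outcome-by-level
family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .language import TopicModel
from .stats import bh_correct, within_center

__all__ = [
    "partial_correlation",
    "associate_topics",
    "rank_topic_words",
]


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing on covariates.

    With no covariates this is the plain Pearson correlation.  The p-value
    uses a t reference with ``n - 2 - c`` degrees of freedom.  The
    covariate matrix must be full rank.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0) \
            or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.ones((x.size, 1))
        c = 0
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(x.size), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")
        c = C.shape[1]
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(Z).all(axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    n = x.size
    if n - 2 - c < 1:
        raise ValueError("too few observations for the partial correlation")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a variable lying in the covariate span has (numerically) no residual
    # variance left: its partial correlation with anything is exactly 0
    if rx.var() <= 1e-14 * max(x.var(), 1e-30) or \
            ry.var() <= 1e-14 * max(y.var(), 1e-30):
        return 0.0, 1.0
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - c
    r_ = min(max(r, -0.999999999), 0.999999999)
    t = r_ * np.sqrt(df / (1 - r_ * r_))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def associate_topics(usage: pd.DataFrame, outcome: pd.Series,
                     covariates: pd.DataFrame | None = None,
                     level: str = "between", q: float = 0.05,
                     person_ids=None) -> pd.DataFrame:
    """Correlate every topic's usage with an outcome.

    ``level='between'``: rows are persons; partial correlations adjust for
    the covariates (age, gender).  ``level='within'``: rows are person-days
    and ``person_ids`` must map rows to persons; usage columns and the
    outcome are within-person centered first and no covariate adjustment is
    applied.  Topics with zero variance are skipped.  BH flags are computed
    over the family of tested topics.
    """
    X = usage.to_numpy(float)
    yv = np.asarray(outcome, float)
    if X.shape[0] != yv.shape[0]:
        raise ValueError("usage and outcome are misaligned")
    if np.nanstd(yv) == 0:
        raise ValueError("outcome has zero variance")

    cov = None
    if level == "within":
        if person_ids is None:
            raise ValueError("within-level associations need person_ids")
        frame = pd.DataFrame(X, columns=usage.columns)
        frame["_y"] = yv
        frame["participant_id"] = np.asarray(person_ids)
        centered = within_center(frame, list(usage.columns) + ["_y"])
        X = centered[usage.columns].to_numpy(float)
        yv = centered["_y"].to_numpy(float)
    elif level == "between":
        if covariates is not None:
            cov = np.asarray(covariates, float)
    else:
        raise ValueError("level must be 'between' or 'within'")

    rows = []
    for j, name in enumerate(usage.columns):
        xj = X[:, j]
        if np.nanstd(xj) == 0:
            rows.append((name, np.nan, np.nan, False))
            continue
        r, p = partial_correlation(xj, yv, cov)
        rows.append((name, r, p, True))
    out = pd.DataFrame(rows, columns=["topic", "r", "p", "tested"])
    flags = np.zeros(len(out), dtype=bool)
    tested = out["tested"].to_numpy()
    if tested.any():
        flags[tested] = bh_correct(out.loc[tested, "p"].to_numpy(), q=q)
    out["bh_significant"] = flags
    out["level"] = level
    return out.drop(columns="tested")


def rank_topic_words(model: TopicModel, topic: int, m: int = 6) -> list[dict]:
    """Display-ready ranked word list for one topic (ties lexicographic)."""
    return [{"word": w, "weight": wt, "rank": i + 1}
            for i, (w, wt) in enumerate(model.top_words(topic, m=m))]
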