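import numpy as np
import pandas as pd
import pytest

from emaswb import preprocess as pp
from emaswb import scoring
from emaswb.synthetic_data import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-person cohort shared across tests (read-only)."""
    cfg = CohortConfig(n_participants=150, seed=11)
    baseline, ema = simulate_cohort(cfg)
    return cfg, baseline, ema


@pytest.fixture(scope="session")
def day_records(small_cohort):
    _, _, ema = small_cohort
    days = pp.build_day_records(ema)
    days, _ = pp.apply_exclusions(days)
    return scoring.score_days(days)


@pytest.fixture(scope="session")
def person_scores(small_cohort, day_records):
    _, baseline, _ = small_cohort
    return scoring.score_persons(day_records, baseline)


@pytest.fixture()
def tiny_ema():
    """Hand-written prompt-level EMA rows exercising the reduction rules."""
    rows = [
        # pid, wave, day, prompt, drinks, alone, valence, stress, burnout, text
        ("A", 1, 1, 1, 2.0, "NA", 0.2, 1.0, 2.0, "sad and down"),
        ("A", 1, 1, 2, 5.0, "NA", 0.4, np.nan, np.nan, "work shift"),
        ("A", 1, 1, 3, 1.0, "NA", 0.6, 3.0, 4.0, "calm now"),
        ("A", 1, 2, 1, np.nan, "NA", 0.5, 2.0, 2.0, "fine"),
        ("A", 1, 2, 2, 3.0, "NA", 0.7, np.nan, np.nan, "good day"),
        ("A", 1, 3, 1, 0.0, "NA", 0.1, 4.0, 5.0, "rough"),
        ("B", 2, 1, 1, 2.0, "alone", 0.3, 2.0, 2.0, "lonely night"),
        ("B", 2, 2, 1, 4.0, "others", 0.8, 1.0, 1.0, "friends dinner"),
        ("B", 2, 3, 1, 1.0, "alone", 0.2, 3.0, 3.0, "sad again"),
    ]
    return pd.DataFrame(rows, columns=[
        "participant_id", "wave", "day_index", "prompt_index", "drinks_24h",
        "alone", "valence", "stress", "burnout", "text"])
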