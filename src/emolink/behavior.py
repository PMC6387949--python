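"""Behavioral measures: intensity ratings, shoot/don't-shoot accuracy,
signal-detection rates, and adjective-checklist anxiety scoring.

Trial outcomes use the standard signal-detection categories: hit (H, shot
a foe), miss (M, failed to shoot a foe), false alarm (FA, shot a friendly),
correct rejection (CR, withheld fire from a friendly). Accuracy is the raw
proportion (H + CR) / N. The anxiety raw score counts endorsed adjectives
from a 10-item subscale; conversion to standard T-scores requires a
user-supplied norm table (the published norms are proprietary and are not
shipped or approximated).
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "DEFAULT_ANXIETY_SUBSCALE",
    "mean_intensity",
    "accuracy",
    "sdt_rates",
    "anxiety_raw",
    "anxiety_tscore",
]

CATEGORIES: tuple[str, ...] = ("H", "M", "FA", "CR")

#: Ten anxiety adjectives: the six published example items plus four
#: common checklist anxiety words completing the 10-item scale. The scale
#: is a parameter everywhere; substitute the licensed item list when
#: scoring real questionnaires.
DEFAULT_ANXIETY_SUBSCALE: tuple[str, ...] = (
    "afraid", "fearful", "frightened", "panicky", "shaky", "tense",
    "nervous", "terrified", "upset", "worrying",
)


def mean_intensity(ratings: pd.DataFrame) -> pd.Series:
    """Per-condition mean of 1-9 intensity ratings.

    ``ratings`` needs columns ``condition`` and ``rating``; missing ratings
    are excluded with a logged count. Trial order does not matter.
    """
    df = ratings.copy()
    n_missing = int(df["rating"].isna().sum())
    if n_missing:
        logger.info("mean_intensity: excluding %d missing ratings", n_missing)
        df = df.dropna(subset=["rating"])
    vals = df["rating"].to_numpy(dtype=float)
    if np.any((vals < 1) | (vals > 9)):
        raise ValueError("ratings must lie in [1, 9]")
    return df.groupby("condition")["rating"].mean()


def _counts(outcomes: Sequence[str]) -> Counter:
    c = Counter(outcomes)
    unknown = set(c) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown outcome categories: {sorted(unknown)}")
    return c


def accuracy(outcomes: Sequence[str], n: int | None = None) -> float:
    """(H + CR) / N. ``n`` defaults to the number of trials supplied."""
    c = _counts(outcomes)
    total = n if n is not None else len(outcomes)
    if total == 0:
        raise ValueError("cannot compute accuracy with N = 0 trials")
    return (c["H"] + c["CR"]) / total


def sdt_rates(outcomes: Sequence[str]) -> dict[str, float]:
    """Hit rate, false-alarm rate, and log-linear-corrected d-prime.

    Rates are raw proportions (H/(H+M), FA/(FA+CR)); d' uses the
    (count + 0.5) / (total + 1) correction so perfect performance stays
    finite.
    """
    c = _counts(outcomes)
    n_sig = c["H"] + c["M"]
    n_noise = c["FA"] + c["CR"]
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need both foe (H/M) and friendly (FA/CR) trials")
    hit_rate = c["H"] / n_sig
    fa_rate = c["FA"] / n_noise
    hr_c = (c["H"] + 0.5) / (n_sig + 1)
    fa_c = (c["FA"] + 0.5) / (n_noise + 1)
    dprime = float(norm.ppf(hr_c) - norm.ppf(fa_c))
    return {"hit_rate": hit_rate, "fa_rate": fa_rate, "dprime": dprime}


def anxiety_raw(endorsed: Iterable[str], subscale: Sequence[str] | None = None) -> int:
    """Count of endorsed adjectives belonging to the subscale
    (case-insensitive)."""
    if subscale is None:
        subscale = DEFAULT_ANXIETY_SUBSCALE
    scale = {w.strip().lower() for w in subscale}
    endorsed_set = {w.strip().lower() for w in endorsed}
    return len(endorsed_set & scale)


def anxiety_tscore(
    raw: int,
    total_checked: int,
    norm_table: Mapping[tuple[int, int], float] | pd.DataFrame | None,
) -> float:
    """T-score lookup keyed by (raw score, total-checked stratum).

    The norm table must be supplied by the user: either a mapping from
    ``(raw, total_checked)`` to T, or a DataFrame with columns
    ``raw``, ``total_checked``, ``t``. No fabricated transform is ever
    applied; a missing table or missing key raises.
    """
    if norm_table is None:
        raise ValueError(
            "no norm table supplied: T-score conversion requires the "
            "publisher's norm table (proprietary, not shipped)"
        )
    if isinstance(norm_table, pd.DataFrame):
        match = norm_table[
            (norm_table["raw"] == raw) & (norm_table["total_checked"] == total_checked)
        ]
        if match.empty:
            raise KeyError(f"norm table has no entry for raw={raw}, total={total_checked}")
        return float(match["t"].iloc[0])
    try:
        return float(norm_table[(raw, total_checked)])
    except KeyError as exc:
        raise KeyError(
            f"norm table has no entry for raw={raw}, total={total_checked}"
        ) from exc
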