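"""From raw prompt records to the analysis-ready lagged dataset.

Three responsibilities: (1) collapse emotion/intensity answers into a signed
valence index, (2) build the person-mean-centered lagged predictor with
day-boundary and missing-prompt exclusion, (3) apply participant exclusion
rules (zero variance / exact linear trend).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from affectdyn import emotions
from affectdyn.data import EmaSeries

logger = logging.getLogger(__name__)

ANALYSIS_COLUMNS = ["person_id", "group", "day", "prompt_index", "y", "x_lag_centered"]


def compute_valence(emotion_label: str, intensity=None, pleasantness: Optional[str] = None) -> float:
    """Signed valence score of one emotion answer.

    Positive emotions keep their intensity, negative emotions get the negated
    intensity, "no emotion" scores zero, and the unnameable-emotion item is
    signed by its pleasantness rating.  Scores lie in [-11, +11].
    """
    label = emotions.canonical_label(emotion_label)
    if label == emotions.NO_EMOTION:
        return 0.0
    if intensity is None or (isinstance(intensity, float) and np.isnan(intensity)):
        raise ValueError(f"intensity required for emotion {emotion_label!r}")
    intensity = float(intensity)
    if not (1 <= intensity <= 11):
        raise ValueError(f"intensity must be in 1..11, got {intensity}")
    if label in emotions.POSITIVE_EMOTIONS:
        return intensity
    if label in emotions.NEGATIVE_EMOTIONS:
        return -intensity
    if label == emotions.UNNAMEABLE:
        if pleasantness is None or (isinstance(pleasantness, float) and np.isnan(pleasantness)):
            raise ValueError("pleasantness rating required for the unnameable-emotion item")
        pleas = str(pleasantness).strip().lower()
        if pleas == emotions.PLEASANT:
            return intensity
        if pleas == emotions.UNPLEASANT:
            return -intensity
        raise ValueError(f"unknown pleasantness value {pleasantness!r}")
    raise ValueError(f"unknown emotion label {emotion_label!r}")


def extract_outcome(frame: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Reduce a long-format frame to one ``y`` value per answered prompt.

    ``outcome="distress"`` takes the distress rating of ``item == "distress"``
    rows; ``outcome="valence"`` scores each emotion row with
    :func:`compute_valence`.  If several emotions were recorded at one prompt
    the signed scores are averaged (with a warning).
    """
    if outcome == "distress":
        sub = frame[frame["item"] == "distress"]
        out = sub[["person_id", "group", "day", "prompt_index"]].copy()
        out["y"] = sub["distress"].to_numpy(dtype=float)
    elif outcome == "valence":
        sub = frame[frame["item"] != "distress"].copy()
        sub["y"] = [
            compute_valence(it, inten, pleas)
            for it, inten, pleas in zip(sub["item"], sub["intensity"], sub["pleasantness"])
        ]
        sizes = sub.groupby(["person_id", "day", "prompt_index"], sort=False).size()
        if (sizes > 1).any():
            logger.warning(
                "extract_outcome: %d prompts had multiple emotion answers; averaging their signed scores",
                int((sizes > 1).sum()),
            )
        out = (
            sub.groupby(["person_id", "group", "day", "prompt_index"], as_index=False, sort=False)["y"]
            .mean()
        )
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return out.sort_values(["person_id", "day", "prompt_index"], kind="stable").reset_index(drop=True)


def _lag_person(sub: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Raw lag values (NaN where invalid) and the person mean of the used lags."""
    day = sub["day"].to_numpy()
    idx = sub["prompt_index"].to_numpy()
    y = sub["y"].to_numpy(dtype=float)
    lag = np.full(len(sub), np.nan)
    # valid lag: previous row is the immediately preceding prompt of the same day
    same = (day[1:] == day[:-1]) & (idx[1:] == idx[:-1] + 1)
    lag[1:][same] = y[:-1][same]
    used = lag[~np.isnan(lag)]
    m = float(used.mean()) if len(used) else np.nan
    return lag, m


def build_lagged(series_or_frame, drop_missing: bool = False) -> pd.DataFrame:
    """Attach the person-mean-centered lagged outcome.

    A prompt's lag is the previous prompt of the *same day*, and only if that
    prompt was answered; day starts and post-gap prompts get a missing lag.
    The centering mean is taken over the values actually used as lags, so the
    centered predictor is exactly mean-zero within person.  Rows with missing
    lags are kept (NaN) unless ``drop_missing`` is set; the number excluded is
    logged either way.
    """
    if isinstance(series_or_frame, EmaSeries):
        frame = series_or_frame.data.copy()
        frame.insert(0, "person_id", series_or_frame.person_id)
        frame.insert(1, "group", series_or_frame.group)
    else:
        frame = series_or_frame.copy()
    frame = frame.sort_values(["person_id", "day", "prompt_index"], kind="stable").reset_index(drop=True)

    pieces = []
    for pid, sub in frame.groupby("person_id", sort=False):
        lag, m = _lag_person(sub)
        usable = int(np.sum(~np.isnan(lag)))
        if usable < 2:
            logger.warning("build_lagged: person %s has %d usable lagged rows; flag for exclusion review", pid, usable)
        out = sub.copy()
        out["x_lag_centered"] = lag - m
        pieces.append(out)
    result = pd.concat(pieces, ignore_index=True)[ANALYSIS_COLUMNS]
    n_missing = int(result["x_lag_centered"].isna().sum())
    logger.info("build_lagged: %d rows have no valid same-day lag and are excluded from model input", n_missing)
    if drop_missing:
        result = result.dropna(subset=["x_lag_centered"]).reset_index(drop=True)
    return result


def exclude_participants(
    frame: pd.DataFrame,
    rules: Sequence[str] = ("zero_variance", "linear_trend"),
    tol: float = 1e-12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop persons whose ratings carry no usable variability.

    ``zero_variance``: the sample variance of the answered ratings is zero.
    ``linear_trend``: the residual variance after an ordinary least-squares fit
    on prompt order is zero within ``tol`` (constant series are a special
    case, so the trend rule subsumes the variance rule when both are active).
    Returns the retained frame and an exclusion log.
    """
    known = {"zero_variance", "linear_trend"}
    bad = set(rules) - known
    if bad:
        raise ValueError(f"unknown exclusion rules: {sorted(bad)}")

    log_rows = []
    keep_ids = []
    for pid, sub in frame.groupby("person_id", sort=False):
        y = sub["y"].to_numpy(dtype=float)
        y = y[~np.isnan(y)]
        triggered = None
        if "zero_variance" in rules and (len(y) < 2 or np.var(y) <= tol):
            triggered = "zero_variance"
        if triggered is None and "linear_trend" in rules and len(y) >= 2:
            t = np.arange(len(y), dtype=float)
            slope, intercept = np.polyfit(t, y, 1)
            resid = y - (intercept + slope * t)
            if np.var(resid) <= tol:
                triggered = "linear_trend"
        if triggered is None:
            keep_ids.append(pid)
        else:
            log_rows.append({"person_id": pid, "rule": triggered, "n_ratings": len(y)})

    log = pd.DataFrame(log_rows, columns=["person_id", "rule", "n_ratings"])
    kept = frame[frame["person_id"].isin(keep_ids)].reset_index(drop=True)
    if kept.empty:
        logger.warning("exclude_participants: every participant was excluded")
    return kept, log
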