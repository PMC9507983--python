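"""Scoring of the three post-exposure behavioural tasks and group statistics.

Rating task: familiarity ratings (1-4) of words, partwords and nonwords; the
composite rating score is the mean word rating minus the mean rating of the
pooled foils. 2AFC: forced choice between a word and a foil, chance = 50 %.
Target detection: speeded presses to a pre-specified syllable embedded in
short structured streams; learning shows up as faster responses to later
(more predictable) syllable positions, summarised by the baseline-adjusted
RT priming effect (S1 - S3) / S1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSE_WINDOW_MS",
    "score_rating",
    "score_afc",
    "score_detection",
    "match_presses",
    "rating_anova",
    "detection_rt_anova",
    "afc_group_test",
    "group_stats",
]

#: Accurate-response window after target syllable onset (duration of 4 syllables).
RESPONSE_WINDOW_MS = {"child": 1400.0, "adult": 1200.0}


def score_rating(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant category means and the composite rating score.

    rating_score = mean(word ratings) - mean(pooled partword + nonword
    ratings). With balanced 4 + 4 foils this equals the mean of the two foil
    category means. Participants who gave the same rating on every trial are
    flagged (``zero_variance``) — the signature of single-key responding.
    """
    required = {"participant_id", "category", "rating"}
    if not required <= set(trials.columns):
        raise ValueError(f"rating trials need columns {sorted(required)}")
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        if len(grp) != 12:
            warnings.warn(
                f"participant {pid}: {len(grp)} rating trials (expected 12)",
                stacklevel=2,
            )
        means = grp.groupby("category")["rating"].mean()
        foils = grp[grp["category"].isin(["partword", "nonword"])]["rating"]
        rows.append(
            dict(
                participant_id=pid,
                mean_word=means.get("word", np.nan),
                mean_partword=means.get("partword", np.nan),
                mean_nonword=means.get("nonword", np.nan),
                rating_score=means.get("word", np.nan) - foils.mean(),
                zero_variance=bool(grp["rating"].nunique() == 1),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class AFCReport:
    scores: pd.DataFrame  # participant_id, afc_accuracy (%)
    t: float
    df: int
    p: float
    cohen_d: float
    mean_accuracy: float


def score_afc(trials: pd.DataFrame) -> AFCReport:
    """Per-participant 2AFC accuracy (%) and a group one-sample t-test vs 50 %."""
    if len(trials) == 0:
        raise ValueError("no 2AFC trials")
    acc = (
        trials.groupby("participant_id")["correct"]
        .mean()
        .mul(100.0)
        .rename("afc_accuracy")
        .reset_index()
    )
    vals = acc["afc_accuracy"].to_numpy(dtype=float)
    if len(vals) > 1 and vals.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(vals, 50.0)
        d = (vals.mean() - 50.0) / vals.std(ddof=1)
    else:
        t, p, d = np.nan, np.nan, np.nan
    return AFCReport(
        scores=acc, t=float(t), df=len(vals) - 1, p=float(p),
        cohen_d=float(d), mean_accuracy=float(vals.mean()),
    )


def match_presses(
    targets: pd.DataFrame, presses: pd.DataFrame, window_ms: float
) -> tuple[pd.DataFrame, int]:
    """Assign presses to targets within one stream-group of trials.

    A press at time t is a hit for an unconsumed target with onset o when
    0 < t - o <= window (strictly after onset). Presses are processed in time
    order; each takes the nearest preceding eligible target, and each target
    consumes at most one press. Unassigned presses are false alarms.

    Returns the target table with ``hit`` and ``rt_ms`` columns, plus the
    false-alarm count.
    """
    tg = targets.sort_values("onset").reset_index(drop=True).copy()
    tg["hit"] = False
    tg["rt_ms"] = np.nan
    n_fa = 0
    win = window_ms / 1000.0
    for t in np.sort(presses["time"].to_numpy(dtype=float)):
        lag = t - tg["onset"].to_numpy()
        eligible = (~tg["hit"].to_numpy()) & (lag > 0) & (lag <= win)
        if eligible.any():
            # nearest preceding target = smallest positive lag
            j = int(np.flatnonzero(eligible)[np.argmin(lag[eligible])])
            tg.loc[j, "hit"] = True
            tg.loc[j, "rt_ms"] = lag[j] * 1000.0
        else:
            n_fa += 1
    return tg, n_fa


def score_detection(
    targets: pd.DataFrame, presses: pd.DataFrame, mode: str = "adult"
) -> pd.DataFrame:
    """Per-participant detection scores from target and press tables.

    Expects ``targets`` with participant_id, stream, onset (s), position
    (1-3) and ``presses`` with participant_id, stream, time (s). Produces
    hit_rate, normalised_fa (false alarms / n targets), mean RT per syllable
    position (s1_rt, s2_rt, s3_rt, ms) and rt_priming = (S1 - S3) / S1.
    """
    try:
        window = RESPONSE_WINDOW_MS[mode]
    except KeyError:
        raise ValueError(f"mode must be 'child' or 'adult', got {mode!r}") from None
    rows = []
    for pid, tg_p in targets.groupby("participant_id"):
        pr_p = presses[presses["participant_id"] == pid]
        matched, n_fa = [], 0
        for stream_i, tg_s in tg_p.groupby("stream"):
            pr_s = pr_p[pr_p["stream"] == stream_i]
            m, fa = match_presses(tg_s, pr_s, window)
            matched.append(m)
            n_fa += fa
        m = pd.concat(matched, ignore_index=True)
        n_targets = len(m)
        hits = m[m["hit"]]
        rt_by_pos = hits.groupby("position")["rt_ms"].mean()
        s1, s2, s3 = (rt_by_pos.get(k, np.nan) for k in (1, 2, 3))
        for k in (1, 2, 3):
            if k not in rt_by_pos.index:
                logger.info("participant %s: no hits at syllable position %d", pid, k)
        priming = (s1 - s3) / s1 if s1 and np.isfinite(s1) and np.isfinite(s3) else np.nan
        rows.append(
            dict(
                participant_id=pid,
                n_targets=n_targets,
                hit_rate=len(hits) / n_targets,
                normalised_fa=n_fa / n_targets,
                s1_rt=s1, s2_rt=s2, s3_rt=s3,
                rt_priming=priming,
                mode=mode,
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# group statistics


def _linear_contrast(wide: pd.DataFrame, ordered_cols: list[str]) -> dict:
    """One-df linear trend across ordered within-subject levels.

    Contrast weights (-1, 0, 1); F(1, n-1) is the squared one-sample t of the
    per-participant contrast scores against zero.
    """
    w = np.linspace(-1, 1, len(ordered_cols))
    scores = (wide[ordered_cols].to_numpy() * w[None, :]).sum(axis=1)
    scores = scores[np.isfinite(scores)]
    n = len(scores)
    if np.std(scores, ddof=1) == 0:
        # no between-participant spread: a zero mean is a flat (null) contrast
        F = 0.0 if scores.mean() == 0 else np.inf
        return dict(F=F, df1=1, df2=n - 1, p=1.0 if F == 0 else 0.0, np2=np.nan)
    t, p = stats.ttest_1samp(scores, 0.0)
    F = float(t**2)
    return dict(F=F, df1=1, df2=n - 1, p=float(p), np2=F / (F + n - 1))


def rating_anova(trials: pd.DataFrame, between: str | None = None) -> dict:
    """Repeated-measures ANOVA of word category on ratings (+ optional between factor).

    Returns the pingouin ANOVA table plus a linear contrast across the ordered
    categories word > partword > nonword.
    """
    data = (
        trials.groupby(
            ["participant_id", "category"] + ([between] if between else [])
        )["rating"].mean().reset_index()
    )
    if between:
        aov = pg.mixed_anova(
            data=data, dv="rating", within="category",
            subject="participant_id", between=between,
        )
    else:
        aov = pg.rm_anova(
            data=data, dv="rating", within="category",
            subject="participant_id", detailed=True,
        )
    wide = data.pivot_table(index="participant_id", columns="category", values="rating")
    contrast = _linear_contrast(wide, ["nonword", "partword", "word"])
    return dict(anova=aov, linear_contrast=contrast)


def detection_rt_anova(scores: pd.DataFrame, between: str | None = None) -> dict:
    """Repeated-measures ANOVA of syllable position on mean RTs."""
    id_vars = ["participant_id"] + ([between] if between else [])
    long = scores.melt(
        id_vars=id_vars,
        value_vars=["s1_rt", "s2_rt", "s3_rt"],
        var_name="position", value_name="rt",
    ).dropna(subset=["rt"])
    complete = long.groupby("participant_id")["position"].nunique()
    keep = complete[complete == 3].index
    dropped = set(long["participant_id"]) - set(keep)
    if dropped:
        logger.info("detection_rt_anova: listwise-dropped %d participant(s)", len(dropped))
    long = long[long["participant_id"].isin(keep)]
    if between:
        aov = pg.mixed_anova(
            data=long, dv="rt", within="position",
            subject="participant_id", between=between,
        )
    else:
        aov = pg.rm_anova(
            data=long, dv="rt", within="position",
            subject="participant_id", detailed=True,
        )
    wide = long.pivot_table(index="participant_id", columns="position", values="rt")
    contrast = _linear_contrast(wide, ["s1_rt", "s2_rt", "s3_rt"])
    return dict(anova=aov, linear_contrast=contrast)


def afc_group_test(scores: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """One-way ANOVA for group differences in 2AFC accuracy."""
    return pg.anova(data=scores, dv="afc_accuracy", between=group_col)


def group_stats(task: str, *args, **kwargs):
    """Dispatch to the task-specific group analysis.

    ``task`` is one of 'rating' (repeated-measures ANOVA + linear contrast),
    'detection' (syllable-position ANOVA) or 'afc' (between-group one-way
    ANOVA).
    """
    fns = {"rating": rating_anova, "detection": detection_rt_anova, "afc": afc_group_test}
    try:
        return fns[task](*args, **kwargs)
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(fns)}") from None
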