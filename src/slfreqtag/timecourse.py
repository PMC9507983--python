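"""Sliding-bundle entrainment trajectories and mixed-effects learning models.

A bundle is a sliding window of ``bundle_size`` (default 5) consecutive
nonoverlapping 12-word epochs, shifted by one epoch per bundle (epochs 1-5,
2-6, ...), so each bundle spans 54 s of exposure and B = n_epochs - 5 + 1
bundles tile the session. ITC/WLI are recomputed within each bundle, giving a
per-participant learning trajectory; linear mixed-effects models with bundle
number as a numeric fixed effect and a participant random intercept test
whether entrainment changes over exposure. Bundles with data from fewer than
half the participants (late, after artifact rejection) are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .entrain import (
    SYLLABLE_FREQ,
    WORD_FREQ,
    compute_itc,
    extract_frequency,
    roi_average,
)
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "Bundle",
    "LMMResult",
    "make_bundles",
    "bundle_itc_series",
    "exclude_sparse_bundles",
    "fit_learning_lmm",
    "surrogate_timecourse",
]


@dataclass(frozen=True)
class Bundle:
    number: int  # 1-based
    epoch_positions: tuple[int, ...]  # positions in the epoch set
    retained_positions: tuple[int, ...]

    @property
    def usable(self) -> bool:
        # ITC needs at least 2 epochs
        return len(self.retained_positions) >= 2


def make_bundles(
    epochs: EpochSet, bundle_size: int = 5, step: int = 1
) -> list[Bundle]:
    """Sliding windows of epoch positions; unusable ones keep < 2 retained epochs."""
    if bundle_size < 2:
        raise ValueError("bundle_size must be >= 2")
    n = epochs.n_epochs
    if n < bundle_size:
        warnings.warn(
            f"{n} epochs < bundle_size {bundle_size}; no bundles", stacklevel=2
        )
        return []
    mask = epochs.retained_mask
    bundles = []
    for k, start in enumerate(range(0, n - bundle_size + 1, step)):
        pos = tuple(range(start, start + bundle_size))
        bundles.append(
            Bundle(
                number=k + 1,
                epoch_positions=pos,
                retained_positions=tuple(p for p in pos if mask[p]),
            )
        )
    return bundles


def bundle_itc_series(
    epochs: EpochSet,
    roi: Sequence[str],
    participant_id: str = "",
    bundle_size: int = 5,
    word_freq: float = WORD_FREQ,
    syllable_freq: float = SYLLABLE_FREQ,
    freq_range: tuple[float, float] = (0.6, 5.0),
) -> pd.DataFrame:
    """Per-bundle ROI-averaged ITC_word, ITC_syllable and WLI for one participant.

    Unusable bundles (fewer than two retained epochs) yield NaN rows rather
    than fabricated values.
    """
    rows = []
    for b in make_bundles(epochs, bundle_size):
        if not b.usable:
            rows.append(
                dict(participant_id=participant_id, bundle=b.number,
                     itc_word=np.nan, itc_syllable=np.nan, wli=np.nan,
                     n_epochs=len(b.retained_positions))
            )
            continue
        sub = epochs.subset(list(b.retained_positions))
        itc = compute_itc(sub, freq_range)
        w = roi_average(extract_frequency(itc, word_freq), roi, itc.ch_names)
        s = roi_average(extract_frequency(itc, syllable_freq), roi, itc.ch_names)
        rows.append(
            dict(participant_id=participant_id, bundle=b.number,
                 itc_word=w, itc_syllable=s,
                 wli=w / s if s > 0 else np.nan,
                 n_epochs=len(b.retained_positions))
        )
    return pd.DataFrame(rows)


def exclude_sparse_bundles(
    series: pd.DataFrame, threshold: float = 0.5, value_col: str = "wli"
) -> pd.DataFrame:
    """Drop bundle numbers missing from more than ``threshold`` of participants.

    A participant is "missing" a bundle if it has no row for it or the value
    is NaN. The retained bundle range is logged.
    """
    participants = series["participant_id"].unique()
    n_part = len(participants)
    if n_part < 1:
        raise ValueError("no participants in series")
    keep = []
    for b, grp in series.groupby("bundle"):
        n_present = grp[value_col].notna().sum()
        if 1 - n_present / n_part <= threshold:
            keep.append(b)
    if not keep:
        raise ValueError("every bundle exceeds the missing-data threshold")
    logger.info("exclude_sparse_bundles: retained bundles %d-%d", min(keep), max(keep))
    return series[series["bundle"].isin(keep)].copy()


@dataclass
class LMMResult:
    """Fixed-effect estimates from a linear mixed-effects fit.

    ``terms`` holds one row per fixed effect: estimate, se, z, p and an
    F-equivalent (z squared). Tests are Wald z with a normal approximation;
    the approximation is recorded in ``method`` so reports are explicit about
    how the p-values were obtained.
    """

    formula: str
    terms: pd.DataFrame
    n_obs: int
    n_groups: int
    method: str = "REML, Wald z (normal approximation)"
    converged: bool = True
    singular: bool = False

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    def slope(self, name: str = "bundle") -> float:
        return float(self.terms.loc[name, "estimate"])

    def slope_ci(self, name: str = "bundle", level: float = 0.95) -> tuple[float, float]:
        row = self.terms.loc[name]
        z = stats.norm.ppf(0.5 + level / 2)
        return (row["estimate"] - z * row["se"], row["estimate"] + z * row["se"])


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str) -> LMMResult:
    data = data.dropna(subset=[c for c in data.columns if c != groups]).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[groups])
        fit = model.fit(reml=True)
    fe = fit.fe_params
    terms = pd.DataFrame(
        dict(
            estimate=fe,
            se=fit.bse_fe,
            z=fe / fit.bse_fe,
            p=2 * stats.norm.sf(np.abs(fe / fit.bse_fe)),
        )
    )
    terms["F"] = terms["z"] ** 2
    var_re = float(np.asarray(fit.cov_re).ravel()[0])
    return LMMResult(
        formula=formula,
        terms=terms,
        n_obs=len(data),
        n_groups=data[groups].nunique(),
        converged=bool(getattr(fit, "converged", True)),
        singular=var_re <= 1e-10,
    )


def fit_learning_lmm(
    series: pd.DataFrame,
    response: str = "wli",
    group_term: str | None = None,
    age_term: str | None = None,
) -> LMMResult:
    """Model entrainment change over exposure with a participant random intercept.

    Fits ``response ~ bundle`` (bundle as a 1-based numeric covariate), with
    optional ``group`` (bundle x group interaction) or ``age`` (bundle x age)
    fixed effects. Complete-case on the response; a singular random-intercept
    variance is flagged in the result, not silenced.
    """
    if response not in ("wli", "itc_word", "itc_syllable"):
        raise ValueError(f"unknown response {response!r}")
    rhs = "bundle"
    cols = ["participant_id", "bundle", response]
    if group_term:
        rhs += f" + {group_term} + bundle:{group_term}"
        cols.append(group_term)
    if age_term:
        rhs += f" + {age_term} + bundle:{age_term}"
        cols.append(age_term)
    formula = f"{response} ~ {rhs}"
    return _fit_mixedlm(formula, series[cols], groups="participant_id")


def surrogate_timecourse(
    series_actual: pd.DataFrame,
    series_surrogate: pd.DataFrame,
    response: str = "itc_word",
) -> LMMResult:
    """Test whether entrainment grows faster in actual than surrogate data.

    Stacks the two bundle series with a ``datatype`` indicator (surrogate = 0,
    actual = 1) and fits ``response ~ bundle * datatype`` with a participant
    random intercept; the bundle:datatype interaction estimates the extra
    per-bundle growth that is stimulus-locked rather than drift.
    """
    for df in (series_actual, series_surrogate):
        if not {"participant_id", "bundle", response} <= set(df.columns):
            raise ValueError("series must have participant_id, bundle and response columns")
    a_keys = set(map(tuple, series_actual[["participant_id", "bundle"]].values))
    s_keys = set(map(tuple, series_surrogate[["participant_id", "bundle"]].values))
    if a_keys != s_keys:
        raise ValueError("actual and surrogate series must cover the same design")
    a = series_actual.copy()
    a["datatype"] = 1.0
    s = series_surrogate.copy()
    s["datatype"] = 0.0
    both = pd.concat([a, s], ignore_index=True)
    formula = f"{response} ~ bundle + datatype + bundle:datatype"
    return _fit_mixedlm(
        formula, both[["participant_id", "bundle", "datatype", response]],
        groups="participant_id",
    )
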