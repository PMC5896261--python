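"""Per-feature effect-size screening of a case/control feature table.

A feature table holds one row per subject, one numeric column per
measurement, and a binary group label.  For every feature both Cohen's d
and the sorting statistic D_s are computed on the missing-dropped values,
together with their calibration classes and a discordance ("V-gap") flag
marking features where D_s is elevated while |d| is near zero — the
signature of a group difference carried by skew or tail mass rather than
a mean shift.

Plotting D_s against d across many features produces a V-shaped scatter:
D_s rises with |d| on either sign.  The two arms are summarised by
sign-split correlations: rho over features with d > 0 and rho over
features with d < 0 (features with d exactly 0 belong to neither side).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    COHEN_D_BAND,
    SORTING_BAND,
    CalibrationBand,
    GroupedSample,
    SigmaMode,
    classify_effect,
    effect_sizes,
)

__all__ = [
    "FeatureTable",
    "ScreenResult",
    "CorrelationSummary",
    "screen_features",
    "correlate_statistics",
    "flag_v_gap",
]

logger = logging.getLogger(__name__)

#: Default thresholds of the discordance flag: elevated D_s, negligible |d|,
#: anchored at the small-effect calibration values of the two statistics.
DEFAULT_DS_MIN = 0.2
DEFAULT_D_ABS_MAX = 0.2


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x measurements matrix plus a binary group label per subject.

    ``group_x`` names the label treated as group x (the sign convention of
    d); by default the lexicographically smaller of the two labels, so a
    "case"/"control" table orients cases as x.
    """

    features: pd.DataFrame
    group_labels: pd.Series
    group_x: str
    group_y: str

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str,
        group_x: str | None = None,
        feature_cols: list[str] | None = None,
    ) -> "FeatureTable":
        if group_col not in df.columns:
            raise KeyError(f"group column {group_col!r} not found in table")
        labels = df[group_col].astype(str)
        uniq = sorted(labels.unique())
        if len(uniq) != 2:
            raise ValueError(f"need exactly two distinct group labels, found {uniq}")
        if group_x is None:
            group_x = uniq[0]
        elif group_x not in uniq:
            raise ValueError(f"group_x {group_x!r} not among labels {uniq}")
        group_y = uniq[1] if group_x == uniq[0] else uniq[0]
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c != group_col]
        feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
        return cls(feats, labels, group_x, group_y)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass(frozen=True)
class CorrelationSummary:
    """Sign-split correlations between D_s and d across features.

    A side with fewer than 3 features reports NaN with the reason in
    ``notes``.
    """

    rho_positive: float
    p_positive: float
    n_positive: int
    rho_negative: float
    p_negative: float
    n_negative: int
    method: str
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "rho_positive": self.rho_positive, "p_positive": self.p_positive,
            "n_positive": self.n_positive,
            "rho_negative": self.rho_negative, "p_negative": self.p_negative,
            "n_negative": self.n_negative,
            "method": self.method, "notes": list(self.notes),
        }


@dataclass
class ScreenResult:
    """Per-feature screening output.

    ``table`` has one row per retained feature with columns
    n_used, m_used, d, ds, d_class, ds_class, v_gap; ``skipped`` maps each
    dropped feature to the reason it could not be screened.
    """

    table: pd.DataFrame
    skipped: dict[str, str] = field(default_factory=dict)
    sigma_mode: str = "joint"
    group_x: str = "x"
    group_y: str = "y"

    def __len__(self) -> int:
        return len(self.table)


def screen_features(
    table: FeatureTable,
    sigma_mode: SigmaMode = "joint",
    bands: Mapping[str, CalibrationBand] | None = None,
    ds_min: float = DEFAULT_DS_MIN,
    d_abs_max: float = DEFAULT_D_ABS_MAX,
) -> ScreenResult:
    """Compute d and D_s for every feature of a table.

    Missing values are dropped per feature (pairwise deletion with logged
    counts); a feature left without at least one value per group is
    skipped with a recorded reason.  Constant features carry ds = 0 and an
    undefined (NaN) d.
    """
    if bands is None:
        bands = {"cohen_d": COHEN_D_BAND, "sorting": SORTING_BAND}
    if not table.feature_names:
        raise ValueError("empty table: no feature columns to screen")
    mask_x = (table.group_labels == table.group_x).to_numpy()
    mask_y = (table.group_labels == table.group_y).to_numpy()

    rows = []
    skipped: dict[str, str] = {}
    for name in table.feature_names:
        col = table.features[name].to_numpy(dtype=float)
        vx = col[mask_x]
        vy = col[mask_y]
        vx = vx[np.isfinite(vx)]
        vy = vy[np.isfinite(vy)]
        if vx.size == 0 or vy.size == 0:
            side = table.group_x if vx.size == 0 else table.group_y
            skipped[name] = f"no usable values in group '{side}' after dropping missing"
            logger.warning("skipping feature %s: %s", name, skipped[name])
            continue
        res = effect_sizes(
            GroupedSample(vx, vy, table.group_x, table.group_y), sigma_mode
        )
        d_class = classify_effect(res.d, bands["cohen_d"]) if res.d_defined else "undefined"
        ds_class = classify_effect(res.ds, bands["sorting"])
        v_gap = res.ds >= ds_min and (res.d_defined and abs(res.d) < d_abs_max)
        rows.append({
            "feature": name, "n_used": res.n, "m_used": res.m,
            "d": res.d, "ds": res.ds,
            "d_class": d_class, "ds_class": ds_class, "v_gap": v_gap,
        })
    out = pd.DataFrame(
        rows,
        columns=["feature", "n_used", "m_used", "d", "ds", "d_class", "ds_class", "v_gap"],
    ).set_index("feature")
    return ScreenResult(out, skipped, sigma_mode, table.group_x, table.group_y)


def correlate_statistics(
    result: ScreenResult,
    method: Literal["spearman", "pearson"] = "spearman",
) -> CorrelationSummary:
    """Correlate D_s with d separately over positive-d and negative-d features.

    The rank (Spearman) estimator is the default; Pearson is available for
    comparison.  Features with undefined or exactly-zero d join neither
    side; a side with fewer than 3 features is reported as NaN, not an
    error.
    """
    corr = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    tab = result.table.dropna(subset=["d"])
    notes: list[str] = []
    out: dict[str, float] = {}
    for side, sel in (("positive", tab["d"] > 0), ("negative", tab["d"] < 0)):
        sub = tab[sel]
        out[f"n_{side}"] = len(sub)
        if len(sub) < 3:
            out[f"rho_{side}"] = math.nan
            out[f"p_{side}"] = math.nan
            note = f"{side} side has {len(sub)} feature(s) (< 3): correlation undefined"
            notes.append(note)
            logger.warning(note)
            continue
        r = corr(sub["d"].to_numpy(), sub["ds"].to_numpy())
        out[f"rho_{side}"] = float(r.statistic)
        out[f"p_{side}"] = float(r.pvalue)
    return CorrelationSummary(
        rho_positive=out["rho_positive"], p_positive=out["p_positive"],
        n_positive=out["n_positive"],
        rho_negative=out["rho_negative"], p_negative=out["p_negative"],
        n_negative=out["n_negative"],
        method=method, notes=tuple(notes),
    )


def flag_v_gap(
    result: ScreenResult,
    ds_min: float = DEFAULT_DS_MIN,
    d_abs_max: float = DEFAULT_D_ABS_MAX,
) -> pd.DataFrame:
    """Features with D_s >= ds_min and |d| < d_abs_max, sorted by D_s descending.

    These are the discordant features the sorting statistic surfaces and a
    mean-based screen would discard.
    """
    if ds_min <= 0 or d_abs_max <= 0:
        raise ValueError("thresholds must be positive")
    tab = result.table
    sel = (tab["ds"] >= ds_min) & (tab["d"].abs() < d_abs_max)
    return tab[sel.fillna(False)].sort_values("ds", ascending=False)
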