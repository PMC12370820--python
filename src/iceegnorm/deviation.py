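"""Deviation scoring of a new subject against the regional normative model.

The clinical use of a normative map: given a new subject's per-ROI RBP
and age, compare each value to the corresponding regional regression line
and quantify the difference.  The out-of-sample prediction is population
level — the hospital offset is set to its prior mean of zero — and the
residual is standardised by the model's residual SD (optionally by the
total SD sqrt(sigma2_hospital + sigma2_residual), which acknowledges that
an out-of-sample subject also carries an unknown hospital offset).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bands import BAND_NAMES
from .cohort import NormativeTable
from .lmm import fit_regional

SCORE_COLUMNS = ["roi", "band", "observed", "predicted", "residual",
                 "score", "flag", "status"]


def score_subject(regional_map: pd.DataFrame, subject_rbp: pd.DataFrame,
                  age: float, sex: Optional[str] = None,
                  denominator: str = "residual",
                  threshold: float = 2.0) -> pd.DataFrame:
    """Score a subject's per-ROI RBP against regional age-model fits.

    Parameters
    ----------
    regional_map : output of :func:`iceegnorm.lmm.fit_regional`
        (rows for one or several bands).
    subject_rbp : DataFrame in normative-table row format: a ``roi``
        column plus the five band columns.
    age : subject age in years.
    sex : accepted for interface symmetry; the regional age model carries
        no sex term, so it does not enter the prediction.
    denominator : {"residual", "total"}
        SD used for standardisation: the model's residual SD (default,
        deviation from the regression line) or
        sqrt(sigma2_hospital + sigma2_residual).
    threshold : |score| above which a deviation is flagged extreme.

    Returns one row per ROI x band, ranked by |score| (extreme deviations
    first).  ROIs absent from the map are marked ``unscorable``; ROIs
    whose fit is singular are scored with the raw residual only.
    """
    if denominator not in {"residual", "total"}:
        raise ValueError("denominator must be 'residual' or 'total'")
    rows = []
    lut = {(r.roi, r.band): r for r in regional_map.itertuples()}
    bands = [b for b in BAND_NAMES if b in subject_rbp.columns]
    map_bands = sorted(regional_map["band"].unique())
    for _, srow in subject_rbp.iterrows():
        for band in bands:
            if band not in map_bands:
                continue
            obs = float(srow[band])
            entry = lut.get((srow["roi"], band))
            if entry is None or not entry.fitted:
                rows.append((srow["roi"], band, obs, np.nan, np.nan, np.nan,
                             False, "unscorable"))
                continue
            pred = entry.intercept + entry.b_age * age
            resid = obs - pred
            if bool(entry.singular):
                rows.append((srow["roi"], band, obs, pred, resid, np.nan,
                             False, "singular"))
                continue
            var = entry.sigma2_residual
            if denominator == "total":
                var = var + entry.sigma2_hospital
            score = resid / np.sqrt(var)
            rows.append((srow["roi"], band, obs, pred, resid, score,
                         bool(abs(score) > threshold), "ok"))
    out = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return out.reindex(
        out["score"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)


class NormativeDeviationScorer(BaseEstimator):
    """Estimator-style wrapper: fit regional normative maps, score subjects.

    Parameters
    ----------
    bands : bands to map (default all five).
    min_rows : minimal rows per ROI for a regional fit.
    ci_method : "wald" or "profile" CIs in the regional map.
    denominator, threshold : see :func:`score_subject`.

    Attributes
    ----------
    regional_maps_ : DataFrame of per-ROI per-band age-model summaries.
    """

    def __init__(self, bands: Sequence[str] = BAND_NAMES, min_rows: int = 10,
                 ci_method: str = "wald", denominator: str = "residual",
                 threshold: float = 2.0):
        self.bands = bands
        self.min_rows = min_rows
        self.ci_method = ci_method
        self.denominator = denominator
        self.threshold = threshold

    def fit(self, table: NormativeTable, y=None):
        maps = [fit_regional(table, band, min_rows=self.min_rows,
                             ci_method=self.ci_method)
                for band in self.bands]
        self.regional_maps_ = pd.concat(maps, ignore_index=True)
        return self

    def score_subject(self, subject_rbp: pd.DataFrame, age: float,
                      sex: Optional[str] = None) -> pd.DataFrame:
        if not hasattr(self, "regional_maps_"):
            raise RuntimeError("scorer is not fitted")
        return score_subject(self.regional_maps_, subject_rbp, age, sex=sex,
                             denominator=self.denominator,
                             threshold=self.threshold)
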