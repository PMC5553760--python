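"""Prediction-accuracy metrics and the birth-year validation split.

Accuracy is the Pearson correlation between GEBV and DRP in the validation
set; bias is the regression coefficient of DRP on GEBV (1 = unbiased scale);
a feature model is called predictive when it improves accuracy over the
single-component baseline by at least 0.001.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PREDICTIVE_DELTA = 0.001


def accuracy(gebv, drp) -> float:
    """Pearson correlation between predictions and DRP (nan if degenerate)."""
    gebv = np.asarray(gebv, dtype=float)
    drp = np.asarray(drp, dtype=float)
    if gebv.size != drp.size or gebv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(gebv) == 0 or np.std(drp) == 0:
        warnings.warn("constant input; accuracy undefined")
        return np.nan
    return float(np.corrcoef(gebv, drp)[0, 1])


def bias(gebv, drp) -> float:
    """Regression coefficient of DRP on GEBV: cov(DRP, GEBV)/Var(GEBV)."""
    gebv = np.asarray(gebv, dtype=float)
    drp = np.asarray(drp, dtype=float)
    var = np.var(gebv)
    if var == 0:
        raise ValueError("zero GEBV variance; bias undefined")
    return float(np.cov(drp, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))


def delta_r(r_model: float, r_baseline: float, threshold: float = PREDICTIVE_DELTA):
    """Accuracy gain over the baseline and the predictive flag (gain >= 0.001)."""
    if not (np.isfinite(r_model) and np.isfinite(r_baseline)):
        raise ValueError("accuracies must be finite")
    d = float(r_model - r_baseline)
    return d, d >= threshold


def split_by_birth_year(phenotypes: pd.DataFrame, cutoff: int = 2006,
                        cutoff_to_validation: bool = True):
    """Training/validation ids by birth year.

    Animals born in or after ``cutoff`` (the younger ones) go to validation;
    set ``cutoff_to_validation=False`` to keep the cutoff year in training.
    Raises if either side is empty.
    """
    years = phenotypes["birth_year"].to_numpy()
    if cutoff_to_validation:
        valid = years >= cutoff
    else:
        valid = years > cutoff
    ids = phenotypes["id"].to_numpy(dtype=object)
    train_ids, valid_ids = ids[~valid], ids[valid]
    if train_ids.size == 0 or valid_ids.size == 0:
        raise ValueError(
            f"degenerate split at cutoff {cutoff}: "
            f"{train_ids.size} training / {valid_ids.size} validation"
        )
    return train_ids, valid_ids
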