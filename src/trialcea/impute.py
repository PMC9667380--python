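"""Chained-equations imputation with predictive mean matching (PMM).

Used inside the bootstrap ("single imputation nested in bootstrapping"):
each bootstrap resample is completed once by cycling linear models over the
wave-level cost, utility and depression-score columns in time order, and a
missing value is always replaced by an *observed* donor value whose
predicted mean is among the k nearest to the missing case's prediction —
so imputed entries live in the observed support by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["chained_pmm_impute"]


def chained_pmm_impute(
    frame: pd.DataFrame,
    target_cols: list[str],
    predictor_cols: list[str],
    rng: np.random.Generator,
    cycles: int = 10,
    donors: int = 5,
) -> pd.DataFrame:
    """Return a completed copy of ``frame``.

    ``target_cols`` may have missing values and are imputed in the given
    order (time order for wave-level data); ``predictor_cols`` must be fully
    observed.  Each target's imputation model regresses it on the predictors
    plus the current completed values of every *other* target.

    Raises ``ValueError`` if a target column has no observed values (the
    caller redraws the bootstrap replicate).
    """
    out = frame.copy()
    X_fixed = out[predictor_cols].to_numpy(dtype=float)
    if np.isnan(X_fixed).any():
        raise ValueError("predictor columns must be fully observed")

    values = {c: out[c].to_numpy(dtype=float).copy() for c in target_cols}
    obs_mask = {c: ~np.isnan(values[c]) for c in target_cols}

    for c in target_cols:
        m = obs_mask[c]
        if not m.any():
            raise ValueError(f"column {c!r} has no observed values to impute from")
        if (~m).any():
            values[c][~m] = rng.choice(values[c][m], size=int((~m).sum()), replace=True)

    need = [c for c in target_cols if (~obs_mask[c]).any()]
    n = len(out)
    ones = np.ones((n, 1))

    for _ in range(cycles):
        for c in need:
            others = [values[o] for o in target_cols if o != c]
            X = np.hstack([ones, X_fixed] + [o[:, None] for o in others])
            m = obs_mask[c]
            beta, *_ = np.linalg.lstsq(X[m], values[c][m], rcond=None)
            pred = X @ beta
            pred_obs = pred[m]
            y_obs = values[c][m]
            mis_idx = np.flatnonzero(~m)
            k = min(donors, len(y_obs))
            # k nearest observed predictions per missing case; draw one donor
            dist = np.abs(pred[mis_idx][:, None] - pred_obs[None, :])
            nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
            pick = rng.integers(0, k, size=len(mis_idx))
            values[c][mis_idx] = y_obs[nearest[np.arange(len(mis_idx)), pick]]

    for c in target_cols:
        out[c] = values[c]
    return out
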