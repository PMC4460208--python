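"""Evaluation metrics for dissolution-profile models.

Three quantities cover the whole study: the root mean squared error of a
fitted model, the FDA similarity factor f2 between two dissolution profiles,
and the percent coefficient of variation used to judge the stability of
fitted equation parameters across cross-validation folds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rmse", "f2", "cv_percent"]


def rmse(obs, pred) -> float:
    """Root mean squared error between paired observation/prediction vectors.

    Parameters
    ----------
    obs, pred : array-like
        Equal-length, nonempty paired vectors.

    Returns
    -------
    float
        ``sqrt(mean((pred - obs)**2))``; zero iff the vectors are equal.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: obs {obs.shape} vs pred {pred.shape}")
    if obs.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def f2(reference, test, truncate_above: float | None = None) -> float:
    """FDA similarity factor between two dissolution profiles.

    f2 = 50 * log10( 100 / sqrt(1 + msd) ) where msd is the mean squared
    difference between the paired release values (% units).  Identical
    profiles give 100; profiles differing by a uniform 10% offset give
    ~49.9.  Values >= 50 are conventionally read as "similar".

    Parameters
    ----------
    reference, test : array-like
        Percent-released values paired by time point.
    truncate_above : float, optional
        If given (regulatory practice uses 85), drop time points after the
        first at which *both* profiles exceed this release level.  Off by
        default: the comparison then uses every supplied point.
    """
    R = np.asarray(reference, dtype=float)
    T = np.asarray(test, dtype=float)
    if R.shape != T.shape:
        raise ValueError(f"shape mismatch: reference {R.shape} vs test {T.shape}")
    if R.size == 0:
        raise ValueError("f2 of empty profiles is undefined")
    if truncate_above is not None:
        over = (R > truncate_above) & (T > truncate_above)
        if over.any():
            keep = int(np.argmax(over)) + 1  # first crossing point stays in
            R, T = R[:keep], T[:keep]
    msd = float(np.mean((R - T) ** 2))
    return float(50.0 * np.log10((1.0 + msd) ** -0.5 * 100.0))


def cv_percent(values) -> float:
    """Percent coefficient of variation, 100 * sample sd / |mean|.

    Uses the n-1 (sample) standard deviation.  Requires at least two values
    and a nonzero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cv_percent needs at least two values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ZeroDivisionError("cv_percent undefined for zero-mean values")
    return float(100.0 * np.std(v, ddof=1) / abs(mean))
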