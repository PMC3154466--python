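"""Mapping tip traits to extinction probabilities.

Traits are standardised to z-scores across the tips of a tree and pushed
through the standard normal CDF, giving extinction probabilities p(ext)
in (0, 1) with batch mean ~ 0.5.  Because the CDF is the probability
integral transform, traits with no phylogenetic signal yield approximately
uniform risks, perfect Brownian motion yields a unimodal quasi-normal
distribution, and extreme clustering (lambda >> 1) yields a bimodal one.

The mean-0.5 distribution is rescaled to mean 0.25 by halving every risk,
and to mean 0.75 by multiplying every risk by a common factor and capping
at 1, with the factor chosen so the sample mean equals the target exactly.
Both maps are rank-preserving and keep all values inside [0, 1]; the cap
is what limits the growth of the risk variance as the mean rises, which in
turn bounds how much extra phylogenetic diversity clustered risks can
destroy at high mean extinction risk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = ["standardize_traits", "z_to_pext", "rescale_mean",
           "capped_scale_to_mean", "traits_to_risks", "SUPPORTED_MEANS"]

SUPPORTED_MEANS = (0.25, 0.50, 0.75)


def _as_series(x, name: str) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    return pd.Series(dict(x) if isinstance(x, dict) else x, dtype=float, name=name)


def standardize_traits(traits: pd.Series | dict, ddof: int = 0) -> pd.Series:
    """z-score traits across tips: (x - mean) / sd.

    ``ddof=0`` (population standard deviation) is the default convention;
    ``ddof=1`` gives the sample-sd variant.  Raises on zero variance.
    """
    x = _as_series(traits, "trait")
    if x.size < 2:
        raise ValueError("need at least 2 tips to standardize")
    sd = float(x.std(ddof=ddof))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("trait standard deviation is zero; cannot standardize")
    z = (x - float(x.mean())) / sd
    z.name = "z"
    return z


def z_to_pext(z: pd.Series | dict) -> pd.Series:
    """Map standardised traits to extinction probabilities via the normal CDF."""
    zz = _as_series(z, "z")
    p = pd.Series(ndtr(zz.to_numpy()), index=zz.index, name="p_ext")
    return p


def capped_scale_to_mean(p: np.ndarray, target_mean: float) -> np.ndarray:
    """Multiply risks by a common factor, cap at 1, hitting the target mean exactly.

    ``mean(min(c*p, 1))`` is continuous and non-decreasing in ``c``, so the
    factor is found by bisection; if the sample mean already exceeds the
    target the map reduces to plain multiplication by ``target/mean``
    (the cap never binds for c < 1).
    """
    p = np.asarray(p, dtype=float)
    mu = float(p.mean())
    if mu == 0:
        raise ValueError("cannot rescale an all-zero risk vector to a positive mean")
    if mu >= target_mean:
        return p * (target_mean / mu)
    hi = 2.0
    while np.minimum(hi * p, 1.0).mean() < target_mean:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"target mean {target_mean} is unreachable by capped scaling")
    c = brentq(lambda c: np.minimum(c * p, 1.0).mean() - target_mean, 1.0, hi,
               xtol=1e-13)
    return np.minimum(c * p, 1.0)


def rescale_mean(risks: pd.Series | dict | np.ndarray, target_mean: float):
    """Rescale a mean-0.5 risk distribution to mean 0.25, 0.50 or 0.75.

    0.25 halves every risk; 0.50 is the identity; 0.75 multiplies by a
    common factor with a cap at 1, the factor chosen so the sample mean is
    exactly 0.75 (see :func:`capped_scale_to_mean`).  All three preserve
    ranks (weakly, once the cap binds) and map [0, 1] into itself.
    """
    if not any(abs(target_mean - m) < 1e-12 for m in SUPPORTED_MEANS):
        raise ValueError(f"target_mean must be one of {SUPPORTED_MEANS}, got {target_mean}")
    arr = risks.to_numpy(dtype=float) if isinstance(risks, pd.Series) else \
        np.array([risks[k] for k in risks], dtype=float) if isinstance(risks, dict) else \
        np.asarray(risks, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("risks must lie in [0, 1]")
    if target_mean == 0.25:
        out = arr / 2.0
    elif target_mean == 0.75:
        out = capped_scale_to_mean(arr, 0.75)
    else:
        out = arr.copy()
    if isinstance(risks, pd.Series):
        return pd.Series(out, index=risks.index, name="p_ext")
    if isinstance(risks, dict):
        return dict(zip(risks, out))
    return out


def traits_to_risks(traits: pd.Series | dict, target_mean: float = 0.5,
                    ddof: int = 0) -> pd.Series:
    """Full trait-to-risk pipeline: standardise, CDF-map, rescale the mean."""
    return rescale_mean(z_to_pext(standardize_traits(traits, ddof=ddof)), target_mean)
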