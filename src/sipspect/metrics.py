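"""Image-similarity measures for projection stacks and reconstructed volumes.

Four measures are provided, each comparing an image IM against a reference
RI of the same shape:

* NRMSE — root-mean-square error normalised by the mean reference value,
* NMAE  — mean absolute error normalised the same way,
* PSNR  — 20 log10(MAX / RMSE), MAX taken over both images,
* SSIM  — structural similarity; by default the single-window (global
  moments) form with the standard stabilisers c1 = (0.01 L)^2,
  c2 = (0.03 L)^2 where L is the dynamic range of the reference.

Normalising by the reference mean makes the error measures comparable
across acquisition time points whose count levels differ by orders of
magnitude.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd


def _check_pair(im, ri):
    im = np.asarray(im, dtype=float)
    ri = np.asarray(ri, dtype=float)
    if im.shape != ri.shape:
        raise ValueError(f"shape mismatch: {im.shape} vs {ri.shape}")
    if im.size == 0:
        raise ValueError("empty arrays")
    return im, ri


def nrmse(im: np.ndarray, ri: np.ndarray) -> float:
    """RMSE(im, ri) normalised by the mean reference value."""
    im, ri = _check_pair(im, ri)
    m = ri.mean()
    if m <= 0:
        raise ValueError("reference mean must be positive for NRMSE")
    return float(np.sqrt(np.mean((im - ri) ** 2)) / m)


def nmae(im: np.ndarray, ri: np.ndarray) -> float:
    """Mean absolute error normalised by the mean reference value."""
    im, ri = _check_pair(im, ri)
    m = ri.mean()
    if m <= 0:
        raise ValueError("reference mean must be positive for NMAE")
    return float(np.mean(np.abs(im - ri)) / m)


def psnr(im: np.ndarray, ri: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    im, ri = _check_pair(im, ri)
    rmse = float(np.sqrt(np.mean((im - ri) ** 2)))
    if rmse == 0.0:
        return math.inf
    mx = float(max(im.max(), ri.max()))
    if mx <= 0:
        raise ValueError("maximum pixel value must be positive for PSNR")
    return float(20.0 * np.log10(mx / rmse))


def ssim(im: np.ndarray, ri: np.ndarray, windowed: bool = False) -> float:
    """Structural similarity between im and ri.

    The default uses image-wide moments (one global window).  With
    ``windowed=True`` the conventional sliding-window mean SSIM is computed
    instead (via scikit-image) — exposed because both conventions are in
    use in the literature.
    """
    im, ri = _check_pair(im, ri)
    if np.array_equal(im, ri):
        return 1.0
    L = float(ri.max() - ri.min())
    if L == 0:
        L = float(max(abs(ri.max()), 1.0))
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(im, ri, data_range=L))
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mu_im, mu_ri = im.mean(), ri.mean()
    var_im = im.var()
    var_ri = ri.var()
    cov = ((im - mu_im) * (ri - mu_ri)).mean()
    return float(
        (2 * mu_im * mu_ri + c1)
        * (2 * cov + c2)
        / ((mu_im**2 + mu_ri**2 + c1) * (var_im + var_ri + c2))
    )


def quality_report(im: np.ndarray, ri: np.ndarray) -> dict[str, float]:
    """All four measures for one candidate/reference pair."""
    return {
        "nrmse": nrmse(im, ri),
        "nmae": nmae(im, ri),
        "psnr_db": psnr(im, ri),
        "ssim": ssim(im, ri),
    }


def compare_sets(
    candidates: Mapping[str, Mapping[float, np.ndarray]],
    reference: Mapping[float, np.ndarray],
    scope: str = "reconstruction",
) -> pd.DataFrame:
    """Score candidate methods against a reference, per time point.

    ``candidates`` maps method label -> {time_point_h: array}; ``reference``
    maps time_point_h -> array.  Returns a tidy table with one row per
    (method, time point) and columns method, scope, time_point,
    nrmse, nmae, psnr_db, ssim.
    """
    rows = []
    for method, series in candidates.items():
        for t, ref in reference.items():
            if t not in series:
                raise KeyError(f"candidate {method!r} missing time point {t}")
            im = np.asarray(series[t])
            if im.shape != np.asarray(ref).shape:
                raise ValueError(
                    f"candidate {method!r} at t={t} has shape {im.shape}, "
                    f"reference has {np.asarray(ref).shape}"
                )
            rows.append(
                {"method": method, "scope": scope, "time_point": t, **quality_report(im, ref)}
            )
    return pd.DataFrame(rows)
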