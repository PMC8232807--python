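"""First-order (histogram and moment) statistics of ROI intensities."""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

__all__ = ["first_order_features"]

_EPS = np.spacing(1.0)


def first_order_features(
    disc: DiscretizedROI, voxel_volume: float = 1.0
) -> dict[str, float]:
    """The 18 default-enabled first-order features.

    Entropy and Uniformity are computed on the discretized histogram;
    everything else on the raw ROI intensities.  Skewness and Kurtosis
    are population moments (Kurtosis is not excess-corrected) and fall
    back to 0 for a constant ROI.
    """
    x = disc.roi_values
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:
        rmad = 0.0

    counts = np.bincount(disc.roi_levels, minlength=disc.n_bins + 1)[1:]
    p = counts / n
    nz = p[p > 0]

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": float(-(nz * np.log2(nz + _EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float((nz**2).sum()),
    }
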