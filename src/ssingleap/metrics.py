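"""Global abundance metrics.

APF (abasic-site fraction) is the number of read pairs that survive all
filters and represent lesions, divided by the number of read pairs carrying
the expected polyG/polyT tag structure; ASF is the identical ratio computed
on a single-strand-break library. APL is the electrophoretic analog: the
fraction of library mass between 180 and 1000 bp (genome-derived product,
above the ~160 bp primer-dimer ceiling) relative to the mass between 1 and
1000 bp.
"""

from __future__ import annotations

import numpy as np

from .io_formats import APSiteSet
from .sitecall import FilterStats

__all__ = ["compute_apf", "compute_apl", "apf_from_stats"]

APL_LOWER = 180.0
APL_UPPER = 1000.0
APL_TOTAL_LOWER = 1.0


def compute_apf(site_read_count: int, tag_pass_pair_count: int) -> float | None:
    """Fraction of tag-structure read pairs that represent lesion sites.

    Read-based: multiple reads at one position all count. Returns None for a
    zero denominator.
    """
    if tag_pass_pair_count == 0:
        return None
    return site_read_count / tag_pass_pair_count


def apf_from_stats(stats: FilterStats) -> float | None:
    return compute_apf(stats.site_reads, stats.tag_pass)


def _band_integral(profile: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of the intensity curve over [lo, hi], with linear
    interpolation at the band edges."""
    sizes, intensities = profile[:, 0], profile[:, 1]
    lo = max(lo, float(sizes[0]))
    hi = min(hi, float(sizes[-1]))
    if lo >= hi:
        return 0.0
    grid = np.unique(np.concatenate([[lo, hi], sizes[(sizes > lo) & (sizes < hi)]]))
    values = np.interp(grid, sizes, intensities)
    return float(np.trapezoid(values, grid))


def compute_apl(profile: np.ndarray) -> float | None:
    """Fraction of library mass in the 180-1000 bp band relative to the
    1-1000 bp band, from a sampled (size_bp, intensity) curve.

    The profile must have strictly increasing sizes and non-negative
    intensities. Returns None if the total band mass is zero.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2 or profile.shape[1] != 2 or len(profile) < 2:
        raise ValueError("profile must be an (n >= 2, 2) array of (size, intensity)")
    if np.any(np.diff(profile[:, 0]) <= 0):
        raise ValueError("profile sizes must be strictly increasing")
    if np.any(profile[:, 1] < 0):
        raise ValueError("intensities must be non-negative")
    total = _band_integral(profile, APL_TOTAL_LOWER, APL_UPPER)
    if total == 0:
        return None
    return _band_integral(profile, APL_LOWER, APL_UPPER) / total
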