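"""Peak detection on the smoothed coverage curve and base attribution.

A peak is a strict local maximum of the smoothed frequency curve — a sample
whose neighbouring samples are smaller — surviving a minimum-height and a
minimum-prominence filter, both expressed as fractions of the curve's
global maximum so defaults are histogram-scale-free.  After widths are
measured (at a fraction of the prominence below the peak top), the retained
coverage axis is partitioned into one region per peak, and each peak's area
is the number of bases of the raw tail-filtered histogram falling in its
region.  Those areas are the C and U quantities of the haploidy score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .histogram import CoverageHistogram, SmoothedCurve

__all__ = ["PeakDetectionParams", "Peak", "detect_peaks", "measure_widths", "assign_regions"]


@dataclass(frozen=True)
class PeakDetectionParams:
    """Thresholds for peak detection, relative to the curve maximum.

    min_height_frac : minimum peak height, as a fraction of max(curve).
    min_prominence_frac : minimum prominence, same scale.
    rel_height : fraction of the prominence below the top at which the
        peak width is measured (0.5 = width at half prominence).
    """

    min_height_frac: float = 0.05
    min_prominence_frac: float = 0.05
    rel_height: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_height_frac", "min_prominence_frac", "rel_height"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class Peak:
    """A detected coverage mode.

    position is the coverage value (X) of the mode; region is the integer
    coverage range [lo, hi] attributed to the peak and area the raw base
    count within it.  label is assigned later by classification.
    """

    position: int
    height: float
    prominence: float
    width_interval: tuple[float, float] | None = None
    region: tuple[int, int] | None = None
    area: int | None = None
    label: str = "unlabeled"
    # scipy prominence bases, kept for width measurement
    _left_base: int = field(default=0, repr=False)
    _right_base: int = field(default=0, repr=False)

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "height": self.height,
            "prominence": self.prominence,
            "width_interval": list(self.width_interval) if self.width_interval else None,
            "region": list(self.region) if self.region else None,
            "area": self.area,
            "label": self.label,
        }


def detect_peaks(
    curve: SmoothedCurve, params: PeakDetectionParams = PeakDetectionParams()
) -> list[Peak]:
    """Find strict local maxima passing the height and prominence filters.

    Plateau maxima report the plateau midpoint.  A curve with no qualifying
    maximum (e.g. strictly constant) yields an empty list.
    """
    y = np.asarray(curve.values, dtype=float)
    if len(y) < 3:
        raise ValueError("curve must have at least 3 samples for peak detection")
    top = float(y.max())
    if top <= 0:
        return []
    idx, props = find_peaks(
        y,
        height=params.min_height_frac * top,
        prominence=params.min_prominence_frac * top,
    )
    peaks = [
        Peak(
            position=int(curve.coverage_bins[i]),
            height=float(y[i]),
            prominence=float(props["prominences"][k]),
            _left_base=int(props["left_bases"][k]),
            _right_base=int(props["right_bases"][k]),
        )
        for k, i in enumerate(idx)
    ]
    peaks.sort(key=lambda p: p.position)
    return peaks


def measure_widths(
    curve: SmoothedCurve,
    peaks: list[Peak],
    params: PeakDetectionParams = PeakDetectionParams(),
) -> list[Peak]:
    """Set each peak's width interval.

    The interval endpoints are the x positions where the curve crosses the
    evaluation height ``peak_height - rel_height * prominence`` on each
    side of the mode, linearly interpolated between samples and clipped to
    the curve domain.
    """
    if not peaks:
        return peaks
    y = np.asarray(curve.values, dtype=float)
    bins = np.asarray(curve.coverage_bins)
    idx = np.array([int(np.searchsorted(bins, p.position)) for p in peaks])
    prominence_data = (
        np.array([p.prominence for p in peaks]),
        np.array([p._left_base for p in peaks]),
        np.array([p._right_base for p in peaks]),
    )
    _, _, left_ips, right_ips = peak_widths(
        y, idx, rel_height=params.rel_height, prominence_data=prominence_data
    )
    lo_dom, hi_dom = float(bins[0]), float(bins[-1])
    for p, li, ri in zip(peaks, left_ips, right_ips):
        p.width_interval = (
            max(lo_dom, float(bins[0] + li)),
            min(hi_dom, float(bins[0] + ri)),
        )
    return peaks


def _boundary(
    left: Peak, right: Peak, curve: SmoothedCurve | None
) -> float:
    """Coverage value separating two consecutive peaks' regions.

    Midpoint of the gap between the left peak's right width-edge and the
    right peak's left width-edge; when the width intervals overlap, the
    coverage of the minimum of the smoothed curve between the two modes
    (lowest coverage on ties).
    """
    r_edge = left.width_interval[1]
    l_edge = right.width_interval[0]
    if r_edge < l_edge:
        return (r_edge + l_edge) / 2.0
    if curve is not None:
        bins = np.asarray(curve.coverage_bins)
        y = np.asarray(curve.values, dtype=float)
        lo = int(np.searchsorted(bins, left.position))
        hi = int(np.searchsorted(bins, right.position))
        if hi > lo + 1:
            seg = y[lo + 1 : hi]
            return float(bins[lo + 1 + int(np.argmin(seg))])
    return (left.position + right.position) / 2.0


def assign_regions(
    hist_filtered: CoverageHistogram,
    peaks: list[Peak],
    curve: SmoothedCurve | None = None,
) -> list[Peak]:
    """Partition the retained coverage range among the peaks and set areas.

    The first region starts at the lowest retained bin, the last ends at
    the highest; interior boundaries come from the peaks' width intervals
    (see :func:`_boundary`).  Areas are sums of the raw tail-filtered
    histogram counts, so the areas of all peaks always sum exactly to the
    filtered histogram total.
    """
    if not peaks:
        raise ValueError("no peaks to attribute")
    for p in peaks:
        if p.width_interval is None:
            raise ValueError("peaks must have measured widths before region assignment")
    covs = sorted(hist_filtered.counts)
    lo_all, hi_all = covs[0], covs[-1]
    boundaries = [_boundary(peaks[i], peaks[i + 1], curve) for i in range(len(peaks) - 1)]
    edges = [lo_all - 1] + [int(np.floor(b)) for b in boundaries] + [hi_all]
    for i, p in enumerate(peaks):
        lo = edges[i] + 1
        hi = edges[i + 1]
        p.region = (lo, hi)
        p.area = sum(n for c, n in hist_filtered.counts.items() if lo <= c <= hi)
    return peaks
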