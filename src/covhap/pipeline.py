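"""End-to-end haploidy estimation from a coverage histogram.

Chains the stages: tail filter -> Savitzky-Golay smoothing -> peak
detection -> width measurement -> region/area attribution -> positional
classification -> haploidy = C / (C + U/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .haploidy import CoverageLimits, HaploidyResult, classify_peaks, haploidy_score
from .histogram import (
    CoverageHistogram,
    SmoothedCurve,
    SmoothingParams,
    TailFilterParams,
    filter_tail,
    smooth,
)
from .peaks import Peak, PeakDetectionParams, assign_regions, detect_peaks, measure_widths

__all__ = ["EstimateResult", "estimate_haploidy"]


@dataclass
class EstimateResult:
    """Everything the haploidy pipeline produced for one histogram."""

    histogram_filtered: CoverageHistogram
    curve: SmoothedCurve
    peaks: list[Peak]
    result: HaploidyResult | None
    warnings: list[str] = field(default_factory=list)

    def to_report(self, *, version: str = "", config: dict | None = None) -> dict:
        return {
            "tool": "covhap",
            "version": version,
            "config": config or {},
            "filtered_histogram": {
                "total_bases": self.histogram_filtered.total_bases,
                "max_coverage": self.histogram_filtered.max_coverage,
            },
            "peaks": [p.to_dict() for p in self.peaks],
            "haploidy": None if self.result is None else self.result.to_dict(),
            "warnings": list(self.warnings),
        }


def estimate_haploidy(
    hist: CoverageHistogram,
    limits: CoverageLimits,
    tail: TailFilterParams = TailFilterParams(),
    smoothing: SmoothingParams = SmoothingParams(),
    detection: PeakDetectionParams = PeakDetectionParams(),
) -> EstimateResult:
    """Run the full haploidy pipeline on a raw coverage histogram.

    When no peak lands in either the collapsed or the uncollapsed range
    the score is undefined: ``result`` is None and a warning explains why,
    rather than raising, so callers can still inspect the peak table.
    """
    warnings: list[str] = []
    filtered = filter_tail(hist, tail)
    curve = smooth(filtered, smoothing)
    peaks = detect_peaks(curve, detection)
    if not peaks:
        warnings.append("no peaks detected in the smoothed coverage curve")
        return EstimateResult(filtered, curve, [], None, warnings)
    peaks = measure_widths(curve, peaks, detection)
    peaks = assign_regions(filtered, peaks, curve)
    peaks = classify_peaks(peaks, limits)
    try:
        result = haploidy_score(peaks)
        warnings.extend(result.warnings)
    except ValueError as exc:
        warnings.append(str(exc))
        result = None
    return EstimateResult(filtered, curve, peaks, result, warnings)
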