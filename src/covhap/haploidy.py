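"""Peak classification and the haploidy score.

In a well-collapsed haploid assembly of a diploid genome, reads from both
haplotypes map to one contig, so the coverage histogram shows a single peak
at the full sequencing depth (the collapsed peak, area C in bases).
Regions assembled as two separate haplotigs split their reads between two
contigs and appear as a peak at roughly half depth (the uncollapsed peak,
area U).  Co-sequenced contaminants show up as a low-coverage peak and are
excluded.  The haploidy score is

    haploidy = C / (C + U/2)

i.e. the collapsed fraction of the bases a perfectly collapsed assembly
would contain (the U bases would contribute U/2 once collapsed).  The
score is 1 when there is no uncollapsed peak and 0 when nothing is
collapsed.  Hemizygous deletions and haploid chromosomes also produce
half-coverage signal, so a perfect score is not always attainable even for
a perfect assembly; no correction is applied for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histogram import SmoothedCurve
from .peaks import Peak

__all__ = ["CoverageLimits", "HaploidyResult", "classify_peaks", "haploidy_score", "suggest_limits"]

CONTAMINANT = "contaminant"
UNCOLLAPSED = "uncollapsed"
COLLAPSED = "collapsed"


@dataclass(frozen=True)
class CoverageLimits:
    """User-supplied coverage thresholds separating the three peak ranges.

    A peak at position <= contaminant_max is a contaminant; one at
    contaminant_max < position <= uncollapsed_max is uncollapsed; anything
    above is collapsed.
    """

    contaminant_max: float
    uncollapsed_max: float

    def __post_init__(self) -> None:
        if not 0 <= self.contaminant_max < self.uncollapsed_max:
            raise ValueError(
                "limits must satisfy 0 <= contaminant_max < uncollapsed_max, "
                f"got ({self.contaminant_max}, {self.uncollapsed_max})"
            )


@dataclass
class HaploidyResult:
    """Classified base areas and the resulting haploidy score."""

    C: int
    U: int
    contaminant_bases: int
    haploidy: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "U": self.U,
            "contaminant_bases": self.contaminant_bases,
            "haploidy": round(self.haploidy, 3),
            "warnings": list(self.warnings),
        }


def classify_peaks(peaks: list[Peak], limits: CoverageLimits) -> list[Peak]:
    """Label each peak by the coverage range its mode falls in.

    Classification is purely positional against the user limits.  When
    several peaks land in the same range they all keep that label (their
    areas are merged downstream) and a warning is attached at scoring time.
    """
    if not peaks:
        raise ValueError("no peaks to classify")
    for p in peaks:
        if p.position <= limits.contaminant_max:
            p.label = CONTAMINANT
        elif p.position <= limits.uncollapsed_max:
            p.label = UNCOLLAPSED
        else:
            p.label = COLLAPSED
    return peaks


def haploidy_score(classified: list[Peak]) -> HaploidyResult:
    """Compute haploidy = C / (C + U/2) from labeled peak areas.

    C is the summed area of collapsed peaks, U of uncollapsed peaks;
    contaminant areas are excluded from the formula.  With no uncollapsed
    peak the score is 1.0; with no collapsed peak it is 0.0; with neither,
    the score is undefined and an error is raised.
    """
    if not classified:
        raise ValueError("no peaks to score")
    warnings: list[str] = []
    sums = {CONTAMINANT: 0, UNCOLLAPSED: 0, COLLAPSED: 0}
    counts = {CONTAMINANT: 0, UNCOLLAPSED: 0, COLLAPSED: 0}
    for p in classified:
        if p.label not in sums:
            raise ValueError(f"peak at {p.position} is unlabeled")
        if p.area is None:
            raise ValueError(f"peak at {p.position} has no area")
        sums[p.label] += p.area
        counts[p.label] += 1
    for label, n in counts.items():
        if n > 1:
            warnings.append(f"{n} peaks classified as {label}; their areas were merged")
    C, U = sums[COLLAPSED], sums[UNCOLLAPSED]
    if C == 0 and U == 0:
        raise ValueError("no collapsed or uncollapsed peak found; haploidy undefined")
    # Advisory: an uncollapsed peak is expected near half the collapsed depth.
    col = [p for p in classified if p.label == COLLAPSED]
    unc = [p for p in classified if p.label == UNCOLLAPSED]
    if col and unc:
        cpos = max(col, key=lambda p: p.height).position
        for p in unc:
            if not 0.35 * cpos <= p.position <= 0.65 * cpos:
                warnings.append(
                    f"uncollapsed peak at {p.position}X is not near half the "
                    f"collapsed peak ({cpos}X); check the coverage limits"
                )
    score = C / (C + U / 2.0)
    return HaploidyResult(
        C=C, U=U, contaminant_bases=sums[CONTAMINANT], haploidy=score, warnings=warnings
    )


def suggest_limits(curve: SmoothedCurve, peaks: list[Peak]) -> CoverageLimits:
    """Propose coverage limits from the detected peak structure.

    Helper only — limits remain a user decision.  contaminant_max is set
    at the curve minimum before the lowest of the two highest peaks (0 if
    there is no lower peak), and uncollapsed_max at the curve minimum
    between the two highest peaks (or 60% of the sole peak's position when
    only one peak exists).
    """
    if not peaks:
        raise ValueError("no peaks detected; cannot suggest limits")
    y = np.asarray(curve.values, dtype=float)
    bins = np.asarray(curve.coverage_bins)
    main = sorted(sorted(peaks, key=lambda p: p.height)[-2:], key=lambda p: p.position)
    if len(main) == 1:
        return CoverageLimits(0.0, 0.6 * main[0].position)
    lo, hi = main[0].position, main[1].position
    i0, i1 = int(np.searchsorted(bins, lo)), int(np.searchsorted(bins, hi))
    unc_max = float(bins[i0 + 1 + int(np.argmin(y[i0 + 1 : i1]))]) if i1 > i0 + 1 else (lo + hi) / 2
    lower = [p for p in peaks if p.position < lo]
    cont_max = 0.0
    if lower:
        j = int(np.searchsorted(bins, max(p.position for p in lower)))
        if i0 > j + 1:
            cont_max = float(bins[j + 1 + int(np.argmin(y[j + 1 : i0]))])
    return CoverageLimits(cont_max, unc_max)
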