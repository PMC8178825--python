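"""Per-assembly scorecard: size, N50, completeness, haploidy.

Four 0-to-1 scores summarise an assembly of a diploid genome against an
estimated haploid genome size G:

* size score      S = 1 - |s - G| / G, where s is the assembly size;
* N50             the length of the largest contig for which half the
                  assembly size is contained in contigs of equal or
                  greater length (raw value; optionally min-max
                  normalized to fit a 0-1 scorecard axis);
* completeness    Comp = (B_norm + K_norm) / 2, the mean of the min-max
                  normalized single-copy BUSCO count and of the k-mer
                  completeness score K = 1 - |k_obs - k_exp| / k_exp
                  (k_exp = 50% for a haploid assembly of a diploid:
                  heterozygous k-mers should be half-represented);
* haploidy        from the coverage-histogram analysis (haploidy module).

Min-max normalization is relative to a user-declared comparison set of
assemblies, so completeness is a within-set ranking, not an absolute.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

__all__ = [
    "ScoreInputs",
    "NormalizationContext",
    "ScoreCard",
    "n50",
    "size_score",
    "kmer_score",
    "minmax_normalize",
    "completeness_score",
    "scorecard",
    "DEFAULT_GENOME_SIZE",
    "DEFAULT_KMER_EXPECTED",
]

# Defaults used throughout: haploid genome size of the studied annelid
# (102 Mb) and the 50% k-mer completeness expected of a collapsed haploid
# assembly of a diploid genome.
DEFAULT_GENOME_SIZE = 102_000_000
DEFAULT_KMER_EXPECTED = 50.0


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class ScoreInputs:
    """Raw inputs of the four scores for one assembly."""

    contig_lengths: list[int]
    genome_size: float = DEFAULT_GENOME_SIZE
    kmer_completeness: float = 0.0  # observed, percent
    kmer_expected: float = DEFAULT_KMER_EXPECTED  # percent
    busco_single: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        if self.kmer_expected <= 0:
            raise ValueError("kmer_expected must be > 0")
        if self.kmer_completeness < 0:
            raise ValueError("kmer_completeness must be >= 0")
        if not self.contig_lengths or any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig_lengths must be non-empty positive integers")

    @property
    def assembly_size(self) -> int:
        return sum(self.contig_lengths)


@dataclass(frozen=True)
class NormalizationContext:
    """Min and max of a metric across the compared assembly set."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min:
            raise ValueError("x_max must be >= x_min")

    @classmethod
    def from_values(cls, values) -> "NormalizationContext":
        vals = list(values)
        if not vals:
            raise ValueError("empty comparison set")
        return cls(x_min=min(vals), x_max=max(vals))


@dataclass
class ScoreCard:
    """The four scores plus their raw ingredients for one assembly."""

    size_score: float
    n50: int
    completeness: float
    haploidy: float | None
    # raw / intermediate values
    assembly_size: int = 0
    size_score_raw: float = 0.0
    n50_normalized: float | None = None
    kmer_score_raw: float = 0.0
    kmer_score_normalized: float = 0.0
    busco_normalized: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "size_score": round(self.size_score, 3),
            "n50": self.n50,
            "n50_normalized": None if self.n50_normalized is None else round(self.n50_normalized, 3),
            "completeness": round(self.completeness, 3),
            "haploidy": None if self.haploidy is None else round(self.haploidy, 3),
            "assembly_size": self.assembly_size,
            "size_score_raw": self.size_score_raw,
            "kmer_score_raw": self.kmer_score_raw,
            "kmer_score_normalized": self.kmer_score_normalized,
            "busco_normalized": self.busco_normalized,
            "warnings": list(self.warnings),
        }


def n50(contig_lengths) -> int:
    """Length of the largest contig such that contigs of that length or
    longer contain at least half the assembly size."""
    lengths = sorted(contig_lengths, reverse=True)
    if not lengths:
        raise ValueError("empty contig length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2.0
    cum = 0
    for l in lengths:
        cum += l
        if cum >= half:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def size_score(s: float, G: float = DEFAULT_GENOME_SIZE) -> float:
    """S = 1 - |s - G| / G (raw; may be negative for s > 2G)."""
    if G <= 0:
        raise ValueError("genome size G must be > 0")
    if s < 0:
        raise ValueError("assembly size must be >= 0")
    return 1.0 - abs(s - G) / G


def kmer_score(k_obs: float, k_exp: float = DEFAULT_KMER_EXPECTED) -> float:
    """K = 1 - |k_obs - k_exp| / k_exp (raw; may be negative for k_obs > 2·k_exp)."""
    if k_exp <= 0:
        raise ValueError("expected k-mer completeness must be > 0")
    return 1.0 - abs(k_obs - k_exp) / k_exp


def minmax_normalize(x_i: float, ctx: NormalizationContext) -> float:
    """(x_i - x_min) / (x_max - x_min); 1.0 with a warning on an all-equal set."""
    if not ctx.x_min <= x_i <= ctx.x_max:
        raise ValueError(f"value {x_i} outside normalization range [{ctx.x_min}, {ctx.x_max}]")
    if ctx.x_max == ctx.x_min:
        _warnings.warn("all-equal normalization set; returning 1.0", stacklevel=2)
        return 1.0
    return (x_i - ctx.x_min) / (ctx.x_max - ctx.x_min)


def completeness_score(B_norm: float, K_norm: float) -> float:
    """Comp = (B_norm + K_norm) / 2, both inputs already on the 0-1 scale."""
    for name, v in (("B_norm", B_norm), ("K_norm", K_norm)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return (B_norm + K_norm) / 2.0


def scorecard(
    inputs: ScoreInputs,
    haploidy: float | None,
    ctx_busco: NormalizationContext,
    ctx_kmer: NormalizationContext,
    ctx_n50: NormalizationContext | None = None,
) -> ScoreCard:
    """Assemble the four scores for one assembly.

    ``ctx_busco`` and ``ctx_kmer`` are min/max of the single-copy BUSCO
    count and of the raw k-mer score K over the comparison set; pass
    ``ctx_n50`` to additionally report a min-max normalized N50 for 0-1
    scorecard plots.  Display scores are clamped to [0, 1]; raw values are
    retained alongside.
    """
    card_warnings: list[str] = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        s_raw = size_score(inputs.assembly_size, inputs.genome_size)
        k_raw = kmer_score(inputs.kmer_completeness, inputs.kmer_expected)
        b_norm = minmax_normalize(float(inputs.busco_single), ctx_busco)
        k_norm = minmax_normalize(k_raw, ctx_kmer)
        comp = completeness_score(_clamp01(b_norm), _clamp01(k_norm))
        n50_val = n50(inputs.contig_lengths)
        n50_norm = None if ctx_n50 is None else minmax_normalize(float(n50_val), ctx_n50)
        card_warnings.extend(str(w.message) for w in caught)
    return ScoreCard(
        size_score=_clamp01(s_raw),
        n50=n50_val,
        completeness=comp,
        haploidy=haploidy,
        assembly_size=inputs.assembly_size,
        size_score_raw=s_raw,
        n50_normalized=n50_norm,
        kmer_score_raw=k_raw,
        kmer_score_normalized=k_norm,
        busco_normalized=b_norm,
        warnings=card_warnings,
    )
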