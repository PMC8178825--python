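"""Synthetic per-base depth profiles with known ground truth.

The generator emulates the three-component structure a long-read coverage
histogram can show: a low-coverage contaminant component, an uncollapsed
component at about half the collapsed depth (reads split between the two
haplotigs of an uncollapsed region), and a collapsed component at the full
sequencing depth.  Each position is assigned a component and its depth is
drawn from an overdispersed count distribution (negative binomial with
mean m and variance m·(1 + dispersion); dispersion 0 recovers a Poisson).
Positions are exchangeable — no along-genome autocorrelation is simulated,
which is irrelevant here because the haploidy metric consumes only the
histogram.  The realized component base counts give an analytic expected
haploidy C/(C + U/2) to test the pipeline against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationParams", "SyntheticTruth", "simulate_depths", "simulate_contig_lengths"]


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth description of a simulated depth profile.

    Fractions are base fractions of the three components and must sum to
    1; depths are mean depths in X; dispersion d sets the count noise
    variance to mean·(1+d) per component (d = 0 → Poisson).
    """

    n_bases: int = 1_000_000
    collapsed_fraction: float = 1.0
    uncollapsed_fraction: float = 0.0
    contaminant_fraction: float = 0.0
    collapsed_depth: float = 100.0
    uncollapsed_depth_ratio: float = 0.5
    contaminant_depth: float = 10.0
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.collapsed_fraction, self.uncollapsed_fraction, self.contaminant_fraction)
        if any(f < 0 for f in fr):
            raise ValueError("component fractions must be >= 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {sum(fr)}")
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        if self.collapsed_depth <= 0 or self.contaminant_depth <= 0:
            raise ValueError("depths must be > 0")
        if not 0 < self.uncollapsed_depth_ratio < 1:
            raise ValueError("uncollapsed_depth_ratio must be in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if (
            self.contaminant_fraction > 0
            and self.contaminant_depth >= self.uncollapsed_depth_ratio * self.collapsed_depth
        ):
            raise ValueError("contaminant_depth must lie below the uncollapsed depth")

    @property
    def uncollapsed_depth(self) -> float:
        return self.uncollapsed_depth_ratio * self.collapsed_depth


@dataclass(frozen=True)
class SyntheticTruth:
    """Realized per-component base counts of a simulated profile."""

    collapsed_bases: int
    uncollapsed_bases: int
    contaminant_bases: int

    @property
    def n_bases(self) -> int:
        return self.collapsed_bases + self.uncollapsed_bases + self.contaminant_bases

    @property
    def expected_haploidy(self) -> float:
        """Haploidy C/(C + U/2) applied to the ground-truth base counts."""
        C, U = self.collapsed_bases, self.uncollapsed_bases
        if C == 0 and U == 0:
            raise ValueError("no collapsed or uncollapsed bases in truth")
        return C / (C + U / 2.0)

    def to_dict(self) -> dict:
        return {
            "collapsed_bases": self.collapsed_bases,
            "uncollapsed_bases": self.uncollapsed_bases,
            "contaminant_bases": self.contaminant_bases,
            "expected_haploidy": (
                self.expected_haploidy
                if (self.collapsed_bases or self.uncollapsed_bases)
                else None
            ),
        }


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    """Counts with the given mean and variance mean·(1+dispersion)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=n).astype(np.int64)
    # negative binomial: var = m + m^2/r = m(1+d)  =>  r = m/d
    r = mean / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n).astype(np.int64)


def simulate_depths(params: SimulationParams) -> tuple[np.ndarray, SyntheticTruth]:
    """Simulate a per-base depth sequence and its ground truth.

    Component membership is multinomial over the base fractions; the truth
    counts report the realized (not nominal) assignment.  Identical params
    and seed give identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_bases
    counts = rng.multinomial(
        n,
        [params.collapsed_fraction, params.uncollapsed_fraction, params.contaminant_fraction],
    )
    n_col, n_unc, n_cont = (int(c) for c in counts)
    depths = np.concatenate(
        [
            _draw_counts(rng, params.collapsed_depth, params.dispersion, n_col),
            _draw_counts(rng, params.uncollapsed_depth, params.dispersion, n_unc),
            _draw_counts(rng, params.contaminant_depth, params.dispersion, n_cont),
        ]
    )
    rng.shuffle(depths)
    truth = SyntheticTruth(
        collapsed_bases=n_col, uncollapsed_bases=n_unc, contaminant_bases=n_cont
    )
    return depths, truth


def simulate_contig_lengths(n_contigs: int, total_size: int, seed: int = 0) -> list[int]:
    """Random positive contig lengths summing exactly to total_size."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if total_size < n_contigs:
        raise ValueError("total_size must be >= n_contigs (lengths are positive)")
    rng = np.random.default_rng(seed)
    # place n_contigs - 1 distinct cut points in (0, total_size)
    cuts = rng.choice(total_size - 1, size=n_contigs - 1, replace=False) + 1
    cuts.sort()
    edges = np.concatenate([[0], cuts, [total_size]])
    return np.diff(edges).astype(int).tolist()
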