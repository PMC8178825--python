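"""File readers and writers for the formats the tool consumes and emits.

Supported formats: per-base depth tables in the samtools-depth dialect
(sequence id, 1-based position, integer depth, tab-separated), two-column
coverage histogram TSV (coverage, base count; '#' comments ignored), FASTA
(contig lengths only), and the JSON report.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .histogram import CoverageHistogram

__all__ = [
    "read_depth_table",
    "read_histogram_tsv",
    "write_histogram_tsv",
    "read_contig_lengths",
    "write_depth_table",
    "write_report",
]


def read_depth_table(path) -> np.ndarray:
    """Read per-base depths from a samtools-depth-style TSV.

    Returns the depth column only; sequence ids and positions are not
    needed by the histogram-based metric.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["seq", "pos", "depth"],
            usecols=[0, 1, 2],
            dtype={"seq": str, "pos": np.int64, "depth": np.int64},
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        # pandas does not report the offending line for dtype errors; rescan.
        line_no = _find_bad_line(path)
        raise ValueError(f"malformed depth table {path}, line {line_no}: {exc}") from exc
    if df.empty:
        raise ValueError(f"empty depth table: {path}")
    return df["depth"].to_numpy()


def _find_bad_line(path: Path) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                return i
            try:
                int(fields[1]), int(fields[2])
            except ValueError:
                return i
    return 0


def read_histogram_tsv(path, *, include_zero: bool = False, source: str | None = None) -> CoverageHistogram:
    """Read a two-column coverage/count TSV into a histogram."""
    path = Path(path)
    counts: dict[int, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed histogram {path}, line {i}: expected 2 columns")
            try:
                cov, n = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(f"malformed histogram {path}, line {i}: {exc}") from exc
            counts[cov] = counts.get(cov, 0) + n
    if not include_zero:
        counts.pop(0, None)
    if not counts:
        raise ValueError(f"empty histogram: {path}")
    return CoverageHistogram(counts=counts, source=source or str(path))


def write_histogram_tsv(hist: CoverageHistogram, path) -> None:
    with open(path, "w") as fh:
        for cov in sorted(hist.counts):
            fh.write(f"{cov}\t{hist.counts[cov]}\n")


def write_depth_table(depths, path, *, seq_id: str = "synthetic") -> None:
    """Write depths as a samtools-depth-style table with 1-based positions."""
    with open(path, "w") as fh:
        for pos, d in enumerate(depths, start=1):
            fh.write(f"{seq_id}\t{pos}\t{int(d)}\n")


def read_contig_lengths(path) -> list[int]:
    """Contig lengths from a FASTA file (sequence content is not interpreted)."""
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not lengths:
        raise ValueError(f"no FASTA records in {path}")
    if any(l == 0 for l in lengths):
        raise ValueError(f"zero-length record in {path}")
    return lengths


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
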