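"""Coverage-track containers, bedGraph I/O, CPM normalization and sliding-window smoothing.

The coverage model is per-base-pair depth over a genome of named chromosomes.
Normalization scales every value by ``1e6 / total_mapped_reads`` (counts per
million mapped reads, CPM) so that samples of different sequencing depth are
comparable.  Smoothing averages a sliding window (default 100 bp) advanced in
fixed steps (default 10 bp), producing a binned track at step resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "BinnedTrack",
    "read_bedgraph",
    "write_bedgraph",
    "write_sgr",
    "cpm_normalize",
    "smooth_and_bin",
]


class BedGraphError(ValueError):
    """Malformed or out-of-bounds bedGraph input."""


@dataclass
class CoverageTrack:
    """Per-bp signal for each chromosome.

    Parameters
    ----------
    data : dict of str -> ndarray
        One float array per chromosome; length equals the chromosome length.
    total_mapped_reads : int or None
        Mapped-read count used for CPM scaling.  Carried as metadata, never
        inferred from the coverage integral.
    normalized : bool
        Whether values are already CPM.
    """

    data: dict[str, np.ndarray]
    total_mapped_reads: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"coverage for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))


@dataclass
class BinnedTrack:
    """Binned/smoothed signal: bin ``i`` covers ``[i*step, i*step + bin_size)``."""

    data: dict[str, np.ndarray]
    bin_size: int
    step: int
    genome_lengths: dict[str, int] = field(default_factory=dict)
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.step < 1 or self.bin_size < self.step:
            raise ValueError("require bin_size >= step >= 1")
        if not self.genome_lengths:
            # fall back to bin extent; exact length is preferred when known
            self.genome_lengths = {
                c: len(a) * self.step for c, a in self.data.items()
            }

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal of the bin whose origin covers genomic base ``pos``."""
        return float(self.data[chrom][pos // self.step])


def read_bedgraph(path, genome_lengths: dict[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based, half-open) into a dense per-bp track.

    Gaps are zero-filled.  Intervals extending past the chromosome end, on
    unknown chromosomes, or overlapping a previously covered base are rejected
    with the offending line number.
    """
    arrays = {c: np.zeros(length, dtype=float) for c, length in genome_lengths.items()}
    covered = {c: np.zeros(length, dtype=bool) for c, length in genome_lengths.items()}
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return CoverageTrack(arrays)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end, value = row.chrom, int(row.start), int(row.end), float(row.value)
        if chrom not in arrays:
            raise BedGraphError(f"line {i}: unknown chromosome {chrom!r}")
        if start < 0 or end > len(arrays[chrom]) or start >= end:
            raise BedGraphError(
                f"line {i}: interval [{start}, {end}) outside chromosome "
                f"{chrom} of length {len(arrays[chrom])}"
            )
        if covered[chrom][start:end].any():
            raise BedGraphError(f"line {i}: interval [{start}, {end}) overlaps earlier interval")
        arrays[chrom][start:end] = value
        covered[chrom][start:end] = True
    return CoverageTrack(arrays)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a dense track as run-length-collapsed bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_sgr(binned: BinnedTrack, path) -> None:
    """Write a binned track as sgr-style TSV: chrom, bin origin, value."""
    with open(path, "w") as fh:
        for chrom in sorted(binned.data):
            vals = binned.data[chrom]
            for i, v in enumerate(vals):
                fh.write(f"{chrom}\t{i * binned.step}\t{v:.6g}\n")


def cpm_normalize(track: CoverageTrack, total_mapped_reads: int | None = None) -> CoverageTrack:
    """Scale every value by ``1e6 / total_mapped_reads``.

    The scaling factor uses the mapped-read count supplied as metadata (or as
    the argument here), which makes the operation exactly invertible by
    multiplying by ``total_mapped_reads / 1e6``.
    """
    if track.normalized:
        raise ValueError("track is already CPM-normalized")
    total = total_mapped_reads if total_mapped_reads is not None else track.total_mapped_reads
    if not total or total <= 0:
        raise ValueError("total_mapped_reads missing or non-positive")
    factor = 1e6 / total
    return CoverageTrack(
        {c: a * factor for c, a in track.data.items()},
        total_mapped_reads=int(total),
        normalized=True,
    )


def smooth_and_bin(track: CoverageTrack, window: int = 100, step: int = 10) -> BinnedTrack:
    """Sliding-window mean at fixed step: one pass of smoothing and binning.

    Bin ``i`` averages per-bp values over ``[i*step, i*step + window)``,
    left-anchored at the bin origin.  Windows running past the chromosome end
    are truncated and averaged over covered bases only, so subtelomeric signal
    is not diluted by zero padding.  Number of bins per chromosome is
    ``ceil(L / step)`` (every origin strictly inside the chromosome).
    """
    if window < step:
        raise ValueError("window must be >= step")
    if step < 1:
        raise ValueError("step must be >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, arr in track.data.items():
        L = len(arr)
        if L == 0:
            out[chrom] = np.zeros(0)
            continue
        n_bins = (L + step - 1) // step
        csum = np.concatenate(([0.0], np.cumsum(arr)))
        starts = np.arange(n_bins) * step
        stops = np.minimum(starts + window, L)
        out[chrom] = (csum[stops] - csum[starts]) / (stops - starts)
    return BinnedTrack(
        out,
        bin_size=window,
        step=step,
        genome_lengths=track.genome_lengths,
        normalized=track.normalized,
    )
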