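"""Spike-in-normalized ChIP signal and ratio tracks.

ChIP signal is computed per bin as IP/input and scaled by spike-in recovery:
a fixed proportion of foreign-genome chromatin is added to each IP, so the
ratio of spike reads recovered in input vs IP measures the combined effect
of IP efficiency and sequencing depth.  The default (input-anchored) scale
factor is ``input_spike_reads / ip_spike_reads``; equal spike recovery gives
factor 1 and uniform depth changes cancel exactly.  For cross-sample
comparisons on IP-only tracks a reference-anchored factor
``ref_spike / sample_spike`` is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoverageTrack",
    "SpikeInStats",
    "spike_scale",
    "reference_spike_scale",
    "normalized_signal",
    "ratio_track",
    "read_bedgraph",
]


@dataclass
class CoverageTrack:
    """Per-chromosome signal arrays at a fixed bin size.

    ``values[chrom]`` has ceil(chrom_size / bin_size) entries.  Raw coverage
    is non-negative; ratio tracks may hold any real (and NaN where masked).
    """

    values: dict[str, np.ndarray]
    bin_size: int = 1
    label: str = ""

    def __post_init__(self):
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def same_bins(self, other: "CoverageTrack") -> bool:
        return (self.bin_size == other.bin_size
                and self.chroms == other.chroms
                and all(self.values[c].shape == other.values[c].shape for c in self.values))

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def scaled(self, factor: float, label: str | None = None) -> "CoverageTrack":
        return CoverageTrack({c: v * factor for c, v in self.values.items()},
                             self.bin_size, label if label is not None else self.label)

    def binned(self, bin_size: int, label: str | None = None) -> "CoverageTrack":
        """Re-bin by averaging; ``bin_size`` must be a multiple of the current one."""
        if bin_size % self.bin_size:
            raise ValueError("new bin size must be a multiple of the current bin size")
        k = bin_size // self.bin_size
        out = {}
        for c, v in self.values.items():
            n = -(-len(v) // k)
            pad = np.full(n * k, np.nan)
            pad[: len(v)] = v
            out[c] = np.nanmean(pad.reshape(n, k), axis=1)
        return CoverageTrack(out, bin_size, label if label is not None else self.label)

    def to_bedgraph(self, path) -> None:
        """Write runs of constant value as bedGraph lines (zero runs skipped)."""
        with open(path, "w") as fh:
            for chrom in self.chroms:
                v = self.values[chrom]
                if len(v) == 0:
                    continue
                change = np.flatnonzero(np.diff(v) != 0) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(v)]])
                for s, e in zip(starts, ends):
                    val = v[s]
                    if val == 0:
                        continue
                    fh.write(f"{chrom}\t{s * self.bin_size}\t{e * self.bin_size}\t{val:.10g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_size: int = 1,
                  label: str = "") -> CoverageTrack:
    """Read a bedGraph into fixed-bin arrays (positions must align to bins)."""
    values = {c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, val = line.split()[:4]
            s, e = int(s), int(e)
            if chrom not in values:
                raise KeyError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s % bin_size or (e % bin_size and e != chrom_sizes[chrom]):
                raise ValueError(f"{path}:{lineno}: interval not aligned to bin size {bin_size}")
            values[chrom][s // bin_size: -(-e // bin_size)] = float(val)
    return CoverageTrack(values, bin_size, label)


@dataclass(frozen=True)
class SpikeInStats:
    ip_target_reads: int
    ip_spike_reads: int
    input_target_reads: int
    input_spike_reads: int

    def __post_init__(self):
        if self.ip_spike_reads <= 0 or self.input_spike_reads <= 0:
            raise ValueError("spike read counts must be positive for normalization")


def spike_scale(stats: SpikeInStats) -> float:
    """Input-anchored spike scale factor: input_spike / ip_spike.

    Multiplying the IP/input ratio by this factor cancels IP efficiency and
    depth; equal spike recovery in IP and input gives exactly 1.
    """
    return stats.input_spike_reads / stats.ip_spike_reads


def reference_spike_scale(sample_spike_reads: int, ref_spike_reads: int) -> float:
    """Reference-anchored factor for cross-sample IP comparisons."""
    if sample_spike_reads <= 0 or ref_spike_reads <= 0:
        raise ValueError("spike read counts must be positive")
    return ref_spike_reads / sample_spike_reads


def normalized_signal(
    ip: CoverageTrack,
    input_: CoverageTrack,
    stats: SpikeInStats,
    pseudocount: float = 1.0,
    input_floor: float = 0.0,
) -> CoverageTrack:
    """Spike-scaled IP/input signal: scale * (ip + psi)/(input + psi) per bin.

    Bins where input coverage falls below ``input_floor`` are masked to NaN
    (spurious extreme ratios at uncovered positions).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not ip.same_bins(input_):
        raise ValueError("IP and input tracks have mismatched bins")
    scale = spike_scale(stats)
    out = {}
    for c in ip.values:
        sig = scale * (ip.values[c] + pseudocount) / (input_.values[c] + pseudocount)
        if input_floor > 0:
            sig = np.where(input_.values[c] >= input_floor, sig, np.nan)
        out[c] = sig
    return CoverageTrack(out, ip.bin_size, f"{ip.label}/input")


def ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    mode: str = "ratio",
    pseudocount: float = 1.0,
) -> CoverageTrack:
    """Per-bin (num + psi)/(den + psi), optionally log2-transformed."""
    if mode not in ("ratio", "log2"):
        raise ValueError(f"unknown mode {mode!r}")
    if not numerator.same_bins(denominator):
        raise ValueError("tracks have mismatched bins")
    out = {}
    for c in numerator.values:
        r = (numerator.values[c] + pseudocount) / (denominator.values[c] + pseudocount)
        out[c] = np.log2(r) if mode == "log2" else r
    label = f"{mode}({numerator.label}/{denominator.label})"
    return CoverageTrack(out, numerator.bin_size, label)
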