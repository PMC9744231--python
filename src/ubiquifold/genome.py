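"""Genomic containers: binned coverage tracks, chromatin domains and annotations.

Coordinates are 0-based, half-open throughout. Coverage is stored per
chromosome as one value per fixed-width bin; the final bin of a chromosome
may be shorter than ``bin_size`` and is averaged over its actual width.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError, ParameterError

#: Chromatin classes assigned by the canonical/noncanonical classifier.
CHROMATIN_CLASSES = ("canonical", "noncanonical", "active", "neutral")
#: Enrichment levels produced by three-state segmentation of a histone mark.
K27_LEVELS = ("none", "intermediate", "high")
#: Accessibility levels produced by three-state segmentation of ATAC coverage.
ACCESSIBILITY_LEVELS = ("low", "intermediate", "high")


def n_bins(length: int, bin_size: int) -> int:
    return -(-int(length) // int(bin_size))


@dataclass
class ChromatinDomain:
    """A labeled genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    label: str
    mean_level: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class PointPeak:
    """A point-source peak (e.g. Pho at a PRE) with its summit position."""

    chrom: str
    summit: int
    enrichment: float
    q_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ParameterError(f"q-value {self.q_value} outside [0, 1]")


class ChromatinAnnotation:
    """A partition of the genome into labeled, non-overlapping domains.

    Parameters
    ----------
    domains : list of ChromatinDomain
        Sorted or unsorted; sorted on construction. Must not overlap.
    genome : dict mapping chromosome name to length in bp.
    fill_label : str or None
        When given, gaps between domains are filled with this label so the
        annotation covers every base; when None the domains must already
        cover the genome.
    """

    def __init__(
        self,
        domains: list[ChromatinDomain],
        genome: dict[str, int],
        fill_label: str | None = None,
    ) -> None:
        self.genome = dict(genome)
        doms = sorted(domains, key=lambda d: (d.chrom, d.start))
        for d in doms:
            if d.chrom not in self.genome:
                raise InputError(f"domain on unknown chromosome {d.chrom!r}")
            if d.end > self.genome[d.chrom]:
                raise InputError(
                    f"domain {d.chrom}:{d.start}-{d.end} exceeds chromosome length"
                )
        for a, b in zip(doms, doms[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise InputError(
                    f"overlapping domains {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
        if fill_label is not None:
            doms = self._fill_gaps(doms, fill_label)
        self.domains = doms

    def _fill_gaps(
        self, doms: list[ChromatinDomain], label: str
    ) -> list[ChromatinDomain]:
        out: list[ChromatinDomain] = []
        by_chrom: dict[str, list[ChromatinDomain]] = {c: [] for c in self.genome}
        for d in doms:
            by_chrom[d.chrom].append(d)
        for chrom in self.genome:
            pos = 0
            for d in by_chrom[chrom]:
                if d.start > pos:
                    out.append(ChromatinDomain(chrom, pos, d.start, label))
                out.append(d)
                pos = d.end
            if pos < self.genome[chrom]:
                out.append(ChromatinDomain(chrom, pos, self.genome[chrom], label))
        return sorted(out, key=lambda d: (d.chrom, d.start))

    def is_partition(self) -> bool:
        """True when the domains exactly tile every chromosome."""
        covered: dict[str, int] = {c: 0 for c in self.genome}
        pos: dict[str, int] = {c: 0 for c in self.genome}
        for d in self.domains:
            if d.start != pos[d.chrom]:
                return False
            pos[d.chrom] = d.end
            covered[d.chrom] += len(d)
        return all(covered[c] == self.genome[c] for c in self.genome)

    def label_at(self, chrom: str, position: int) -> str | None:
        """Label of the domain containing ``position`` (None if uncovered)."""
        for d in self.domains:
            if d.chrom == chrom and d.start <= position < d.end:
                return d.label
        return None

    def class_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.domains:
            out[d.label] = out.get(d.label, 0) + len(d)
        return out

    def of_class(self, label: str) -> list[ChromatinDomain]:
        return [d for d in self.domains if d.label == label]

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)


@dataclass
class CoverageTrack:
    """Binned coverage for one mark/sample over a genome.

    ``values[chrom]`` holds one value per bin; bins tile the chromosome
    0-based half-open with the last bin possibly truncated.
    """

    genome: dict[str, int]
    bin_size: int
    values: dict[str, np.ndarray]
    mark: str = ""
    sample: str = ""
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ParameterError("bin_size must be positive")
        for chrom, length in self.genome.items():
            if chrom not in self.values:
                raise InputError(f"missing values for chromosome {chrom!r}")
            v = np.asarray(self.values[chrom], dtype=float)
            if v.shape != (n_bins(length, self.bin_size),):
                raise InputError(
                    f"{chrom}: expected {n_bins(length, self.bin_size)} bins, "
                    f"got {v.shape[0]}"
                )
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise InputError(f"{chrom}: coverage must be finite and >= 0")
            self.values[chrom] = v

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor <= 0:
            raise ParameterError("scale factor must be positive")
        return replace(
            self,
            values={c: v * factor for c, v in self.values.items()},
            scale_factor=self.scale_factor * factor,
        )

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean coverage over [start, end).

        Partial bins contribute in proportion to their overlap with the
        interval; raises for intervals outside the genome.
        """
        if chrom not in self.genome:
            raise InputError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.genome[chrom] or start >= end:
            raise InputError(f"interval {chrom}:{start}-{end} outside genome")
        bs = self.bin_size
        first, last = start // bs, (end - 1) // bs
        v = self.values[chrom][first : last + 1]
        edges_lo = np.arange(first, last + 1) * bs
        edges_hi = edges_lo + bs
        w = np.minimum(edges_hi, end) - np.maximum(edges_lo, start)
        return float(np.sum(v * w) / np.sum(w))


def bin_class_labels(
    annotation: ChromatinAnnotation, bin_size: int
) -> dict[str, np.ndarray]:
    """Per-bin class label (by bin midpoint) for every chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom, length in annotation.genome.items():
        nb = n_bins(length, bin_size)
        labels = np.empty(nb, dtype=object)
        mids = np.minimum(
            np.arange(nb) * bin_size + bin_size // 2, length - 1
        )
        doms = [d for d in annotation.domains if d.chrom == chrom]
        starts = np.array([d.start for d in doms])
        idx = np.searchsorted(starts, mids, side="right") - 1
        for i, j in enumerate(idx):
            labels[i] = doms[j].label if j >= 0 and mids[i] < doms[j].end else None
        out[chrom] = labels
    return out
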