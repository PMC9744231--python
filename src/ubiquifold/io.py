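"""Readers and writers for the plain-text formats the pipeline uses.

Traces travel as long-format CSV (molecule_id, frame, donor, acceptor);
coverage as bedGraph rasterized onto the configured bin grid; domains and
annotations as BED4 with the class label in column 4. All genomic
coordinates are 0-based, half-open.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .genome import ChromatinAnnotation, ChromatinDomain, CoverageTrack, n_bins
from .traces import FluorescenceTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_bedgraph",
    "write_bedgraph",
    "read_domains_bed",
    "write_domains_bed",
    "write_json",
]

TRACE_COLUMNS = ["molecule_id", "frame", "donor", "acceptor"]


def read_traces(path: str | Path, frame_interval_s: float = 0.1) -> list[FluorescenceTrace]:
    """Read long-format trace CSV; frames are sorted, gaps rejected."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty trace file") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("frame", "donor", "acceptor"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric {col!r} at line {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise FormatError(f"{path}: missing {col!r} at line {row}")
        df[col] = coerced
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        if np.unique(frames).size != frames.size:
            dup = frames[np.where(np.diff(frames) == 0)[0][0]]
            raise FormatError(f"{path}: duplicate frame {dup} for molecule {mol!r}")
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + frames.size)):
            raise FormatError(f"{path}: non-contiguous frames for molecule {mol!r}")
        traces.append(
            FluorescenceTrace(
                molecule_id=str(mol),
                donor=grp["donor"].to_numpy(dtype=float),
                acceptor=grp["acceptor"].to_numpy(dtype=float),
                frame_interval_s=frame_interval_s,
            )
        )
    return traces


def write_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "molecule_id": t.molecule_id,
                "frame": np.arange(t.n_frames),
                "donor": t.donor,
                "acceptor": t.acceptor,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_bedgraph(
    path: str | Path,
    genome: dict[str, int],
    bin_size: int,
    mark: str = "",
    sample: str = "",
) -> CoverageTrack:
    """Rasterize a bedGraph onto the bin grid (bp-weighted mean per bin;
    uncovered bases count as 0)."""
    path = Path(path)
    sums = {c: np.zeros(n_bins(l, bin_size)) for c, l in genome.items()}
    last_end: dict[str, int] = {}
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 tab-separated fields")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric coordinates/value") from exc
            if chrom not in genome:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start < 0 or end > genome[chrom] or start >= end:
                raise FormatError(f"{path}:{ln}: interval outside genome")
            records.append((chrom, start, end, value, ln))
    records.sort(key=lambda r: (r[0], r[1]))
    for chrom, start, end, value, ln in records:
        if last_end.get(chrom, 0) > start:
            raise FormatError(f"{path}:{ln}: overlapping intervals on {chrom}")
        last_end[chrom] = end
        first, last = start // bin_size, (end - 1) // bin_size
        for b in range(first, last + 1):
            lo, hi = b * bin_size, (b + 1) * bin_size
            sums[chrom][b] += value * (min(hi, end) - max(lo, start))
    values = {}
    for chrom, length in genome.items():
        widths = np.minimum(
            (np.arange(sums[chrom].size) + 1) * bin_size, length
        ) - np.arange(sums[chrom].size) * bin_size
        values[chrom] = sums[chrom] / widths
    return CoverageTrack(
        genome=dict(genome), bin_size=bin_size, values=values, mark=mark, sample=sample
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write sorted, non-overlapping records, merging equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.genome):
            v = track.values[chrom]
            length = track.genome[chrom]
            i = 0
            while i < v.size:
                j = i
                while j < v.size and v[j] == v[i]:
                    j += 1
                start = i * track.bin_size
                end = min(j * track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v[i]:.6g}\n")
                i = j


def read_domains_bed(path: str | Path) -> list[ChromatinDomain]:
    """Read BED4 domains; unsorted input is sorted with a warning."""
    path = Path(path)
    domains = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected BED4 (chrom start end label)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{ln}: invalid interval {start}-{end}")
            domains.append(ChromatinDomain(parts[0], start, end, parts[3]))
    ordered = sorted(domains, key=lambda d: (d.chrom, d.start))
    if [(d.chrom, d.start) for d in domains] != [(d.chrom, d.start) for d in ordered]:
        warnings.warn(f"{path}: BED records were unsorted; sorted on read", stacklevel=2)
    return ordered


def write_domains_bed(
    annotation: ChromatinAnnotation | list[ChromatinDomain], path: str | Path
) -> None:
    domains = list(annotation)
    with open(path, "w") as fh:
        for d in sorted(domains, key=lambda d: (d.chrom, d.start)):
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.label}\n")


def write_json(obj, path: str | Path) -> None:
    """JSON writer tolerant of numpy scalars/arrays and dataclass dicts."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
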