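"""Spike-in normalization and quantitative track comparisons.

Spike-in chromatin added to each ChIP sample lets coverage be placed on
an absolute, cross-sample scale: each sample is rescaled so that its
spike-in read count matches the reference sample's,

    scale_factor_s = spikein_reads_ref / spikein_reads_s,

with the reference (the wild-type sample of the matching stage) fixed at
1. On the normalized tracks the module computes length-weighted gene-body
means, per-gene mutant/wild-type fold changes with class-level median
summaries, average metaprofiles over length-normalized domains with fixed
flanks, and the joint ATAC-FC vs H2Aub1-FC region table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .genome import ChromatinAnnotation, ChromatinDomain, CoverageTrack

__all__ = [
    "SpikeInStats",
    "MetaProfile",
    "spikein_scale_factors",
    "normalize_track",
    "gene_body_coverage",
    "fold_changes",
    "class_median_fc",
    "domain_metaprofile",
    "accessibility_fc_scatter",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class SpikeInStats:
    """Read counts and the derived normalizer for one sample."""

    sample: str
    target_reads: int
    spikein_reads: int
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        if self.target_reads < 0 or self.spikein_reads < 0:
            raise InputError("read counts must be >= 0")


@dataclass
class MetaProfile:
    """Average coverage over length-normalized domains plus fixed flanks."""

    n_bins_body: int
    n_bins_flank: int
    profile: np.ndarray
    n_domains: int

    def __post_init__(self) -> None:
        expected = self.n_bins_body + 2 * self.n_bins_flank
        if self.profile.size != expected:
            raise InputError(
                f"profile length {self.profile.size} != {expected}"
            )

    @property
    def body_slice(self) -> slice:
        return slice(self.n_bins_flank, self.n_bins_flank + self.n_bins_body)


def spikein_scale_factors(
    stats: list[SpikeInStats], reference_sample: str
) -> list[SpikeInStats]:
    """Fill in reference-adjusted spike-in scale factors (reference = 1)."""
    by_name = {s.sample: s for s in stats}
    if reference_sample not in by_name:
        raise InputError(f"reference sample {reference_sample!r} not supplied")
    if any(s.spikein_reads <= 0 for s in stats):
        raise InputError("every sample needs > 0 spike-in reads")
    ref = by_name[reference_sample].spikein_reads
    return [
        SpikeInStats(
            s.sample, s.target_reads, s.spikein_reads, ref / s.spikein_reads
        )
        for s in stats
    ]


def normalize_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply every bin by ``factor`` and record it in scale_factor."""
    if factor <= 0:
        raise ParameterError("normalization factor must be > 0")
    return track.scaled(factor)


def gene_body_coverage(
    track: CoverageTrack,
    genes: pd.DataFrame,
    annotation: ChromatinAnnotation | None = None,
) -> pd.DataFrame:
    """Length-weighted mean coverage per gene body.

    Partial bins are weighted by their overlap fraction with the gene.
    The chromatin class is the annotation label at the gene midpoint.
    Genes outside the genome are skipped and counted in
    ``result.attrs["n_skipped"]``.
    """
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(genes.columns):
        raise InputError(f"gene table needs columns {sorted(required)}")
    rows, skipped = [], 0
    for g in genes.itertuples(index=False):
        try:
            mean = track.interval_mean(g.chrom, int(g.start), int(g.end))
        except InputError:
            skipped += 1
            continue
        mid = (int(g.start) + int(g.end)) // 2
        cls = annotation.label_at(g.chrom, mid) if annotation is not None else None
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": int(g.start),
                "end": int(g.end),
                "class": cls,
                "mean_coverage": mean,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "class", "mean_coverage"],
    )
    out.attrs["n_skipped"] = skipped
    return out


def fold_changes(
    quant_mut: pd.DataFrame,
    quant_wt: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene mutant/wild-type fold changes on normalized coverage.

    FC = (mut + pc) / (wt + pc); the pseudocount stabilizes low-coverage
    genes without distorting strong (20-30x) gains. Gene sets must match.
    """
    if set(quant_mut["gene_id"]) != set(quant_wt["gene_id"]):
        raise InputError("mutant and wild-type gene sets differ")
    m = quant_mut.set_index("gene_id").sort_index()
    w = quant_wt.set_index("gene_id").sort_index()
    fc = (m["mean_coverage"] + pseudocount) / (w["mean_coverage"] + pseudocount)
    out = m.reset_index()[["gene_id", "chrom", "start", "end", "class"]].copy()
    out["mean_coverage_mut"] = m["mean_coverage"].to_numpy()
    out["mean_coverage_wt"] = w["mean_coverage"].to_numpy()
    out["fold_change"] = fc.to_numpy()
    out["log2_fc"] = np.log2(fc.to_numpy())
    return out


def class_median_fc(fc_table: pd.DataFrame) -> pd.Series:
    """Median gene fold change per chromatin class (robust to the
    long-tailed per-gene FC distribution)."""
    return fc_table.groupby("class", dropna=False)["fold_change"].median()


def domain_metaprofile(
    track: CoverageTrack,
    domains: list[ChromatinDomain],
    n_bins_body: int = 50,
    n_bins_flank: int = 25,
    flank_bp: int = 5000,
) -> MetaProfile:
    """Average coverage profile across length-normalized domains.

    Each domain body is rescaled to ``n_bins_body`` meta-bins by linear
    interpolation of its per-bin coverage; flanks of ``flank_bp`` are split
    into ``n_bins_flank`` fixed-width meta-bins each side. Domains carry
    equal weight; flank meta-bins outside the chromosome are dropped from
    the average.
    """
    if not domains:
        raise InputError("no domains supplied")
    width = n_bins_body + 2 * n_bins_flank
    rows = np.full((len(domains), width), np.nan)
    for i, dom in enumerate(domains):
        length = len(dom)
        # body: sample the domain at meta-bin centers via interpolation
        centers = dom.start + (np.arange(n_bins_body) + 0.5) * length / n_bins_body
        bs = track.bin_size
        v = track.values[dom.chrom]
        bin_centers = (np.arange(v.size) + 0.5) * bs
        rows[i, n_bins_flank : n_bins_flank + n_bins_body] = np.interp(
            centers, bin_centers, v
        )
        fw = flank_bp / n_bins_flank
        for j in range(n_bins_flank):
            lo = dom.start - flank_bp + j * fw
            hi = lo + fw
            if lo >= 0:
                rows[i, j] = track.interval_mean(
                    dom.chrom, int(round(lo)), int(round(hi))
                )
            lo2 = dom.end + j * fw
            hi2 = lo2 + fw
            if hi2 <= track.genome[dom.chrom]:
                rows[i, n_bins_flank + n_bins_body + j] = track.interval_mean(
                    dom.chrom, int(round(lo2)), int(round(hi2))
                )
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(rows, axis=0)
    return MetaProfile(
        n_bins_body=n_bins_body,
        n_bins_flank=n_bins_flank,
        profile=profile,
        n_domains=len(domains),
    )


def accessibility_fc_scatter(
    atac_mut: CoverageTrack,
    atac_wt: CoverageTrack,
    h2aub_mut: CoverageTrack,
    h2aub_wt: CoverageTrack,
    regions: list[ChromatinDomain],
    annotation: ChromatinAnnotation | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-region ATAC and H2Aub1 log2 fold changes for the joint scatter.

    ``regions`` are accessibility segments (their labels become the
    accessibility class); the chromatin class is looked up at the region
    midpoint when an annotation is given. Regions outside any track's
    genome are skipped and counted in ``result.attrs["n_skipped"]``.
    """
    rows, skipped = [], 0
    for r in regions:
        try:
            am = atac_mut.interval_mean(r.chrom, r.start, r.end)
            aw = atac_wt.interval_mean(r.chrom, r.start, r.end)
            hm = h2aub_mut.interval_mean(r.chrom, r.start, r.end)
            hw = h2aub_wt.interval_mean(r.chrom, r.start, r.end)
        except InputError:
            skipped += 1
            continue
        mid = (r.start + r.end) // 2
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "accessibility": r.label,
                "class": annotation.label_at(r.chrom, mid)
                if annotation is not None
                else None,
                "atac_log2_fc": float(
                    np.log2((am + pseudocount) / (aw + pseudocount))
                ),
                "h2aub_log2_fc": float(
                    np.log2((hm + pseudocount) / (hw + pseudocount))
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "accessibility", "class",
            "atac_log2_fc", "h2aub_log2_fc",
        ],
    )
    out.attrs["n_skipped"] = skipped
    return out
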