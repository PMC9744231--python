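"""Chromatin-state segmentation and PRE-like peak calling.

Domain-scale signals (H3K27me3, ATAC) are segmented by a three-state
Gaussian-emission HMM on log-transformed, lightly smoothed coverage;
states are ordered by emission mean so they map onto the three visual
levels of such tracks (background / intermediate / high). Point-source
signals (Pho at PREs) are called by a per-bin Poisson test against the
larger of the global and local background, with Benjamini-Hochberg FDR
control. The canonical / noncanonical / active / neutral classification
combines the two: high-H3K27me3 domains containing a Pho peak are
canonical Polycomb domains, H3K27me3 domains without Pho are
noncanonical, H3K27me3-free intervals dominated by H3K36me2 are active,
and the remainder is neutral.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.stats import poisson
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError
from .genome import (
    ACCESSIBILITY_LEVELS,
    K27_LEVELS,
    ChromatinAnnotation,
    ChromatinDomain,
    CoverageTrack,
    PointPeak,
)

# the EM monitor logs a warning when the bound oscillates within tolerance
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "CoverageHMMSegmenter",
    "segment_three_state",
    "segment_accessibility",
    "call_point_peaks",
    "classify_chromatin",
    "merge_short_segments",
]


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def merge_short_segments(
    states: np.ndarray,
    log_values: np.ndarray,
    state_means: np.ndarray,
    min_bins: int,
) -> np.ndarray:
    """Absorb runs shorter than ``min_bins`` into the flanking level whose
    emission mean is closer to the run's observed mean.

    Runs are processed shortest-first; a run with a single flank (trace
    edge) is absorbed into that flank. Repeats until no short run remains.
    """
    states = states.copy()
    while True:
        runs = []
        i = 0
        while i < states.size:
            j = i
            while j < states.size and states[j] == states[i]:
                j += 1
            runs.append((i, j, states[i]))
            i = j
        if len(runs) == 1:
            return states
        short = [
            (idx, r) for idx, r in enumerate(runs) if r[1] - r[0] < min_bins
        ]
        if not short:
            return states
        idx, (lo, hi, _) = min(short, key=lambda t: t[1][1] - t[1][0])
        obs = log_values[lo:hi].mean()
        candidates = []
        if idx > 0:
            candidates.append(runs[idx - 1][2])
        if idx < len(runs) - 1:
            candidates.append(runs[idx + 1][2])
        new = min(candidates, key=lambda s: abs(state_means[s] - obs))
        states[lo:hi] = new


class CoverageHMMSegmenter(BaseEstimator):
    """Three-state Gaussian HMM segmenter for binned coverage.

    ``fit`` estimates emissions and transitions by EM on
    log(smooth(coverage) + pseudocount) across all chromosomes;
    ``predict`` returns the Viterbi level per bin with states relabeled by
    ascending emission mean (0 = background ... 2 = high). Initialization
    is deterministic (quantile-based means, sticky transitions); no random
    restarts, so identical inputs give identical segmentations.

    Parameters
    ----------
    n_states : number of emission levels (fixed at 3 for the analyses here).
    pseudocount : added before the log transform.
    smooth_bp : moving-average window in bp applied before transformation.
    self_transition : prior stickiness of the transition matrix.
    min_domain_length : bp; shorter Viterbi segments are absorbed into the
        flanking level with the closer emission mean.
    min_state_separation : log-units; fitted states whose emission means
        are closer than this are collapsed onto one level, so a track with
        only two real levels does not get its background split in two.
    """

    def __init__(
        self,
        n_states: int = 3,
        pseudocount: float = 0.5,
        smooth_bp: int = 1000,
        self_transition: float = 0.99,
        min_domain_length: int = 1000,
        min_state_separation: float = 0.5,
        n_iter: int = 100,
    ):
        self.n_states = n_states
        self.pseudocount = pseudocount
        self.smooth_bp = smooth_bp
        self.self_transition = self_transition
        self.min_domain_length = min_domain_length
        self.min_state_separation = min_state_separation
        self.n_iter = n_iter

    def _transform(self, track: CoverageTrack) -> dict[str, np.ndarray]:
        w = max(1, int(round(self.smooth_bp / track.bin_size)))
        return {
            c: np.log(_smooth(v, w) + self.pseudocount)
            for c, v in track.values.items()
        }

    def fit(self, track: CoverageTrack) -> "CoverageHMMSegmenter":
        logs = self._transform(track)
        x = np.concatenate([logs[c] for c in sorted(logs)])
        self.degenerate_ = bool(np.std(x) < 1e-6)
        if self.degenerate_:
            warnings.warn(
                "constant coverage track: returning a single background state",
                stacklevel=2,
            )
            self.level_of_state_ = np.zeros(self.n_states, dtype=int)
            self.level_means_ = np.array([x.mean() if x.size else 0.0])
            return self
        k = self.n_states
        quantiles = np.linspace(0.3, 0.99, k)
        means = np.quantile(x, quantiles).reshape(-1, 1)
        # guarantee distinct inits even on near-flat data
        means += np.arange(k).reshape(-1, 1) * 1e-6
        hmm = GaussianHMM(
            n_components=k,
            covariance_type="diag",
            n_iter=self.n_iter,
            init_params="",
            params="stmc",
            random_state=0,
        )
        hmm.startprob_ = np.full(k, 1.0 / k)
        off = (1.0 - self.self_transition) / (k - 1)
        hmm.transmat_ = np.full((k, k), off) + np.eye(k) * (
            self.self_transition - off
        )
        hmm.means_ = means
        hmm.covars_ = np.full((k, 1), max(np.var(x), 1e-4))
        lengths = [logs[c].size for c in sorted(logs)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hmm.fit(x.reshape(-1, 1), lengths)
        self.hmm_ = hmm
        order = np.argsort(hmm.means_.ravel())
        sorted_means = hmm.means_.ravel()[order]
        # collapse states with near-identical emissions onto one level
        level_of_sorted = np.zeros(k, dtype=int)
        for i in range(1, k):
            gap = sorted_means[i] - sorted_means[i - 1]
            level_of_sorted[i] = level_of_sorted[i - 1] + (
                1 if gap >= self.min_state_separation else 0
            )
        self.level_of_state_ = np.empty(k, dtype=int)
        self.level_of_state_[order] = level_of_sorted
        n_levels = level_of_sorted[-1] + 1
        self.level_means_ = np.array(
            [
                sorted_means[level_of_sorted == lv].mean()
                for lv in range(n_levels)
            ]
        )
        return self

    def predict(self, track: CoverageTrack) -> dict[str, np.ndarray]:
        """Per-bin level index (0..n_states-1) for every chromosome."""
        logs = self._transform(track)
        min_bins = max(1, int(round(self.min_domain_length / track.bin_size)))
        out: dict[str, np.ndarray] = {}
        if self.degenerate_:
            return {c: np.zeros(v.size, dtype=int) for c, v in logs.items()}
        for chrom, lv in logs.items():
            raw = self.hmm_.predict(lv.reshape(-1, 1))
            levels = self.level_of_state_[raw]
            out[chrom] = merge_short_segments(
                levels, lv, self.level_means_, min_bins
            )
        return out

    def fit_predict(self, track: CoverageTrack) -> dict[str, np.ndarray]:
        return self.fit(track).predict(track)


def _levels_to_domains(
    track: CoverageTrack, levels: dict[str, np.ndarray], names: tuple[str, ...]
) -> list[ChromatinDomain]:
    domains = []
    for chrom in sorted(levels):
        lv, length = levels[chrom], track.genome[chrom]
        i = 0
        while i < lv.size:
            j = i
            while j < lv.size and lv[j] == lv[i]:
                j += 1
            start = i * track.bin_size
            end = min(j * track.bin_size, length)
            domains.append(
                ChromatinDomain(
                    chrom,
                    start,
                    end,
                    names[lv[i]],
                    mean_level=float(
                        track.values[chrom][i:j].mean()
                    ),
                )
            )
            i = j
    return domains


def segment_three_state(
    track: CoverageTrack,
    min_domain_length: int = 1000,
    pseudocount: float = 0.5,
    smooth_bp: int = 1000,
    level_names: tuple[str, ...] = K27_LEVELS,
) -> list[ChromatinDomain]:
    """Segment a domain-scale mark into none / intermediate / high levels.

    Three-state Gaussian HMM on log(coverage + pseudocount) after light
    smoothing; Viterbi path; contiguous equal-level bins merged; segments
    shorter than ``min_domain_length`` absorbed into the closer flank. A
    constant track yields one background-level domain per chromosome (with
    a warning).
    """
    seg = CoverageHMMSegmenter(
        pseudocount=pseudocount,
        smooth_bp=smooth_bp,
        min_domain_length=min_domain_length,
    )
    levels = seg.fit_predict(track)
    n_levels = seg.level_means_.size
    if n_levels >= len(level_names):
        names = level_names
    elif n_levels == 2:  # two real levels: background and enriched
        names = (level_names[0], level_names[-1])
    else:
        names = (level_names[0],)
    return _levels_to_domains(track, levels, names)


def segment_accessibility(
    track: CoverageTrack,
    min_domain_length: int = 1000,
    pseudocount: float = 0.5,
    smooth_bp: int = 1000,
) -> list[ChromatinDomain]:
    """Segment ATAC coverage into low / intermediate / high accessibility."""
    return segment_three_state(
        track,
        min_domain_length=min_domain_length,
        pseudocount=pseudocount,
        smooth_bp=smooth_bp,
        level_names=ACCESSIBILITY_LEVELS,
    )


def _local_means(x: np.ndarray, window_bins: int) -> np.ndarray:
    return _smooth(x, 2 * window_bins + 1)


def call_point_peaks(
    track: CoverageTrack,
    control: CoverageTrack | None = None,
    q_threshold: float = 0.01,
    merge_distance: int = 1000,
    local_windows_bp: tuple[int, ...] = (5000, 10000),
) -> list[PointPeak]:
    """Call point-source peaks (e.g. Pho at PREs) by a per-bin Poisson test.

    The expected rate per bin is the maximum of the track-wide mean and
    the local means in windows of +-5 kb and +-10 kb (computed on the
    control when one is supplied, rescaled to the treatment depth).
    Benjamini-Hochberg q-values across all bins; significant bins within
    ``merge_distance`` are merged, the summit is the center of the highest
    bin. Deterministic.
    """
    bg = control if control is not None else track
    ratio = track.total() / bg.total() if bg.total() > 0 else 1.0
    global_mean = (
        ratio * bg.total() / sum(v.size for v in bg.values.values())
    )
    chroms = sorted(track.values)
    pvals, index = [], []
    lam_all = {}
    for chrom in chroms:
        x = track.values[chrom]
        b = bg.values[chrom] * ratio
        lam = np.full(x.size, max(global_mean, 1e-9))
        for wbp in local_windows_bp:
            wb = max(1, wbp // track.bin_size)
            lam = np.maximum(lam, _local_means(b, wb))
        lam_all[chrom] = lam
        pvals.append(poisson.sf(np.round(x) - 1, lam))
        index.extend((chrom, i) for i in range(x.size))
    p = np.concatenate(pvals)
    if p.size == 0:
        return []
    _, q, _, _ = multipletests(p, method="fdr_bh")
    sig = {}
    for (chrom, i), qi in zip(index, q):
        if qi < q_threshold:
            sig.setdefault(chrom, []).append((i, qi))
    peaks: list[PointPeak] = []
    gap_bins = max(1, merge_distance // track.bin_size)
    for chrom in sorted(sig):
        bins = sorted(sig[chrom])
        cluster = [bins[0]]
        for b in bins[1:]:
            if b[0] - cluster[-1][0] <= gap_bins:
                cluster.append(b)
            else:
                peaks.append(_cluster_to_peak(track, lam_all, chrom, cluster))
                cluster = [b]
        peaks.append(_cluster_to_peak(track, lam_all, chrom, cluster))
    return peaks


def _cluster_to_peak(
    track: CoverageTrack,
    lam_all: dict[str, np.ndarray],
    chrom: str,
    cluster: list[tuple[int, float]],
) -> PointPeak:
    idx = [i for i, _ in cluster]
    vals = track.values[chrom][idx]
    top = idx[int(np.argmax(vals))]
    summit = min(
        top * track.bin_size + track.bin_size // 2, track.genome[chrom] - 1
    )
    return PointPeak(
        chrom=chrom,
        summit=int(summit),
        enrichment=float(
            track.values[chrom][top] / max(lam_all[chrom][top], 1e-9)
        ),
        q_value=float(min(q for _, q in cluster)),
    )


def classify_chromatin(
    k27_domains: list[ChromatinDomain],
    pho_peaks: list[PointPeak],
    k36_domains: list[ChromatinDomain],
    active_overlap_fraction: float = 0.5,
) -> ChromatinAnnotation:
    """Combine H3K27me3 levels, Pho peaks and H3K36me2 into the four-class
    chromatin annotation.

    * high-level H3K27me3 domain containing >= 1 Pho peak -> canonical;
    * high (flagged for review) or intermediate H3K27me3 domain without a
      Pho peak -> noncanonical;
    * H3K27me3-free intervals are subdivided at H3K36me2 domain
      boundaries; a piece overlapping an H3K36me2-enriched domain by
      >= ``active_overlap_fraction`` of its length -> active;
    * the remainder -> neutral.

    The H3K27me3 domains must partition the genome (as produced by
    ``segment_three_state``); the output is a partition too.
    """
    genome: dict[str, int] = {}
    for d in k27_domains:
        genome[d.chrom] = max(genome.get(d.chrom, 0), d.end)
    k36_genome: dict[str, int] = {}
    for d in k36_domains:
        k36_genome[d.chrom] = max(k36_genome.get(d.chrom, 0), d.end)
    if k36_domains and k36_genome != genome:
        raise InputError("H3K27me3 and H3K36me2 domains cover different genomes")

    k36_active = [d for d in k36_domains if d.label != "none"]
    out: list[ChromatinDomain] = []
    for d in k27_domains:
        has_pho = any(
            p.chrom == d.chrom and d.start <= p.summit < d.end for p in pho_peaks
        )
        if d.label == "high":
            if has_pho:
                label, flagged = "canonical", False
            else:
                label, flagged = "noncanonical", True
        elif d.label == "intermediate":
            label, flagged = "noncanonical", False
        else:
            cuts = sorted(
                {d.start, d.end}
                | {
                    p
                    for a in k36_domains
                    if a.chrom == d.chrom
                    for p in (a.start, a.end)
                    if d.start < p < d.end
                }
            )
            for lo, hi in zip(cuts, cuts[1:]):
                ov = sum(
                    a.overlap(lo, hi) for a in k36_active if a.chrom == d.chrom
                )
                lbl = (
                    "active"
                    if ov >= active_overlap_fraction * (hi - lo)
                    else "neutral"
                )
                out.append(ChromatinDomain(d.chrom, lo, hi, lbl))
            continue
        out.append(
            ChromatinDomain(
                d.chrom, d.start, d.end, label, mean_level=d.mean_level,
                flagged=flagged,
            )
        )
    merged = _merge_adjacent(out)
    annotation = ChromatinAnnotation(merged, genome)
    if not annotation.is_partition():
        raise InputError("H3K27me3 domains do not partition the genome")
    return annotation


def _merge_adjacent(domains: list[ChromatinDomain]) -> list[ChromatinDomain]:
    domains = sorted(domains, key=lambda d: (d.chrom, d.start))
    merged: list[ChromatinDomain] = []
    for d in domains:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.chrom == d.chrom
            and last.end == d.start
            and last.label == d.label
        ):
            merged[-1] = ChromatinDomain(
                last.chrom, last.start, d.end, last.label,
                mean_level=None, flagged=last.flagged or d.flagged,
            )
        else:
            merged.append(d)
    return merged
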