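"""Synthetic data with known ground truth.

Two generators back the test strategy of the whole package:

* ``simulate_smfret_trace`` — a forward model of a two-color smFRET
  experiment on an immobilized chromatin fiber. Conformational state
  switching is a discrete-time Markov chain with geometric dwell times;
  per frame with true efficiency E and total detected intensity I, the
  ideal channels are F_D = I*(1-E) and F_A = gamma*I*E + beta*F_D (donor
  detection efficiency taken as 1, so gamma is the acceptor/donor
  detection ratio). Photobleaching is a single irreversible step per
  channel: after acceptor bleach the donor reverts to I and the acceptor
  retains only the leakage pedestal beta*I; after donor bleach both
  channels go dark (no excitation reaches either dye). Additive Gaussian
  noise per channel; no EMCCD/shot-noise camera model. Applying the E_FRET
  correction with the true (beta, gamma) to a noise-free trace recovers E
  exactly on every pre-bleach frame.

* ``simulate_genome`` / ``simulate_coverage`` — a genome with planted
  canonical / noncanonical / active / neutral intervals plus PRE point
  positions, and per-bin read counts drawn Poisson (or negative binomial
  with user dispersion) around background_rate times a per-(mark, class,
  genotype) enrichment multiplier. A spike-in read count is derived from
  the target total so that counts are partitioned, never resampled:
  spikein = round(total * f / (1 - f)) gives a library whose spike-in
  fraction is f.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genome import (
    ChromatinAnnotation,
    ChromatinDomain,
    CoverageTrack,
    bin_class_labels,
    n_bins,
)
from .traces import FluorescenceTrace

__all__ = [
    "TraceSimParams",
    "TraceTruth",
    "GenomeSimParams",
    "SyntheticTruth",
    "simulate_smfret_trace",
    "simulate_genome",
    "simulate_coverage",
    "expected_target_total",
    "implied_spikein_fraction",
    "caly_like_design",
]


@dataclass
class TraceSimParams:
    """Forward-model parameters for one simulated smFRET trace.

    Defaults follow typical TIRF acquisition for chromatin-fiber FRET:
    ~2000 frames at 100 ms integration.
    """

    state_efret_levels: list[float] = field(default_factory=lambda: [0.05, 0.66])
    state_dwell_mean_frames: float = 100.0
    total_intensity: float = 1000.0
    noise_sd: float = 20.0
    beta_true: float = 0.161
    gamma_true: float = 0.436
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None
    n_frames: int = 2000
    frame_interval_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.state_efret_levels:
            raise ParameterError("need at least one FRET state")
        if any(not 0.0 <= e <= 1.0 for e in self.state_efret_levels):
            raise ParameterError("E levels must lie in [0, 1]")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.beta_true < 0:
            raise ParameterError("beta_true must be >= 0")
        if self.gamma_true <= 0:
            raise ParameterError("gamma_true must be > 0")
        if self.state_dwell_mean_frames < 1:
            raise ParameterError("mean dwell must be >= 1 frame")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class TraceTruth:
    """Hidden variables of one simulated trace."""

    state_index: np.ndarray
    true_efret: np.ndarray
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    beta_true: float
    gamma_true: float

    def prebleach_mask(self) -> np.ndarray:
        n = self.true_efret.size
        first = min(
            f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame, n)
            if f is not None
        )
        return np.arange(n) < first


def simulate_smfret_trace(
    params: TraceSimParams, molecule_id: str = "sim"
) -> tuple[FluorescenceTrace, TraceTruth]:
    """Simulate one donor/acceptor trace plus its ground truth."""
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    k = len(params.state_efret_levels)
    states = np.zeros(n, dtype=int)
    if k > 1:
        p_switch = 1.0 / params.state_dwell_mean_frames
        s = int(rng.integers(k))
        for t in range(n):
            states[t] = s
            if rng.random() < p_switch:
                others = [j for j in range(k) if j != s]
                s = others[int(rng.integers(k - 1))]
    e = np.asarray(params.state_efret_levels, dtype=float)[states]

    i0, beta, gamma = params.total_intensity, params.beta_true, params.gamma_true
    donor = i0 * (1.0 - e)
    acceptor = gamma * i0 * e + beta * donor

    fa_bleach = params.acceptor_bleach_frame
    fd_bleach = params.donor_bleach_frame
    frames = np.arange(n)
    if fa_bleach is not None:
        after = frames >= fa_bleach
        donor[after] = i0  # FRET lost: donor back to full emission
        acceptor[after] = beta * i0  # leakage pedestal only
    if fd_bleach is not None:
        after = frames >= fd_bleach
        donor[after] = 0.0
        acceptor[after] = 0.0  # no excitation transfer, no leakage

    if params.noise_sd > 0:
        donor = donor + rng.normal(0.0, params.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, params.noise_sd, n)

    trace = FluorescenceTrace(
        molecule_id=molecule_id,
        donor=donor,
        acceptor=acceptor,
        frame_interval_s=params.frame_interval_s,
    )
    truth = TraceTruth(
        state_index=states,
        true_efret=e,
        donor_bleach_frame=fd_bleach,
        acceptor_bleach_frame=fa_bleach,
        beta_true=beta,
        gamma_true=gamma,
    )
    return trace, truth


@dataclass
class GenomeSimParams:
    """Planted-genome parameters.

    ``planted_domains`` are (chrom, start, end, class) with class in
    {canonical, noncanonical, active, neutral}; gaps become neutral.
    ``enrichment`` maps (mark, class, genotype) to a multiplicative gain
    over ``background_rate``; the pseudo-class "pre" plants point-source
    enrichment (e.g. Pho) on bins containing a PRE position. Counts are
    negative binomial with variance mu + dispersion * mu^2, Poisson when
    dispersion is None.
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr2L": 1_000_000})
    bin_size: int = 200
    planted_domains: list[tuple[str, int, int, str]] = field(default_factory=list)
    pre_positions: list[tuple[str, int]] = field(default_factory=list)
    enrichment: dict[tuple[str, str, str], float] = field(default_factory=dict)
    background_rate: float = 10.0
    dispersion: float | None = None
    spikein_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ParameterError("bin_size must be positive")
        if not 0.0 < self.spikein_fraction < 1.0:
            raise ParameterError("spikein_fraction must lie in (0, 1)")
        if self.background_rate <= 0:
            raise ParameterError("background_rate must be positive")
        if any(m <= 0 for m in self.enrichment.values()):
            raise ParameterError("enrichment multipliers must be > 0")
        doms = sorted(self.planted_domains, key=lambda d: (d[0], d[1]))
        for chrom, start, end, cls in doms:
            if chrom not in self.chrom_lengths:
                raise ParameterError(f"domain on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ParameterError(
                    f"domain {chrom}:{start}-{end} outside chromosome bounds"
                )
        for (c1, s1, e1, _), (c2, s2, e2, _) in zip(doms, doms[1:]):
            if c1 == c2 and e1 > s2:
                raise ParameterError(
                    f"overlapping planted domains {c1}:{s1}-{e1} and {c2}:{s2}-{e2}"
                )


@dataclass
class SyntheticTruth:
    """Planted parameters for recovery tests, JSON-serializable."""

    domains: list[tuple[str, int, int, str]]
    pre_positions: list[tuple[str, int]]
    enrichment: dict[tuple[str, str, str], float]
    background_rate: float
    spikein_fraction: float
    seed: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "domains": [list(d) for d in self.domains],
            "pre_positions": [list(p) for p in self.pre_positions],
            "enrichment": {"|".join(k): v for k, v in self.enrichment.items()},
            "background_rate": self.background_rate,
            "spikein_fraction": self.spikein_fraction,
            "seed": self.seed,
        }


def _tile_genes(
    annotation: ChromatinAnnotation, gene_length: int = 5000, spacing: int = 15000
) -> pd.DataFrame:
    """Place genes inside every annotation interval so each class has >= 1
    gene; long intervals get one gene per ``spacing`` bp."""
    rows = []
    gid = 0
    for dom in annotation:
        length = len(dom)
        glen = min(gene_length, max(length // 2, 1))
        count = max(1, length // spacing)
        for j in range(count):
            center = dom.start + (2 * j + 1) * length // (2 * count)
            start = max(dom.start, center - glen // 2)
            end = min(dom.end, start + glen)
            gid += 1
            rows.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "chrom": dom.chrom,
                    "start": int(start),
                    "end": int(end),
                    "class": dom.label,
                }
            )
    return pd.DataFrame(rows)


def simulate_genome(
    params: GenomeSimParams,
) -> tuple[ChromatinAnnotation, pd.DataFrame, SyntheticTruth]:
    """Build the planted annotation, tiled gene models and the truth record.

    Gaps between planted domains are neutral. Every canonical domain is
    guaranteed at least one PRE: a midpoint PRE is planted when the caller
    supplied none inside it.
    """
    domains = [
        ChromatinDomain(c, s, e, cls) for c, s, e, cls in params.planted_domains
    ]
    annotation = ChromatinAnnotation(
        domains, params.chrom_lengths, fill_label="neutral"
    )
    pres = list(params.pre_positions)
    for dom in annotation.of_class("canonical"):
        if not any(c == dom.chrom and dom.start <= p < dom.end for c, p in pres):
            pres.append((dom.chrom, (dom.start + dom.end) // 2))
    genes = _tile_genes(annotation)
    truth = SyntheticTruth(
        domains=[(d.chrom, d.start, d.end, d.label) for d in annotation],
        pre_positions=pres,
        enrichment=dict(params.enrichment),
        background_rate=params.background_rate,
        spikein_fraction=params.spikein_fraction,
        seed=params.seed,
    )
    return annotation, genes, truth


def _stream_seed(seed: int, mark: str, genotype: str) -> list[int]:
    """Independent, reproducible substream per (mark, genotype)."""
    return [seed & 0x7FFFFFFF, zlib.crc32(f"{mark}|{genotype}".encode()) & 0x7FFFFFFF]


def expected_target_total(
    annotation: ChromatinAnnotation,
    params: GenomeSimParams,
    mark: str,
    genotype: str,
) -> float:
    """Expected total target reads for one mark/genotype (no PRE gains)."""
    labels = bin_class_labels(annotation, params.bin_size)
    total = 0.0
    for chrom in annotation.genome:
        total += sum(
            params.enrichment.get((mark, lbl, genotype), 1.0)
            for lbl in labels[chrom]
        )
    return params.background_rate * total


def implied_spikein_fraction(
    annotation: ChromatinAnnotation,
    params: GenomeSimParams,
    mark: str,
    genotype: str,
    reference_genotype: str,
) -> float:
    """Spike-in read fraction for a sample sharing spike-in material with
    the reference sample.

    ``params.spikein_fraction`` is the reference sample's fraction. With a
    fixed amount of spike-in chromatin added per sample, a genotype whose
    target yield is higher (e.g. a global H2Aub1 gain) sequesters a larger
    share of the library, so its spike-in read fraction shrinks:
    f_s = S / (S + T_s) with S the spike-in yield implied by the reference.
    """
    f0 = params.spikein_fraction
    t_ref = expected_target_total(annotation, params, mark, reference_genotype)
    t_s = expected_target_total(annotation, params, mark, genotype)
    spike_units = f0 / (1.0 - f0) * t_ref
    return spike_units / (spike_units + t_s)


def simulate_coverage(
    annotation: ChromatinAnnotation,
    params: GenomeSimParams,
    mark: str,
    genotype: str,
    pre_positions: list[tuple[str, int]] | None = None,
    spikein_fraction: float | None = None,
) -> tuple[CoverageTrack, int]:
    """Per-bin read counts for one mark/genotype plus the spike-in count.

    Bin class is taken at the bin midpoint; the bin mean is
    background_rate * multiplier(mark, class, genotype), with an extra
    (mark, "pre", genotype) gain on bins containing a PRE. The returned
    spike-in read count makes the sample's spike-in fraction of the
    combined library exact up to rounding (``spikein_fraction`` overrides
    the parameter default; see ``implied_spikein_fraction`` for samples
    that share spike-in material with a reference genotype).
    """
    marks = {k[0] for k in params.enrichment}
    genotypes = {k[2] for k in params.enrichment}
    if params.enrichment and (mark not in marks or genotype not in genotypes):
        raise ParameterError(
            f"({mark!r}, {genotype!r}) not present in the enrichment map"
        )
    rng = np.random.default_rng(_stream_seed(params.seed, mark, genotype))
    labels = bin_class_labels(annotation, params.bin_size)
    values: dict[str, np.ndarray] = {}
    for chrom, length in annotation.genome.items():
        nb = n_bins(length, params.bin_size)
        mult = np.array(
            [
                params.enrichment.get((mark, labels[chrom][i], genotype), 1.0)
                for i in range(nb)
            ]
        )
        if pre_positions:
            pre_gain = params.enrichment.get((mark, "pre", genotype), 1.0)
            for c, p in pre_positions:
                if c == chrom and 0 <= p < length:
                    mult[p // params.bin_size] *= pre_gain
        mu = params.background_rate * mult
        if params.dispersion is None:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / params.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        values[chrom] = counts.astype(float)
    track = CoverageTrack(
        genome=dict(annotation.genome),
        bin_size=params.bin_size,
        values=values,
        mark=mark,
        sample=genotype,
    )
    f = params.spikein_fraction if spikein_fraction is None else spikein_fraction
    if not 0.0 < f < 1.0:
        raise ParameterError("spikein_fraction must lie in (0, 1)")
    spikein = int(round(track.total() * f / (1.0 - f)))
    return track, spikein


def caly_like_design(seed: int = 0) -> GenomeSimParams:
    """Standard planted genome emulating a PR-DUB catalytic mutant study.

    One 600-kb chromosome with two canonical Polycomb domains (high
    H3K27me3, Pho-bound PREs), one noncanonical domain (intermediate
    H3K27me3, no Pho), one active H3K36me2 domain and neutral background.
    The mutant genotype carries a global fourfold H2Aub1 gain plus a
    canonical-domain-restricted 20-fold gain, and a twofold ATAC
    accessibility gain restricted to canonical domains — the signature of
    losing H2A deubiquitinase activity. Background coverage is 10 reads
    per 200-bp bin (Poisson) with a 10% spike-in fraction in the
    reference (wild-type) library.
    """
    return GenomeSimParams(
        chrom_lengths={"chr2L": 600_000},
        planted_domains=[
            ("chr2L", 60_000, 110_000, "canonical"),
            ("chr2L", 180_000, 220_000, "noncanonical"),
            ("chr2L", 300_000, 360_000, "active"),
            ("chr2L", 450_000, 480_000, "canonical"),
        ],
        pre_positions=[("chr2L", 80_000), ("chr2L", 100_000), ("chr2L", 465_000)],
        enrichment={
            ("H3K27me3", "canonical", "wt"): 8.0,
            ("H3K27me3", "noncanonical", "wt"): 3.0,
            ("H3K36me2", "active", "wt"): 6.0,
            ("Pho", "pre", "wt"): 40.0,
            ("H2Aub1", "canonical", "wt"): 1.0,
            ("H2Aub1", "neutral", "mut"): 4.0,
            ("H2Aub1", "active", "mut"): 4.0,
            ("H2Aub1", "noncanonical", "mut"): 4.0,
            ("H2Aub1", "canonical", "mut"): 20.0,
            ("ATAC", "canonical", "wt"): 1.0,
            ("ATAC", "canonical", "mut"): 2.0,
        },
        background_rate=10.0,
        dispersion=None,
        spikein_fraction=0.1,
        seed=seed,
    )
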