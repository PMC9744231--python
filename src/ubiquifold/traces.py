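"""Per-molecule smFRET trace processing.

Implements the standard correction chain for two-color smFRET on
surface-immobilized chromatin fibers: FRET efficiency from raw donor (F_D)
and acceptor (F_A) intensities with donor-leakage (beta) and
detection-ratio (gamma) corrections,

    E = (F_A - beta * F_D) / (F_A - beta * F_D + gamma * F_D),

single-step photobleach detection per channel, and gamma calibration from
acceptor bleach steps: when the acceptor photobleaches, the loss of
FRET-sensitized acceptor emission and the concurrent recovery of donor
emission report the same change in transferred excitation, so their ratio
equals the relative detection efficiency gamma. The acceptor step is
measured on the leakage-corrected channel F_A - beta * F_D; on the raw
acceptor channel the step ratio would be biased low by beta, because the
leakage pedestal rises together with the donor.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, InputError, ParameterError

__all__ = [
    "FluorescenceTrace",
    "CorrectionFactors",
    "BleachEvent",
    "EfretTrace",
    "GammaEstimate",
    "compute_efret",
    "detect_bleach_steps",
    "estimate_gamma",
]

#: Calibration of the reference instrument (donor leakage, detection ratio).
DEFAULT_BETA = 0.161
DEFAULT_GAMMA = 0.436

#: E values outside this range are clamped; noise can push E slightly
#: outside [0, 1] and histograms must admit slightly negative values.
EFRET_CLAMP = (-0.2, 1.2)


@dataclass
class FluorescenceTrace:
    """Donor/acceptor intensity time series for one immobilized molecule."""

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval_s: float = 0.1
    condition: str = ""

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.donor.shape != self.acceptor.shape:
            raise InputError("donor and acceptor must be 1-D arrays of equal length")
        if self.donor.size < 2:
            raise InputError("trace must have at least 2 frames")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise InputError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.donor.size


@dataclass(frozen=True)
class CorrectionFactors:
    """Donor leakage fraction beta and detection-efficiency ratio gamma."""

    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")


@dataclass
class BleachEvent:
    """A single irreversible photobleaching step in one channel.

    ``delta_fa`` is the drop (pre minus post, positive for a loss) in the
    leakage-corrected acceptor channel; ``delta_fd`` is the signed change
    (post minus pre) in the donor channel, positive for the donor rise that
    accompanies acceptor bleaching.
    """

    channel: str  # "donor" | "acceptor"
    frame: int
    delta_fa: float
    delta_fd: float

    def __post_init__(self) -> None:
        if self.channel not in ("donor", "acceptor"):
            raise ParameterError(f"unknown channel {self.channel!r}")
        if self.frame < 0:
            raise ParameterError("bleach frame must be >= 0")


@dataclass
class EfretTrace:
    """Corrected per-frame FRET efficiency with a validity mask."""

    molecule_id: str
    efret: np.ndarray
    valid_mask: np.ndarray

    def valid_values(self) -> np.ndarray:
        return self.efret[self.valid_mask]


@dataclass
class GammaEstimate:
    """Robust gamma from acceptor bleach steps across molecules."""

    gamma: float
    mad: float
    n_used: int
    n_excluded: int
    per_event: np.ndarray


def compute_efret(
    trace: FluorescenceTrace,
    factors: CorrectionFactors | None = None,
    bleach_events: list[BleachEvent] | None = None,
    clamp: tuple[float, float] = EFRET_CLAMP,
    denom_floor_rel: float = 1e-6,
) -> EfretTrace:
    """Corrected FRET efficiency trace.

    E = (F_A - beta F_D) / (F_A - beta F_D + gamma F_D) per frame. Frames
    whose denominator magnitude falls below ``denom_floor_rel`` times the
    median total intensity are masked out; values are clamped to ``clamp``.
    When bleach events are supplied, only frames strictly before the first
    event of either channel are marked valid (the correction assumes both
    dyes active).
    """
    if factors is None:
        factors = CorrectionFactors()
    num = trace.acceptor - factors.beta * trace.donor
    den = num + factors.gamma * trace.donor
    floor = denom_floor_rel * max(
        float(np.median(trace.donor + trace.acceptor)), 1.0
    )
    ok = np.abs(den) >= floor
    e = np.full(trace.n_frames, np.nan)
    e[ok] = num[ok] / den[ok]
    e[ok] = np.clip(e[ok], clamp[0], clamp[1])
    if bleach_events:
        first = min(ev.frame for ev in bleach_events)
        ok = ok & (np.arange(trace.n_frames) < first)
    return EfretTrace(trace.molecule_id, e, ok)


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise sd from the median absolute first difference (step-insensitive)."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Least-squares single changepoint: index of first right-segment frame
    and the reduction in summed squared error. Earliest frame wins ties."""
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    total = cs2[-1] - cs[-1] ** 2 / n
    k = np.arange(1, n)
    left = cs2[k - 1] - cs[k - 1] ** 2 / k
    right = (cs2[-1] - cs2[k - 1]) - (cs[-1] - cs[k - 1]) ** 2 / (n - k)
    gains = total - (left + right)
    i = int(np.argmax(gains))  # argmax returns the first maximal index
    return int(k[i]), float(gains[i])


def _binary_segmentation(
    x: np.ndarray, penalty: float, min_size: int = 3, max_splits: int = 6
) -> list[int]:
    """Changepoints by greedy binary segmentation with an SSE-gain penalty."""
    cps: list[int] = []
    segments = [(0, x.size)]
    for _ in range(max_splits):
        best = None
        for lo, hi in segments:
            if hi - lo < 2 * min_size:
                continue
            k, gain = _best_split(x[lo:hi])
            if k < min_size or (hi - lo) - k < min_size:
                continue
            if gain > penalty and (best is None or gain > best[0]):
                best = (gain, lo + k, (lo, hi))
        if best is None:
            break
        _, cp, seg = best
        segments.remove(seg)
        segments.extend([(seg[0], cp), (cp, seg[1])])
        cps.append(cp)
    return sorted(cps)


def _segment_means(x: np.ndarray, cps: list[int]) -> list[tuple[int, int, float]]:
    bounds = [0, *cps, x.size]
    return [
        (lo, hi, float(x[lo:hi].mean())) for lo, hi in zip(bounds, bounds[1:])
    ]


def _first_sustained_drop(
    x: np.ndarray, cps: list[int], min_step: float
) -> tuple[int, float] | None:
    """First changepoint where the level drops by >= min_step and never
    recovers: every later segment mean stays below pre-level - min_step/2."""
    segs = _segment_means(x, cps)
    for i in range(1, len(segs)):
        pre = segs[i - 1][2]
        post_means = [s[2] for s in segs[i:]]
        if pre - segs[i][2] >= min_step and all(
            m <= pre - min_step / 2 for m in post_means
        ):
            return segs[i][0], pre - segs[i][2]
    return None


def _window_delta(x: np.ndarray, frame: int, window: int) -> float:
    """Signed step (post minus pre) over symmetric windows around ``frame``."""
    lo = max(0, frame - window)
    hi = min(x.size, frame + window)
    return float(x[frame:hi].mean() - x[lo:frame].mean())


def detect_bleach_steps(
    trace: FluorescenceTrace,
    penalty: float | None = None,
    min_step: float | None = None,
    beta: float = 0.0,
    window: int = 20,
) -> list[BleachEvent]:
    """Detect at most one irreversible photobleaching step per channel.

    Each channel is scanned by binary-segmentation changepoint detection;
    the first drop of at least ``min_step`` sustained to the trace end is
    the bleach candidate. An acceptor-channel drop coinciding (within 2
    frames) with a donor-channel drop is attributed to donor bleaching
    (the acceptor goes dark because excitation transfer stops, not because
    it bleached). ``beta`` leakage-corrects the acceptor channel before
    step measurement so that acceptor-step / donor-rise ratios estimate
    gamma without leakage bias.

    Defaults: ``min_step`` is 6x the robust per-frame noise sd of the
    channel; ``penalty`` is a BIC-like 2 * sigma^2 * log(n) gain threshold.
    Returns an empty list when no step qualifies.
    """
    if trace.n_frames < 10:
        raise InputError("bleach detection requires >= 10 frames")
    acceptor = trace.acceptor - beta * trace.donor
    channels = {"donor": trace.donor, "acceptor": acceptor}
    drops: dict[str, tuple[int, float]] = {}
    for name, x in channels.items():
        sd = _robust_noise_sd(x)
        pen = penalty if penalty is not None else max(2 * sd * sd * np.log(x.size), 1e-12)
        step = min_step if min_step is not None else 6 * sd
        cps = _binary_segmentation(x, pen)
        hit = _first_sustained_drop(x, cps, max(step, 1e-12))
        if hit is not None:
            drops[name] = hit

    events: list[BleachEvent] = []
    donor_frame = drops["donor"][0] if "donor" in drops else None
    if "acceptor" in drops:
        fa_frame = drops["acceptor"][0]
        if donor_frame is not None and abs(fa_frame - donor_frame) <= 2:
            pass  # concurrent drops: donor bleach, acceptor merely went dark
        else:
            events.append(
                BleachEvent(
                    channel="acceptor",
                    frame=fa_frame,
                    delta_fa=-_window_delta(acceptor, fa_frame, window),
                    delta_fd=_window_delta(trace.donor, fa_frame, window),
                )
            )
    if donor_frame is not None:
        events.append(
            BleachEvent(
                channel="donor",
                frame=donor_frame,
                delta_fa=-_window_delta(acceptor, donor_frame, window),
                delta_fd=_window_delta(trace.donor, donor_frame, window),
            )
        )
    return sorted(events, key=lambda ev: ev.frame)


def estimate_gamma(events: list[BleachEvent]) -> GammaEstimate:
    """Detection-ratio gamma from acceptor bleach steps, pooled across
    molecules: per event gamma_i = delta_fa / delta_fd; the estimate is the
    median with its median absolute deviation. Events that are not acceptor
    bleaches or have a nonpositive donor rise are excluded and counted.
    """
    usable = [
        ev for ev in events if ev.channel == "acceptor" and ev.delta_fd > 0
    ]
    n_excluded = len(events) - len(usable)
    if not usable:
        raise EstimationError(
            "no acceptor bleach events with a positive donor rise; "
            "use a fixed gamma (e.g. the instrument calibration)"
        )
    g = np.array([ev.delta_fa / ev.delta_fd for ev in usable])
    med = float(np.median(g))
    mad = float(np.median(np.abs(g - med)))
    return GammaEstimate(med, mad, len(usable), n_excluded, g)
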