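"""E_FRET histograms and Gaussian population decomposition.

Per-frame E values from many molecules are pooled into a time-averaged
histogram over [-0.2, 1.2] and decomposed into at most two Gaussian
components

    y(x) = sum_i A_i * exp(-0.5 * ((x - c_i) / d_i)^2)

by bounded nonlinear least squares on the binned densities, the standard
treatment for smFRET population histograms. Components are then labeled
open (unfolded fibers, center below ~0.1), medium (transient
nucleosome-stacking intermediate) or high (folded fibers); population
fractions come from component areas A_i * d_i * sqrt(2*pi).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import FitError, InputError, ParameterError
from .traces import EFRET_CLAMP, EfretTrace

__all__ = [
    "EfretHistogram",
    "GaussianComponent",
    "GaussianFitResult",
    "PopulationCall",
    "FretPopulationModel",
    "build_histogram",
    "fit_gaussians",
    "classify_populations",
    "fit_mixture_em",
]

DEFAULT_BIN_WIDTH = 0.02
#: amplitude ratio below which a 2-component fit is effectively unimodal
UNIMODAL_AMPLITUDE_RATIO = 0.01


@dataclass
class EfretHistogram:
    """Pooled E_FRET distribution: per-bin probability mass (sums to 1)."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_edges.size != self.density.size + 1:
            raise InputError("bin_edges must have one more element than density")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise InputError("bin_edges must be strictly increasing")
        if np.any(self.density < 0):
            raise InputError("density must be nonnegative")
        if self.n_repeats < 1:
            raise InputError("n_repeats must be >= 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.density) / np.sum(self.density))


@dataclass(frozen=True)
class GaussianComponent:
    """One population: amplitude A, center c (E units) and width d."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.width <= 0:
            raise ParameterError("width must be > 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.width * np.sqrt(2.0 * np.pi)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass
class GaussianFitResult:
    """Fitted mixture, sorted by ascending center."""

    components: list[GaussianComponent]
    rss: float
    stderr: np.ndarray  # one row (A, c, d) per component; NaN when singular
    effectively_unimodal: bool = False

    def envelope(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum((comp(x) for comp in self.components), np.zeros_like(x))


@dataclass
class PopulationCall:
    """Open/medium/high label and area fraction per fitted component."""

    labels: list[str]
    fractions: list[float]

    def __post_init__(self) -> None:
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ParameterError("fractions must lie in [0, 1]")
        if sum(self.fractions) > 1 + 1e-6:
            raise ParameterError("fractions must sum to <= 1")


def _one_repeat_density(
    traces: Sequence[EfretTrace], edges: np.ndarray, per_molecule: bool
) -> tuple[np.ndarray, int]:
    if per_molecule:
        vals = np.array(
            [t.valid_values().mean() for t in traces if t.valid_values().size]
        )
    else:
        pools = [t.valid_values() for t in traces if t.valid_values().size]
        vals = np.concatenate(pools) if pools else np.array([])
    if vals.size == 0:
        raise InputError("no valid E_FRET frames to histogram")
    counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1]), bins=edges)
    return counts / counts.sum(), len(traces)


def build_histogram(
    efret_traces: Sequence[EfretTrace] | Sequence[Sequence[EfretTrace]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    value_range: tuple[float, float] = EFRET_CLAMP,
    per_molecule: bool = False,
) -> EfretHistogram:
    """Pool valid (pre-bleach) frames into a normalized E_FRET histogram.

    Every valid frame carries equal weight (per-molecule means instead when
    ``per_molecule``). A list of lists is treated as independent repeats
    whose per-repeat densities are averaged with equal weight, as when
    averaging histograms from independent imaging sessions.
    """
    if len(efret_traces) == 0:
        raise InputError("no traces supplied")
    lo, hi = value_range
    n = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n + 1)
    repeats: Sequence[Sequence[EfretTrace]]
    if isinstance(efret_traces[0], EfretTrace):
        repeats = [efret_traces]  # type: ignore[list-item]
    else:
        repeats = efret_traces  # type: ignore[assignment]
    densities, n_mol = [], 0
    for rep in repeats:
        dens, nm = _one_repeat_density(rep, edges, per_molecule)
        densities.append(dens)
        n_mol += nm
    return EfretHistogram(
        bin_edges=edges,
        density=np.mean(densities, axis=0),
        n_molecules=n_mol,
        n_repeats=len(repeats),
    )


class FretPopulationModel(BaseEstimator):
    """Least-squares Gaussian decomposition of a binned E_FRET histogram.

    A scikit-learn style curve-fit estimator: ``fit(x, y)`` takes bin
    centers and densities and fits ``n_components`` (1 or 2) Gaussians with
    bounds A >= 0, d > 0 and c inside the data range, multi-started from
    quantile-based initial centers for robustness against the (shallow)
    two-peak likelihood surface.

    Attributes
    ----------
    components_ : list of GaussianComponent, sorted by ascending center.
    rss_ : residual sum of squares of the best start.
    stderr_ : (n_components, 3) asymptotic standard errors for (A, c, d).
    effectively_unimodal_ : True when a 2-component fit collapses (one
        amplitude below 1% of the other).
    """

    def __init__(self, n_components: int = 2, max_nfev: int = 2000):
        self.n_components = n_components
        self.max_nfev = max_nfev

    @staticmethod
    def _model(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        y = np.zeros_like(x)
        for a, c, d in theta.reshape(-1, 3):
            y = y + a * np.exp(-0.5 * ((x - c) / d) ** 2)
        return y

    def _starts(self, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        w = y / y.sum() if y.sum() > 0 else np.full_like(y, 1.0 / y.size)
        cdf = np.cumsum(w)
        span = x[-1] - x[0]

        def q(p: float) -> float:
            return float(np.interp(p, cdf, x))

        a0 = max(float(y.max()), 1e-12)
        d0 = max(0.05, span / 20)
        if self.n_components == 1:
            center_sets = [[q(0.5)], [x[int(np.argmax(y))]]]
        else:
            peak = x[int(np.argmax(y))]
            center_sets = [
                [q(0.25), q(0.75)],
                [q(0.1), q(0.9)],
                [q(0.4), q(0.6)],
                [peak, q(0.9) if peak < q(0.5) else q(0.1)],
            ]
        starts = []
        for centers in center_sets:
            theta = []
            for c in sorted(centers):
                theta.extend([a0, c, d0])
            starts.append(np.array(theta))
        return starts

    def fit(self, x: np.ndarray, y: np.ndarray) -> "FretPopulationModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x.ravel()
        if x.shape != y.shape or x.ndim != 1 or x.size < 3 * self.n_components:
            raise InputError("need 1-D x, y of equal length with enough bins")
        if self.n_components not in (1, 2):
            raise ParameterError("n_components must be 1 or 2")
        lo = np.tile([0.0, x[0], 1e-4], self.n_components)
        hi = np.tile([np.inf, x[-1], x[-1] - x[0]], self.n_components)
        best = None
        for theta0 in self._starts(x, y):
            try:
                sol = least_squares(
                    lambda t: self._model(t, x) - y,
                    np.clip(theta0, lo, hi),
                    bounds=(lo, hi),
                    max_nfev=self.max_nfev,
                )
            except Exception:  # noqa: BLE001 - a failed start is not fatal
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError(
                f"Gaussian fit did not converge from any start "
                f"(n_components={self.n_components}, {x.size} bins)"
            )
        theta = best.x.reshape(-1, 3)
        order = np.argsort(theta[:, 1])
        theta = theta[order]
        self.components_ = [
            GaussianComponent(a, c, max(d, 1e-12)) for a, c, d in theta
        ]
        self.rss_ = float(2 * best.cost)
        self.stderr_ = self._stderr(best, x.size)[order]
        amps = theta[:, 0]
        self.effectively_unimodal_ = bool(
            self.n_components == 2 and amps.min() < UNIMODAL_AMPLITUDE_RATIO * amps.max()
        )
        return self

    def _stderr(self, sol, n_obs: int) -> np.ndarray:
        dof = n_obs - sol.x.size
        if dof <= 0:
            return np.full((self.n_components, 3), np.nan)
        s2 = 2 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            return np.sqrt(np.diag(cov)).reshape(-1, 3)
        except np.linalg.LinAlgError:
            return np.full((self.n_components, 3), np.nan)

    def predict(self, x: np.ndarray) -> np.ndarray:
        theta = np.concatenate(
            [[c.amplitude, c.center, c.width] for c in self.components_]
        )
        return self._model(theta, np.asarray(x, dtype=float).ravel())


def fit_gaussians(
    hist: EfretHistogram, k: int = 2, init: Sequence[float] | None = None
) -> GaussianFitResult:
    """Fit k (1 or 2) Gaussian components to a histogram's densities.

    ``init`` optionally supplies initial centers, replacing the default
    quantile-based multi-start.
    """
    model = FretPopulationModel(n_components=k)
    x, y = hist.bin_centers, hist.density
    if init is not None:
        if len(init) != k:
            raise ParameterError("init must supply one center per component")
        starts = model._starts(x, y)
        a0, d0 = max(float(y.max()), 1e-12), 0.05
        theta = []
        for c in sorted(init):
            theta.extend([a0, c, d0])
        model._starts = lambda *_: [np.array(theta), *starts]  # type: ignore[method-assign]
    model.fit(x, y)
    return GaussianFitResult(
        components=model.components_,
        rss=model.rss_,
        stderr=model.stderr_,
        effectively_unimodal=model.effectively_unimodal_,
    )


def classify_populations(
    fit: GaussianFitResult,
    open_threshold: float = 0.1,
    mid_threshold: float = 0.5,
) -> PopulationCall:
    """Label fitted components as open / medium / high FRET populations.

    Centers below ``open_threshold`` are the open (unfolded) population;
    the rest split at ``mid_threshold`` into the transient stacking
    intermediate (medium) and the folded high-FRET state. Area fractions
    are component areas normalized by the total fitted area.
    """
    labels = []
    for comp in fit.components:
        if comp.center < open_threshold:
            labels.append("open")
        elif comp.center < mid_threshold:
            labels.append("medium")
        else:
            labels.append("high")
    areas = np.array([c.area for c in fit.components])
    total = areas.sum()
    fractions = (areas / total if total > 0 else areas).tolist()
    return PopulationCall(labels=labels, fractions=fractions)


def fit_mixture_em(
    values: np.ndarray, k: int = 2, random_state: int = 0
) -> GaussianFitResult:
    """Maximum-likelihood Gaussian mixture on raw E values (EM cross-check
    for the histogram least-squares fit); amplitudes are scaled so that
    component areas match the mixture weights."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if values.size < 2 * k:
        raise InputError("too few values for EM fit")
    gm = GaussianMixture(n_components=k, random_state=random_state, n_init=3)
    gm.fit(values)
    comps = []
    for w, m, v in zip(
        gm.weights_, gm.means_.ravel(), gm.covariances_.ravel()
    ):
        d = float(np.sqrt(v))
        comps.append(GaussianComponent(w / (d * np.sqrt(2 * np.pi)), float(m), d))
    comps.sort(key=lambda c: c.center)
    return GaussianFitResult(
        components=comps,
        rss=float("nan"),
        stderr=np.full((k, 3), np.nan),
        effectively_unimodal=False,
    )
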