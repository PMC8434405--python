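"""Translational transport metrics.

Multi-time-origin mean square displacement MSD(lag) = <|r_i(t0+lag) - r_i(t0)|^2>
averaged over particles and origins; the Einstein relation MSD = 6 D t yields
the diffusion coefficient from the slope over a user-chosen linear regime.
Windowed MSD summarises a long run as the mean +/- sd of start-to-end squared
displacements over non-overlapping periods. The radial distribution function
g(r) compares the local pair density around centre atoms with the bulk target
density; its first maximum/minimum delimit the first hydration layer, and the
ratio g_min/g_max measures the layer's de-packing. A two-segment least-squares
scan locates the dynamical-transition breakpoint in observable-vs-temperature
curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError, ParameterError
from .trajectory import Trajectory, _box_edges, minimum_image_displacement


@dataclass
class MSDSeries:
    lag: np.ndarray        # ps
    msd: np.ndarray        # nm^2
    n_samples: np.ndarray  # origin*atom samples per lag


@dataclass
class RDFCurve:
    r: np.ndarray          # bin centres, nm
    g: np.ndarray
    bin_width: float
    n_center: int
    n_target: int


@dataclass
class PeakStats:
    first_max_r: float
    first_max_g: float
    first_min_r: float
    first_min_g: float

    @property
    def ratio(self) -> float:
        """De-packing ratio g(r)min / g(r)max of the first hydration layer."""
        return self.first_min_g / self.first_max_g


@dataclass
class DiffusionResult:
    D: float               # nm^2/ps
    stderr: float
    r_squared: float
    n_points: int


@dataclass
class TransitionResult:
    breakpoint: float
    slope_low: float
    slope_high: float
    sse: float
    degenerate: bool       # True when the two segment slopes are indistinguishable


def _check_unwrapped(traj: Trajectory, sel: np.ndarray) -> None:
    if traj.box is None or traj.n_frames < 2:
        return
    edges = _box_edges(traj.box)
    steps = np.abs(np.diff(traj.coordinates[:, sel, :], axis=0))
    if np.any(steps > 0.5 * edges):
        raise ParameterError(
            "trajectory appears to be wrapped (frame-to-frame jumps of ~ a box "
            "edge); apply unwrap_coordinates before computing MSD")


def msd(traj: Trajectory, selection=None, max_lag: float | None = None,
        origin_stride: int = 1) -> MSDSeries:
    """Multi-time-origin mean square displacement.

    For each lag on the frame grid up to ``max_lag`` (ps), the squared
    displacement is averaged over all selected atoms and all time origins on
    the ``origin_stride`` grid. Coordinates must be unwrapped; wrapped input
    is detected by its box-edge-sized jumps and rejected.
    """
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    if sel.size == 0:
        raise ParameterError("selection is empty")
    if origin_stride < 1:
        raise ParameterError("origin_stride must be >= 1")
    if traj.n_frames < 2:
        raise ParameterError("MSD needs at least 2 frames")
    _check_unwrapped(traj, sel)
    dt = traj.dt
    max_lag_frames = traj.n_frames - 1 if max_lag is None else int(round(max_lag / dt))
    if max_lag_frames < 1 or max_lag_frames > traj.n_frames - 1:
        raise ParameterError("max_lag must lie within the trajectory span")
    X = traj.coordinates[:, sel, :]
    lags = np.arange(max_lag_frames + 1)
    out = np.zeros(len(lags))
    n_samples = np.zeros(len(lags), dtype=int)
    n_samples[0] = ((traj.n_frames - 1) // origin_stride + 1) * len(sel)
    for k in lags[1:]:
        origins = np.arange(0, traj.n_frames - k, origin_stride)
        disp = X[origins + k] - X[origins]
        out[k] = np.mean(np.sum(disp ** 2, axis=2))
        n_samples[k] = disp.shape[0] * disp.shape[1]
    return MSDSeries(lag=lags * dt, msd=out, n_samples=n_samples)


def msd_windowed(traj: Trajectory, selection=None, window: float = 200.0):
    """Start-to-end squared displacement per non-overlapping window.

    The analysed span is divided into ``window``-ps periods; in each, the
    squared displacement between the period's first and last frame is
    averaged over atoms. Returns ``(mean, sd)`` over periods (sample sd).
    """
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    if sel.size == 0:
        raise ParameterError("selection is empty")
    dt = traj.dt
    w = int(round(window / dt))
    if w < 1 or w > traj.n_frames - 1:
        raise ParameterError("window must be positive and no longer than the trajectory")
    n_windows = (traj.n_frames - 1) // w
    if n_windows < 2:
        raise ParameterError("window must divide the span into at least 2 periods")
    _check_unwrapped(traj, sel)
    X = traj.coordinates[:, sel, :]
    starts = np.arange(n_windows) * w
    disp = X[starts + w] - X[starts]
    per_window = np.mean(np.sum(disp ** 2, axis=2), axis=1)
    return float(per_window.mean()), float(per_window.std(ddof=1))


def diffusion_coefficient(series: MSDSeries, fit_min: float,
                          fit_max: float) -> DiffusionResult:
    """Diffusion coefficient from the Einstein relation, D = slope/6.

    Least-squares line over lags in [fit_min, fit_max]; the reported R^2
    flags non-diffusive (e.g. ballistic, caged) regimes.
    """
    mask = (series.lag >= fit_min) & (series.lag <= fit_max)
    if mask.sum() < 3:
        raise ParameterError("fit range must contain at least 3 lag points")
    res = stats.linregress(series.lag[mask], series.msd[mask])
    return DiffusionResult(D=res.slope / 6.0, stderr=res.stderr / 6.0,
                           r_squared=res.rvalue ** 2, n_points=int(mask.sum()))


def rdf(traj: Trajectory, center_selection, target_selection,
        r_max: float = 3.0, bin_width: float = 0.002) -> RDFCurve:
    """Radial distribution function g(r) between two selections.

    Minimum-image centre-target distances are histogrammed per frame and
    normalised by the exact spherical-shell volume and the instantaneous bulk
    target density N_B/V, then averaged over frames. Self-pairs (identical
    atom index) are excluded; g -> 1 at large r for a homogeneous target.
    """
    if traj.box is None:
        raise ParameterError("RDF requires a periodic box")
    edges = _box_edges(traj.box)
    if r_max > edges.min() / 2:
        raise ParameterError(
            f"r_max={r_max} exceeds half the smallest box edge ({edges.min() / 2:.3g})")
    centers = np.asarray(center_selection, dtype=int)
    targets = np.asarray(target_selection, dtype=int)
    if centers.size == 0:
        raise ParameterError("center selection is empty")
    n_bins = int(np.ceil(r_max / bin_width))
    bin_edges = np.arange(n_bins + 1) * bin_width
    shell_vol = 4.0 / 3.0 * np.pi * (bin_edges[1:] ** 3 - bin_edges[:-1] ** 3)
    volume = float(np.prod(edges))
    g = np.zeros(n_bins)
    if targets.size:
        self_mask = centers[:, None] == targets[None, :]
        rho = len(targets) / volume
        for f in range(traj.n_frames):
            pos = traj.coordinates[f]
            d = minimum_image_displacement(pos[centers][:, None, :],
                                           pos[targets][None, :, :], traj.box)
            dist = np.linalg.norm(d, axis=2)
            dist = dist[~self_mask]
            hist, _ = np.histogram(dist, bins=bin_edges)
            g += hist / (len(centers) * rho * shell_vol)
        g /= traj.n_frames
    r = 0.5 * (bin_edges[1:] + bin_edges[:-1])
    return RDFCurve(r=r, g=g, bin_width=bin_width,
                    n_center=len(centers), n_target=len(targets))


def rdf_peak_stats(curve: RDFCurve, smoothing_window: int = 5) -> PeakStats:
    """First-peak statistics of an RDF curve.

    After optional moving-average smoothing, locates the first local maximum
    following the first non-zero bin and the first local minimum after it.
    The ratio g_min/g_max measures first-layer de-packing.
    """
    g = np.asarray(curve.g, dtype=float)
    r = np.asarray(curve.r, dtype=float)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        gp = np.pad(g, pad, mode="edge")
        g = np.convolve(gp, kernel, mode="valid")[: len(r)]
    nz = np.flatnonzero(g > 0)
    if nz.size == 0:
        raise AnalysisError("RDF curve is identically zero")
    i_max = None
    for i in range(max(nz[0], 1), len(g) - 1):
        if g[i - 1] < g[i] >= g[i + 1]:
            i_max = i
            break
    if i_max is None:
        raise AnalysisError("no first maximum found; try smoothing or longer sampling")
    i_min = None
    for i in range(i_max + 1, len(g) - 1):
        if g[i - 1] > g[i] <= g[i + 1]:
            i_min = i
            break
    if i_min is None:
        raise AnalysisError("no first minimum found after the maximum; "
                            "try smoothing or longer sampling")
    return PeakStats(first_max_r=float(r[i_max]), first_max_g=float(g[i_max]),
                     first_min_r=float(r[i_min]), first_min_g=float(g[i_min]))


def detect_transition(x, y, slope_tol: float = 1e-8) -> TransitionResult:
    """Two-segment least-squares breakpoint detection.

    Scans every interior grid point as a candidate breakpoint (the candidate
    sample belongs to both segments, each of which must hold >= 2 points),
    fits two independent lines, and returns the candidate minimising the
    total squared error. ``degenerate`` is set when the winning segments have
    equal slopes within ``slope_tol`` relative tolerance (no real transition).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ParameterError("breakpoint detection needs at least 5 (x, y) points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    best = None
    for k in range(1, len(x) - 1):
        xl, yl = x[: k + 1], y[: k + 1]
        xr, yr = x[k:], y[k:]
        sse = 0.0
        slopes = []
        for xs, ys in ((xl, yl), (xr, yr)):
            A = np.stack([xs, np.ones_like(xs)], axis=1)
            coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
            sse += float(np.sum((A @ coef - ys) ** 2))
            slopes.append(coef[0])
        if best is None or sse < best[1]:
            best = (k, sse, slopes)
    k, sse, (s1, s2) = best
    scale = max(abs(s1), abs(s2), 1e-300)
    degenerate = bool(abs(s1 - s2) / scale <= slope_tol)
    return TransitionResult(breakpoint=float(x[k]), slope_low=float(s1),
                            slope_high=float(s2), sse=sse, degenerate=degenerate)
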