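"""Geometric hydrogen-bond detection and population dynamics.

A donor-hydrogen-acceptor triple (D, H, A) is bonded when the minimum-image
D-A distance is below ``da_cutoff`` (0.35 nm) and the angle at the donor
between D->H and D->A is below ``angle_cutoff`` (30 degrees) — the standard
geometric criterion; both comparisons are strict. Population dynamics are
summarised by two time scales: the continuous lifetime tau_HB, the mean
duration of unbroken bonded intervals (sub-picosecond partner-exchange
kinetics), and the relaxation time tau_R at which the intermittent
population correlation c(t) = <h(0)h(t)>/<h> — which ignores transient
breaks — first decays to 1/e (slow, diffusion-controlled relaxation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ParameterError, TopologyError
from .hydration import CorrelationSeries, ShellMembership, shell_membership
from .trajectory import Frame, Topology, Trajectory, minimum_image_displacement


@dataclass
class HBondCriterion:
    """Geometric criterion: strict D-A distance (nm) and H-D-A angle (deg) bounds."""

    da_cutoff: float = 0.35
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ParameterError("cutoffs must be positive")
        if self.angle_cutoff >= 90:
            raise ParameterError("angle cutoff must be below 90 degrees")


@dataclass
class HBondSeries:
    """Per-frame presence indicator for every (D, H, A) triple ever bonded."""

    pairs: list
    h: np.ndarray            # (n_pairs, n_frames), 0/1
    dt: float                # ps

    @classmethod
    def from_matrix(cls, h: np.ndarray, dt: float) -> "HBondSeries":
        h = np.asarray(h)
        return cls(pairs=[None] * h.shape[0], h=h, dt=dt)


@dataclass
class CountSeries:
    counts: np.ndarray
    mean: float
    sd: float


@dataclass
class HBondTimes:
    tau_hb: float            # ps, continuous lifetime
    tau_r: float             # ps, 1/e relaxation of c(t)
    c_curve: CorrelationSeries
    tau_r_extrapolated: bool = False


def _donor_triples(topology: Topology, donors_from: np.ndarray) -> list[tuple[int, int]]:
    """(D, H) pairs for flagged donors in the given selection."""
    out = []
    for d in donors_from:
        if not topology.donor_flag[d]:
            continue
        hs = topology.bonded_hydrogens(int(d))
        if hs.size == 0:
            raise TopologyError(f"donor atom {int(d)} has no bonded hydrogen")
        out.extend((int(d), int(h)) for h in hs)
    return out


def detect_hbonds(frame: Frame, topology: Topology, donors_from=None,
                  acceptors_from=None,
                  criterion: HBondCriterion | None = None) -> list[tuple[int, int, int]]:
    """All hydrogen-bonded (D, H, A) triples in one frame.

    Donors are taken from ``donors_from`` (donor-flagged atoms with their
    bonded hydrogens), acceptors from ``acceptors_from`` (acceptor-flagged);
    both default to the whole topology. Pairs within the same molecule are
    excluded. Returns triples sorted lexicographically.
    """
    criterion = criterion or HBondCriterion()
    donors_from = (np.arange(topology.n_atoms) if donors_from is None
                   else np.asarray(donors_from, dtype=int))
    acceptors_from = (np.arange(topology.n_atoms) if acceptors_from is None
                      else np.asarray(acceptors_from, dtype=int))
    dh = _donor_triples(topology, donors_from)
    acceptors = acceptors_from[topology.acceptor_flag[acceptors_from]]
    if not dh or acceptors.size == 0:
        return []
    d_idx = np.array([d for d, _ in dh], dtype=int)
    h_idx = np.array([h for _, h in dh], dtype=int)
    pos = frame.coordinates

    def disp(a, b):
        if frame.box is not None:
            return minimum_image_displacement(a, b, frame.box)
        return b - a

    da = disp(pos[d_idx][:, None, :], pos[acceptors][None, :, :])  # (nDH, nA, 3)
    dist = np.linalg.norm(da, axis=2)
    same_mol = (topology.molecule_id[d_idx][:, None]
                == topology.molecule_id[acceptors][None, :])
    same_atom = d_idx[:, None] == acceptors[None, :]
    cand = (dist < criterion.da_cutoff) & ~same_mol & ~same_atom
    if not cand.any():
        return []
    dhv = disp(pos[d_idx], pos[h_idx])  # (nDH, 3)
    dhu = dhv / np.linalg.norm(dhv, axis=1, keepdims=True)
    out = []
    cos_cut = np.cos(np.deg2rad(criterion.angle_cutoff))
    rows, cols = np.nonzero(cand)
    cosang = np.einsum("kd,kd->k", dhu[rows], da[rows, cols] / dist[rows, cols][:, None])
    ok = cosang > cos_cut
    for r, c in zip(rows[ok], cols[ok]):
        out.append((int(d_idx[r]), int(h_idx[r]), int(acceptors[c])))
    return sorted(set(out))


def _frame(traj: Trajectory, f: int) -> Frame:
    return Frame(traj.coordinates[f], traj.box, float(traj.times[f]))


def _bonds_between(traj: Trajectory, f: int, group_a, group_b,
                   criterion: HBondCriterion) -> set[tuple[int, int, int]]:
    """Bond triples with donor in one group and acceptor in the other; when
    the groups coincide, within-group bonds counted once per triple."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both atom groups must be non-empty")
    frame = _frame(traj, f)
    bonds = set(detect_hbonds(frame, traj.topology, a, b, criterion))
    if not np.array_equal(np.sort(a), np.sort(b)):
        bonds |= set(detect_hbonds(frame, traj.topology, b, a, criterion))
    return bonds


def hbond_count_series(traj: Trajectory, group_a, group_b,
                       criterion: HBondCriterion | None = None) -> CountSeries:
    """Per-frame hydrogen-bond counts between two groups, with mean +/- sd.

    Both donor->acceptor directions are counted; each (D, H, A) triple counts
    once. Identical groups give the within-group (e.g. water-water) count.
    """
    criterion = criterion or HBondCriterion()
    counts = np.array([len(_bonds_between(traj, f, group_a, group_b, criterion))
                       for f in range(traj.n_frames)])
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return CountSeries(counts=counts, mean=float(counts.mean()), sd=sd)


def hbond_existence(traj: Trajectory, group_a, group_b,
                    criterion: HBondCriterion | None = None) -> HBondSeries:
    """Presence indicator h_i(t) for the union of all triples ever bonded."""
    criterion = criterion or HBondCriterion()
    per_frame = [_bonds_between(traj, f, group_a, group_b, criterion)
                 for f in range(traj.n_frames)]
    pairs = sorted(set().union(*per_frame)) if per_frame else []
    if not pairs:
        raise AnalysisError("no hydrogen bond detected in any frame")
    index = {p: i for i, p in enumerate(pairs)}
    h = np.zeros((len(pairs), traj.n_frames), dtype=np.uint8)
    for f, bonds in enumerate(per_frame):
        for p in bonds:
            h[index[p], f] = 1
    return HBondSeries(pairs=pairs, h=h, dt=traj.dt)


def continuous_lifetime(series: HBondSeries) -> float:
    """Mean duration (ps) of unbroken bonded intervals, tau_HB.

    Runs that touch either end of the trajectory are censored (their true
    length is unknown) and excluded from the mean.
    """
    h = np.asarray(series.h)
    n_pairs, n_frames = h.shape
    # pad rows with zeros so runs never span row boundaries after flattening
    padded = np.zeros((n_pairs, n_frames + 2), dtype=np.int8)
    padded[:, 1:-1] = h
    flat = padded.ravel()
    d = np.diff(flat)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if starts.size == 0:
        raise AnalysisError("series contains no bonded interval")
    width = n_frames + 2
    col_start = starts % width
    col_end = ends % width
    interior = (col_start > 1) & (col_end < width - 1)
    lengths = (ends - starts)[interior]
    if lengths.size == 0:
        raise AnalysisError("only censored bonded intervals found; "
                            "a longer trajectory is needed for tau_HB")
    return float(lengths.mean() * series.dt)


def intermittent_correlation(series: HBondSeries, max_lag: float | None = None,
                             origin_stride: int = 1,
                             weighting: str = "occupancy") -> CorrelationSeries:
    """Intermittent population correlation c(t) = <h(0) h(t)> / <h>.

    A pair bonded at t0 contributes whether or not the bond broke in between.
    The default ``weighting="occupancy"`` pools numerator and denominator
    over pairs and origins — the plain ensemble average, and an unbiased
    conditional-probability estimator. ``weighting="pair"`` instead averages
    each pair's own normalised correlation with equal weight (pairs never
    bonded on a lag's origin grid are skipped); note this ratio-of-ratios
    carries a small Jensen bias when per-pair bonded time fluctuates. Both
    give c(0) = 1 exactly.
    """
    if weighting not in ("pair", "occupancy"):
        raise ParameterError("weighting must be 'pair' or 'occupancy'")
    h = np.asarray(series.h, dtype=np.uint8)
    if h.sum() == 0:
        raise AnalysisError("indicator series is identically zero")
    n_pairs, n_frames = h.shape
    dt = series.dt
    max_lag_frames = (n_frames - 1 if max_lag is None
                      else int(round(max_lag / dt)))
    if max_lag_frames < 1 or max_lag_frames > n_frames - 1:
        raise ParameterError("max_lag must lie within the trajectory span")
    if origin_stride < 1:
        raise ParameterError("origin_stride must be >= 1")
    value = np.empty(max_lag_frames + 1)
    n_origins = np.empty(max_lag_frames + 1, dtype=int)
    for k in range(max_lag_frames + 1):
        origins = np.arange(0, n_frames - k, origin_stride)
        h0 = h[:, origins]
        hk = h[:, origins + k]
        num = (h0 & hk).sum(axis=1, dtype=np.int64)
        den = h0.sum(axis=1, dtype=np.int64)
        if weighting == "pair":
            alive = den > 0
            value[k] = float(np.mean(num[alive] / den[alive]))
        else:
            value[k] = float(num.sum() / den.sum())
        n_origins[k] = origins.size
    return CorrelationSeries(lag=np.arange(max_lag_frames + 1) * dt, value=value,
                             n_origins=n_origins)


def relaxation_time(c_curve: CorrelationSeries, extrapolate: bool = False):
    """Relaxation time tau_R: the lag at which c(t) first decays to 1/e.

    The crossing is located by linear interpolation between the bracketing
    lags. If c never reaches 1/e within the sampled window, an exponential
    tail fit is used when ``extrapolate`` is enabled (returned with a flag),
    otherwise an :class:`AnalysisError` names the plateau value.

    Returns ``(tau_r, extrapolated)``.
    """
    t = np.asarray(c_curve.lag, dtype=float)
    c = np.asarray(c_curve.value, dtype=float)
    target = np.exp(-1.0)
    below = np.flatnonzero(c < target)
    if below.size:
        i = below[0]
        if i == 0:
            return float(t[0]), False
        t0, t1 = t[i - 1], t[i]
        c0, c1 = c[i - 1], c[i]
        tau = t0 + (c0 - target) / (c0 - c1) * (t1 - t0)
        return float(tau), False
    if not extrapolate:
        raise AnalysisError(
            f"c(t) plateaus at {c.min():.4f} > 1/e within the sampled lags; "
            "extend the window or enable extrapolation")
    # exponential fit to the decaying tail (second half of the window)
    half = len(t) // 2
    ts, cs = t[half:], c[half:]
    if np.any(cs <= 0) or cs[0] <= cs[-1]:
        raise AnalysisError("tail is not decaying; cannot extrapolate tau_R")
    coef = np.polyfit(ts, np.log(cs), 1)
    if coef[0] >= 0:
        raise AnalysisError("tail is not decaying; cannot extrapolate tau_R")
    tau = (coef[1] - np.log(target)) / (-coef[0])
    return float(tau), True


def hbond_times(traj: Trajectory, group_a, group_b,
                criterion: HBondCriterion | None = None,
                max_lag: float | None = None, origin_stride: int = 1,
                extrapolate_tau_r: bool = False) -> HBondTimes:
    """Convenience wrapper: existence series, tau_HB, c(t) and tau_R in one call."""
    series = hbond_existence(traj, group_a, group_b, criterion)
    tau_hb = continuous_lifetime(series)
    c = intermittent_correlation(series, max_lag=max_lag, origin_stride=origin_stride)
    tau_r, flag = relaxation_time(c, extrapolate=extrapolate_tau_r)
    return HBondTimes(tau_hb=tau_hb, tau_r=tau_r, c_curve=c, tau_r_extrapolated=flag)


def shell_water_count(traj: Trajectory, reference_selection, cutoff: float):
    """Per-frame count of waters within ``cutoff`` of the reference selection.

    Column sums of :func:`hydrashell.hydration.shell_membership`; returns
    ``(counts, mean)``.
    """
    membership = shell_membership(traj, reference_selection, cutoff)
    counts = membership.counts
    return counts, float(counts.mean())
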