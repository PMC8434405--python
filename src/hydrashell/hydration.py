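"""Hydration-shell residence and water reorientation dynamics.

Shell membership tags each water whose oxygen lies within a cutoff
(0.6 nm protein-wide by convention) of any reference atom. The residence
correlation C_r(t) is the origin-averaged fraction of the waters present at
t0 that are (intermittent convention) again present at t0+t; it is fitted by
the biphasic model

    C_r(t) = n_s * exp(-(t/tau_s)^gamma) + n_1 * exp(-t/tau_1),

a stretched (KWW) slow term for collective escape from the heterogeneous
surface plus a fast exponential for boundary exchange. Water reorientation
is probed by the rank-1 dipole autocorrelation C_mu(t) = <u(0).u(t)> with a
single-exponential fit A_mu * exp(-t/t_mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError, ParameterError, TopologyError
from .trajectory import Frame, Topology, Trajectory, minimum_image_displacement


@dataclass
class ShellMembership:
    water_ids: np.ndarray        # molecule ids, one per tracked water
    occupancy: np.ndarray        # (n_waters, n_frames) bool
    cutoff: float                # nm
    reference_selection: np.ndarray
    dt: float                    # ps

    @property
    def counts(self) -> np.ndarray:
        """Per-frame number of shell waters."""
        return self.occupancy.sum(axis=0)


@dataclass
class CorrelationSeries:
    lag: np.ndarray              # ps
    value: np.ndarray
    n_origins: np.ndarray


@dataclass
class FitResult:
    model: str                   # "biexp_stretched" | "single_exp"
    params: dict
    param_uncertainty: dict
    rms_residual: float
    converged: bool
    message: str = ""


def shell_membership(traj: Trajectory, reference_selection, cutoff: float) -> ShellMembership:
    """Boolean shell occupancy of every water over every frame.

    Water i occupies the shell at frame t iff the minimum-image distance from
    its oxygen to the nearest reference atom is <= cutoff (nm). A cutoff of 0
    is the degenerate always-empty shell; negative cutoffs are rejected.
    """
    if cutoff < 0:
        raise ParameterError("cutoff must be non-negative")
    ref = np.asarray(reference_selection, dtype=int)
    if ref.size == 0:
        raise ParameterError("reference selection is empty")
    waters = traj.topology.water_molecules()
    if not waters:
        raise TopologyError("no water molecules (1 O + 2 H) found in the topology")
    oxy = np.array([o for o, _, _ in waters], dtype=int)
    mol_ids = traj.topology.molecule_id[oxy]
    occ = np.zeros((len(oxy), traj.n_frames), dtype=bool)
    if cutoff > 0:
        for f in range(traj.n_frames):
            pos = traj.coordinates[f]
            if traj.box is not None:
                d = minimum_image_displacement(pos[oxy][:, None, :],
                                               pos[ref][None, :, :], traj.box)
            else:
                d = pos[ref][None, :, :] - pos[oxy][:, None, :]
            occ[:, f] = (np.linalg.norm(d, axis=2).min(axis=1) <= cutoff)
    return ShellMembership(water_ids=mol_ids, occupancy=occ, cutoff=cutoff,
                           reference_selection=ref, dt=traj.dt)


def residence_correlation(membership: ShellMembership, window: float,
                          origin_stride: int = 1,
                          mode: str = "intermittent") -> CorrelationSeries:
    """Origin-averaged shell residence correlation C_r(t).

    C_r(t) = < (1/N_t0) sum_{i in shell(t0)} delta_i(t0 + t) > over origins
    on the stride grid. ``mode="intermittent"`` evaluates membership at t0+t
    regardless of excursions in between (the default counting rule);
    ``mode="continuous"`` removes a water permanently at its first exit.
    Origins with an empty shell are skipped (their number is reflected in
    ``n_origins``).
    """
    if mode not in ("intermittent", "continuous"):
        raise ParameterError("mode must be 'intermittent' or 'continuous'")
    occ = membership.occupancy.astype(np.float64)
    n_frames = occ.shape[1]
    dt = membership.dt
    max_lag = int(round(window / dt))
    if max_lag < 1 or max_lag > n_frames - 1:
        raise ParameterError("window must be positive and within the trajectory span")
    if origin_stride < 1:
        raise ParameterError("origin_stride must be >= 1")
    counts = occ.sum(axis=0)
    value = np.empty(max_lag + 1)
    n_origins = np.empty(max_lag + 1, dtype=int)
    for k in range(max_lag + 1):
        origins = np.arange(0, n_frames - k, origin_stride)
        origins = origins[counts[origins] > 0]
        if origins.size == 0:
            raise AnalysisError("no origin has a non-empty shell")
        if mode == "intermittent":
            later = occ[:, origins + k]
        else:
            # survived: in shell continuously from t0 through t0+k
            later = np.ones((occ.shape[0], origins.size))
            for j, t0 in enumerate(origins):
                later[:, j] = occ[:, t0:t0 + k + 1].min(axis=1)
        frac = (occ[:, origins] * later).sum(axis=0) / counts[origins]
        value[k] = frac.mean()
        n_origins[k] = origins.size
    return CorrelationSeries(lag=np.arange(max_lag + 1) * dt, value=value,
                             n_origins=n_origins)


def _fit_uncertainty(res, n_params: int) -> np.ndarray:
    """1-sigma parameter uncertainties from the local quadratic model at the
    optimum: cov = (J^T J)^-1 * s^2."""
    m = len(res.fun)
    dof = max(m - n_params, 1)
    s2 = 2.0 * res.cost / dof
    JTJ = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(JTJ) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def fit_residence(series: CorrelationSeries, initial: dict | None = None,
                  bounds: dict | None = None, n_restarts: int = 5,
                  seed: int = 0, fix_gamma: float | None = None) -> FitResult:
    """Fit the biphasic stretched-exponential residence model.

    Nonlinear least squares of
    ``n_s exp(-(t/tau_s)^gamma) + n_1 exp(-t/tau_1)`` with multi-start
    (``n_restarts`` seeded initialisations plus any user initial guess);
    the best-objective solution is kept and relabelled so tau_s > tau_1.
    ``fix_gamma`` pins the stretch exponent (e.g. 1.0 for a biexponential).
    Default bounds: n_s, n_1 in [0, 1.5]; gamma in (0.2, 1]; time constants
    in (dt, 10 x span). A warning note is attached when n_s + n_1 strays
    from 1 by more than 0.1.
    """
    t = np.asarray(series.lag, dtype=float)
    c = np.asarray(series.value, dtype=float)
    if len(t) < 10:
        raise ParameterError("residence fit needs at least 10 lag points")
    if np.any(c <= -0.1) or np.any(c > 1.1):
        raise ParameterError("correlation values outside (-0.1, 1.1]")
    if c.max() - c.min() < 1e-12:
        return FitResult("biexp_stretched", {}, {}, rms_residual=float("nan"),
                         converged=False, message="degenerate: series shows no decay")
    dt = t[1] - t[0]
    span = t[-1] - t[0]
    b = {"n_s": (0.0, 1.5), "n_1": (0.0, 1.5), "gamma": (0.2, 1.0),
         "tau_s": (dt, 10.0 * span), "tau_1": (dt, 10.0 * span)}
    b.update(bounds or {})
    names = ["n_s", "tau_s", "gamma", "n_1", "tau_1"]
    free = [n for n in names if not (n == "gamma" and fix_gamma is not None)]

    def model(theta: np.ndarray) -> np.ndarray:
        p = dict(zip(free, theta))
        if fix_gamma is not None:
            p["gamma"] = fix_gamma
        with np.errstate(over="ignore"):
            slow = p["n_s"] * np.exp(-((t / p["tau_s"]) ** p["gamma"]))
            fast = p["n_1"] * np.exp(-t / p["tau_1"])
        return slow + fast

    lo = np.array([b[n][0] for n in free])
    hi = np.array([b[n][1] for n in free])
    rng = np.random.default_rng(seed)
    starts = []
    if initial is not None:
        starts.append(np.array([initial.get(n, 0.5 * (b[n][0] + b[n][1])) for n in free]))
    # heuristic start: amplitude split, tau from the 1/e crossing
    i_e = int(np.argmin(np.abs(c - np.exp(-1.0))))
    tau_guess = max(t[i_e], dt)
    base = {"n_s": 0.5, "tau_s": min(5 * tau_guess, b["tau_s"][1]),
            "gamma": 0.8, "n_1": 0.5, "tau_1": max(tau_guess / 5, b["tau_1"][0])}
    starts.append(np.array([base[n] for n in free]))
    while len(starts) < n_restarts + (initial is not None) + 1:
        u = rng.random(len(free))
        theta = np.array([
            b[n][0] + u[i] * (b[n][1] - b[n][0]) if n in ("n_s", "n_1", "gamma")
            else np.exp(np.log(max(b[n][0], 1e-6))
                        + u[i] * (np.log(b[n][1]) - np.log(max(b[n][0], 1e-6))))
            for i, n in enumerate(free)])
        starts.append(theta)

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(lambda th: model(th) - c, theta0, bounds=(lo, hi))
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return FitResult("biexp_stretched", {}, {}, rms_residual=float("nan"),
                         converged=False, message="no restart converged")
    params = dict(zip(free, best.x))
    if fix_gamma is not None:
        params["gamma"] = fix_gamma
    unc = dict(zip(free, _fit_uncertainty(best, len(free))))
    if fix_gamma is not None:
        unc["gamma"] = 0.0
    message = ""
    if params["tau_s"] < params["tau_1"]:
        params["n_s"], params["n_1"] = params["n_1"], params["n_s"]
        params["tau_s"], params["tau_1"] = params["tau_1"], params["tau_s"]
        unc["n_s"], unc["n_1"] = unc["n_1"], unc["n_s"]
        unc["tau_s"], unc["tau_1"] = unc["tau_1"], unc["tau_s"]
        message = "components relabelled so tau_s > tau_1; "
    total = params["n_s"] + params["n_1"]
    if abs(total - 1.0) > 0.1:
        message += f"warning: n_s + n_1 = {total:.3f} deviates from 1 by > 0.1"
    rms = float(np.sqrt(np.mean((model(best.x) - c) ** 2)))
    return FitResult("biexp_stretched", params, unc, rms_residual=rms,
                     converged=True, message=message.strip())


def water_dipoles(frame: Frame, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Unit dipole direction of every 3-site water in a frame.

    The dipole points from the oxygen along the bisector of the two O-H
    bonds (H positions taken minimum-image relative to O, so a water
    straddling the periodic boundary behaves like its re-imaged copy).
    Returns ``(dipoles, molecule_ids)``.
    """
    waters = topology.water_molecules()
    if not waters:
        raise TopologyError("no water molecules (1 O + 2 H) found in the topology")
    bad = [int(topology.molecule_id[o]) for o, h1, h2 in waters
           if topology.element[h1] != "H" or topology.element[h2] != "H"]
    if bad:
        raise TopologyError(f"malformed waters for molecule ids {bad}")
    idx = np.array(waters, dtype=int)
    pos = frame.coordinates
    o, h1, h2 = pos[idx[:, 0]], pos[idx[:, 1]], pos[idx[:, 2]]
    if frame.box is not None:
        v1 = minimum_image_displacement(o, h1, frame.box)
        v2 = minimum_image_displacement(o, h2, frame.box)
    else:
        v1, v2 = h1 - o, h2 - o
    u1 = v1 / np.linalg.norm(v1, axis=1, keepdims=True)
    u2 = v2 / np.linalg.norm(v2, axis=1, keepdims=True)
    mu = u1 + u2
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    return mu, topology.molecule_id[idx[:, 0]]


def dipole_autocorrelation(traj: Trajectory, water_subset: ShellMembership | None = None,
                           max_lag: float | None = None,
                           origin_stride: int = 1) -> CorrelationSeries:
    """Rank-1 dipole reorientation correlation C_mu(t) = <u(t0).u(t0+t)>.

    Averages the dot product of unit dipoles over waters and time origins on
    the stride grid. With ``water_subset`` (a :class:`ShellMembership`), only
    waters inside the shell at each origin contribute to that origin.
    C_mu(0) = 1 exactly since dipoles are unit vectors.
    """
    dip = np.stack([water_dipoles(Frame(traj.coordinates[f], traj.box,
                                        float(traj.times[f])), traj.topology)[0]
                    for f in range(traj.n_frames)])  # (F, W, 3)
    n_frames, n_waters = dip.shape[0], dip.shape[1]
    dt = traj.dt
    max_lag_frames = (n_frames - 1 if max_lag is None
                      else int(round(max_lag / dt)))
    if max_lag_frames < 1 or max_lag_frames > n_frames - 1:
        raise ParameterError("max_lag must lie within the trajectory span")
    weights = None
    if water_subset is not None:
        if water_subset.occupancy.shape != (n_waters, n_frames):
            raise ParameterError("membership shape does not match the trajectory waters")
        weights = water_subset.occupancy.astype(float)
        if weights.sum() == 0:
            raise AnalysisError("water subset is empty at every origin")
    value = np.empty(max_lag_frames + 1)
    n_origins = np.empty(max_lag_frames + 1, dtype=int)
    for k in range(max_lag_frames + 1):
        origins = np.arange(0, n_frames - k, origin_stride)
        dots = np.einsum("owd,owd->ow", dip[origins], dip[origins + k])
        if weights is None:
            value[k] = dots.mean()
        else:
            w = weights[:, origins].T
            denom = w.sum()
            if denom == 0:
                raise AnalysisError("water subset empty at all origins for this lag")
            value[k] = (dots * w).sum() / denom
        n_origins[k] = origins.size
    return CorrelationSeries(lag=np.arange(max_lag_frames + 1) * dt, value=value,
                             n_origins=n_origins)


def fit_reorientation(series: CorrelationSeries) -> FitResult:
    """Single-exponential fit C_mu(t) = A_mu exp(-t/t_mu)."""
    t = np.asarray(series.lag, dtype=float)
    c = np.asarray(series.value, dtype=float)
    if len(t) < 5:
        raise ParameterError("reorientation fit needs at least 5 lag points")
    if c.max() - c.min() < 1e-12:
        return FitResult("single_exp", {}, {}, rms_residual=float("nan"),
                         converged=False, message="degenerate: series shows no decay")
    pos = c > 0
    if pos.sum() < max(3, len(c) // 4):
        return FitResult("single_exp", {}, {}, rms_residual=float("nan"),
                         converged=False,
                         message="non-positive values dominate; no exponential regime")
    # log-linear initial guess on the positive part
    coef = np.polyfit(t[pos], np.log(c[pos]), 1)
    tau0 = -1.0 / coef[0] if coef[0] < 0 else t[-1]
    A0 = float(np.exp(coef[1]))
    dt = t[1] - t[0] if len(t) > 1 else 1.0

    def resid(theta):
        A, tau = theta
        return A * np.exp(-t / tau) - c

    res = least_squares(resid, np.array([max(A0, 1e-3), max(tau0, dt)]),
                        bounds=([0.0, dt * 1e-3], [2.0, 1e6 * dt]))
    if not res.success:
        return FitResult("single_exp", {}, {}, rms_residual=float("nan"),
                         converged=False, message=res.message)
    unc = _fit_uncertainty(res, 2)
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return FitResult("single_exp",
                     {"A_mu": float(res.x[0]), "t_mu": float(res.x[1])},
                     {"A_mu": float(unc[0]), "t_mu": float(unc[1])},
                     rms_residual=rms, converged=True)
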