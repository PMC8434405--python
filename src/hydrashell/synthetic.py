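"""Synthetic trajectories and indicator series with known ground-truth dynamics.

Every estimator in the package is validated against data produced here:
Brownian walkers with a prescribed translational diffusion coefficient,
rigid 3-site waters under isotropic rotational diffusion with a prescribed
reorientation time, two-state Markov on/off series with prescribed exchange
rates (the generative model for both hydration-shell occupancy and
hydrogen-bond population operators), a geometric shell system whose
occupancy is recoverable exactly by construction, and piecewise-linear
temperature curves with a planted breakpoint.

Units: nm, ps. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .trajectory import Topology, Trajectory, assign_donor_acceptor_flags, wrap_coordinates

# SPC/E rigid water geometry: O-H 0.1 nm, H-O-H 109.47 deg; the dipole points
# from O along the H-H bisector.
SPCE_OH_NM = 0.1
SPCE_HOH_DEG = 109.47


@dataclass(frozen=True)
class GroundTruth:
    """Parameters a generator promises its output realises."""

    D_trans: float = 0.0   # nm^2/ps
    D_rot: float = 0.0     # 1/ps
    k_on: float = 0.0      # 1/ps
    k_off: float = 0.0     # 1/ps
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D_trans", "D_rot", "k_on", "k_off"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def stationary_occupancy(self) -> float:
        total = self.k_on + self.k_off
        return self.k_on / total if total > 0 else 0.0


def _point_topology(n: int, name: str = "CA", element: str = "C",
                    resname: str = "PNT") -> Topology:
    return Topology(
        atom_name=np.array([name] * n, dtype=object),
        element=np.array([element] * n, dtype=object),
        residue_id=np.arange(1, n + 1),
        residue_name=np.array([resname] * n, dtype=object),
        molecule_id=np.arange(n),
    )


def _water_site_offsets() -> np.ndarray:
    """O, H1, H2 offsets (nm) for SPC/E water in its body frame.

    The dipole (H-H bisector from O) lies along +z.
    """
    half = np.deg2rad(SPCE_HOH_DEG) / 2.0
    o = np.zeros(3)
    h1 = SPCE_OH_NM * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = SPCE_OH_NM * np.array([-np.sin(half), 0.0, np.cos(half)])
    return np.stack([o, h1, h2])


def _water_topology(n_molecules: int, extra_ref: bool = False) -> Topology:
    """Topology of ``n_molecules`` SOL waters, optionally preceded by one
    immobile reference site (atom 0, residue PRT)."""
    names, elements, resids, resnames, molids, bonds = [], [], [], [], [], []
    offset = 0
    if extra_ref:
        # amide-like nitrogen so the site is a valid H-bond acceptor
        names += ["REF"]
        elements += ["N"]
        resids += [1]
        resnames += ["PRT"]
        molids += [0]
        offset = 1
    for m in range(n_molecules):
        base = offset + 3 * m
        names += ["OW", "HW1", "HW2"]
        elements += ["O", "H", "H"]
        resids += [offset + m + 1] * 3
        resnames += ["SOL"] * 3
        molids += [m + (1 if extra_ref else 0)] * 3
        bonds += [(base, base + 1), (base, base + 2)]
    top = Topology(
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        residue_id=np.array(resids),
        residue_name=np.array(resnames, dtype=object),
        molecule_id=np.array(molids),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
    )
    assign_donor_acceptor_flags(top)
    return top


def gen_brownian(n_particles: int, D: float, box_edge: float, dt: float,
                 n_frames: int, seed: int = 0) -> Trajectory:
    """Independent Brownian walkers in a cubic periodic box.

    Per-step displacements are i.i.d. Gaussian with variance ``2*D*dt`` per
    Cartesian component, so the unwrapped walk obeys the 3-D Einstein relation
    MSD = 6*D*t. Returned coordinates are wrapped into the box; the unwrapped
    ground truth is kept in ``metadata["unwrapped_coordinates"]``.
    """
    if D < 0:
        raise ParameterError("diffusion coefficient D must be non-negative")
    if n_frames < 2:
        raise ParameterError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, box_edge, size=(n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, n_particles, 3))
    unwrapped = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)], axis=0)
    box = np.diag([box_edge] * 3)
    wrapped = wrap_coordinates(unwrapped, box)
    times = np.arange(n_frames) * dt
    meta = {"ground_truth": GroundTruth(D_trans=D, seed=seed),
            "unwrapped_coordinates": unwrapped}
    return Trajectory(_point_topology(n_particles), wrapped, box, times, meta)


def gen_rotors(n_molecules: int, D_rot: float, dt: float, n_frames: int,
               seed: int = 0, box_edge: float = 5.0) -> Trajectory:
    """Rigid SPC/E-geometry waters under isotropic rotational diffusion.

    Each step applies a small random rotation with rotation-vector components
    i.i.d. N(0, 2*D_rot*dt), which realises the l=1 orientational correlation
    <u(0).u(t)> = exp(-2*D_rot*t). Molecular centres are static; only
    orientations evolve. Requires ``dt*D_rot <= 0.05`` for the small-step
    integrator to be valid.
    """
    if D_rot < 0:
        raise ParameterError("D_rot must be non-negative")
    if D_rot * dt > 0.05:
        raise ParameterError(
            f"dt*D_rot = {D_rot * dt:.3g} exceeds the small-step bound 0.05; "
            "use a smaller dt")
    rng = np.random.default_rng(seed)
    centres = rng.uniform(0.0, box_edge, size=(n_molecules, 3))
    orientations = Rotation.random(n_molecules, random_state=rng)
    sites = _water_site_offsets()  # (3, 3)

    coords = np.empty((n_frames, 3 * n_molecules, 3))
    sigma = np.sqrt(2.0 * D_rot * dt)
    for f in range(n_frames):
        mats = orientations.as_matrix()  # (M, 3, 3)
        placed = np.einsum("mij,sj->msi", mats, sites)  # (M, 3 sites, 3)
        coords[f] = (centres[:, None, :] + placed).reshape(-1, 3)
        if f < n_frames - 1 and D_rot > 0:
            kicks = Rotation.from_rotvec(rng.normal(0.0, sigma, size=(n_molecules, 3)))
            orientations = kicks * orientations
    times = np.arange(n_frames) * dt
    meta = {"ground_truth": GroundTruth(D_rot=D_rot, seed=seed)}
    return Trajectory(_water_topology(n_molecules), coords,
                      np.diag([box_edge] * 3), times, meta)


def gen_two_state_series(n_series: int, k_on: float, k_off: float, dt: float,
                         n_frames: int, seed: int = 0,
                         start: str = "stationary") -> np.ndarray:
    """Discrete-time sampling of independent two-state (off/on) Markov chains.

    Per-step transition probabilities are first-order: P(0->1) = k_on*dt,
    P(1->0) = k_off*dt, requiring ``dt*(k_on + k_off) <= 0.1``. Stationary
    occupancy is k_on/(k_on+k_off); the autocorrelation of the indicator
    decays with rate k_on+k_off (up to O(dt) discretisation). ``start`` is
    ``"stationary"`` (Bernoulli draw at the stationary occupancy) or ``"on"``.

    Returns an (n_series, n_frames) uint8 matrix of 0/1 indicators.
    """
    if k_on < 0 or k_off < 0 or (k_on + k_off) <= 0:
        raise ParameterError("rates must be non-negative with k_on + k_off > 0")
    if dt * (k_on + k_off) > 0.1:
        raise ParameterError(
            f"dt*(k_on+k_off) = {dt * (k_on + k_off):.3g} exceeds the first-order "
            "bound 0.1; use a smaller dt")
    if start not in ("stationary", "on"):
        raise ParameterError("start must be 'stationary' or 'on'")
    rng = np.random.default_rng(seed)
    p_on = k_on * dt
    p_off = k_off * dt
    h = np.empty((n_series, n_frames), dtype=np.uint8)
    if start == "on":
        state = np.ones(n_series, dtype=np.uint8)
    else:
        p = k_on / (k_on + k_off)
        state = (rng.random(n_series) < p).astype(np.uint8)
    h[:, 0] = state
    for t in range(1, n_frames):
        u = rng.random(n_series)
        flip_on = (state == 0) & (u < p_on)
        flip_off = (state == 1) & (u < p_off)
        state = state.copy()
        state[flip_on] = 1
        state[flip_off] = 0
        h[:, t] = state
    return h


def two_state_correlation(t: np.ndarray, k_on: float, k_off: float) -> np.ndarray:
    """Closed-form normalized indicator autocorrelation of the two-state chain,
    c(t) = p + (1-p) * exp(-(k_on+k_off) t) with p = k_on/(k_on+k_off)."""
    p = k_on / (k_on + k_off)
    return p + (1.0 - p) * np.exp(-(k_on + k_off) * np.asarray(t, dtype=float))


def gen_shell_system(n_waters: int, k_on: float, k_off: float, cutoff: float,
                     box_edge: float, dt: float, n_frames: int,
                     seed: int = 0) -> Trajectory:
    """Waters hopping in and out of a spherical shell around a central site.

    A single immobile reference atom sits at the box centre. Each water's
    occupancy follows an independent two-state Markov chain; in frames where
    the indicator is 1 the water oxygen is placed uniformly inside radius
    ``0.9*cutoff`` of the reference, otherwise uniformly in the box at
    minimum-image distance beyond ``1.1*cutoff``. The 10% margins make
    geometric membership recovery exact, so ``shell_membership`` applied to
    the output must reproduce ``metadata["occupancy"]`` bit for bit.
    """
    if cutoff >= box_edge / 2:
        raise ParameterError("cutoff must be below half the box edge")
    rng = np.random.default_rng(seed)
    occ = (gen_two_state_series(n_waters, k_on, k_off, dt, n_frames,
                                seed=int(rng.integers(2 ** 31)))
           if n_waters else np.zeros((0, n_frames), dtype=np.uint8))
    centre = np.full(3, box_edge / 2.0)
    box = np.diag([box_edge] * 3)

    def sample_inside(n: int) -> np.ndarray:
        vec = rng.normal(size=(n, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        r = 0.9 * cutoff * rng.random(n) ** (1.0 / 3.0)
        return centre + vec * r[:, None]

    def sample_outside(n: int) -> np.ndarray:
        out = np.empty((n, 3))
        need = np.arange(n)
        while len(need):
            cand = rng.uniform(0.0, box_edge, size=(len(need), 3))
            d = np.linalg.norm(cand - centre, axis=1)  # centre is the box midpoint:
            ok = d > 1.1 * cutoff                      # no image closer than the direct one
            out[need[ok]] = cand[ok]
            need = need[~ok]
        return out

    sites = _water_site_offsets()
    n_atoms = 1 + 3 * n_waters
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, 0, :] = centre
    for f in range(n_frames):
        inside = occ[:, f].astype(bool)
        o_pos = np.empty((n_waters, 3))
        if inside.any():
            o_pos[inside] = sample_inside(int(inside.sum()))
        if (~inside).any():
            o_pos[~inside] = sample_outside(int((~inside).sum()))
        rots = Rotation.random(n_waters, random_state=rng) if n_waters else None
        if n_waters:
            placed = np.einsum("mij,sj->msi", rots.as_matrix(), sites)
            coords[f, 1:, :] = (o_pos[:, None, :] + placed).reshape(-1, 3)
    times = np.arange(n_frames) * dt
    meta = {"ground_truth": GroundTruth(k_on=k_on, k_off=k_off, seed=seed),
            "occupancy": occ, "cutoff": cutoff, "reference_index": 0}
    return Trajectory(_water_topology(n_waters, extra_ref=True), coords, box, times, meta)


def gen_piecewise_linear(x: np.ndarray, break_x: float, slope1: float,
                         slope2: float, intercept: float, noise_sd: float = 0.0,
                         seed: int = 0) -> dict[str, np.ndarray]:
    """Continuous piecewise-linear curve with a slope change at ``break_x``
    plus i.i.d. Gaussian noise; fixture for breakpoint detection."""
    x = np.asarray(x, dtype=float)
    if not (x.min() <= break_x <= x.max()):
        raise ParameterError("break_x must lie inside the x grid range")
    y = np.where(x <= break_x,
                 intercept + slope1 * x,
                 intercept + slope1 * break_x + slope2 * (x - break_x))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.shape)
    return {"x": x, "y": y}
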