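"""Structural fluctuation metrics: RMSF, rigid-body superposition, RMSD,
and solvent-accessible surface area.

RMSF of atom i is the root of the time-averaged squared deviation from its
time-mean position, sqrt( (1/T) sum_t |x_i(t) - <x_i>|^2 ); it quantifies
per-atom (or per-residue) flexibility. RMSD against a reference frame,
optionally after least-squares rigid-body superposition, tracks internal
mobility over time. SASA uses numerical sphere-point (Shrake-Rupley-style)
burial counting with a water-sized probe.

Periodic images are ignored here: the analysed selection is assumed
contiguous (re-image molecules beforehand if needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ParameterError
from .trajectory import Frame, Trajectory

#: Bondi van der Waals radii, nm
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
    "F": 0.147,
    "CL": 0.175,
}


@dataclass
class RMSFProfile:
    ids: np.ndarray          # atom or residue ids
    rmsf: np.ndarray         # nm
    by_residue: bool = False


@dataclass
class RMSDSeries:
    time: np.ndarray         # ps
    rmsd: np.ndarray         # nm
    superposed: bool = True


@dataclass
class SASAResult:
    total: float             # nm^2
    per_atom: np.ndarray     # nm^2, aligned with the selection
    n_sphere_points: int = 960


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    if sel.size == 0:
        raise ParameterError("selection is empty")
    return sel


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns ``(rotation, translation, rmsd_after)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to ``reference``
    over all proper rigid transforms. The rotation determinant is +1.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise ParameterError("mobile and reference must have equal point counts")
    if len(mob) < 3:
        raise ParameterError("superposition needs at least 3 points")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise ParameterError("mobile points are collinear: superposition is degenerate")
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ref.mean(axis=0) - mob.mean(axis=0) @ R.T
    fitted = mob @ R.T + t
    rmsd_after = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd_after


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def rmsf(traj: Trajectory, selection=None, align_first: bool = False,
         by_residue: bool = False) -> RMSFProfile:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    With ``align_first`` every frame is first superposed onto frame 0 over
    the selection, so global rigid-body drift does not inflate the profile.
    ``by_residue`` averages atom RMSF values within each residue (unweighted).
    """
    if traj.n_frames < 2:
        raise ParameterError("RMSF needs at least 2 frames")
    sel = _resolve_selection(traj, selection)
    X = traj.coordinates[:, sel, :].copy()
    if align_first:
        for f in range(1, len(X)):
            R, t, _ = superpose(X[f], X[0])
            X[f] = apply_transform(X[f], R, t)
    mean = X.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    if not by_residue:
        return RMSFProfile(ids=sel, rmsf=per_atom, by_residue=False)
    resids = traj.topology.residue_id[sel]
    uniq = np.unique(resids)
    agg = np.array([per_atom[resids == r].mean() for r in uniq])
    return RMSFProfile(ids=uniq, rmsf=agg, by_residue=True)


def rmsd_series(traj: Trajectory, reference_frame: int = 0, selection=None,
                superpose_flag: bool = True) -> RMSDSeries:
    """RMSD of each frame against a reference frame over a selection.

    Default superposition removes rigid-body motion so the series reflects
    internal mobility only.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise ParameterError(f"reference frame {reference_frame} out of range")
    sel = _resolve_selection(traj, selection)
    X = traj.coordinates[:, sel, :]
    ref = X[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if superpose_flag:
            _, _, out[f] = superpose(X[f], ref)
        else:
            out[f] = np.sqrt(np.mean(np.sum((X[f] - ref) ** 2, axis=1)))
    return RMSDSeries(time=traj.times.copy(), rmsd=out, superposed=superpose_flag)


def _golden_spiral_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(frame: Frame, topology=None, selection=None,
         radii: dict[str, float] | None = None, probe: float = 0.14,
         n_sphere_points: int = 960) -> SASAResult:
    """Solvent-accessible surface area by sphere-point burial counting.

    Each selected atom is dressed with ``n_sphere_points`` quasi-uniform
    points at radius r_vdw + probe; points inside any other selected atom's
    extended sphere are buried. Per-atom area is the exposed point fraction
    times the full extended-sphere area; the total is the sum. Defaults:
    Bondi radii, 0.14 nm water probe, 960 points.
    """
    if n_sphere_points < 32:
        raise ParameterError("n_sphere_points must be at least 32")
    coords = frame.coordinates
    if topology is not None:
        elements = topology.element
    else:
        elements = np.array(["C"] * len(coords), dtype=object)
    sel = (np.arange(len(coords)) if selection is None
           else np.asarray(selection, dtype=int))
    if sel.size == 0:
        raise ParameterError("selection is empty")
    table = {**VDW_RADII_NM, **(radii or {})}
    try:
        r = np.array([table[str(elements[i]).upper()] for i in sel])
    except KeyError as exc:
        raise ParameterError(f"no van der Waals radius for element {exc.args[0]!r}; "
                             "supply one via the radii argument") from exc
    ext = r + probe
    pos = coords[sel]
    sphere = _golden_spiral_points(n_sphere_points)
    per_atom = np.empty(len(sel))
    for a in range(len(sel)):
        pts = pos[a] + ext[a] * sphere
        # neighbour prefilter: only atoms whose extended spheres can occlude
        d = np.linalg.norm(pos - pos[a], axis=1)
        nb = np.flatnonzero((d < ext[a] + ext) & (np.arange(len(sel)) != a))
        exposed = np.ones(n_sphere_points, dtype=bool)
        for b in nb:
            exposed &= np.linalg.norm(pts - pos[b], axis=1) >= ext[b]
        per_atom[a] = exposed.mean() * 4.0 * np.pi * ext[a] ** 2
    return SASAResult(total=float(per_atom.sum()), per_atom=per_atom,
                      n_sphere_points=n_sphere_points)
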