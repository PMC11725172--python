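"""Kabsch superposition, region-resolved RMSD kinetics, biexponential fits.

The RMSD protocol follows the stability analysis of the photoactivation study:
every frame of a replica is rigidly superposed onto that replica's initial
frame using the whole backbone (all BB beads), and the RMSD is then evaluated
over the BB beads of the region of interest.  The ensemble mean RMSD curve is
summarized by a biexponential relaxation

    R(t) = R_inf - c1 * exp(-t/tau1) - c2 * exp(-t/tau2),   R(0) fixed,

whose weighted mean time constant tau_eff = (c1*tau1 + c2*tau2)/(c1 + c2) is
the region's effective response time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DegeneracyError, FitError, ShapeError
from .trajectory_io import Ensemble, RegionSet, select

__all__ = [
    "kabsch_superpose",
    "superpose_frames",
    "superpose_to_reference",
    "rmsd",
    "rmsd_series",
    "RMSDResult",
    "BiexpFit",
    "fit_biexponential",
]

_DEGENERACY_RTOL = 1e-8


def _check_fit_set(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegeneracyError("superposition needs at least 3 fit beads")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= _DEGENERACY_RTOL * max(s[0], 1.0):
        raise DegeneracyError("fit beads are collinear or coincident")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of one frame onto a reference frame.

    Returns ``(rotation, translation, transformed)`` such that
    ``transformed = mobile @ rotation.T + translation`` minimizes the RMSD over
    ``fit_indices`` (all beads when None).  The rotation is proper
    (determinant +1, reflections excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ShapeError(f"frame shapes differ: {mobile.shape} vs {reference.shape}")
    idx = np.arange(mobile.shape[0]) if fit_indices is None else np.asarray(fit_indices)
    m, r = mobile[idx], reference[idx]
    _check_fit_set(m)
    _check_fit_set(r)

    mc, rc = m.mean(axis=0), r.mean(axis=0)
    H = (m - mc).T @ (r - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t, mobile @ R.T + t


def _kabsch_batch(frames: np.ndarray, reference: np.ndarray,
                  fit_idx: np.ndarray) -> np.ndarray:
    """Superpose many frames (F, N, 3) onto one reference frame; vectorized."""
    m = frames[:, fit_idx]
    r = reference[fit_idx]
    mc = m.mean(axis=1, keepdims=True)
    rc = r.mean(axis=0)
    H = np.einsum("fni,nj->fij", m - mc, r - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fji,fkj->fik", Vt, U)))
    Vt[:, 2] *= d[:, None]
    R = np.einsum("fji,fkj->fik", Vt, U)          # R = V D U^T, acting as x @ R.T
    t = rc - np.einsum("fij,fj->fi", R, mc[:, 0])
    return np.einsum("fij,fnj->fni", R, frames) + t[:, None]


def superpose_frames(frames: np.ndarray, reference: np.ndarray,
                     fit_indices: np.ndarray) -> np.ndarray:
    """Superpose a stack of frames onto a reference frame over fit beads."""
    _check_fit_set(reference[fit_indices])
    return _kabsch_batch(np.asarray(frames, dtype=float),
                         np.asarray(reference, dtype=float),
                         np.asarray(fit_indices))


def superpose_to_reference(
    ensemble: Ensemble,
    reference_structure: np.ndarray,
    fit_indices: np.ndarray | None = None,
    label: str = "reference",
) -> Ensemble:
    """Superpose every frame of every replica onto one common structure.

    Marks the result with ``aligned_to=label`` so that downstream ensemble
    comparisons can verify a shared superposition target.
    """
    reference_structure = np.asarray(reference_structure, dtype=float)
    if reference_structure.shape != (ensemble.n_beads, 3):
        raise ShapeError("reference structure shape does not match ensemble beads")
    fit_idx = (ensemble.topology.bb_indices if fit_indices is None
               else np.asarray(fit_indices))
    coords = np.empty_like(ensemble.coordinates)
    for r in range(ensemble.n_replicas):
        coords[r] = _kabsch_batch(ensemble.coordinates[r], reference_structure, fit_idx)
    return replace(ensemble, coordinates=coords, aligned_to=label)


def rmsd(a: np.ndarray, b: np.ndarray, indices: np.ndarray | None = None) -> float:
    """Plain (unfitted) RMSD between two frames over the given beads."""
    if indices is not None:
        a, b = a[indices], b[indices]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


@dataclass(frozen=True)
class RMSDResult:
    """Per-region RMSD time series of an ensemble."""

    region: str
    frame_times: np.ndarray        # (n_frames,) us
    per_replica: np.ndarray        # (n_replicas, n_frames) Angstrom
    mean: np.ndarray               # (n_frames,)
    std: np.ndarray                # (n_frames,)


def rmsd_series(
    ensemble: Ensemble,
    region: str | tuple[int, int] = "all",
    regions: RegionSet | None = None,
    fit_scope: str = "whole_backbone",
) -> RMSDResult:
    """Region-resolved RMSD relative to each replica's own initial frame.

    fit_scope: 'whole_backbone' superposes on all BB beads (default, keeps the
    region RMSD sensitive to motion relative to the protein body);
    'region_only' superposes on the region's own beads.
    """
    if ensemble.n_frames < 2:
        raise ShapeError("RMSD time series needs at least 2 frames")
    topo = ensemble.topology
    if region == "all":
        region_idx = topo.bb_indices
        name = "all"
    else:
        region_idx = select(ensemble, region, regions=regions)
        name = region if isinstance(region, str) else f"{region[0]}-{region[1]}"
    if fit_scope == "whole_backbone":
        fit_idx = topo.bb_indices
    elif fit_scope == "region_only":
        fit_idx = region_idx
    else:
        raise ValueError(f"unknown fit_scope {fit_scope!r}")

    out = np.empty((ensemble.n_replicas, ensemble.n_frames))
    for r in range(ensemble.n_replicas):
        ref = ensemble.coordinates[r, 0]
        fitted = _kabsch_batch(ensemble.coordinates[r], ref, fit_idx)
        diff = fitted[:, region_idx] - ref[region_idx]
        out[r] = np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))
    out[:, 0] = 0.0  # frame 0 vs itself is exact, not float residue
    return RMSDResult(region=name, frame_times=ensemble.frame_times,
                      per_replica=out, mean=out.mean(axis=0), std=out.std(axis=0))


# ---------------------------------------------------------------------------
# biexponential relaxation fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiexpFit:
    """Fitted relaxation parameters of an RMSD curve.

    c1/c2 are amplitudes in Angstrom; tau_eff is their weighted mean time
    constant.  ``model`` records whether the two-component fit was kept or the
    single-exponential fallback was used.
    """

    plateau: float
    c1: float
    c2: float
    tau1: float
    tau2: float
    tau_eff: float
    residual_norm: float
    converged: bool
    model: str = "biexponential"

    def predict(self, t: np.ndarray) -> np.ndarray:
        return (self.plateau - self.c1 * np.exp(-t / self.tau1)
                - self.c2 * np.exp(-t / self.tau2))


_TAU_DEGENERACY = 1e-3


def _biexp_model(t, r0, A, w, tau1, tau2):
    return r0 + A * (1.0 - w * np.exp(-t / tau1) - (1.0 - w) * np.exp(-t / tau2))


def _fit_once(t, y, r0, x0, bounds):
    def resid(p):
        return _biexp_model(t, r0, *p) - y
    return least_squares(resid, x0=x0, bounds=bounds)


def fit_biexponential(times: np.ndarray, values: np.ndarray) -> BiexpFit:
    """Least-squares biexponential fit with R(0) pinned to the first sample.

    Parameterized as R(t) = R0 + A(1 - w e^{-t/tau1} - (1-w) e^{-t/tau2}) with
    A >= 0 and w in [0, 1], which enforces R(0) = R0 and non-negative
    amplitudes; tau bounds are [dt, 10*t_max].  Falls back to a single
    exponential when the two time constants are degenerate (relative gap
    below 1e-3) or the two-component fit fails.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ShapeError("times and values must be matching 1-D arrays")
    if len(t) < 8:
        raise FitError("need at least 8 time points for a relaxation fit")
    if np.any(y < -1e-9):
        raise FitError("RMSD values must be non-negative")
    y = np.clip(y, 0.0, None)
    r0 = float(y[0])
    t_max = float(t[-1])
    dt = float(np.min(np.diff(t)))
    amp0 = max(float(y[-1]) - r0, 1e-6)
    tau_lo, tau_hi = dt, 10.0 * t_max

    bounds = ([0.0, 0.0, tau_lo, tau_lo], [np.inf, 1.0, tau_hi, tau_hi])
    starts = [
        (amp0, 0.5, 0.1 * t_max, 0.5 * t_max),
        (amp0, 0.3, 0.05 * t_max, 0.3 * t_max),
        (amp0, 0.7, 0.02 * t_max, 0.2 * t_max),
    ]
    best = None
    for x0 in starts:
        try:
            res = _fit_once(t, y, r0, x0, bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is not None and best.success:
        A, w, tau1, tau2 = best.x
        if tau1 > tau2:  # canonical order: tau1 fast
            tau1, tau2, w = tau2, tau1, 1.0 - w
        degenerate = abs(tau1 - tau2) / max(tau1, tau2) < _TAU_DEGENERACY
        if not degenerate:
            c1, c2 = A * w, A * (1.0 - w)
            tau_eff = ((c1 * tau1 + c2 * tau2) / (c1 + c2)) if A > 0 else tau1
            return BiexpFit(plateau=r0 + A, c1=c1, c2=c2, tau1=tau1, tau2=tau2,
                            tau_eff=tau_eff,
                            residual_norm=float(np.sqrt(2.0 * best.cost)),
                            converged=True)

    # single-exponential fallback: R(t) = R0 + A(1 - e^{-t/tau})
    def resid1(p):
        A, tau = p
        return r0 + A * (1.0 - np.exp(-t / tau)) - y

    try:
        res1 = least_squares(resid1, x0=[amp0, 0.2 * t_max],
                             bounds=([0.0, tau_lo], [np.inf, tau_hi]))
    except Exception as exc:
        raise FitError("both biexponential and single-exponential fits failed",
                       diagnostics={"error": str(exc)}) from exc
    if not res1.success:
        raise FitError("both biexponential and single-exponential fits failed",
                       diagnostics={"status": res1.status, "cost": res1.cost})
    A, tau = res1.x
    return BiexpFit(plateau=r0 + A, c1=A, c2=0.0, tau1=tau, tau2=tau,
                    tau_eff=tau, residual_norm=float(np.sqrt(2.0 * res1.cost)),
                    converged=True, model="single_exponential")
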