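"""Synthetic coarse-grained trajectory ensembles with known ground truth.

The generator emulates the statistical structure that the downstream analyses
assume of a photoactivated-protein ensemble:

* each residue's mean position relaxes from the dark-state structure toward a
  shifted equilibrium with biexponential kinetics
  ``Delta * (1 - c1*exp(-t/tau1) - c2*exp(-t/tau2))`` along a fixed,
  seed-determined unit direction;
* stationary thermal fluctuation is an exact-discretization Ornstein-Uhlenbeck
  process per coordinate (std ``sigma``, autocorrelation time ``tau_ou``);
* an irreversible two-site swap: per replica an exponential waiting time
  ``T ~ Exp(tau_flip)`` is drawn and, from the first frame at or after ``T``,
  the SC2 beads of the two designated tryptophans exchange their mean
  positions, swapping their distances to the flavin site;
* optional replica-level coupling: a mean-one log-normal amplitude factor
  shared by all residues of a named region group, giving the cross-replica
  heterogeneity that a divergence-correlation network can detect.

A matched stationary reference ensemble (dark state, ``DS``) uses the same base
structure and fluctuations with all displacement amplitudes forced to zero.
All randomness flows through :class:`numpy.random.Generator` seeded from a
single integer, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecValidationError
from .trajectory_io import BeadTopology, Ensemble, RegionSet, PRIMARY_REGIONS

__all__ = [
    "RegionKinetics",
    "SynthSpec",
    "GroundTruth",
    "build_toy_structure",
    "generate_reference",
    "generate_ensemble",
    "default_kinetics",
    "paper_preset",
    "toy_preset",
]

#: bead names of every protein residue in the toy structure
_RESIDUE_BEADS = ("BB", "SC1", "SC2")


@dataclass(frozen=True)
class RegionKinetics:
    """Biexponential relaxation parameters of one region's mean displacement.

    delta : displacement amplitude (Angstrom); tau1/tau2 in microseconds;
    c1 + c2 = 1 so that tau_eff = c1*tau1 + c2*tau2.
    """

    delta: float
    c1: float = 1.0
    c2: float = 0.0
    tau1: float = 1.0
    tau2: float = 1.0

    def __post_init__(self):
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise SpecValidationError("time constants must be positive")
        if self.c1 < 0 or self.c2 < 0 or abs(self.c1 + self.c2 - 1.0) > 1e-9:
            raise SpecValidationError("weights must be non-negative with c1 + c2 = 1")
        if self.delta < 0:
            raise SpecValidationError("delta must be non-negative")

    @property
    def tau_eff(self) -> float:
        return self.c1 * self.tau1 + self.c2 * self.tau2

    def relaxation(self, t: np.ndarray) -> np.ndarray:
        """Fractional approach to the shifted equilibrium at times t."""
        return 1.0 - self.c1 * np.exp(-t / self.tau1) - self.c2 * np.exp(-t / self.tau2)


def default_kinetics() -> dict[str, RegionKinetics]:
    """Default per-region kinetics of the photoactivation preset.

    Effective time constants follow the characteristic hierarchy of the
    activation response: a ~3 microsecond global relaxation, a fast connecting
    loop, an intermediate C-terminal tail (4.7) and EEE motif (5.7), a slow
    phosphate-binding loop (9.0), and a nearly rigid reference helix.
    Amplitudes (Angstrom) order the regions by their divergence from the dark
    state: EEE and CL largest, CT and REF smallest.
    """
    return {
        "background": RegionKinetics(3.36, 0.7, 0.3, 1.5, 6.5),        # tau_eff 3.0
        "PBL":        RegionKinetics(2.50, 0.4, 0.6, 7.0, 31 / 3),     # tau_eff 9.0
        "CT":         RegionKinetics(2.00, 0.3, 0.7, 1.5, 4.25 / 0.7),  # tau_eff 4.7
        "EEE":        RegionKinetics(4.50, 0.5, 0.5, 2.4, 9.0),        # tau_eff 5.7
        "CL":         RegionKinetics(4.00, 0.8, 0.2, 1.0, 5.0),        # tau_eff 1.8
        "OPP":        RegionKinetics(3.80, 0.8, 0.2, 1.0, 5.0),        # tau_eff 1.8
        "REF":        RegionKinetics(1.20, 0.4, 0.6, 2.0, 11 / 3),     # rigid helix
        "R20_33":     RegionKinetics(3.50, 0.5, 0.5, 1.8, 4.2),        # tau_eff 3.0
        "R110_125":   RegionKinetics(3.50, 0.5, 0.5, 1.8, 4.2),
        "tetrad":     RegionKinetics(2.50, 0.5, 0.5, 1.8, 4.2),
    }


@dataclass
class SynthSpec:
    """Full specification of a synthetic ensemble.

    Defaults reproduce the study conditions of the photoactivation analysis:
    20 replicas of 20 microseconds sampled every 0.02 microseconds, region
    registry proportional to the canonical 497-residue protein, fast thermal
    jitter sigma = 0.1 A about the conformational mean path (tau_ou = 0.05 us),
    and a tryptophan-swap waiting time of 7.5 us.  Background displacement
    amplitude is calibrated so the whole-backbone RMSD plateaus at 3.35 A.
    """

    n_replicas: int = 20
    n_frames: int = 1001
    dt: float = 0.02
    n_residues: int = 100
    regions: RegionSet | None = None
    kinetics: dict[str, RegionKinetics] = field(default_factory=default_kinetics)
    sigma: float = 0.1
    tau_ou: float = 0.05
    tau_flip: float = 7.5              # math.inf disables flips
    flip_pair: tuple[str, str] = ("Trp_C", "Trp_D")
    forced_flip_count: int | None = None
    coupling_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"trp_ct": ("tetrad", "CT"), "eee_pbl": ("EEE", "PBL")})
    coupling_cv: float = 0.3

    def __post_init__(self):
        if self.regions is None:
            self.regions = RegionSet.rescaled(self.n_residues)
        self.validate()

    def validate(self) -> None:
        if self.n_replicas < 1 or self.n_frames < 1:
            raise SpecValidationError("n_replicas and n_frames must be >= 1")
        if self.dt <= 0 or self.tau_ou <= 0 or self.tau_flip <= 0:
            raise SpecValidationError("dt, tau_ou and tau_flip must be positive")
        if self.sigma < 0:
            raise SpecValidationError("sigma must be non-negative")
        if "background" not in self.kinetics:
            raise SpecValidationError("kinetics must include a 'background' entry")
        known = set(self.regions.ranges) | set(self.regions.residue_sets) | {"background"}
        unknown = set(self.kinetics) - known
        if unknown:
            raise SpecValidationError(f"kinetics for unknown regions: {sorted(unknown)}")
        tetrad = self.regions.residue_sets.get("tetrad", {})
        for label in self.flip_pair:
            if label not in tetrad:
                raise SpecValidationError(f"flip pair member {label!r} not in tetrad")
        if self.forced_flip_count is not None and not (
                0 <= self.forced_flip_count <= self.n_replicas):
            raise SpecValidationError("forced_flip_count outside [0, n_replicas]")
        for name, members in self.coupling_groups.items():
            for m in members:
                if m not in known:
                    raise SpecValidationError(f"coupling group {name!r} names unknown region {m!r}")
        if self.coupling_cv < 0:
            raise SpecValidationError("coupling_cv must be non-negative")

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def kinetics_key(self, residue: int) -> str:
        """Kinetics entry governing a residue: tetrad first, then primary regions."""
        tetrad = self.regions.residue_sets.get("tetrad", {})
        if "tetrad" in self.kinetics and residue in tetrad.values():
            return "tetrad"
        for name in PRIMARY_REGIONS:
            if name in self.kinetics:
                lo, hi = self.regions.ranges[name]
                if lo <= residue <= hi:
                    return name
        return "background"

    def true_tau_eff(self) -> dict[str, float]:
        return {name: k.tau_eff for name, k in self.kinetics.items()}


@dataclass(frozen=True)
class GroundTruth:
    """Generation-time bookkeeping for parameter-recovery tests."""

    tau_eff: dict[str, float]             # per kinetics entry
    flip_times: tuple[float | None, ...]  # first frame time with swapped order
    flip_waiting_times: tuple[float | None, ...]  # raw exponential draws < duration
    seed: int

    @property
    def n_flipped(self) -> int:
        return sum(t is not None for t in self.flip_times)


# ---------------------------------------------------------------------------
# toy structure
# ---------------------------------------------------------------------------

def build_toy_structure(
    n_residues: int,
    regions: RegionSet | None = None,
) -> tuple[BeadTopology, np.ndarray]:
    """Deterministic toy protein: helical backbone, side chains, flavin site.

    Each residue carries BB/SC1/SC2 beads on a coarse helix (radius 8 A, rise
    1.5 A per residue); the flavin cofactor FLA1-FLA5 sits on the helix axis at
    mid-height.  The four tetrad tryptophans are repositioned radially around
    the flavin so that residue centroids sit at 6.5/9.5/12.5/15.5 A and SC2
    beads at 5.5/8.5/11.5/14.5 A from the FLA2 bead, fixing the canonical
    distance order Trp_A < Trp_B < Trp_C < Trp_D before any flip.
    """
    regions = regions or RegionSet.rescaled(n_residues)
    tetrad = regions.residue_sets.get("tetrad", {})

    n_prot_beads = n_residues * len(_RESIDUE_BEADS)
    coords = np.zeros((n_prot_beads + 5, 3))
    names, resids, resnames = [], [], []

    turn = math.radians(100.0)
    for i in range(n_residues):
        res = i + 1
        theta = i * turn
        bb = np.array([8.0 * math.cos(theta), 8.0 * math.sin(theta), 1.5 * i])
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        offsets = {"BB": bb, "SC1": bb + 2.0 * radial, "SC2": bb + 3.5 * radial}
        for j, bead in enumerate(_RESIDUE_BEADS):
            coords[i * 3 + j] = offsets[bead]
            names.append(bead)
            resids.append(res)
            resnames.append("TRP" if res in tetrad.values() else "ALA")

    # flavin site on the helix axis at mid-height
    fla_center = np.array([0.0, 0.0, 1.5 * (n_residues - 1) / 2.0])
    ring = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.31, 0.95, 0.0],
        [-0.81, 0.59, 0.0],
        [-0.81, -0.59, 0.0],
    ])
    fla_coords = fla_center + ring
    fla2 = fla_coords[1]

    # reposition tetrad residues radially from FLA2, SC2 innermost
    directions = np.array([
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, -1.0, 0.0],
    ])
    order = ("Trp_A", "Trp_B", "Trp_C", "Trp_D")
    for k, label in enumerate(order):
        res = tetrad[label]
        e = directions[k]
        base_dist = 5.5 + 3.0 * k
        i0 = (res - 1) * 3
        coords[i0 + 0] = fla2 + (base_dist + 2.0) * e   # BB
        coords[i0 + 1] = fla2 + (base_dist + 1.0) * e   # SC1
        coords[i0 + 2] = fla2 + base_dist * e           # SC2

    coords[n_prot_beads:] = fla_coords
    names += list(("FLA1", "FLA2", "FLA3", "FLA4", "FLA5"))
    resids += [n_residues + 1] * 5
    resnames += ["FAD"] * 5

    topo = BeadTopology(
        bead_id=np.arange(len(names)),
        residue_index=np.array(resids),
        residue_name=np.array(resnames),
        bead_name=np.array(names),
        chain_id=np.full(len(names), "A"),
    )
    return topo, coords


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    dirs, flips, coupling, noise = ss.spawn(4)
    return {
        "directions": np.random.default_rng(dirs),
        "flips": np.random.default_rng(flips),
        "coupling": np.random.default_rng(coupling),
        "noise": np.random.default_rng(noise),
    }


def _unit_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ou_noise(rng: np.random.Generator, n_frames: int, n_coords: int,
              sigma: float, rho: float) -> np.ndarray:
    """Stationary OU path per coordinate, exact discretization."""
    out = np.empty((n_frames, n_coords))
    if sigma == 0.0:
        out.fill(0.0)
        return out
    out[0] = sigma * rng.standard_normal(n_coords)
    innov = sigma * math.sqrt(1.0 - rho * rho)
    for k in range(1, n_frames):
        out[k] = rho * out[k - 1] + innov * rng.standard_normal(n_coords)
    return out


def _bead_fields(spec: SynthSpec, topo: BeadTopology):
    """Per-bead amplitude, kinetics-key index and relaxation table."""
    keys = sorted(spec.kinetics)
    key_index = {k: i for i, k in enumerate(keys)}
    f_table = np.stack([spec.kinetics[k].relaxation(spec.frame_times) for k in keys])

    n_beads = topo.n_beads
    delta = np.zeros(n_beads)
    key_of_bead = np.zeros(n_beads, dtype=int)
    tetrad = spec.regions.residue_sets.get("tetrad", {})
    flip_res = {tetrad[label] for label in spec.flip_pair}
    for b in range(n_beads):
        if not topo.protein_mask[b]:
            continue                                   # cofactor static
        res = int(topo.residue_index[b])
        key = spec.kinetics_key(res)
        key_of_bead[b] = key_index[key]
        if res in flip_res and topo.bead_name[b] == "SC2":
            continue                                   # flip geometry kept clean
        delta[b] = spec.kinetics[key].delta
    return keys, key_of_bead, delta, f_table


def _coupling_scales(spec: SynthSpec, rng: np.random.Generator,
                     keys: list[str]) -> np.ndarray:
    """(n_replicas, n_keys) mean-one log-normal amplitude factors."""
    scales = np.ones((spec.n_replicas, len(keys)))
    if spec.coupling_cv == 0 or not spec.coupling_groups:
        return scales
    s_ln = math.sqrt(math.log(1.0 + spec.coupling_cv ** 2))
    for members in spec.coupling_groups.values():
        z = rng.standard_normal(spec.n_replicas)
        factor = np.exp(s_ln * z - 0.5 * s_ln * s_ln)
        for m in members:
            if m in keys:
                scales[:, keys.index(m)] *= factor
    return scales


def generate_reference(
    spec: SynthSpec,
    seed: int,
    n_replicas: int = 1,
    n_frames: int | None = None,
) -> Ensemble:
    """Stationary dark-state ensemble: base structure plus OU fluctuation only."""
    topo, base = build_toy_structure(spec.n_residues, spec.regions)
    n_frames = n_frames or spec.n_frames
    rngs = _child_rngs(seed)
    rho = math.exp(-spec.dt / spec.tau_ou)
    coords = np.empty((n_replicas, n_frames, topo.n_beads, 3))
    flat_base = base.reshape(-1)
    for r in range(n_replicas):
        noise = _ou_noise(rngs["noise"], n_frames, flat_base.size, spec.sigma, rho)
        coords[r] = (flat_base + noise).reshape(n_frames, topo.n_beads, 3)
    return Ensemble(topology=topo, coordinates=coords,
                    frame_times=np.arange(n_frames) * spec.dt, label="DS")


def _draw_flip_times(spec: SynthSpec, rng: np.random.Generator) -> list[float | None]:
    """Per-replica waiting time of the irreversible swap, None when censored."""
    n, tmax = spec.n_replicas, spec.duration
    if math.isinf(spec.tau_flip):
        return [None] * n
    if spec.forced_flip_count is None:
        draws = rng.exponential(spec.tau_flip, size=n)
        return [float(t) if t <= tmax else None for t in draws]
    # conditional sampler: exactly k replicas flip, waiting times follow the
    # exponential law truncated to the observation window
    k = spec.forced_flip_count
    which = rng.permutation(n)[:k]
    out: list[float | None] = [None] * n
    p_obs = 1.0 - math.exp(-tmax / spec.tau_flip)
    for i in which:
        u = rng.uniform()
        out[i] = float(-spec.tau_flip * math.log(1.0 - u * p_obs))
    return out


def generate_ensemble(spec: SynthSpec, seed: int) -> tuple[Ensemble, GroundTruth]:
    """Photoactivated ensemble with biexponential relaxation and the Trp swap."""
    topo, base = build_toy_structure(spec.n_residues, spec.regions)
    rngs = _child_rngs(seed)

    dirs_res = _unit_directions(rngs["directions"], spec.n_residues)
    dirs_bead = np.zeros((topo.n_beads, 3))
    prot = topo.protein_mask
    dirs_bead[prot] = dirs_res[topo.residue_index[prot] - 1]

    keys, key_of_bead, delta, f_table = _bead_fields(spec, topo)
    scales = _coupling_scales(spec, rngs["coupling"], keys)
    waiting = _draw_flip_times(spec, rngs["flips"])

    tetrad = spec.regions.residue_sets["tetrad"]
    sc2_c = topo.bead_index(tetrad[spec.flip_pair[0]], "SC2")
    sc2_d = topo.bead_index(tetrad[spec.flip_pair[1]], "SC2")

    times = spec.frame_times
    rho = math.exp(-spec.dt / spec.tau_ou)
    coords = np.empty((spec.n_replicas, spec.n_frames, topo.n_beads, 3))
    flip_times: list[float | None] = []

    F = f_table[key_of_bead].T                     # (n_frames, n_beads)
    for r in range(spec.n_replicas):
        amp = delta * scales[r, key_of_bead]       # (n_beads,)
        mean = base[None] + (F * amp)[:, :, None] * dirs_bead[None]
        T = waiting[r]
        if T is None:
            flip_times.append(None)
        else:
            k0 = int(np.searchsorted(times, T, side="left"))
            mean[k0:, [sc2_c, sc2_d]] = mean[k0:, [sc2_d, sc2_c]]
            flip_times.append(float(times[k0]))
        noise = _ou_noise(rngs["noise"], spec.n_frames, topo.n_beads * 3,
                          spec.sigma, rho)
        coords[r] = mean + noise.reshape(spec.n_frames, topo.n_beads, 3)

    ens = Ensemble(topology=topo, coordinates=coords, frame_times=times, label="RP")
    truth = GroundTruth(
        tau_eff=spec.true_tau_eff(),
        flip_times=tuple(flip_times),
        flip_waiting_times=tuple(waiting),
        seed=seed,
    )
    return ens, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def paper_preset(**overrides) -> SynthSpec:
    """Full-scale study conditions: 497 residues, 20 replicas x 20 us at 0.02 us."""
    kw = dict(n_replicas=20, n_frames=1001, dt=0.02, n_residues=497)
    kw.update(overrides)
    return SynthSpec(**kw)


def toy_preset(**overrides) -> SynthSpec:
    """Fast test conditions: 100-residue toy protein, same kinetics registry."""
    kw = dict(n_replicas=20, n_frames=1001, dt=0.02, n_residues=100)
    kw.update(overrides)
    return SynthSpec(**kw)
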