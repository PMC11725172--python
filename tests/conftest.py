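import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cryact.trajectory_io import BeadTopology, Ensemble

settings.register_profile(
    "cryact",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cryact")


def gro_text(records: list[tuple[int, str, str, float, float, float]]) -> str:
    """Minimal GRO file from (resid, resname, beadname, x, y, z[nm]) records."""
    lines = ["toy bead structure", f"{len(records)}"]
    for i, (resid, resname, bead, x, y, z) in enumerate(records, start=1):
        lines.append(f"{resid:5d}{resname:<5s}{bead:>5s}{i:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append("  10.00000  10.00000  10.00000")
    return "\n".join(lines) + "\n"


def three_residue_records(with_fad: bool = False, skip_bb_residue: int | None = None,
                          duplicate_fla: bool = False):
    records = []
    for res in (1, 2, 3):
        for j, bead in enumerate(("BB", "SC1", "SC2")):
            if bead == "BB" and res == skip_bb_residue:
                bead = "SC3"
            records.append((res, "ALA", bead, 0.1 * res, 0.05 * j, 0.0))
    if with_fad:
        for k in range(1, 6):
            name = "FLA2" if (duplicate_fla and k == 3) else f"FLA{k}"
            records.append((4, "FAD", name, 0.5, 0.1 * k, 0.2))
    return records


@pytest.fixture
def toy_gro(tmp_path):
    path = tmp_path / "toy.gro"
    path.write_text(gro_text(three_residue_records()))
    return path


@pytest.fixture
def toy_gro_fad(tmp_path):
    path = tmp_path / "toy_fad.gro"
    path.write_text(gro_text(three_residue_records(with_fad=True)))
    return path


def bb_only_topology(n_residues: int) -> BeadTopology:
    """One BB bead per residue; the smallest valid protein topology."""
    return BeadTopology(
        bead_id=np.arange(n_residues),
        residue_index=np.arange(1, n_residues + 1),
        residue_name=np.array(["ALA"] * n_residues),
        bead_name=np.array(["BB"] * n_residues),
        chain_id=np.array(["A"] * n_residues),
    )


def make_ensemble(coords: np.ndarray, dt: float = 1.0, label: str = "") -> Ensemble:
    """Ensemble around raw (n_replicas, n_frames, n_beads, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    topo = bb_only_topology(coords.shape[2])
    times = np.arange(coords.shape[1]) * dt
    return Ensemble(topology=topo, coordinates=coords, frame_times=times, label=label)
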