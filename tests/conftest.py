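import numpy as np
import pytest

from e2screen.peaks import Spectrum


def brute_force_apexes(y: np.ndarray, noise_sd: float, snr_threshold: float):
    """Independent oracle: every strict local maximum above the S/N gate."""
    idx = []
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] > 0:
            if noise_sd == 0 or y[i] / noise_sd >= snr_threshold:
                idx.append(i)
    return idx


def gaussian_spectrum(centers, amplitudes, sigma=4.0, grid=(8000.0, 9200.0, 0.5),
                      baseline=None, noise_sd=0.0, seed=0):
    """Hand-built spectrum (independent of the simulator) for peak tests."""
    start, stop, step = grid
    mz = np.arange(start, stop + step / 2, step)
    y = np.zeros_like(mz)
    for mu, amp in zip(centers, amplitudes):
        y += amp * np.exp(-0.5 * ((mz - mu) / sigma) ** 2)
    if baseline is not None:
        y += baseline(mz)
    if noise_sd:
        y += np.random.default_rng(seed).normal(0, noise_sd, mz.size)
    return Spectrum(mz=mz, intensity=y)


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  occ=1.0, altloc=" ", element=None):
    element = element or name[0]
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm}{altloc}{resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def hexagon(center, radius=1.39, axis="z"):
    """Regular hexagon of six points around ``center``, in the plane
    perpendicular to ``axis`` (bond length ~ benzene C-C)."""
    cx, cy, cz = center
    pts = []
    for k in range(6):
        a = np.pi / 3 * k
        if axis == "z":
            pts.append((cx + radius * np.cos(a), cy + radius * np.sin(a), cz))
        else:
            pts.append((cx, cy + radius * np.cos(a), cz + radius * np.sin(a)))
    return pts


def trp_sixring_pdb(tmp_path, centroid, cz=(0.0, 0.0, 0.0)):
    """Arg CZ on chain A facing a Trp six-membered ring on chain B whose
    centroid sits at ``centroid``."""
    names = ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")
    lines = [pdb_atom_line(1, "CZ", "ARG", "A", 74, *cz)]
    for i, (name, pt) in enumerate(zip(names, hexagon(centroid)), start=2):
        lines.append(pdb_atom_line(i, name, "TRP", "B", 414, *pt))
    return write_pdb(tmp_path / "cation_pi.pdb", lines)


@pytest.fixture
def toy_pdb(tmp_path):
    """Two-atom structure with exactly known coordinates."""
    lines = [
        pdb_atom_line(1, "CA", "GLY", "A", 1, 1.0, 2.0, 3.0),
        pdb_atom_line(2, "CA", "ALA", "B", 1, 4.0, 5.0, 6.0),
    ]
    return write_pdb(tmp_path / "toy.pdb", lines)
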