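"""Voxel-grid encoding of receptor / trimmed-ligand complexes.

A complex is rendered as a 9-channel 24x24x24 grid of atomic densities with
0.75 Angstrom spacing, centered on the trimmed-ligand branching atom.
Channels 0-4 hold receptor C, O, N, S and other heavy atoms; channels 5-8
hold trimmed-ligand C, O, N and other heavy atoms. Each atom contributes

    d(x) = exp(-(|x - atom| / r)^2)   for |x - atom| <= 1.75 r

to the grid points of its channel, where r is the element's van der Waals
radius; contributions are additive across atoms. The decay function is
pluggable (``density_fn``) so alternative smoothing kernels can be swapped in.

With 24 points per axis there is no single central grid point; grid
coordinates are center + (i - 11.5) * 0.75 for i in 0..23, placing the
branching atom midway between the two central planes.

Rotation augmentation applies a uniform random rotation to the centered
coordinates before gridding (never to the discretized grid), avoiding
resampling artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .elements import vdw_radius
from .mol import InputError, Molecule

GRID_POINTS = 24
GRID_SPACING = 0.75
N_CHANNELS = 9
DENSITY_CUTOFF_FACTOR = 1.75

#: channel layout: receptor [C,O,N,S,other] then ligand [C,O,N,other]
RECEPTOR_CHANNELS: dict[str, int] = {"C": 0, "O": 1, "N": 2, "S": 3}
RECEPTOR_OTHER = 4
LIGAND_CHANNELS: dict[str, int] = {"C": 5, "O": 6, "N": 7}
LIGAND_OTHER = 8

#: grid axis coordinates relative to the branching atom, Angstrom
GRID_AXIS = (np.arange(GRID_POINTS) - (GRID_POINTS - 1) / 2.0) * GRID_SPACING


def smooth_density(distance: np.ndarray, radius: float) -> np.ndarray:
    """Exponential-decay atomic density exp(-(d/r)^2), truncated at 1.75 r."""
    d = np.asarray(distance)
    out = np.exp(-((d / radius) ** 2))
    out[d > DENSITY_CUTOFF_FACTOR * radius] = 0.0
    return out


DensityFn = Callable[[np.ndarray, float], np.ndarray]


@dataclass
class VoxelGrid:
    values: np.ndarray  # (9, 24, 24, 24) float32, non-negative
    center: np.ndarray  # (3,) Angstrom, position of the branching atom
    rotation: np.ndarray  # unit quaternion (x, y, z, w)

    def __post_init__(self) -> None:
        if self.values.shape != (N_CHANNELS, GRID_POINTS, GRID_POINTS, GRID_POINTS):
            raise InputError(f"voxel grid has shape {self.values.shape}")


def random_rotation(seed: int) -> np.ndarray:
    """Unit quaternion (x, y, z, w) drawn uniformly from the rotation group."""
    rng = np.random.default_rng(seed)
    return Rotation.random(random_state=rng).as_quat()


IDENTITY_ROTATION = np.array([0.0, 0.0, 0.0, 1.0])


def _channel_of(element: str, *, ligand: bool) -> int:
    if ligand:
        return LIGAND_CHANNELS.get(element, LIGAND_OTHER)
    return RECEPTOR_CHANNELS.get(element, RECEPTOR_OTHER)


@dataclass
class VoxelReadyExample:
    """Pre-extracted arrays for fast repeated voxelization under rotations."""

    coords: np.ndarray  # (n_atoms, 3) centered on the branching atom
    channels: np.ndarray  # (n_atoms,) int
    radii: np.ndarray  # (n_atoms,) vdW radii
    center: np.ndarray  # (3,) original branching-atom position
    target: np.ndarray | None = None  # optional fingerprint target


def prepare_example(
    receptor: Molecule,
    trimmed: Molecule,
    branch_atom: int,
    target: np.ndarray | None = None,
) -> VoxelReadyExample:
    """Center receptor + trimmed-ligand heavy atoms on the branching atom."""
    if not (0 <= branch_atom < trimmed.n_heavy):
        raise InputError(f"branch atom {branch_atom} out of range for {trimmed.n_heavy} atoms")
    center = trimmed.atoms[branch_atom].coords
    coords, channels, radii = [], [], []
    for mol, is_ligand in ((receptor, False), (trimmed, True)):
        for atom in mol.atoms:
            if atom.element in ("H", "*"):
                continue
            coords.append(atom.coords - center)
            channels.append(_channel_of(atom.element, ligand=is_ligand))
            radii.append(vdw_radius(atom.element))
    return VoxelReadyExample(
        coords=np.asarray(coords, dtype=np.float64),
        channels=np.asarray(channels, dtype=np.int64),
        radii=np.asarray(radii, dtype=np.float64),
        center=np.asarray(center, dtype=np.float64),
        target=target,
    )


def voxelize_prepared(
    prepared: VoxelReadyExample,
    rotation: np.ndarray | None = None,
    density_fn: DensityFn = smooth_density,
) -> VoxelGrid:
    """Render a prepared example into the 9-channel grid.

    Each atom only touches the sub-box of grid points within its density
    cutoff, so cost is linear in atom count.
    """
    quat = IDENTITY_ROTATION if rotation is None else np.asarray(rotation, dtype=np.float64)
    coords = prepared.coords
    if not np.allclose(quat, IDENTITY_ROTATION):
        coords = coords @ Rotation.from_quat(quat).as_matrix().T

    grid = np.zeros((N_CHANNELS, GRID_POINTS, GRID_POINTS, GRID_POINTS), dtype=np.float64)
    half = (GRID_POINTS - 1) / 2.0
    for pos, channel, radius in zip(coords, prepared.channels, prepared.radii):
        cutoff = DENSITY_CUTOFF_FACTOR * radius
        lo = np.ceil((pos - cutoff) / GRID_SPACING + half).astype(int)
        hi = np.floor((pos + cutoff) / GRID_SPACING + half).astype(int)
        lo = np.clip(lo, 0, GRID_POINTS - 1)
        hi = np.clip(hi, 0, GRID_POINTS - 1)
        if np.any(lo > hi):
            continue
        ax = [GRID_AXIS[lo[k] : hi[k] + 1] - pos[k] for k in range(3)]
        d = np.sqrt(
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        grid[channel, lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += density_fn(
            d, radius
        )
    return VoxelGrid(values=grid.astype(np.float32), center=prepared.center, rotation=quat)


def voxelize(
    receptor: Molecule,
    trimmed: Molecule,
    branch_atom: int,
    rotation: np.ndarray | None = None,
    density_fn: DensityFn = smooth_density,
) -> VoxelGrid:
    """Voxelize a receptor / trimmed-ligand pair about its branching atom."""
    return voxelize_prepared(prepare_example(receptor, trimmed, branch_atom), rotation, density_fn)


def voxelize_batch(
    prepared: Sequence[VoxelReadyExample],
    rotations: Sequence[np.ndarray | None],
    density_fn: DensityFn = smooth_density,
) -> np.ndarray:
    """Stack grids for a batch of prepared examples; (B, 9, 24, 24, 24) float32."""
    return np.stack(
        [voxelize_prepared(p, r, density_fn).values for p, r in zip(prepared, rotations, strict=True)]
    )
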