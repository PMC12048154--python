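"""Ground-truth sample geometry: spherical neurons with dark nuclei.

Neurons are modelled as spheres whose radius is drawn from N(10, 3) µm and
whose central, non-fluorescent nuclear region has half-width drawn from
N(5, 1) µm. Only the spherical shell between nucleus and soma boundary
expresses the indicator. Somata are placed by random sequential addition
with a hard non-overlap constraint until a target density is reached or the
volume jams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NeuronGeom",
    "TissueVolume",
    "sample_neuron_geometry",
    "place_neurons",
    "rasterize",
    "shell_voxel_indices",
    "save_ground_truth",
    "load_ground_truth",
]

# anatomical defaults (µm)
SOMA_RADIUS_MEAN = 10.0
SOMA_RADIUS_SD = 3.0
NUCLEUS_MEAN = 5.0
NUCLEUS_SD = 1.0
#: printed target density, cells per mm^3
DENSITY_TARGET = 26.8e4


@dataclass(frozen=True)
class NeuronGeom:
    """One spherical neuron: centre (µm), soma radius, nucleus half-width."""

    id: int
    center: np.ndarray  # (3,) µm, order (x, y, z)
    soma_radius: float
    nucleus_halfwidth: float

    def __post_init__(self):
        if not (self.soma_radius > 0):
            raise ValueError("soma_radius must be positive")
        if not (0.0 <= self.nucleus_halfwidth < self.soma_radius):
            raise ValueError("nucleus must lie strictly inside the soma")


@dataclass
class TissueVolume:
    """A realised 3D sample: placed neurons plus grid metadata."""

    dims: np.ndarray  # (3,) µm
    voxel_size: np.ndarray  # (3,) µm
    neurons: list[NeuronGeom]
    density_target: float  # per mm^3
    realized_density: float  # per mm^3
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def centers(self) -> np.ndarray:
        if not self.neurons:
            return np.zeros((0, 3))
        return np.stack([n.center for n in self.neurons])

    def radii(self) -> np.ndarray:
        return np.array([n.soma_radius for n in self.neurons])

    def nucleus_halfwidths(self) -> np.ndarray:
        return np.array([n.nucleus_halfwidth for n in self.neurons])

    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(np.ceil(d / v)) for d, v in zip(self.dims, self.voxel_size))


def sample_neuron_geometry(
    rng: np.random.Generator,
    radius_mean: float = SOMA_RADIUS_MEAN,
    radius_sd: float = SOMA_RADIUS_SD,
    nucleus_mean: float = NUCLEUS_MEAN,
    nucleus_sd: float = NUCLEUS_SD,
    neuron_id: int = 0,
    center: np.ndarray | None = None,
    max_tries: int = 1000,
) -> NeuronGeom:
    """Draw a soma radius and nucleus half-width, resampling invalid draws.

    The radius is redrawn while non-positive; the nucleus half-width is then
    redrawn (given the radius) while it does not fit strictly inside the
    soma. Resampling the nucleus conditionally keeps the soma-radius
    distribution unbiased.
    """
    if radius_mean <= 0:
        raise ValueError("radius_mean must be positive")
    if center is None:
        center = np.zeros(3)
    r = h = None
    for _ in range(max_tries):
        r = rng.normal(radius_mean, radius_sd)
        if r > 0:
            break
    else:
        raise RuntimeError("could not draw a positive soma radius")
    for _ in range(max_tries):
        h = rng.normal(nucleus_mean, nucleus_sd)
        if 0.0 <= h < r:
            break
    else:
        # a soma too small for any plausible nucleus: clip into range
        h = float(np.clip(h, 0.0, 0.95 * r))
    return NeuronGeom(neuron_id, np.asarray(center, float), float(r), float(h))


def place_neurons(
    dims,
    voxel_size=(0.8, 0.8, 1.0),
    density_target: float = DENSITY_TARGET,
    geometry_params: dict | None = None,
    seed: int | np.random.Generator = 0,
    max_consecutive_rejections: int = 10_000,
    preplaced: list[NeuronGeom] | None = None,
) -> TissueVolume:
    """Random sequential addition of non-overlapping spheres.

    Insertion stops when the realised density reaches ``density_target``
    (cells per mm^3) or after ``max_consecutive_rejections`` failed draws in
    a row, whichever comes first; the printed density target exceeds the
    jamming density of spheres of this size, so the rejection cutoff is what
    normally terminates placement. Centres are uniform inside ``dims``;
    somata may protrude beyond the faces.
    """
    dims = np.asarray(dims, float)
    voxel_size = np.asarray(voxel_size, float)
    if np.any(dims <= 0):
        raise ValueError("dims must be positive")
    if density_target < 0:
        raise ValueError("density_target must be >= 0")
    gp = dict(
        radius_mean=SOMA_RADIUS_MEAN,
        radius_sd=SOMA_RADIUS_SD,
        nucleus_mean=NUCLEUS_MEAN,
        nucleus_sd=NUCLEUS_SD,
    )
    if geometry_params:
        gp.update(geometry_params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    volume_mm3 = float(np.prod(dims)) * 1e-9  # µm^3 -> mm^3
    n_target = int(np.floor(density_target * volume_mm3))

    neurons: list[NeuronGeom] = list(preplaced or [])
    # cell list for neighbour queries; cell edge >= max plausible diameter
    cell = max(2.0 * (gp["radius_mean"] + 4.0 * abs(gp["radius_sd"])), 1.0)
    nx, ny, nz = (max(1, int(np.ceil(d / cell))) for d in dims)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    cap = max(n_target, len(neurons), 64)
    centers_arr = np.empty((cap, 3))
    radii_arr = np.empty(cap)

    def bucket_of(p):
        return (
            min(int(p[0] / cell), nx - 1),
            min(int(p[1] / cell), ny - 1),
            min(int(p[2] / cell), nz - 1),
        )

    def overlaps(p, r) -> bool:
        bx, by, bz = bucket_of(p)
        cand: list[int] = []
        for ix in range(max(0, bx - 1), min(nx, bx + 2)):
            for iy in range(max(0, by - 1), min(ny, by + 2)):
                for iz in range(max(0, bz - 1), min(nz, bz + 2)):
                    lst = buckets.get((ix, iy, iz))
                    if lst:
                        cand.extend(lst)
        if not cand:
            return False
        idx = np.asarray(cand)
        d2 = ((centers_arr[idx] - p) ** 2).sum(axis=1)
        return bool(np.any(d2 < (radii_arr[idx] + r) ** 2))

    for i, n in enumerate(neurons):
        buckets.setdefault(bucket_of(n.center), []).append(i)
        centers_arr[i] = n.center
        radii_arr[i] = n.soma_radius

    rejections = 0
    batch = 256
    done = False
    while not done and len(neurons) < n_target and rejections < max_consecutive_rejections:
        ps = rng.uniform(0.0, 1.0, size=(batch, 3)) * dims
        rs = rng.normal(gp["radius_mean"], gp["radius_sd"], size=batch)
        hs = rng.normal(gp["nucleus_mean"], gp["nucleus_sd"], size=batch)
        for b in np.flatnonzero(rs <= 0):
            while rs[b] <= 0:
                rs[b] = rng.normal(gp["radius_mean"], gp["radius_sd"])
        for b in np.flatnonzero(~((hs >= 0) & (hs < rs))):
            for _ in range(100):
                hs[b] = rng.normal(gp["nucleus_mean"], gp["nucleus_sd"])
                if 0 <= hs[b] < rs[b]:
                    break
            else:
                hs[b] = np.clip(hs[b], 0.0, 0.95 * rs[b])
        for b in range(batch):
            if overlaps(ps[b], rs[b]):
                rejections += 1
                if rejections >= max_consecutive_rejections:
                    done = True
                    break
                continue
            rejections = 0
            i = len(neurons)
            buckets.setdefault(bucket_of(ps[b]), []).append(i)
            centers_arr[i] = ps[b]
            radii_arr[i] = rs[b]
            neurons.append(
                NeuronGeom(i, ps[b].copy(), float(rs[b]), float(hs[b]))
            )
            if len(neurons) >= n_target:
                done = True
                break

    realized = len(neurons) / volume_mm3 if volume_mm3 > 0 else 0.0
    return TissueVolume(dims, voxel_size, neurons, density_target, realized, seed_val)


def rasterize(volume: TissueVolume) -> np.ndarray:
    """Rasterise neurons onto the voxel grid as a signed label field.

    Returns an int32 array of shape ``volume.grid_shape()`` (x, y, z order).
    Voxel values: ``0`` empty, ``i+1`` fluorescent shell of neuron ``i``,
    ``-(i+1)`` nuclear (dark) region of neuron ``i``. Membership is tested at
    voxel centres; non-overlap of somata guarantees single ownership.
    """
    vs = volume.voxel_size
    if np.any(vs <= 0):
        raise ValueError("voxel_size must be positive")
    shape = volume.grid_shape()
    labels = np.zeros(shape, dtype=np.int32)
    for i, n in enumerate(volume.neurons):
        _mark_neuron(labels, n, i + 1, vs)
    return labels


def _mark_neuron(labels: np.ndarray, n: NeuronGeom, label: int, vs: np.ndarray) -> None:
    shape = labels.shape
    lo = np.maximum(np.floor((n.center - n.soma_radius) / vs - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil((n.center + n.soma_radius) / vs - 0.5).astype(int) + 1, shape
    )
    if np.any(lo >= hi):
        return  # entirely outside the grid
    ax = [(np.arange(lo[d], hi[d]) + 0.5) * vs[d] - n.center[d] for d in range(3)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    inside = d2 <= n.soma_radius**2
    nucleus = d2 <= n.nucleus_halfwidth**2
    sub[inside & ~nucleus] = label
    sub[nucleus] = -label


def shell_voxel_indices(labels: np.ndarray, neuron_index: int) -> np.ndarray:
    """Indices (N, 3) of fluorescent-shell voxels of neuron ``neuron_index``."""
    return np.argwhere(labels == neuron_index + 1)


def save_ground_truth(volume: TissueVolume, path: str | Path) -> None:
    """Write the neuron table as CSV plus a JSON sidecar with grid metadata."""
    path = Path(path)
    rows = [
        dict(
            id=n.id,
            x=n.center[0],
            y=n.center[1],
            z=n.center[2],
            soma_radius=n.soma_radius,
            nucleus_halfwidth=n.nucleus_halfwidth,
        )
        for n in volume.neurons
    ]
    pd.DataFrame(rows, columns=["id", "x", "y", "z", "soma_radius", "nucleus_halfwidth"]).to_csv(
        path, index=False
    )
    meta = dict(
        dims=list(map(float, volume.dims)),
        voxel_size=list(map(float, volume.voxel_size)),
        density_target=volume.density_target,
        realized_density=volume.realized_density,
        seed=volume.seed,
    )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_ground_truth(path: str | Path) -> TissueVolume:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    neurons = [
        NeuronGeom(
            int(r.id),
            np.array([r.x, r.y, r.z]),
            float(r.soma_radius),
            float(r.nucleus_halfwidth),
        )
        for r in df.itertuples()
    ]
    return TissueVolume(
        np.array(meta["dims"]),
        np.array(meta["voxel_size"]),
        neurons,
        meta["density_target"],
        meta["realized_density"],
        meta["seed"],
    )
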