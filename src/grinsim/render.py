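"""Synthetic t-series assembly.

The imaging model scans a binary excitation ellipsoid (semi-axes = half the
lateral/axial PSF FWHM at the pixel's radial distance) along the focal
surface(s), with its axis orthogonal to the surface. Every tissue voxel
whose centre falls inside the ellipsoid contributes to the pixel: shell
voxels contribute the neuron's fluorescence, nucleus voxels contribute
zero signal, empty voxels contribute a static background level. The
per-pixel weight of a neuron is the fraction of in-ellipsoid voxels lying
in that neuron's fluorescent shell, so the whole geometry collapses to a
static pixel x neuron mixing matrix and rendering a frame is a sparse
product plus noise.

Three pixel-noise regimes (coefficients fitted to in vivo microendoscope
recordings):

* FOV edge (outside the circular FOV): temporal mean drawn from a
  two-component Gaussian mixture, SD linear in the mean (clamped at 0).
* central, no neuron in the excitation volume: mean drawn from a lognormal,
  SD linear in the square root of the mean.
* central, occupied: every in-ellipsoid voxel carries Gaussian noise with
  SD = p0 + p1*sqrt(voxel temporal mean); voxel values are averaged over
  the excitation volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import sparse

from .activity import ActivitySet
from .optics import (
    OpticsModel,
    psf_axes,
    real_distance,
    surface_depth,
    _surface_slope,
)
from .tissue import TissueVolume

__all__ = [
    "NoiseModel",
    "PixelGrid",
    "MixingMatrix",
    "SyntheticMovie",
    "make_pixel_grid",
    "build_mixing_matrix",
    "sample_static_noise_maps",
    "sample_background_field",
    "render",
    "FRAME_RATE",
]

FRAME_RATE = 30.0  # Hz


@dataclass
class NoiseModel:
    """Fitted pixel-noise coefficients (intensity units of the recordings)."""

    # (proportion, mean, SD) per mixture component, FOV-edge dark noise
    edge_gmm: tuple = ((0.35, 137.48, 48.96), (0.65, 126.83, 5.02))
    edge_sd_linear: tuple = (-175.39, 1.57)  # SD = p0 + p1 * mean, clamped >= 0
    background_lognormal: tuple = (6.54, 0.78)  # log-space parameters
    background_sd_vs_sqrtmean: tuple = (29.91, 7.75)  # SD = p0 + p1 * sqrt(mean)
    roi_sd_vs_sqrtmean: tuple = (322.18, 0.98)  # neuron-voxel SD law
    lognormal_log_space: bool = True

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) in log space for the background-mean distribution."""
        m, s = self.background_lognormal
        if self.lognormal_log_space:
            return m, s
        sigma2 = np.log(1.0 + (s / m) ** 2)
        return float(np.log(m) - sigma2 / 2.0), float(np.sqrt(sigma2))

    def edge_mixture_mean(self) -> float:
        return sum(w * m for w, m, _ in self.edge_gmm)


@dataclass
class PixelGrid:
    """Imaging pixel grid and its mapping into sample space.

    Pixel centres sit at ``(i + 0.5) * nominal pixel size`` from the FOV
    corner; nominal coordinates are relative to the FOV centre (optical
    axis). Real (sample-space) positions are obtained by inverting the
    distance-calibration quartic radially, so the grid resolution is
    non-uniform when the probe distorts the FOV.
    """

    n_px: int
    nominal_pixel_size: float  # µm / pixel
    x_nom: np.ndarray  # (n_px*n_px,) µm from axis
    y_nom: np.ndarray
    r_nom: np.ndarray
    r_real: np.ndarray
    x_sample: np.ndarray  # µm in tissue coordinates (origin = volume corner)
    y_sample: np.ndarray
    edge_mask: np.ndarray  # True outside the circular FOV
    central_idx: np.ndarray  # flat indices of central pixels


def make_pixel_grid(optics: OpticsModel, n_px: int, tissue_dims) -> PixelGrid:
    ps = optics.fov_um / n_px
    coords = (np.arange(n_px) + 0.5) * ps - optics.fov_um / 2.0
    xx, yy = np.meshgrid(coords, coords, indexing="xy")  # row = y, col = x
    x_nom = xx.ravel()
    y_nom = yy.ravel()
    r_nom = np.hypot(x_nom, y_nom)
    r_real = real_distance(r_nom, optics.magnification)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_nom > 0, r_real / r_nom, 1.0)
    dims = np.asarray(tissue_dims, float)
    x_sample = x_nom * scale + dims[0] / 2.0
    y_sample = y_nom * scale + dims[1] / 2.0
    edge_mask = r_nom > optics.edge_radius_um
    central_idx = np.flatnonzero(~edge_mask)
    return PixelGrid(
        n_px, ps, x_nom, y_nom, r_nom, r_real, x_sample, y_sample, edge_mask, central_idx
    )


@dataclass
class ShellSampling:
    """Per-shell voxel-sampling summary over central pixels."""

    counts: sparse.csr_matrix  # (n_central, n_neurons) shell-voxel counts
    n_in: np.ndarray  # in-ellipsoid voxel count per central pixel
    n_nucleus: np.ndarray  # nucleus-voxel count per central pixel
    bg_mean_sum: np.ndarray  # sum of static background means over empty voxels
    bg_sd2_sum: np.ndarray  # sum of squared background SDs over empty voxels


@dataclass
class MixingMatrix:
    """Static pixel x neuron mixing weights plus per-pixel noise aggregates."""

    grid: PixelGrid
    shells: list[ShellSampling]
    shell_weights: tuple[float, ...]
    n_neurons: int

    @property
    def weights(self) -> sparse.csr_matrix:
        """Combined (n_central, n_neurons) fractional weights."""
        w = None
        for sw, sh in zip(self.shell_weights, self.shells):
            denom = np.maximum(sh.n_in, 1)
            part = sparse.diags(sw / denom) @ sh.counts
            w = part if w is None else w + part
        return sparse.csr_matrix(w)

    @property
    def occupancy(self) -> np.ndarray:
        """Shell-weighted fraction of in-ellipsoid voxels containing a neuron."""
        occ = np.zeros(len(self.grid.central_idx))
        for sw, sh in zip(self.shell_weights, self.shells):
            denom = np.maximum(sh.n_in, 1)
            neuron_vox = np.asarray(sh.counts.sum(axis=1)).ravel() + sh.n_nucleus
            occ += sw * neuron_vox / denom
        return occ

    def footprint_pixels(self, neuron: int) -> np.ndarray:
        """Flat pixel indices (full grid) with nonzero weight for ``neuron``."""
        w = self.weights[:, neuron]
        rows = w.tocoo().row
        return self.grid.central_idx[rows]


@njit(cache=True)
def _sample_pixels(
    px_x, px_y, ux, uy, surf_z, slope, a_lat, a_ax,
    labels, bg_mean_field, vx, vy, vz, q0, q1,
    n_in, n_nuc, bg_sum, bg_sd2, coo_px, coo_neu, coo_cnt,
):
    """Count, per pixel, the in-ellipsoid voxels by kind.

    Returns the number of (pixel, neuron) entries written, or -1 on buffer
    overflow. ``labels``: 0 empty, +id shell, -id nucleus. The ellipsoid at
    each pixel has its symmetry axis along the focal-surface normal
    ``normalize((-slope*ux, -slope*uy, 1))`` and semi-axes (a_lat, a_lat,
    a_ax).
    """
    nx_g, ny_g, nz_g = labels.shape
    max_entries = coo_px.size
    ptr = 0
    loc_lab = np.empty(128, np.int64)
    loc_cnt = np.empty(128, np.int64)
    for p in range(px_x.size):
        cx, cy, cz = px_x[p], px_y[p], surf_z[p]
        nxv = -slope[p] * ux[p]
        nyv = -slope[p] * uy[p]
        nzv = 1.0
        nn = np.sqrt(nxv * nxv + nyv * nyv + nzv * nzv)
        nxv, nyv, nzv = nxv / nn, nyv / nn, nzv / nn
        al2 = a_lat[p] * a_lat[p]
        aa2 = a_ax[p] * a_ax[p]
        # support of the ellipsoid along each grid axis
        ex = np.sqrt(aa2 * nxv * nxv + al2 * (1.0 - nxv * nxv))
        ey = np.sqrt(aa2 * nyv * nyv + al2 * (1.0 - nyv * nyv))
        ez = np.sqrt(aa2 * nzv * nzv + al2 * (1.0 - nzv * nzv))
        i0 = max(0, int(np.ceil((cx - ex) / vx - 0.5)))
        i1 = min(nx_g - 1, int(np.floor((cx + ex) / vx - 0.5)))
        j0 = max(0, int(np.ceil((cy - ey) / vy - 0.5)))
        j1 = min(ny_g - 1, int(np.floor((cy + ey) / vy - 0.5)))
        k0 = max(0, int(np.ceil((cz - ez) / vz - 0.5)))
        k1 = min(nz_g - 1, int(np.floor((cz + ez) / vz - 0.5)))
        n_loc = 0
        cnt_in = 0
        cnt_nuc = 0
        s_bg = 0.0
        s_bg2 = 0.0
        for i in range(i0, i1 + 1):
            dx = (i + 0.5) * vx - cx
            for j in range(j0, j1 + 1):
                dy = (j + 0.5) * vy - cy
                for k in range(k0, k1 + 1):
                    dz = (k + 0.5) * vz - cz
                    ax_comp = dx * nxv + dy * nyv + dz * nzv
                    d2 = dx * dx + dy * dy + dz * dz
                    perp2 = d2 - ax_comp * ax_comp
                    if perp2 < 0.0:
                        perp2 = 0.0
                    if ax_comp * ax_comp / aa2 + perp2 / al2 > 1.0:
                        continue
                    cnt_in += 1
                    lab = labels[i, j, k]
                    if lab == 0:
                        mu = np.float64(bg_mean_field[i, j, k])
                        sd = q0 + q1 * np.sqrt(mu)
                        s_bg += mu
                        s_bg2 += sd * sd
                    elif lab < 0:
                        cnt_nuc += 1
                    else:
                        found = False
                        for t in range(n_loc):
                            if loc_lab[t] == lab:
                                loc_cnt[t] += 1
                                found = True
                                break
                        if not found:
                            if n_loc >= 128:
                                return -1
                            loc_lab[n_loc] = lab
                            loc_cnt[n_loc] = 1
                            n_loc += 1
        n_in[p] = cnt_in
        n_nuc[p] = cnt_nuc
        bg_sum[p] = s_bg
        bg_sd2[p] = s_bg2
        for t in range(n_loc):
            if ptr >= max_entries:
                return -1
            coo_px[ptr] = p
            coo_neu[ptr] = loc_lab[t] - 1
            coo_cnt[ptr] = loc_cnt[t]
            ptr += 1
    return ptr


def sample_background_field(
    shape, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Static per-voxel background mean field (lognormal draws)."""
    mu, sigma = noise.lognormal_params()
    return rng.lognormal(mu, sigma, size=shape).astype(np.float32)


def build_mixing_matrix(
    tissue: TissueVolume,
    labels: np.ndarray,
    optics: OpticsModel,
    n_px: int,
    noise: NoiseModel,
    bg_mean_field: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MixingMatrix, np.ndarray]:
    """Scan excitation ellipsoids along the focal surface(s).

    Returns the mixing matrix and the static background-mean voxel field it
    consumed (drawn here when not supplied, so the caller can reuse it for a
    brute-force comparison).
    """
    grid = make_pixel_grid(optics, n_px, tissue.dims)
    if bg_mean_field is None:
        if rng is None:
            rng = np.random.default_rng(0)
        bg_mean_field = sample_background_field(labels.shape, noise, rng)
    cidx = grid.central_idx
    # pixels with zero excitation efficiency cannot carry neural signal;
    # they are left unsampled and fall into the empty-centre noise regime
    active = optics.intensity(grid.r_real[cidx]) > 0.0
    aidx = np.flatnonzero(active)
    px_x = grid.x_sample[cidx][aidx]
    px_y = grid.y_sample[cidx][aidx]
    r = grid.r_real[cidx][aidx]
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, (px_x - tissue.dims[0] / 2.0) / r, 0.0)
        uy = np.where(r > 0, (px_y - tissue.dims[1] / 2.0) / r, 0.0)
    lat, ax = psf_axes(r, optics.psf)
    a_lat = lat / 2.0
    a_ax = ax / 2.0
    vx, vy, vz = tissue.voxel_size
    q0, q1 = noise.background_sd_vs_sqrtmean
    fs = optics.focal_surface
    depths = np.atleast_2d(surface_depth(r, fs))
    if fs.kind == "polynomial":
        depths = depths.reshape(1, -1)

    n_neurons = tissue.n_neurons
    shells: list[ShellSampling] = []
    cap = max(cidx.size * 16, 1024)
    for s in range(fs.n_surfaces):
        slope = np.asarray(_surface_slope(r, fs, s), dtype=float) * fs.sign
        n_in_a = np.zeros(aidx.size, dtype=np.int64)
        n_nuc_a = np.zeros(aidx.size, dtype=np.int64)
        bg_sum_a = np.zeros(aidx.size)
        bg_sd2_a = np.zeros(aidx.size)
        while True:
            coo_px = np.zeros(cap, dtype=np.int64)
            coo_neu = np.zeros(cap, dtype=np.int64)
            coo_cnt = np.zeros(cap, dtype=np.int64)
            ptr = _sample_pixels(
                px_x, px_y, ux, uy, depths[s], slope, a_lat, a_ax,
                labels, bg_mean_field, vx, vy, vz, q0, q1,
                n_in_a, n_nuc_a, bg_sum_a, bg_sd2_a, coo_px, coo_neu, coo_cnt,
            )
            if ptr >= 0:
                break
            cap *= 4
        n_in = np.zeros(cidx.size, dtype=np.int64)
        n_nuc = np.zeros(cidx.size, dtype=np.int64)
        bg_sum = np.zeros(cidx.size)
        bg_sd2 = np.zeros(cidx.size)
        n_in[aidx] = n_in_a
        n_nuc[aidx] = n_nuc_a
        bg_sum[aidx] = bg_sum_a
        bg_sd2[aidx] = bg_sd2_a
        counts = sparse.coo_matrix(
            (coo_cnt[:ptr], (aidx[coo_px[:ptr]], coo_neu[:ptr])),
            shape=(cidx.size, n_neurons),
        ).tocsr()
        shells.append(ShellSampling(counts, n_in, n_nuc, bg_sum, bg_sd2))
    mix = MixingMatrix(grid, shells, optics.shell_weights, n_neurons)
    return mix, bg_mean_field


@dataclass
class SyntheticMovie:
    """Rendered frame stack with its ground-truth links."""

    frames: np.ndarray  # (T, n_px, n_px) float32
    frame_rate: float
    duration: float
    probe_type: str
    mixing: MixingMatrix
    tissue: TissueVolume
    activity: ActivitySet
    optics: OpticsModel
    noise: NoiseModel
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def median_projection(self) -> np.ndarray:
        return np.median(self.frames, axis=0)


def sample_static_noise_maps(
    noise: NoiseModel, grid: PixelGrid, rng: np.random.Generator
) -> dict:
    """Per-pixel static mean/SD maps for the edge and empty-centre regimes."""
    n_total = grid.x_nom.size
    edge = grid.edge_mask
    n_edge = int(edge.sum())
    weights = np.array([c[0] for c in noise.edge_gmm])
    means = np.array([c[1] for c in noise.edge_gmm])
    sds = np.array([c[2] for c in noise.edge_gmm])
    comp = rng.choice(len(weights), size=n_edge, p=weights / weights.sum())
    edge_mean = rng.normal(means[comp], sds[comp])
    p0, p1 = noise.edge_sd_linear
    edge_sd = np.clip(p0 + p1 * edge_mean, 0.0, None)

    mu, sigma = noise.lognormal_params()
    n_central = n_total - n_edge
    bg_mean = rng.lognormal(mu, sigma, size=n_central)
    q0, q1 = noise.background_sd_vs_sqrtmean
    bg_sd = q0 + q1 * np.sqrt(bg_mean)
    return dict(edge_mean=edge_mean, edge_sd=edge_sd, bg_mean=bg_mean, bg_sd=bg_sd)


def render(
    tissue: TissueVolume,
    activity: ActivitySet,
    optics: OpticsModel,
    noise: NoiseModel,
    mixing: MixingMatrix | None = None,
    labels: np.ndarray | None = None,
    n_px: int = 256,
    frame_rate: float = FRAME_RATE,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
    noise_on: bool = True,
    modulate_noise: bool = False,
    time_chunk: int = 300,
) -> SyntheticMovie:
    """Render a 30 Hz synthetic t-series.

    Activity is bin-averaged from the simulation step onto the frame grid
    (approximating frame integration). When ``noise_on`` is False all random
    per-frame draws are suppressed and static background means are kept, so
    the movie is constant in time up to the neural signal. The radial
    intensity modulation multiplies the full central-pixel value
    (``modulate_noise=False`` restricts it to the neural signal); edge
    pixels carry unmodulated detector dark noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    if duration is None:
        duration = activity.duration
    if duration > activity.duration + 1e-9:
        raise ValueError("activity shorter than requested movie duration")
    if mixing is None:
        if labels is None:
            from .tissue import rasterize

            labels = rasterize(tissue)
        mixing, _ = build_mixing_matrix(tissue, labels, optics, n_px, noise, rng=rng)
    grid = mixing.grid
    if grid.n_px != n_px:
        raise ValueError("mixing matrix grid does not match requested n_px")

    n_frames = int(round(duration * frame_rate))
    traces = activity.frame_traces(frame_rate)[:, :n_frames]

    W = mixing.weights
    occ = mixing.occupancy
    occupied = occ > 0
    cidx = grid.central_idx

    # static background term and per-pixel noise SD for occupied pixels
    bg_static = np.zeros(cidx.size)
    sigma2 = np.zeros(cidx.size)
    p0, p1 = noise.roi_sd_vs_sqrtmean
    neuron_mean = activity.mean_fluorescence()
    sd_neuron = p0 + p1 * np.sqrt(neuron_mean)
    for sw, sh in zip(mixing.shell_weights, mixing.shells):
        denom = np.maximum(sh.n_in, 1)
        bg_static += sw * sh.bg_mean_sum / denom
        neu_sd2 = np.asarray(sh.counts @ (sd_neuron**2)).ravel() + sh.n_nucleus * p0**2
        sigma2 += sw**2 * (sh.bg_sd2_sum + neu_sd2) / denom**2
    sigma = np.sqrt(sigma2)

    maps = sample_static_noise_maps(noise, grid, rng)
    modulation = optics.intensity(grid.r_real[cidx])

    signal_static = np.where(occupied, bg_static, maps["bg_mean"])
    signal_sd = np.where(occupied, sigma, maps["bg_sd"])
    if not noise_on:
        signal_sd = np.zeros_like(signal_sd)
        edge_sd = np.zeros_like(maps["edge_sd"])
    else:
        edge_sd = maps["edge_sd"]

    movie = np.empty((n_frames, n_px * n_px), dtype=np.float32)
    edge_flat = np.flatnonzero(grid.edge_mask)
    for t0 in range(0, n_frames, time_chunk):
        t1 = min(t0 + time_chunk, n_frames)
        nt = t1 - t0
        neural = np.asarray(W @ traces[:, t0:t1])  # (n_central, nt)
        draws = (
            rng.normal(size=(cidx.size, nt)) * signal_sd[:, None]
            if noise_on
            else 0.0
        )
        if modulate_noise:
            sig = (neural + signal_static[:, None] + draws) * modulation[:, None]
        else:
            sig = neural * modulation[:, None] + signal_static[:, None] + draws
        edge_vals = maps["edge_mean"][:, None] + (
            rng.normal(size=(edge_flat.size, nt)) * edge_sd[:, None]
            if noise_on
            else 0.0
        )
        block = movie[t0:t1]
        block[:, cidx] = sig.T
        block[:, edge_flat] = np.asarray(edge_vals).T
    movie = movie.reshape(n_frames, n_px, n_px)
    return SyntheticMovie(
        movie, frame_rate, duration, optics.probe_type, mixing, tissue, activity,
        optics, noise, seed_val,
    )
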