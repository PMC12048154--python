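"""Independent brute-force oracles used by the test suite.

Everything here is implemented from the definitions, not by calling the
package's computational path: voxel scans use dense meshgrids, percentiles
use sorting through numpy on explicit windows, regression fits use
statsmodels. Tests compare the package against these.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from grinsim.optics import OpticsModel, psf_axes, surface_depth, _surface_slope
from grinsim.render import make_pixel_grid


def shell_volume(soma_radius: float, nucleus_halfwidth: float) -> float:
    """Analytic volume of the fluorescent shell (µm^3)."""
    return 4.0 / 3.0 * np.pi * (soma_radius**3 - nucleus_halfwidth**3)


def brute_force_pixel_sampling(
    tissue, labels, optics: OpticsModel, n_px: int, bg_mean_field, noise
):
    """Dense voxel scan of the excitation ellipsoids.

    For every central pixel and every focal surface, classifies each voxel
    of the full grid as in/out of the tilted ellipsoid with a vectorised
    meshgrid test, and accumulates shell counts per neuron, nucleus counts,
    in-ellipsoid totals and background mean sums. Returns one dict per
    focal surface.
    """
    grid = make_pixel_grid(optics, n_px, tissue.dims)
    vx, vy, vz = tissue.voxel_size
    shape = labels.shape
    xs = (np.arange(shape[0]) + 0.5) * vx
    ys = (np.arange(shape[1]) + 0.5) * vy
    zs = (np.arange(shape[2]) + 0.5) * vz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    fs = optics.focal_surface
    q0, q1 = noise.background_sd_vs_sqrtmean
    out = []
    cidx = grid.central_idx
    active = optics.intensity(grid.r_real[cidx]) > 0.0
    for s in range(fs.n_surfaces):
        res = {
            "n_in": np.zeros(cidx.size, dtype=int),
            "n_nuc": np.zeros(cidx.size, dtype=int),
            "bg_sum": np.zeros(cidx.size),
            "bg_sd2": np.zeros(cidx.size),
            "counts": np.zeros((cidx.size, tissue.n_neurons), dtype=int),
        }
        for p, flat in enumerate(cidx):
            if not active[p]:
                continue
            px = grid.x_sample[flat]
            py = grid.y_sample[flat]
            r = grid.r_real[flat]
            lat, ax = psf_axes(r, optics.psf)
            a_lat, a_ax = lat / 2.0, ax / 2.0
            depth = np.atleast_1d(np.asarray(surface_depth(r, fs)).ravel())[s]
            slope = float(np.asarray(_surface_slope(r, fs, s))) * fs.sign
            if r > 0:
                ux = (px - tissue.dims[0] / 2.0) / r
                uy = (py - tissue.dims[1] / 2.0) / r
            else:
                ux = uy = 0.0
            n = np.array([-slope * ux, -slope * uy, 1.0])
            n /= np.linalg.norm(n)
            dx, dy, dz = gx - px, gy - py, gz - depth
            ax_comp = dx * n[0] + dy * n[1] + dz * n[2]
            d2 = dx**2 + dy**2 + dz**2
            perp2 = np.clip(d2 - ax_comp**2, 0.0, None)
            inside = ax_comp**2 / a_ax**2 + perp2 / a_lat**2 <= 1.0
            res["n_in"][p] = int(inside.sum())
            lab = labels[inside]
            res["n_nuc"][p] = int((lab < 0).sum())
            empty = lab == 0
            if empty.any():
                mu = bg_mean_field[inside][empty].astype(np.float64)
                res["bg_sum"][p] = mu.sum()
                res["bg_sd2"][p] = ((q0 + q1 * np.sqrt(mu)) ** 2).sum()
            pos = lab[lab > 0]
            if pos.size:
                res["counts"][p] = np.bincount(pos, minlength=tissue.n_neurons + 1)[1:]
        out.append(res)
    return grid, out


def brute_force_noiseless_render(
    tissue, labels, optics, n_px, bg_mean_field, noise, frame_traces
):
    """Per-frame voxel render of occupied pixels, no noise draws.

    Pixel value = shell-weighted mean over focal surfaces of
    (sum of neuron fluorescence + sum of empty-voxel background means) /
    n_in, with the radial intensity modulation applied to the neural part
    only. Returns (flat pixel values (n_central, T), occupied mask).
    """
    grid, samples = brute_force_pixel_sampling(
        tissue, labels, optics, n_px, bg_mean_field, noise
    )
    cidx = grid.central_idx
    modulation = optics.intensity(grid.r_real[cidx])
    T = frame_traces.shape[1]
    vals = np.zeros((cidx.size, T))
    occupied = np.zeros(cidx.size, dtype=bool)
    for sw, res in zip(optics.shell_weights, samples):
        denom = np.maximum(res["n_in"], 1)
        neural = (res["counts"] / denom[:, None]) @ frame_traces
        vals += sw * (neural * modulation[:, None] + (res["bg_sum"] / denom)[:, None])
        occupied |= (res["counts"].sum(axis=1) + res["n_nuc"]) > 0
    return grid, vals, occupied


def windowed_percentile_baseline(f, frame_rate, window_s=10.0, q=20.0):
    """Loop implementation of the truncated centred sliding percentile."""
    half = max(int(round(window_s * frame_rate / 2.0)), 0)
    n = len(f)
    return np.array(
        [np.percentile(f[max(0, t - half) : t + half + 1], q) for t in range(n)]
    )


def peak_snr_direct(dff):
    dff = np.asarray(dff, float)
    q = np.percentile(dff, 25.0)
    tail = dff[dff < q]
    sd = tail.std() if tail.size else 0.0
    return np.inf if sd == 0 else dff.max() / sd


def percentile_band_mean(values, lo_q=80.0, hi_q=95.0):
    """Sort-based [lo_q, hi_q] percentile-band mean of one frame's box."""
    v = np.sort(np.asarray(values, float).ravel())
    lo = np.percentile(v, lo_q)
    hi = np.percentile(v, hi_q)
    sel = v[(v >= lo) & (v <= hi)]
    if sel.size == 0:
        sel = v
    return sel.mean()


def purity_via_statsmodels(y, sources):
    """GLM (gaussian, identity link) fit and purity, the reference route."""
    x = sm.add_constant(np.asarray(sources, float).T)
    fit = sm.GLM(np.asarray(y, float), x).fit()
    a = fit.params[1:]
    return a, float(np.max(a**2) / np.sum(a**2))


def adjacent_fraction_enumeration(
    positions, correlations, snrs, threshold, cutoff, adjacency_um=25.0
):
    """Exhaustive pair enumeration for the adjacent-pair fraction."""
    n = len(positions)
    above = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not (np.isfinite(snrs[i]) and np.isfinite(snrs[j])):
                continue
            if snrs[i] <= cutoff or snrs[j] <= cutoff:
                continue
            d = np.linalg.norm(np.asarray(positions[i]) - np.asarray(positions[j]))
            if d > adjacency_um:
                continue
            total += 1
            if correlations[i][j] > threshold:
                above += 1
    return above, total
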