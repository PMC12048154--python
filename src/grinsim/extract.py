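"""ROI detection and activity-trace extraction.

Bounding boxes come either from the ground-truth mixing matrix (the default:
the axis-aligned bounding rectangle of each neuron's nonzero pixel
footprint, a deterministic stand-in for a trained cell detector), from a
blob detector on the median-intensity projection, or from an externally
supplied box list. Within each box and for every frame, the ROI is the set
of pixels whose intensity falls between the 80th and 95th percentile of the
box's intensity distribution; the trace is the ROI mean minus a per-frame
background estimated from non-box pixels brighter than the corner dark
noise and dimmer than the brightest box pixel.

dF/F0 uses a running 20th-percentile baseline in a 10 s window centred on
each frame (truncated at the trace ends); peak SNR is max(dF/F0) divided by
the SD of the dF/F0 values lying below the trace's 25th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .optics import MagnificationModel, real_distance
from .render import MixingMatrix, SyntheticMovie

__all__ = [
    "Box",
    "DetectorSpec",
    "ROIRecord",
    "detect_rois",
    "ground_truth_boxes",
    "roi_trace",
    "contributing_sources",
    "background_trace",
    "compute_dff",
    "peak_snr",
    "centroid_to_um",
    "extract_all",
    "SNR_THRESHOLD_GRID",
]

#: standard peak-SNR threshold sweep for ROI selection curves
SNR_THRESHOLD_GRID = (0, 5, 10, 11, 12.5, 15, 16.5, 17.5, 20, 22.5, 25, 27.5, 30)

PERCENTILE_BAND = (80.0, 95.0)
BASELINE_PERCENTILE = 20.0
BASELINE_WINDOW_S = 10.0
NOISE_PERCENTILE = 25.0


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, 0-based, half-open ([y0,y1) x [x0,x1))."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self):
        if self.y1 <= self.y0 or self.x1 <= self.x0:
            raise ValueError("degenerate box")

    @property
    def centroid_px(self) -> tuple[float, float]:
        """(x, y) centre of the rectangle in pixel coordinates."""
        return ((self.x0 + self.x1) / 2.0 - 0.5, (self.y0 + self.y1) / 2.0 - 0.5)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass
class DetectorSpec:
    """Which ROI detector to use.

    ``ground_truth_projection`` (default) builds one box per neuron with a
    nonzero mixing-matrix footprint; ``intensity_blob`` runs a local-maxima
    + threshold detector on the median projection; ``external_boxes`` takes
    ``boxes`` as given.
    """

    mode: str = "ground_truth_projection"
    threshold_sd: float = 4.0  # blob mode: threshold above background, in SDs
    min_area_px: int = 4
    boxes: list[Box] | None = None


@dataclass
class ROIRecord:
    """One extracted ROI with its traces and summary statistics."""

    roi_id: int
    box: Box
    centroid_px: tuple[float, float]
    centroid_um_r: float
    trace_f: np.ndarray
    dff: np.ndarray
    peak_snr: float
    contributing_sources: np.ndarray
    source_id: int | None = None  # ground-truth neuron for gt-projection boxes
    baseline_ok: bool = True


def detect_rois(
    movie: SyntheticMovie | np.ndarray,
    detector: DetectorSpec | None = None,
    mixing: MixingMatrix | None = None,
) -> list[Box]:
    """Return bounding boxes under the requested detector mode."""
    detector = detector or DetectorSpec()
    if detector.mode == "external_boxes":
        if detector.boxes is None:
            raise ValueError("external_boxes mode needs boxes")
        return list(detector.boxes)
    if detector.mode == "ground_truth_projection":
        if mixing is None:
            if not isinstance(movie, SyntheticMovie):
                raise ValueError("ground-truth mode needs the mixing matrix")
            mixing = movie.mixing
        return [b for _, b in ground_truth_boxes(mixing)]
    if detector.mode == "intensity_blob":
        frames = movie.frames if isinstance(movie, SyntheticMovie) else movie
        if frames.shape[0] == 0:
            return []
        return _blob_boxes(np.median(frames, axis=0), detector)
    raise ValueError(f"unknown detector mode {detector.mode!r}")


def ground_truth_boxes(mixing: MixingMatrix) -> list[tuple[int, Box]]:
    """(neuron id, bounding rectangle) of each neuron's nonzero footprint,
    ordered by neuron id; neurons outside focal reach are skipped."""
    boxes = []
    n_px = mixing.grid.n_px
    coo = mixing.weights.tocoo()
    by_neuron: dict[int, list[int]] = {}
    for r, c in zip(coo.row, coo.col):
        by_neuron.setdefault(int(c), []).append(int(r))
    for neuron in sorted(by_neuron):
        flat = mixing.grid.central_idx[by_neuron[neuron]]
        ys, xs = np.divmod(flat, n_px)
        boxes.append(
            (neuron, Box(int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1))
        )
    return boxes


def _blob_boxes(proj: np.ndarray, detector: DetectorSpec) -> list[Box]:
    bg = np.median(proj)
    mad = np.median(np.abs(proj - bg)) * 1.4826 + 1e-12
    mask = proj > bg + detector.threshold_sd * mad
    lab, n = ndimage.label(mask)
    boxes = []
    for sl_y, sl_x in ndimage.find_objects(lab):
        area = (sl_y.stop - sl_y.start) * (sl_x.stop - sl_x.start)
        if area >= detector.min_area_px:
            boxes.append(Box(sl_y.start, sl_y.stop, sl_x.start, sl_x.stop))
    return boxes


def background_trace(
    frames: np.ndarray, boxes: list[Box], edge_mask: np.ndarray
) -> np.ndarray:
    """Per-frame background: mean of pixels outside every box whose value
    exceeds the frame's mean corner (outside-FOV) level and stays below the
    frame's maximum inside the boxes. Falls back to the previous frame when
    the candidate set is empty."""
    n_frames, n_py, n_px = frames.shape
    in_box = np.zeros((n_py, n_px), dtype=bool)
    for b in boxes:
        in_box[b.slices()] = True
    flat = frames.reshape(n_frames, -1)
    edge_flat = edge_mask.ravel()
    corner_mean = flat[:, edge_flat].mean(axis=1) if edge_flat.any() else np.full(
        n_frames, -np.inf
    )
    inbox_flat = in_box.ravel()
    box_max = (
        flat[:, inbox_flat].max(axis=1) if inbox_flat.any() else np.full(n_frames, np.inf)
    )
    candidates = ~inbox_flat & ~edge_flat
    out = np.empty(n_frames)
    carried = 0
    prev = 0.0
    for t in range(n_frames):
        v = flat[t, candidates]
        sel = v[(v > corner_mean[t]) & (v < box_max[t])]
        if sel.size:
            prev = sel.mean()
        else:
            carried += 1
        out[t] = prev
    if carried:
        warnings.warn(
            f"background candidate set empty in {carried} frame(s); carried forward",
            stacklevel=2,
        )
    return out


def roi_trace(frames: np.ndarray, box: Box, background: np.ndarray) -> np.ndarray:
    """Percentile-band ROI mean minus background, per frame.

    The ROI in each frame is the set of box pixels whose value lies in the
    closed [80th, 95th] percentile band (linear-interpolation percentiles);
    a constant box degenerates to the whole box.
    """
    sub = frames[:, box.slices()[0], box.slices()[1]].reshape(frames.shape[0], -1)
    lo = np.percentile(sub, PERCENTILE_BAND[0], axis=1)
    hi = np.percentile(sub, PERCENTILE_BAND[1], axis=1)
    sel = (sub >= lo[:, None]) & (sub <= hi[:, None])
    counts = sel.sum(axis=1)
    # ties/degenerate distributions: include the whole box
    empty = counts == 0
    if empty.any():
        sel[empty] = True
        counts = sel.sum(axis=1)
    means = (sub * sel).sum(axis=1) / counts
    return means - background


def compute_dff(
    f: np.ndarray, frame_rate: float, window_s: float = BASELINE_WINDOW_S
) -> tuple[np.ndarray, bool]:
    """Sliding-percentile dF/F0.

    F0(t) is the 20th percentile of F in a ``window_s`` interval centred on
    t, truncated at the trace ends. Returns (dff, baseline_ok); when F0 is
    non-positive anywhere the ROI is flagged and dff computed with the
    offending frames' F0 left in place (callers exclude flagged ROIs from
    SNR statistics).
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise ValueError("trace too short")
    # window for frame t is f[max(0, t-half) : t+half+1] (truncated at ends)
    half = max(int(round(window_s * frame_rate / 2.0)), 0)
    w = 2 * half + 1
    n = f.size
    if w >= n:
        f0 = np.full(n, np.percentile(f, BASELINE_PERCENTILE))
    else:
        f0 = np.empty(n)
        windows = np.lib.stride_tricks.sliding_window_view(f, w)
        f0[half : half + windows.shape[0]] = np.percentile(
            windows, BASELINE_PERCENTILE, axis=1
        )
        for t in range(half):
            f0[t] = np.percentile(f[: t + half + 1], BASELINE_PERCENTILE)
        for t in range(half + windows.shape[0], n):
            f0[t] = np.percentile(f[t - half :], BASELINE_PERCENTILE)
    ok = bool(np.all(f0 > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0) / f0
    return dff, ok


def peak_snr(dff: np.ndarray) -> float:
    """max(dF/F0) / SD(values strictly below the trace's 25th percentile).

    Returns inf (flagged, excluded from threshold sweeps) when the lower
    tail is degenerate.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size < 2:
        raise ValueError("trace too short")
    q = np.percentile(dff, NOISE_PERCENTILE)
    tail = dff[dff < q]
    noise = tail.std(ddof=0) if tail.size >= 2 else 0.0
    if noise == 0.0:
        return float("inf")
    return float(dff.max() / noise)


def centroid_to_um(
    centroid_px: tuple[float, float],
    model: MagnificationModel,
    fov_center_px: float,
    nominal_pixel_size: float | None = None,
) -> float:
    """Calibrated radial distance (µm) of a pixel centroid.

    Pixel coordinates are converted to nominal µm with the nominal pixel
    size and the radial distance is then mapped through the inverse of the
    distance-calibration quartic to a real distance in the sample.
    """
    ps = nominal_pixel_size if nominal_pixel_size is not None else model.nominal_pixel_size
    dx = (centroid_px[0] - fov_center_px) * ps
    dy = (centroid_px[1] - fov_center_px) * ps
    r_nom = float(np.hypot(dx, dy))
    return float(real_distance(r_nom, model))


def boxes_from_csv(path) -> list[Box]:
    """Load externally supplied bounding boxes (columns y0, y1, x0, x1),
    e.g. the output of another cell detector."""
    import pandas as pd

    df = pd.read_csv(path)
    return [
        Box(int(r.y0), int(r.y1), int(r.x0), int(r.x1)) for r in df.itertuples()
    ]


def contributing_sources(mixing: MixingMatrix, box: Box) -> np.ndarray:
    """Ground-truth neurons whose footprint overlaps the box by >= 1 pixel."""
    n_px = mixing.grid.n_px
    coo = mixing.weights.tocoo()
    flat = mixing.grid.central_idx[coo.row]
    ys, xs = np.divmod(flat, n_px)
    inside = (ys >= box.y0) & (ys < box.y1) & (xs >= box.x0) & (xs < box.x1)
    return np.unique(coo.col[inside])


def extract_all(
    movie: SyntheticMovie,
    detector: DetectorSpec | None = None,
    nominal_pixel_size: float | None = None,
) -> list[ROIRecord]:
    """Detect boxes and extract a full :class:`ROIRecord` per ROI."""
    detector = detector or DetectorSpec()
    mixing = movie.mixing
    grid = mixing.grid
    if detector.mode == "ground_truth_projection":
        pairs = ground_truth_boxes(mixing)
    else:
        pairs = [(None, b) for b in detect_rois(movie, detector, mixing)]
    boxes = [b for _, b in pairs]
    edge_mask = grid.edge_mask.reshape(grid.n_px, grid.n_px)
    bg = background_trace(movie.frames, boxes, edge_mask)
    ps = (
        nominal_pixel_size
        if nominal_pixel_size is not None
        else grid.nominal_pixel_size
    )
    center_px = (grid.n_px - 1) / 2.0
    records = []
    for roi_id, (src, box) in enumerate(pairs):
        f = roi_trace(movie.frames, box, bg)
        dff, ok = compute_dff(f, movie.frame_rate)
        snr = peak_snr(dff) if ok else float("nan")
        cpx = box.centroid_px
        r_um = centroid_to_um(cpx, movie.optics.magnification, center_px, ps)
        records.append(
            ROIRecord(
                roi_id=roi_id,
                box=box,
                centroid_px=cpx,
                centroid_um_r=r_um,
                trace_f=f,
                dff=dff,
                peak_snr=snr,
                contributing_sources=contributing_sources(mixing, box),
                source_id=src,
                baseline_ok=ok,
            )
        )
    return records
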