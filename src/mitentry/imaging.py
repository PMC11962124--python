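"""Per-nucleus quantification metrics for label + intensity movies.

Segmentation and tracking are consumed, not computed: the inputs are
integer label images (0 = background) aligned with intensity frames,
as produced by any nucleus segmenter.  The metrics are the ones used to
characterise cells held in a prophase-like state by PLK1 inhibition:

- chromosome condensation: SD of nuclear intensity over the
  background-corrected mean (division by the corrected mean also cancels
  photobleaching);
- nuclear:cytoplasmic ratio of a translocating marker, the cytoplasm
  taken as a dilated ring clipped to each nucleus's Voronoi territory;
- FRET ratio (YFP/CFP, both background-corrected) of a CDK activity
  biosensor;
- cell-outline eccentricity time course, normalised to just after NEBD
  (cells round up, eccentricity falls);
- z centroid of nuclear signal (cells lift off the substrate);
- intensity-foci count (e.g. gamma-H2AX) by topographic prominence;
- cumulative NEBD percentage over a field of view.

Conventions: frame indices are 0-based in memory (exports add 1),
image origin is the top-left pixel, and SDs are population SDs
(divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops, label as cc_label
from skimage.morphology import disk, h_maxima
from skimage.segmentation import clear_border

__all__ = [
    "LabeledMovie",
    "filter_labels",
    "condensation_score",
    "voronoi_territories",
    "nc_ratio",
    "normalize_to_first_frames",
    "fret_ratio",
    "eccentricity",
    "eccentricity_course",
    "z_centroid",
    "count_foci",
    "cumulative_nebd",
    "condensation_course",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. mean below background)."""


@dataclass
class LabeledMovie:
    """Time-ordered intensity frames with aligned integer label images.

    ``frames``: (T, Y, X) array per channel, keyed by channel name.
    ``labels``: (T, Y, X) integer array, 0 = background.
    ``background``: global background intensity per channel.
    ``z_stacks``: optional (T, Z, Y, X) array per channel.
    """

    frames: dict[str, np.ndarray]
    labels: np.ndarray
    background: dict[str, float]
    frame_interval_min: float
    z_stacks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        labels = np.asarray(self.labels)
        for name, arr in self.frames.items():
            if arr.shape != labels.shape:
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} does not match labels "
                    f"{labels.shape}"
                )
        if labels.min() < 0:
            raise ValueError("label ids must be non-negative integers")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def filter_labels(
    label_image: np.ndarray, min_area: int = 1000, drop_border: bool = True
) -> np.ndarray:
    """Remove labels smaller than ``min_area`` pixels and, optionally,
    labels touching any image border."""
    lab = np.asarray(label_image)
    out = clear_border(lab) if drop_border else lab.copy()
    ids, counts = np.unique(out[out > 0], return_counts=True)
    small = ids[counts < min_area]
    if small.size:
        out[np.isin(out, small)] = 0
    return out


def condensation_score(pixels: np.ndarray, background: float) -> float:
    """Chromosome-condensation proxy: SD over background-corrected mean.

    Population SD convention.  The division by the corrected mean makes
    the score invariant to multiplicative bleaching of the signal above
    background and to intensity rescaling.
    """
    px = np.asarray(pixels, dtype=float).ravel()
    if px.size == 0:
        raise UndefinedMetricError("empty pixel set")
    mean = px.mean()
    if mean <= background:
        raise UndefinedMetricError(
            f"nucleus mean {mean} is not above background {background}"
        )
    return float(px.std(ddof=0) / (mean - background))


def voronoi_territories(label_image: np.ndarray) -> np.ndarray:
    """Assign every pixel to its nearest labelled nucleus (generalised
    Voronoi partition); an all-zero label image maps to all zeros."""
    lab = np.asarray(label_image)
    if not np.any(lab > 0):
        return np.zeros_like(lab)
    _, (iy, ix) = ndimage.distance_transform_edt(lab == 0, return_indices=True)
    return lab[iy, ix]


def nc_ratio(
    frame: np.ndarray,
    labels: np.ndarray,
    nucleus_id: int,
    background: float = 0.0,
    dilation_radius: int = 10,
) -> dict:
    """Nuclear over cytoplasmic mean intensity for one nucleus.

    The cytoplasm is the ring obtained by dilating the nucleus mask by
    ``dilation_radius`` pixels (disk structuring element), clipping to the
    nucleus's Voronoi territory so neighbouring cells do not contaminate
    the ring, and subtracting the nuclear mask.  Both compartment means
    are background-subtracted.  Returns ``ratio``, ``nuclear_mean`` and
    ``cytoplasm_mean`` (corrected means).
    """
    lab = np.asarray(labels)
    img = np.asarray(frame, dtype=float)
    nucleus = lab == nucleus_id
    if not nucleus.any():
        raise UndefinedMetricError(f"label {nucleus_id} absent from frame")
    dilated = ndimage.binary_dilation(nucleus, structure=disk(dilation_radius))
    territory = voronoi_territories(lab) == nucleus_id
    ring = dilated & territory & (lab == 0)
    if not ring.any():
        raise UndefinedMetricError("empty cytoplasmic ring")
    nuc_mean = img[nucleus].mean() - background
    cyto_mean = img[ring].mean() - background
    if cyto_mean <= 0:
        raise UndefinedMetricError("cytoplasmic mean not above background")
    return {
        "ratio": float(nuc_mean / cyto_mean),
        "nuclear_mean": float(nuc_mean),
        "cytoplasm_mean": float(cyto_mean),
    }


def normalize_to_first_frames(series: np.ndarray, n_frames: int = 5) -> np.ndarray:
    """Divide a time series by its mean over the first ``n_frames`` frames,
    the convention used for cytoplasmic marker and z-centroid courses."""
    s = np.asarray(series, dtype=float)
    if s.size < n_frames:
        raise ValueError(f"series has {s.size} frames, need >= {n_frames}")
    ref = s[:n_frames].mean()
    if ref == 0:
        raise UndefinedMetricError("normalisation window mean is zero")
    return s / ref


def fret_ratio(
    yfp_mean: float, cfp_mean: float, yfp_bg: float = 0.0, cfp_bg: float = 0.0
) -> float:
    """Background-corrected YFP/CFP emission ratio of the CDK biosensor."""
    denom = cfp_mean - cfp_bg
    if denom <= 0:
        raise UndefinedMetricError("CFP mean not above background")
    return float((yfp_mean - yfp_bg) / denom)


def eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the second-moments ellipse fitted to a binary mask."""
    m = np.asarray(mask).astype(np.uint8)
    if not m.any():
        raise UndefinedMetricError("empty mask")
    props = regionprops(cc_label(m > 0))
    largest = max(props, key=lambda r: r.area)
    return float(largest.eccentricity)


def eccentricity_course(
    masks: np.ndarray,
    nebd_frame: int,
    frame_interval_min: float,
    window_min: float = 10.0,
    tol: float = 1e-6,
) -> dict:
    """Cell-outline eccentricity over time, normalised to just after NEBD.

    The series is divided by the mean eccentricity of the frames within
    ``window_min`` minutes after NEBD (2 frames at a 5-min interval).  If
    the cell is near-circular there (window mean below ``tol``), the raw
    series is returned with ``status='unnormalized'`` instead of dividing
    by noise.
    """
    masks = np.asarray(masks)
    n = masks.shape[0]
    if not 0 <= nebd_frame < n:
        raise ValueError(f"nebd_frame {nebd_frame} outside series of {n} frames")
    raw = np.array([eccentricity(m) for m in masks])
    n_window = max(int(round(window_min / frame_interval_min)), 1)
    start = nebd_frame + 1
    window = raw[start:start + n_window]
    if window.size == 0 or window.mean() < tol:
        return {"series": raw, "status": "unnormalized", "reference": np.nan}
    ref = float(window.mean())
    return {"series": raw / ref, "status": "normalized", "reference": ref}


def z_centroid(z_stack: np.ndarray, mask: np.ndarray) -> float:
    """Intensity-weighted centroid position along z, in z-step units.

    Sum over planes of (plane index x integrated masked density) divided
    by the total integrated density; plane indices are 0-based.
    """
    zs = np.asarray(z_stack, dtype=float)
    if zs.ndim != 3 or zs.shape[0] < 2:
        raise ValueError("z_stack must be (Z, Y, X) with >= 2 planes")
    m = np.asarray(mask).astype(bool)
    dens = np.array([plane[m].sum() for plane in zs])
    total = dens.sum()
    if total <= 0:
        raise UndefinedMetricError("zero integrated density under the mask")
    return float(np.dot(np.arange(zs.shape[0]), dens) / total)


def count_foci(
    frame: np.ndarray, nucleus_mask: np.ndarray, prominence: float = 100.0
) -> int:
    """Number of local intensity maxima of topographic prominence
    exceeding ``prominence`` inside the mask (8-connected)."""
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    img = np.asarray(frame, dtype=float)
    m = np.asarray(nucleus_mask).astype(bool)
    peaks = h_maxima(img, prominence, footprint=np.ones((3, 3)))
    labelled = cc_label(peaks, connectivity=2)
    ids = np.unique(labelled[m & (labelled > 0)])
    return int(ids.size)


def cumulative_nebd(
    events: list[int | None], n_initial: int, grid: np.ndarray
) -> np.ndarray:
    """Cumulative NEBD percentage over a field of view.

    ``events`` holds the NEBD frame per cell (``None`` = never observed);
    the denominator ``n_initial`` is the number of nuclei counted on the
    first frame.  Returns the percentage of cells with NEBD at or before
    each grid frame.
    """
    have = sorted(e for e in events if e is not None)
    if n_initial < len(have):
        raise ValueError("n_initial smaller than the number of NEBD events")
    if n_initial == 0:
        return np.zeros(len(np.atleast_1d(grid)))
    g = np.atleast_1d(np.asarray(grid))
    counts = np.searchsorted(have, g, side="right")
    return 100.0 * counts / n_initial


def condensation_course(
    movie: LabeledMovie,
    channel: str,
    min_area: int = 0,
    drop_border: bool = False,
) -> pd.DataFrame:
    """Condensation score per nucleus per frame, long format.

    Columns: ``frame`` (0-based), ``label``, ``score``.  Nuclei whose
    mean does not exceed background in a frame are skipped.
    """
    bg = movie.background[channel]
    rows = []
    for t in range(movie.n_frames):
        lab = movie.labels[t]
        if min_area or drop_border:
            lab = filter_labels(lab, min_area=min_area, drop_border=drop_border)
        img = movie.frames[channel][t]
        for lid in np.unique(lab[lab > 0]):
            px = img[lab == lid]
            try:
                score = condensation_score(px, bg)
            except UndefinedMetricError:
                continue
            rows.append({"frame": t, "label": int(lid), "score": score})
    return pd.DataFrame(rows, columns=["frame", "label", "score"])
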