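"""Object detection in single-channel fluorescence frames.

The pipeline is: robust background estimate -> contrast-relative threshold
-> 8-connected component labeling (with a centroid-interior border policy)
-> distance-transform declustering of touching cells -> feature measurement
(area, equivalent diameter, isoperimetric roundness, intensities) ->
profile-based filtering on the diameter and roundness gates.

Threshold semantics: a pixel is foreground iff its intensity exceeds
``background + (fluorescent_threshold / 100) * (frame_max - background)``.
The vendor's threshold units are undocumented, so this artifact defines
them as percent of the background-subtracted dynamic range — scale
invariant, and reproducing the ordering of the published parameter sets.

Decluster semantics: candidate centers are local maxima of the (smoothed)
Euclidean distance transform of the foreground mask; two candidates are
merged into one object when the saddle height between them exceeds
``decluster_factor`` times the lower peak height.  A factor near 0 merges
everything (one object per blob); a factor of 1.0 splits maximally; the
stock 0.90 splits only well-separated lobes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

from .profiles import CountingProfile, OpticsConfig

__all__ = [
    "ImageFrame",
    "Component",
    "DetectedObject",
    "ConfigurationError",
    "estimate_background",
    "threshold_mask",
    "label_components",
    "decluster",
    "measure",
    "filter_objects",
    "detect_frame",
]

#: sigma (pixels) of the smoothing applied to the distance transform before
#: peak finding; suppresses the discretization ripple along thin ridges.
_DT_SMOOTH_SIGMA = 0.75

#: a frame is considered signal-free when its maximum rises less than this
#: many (robust) noise sigmas above the background.
_MIN_SIGNAL_SIGMAS = 6.0


class ConfigurationError(ValueError):
    """Inconsistent frame / profile / geometry configuration."""


@dataclass
class ImageFrame:
    """A single-channel micrograph with its pixel geometry.

    ``pixels`` is a 2-D non-negative intensity array (any integer or float
    dtype); ``pixel_area`` is the sample-plane area per pixel in um^2.
    """

    pixels: np.ndarray
    pixel_area: float
    channel_role: str = "total"
    frame_id: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not self.pixel_area > 0:
            raise ValueError(f"pixel_area must be > 0, got {self.pixel_area}")
        if self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities exceed the declared bit depth")

    @property
    def pixel_side_um(self) -> float:
        return math.sqrt(self.pixel_area)


@dataclass
class Component:
    """A preliminary object: the pixel membership of one connected blob."""

    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def centroid_px(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())


@dataclass
class DetectedObject:
    """A segmented object with the features used by the counting filters."""

    object_id: int
    pixel_count: int
    area_um2: float
    equivalent_diameter_um: float
    roundness: float
    perimeter_um: float
    centroid_x_um: float
    centroid_y_um: float
    mean_intensity: float
    peak_intensity: float
    source_frame: str = ""


def estimate_background(frame: ImageFrame) -> float:
    """Robust background level of a frame (median intensity).

    Warns when the frame is fully saturated, in which case the returned
    level equals full scale and no object can be detected.
    """
    pixels = frame.pixels
    bg = float(np.median(pixels))
    full_scale = 2**frame.bit_depth - 1
    if pixels.min() >= full_scale:
        warnings.warn(
            f"frame {frame.frame_id!r} is fully saturated; background "
            "estimate equals full scale",
            stacklevel=2,
        )
    return bg


def _noise_sigma(pixels: np.ndarray, bg: float) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    return 1.4826 * float(np.median(np.abs(pixels.astype(np.float64) - bg)))


def threshold_mask(frame: ImageFrame, profile: CountingProfile) -> np.ndarray:
    """Binary foreground mask at the profile's fluorescent threshold.

    Foreground iff intensity > bg + (threshold/100) * (max - bg).  A frame
    whose maximum does not rise meaningfully above the background noise
    (within ``_MIN_SIGNAL_SIGMAS`` robust sigmas) yields an all-background
    mask rather than thresholding pure noise.
    """
    pixels = frame.pixels.astype(np.float64)
    bg = estimate_background(frame)
    fmax = float(pixels.max())
    if fmax <= bg:
        return np.zeros(frame.pixels.shape, dtype=bool)
    sigma = _noise_sigma(pixels, bg)
    if fmax < bg + _MIN_SIGNAL_SIGMAS * sigma:
        return np.zeros(frame.pixels.shape, dtype=bool)
    if profile.fluorescent_threshold >= 100.0:
        # boundary semantics: only pixels at the frame maximum survive
        return pixels >= fmax
    cut = bg + (profile.fluorescent_threshold / 100.0) * (fmax - bg)
    return pixels > cut


def _border_keep(lab: np.ndarray, n: int) -> np.ndarray:
    """Keep flags for labels 1..n under the centroid-interior border policy.

    A component touching the frame border is retained iff its centroid
    pixel (rounded) is not itself on the border ring.
    """
    h, w = lab.shape
    keep = np.ones(n + 1, dtype=bool)
    if n == 0:
        return keep
    border_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    if border_labels.size == 0:
        return keep
    cent = ndimage.center_of_mass(np.ones_like(lab), lab, border_labels)
    for lbl, (cr, cc) in zip(border_labels, cent):
        r, c = int(round(cr)), int(round(cc))
        if r <= 0 or c <= 0 or r >= h - 1 or c >= w - 1:
            keep[lbl] = False
    return keep


def _label_image(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling with the border policy applied. Internal."""
    lab, n = sk_label(mask, connectivity=2, return_num=True)
    keep = _border_keep(lab, n)
    if not keep.all():
        lab = np.where(keep[lab], lab, 0)
        # compact labels
        lab, n = sk_label(lab > 0, connectivity=2, return_num=True)
    return lab, n


def label_components(mask: np.ndarray) -> list[Component]:
    """8-connected components of a binary mask, as pixel-membership lists.

    Components touching the frame border are retained iff their centroid is
    interior (documented border policy; switchable by pre-cropping).
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = _label_image(mask)
    out: list[Component] = []
    for sl, lbl in zip(ndimage.find_objects(lab, n), range(1, n + 1)):
        if sl is None:
            continue
        rr, cc = np.nonzero(lab[sl] == lbl)
        out.append(Component(rr + sl[0].start, cc + sl[1].start))
    return out


# ---------------------------------------------------------------------------
# declustering


def _find_peaks(dist_s: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Candidate-center coordinates: local maxima of the smoothed EDT."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    return peak_local_max(
        np.where(mask, dist_s, 0.0),
        min_distance=1,
        threshold_abs=1e-9,
        exclude_border=False,
    )


def _merge_groups(
    ws: np.ndarray,
    dist_s: np.ndarray,
    peak_heights: np.ndarray,
    factor: float,
) -> np.ndarray:
    """Union-find grouping of watershed regions by the saddle criterion.

    ``ws`` holds region labels 1..K (0 = background). Returns, for each
    label 1..K, its group root (array of length K+1). Regions are merged
    when the saddle height between them exceeds ``factor`` times the lower
    of their peak heights.
    """
    k = len(peak_heights) - 1  # peak_heights is 1-indexed
    parent = np.arange(k + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # collect boundary pixel pairs under 8-connectivity
    lo_all, hi_all, sad_all = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if (dr, dc) == (0, 1):
            a, b = ws[:, :-1], ws[:, 1:]
            da, db = dist_s[:, :-1], dist_s[:, 1:]
        elif (dr, dc) == (1, 0):
            a, b = ws[:-1, :], ws[1:, :]
            da, db = dist_s[:-1, :], dist_s[1:, :]
        elif (dr, dc) == (1, 1):
            a, b = ws[:-1, :-1], ws[1:, 1:]
            da, db = dist_s[:-1, :-1], dist_s[1:, 1:]
        else:  # (1, -1)
            a, b = ws[:-1, 1:], ws[1:, :-1]
            da, db = dist_s[:-1, 1:], dist_s[1:, :-1]
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        av, bv = a[sel], b[sel]
        lo_all.append(np.minimum(av, bv))
        hi_all.append(np.maximum(av, bv))
        sad_all.append(np.minimum(da[sel], db[sel]))
    if lo_all:
        lo = np.concatenate(lo_all)
        hi = np.concatenate(hi_all)
        sad = np.concatenate(sad_all)
        key = lo.astype(np.int64) * (k + 1) + hi
        order = np.argsort(key, kind="stable")
        key, sad = key[order], sad[order]
        starts = np.flatnonzero(np.r_[True, key[1:] != key[:-1]])
        max_sad = np.maximum.reduceat(sad, starts)
        for kk, s in zip(key[starts], max_sad):
            a_lbl, b_lbl = int(kk // (k + 1)), int(kk % (k + 1))
            low_peak = min(peak_heights[a_lbl], peak_heights[b_lbl])
            if s > factor * low_peak:
                ra, rb = find(a_lbl), find(b_lbl)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(k + 1)])
    return roots


def _split_component(
    mask: np.ndarray,
    dist_s: np.ndarray,
    peaks: np.ndarray,
    factor: float,
) -> np.ndarray:
    """Split one component into children; returns a child-label image.

    ``peaks`` are (row, col) candidate centers inside ``mask``.  Children
    partition the component exactly: every mask pixel is assigned to the
    nearest surviving center.
    """
    if len(peaks) <= 1:
        return mask.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
    ws = watershed(-dist_s, markers, mask=mask, connectivity=2)
    heights = np.zeros(len(peaks) + 1)
    heights[1:] = dist_s[peaks[:, 0], peaks[:, 1]]
    roots = _merge_groups(ws, dist_s, heights, factor)
    group_ids = np.unique(roots[1:])
    if len(group_ids) == 1:
        return mask.astype(np.int32)
    # representative center per group: its highest peak
    centers = []
    for g in group_ids:
        members = np.flatnonzero(roots[1:] == g) + 1
        best = members[np.argmax(heights[members])]
        centers.append(peaks[best - 1])
    centers = np.asarray(centers, dtype=np.float64)
    rr, cc = np.nonzero(mask)
    d2 = (rr[:, None] - centers[None, :, 0]) ** 2 + (
        cc[:, None] - centers[None, :, 1]
    ) ** 2
    child = np.argmin(d2, axis=1) + 1
    out = np.zeros(mask.shape, dtype=np.int32)
    out[rr, cc] = child
    return out


def decluster(
    component: Component, frame: ImageFrame, profile: CountingProfile
) -> list[Component]:
    """Split a touching-cell blob into its constituent objects.

    Children always partition the parent: their pixel sets are pairwise
    disjoint and their union is exactly the parent's pixel set.  A single
    compact object comes back unchanged.
    """
    if len(component) == 0:
        raise ValueError("component is empty")
    r0, c0 = component.rows.min(), component.cols.min()
    h = component.rows.max() - r0 + 3
    w = component.cols.max() - c0 + 3
    mask = np.zeros((h, w), dtype=bool)
    mask[component.rows - r0 + 1, component.cols - c0 + 1] = True
    dist = ndimage.distance_transform_edt(mask)
    dist_s = ndimage.gaussian_filter(dist, _DT_SMOOTH_SIGMA)
    peaks = _find_peaks(dist_s, mask)
    child_lab = _split_component(mask, dist_s, peaks, profile.decluster_factor)
    out = []
    for lbl in range(1, child_lab.max() + 1):
        rr, cc = np.nonzero(child_lab == lbl)
        if rr.size:
            out.append(Component(rr + r0 - 1, cc + c0 - 1))
    return out


def _decluster_labels(
    mask: np.ndarray, lab: np.ndarray, n: int, factor: float
) -> tuple[np.ndarray, int]:
    """Frame-level declustering; returns a child-label image.

    Components whose smoothed distance transform carries a single candidate
    center pass through untouched; multi-center components are split via
    the saddle-merge rule.  Vectorized peak search keeps the per-component
    Python work restricted to actual clusters.
    """
    if n == 0:
        return lab.astype(np.int32), 0
    dist = ndimage.distance_transform_edt(mask)
    dist_s = ndimage.gaussian_filter(dist, _DT_SMOOTH_SIGMA)
    peaks = _find_peaks(dist_s, mask)
    comp_of_peak = lab[peaks[:, 0], peaks[:, 1]] if len(peaks) else np.array([], int)
    n_peaks = np.bincount(comp_of_peak, minlength=n + 1)
    out = lab.astype(np.int32).copy()
    next_label = n + 1
    slices = ndimage.find_objects(lab, n)
    multi = np.flatnonzero(n_peaks[1:] > 1) + 1
    for lbl in multi:
        sl = slices[lbl - 1]
        sl_pad = (
            slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, mask.shape[0])),
            slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, mask.shape[1])),
        )
        sub_mask = lab[sl_pad] == lbl
        sub_dist = np.where(sub_mask, dist_s[sl_pad], 0.0)
        sel = comp_of_peak == lbl
        sub_peaks = peaks[sel] - np.array(
            [sl_pad[0].start, sl_pad[1].start], dtype=int
        )
        child = _split_component(sub_mask, sub_dist, sub_peaks, factor)
        n_child = child.max()
        if n_child <= 1:
            continue
        rr, cc = np.nonzero(sub_mask)
        new_ids = np.where(
            child[rr, cc] == 1, lbl, next_label + child[rr, cc] - 2
        )
        out[rr + sl_pad[0].start, cc + sl_pad[1].start] = new_ids
        next_label += n_child - 1
    return out, next_label - 1


# ---------------------------------------------------------------------------
# measurement and filtering


def measure(
    objects: Sequence[Component] | np.ndarray,
    frame: ImageFrame,
    optics: OpticsConfig | None = None,
) -> list[DetectedObject]:
    """Measure the filter features of each object.

    ``objects`` may be a sequence of :class:`Component` (disjoint pixel
    sets) or a ready-made label image.  Area is pixel count times pixel
    area; equivalent diameter is ``2*sqrt(area/pi)``; roundness is the
    isoperimetric ratio ``4*pi*area/perimeter^2`` clamped to [0, 1], with
    the perimeter taken as the contour length with diagonal correction.
    """
    pixel_area = optics.pixel_area if optics is not None else frame.pixel_area
    side = math.sqrt(pixel_area)
    if isinstance(objects, np.ndarray):
        lab = objects
    else:
        lab = np.zeros(frame.pixels.shape, dtype=np.int32)
        for i, comp in enumerate(objects, start=1):
            if (lab[comp.rows, comp.cols] != 0).any():
                raise ValueError("objects must have disjoint pixel sets")
            lab[comp.rows, comp.cols] = i
    if lab.max() == 0:
        return []
    pixels = frame.pixels.astype(np.float64)
    props = regionprops_table(
        lab,
        intensity_image=pixels,
        properties=(
            "label",
            "num_pixels",
            "perimeter",
            "centroid",
            "intensity_mean",
            "intensity_max",
        ),
    )
    out: list[DetectedObject] = []
    for i in range(len(props["label"])):
        npx = int(props["num_pixels"][i])
        area = npx * pixel_area
        eqd = 2.0 * math.sqrt(area / math.pi)
        perim = float(props["perimeter"][i]) * side
        if perim > 0:
            roundness = min(1.0, 4.0 * math.pi * area / perim**2)
        else:  # single pixel / degenerate contour: treat as perfectly round
            roundness = 1.0
        out.append(
            DetectedObject(
                object_id=int(props["label"][i]),
                pixel_count=npx,
                area_um2=float(area),
                equivalent_diameter_um=float(eqd),
                roundness=float(max(0.0, roundness)),
                perimeter_um=perim,
                centroid_x_um=(float(props["centroid-1"][i]) + 0.5) * side,
                centroid_y_um=(float(props["centroid-0"][i]) + 0.5) * side,
                mean_intensity=float(props["intensity_mean"][i]),
                peak_intensity=float(props["intensity_max"][i]),
                source_frame=frame.frame_id,
            )
        )
    return out


def filter_objects(
    objects: Iterable[DetectedObject], profile: CountingProfile
) -> list[DetectedObject]:
    """Apply the diameter and roundness gates (inclusive bounds)."""
    return [
        o
        for o in objects
        if profile.diameter_min_um
        <= o.equivalent_diameter_um
        <= profile.diameter_max_um
        and o.roundness >= profile.roundness_min
    ]


def detect_frame(
    frame: ImageFrame,
    profile: CountingProfile,
    optics: OpticsConfig | None = None,
    *,
    filtered: bool = True,
) -> list[DetectedObject]:
    """Full single-frame pipeline: threshold, label, decluster, measure, filter."""
    mask = threshold_mask(frame, profile)
    lab, n = _label_image(mask)
    child_lab, _ = _decluster_labels(mask & (lab > 0), lab, n, profile.decluster_factor)
    objs = measure(child_lab, frame, optics)
    return filter_objects(objs, profile) if filtered else objs
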