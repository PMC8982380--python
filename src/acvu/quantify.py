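"""Nucleus segmentation and per-nucleus GFP quantification.

Nuclei are segmented from the mCherry (nuclear histone marker) channel and
GFP is then integrated per nucleus by one of two methods:

``sumproj_bgcorr`` (method A)
    Sum z-projection over the slices the nucleus occupies; GFP integrated
    intensity inside the planar segmentation boundary, minus the GFP
    integrated intensity of a region of identical planar dimensions placed
    outside the animal, over the same slices.

``top5`` (method B)
    The five z-slices of the nucleus with the highest per-slice integrated
    mCherry are selected and the GFP integrated intensity inside the
    boundary on exactly those slices is summed.  No background correction
    is applied, which makes the method simple and monotone but insensitive
    to dim signals.

Because selection is separable (the GFP sum over a set of slices is the sum
of per-slice contributions and slices are ranked by an independent key),
the top-5-by-slice rule attains the brute-force optimum over all 5-subsets
of slices ranked by mCherry sum.

Segmentation quality control mirrors manual-curation practice: nuclei may
be rejected because two nuclei merged into one object, one nucleus
fragmented into several objects, or the marker signal was too dim to
segment against background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .synth import ImageStack, NucleusTruth

# QC flag vocabulary
FLAG_MERGED = "merged-nuclei"
FLAG_FRAGMENTED = "fragmented-nuclei"
FLAG_DIM = "dim-marker"
FLAG_SHORT_SPAN = "short-span"
FLAG_NEGATIVE = "negative-value"

METHOD_A = "sumproj_bgcorr"
METHOD_B = "top5"


@dataclass
class SegmentedNucleus:
    """One connected labelled region recovered from the mCherry channel."""

    label: int
    voxels: np.ndarray  # boolean (z, y, x) support
    centroid: tuple[float, float, float]  # (x, y, z)
    per_slice_mcherry: list  # [(z, integrated mCherry AU)] for occupied slices

    @property
    def z_slices(self) -> list[int]:
        return [z for z, _ in self.per_slice_mcherry]

    @property
    def boundary_2d(self) -> np.ndarray:
        """Planar footprint: union of the per-slice regions."""
        return self.voxels.any(axis=0)

    @property
    def volume(self) -> int:
        return int(self.voxels.sum())


@dataclass
class CellMeasurement:
    """One cell's GFP value with its role label and QC status."""

    animal_id: str
    label: int
    gfp_value: float
    method: str
    role: str = "unknown"
    excluded: bool = False
    exclusion_reason: str = ""
    centroid: tuple[float, float, float] | None = None
    truth_cell_id: str | None = None
    cell_class: str | None = None  # "alpha" | "beta" when known
    n_slices: int = 0
    z_used: tuple = ()
    flags: tuple = ()

    def __post_init__(self):
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded measurements must carry an exclusion_reason")
        if not math.isfinite(self.gfp_value):
            raise ValueError("gfp_value must be finite")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _robust_sigma(arr: np.ndarray) -> float:
    med = np.median(arr)
    return 1.4826 * float(np.median(np.abs(arr - med)))


def _extract(labels: np.ndarray, mcherry: np.ndarray) -> list[SegmentedNucleus]:
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        support = labels == lab
        zc, yc, xc = ndimage.center_of_mass(support)
        per_slice = []
        for z in np.nonzero(support.any(axis=(1, 2)))[0]:
            per_slice.append((int(z), float(mcherry[z][support[z]].sum())))
        out.append(
            SegmentedNucleus(
                label=int(lab),
                voxels=support,
                centroid=(float(xc), float(yc), float(zc)),
                per_slice_mcherry=per_slice,
            )
        )
    return out


def segment_nuclei(
    stack: ImageStack,
    expected_n: int = 4,
    smooth_sigma: float = 1.0,
    min_size: int = 10,
    split_factor: float = 1.8,
    isophote_fraction: float = 0.35,
) -> tuple[list[SegmentedNucleus], list[str]]:
    """Segment nuclei from the mCherry channel; return nuclei and QC flags.

    Gaussian-smoothed mCherry is thresholded (Otsu, floored at a robust
    background cutoff since nuclei occupy a tiny voxel fraction), connected
    components are labelled in 3-D (26-connectivity), and components whose
    volume exceeds ``split_factor`` x the median component volume are split
    by marker-based watershed.  Each component is then refined to the
    voxels above ``isophote_fraction`` of its own smoothed peak, so the
    boundary size is normalised across marker-brightness differences (a
    global threshold would give bright nuclei systematically larger
    boundaries, coupling the uncorrected background contribution to marker
    level).  Flags raised: ``merged-nuclei`` when an oversized component
    resists splitting, ``fragmented-nuclei`` when more components than
    expected survive, ``dim-marker`` when fewer than expected are found
    against a weak marker signal.
    """
    mch = stack.mcherry
    flags: list[str] = []
    if mch.max() <= 0:
        return [], [FLAG_DIM]

    smoothed = ndimage.gaussian_filter(mch, smooth_sigma)
    med = float(np.median(smoothed))
    sig = _robust_sigma(smoothed)
    floor = med + 6.0 * sig
    try:
        thr = max(float(threshold_otsu(smoothed)), floor)
    except ValueError:  # constant image
        return [], [FLAG_DIM]
    if smoothed.max() <= floor:
        return [], [FLAG_DIM]

    binary = smoothed > thr
    labels, _ = ndimage.label(binary, structure=_STRUCT_26)
    sizes = np.bincount(labels.ravel())
    for lab in np.nonzero(sizes < min_size)[0]:
        labels[labels == lab] = 0
    labels, n = ndimage.label(labels > 0, structure=_STRUCT_26)
    if n == 0:
        return [], [FLAG_DIM]

    # split components that look like two touching nuclei
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    median_vol = float(np.median(sizes))
    merged = False
    for lab, vol in enumerate(sizes, start=1):
        if vol > split_factor * median_vol:
            comp = labels == lab
            split = _watershed_split(smoothed, comp, smooth_sigma)
            if split is None:
                merged = True
            else:
                labels[comp] = 0
                labels[split > 0] = split[split > 0] + labels.max()
    labels, n = ndimage.label(labels > 0, structure=_STRUCT_26)

    if merged:
        flags.append(FLAG_MERGED)
    if n > expected_n:
        flags.append(FLAG_FRAGMENTED)
    elif n < expected_n:
        flags.append(FLAG_DIM)

    if isophote_fraction > 0:
        labels = _refine_isophote(smoothed, labels, n, floor, isophote_fraction)
    return _extract(labels, mch), flags


def _refine_isophote(smoothed, labels, n, floor, fraction):
    """Redraw each nucleus boundary at ``fraction`` of its own smoothed peak.

    The detection threshold tracks the global intensity mix, so detected
    components are larger for bright nuclei and smaller for dim ones; a
    per-nucleus isophote decouples boundary size from marker brightness.
    Above-floor voxels are first partitioned among nuclei by watershed so a
    dim nucleus can extend beyond its detected component without invading a
    neighbour."""
    territory = watershed(-smoothed, labels, mask=smoothed > floor)
    refined = np.zeros_like(labels)
    for lab in range(1, n + 1):
        terr = territory == lab
        if not terr.any():
            continue
        peak = smoothed[terr].max()
        region = terr & (smoothed >= fraction * peak)
        sub, n_sub = ndimage.label(region, structure=_STRUCT_26)
        if n_sub > 1:  # keep the piece holding the peak; noise can nick the isophote
            peak_label = sub[terr & (smoothed == peak)].flat[0]
            region &= sub == peak_label
        refined[region] = lab
    return refined


def _watershed_split(smoothed, component, sigma):
    """Attempt to split one component at its mCherry local maxima; returns a
    label image over the component or None if only one maximum exists."""
    masked = np.where(component, smoothed, 0.0)
    # local maxima separated by at least one expected nuclear radius
    maxfilt = ndimage.maximum_filter(masked, size=5)
    peaks = (masked == maxfilt) & component & (masked > 0)
    pk_labels, n_pk = ndimage.label(peaks, structure=_STRUCT_26)
    if n_pk < 2:
        return None
    markers = np.zeros_like(pk_labels)
    for lab in range(1, n_pk + 1):
        zs, ys, xs = np.nonzero(pk_labels == lab)
        markers[zs[0], ys[0], xs[0]] = lab
    return watershed(-masked, markers, mask=component)


def match_segments_to_truth(
    segments: list[SegmentedNucleus],
    truths: list[NucleusTruth],
    max_dist: float = 3.0,
) -> dict:
    """Greedy nearest-centroid matching; returns ``{segment label: cell_id}``
    (unmatched segments absent)."""
    pairs = []
    for seg in segments:
        for t in truths:
            d = math.dist(seg.centroid, t.center)
            if d <= max_dist:
                pairs.append((d, seg.label, t.cell_id))
    pairs.sort()
    seg_used, truth_used, out = set(), set(), {}
    for d, lab, cid in pairs:
        if lab in seg_used or cid in truth_used:
            continue
        seg_used.add(lab)
        truth_used.add(cid)
        out[lab] = cid
    return out


def qc_from_truth(segments: list[SegmentedNucleus], truths: list[NucleusTruth]) -> list[str]:
    """Authoritative QC against ground truth: a segment covering two truth
    centers is merged, two segments on one truth is fragmentation, a truth
    nucleus with no covering segment is a dim-marker failure."""
    flags = []

    def covering(t):
        out = []
        x, y, z = t.center
        for seg in segments:
            zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
            nz, ny, nx = seg.voxels.shape
            if 0 <= zi < nz and 0 <= yi < ny and 0 <= xi < nx and seg.voxels[zi, yi, xi]:
                out.append(seg.label)
            elif math.dist(seg.centroid, t.center) <= t.radius:
                out.append(seg.label)
        return out

    cover_map = {t.cell_id: covering(t) for t in truths}
    by_segment: dict[int, list[str]] = {}
    for cid, labs in cover_map.items():
        for lab in labs:
            by_segment.setdefault(lab, []).append(cid)
    if any(len(cids) > 1 for cids in by_segment.values()):
        flags.append(FLAG_MERGED)
    if any(len(labs) > 1 for labs in cover_map.values()):
        flags.append(FLAG_FRAGMENTED)
    if any(len(labs) == 0 for labs in cover_map.values()):
        flags.append(FLAG_DIM)
    return flags


# ---------------------------------------------------------------------------
# background regions
# ---------------------------------------------------------------------------


def select_background_region(stack: ImageStack, footprint: np.ndarray) -> np.ndarray:
    """First raster-order placement of ``footprint`` fully outside the larva.

    ``footprint`` is a 2-D boolean planar shape (any frame size); the
    returned region is a full-frame 2-D boolean mask with the same area.
    Raises ValueError when no placement exists.
    """
    footprint = np.asarray(footprint, dtype=bool)
    ys, xs = np.nonzero(footprint)
    if ys.size == 0:
        raise ValueError("footprint is empty")
    shape_local = footprint[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = shape_local.shape
    inside_2d = stack.larva_mask.any(axis=0)
    ny, nx = inside_2d.shape
    for y0 in range(ny - h + 1):
        for x0 in range(nx - w + 1):
            window = inside_2d[y0 : y0 + h, x0 : x0 + w]
            if not np.any(window & shape_local):
                region = np.zeros((ny, nx), dtype=bool)
                region[y0 : y0 + h, x0 : x0 + w] = shape_local
                return region
    raise ValueError("no outside-larva region fits the requested shape")


@dataclass(frozen=True)
class BackgroundStats:
    """Median and dispersion of per-region background sums, from regions of a
    given planar shape placed outside the larva."""

    median: float
    dispersion: float
    n_regions: int


def estimate_background_stats(
    stack: ImageStack,
    footprint: np.ndarray,
    z_slices,
    min_regions: int = 8,
) -> BackgroundStats:
    """Tile non-overlapping copies of ``footprint`` outside the larva and
    summarise the GFP sum over ``z_slices`` in each (median + SD)."""
    footprint = np.asarray(footprint, dtype=bool)
    ys, xs = np.nonzero(footprint)
    if ys.size == 0:
        raise ValueError("footprint is empty")
    shape_local = footprint[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = shape_local.shape
    inside_2d = stack.larva_mask.any(axis=0)
    ny, nx = inside_2d.shape
    gfp_proj = stack.gfp[list(z_slices)].sum(axis=0)
    sums = []
    for y0 in range(0, ny - h + 1, h):
        for x0 in range(0, nx - w + 1, w):
            window = inside_2d[y0 : y0 + h, x0 : x0 + w]
            if not np.any(window & shape_local):
                sums.append(float(gfp_proj[y0 : y0 + h, x0 : x0 + w][shape_local].sum()))
    if len(sums) < min_regions:
        raise ValueError(
            f"only {len(sums)} outside-larva regions fit; need >= {min_regions}"
        )
    sums = np.asarray(sums)
    return BackgroundStats(
        median=float(np.median(sums)),
        dispersion=float(np.std(sums, ddof=1)),
        n_regions=len(sums),
    )


# ---------------------------------------------------------------------------
# measurement methods
# ---------------------------------------------------------------------------


def measure_sumproj_bgcorr(
    stack: ImageStack,
    nucleus: SegmentedNucleus,
    bg_region: np.ndarray,
    animal_id: str = "",
) -> CellMeasurement:
    """Method A: background-corrected integrated GFP on a per-nucleus sum
    z-projection.

    ``bg_region`` must have the same planar area as the nucleus boundary
    and lie wholly outside the larva mask.  Negative corrected values are
    retained (clamping would bias condition means) and flagged.
    """
    boundary = nucleus.boundary_2d
    bg_region = np.asarray(bg_region, dtype=bool)
    if bg_region.sum() != boundary.sum():
        raise ValueError(
            f"background region area {int(bg_region.sum())} does not match "
            f"boundary area {int(boundary.sum())}"
        )
    zs = nucleus.z_slices
    if np.any(stack.larva_mask[zs].any(axis=0) & bg_region):
        raise ValueError("background region intersects the larva mask")
    proj = stack.gfp[zs].sum(axis=0)
    value = float(proj[boundary].sum() - proj[bg_region].sum())
    flags = (FLAG_NEGATIVE,) if value < 0 else ()
    return CellMeasurement(
        animal_id=animal_id,
        label=nucleus.label,
        gfp_value=value,
        method=METHOD_A,
        centroid=nucleus.centroid,
        n_slices=len(zs),
        z_used=tuple(zs),
        flags=flags,
    )


def top5_slices(per_slice_mcherry, k: int = 5) -> list[int]:
    """Indices of the ``k`` slices with highest integrated mCherry.

    Ties break toward lower z (stable ascending-z order), so uniform
    profiles select the lowest z indices.  Returned sorted ascending.
    """
    order = sorted(per_slice_mcherry, key=lambda zm: (-zm[1], zm[0]))
    return sorted(z for z, _ in order[:k])


def measure_top5(
    stack: ImageStack,
    nucleus: SegmentedNucleus,
    animal_id: str = "",
    k: int = 5,
) -> CellMeasurement:
    """Method B: GFP summed inside the boundary over the ``k`` slices with
    highest per-slice integrated mCherry; no background correction.

    Nuclei spanning fewer than ``k`` slices use all their slices and are
    flagged ``short-span`` rather than dropped (dropping would bias
    screens against small nuclei).
    """
    selected = top5_slices(nucleus.per_slice_mcherry, k=k)
    flags = (FLAG_SHORT_SPAN,) if len(nucleus.per_slice_mcherry) < k else ()
    value = 0.0
    for z in selected:
        value += float(stack.gfp[z][nucleus.voxels[z]].sum())
    return CellMeasurement(
        animal_id=animal_id,
        label=nucleus.label,
        gfp_value=value,
        method=METHOD_B,
        centroid=nucleus.centroid,
        n_slices=len(selected),
        z_used=tuple(selected),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# per-animal pipeline helper
# ---------------------------------------------------------------------------


def measure_animal(
    stack: ImageStack,
    method: str = METHOD_B,
    expected_n: int = 4,
    truths: list[NucleusTruth] | None = None,
    animal_id: str = "",
) -> tuple[list[CellMeasurement], list[str], list[SegmentedNucleus]]:
    """Segment and measure every nucleus in one stack.

    With ground truth available, segments are matched to truth nuclei by
    centroid (populating ``truth_cell_id`` and ``cell_class``) and the
    truth-based QC flags are authoritative.  Returns the measurements, the
    animal-level QC flags, and the segments themselves.
    """
    segments, flags = segment_nuclei(stack, expected_n=expected_n)
    if truths is not None:
        flags = qc_from_truth(segments, truths)
    matching = match_segments_to_truth(segments, truths) if truths else {}

    measurements = []
    bg_region = None
    for seg in segments:
        if method == METHOD_A:
            if bg_region is None or bg_region.sum() != seg.boundary_2d.sum():
                bg_region = select_background_region(stack, seg.boundary_2d)
            m = measure_sumproj_bgcorr(stack, seg, bg_region, animal_id=animal_id)
        elif method == METHOD_B:
            m = measure_top5(stack, seg, animal_id=animal_id)
        else:
            raise ValueError(f"unknown method {method!r}")
        cid = matching.get(seg.label)
        m.truth_cell_id = cid
        if cid is not None:
            m.cell_class = "alpha" if cid.startswith("alpha") else "beta"
        measurements.append(m)
    return measurements, flags, segments
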