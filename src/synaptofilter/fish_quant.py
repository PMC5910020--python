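"""Per-cell FISH puncta quantification.

Pipeline: combine adjacent z-slices (maximum-intensity projection by
default), threshold each channel to remove background, segment somata from
the marker channel by seeded watershed, detect diffraction-limited puncta
as local maxima at the punctum scale, count puncta within established cell
boundaries, classify each cell by a strict puncta-count cutoff
(positive when count > cutoff), and tabulate co-expression with explicit
denominators.  Cells that span two z-groups are deduplicated by centroid
proximity, summing their per-group counts (each punctum lives in exactly
one disjoint group, so the sum is exact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core_io import (
    AnalysisConfig,
    ConfigurationError,
    ImageStack,
    ValidationError,
)


# ---------------------------------------------------------------------------
# z-combining and thresholding
# ---------------------------------------------------------------------------

def combine_z(
    stack: ImageStack, group_size: int = 3, mode: str = "max"
) -> list[dict[str, np.ndarray]]:
    """Combine adjacent z-slices into 2D frames, one frame set per group.

    Groups are disjoint runs of ``group_size`` adjacent slices (the final
    group may be shorter).  ``mode`` is ``max`` (maximum-intensity
    projection, the default: preserves punctum peak intensity) or ``sum``.
    Returns, per group, a dict mapping each declared channel role to its 2D
    image.
    """
    if group_size < 1:
        raise ValidationError("group_size must be >= 1")
    if group_size > stack.n_z:
        raise ValidationError(
            f"group_size {group_size} exceeds stack depth {stack.n_z}"
        )
    if mode not in ("max", "sum"):
        raise ValidationError("mode must be 'max' or 'sum'")
    reducer = np.max if mode == "max" else np.sum
    groups = []
    for z0 in range(0, stack.n_z, group_size):
        frame = {
            role: reducer(stack.channel(role)[z0 : z0 + group_size], axis=0)
            for role in stack.channel_roles
        }
        groups.append(frame)
    return groups


@dataclass(frozen=True)
class ThresholdResult:
    """A background-suppressed image and the threshold applied to it."""

    image: np.ndarray
    threshold: float
    fallback: bool = False  # Otsu degenerate; fixed floor used instead


def threshold_channel(
    image: np.ndarray, method: str = "otsu", value: float = 0.0
) -> ThresholdResult:
    """Zero sub-threshold intensities; record the threshold used.

    ``method='otsu'`` falls back to the fixed floor ``value`` (flagged) when
    the image is constant and Otsu is undefined.
    """
    image = np.asarray(image, dtype=np.float64)
    fallback = False
    if method == "fixed":
        thr = float(value)
    elif method == "otsu":
        if np.ptp(image) == 0:
            thr, fallback = float(value), True
        else:
            thr = float(threshold_otsu(image))
    else:
        raise ValidationError("threshold method must be 'fixed' or 'otsu'")
    out = np.where(image > thr, image, 0.0)
    return ThresholdResult(image=out, threshold=thr, fallback=fallback)


# ---------------------------------------------------------------------------
# segmentation and puncta detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSegment:
    """One segmented soma."""

    label: int
    centroid: tuple[float, float]  # (y, x)
    area: float  # px^2


def _dedupe_seeds(coords: np.ndarray, min_distance: float) -> np.ndarray:
    """Greedy suppression of seed points closer than ``min_distance``."""
    kept: list[np.ndarray] = []
    for c in coords:
        if all(np.hypot(*(c - k)) >= min_distance for k in kept):
            kept.append(c)
    return np.array(kept).reshape(-1, 2)


def segment_cells(
    marker_image: np.ndarray, config: AnalysisConfig | None = None
) -> tuple[np.ndarray, list[CellSegment]]:
    """Watershed segmentation of somata from a thresholded marker image.

    Seeds are local maxima of the smoothed marker intensity separated by at
    least the expected soma diameter; the watershed runs on the inverted
    smoothed intensity constrained to the thresholded foreground.  Segments
    below the minimum area are discarded.  Returns the label image and the
    retained segments (an empty result is allowed).
    """
    config = config or AnalysisConfig()
    marker_image = np.asarray(marker_image, dtype=np.float64)
    mask = marker_image > 0
    if not mask.any():
        return np.zeros(marker_image.shape, dtype=np.int32), []
    smoothed = gaussian(marker_image, sigma=config.segment_smooth_sigma_px,
                        preserve_range=True)
    coords = peak_local_max(
        smoothed,
        min_distance=config.seed_min_distance_px,
        labels=mask,
        exclude_border=False,
    )
    coords = _dedupe_seeds(coords, config.seed_min_distance_px)
    markers = np.zeros(marker_image.shape, dtype=np.int32)
    for i, (y, x) in enumerate(coords, start=1):
        markers[int(y), int(x)] = i
    labels = watershed(-smoothed, markers, mask=mask)
    segments = []
    for rp in regionprops(labels):
        if rp.area < config.min_cell_area_px2:
            labels[labels == rp.label] = 0
            continue
        segments.append(
            CellSegment(label=int(rp.label),
                        centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                        area=float(rp.area))
        )
    return labels, segments


def detect_puncta(
    image: np.ndarray,
    config: AnalysisConfig | None = None,
    spot_sigma_px: float = 1.0,
    k: float = 4.5,
) -> np.ndarray:
    """Detect diffraction-limited puncta as (y, x) coordinates.

    The image (already background-thresholded) is smoothed at the punctum
    scale; puncta are local maxima exceeding a robust floor of
    ``median + k x MAD-scaled SD`` of the smoothed image, then greedily
    suppressed so surviving peaks are separated by at least
    ``config.puncta_min_separation_px`` in Euclidean distance (brightest
    kept).  On a noiseless thresholded image the floor collapses to zero
    and every placed spot is a detection.
    """
    config = config or AnalysisConfig()
    image = np.asarray(image, dtype=np.float64)
    if not (image > 0).any():
        return np.empty((0, 2))
    smoothed = gaussian(image, sigma=spot_sigma_px, preserve_range=True)
    med = float(np.median(smoothed))
    noise = 1.4826 * float(np.median(np.abs(smoothed - med)))
    floor = med + k * noise if noise > 0 else 1e-9
    coords = peak_local_max(
        smoothed, min_distance=1, threshold_abs=floor, exclude_border=False
    )
    if coords.size == 0:
        return np.empty((0, 2))
    # Euclidean minimum-separation suppression, brightest first
    order = np.argsort(smoothed[coords[:, 0], coords[:, 1]])[::-1]
    kept: list[np.ndarray] = []
    min_sep = float(config.puncta_min_separation_px)
    for c in coords[order]:
        if all(np.hypot(*(c - p)) >= min_sep for p in kept):
            kept.append(c)
    return np.array(kept, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# counting, classification, co-expression
# ---------------------------------------------------------------------------

def count_per_cell(
    labels: np.ndarray,
    coords_per_channel: Mapping[str, np.ndarray],
    segments: Sequence[CellSegment],
) -> pd.DataFrame:
    """Assign each punctum to the segment containing its rounded coordinate.

    Puncta outside every mask are uncounted.  Returns one row per segment
    with ``count_<channel>`` columns.
    """
    rows = {
        seg.label: {
            "label": seg.label,
            "y": seg.centroid[0],
            "x": seg.centroid[1],
            "area_px2": seg.area,
        }
        for seg in segments
    }
    for channel, coords in coords_per_channel.items():
        col = f"count_{channel}"
        for r in rows.values():
            r[col] = 0
        for y, x in np.asarray(coords).reshape(-1, 2):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < labels.shape[0] and 0 <= ix < labels.shape[1]:
                lab = int(labels[iy, ix])
                if lab in rows:
                    rows[lab][col] += 1
    return pd.DataFrame(list(rows.values()))


def classify_cells(
    counts: pd.DataFrame, cutoffs: Mapping[str, float]
) -> pd.DataFrame:
    """Flag cells positive per channel when count > cutoff (strict).

    The strict inequality matches the published convention (a cell is
    positive for a transcript when it contains more than the cutoff number
    of puncta, e.g. >10).
    """
    out = counts.copy()
    for channel, cutoff in cutoffs.items():
        col = f"count_{channel}"
        if col not in out.columns:
            continue
        out[f"flag_{channel}"] = out[col] > cutoff
    for col in counts.columns:
        if col.startswith("count_"):
            channel = col[len("count_"):]
            if channel not in cutoffs:
                raise ConfigurationError(
                    f"no classification cutoff configured for channel "
                    f"{channel!r}"
                )
    return out


@dataclass(frozen=True)
class CalibrationResult:
    """Cutoff maximizing agreement with manual labels."""

    threshold: int
    accuracy: float
    separable: bool  # accuracy == 1 at the returned threshold


def calibrate_threshold(
    counts: Sequence[int], manual_labels: Sequence[bool]
) -> CalibrationResult:
    """Integer cutoff maximizing agreement with manual positive/negative calls.

    Exhaustive scan over the observed count range, classifying positive when
    ``count > t``; ties broken toward the smallest threshold.  When no
    threshold separates the classes the best one is returned with its
    (sub-unity) accuracy.
    """
    counts = np.asarray(counts, dtype=int)
    labels = np.asarray(manual_labels, dtype=bool)
    if counts.size == 0 or counts.size != labels.size:
        raise ValidationError("counts and labels must be equal-length, non-empty")
    if labels.all() or (~labels).all():
        raise ValidationError("need at least one labeled cell per class")
    best_t, best_acc = int(counts.min()) - 1, -1.0
    for t in range(int(counts.min()) - 1, int(counts.max()) + 1):
        acc = float(np.mean((counts > t) == labels))
        if acc > best_acc:
            best_t, best_acc = t, acc
    return CalibrationResult(
        threshold=best_t, accuracy=best_acc, separable=best_acc == 1.0
    )


@dataclass(frozen=True)
class CoexpressionTable:
    """Joint-class counts with explicit-denominator proportions."""

    joint_counts: dict[str, int]
    n_cells: int

    def proportion(
        self, numerator: Sequence[str], denominator: Sequence[str]
    ) -> float | None:
        """Fraction of denominator-positive cells that are numerator-positive.

        Returns ``None`` (flagged absent) when the denominator is empty.
        """
        num = self.joint_counts[_combo_key(numerator)]
        den = self.joint_counts[_combo_key(denominator)]
        if den == 0:
            return None
        if num > den and set(denominator) <= set(numerator):
            raise ValidationError("joint count exceeds its marginal")
        return num / den


def _combo_key(channels: Sequence[str]) -> str:
    return "+".join(sorted(channels))


def coexpression_table(flags: pd.DataFrame) -> CoexpressionTable:
    """Joint positive-class counts over every combination of flag columns.

    ``flags`` holds one boolean column per channel (``flag_`` prefixes are
    stripped).  Each key in the result is a sorted ``a+b`` combination and
    its value the number of cells positive for all channels in it.
    """
    cols = [c for c in flags.columns if flags[c].dtype == bool]
    if len(cols) < 2:
        raise ValidationError("co-expression requires flags for >= 2 channels")
    clean = {c: c.removeprefix("flag_") for c in cols}
    joint: dict[str, int] = {}
    from itertools import combinations

    for k in range(1, len(cols) + 1):
        for combo in combinations(cols, k):
            key = _combo_key([clean[c] for c in combo])
            mask = np.logical_and.reduce([flags[c].to_numpy() for c in combo])
            joint[key] = int(mask.sum())
    return CoexpressionTable(joint_counts=joint, n_cells=len(flags))


# ---------------------------------------------------------------------------
# end-to-end stack quantification
# ---------------------------------------------------------------------------

def quantify_stack(
    stack: ImageStack, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Run the full pipeline on one stack.

    Combine z-groups, threshold every channel, segment somata per group,
    detect and count puncta per group, then merge cells that appear in more
    than one group (centroids closer than ``config.dedup_centroid_px``),
    summing their counts.  Returns one row per unique cell with counts and
    classification flags for each non-marker channel.
    """
    config = config or AnalysisConfig()
    groups = combine_z(stack, config.z_group_size, config.z_project)
    punct_channels = [r for r in stack.channel_roles if r != "marker"]

    per_group: list[pd.DataFrame] = []
    for frame in groups:
        marker = threshold_channel(
            frame["marker"], config.threshold_method, config.threshold_value
        ).image
        labels, segments = segment_cells(marker, config)
        coords = {}
        for ch in punct_channels:
            img = threshold_channel(
                frame[ch], config.threshold_method, config.threshold_value
            ).image
            coords[ch] = detect_puncta(img, config)
        per_group.append(count_per_cell(labels, coords, segments))

    merged: list[dict] = []
    for df in per_group:
        for _, row in df.iterrows():
            match = None
            for m in merged:
                if np.hypot(m["y"] - row["y"], m["x"] - row["x"]) < config.dedup_centroid_px:
                    match = m
                    break
            if match is None:
                merged.append(row.to_dict())
            else:
                for ch in punct_channels:
                    match[f"count_{ch}"] += row[f"count_{ch}"]
                match["area_px2"] = max(match["area_px2"], row["area_px2"])
    cells = pd.DataFrame(merged)
    if cells.empty:
        return cells
    cells = cells.drop(columns=["label"]).reset_index(drop=True)
    cells.insert(0, "cell", cells.index)
    cutoffs = {ch: config.class_cutoffs[ch]
               for ch in punct_channels if ch in config.class_cutoffs}
    return classify_cells(cells, cutoffs)
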