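"""OCT B-scan quantification of biofilm dissolution and disruption.

A B-scan is a 2-D greyscale cross-section of a biofilm sitting on a
substrate. Multilevel (3-class) Otsu thresholding of the region above the
substrate separates background from two biofilm strata: a low-intensity
"disrupted" layer and a high-intensity "coherent" layer. Per-column pixel
counts of each stratum, scaled by the pixel pitch, give layer thickness
profiles; comparing the pre- and post-treatment mean thicknesses gives the
two outcome measures:

- dissolution: per cent reduction of the coherent layer,
- disruption: per cent increase of the disrupted layer, normalized by the
  pre-treatment total (coherent + disrupted) thickness.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BScan",
    "LayerMask",
    "HeightProfile",
    "BiofilmChangeMetrics",
    "multilevel_otsu",
    "segment_layers",
    "column_heights",
    "dissolution_pct",
    "disruption_pct",
    "analyze_pair",
    "DegenerateHistogramError",
]

BACKGROUND, DISRUPTED, COHERENT = 0, 1, 2

#: Maximum number of histogram bins used when segmenting images with many
#: distinct grey levels (16-bit scans are re-binned to this resolution).
MAX_HISTOGRAM_BINS = 256


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has too few occupied levels to threshold."""


@dataclass(frozen=True)
class BScan:
    """A 2-D OCT cross-section with physical metadata.

    Row 0 is the top of the image; rows increase downward. The biofilm
    occupies rows strictly above ``substrate_row``. ``pixel_pitch_um`` is
    assumed already corrected for the acquisition refraction index
    (default 1.33), which is carried as metadata only.
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    substrate_row: int
    refraction_index: float = 1.33

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if not (0 <= self.substrate_row <= px.shape[0]):
            raise ValueError(
                f"substrate_row {self.substrate_row} outside image with "
                f"{px.shape[0]} rows"
            )
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class LayerMask:
    """Per-pixel stratum labels (0 background, 1 disrupted, 2 coherent)."""

    labels: np.ndarray
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        object.__setattr__(self, "labels", lab)


@dataclass(frozen=True)
class HeightProfile:
    """Per-column coherent and disrupted layer thicknesses in micrometres."""

    coherent_um: np.ndarray
    disrupted_um: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coherent_um, dtype=float)
        d = np.asarray(self.disrupted_um, dtype=float)
        if c.shape != d.shape or c.ndim != 1:
            raise ValueError("coherent_um and disrupted_um must be equal-length 1-D")
        if np.any(c < 0) or np.any(d < 0):
            raise ValueError("layer thicknesses must be non-negative")
        object.__setattr__(self, "coherent_um", c)
        object.__setattr__(self, "disrupted_um", d)

    @property
    def n_columns(self) -> int:
        return self.coherent_um.size

    @property
    def mean_coherent_um(self) -> float:
        return float(self.coherent_um.mean())

    @property
    def mean_disrupted_um(self) -> float:
        return float(self.disrupted_um.mean())


@dataclass(frozen=True)
class BiofilmChangeMetrics:
    """The two outcome measures of a pre/post scan pair."""

    dissolution_pct: float
    disruption_pct: float


def _as_histogram(histogram) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a histogram argument to sorted (levels, counts) arrays."""
    if isinstance(histogram, Mapping):
        levels = np.asarray(sorted(histogram), dtype=float)
        counts = np.asarray([histogram[k] for k in sorted(histogram)], dtype=float)
    else:
        levels, counts = histogram
        levels = np.asarray(levels, dtype=float)
        counts = np.asarray(counts, dtype=float)
        order = np.argsort(levels, kind="stable")
        levels, counts = levels[order], counts[order]
    if levels.size != counts.size:
        raise ValueError("levels and counts must have equal length")
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    return levels, counts


def multilevel_otsu(histogram, n_classes: int = 3) -> tuple[float, ...]:
    """Optimal ordered thresholds maximizing between-class variance.

    ``histogram`` is an intensity-count table: a mapping ``{level: count}``
    or a ``(levels, counts)`` pair. With thresholds ``t1 < t2 < ...`` class
    ``k`` contains the levels in ``(t_k, t_{k+1}]`` (lowest class:
    ``level <= t1``; highest: ``level > t_last``). The search is exhaustive
    over all ordered tuples of occupied levels, which is equivalent to an
    exhaustive search over the full grey range because shrinking a threshold
    down to the largest level of its lower class never changes the
    partition; ties are broken by the lexicographically smallest tuple.

    Returns ``n_classes - 1`` threshold values.

    Raises
    ------
    DegenerateHistogramError
        If fewer than ``n_classes`` distinct occupied levels exist.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    levels, counts = _as_histogram(histogram)
    occ = counts > 0
    levels, counts = levels[occ], counts[occ]
    n_levels = levels.size
    if n_levels < n_classes:
        raise DegenerateHistogramError(
            f"histogram has {n_levels} distinct occupied level(s); "
            f"{n_classes} classes need at least {n_classes} "
            f"(deficit {n_classes - n_levels})"
        )

    w = counts.astype(float)
    s = w * levels
    cw = np.cumsum(w)
    cs = np.cumsum(s)

    def _crit_term(w_k: np.ndarray, s_k: np.ndarray) -> np.ndarray:
        # sum_k w_k * mu_k^2 == sum_k s_k^2 / w_k (maximizing this maximizes
        # between-class variance for a fixed total mean)
        return s_k * s_k / w_k

    if n_classes == 2:
        i = np.arange(n_levels - 1)
        crit = _crit_term(cw[i], cs[i]) + _crit_term(cw[-1] - cw[i], cs[-1] - cs[i])
        best = int(np.argmax(crit))
        return (float(levels[best]),)

    if n_classes == 3:
        # candidates i < j over occupied levels, excluding the last level so
        # the top class is non-empty
        i = np.arange(n_levels - 1)[:, None]
        j = np.arange(n_levels - 1)[None, :]
        w0, s0 = cw[i], cs[i]
        w1, s1 = cw[j] - cw[i], cs[j] - cs[i]
        w2, s2 = cw[-1] - cw[j], cs[-1] - cs[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            crit = _crit_term(w0, s0) + _crit_term(w1, s1) + _crit_term(w2, s2)
        crit = np.where(j > i, crit, -np.inf)
        flat = int(np.argmax(crit))  # row-major argmax == lexicographic tie-break
        bi, bj = divmod(flat, n_levels - 1)
        return (float(levels[bi]), float(levels[bj]))

    # general (rarely used) path: explicit combinations
    best_crit, best_tuple = -np.inf, None
    for combo in itertools.combinations(range(n_levels - 1), n_classes - 1):
        edges = (-1, *combo, n_levels - 1)
        crit = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            w_k = cw[hi] - (cw[lo] if lo >= 0 else 0.0)
            s_k = cs[hi] - (cs[lo] if lo >= 0 else 0.0)
            if w_k > 0:
                crit += s_k * s_k / w_k
        if crit > best_crit:
            best_crit, best_tuple = crit, combo
    return tuple(float(levels[k]) for k in best_tuple)


def _scan_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of scan intensities, re-binned when too many levels."""
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size <= MAX_HISTOGRAM_BINS:
        return uniq.astype(float), counts.astype(float)
    hist, edges = np.histogram(values, bins=MAX_HISTOGRAM_BINS)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist.astype(float)


def _classify(scan: BScan, thresholds: tuple[float, float]) -> np.ndarray:
    t1, t2 = thresholds
    px = scan.pixels
    labels = np.zeros(px.shape, dtype=np.uint8)
    labels[px > t1] = DISRUPTED
    labels[px > t2] = COHERENT
    labels[scan.substrate_row:, :] = BACKGROUND
    return labels


def segment_layers(scan: BScan, thresholds: tuple[float, float] | None = None,
                   min_signal_levels: int = 3) -> LayerMask:
    """Label each pixel above the substrate as background/disrupted/coherent.

    Thresholds default to 3-class :func:`multilevel_otsu` on the histogram of
    the rows above ``substrate_row``; pass ``thresholds`` explicitly to use a
    shared threshold pair (e.g. from a pooled pre+post histogram). Rows at or
    below the substrate are always background.

    A scan whose above-substrate region holds fewer than ``min_signal_levels``
    distinct grey levels is treated as signal-free: an all-background mask is
    returned with a warning rather than an error.
    """
    region = scan.pixels[: scan.substrate_row, :]
    if thresholds is None:
        hist = _scan_histogram(region)
        try:
            thresholds = multilevel_otsu(hist, n_classes=3)
        except DegenerateHistogramError:
            if np.unique(region).size < min_signal_levels:
                warnings.warn(
                    "scan has too few grey levels above the substrate; "
                    "returning an all-background mask",
                    stacklevel=2,
                )
                labels = np.zeros(scan.pixels.shape, dtype=np.uint8)
                hi = float(region.max()) if region.size else 0.0
                return LayerMask(labels=labels, thresholds=(hi, hi))
            raise
    return LayerMask(labels=_classify(scan, thresholds), thresholds=tuple(thresholds))


def column_heights(mask: LayerMask, scan: BScan) -> HeightProfile:
    """Per-column layer thicknesses from pixel counts.

    Thickness is the count of same-label pixels above the substrate times
    the pixel pitch (hole-insensitive counting convention, not the distance
    from substrate to the topmost class pixel).
    """
    if mask.labels.shape != scan.pixels.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} != scan shape {scan.pixels.shape}"
        )
    above = mask.labels[: scan.substrate_row, :]
    coh = (above == COHERENT).sum(axis=0) * scan.pixel_pitch_um
    dis = (above == DISRUPTED).sum(axis=0) * scan.pixel_pitch_um
    return HeightProfile(coherent_um=coh, disrupted_um=dis)


def dissolution_pct(pre: HeightProfile, post: HeightProfile) -> float:
    """Per cent reduction of the mean coherent-layer thickness.

    ``100 * (mean_pre - mean_post) / mean_pre``; negative values indicate
    swelling. Raises if the pre-treatment coherent layer has zero mean
    thickness (the ratio is undefined).
    """
    pre_mean = pre.mean_coherent_um
    if pre_mean <= 0:
        raise ZeroDivisionError(
            "pre-treatment coherent layer has zero mean thickness; "
            "dissolution is undefined"
        )
    return 100.0 * (pre_mean - post.mean_coherent_um) / pre_mean


def disruption_pct(pre: HeightProfile, post: HeightProfile) -> float:
    """Per cent increase of the mean disrupted-layer thickness.

    Normalized by the pre-treatment TOTAL (coherent + disrupted) mean
    thickness so the metric stays bounded when the pre-treatment disrupted
    layer is near zero.
    """
    pre_total = pre.mean_coherent_um + pre.mean_disrupted_um
    if pre_total <= 0:
        raise ZeroDivisionError(
            "pre-treatment total thickness is zero; disruption is undefined"
        )
    return 100.0 * (post.mean_disrupted_um - pre.mean_disrupted_um) / pre_total


def analyze_pair(pre: BScan, post: BScan,
                 shared_thresholds: bool = True) -> BiofilmChangeMetrics:
    """Run the full chain on a pre/post scan pair.

    With ``shared_thresholds=True`` (default) one threshold pair is computed
    from the pooled pre+post above-substrate histogram and applied to both
    scans, so the stratum definitions are commensurable even when a stratum
    vanishes entirely in the post scan. ``shared_thresholds=False`` thresholds
    each image independently (per-image ImageJ-style practice).
    """
    if shared_thresholds:
        pooled = np.concatenate([
            pre.pixels[: pre.substrate_row, :].ravel(),
            post.pixels[: post.substrate_row, :].ravel(),
        ])
        thr = multilevel_otsu(_scan_histogram(pooled), n_classes=3)
        pre_mask = segment_layers(pre, thresholds=thr)
        post_mask = segment_layers(post, thresholds=thr)
    else:
        pre_mask = segment_layers(pre)
        post_mask = segment_layers(post)
    pre_h = column_heights(pre_mask, pre)
    post_h = column_heights(post_mask, post)
    return BiofilmChangeMetrics(
        dissolution_pct=dissolution_pct(pre_h, post_h),
        disruption_pct=disruption_pct(pre_h, post_h),
    )
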