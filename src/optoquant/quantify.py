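"""Volumetric quantification of GFP-normalized effector signal.

Implements the per-sample measurement chain: thresholded 3D region masks
(nuclear/DAPI, reporter/GFP, and their intersection), voxelwise division
of the effector channel by the reporter channel, the six region-median
statistics, maximum-intensity projections, automatable QC gates, and the
spatial ROI-overlap readout.

Mask membership uses a strict inequality (intensity > threshold).
Division-by-zero voxels are marked undefined (NaN) and excluded from all
downstream medians rather than clamped with an epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ChannelVolume, SampleMeta

__all__ = [
    "RegionMask",
    "QCConfig",
    "QCResult",
    "QuantRecord",
    "make_region_mask",
    "auto_threshold",
    "intersect_masks",
    "normalize_effector",
    "region_medians",
    "max_projection",
    "embryo_extent",
    "qc_check",
    "roi_overlap",
    "quantify_sample",
    "REGION_RULE",
]

#: Per-pathway region-selection rule: which normalized median feeds
#: downstream analysis (nuclear effectors use the DAPI∩GFP region).
REGION_RULE = {"FGF": "norm_gfp", "BMP": "norm_gfp", "Nodal": "norm_dapi_gfp"}


@dataclass
class RegionMask:
    """Boolean 3D mask of a named region, tied to its source threshold."""

    voxels: np.ndarray
    region_name: Literal["DAPI", "GFP", "DAPI_GFP"]
    source_threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class QCConfig:
    """Thresholds for the automatable QC gates.

    ``min_gfp_coverage``: minimum fraction of the embryo extent covered
    by the GFP mask (samples below are excluded as under-injected).
    ``max_saturated_fraction``: per-channel saturated-voxel fraction
    above which saturation streaking is flagged (heuristic stand-in for
    the visual criterion).  ``max_dapi_hole_fraction``: largest
    intra-embryo hole in the DAPI-positive region, as a fraction of
    embryo voxels, above which nuclear damage is flagged.
    ``background_fraction_of_otsu``: the low background threshold that
    defines the embryo extent, as a fraction of the DAPI Otsu threshold.
    """

    min_gfp_coverage: float = 0.05
    max_saturated_fraction: float = 0.01
    max_dapi_hole_fraction: float = 1.0 / 3.0
    background_fraction_of_otsu: float = 0.1


@dataclass
class QCResult:
    """QC outcome; ``passed`` iff ``reasons`` is empty."""

    reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass
class QuantRecord:
    """The six region medians plus coverage, QC outcome and metadata.

    Medians are NaN (never silent zero) when a mask is empty or all its
    normalized voxels are undefined; such cases add an ``empty_region:*``
    QC reason.
    """

    raw_dapi: float
    norm_dapi: float
    raw_gfp: float
    norm_gfp: float
    raw_dapi_gfp: float
    norm_dapi_gfp: float
    gfp_coverage: float
    qc: QCResult
    meta: SampleMeta | None = None

    def selected_value(self, tool: str | None = None) -> float:
        """The median used downstream, per the pathway region rule."""
        tool = tool or (self.meta.tool if self.meta else "FGF")
        return getattr(self, REGION_RULE.get(tool, "norm_gfp"))


def make_region_mask(
    volume: ChannelVolume,
    channel: str,
    threshold: float,
    region_name: Literal["DAPI", "GFP", "DAPI_GFP"] | None = None,
) -> RegionMask:
    """Mask of voxels with intensity strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    data = volume.channel(channel)
    name = region_name or ("DAPI" if channel == "DAPI" else "GFP")
    return RegionMask(voxels=data > threshold, region_name=name, source_threshold=threshold)


def auto_threshold(
    volume: ChannelVolume,
    channel: str,
    method: Literal["otsu", "manual"] = "otsu",
    manual_value: float | None = None,
) -> float:
    """Pick a mask threshold: Otsu's between-class-variance split, or a
    user-supplied manual value returned unchanged."""
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual thresholding requires manual_value")
        return float(manual_value)
    if method != "otsu":
        raise ValueError("method must be 'otsu' or 'manual'")
    data = np.asarray(volume.channel(channel))
    if np.all(data == data.flat[0]):
        raise ValueError(f"channel {channel!r} is constant; Otsu split undefined")
    t = threshold_otsu(data.ravel())
    # place the cut mid-gap so it lies strictly between the separated
    # populations; the induced (strict >) mask is unchanged
    lo = data[data <= t]
    hi = data[data > t]
    if lo.size and hi.size:
        return float((float(lo.max()) + float(hi.min())) / 2.0)
    return float(t)


def intersect_masks(m1: RegionMask, m2: RegionMask) -> RegionMask:
    """Voxelwise conjunction; the DAPI∩GFP region of the pipeline."""
    if m1.voxels.shape != m2.voxels.shape:
        raise ValueError(f"mask shapes differ: {m1.voxels.shape} vs {m2.voxels.shape}")
    return RegionMask(voxels=m1.voxels & m2.voxels, region_name="DAPI_GFP")


def normalize_effector(
    volume: ChannelVolume,
    effector_channel: str = "EFFECTOR",
    gfp_channel: str = "GFP",
    zero_policy: Literal["exclude"] = "exclude",
) -> np.ndarray:
    """Voxelwise effector / reporter ratio (AU/AU).

    Voxels with zero reporter intensity are undefined (NaN) and excluded
    from downstream medians.  An all-zero reporter channel triggers a
    warning and an all-NaN array.
    """
    if zero_policy != "exclude":
        raise ValueError("only zero_policy='exclude' is supported")
    eff = np.asarray(volume.channel(effector_channel), dtype=float)
    gfp = np.asarray(volume.channel(gfp_channel), dtype=float)
    out = np.full(eff.shape, np.nan)
    np.divide(eff, gfp, out=out, where=gfp > 0)
    if not np.any(gfp > 0):
        warnings.warn("reporter channel is all zero; normalized array is all-undefined")
    return out


def _masked_median(values: np.ndarray, mask: np.ndarray) -> float:
    sel = values[mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        return float("nan")
    return float(np.median(sel))


def region_medians(
    volume: ChannelVolume,
    normalized: np.ndarray,
    masks: Mapping[str, RegionMask],
    effector_channel: str = "EFFECTOR",
    gfp_coverage: float = float("nan"),
    meta: SampleMeta | None = None,
    qc: QCResult | None = None,
) -> QuantRecord:
    """Compute the six region medians (raw and GFP-normalized effector
    within DAPI, GFP, DAPI∩GFP) over defined voxels."""
    eff = np.asarray(volume.channel(effector_channel), dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape != eff.shape:
        raise ValueError("normalized array shape must match the volume")
    out: dict[str, float] = {}
    empty_reasons: list[str] = []
    for key, prefix in (("DAPI", "dapi"), ("GFP", "gfp"), ("DAPI_GFP", "dapi_gfp")):
        mask = masks[key]
        if mask.voxels.shape != eff.shape:
            raise ValueError(f"mask {key} shape mismatch")
        out[f"raw_{prefix}"] = _masked_median(eff, mask.voxels)
        out[f"norm_{prefix}"] = _masked_median(normalized, mask.voxels)
        for stat in ("raw", "norm"):
            if np.isnan(out[f"{stat}_{prefix}"]):
                empty_reasons.append(f"empty_region:{stat}_{prefix}")
    reasons = tuple(qc.reasons) if qc is not None else ()
    qc_out = QCResult(reasons=reasons + tuple(empty_reasons))
    return QuantRecord(gfp_coverage=gfp_coverage, qc=qc_out, meta=meta, **out)


def max_projection(
    volume: ChannelVolume,
    channel: str,
    mask: RegionMask | None = None,
) -> np.ndarray:
    """Maximum-intensity z-projection; an optional mask (e.g. the DAPI
    region for a nuclear projection) is applied voxelwise first."""
    data = np.asarray(volume.channel(channel), dtype=float)
    if data.shape[0] < 1:
        raise ValueError("volume has no z-slices")
    if mask is not None:
        if mask.voxels.shape != data.shape:
            raise ValueError("mask shape mismatch")
        data = np.where(mask.voxels, data, 0.0)
    return data.max(axis=0)


def embryo_extent(
    volume: ChannelVolume,
    dapi_channel: str = "DAPI",
    background_threshold: float | None = None,
    config: QCConfig | None = None,
) -> np.ndarray:
    """Embryo extent: largest connected component of the DAPI channel
    above a low background threshold (default: a fraction of the DAPI
    Otsu threshold)."""
    config = config or QCConfig()
    dapi = np.asarray(volume.channel(dapi_channel), dtype=float)
    if background_threshold is None:
        try:
            background_threshold = config.background_fraction_of_otsu * auto_threshold(
                volume, dapi_channel
            )
        except ValueError:
            background_threshold = 0.0
    above = dapi > background_threshold
    labels, n = ndimage.label(above)
    if n == 0:
        return np.zeros(dapi.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _largest_hole_fraction(extent: np.ndarray) -> float:
    """Largest DAPI-negative cavity inside the embryo extent, as a
    fraction of embryo voxels (damage shows as a dark region in DAPI)."""
    n_embryo = int(extent.sum())
    if n_embryo == 0:
        return 0.0
    interior = ndimage.binary_fill_holes(extent)
    holes = interior & ~extent
    labels, n = ndimage.label(holes)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return float(sizes.max() / n_embryo)


def qc_check(
    volume: ChannelVolume,
    masks: Mapping[str, RegionMask],
    config: QCConfig | None = None,
    meta: SampleMeta | None = None,
    extent: np.ndarray | None = None,
    saturation_value: float | None = None,
) -> tuple[QCResult, float]:
    """Run the automatable QC gates; returns (result, gfp_coverage).

    Gates: reporter coverage of the embryo extent below the 5% floor
    (under-injected sample), saturated-voxel fraction in any channel
    above the streak trigger, and a DAPI-negative hole spanning more
    than a third of the embryo (damage).  Visual criteria arrive as
    manual flags on the sample metadata and pass straight through.
    """
    config = config or QCConfig()
    if extent is None:
        extent = embryo_extent(volume, config=config)
    n_embryo = int(extent.sum())
    reasons: list[str] = []

    gfp_mask = masks["GFP"].voxels
    coverage = float((gfp_mask & extent).sum() / n_embryo) if n_embryo else 0.0
    if coverage < config.min_gfp_coverage:
        reasons.append("low_gfp_coverage")

    sat = saturation_value if saturation_value is not None else volume.max_intensity
    for i, name in enumerate(volume.channel_names):
        frac = float(np.mean(volume.voxels[i] >= sat))
        if frac > config.max_saturated_fraction:
            reasons.append("saturation_streaking")
            break

    if _largest_hole_fraction(extent) > config.max_dapi_hole_fraction:
        reasons.append("dapi_damage")

    if meta is not None and meta.manual_flags:
        reasons.append("manual_flag")

    return QCResult(reasons=tuple(reasons)), coverage


def roi_overlap(
    activation_mask: RegionMask, illuminated_mask: RegionMask
) -> dict[str, float]:
    """Overlap of an activation region A with the illuminated ROI R.

    Returns ``inside`` = |A∩R|/|A|, ``outside`` = 1 − inside and
    ``dice`` = 2|A∩R|/(|A|+|R|).  An empty activation mask is reported
    as zero overlap with a QC note rather than NaN.
    """
    a = activation_mask.voxels
    r = illuminated_mask.voxels
    if a.shape != r.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {r.shape}")
    n_a = int(a.sum())
    n_r = int(r.sum())
    n_ar = int((a & r).sum())
    if n_a == 0:
        return {"inside": 0.0, "outside": 0.0, "dice": 0.0, "empty_activation": 1.0}
    inside = n_ar / n_a
    dice = 2.0 * n_ar / (n_a + n_r) if (n_a + n_r) else 0.0
    return {"inside": inside, "outside": 1.0 - inside, "dice": dice, "empty_activation": 0.0}


def quantify_sample(
    volume: ChannelVolume,
    meta: SampleMeta | None = None,
    dapi_threshold: float | None = None,
    gfp_threshold: float | None = None,
    qc_config: QCConfig | None = None,
) -> QuantRecord:
    """One-call per-sample quantification: thresholds (Otsu by default),
    masks, normalization, QC gates and the six medians."""
    volume.require_channels(("DAPI", "GFP", "EFFECTOR"))
    if dapi_threshold is None:
        dapi_threshold = auto_threshold(volume, "DAPI")
    if gfp_threshold is None:
        gfp_threshold = auto_threshold(volume, "GFP")
    dapi_mask = make_region_mask(volume, "DAPI", dapi_threshold, "DAPI")
    gfp_mask = make_region_mask(volume, "GFP", gfp_threshold, "GFP")
    masks = {
        "DAPI": dapi_mask,
        "GFP": gfp_mask,
        "DAPI_GFP": intersect_masks(dapi_mask, gfp_mask),
    }
    qc, coverage = qc_check(volume, masks, config=qc_config, meta=meta)
    normalized = normalize_effector(volume)
    return region_medians(
        volume, normalized, masks, gfp_coverage=coverage, meta=meta, qc=qc
    )
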