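"""Template extraction, NCC template matching, Otsu binarization, centroid.

The tumor template is the GTV circumscribing cuboid cropped from the 1 mm
planning CT (raw, Sobel-filtered, or BSE-filtered).  It is slid over the
(identically filtered) search region of the MV-CBCT at every integer 1 mm
placement; the GTV mask is planted at the NCC argmax, the voxels inside it
are binarized by Otsu's method, and the tumor location is the centroid of
the binarized set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import preprocess as _pre
from .enhancement import BSEParams, bse_filter, sobel3d
from .registration import (
    SearchRegion,
    TranslationResult,
    _argmax_lex_zyx,
    build_search_region,
    map_gtv_to_cbct,
    score_map,
)
from .volumes import GTVStructure, Volume

__all__ = [
    "MODES",
    "TumorTemplate",
    "LocalizationResult",
    "extract_template",
    "match_template",
    "otsu_threshold",
    "binarize_gtv",
    "centroid",
    "localize",
]

MODES = ("none", "sobel", "bse")

#: histogram resolution for Otsu thresholding of the placed GTV intensities
OTSU_BINS = 256


@dataclass
class TumorTemplate:
    """Cropped planning-CT cuboid (optionally enhancement-filtered) + GTV mask."""

    image: np.ndarray
    gtv_mask: np.ndarray
    mode: str
    bbox: tuple[tuple[int, int, int], tuple[int, int, int]]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.image.shape != self.gtv_mask.shape:
            raise ValueError("template image and mask shapes differ")
        if not self.gtv_mask.any():
            raise ValueError("template GTV mask is empty")
        if self.mode not in MODES:
            raise ValueError(f"unknown template mode {self.mode!r}")


@dataclass
class LocalizationResult:
    """Outcome of one tumor localization in an MV-CBCT volume."""

    matched_offset: tuple[int, int, int]       # template placement in region indices
    region: SearchRegion
    placed_mask: np.ndarray                    # GTV planted at the match, CBCT grid
    binarized_mask: np.ndarray                 # Otsu foreground, subset of placed_mask
    centroid_mm: tuple[float, float, float]
    score: float
    mode: str
    warnings: list[str] = field(default_factory=list)


def _filter_support_vox(mode: str, p: BSEParams | None,
                        spacing: tuple[float, float, float]) -> int:
    """Padding (voxels) that makes the mode filter boundary-clean on a crop."""
    if mode == "sobel":
        return 1
    if mode == "bse":
        if p is None:
            raise ValueError("BSE mode requires BSEParams")
        return int(np.ceil(_pre.GAUSS_TRUNCATE * p.sigma_mm / min(spacing))) + 1
    return 0


def _apply_mode_filter(v: Volume, mode: str, p: BSEParams | None) -> Volume:
    if mode == "none":
        return v
    if mode == "sobel":
        return sobel3d(v)
    if mode == "bse":
        return bse_filter(v, p)
    raise ValueError(f"unknown mode {mode!r}")


def _filtered_crop(ct: Volume, lo, hi, mode: str, p: BSEParams | None) -> np.ndarray:
    """Filter a cuboid crop with enough padding to avoid boundary contamination."""
    pad = _filter_support_vox(mode, p, ct.spacing)
    plo = [max(0, l - pad) for l in lo]
    phi = [min(n, h + pad) for h, n in zip(hi, ct.shape)]
    sub = Volume(data=ct.data[tuple(slice(a, b) for a, b in zip(plo, phi))],
                 spacing=ct.spacing,
                 origin=tuple(o + a * s for o, a, s in zip(ct.origin, plo, ct.spacing)))
    filt = _apply_mode_filter(sub, mode, p)
    inner = tuple(slice(l - a, h - a) for l, h, a in zip(lo, hi, plo))
    return filt.data[inner]


def extract_template(ct1: Volume, g: GTVStructure, mode: str = "none",
                     p: BSEParams | None = None) -> TumorTemplate:
    """Crop the GTV circumscribing cuboid from the planning CT as a template.

    ``mode="none"`` returns raw intensities; ``"sobel"``/``"bse"`` apply the
    corresponding enhancement, computed on a crop padded by the filter
    support and then trimmed back, so the template is identical to cropping
    a whole-image filtering.  For BSE, ``p`` defaults to sigma = d/4 and
    gamma = 1 derived from the GTV.
    """
    if mode not in MODES:
        raise ValueError(f"unknown template mode {mode!r}")
    if mode == "bse" and p is None:
        p = BSEParams.from_effective_diameter(g.d)
    lo, hi = g.bbox
    if any(h > n for h, n in zip(hi, ct1.shape)):
        raise ValueError("GTV bounding box exceeds the planning CT grid")
    image = _filtered_crop(ct1, lo, hi, mode, p)
    mask = g.mask[g.bbox_slices()]
    return TumorTemplate(image=np.asarray(image, dtype=float), gtv_mask=mask,
                         mode=mode, bbox=g.bbox, spacing=ct1.spacing)


def match_template(region_image: np.ndarray, tpl: TumorTemplate) -> tuple[tuple[int, int, int], float]:
    """Exhaustive NCC placement of the template inside the region image.

    Returns the argmax offset (region indices of the template's min corner)
    and its NCC score; ties break to the smallest offset in lexicographic
    (z, y, x) order.
    """
    s = score_map(np.asarray(region_image, dtype=float), tpl.image)
    offset = _argmax_lex_zyx(s)
    return offset, float(s[offset])


def otsu_threshold(values: np.ndarray, nbins: int = OTSU_BINS) -> float:
    """Otsu's threshold of a 1D sample: the histogram cut (over ``nbins``
    equal-width bins spanning min..max) maximizing between-class variance.

    Returns the upper edge of the last background bin, so foreground is
    ``values >= threshold``.  Ties take the lowest cut.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError("constant sample has no Otsu threshold")
    counts, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m0 = np.cumsum(counts * centers)
    mtot = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)  # cut after bin i, i < nbins-1
    i = int(np.argmax(sigma_b))
    return float(edges[i + 1])


def binarize_gtv(cbct1: Volume, placed_gtv: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Otsu-binarize the MV-CBCT intensities inside the placed GTV mask.

    The histogram domain is the placed-GTV voxel set only.  Returns the
    foreground mask (subset of ``placed_gtv``) and any warnings; degenerate
    sets (constant intensities or empty foreground) fall back to the full
    mask with a warning.
    """
    placed_gtv = np.asarray(placed_gtv, dtype=bool)
    if not placed_gtv.any():
        raise ValueError("placed GTV mask is empty")
    vals = cbct1.data[placed_gtv]
    warns: list[str] = []
    if vals.min() == vals.max():
        warns.append("constant intensities in GTV; falling back to full mask")
        warnings.warn(warns[-1], stacklevel=2)
        return placed_gtv.copy(), warns
    thr = otsu_threshold(vals)
    fg = np.zeros_like(placed_gtv)
    fg[placed_gtv] = cbct1.data[placed_gtv] >= thr
    if not fg.any():
        warns.append("empty Otsu foreground; falling back to full mask")
        warnings.warn(warns[-1], stacklevel=2)
        return placed_gtv.copy(), warns
    return fg, warns


def centroid(voxels: np.ndarray, spacing, origin) -> tuple[float, float, float]:
    """Arithmetic mean of member voxel world coordinates (mm).

    ``voxels`` is a boolean mask or an (n, 3) index array.
    """
    voxels = np.asarray(voxels)
    idx = np.argwhere(voxels) if voxels.dtype == bool else voxels
    if idx.size == 0:
        raise ValueError("empty voxel set has no centroid")
    c = np.asarray(origin, dtype=float) + idx.mean(axis=0) * np.asarray(spacing, dtype=float)
    return tuple(float(v) for v in c)


def localize(ct1: Volume, cbct1: Volume, g: GTVStructure, tr: TranslationResult,
             mode: str = "bse", *, gamma: float = 1.0, sigma_mm: float | None = None,
             dilation_px: int = 20, cbct_pre: Volume | None = None,
             median_size: int = 3, log_sigma_px: float = 0.7,
             log_mode: str = "sharpen") -> LocalizationResult:
    """Full tumor localization in one MV-CBCT volume.

    Pipeline: map the GTV into CBCT space with the coarse registration,
    build the search region (GTV cuboid + ``dilation_px``), extract the
    (mode-filtered) planning-CT template, match it inside the identically
    filtered preprocessed search region, plant the GTV mask at the match,
    Otsu-binarize the raw CBCT intensities inside it, and return the
    binarized set's centroid.  Deterministic for fixed inputs.

    ``cbct_pre`` optionally supplies an already-preprocessed CBCT (reused
    when several modes run on the same fraction).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    params = None
    if mode == "bse":
        params = BSEParams(sigma_mm=sigma_mm if sigma_mm is not None else g.d / 4.0,
                           gamma=gamma)
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        mapped = map_gtv_to_cbct(g, tr, cbct1)
        region = build_search_region(mapped, cbct1, dilation_px=dilation_px)
        tpl = extract_template(ct1, g, mode=mode, p=params)
        if any(t > r for t, r in zip(tpl.image.shape, region.shape)):
            raise ValueError(
                f"template {tpl.image.shape} larger than search region {region.shape}"
            )
        if cbct_pre is None:
            cbct_pre = _pre.preprocess_cbct(cbct1, median_size=median_size,
                                            log_sigma_px=log_sigma_px, log_mode=log_mode)
        region_img = _filtered_crop(cbct_pre, region.box_min, region.box_max, mode, params)
        offset, score = match_template(region_img, tpl)
        placed = np.zeros(cbct1.shape, dtype=bool)
        corner = tuple(b + o for b, o in zip(region.box_min, offset))
        placed[tuple(slice(c, c + s) for c, s in zip(corner, tpl.gtv_mask.shape))] = tpl.gtv_mask
        fg, bwarns = binarize_gtv(cbct1, placed)
        warns.extend(bwarns)
        c = centroid(fg, cbct1.spacing, cbct1.origin)
    warns.extend(str(w.message) for w in wrec
                 if str(w.message) not in warns)
    return LocalizationResult(matched_offset=offset, region=region, placed_mask=placed,
                              binarized_mask=fg, centroid_mm=c, score=score,
                              mode=mode, warnings=warns)
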