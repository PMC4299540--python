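"""Exhaustive translation-only rigid registration of planning CT to MV-CBCT.

Registration runs on 5 mm isotropic resamples of both volumes: the (smaller)
MV-CBCT grid is slid over the planning CT grid at every integer offset and
the normalized cross-correlation (NCC) is maximized.  The offset ranges are
R = X - L per axis (CT minus CBCT matrix size), so the overlap window always
equals the full CBCT matrix.  The coarse 5 mm optimum seeds the 1 mm search
region used by template matching downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template as _skimage_match_template

from .volumes import GTVStructure, Volume

__all__ = [
    "DegenerateInputError",
    "TranslationResult",
    "SearchRegion",
    "ncc",
    "register_translation",
    "map_gtv_to_cbct",
    "build_search_region",
]


class DegenerateInputError(Exception):
    """An input has zero intensity variance, so NCC is undefined."""


@dataclass
class TranslationResult:
    """Optimal integer-grid rigid offset and its NCC score.

    ``offset`` is the argmax voxel offset of the CBCT window inside the CT
    grid (coarse-grid indices); ``offset_mm`` the same in millimetres.
    ``translation_mm`` is the world-space displacement that carries a point
    of anatomy from CT world coordinates to CBCT world coordinates (it folds
    in the two volumes' origins, so downstream mapping is origin-agnostic).
    """

    offset: tuple[int, int, int]
    offset_mm: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    score: float
    spacing_mm: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError(f"NCC score outside [-1, 1]: {self.score}")


@dataclass
class SearchRegion:
    """Half-open voxel box in 1 mm MV-CBCT index space to search for the tumor."""

    box_min: tuple[int, int, int]
    box_max: tuple[int, int, int]
    provenance: dict = field(default_factory=dict)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.box_min, self.box_max))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.box_min, self.box_max))


def ncc(t_sub: np.ndarray, f_sub: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape grids.

    (1/LMN) * sum((t - t_mean) (f - f_mean)) / (sigma_t * sigma_f), computed
    over the full overlap; the result lies in [-1, 1] up to floating error.

    Raises
    ------
    DegenerateInputError
        If either grid has zero standard deviation.
    """
    t = np.asarray(t_sub, dtype=float)
    f = np.asarray(f_sub, dtype=float)
    if t.shape != f.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {f.shape}")
    st = t.std()
    sf = f.std()
    if st == 0 or sf == 0:
        raise DegenerateInputError("zero intensity variance; NCC undefined")
    return float(np.mean((t - t.mean()) * (f - f.mean())) / (st * sf))


def _argmax_lex_zyx(score: np.ndarray) -> tuple[int, int, int]:
    """Argmax of a (x, y, z)-indexed score map, ties broken by smallest
    offset in lexicographic (z, y, x) order."""
    best = score.max()
    cand = np.argwhere(score == best)
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))  # keys x<y<z, z primary
    return tuple(int(v) for v in cand[order[0]])


def score_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """NCC of ``template`` at every full-overlap integer placement in ``image``.

    Thin wrapper over skimage's FFT-accelerated ``match_template``; output
    shape is ``image.shape - template.shape + 1`` and values are clipped to
    [-1, 1] to absorb floating error.
    """
    if any(ti > ii for ti, ii in zip(template.shape, image.shape)):
        raise ValueError(
            f"template {template.shape} exceeds image {image.shape} on some axis; "
            "offset ranges R = X - L must be nonnegative on every axis"
        )
    if np.std(template) == 0:
        raise DegenerateInputError("template has zero intensity variance")
    if np.std(image) == 0:
        raise DegenerateInputError("search image has zero intensity variance")
    out = _skimage_match_template(np.asarray(image, dtype=float),
                                  np.asarray(template, dtype=float), pad_input=False)
    return np.clip(np.nan_to_num(out, nan=-1.0), -1.0, 1.0)


def register_translation(ct5: Volume, cbct5: Volume) -> TranslationResult:
    """Exhaustive NCC registration of the CBCT grid inside the CT grid.

    Both volumes must share the same isotropic (coarse) spacing and the CT
    grid must be at least as large as the CBCT grid on every axis.  All
    integer offsets in [0, R_x] x [0, R_y] x [0, R_z] are scored; ties are
    broken by the smallest offset in lexicographic (z, y, x) order.
    """
    if not ct5.is_isotropic() or not cbct5.is_isotropic():
        raise ValueError("registration requires isotropic volumes")
    if not np.isclose(ct5.spacing[0], cbct5.spacing[0]):
        raise ValueError(
            f"spacing mismatch: CT {ct5.spacing[0]} mm vs CBCT {cbct5.spacing[0]} mm"
        )
    s = score_map(ct5.data, cbct5.data)
    offset = _argmax_lex_zyx(s)
    sp = float(ct5.spacing[0])
    offset_mm = tuple(o * sp for o in offset)
    translation = tuple(
        float(co - cto - om)
        for co, cto, om in zip(cbct5.origin, ct5.origin, offset_mm)
    )
    return TranslationResult(offset=offset, offset_mm=offset_mm,
                             translation_mm=translation, score=float(s[offset]),
                             spacing_mm=sp)


def map_gtv_to_cbct(g: GTVStructure, tr: TranslationResult, cbct1: Volume) -> GTVStructure:
    """Translate the planning GTV into 1 mm MV-CBCT index space.

    The mask is shifted rigidly by the registration's world translation
    (rounded to the nearest CBCT voxel) and clipped to the image bounds, with
    a warning if clipping discards voxels.
    """
    shift_vox = np.asarray(g.origin) + np.asarray(tr.translation_mm) - np.asarray(cbct1.origin)
    shift_vox = shift_vox / np.asarray(cbct1.spacing)
    shift = np.rint(shift_vox).astype(int)
    src_idx = np.argwhere(g.mask)
    dst_idx = src_idx + shift
    inb = np.all((dst_idx >= 0) & (dst_idx < np.asarray(cbct1.shape)), axis=1)
    if not inb.any():
        raise ValueError("mapped GTV lies entirely outside the MV-CBCT volume")
    if not inb.all():
        warnings.warn("mapped GTV clipped at the MV-CBCT border", stacklevel=2)
    mask = np.zeros(cbct1.shape, dtype=bool)
    dst = dst_idx[inb]
    mask[dst[:, 0], dst[:, 1], dst[:, 2]] = True
    iso = tuple(np.asarray(g.isocenter) + np.asarray(tr.translation_mm))
    return GTVStructure(mask=mask, spacing=cbct1.spacing, origin=cbct1.origin,
                        isocenter=iso, name=g.name)


def build_search_region(g_mapped: GTVStructure, cbct1: Volume,
                        dilation_px: int = 20) -> SearchRegion:
    """Search region = GTV circumscribing cuboid dilated by ``dilation_px``.

    Expanding a filled cuboid by 20 iterations of 26-neighbor binary dilation
    grows every face by 20 voxels, so the box arithmetic here is exact; the
    box is clipped to the image bounds.
    """
    if dilation_px < 0:
        raise ValueError("dilation must be nonnegative")
    lo, hi = g_mapped.bbox
    box_min = tuple(max(0, l - dilation_px) for l in lo)
    box_max = tuple(min(n, h + dilation_px) for h, n in zip(hi, cbct1.shape))
    return SearchRegion(box_min=box_min, box_max=box_max,
                        provenance={"gtv_bbox": g_mapped.bbox, "dilation_px": dilation_px})
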