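"""Digital lung phantom and MV-CBCT degradation model.

Stands in for a physical lung-screening phantom and for clinical scans: a
thorax-like volume (soft-tissue ellipsoid containing two lung fields at
-900 HU) with spherical simulated tumors at +270 HU contrast, placed at the
lung apex, the tracheal-bifurcation level, or the lung base.  The
degradation model turns the planning CT into an MV-CBCT-like verification
image: reduced soft-tissue contrast, a known rigid translation, Gaussian
blur and additive Gaussian noise, cropped to a cubic field of view centered
on the isocenter.  Ground truth (tumor centers and the applied shift) is
recorded exactly, so localization errors are well-defined without any
observer input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import GTVStructure, Volume, sample_at_world

__all__ = [
    "TumorSpec",
    "PhantomSpec",
    "DegradationSpec",
    "ClinicalCase",
    "TABLE1_DIAMETERS_MM",
    "TABLE1_STATIONS",
    "make_phantom_ct",
    "degrade_to_cbct",
    "make_clinical_like_cases",
    "generate_case",
]

#: effective diameters (mm) of the ten clinical tumors the simulator emulates
TABLE1_DIAMETERS_MM = (9.35, 12.30, 11.94, 10.07, 12.91, 14.35, 5.90, 5.38, 9.00, 13.12)

#: lung station of each clinical case: 5 upper, 2 middle, 3 lower
TABLE1_STATIONS = ("upper", "middle", "middle", "upper", "upper",
                   "lower", "lower", "upper", "upper", "lower")

#: cases whose tumors are close to / attached to the lung wall (1-based ids 6, 10)
WALL_ABUTTING_CASES = (6, 10)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TumorSpec:
    """One spherical simulated tumor: station label, center (mm), diameter (mm)."""

    station: str
    center_mm: tuple[float, float, float]
    diameter_mm: float
    wall_abutting: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of the digital thorax phantom.

    Defaults reproduce the validation conditions: lung fields at -900 HU,
    tumors at lung + 270 HU contrast (-630 HU), 10 mm spheres at the apex,
    tracheal-bifurcation and base stations, on a 1 mm isotropic grid.
    """

    shape: tuple[int, int, int] = (176, 176, 176)
    spacing_mm: float = 1.0
    lung_hu: float = -900.0
    tumor_contrast_hu: float = 270.0
    body_hu: float = 40.0
    background_hu: float = -1000.0
    tumors: tuple[TumorSpec, ...] = ()
    supersample: int = 3  # per-axis sub-voxel samples for sphere anti-aliasing

    # pulmonary-vessel surrogates: soft-tissue tubes threading each lung field.
    # They give the search region the plate/tube clutter that real MV-CBCT
    # matching has to reject (and that the blob filter suppresses by design).
    include_vessels: bool = True
    vessel_radius_mm: float = 2.2
    vessel_hu: float = 40.0
    vessel_offset_mm: tuple[float, float] = (8.0, 6.0)  # lateral offset from stations

    # thorax geometry, as fractions of the half-extent
    body_semiaxes_frac: tuple[float, float, float] = (0.92, 0.72, 0.98)
    lung_semiaxes_frac: tuple[float, float, float] = (0.34, 0.46, 0.72)
    lung_offset_frac: float = 0.42  # lateral offset of each lung center

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        for t in self.tumors:
            if t.diameter_mm <= 2.0 * self.spacing_mm:
                raise ValueError(
                    f"tumor diameter {t.diameter_mm} mm must exceed twice the "
                    f"voxel size ({self.spacing_mm} mm)"
                )

    @property
    def center_mm(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.shape) - 1) * self.spacing_mm

    @property
    def tumor_hu(self) -> float:
        return self.lung_hu + self.tumor_contrast_hu

    def lung_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.center_mm
        half = 0.5 * np.asarray(self.shape) * self.spacing_mm
        off = self.lung_offset_frac * half[0]
        return c - np.array([off, 0, 0]), c + np.array([off, 0, 0])

    def lung_semiaxes_mm(self) -> np.ndarray:
        half = 0.5 * np.asarray(self.shape) * self.spacing_mm
        return np.asarray(self.lung_semiaxes_frac) * half

    def station_center(self, station: str, side: int = 1,
                       wall_abutting: bool = False,
                       diameter_mm: float = 10.0,
                       wall_gap_mm: float = 3.0) -> tuple[float, float, float]:
        """World center of a named lung station (apex / bifurcation / base,
        or the clinical labels upper / middle / lower).

        Near-wall tumors are pushed laterally until the sphere surface sits
        ``wall_gap_mm`` from the lung-field boundary at that axial level
        ("close to the lung wall"); a gap of zero buries part of the sphere
        in the chest wall, where the blob signature is genuinely lost.
        """
        zfrac = {"apex": 0.62, "upper": 0.62, "bifurcation": 0.0, "middle": 0.0,
                 "base": -0.62, "lower": -0.62}
        if station not in zfrac:
            raise ValueError(f"unknown station {station!r}")
        left, right = self.lung_centers_mm()
        lung_c = right if side > 0 else left
        semi = self.lung_semiaxes_mm()
        z = lung_c[2] + zfrac[station] * semi[2]
        # in-plane lung semi-axes at this axial level
        shrink = np.sqrt(max(1.0 - (zfrac[station]) ** 2, 0.0))
        center = np.array([lung_c[0], lung_c[1], z])
        if wall_abutting:
            ax = shrink * semi[0]
            center[0] = lung_c[0] + side * max(
                ax - 0.5 * diameter_mm - wall_gap_mm, 0.0)
        return tuple(float(v) for v in center)

    def default_validation_tumors(self, diameter_mm: float = 10.0) -> "PhantomSpec":
        """Three tumors at apex / bifurcation / base, alternating lungs."""
        tumors = tuple(
            TumorSpec(station=st, center_mm=self.station_center(st, side=sd),
                      diameter_mm=diameter_mm)
            for st, sd in (("apex", +1), ("bifurcation", -1), ("base", +1))
        )
        return replace(self, tumors=tumors)


def _ellipsoid_mask(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (((x - cx) / ax)[:, None, None] ** 2
            + ((y - cy) / ay)[None, :, None] ** 2
            + ((z - cz) / az)[None, None, :] ** 2) <= 1.0


def _vessel_segments(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    """Tapered vessel surrogates per lung: (a, b, r_a, r_b) with radii in mm.

    Each lung gets a near-vertical trunk (offset laterally from the tumor
    station column, thick at the base and tapering toward the apex) and a
    non-intersecting oblique branch.  Segments deliberately overshoot the
    lung field: the ``& lungs`` clip then ends every tube exactly on the
    lung boundary, merging it into the chest-wall plate the way vessels run
    into the hilum and diaphragm — a free-standing tube end-cap would be a
    sphere-like structure no real vasculature presents.
    """
    segs = []
    dx, dy = spec.vessel_offset_mm
    r = spec.vessel_radius_mm
    semi = spec.lung_semiaxes_mm()
    for side, lc in zip((-1, +1), spec.lung_centers_mm()):
        z0, z1 = lc[2] - 1.1 * semi[2], lc[2] + 1.1 * semi[2]
        segs.append((np.array([lc[0] + side * dx, lc[1] + dy, z0]),
                     np.array([lc[0] + side * (dx - 4.0), lc[1] + dy - 3.0, z1]),
                     1.3 * r, 0.4 * r))
        segs.append((np.array([lc[0] - side * 1.1 * semi[0], lc[1] - dy, lc[2] - 12.0]),
                     np.array([lc[0] + side * 1.1 * semi[0], lc[1] - dy, lc[2] + 22.0]),
                     r, 0.4 * r))
    return segs


def _paint_vessels(data: np.ndarray, spec: PhantomSpec, lungs: np.ndarray,
                   coords) -> None:
    """Rasterize tapered vessel tubes (clipped to the lung fields)."""
    x, y, z = coords
    for a, b, ra, rb in _vessel_segments(spec):
        ab = b - a
        rmax = max(ra, rb)
        lo = np.maximum(np.floor((np.minimum(a, b) - rmax) / spec.spacing_mm) - 1, 0).astype(int)
        hi = np.minimum(np.ceil((np.maximum(a, b) + rmax) / spec.spacing_mm) + 2,
                        np.asarray(data.shape)).astype(int)
        sl = tuple(slice(p, q) for p, q in zip(lo, hi))
        px = (x[sl[0]] - a[0])[:, None, None]
        py = (y[sl[1]] - a[1])[None, :, None]
        pz = (z[sl[2]] - a[2])[None, None, :]
        t = (px * ab[0] + py * ab[1] + pz * ab[2]) / (ab @ ab)
        t = np.clip(t, 0.0, 1.0)
        d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
        rt = ra + (rb - ra) * t
        tube = (d2 <= rt * rt) & lungs[sl]
        data[sl][tube] = spec.vessel_hu


def _paint_sphere(data: np.ndarray, spec: PhantomSpec, t: TumorSpec) -> None:
    """Blend an anti-aliased sphere of tumor HU into ``data`` in place.

    Voxel occupancy is estimated from ``supersample``^3 sub-voxel samples;
    the voxel value is linearly blended between its current value and the
    tumor HU by the occupied fraction.
    """
    sp = spec.spacing_mm
    r = 0.5 * t.diameter_mm
    c = np.asarray(t.center_mm)
    lo = np.maximum(np.floor((c - r) / sp - 1), 0).astype(int)
    hi = np.minimum(np.ceil((c + r) / sp + 2), np.asarray(data.shape)).astype(int)
    ss = spec.supersample
    sub = (np.arange(ss) + 0.5) / ss - 0.5  # sub-voxel offsets in voxel units
    frac = np.zeros(tuple(hi - lo), dtype=float)
    for dx in sub:
        for dy in sub:
            for dz in sub:
                xs = (np.arange(lo[0], hi[0]) + dx) * sp - c[0]
                ys = (np.arange(lo[1], hi[1]) + dy) * sp - c[1]
                zs = (np.arange(lo[2], hi[2]) + dz) * sp - c[2]
                frac += (xs[:, None, None] ** 2 + ys[None, :, None] ** 2
                         + zs[None, None, :] ** 2) <= r * r
    frac /= ss ** 3
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    data[sl] = data[sl] * (1 - frac) + spec.tumor_hu * frac


def make_phantom_ct(spec: PhantomSpec) -> tuple[Volume, list[GTVStructure], dict]:
    """Rasterize the digital phantom.

    Returns the CT volume, one GTV per tumor (mask = voxel centers within the
    analytic sphere) and a ground-truth dict mapping station label to the
    exact analytic center (mm).  Raises if a tumor center lies outside the
    lung fields.
    """
    if not spec.tumors:
        spec = spec.default_validation_tumors()
    sp = spec.spacing_mm
    coords = tuple(np.arange(n) * sp for n in spec.shape)
    data = np.full(spec.shape, spec.background_hu, dtype=float)
    half = 0.5 * np.asarray(spec.shape) * sp
    body = _ellipsoid_mask(coords, spec.center_mm, np.asarray(spec.body_semiaxes_frac) * half)
    data[body] = spec.body_hu
    lungs = np.zeros(spec.shape, dtype=bool)
    for lc in spec.lung_centers_mm():
        lungs |= _ellipsoid_mask(coords, lc, spec.lung_semiaxes_mm())
    lungs &= body
    data[lungs] = spec.lung_hu
    if spec.include_vessels:
        _paint_vessels(data, spec, lungs, coords)

    iso = tuple(float(v) for v in spec.center_mm)
    gtvs: list[GTVStructure] = []
    truth: dict = {}
    for t in spec.tumors:
        ci = np.asarray(t.center_mm) / sp
        if not (np.all(ci >= 0) and np.all(ci < np.asarray(spec.shape))):
            raise ValueError(f"tumor station {t.station!r} outside the volume")
        if not lungs[tuple(np.round(ci).astype(int))]:
            raise ValueError(f"tumor station {t.station!r} lies outside the lung fields")
        _paint_sphere(data, spec, t)
        r = 0.5 * t.diameter_mm
        d2 = ((coords[0] - t.center_mm[0])[:, None, None] ** 2
              + (coords[1] - t.center_mm[1])[None, :, None] ** 2
              + (coords[2] - t.center_mm[2])[None, None, :] ** 2)
        mask = d2 <= r * r
        gtvs.append(GTVStructure(mask=mask, spacing=(sp,) * 3, origin=(0.0, 0.0, 0.0),
                                 isocenter=iso, name=t.station))
        truth[t.station] = tuple(float(v) for v in t.center_mm)
    ct = Volume(data=data, spacing=(sp,) * 3, origin=(0.0, 0.0, 0.0))
    return ct, gtvs, truth


@dataclass(frozen=True)
class DegradationSpec:
    """MV-CBCT degradation model parameters.

    Blur, noise and contrast defaults are surrogates chosen to emulate the
    qualitative character of megavoltage cone-beam imaging (heavy quantum
    noise, washed-out soft-tissue contrast, blurred edges); they are not
    measured values.  ``shift_mm`` is the known rigid setup displacement the
    pipeline is asked to recover.
    """

    blur_fwhm_mm: float = 3.0
    noise_sd: float = 20.0
    contrast_scale: float = 0.6
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fov_mm: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("blur FWHM and noise SD must be nonnegative")
        if not (0.0 < self.contrast_scale <= 1.0):
            raise ValueError("contrast scale must lie in (0, 1]")


def degrade_to_cbct(ct: Volume, d: DegradationSpec,
                    isocenter_mm: tuple[float, float, float] | None = None
                    ) -> tuple[Volume, dict]:
    """Turn a planning CT into an MV-CBCT-like verification image.

    Applied in order: contrast scaling about the lung baseline (-900 HU),
    rigid translation by ``shift_mm`` (tricubic resampling), Gaussian blur,
    additive Gaussian noise (seeded), then cropping to a cubic ``fov_mm``
    field of view centered on the isocenter.  Anatomy at CT world point p
    appears at CBCT world point p + shift.  Returns the volume and a record
    of the exact applied shift.
    """
    iso = np.asarray(isocenter_mm if isocenter_mm is not None
                     else 0.5 * (np.asarray(ct.shape) - 1) * np.asarray(ct.spacing))
    n = int(round(d.fov_mm / min(ct.spacing)))
    sp_out = float(min(ct.spacing))
    extent = (np.asarray(ct.shape) - 1) * np.asarray(ct.spacing)
    if d.fov_mm > extent.min() + 1e-9:
        raise ValueError(f"FOV {d.fov_mm} mm exceeds the CT extent {extent} mm")
    origin = iso - 0.5 * (n - 1) * sp_out
    coords = tuple(origin[a] + sp_out * np.arange(n) - d.shift_mm[a] for a in range(3))

    scaled = ct.copy_with(data=(-900.0 + d.contrast_scale * (ct.data - (-900.0))))
    data = sample_at_world(scaled, coords, method="tricubic")
    if d.blur_fwhm_mm > 0:
        data = ndimage.gaussian_filter(data, sigma=d.blur_fwhm_mm * FWHM_TO_SIGMA / sp_out,
                                       mode="nearest")
    if d.noise_sd > 0:
        rng = np.random.default_rng(d.seed)
        data = data + rng.normal(0.0, d.noise_sd, size=data.shape)
    cbct = Volume(data=data, spacing=(sp_out,) * 3,
                  origin=tuple(float(v) for v in origin))
    record = {"applied_shift_mm": tuple(float(s) for s in d.shift_mm),
              "seed": d.seed, "fov_mm": d.fov_mm}
    return cbct, record


@dataclass(frozen=True)
class ClinicalCase:
    """One simulated clinical case: a single-tumor phantom + 4 CBCT fractions."""

    case_id: int
    spec: PhantomSpec
    fractions: tuple[DegradationSpec, ...]

    @property
    def tumor(self) -> TumorSpec:
        return self.spec.tumors[0]


def make_clinical_like_cases(n: int = 10,
                             diameters_mm=TABLE1_DIAMETERS_MM,
                             stations=TABLE1_STATIONS,
                             n_fractions: int = 4,
                             seed: int = 0,
                             degradation: DegradationSpec = DegradationSpec(),
                             max_shift_mm: float = 6.0,
                             tumor_contrast_hu: float = 940.0,
                             wall_gap_mm: float = 3.0) -> list[ClinicalCase]:
    """Build ``n`` single-tumor cases emulating the clinical cohort.

    Effective diameters cycle through the ten tabulated values (5.38-14.35
    mm), stations are distributed 5 upper / 2 middle / 3 lower, two cases
    sit close to the lung wall, and each case gets ``n_fractions`` degraded
    CBCT fractions with random sub-voxel rigid shifts drawn uniformly from
    [-max_shift_mm, +max_shift_mm] per axis.  Fully deterministic for a
    fixed seed.

    Unlike the validation phantom's foam spheres (lung + 270 HU = -630 HU),
    clinical solid lung cancers are soft-tissue density, so the default
    tumor contrast here is 940 HU over lung (tumor ~ +40 HU, matching the
    chest wall and vasculature).
    """
    if n < 1:
        raise ValueError("need n >= 1 cases")
    ss = np.random.SeedSequence(seed)
    cases: list[ClinicalCase] = []
    base = PhantomSpec(tumor_contrast_hu=tumor_contrast_hu)
    for i in range(n):
        case_id = i + 1
        dmm = float(diameters_mm[i % len(diameters_mm)])
        station = stations[i % len(stations)]
        wall = ((i % len(diameters_mm)) + 1) in WALL_ABUTTING_CASES
        side = +1 if i % 2 == 0 else -1
        center = base.station_center(station, side=side, wall_abutting=wall,
                                     diameter_mm=dmm, wall_gap_mm=wall_gap_mm)
        spec = replace(base, tumors=(TumorSpec(station=station, center_mm=center,
                                               diameter_mm=dmm, wall_abutting=wall),))
        fracs = []
        for j, child in enumerate(ss.spawn(n_fractions)):
            rng = np.random.default_rng(child)
            shift = tuple(float(v) for v in rng.uniform(-max_shift_mm, max_shift_mm, 3))
            fracs.append(replace(degradation, shift_mm=shift,
                                 seed=int(rng.integers(0, 2**31 - 1))))
        ss = ss.spawn(1)[0]
        cases.append(ClinicalCase(case_id=case_id, spec=spec, fractions=tuple(fracs)))
    return cases


def generate_case(case: ClinicalCase) -> tuple[Volume, GTVStructure, dict]:
    """Rasterize a clinical-like case's planning CT and its single GTV."""
    ct, gtvs, truth = make_phantom_ct(case.spec)
    return ct, gtvs[0], truth
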