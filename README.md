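# tumorloc

Automated estimation of lung tumor locations in megavoltage cone-beam CT
(MV-CBCT) verification images, for tumor-based patient positioning in
stereotactic body radiotherapy (SBRT).

In SBRT of lung cancer, the patient is aligned on the treatment couch using
a verification image acquired on the machine. Bone-based alignment leaves
residual tumor misalignment (baseline shifts), and manual tumor alignment is
slow and subjective. `tumorloc` implements an automated framework that
estimates the tumor position directly: a tumor template cropped from the
planning CT is matched against the MV-CBCT inside a search region, after the
tumor has been enhanced with a Hessian-eigenvalue blob filter that responds
to sphere-like structures while suppressing the plates (chest wall) and
tubes (vessels) that distract edge-based matching. Because MV-CBCT scans of
patients are not redistributable, the package ships a digital thorax phantom
and an MV-CBCT degradation model, so the entire pipeline is testable and
reproducible from code alone.

## Method

Given a planning CT volume `f`, an MV-CBCT volume `t`, and the GTV (gross
tumor volume) delineation:

1. **Preprocessing** — both volumes are resampled to 1 mm isotropic voxels
   (tricubic); the MV-CBCT is cleaned with a 3×3×3 median filter and
   edge-enhanced with a Laplacian of Gaussian at σ = 0.7 px.
2. **Coarse registration** — both volumes are downsampled to 5 mm and the
   CBCT grid is slid over the CT grid at every integer offset
   (x, y, z) ∈ [0, X−L] × [0, Y−M] × [0, Z−N], maximizing the normalized
   cross-correlation

       C(x,y,z) = (1/LMN) Σᵢⱼₖ (t(i,j,k) − t̄)(f(x+i, y+j, z+k) − f̄) / (σ_t σ_f).

3. **Search region** — the GTV, mapped into CBCT space by the coarse
   registration, is circumscribed by a cuboid and dilated by 20 voxels.
4. **Template matching** — the GTV cuboid cropped from the planning CT (raw,
   Sobel-filtered, or blob-enhanced) is matched exhaustively inside the
   identically filtered search region by the same NCC.
5. **Blob structure enhancement (BSE)** — with λ₃ ≤ λ₂ ≤ λ₁ the eigenvalues
   of the Gaussian-scale Hessian H(p, σ), the filter emits
   `|λ₃|·(λ₂/λ₃)^γ·(λ₁/λ₂)^γ` where all eigenvalues are negative, else 0.
   The scale is tied to tumor size, σ = d/4, via the effective diameter
   `d = 2·(3·V_GTV / 4π)^(1/3)`, and γ = 1.
6. **Localization** — the GTV mask is planted at the match, binarized by
   Otsu's threshold over its own intensity histogram (256 bins), and the
   tumor position is the centroid `(x_c, y_c, z_c) = (Σxᵢ, Σyᵢ, Σzᵢ)/T` of
   the binarized voxels — naturally sub-voxel.

Accuracy is reported as signed left-right / anterior-posterior /
superior-inferior errors and their Euclidean distance, compared across
template modes with pooled-variance t-tests (means) and F-tests (variances).

## Worked example

`examples/05_localize_phantom.py` simulates the three-station validation
phantom (10 mm spheres at −630 HU in −900 HU lung), degrades it to an
MV-CBCT with a known 4/−3/6 mm setup shift, and localizes every station
with each template mode:

```
applied shift [ 4. -3.  6.] mm; coarse registration [ 4. -1.  4.] mm
station        mode        error LR/AP/SI (mm)  |e| (mm)    NCC
apex           none      0.22    0.26    0.09      0.35  0.810
apex           sobel     0.48    0.46   -9.71      9.73  0.796
apex           bse       0.22    0.26    0.09      0.35  0.974
bifurcation    none     -0.11    0.12    0.03      0.17  0.763
bifurcation    sobel    -0.11    0.12    0.03      0.17  0.879
bifurcation    bse      -0.11    0.12    0.03      0.17  0.982
base           none     -0.04   -0.08   -0.19      0.21  0.859
base           sobel    -0.04   -0.08   -0.19      0.21  0.779
base           bse      -0.04   -0.08   -0.19      0.21  0.993
```

Each row is the estimated minus true tumor position: the BSE-filtered
templates recover all three stations to well under 1 mm — including the
sub-voxel part of the shift, which the binarized-GTV centroid supplies —
while the Sobel template loses the apex station to vessel structure. The
other examples walk through the phantom (`01`), the degradation model
(`02`), registration and search regions (`03`) and the blob filter's
sphere/plate/tube selectivity (`04`).

The same pipeline is scriptable from a shell:

```sh
tumorloc simulate --out sim --seed 1 --shift 4 -3 6
tumorloc localize --ct sim/ct.nii.gz --cbct sim/cbct.nii.gz \
    --gtv sim/gtv_contours.json --mode bse
tumorloc run-all --experiment clinical --seed 0 --out results
```

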