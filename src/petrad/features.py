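"""The 51 radiomic features: conventional SUV statistics, intensity-histogram
descriptors, shape descriptors and gray-level texture features.

Feature families and conventions
--------------------------------
* 10 conventional features are computed on the raw SUV values inside the
  mask and are therefore independent of any discretization setting.
  TLSRE (total lesion somatostatin-receptor expression) is the receptor
  tracer's analogue of total lesion glycolysis: SUVmean x volume (mL).
* 5 histogram features are moments/information measures of the discretized
  gray-level distribution.  Kurtosis is non-excess (a normal distribution
  scores 3).  Quartiles of the conventional family use linear interpolation
  of the empirical distribution.
* 4 shape features; the surface area comes from a marching-cubes mesh of the
  lightly smoothed binary mask, Sphericity = pi^(1/3) (6V)^(2/3) / A and
  Compacity = A^(3/2) / V (larger = less compact).
* 32 texture features from four matrix families, all built on one merged
  matrix per family: pair/run counts are summed over the 13 unique 3-D
  directions at distance 1 before any feature is computed, zones use
  26-connectivity.  The NGLDM family accumulates, per gray level, the
  absolute difference between each voxel and the mean of its in-mask
  26-neighbours.

NaN is used wherever a feature is undefined (zero variance, no valid voxel
pairs, isolated voxels) and is distinct from a true zero.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import EmptyVOIError, SUVImage, VOIMask, check_aligned
from .discretization import DiscretizationSetting, DiscretizedVOI, discretize

# 13 unique direction offsets of the 3-D distance-1 neighbourhood
# (one representative per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

CONVENTIONAL_NAMES = (
    "CONV_SUVmax", "CONV_SUVmean", "CONV_SUVmin", "CONV_SUVstd",
    "CONV_SUVpeak_0.5mL", "CONV_SUVpeak_1mL",
    "CONV_SUVQ1", "CONV_SUVQ2", "CONV_SUVQ3", "CONV_TLSRE",
)
HISTOGRAM_NAMES = (
    "HISTO_Skewness", "HISTO_Kurtosis", "HISTO_Energy",
    "HISTO_Entropy_log2", "HISTO_Entropy_log10",
)
SHAPE_NAMES = (
    "SHAPE_Volume_mL", "SHAPE_Volume_vox", "SHAPE_Sphericity", "SHAPE_Compacity",
)
GLCM_NAMES = (
    "GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast", "GLCM_Correlation",
    "GLCM_Entropy_log10", "GLCM_Entropy_log2", "GLCM_Dissimilarity",
)
GLRLM_NAMES = tuple(
    "GLRLM_" + s for s in
    ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
     "GLNU", "RLNU", "RP")
)
GLZLM_NAMES = tuple(
    "GLZLM_" + s for s in
    ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
     "GLNU", "ZLNU", "ZP")
)
NGLDM_NAMES = ("NGLDM_Coarseness", "NGLDM_Contrast", "NGLDM_Busyness")

TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLZLM_NAMES + NGLDM_NAMES
ALL_FEATURE_NAMES = (
    CONVENTIONAL_NAMES + HISTOGRAM_NAMES + SHAPE_NAMES + TEXTURE_NAMES
)
assert len(ALL_FEATURE_NAMES) == 51


# ---------------------------------------------------------------------------
# conventional
# ---------------------------------------------------------------------------

def suv_peak(image: SUVImage, mask: VOIMask, sphere_volume_ml: float) -> float:
    """Maximum, over in-mask sphere centers, of the mean SUV in a digital
    sphere of the given volume.

    The sphere includes every voxel whose center lies within the sphere
    radius of the center voxel's center.  It may extend outside the mask but
    not outside the image: portions beyond the image border are excluded
    from the mean.
    """
    check_aligned(image, mask)
    if mask.voxel_count() == 0:
        raise EmptyVOIError("SUVpeak of an empty VOI")
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    sp = np.asarray(image.spacing)
    half = np.floor(radius_mm / sp).astype(int)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, sp)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    kernel = (dx**2 + dy**2 + dz**2 <= radius_mm**2).astype(float)
    sums = ndimage.convolve(image.values, kernel, mode="constant", cval=0.0)
    cnts = ndimage.convolve(np.ones(image.shape), kernel, mode="constant", cval=0.0)
    means = sums / cnts
    return float(means[mask.values].max())


def conventional_features(image: SUVImage, mask: VOIMask) -> dict[str, float]:
    """Order statistics and moments of the in-mask SUV values, the two
    SUVpeak variants, and TLSRE = SUVmean x Volume_mL."""
    check_aligned(image, mask)
    if mask.voxel_count() == 0:
        raise EmptyVOIError("conventional features of an empty VOI")
    vals = image.values[mask.values]
    vol_ml = mask.volume_ml()
    mean = float(vals.mean())
    q1, q2, q3 = (float(q) for q in np.percentile(vals, (25, 50, 75)))
    return {
        "CONV_SUVmax": float(vals.max()),
        "CONV_SUVmean": mean,
        "CONV_SUVmin": float(vals.min()),
        "CONV_SUVstd": float(vals.std(ddof=0)),
        "CONV_SUVpeak_0.5mL": suv_peak(image, mask, 0.5),
        "CONV_SUVpeak_1mL": suv_peak(image, mask, 1.0),
        "CONV_SUVQ1": q1,
        "CONV_SUVQ2": q2,
        "CONV_SUVQ3": q3,
        "CONV_TLSRE": mean * vol_ml,
    }


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(disc: DiscretizedVOI) -> dict[str, float]:
    """Moments and information measures of the gray-level distribution."""
    lev = disc.in_mask_levels.astype(float)
    n = lev.size
    if n == 0:
        raise EmptyVOIError("histogram features of an empty VOI")
    counts = np.bincount(disc.in_mask_levels)[1:]
    p = counts[counts > 0] / n
    mu = lev.mean()
    var = float(((lev - mu) ** 2).mean())
    if var > 0:
        skew = float(((lev - mu) ** 3).mean() / var**1.5)
        kurt = float(((lev - mu) ** 4).mean() / var**2)  # non-excess
    else:
        skew = kurt = float("nan")
    return {
        "HISTO_Skewness": skew,
        "HISTO_Kurtosis": kurt,
        "HISTO_Energy": float((p**2).sum()),
        "HISTO_Entropy_log2": float(-(p * np.log2(p)).sum()),
        "HISTO_Entropy_log10": float(-(p * np.log10(p)).sum()),
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

_MC_SIGMA_VOX = 0.7  # pre-smoothing keeps the mesh area of a digital ball
                     # within ~1% of the analytic sphere area


def mask_surface_area_mm2(mask: VOIMask) -> float:
    """Surface area of the mask from a marching-cubes mesh at the 0.5
    iso-level of the (lightly smoothed) binary indicator."""
    idx = np.nonzero(mask.values)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    tight = mask.values[sl]  # canonical crop: same mesh whatever the margin
    padded = np.pad(tight.astype(float), 3)
    smoothed = ndimage.gaussian_filter(padded, _MC_SIGMA_VOX, mode="constant")
    level_src = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(
        level_src, level=0.5, spacing=mask.spacing
    )
    return float(measure.mesh_surface_area(verts, faces))


def shape_features(mask: VOIMask) -> dict[str, float]:
    if mask.voxel_count() == 0:
        raise EmptyVOIError("shape features of an empty VOI")
    n = mask.voxel_count()
    vol_mm3 = n * mask.voxel_volume_mm3
    area = mask_surface_area_mm2(mask)
    sphericity = math.pi ** (1.0 / 3.0) * (6.0 * vol_mm3) ** (2.0 / 3.0) / area
    compacity = area**1.5 / vol_mm3
    return {
        "SHAPE_Volume_mL": vol_mm3 / 1000.0,
        "SHAPE_Volume_vox": float(n),
        "SHAPE_Sphericity": sphericity,
        "SHAPE_Compacity": compacity,
    }


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def _crop_levels(disc: DiscretizedVOI) -> np.ndarray:
    """Level array (0 outside mask) cropped to the mask bounding box."""
    idx = np.nonzero(disc.mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    lev = np.where(disc.mask, disc.levels, 0)
    return lev[sl]


def glcm_matrix(disc: DiscretizedVOI) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix, pair counts
    merged over the 13 unique distance-1 directions (both orders counted).
    Gray axis spans levels 1..max observed.  Returns a G x G matrix summing
    to 1, or an empty array when no valid in-mask pair exists."""
    lev = _crop_levels(disc)
    g = int(lev.max())
    mat = np.zeros((g, g), dtype=float)
    for d in DIRECTIONS_13:
        s_a = tuple(slice(max(0, -o), lev.shape[ax] - max(0, o)) for ax, o in enumerate(d))
        s_b = tuple(slice(max(0, o), lev.shape[ax] - max(0, -o)) for ax, o in enumerate(d))
        a, b = lev[s_a], lev[s_b]
        ok = (a > 0) & (b > 0)
        ai, bi = a[ok] - 1, b[ok] - 1
        np.add.at(mat, (ai, bi), 1.0)
        np.add.at(mat, (bi, ai), 1.0)
    total = mat.sum()
    if total == 0:
        return np.zeros((0, 0))
    return mat / total


def glrlm_matrix(disc: DiscretizedVOI) -> np.ndarray:
    """Run-length counts R(i, j): maximal same-level runs of length j at
    gray level i, merged over the 13 directions."""
    lev = _crop_levels(disc)
    g = int(lev.max())
    shape = np.asarray(lev.shape)
    maxlen = int(np.ceil(np.linalg.norm(shape, np.inf))) + 1
    mat = np.zeros((g, max(shape.max(), 1)), dtype=float)
    inmask = lev > 0
    for d in DIRECTIONS_13:
        dv = np.asarray(d)
        # run starts: in-mask voxels with no same-level in-mask predecessor
        pred_same = np.zeros(lev.shape, dtype=bool)
        s_cur = tuple(slice(max(0, o), lev.shape[ax] - max(0, -o)) for ax, o in enumerate(d))
        s_pre = tuple(slice(max(0, -o), lev.shape[ax] - max(0, o)) for ax, o in enumerate(d))
        pred_same[s_cur] = (lev[s_cur] == lev[s_pre]) & (lev[s_pre] > 0)
        starts = inmask & ~pred_same
        pos = np.argwhere(starts)
        run_lev = lev[starts]
        length = np.ones(len(pos), dtype=int)
        cur = pos + dv
        active = np.arange(len(pos))
        while active.size:
            c = cur[active]
            inb = np.all((c >= 0) & (c < shape), axis=1)
            ok = inb.copy()
            if inb.any():
                cc = c[inb]
                ok[inb] = lev[cc[:, 0], cc[:, 1], cc[:, 2]] == run_lev[active][inb]
            cont = active[ok]
            length[cont] += 1
            cur[cont] += dv
            active = cont
        np.add.at(mat, (run_lev - 1, length - 1), 1.0)
    # trim trailing empty run-length columns
    nz = np.nonzero(mat.sum(axis=0))[0]
    if nz.size:
        mat = mat[:, : nz[-1] + 1]
    return mat


def glzlm_matrix(disc: DiscretizedVOI) -> np.ndarray:
    """Zone counts Z(i, j): 26-connected components of j voxels at gray
    level i (size-zone matrix)."""
    lev = _crop_levels(disc)
    g = int(lev.max())
    n_vox = int((lev > 0).sum())
    structure = np.ones((3, 3, 3), dtype=int)
    sizes_per_level: dict[int, np.ndarray] = {}
    max_size = 1
    for gl in np.unique(lev[lev > 0]):
        lab, nlab = ndimage.label(lev == gl, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level[int(gl)] = sizes
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((g, min(max_size, n_vox)), dtype=float)
    for gl, sizes in sizes_per_level.items():
        np.add.at(mat, (gl - 1, sizes - 1), 1.0)
    return mat


def ngldm_table(disc: DiscretizedVOI) -> tuple[np.ndarray, np.ndarray]:
    """Per-gray-level accumulation of neighbourhood differences.

    Returns ``(n_i, s_i)`` indexed by gray level 1..G: ``n_i`` counts the
    voxels of level i that have at least one in-mask 26-neighbour and
    ``s_i`` sums, over those voxels, |level - mean(in-mask neighbours)|.
    """
    lev = _crop_levels(disc)
    g = int(lev.max())
    inmask = lev > 0
    kernel = np.ones((3, 3, 3), dtype=float)
    kernel[1, 1, 1] = 0.0
    nsum = ndimage.convolve(lev.astype(float), kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(inmask.astype(float), kernel, mode="constant", cval=0.0)
    valid = inmask & (ncnt > 0)
    diff = np.zeros(lev.shape)
    diff[valid] = np.abs(lev[valid] - nsum[valid] / ncnt[valid])
    n_i = np.bincount(lev[valid], minlength=g + 1)[1:].astype(float)
    s_i = np.bincount(lev[valid], weights=diff[valid], minlength=g + 1)[1:]
    return n_i, s_i


# ---------------------------------------------------------------------------
# texture features
# ---------------------------------------------------------------------------

def _nan_features(names) -> dict[str, float]:
    return {n: float("nan") for n in names}


def glcm_features(disc: DiscretizedVOI) -> dict[str, float]:
    p = glcm_matrix(disc)
    if p.size == 0:
        return _nan_features(GLCM_NAMES)
    g = p.shape[0]
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, g + 1)[None, :]
    pz = p[p > 0]
    px = p.sum(axis=1)
    mu = float((np.arange(1, g + 1) * px).sum())
    sig2 = float(((np.arange(1, g + 1) - mu) ** 2 * px).sum())
    if sig2 > 0:
        corr = float((((i - mu) * (j - mu) * p).sum()) / sig2)
    else:
        corr = float("nan")
    return {
        "GLCM_Homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Contrast": float(((i - j) ** 2 * p).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Entropy_log10": float(-(pz * np.log10(pz)).sum()),
        "GLCM_Entropy_log2": float(-(pz * np.log2(pz)).sum()),
        "GLCM_Dissimilarity": float((np.abs(i - j) * p).sum()),
    }


def _run_zone_features(mat: np.ndarray, n_vox: int, prefix: str,
                       per_voxel_total: float) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``per_voxel_total`` is the denominator of the percentage feature
    (13 * N_vox for runs, N_vox for zones)."""
    names = GLRLM_NAMES if prefix == "GLRLM" else GLZLM_NAMES
    total = mat.sum()
    if total == 0:
        return _nan_features(names)
    g, jmax = mat.shape
    i2 = (np.arange(1, g + 1) ** 2)[:, None].astype(float)
    j2 = (np.arange(1, jmax + 1) ** 2)[None, :].astype(float)
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    short = "SRE" if prefix == "GLRLM" else "SZE"
    long_ = "LRE" if prefix == "GLRLM" else "LZE"
    lg = "LGRE" if prefix == "GLRLM" else "LGZE"
    hg = "HGRE" if prefix == "GLRLM" else "HGZE"
    sl = "SRLGE" if prefix == "GLRLM" else "SZLGE"
    sh = "SRHGE" if prefix == "GLRLM" else "SZHGE"
    ll = "LRLGE" if prefix == "GLRLM" else "LZLGE"
    lh = "LRHGE" if prefix == "GLRLM" else "LZHGE"
    nu2 = "RLNU" if prefix == "GLRLM" else "ZLNU"
    pct = "RP" if prefix == "GLRLM" else "ZP"
    return {
        f"{prefix}_{short}": float((mat / j2).sum() / total),
        f"{prefix}_{long_}": float((mat * j2).sum() / total),
        f"{prefix}_{lg}": float((mat / i2).sum() / total),
        f"{prefix}_{hg}": float((mat * i2).sum() / total),
        f"{prefix}_{sl}": float((mat / (i2 * j2)).sum() / total),
        f"{prefix}_{sh}": float((mat * i2 / j2).sum() / total),
        f"{prefix}_{ll}": float((mat * j2 / i2).sum() / total),
        f"{prefix}_{lh}": float((mat * i2 * j2).sum() / total),
        f"{prefix}_GLNU": float((row**2).sum() / total),
        f"{prefix}_{nu2}": float((col**2).sum() / total),
        f"{prefix}_{pct}": float(total / per_voxel_total),
    }


def glrlm_features(disc: DiscretizedVOI) -> dict[str, float]:
    mat = glrlm_matrix(disc)
    return _run_zone_features(mat, disc.n_voxels, "GLRLM",
                              13.0 * disc.n_voxels)


def glzlm_features(disc: DiscretizedVOI) -> dict[str, float]:
    mat = glzlm_matrix(disc)
    return _run_zone_features(mat, disc.n_voxels, "GLZLM",
                              float(disc.n_voxels))


def ngldm_features(disc: DiscretizedVOI) -> dict[str, float]:
    """Coarseness, Contrast and Busyness from the neighbourhood gray-level
    difference accumulators (26-connected, in-mask neighbours only)."""
    n_i, s_i = ngldm_table(disc)
    n_tot = n_i.sum()
    if n_tot == 0:  # every voxel isolated
        return _nan_features(NGLDM_NAMES)
    p_i = n_i / n_tot
    occ = p_i > 0
    lev = np.arange(1, len(p_i) + 1, dtype=float)
    ng = int(occ.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else float("nan")
    if ng > 1:
        pi = p_i[occ][:, None]
        pj = p_i[occ][None, :]
        li = lev[occ][:, None]
        lj = lev[occ][None, :]
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum() / (ng * (ng - 1)) * (s_i.sum() / n_tot)
        )
        denom = float(np.abs(li * pi - lj * pj).sum())
        busyness = ps / denom if denom > 0 else float("nan")
    else:
        contrast = 0.0
        busyness = float("nan")
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def texture_features(disc: DiscretizedVOI) -> dict[str, float]:
    out: dict[str, float] = {}
    out.update(glcm_features(disc))
    out.update(glrlm_features(disc))
    out.update(glzlm_features(disc))
    out.update(ngldm_features(disc))
    return out


def extract_all(
    image: SUVImage,
    mask: VOIMask,
    setting: DiscretizationSetting,
    min_voxels_texture: int = 8,
    lifex_small_voi_zero_fill: bool = False,
) -> dict[str, float]:
    """Compute the full 51-entry feature vector for one (image, mask,
    discretization) combination.

    Texture features are NaN when the VOI has fewer than
    ``min_voxels_texture`` voxels or only one occupied gray level — small or
    flat VOIs carry no measurable texture.  With
    ``lifex_small_voi_zero_fill`` the Sphericity/Compacity entries of VOIs
    under 64 voxels are replaced by 0.0, emulating the LifeX behaviour of
    writing an artificial zero for small VOIs (off by default; the zero is
    an artifact, not a measurement).
    """
    check_aligned(image, mask)
    if mask.voxel_count() == 0:
        raise EmptyVOIError("feature extraction on an empty VOI")
    out: dict[str, float] = {}
    out.update(conventional_features(image, mask))
    disc = discretize(image, mask, setting)
    out.update(histogram_features(disc))
    out.update(shape_features(mask))
    if disc.n_voxels < min_voxels_texture or disc.single_level:
        out.update(_nan_features(TEXTURE_NAMES))
    else:
        out.update(texture_features(disc))
    if lifex_small_voi_zero_fill and mask.voxel_count() < 64:
        out["SHAPE_Sphericity"] = 0.0
        out["SHAPE_Compacity"] = 0.0
    ordered = {name: out[name] for name in ALL_FEATURE_NAMES}
    return ordered
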