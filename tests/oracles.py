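"""Independent brute-force oracles for the texture features.

Everything here is deliberately naive — explicit Python loops over voxels,
pairs, runs, zones and neighbourhoods — and shares no code with the package
implementation it checks.
"""

import itertools
import math

import numpy as np

OFFSETS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]
DIRS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def _inb(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def glcm_oracle(levels, mask):
    """Symmetric direction-merged co-occurrence features by explicit pair
    enumeration over all 26 neighbour offsets."""
    shape = mask.shape
    g = int(levels[mask].max())
    counts = np.zeros((g, g))
    for p in np.argwhere(mask):
        for d in OFFSETS_26:
            q = tuple(p + d)
            if _inb(q, shape) and mask[q]:
                counts[levels[tuple(p)] - 1, levels[q] - 1] += 1
    total = counts.sum()
    if total == 0:
        return {k: float("nan") for k in
                ("homogeneity", "energy", "contrast", "correlation",
                 "entropy_log10", "entropy_log2", "dissimilarity")}
    p_mat = counts / total
    homo = energy = contrast = dissim = e2 = e10 = 0.0
    mu = 0.0
    for i in range(g):
        for j in range(g):
            mu += (i + 1) * p_mat[i, j]
    var = 0.0
    for i in range(g):
        var += (i + 1 - mu) ** 2 * p_mat[i, :].sum()
    corr_num = 0.0
    for i in range(g):
        for j in range(g):
            pij = p_mat[i, j]
            homo += pij / (1 + abs(i - j))
            energy += pij**2
            contrast += (i - j) ** 2 * pij
            dissim += abs(i - j) * pij
            corr_num += (i + 1 - mu) * (j + 1 - mu) * pij
            if pij > 0:
                e2 -= pij * math.log2(pij)
                e10 -= pij * math.log10(pij)
    corr = corr_num / var if var > 0 else float("nan")
    return {"homogeneity": homo, "energy": energy, "contrast": contrast,
            "correlation": corr, "entropy_log10": e10, "entropy_log2": e2,
            "dissimilarity": dissim}


def glrlm_counts_oracle(levels, mask):
    """Run-length counts by per-direction linear scanning."""
    shape = mask.shape
    g = int(levels[mask].max())
    runs = {}
    for d in DIRS_13:
        for p in np.argwhere(mask):
            prev = tuple(p - d)
            lv = levels[tuple(p)]
            if _inb(prev, shape) and mask[prev] and levels[prev] == lv:
                continue  # not a run start
            length = 1
            q = tuple(p + d)
            while _inb(q, shape) and mask[q] and levels[q] == lv:
                length += 1
                q = tuple(np.asarray(q) + d)
            runs[(lv, length)] = runs.get((lv, length), 0) + 1
    jmax = max((l for (_, l) in runs), default=1)
    mat = np.zeros((g, jmax))
    for (lv, length), c in runs.items():
        mat[lv - 1, length - 1] = c
    return mat


def glzlm_counts_oracle(levels, mask):
    """Size-zone counts by explicit 26-connected flood fill."""
    shape = mask.shape
    g = int(levels[mask].max())
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p0 in map(tuple, np.argwhere(mask)):
        if seen[p0]:
            continue
        lv = levels[p0]
        stack = [p0]
        seen[p0] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in OFFSETS_26:
                q = tuple(np.asarray(p) + d)
                if _inb(q, shape) and mask[q] and not seen[q] and levels[q] == lv:
                    seen[q] = True
                    stack.append(q)
        zones.append((lv, size))
    jmax = max((s for (_, s) in zones), default=1)
    mat = np.zeros((g, jmax))
    for lv, size in zones:
        mat[lv - 1, size - 1] += 1
    return mat


def run_zone_features_oracle(mat, n_vox, per_voxel_total):
    """Standard run/zone formulas evaluated with explicit loops."""
    total = mat.sum()
    if total == 0:
        return None
    g, jmax = mat.shape
    feats = dict.fromkeys(
        ("short", "long", "lg", "hg", "sl", "sh", "ll", "lh"), 0.0)
    for i in range(g):
        for j in range(jmax):
            c = mat[i, j]
            if c == 0:
                continue
            ii, jj = (i + 1) ** 2, (j + 1) ** 2
            feats["short"] += c / jj
            feats["long"] += c * jj
            feats["lg"] += c / ii
            feats["hg"] += c * ii
            feats["sl"] += c / (ii * jj)
            feats["sh"] += c * ii / jj
            feats["ll"] += c * jj / ii
            feats["lh"] += c * ii * jj
    out = {k: v / total for k, v in feats.items()}
    out["glnu"] = sum(mat[i, :].sum() ** 2 for i in range(g)) / total
    out["lnu"] = sum(mat[:, j].sum() ** 2 for j in range(jmax)) / total
    out["pct"] = total / per_voxel_total
    return out


def ngldm_oracle(levels, mask):
    """Coarseness/Contrast/Busyness by direct neighbourhood loops."""
    shape = mask.shape
    g = int(levels[mask].max())
    n_i = np.zeros(g)
    s_i = np.zeros(g)
    n_tot = 0
    for p in map(tuple, np.argwhere(mask)):
        neigh = []
        for d in OFFSETS_26:
            q = tuple(np.asarray(p) + d)
            if _inb(q, shape) and mask[q]:
                neigh.append(levels[q])
        if not neigh:
            continue
        lv = levels[p]
        n_i[lv - 1] += 1
        s_i[lv - 1] += abs(lv - sum(neigh) / len(neigh))
        n_tot += 1
    if n_tot == 0:
        return {"coarseness": float("nan"), "contrast": float("nan"),
                "busyness": float("nan")}
    p_i = n_i / n_tot
    ps = sum(p_i[i] * s_i[i] for i in range(g))
    coars = 1.0 / ps if ps > 0 else float("nan")
    occ = [i for i in range(g) if p_i[i] > 0]
    ng = len(occ)
    if ng > 1:
        acc = 0.0
        for i in occ:
            for j in occ:
                acc += p_i[i] * p_i[j] * (i - j) ** 2
        contrast = acc / (ng * (ng - 1)) * (s_i.sum() / n_tot)
        denom = 0.0
        for i in occ:
            for j in occ:
                denom += abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
        busy = ps / denom if denom > 0 else float("nan")
    else:
        contrast = 0.0
        busy = float("nan")
    return {"coarseness": coars, "contrast": contrast, "busyness": busy}


def suv_peak_oracle(values, mask, spacing, sphere_volume_ml):
    """SUVpeak by exhaustive sphere placement on every in-mask voxel."""
    radius = (3.0 * sphere_volume_ml * 1000.0 / (4 * math.pi)) ** (1 / 3)
    shape = values.shape
    best = -math.inf
    offs = []
    reach = [int(radius // s) for s in spacing]
    for d in itertools.product(*[range(-r, r + 1) for r in reach]):
        if sum((d[a] * spacing[a]) ** 2 for a in range(3)) <= radius**2:
            offs.append(d)
    for p in map(tuple, np.argwhere(mask)):
        vals = []
        for d in offs:
            q = tuple(p[a] + d[a] for a in range(3))
            if _inb(q, shape):
                vals.append(values[q])
        best = max(best, sum(vals) / len(vals))
    return best
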