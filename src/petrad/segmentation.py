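"""Lesion delineation: seed-initialized hybrid level set (SAEB), within-VOI
SUVmax-percentage thresholding, and STAPLE consensus estimation.

SAEB — semi-automatic edge-based segmentation — evolves a single closed
surface under a two-term Chan-Vese energy evaluated on *both* the original
SUV image and its edge-enhanced version (Gaussian-smoothed gradient
magnitude):

    E = (1 - lambda_edge) * CV(SUV image) + lambda_edge * CV(edge image)

The only operator input is the seed point at the lesion center; iteration 0
of the level set is a small sphere around it.  Both region terms are
normalized by their image's dynamic range, which makes the segmentation
invariant to multiplying the image by any positive constant.

Thresholded VOIs follow the within-VOI convention for receptor tracers:
the threshold is a percentage of the maximum SUV *inside the parent VOI*
and only parent voxels are eligible, which excludes surrounding
physiological uptake by construction.

STAPLE estimates, by expectation-maximization, a per-voxel posterior
probability of true foreground together with each rater's sensitivity p and
specificity q, using the voxel-wise mean of the rater masks as a spatially
varying prior and restricting computation to the union bounding box plus a
margin so distant background does not swamp the specificity estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    EmptyResultError,
    EmptyVOIError,
    SUVImage,
    VOIMask,
    check_aligned,
)


@dataclass
class SAEBParams:
    """Tunables of the hybrid level set.

    ``edge_sigma_mm``: smoothing of the gradient-magnitude edge filter.
    ``lambda_edge``: weight of the edge-image Chan-Vese term (0..1).
    ``mu_smooth``: number of binary median-filter smoothing passes per
    iteration, the curvature-like regularizer.
    ``init_radius_vox``: radius of the iteration-0 sphere at the seed.
    ``tol_frac``: convergence when the fraction of voxels changing side
    drops below this for a few consecutive iterations.
    """

    edge_sigma_mm: float = 2.0
    lambda_edge: float = 0.3
    mu_smooth: int = 1
    init_radius_vox: float = 2.0
    max_iter: int = 300
    tol_frac: float = 1e-3
    polish_iter: int = 10

    def __post_init__(self):
        if self.edge_sigma_mm <= 0:
            raise ValueError("edge_sigma_mm must be > 0")
        if not 0.0 <= self.lambda_edge <= 1.0:
            raise ValueError("lambda_edge must be in [0, 1]")
        if self.mu_smooth < 0:
            raise ValueError("mu_smooth must be >= 0")
        if self.init_radius_vox < 1:
            raise ValueError("init_radius_vox must be >= 1")
        if not 0.0 < self.tol_frac < 1.0:
            raise ValueError("tol_frac must be in (0, 1)")


def edge_enhance(image: SUVImage, sigma_mm: float) -> SUVImage:
    """Gaussian-smoothed gradient-magnitude image (edge enhancement).

    Non-negative, same grid; adding a constant to the input leaves the
    output unchanged, multiplying by c > 0 scales it by c.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    sigma_vox = [sigma_mm / s for s in image.spacing]
    grad2 = np.zeros(image.shape)
    for ax in range(3):
        g = ndimage.gaussian_filter1d(image.values, sigma_vox[ax], axis=ax, order=1,
                                      mode="nearest")
        g /= image.spacing[ax]
        other = [a for a in range(3) if a != ax]
        for oax in other:
            g = ndimage.gaussian_filter1d(g, sigma_vox[oax], axis=oax, mode="nearest")
        grad2 += g * g
    return SUVImage(np.sqrt(grad2), image.spacing, image.origin)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def segment_saeb(
    image: SUVImage,
    seed_point: tuple[int, int, int],
    params: SAEBParams | None = None,
) -> VOIMask:
    """Segment the lesion around ``seed_point`` with the hybrid level set.

    The curve is evolved with a morphological two-phase scheme: at each
    iteration the combined region force (original + edge image) flips only
    the voxels on the current boundary, followed by ``mu_smooth`` binary
    median passes that act as curvature regularization.  Returns the inside
    region of the converged evolution, restricted to the connected
    component containing the seed.  Raises :class:`EmptyResultError` when
    the image has no usable contrast or the evolution collapses to the
    empty set.
    """
    params = params or SAEBParams()
    seed = tuple(int(s) for s in seed_point)
    if not all(0 <= s < n for s, n in zip(seed, image.shape)):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")

    img = image.values
    rng_i = float(img.max() - img.min())
    if rng_i <= 1e-12 * max(1.0, float(np.abs(img).max())):
        raise EmptyResultError("image has no contrast: nothing to segment")
    edge = edge_enhance(image, params.edge_sigma_mm).values
    rng_e = float(edge.max() - edge.min())
    if rng_e <= 0:
        raise EmptyResultError("edge image is flat: nothing to segment")

    idx = np.indices(image.shape, dtype=float)
    dist = np.sqrt(sum((idx[a] - seed[a]) ** 2 for a in range(3)))
    u = dist <= params.init_radius_vox

    lam = params.lambda_edge
    converged = False
    calm_streak = 0
    for it in range(params.max_iter):
        n_in = int(u.sum())
        if n_in == 0 or n_in == u.size:
            break
        force = np.zeros(image.shape)
        for w, arr, rng_a in ((1.0 - lam, img, rng_i), (lam, edge, rng_e)):
            if w == 0.0:
                continue
            c1 = arr[u].mean()
            c2 = arr[~u].mean()
            force += w * ((arr - c1) ** 2 - (arr - c2) ** 2) / rng_a**2

        boundary = ndimage.binary_dilation(u, _STRUCT6) ^ ndimage.binary_erosion(
            u, _STRUCT6, border_value=1
        )
        new_u = u.copy()
        new_u[boundary & (force < 0)] = True
        new_u[boundary & (force > 0)] = False
        for _ in range(params.mu_smooth):
            smoothed = ndimage.median_filter(new_u.astype(np.uint8), size=3) > 0
            if not smoothed.any():  # median pass would annihilate a tiny region
                break
            new_u = smoothed
        changed = int(np.logical_xor(new_u, u).sum())
        u = new_u
        frac = changed / max(n_in, 1)
        calm_streak = calm_streak + 1 if frac < params.tol_frac else 0
        if calm_streak >= 3 and it > 5:
            converged = True
            break

    # polish: release the curvature constraint and let the pure region/edge
    # force reclaim corner voxels shaved off by the median smoothing
    for _ in range(params.polish_iter):
        if not u.any() or u.all():
            break
        force = np.zeros(image.shape)
        for w, arr, rng_a in ((1.0 - lam, img, rng_i), (lam, edge, rng_e)):
            if w == 0.0:
                continue
            c1 = arr[u].mean()
            c2 = arr[~u].mean()
            force += w * ((arr - c1) ** 2 - (arr - c2) ** 2) / rng_a**2
        boundary = ndimage.binary_dilation(u, _STRUCT6) ^ ndimage.binary_erosion(
            u, _STRUCT6, border_value=1
        )
        new_u = u.copy()
        new_u[boundary & (force < 0)] = True
        new_u[boundary & (force > 0)] = False
        if (new_u == u).all():
            break
        u = new_u

    if not u.any():
        raise EmptyResultError("level set collapsed: seed region indistinguishable "
                               "from background")
    lab, nlab = ndimage.label(u, structure=np.ones((3, 3, 3), dtype=int))
    seed_lab = lab[seed]
    if seed_lab == 0:
        # curve drifted off the seed: keep the component nearest to it
        comp_dist = [dist[lab == k].min() for k in range(1, nlab + 1)]
        seed_lab = int(np.argmin(comp_dist)) + 1
    final = lab == seed_lab
    if not converged:
        warnings.warn("SAEB level set did not converge within max_iter",
                      stacklevel=2)
    return VOIMask(final, image.spacing, image.origin, label="SAEB")


def threshold_voi(image: SUVImage, parent: VOIMask, pct: float) -> VOIMask:
    """Keep the parent voxels with SUV >= (pct/100) x max SUV in the parent.

    The result always contains the parent's max-SUV voxel and is a subset
    of the parent; raising the percentage never adds voxels.
    """
    check_aligned(image, parent)
    if parent.voxel_count() == 0:
        raise EmptyVOIError("cannot threshold an empty parent VOI")
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    vmax = image.values[parent.values].max()
    keep = parent.values & (image.values >= (pct / 100.0) * vmax)
    return VOIMask(keep, parent.spacing, parent.origin,
                   label=f"{parent.label}_thr{pct:g}")


@dataclass
class StapleResult:
    """STAPLE posterior and per-rater performance estimates.

    ``probability`` is the posterior of true foreground on the full grid,
    ``sensitivity``/``specificity`` are per rater; ``degenerate`` marks
    adversarial inputs (e.g. complementary raters) where the posterior
    mostly reflects the prior.
    """

    probability: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    iterations: int
    converged: bool
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    degenerate: bool = False


_EPS = 1e-7


def staple(
    raters: list[VOIMask],
    max_iter: int = 100,
    tol: float = 1e-5,
    bbox_margin: int = 5,
) -> StapleResult:
    """EM estimation of the true segmentation from multiple raters.

    E step: posterior W of foreground from the rater decisions under the
    current (p, q); M step: p_j, q_j re-estimated from W.  Initialization
    p = q = 0.99; prior = voxel-wise mean of the rater masks; computation
    restricted to the union bounding box plus ``bbox_margin`` voxels.
    Convergence when max |change in (p, q)| < tol.
    """
    if len(raters) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    shape = raters[0].shape
    for r in raters[1:]:
        if r.shape != shape:
            raise ValueError("raters must share one grid")
    union = np.zeros(shape, dtype=bool)
    for r in raters:
        union |= r.values
    if not union.any():
        raise EmptyVOIError("all raters are empty")
    idx = np.nonzero(union)
    lo = [max(0, int(a.min()) - bbox_margin) for a in idx]
    hi = [min(s, int(a.max()) + 1 + bbox_margin) for a, s in zip(idx, shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))

    D = np.stack([r.values[sl].ravel() for r in raters]).astype(float)  # J x V
    J, V = D.shape
    degenerate = False
    for j in range(J):
        frac = D[j].mean()
        if frac == 0.0 or frac == 1.0:
            warnings.warn(f"rater {j} is empty or full inside the STAPLE box; "
                          "its performance estimate is pinned", stacklevel=2)
            degenerate = True

    prior = np.clip(D.mean(axis=0), _EPS, 1.0 - _EPS)
    p = np.full(J, 0.99)
    q = np.full(J, 0.99)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        log_a = np.log(prior) + (
            D * np.log(p)[:, None] + (1 - D) * np.log(1 - p)[:, None]
        ).sum(axis=0)
        log_b = np.log(1 - prior) + (
            (1 - D) * np.log(q)[:, None] + D * np.log(1 - q)[:, None]
        ).sum(axis=0)
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        W = a / (a + b)
        sw = W.sum()
        snw = (1.0 - W).sum()
        p_new = np.clip((D * W).sum(axis=1) / max(sw, _EPS), _EPS, 1 - _EPS)
        q_new = np.clip(((1 - D) * (1 - W)).sum(axis=1) / max(snw, _EPS),
                        _EPS, 1 - _EPS)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    prob = np.zeros(shape)
    prob[sl] = W.reshape(tuple(b - a for a, b in zip(lo, hi)))
    # complementary/adversarial raters: posterior hugs the prior
    if np.abs(p - 0.5).min() < 0.05 and np.abs(q - 0.5).min() < 0.05:
        degenerate = True
    return StapleResult(
        probability=prob,
        sensitivity=p,
        specificity=q,
        iterations=it,
        converged=converged,
        spacing=raters[0].spacing,
        origin=raters[0].origin,
        degenerate=degenerate,
    )


def staple_consensus(result: StapleResult, cutoff: float = 0.5) -> VOIMask:
    """Binarize the STAPLE posterior at ``cutoff`` (default 0.5)."""
    return VOIMask(result.probability >= cutoff, result.spacing, result.origin,
                   label="STAPLE")
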