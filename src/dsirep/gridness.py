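"""Rate maps, spatial autocorrelograms and gridness classification.

A unit's rate map lays its embedding column out on the room grid (barrier
cells masked).  The spatial autocorrelogram is the Pearson correlation of
the map with itself at every 2-D offset, computed over the overlapping
unmasked cells.  The gridness score contrasts the correlation of an
annulus of the autocorrelogram (bracketing the ring of six nearest peaks)
with itself rotated by 60/120 degrees versus 30/90/150 degrees:

    score = min(r60, r120) - max(r30, r90, r150)

A unit counts as grid-like when its score exceeds both zero and the 95th
percentile of a shuffling null (value-multiset-preserving circular shifts
of the flattened free-cell order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2
from scipy.ndimage import map_coordinates

from .factorization import DSIEmbedding
from .gridworld import EnvGraph

ROTATIONS = (30, 60, 90, 120, 150)
_POS_ROT = (60, 120)
_NEG_ROT = (30, 90, 150)


@dataclass
class RateMap:
    values: np.ndarray  # height x width, NaN at barrier cells
    unit: int
    source: str  # "X" | "W"


@dataclass
class GridnessResult:
    unit: int
    score: float  # NaN when undefined (no detectable peak ring)
    null_threshold: float
    is_grid: bool
    rotation_corr: dict


def rate_map(embedding: DSIEmbedding, env: EnvGraph, unit: int, source: str = "X") -> RateMap:
    """Lay one unit's activity out on the 2-D room grid."""
    M = embedding.X if source == "X" else embedding.W
    if not 0 <= unit < M.shape[1]:
        raise ValueError("unit out of range")
    return RateMap(values=values_to_map(env, M[:, unit]), unit=unit, source=source)


def values_to_map(env: EnvGraph, values: np.ndarray) -> np.ndarray:
    grid = np.full((env.height, env.width), np.nan)
    rows, cols = zip(*env.states)
    grid[np.array(rows), np.array(cols)] = values
    return grid


def map_to_values(env: EnvGraph, grid: np.ndarray) -> np.ndarray:
    rows, cols = zip(*env.states)
    return grid[np.array(rows), np.array(cols)]


def spatial_autocorrelogram(map_values: np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Masked 2-D autocorrelogram of a single rate map.

    Returns a ``(2H-1) x (2W-1)`` array of Pearson correlations; offsets
    with fewer than ``min_overlap`` overlapping unmasked cells (or with
    zero variance in the overlap) are NaN.
    """
    return autocorrelogram_batch(map_values[None], min_overlap)[0]


def autocorrelogram_batch(maps: np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Masked autocorrelograms of a stack of maps sharing one mask.

    ``maps`` is ``(B, H, W)`` with NaN marking masked cells (identical
    across the batch).  FFT-accelerated; used heavily by the shuffling
    null.
    """
    maps = np.asarray(maps, dtype=float)
    B, H, W = maps.shape
    valid = np.isfinite(maps[0])
    if valid.sum() < 2:
        raise ValueError("need at least 2 unmasked cells")
    fh, fw = 2 * H - 1, 2 * W - 1
    sh, sw = next_fast_len(fh), next_fast_len(fw)

    v = valid.astype(float)
    a = np.where(valid, maps, 0.0)
    Fv = rfft2(v, s=(sh, sw))
    Fa = rfft2(a, s=(sh, sw), axes=(-2, -1))
    Fa2 = rfft2(a * a, s=(sh, sw), axes=(-2, -1))

    def xcorr(Fx, Fy):
        # sum_t x[t] * y[t + d]  for all 2-D lags d
        out = irfft2(np.conj(Fx) * Fy, s=(sh, sw), axes=(-2, -1))
        return np.roll(out, (H - 1, W - 1), axis=(-2, -1))[..., :fh, :fw]

    n = xcorr(Fv, Fv)
    s1 = xcorr(Fa, Fv)         # sum of a over overlap (left term)
    s2 = xcorr(Fv, Fa)         # sum of shifted a over overlap
    s11 = xcorr(Fa2, Fv)
    s22 = xcorr(Fv, Fa2)
    s12 = xcorr(Fa, Fa)

    n = np.maximum(np.rint(n), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s12 - s1 * s2 / n
        var1 = s11 - s1 * s1 / n
        var2 = s22 - s2 * s2 / n
        corr = cov / np.sqrt(var1 * var2)
    bad = (n < max(min_overlap, 2)) | (var1 <= 1e-12) | (var2 <= 1e-12)
    corr = np.where(bad, np.nan, corr)
    return np.clip(corr, -1.0, 1.0)


from functools import lru_cache


@lru_cache(maxsize=16)
def _radius_index(shape):
    H, W = shape
    cy, cx = H // 2, W // 2
    yy, xx = np.mgrid[0:H, 0:W]
    return np.rint(np.hypot(yy - cy, xx - cx)).astype(int)


def _radial_profile(acorr: np.ndarray) -> np.ndarray:
    r = _radius_index(acorr.shape)
    rmax = r.max()
    prof = np.full(rmax + 1, np.nan)
    finite = np.isfinite(acorr)
    sums = np.bincount(r[finite], weights=acorr[finite], minlength=rmax + 1)
    cnts = np.bincount(r[finite], minlength=rmax + 1)
    nz = cnts > 0
    prof[nz] = sums[nz] / cnts[nz]
    return prof


def _annulus_radii(acorr: np.ndarray):
    """Inner radius = first local minimum of the radially averaged
    autocorrelogram; outer = 2.5x the first subsequent peak radius,
    clipped to the usable map radius.  Returns None when no peak ring is
    detectable (e.g. constant or single-bump maps)."""
    prof = _radial_profile(acorr)
    usable = min(acorr.shape) // 2
    limit = min(len(prof) - 1, usable)
    # ring annulus: first local minimum of the radial profile (the trough
    # between the central peak and the ring of six nearest peaks) followed
    # by a ring peak clearly above the noise floor
    r_min = None
    for r in range(1, limit):
        if not (np.isfinite(prof[r - 1]) and np.isfinite(prof[r]) and np.isfinite(prof[r + 1])):
            break
        if prof[r] <= prof[r - 1] and prof[r] <= prof[r + 1]:
            r_min = r
            break
    r_peak = None
    if r_min is not None:
        for r in range(r_min + 1, limit):
            if not np.isfinite(prof[r + 1]):
                break
            if prof[r] >= prof[r - 1] and prof[r] >= prof[r + 1] and prof[r] > 0:
                r_peak = r
                break
    if r_min is not None and r_peak is not None:
        outer = min(2.5 * r_peak, usable)
        if outer > r_min + 1:
            return "ring", float(r_min), float(outer)
    # no detectable ring (e.g. a single central bump): annulus over the
    # central peak's decaying flank — from the 0.2 crossing to the first
    # zero crossing — which is rotation-invariant for radially symmetric
    # maps and excludes the noisy far field
    inner = None
    for r in range(1, min(len(prof), usable)):
        if not np.isfinite(prof[r]):
            break
        if prof[r] < 0.2:
            inner = r
            break
    if inner is None:
        return None
    outer = None
    for r in range(inner, min(len(prof), usable)):
        if not np.isfinite(prof[r]) or prof[r] < 0:
            outer = float(r)
            break
    if outer is None:
        outer = min(2.5 * inner, float(usable))
    if outer <= inner + 1:
        outer = min(inner + 2.0, float(usable))
    if outer <= inner + 0.5:
        return None
    return "flank", float(inner), float(outer)


@lru_cache(maxsize=512)
def _annulus_coords(shape, inner: float, outer: float, dr: float = 0.5, dtheta_deg: float = 3.0):
    """Interpolation coordinates of the annulus at the base angle and each
    rotation, cached per (map shape, annulus radii)."""
    H, W = shape
    cy, cx = H // 2, W // 2
    radii = np.arange(inner, outer + 1e-9, dr)
    angles = np.deg2rad(np.arange(0.0, 360.0, dtheta_deg))
    rr, aa = (g.ravel() for g in np.meshgrid(radii, angles, indexing="ij"))
    thetas = np.deg2rad([0.0, *ROTATIONS])[:, None]
    ys = cy + rr[None, :] * np.sin(aa[None, :] + thetas)
    xs = cx + rr[None, :] * np.cos(aa[None, :] + thetas)
    return ys, xs


def _sample_annulus(acorr: np.ndarray, inner: float, outer: float) -> np.ndarray:
    ys, xs = _annulus_coords(acorr.shape, inner, outer)
    return map_coordinates(
        acorr, [ys.ravel(), xs.ravel()], order=1, mode="constant", cval=np.nan
    ).reshape(ys.shape)


def gridness_score(acorr: np.ndarray) -> tuple[float, dict]:
    """Gridness of one autocorrelogram.

    Returns ``(score, rotation_corr)``; score is NaN when the annulus is
    undefined (no peak ring in the radial profile).
    """
    score, rot_corr, _ = _score_with_annulus_kind(acorr)
    return score, rot_corr


def _score_with_annulus_kind(acorr: np.ndarray):
    """As :func:`gridness_score` but also reports whether the annulus
    bracketed a detected peak ring (``"ring"``) or fell back to the
    central peak's flank (``"flank"``) — the shuffling null pools only
    ring-annulus scores."""
    radii = _annulus_radii(acorr)
    if radii is None:
        return float("nan"), {}, "none"
    kind, inner, outer = radii
    samples = _sample_annulus(acorr, inner, outer)
    # complete-case columns (defined at the base angle and every rotation)
    ok = np.isfinite(samples).all(axis=0)
    if ok.sum() < 10:
        return float("nan"), {}, "none"
    S = samples[:, ok]
    S = S - S.mean(axis=1, keepdims=True)
    norms = np.sqrt((S**2).sum(axis=1))
    if (norms <= 1e-9).any():
        return float("nan"), {}, "none"
    c = (S[1:] @ S[0]) / (norms[1:] * norms[0])
    rot_corr = {deg: float(c[i]) for i, deg in enumerate(ROTATIONS)}
    score = min(rot_corr[d] for d in _POS_ROT) - max(rot_corr[d] for d in _NEG_ROT)
    return float(score), rot_corr, kind


def _gridness_of_values(env: EnvGraph, values: np.ndarray, min_overlap: int):
    acorr = autocorrelogram_batch(values_to_map(env, values)[None], min_overlap)[0]
    return gridness_score(acorr)


def classify_grid_units(
    embedding: DSIEmbedding,
    env: EnvGraph,
    n_shuffles: int = 100,
    seed: int = 0,
    source: str = "X",
    min_overlap: int = 20,
):
    """Classify every unit as grid / non-grid against a shuffling null.

    The null pools, over all units, the gridness of ``n_shuffles`` random
    permutations of each unit's flattened free-cell values (value-multiset
    preserving, spatially white); a unit is a grid cell when its score is
    defined and exceeds both 0 and the pooled 95th percentile.  Returns
    ``(results, grid_fraction)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    M = embedding.X if source == "X" else embedding.W
    n, D = M.shape
    scores = np.full(D, np.nan)
    rot_corrs = [{} for _ in range(D)]
    null_scores = []
    rows, cols = map(np.array, zip(*env.states))
    for k in range(D):
        vals = M[:, k]
        scores[k], rot_corrs[k] = _gridness_of_values(env, vals, min_overlap)
        perm = rng.permuted(
            np.broadcast_to(np.arange(n), (n_shuffles, n)).copy(), axis=1
        )
        maps = np.full((n_shuffles, env.height, env.width), np.nan)
        maps[:, rows, cols] = vals[perm]
        acs = autocorrelogram_batch(maps, min_overlap)
        for i in range(n_shuffles):
            s, _, akind = _score_with_annulus_kind(acs[i])
            # the null characterises chance ring-like structure; flank
            # fallback scores answer a different question and are excluded
            if np.isfinite(s) and akind == "ring":
                null_scores.append(s)
    threshold = float(np.percentile(null_scores, 95)) if null_scores else float("inf")
    results = []
    for k in range(D):
        defined = np.isfinite(scores[k])
        is_grid = bool(defined and scores[k] > max(threshold, 0.0))
        results.append(
            GridnessResult(
                unit=k,
                score=float(scores[k]) if defined else float("nan"),
                null_threshold=threshold,
                is_grid=is_grid,
                rotation_corr=rot_corrs[k],
            )
        )
    fraction = sum(r.is_grid for r in results) / D
    return results, fraction
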