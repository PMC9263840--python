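"""Gray-level texture matrices and their feature families.

Implements the five standard families over discretized ROI intensities:

* GLCM  — co-occurrence at distance 1, symmetric, 13 unique 3-D directions,
          features averaged over directions (24 features)
* GLRLM — run lengths along the same 13 directions, averaged (16)
* GLSZM — zones by 26-connectivity (16)
* GLDM  — dependence counts at Chebyshev distance 1 with tolerance alpha=0;
          the dependence size includes the center voxel, so j >= 1 (14)
* NGTDM — neighborhood gray-tone difference at distance 1 (5)

Discretization is fixed-bin-width: level = floor((x - min)/width) + 1.
Degenerate single-level ROIs return the conventional guards (correlation-type
features 1, entropy-type 0, eps-guarded ratios), each logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

EPS = 1e-12

# 13 unique direction vectors of the 26-neighborhood (one per +/- pair).
DIRECTIONS_13 = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class DiscretizedRoi:
    """Integer gray levels on the mask bounding box; 0 marks out-of-mask."""

    levels: np.ndarray          # int array, cropped to bbox, 0 outside mask
    mask: np.ndarray            # bool, same grid
    bin_width: float
    n_levels: int
    intensities: np.ndarray     # continuous in-mask values (for first order)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(volume_values: np.ndarray, mask_values: np.ndarray,
               bin_width: float) -> DiscretizedRoi:
    """Fixed-bin-width discretization of in-mask intensities.

    level = floor((x - min_in_mask) / bin_width) + 1; levels start at 1 and
    n_levels is the maximum observed level.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be > 0, got {bin_width}")
    mask = np.asarray(mask_values, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    vals = np.asarray(volume_values, dtype=np.float64)
    if vals.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    # crop to bounding box with a 1-voxel margin for neighborhood ops
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - 1) for i in idx]
    hi = [min(s, int(i.max()) + 2) for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    mask_c = mask[sl]
    vals_c = vals[sl]
    inmask = vals_c[mask_c]
    levels = np.zeros(mask_c.shape, dtype=np.int64)
    levels[mask_c] = np.floor((inmask - inmask.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedRoi(levels=levels, mask=mask_c, bin_width=float(bin_width),
                          n_levels=int(levels.max()), intensities=inmask)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrices(droi: DiscretizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric co-occurrence count matrices for the 13 directions.

    Returns (stack of 13 matrices over observed gray values, gray values).
    Empty gray levels are dropped so feature formulas use actual level values.
    """
    lv = droi.levels
    grays = np.unique(lv[droi.mask])
    ng = grays.size
    remap = np.zeros(int(grays.max()) + 1, dtype=np.int64)
    remap[grays] = np.arange(ng)
    mats = np.zeros((13, ng, ng), dtype=np.float64)
    for k, (dx, dy, dz) in enumerate(DIRECTIONS_13):
        a, b = _shifted_pairs(lv, droi.mask, (dx, dy, dz))
        if a.size == 0:
            continue
        np.add.at(mats[k], (remap[a], remap[b]), 1.0)
        mats[k] = mats[k] + mats[k].T  # symmetric
    return mats, grays.astype(np.float64)


def _shifted_pairs(lv: np.ndarray, mask: np.ndarray, off):
    """Gray-level pairs (center, neighbor at offset) with both in the mask."""
    sl_a, sl_b = [], []
    for o, n in zip(off, lv.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return lv[tuple(sl_a)][valid], lv[tuple(sl_b)][valid]


def _batch_entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) along the last axis for a stack of pmfs."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=-1)


def glcm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """24 co-occurrence features averaged over the 13 directions.

    All directions are processed as one (13, Ng, Ng) stack.
    """
    mats, g = glcm_matrices(droi)
    ng = g.size
    tot = mats.sum(axis=(1, 2))
    mats = mats[tot > 0]
    tot = tot[tot > 0]
    P = mats / tot[:, None, None]               # (D, ng, ng)
    D = P.shape[0]
    if ng == 1:
        logger.debug("single-level ROI: GLCM correlation-type features -> 1")
    px = P.sum(axis=2)                          # (D, ng), = py by symmetry
    mu = (px * g).sum(axis=1)                   # (D,)
    var = (px * (g[None, :] - mu[:, None]) ** 2).sum(axis=1)
    gi = g[:, None]
    gj = g[None, :]
    Pr = P.reshape(D, -1)

    sum_vals, sum_inv = np.unique((gi + gj).ravel(), return_inverse=True)
    diff_vals, diff_inv = np.unique(np.abs(gi - gj).ravel(), return_inverse=True)
    pxy_sum = np.bincount(
        (sum_inv[None, :] + np.arange(D)[:, None] * sum_vals.size).ravel(),
        weights=Pr.ravel(), minlength=D * sum_vals.size
    ).reshape(D, sum_vals.size)
    pxy_diff = np.bincount(
        (diff_inv[None, :] + np.arange(D)[:, None] * diff_vals.size).ravel(),
        weights=Pr.ravel(), minlength=D * diff_vals.size
    ).reshape(D, diff_vals.size)

    da = (diff_vals * pxy_diff).sum(axis=1)
    hx = _batch_entropy(px)
    hxy = _batch_entropy(Pr)
    pxpy = px[:, :, None] * px[:, None, :]
    log_pxpy = np.log2(pxpy + EPS)
    hxy1 = -(P * log_pxpy).sum(axis=(1, 2))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))

    gsum = gi + gj
    gdiff2 = (gi - gj) ** 2
    gprod = gi * gj
    acor = (P * gprod).sum(axis=(1, 2))
    dev = gsum[None, :, :] - 2 * mu[:, None, None]
    nzd = diff_vals > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        rows = {
            "Autocorrelation": acor,
            "JointAverage": mu,
            "ClusterProminence": (P * dev ** 4).sum(axis=(1, 2)),
            "ClusterShade": (P * dev ** 3).sum(axis=(1, 2)),
            "ClusterTendency": (P * dev ** 2).sum(axis=(1, 2)),
            "Contrast": (P * gdiff2).sum(axis=(1, 2)),
            "Correlation": np.where(var <= EPS, 1.0,
                                    (acor - mu ** 2) / np.where(var <= EPS, 1.0, var)),
            "DifferenceAverage": da,
            "DifferenceEntropy": _batch_entropy(pxy_diff),
            "DifferenceVariance":
                (((diff_vals[None, :] - da[:, None]) ** 2) * pxy_diff).sum(axis=1),
            "Id": (pxy_diff / (1.0 + diff_vals)).sum(axis=1),
            "Idm": (pxy_diff / (1.0 + diff_vals ** 2)).sum(axis=1),
            "Idmn": (pxy_diff / (1.0 + (diff_vals / ng) ** 2)).sum(axis=1),
            "Idn": (pxy_diff / (1.0 + diff_vals / ng)).sum(axis=1),
            "Imc1": np.where(hx <= EPS, 0.0,
                             (hxy - hxy1) / np.where(hx <= EPS, 1.0, hx)),
            "Imc2": np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0, None)),
            "InverseVariance": (pxy_diff[:, nzd] / diff_vals[nzd] ** 2).sum(axis=1),
            "JointEnergy": (P ** 2).sum(axis=(1, 2)),
            "JointEntropy": hxy,
            "MCC": _mcc_batch(P, px),
            "MaximumProbability": P.max(axis=(1, 2)),
            "SumAverage": (sum_vals * pxy_sum).sum(axis=1),
            "SumEntropy": _batch_entropy(pxy_sum),
            "SumSquares": var,
        }
    return {name: float(np.mean(vals)) for name, vals in rows.items()}


def _mcc_batch(P: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Second-largest eigenvalue of Q = Dx^-1 P Dy^-1 P^T, per direction.

    Q is similar to the symmetric PSD matrix S S^T with
    S = Dx^-1/2 P Dy^-1/2, so the (real, non-negative) spectrum comes from
    eigvalsh, which is faster and numerically stable.
    """
    ng = P.shape[1]
    if ng == 1:
        return np.ones(P.shape[0])
    root = np.sqrt(px) + EPS
    S = P / (root[:, :, None] * root[:, None, :])
    Q = S @ np.swapaxes(S, 1, 2)
    ev = np.linalg.eigvalsh(Q)  # ascending
    return np.sqrt(np.clip(ev[:, -2], 0.0, None))


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(droi: DiscretizedRoi, direction) -> np.ndarray:
    """Run-length count matrix P[gray-1, runlen-1] for one direction."""
    lv = droi.levels
    coords = np.argwhere(droi.mask)
    d = np.asarray(direction)
    # step index along the line: pick the first axis with d != 0; one step
    # along d changes that coordinate by d[a], so k = c[a]*d[a] advances by 1
    a = int(np.flatnonzero(d)[0])
    k_idx = coords[:, a] * d[a]
    # line id = coordinate minus k*d (constant along a line)
    line = coords - np.outer(k_idx, d)
    # sort by (line, k); runs are maximal stretches of equal level with
    # consecutive k on the same line
    key = np.lexsort((k_idx, line[:, 2], line[:, 1], line[:, 0]))
    cs = coords[key]
    ks = k_idx[key]
    gs = lv[cs[:, 0], cs[:, 1], cs[:, 2]]
    same_line = np.all(np.diff(cs - np.outer(ks, d), axis=0) == 0, axis=1)
    adjacent = np.diff(ks) == 1
    cont = same_line & adjacent & (np.diff(gs) == 0)
    # run boundaries
    breaks = np.flatnonzero(~cont)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [gs.size - 1]))
    lengths = ends - starts + 1
    gvals = gs[starts]
    ng = droi.n_levels
    out = np.zeros((ng, int(lengths.max())), dtype=np.float64)
    np.add.at(out, (gvals - 1, lengths - 1), 1.0)
    return out


GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def glrlm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    acc: dict[str, list[float]] = {}
    for d in DIRECTIONS_13:
        P = glrlm_matrix(droi, d)
        f = _glrlm_single(P, droi.n_voxels)
        for k, v in f.items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _glrlm_single(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    g = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    r = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nr
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_r = float((p * r).sum())
    return {
        "ShortRunEmphasis": float((P / r ** 2).sum() / nr),
        "LongRunEmphasis": float((P * r ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nr ** 2),
        "RunLengthNonUniformity": float((pr ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "RunVariance": float((p * (r - mu_r) ** 2).sum()),
        "RunEntropy": _entropy(p.ravel()),
        "LowGrayLevelRunEmphasis": float((P / g ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * g ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (g ** 2 * r ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * g ** 2 / r ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * r ** 2 / g ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * g ** 2 * r ** 2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# GLSZM


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(droi: DiscretizedRoi) -> np.ndarray:
    """Zone count matrix P[gray-1, size-1]; zones by 26-connectivity."""
    lv = droi.levels
    ng = droi.n_levels
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for gval in np.unique(lv[droi.mask]):
        lab, n = ndimage.label(lv == gval, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append((int(gval), sizes))
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((ng, max_size), dtype=np.float64)
    for gval, sizes in sizes_per_level:
        np.add.at(P, (gval - 1, sizes - 1), 1.0)
    return P


def glszm_features(droi: DiscretizedRoi) -> dict[str, float]:
    P = glszm_matrix(droi)
    nz = P.sum()
    g = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    return {
        "SmallAreaEmphasis": float((P / s ** 2).sum() / nz),
        "LargeAreaEmphasis": float((P * s ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((ps ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / droi.n_voxels),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": _entropy(p.ravel()),
        "LowGrayLevelZoneEmphasis": float((P / g ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * g ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (g ** 2 * s ** 2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * g ** 2 / s ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s ** 2 / g ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * g ** 2 * s ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(droi: DiscretizedRoi, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[gray-1, j-1], j = dependent neighbors + 1.

    A 26-neighbor is dependent if |level difference| <= alpha; neighbors
    outside the mask never count.
    """
    lv = droi.levels
    mask = droi.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        a, b = _shifted_slices(lv.shape, d)
        ok = mask[a] & mask[b] & (np.abs(lv[a] - lv[b]) <= alpha)
        dep[a] += ok
    j = dep[mask] + 1  # center voxel included
    gvals = lv[mask]
    P = np.zeros((droi.n_levels, int(j.max())), dtype=np.float64)
    np.add.at(P, (gvals - 1, j - 1), 1.0)
    return P


def _shifted_slices(shape, off):
    sl_a, sl_b = [], []
    for o, n in zip(off, shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


def gldm_features(droi: DiscretizedRoi, alpha: int = 0) -> dict[str, float]:
    P = gldm_matrix(droi, alpha)
    nz = P.sum()
    g = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    pg = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_j = float((p * j).sum())
    return {
        "SmallDependenceEmphasis": float((P / j ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((P * j ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "DependenceNonUniformity": float((pj ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": _entropy(p.ravel()),
        "LowGrayLevelEmphasis": float((P / g ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * g ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis":
            float((P / (g ** 2 * j ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis":
            float((P * g ** 2 / j ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis":
            float((P * j ** 2 / g ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis":
            float((P * g ** 2 * j ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(droi: DiscretizedRoi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_i, p_i, s_i) per gray level i = 1..n_levels.

    s_i sums |level - mean of in-mask 26-neighbors| over voxels of level i;
    voxels with no in-mask neighbor are excluded.
    """
    lv = droi.levels
    mask = droi.mask
    nb_sum = np.zeros(lv.shape, dtype=np.float64)
    nb_cnt = np.zeros(lv.shape, dtype=np.int64)
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        a, b = _shifted_slices(lv.shape, d)
        ok = mask[a] & mask[b]
        nb_sum[a] += np.where(ok, lv[b], 0)
        nb_cnt[a] += ok
    valid = mask & (nb_cnt > 0)
    gv = lv[valid]
    diff = np.abs(gv - nb_sum[valid] / nb_cnt[valid])
    ng = droi.n_levels
    n_i = np.bincount(gv - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(gv - 1, weights=diff, minlength=ng)
    nvp = n_i.sum()
    p_i = n_i / nvp if nvp else n_i
    return n_i, p_i, s_i


def ngtdm_features(droi: DiscretizedRoi) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(droi)
    nvp = n_i.sum()
    g = np.arange(1, n_i.size + 1, dtype=np.float64)
    nz = p_i > 0
    ngp = int(nz.sum())
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > EPS else 1e6  # capped, matching convention
    if ngp > 1:
        gi = g[nz][:, None]
        gj = g[nz][None, :]
        pi = p_i[nz][:, None]
        pj = p_i[nz][None, :]
        contrast = float((pi * pj * (gi - gj) ** 2).sum()) \
            / (ngp * (ngp - 1)) * float(s_i.sum()) / nvp
        busy_den = float(np.abs(gi * pi - gj * pj).sum())
        busyness = ps / busy_den if busy_den > EPS else 0.0
        si = s_i[nz][:, None]
        sj = s_i[nz][None, :]
        complexity = float((np.abs(gi - gj) * (pi * si + pj * sj)
                            / (pi + pj)).sum()) / nvp
        s_sum = float(s_i.sum())
        strength = float(((pi + pj) * (gi - gj) ** 2).sum()) / s_sum \
            if s_sum > EPS else 0.0
    else:
        logger.debug("single-level ROI: NGTDM contrast/busyness/complexity/strength -> 0")
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# family dispatcher


def texture_family_features(droi: DiscretizedRoi, family: str) -> dict[str, float]:
    """Compute one family's features; family in {GLCM, GLRLM, GLSZM, GLDM, NGTDM}."""
    if family == "GLCM":
        return glcm_features(droi)
    if family == "GLRLM":
        return glrlm_features(droi)
    if family == "GLSZM":
        return glszm_features(droi)
    if family == "GLDM":
        return gldm_features(droi)
    if family == "NGTDM":
        return ngtdm_features(droi)
    raise ValueError(f"unknown texture family {family!r}")
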