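"""Independent brute-force oracles used by the test suite.

Everything here is written as naive scalar loops over voxels, pairs, runs
and zones, deliberately sharing no code with the package implementation.
Only usable on tiny ROIs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3)
              if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3)
                 if d > (0, 0, 0)]


def brute_glcm(levels: np.ndarray, mask: np.ndarray, direction
               ) -> dict[tuple[int, int], int]:
    """Symmetric co-occurrence counts {(g1, g2): n} for one direction."""
    counts: dict[tuple[int, int], int] = {}
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for sign in (1, -1):
                    dx, dy, dz = (sign * direction[0], sign * direction[1],
                                  sign * direction[2])
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                            and mask[u, v, w]:
                        key = (int(levels[x, y, z]), int(levels[u, v, w]))
                        counts[key] = counts.get(key, 0) + 1
    return counts


def brute_glcm_features_one_direction(levels, mask, direction,
                                      grays) -> dict[str, float]:
    """Features for one direction; ``grays`` is the ROI-wide level list
    (rows for levels unseen in this direction stay zero, as in the
    full-matrix convention)."""
    counts = brute_glcm(levels, mask, direction)
    total = sum(counts.values())
    ng = len(grays)
    p = {pair: c / total for pair, c in counts.items()}
    px = {g: sum(v for (a, _), v in p.items() if a == g) for g in grays}
    mu = sum(g * px[g] for g in grays)
    var = sum((g - mu) ** 2 * px[g] for g in grays)
    psum: dict[int, float] = {}
    pdiff: dict[int, float] = {}
    for (a, b), v in p.items():
        psum[a + b] = psum.get(a + b, 0.0) + v
        pdiff[abs(a - b)] = pdiff.get(abs(a - b), 0.0) + v
    eps = 1e-12

    def ent(d):
        return -sum(v * math.log2(v) for v in d if v > 0)

    hx = ent(px.values())
    hxy = ent(p.values())
    hxy1 = -sum(v * math.log2(px[a] * px[b] + eps) for (a, b), v in p.items())
    hxy2 = -sum(px[a] * px[b] * math.log2(px[a] * px[b] + eps)
                for a in grays for b in grays)
    da = sum(k * v for k, v in pdiff.items())

    # MCC via the full Q matrix and numpy eigvals (small); terms with
    # zero marginal contribute nothing (their P entries are zero too)
    if ng == 1:
        mcc = 1.0
    else:
        Q = np.zeros((ng, ng))
        gidx = {g: i for i, g in enumerate(grays)}
        for a in grays:
            if px[a] == 0:
                continue
            for b in grays:
                s = 0.0
                for k in grays:
                    if px[k] == 0:
                        continue
                    s += p.get((a, k), 0.0) * p.get((b, k), 0.0) \
                        / (px[a] * px[k])
                Q[gidx[a], gidx[b]] = s
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, ev[-2]))

    feats = {
        "Autocorrelation": sum(a * b * v for (a, b), v in p.items()),
        "JointAverage": mu,
        "ClusterProminence": sum((a + b - 2 * mu) ** 4 * v
                                 for (a, b), v in p.items()),
        "ClusterShade": sum((a + b - 2 * mu) ** 3 * v
                            for (a, b), v in p.items()),
        "ClusterTendency": sum((a + b - 2 * mu) ** 2 * v
                               for (a, b), v in p.items()),
        "Contrast": sum((a - b) ** 2 * v for (a, b), v in p.items()),
        "Correlation": 1.0 if var <= eps else
            (sum(a * b * v for (a, b), v in p.items()) - mu * mu) / var,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pdiff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(v / (1 + k) for k, v in pdiff.items()),
        "Idm": sum(v / (1 + k ** 2) for k, v in pdiff.items()),
        "Idmn": sum(v / (1 + (k / ng) ** 2) for k, v in pdiff.items()),
        "Idn": sum(v / (1 + k / ng) for k, v in pdiff.items()),
        "Imc1": 0.0 if hx <= eps else (hxy - hxy1) / hx,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(v / k ** 2 for k, v in pdiff.items() if k > 0),
        "JointEnergy": sum(v ** 2 for v in p.values()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": ent(psum.values()),
        "SumSquares": var,
    }
    return feats


def brute_glcm_features(levels, mask) -> dict[str, float]:
    grays = sorted(int(g) for g in np.unique(levels[mask]))
    acc: dict[str, list[float]] = {}
    for d in DIRECTIONS_13:
        if not brute_glcm(levels, mask, d):
            continue
        feats = brute_glcm_features_one_direction(levels, mask, d, grays)
        for k, v in feats.items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def brute_glrlm(levels, mask, direction, n_levels) -> np.ndarray:
    """Run-length counts by walking every line voxel by voxel."""
    nx, ny, nz = levels.shape
    d = np.array(direction)
    runs: list[tuple[int, int]] = []
    visited = set()
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or (x, y, z) in visited:
                    continue
                # walk back to the start of this run
                cx, cy, cz = x, y, z
                g = levels[x, y, z]
                while True:
                    px_, py_, pz_ = cx - d[0], cy - d[1], cz - d[2]
                    if 0 <= px_ < nx and 0 <= py_ < ny and 0 <= pz_ < nz \
                            and mask[px_, py_, pz_] and levels[px_, py_, pz_] == g:
                        cx, cy, cz = px_, py_, pz_
                    else:
                        break
                length = 0
                while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz \
                        and mask[cx, cy, cz] and levels[cx, cy, cz] == g:
                    visited.add((cx, cy, cz))
                    length += 1
                    cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                runs.append((int(g), length))
    max_len = max(l for _, l in runs)
    P = np.zeros((n_levels, max_len))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def rlm_features_from_matrix(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    feats = {k: 0.0 for k in
             ("ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
              "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
              "RunLengthNonUniformityNormalized", "RunPercentage",
              "GrayLevelVariance", "RunVariance", "RunEntropy",
              "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
              "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
              "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis")}
    mu_g = sum((i + 1) * P[i, j] / nr for i in range(P.shape[0])
               for j in range(P.shape[1]))
    mu_r = sum((j + 1) * P[i, j] / nr for i in range(P.shape[0])
               for j in range(P.shape[1]))
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            v = P[i, j]
            if v == 0:
                continue
            g, r = i + 1, j + 1
            feats["ShortRunEmphasis"] += v / r ** 2 / nr
            feats["LongRunEmphasis"] += v * r ** 2 / nr
            feats["GrayLevelVariance"] += v / nr * (g - mu_g) ** 2
            feats["RunVariance"] += v / nr * (r - mu_r) ** 2
            feats["RunEntropy"] -= v / nr * math.log2(v / nr)
            feats["LowGrayLevelRunEmphasis"] += v / g ** 2 / nr
            feats["HighGrayLevelRunEmphasis"] += v * g ** 2 / nr
            feats["ShortRunLowGrayLevelEmphasis"] += v / (g * r) ** 2 / nr
            feats["ShortRunHighGrayLevelEmphasis"] += v * g ** 2 / r ** 2 / nr
            feats["LongRunLowGrayLevelEmphasis"] += v * r ** 2 / g ** 2 / nr
            feats["LongRunHighGrayLevelEmphasis"] += v * (g * r) ** 2 / nr
    for i in range(P.shape[0]):
        feats["GrayLevelNonUniformity"] += P[i, :].sum() ** 2 / nr
        feats["GrayLevelNonUniformityNormalized"] += P[i, :].sum() ** 2 / nr ** 2
    for j in range(P.shape[1]):
        feats["RunLengthNonUniformity"] += P[:, j].sum() ** 2 / nr
        feats["RunLengthNonUniformityNormalized"] += P[:, j].sum() ** 2 / nr ** 2
    feats["RunPercentage"] = nr / n_voxels
    return feats


def brute_glrlm_features(levels, mask, n_levels) -> dict[str, float]:
    acc: dict[str, list[float]] = {}
    n_vox = int(mask.sum())
    for d in DIRECTIONS_13:
        P = brute_glrlm(levels, mask, d, n_levels)
        for k, v in rlm_features_from_matrix(P, n_vox).items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM (zones by flood fill over 26-connectivity)


def brute_glszm(levels, mask, n_levels) -> np.ndarray:
    zones = []
    visited = set()
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or (x, y, z) in visited:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                visited.add((x, y, z))
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in OFFSETS_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                                and mask[u, v, w] and levels[u, v, w] == g \
                                and (u, v, w) not in visited:
                            visited.add((u, v, w))
                            stack.append((u, v, w))
                zones.append((int(g), size))
    max_size = max(s for _, s in zones)
    P = np.zeros((n_levels, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def brute_glszm_features(levels, mask, n_levels) -> dict[str, float]:
    P = brute_glszm(levels, mask, n_levels)
    base = rlm_features_from_matrix(P, int(mask.sum()))
    rename = {
        "ShortRunEmphasis": "SmallAreaEmphasis",
        "LongRunEmphasis": "LargeAreaEmphasis",
        "RunLengthNonUniformity": "SizeZoneNonUniformity",
        "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "RunPercentage": "ZonePercentage",
        "RunVariance": "ZoneVariance",
        "RunEntropy": "ZoneEntropy",
        "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
        "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
    }
    return {rename.get(k, k): v for k, v in base.items()}


# ---------------------------------------------------------------------------
# GLDM


def brute_gldm(levels, mask, n_levels, alpha=0) -> np.ndarray:
    nx, ny, nz = levels.shape
    entries = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                g = int(levels[x, y, z])
                dep = 0
                for dx, dy, dz in OFFSETS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                            and mask[u, v, w] \
                            and abs(int(levels[u, v, w]) - g) <= alpha:
                        dep += 1
                entries.append((g, dep + 1))
    max_dep = max(d for _, d in entries)
    P = np.zeros((n_levels, max_dep))
    for g, d in entries:
        P[g - 1, d - 1] += 1
    return P


def brute_gldm_features(levels, mask, n_levels, alpha=0) -> dict[str, float]:
    P = brute_gldm(levels, mask, n_levels, alpha)
    nz = P.sum()
    feats = {k: 0.0 for k in
             ("SmallDependenceEmphasis", "LargeDependenceEmphasis",
              "GrayLevelNonUniformity", "DependenceNonUniformity",
              "DependenceNonUniformityNormalized", "GrayLevelVariance",
              "DependenceVariance", "DependenceEntropy",
              "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
              "SmallDependenceLowGrayLevelEmphasis",
              "SmallDependenceHighGrayLevelEmphasis",
              "LargeDependenceLowGrayLevelEmphasis",
              "LargeDependenceHighGrayLevelEmphasis")}
    mu_g = sum((i + 1) * P[i, j] / nz for i in range(P.shape[0])
               for j in range(P.shape[1]))
    mu_j = sum((j + 1) * P[i, j] / nz for i in range(P.shape[0])
               for j in range(P.shape[1]))
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            v = P[i, j]
            if v == 0:
                continue
            g, dep = i + 1, j + 1
            feats["SmallDependenceEmphasis"] += v / dep ** 2 / nz
            feats["LargeDependenceEmphasis"] += v * dep ** 2 / nz
            feats["GrayLevelVariance"] += v / nz * (g - mu_g) ** 2
            feats["DependenceVariance"] += v / nz * (dep - mu_j) ** 2
            feats["DependenceEntropy"] -= v / nz * math.log2(v / nz)
            feats["LowGrayLevelEmphasis"] += v / g ** 2 / nz
            feats["HighGrayLevelEmphasis"] += v * g ** 2 / nz
            feats["SmallDependenceLowGrayLevelEmphasis"] += v / (g * dep) ** 2 / nz
            feats["SmallDependenceHighGrayLevelEmphasis"] += v * g ** 2 / dep ** 2 / nz
            feats["LargeDependenceLowGrayLevelEmphasis"] += v * dep ** 2 / g ** 2 / nz
            feats["LargeDependenceHighGrayLevelEmphasis"] += v * (g * dep) ** 2 / nz
    for i in range(P.shape[0]):
        feats["GrayLevelNonUniformity"] += P[i, :].sum() ** 2 / nz
    for j in range(P.shape[1]):
        feats["DependenceNonUniformity"] += P[:, j].sum() ** 2 / nz
        feats["DependenceNonUniformityNormalized"] += P[:, j].sum() ** 2 / nz ** 2
    return feats


# ---------------------------------------------------------------------------
# NGTDM


def brute_ngtdm_features(levels, mask, n_levels) -> dict[str, float]:
    nx, ny, nz = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for dx, dy, dz in OFFSETS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                            and mask[u, v, w]:
                        nbrs.append(int(levels[u, v, w]))
                if not nbrs:
                    continue
                g = int(levels[x, y, z])
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    nvp = n_i.sum()
    p_i = n_i / nvp
    grays = [i + 1 for i in range(n_levels) if p_i[i] > 0]
    ngp = len(grays)
    ps = sum(p_i[g - 1] * s_i[g - 1] for g in grays)
    eps = 1e-12
    coarseness = 1.0 / ps if ps > eps else 1e6
    if ngp > 1:
        contrast = sum(p_i[a - 1] * p_i[b - 1] * (a - b) ** 2
                       for a in grays for b in grays) / (ngp * (ngp - 1)) \
            * s_i.sum() / nvp
        den = sum(abs(a * p_i[a - 1] - b * p_i[b - 1])
                  for a in grays for b in grays)
        busyness = ps / den if den > eps else 0.0
        complexity = sum(abs(a - b) * (p_i[a - 1] * s_i[a - 1]
                                       + p_i[b - 1] * s_i[b - 1])
                         / (p_i[a - 1] + p_i[b - 1])
                         for a in grays for b in grays) / nvp
        strength = sum((p_i[a - 1] + p_i[b - 1]) * (a - b) ** 2
                       for a in grays for b in grays) / s_i.sum() \
            if s_i.sum() > eps else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


# ---------------------------------------------------------------------------
# AUC by exhaustive pair counting


def brute_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Ring by brute-force distance enumeration


def brute_ring(tumor: np.ndarray, distance: float, spacing, in_plane: bool
               ) -> np.ndarray:
    nx, ny, nz = tumor.shape
    ring = np.zeros_like(tumor, dtype=bool)
    tum_idx = np.argwhere(tumor)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if tumor[x, y, z]:
                    continue
                best = np.inf
                for tx, ty, tz in tum_idx:
                    if in_plane and tz != z:
                        continue
                    dx = (x - tx) * spacing[0]
                    dy = (y - ty) * spacing[1]
                    dz = 0.0 if in_plane else (z - tz) * spacing[2]
                    best = min(best, math.sqrt(dx * dx + dy * dy + dz * dz))
                if best <= distance + 1e-9:
                    ring[x, y, z] = True
    return ring
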