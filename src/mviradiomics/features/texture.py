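"""Gray-level texture-matrix features: GLCM, GLSZM, GLRLM, NGTDM, GLDM.

All families operate on a discretized gray-level volume (integer levels
``1..Ng``, see :mod:`.discretize`) restricted to a binary mask.  Conventions:

* neighborhoods / zone connectivity are fully connected (26 neighbors in 3D,
  8 in 2D);
* GLCM and GLRLM accumulate one matrix per unique direction at offset 1
  (13 directions in 3D, 4 in 2D), compute each feature per direction and
  average over directions (GLCM matrices are symmetrized);
* degenerate regions (a single gray level, empty difference sets) return the
  documented finite conventions rather than NaN, so that downstream model
  benchmarking never sees missing values.

The functions are dimension-agnostic over 2-D and 3-D arrays; 2-D inputs are
mainly useful for worked examples and oracle tests.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .catalogue import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)

def unique_directions(ndim: int) -> list[tuple[int, ...]]:
    """Unique offset-1 directions up to sign: 13 in 3D, 4 in 2D."""
    dirs = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        # keep one of each +/- pair: first nonzero component positive
        first = next(o for o in off if o != 0)
        if first > 0:
            dirs.append(off)
    return dirs


def all_neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    """All 3**ndim - 1 unit-cube neighbor offsets (26 in 3D, 8 in 2D)."""
    return [
        off
        for off in itertools.product((-1, 0, 1), repeat=ndim)
        if any(o != 0 for o in off)
    ]


def _check(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if levels[mask].min() < 1:
        raise ValueError("gray levels must be >= 1")
    return levels, mask


def _shift_pairs(shape: tuple[int, ...], offset: tuple[int, ...]):
    """Index slices (src, dst) such that arr[dst] is arr[src] shifted by offset."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrices(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: list[tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Symmetric, per-direction normalized co-occurrence matrices.

    Returns an array of shape ``(n_directions, Ng, Ng)``; each direction's
    matrix sums to 1 (directions with no valid pair are dropped).
    """
    levels, mask = _check(levels, mask)
    if directions is None:
        directions = unique_directions(levels.ndim)
    ng = int(levels[mask].max())
    mats = []
    for off in directions:
        src, dst = _shift_pairs(levels.shape, off)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        m = np.zeros((ng, ng))
        np.add.at(m, (a, b), 1.0)
        m = m + m.T  # symmetric accumulation
        mats.append(m / m.sum())
    if not mats:
        raise ValueError("no voxel pairs in any direction (single-voxel mask?)")
    return np.stack(mats)


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    diff_avg = float((k_diff * p_diff).sum())
    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())

    pxpy = np.outer(px, py)
    nzm = (pxpy > 0) & nz
    hxy1 = float(-(p[nzm] * np.log2(pxpy[nzm])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    denom = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0)))

    if sig_x > 0 and sig_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0  # perfectly homogeneous region

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag].astype(float) ** 2).sum())

    # MCC via the Q matrix on present levels only
    present = px > 0
    if present.sum() <= 1:
        mcc = 1.0
    else:
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        pys = py[present]
        q = (ps[:, None, :] * ps[None, :, :] / (pxs[:, None, None] * pys[None, None, :])).sum(
            axis=2
        )
        eig = np.linalg.eigvals(q)
        eig = np.sort(eig.real)
        mcc = float(np.sqrt(max(eig[-2], 0.0)))

    pdnz = p_diff > 0
    psnz = p_sum > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": float((ii * p).sum()),
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff[pdnz] * np.log2(p_diff[pdnz])).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[psnz] * np.log2(p_sum[psnz])).sum()),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
        "MCC": mcc,
    }


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: list[tuple[int, ...]] | None = None,
) -> dict[str, float]:
    """24 co-occurrence features, averaged over directions."""
    mats = glcm_matrices(levels, mask, directions)
    per_dir = [_glcm_features_single(m) for m in mats]
    out = {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_FEATURES}
    return out


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zone matrix ``P[i-1, j-1]`` = number of connected zones of level i, size j."""
    levels, mask = _check(levels, mask)
    ng = int(levels[mask].max())
    structure = np.ones((3,) * levels.ndim, dtype=int)
    zone_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for lvl in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == lvl) & mask, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zone_counts[(int(lvl), int(s))] = zone_counts.get((int(lvl), int(s)), 0) + 1
            max_size = max(max_size, int(s))
    m = np.zeros((ng, max_size))
    for (lvl, size), c in zone_counts.items():
        m[lvl - 1, size - 1] = c
    return m


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """16 size-zone features.

    Notably GrayLevelNonUniformityNormalized (GLNN) = sum_i (sum_j P)^2 /
    N_z^2: lower values mean no single gray level dominates the zones, i.e.
    the region is more heterogeneous in gray-level composition.
    """
    levels, mask = _check(levels, mask)
    m = glszm_matrix(levels, mask)
    nz_total = m.sum()
    p = m / nz_total
    ng, ns = m.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, ns + 1, dtype=float)[None, :]
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pnz = p[p > 0]
    out = {
        "SmallAreaEmphasis": float((p / j**2).sum()),
        "LargeAreaEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((row**2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((row**2).sum() / nz_total**2),
        "SizeZoneNonUniformity": float((col**2).sum() / nz_total),
        "SizeZoneNonUniformityNormalized": float((col**2).sum() / nz_total**2),
        "ZonePercentage": float(nz_total / mask.sum()),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / i**2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * i**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }
    assert tuple(out) == GLSZM_FEATURES
    return out


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def glrlm_matrices(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: list[tuple[int, ...]] | None = None,
) -> list[np.ndarray]:
    """Run-length matrices ``P[i-1, j-1]`` (level i, run length j), one per direction."""
    levels, mask = _check(levels, mask)
    if directions is None:
        directions = unique_directions(levels.ndim)
    ng = int(levels[mask].max())
    shape = levels.shape
    coords = np.argwhere(mask)
    lvl_at = levels[mask]
    mats = []
    for off in directions:
        d = np.asarray(off)
        # run starts: predecessor out of bounds / out of mask / different level
        prev = coords - d
        in_bounds = np.all((prev >= 0) & (prev < shape), axis=1)
        same = np.zeros(len(coords), dtype=bool)
        if in_bounds.any():
            pi = tuple(prev[in_bounds].T)
            same[in_bounds] = mask[pi] & (levels[pi] == lvl_at[in_bounds])
        start = ~same
        pos = coords[start]
        lv = lvl_at[start]
        lengths = np.ones(len(pos), dtype=np.int64)
        active = np.arange(len(pos))
        cur = pos.copy()
        while active.size:
            nxt = cur[active] + d
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(active.size, dtype=bool)
            if ok.any():
                ni = tuple(nxt[ok].T)
                cont[ok] = mask[ni] & (levels[ni] == lv[active[ok]])
            lengths[active[cont]] += 1
            cur[active[cont]] = nxt[cont]
            active = active[cont]
        max_len = int(lengths.max())
        m = np.zeros((ng, max_len))
        np.add.at(m, (lv - 1, lengths - 1), 1.0)
        mats.append(m)
    return mats


def _glrlm_features_single(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = m.sum()
    p = m / nr
    ng, nl = m.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nl + 1, dtype=float)[None, :]
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pnz = p[p > 0]
    return {
        "ShortRunEmphasis": float((p / j**2).sum()),
        "LongRunEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((row**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((row**2).sum() / nr**2),
        "RunLengthNonUniformity": float((col**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((col**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (j - mu_j) ** 2).sum()),
        "RunEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelRunEmphasis": float((p / i**2).sum()),
        "HighGrayLevelRunEmphasis": float((p * i**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


def glrlm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: list[tuple[int, ...]] | None = None,
) -> dict[str, float]:
    """16 run-length features, averaged over directions."""
    levels, mask = _check(levels, mask)
    mats = glrlm_matrices(levels, mask, directions)
    n_vox = int(mask.sum())
    per_dir = [_glrlm_features_single(m, n_vox) for m in mats]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_FEATURES}


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def ngtdm_table(
    levels: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level tables ``(n_i, s_i)`` and the valid-voxel count N_vp.

    A voxel is *valid* when it has at least one masked neighbor; its
    contribution to ``s_i`` is ``|v - mean(masked neighbors)|``.
    """
    levels, mask = _check(levels, mask)
    ng = int(levels[mask].max())
    nsum = np.zeros(levels.shape)
    ncnt = np.zeros(levels.shape)
    for off in all_neighbor_offsets(levels.ndim):
        src, dst = _shift_pairs(levels.shape, off)
        nsum[dst] += np.where(mask[src], levels[src], 0)
        ncnt[dst] += mask[src]
    valid = mask & (ncnt > 0)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = levels[valid]
    diffs = np.abs(lv - nsum[valid] / ncnt[valid])
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, diffs)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """5 neighborhood gray-tone difference features.

    Degenerate conventions: a region with a single present gray level (or no
    valid neighborhoods) returns 0 for all five features.
    """
    n_i, s_i, nvp = ngtdm_table(levels, mask)
    if nvp == 0:
        return {name: 0.0 for name in NGTDM_FEATURES}
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i_vals = np.arange(1, len(n_i) + 1, dtype=float)

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 0.0

    if ngp > 1:
        pi_p = p_i[present]
        si_p = s_i[present]
        iv = i_vals[present]
        di = iv[:, None] - iv[None, :]
        contrast = float(
            (pi_p[:, None] * pi_p[None, :] * di**2).sum()
            / (ngp * (ngp - 1))
            * s_i.sum()
            / nvp
        )
        denom = np.abs(iv[:, None] * pi_p[:, None] - iv[None, :] * pi_p[None, :]).sum()
        busyness = float(ps / denom) if denom > 0 else 0.0
        complexity = float(
            (
                np.abs(di)
                * (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
                / (pi_p[:, None] + pi_p[None, :])
            ).sum()
            / nvp
        )
        s_total = si_p.sum()
        strength = (
            float(((pi_p[:, None] + pi_p[None, :]) * di**2).sum() / s_total)
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, alpha: int = 0
) -> np.ndarray:
    """Dependence matrix ``P[i-1, j-1]``: voxels of level i with dependence j.

    Dependence of a voxel = 1 + number of masked neighbors whose gray level
    differs by at most ``alpha``.
    """
    levels, mask = _check(levels, mask)
    ng = int(levels[mask].max())
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in all_neighbor_offsets(levels.ndim):
        src, dst = _shift_pairs(levels.shape, off)
        dep[dst] += mask[src] & (np.abs(levels[src] - levels[dst]) <= alpha)
    d = dep[mask] + 1
    lv = levels[mask]
    m = np.zeros((ng, int(d.max())))
    np.add.at(m, (lv - 1, d - 1), 1.0)
    return m


def gldm_features(
    levels: np.ndarray, mask: np.ndarray, alpha: int = 0
) -> dict[str, float]:
    """14 gray-level dependence features."""
    m = gldm_matrix(levels, mask, alpha)
    nz = m.sum()
    p = m / nz
    ng, nd = m.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nd + 1, dtype=float)[None, :]
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pnz = p[p > 0]
    out = {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((row**2).sum() / nz),
        "DependenceNonUniformity": float((col**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((col**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }
    assert tuple(out) == GLDM_FEATURES
    return out
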