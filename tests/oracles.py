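"""Independent brute-force oracles for texture features and region geometry.

Everything here is written as plain nested loops over voxels, deliberately
avoiding the vectorized code paths of the package, so that agreement between
the two is evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _neighbors(idx, shape):
    for off in itertools.product((-1, 0, 1), repeat=len(shape)):
        if all(o == 0 for o in off):
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= x < s for x, s in zip(nb, shape)):
            yield nb


def _half_directions(ndim):
    out = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        nz = [o for o in off if o != 0]
        if nz and nz[0] > 0:
            out.append(off)
    return out


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def brute_glcm_matrices(levels, mask, directions=None):
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    if directions is None:
        directions = _half_directions(levels.ndim)
    ng = int(levels[mask].max())
    mats = []
    for d in directions:
        m = np.zeros((ng, ng))
        for idx in np.ndindex(levels.shape):
            if not mask[idx]:
                continue
            nb = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= x < s for x, s in zip(nb, levels.shape)) and mask[nb]:
                a, b = levels[idx] - 1, levels[nb] - 1
                m[a, b] += 1
                m[b, a] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    return mats


def brute_glcm_features(levels, mask, directions=None):
    per_dir = [
        _brute_glcm_single(p) for p in brute_glcm_matrices(levels, mask, directions)
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def _brute_glcm_single(p):
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum(px[i] * ((i + 1) - mu_x) ** 2 for i in range(ng)))
    sig_y = math.sqrt(sum(py[j] * ((j + 1) - mu_y) ** 2 for j in range(ng)))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j + 2] += p[i, j]

    autoc = joint_avg = contrast = 0.0
    prom = shade = tend = 0.0
    energy = entropy = 0.0
    idm = idmn = idv = idn = invvar = 0.0
    sumsq = corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            a, b = i + 1, j + 1
            autoc += v * a * b
            joint_avg += v * a
            contrast += v * (a - b) ** 2
            prom += v * (a + b - mu_x - mu_y) ** 4
            shade += v * (a + b - mu_x - mu_y) ** 3
            tend += v * (a + b - mu_x - mu_y) ** 2
            energy += v * v
            if v > 0:
                entropy -= v * math.log2(v)
            idm += v / (1 + (a - b) ** 2)
            idmn += v / (1 + ((a - b) / ng) ** 2)
            idv += v / (1 + abs(a - b))
            idn += v / (1 + abs(a - b) / ng)
            if a != b:
                invvar += v / (a - b) ** 2
            sumsq += v * (a - mu_x) ** 2
            corr_num += v * a * b
    correlation = (
        (corr_num - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else 1.0
    )
    diff_avg = sum(k * p_diff[k] for k in range(ng))
    diff_ent = -sum(q * math.log2(q) for q in p_diff if q > 0)
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(ng))
    sum_avg = sum(k * p_sum[k] for k in range(len(p_sum)))
    sum_ent = -sum(q * math.log2(q) for q in p_sum if q > 0)

    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hy = -sum(q * math.log2(q) for q in py if q > 0)
    hxy1 = hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            if px[i] * py[j] > 0:
                if p[i, j] > 0:
                    hxy1 -= p[i, j] * math.log2(px[i] * py[j])
                hxy2 -= px[i] * py[j] * math.log2(px[i] * py[j])
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(1 - math.exp(-2 * (hxy2 - entropy)), 0.0))

    present = [i for i in range(ng) if px[i] > 0]
    if len(present) <= 1:
        mcc = 1.0
    else:
        q = np.zeros((len(present), len(present)))
        for ai, i in enumerate(present):
            for bi, j in enumerate(present):
                q[ai, bi] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k])
                    for k in present
                    if py[k] > 0
                )
        eig = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(eig[-2], 0.0))

    return {
        "Autocorrelation": autoc,
        "JointAverage": joint_avg,
        "ClusterProminence": prom,
        "ClusterShade": shade,
        "ClusterTendency": tend,
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": diff_var,
        "JointEnergy": energy,
        "JointEntropy": entropy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": idm,
        "Idmn": idmn,
        "Id": idv,
        "Idn": idn,
        "InverseVariance": invvar,
        "MaximumProbability": float(p.max()),
        "SumAverage": sum_avg,
        "SumEntropy": sum_ent,
        "SumSquares": sumsq,
        "MCC": mcc,
    }


# --------------------------------------------------------------------------
# GLSZM (flood-fill zone enumeration)
# --------------------------------------------------------------------------

def brute_glszm_zones(levels, mask):
    """List of (level, size) zones by BFS flood fill, full connectivity."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    seen = np.zeros(levels.shape, bool)
    zones = []
    for idx in np.ndindex(levels.shape):
        if not mask[idx] or seen[idx]:
            continue
        lvl = levels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for nb in _neighbors(cur, levels.shape):
                if mask[nb] and not seen[nb] and levels[nb] == lvl:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(lvl), size))
    return zones


def brute_glszm_features(levels, mask):
    zones = brute_glszm_zones(levels, mask)
    nz = len(zones)
    n_vox = int(np.asarray(mask, bool).sum())
    ng = int(np.asarray(levels)[np.asarray(mask, bool)].max())
    row = [0.0] * (ng + 1)
    sizes = sorted({s for _, s in zones})
    col = {s: 0.0 for s in sizes}
    for lvl, s in zones:
        row[lvl] += 1
        col[s] += 1
    mu_i = sum(lvl for lvl, _ in zones) / nz
    mu_j = sum(s for _, s in zones) / nz
    from collections import Counter

    probs = Counter(zones)
    ent = -sum((c / nz) * math.log2(c / nz) for c in probs.values())
    return {
        "SmallAreaEmphasis": sum(1 / s**2 for _, s in zones) / nz,
        "LargeAreaEmphasis": sum(s**2 for _, s in zones) / nz,
        "GrayLevelNonUniformity": sum(r**2 for r in row) / nz,
        "GrayLevelNonUniformityNormalized": sum(r**2 for r in row) / nz**2,
        "SizeZoneNonUniformity": sum(c**2 for c in col.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum(c**2 for c in col.values()) / nz**2,
        "ZonePercentage": nz / n_vox,
        "GrayLevelVariance": sum((lvl - mu_i) ** 2 for lvl, _ in zones) / nz,
        "ZoneVariance": sum((s - mu_j) ** 2 for _, s in zones) / nz,
        "ZoneEntropy": ent,
        "LowGrayLevelZoneEmphasis": sum(1 / lvl**2 for lvl, _ in zones) / nz,
        "HighGrayLevelZoneEmphasis": sum(lvl**2 for lvl, _ in zones) / nz,
        "SmallAreaLowGrayLevelEmphasis": sum(
            1 / (lvl**2 * s**2) for lvl, s in zones
        )
        / nz,
        "SmallAreaHighGrayLevelEmphasis": sum(
            lvl**2 / s**2 for lvl, s in zones
        )
        / nz,
        "LargeAreaLowGrayLevelEmphasis": sum(
            s**2 / lvl**2 for lvl, s in zones
        )
        / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(
            lvl**2 * s**2 for lvl, s in zones
        )
        / nz,
    }


# --------------------------------------------------------------------------
# GLRLM (naive run tracing)
# --------------------------------------------------------------------------

def brute_glrlm_runs(levels, mask, direction):
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    runs = []
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        prev = tuple(i - o for i, o in zip(idx, direction))
        if (
            all(0 <= x < s for x, s in zip(prev, levels.shape))
            and mask[prev]
            and levels[prev] == levels[idx]
        ):
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(i + o for i, o in zip(cur, direction))
            if (
                all(0 <= x < s for x, s in zip(nxt, levels.shape))
                and mask[nxt]
                and levels[nxt] == levels[idx]
            ):
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(levels[idx]), length))
    return runs


def brute_glrlm_features(levels, mask, directions=None):
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    if directions is None:
        directions = _half_directions(levels.ndim)
    n_vox = int(mask.sum())
    per_dir = []
    for d in directions:
        runs = brute_glrlm_runs(levels, mask, d)
        nr = len(runs)
        mu_i = sum(l for l, _ in runs) / nr
        mu_j = sum(j for _, j in runs) / nr
        from collections import Counter

        row = Counter(l for l, _ in runs)
        col = Counter(j for _, j in runs)
        probs = Counter(runs)
        ent = -sum((c / nr) * math.log2(c / nr) for c in probs.values())
        per_dir.append(
            {
                "ShortRunEmphasis": sum(1 / j**2 for _, j in runs) / nr,
                "LongRunEmphasis": sum(j**2 for _, j in runs) / nr,
                "GrayLevelNonUniformity": sum(c**2 for c in row.values()) / nr,
                "GrayLevelNonUniformityNormalized": sum(
                    c**2 for c in row.values()
                )
                / nr**2,
                "RunLengthNonUniformity": sum(c**2 for c in col.values()) / nr,
                "RunLengthNonUniformityNormalized": sum(
                    c**2 for c in col.values()
                )
                / nr**2,
                "RunPercentage": nr / n_vox,
                "GrayLevelVariance": sum((l - mu_i) ** 2 for l, _ in runs) / nr,
                "RunVariance": sum((j - mu_j) ** 2 for _, j in runs) / nr,
                "RunEntropy": ent,
                "LowGrayLevelRunEmphasis": sum(1 / l**2 for l, _ in runs) / nr,
                "HighGrayLevelRunEmphasis": sum(l**2 for l, _ in runs) / nr,
                "ShortRunLowGrayLevelEmphasis": sum(
                    1 / (l**2 * j**2) for l, j in runs
                )
                / nr,
                "ShortRunHighGrayLevelEmphasis": sum(
                    l**2 / j**2 for l, j in runs
                )
                / nr,
                "LongRunLowGrayLevelEmphasis": sum(
                    j**2 / l**2 for l, j in runs
                )
                / nr,
                "LongRunHighGrayLevelEmphasis": sum(
                    l**2 * j**2 for l, j in runs
                )
                / nr,
            }
        )
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def brute_ngtdm_features(levels, mask):
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    ng = int(levels[mask].max())
    n_i = [0.0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    nvp = 0
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        nb_vals = [levels[nb] for nb in _neighbors(idx, levels.shape) if mask[nb]]
        if not nb_vals:
            continue
        nvp += 1
        lvl = int(levels[idx])
        n_i[lvl] += 1
        s_i[lvl] += abs(lvl - sum(nb_vals) / len(nb_vals))
    if nvp == 0:
        return dict.fromkeys(
            ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"], 0.0
        )
    p_i = [n / nvp for n in n_i]
    present = [i for i in range(1, ng + 1) if p_i[i] > 0]
    ngp = len(present)
    ps = sum(p_i[i] * s_i[i] for i in present)
    coarse = 1.0 / ps if ps > 0 else 0.0
    if ngp > 1:
        contrast = (
            sum(
                p_i[i] * p_i[j] * (i - j) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
            * sum(s_i[i] for i in present)
            / nvp
        )
        denom = sum(
            abs(i * p_i[i] - j * p_i[j]) for i in present for j in present
        )
        busy = ps / denom if denom > 0 else 0.0
        compl = (
            sum(
                abs(i - j)
                * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                / (p_i[i] + p_i[j])
                for i in present
                for j in present
            )
            / nvp
        )
        s_tot = sum(s_i[i] for i in present)
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in present for j in present)
            / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busy = compl = strength = 0.0
    return {
        "Coarseness": coarse,
        "Contrast": contrast,
        "Busyness": busy,
        "Complexity": compl,
        "Strength": strength,
    }


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def brute_gldm_features(levels, mask, alpha=0):
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    entries = []  # (level, dependence)
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        dep = 1 + sum(
            1
            for nb in _neighbors(idx, levels.shape)
            if mask[nb] and abs(int(levels[nb]) - int(levels[idx])) <= alpha
        )
        entries.append((int(levels[idx]), dep))
    nz = len(entries)
    from collections import Counter

    row = Counter(l for l, _ in entries)
    col = Counter(j for _, j in entries)
    probs = Counter(entries)
    mu_i = sum(l for l, _ in entries) / nz
    mu_j = sum(j for _, j in entries) / nz
    ent = -sum((c / nz) * math.log2(c / nz) for c in probs.values())
    return {
        "SmallDependenceEmphasis": sum(1 / j**2 for _, j in entries) / nz,
        "LargeDependenceEmphasis": sum(j**2 for _, j in entries) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in row.values()) / nz,
        "DependenceNonUniformity": sum(c**2 for c in col.values()) / nz,
        "DependenceNonUniformityNormalized": sum(c**2 for c in col.values())
        / nz**2,
        "GrayLevelVariance": sum((l - mu_i) ** 2 for l, _ in entries) / nz,
        "DependenceVariance": sum((j - mu_j) ** 2 for _, j in entries) / nz,
        "DependenceEntropy": ent,
        "LowGrayLevelEmphasis": sum(1 / l**2 for l, _ in entries) / nz,
        "HighGrayLevelEmphasis": sum(l**2 for l, _ in entries) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            1 / (l**2 * j**2) for l, j in entries
        )
        / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            l**2 / j**2 for l, j in entries
        )
        / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            j**2 / l**2 for l, j in entries
        )
        / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            l**2 * j**2 for l, j in entries
        )
        / nz,
    }


# --------------------------------------------------------------------------
# geometry and AUC
# --------------------------------------------------------------------------

def brute_expand_region(core, liver, barrier, spacing, distance_mm):
    """All-pairs physical-distance peritumoral shell."""
    core = np.asarray(core, bool)
    liver = np.asarray(liver, bool)
    barrier = np.zeros_like(core) if barrier is None else np.asarray(barrier, bool)
    spacing = np.asarray(spacing, float)
    core_pts = np.argwhere(core) * spacing
    out = np.zeros_like(core)
    for idx in np.ndindex(core.shape):
        if core[idx] or not liver[idx] or barrier[idx]:
            continue
        pt = np.asarray(idx) * spacing
        d2 = ((core_pts - pt) ** 2).sum(axis=1)
        if d2.min() <= distance_mm**2:
            out[idx] = True
    return out


def brute_auc(scores, labels):
    """Pair-counting AUC with half-credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
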