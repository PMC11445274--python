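"""Independent brute-force oracles for radiomics features and majority votes.

Deliberately naive: explicit Python loops over voxel pairs and literal
textbook formulas, sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
]


def naive_discretize(values, bins):
    """Fixed-bin-count gray levels 1..bins (single level if constant)."""
    values = [float(v) for v in values]
    lo, hi = min(values), max(values)
    if hi <= lo:
        return [1 for _ in values]
    out = []
    for v in values:
        g = int(math.floor(bins * (v - lo) / (hi - lo))) + 1
        out.append(min(g, bins))
    return out


def naive_first_order(values, bins=32, voxel_volume=1.0):
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    p10, p25, p50, p75, p90 = (
        float(np.percentile(v, q)) for q in (10, 25, 50, 75, 90)
    )
    energy = sum(x * x for x in v)
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    hist = {}
    for g in naive_discretize(v, bins):
        hist[g] = hist.get(g, 0) + 1
    probs = [c / n for c in hist.values()]
    if var > 0:
        skew = (sum((x - mean) ** 3 for x in v) / n) / var**1.5
        kurt = (sum((x - mean) ** 4 for x in v) / n) / var**2
    else:
        skew = kurt = 0.0
    return {
        "energy": energy,
        "total_energy": voxel_volume * energy,
        "entropy": -sum(p * math.log2(p) for p in probs),
        "minimum": v[0],
        "p10": p10,
        "p90": p90,
        "maximum": v[-1],
        "mean": mean,
        "median": p50,
        "iqr": p75 - p25,
        "range": v[-1] - v[0],
        "mad": sum(abs(x - mean) for x in v) / n,
        "rmad": sum(abs(x - rmean) for x in robust) / len(robust) if robust else 0.0,
        "rms": math.sqrt(energy / n),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": var,
        "uniformity": sum(p * p for p in probs),
    }


def naive_glcm_one_direction(gray, member, offset):
    """Symmetric co-occurrence counts {(i, j): count} for one offset,
    counting only pairs with both voxels inside the member set."""
    counts = {}
    nz, ny, nx = gray.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not member[z, y, x]:
                    continue
                z2, y2, x2 = z + offset[0], y + offset[1], x + offset[2]
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                if not member[z2, y2, x2]:
                    continue
                a, b = int(gray[z, y, x]), int(gray[z2, y2, x2])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def naive_glcm_features_one(counts, levels=None):
    """The 24 texture features of one normalized symmetric GLCM.

    ``levels`` is the gray-level universe (all levels present in the
    supervoxel); levels without any pair in this direction keep zero
    marginals but still count toward Ng.
    """
    total = sum(counts.values())
    p = {k: c / total for k, c in counts.items()}
    if levels is None:
        levels = sorted({i for i, _ in p} | {j for _, j in p})
    ng = len(levels)
    px = {i: sum(v for (a, _), v in p.items() if a == i) for i in levels}
    py = {j: sum(v for (_, b), v in p.items() if b == j) for j in levels}
    mu_x = sum(i * px[i] for i in levels)
    mu_y = sum(j * py[j] for j in levels)
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in levels))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in levels))

    p_diff = {}
    p_sum = {}
    for (i, j), v in p.items():
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + v
        p_sum[i + j] = p_sum.get(i + j, 0.0) + v
    diff_avg = sum(k * v for k, v in p_diff.items())
    sum_avg = sum(k * v for k, v in p_sum.items())

    eps = np.spacing(1.0)
    hxy = -sum(v * math.log2(v + eps) for v in p.values())
    hx = -sum(v * math.log2(v + eps) for v in px.values())
    hy = -sum(v * math.log2(v + eps) for v in py.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j] + eps) for (i, j), v in p.items())
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + eps)
        for i in levels
        for j in levels
    )
    max_h = max(hx, hy)
    imc1 = (hxy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    if sig_x > 0 and sig_y > 0:
        corr = (
            sum(i * j * v for (i, j), v in p.items()) - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        corr = 1.0

    if ng > 1:
        Q = np.zeros((ng, ng))
        li = {lv: n for n, lv in enumerate(levels)}
        for a in levels:
            for b in levels:
                s = 0.0
                for k in levels:
                    pak = p.get((a, k), 0.0)
                    pbk = p.get((b, k), 0.0)
                    if px[a] > 0 and py[k] > 0:
                        s += pak * pbk / (px[a] * py[k])
                Q[li[a], li[b]] = s
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0

    return {
        "autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "joint_average": mu_x,
        "cluster_prominence": sum(
            (i + j - mu_x - mu_y) ** 4 * v for (i, j), v in p.items()
        ),
        "cluster_shade": sum(
            (i + j - mu_x - mu_y) ** 3 * v for (i, j), v in p.items()
        ),
        "cluster_tendency": sum(
            (i + j - mu_x - mu_y) ** 2 * v for (i, j), v in p.items()
        ),
        "contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "correlation": corr,
        "difference_average": diff_avg,
        "difference_entropy": -sum(
            v * math.log2(v + eps) for v in p_diff.values()
        ),
        "difference_variance": sum(
            (k - diff_avg) ** 2 * v for k, v in p_diff.items()
        ),
        "joint_energy": sum(v * v for v in p.values()),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items()),
        "idmn": sum(
            v / (1.0 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()
        ),
        "id": sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items()),
        "idn": sum(v / (1.0 + abs(i - j) / ng) for (i, j), v in p.items()),
        "inverse_variance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "maximum_probability": max(p.values()),
        "sum_average": sum_avg,
        "sum_entropy": -sum(v * math.log2(v + eps) for v in p_sum.values()),
        "sum_squares": sum((i - mu_x) ** 2 * v for (i, j), v in p.items()),
        "mcc": mcc,
    }


def naive_glcm_features(volume, member, bins=32):
    """Direction-averaged GLCM features of one voxel set (13 offsets)."""
    member = np.asarray(member, bool)
    gray = np.zeros(member.shape, int)
    vals = np.asarray(volume, float)[member]
    disc = naive_discretize(list(vals), bins)
    for (idx, g) in zip(np.argwhere(member), disc):
        gray[tuple(idx)] = g

    acc = None
    nvalid = 0
    for off in OFFSETS_13:
        counts = naive_glcm_one_direction(gray, member, off)
        if not counts:
            continue
        feats = naive_glcm_features_one(counts, sorted(set(disc)))
        nvalid += 1
        if acc is None:
            acc = dict(feats)
        else:
            for k, v in feats.items():
                acc[k] += v
    if acc is None:
        return None
    return {k: v / nvalid for k, v in acc.items()}


def naive_majority_labels(ids, labels, tp_code=1, psp_code=2):
    """Per-supervoxel majority label by explicit per-id histogram count."""
    out = {}
    for i in np.unique(ids[ids > 0]):
        lab = labels[ids == i]
        n_tp = int((lab == tp_code).sum())
        n_psp = int((lab == psp_code).sum())
        out[int(i)] = {
            "label": tp_code if n_tp >= n_psp else psp_code,
            "majority_fraction": max(n_tp, n_psp) / (n_tp + n_psp),
            "n_voxels": n_tp + n_psp,
        }
    return out
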