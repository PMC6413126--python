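"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over the mathematical definitions,
deliberately sharing no code with the package.
"""

import numpy as np


def brute_force_normals(points: np.ndarray, radius: float):
    """All-pairs neighborhood search + explicit per-point eigen-solve.

    Mirrors the estimation contract: closed ball including the point, population
    covariance about the neighborhood mean, smallest-eigenvalue eigenvector,
    flipped to z <= 0; invalid when < 3 neighbors or the two smallest
    eigenvalues are relatively tied.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    normals = np.zeros((n, 3))
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        neigh = []
        for j in range(n):
            if np.sqrt(np.sum((points[i] - points[j]) ** 2)) <= radius:
                neigh.append(points[j])
        neigh = np.array(neigh)
        if len(neigh) < 3:
            continue
        mu = neigh.mean(axis=0)
        cov = np.zeros((3, 3))
        for p in neigh:
            d = p - mu
            cov += np.outer(d, d)
        cov /= len(neigh)
        w, v = np.linalg.eigh(cov)
        scale = max(w[2], np.finfo(float).tiny)
        if w[2] <= 0 or (w[1] - w[0]) <= 1e-9 * scale:
            continue
        nrm = v[:, 0]
        if nrm[2] > 0:
            nrm = -nrm
        elif nrm[2] == 0:
            if nrm[0] < 0 or (nrm[0] == 0 and nrm[1] < 0):
                nrm = -nrm
        normals[i] = nrm
        valid[i] = True
    return normals, valid


def brute_force_regions(pixels: np.ndarray, normals: np.ndarray,
                        valid: np.ndarray):
    """Quadrant accumulation by explicit midline comparisons per pixel."""
    rows = pixels[:, 0]
    cols = pixels[:, 1]
    rmid = (rows.min() + rows.max()) / 2.0
    cmid = (cols.min() + cols.max()) / 2.0
    acc = {"TL": np.zeros(3), "TR": np.zeros(3),
           "BL": np.zeros(3), "BR": np.zeros(3)}
    for k in range(len(pixels)):
        if not valid[k]:
            continue
        key = ("T" if rows[k] <= rmid else "B") + \
              ("L" if cols[k] <= cmid else "R")
        acc[key] = acc[key] + normals[k]
    return acc


def oracle_angle(uL, uR, plane: str) -> float:
    """Step-by-step projection/reflection/arccos evaluation."""
    uL = np.asarray(uL, float)
    uR = np.asarray(uR, float)
    if plane == "transverse":
        a = np.array([uL[0], 0.0, uL[2]])
        b = np.array([uR[0], 0.0, uR[2]])
        z = np.array([0.0, 0.0, 1.0])
        b = 2.0 * np.dot(z, b) * z - b
    elif plane == "sagittal":
        a = np.array([0.0, uL[1], uL[2]])
        b = np.array([0.0, uR[1], uR[2]])
    elif plane == "coronal":
        a = np.array([uL[0], uL[1], 0.0])
        b = np.array([uR[0], uR[1], 0.0])
        y = np.array([0.0, 1.0, 0.0])
        b = 2.0 * np.dot(y, b) * y - b
    else:
        raise ValueError(plane)
    cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


def oracle_basic_index(region_vectors, plane: str) -> float:
    """Eq.-by-eq. top + bottom evaluation from the four accumulated vectors."""
    return (oracle_angle(region_vectors.vTL, region_vectors.vTR, plane)
            + oracle_angle(region_vectors.vBL, region_vectors.vBR, plane))


def pair_count_auc(normal_scores, abnormal_scores) -> float:
    """Mann-Whitney AUC by enumerating every (abnormal, normal) pair."""
    wins = 0.0
    for a in abnormal_scores:
        for n in normal_scores:
            if a > n:
                wins += 1.0
            elif a == n:
                wins += 0.5
    return wins / (len(abnormal_scores) * len(normal_scores))
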