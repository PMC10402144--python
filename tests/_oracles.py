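"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (explicit loops, no shared code with
the package) so it can serve as an oracle for the vectorized
implementations.
"""

import math

import numpy as np


def lddt_brute(ca_model, ca_ref, radius=10.0, tolerances=(0.5, 1.0, 2.0, 4.0)):
    """Overall and per-residue LDDT by explicit pair/tolerance enumeration."""
    n = len(ca_ref)
    num = den = 0
    per_num = [0.0] * n
    per_den = [0] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d_ref = math.dist(ca_ref[i], ca_ref[j])
            if d_ref >= radius:
                continue
            d_mod = math.dist(ca_model[i], ca_model[j])
            delta = abs(d_ref - d_mod)
            s = sum(1 for t in tolerances if delta < t) / len(tolerances)
            num += s
            den += 1
            per_num[i] += s
            per_den[i] += 1
    overall = num / den if den else None
    per_res = [
        (per_num[i] / per_den[i]) if per_den[i] else None for i in range(n)
    ]
    return overall, per_res


def auc_pairwise(scores, labels):
    """Mann-Whitney AUC: fraction of positive/negative pairs ranked correctly."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = wins = 0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def mobile_runs_brute(profile, threshold=80.0, min_len=3):
    """Contiguous low-confidence runs by explicit scanning."""
    runs = []
    current = []
    prev = None
    for chain, pos, plddt in profile:
        if current and not (chain == prev[0] and pos == prev[1] + 1):
            if len(current) >= min_len:
                runs.append((current[0][0], current[0][1], current[-1][1]))
            current = []
        if plddt < threshold:
            current.append((chain, pos))
        else:
            if len(current) >= min_len:
                runs.append((current[0][0], current[0][1], current[-1][1]))
            current = []
        prev = (chain, pos)
    if len(current) >= min_len:
        runs.append((current[0][0], current[0][1], current[-1][1]))
    return runs


def coarse_score_brute(rec_cb, lig_cb, d_clash=3.5, w_rep=10.0, w_att=1.0):
    """Cross-partner contact score by explicit per-pair summation."""

    def switch(d):
        if d <= 3.5 or d >= 8.0:
            return 0.0
        if d < 4.0:
            return 0.5 * (1.0 - math.cos(math.pi * (d - 3.5) / 0.5))
        if d <= 6.0:
            return 1.0
        return 0.5 * (1.0 + math.cos(math.pi * (d - 6.0) / 2.0))

    e = 0.0
    for a in rec_cb:
        for b in lig_cb:
            d = math.dist(a, b)
            e += w_rep * max(0.0, d_clash - d) ** 2 - w_att * switch(d)
    return e


def interface_residues_brute(residues_a, residues_b, cutoff=8.0):
    """Index sets of interfacial residues by exhaustive atom-pair scanning."""
    hits_a, hits_b = set(), set()
    for i, ra in enumerate(residues_a):
        for j, rb in enumerate(residues_b):
            for atom_a in ra.atoms:
                for atom_b in rb.atoms:
                    if math.dist(atom_a.coords, atom_b.coords) < cutoff:
                        hits_a.add(i)
                        hits_b.add(j)
    return hits_a, hits_b


def random_rotation_rmsd_min(a, b, n_rotations, rng):
    """Minimum RMSD of a onto b over random rotations (translation optimal)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    q = rng.normal(size=(n_rotations, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n_rotations, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    rotated = np.einsum("rij,nj->rni", R, a0)
    rmsds = np.sqrt(np.mean(np.sum((rotated - b0) ** 2, axis=2), axis=1))
    return float(rmsds.min())
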