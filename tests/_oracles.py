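"""Independent reference implementations used by the tests.

Everything here is deliberately naive — pure-Python loops and closed-form
arithmetic — so it shares no code path with the package implementations it
checks.
"""

import itertools
import math

import numpy as np


def brute_force_hbonds(ensemble, frame_index, donors, acceptors, criteria):
    """O(N²) H-bond search: all donor-acceptor pairs, all bonded hydrogens."""
    coords = ensemble.frames[frame_index]
    index = ensemble.atom_index()
    residue_of = ensemble.residue_of_atom()
    atoms = ensemble.atoms
    found = set()
    for ds in donors:
        for as_ in acceptors:
            di, ai = index[ds], index[as_]
            rd, ra = residue_of[di], residue_of[ai]
            if rd == ra or rd.role == ra.role:
                continue
            d = math.dist(coords[di], coords[ai])
            if d > criteria.heavy_distance_cutoff:
                continue
            for hs in atoms[di].bonded_hydrogens:
                h = coords[index[hs]]
                vd = coords[di] - h
                va = coords[ai] - h
                cosang = float(np.dot(vd, va) / (np.linalg.norm(vd) * np.linalg.norm(va)))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle >= criteria.dha_angle_cutoff:
                    found.add((ds, hs, as_))
                    break
    return found


def lj_energy(rmin_half_1, eps1, rmin_half_2, eps2, r):
    rmin = rmin_half_1 + rmin_half_2
    eps = math.sqrt(eps1 * eps2)
    return eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)


def coulomb_vacuum(q1, q2, r, eps_in, k=332.0636):
    return k * q1 * q2 / (eps_in * r)


def gb_reaction_field(q1, q2, r, radius1, radius2, eps_in, eps_solv, k=332.0636):
    f_gb = math.sqrt(r * r + radius1 * radius2 * math.exp(-r * r / (4 * radius1 * radius2)))
    return -k * (1 / eps_in - 1 / eps_solv) * q1 * q2 / f_gb


def exhaustive_rmsatd(coords_a, coords_b, elements_a, elements_b):
    """Minimum RMS over every same-element one-to-one pairing (small inputs)."""
    by_el_a, by_el_b = {}, {}
    for i, el in enumerate(elements_a):
        by_el_a.setdefault(el, []).append(i)
    for i, el in enumerate(elements_b):
        by_el_b.setdefault(el, []).append(i)
    common = sorted(set(by_el_a) & set(by_el_b))

    def pairings(el):
        ia, ib = by_el_a[el], by_el_b[el]
        if len(ia) <= len(ib):
            for perm in itertools.permutations(ib, len(ia)):
                yield list(zip(ia, perm))
        else:
            for perm in itertools.permutations(ia, len(ib)):
                yield list(zip(perm, ib))

    best = None
    for combo in itertools.product(*(list(pairings(el)) for el in common)):
        sq = 0.0
        n = 0
        for matches in combo:
            for i, j in matches:
                sq += float(np.sum((coords_a[i] - coords_b[j]) ** 2))
                n += 1
        value = math.sqrt(sq / n)
        best = value if best is None else min(best, value)
    return best


def pearson_direct(x, y):
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def welch_direct(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, p


def sklearn_dbscan_labels(distance_matrix, epsilon, minpoints):
    from sklearn.cluster import DBSCAN

    model = DBSCAN(eps=epsilon, min_samples=minpoints, metric="precomputed")
    return model.fit_predict(distance_matrix)


def dbscan_labels_compatible(distance_matrix, epsilon, minpoints, a, b):
    """Partition agreement modulo border-point policy.

    Core points (>= minpoints neighbours within ε, self included) must form
    identical clusters up to label permutation, and the noise sets must match
    exactly.  A border point may be claimed by any cluster with a core point
    within ε of it — implementations differ here — so each border label only
    has to be *reachable*, in both labelings.
    """
    d = np.asarray(distance_matrix)
    a, b = np.asarray(a), np.asarray(b)
    n = d.shape[0]
    core = np.array([(d[i] <= epsilon).sum() >= minpoints for i in range(n)])
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    used = set()
    for i in np.nonzero(core)[0]:
        la, lb = a[i], b[i]
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in used:
                return False
            mapping[la] = lb
            used.add(lb)
    for i in np.nonzero(~core)[0]:
        if a[i] == -1:
            continue
        core_nb = [j for j in np.nonzero(core)[0] if d[i, j] <= epsilon]
        if a[i] not in {a[j] for j in core_nb} or b[i] not in {b[j] for j in core_nb}:
            return False
    return True


def labels_agree_up_to_permutation(a, b):
    """Same partition: noise matches exactly, clusters match as sets."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    used = set()
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in used:
                return False
            mapping[la] = lb
            used.add(lb)
    return True
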