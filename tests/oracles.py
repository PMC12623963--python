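"""Independent brute-force oracles used by the test suite and the
acceptance script.

These deliberately avoid the library's search code paths: superposition
uses scipy's ``Rotation.align_vectors``, and the TM/GDT searches
enumerate every contiguous seed window plus a dense rotation grid with
residue-pair-anchored translations (narrow optima require the
translation to be right within ~d0, which centroid-style translations
miss).  The best few thousand candidates are refined by reweighted
superposition and the top frames polished with a derivative-free
optimiser.  The signed-rank p-value is computed by enumerating all
sign assignments.  Meant for chains of ~15 residues or fewer.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata


def kabsch_scipy(ref: np.ndarray, mov: np.ndarray):
    """Least-squares superposition via scipy (independent of the library)."""
    cr, cm = ref.mean(axis=0), mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - cr, mov - cm)
    R = rot.as_matrix()
    return R, cr - R @ cm


def tm_of_transform(A, B, R, t, d0, l_ref):
    d = np.linalg.norm(A - (B @ R.T + t), axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def _window_transforms(A, B):
    out = []
    n = len(A)
    for w in range(3, n + 1):
        for s in range(n - w + 1):
            out.append(kabsch_scipy(A[s : s + w], B[s : s + w]))
    return out


def _grid_candidates(A, B, d0, step):
    """Euler grid rotations paired with centroid/reweighted and
    residue-pair-anchored translations; returns (Rs, ts) stacks."""
    angles = np.array(list(product(
        range(0, 360, step), range(0, 181, step), range(0, 360, step)
    )))
    Rg = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()  # (g,3,3)
    RB = np.einsum("gij,nj->gni", Rg, B)  # (g,n,3)
    tc = A.mean(axis=0)[None, :] - RB.mean(axis=1)
    for _ in range(3):
        d = np.linalg.norm(A[None, :, :] - RB - tc[:, None, :], axis=2)
        w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
        tc = np.einsum("gn,gni->gi", w, A[None, :, :] - RB) / w.sum(axis=1)[:, None]
    t_pin = A[None, :, :] - RB  # (g, n, 3): translation pinning pair i exactly
    g, n, _ = t_pin.shape
    Rs = np.concatenate([Rg, np.repeat(Rg, n, axis=0)])
    ts = np.concatenate([tc, t_pin.reshape(g * n, 3)])
    return Rs, ts


def _score_batch(A, B, Rs, ts, d0, l_ref):
    RB = np.einsum("cij,nj->cni", Rs, B)
    d = np.linalg.norm(A[None, :, :] - RB - ts[:, None, :], axis=2)
    return (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref


def _weighted_kabsch_batch(A, B, w):
    """Batched weighted Kabsch: A fixed ref (n,3); B fixed mov (n,3);
    w (c, n) per-candidate weights."""
    wsum = w.sum(axis=1)[:, None]
    ca = (w[:, :, None] * A[None, :, :]).sum(axis=1) / wsum
    cb = (w[:, :, None] * B[None, :, :]).sum(axis=1) / wsum
    Ac = A[None, :, :] - ca[:, None, :]
    Bc = B[None, :, :] - cb[:, None, :]
    H = np.einsum("cn,cni,cnj->cij", w, Bc, Ac)
    U, _, Vt = np.linalg.svd(H)
    det = np.sign(np.linalg.det(np.einsum("cji,ckj->cik", Vt, U)))
    Vt = Vt.copy()
    Vt[:, 2, :] *= det[:, None]
    R = np.einsum("cji,ckj->cik", Vt, U)
    t = ca - np.einsum("cij,cj->ci", R, cb)
    return R, t


def _irls_batch(A, B, Rs, ts, d0, l_ref, iters=20, collect=None):
    """Reweighted-superposition ascent from every candidate at once.

    ``collect(d)`` (d of shape (candidates, n)) is invoked at every
    iteration so counting objectives can harvest intermediate frames."""
    best = np.full(len(Rs), -np.inf)
    best_frames = (Rs.copy(), ts.copy())
    for _ in range(iters):
        RB = np.einsum("cij,nj->cni", Rs, B)
        d = np.linalg.norm(A[None, :, :] - RB - ts[:, None, :], axis=2)
        if collect is not None:
            collect(d)
        tm = (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref
        gain = tm > best
        best_frames[0][gain] = Rs[gain]
        best_frames[1][gain] = ts[gain]
        np.maximum(best, tm, out=best)
        w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
        Rs, ts = _weighted_kabsch_batch(A, B, w)
    return best, best_frames


def _subset_minimax_oracle(A, B, collect, thresholds=None,
                           schedule=((1.0, 6), (2.0, 6), (4.0, 6),
                                     (8.0, 6), (16.0, 6), (32.0, 6)),
                           margin=1.25, per_threshold=40):
    """Chebyshev-style fit of every residue subset of size >= 3:
    reweighted Kabsch with weights d^q restricted to the subset (q
    annealed upward) pulls the whole subset under a common distance
    ceiling, deciding whether it is jointly superimposable; subsets
    stalling just above a cutoff get a smooth-max Nelder-Mead polish.
    ``collect`` sees every frame."""
    n = len(A)
    masks = np.arange(1, 2**n, dtype=np.uint32)
    w0 = ((masks[:, None] >> np.arange(n)) & 1).astype(np.float64)
    w0 = w0[w0.sum(axis=1) >= 3]
    member = w0.astype(bool)
    Rs, ts = _weighted_kabsch_batch(A, B, w0)
    subset_maxd = np.full(len(w0), np.inf)
    for q, iters in schedule:
        for _ in range(iters):
            RB = np.einsum("cij,nj->cni", Rs, B)
            d = np.linalg.norm(A[None, :, :] - RB - ts[:, None, :], axis=2)
            collect(d)
            np.minimum(subset_maxd, np.where(member, d, 0.0).max(axis=1),
                       out=subset_maxd)
            w = w0 * (np.maximum(d, 1e-6) ** q + 1e-9)
            Rs, ts = _weighted_kabsch_batch(A, B, w)
    RB = np.einsum("cij,nj->cni", Rs, B)
    d = np.linalg.norm(A[None, :, :] - RB - ts[:, None, :], axis=2)
    collect(d)
    np.minimum(subset_maxd, np.where(member, d, 0.0).max(axis=1),
               out=subset_maxd)
    if thresholds is None:
        return
    sizes = member.sum(axis=1)
    polished = set()
    for thr in np.asarray(thresholds, float):
        certified = sizes[subset_maxd <= thr].max(initial=0)
        cand = np.flatnonzero((subset_maxd > thr)
                              & (subset_maxd <= margin * thr)
                              & (sizes > certified))
        order = cand[np.lexsort((subset_maxd[cand], -sizes[cand]))]
        for k in order[:per_threshold]:
            k = int(k)
            if k in polished:
                continue
            polished.add(k)
            S = np.flatnonzero(member[k])
            AS, BS = A[S], B[S]

            def smooth_max(x, T=0.05):
                Rm = Rotation.from_rotvec(x[:3]).as_matrix()
                dS = np.linalg.norm(AS - (BS @ Rm.T + x[3:]), axis=1)
                m = dS.max()
                return m + T * np.log(np.exp((dS - m) / T).sum())

            x0 = np.concatenate([Rotation.from_matrix(Rs[k]).as_rotvec(),
                                 ts[k]])
            for _ in range(2):  # restart from the endpoint for robustness
                res = minimize(smooth_max, x0, method="Nelder-Mead",
                               options={"xatol": 1e-7, "fatol": 1e-10,
                                        "maxiter": 2000})
                x0 = res.x
            Rm = Rotation.from_rotvec(res.x[:3]).as_matrix()
            dfull = np.linalg.norm(A - (B @ Rm.T + res.x[3:]), axis=1)
            collect(dfull[None, :])


def _all_candidates(A, B, d0, l_ref, step):
    wins = _window_transforms(A, B)
    Rw = np.stack([R for R, _ in wins])
    tw = np.stack([t for _, t in wins])
    Rg, tg = _grid_candidates(A, B, d0, step)
    Rs = np.concatenate([Rw, Rg])
    ts = np.concatenate([tw, tg])
    scores = _score_batch(A, B, Rs, ts, d0, l_ref)
    return Rs, ts, scores


def _polish(A, B, d0, l_ref, starts, maxiter=2000, restarts=2):
    """Nelder-Mead ascent on the TM objective from each start frame."""
    out = []

    def negtm(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return -tm_of_transform(A, B, R, x[3:], d0, l_ref)

    for R, t in starts:
        x0 = np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
        res = None
        for _ in range(restarts):
            res = minimize(negtm, x0, method="Nelder-Mead",
                           options={"xatol": 1e-7, "fatol": 1e-12,
                                    "maxiter": maxiter})
            x0 = res.x
        out.append((-res.fun, Rotation.from_rotvec(res.x[:3]).as_matrix(),
                    res.x[3:]))
    return out


def oracle_tm(A, B, d0, l_ref, step=18, n_irls=1200, n_polish=8):
    """Brute-force TM-score: exhaustive seeds + rotation grid with
    pair-anchored translations + batched reweighted refinement + polish."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Rs, ts, scores = _all_candidates(A, B, d0, l_ref, step)
    top = np.argsort(scores)[::-1][:n_irls]
    refined, (Rf, tf) = _irls_batch(A, B, Rs[top], ts[top], d0, l_ref)
    order = np.argsort(refined)[::-1][:n_polish]
    polished = _polish(A, B, d0, l_ref, [(Rf[k], tf[k]) for k in order])
    return max(float(scores.max()), float(refined.max()),
               max(s for s, _, _ in polished))


def oracle_gdt(A, B, thresholds, l_ref, d0=0.5, step=30, n_refine=60):
    """Brute-force GDT: fractions maximised over exhaustive window and
    residue-triple seeds, a rotation grid with pair-anchored
    translations, reweighted refinements at every threshold's distance
    scale, rank-trimmed Chebyshev growth, and per-threshold iterative
    re-superposition.  Every visited frame is counted."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    thresholds = np.asarray(thresholds, float)
    best = np.zeros(len(thresholds))

    def count_d(d):  # d: (c, n) distances per frame
        frac = (d[:, :, None] <= thresholds[None, None, :]).sum(axis=1) / l_ref
        np.maximum(best, frac.max(axis=0), out=best)

    def update_batch(Rs, ts):
        RB = np.einsum("cij,nj->cni", Rs, B)
        count_d(np.linalg.norm(A[None, :, :] - RB - ts[:, None, :], axis=2))

    def update(R, t):
        d = np.linalg.norm(A - (B @ R.T + t), axis=1)
        np.maximum(best, (d[:, None] <= thresholds).sum(axis=0) / l_ref, out=best)

    def mask_refine(R, t, thr):
        prev = None
        for _ in range(30):
            d = np.linalg.norm(A - (B @ R.T + t), axis=1)
            update(R, t)
            mask = d <= thr
            if mask.sum() < 3 or (prev is not None and np.array_equal(mask, prev)):
                break
            prev = mask
            R, t = kabsch_scipy(A[mask], B[mask])
        return R, t

    windows = _window_transforms(A, B)
    for R0, t0 in windows:
        Rc, tc = R0, t0
        for thr in sorted(thresholds, reverse=True):
            mask_refine(R0, t0, thr)
            Rc, tc = mask_refine(Rc, tc, thr)  # loose-to-tight cascade

    # reweighted ascent from every window seed at each threshold's scale
    Rw = np.stack([R for R, _ in windows])
    tw = np.stack([t for _, t in windows])
    for scale in thresholds:
        refined, (Rf, tf) = _irls_batch(A, B, Rw.copy(), tw.copy(), scale,
                                        l_ref, iters=12, collect=count_d)
        update_batch(Rf, tf)
        for k in range(len(Rf)):
            mask_refine(Rf[k], tf[k], scale)

    if len(A) <= 12:
        # exhaustive subset feasibility: minimax-fit every residue
        # subset and count all thresholds at each visited frame
        _subset_minimax_oracle(A, B, count_d, thresholds=thresholds)

    # grid + pinned-translation candidates counted at each threshold's
    # own distance scale, the best mask-refined at that threshold
    for scale in thresholds:
        Rs, ts, scores = _all_candidates(A, B, scale, l_ref, step)
        update_batch(Rs, ts)
        for k in np.argsort(scores)[::-1][:n_refine]:
            mask_refine(Rs[k], ts[k], scale)
    return float(best.mean())


def exact_wilcoxon_greater(a, b):
    """One-sided signed-rank p-value by enumerating all 2^n sign vectors."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    assert n <= 16, "enumeration oracle limited to small n"
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n
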