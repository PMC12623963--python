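"""CA-based structure superposition and accuracy scores.

TM-score and GDT-TS are computed over the residues shared (by author
number) between a reference and a model.  Both scores maximise over
rigid-body superpositions found by a deterministic seed-window search:
superpose on a contiguous window, then alternate between selecting
close residue pairs and re-superposing on them, keeping the best score
seen at any superposition.  There are no randomised restarts, so scores
are bit-reproducible.

TM-score is normalised by the number of residues in the reference
(first argument); the pairwise similarity matrix symmetrises the two
directions by their mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .containers import StructureModel
from .errors import ArgumentError

__all__ = [
    "ScoringParams",
    "SuperpositionResult",
    "kabsch_superpose",
    "tm_score",
    "gdt_ts",
    "tm_d0",
    "pairwise_matrix",
]

#: cutoff floor for the residue-selection step of the iterative
#: refinement; below d0 the selection would starve on short chains.
_REFINE_CUTOFF_FLOOR = 3.0


@dataclass(frozen=True)
class ScoringParams:
    """Hyperparameters of the superposition search.

    ``seed_window_lengths`` may mix integers with the strings ``"half"``
    and ``"full"`` (resolved against the number of aligned residues).
    ``("full",)`` restricts the search to one global seed — much faster
    and adequate for pools of same-fold decoys — and enables the
    vectorised pairwise fast path.
    """

    d0_floor: float = 0.5
    gdt_thresholds: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    seed_window_lengths: tuple[int | str, ...] = (3, 5, 7, "half", "full")
    seed_stride: int | None = None  # default: max(1, n_aligned // 20)
    #: below this chain length every window length is seeded — the cost
    #: is negligible and short chains have rugged score landscapes
    exhaustive_below: int = 20
    max_refine_iters: int = 20
    convergence_tol: float = 1e-5

    def __post_init__(self) -> None:
        t = self.gdt_thresholds
        if any(x <= 0 for x in t) or list(t) != sorted(t):
            raise ArgumentError("gdt_thresholds must be positive ascending")

    def resolve_windows(self, n: int, exhaustive: bool = True) -> list[int]:
        if exhaustive and self.exhaustive_below and n <= self.exhaustive_below \
                and not self.global_seed_only:
            return list(range(3, n + 1))
        out = set()
        for w in self.seed_window_lengths:
            if w == "half":
                w = n // 2
            elif w == "full":
                w = n
            out.add(min(max(int(w), 3), n))
        return sorted(out)

    def stride(self, n: int) -> int:
        return self.seed_stride if self.seed_stride else max(1, n // 20)

    @property
    def global_seed_only(self) -> bool:
        return tuple(self.seed_window_lengths) == ("full",)


#: convenience preset for large same-fold pools (single global seed)
FAST_POOL_PARAMS = ScoringParams(seed_window_lengths=("full",))


@dataclass
class SuperpositionResult:
    """Rigid transform mapping the moving coordinates onto the reference.

    ``rotation @ mov + translation`` approximates ``ref``; the rotation
    is proper (det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float
    per_residue_distance: np.ndarray  # (n,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch_core(
    ref: np.ndarray, mov: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (optionally weighted) rotation/translation,
    reflection-corrected."""
    if weights is None:
        cr = ref.mean(axis=0)
        cm = mov.mean(axis=0)
        H = (mov - cm).T @ (ref - cr)
    else:
        wsum = weights.sum()
        cr = (weights[:, None] * ref).sum(axis=0) / wsum
        cm = (weights[:, None] * mov).sum(axis=0) / wsum
        H = ((mov - cm) * weights[:, None]).T @ (ref - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = (Vt.T * np.array([1.0, 1.0, d])) @ U.T
    return R, cr - R @ cm


def kabsch_superpose(ref: np.ndarray, mov: np.ndarray) -> SuperpositionResult:
    """Optimal (least-RMSD) rigid superposition of two equal-length sets."""
    ref = np.asarray(ref, dtype=np.float64)
    mov = np.asarray(mov, dtype=np.float64)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ArgumentError(f"coordinate shapes differ: {ref.shape} vs {mov.shape}")
    if len(ref) < 3:
        raise ArgumentError("superposition requires at least 3 points")
    R, t = _kabsch_core(ref, mov)
    d = np.linalg.norm(ref - (mov @ R.T + t), axis=1)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=float(np.sqrt(np.mean(d**2))),
        per_residue_distance=d,
    )


def tm_d0(l_ref: int, d0_floor: float = 0.5) -> float:
    """Length-dependent TM-score scale ``1.24 (L-15)^(1/3) - 1.8``, floored."""
    if l_ref > 15:
        return max(d0_floor, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)
    return d0_floor


def _shared_coords(ref: StructureModel, model: StructureModel):
    shared, ref_idx, mod_idx = np.intersect1d(
        ref.residue_ids, model.residue_ids, return_indices=True
    )
    if len(shared) < 3:
        raise ArgumentError(
            f"{ref.model_id} vs {model.model_id}: only {len(shared)} shared "
            "residues; need at least 3"
        )
    return ref.ca_coords[ref_idx], model.ca_coords[mod_idx]


def _seed_transforms(
    A: np.ndarray, B: np.ndarray, params: ScoringParams, exhaustive: bool = True
):
    n = len(A)
    stride = params.stride(n)
    for w in params.resolve_windows(n, exhaustive=exhaustive):
        starts = list(range(0, n - w + 1, stride))
        if starts[-1] != n - w:
            starts.append(n - w)
        for s in starts:
            yield _kabsch_core(A[s : s + w], B[s : s + w])


def _refine_tm(
    A: np.ndarray,
    B: np.ndarray,
    R: np.ndarray,
    t: np.ndarray,
    d0: float,
    l_ref: int,
    params: ScoringParams,
    collect=None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Iterate {score, select close pairs, re-superpose on them}.

    Returns the best score visited and the final transform."""
    best = -np.inf
    prev_mask: np.ndarray | None = None
    for _ in range(params.max_refine_iters):
        d = np.linalg.norm(A - (B @ R.T + t), axis=1)
        if collect is not None:
            collect(d)
        tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)
        improved = tm > best + params.convergence_tol
        best = max(best, tm)
        cutoff = max(d0, _REFINE_CUTOFF_FLOOR)
        mask = d < cutoff
        while mask.sum() < 3:
            cutoff += 0.5
            mask = d < cutoff
        if prev_mask is not None and np.array_equal(mask, prev_mask) and not improved:
            break
        prev_mask = mask
        R, t = _kabsch_core(A[mask], B[mask])
    return best, R, t


def _irls_tm(
    A: np.ndarray,
    B: np.ndarray,
    R: np.ndarray,
    t: np.ndarray,
    d0: float,
    l_ref: int,
    params: ScoringParams,
    collect=None,
) -> float:
    """Weighted-superposition ascent on the TM objective.

    Re-superposing with weights proportional to the derivative of the
    per-residue TM term climbs directly toward superpositions with many
    residues near d0 — complements the hard-cutoff refinement, which
    struggles when d0 is far below the selection cutoff."""
    best = -np.inf
    prev_tm: float | None = None
    for _ in range(params.max_refine_iters):
        d = np.linalg.norm(A - (B @ R.T + t), axis=1)
        if collect is not None:
            collect(d)
        tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)
        best = max(best, tm)
        if prev_tm is not None and abs(tm - prev_tm) < params.convergence_tol:
            break
        prev_tm = tm
        w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
        R, t = _kabsch_core(A, B, w)
    return best, R, t


def _minimax_grow(
    A: np.ndarray,
    B: np.ndarray,
    R: np.ndarray,
    t: np.ndarray,
    collect,
    growth_iters: int = 2,
) -> None:
    """Rank-trimmed Chebyshev-style refit for counting objectives.

    Grow the fitted subset one residue at a time (nearest first),
    re-superposing with weights that emphasise the subset's farthest
    members, so the whole subset is pulled under a common ceiling
    rather than toward its least-squares fit — the frame maximising
    "residues within a cutoff" is generally not an LS frame of its
    inliers.  Every visited frame is reported through ``collect``."""
    n = len(A)
    for k in range(4, n + 1):
        for _ in range(growth_iters):
            d = np.linalg.norm(A - (B @ R.T + t), axis=1)
            collect(d)
            S = np.argsort(d)[:k]
            w = np.zeros(n)
            w[S] = np.maximum(d[S], 1e-6) ** 4 + 1e-9
            R, t = _kabsch_core(A, B, w)
    collect(np.linalg.norm(A - (B @ R.T + t), axis=1))


def tm_score(
    ref: StructureModel, model: StructureModel, params: ScoringParams | None = None
) -> float:
    """Template-modeling score of ``model`` against ``ref`` in (0, 1].

    Normalised by the full reference length; residues of the reference
    missing from the model contribute zero."""
    params = params or ScoringParams()
    A, B = _shared_coords(ref, model)
    l_ref = len(ref)
    d0 = tm_d0(l_ref, params.d0_floor)
    best = -np.inf
    for R0, t0 in _seed_transforms(A, B, params):
        b1, R1, t1 = _refine_tm(A, B, R0, t0, d0, l_ref, params)
        b2, _, _ = _irls_tm(A, B, R0, t0, d0, l_ref, params)
        b3, _, _ = _irls_tm(A, B, R1, t1, d0, l_ref, params)
        best = max(best, b1, b2, b3)
    n = len(A)
    if n <= params.exhaustive_below:
        # short chains: sweep a rotation grid with residue-anchored
        # translations too — with d0 at its floor the score landscape
        # has narrow basins no contiguous-window seed reaches
        best = max(best, _tm_grid_stage(A, B, d0, l_ref, params))
    return best


def _tm_grid_stage(A, B, d0, l_ref, params, n_irls: int = 1500) -> float:
    """Grid + anchored-translation candidates, refined by batched
    reweighted ascent on the TM objective; returns the best score."""
    Rg, tg = _rotation_grid_candidates(A, B)
    RB = np.einsum("cij,nj->cni", Rg, B)
    d = np.linalg.norm(A[None, :, :] - RB - tg[:, None, :], axis=2)
    tm = (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref
    best = float(tm.max())
    top = np.argsort(tm)[::-1][:n_irls]
    Rs, ts = Rg[top], tg[top]
    c, n = len(Rs), len(A)
    A_s = np.broadcast_to(A, (c, n, 3))
    B_s = np.broadcast_to(B, (c, n, 3))
    for _ in range(params.max_refine_iters):
        Bt = np.einsum("cij,cnj->cni", Rs, B_s) + ts[:, None, :]
        d = np.linalg.norm(A_s - Bt, axis=2)
        tm = (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref
        best = max(best, float(tm.max()))
        w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
        Rs, ts = _batched_kabsch(A_s, B_s, w)
    Bt = np.einsum("cij,cnj->cni", Rs, B_s) + ts[:, None, :]
    d = np.linalg.norm(A_s - Bt, axis=2)
    tm = (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref
    return max(best, float(tm.max()))


def gdt_ts(
    ref: StructureModel, model: StructureModel, params: ScoringParams | None = None
) -> float:
    """Global distance test (total score) of ``model`` against ``ref``.

    Mean over the distance cutoffs of the maximal fraction of reference
    residues superimposable within the cutoff.  The search scores every
    frame it visits: seed-window superpositions, their mask refinements
    and reweighted ascents, and — for short chains, where the counting
    landscape is rugged and the cost negligible — an exhaustive stack of
    window, residue-triple and rotation-grid frames with rank-trimmed
    Chebyshev growth (counting optima are generally not least-squares
    fits of their inliers)."""
    params = params or ScoringParams()
    A, B = _shared_coords(ref, model)
    l_ref = len(ref)
    thresholds = np.asarray(params.gdt_thresholds)
    best = np.zeros(len(thresholds))

    def update(d: np.ndarray) -> None:
        np.maximum(best, (d[:, None] <= thresholds).sum(axis=0) / l_ref, out=best)

    def update_batch(d: np.ndarray) -> None:  # d: (frames, n)
        frac = (d[:, :, None] <= thresholds[None, None, :]).sum(axis=1) / l_ref
        np.maximum(best, frac.max(axis=0), out=best)

    def mask_refine(R, t, thr):
        prev_mask: np.ndarray | None = None
        for _ in range(params.max_refine_iters):
            d = np.linalg.norm(A - (B @ R.T + t), axis=1)
            update(d)
            mask = d <= thr
            if mask.sum() < 3 or (
                prev_mask is not None and np.array_equal(mask, prev_mask)
            ):
                break
            prev_mask = mask
            R, t = _kabsch_core(A[mask], B[mask])
        return R, t

    d0 = tm_d0(l_ref, params.d0_floor)
    for R0, t0 in _seed_transforms(A, B, params, exhaustive=False):
        d = np.linalg.norm(A - (B @ R0.T + t0), axis=1)
        update(d)
        # frames visited by the TM search are good GDT frames too
        _, R1, t1 = _refine_tm(A, B, R0, t0, d0, l_ref, params, collect=update)
        _irls_tm(A, B, R0, t0, d0, l_ref, params, collect=update)
        # cascade: the frame refined at a loose cutoff seeds the next
        # tighter one, on top of per-threshold starts from the raw seed
        Rc, tc = R0, t0
        for thr in sorted(thresholds, reverse=True):
            # reweighted ascent at the threshold's own distance scale
            # pulls many residues just inside the cutoff
            _, Rw, tw = _irls_tm(A, B, R0, t0, thr, l_ref, params,
                                 collect=update)
            mask_refine(R0, t0, thr)
            mask_refine(R1, t1, thr)
            mask_refine(Rw, tw, thr)
            Rc, tc = mask_refine(Rc, tc, thr)
        _minimax_grow(A, B, R0, t0, update)

    n = len(A)
    if n <= params.exhaustive_below:
        # exhaustive frame stack: every contiguous window, every residue
        # triple, and a rotation grid with residue-anchored translations
        win_frames = [
            _kabsch_core(A[s : s + w], B[s : s + w])
            for w in range(3, n + 1)
            for s in range(n - w + 1)
        ]
        triples = np.array(list(combinations(range(n), 3)))
        w3 = np.zeros((len(triples), n))
        w3[np.arange(len(triples))[:, None], triples] = 1.0
        A_s = np.broadcast_to(A, (len(triples), n, 3))
        B_s = np.broadcast_to(B, (len(triples), n, 3))
        R3, t3 = _batched_kabsch(A_s, B_s, w3)
        Rg, tg = _rotation_grid_candidates(A, B)
        Rall = np.concatenate([np.stack([R for R, _ in win_frames]), R3, Rg])
        tall = np.concatenate([np.stack([t for _, t in win_frames]), t3, tg])
        for scale in thresholds:
            sc = _count_frames(A, B, Rall, tall, float(scale), update_batch)
            for k in np.argsort(sc)[::-1][:40]:
                mask_refine(Rall[k], tall[k], float(scale))
        if n <= 12:
            # near-exact: test every residue subset for joint
            # superimposability via a Chebyshev-style (minimax) fit
            _subset_minimax(A, B, update_batch, thresholds=thresholds)
    return float(best.mean())


def _all_subset_weights(n: int) -> np.ndarray:
    """0/1 weight rows for every residue subset of size >= 3."""
    masks = np.arange(1, 2**n, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(np.float64)
    return bits[bits.sum(axis=1) >= 3]


#: annealing schedule for the subset minimax fit: (exponent, iterations);
#: ramping the exponent slowly avoids the local minima a sharp
#: Chebyshev weighting falls into from a least-squares start
_MINIMAX_SCHEDULE = ((1.0, 6), (2.0, 6), (4.0, 6), (8.0, 6), (16.0, 6), (32.0, 6))


def _subset_minimax(A, B, update_batch, thresholds=None) -> None:
    """Feasibility test for the counting objective, one subset at a time.

    The frame maximising "residues within t" places some inlier subset
    S entirely under t; whether that is possible is decided by the
    minimax (Chebyshev) fit of S, approximated by reweighted Kabsch
    with weights d^q restricted to S and q annealed upward, plus a
    derivative-free smooth-max polish for subsets that end up just
    outside a cutoff (the reweighted iteration stalls near feasibility
    boundaries).  Enumerating all subsets makes the short-chain GDT
    search effectively exact; every visited frame is counted against
    all thresholds."""
    n = len(A)
    w0 = _all_subset_weights(n)
    c = len(w0)
    A_s = np.broadcast_to(A, (c, n, 3))
    B_s = np.broadcast_to(B, (c, n, 3))
    Rs, ts = _batched_kabsch(A_s, B_s, w0)
    subset_maxd = np.full(c, np.inf)
    member = w0.astype(bool)
    for q, iters in _MINIMAX_SCHEDULE:
        for _ in range(iters):
            Bt = np.einsum("cij,cnj->cni", Rs, B_s) + ts[:, None, :]
            d = np.linalg.norm(A_s - Bt, axis=2)
            update_batch(d)
            np.minimum(subset_maxd, np.where(member, d, 0.0).max(axis=1),
                       out=subset_maxd)
            w = w0 * (np.maximum(d, 1e-6) ** q + 1e-9)
            Rs, ts = _batched_kabsch(A_s, B_s, w)
    Bt = np.einsum("cij,cnj->cni", Rs, B_s) + ts[:, None, :]
    d = np.linalg.norm(A_s - Bt, axis=2)
    update_batch(d)
    np.minimum(subset_maxd, np.where(member, d, 0.0).max(axis=1),
               out=subset_maxd)
    if thresholds is not None:
        _polish_borderline_subsets(A, B, member, subset_maxd, Rs, ts,
                                   np.asarray(thresholds), update_batch)


def _polish_borderline_subsets(A, B, member, subset_maxd, Rs, ts, thresholds,
                               update_batch, margin: float = 1.25,
                               per_threshold: int = 40) -> None:
    """Smooth-max (log-sum-exp) Nelder-Mead polish of subsets whose
    reweighted fit stalled just above a cutoff; only subsets large
    enough to raise that cutoff's certified count are worth polishing."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    sizes = member.sum(axis=1)
    polished: set[int] = set()
    for thr in thresholds:
        certified = sizes[subset_maxd <= thr].max(initial=0)
        cand = np.flatnonzero(
            (subset_maxd > thr) & (subset_maxd <= margin * thr)
            & (sizes > certified)
        )
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
            d = np.linalg.norm(A - (B @ Rm.T + res.x[3:]), axis=1)
            update_batch(d[None, :])


def _rotation_grid_candidates(A: np.ndarray, B: np.ndarray, step: int = 30):
    """Euler-angle grid paired with residue-anchored translations."""
    from scipy.spatial.transform import Rotation

    angles = [(a, b, g)
              for a in range(0, 360, step)
              for b in range(0, 181, step)
              for g in range(0, 360, step)]
    Rg = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
    RB = np.einsum("gij,nj->gni", Rg, B)
    tc = A.mean(axis=0)[None, :] - RB.mean(axis=1)
    t_pin = A[None, :, :] - RB
    g, n, _ = t_pin.shape
    Rs = np.concatenate([Rg, np.repeat(Rg, n, axis=0)])
    ts = np.concatenate([tc, t_pin.reshape(g * n, 3)])
    return Rs, ts


def _count_frames(A, B, Rs, ts, scale, update_batch):
    """Count fractions for a stack of frames; returns per-frame scores
    at the given distance scale for shortlisting."""
    RB = np.einsum("cij,nj->cni", Rs, B)
    d = np.linalg.norm(A[None, :, :] - RB - ts[:, None, :], axis=2)
    update_batch(d)
    return (1.0 / (1.0 + (d / scale) ** 2)).sum(axis=1)


def _irls_grid(A, B, Rs, ts, scale, params, update_batch, iters: int = 12):
    """Reweighted ascent at one distance scale over a frame stack,
    harvesting every intermediate frame for the counting objective."""
    c, n = len(Rs), len(A)
    A_s = np.broadcast_to(A, (c, n, 3))
    B_s = np.broadcast_to(B, (c, n, 3))
    for _ in range(iters):
        Bt = np.einsum("cij,cnj->cni", Rs, B_s) + ts[:, None, :]
        d = np.linalg.norm(A_s - Bt, axis=2)
        update_batch(d)
        w = 1.0 / (1.0 + (d / scale) ** 2) ** 2
        Rs, ts = _batched_kabsch(A_s, B_s, w)
    Bt = np.einsum("cij,cnj->cni", Rs, B_s) + ts[:, None, :]
    update_batch(np.linalg.norm(A_s - Bt, axis=2))
    return Rs, ts


# ---------------------------------------------------------------------------
# Pairwise similarity matrices
# ---------------------------------------------------------------------------

def pairwise_matrix(
    models: Sequence[StructureModel],
    metric: Literal["tm", "gdt"] = "tm",
    params: ScoringParams | None = None,
) -> np.ndarray:
    """All-against-all similarity, symmetrised by the mean of the two
    directions; diagonal fixed at 1.

    When every model shares one residue set and ``params`` request only
    the global seed window, a vectorised implementation of the identical
    algorithm is used (the two paths agree to floating-point noise).
    """
    if len(models) < 2:
        raise ArgumentError("pairwise matrix requires at least 2 models")
    params = params or ScoringParams()
    if metric not in ("tm", "gdt"):
        raise ArgumentError(f"unknown metric {metric!r}")
    same_residues = all(
        np.array_equal(m.residue_ids, models[0].residue_ids) for m in models[1:]
    )
    if metric == "tm" and params.global_seed_only and same_residues:
        return _pairwise_tm_batched(models, params)
    n = len(models)
    mat = np.eye(n)
    score = tm_score if metric == "tm" else gdt_ts
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.5 * (score(models[i], models[j], params)
                       + score(models[j], models[i], params))
            mat[i, j] = mat[j, i] = s
    return mat


def _batched_kabsch(A, B, w):
    """Weighted Kabsch over a batch: A, B (p, n, 3); w (p, n) in {0, 1}."""
    wsum = w.sum(axis=1)[:, None]
    ca = (w[:, :, None] * A).sum(axis=1) / wsum
    cb = (w[:, :, None] * B).sum(axis=1) / wsum
    Ac = A - ca[:, None, :]
    Bc = B - cb[:, None, :]
    H = np.einsum("pn,pni,pnj->pij", w, Bc, Ac)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("pij,pkj->pik", Vt.transpose(0, 2, 1), U)))
    Vt = Vt.copy()
    Vt[:, 2, :] *= d[:, None]
    R = np.einsum("pji,pjk->pik", Vt, U.transpose(0, 2, 1))
    # note: R = Vt^T diag(1,1,d) U^T computed via the sign-folded Vt
    t = ca - np.einsum("pij,pj->pi", R, cb)
    return R, t


def _pairwise_tm_batched(
    models: Sequence[StructureModel], params: ScoringParams
) -> np.ndarray:
    """Global-seed TM refinement run simultaneously for every pair.

    Mirrors :func:`_refine_tm` exactly; valid because with a shared
    residue set the two scoring directions coincide (the superposition
    distances are symmetric and L_ref is common)."""
    coords = np.stack([m.ca_coords for m in models])
    n_models, n, _ = coords.shape
    l_ref = n
    d0 = tm_d0(l_ref, params.d0_floor)
    ii, jj = np.triu_indices(n_models, k=1)
    A = coords[ii]
    B = coords[jj]
    p = len(ii)
    R0, t0 = _batched_kabsch(A, B, np.ones((p, n)))

    best = np.full(p, -np.inf)
    best, R1, t1 = _batched_mask_refine(A, B, R0, t0, d0, l_ref, params, best)
    best = _batched_irls(A, B, R0, t0, d0, l_ref, params, best)
    best = _batched_irls(A, B, R1, t1, d0, l_ref, params, best)

    mat = np.eye(n_models)
    mat[ii, jj] = best
    mat[jj, ii] = best
    return mat


def _batched_mask_refine(A, B, R, t, d0, l_ref, params, best):
    """Vectorised counterpart of :func:`_refine_tm` over all pairs.

    Converged pairs drop out of the working set, so late iterations
    only touch the stragglers."""
    R, t = R.copy(), t.copy()
    p, n, _ = A.shape
    best = best.copy()
    prev_mask = np.zeros((p, n), dtype=bool)
    have_prev = np.zeros(p, dtype=bool)
    idx = np.arange(p)
    for _ in range(params.max_refine_iters):
        Ai, Bi = A[idx], B[idx]
        Bt = np.einsum("pij,pnj->pni", R[idx], Bi) + t[idx][:, None, :]
        d = np.linalg.norm(Ai - Bt, axis=2)
        tm = (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref
        improved = tm > best[idx] + params.convergence_tol
        best[idx] = np.maximum(best[idx], tm)
        cutoff = np.full(len(idx), max(d0, _REFINE_CUTOFF_FLOOR))
        mask = d < cutoff[:, None]
        while True:
            starved = mask.sum(axis=1) < 3
            if not starved.any():
                break
            cutoff[starved] += 0.5
            mask[starved] = d[starved] < cutoff[starved, None]
        converged = have_prev[idx] & (mask == prev_mask[idx]).all(axis=1) \
            & ~improved
        prev_mask[idx] = mask
        have_prev[idx] = True
        keep = ~converged
        idx = idx[keep]
        if idx.size == 0:
            break
        R[idx], t[idx] = _batched_kabsch(
            A[idx], B[idx], mask[keep].astype(np.float64)
        )
    return best, R, t


def _batched_irls(A, B, R, t, d0, l_ref, params, best):
    """Vectorised counterpart of :func:`_irls_tm` over all pairs, with
    converged pairs dropping out of the working set."""
    R, t = R.copy(), t.copy()
    best = best.copy()
    p = A.shape[0]
    prev_tm = np.full(p, np.nan)
    idx = np.arange(p)
    for _ in range(params.max_refine_iters):
        Bi = B[idx]
        Bt = np.einsum("pij,pnj->pni", R[idx], Bi) + t[idx][:, None, :]
        d = np.linalg.norm(A[idx] - Bt, axis=2)
        tm = (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / l_ref
        best[idx] = np.maximum(best[idx], tm)
        converged = np.isfinite(prev_tm[idx]) \
            & (np.abs(tm - prev_tm[idx]) < params.convergence_tol)
        prev_tm[idx] = tm
        keep = ~converged
        idx = idx[keep]
        if idx.size == 0:
            break
        w = 1.0 / (1.0 + (d[keep] / d0) ** 2) ** 2
        R[idx], t[idx] = _batched_kabsch(A[idx], B[idx], w)
    return best
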