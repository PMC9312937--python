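"""Per-loop similarity and confidence metrics.

Four quantities are computed for every experimental/predicted loop pair:

* RMSD (A) after an optimal least-squares rigid superposition of the two
  fragments (Kabsch algorithm, reflections excluded), by default over the
  backbone atoms N, CA, C, O of each residue;
* TM-score of the fragment pair, normalised by the loop's own length L
  with d0 = max(d0_min, 1.24 (L-15)^(1/3) - 1.8) and maximised over rigid
  superpositions with the standard iterative fragment-seeded search;
* the secondary-structure gain dSSE = 100 (n_pred_regular -
  n_exp_regular) / L, where "regular" means helix or sheet classes
  {H, G, I, E, B} of the full-structure assignment restricted to the span;
* the mean predicted confidence (pLDDT), averaged over ALL atoms of the
  predicted fragment (atom-weighted, not residue-weighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loops import LoopPair, LoopRegion
from .secstruct import REGULAR_CLASSES
from .structure_io import Structure, StructureError

log = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "tm_d0",
    "kabsch_superpose",
    "loop_rmsd",
    "tm_score",
    "tm_score_coords",
    "delta_sse",
    "mean_plddt",
    "global_superposition",
    "compute_pair_metrics",
]

ATOM_SETS = {
    "CA": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
    "heavy": None,  # all non-hydrogen atoms
}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector
    rmsd: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    SVD-based Kabsch algorithm; the sign of the smallest singular vector is
    corrected so the rotation is proper (no reflection).  Collinear or
    otherwise rank-deficient point sets still return a minimiser, flagged
    ``degenerate``.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("fixed and mobile must both be N x 3")
    if fixed.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(fixed)) and np.all(np.isfinite(mobile))):
        raise ValueError("coordinates must be finite")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    h = (mobile - cm).T @ (fixed - cf)
    u, sing, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cf - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    degenerate = sing[-1] < 1e-8 * max(sing[0], 1.0)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               degenerate=bool(degenerate))


def _matched_coords(pair: LoopPair, atom_set: str) -> tuple[np.ndarray, np.ndarray]:
    names = ATOM_SETS.get(atom_set, "missing")
    if names == "missing":
        raise ValueError(f"unknown atom set {atom_set!r}")
    fixed, mobile = [], []
    for re_, rp in zip(pair.exp.residues, pair.pred.residues):
        wanted = names
        if wanted is None:  # heavy: intersection of non-H atom names
            exp_names = [a.name for a in re_.atoms if a.element != "H"]
            wanted = tuple(n for n in exp_names if rp.get(n) is not None)
        for n in wanted:
            ce, cp = re_.coord(n), rp.coord(n)
            if ce is None or cp is None:
                return np.empty((0, 3)), np.empty((0, 3))  # caller falls back
            fixed.append(ce)
            mobile.append(cp)
    return np.asarray(fixed), np.asarray(mobile)


def loop_rmsd(
    pair: LoopPair,
    atom_set: str = "backbone",
    transform: SuperpositionResult | None = None,
) -> float:
    """RMSD of the predicted loop fragment against the experimental one.

    Default frame is local: the two fragments themselves are superposed
    before measuring.  Passing ``transform`` (e.g. from
    :func:`global_superposition` of the full structures) instead measures
    the deviation in that fixed frame without refitting.  Missing atoms
    trigger a logged fall-back to CA-only.
    """
    fixed, mobile = _matched_coords(pair, atom_set)
    if fixed.shape[0] == 0 and atom_set != "CA":
        log.warning("pair %s: incomplete %s atoms, falling back to CA",
                    pair.pair_id, atom_set)
        fixed, mobile = _matched_coords(pair, "CA")
    if fixed.shape[0] == 0:
        raise StructureError(f"pair {pair.pair_id}: no matchable atoms")
    if transform is not None:
        moved = transform.apply(mobile)
        return float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return kabsch_superpose(fixed, mobile).rmsd


def tm_d0(length: int, d0_min: float = 0.5) -> float:
    """TM-score distance scale with a floor for short fragments."""
    if length < 3:
        raise ValueError("TM-score needs length >= 3")
    raw = 1.24 * np.cbrt(length - 15.0) - 1.8 if length > 15 else -np.inf
    return float(max(d0_min, raw))


def tm_score_coords(
    fixed: np.ndarray,
    mobile: np.ndarray,
    norm_length: int | None = None,
    d0_min: float = 0.5,
    max_iter: int = 20,
) -> float:
    """TM-score of two equal-length CA traces with fixed correspondence.

    Maximisation over rigid superpositions uses the standard heuristic:
    superpositions are seeded from every contiguous fragment of lengths
    L, L/2 and L/4 (minimum 4) plus the full-length fit, then each seed is
    iteratively refined by re-superposing on the residue subset within a
    distance cutoff until the subset is stable.  The best score over all
    seeds is returned, so the result is never below the naive single
    Kabsch superposition's score.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.shape[0] < 3:
        raise ValueError("need two equal N x 3 arrays with N >= 3")
    n = fixed.shape[0]
    ln = int(norm_length or n)
    d0 = tm_d0(ln, d0_min=d0_min)

    def score(dists: np.ndarray) -> float:
        return float(np.mean(1.0 / (1.0 + (dists / d0) ** 2)))

    frag_lengths = sorted({n, max(n // 2, 4), max(n // 4, 4)}, reverse=True)
    seeds = [np.arange(n)]
    for fl in frag_lengths:
        if fl >= n:
            continue
        for start in range(0, n - fl + 1):
            seeds.append(np.arange(start, start + fl))

    best = 0.0
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []
    for seed in seeds:
        subset = seed
        seen = set()
        for _ in range(max_iter):
            if subset.shape[0] < 3:
                break
            sup = kabsch_superpose(fixed[subset], mobile[subset])
            d = np.linalg.norm(sup.apply(mobile) - fixed, axis=1)
            sc = score(d)
            candidates.append((sc, sup.rotation, sup.translation))
            best = max(best, sc)
            cut = max(d0, 1.0)
            new = np.nonzero(d < cut)[0]
            while new.shape[0] < 3:
                cut += 0.5
                new = np.nonzero(d < cut)[0]
            key = new.tobytes()
            if key in seen:
                break
            seen.add(key)
            subset = new

    # The score is defined as a maximum over rigid superpositions; the
    # subset-Kabsch fits above are RMSD-optimal, not TM-optimal, so polish
    # the best candidates with a direct local maximisation of the score
    # over rotation + translation parameters.
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def neg_tm(p: np.ndarray) -> float:
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        d = np.linalg.norm(mobile @ rot.T + p[3:] - fixed, axis=1)
        return -score(d)

    candidates.sort(key=lambda c: -c[0])
    polished = set()
    for sc, rot, trans in candidates[:6]:
        key = np.round(np.concatenate([rot.ravel(), trans]), 3).tobytes()
        if key in polished:
            continue
        polished.add(key)
        x0 = np.concatenate([Rotation.from_matrix(rot).as_rotvec(), trans])
        res = minimize(neg_tm, x0, method="Nelder-Mead",
                       options={"maxiter": 1500, "xatol": 1e-6, "fatol": 1e-11})
        best = max(best, float(-res.fun))
    return best


def tm_score(pair: LoopPair, d0_min: float = 0.5) -> float:
    """TM-score of a loop pair over CA atoms, normalised by loop length."""
    if pair.length < 3:
        raise ValueError("TM-score needs loops of length >= 3")
    fixed, mobile = _matched_coords(pair, "CA")
    if fixed.shape[0] != pair.length:
        raise StructureError(f"pair {pair.pair_id}: missing CA atoms")
    return tm_score_coords(fixed, mobile, norm_length=pair.length, d0_min=d0_min)


def delta_sse(pair: LoopPair, exp_classes: str | None = None,
              pred_classes: str | None = None) -> float:
    """Percent change in regular secondary-structure content over the span.

    Positive values mean the prediction shows more helix/sheet residues in
    the loop span than the experimental structure; for dataset-conforming
    loops the experimental term is zero by construction.
    """
    exp_classes = pair.exp.classes if exp_classes is None else exp_classes
    pred_classes = pair.pred.classes if pred_classes is None else pred_classes
    if len(exp_classes) != pair.length or len(pred_classes) != pair.length:
        raise StructureError(
            f"pair {pair.pair_id}: class strings do not cover the span")
    n_exp = sum(c in REGULAR_CLASSES for c in exp_classes)
    n_pred = sum(c in REGULAR_CLASSES for c in pred_classes)
    return 100.0 * (n_pred - n_exp) / pair.length


def mean_plddt(pred_loop: LoopRegion) -> float:
    """Mean confidence over ALL atoms of a predicted loop fragment
    (atom-weighted; inferred hydrogens carry no confidence and are skipped)."""
    if pred_loop.source != "predicted":
        raise StructureError("mean_plddt expects a predicted-source fragment")
    vals = [a.bfactor for r in pred_loop.residues for a in r.atoms
            if a.element != "H"]
    if not vals:
        raise StructureError("fragment has no atoms")
    return float(np.mean(vals))


def global_superposition(exp: Structure, pred: Structure) -> SuperpositionResult:
    """Kabsch fit of the full predicted structure onto the experimental one
    over shared CA atoms (for the global-frame RMSD option)."""
    fixed, mobile = [], []
    for cid, residues in exp.chains.items():
        if cid not in pred.chains:
            continue
        smap = {r.seq_id: r for r in pred.chains[cid]}
        for re_ in residues:
            rp = smap.get(re_.seq_id)
            if rp is None:
                continue
            ce, cp = re_.coord("CA"), rp.coord("CA")
            if ce is not None and cp is not None:
                fixed.append(ce)
                mobile.append(cp)
    return kabsch_superpose(np.asarray(fixed), np.asarray(mobile))


def compute_pair_metrics(
    pairs: list[LoopPair],
    atom_set: str = "backbone",
    frame: str = "local",
    d0_min: float = 0.5,
    global_transforms: dict[str, SuperpositionResult] | None = None,
) -> pd.DataFrame:
    """Per-loop metric table: one row per pair.

    Columns: pair_id, length, rmsd_A, tm, delta_sse_pct, mean_plddt,
    atom_set, frame.
    """
    rows = []
    for pair in pairs:
        transform = None
        if frame == "global":
            if not global_transforms or pair.exp.parent_id not in global_transforms:
                raise ValueError("global frame requires per-structure transforms")
            transform = global_transforms[pair.exp.parent_id]
        rows.append({
            "pair_id": pair.pair_id,
            "length": pair.length,
            "rmsd_A": loop_rmsd(pair, atom_set=atom_set, transform=transform),
            "tm": tm_score(pair, d0_min=d0_min),
            "delta_sse_pct": delta_sse(pair),
            "mean_plddt": mean_plddt(pair.pred),
            "atom_set": atom_set,
            "frame": frame,
        })
    return pd.DataFrame(rows)
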