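"""Loop extraction and experimental/predicted pairing.

A loop is a maximal run of residues whose secondary-structure class is
none, turn, or bend (the collapsed loop mask), at least ``min_len``
residues long, never crossing a chain break or an incomplete residue.
Loop spans are always defined on the EXPERIMENTAL structure; the predicted
fragment is looked up at the same author residue numbers and the pair is
accepted only under 100% sequence identity, which fixes the residue
correspondence for every downstream metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .secstruct import LOOP_CLASSES, SecStructAssignment
from .structure_io import Residue, Structure, StructureError

log = logging.getLogger(__name__)

__all__ = ["LoopRegion", "LoopPair", "PairingError", "extract_loops", "pair_loops"]


class PairingError(StructureError):
    """Predicted structure cannot be matched to the experimental loops."""


@dataclass
class LoopRegion:
    parent_id: str
    chain: str
    start: int                   # half-open [start, end) 0-based chain indices
    end: int
    sequence: str
    residues: list[Residue]
    classes: str = ""            # 8-class codes restricted to the span
    sense: np.ndarray | None = None
    source: str = "experimental"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def seq_ids(self) -> list[str]:
        return [r.seq_id for r in self.residues]

    def backbone_coords(self, names=("N", "CA", "C", "O")) -> np.ndarray:
        return np.array([r.coord(n) for r in self.residues for n in names])


@dataclass
class LoopPair:
    exp: LoopRegion
    pred: LoopRegion
    pair_id: str

    @property
    def length(self) -> int:
        return self.exp.length


def extract_loops(
    s: Structure,
    assignment: SecStructAssignment | np.ndarray,
    min_len: int = 3,
) -> list[LoopRegion]:
    """Maximal loop-mask runs per chain, discarding runs shorter than ``min_len``.

    ``assignment`` may be a full :class:`SecStructAssignment` (preferred:
    runs then also honour chain breaks and incomplete residues) or a bare
    boolean mask concatenated over chains.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    use_assignment = isinstance(assignment, SecStructAssignment)
    if not use_assignment:
        mask_all = np.asarray(assignment, dtype=bool)
        if mask_all.size != s.n_residues:
            raise StructureError(
                f"mask length {mask_all.size} != residue count {s.n_residues}")
    loops: list[LoopRegion] = []
    offset = 0
    for cid, residues in s.chains.items():
        nres = len(residues)
        if use_assignment:
            ca = assignment.chains[cid]
            mask = ca.loop_mask.copy()
            segment = ca.segment
            classes = ca.classes
            sense = ca.sense
        else:
            mask = mask_all[offset:offset + nres].copy()
            segment = np.zeros(nres, dtype=int)
            classes = "".join("C" if m else "H" for m in mask)
            sense = np.zeros(nres, dtype=int)
            offset += nres
        for j, res in enumerate(residues):
            if not res.is_complete:
                mask[j] = False  # incomplete residues split a run
        start = None
        for j in range(nres + 1):
            boundary = (
                j == nres
                or not mask[j]
                or (start is not None and segment[j] != segment[j - 1])
            )
            if start is None and j < nres and mask[j]:
                start = j
                continue
            if start is not None and boundary:
                if j - start >= min_len:
                    loops.append(LoopRegion(
                        parent_id=s.id,
                        chain=cid,
                        start=start,
                        end=j,
                        sequence="".join(r.aa for r in residues[start:j]),
                        residues=residues[start:j],
                        classes=classes[start:j],
                        sense=np.asarray(sense[start:j]),
                        source=s.source,
                    ))
                start = j if (j < nres and mask[j]) else None
    return loops


def pair_loops(
    exp: Structure,
    exp_loops: list[LoopRegion],
    pred: Structure,
    pred_assignment: SecStructAssignment | None = None,
) -> tuple[list[LoopPair], list[LoopRegion]]:
    """Match each experimental loop with the predicted fragment at the same
    author residue numbers.

    Requires 100% sequence identity over the span; mismatching or missing
    spans are rejected (logged, returned separately).  A chain present in
    the experimental loops but absent from the prediction is a fatal
    :class:`PairingError`.  When ``pred_assignment`` is given, the
    predicted fragment records the full-structure secondary-structure
    classes restricted to the span (needed for the secondary-structure
    gain statistic).
    """
    pairs: list[LoopPair] = []
    rejected: list[LoopRegion] = []
    index: dict[str, dict[str, int]] = {}
    for loop in exp_loops:
        if loop.chain not in pred.chains:
            raise PairingError(
                f"chain {loop.chain!r} of {exp.id} missing from prediction {pred.id}")
        if loop.chain not in index:
            index[loop.chain] = {r.seq_id: k
                                 for k, r in enumerate(pred.chains[loop.chain])}
        smap = index[loop.chain]
        positions = [smap.get(sid) for sid in loop.seq_ids]
        if any(p is None for p in positions) or \
                positions != list(range(positions[0], positions[0] + loop.length)):
            log.warning("loop %s:%s %s-%s absent or non-contiguous in prediction",
                        loop.parent_id, loop.chain, loop.seq_ids[0], loop.seq_ids[-1])
            rejected.append(loop)
            continue
        p0 = positions[0]
        pred_res = pred.chains[loop.chain][p0:p0 + loop.length]
        pred_seq = "".join(r.aa for r in pred_res)
        if pred_seq != loop.sequence:
            log.warning("sequence mismatch for loop %s:%s (%s vs %s)",
                        loop.parent_id, loop.chain, loop.sequence, pred_seq)
            rejected.append(loop)
            continue
        classes = ""
        sense = None
        if pred_assignment is not None:
            ca = pred_assignment.chains[loop.chain]
            classes = ca.classes[p0:p0 + loop.length]
            sense = np.asarray(ca.sense[p0:p0 + loop.length])
        pairs.append(LoopPair(
            exp=loop,
            pred=LoopRegion(
                parent_id=pred.id,
                chain=loop.chain,
                start=p0,
                end=p0 + loop.length,
                sequence=pred_seq,
                residues=pred_res,
                classes=classes,
                sense=sense,
                source=pred.source,
            ),
            pair_id=f"{exp.id}_{loop.chain}_{loop.seq_ids[0]}-{loop.seq_ids[-1]}",
        ))
    return pairs, rejected
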