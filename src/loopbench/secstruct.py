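"""DSSP-style secondary-structure assignment from backbone hydrogen bonds.

Implements the classic dictionary-of-protein-secondary-structure scheme:
amide hydrogens are rebuilt from the preceding peptide C=O direction, a
backbone N-H...O=C hydrogen bond is accepted when the Kabsch-Sander
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

falls below -0.5 kcal/mol, and the bond patterns are translated into the
eight classes

    H alpha helix, G 3-10 helix, I pi helix,
    E sheet (ladder), B isolated bridge,
    T hydrogen-bonded turn, S bend (Calpha curvature > 70 deg), C none.

A residue is "loop" when its class is in {C, T, S}; the collapsed boolean
mask is what the loop-extraction stage consumes.

Chains are split into segments at chain breaks (consecutive Calpha-Calpha
distance > 4.5 A) and at residues missing backbone atoms; turn and helix
patterns never span a break, while bridge partners may sit on different
chains or segments (beta sheets routinely do).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._geom import angle_deg, unit
from .structure_io import Atom, Structure

__all__ = [
    "HydrogenBond",
    "ChainAssignment",
    "SecStructAssignment",
    "place_amide_hydrogens",
    "kabsch_sander_hbonds",
    "assign_secstruct",
    "loop_mask",
    "assignment_table",
    "LOOP_CLASSES",
    "REGULAR_CLASSES",
]

LOOP_CLASSES = frozenset("CTS")
REGULAR_CLASSES = frozenset("HGIEB")

HBOND_CUTOFF = -0.5          # kcal/mol
HBOND_Q1Q2F = 0.084 * 332.0  # kcal*A/mol, Kabsch-Sander constant
CA_BREAK_DIST = 4.5          # A, chain-break threshold
BEND_KAPPA = 70.0            # deg
CA_NEIGHBOUR_CUTOFF = 9.0    # A, prefilter for H-bond candidates
MIN_ENERGY = -9.9            # clamp for near-clashing geometries


@dataclass(frozen=True)
class HydrogenBond:
    donor_res: int      # flat residue index of the N-H side
    acceptor_res: int   # flat residue index of the C=O side
    energy: float       # kcal/mol


@dataclass
class ChainAssignment:
    classes: str
    loop_mask: np.ndarray          # bool, per residue
    kappa: np.ndarray              # deg, NaN where undefined
    sense: np.ndarray              # +1 parallel / -1 antiparallel / 0 for E,B residues
    segment: np.ndarray            # int segment label (breaks increment it)


@dataclass
class SecStructAssignment:
    structure_id: str
    chains: dict[str, ChainAssignment] = field(default_factory=dict)

    def classes_for(self, chain: str) -> str:
        return self.chains[chain].classes

    @property
    def all_classes(self) -> str:
        return "".join(c.classes for c in self.chains.values())

    @property
    def all_loop_mask(self) -> np.ndarray:
        return np.concatenate([c.loop_mask for c in self.chains.values()])


def place_amide_hydrogens(s: Structure) -> Structure:
    """Add inferred backbone amide hydrogens (atom name ``H``) in place.

    For each residue after the first of a segment, H sits 1.0 A from N
    along the C->O-reversed direction of the preceding carbonyl (the
    original DSSP convention).  Prolines and segment-start residues get no
    hydrogen.  Returns the same structure for chaining.
    """
    for residues in s.chains.values():
        prev = None
        for res in residues:
            if prev is not None and res.name != "PRO" and res.get("H") is None:
                n = res.coord("N")
                c_prev, o_prev = prev.coord("C"), prev.coord("O")
                ca, ca_prev = res.coord("CA"), prev.coord("CA")
                broken = (
                    n is None or c_prev is None or o_prev is None
                    or ca is None or ca_prev is None
                    or np.linalg.norm(ca - ca_prev) > CA_BREAK_DIST
                )
                if not broken:
                    h = n + unit(c_prev - o_prev)
                    res.atoms.append(Atom(name="H", element="H", coords=h))
            prev = res
    return s


def _flatten(s: Structure):
    """Flat residue arrays + segment labels used by the pattern search."""
    residues, chain_of, idx_in_chain = [], [], []
    for cid, chain_residues in s.chains.items():
        for j, res in enumerate(chain_residues):
            residues.append(res)
            chain_of.append(cid)
            idx_in_chain.append(j)
    n = len(residues)
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O", "H")}
    for i, res in enumerate(residues):
        for name in coords:
            c = res.coord(name)
            if c is not None:
                coords[name][i] = c
    segment = np.zeros(n, dtype=int)
    seg = 0
    for i in range(1, n):
        new_seg = chain_of[i] != chain_of[i - 1]
        if not new_seg:
            ca1, ca0 = coords["CA"][i], coords["CA"][i - 1]
            incomplete = not (residues[i].is_complete and residues[i - 1].is_complete)
            far = np.any(np.isnan(ca1)) or np.any(np.isnan(ca0)) or \
                np.linalg.norm(ca1 - ca0) > CA_BREAK_DIST
            new_seg = incomplete or far
        if new_seg:
            seg += 1
        segment[i] = seg
    return residues, chain_of, idx_in_chain, coords, segment


def kabsch_sander_hbonds(s: Structure) -> list[HydrogenBond]:
    """All accepted backbone hydrogen bonds of a structure.

    Bonds are scored with the Kabsch-Sander four-distance electrostatic
    energy and accepted below -0.5 kcal/mol; at most the two best bonds per
    donor are retained, pairs closer than two residues in the flat order
    are excluded, and candidates are prefiltered to Calpha pairs within
    9 A.  Residues missing any required atom are silently skipped.
    """
    place_amide_hydrogens(s)
    _, _, _, coords, _ = _flatten(s)
    n = coords["CA"].shape[0]
    if n == 0:
        return []
    ca = coords["CA"]
    ca_ok = ~np.isnan(ca).any(axis=1)
    donor_ok = ~np.isnan(coords["N"]).any(axis=1) & ~np.isnan(coords["H"]).any(axis=1)
    acceptor_ok = ~np.isnan(coords["C"]).any(axis=1) & ~np.isnan(coords["O"]).any(axis=1)

    ca_filled = np.where(ca_ok[:, None], ca, 1e6)
    near = cdist(ca_filled, ca_filled) < CA_NEIGHBOUR_CUTOFF

    bonds_per_donor: dict[int, list[HydrogenBond]] = {}
    donors = np.nonzero(donor_ok & ca_ok)[0]
    for i in donors:
        js = np.nonzero(near[i] & acceptor_ok & ca_ok)[0]
        js = js[np.abs(js - i) >= 2]
        if js.size == 0:
            continue
        r_on = np.linalg.norm(coords["O"][js] - coords["N"][i], axis=1)
        r_ch = np.linalg.norm(coords["C"][js] - coords["H"][i], axis=1)
        r_oh = np.linalg.norm(coords["O"][js] - coords["H"][i], axis=1)
        r_cn = np.linalg.norm(coords["C"][js] - coords["N"][i], axis=1)
        with np.errstate(divide="ignore"):
            e = HBOND_Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        e = np.where(np.minimum.reduce([r_on, r_ch, r_oh, r_cn]) < 0.5, MIN_ENERGY, e)
        e = np.maximum(e, MIN_ENERGY)
        keep = e < HBOND_CUTOFF
        cand = sorted(zip(e[keep], js[keep]))[:2]  # two best bonds per donor
        if cand:
            bonds_per_donor[int(i)] = [
                HydrogenBond(donor_res=int(i), acceptor_res=int(j), energy=float(ev))
                for ev, j in cand
            ]
    return [b for group in bonds_per_donor.values() for b in group]


def _kappa(ca: np.ndarray, segment: np.ndarray) -> np.ndarray:
    n = ca.shape[0]
    kappa = np.full(n, np.nan)
    for i in range(2, n - 2):
        if segment[i - 2] != segment[i] or segment[i] != segment[i + 2]:
            continue
        if np.isnan(ca[[i - 2, i, i + 2]]).any():
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        try:
            kappa[i] = angle_deg(u, v)
        except ValueError:
            continue
    return kappa


def assign_secstruct(s: Structure) -> SecStructAssignment:
    """Eight-class secondary structure for every residue of ``s``.

    Pattern rules: an n-turn at i is a bond from N-H(i+n) to C=O(i)
    (n = 3, 4, 5); two consecutive n-turns start a minimal helix (G/H/I);
    bridges follow the parallel/antiparallel double-bond patterns, with
    consecutive bridges forming ladders (E) and isolated ones kept as B;
    remaining turn-pattern residues become T and high-curvature residues
    (kappa > 70 deg over i-2, i, i+2) become S.  Overlaps resolve with
    priority H > E > B > G > I > T > S > C.
    """
    bonds = kabsch_sander_hbonds(s)
    residues, chain_of, idx_in_chain, coords, segment = _flatten(s)
    n = len(residues)
    hb = {(b.donor_res, b.acceptor_res) for b in bonds}

    def same_seg(i, j):
        return segment[i] == segment[j]

    # --- n-turns -------------------------------------------------------
    turn = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in turn:
        for i in range(n - m):
            if same_seg(i, i + m) and (i + m, i) in hb:
                turn[m][i] = True

    # --- helices: two consecutive n-turns start a minimal helix --------
    helix_mark = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in turn:
        for i in range(1, n - m):
            if turn[m][i - 1] and turn[m][i]:
                helix_mark[m][i:i + m] = True

    # --- bridges and ladders ------------------------------------------
    def interior(i):
        return 0 < i < n - 1 and same_seg(i - 1, i + 1)

    bridges: dict[tuple[int, int], int] = {}  # (i, j) i<j -> +1 par / -1 anti
    acceptors_of: dict[int, set[int]] = {}
    for d, a in hb:
        acceptors_of.setdefault(d, set()).add(a)

    def hbond(a, b):  # C=O of a accepts N-H of b
        return a in acceptors_of.get(b, ())

    candidates = set()
    for d, a in hb:
        for i, j in ((d, a), (a, d)):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < n and abs(ii - jj) >= 3:
                        candidates.add((min(ii, jj), max(ii, jj)))
    for i, j in candidates:
        if not (interior(i) and interior(j)):
            continue
        par = (hbond(i - 1, j) and hbond(j, i + 1)) or (hbond(j - 1, i) and hbond(i, j + 1))
        anti = (hbond(i, j) and hbond(j, i)) or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
        if par:
            bridges[(i, j)] = 1
        elif anti:
            bridges[(i, j)] = -1

    # Ladders: bridges of the same sense at (i+1, j+1) (parallel) or
    # (i+1, j-1) (antiparallel) chain together; ladders of >= 2 bridges are E.
    in_ladder = set()
    for (i, j), sense in bridges.items():
        nxt = (i + 1, j + 1) if sense == 1 else (min(i + 1, j - 1), max(i + 1, j - 1))
        if bridges.get(nxt) == sense:
            in_ladder.update({(i, j), nxt})

    e_mark = np.zeros(n, dtype=bool)
    b_mark = np.zeros(n, dtype=bool)
    sense_acc = np.zeros(n)
    for (i, j), sense in bridges.items():
        target = e_mark if (i, j) in in_ladder else b_mark
        target[i] = target[j] = True
        sense_acc[i] += sense
        sense_acc[j] += sense

    # --- turns (T candidates) and bends -------------------------------
    t_mark = np.zeros(n, dtype=bool)
    for m in turn:
        for i in np.nonzero(turn[m])[0]:
            t_mark[i + 1:i + m] = True
    kappa = _kappa(coords["CA"], segment)
    s_mark = np.nan_to_num(kappa, nan=0.0) > BEND_KAPPA

    # --- priority resolution ------------------------------------------
    classes = np.full(n, "C", dtype="<U1")
    classes[s_mark] = "S"
    classes[t_mark] = "T"
    classes[helix_mark[5]] = "I"
    classes[helix_mark[3]] = "G"
    classes[b_mark] = "B"
    classes[e_mark] = "E"
    classes[helix_mark[4]] = "H"

    sense_sign = np.sign(sense_acc).astype(int)
    sense_sign[~np.isin(classes, ["E", "B"])] = 0

    out = SecStructAssignment(structure_id=s.id)
    for cid, chain_residues in s.chains.items():
        idx = [k for k in range(n) if chain_of[k] == cid]
        cls = "".join(classes[idx])
        mask = np.array([c in LOOP_CLASSES for c in cls])
        out.chains[cid] = ChainAssignment(
            classes=cls,
            loop_mask=mask,
            kappa=kappa[idx],
            sense=sense_sign[idx],
            segment=segment[idx],
        )
        assert len(cls) == len(chain_residues)
    return out


def loop_mask(a: SecStructAssignment | str) -> np.ndarray:
    """Collapsed loop/non-loop mask: True where the class is none/turn/bend."""
    if isinstance(a, str):
        return np.array([c in LOOP_CLASSES for c in a])
    return a.all_loop_mask


def assignment_table(s: Structure, a: SecStructAssignment):
    """Per-residue TSV-ready table: chain, seq_id, aa, class8, loop_flag, kappa."""
    import pandas as pd

    rows = []
    for cid, residues in s.chains.items():
        ca = a.chains[cid]
        for j, res in enumerate(residues):
            rows.append({
                "chain": cid,
                "seq_id": res.seq_id,
                "aa": res.aa,
                "class8": ca.classes[j],
                "loop_flag": bool(ca.loop_mask[j]),
                "kappa": float(ca.kappa[j]) if np.isfinite(ca.kappa[j]) else np.nan,
            })
    return pd.DataFrame(rows)
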