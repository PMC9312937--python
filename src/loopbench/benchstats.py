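"""Aggregate benchmark statistics over per-loop metric tables.

Covers the dataset-level summaries of a loop benchmark: the loop-residue
fraction of each protein, length-stratified means with standard errors,
ordinary least-squares fits with R^2 (per-loop or on per-length bin
means), eight-class composition tables of loop residues, representative
loop selection, experimental-ensemble variability, confidence-vs-accuracy
binning, Pearson correlations, and a mean hydropathy index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loops import LoopPair, LoopRegion, extract_loops, pair_loops
from .metrics import loop_rmsd
from .secstruct import REGULAR_CLASSES, SecStructAssignment, assign_secstruct
from .structure_io import Structure, StructureError

log = logging.getLogger(__name__)

__all__ = [
    "LengthBinSummary",
    "RegressionFit",
    "loop_fraction",
    "stratify_by_length",
    "linear_fit",
    "sse_composition",
    "select_representatives",
    "ensemble_variability",
    "correlate",
    "binned_profile",
    "hydropathy_index",
    "KYTE_DOOLITTLE",
]

# Kyte-Doolittle hydropathy scale (one value per standard amino acid).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

COMPOSITION_CLASSES = [
    "none", "turn", "bend",
    "parallel_sheet", "antiparallel_sheet",
    "alpha_helix", "pi_helix", "three_ten_helix",
]


@dataclass
class LengthBinSummary:
    length: int
    n: int
    mean: float
    se: float
    min: float
    max: float


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def loop_fraction(a: SecStructAssignment) -> float:
    """Fraction of a structure's residues classified as loop (none/turn/bend)."""
    mask = a.all_loop_mask
    if mask.size == 0:
        raise StructureError("empty assignment")
    return float(mask.mean())


def stratify_by_length(rows: pd.DataFrame, field: str) -> list[LengthBinSummary]:
    """One summary per distinct loop length, sorted ascending.

    Standard error is sample sd (n-1 denominator) / sqrt(n); singleton
    lengths report se = 0.
    """
    if rows.empty:
        raise ValueError("empty metrics table")
    if field not in rows.columns:
        raise KeyError(f"unknown field {field!r}")
    out = []
    for length, grp in rows.groupby("length"):
        vals = grp[field].to_numpy(dtype=float)
        n = vals.size
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(LengthBinSummary(
            length=int(length), n=int(n), mean=float(vals.mean()), se=se,
            min=float(vals.min()), max=float(vals.max()),
        ))
    return sorted(out, key=lambda b: b.length)


def linear_fit(x, y, on_bin_means: bool = False) -> RegressionFit:
    """Ordinary least squares with R^2 = 1 - SSres/SStot.

    With ``on_bin_means`` the fit is computed on the per-length mean of y
    (x must then be the lengths), reproducing fits of binned averages
    rather than raw per-loop scatter.  Constant y has R^2 defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 points")
    if on_bin_means:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False).mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("all x values identical")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.ptp(y) == 0 or np.isnan(res.rvalue) else float(res.rvalue ** 2)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=r2, n=int(x.size))


def _loop_class_counts(loops: list[LoopRegion]) -> dict[str, int]:
    counts = dict.fromkeys(COMPOSITION_CLASSES, 0)
    for loop in loops:
        sense = loop.sense if loop.sense is not None else np.zeros(loop.length)
        for c, sn in zip(loop.classes, sense):
            if c == "C":
                counts["none"] += 1
            elif c == "T":
                counts["turn"] += 1
            elif c == "S":
                counts["bend"] += 1
            elif c in "EB":
                # isolated bridges are counted with the sheets
                key = "parallel_sheet" if sn > 0 else "antiparallel_sheet"
                counts[key] += 1
            elif c == "H":
                counts["alpha_helix"] += 1
            elif c == "I":
                counts["pi_helix"] += 1
            elif c == "G":
                counts["three_ten_helix"] += 1
    return counts


def sse_composition(loops_by_source: dict[str, list[LoopRegion]]) -> pd.DataFrame:
    """Eight-class residue composition of loop-span residues per source.

    Input maps a source tag (``experimental`` / ``predicted``) to the loop
    fragments carrying their full-structure classes restricted to the
    span.  Fractions within a source sum to 1.  Two extra rows report the
    aggregate regular-SS fraction and, of that, the helix share.
    """
    data = {}
    for source, loops in loops_by_source.items():
        counts = _loop_class_counts(loops)
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"no loop residues for source {source!r}")
        frac = {k: v / total for k, v in counts.items()}
        regular = sum(frac[k] for k in ("parallel_sheet", "antiparallel_sheet",
                                        "alpha_helix", "pi_helix",
                                        "three_ten_helix"))
        helix = sum(frac[k] for k in ("alpha_helix", "pi_helix",
                                      "three_ten_helix"))
        frac["regular_ss_fraction"] = regular
        frac["helix_share_of_regular"] = helix / regular if regular > 0 else 0.0
        data[source] = frac
    df = pd.DataFrame(data)
    core = df.loc[COMPOSITION_CLASSES]
    assert np.allclose(core.sum(axis=0), 1.0, atol=1e-9)
    return df


def select_representatives(rows: pd.DataFrame, lengths: list[int]) -> dict[int, str]:
    """Per requested length, the pair whose RMSD is closest to the mean
    RMSD of loops of that length (ties go to the smaller pair_id)."""
    out: dict[int, str] = {}
    for length in lengths:
        grp = rows[rows["length"] == length]
        if grp.empty:
            log.warning("no loops of length %d; skipped", length)
            continue
        mean = grp["rmsd_A"].mean()
        grp = grp.assign(_dist=(grp["rmsd_A"] - mean).abs())
        grp = grp.sort_values(["_dist", "pair_id"])
        out[length] = str(grp.iloc[0]["pair_id"])
    return out


def ensemble_variability(
    exp_structures: list[Structure],
    pred: Structure,
    min_len: int = 3,
    atom_set: str = "backbone",
) -> dict:
    """Loop-level RMSD spread of an experimental ensemble vs the prediction.

    Loop spans are defined on the first experimental structure (the
    reference).  Set 1 holds all pairwise experimental-experimental loop
    RMSDs (the experimental range of accuracy), set 2 all
    predicted-experimental loop RMSDs.  Returns both collections and their
    means.
    """
    if len(exp_structures) < 2:
        raise ValueError("need at least 2 experimental structures")
    ref = exp_structures[0]
    assignment = assign_secstruct(ref)
    ref_loops = extract_loops(ref, assignment, min_len=min_len)

    def fragments(target: Structure) -> list:
        pairs, rejected = pair_loops(ref, ref_loops, target)
        if rejected:
            log.warning("%d loops unmatched in %s", len(rejected), target.id)
        return pairs

    exp_exp, pred_exp = [], []
    per_structure_pairs = [fragments(st) for st in exp_structures[1:]]
    pred_pairs_by_ref = fragments(pred)
    # exp-exp: reference vs each replicate, and replicates among themselves
    for pairs in per_structure_pairs:
        exp_exp.extend(loop_rmsd(p, atom_set=atom_set) for p in pairs)
    for a in range(len(exp_structures[1:])):
        for b in range(a + 1, len(exp_structures[1:])):
            by_id = {p.pair_id: p for p in per_structure_pairs[b]}
            for p in per_structure_pairs[a]:
                q = by_id.get(p.pair_id)
                if q is None:
                    continue
                exp_exp.append(loop_rmsd(
                    LoopPair(exp=p.pred, pred=q.pred, pair_id=p.pair_id),
                    atom_set=atom_set))
    # pred-exp: prediction against every experimental structure
    pred_exp.extend(loop_rmsd(p, atom_set=atom_set) for p in pred_pairs_by_ref)
    for pairs in per_structure_pairs:
        by_id = {p.pair_id: p for p in pred_pairs_by_ref}
        for p in pairs:
            q = by_id.get(p.pair_id)
            if q is None:
                continue
            pred_exp.append(loop_rmsd(
                LoopPair(exp=p.pred, pred=q.pred, pair_id=p.pair_id),
                atom_set=atom_set))
    return {
        "exp_exp": np.asarray(exp_exp),
        "pred_exp": np.asarray(pred_exp),
        "exp_exp_mean": float(np.mean(exp_exp)) if exp_exp else np.nan,
        "pred_exp_mean": float(np.mean(pred_exp)) if pred_exp else np.nan,
        "n_loops": len(ref_loops),
    }


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson r and r^2 of two equal-length vectors (length >= 3)."""
    if method != "pearson":
        raise ValueError("only pearson correlation is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        # near-constant inputs are routine (e.g. mostly-zero SS gain)
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def binned_profile(x, y, width: float = 0.05,
                   x_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-bin mean/min/max/count of y against binned x (e.g. confidence
    as a function of TM-score)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = x_range if x_range else (np.floor(x.min() / width) * width, x.max())
    edges = np.arange(lo, hi + width, width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = y[idx == b]
        if sel.size == 0:
            continue
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "n": int(sel.size),
            "mean": float(sel.mean()), "min": float(sel.min()),
            "max": float(sel.max()),
        })
    return pd.DataFrame(rows)


def hydropathy_index(sequence: str, scale: dict[str, float] | None = None) -> float:
    """Mean hydropathy of a sequence (Kyte-Doolittle by default);
    nonstandard residues are excluded from the mean."""
    scale = scale or KYTE_DOOLITTLE
    vals = [scale[c] for c in sequence.upper() if c in scale]
    skipped = len(sequence) - len(vals)
    if skipped:
        log.info("hydropathy: excluded %d nonstandard residues", skipped)
    if not vals:
        raise ValueError("no standard residues in sequence")
    return float(np.mean(vals))
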