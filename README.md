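# loopbench

Loop-level benchmarking of predicted protein structures against
experimental references.

Loops — the regions of a protein that are neither α-helix nor β-strand —
are the least conserved and most flexible parts of a structure, and the
hardest for structure predictors to get right. `loopbench` is for
structural bioinformaticians who want to quantify, loop by loop, how well
a predicted model (e.g. an AlphaFold-style model carrying per-residue
confidence in the B-factor column) reproduces an experimentally determined
structure.

Given pairs of PDB files (experimental reference, predicted model), the
pipeline:

1. assigns 8-class secondary structure to both full structures with a
   from-scratch DSSP-style algorithm: backbone amide hydrogens are rebuilt,
   an N–H···O=C hydrogen bond is accepted when the Kabsch–Sander
   electrostatic energy
   `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol
   falls below −0.5 kcal/mol, and bond patterns yield the classes
   H, G, I (helices), E, B (sheets/bridges), T (turn), S (bend), C (none);
2. extracts **loops** — maximal runs of residues classed none/turn/bend,
   at least 3 residues long — from the *experimental* assignment, and pairs
   each with the predicted fragment at the same residue numbers under a
   100% sequence-identity contract;
3. scores every loop pair with
   - **RMSD** (Å) after an optimal Kabsch superposition of the fragments
     (backbone atoms N, CA, C, O by default),
   - **TM-score** `max (1/L) Σᵢ 1/(1+(dᵢ/d₀)²)` over rigid superpositions,
     with `d₀ = max(0.5, 1.24·(L−15)^⅓ − 1.8)` and L the loop length,
   - **ΔSSE**, the percent of loop residues that gained regular secondary
     structure in the prediction, and
   - **mean pLDDT**, the per-atom average of the predicted confidence;
4. aggregates: length-stratified means with standard errors, OLS fits with
   R², 8-class composition tables, representative-loop selection,
   confidence-vs-accuracy binning, and an ensemble-variability comparison
   (replicate-vs-replicate loop RMSD against prediction-vs-experiment).

A first-class synthetic generator (`loopbench.synthetic_data`) builds
paired structures from ideal backbone torsions with controlled loop-length
distribution, length-dependent coordinate noise, spurious-helix injection
and a confidence score anticorrelated with the local error — so the whole
analysis runs and is tested without downloading a single structure.

## Worked example

```python
from loopbench import (SyntheticSpec, build_protein, perturb_to_prediction,
                       assign_secstruct, extract_loops, pair_loops,
                       compute_pair_metrics)

spec = SyntheticSpec(seed=3)
exp = build_protein(spec, seed=3, struct_id="demo")
pred, truth = perturb_to_prediction(exp, spec, seed=4)

loops = extract_loops(exp, assign_secstruct(exp), min_len=3)
pairs, _ = pair_loops(exp, loops, pred, assign_secstruct(pred))
print(compute_pair_metrics(pairs).round(3).head())
```

prints (abridged):

```
       pair_id  length  rmsd_A    tm  delta_sse_pct  mean_plddt
   demo_A_7-11       5   0.221 0.950            0.0      88.928
  demo_A_31-46      16   0.946 0.404            0.0      74.136
demo_A_108-110       3   0.105 0.994            0.0      93.173
```

Each row is one loop: a 5-residue loop reproduced to 0.22 Å with TM-score
0.95 and high confidence, a 16-residue loop that drifted to 0.95 Å / TM
0.40 with visibly lower confidence, and no spurious secondary structure in
either (`delta_sse_pct = 0`). The same numbers come from the shell:

```bash
loopbench simulate --out bench --n-proteins 8 --seed 42
loopbench run --manifest bench/manifest.tsv --out results/
loopbench ensemble --reference a_exp.pdb --replicate b_exp.pdb \
    --prediction a_pred.pdb --out ensemble.tsv
```

The `examples/` directory holds one short narrative script per capability.

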