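"""Generate a small synthetic benchmark set of paired structures.

Each protein is written twice: an idealised "experimental" backbone and a
"predicted" copy with length-dependent coordinate noise, occasional
spurious helices, and per-residue confidence in the B-factor column.
"""

from pathlib import Path

import pandas as pd

from loopbench import SyntheticSpec, generate_benchmark_set

out = Path("scratch/example_bench")
spec = SyntheticSpec(n_proteins=4, seed=7)
manifest = generate_benchmark_set(spec, out)

print(manifest.to_string(index=False))
truth = pd.read_csv(out / "truth.tsv", sep="\t")
print(f"\n{len(truth)} simulated loops; "
      f"{truth.injected.mean():.1%} carry an injected helix")
print("Loop length distribution (drawn):")
print((truth.loop_end - truth.loop_start).describe().round(2).to_string())
# The manifest pairs the files; truth.tsv records the spans and noise
# amplitudes actually applied, for parameter-recovery checks.
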