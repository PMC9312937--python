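"""Run the full pipeline over a small benchmark and print the aggregate
tables: length-stratified accuracy and the 8-class composition of loop
residues in both sources."""

import tempfile

import pandas as pd

from loopbench import SyntheticSpec, generate_benchmark_set
from loopbench.pipeline import RunConfig, run_benchmark, summaries_from_results

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_benchmark_set(SyntheticSpec(n_proteins=8, seed=42), tmp)
    result = run_benchmark(list(manifest.itertuples(index=False, name=None)),
                           RunConfig())

tables = summaries_from_results(result)
print("Mean RMSD by loop length (A):")
print(tables["rmsd_by_length"].round(3).to_string(index=False))
print("\nLoop-residue composition (fractions per source):")
print(tables["composition"].round(4).to_string(index=False))
# The experimental column shows 0 for every helix/sheet class: loop spans
# are defined on the experimental assignment, so only the predicted copy
# can contain regular secondary structure inside a loop span.
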