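"""Assign 8-class secondary structure to an ideal helix and collapse it to
the loop mask (loop = none/turn/bend)."""

from loopbench import assign_secstruct, make_ideal_segment
from loopbench.secstruct import assignment_table

helix = make_ideal_segment("alpha_helix", 12)
assignment = assign_secstruct(helix)

print("classes  :", assignment.chains["A"].classes)
print("loop mask:", "".join("L" if m else "." for m in assignment.chains["A"].loop_mask))
print(assignment_table(helix, assignment).to_string(index=False))
# Interior residues are H (alpha helix); the two termini lack the double
# i->i+4 hydrogen-bond pattern and fall back to the loop class C.
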