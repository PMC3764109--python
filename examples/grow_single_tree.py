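"""Grow one lineage under asymmetric dilution, deterministically and with
binomial segregation noise, and print the resulting trees.

A founder cell holds a division factor (content 1, or n0 molecules).  Each
division passes a fraction p to one daughter and 1-p to the other; a cell
below the threshold phi exits the cycle.  The final population size N_f is
set purely by (p, phi) — no feedback, no external signal.
"""

from hourglass import (
    export_newick,
    grow_deterministic,
    grow_stochastic,
    validate_params,
)

params = validate_params(p=0.3, phi=0.5)

det = grow_deterministic(params)
print(f"deterministic: N_f = {det.final_size}, curve = {list(det.growth_curve.sizes)}")
print("  newick:", export_newick(det))
# N_f = 3: the founder splits 0.7/0.3; 0.3 is quiescent, 0.7 splits into
# 0.49/0.21, both below 0.5 -> three quiescent cells after 2 iterations.

sto = grow_stochastic(params, n0=10_000, seed=42)
print(f"stochastic (n0=10,000): N_f = {sto.final_size}, "
      f"curve = {list(sto.growth_curve.sizes)}")
print("  leaf molecule counts:", [int(n.content) for n in sto.leaves()],
      "(sum = n0: molecules are conserved)")
# With 10,000 molecules the binomial noise per division is ~1%, so the
# stochastic lineage almost always reproduces the deterministic N_f = 3.
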