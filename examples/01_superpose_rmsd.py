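"""Global C-alpha RMSD between two conformations of the same protein.

Builds two synthetic two-lobe structures that differ by a 16-degree
opening of the large lobe plus 0.2 A coordinate noise, matches their
residues by author numbering, and reports the least-squares RMSD —
the same "global RMSD over n CA atoms" statistic used to compare
crystal structures of a kinase.
"""

from conformap import Selection, match_core_by_number, superpose
from conformap.synth import TwoLobeParams, make_two_lobe

closed, _ = make_two_lobe(TwoLobeParams(theta_open=0.0, noise_sd=0.2, seed=1))
open_, _ = make_two_lobe(TwoLobeParams(theta_open=16.0, noise_sd=0.2, seed=2))

core = match_core_by_number(closed, open_, Selection())
result, moved = superpose(closed, open_, core)

print(f"matched CA atoms : {result.n_atoms}")
print(f"global RMSD      : {result.rmsd:.2f} A")
print()
print("The RMSD mixes the rigid 16-degree domain motion with the noise;")
print("aligning on the full chain spreads the lobe displacement over all")
print("atoms, which is why whole-molecule RMSD understates domain motion.")

core_small = match_core_by_number(closed, open_, Selection(ranges=((1, 60),)))
res_small, _ = superpose(closed, open_, core_small)
print(f"small-lobe-only RMSD over {res_small.n_atoms} atoms: "
      f"{res_small.rmsd:.2f} A (the lobes themselves barely change)")
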