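"""Classifying a solvent peak as K+, Na+ or water from coordination geometry.

Builds a distorted octahedral site with six oxygen ligands at ~2.8 A
(potassium-like) and one at ~2.4 A (sodium-like), and a sparse site,
then runs the rule cascade a crystallographer would apply: coordination
number, mean ligand distance, and the number of acceptor-only contacts
a water would have to satisfy by donating hydrogen bonds.
"""

import json

from conformap import classify_site, coordination_shell, site_report
from conformap.synth import make_ion_site, make_scan_scene
from conformap.ions import scan_solvent_sites

for species, dist in [("potassium", 2.8), ("sodium", 2.4)]:
    site, _ = make_ion_site(species, dist, 6, distortion_sd=0.05, seed=3)
    cls = classify_site(coordination_shell(site, (0, 0, 0)))
    print(f"{species:9s} site: CN={cls.coordination_number}, "
          f"mean={cls.mean_distance:.2f} A -> call: {cls.call}")

print()
scene = make_scan_scene(n_bulk_waters=20, seed=0)
results = scan_solvent_sites(scene)
top_id, top = results[0]
print(f"scan of {len(results)} solvent/ion sites: top hit {top_id} -> {top.call}")
print(f"rationale: {top.rationale}")
print()
print("Full per-ligand report of the buried site:")
print(json.dumps(site_report(scene, (0, 0, 0)), indent=2)[:600], "...")
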