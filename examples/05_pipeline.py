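"""Config-driven pipeline: PCA + pairwise comparisons from coordinate files.

Writes a small synthetic ensemble to PDB files, builds a YAML config
naming the structures, an ensemble and two comparisons, validates it,
and runs every task, producing projections.csv, comparisons.csv and a
machine-readable report.json.
"""

import json
import tempfile
from pathlib import Path

import yaml

from conformap.io import write_structure
from conformap.pipeline import run_pipeline, validate_config
from conformap.synth import make_ensemble

workdir = Path(tempfile.mkdtemp(prefix="conformap_demo_"))
structures, truth = make_ensemble([0, 8, 16, 24, 32, 40], [0.0],
                                  noise_sd=0.05, seed=1)
for s in structures:
    write_structure(s, workdir / f"{s.identifier}.pdb")

config = {
    "seed": 1,
    "output_dir": str(workdir / "out"),
    "structures": [{"id": s.identifier, "path": str(workdir / f"{s.identifier}.pdb")}
                   for s in structures],
    "selections": {"all": "1-180", "small": "1-60", "large": "61-180"},
    "ensemble": {"members": [s.identifier for s in structures],
                 "reference": structures[0].identifier, "selection": "all"},
    "comparisons": [
        {"pair": [structures[0].identifier, structures[2].identifier],
         "align": "small", "moving": "large", "rmsd_selection": "all"},
        {"pair": [structures[0].identifier, structures[5].identifier],
         "align": "small", "moving": "large", "rmsd_selection": "all"},
    ],
}
cfg_path = workdir / "config.yaml"
cfg_path.write_text(yaml.safe_dump(config))

cfg = validate_config(cfg_path)
report = run_pipeline(cfg)

for task in report["tasks"]:
    line = {k: v for k, v in task.items()
            if k in ("task", "status", "pair", "rmsd_global", "n_atoms",
                     "interlobe_angle", "significant_modes", "core_size")}
    print(json.dumps(line))
print(f"\noutputs in {cfg.output_dir}:",
      sorted(p.name for p in Path(cfg.output_dir).iterdir()))
print("The two comparisons recover the generator's 16- and 40-degree")
print("openings; the ensemble PCA finds one dominant (opening) mode.")
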