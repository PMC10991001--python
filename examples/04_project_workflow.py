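"""Project-folder workflow: import -> annotate -> process -> export.

Mirrors the shell workflow (`gazeval init/import/process/export`) from
Python: two synthetic recordings are imported into a project, data
quality is computed for their annotated validation episodes, and a
single summary table is exported across recordings.
"""

import tempfile
from pathlib import Path

import pandas as pd

import gazeval as gv

root = Path(tempfile.mkdtemp())
poster = gv.default_poster()

for name, seed in (("participant_01", 1), ("participant_02", 2)):
    cfg = gv.SimulationConfig(poster=poster, offset_deg=(0.8, 0.0),
                              noise_sigma_deg=0.1, seed=seed)
    rec, _ = gv.simulate_recording(cfg)
    gv.write_recording(rec, root / "raw" / name)

proj = gv.Project.init(root / "project")
report = proj.import_recordings([root / "raw" / "participant_01",
                                 root / "raw" / "participant_02"])
print("import:", report)
for name in report:
    proj.process(name)
out = proj.export(average_over_targets=True)
df = pd.read_csv(out)
print(df[["recording", "accuracy_deg", "rms_s2s_deg", "std_deg",
          "data_loss_percent"]].round(3).to_string(index=False))
# One row per recording x episode; accuracy should recover the 0.8 deg
# offset and the precision columns the injected 0.1 deg noise level.
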