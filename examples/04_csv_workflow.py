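"""Round-tripping recorded data: CSV condition folders and the CLI.

Recorded sessions live as one folder per condition with one CSV per
repetition (columns: time_s, then one column per joint).  This script
writes a simulated condition in that layout, loads it back, and shows
the equivalent shell commands.
"""

import tempfile
from pathlib import Path

from jointcoord import ArmSpec, load_dataset, make_reaching_dataset, write_dataset

root = Path(tempfile.mkdtemp()) / "session"

ds = make_reaching_dataset(ArmSpec(strategy="physiological", seed=1))
write_dataset(ds, root / "physiological")
print(f"wrote {len(ds)} repetitions to {root / 'physiological'}")
print("files:", sorted(p.name for p in (root / 'physiological').glob('*.csv'))[:4], "...")

back = load_dataset(root / "physiological")
print(f"loaded back: {len(back)} repetitions, joints {back.joint_names}, "
      f"unit {back.angle_unit}")
rep = back.repetitions[0]
print(f"first repetition: {rep.n_samples} samples, target {rep.meta['target']}")

print()
print("The same pipeline from a shell:")
print("  jointcoord simulate --strategy physiological --out phys/")
print("  jointcoord simulate --strategy shoulder_only --out sho/")
print("  jointcoord report --reference phys/ --compare sho/ --out report/")
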