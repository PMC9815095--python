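"""Write a complete on-disk fixture: PDB models, MRC channels, truth JSON.

Everything the command-line pipeline consumes can be generated from a seed:
a clean model, a register-shifted copy, 20 single-channel MRC probability
maps with a JSON manifest, and a ground-truth record.
"""

import json
import pathlib
import tempfile

from daqrefine import write_model, write_probability_volume
from daqrefine.synthetic import core_fixture

out = pathlib.Path(tempfile.mkdtemp(prefix="daqrefine_fixture_"))
spec, clean, shifted, volume = core_fixture(seed=0, n=60, region=(26, 35))

write_model(clean, out / "model.pdb")
write_model(shifted, out / "shifted.pdb")
manifest = write_probability_volume(volume, out, stem="prob")
(out / "truth.json").write_text(json.dumps(
    {"seed": 0, "region": [26, 35], "shift": 3,
     "sequence": spec.sequence}, indent=1))

print(f"fixture written to {out}")
print(f"volume: {volume.dims} voxels, origin {volume.origin.tolist()}")
print("files:", sorted(p.name for p in out.iterdir())[:6], "...")
print("\nequivalent CLI: daqrefine simulate --out-dir DIR --n 60 "
      "--region 26 35 --seed 0")
# The manifest lists the 20 MRC channels; `daqrefine score` consumes it.
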