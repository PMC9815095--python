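"""Select the best candidate model by total DAQ(AA).

Scores an ensemble of progressively damaged models against the same
probability volume, ranks them, and correlates the DAQ total with true
quality (GDT-HA against the clean reference).
"""

from daqrefine import correlate_quality, rank_candidates
from daqrefine.synthetic import core_fixture, inject_register_shift

spec, clean, shifted10, volume = core_fixture(seed=0)
candidates = {
    "clean": clean,
    "shift_5res": inject_register_shift(clean, (46, 50), 3),
    "shift_10res": shifted10,
}

cset = rank_candidates(list(candidates.values()), volume,
                       labels=list(candidates))
print("rank  label        total DAQ(AA)")
for i, (label, total) in enumerate(zip(cset.labels, cset.totals), start=1):
    print(f"{i:4d}  {label:<12s} {total:10.1f}")
print(f"selected final model: {cset.selected[0]}")
# Larger planted errors give lower totals, so the undamaged model is
# selected; this is the selection step of the refinement protocol.
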