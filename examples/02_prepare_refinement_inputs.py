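"""Build the trimmed template and masked MSA for local re-prediction.

Low-confidence residues (windowed DAQ(AA) <= 0) are removed from the
template so a structure predictor is free to re-model them; the MSA columns
of the *confident* residues are gapped so the predictor has no evolutionary
signal with which to alter them.
"""

from daqrefine import compute_daq, mask_msa, trim_template
from daqrefine.io_formats import MaskedMSA
from daqrefine.synthetic import core_fixture

spec, clean, shifted, volume = core_fixture(seed=0)
track = compute_daq(shifted, volume)

template = trim_template(shifted, track)
print(f"template keeps {len(template.kept)} of "
      f"{len(template.kept) + len(template.removed)} residues "
      f"(criterion: {template.criterion})")
print("removed residues:", sorted(k.number for k in template.removed))

query = shifted.sequence
msa = MaskedMSA(query=query, names=["query", "homolog1", "homolog2"],
                rows=[query, query, query])
masked = mask_msa(msa, track)
print(f"masked {len(masked.mask)} of {len(query)} MSA positions "
      f"(the confident complement of the trimmed residues)")
print("non-query row around the planted error (cols 40-61):")
print(" ", masked.rows[1][39:61])
# The template drops exactly the planted shift region (and its windowed
# shoulders); the MSA keeps evolutionary signal only for those residues.
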