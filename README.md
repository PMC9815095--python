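# daqrefine

DAQ-guided quality assessment of cryo-EM protein models and preparation of
inputs for local refinement.

## The problem

Models built into 3–5 Å cryo-EM maps frequently contain *register shifts*:
the main-chain trace is essentially right, but amino-acid identities are
assigned offset by a few positions, typically along a helix. A deep network
scanning the map produces, for every grid position, a probability
distribution over the 20 amino-acid types. This package consumes those
probabilities (as 20 single-channel MRC maps or a per-residue table) and
scores each residue *i* carrying type *a* with the log-ratio

    DAQ(AA)_i = ln( p_i(a) / (1/N) Σ_j p_j(a) )

where `p_i(a)` is the probability of type *a* at the residue's Cα and the
denominator averages that type's probability over all `N` scored positions
in the model. The score is positive exactly when the position looks more
like its assigned type than the model-wide average; a global rescaling of
any channel cancels. Raw scores are averaged with a 19-residue sliding
window along the sequence, and windowed scores below −0.5 mark residues
that very likely do not fit the local density.

On top of the score, the toolkit implements the surrounding refinement
protocol machinery:

* **Template trimming** — residues with windowed DAQ(AA) ≤ 0 are removed
  from the model, producing a template that covers only confident regions.
* **MSA masking** — the alignment columns of *confident* (score ≥ 0)
  positions are gapped in all non-query rows, so a structure predictor
  (e.g. AlphaFold2 run with a custom template and MSA) has no evolutionary
  signal with which to alter the trusted regions, and full freedom in the
  doubtful ones. Running the predictor itself is out of scope: the package
  prepares its inputs and evaluates its outputs.
* **Model selection** — candidate refined models are superposed on the
  trimmed template, scored against the same volume, and the model with the
  highest total windowed DAQ(AA) is selected.
* **Quality metrics** — Kabsch superposition, Cα r.m.s.d., GDT-HA (mean
  over 0.5/1/2/4 Å thresholds of the maximal fraction of Cα pairs
  superposable within each threshold), and a misaligned-segment detector
  (≥4 contiguous residues that sit >2 Å from their counterparts while
  lying close to a *different* reference residue).
* **Synthetic fixtures** — seeded toy backbones, oracle probability
  volumes, and injectable register/conformational errors give the whole
  pipeline a closed, downloadable-data-free testing loop.

## Worked example

```python
from daqrefine import compute_daq, total_daq, trim_template
from daqrefine.synthetic import core_fixture

spec, clean, shifted, volume = core_fixture(seed=0)   # 100-residue helix,
track = compute_daq(shifted, volume, window=19)       # 10-residue +3 shift
```

Around the planted error (`python examples/01_score_a_model.py`):

```
residue  aa  raw     windowed
     45  F    2.45     -0.31
     46  K   -3.38     -0.61 <- planted shift
     ...
     55  V   -3.40     -0.61 <- planted shift
     56  S    2.45     -0.31

10 residues flagged below -0.5 (planted region: 46-55)
total DAQ(AA): shifted 187.1 vs clean 245.4
```

Raw scores drop from ≈ +2.5 to ≈ −3.4 exactly over the shifted residues;
the 19-residue window localises the error, every planted residue is
flagged at the −0.5 threshold, and the damaged model's total falls well
below the clean model's, so selection picks the clean model. The
`examples/` directory walks through each capability (scoring, input
preparation, evaluation, ranking, fixture simulation); a thin CLI exposes
the same stages as `daqrefine simulate|score|prep|evaluate|select`.

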