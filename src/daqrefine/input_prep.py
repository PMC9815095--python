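"""Preparation of refinement inputs from a scored model.

Two complementary artefacts steer an external structure predictor toward
re-modelling only the low-confidence regions of an initial model:

* the **trimmed template** — the initial model with every residue whose
  windowed DAQ(AA) is non-positive removed, so the template covers only the
  confident regions;
* the **masked MSA** — the full alignment with the match columns of every
  *confident* (non-negative score) position gapped out in all non-query
  rows, so the predictor has no evolutionary signal with which to alter
  those regions.  The query row is never touched: the predictor must still
  see the complete target sequence.

Candidate models coming back from the predictor are superposed onto the
trimmed template (Kabsch over shared Cα pairs) before relaxation and
selection.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import MaskedMSA, ProteinModel
from .daq_scoring import ResidueScoreTrack
from .model_metrics import kabsch


@dataclass
class TrimmedTemplate:
    """A template model restricted to confidently modelled residues."""

    model: ProteinModel
    kept: set
    removed: set
    criterion: str
    status: str = "ok"   # "ok" | "empty_template"


def trim_template(model: ProteinModel, track: ResidueScoreTrack,
                  rule: str = "le0") -> TrimmedTemplate:
    """Drop low-confidence residues from the model.

    ``rule="le0"`` (default) removes residues with windowed DAQ(AA) ≤ 0;
    ``rule="lt0"`` removes only strictly negative ones.  Kept residues are
    carried over untouched — coordinates, numbering and atoms are those of
    the source model.  An empty result is flagged (``status =
    "empty_template"``) rather than silently returned.
    """
    if rule not in ("le0", "lt0"):
        raise ValidationError(f"unknown trim rule {rule!r}")
    scores = {e.key: e.windowed for e in track.entries}
    model_keys = [r.key(model.chain_id) for r in model.scoreable()]
    missing = [k for k in model_keys if k not in scores]
    if missing:
        raise ValidationError(
            f"track does not cover {len(missing)} model residues "
            f"(first: {missing[0]})")
    cut = (lambda v: v <= 0.0) if rule == "le0" else (lambda v: v < 0.0)
    removed = {k for k in model_keys if cut(scores[k])}
    kept = set(model_keys) - removed
    residues = [r for r in model.residues
                if r.key(model.chain_id) not in removed]
    trimmed = ProteinModel(chain_id=model.chain_id, residues=residues,
                           source_path=model.source_path)
    crit = "windowed_daq <= 0" if rule == "le0" else "windowed_daq < 0"
    status = "ok" if kept else "empty_template"
    return TrimmedTemplate(model=trimmed, kept=kept, removed=removed,
                           criterion=crit, status=status)


def mask_msa(msa: MaskedMSA, track: ResidueScoreTrack,
             threshold: float = 0.0) -> MaskedMSA:
    """Gap out the confident columns of the alignment.

    Query positions whose windowed DAQ(AA) is ≥ ``threshold`` (default 0)
    have their match column replaced by ``-`` in every non-query row.
    Lowercase insertion states are preserved and the query row is returned
    unchanged.  Masking is idempotent.
    """
    if len(msa.query) != len(track.entries):
        raise ValidationError(
            f"MSA query has {len(msa.query)} residues but the track covers "
            f"{len(track.entries)}; they must describe the same chain")
    mask = {i + 1 for i, e in enumerate(track.entries)
            if e.windowed >= threshold}
    masked_cols = {msa.col_to_query.index(p) for p in mask}

    new_rows = [msa.rows[0]]
    for row in msa.rows[1:]:
        out = []
        col = 0
        for ch in row:
            if ch == "-" or ch.isupper():
                out.append("-" if col in masked_cols else ch)
                col += 1
            else:
                out.append(ch)  # insertion state, not a match column
        new_rows.append("".join(out))
    return MaskedMSA(query=msa.query, names=list(msa.names), rows=new_rows,
                     col_to_query=list(msa.col_to_query),
                     mask=msa.mask | mask)


def superpose_on_template(candidate: ProteinModel,
                          template: TrimmedTemplate) -> ProteinModel:
    """Rigidly fit a candidate model onto the trimmed template.

    The Kabsch transform is computed over the Cα of residues shared by key
    between candidate and template, then applied to every atom of the
    candidate, so its internal geometry is untouched.
    """
    tmpl = template.model
    tmpl_ca = {r.key(tmpl.chain_id): r.ca for r in tmpl.scoreable()}
    pairs = [(r.ca, tmpl_ca[r.key(candidate.chain_id)])
             for r in candidate.scoreable()
             if r.key(candidate.chain_id) in tmpl_ca]
    if len(pairs) < 3:
        raise ValidationError(
            f"candidate and template share only {len(pairs)} residues; "
            "need at least 3 for superposition")
    X = np.array([p for p, _ in pairs])
    Y = np.array([q for _, q in pairs])
    T = kabsch(X, Y).transform

    moved = copy.deepcopy(candidate)
    for res in moved.residues:
        res.atoms = [(name, T.apply(xyz)) for name, xyz in res.atoms]
        if res.ca is not None:
            res.ca = T.apply(res.ca)
    return moved
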