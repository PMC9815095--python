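"""DAQ-based ranking of candidate refined models.

All candidates are scored against the same probability volume; the model
with the highest total windowed DAQ(AA) is the final model.  Ties are broken
by input order (first listed wins) and recorded.  For ensembles of models
with unequal length a mean-per-residue ranking mode is available, since the
total is only comparable between models of the same chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .errors import ValidationError
from .daq_scoring import DEFAULT_WINDOW, compute_daq, total_daq
from .model_metrics import gdt_ha


@dataclass
class CandidateSet:
    """Candidates ordered best-first by total DAQ(AA)."""

    labels: list
    models: list
    tracks: list
    totals: list
    ties: list = field(default_factory=list)  # groups of tied labels, best-first
    ranking_mode: str = "total_windowed"

    def __post_init__(self):
        if not (len(self.labels) == len(self.models) == len(self.tracks)
                == len(self.totals)):
            raise ValidationError("candidate fields must have equal lengths")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("candidate labels must be unique")

    @property
    def selected(self):
        """(label, model) of the final model — the top-ranked candidate."""
        return self.labels[0], self.models[0]


def rank_candidates(models, volume, labels=None, window=DEFAULT_WINDOW,
                    per_residue=False, use_raw=False) -> CandidateSet:
    """Score and rank candidate models against one probability volume.

    Candidates are sorted by decreasing total windowed DAQ(AA) (or the
    per-residue mean with ``per_residue``, or raw totals with ``use_raw``).
    The sort is stable, so tied candidates keep their input order; tie
    groups are recorded in ``ties``.
    """
    models = list(models)
    if not models:
        raise ValidationError("no candidate models to rank")
    if labels is None:
        labels = [f"model_{i + 1}" for i in range(len(models))]
    labels = list(labels)

    tracks = [compute_daq(m, volume, window=window) for m in models]
    totals = []
    for tr in tracks:
        tot = total_daq(tr, use_raw=use_raw)
        totals.append(tot / len(tr.entries) if per_residue else tot)

    order = sorted(range(len(models)), key=lambda i: (-totals[i], i))
    ties = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and totals[order[j + 1]] == totals[order[i]]:
            j += 1
        if j > i:
            ties.append([labels[k] for k in order[i:j + 1]])
        i = j + 1

    mode = ("raw" if use_raw else "windowed")
    mode = ("mean_per_residue_" if per_residue else "total_") + mode
    return CandidateSet(
        labels=[labels[i] for i in order],
        models=[models[i] for i in order],
        tracks=[tracks[i] for i in order],
        totals=[totals[i] for i in order],
        ties=ties, ranking_mode=mode)


class CorrelationResult(NamedTuple):
    r: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    n: int
    status: str  # "ok" | "undefined"


def correlate_quality(candidates: CandidateSet, reference,
                      mapping=None) -> CorrelationResult:
    """Pearson correlation (and regression line) of total DAQ(AA) vs GDT-HA.

    Quantifies how well the DAQ total tracks true model quality across an
    ensemble.  With zero variance in either variable the correlation is
    undefined and reported as such rather than as a number.
    """
    if len(candidates.models) < 3:
        raise ValidationError("need at least 3 candidates for a correlation")
    daq = np.array(candidates.totals, dtype=float)
    quality = np.array([gdt_ha(m, reference, mapping=mapping).gdt_ha
                        for m in candidates.models])
    if np.ptp(daq) == 0.0 or np.ptp(quality) == 0.0:
        return CorrelationResult(None, None, None, len(daq), "undefined")
    fit = stats.linregress(daq, quality)
    return CorrelationResult(float(fit.rvalue), float(fit.slope),
                             float(fit.intercept), len(daq), "ok")
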