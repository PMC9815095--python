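"""Per-residue DAQ(AA) scoring.

The DAQ(AA) score of residue *i* carrying amino-acid type *a* is the log-ratio

    DAQ(AA)_i = ln( p_i(a) / mean_j p_j(a) )

where ``p_i(a)`` is the probability of type *a* at the residue's scoring
position (its Cα, by default) read from the 20-channel probability volume,
and the denominator averages that type's probability over all scoring
positions *j* in the model.  By construction the score is positive exactly
when the position looks more like its assigned type than the model-wide
average, and any global rescaling of a channel cancels.

Raw scores are then averaged along the sequence with a sliding window
(default 19 residues) to expose local register shifts; residues whose
windowed score falls below a threshold (default −0.5) are flagged as likely
modelling errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryMismatchError, ValidationError
from .io_formats import (AA20, AA_INDEX, ProbabilityVolume, ProteinModel,
                         ResidueKey, ResidueProbabilityTable)

DEFAULT_WINDOW = 19
DEFAULT_FLAG_THRESHOLD = -0.5
DEFAULT_FLOOR = 1e-6


@dataclass
class LookupDiagnostics:
    """Counts of degenerate probability lookups (never fatal)."""

    n_lookups: int = 0
    n_out_of_grid: int = 0
    n_floored: int = 0

    def merge(self, other):
        self.n_lookups += other.n_lookups
        self.n_out_of_grid += other.n_out_of_grid
        self.n_floored += other.n_floored


@dataclass
class ScoreEntry:
    key: ResidueKey
    aa: str
    raw: float
    windowed: float


@dataclass
class ResidueScoreTrack:
    """Raw and window-smoothed DAQ(AA) values, one entry per scored residue."""

    entries: list
    chain_id: str = "A"
    window: int = 1
    floor: float = DEFAULT_FLOOR
    diagnostics: LookupDiagnostics = field(default_factory=LookupDiagnostics)

    def raw_values(self) -> np.ndarray:
        return np.array([e.raw for e in self.entries])

    def windowed_values(self) -> np.ndarray:
        return np.array([e.windowed for e in self.entries])

    def keys(self) -> list:
        return [e.key for e in self.entries]

    def value_by_key(self, key: ResidueKey, windowed=True) -> float:
        for e in self.entries:
            if e.key == key:
                return e.windowed if windowed else e.raw
        raise KeyError(key)


# ---------------------------------------------------------------------------
# Probability lookup
# ---------------------------------------------------------------------------

def interpolate_channel(volume: ProbabilityVolume, points, channel,
                        mode="trilinear", floor=DEFAULT_FLOOR,
                        diagnostics: Optional[LookupDiagnostics] = None):
    """Probabilities of one amino-acid channel at Cartesian points.

    Trilinear interpolation by default (``mode="nearest"`` snaps to the
    closest voxel).  Points outside the grid, and interpolated values below
    ``floor``, return ``floor``; both cases are tallied in ``diagnostics``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValidationError("non-finite lookup coordinates")
    ci = channel if isinstance(channel, int) else AA_INDEX[channel]
    inside = volume.contains(points)
    out = np.full(len(points), floor, dtype=float)
    if inside.any():
        frac = volume.fractional_index(points[inside])
        if mode == "nearest":
            idx = np.rint(frac).astype(int).T
            vals = volume.data[ci][tuple(idx)]
        elif mode == "trilinear":
            vals = map_coordinates(volume.data[ci], frac.T, order=1, mode="nearest")
        else:
            raise ValidationError(f"unknown interpolation mode {mode!r}")
        out[inside] = np.maximum(vals, floor)
    if diagnostics is not None:
        diagnostics.n_lookups += len(points)
        diagnostics.n_out_of_grid += int((~inside).sum())
        diagnostics.n_floored += int((out <= floor).sum())
    return out


def probability_at(volume, point, aa, mode="trilinear", floor=DEFAULT_FLOOR,
                   diagnostics=None) -> float:
    """Probability of amino-acid type ``aa`` at a single point (Å)."""
    return float(interpolate_channel(volume, point, aa, mode=mode,
                                     floor=floor, diagnostics=diagnostics)[0])


def _probability_matrix(volume, points, mode, floor, diagnostics):
    """(n_points, 20) matrix of channel probabilities at the given points."""
    cols = [interpolate_channel(volume, points, c, mode=mode, floor=floor,
                                diagnostics=diagnostics) for c in range(20)]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# Raw scoring
# ---------------------------------------------------------------------------

def raw_daq_aa(model: ProteinModel, volume, positions="ca",
               mode="trilinear", floor=DEFAULT_FLOOR) -> ResidueScoreTrack:
    """Raw DAQ(AA) for every scoreable residue of ``model``.

    ``positions`` selects the normalisation set: ``"ca"`` (default) averages
    each type's probability over the Cα of every scored residue; ``"all"``
    averages over every atom position in the model.  The score of residue
    *i* is always evaluated at its Cα.

    Raises :class:`GeometryMismatchError` when more than half of the Cα
    lookups fall outside the grid, which almost always means the model and
    the volume are not in the same coordinate frame.
    """
    scoreable = model.scoreable()
    if not scoreable:
        raise ValidationError("model has no residues with a Cα coordinate")
    aa_idx = np.array([AA_INDEX[r.aa_type] for r in scoreable])
    diags = LookupDiagnostics()

    if isinstance(volume, ResidueProbabilityTable):
        P = np.stack([volume.row(r.number) for r in scoreable])
        P = np.maximum(P, floor)
        norm = P
    else:
        ca = np.stack([r.ca for r in scoreable])
        n_inside = int(volume.contains(ca).sum())
        if n_inside < 0.5 * len(ca):
            raise GeometryMismatchError(
                f"only {n_inside}/{len(ca)} Cα positions fall inside the grid; "
                "check that the model and the probability volume share a frame "
                "(origin/spacing)")
        P = _probability_matrix(volume, ca, mode, floor, diags)
        if positions == "ca":
            norm = P
        elif positions == "all":
            pts = np.concatenate(
                [[xyz for _, xyz in r.atoms] for r in model.residues])
            norm = _probability_matrix(volume, pts, mode, floor, diags)
        else:
            raise ValidationError(f"unknown normalisation set {positions!r}")

    mean_per_type = norm.mean(axis=0)  # average of each channel over positions j
    own = P[np.arange(len(scoreable)), aa_idx]
    raw = np.log(own) - np.log(mean_per_type[aa_idx])

    entries = [ScoreEntry(key=r.key(model.chain_id), aa=r.aa_type,
                          raw=float(v), windowed=float(v))
               for r, v in zip(scoreable, raw)]
    return ResidueScoreTrack(entries=entries, chain_id=model.chain_id,
                             window=1, floor=floor, diagnostics=diags)


# ---------------------------------------------------------------------------
# Smoothing, flagging, totals
# ---------------------------------------------------------------------------

def _contiguous_segments(entries):
    """Index ranges of entries contiguous in author numbering (chain breaks split)."""
    segments = []
    start = 0
    for i in range(1, len(entries)):
        prev, cur = entries[i - 1].key, entries[i].key
        step = cur.number - prev.number
        contiguous = step == 1 or (step == 0 and cur.icode != prev.icode)
        if not contiguous:
            segments.append((start, i))
            start = i
    segments.append((start, len(entries)))
    return segments


def smooth_track(track: ResidueScoreTrack, window: int = DEFAULT_WINDOW) -> ResidueScoreTrack:
    """Average raw scores over a centred sliding window along the sequence.

    The window covers up to ``(window-1)//2`` residues on each side, shrinks
    at chain termini, and never crosses a gap in author numbering.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and positive, got {window}")
    raw = track.raw_values()
    half = (window - 1) // 2
    smoothed = np.empty_like(raw)
    for a, b in _contiguous_segments(track.entries):
        for i in range(a, b):
            lo, hi = max(a, i - half), min(b, i + half + 1)
            smoothed[i] = raw[lo:hi].mean()
    entries = [replace(e, windowed=float(s)) for e, s in zip(track.entries, smoothed)]
    return ResidueScoreTrack(entries=entries, chain_id=track.chain_id,
                             window=window, floor=track.floor,
                             diagnostics=track.diagnostics)


def flag_low_confidence(track: ResidueScoreTrack,
                        threshold: float = DEFAULT_FLAG_THRESHOLD) -> set:
    """Residue keys whose windowed score falls below ``threshold``."""
    return {e.key for e in track.entries if e.windowed < threshold}


def total_daq(track: ResidueScoreTrack, use_raw: bool = False) -> float:
    """Sum of windowed (or raw) DAQ(AA) over the track; compares models of one chain."""
    if not track.entries:
        raise ValidationError("cannot total an empty track")
    vals = track.raw_values() if use_raw else track.windowed_values()
    return float(vals.sum())


def compute_daq(model, volume, window: int = DEFAULT_WINDOW, positions="ca",
                mode="trilinear", floor=DEFAULT_FLOOR) -> ResidueScoreTrack:
    """Raw scoring followed by window smoothing in one call."""
    return smooth_track(raw_daq_aa(model, volume, positions=positions,
                                   mode=mode, floor=floor), window=window)
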