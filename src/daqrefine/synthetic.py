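"""Desk-scale synthetic fixtures with known ground truth.

Generates toy Cα backbones, oracle amino-acid probability volumes peaked at
the true residue identities, and copies of a model carrying injected errors
(register shifts, conformational displacements).  Together these give every
other module a closed testing loop with no external data.

Signal model
------------
Each residue imprints a Gaussian-weighted probability distribution around
its Cα.  The imprint gives the residue's own type ``peak_prob`` (default
0.6), each of the two *sequence-neighbour* types ``neighbor_prob`` (default
0.19) and spreads the small remainder uniformly over the other types.  The
neighbour mass mimics the dominant confusion mode of a sliding-box density
classifier, whose receptive field overlaps the adjacent residues; it also
keeps the probability of an unrelated type at an occupied position low,
which is what makes an assignment error sharply visible in the log-ratio
score.  Imprints are blended with a weak uniform background
(``background_weight``); voxel distributions always sum to one exactly and
the field is uniform (1/20 per type) far from the model.  The default
``blur_sigma`` of 1.3 Å keeps the imprints of residues three apart on a
helix (≈5 Å contacts) from cross-talking, which is what lets the windowed
score separate a planted register shift at the −0.5 threshold.

With ``peak_prob = 1/20`` the imprint degenerates to the uniform
distribution (no signal) and every DAQ(AA) score is identically zero.

All randomness (random sequences, Dirichlet-style voxel noise, jitter)
derives from the single ``seed`` of the spec; identical seeds reproduce
identical outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .io_formats import AA20, AA_INDEX, ProbabilityVolume, ProteinModel, Residue

HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å
EXTENDED_SPACING = 3.8  # Å between consecutive Cα


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic fixture.

    ``peak_prob`` is the probability mass on the true amino-acid type at a
    residue's Cα; ``neighbor_prob`` the mass on each of the two
    sequence-neighbour types; ``blur_sigma`` the Gaussian radius (Å) of the
    imprint; ``noise`` the scale of multiplicative log-normal perturbation
    of voxel distributions (0 = noiseless oracle).
    """

    n_residues: int = 100
    geometry: str = "helix"        # helix | extended | mixed
    sequence: Optional[str] = None  # explicit, or None for seed-random
    peak_prob: float = 0.6
    neighbor_prob: float = 0.19
    blur_sigma: float = 1.3
    background_weight: float = 0.01
    noise: float = 0.0
    spacing: float = 1.0
    padding: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValidationError("need at least 5 residues")
        if not (1 / 20 - 1e-12) <= self.peak_prob <= 1.0:
            raise ValidationError("peak_prob must lie in [1/20, 1]")
        if self.neighbor_prob < 0 or self.peak_prob + 2 * self.neighbor_prob > 1.0:
            raise ValidationError("peak_prob + 2*neighbor_prob must not exceed 1")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValidationError("explicit sequence length must equal n_residues")

    def rng(self):
        return np.random.default_rng(self.seed)


def cyclic_sequence(n: int) -> str:
    """Deterministic sequence cycling through the 20 amino acids.

    Guarantees that any register shift with 0 < |k| < 20 changes the
    amino-acid identity at every shifted position, so a planted shift is
    never silently identity-preserving.
    """
    return (AA20 * (n // 20 + 1))[:n]


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

def make_backbone(spec: SyntheticSpec) -> ProteinModel:
    """Ideal-geometry Cα trace (helix / extended / mixed), chain A, numbered from 1."""
    n = spec.n_residues
    if spec.sequence is not None:
        seq = spec.sequence.upper()
    else:
        rng = spec.rng()
        seq = "".join(rng.choice(list(AA20), size=n))
    bad = sorted({c for c in seq} - set(AA20))
    if bad:
        raise ValidationError(f"sequence contains non-canonical letters {bad}")

    if spec.geometry == "helix":
        coords = _helix_coords(np.arange(n))
    elif spec.geometry == "extended":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * EXTENDED_SPACING
    elif spec.geometry == "mixed":
        h = n // 2
        coords = np.zeros((n, 3))
        coords[:h] = _helix_coords(np.arange(h))
        start = coords[h - 1] if h else np.zeros(3)
        coords[h:, 0] = start[0] + EXTENDED_SPACING * np.arange(1, n - h + 1)
        coords[h:, 1] = start[1]
        coords[h:, 2] = start[2]
    else:
        raise ValidationError(f"unknown geometry {spec.geometry!r}")

    residues = [Residue(number=i + 1, aa_type=seq[i],
                        atoms=[("CA", coords[i].copy())], ca=coords[i].copy())
                for i in range(n)]
    return ProteinModel(chain_id="A", residues=residues, source_path="<synthetic>")


def _helix_coords(idx):
    theta = np.deg2rad(HELIX_TWIST) * idx
    return np.column_stack([HELIX_RADIUS * np.cos(theta),
                            HELIX_RADIUS * np.sin(theta),
                            HELIX_RISE * idx])


# ---------------------------------------------------------------------------
# Probability volumes
# ---------------------------------------------------------------------------

def _imprint_distribution(spec, own_idx, neighbor_idx):
    """The 20-type distribution a residue imprints at its Cα."""
    q = np.zeros(20)
    if spec.peak_prob <= 1 / 20 + 1e-12:
        q[:] = 1 / 20  # degenerate: no signal
        return q
    q[own_idx] = spec.peak_prob
    for nb in neighbor_idx:
        q[nb] += spec.neighbor_prob
    leftover = 1.0 - q.sum()
    rest = q == 0.0
    if rest.any():
        q[rest] = leftover / rest.sum()
    else:
        q += leftover / 20
    return q


def make_probability_volume(model: ProteinModel, spec: SyntheticSpec,
                            rng=None) -> ProbabilityVolume:
    """Oracle probability volume for a model.

    The grid covers the model with ``spec.padding`` Å margin at
    ``spec.spacing`` Å per voxel.  Each residue adds its imprint
    distribution with Gaussian weight exp(−d²/2σ²) (σ = ``blur_sigma``,
    truncated at 3σ); voxels blend with the uniform background and are
    exactly normalised.  ``noise > 0`` applies a seeded multiplicative
    log-normal perturbation per channel and voxel, renormalised per voxel.
    """
    ca = model.ca_coords()
    origin = np.floor(ca.min(axis=0) - spec.padding)
    top = np.ceil(ca.max(axis=0) + spec.padding)
    dims = (np.rint((top - origin) / spec.spacing).astype(int) + 1)
    weighted = np.zeros((20, *dims))
    wsum = np.zeros(tuple(dims))

    residues = model.scoreable()
    seq_idx = [AA_INDEX[r.aa_type] for r in residues]
    reach = int(math.ceil(3 * spec.blur_sigma / spec.spacing))
    for i, res in enumerate(residues):
        nb = [seq_idx[j] for j in (i - 1, i + 1) if 0 <= j < len(residues)]
        q = _imprint_distribution(spec, seq_idx[i], nb)
        centre = (res.ca - origin) / spec.spacing
        lo = np.maximum(np.floor(centre).astype(int) - reach, 0)
        hi = np.minimum(np.floor(centre).astype(int) + reach + 1, dims)
        gx, gy, gz = [np.arange(lo[d], hi[d]) for d in range(3)]
        dist2 = ((gx[:, None, None] - centre[0]) ** 2
                 + (gy[None, :, None] - centre[1]) ** 2
                 + (gz[None, None, :] - centre[2]) ** 2) * spec.spacing ** 2
        w = np.exp(-dist2 / (2 * spec.blur_sigma ** 2))
        w[dist2 > (3 * spec.blur_sigma) ** 2] = 0.0
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        wsum[sl] += w
        weighted[(slice(None), *sl)] += w * q[:, None, None, None]

    beta = spec.background_weight
    data = (weighted + beta / 20) / (wsum + beta)

    if spec.noise > 0:
        rng = rng if rng is not None else spec.rng()
        data = data * np.exp(spec.noise * rng.standard_normal(data.shape))
        data /= data.sum(axis=0, keepdims=True)

    vol = ProbabilityVolume(origin=origin,
                            spacing=np.full(3, float(spec.spacing)),
                            data=data)
    return vol.validate()


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def _residue_index(model, number):
    for i, r in enumerate(model.residues):
        if r.number == number and not r.icode:
            return i
    raise ValidationError(f"model has no residue numbered {number}")


def _check_region(model, region, shift=0):
    a, b = region
    if a > b:
        raise ValidationError(f"empty region {region}")
    for num in (a, b, a + shift, b + shift):
        _residue_index(model, num)


def inject_register_shift(model: ProteinModel, region, shift: int) -> ProteinModel:
    """Plant a sequence-assignment (register) error.

    Residues numbered within ``region`` (inclusive) take the amino-acid type
    of the residue ``shift`` positions further along the chain; coordinates
    are untouched.  This is exactly an assignment error, not a
    conformational one.
    """
    _check_region(model, region, shift)
    a, b = region
    source_type = {r.number: r.aa_type for r in model.residues}
    residues = []
    for r in model.residues:
        aa = r.aa_type
        if a <= r.number <= b and not r.icode:
            aa = source_type[r.number + shift]
        residues.append(Residue(number=r.number, icode=r.icode, aa_type=aa,
                                atoms=[(n, xyz.copy()) for n, xyz in r.atoms],
                                ca=None if r.ca is None else r.ca.copy()))
    return ProteinModel(chain_id=model.chain_id, residues=residues,
                        source_path=model.source_path)


def inject_trace_shift(model: ProteinModel, region, shift: int) -> ProteinModel:
    """Plant the geometric face of a register error.

    Residues within ``region`` take the *coordinates* of the residue
    ``shift`` positions along the chain while keeping their own type and
    number — the trace runs along the reference backbone but one register
    off, which is what two depositions of the same chain with a local
    sequence shift look like when compared.
    """
    _check_region(model, region, shift)
    a, b = region
    coords = {r.number: r for r in model.residues}
    residues = []
    for r in model.residues:
        src = coords[r.number + shift] if (a <= r.number <= b and not r.icode) else r
        residues.append(Residue(number=r.number, icode=r.icode, aa_type=r.aa_type,
                                atoms=[(n, xyz.copy()) for n, xyz in src.atoms],
                                ca=None if src.ca is None else src.ca.copy()))
    return ProteinModel(chain_id=model.chain_id, residues=residues,
                        source_path=model.source_path)


def inject_conformational_error(model: ProteinModel, region, displacement: float,
                                direction=(0.0, 0.0, 1.0), jitter: float = 0.0,
                                seed: int = 0) -> ProteinModel:
    """Displace a region coherently; amino-acid types are unchanged.

    The region is moved rigidly by ``displacement`` Å along ``direction``
    plus optional per-residue Gaussian jitter (σ = ``jitter`` Å, seeded).
    The default direction is the helix axis (+z of the synthetic builder):
    an axial displacement leaves no compromise superposition that could
    partially recapture the displaced residues, so the planted inlier count
    is exactly what every superposition search must report.
    """
    _check_region(model, region)
    a, b = region
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    rng = np.random.default_rng(seed)
    residues = []
    for r in model.residues:
        if a <= r.number <= b and not r.icode:
            delta = displacement * u
            if jitter > 0:
                delta = delta + rng.normal(scale=jitter, size=3)
            atoms = [(n, xyz + delta) for n, xyz in r.atoms]
            ca = None if r.ca is None else r.ca + delta
        else:
            atoms = [(n, xyz.copy()) for n, xyz in r.atoms]
            ca = None if r.ca is None else r.ca.copy()
        residues.append(Residue(number=r.number, icode=r.icode,
                                aa_type=r.aa_type, atoms=atoms, ca=ca))
    return ProteinModel(chain_id=model.chain_id, residues=residues,
                        source_path=model.source_path)


# ---------------------------------------------------------------------------
# The core planted-shift experiment fixture
# ---------------------------------------------------------------------------

CORE_REGION = (46, 55)
CORE_SHIFT = 3


def core_fixture(seed: int = 0, n: int = 100, region=CORE_REGION,
                 shift: int = CORE_SHIFT, noise: float = 0.0):
    """The toolkit's standard recovery experiment.

    A 100-residue helix with a deterministic cyclic sequence (so the planted
    shift changes the identity at every shifted position), its noiseless
    oracle volume, and a copy with a ``shift``-register error planted on
    ``region``.  Returns ``(spec, clean_model, shifted_model, volume)``.
    """
    spec = SyntheticSpec(n_residues=n, geometry="helix",
                         sequence=cyclic_sequence(n), noise=noise, seed=seed)
    clean = make_backbone(spec)
    volume = make_probability_volume(clean, spec)
    shifted = inject_register_shift(clean, region, shift)
    return spec, clean, shifted, volume
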