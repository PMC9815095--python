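"""Domain types and file I/O.

Canonical in-memory objects for the toolkit — protein chain models, 20-channel
amino-acid probability volumes, multiple sequence alignments — together with
readers and writers for the external formats that carry them: PDB/mmCIF
(structures, via gemmi), MRC (probability channels, one single-channel map per
amino-acid type plus a JSON manifest), TSV (per-residue probability tables and
score tracks), A3M/FASTA (alignments) and JSON (quality reports).

Conventions
-----------
* Coordinates are in Å, in the same frame as the MRC header origin.
* Voxel indexing is 0-based; the centre of voxel (i, j, k) sits at
  ``origin + index * spacing``.
* Author residue numbering (with insertion codes) is preserved everywhere.
* Amino-acid channels are ordered by one-letter code: ``ACDEFGHIKLMNPQRSTVWY``.
"""

from __future__ import annotations

import json

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import gemmi
import numpy as np

from .errors import ParseError, ValidationError

#: Canonical amino acids in one-letter alphabetical order; fixes channel order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

#: Default mapping applied to common modified residues before rejection.
DEFAULT_NONSTANDARD = {"MSE": "M", "SEC": "C", "PYL": "K"}


class ResidueKey(NamedTuple):
    """Identity of a residue: chain id, author number, insertion code."""

    chain: str
    number: int
    icode: str = ""


@dataclass
class Residue:
    """One amino-acid residue with its atoms.

    ``ca``, when present, is the coordinate of the atom named CA and is the
    position used for probability lookups and superposition.
    """

    number: int
    aa_type: str
    atoms: list  # list of (atom_name, np.ndarray shape (3,))
    icode: str = ""
    ca: Optional[np.ndarray] = None

    def key(self, chain: str) -> ResidueKey:
        return ResidueKey(chain, self.number, self.icode)


@dataclass
class ProteinModel:
    """An ordered single-chain protein model."""

    chain_id: str
    residues: list
    source_path: str = ""

    def __post_init__(self):
        nums = [(r.number, r.icode) for r in self.residues]
        if nums != sorted(nums):
            raise ValidationError(
                f"residue numbers in chain {self.chain_id!r} are not increasing")
        for r in self.residues:
            if r.aa_type not in AA_INDEX:
                raise ValidationError(
                    f"residue {r.number}{r.icode} has non-canonical type {r.aa_type!r}")

    def keys(self) -> list:
        return [r.key(self.chain_id) for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)

    def scoreable(self) -> list:
        """Residues carrying a Cα coordinate, in chain order."""
        return [r for r in self.residues if r.ca is not None]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.scoreable()], dtype=float)

    def residue_by_key(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key(self.chain_id) == key:
                return r
        raise KeyError(key)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def load_model(path, chain, nonstandard_map=None):
    """Read one chain of a PDB or mmCIF file as a :class:`ProteinModel`.

    Waters and hetero-compounds are excluded.  Alternate locations are
    resolved to the highest-occupancy conformer (first listed on a tie).
    Modified residues listed in ``nonstandard_map`` (three-letter code →
    one-letter code; defaults to MSE/SEC/PYL) are accepted; any other
    non-canonical polymer residue raises :class:`ParseError`.
    """
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    mapping = dict(DEFAULT_NONSTANDARD)
    if nonstandard_map:
        mapping.update(nonstandard_map)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot read structure {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain not in names:
        raise ParseError(
            f"chain {chain!r} not in {path}; available chains: {sorted(set(names))}")

    residues = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.is_water():
                continue
            one = _THREE_TO_ONE.get(res.name) or mapping.get(res.name)
            if one is None:
                if res.het_flag == "H":
                    continue  # ligand etc.
                raise ParseError(
                    f"residue {res.seqid.num}{res.seqid.icode.strip()} in chain "
                    f"{chain} has unmapped non-canonical type {res.name!r}")
            atoms, ca = _collapse_altlocs(res)
            residues.append(Residue(
                number=res.seqid.num,
                icode=res.seqid.icode.strip(),
                aa_type=one, atoms=atoms, ca=ca))
    if not residues:
        raise ParseError(f"chain {chain!r} of {path} has no amino-acid residues")
    return ProteinModel(chain_id=chain, residues=residues, source_path=str(path))


def _collapse_altlocs(res):
    """Pick one atom per name: highest occupancy, then first listed."""
    best = {}
    order = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    atoms = []
    ca = None
    for name in order:
        a = best[name]
        xyz = np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float)
        atoms.append((name, xyz))
        if name == "CA":
            ca = xyz
    return atoms, ca


def write_model(model: ProteinModel, path) -> None:
    """Write a model as PDB, preserving author numbering and insertion codes."""
    st = gemmi.Structure()
    st.name = os.path.splitext(os.path.basename(str(path)))[0]
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id)
    for r in model.residues:
        gr = gemmi.Residue()
        gr.name = _ONE_TO_THREE[r.aa_type]
        gr.seqid = gemmi.SeqId(r.number, r.icode or " ")
        for name, xyz in r.atoms:
            ga = gemmi.Atom()
            ga.name = name
            ga.pos = gemmi.Position(*map(float, xyz))
            ga.element = gemmi.Element(name[:1] if name[:1] != "H" else "H")
            ga.occ = 1.0
            ga.b_iso = 0.0
            gr.add_atom(ga)
        ch.add_residue(gr)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Probability volumes
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityVolume:
    """A 20-channel amino-acid probability field on a regular grid.

    ``data`` has shape ``(20, nx, ny, nz)`` with channels in :data:`AA20`
    order.  At every voxel the 20 channel values form a probability
    distribution; :meth:`validate` checks this and records the worst
    deviation.
    """

    origin: np.ndarray      # (3,) Å
    spacing: np.ndarray     # (3,) Å per voxel
    data: np.ndarray        # (20, nx, ny, nz)
    sum_deviation: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.data.shape[0] != 20:
            raise ValidationError("probability volume needs 20 channels")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be positive")

    @property
    def dims(self):
        return self.data.shape[1:]

    def validate(self, hard_tol=1e-3, soft_tol=1e-6):
        """Check channel non-negativity and per-voxel sums.

        Deviations above ``hard_tol`` reject the volume, reporting the worst
        offending voxel; smaller deviations are recorded in
        ``sum_deviation``.
        """
        if np.any(self.data < 0):
            idx = np.unravel_index(int(np.argmin(self.data)), self.data.shape)
            raise ValidationError(f"negative probability at channel/voxel {idx}")
        sums = self.data.sum(axis=0)
        dev = np.abs(sums - 1.0)
        worst = np.unravel_index(int(np.argmax(dev)), dev.shape)
        self.sum_deviation = float(dev[worst])
        if self.sum_deviation > hard_tol:
            raise ValidationError(
                f"channel sums deviate from 1 by {self.sum_deviation:.3g} "
                f"at voxel {tuple(int(i) for i in worst)} "
                f"(sum={float(sums[worst]):.6f})")
        return self

    def fractional_index(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside the interpolatable grid."""
        f = self.fractional_index(points)
        upper = np.array(self.dims, dtype=float) - 1.0
        return np.all((f >= 0.0) & (f <= upper), axis=1)


@dataclass
class ResidueProbabilityTable:
    """Degenerate 'volume': per-residue amino-acid probabilities by residue number.

    Used when the probability field is supplied as a table (residue id + 20
    columns) rather than as grids; lookups are answered by residue identity
    only, so interpolation settings do not apply.
    """

    probs: dict  # residue number -> np.ndarray (20,)

    def row(self, number: int) -> np.ndarray:
        try:
            return self.probs[number]
        except KeyError:
            raise ValidationError(f"no probability row for residue {number}")


def load_probability_volume(source):
    """Load a probability field.

    ``source`` is either a JSON manifest pointing at 20 single-channel MRC
    maps (keys = one-letter codes) or a TSV table ``residue <tab> 20 columns``
    (header names the amino acids).  MRC channels must share origin, spacing
    and dimensions exactly; per-voxel channel sums are validated.
    """
    source = str(source)
    if source.endswith((".tsv", ".txt", ".csv")):
        return _load_probability_table(source)
    with open(source) as fh:
        manifest = json.load(fh)
    channels = manifest.get("channels")
    if not channels or sorted(channels) != sorted(AA20):
        raise ParseError(f"manifest {source} must name exactly the 20 channels")
    base = os.path.dirname(os.path.abspath(source))
    grids = []
    geom = None
    for aa in AA20:
        path = channels[aa]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        arr, origin, spacing = _read_mrc(path)
        if geom is None:
            geom = (arr.shape, tuple(origin), tuple(spacing))
        elif geom != (arr.shape, tuple(origin), tuple(spacing)):
            raise ValidationError(
                f"channel {aa} ({path}) header disagrees with channel "
                f"{AA20[0]}: {(arr.shape, tuple(origin), tuple(spacing))} vs {geom}")
        grids.append(arr)
    vol = ProbabilityVolume(
        origin=np.array(geom[1]), spacing=np.array(geom[2]),
        data=np.stack(grids).astype(np.float64))
    return vol.validate()


def write_probability_volume(vol: ProbabilityVolume, out_dir, stem="prob") -> str:
    """Write 20 MRC channel maps plus a JSON manifest; returns manifest path.

    MRC stores 32-bit floats (mode 2), so channel data are cast to float32.
    """
    os.makedirs(out_dir, exist_ok=True)
    channels = {}
    for i, aa in enumerate(AA20):
        name = f"{stem}_{aa}.mrc"
        _write_mrc(os.path.join(out_dir, name),
                   vol.data[i], vol.origin, vol.spacing)
        channels[aa] = name
    manifest = {
        "format": "daqrefine probability volume",
        "channels": channels,
        "origin": [float(x) for x in vol.origin],
        "spacing": [float(x) for x in vol.spacing],
        "dims": [int(d) for d in vol.dims],
    }
    mpath = os.path.join(out_dir, f"{stem}_manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return mpath


def _read_mrc(path):
    if not os.path.exists(path):
        raise ParseError(f"no such map file: {path}")
    m = gemmi.read_ccp4_map(str(path))
    grid = m.grid
    arr = np.array(grid, copy=True).astype(np.float64)
    spacing = np.array([grid.unit_cell.a / grid.nu,
                        grid.unit_cell.b / grid.nv,
                        grid.unit_cell.c / grid.nw])
    # MRC2014 ORIGIN words 50-52; fall back to NXSTART-style start words.
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    if np.all(origin == 0.0):
        start = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float)
        origin = start * spacing
    return arr, origin, spacing


def _write_mrc(path, arr, origin, spacing):
    arr32 = np.ascontiguousarray(arr, dtype=np.float32)
    nx, ny, nz = arr32.shape
    cell = gemmi.UnitCell(nx * spacing[0], ny * spacing[1], nz * spacing[2],
                          90.0, 90.0, 90.0)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr32, cell, gemmi.SpaceGroup("P1"))
    m.update_ccp4_header()
    m.set_header_float(50, float(origin[0]))
    m.set_header_float(51, float(origin[1]))
    m.set_header_float(52, float(origin[2]))
    m.write_ccp4_map(str(path))


def _load_probability_table(path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"empty probability table: {path}")
    header = lines[0].split("\t")
    if header[0].lower() not in ("residue", "residue_number", "resnum"):
        raise ParseError(f"{path}: first column must be the residue number")
    try:
        cols = [AA_INDEX[h] for h in header[1:]]
    except KeyError as exc:
        raise ParseError(f"{path}: unknown amino-acid column {exc}")
    if sorted(cols) != list(range(20)):
        raise ParseError(f"{path}: header must name each of the 20 amino acids once")
    probs = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != 21:
            raise ParseError(f"{path}:{lineno}: expected 21 columns, got {len(fields)}")
        row = np.empty(20)
        for c, v in zip(cols, fields[1:]):
            row[c] = float(v)
        if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-3:
            raise ValidationError(
                f"{path}:{lineno}: probabilities invalid (sum={row.sum():.6f})")
        probs[int(fields[0])] = row
    return ResidueProbabilityTable(probs=probs)


# ---------------------------------------------------------------------------
# Multiple sequence alignments
# ---------------------------------------------------------------------------

@dataclass
class MaskedMSA:
    """An A3M-style alignment with the query as the first row.

    ``rows`` keep lowercase insertion states; match columns are uppercase
    letters and gap characters.  ``col_to_query`` maps match-column index
    (0-based) to query position (1-based) and ``mask`` records query
    positions whose columns have been blanked in the non-query rows.
    """

    query: str
    names: list
    rows: list
    col_to_query: list = field(default_factory=list)
    mask: set = field(default_factory=set)

    def __post_init__(self):
        if not self.col_to_query:
            self.col_to_query = list(range(1, len(self.query) + 1))
        bad = {p for p in self.mask if not 1 <= p <= len(self.query)}
        if bad:
            raise ValidationError(f"mask positions outside query: {sorted(bad)}")

    @property
    def n_rows(self):
        return len(self.rows)


def _match_columns(row: str) -> int:
    return sum(1 for ch in row if ch == "-" or ch.isupper())


def load_msa(path) -> MaskedMSA:
    """Read an A3M or aligned-FASTA alignment; the first sequence is the query.

    Aligned FASTA with gap columns in the query is converted to A3M
    convention (query-gap columns become lowercase insertion states).
    '.' placeholders are dropped.  Every row must cover the same number of
    match columns as the query; offenders are reported by row index.
    """
    entries = _read_fasta(path)
    if not entries:
        raise ParseError(f"empty alignment file: {path}")
    names = [n for n, _ in entries]
    seqs = [s.replace(".", "") for _, s in entries]
    if any(c in seqs[0] for c in "-"):
        seqs = _aligned_fasta_to_a3m(seqs)
    query = "".join(ch for ch in seqs[0] if not ch.islower()).upper()
    if "-" in query or not query:
        raise ParseError(f"{path}: query row still contains gaps after conversion")
    for i, s in enumerate(seqs):
        mc = _match_columns(s)
        if mc != len(query):
            raise ParseError(
                f"{path}: row {i} ({names[i]!r}) covers {mc} match columns, "
                f"query has {len(query)}")
    return MaskedMSA(query=query, names=names, rows=seqs)


def _read_fasta(path):
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    entries = []
    name, chunks = None, []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith(">"):
                if name is not None:
                    entries.append((name, "".join(chunks)))
                name, chunks = ln[1:].strip(), []
            elif ln.strip():
                if name is None:
                    raise ParseError(f"{path}: sequence data before first header")
                chunks.append(ln.strip())
    if name is not None:
        entries.append((name, "".join(chunks)))
    return entries


def _aligned_fasta_to_a3m(seqs):
    """Columns where the query is gapped become insertion states."""
    qlen = len(seqs[0])
    keep = [c != "-" for c in seqs[0]]
    out = []
    for s in seqs:
        if len(s) != qlen:
            raise ParseError("aligned FASTA rows differ in length")
        chars = []
        for k, ch in zip(keep, s):
            if k:
                chars.append(ch.upper() if ch.isalpha() else "-")
            elif ch.isalpha():
                chars.append(ch.lower())
        out.append("".join(chars))
    return out


def write_msa(msa: MaskedMSA, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Score tracks and reports
# ---------------------------------------------------------------------------

def write_track(track, path, threshold=-0.5) -> None:
    """Write a score track as TSV.

    Columns: residue_number, insertion_code, aa, raw_daq, windowed_daq,
    flagged (windowed below ``threshold``).  Floats use shortest-round-trip
    formatting so read/write is bit-stable.
    """
    with open(path, "w") as fh:
        fh.write(f"# chain={track.chain_id} window={track.window} "
                 f"floor={track.floor!r} threshold={threshold!r}\n")
        fh.write("residue_number\tinsertion_code\taa\traw_daq\twindowed_daq\tflagged\n")
        for e in track.entries:
            flag = 1 if e.windowed < threshold else 0
            fh.write(f"{e.key.number}\t{e.key.icode}\t{e.aa}\t"
                     f"{e.raw!r}\t{e.windowed!r}\t{flag}\n")


def read_track(path):
    from .daq_scoring import ResidueScoreTrack, ScoreEntry  # local: avoids cycle
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}: missing track header line")
    meta = dict(tok.split("=", 1) for tok in lines[0][1:].split())
    entries = []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        num, icode, aa, raw, windowed, _flag = ln.split("\t")
        entries.append(ScoreEntry(
            key=ResidueKey(meta["chain"], int(num), icode),
            aa=aa, raw=float(raw), windowed=float(windowed)))
    return ResidueScoreTrack(
        entries=entries, chain_id=meta["chain"],
        window=int(meta["window"]), floor=float(meta["floor"]))


def write_report(report, path) -> None:
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path):
    from .model_metrics import QualityReport  # local import avoids a cycle
    with open(path) as fh:
        return QualityReport.from_dict(json.load(fh))
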