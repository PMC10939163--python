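"""Martin-numbered antibody Fv structures: PDB I/O, regions, backbone torsions.

The structures handled here follow the AbDb file-naming dialect
``<pdb>_<index>[P|H|N]`` where the optional suffix encodes the antigen type
(protein/peptide, hapten, nucleic acid) and its absence marks an unbound
entry.  Residues carry Martin-scheme numbers, which are treated as opaque
ordered labels: no renumbering is ever performed.

CDRs use the AbM (Martin) definition: L24-L34, L50-L56, L89-L97, H26-H35,
H50-H58, H95-H102.  The framework used for global fitting is every non-CDR
residue of a chain except the two N-terminal and the flexible C-terminal
positions (H109-H113, L106-L110).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "CDR_NAMES",
    "CDR_RANGES",
    "FRAMEWORK_EXCLUSIONS",
    "CIS_OMEGA_THRESHOLD",
    "PEPTIDE_BOND_MAX",
    "ResidueID",
    "Atom",
    "Residue",
    "Torsion",
    "AntibodyEntry",
    "RegionDefinition",
    "CDRLoop",
    "FilenameError",
    "StructureError",
    "parse_abdb_filename",
    "format_entry_id",
    "read_entry",
    "write_entry",
    "extract_cdr",
    "extract_framework",
    "compute_torsions",
    "is_cis",
]

# AbM (Martin) CDR definitions: chain, first and last Martin number (inclusive).
CDR_RANGES: dict[str, tuple[str, int, int]] = {
    "H1": ("H", 26, 35),
    "H2": ("H", 50, 58),
    "H3": ("H", 95, 102),
    "L1": ("L", 24, 34),
    "L2": ("L", 50, 56),
    "L3": ("L", 89, 97),
}
CDR_NAMES: tuple[str, ...] = ("H1", "H2", "H3", "L1", "L2", "L3")

# Terminal ranges excluded from the fitted framework (flexible, often missing).
FRAMEWORK_EXCLUSIONS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "H": ((1, 2), (109, 113)),
    "L": ((1, 2), (106, 110)),
}

#: |omega| below this (degrees) marks a cis peptide bond.
CIS_OMEGA_THRESHOLD = 30.0

#: C(i-1)-N(i) distances above this (Angstrom) are treated as chain breaks.
PEPTIDE_BOND_MAX = 2.5

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


class FilenameError(ValueError):
    """Raised for names not matching the AbDb dialect."""


class StructureError(ValueError):
    """Raised for structurally unusable input (e.g. missing chains)."""


_FILENAME_RE = re.compile(
    r"^(?P<code>[0-9][0-9a-z]{3})_(?P<index>\d+)(?P<antigen>[PHN])?$"
)


def parse_abdb_filename(name: str) -> tuple[str, int, Optional[str]]:
    """Parse ``<pdb>_<index>[P|H|N]`` (with or without a .pdb/.ent extension).

    Returns ``(pdb_code, index, antigen_type)`` where ``antigen_type`` is
    ``None`` for an unbound entry.
    """
    stem = Path(name).name
    for ext in (".pdb", ".ent"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    m = _FILENAME_RE.match(stem)
    if m is None:
        if "_" not in stem:
            raise FilenameError(f"missing '_' separator in entry name {stem!r}")
        code, _, rest = stem.partition("_")
        if not re.fullmatch(r"[0-9][0-9a-z]{3}", code):
            raise FilenameError(f"bad PDB code token {code!r} in {stem!r}")
        raise FilenameError(f"bad index/antigen token {rest!r} in {stem!r}")
    return m["code"], int(m["index"]), m["antigen"]


def format_entry_id(pdb_code: str, index: int, antigen_type: Optional[str]) -> str:
    return f"{pdb_code}_{index}{antigen_type or ''}"


@dataclass(frozen=True, order=True)
class ResidueID:
    """Chain label + Martin number + insertion code, totally ordered.

    Ordering is (chain, number, insertion) with a blank insertion code
    sorting before 'A' < 'B' < ... (lexicographic on the empty string).
    """

    chain: str
    number: int
    insertion: str = ""

    def __str__(self) -> str:  # e.g. "H100A"
        return f"{self.chain}{self.number}{self.insertion}"


class Atom(NamedTuple):
    coord: tuple[float, float, float]
    b: float = 20.0
    occ: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


class Torsion(NamedTuple):
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float]


@dataclass
class Residue:
    id: ResidueID
    amino_acid: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def coord(self, atom: str) -> np.ndarray:
        return self.atoms[atom].xyz


@dataclass
class RegionDefinition:
    """CDR ranges and framework terminal exclusions (AbM defaults)."""

    cdr_ranges: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(CDR_RANGES)
    )
    framework_exclusions: dict[str, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: dict(FRAMEWORK_EXCLUSIONS)
    )

    def cdrs_for_chain(self, chain: str) -> list[str]:
        return [c for c, (ch, _, _) in self.cdr_ranges.items() if ch == chain]

    def in_cdr(self, rid: ResidueID, cdr: Optional[str] = None) -> bool:
        cdrs = [cdr] if cdr else self.cdrs_for_chain(rid.chain)
        for name in cdrs:
            chain, start, end = self.cdr_ranges[name]
            if rid.chain == chain and start <= rid.number <= end:
                return True
        return False

    def in_terminal_exclusion(self, rid: ResidueID) -> bool:
        for start, end in self.framework_exclusions.get(rid.chain, ()):
            if start <= rid.number <= end:
                return True
        return False

    def in_framework(self, rid: ResidueID) -> bool:
        return not self.in_cdr(rid) and not self.in_terminal_exclusion(rid)


DEFAULT_REGIONS = RegionDefinition()


@dataclass
class AntibodyEntry:
    """One AbDb-style structure: identity, chains of ordered residues, header."""

    pdb_code: str
    index: int
    antigen_type: Optional[str]
    chains: dict[str, list[Residue]]
    resolution: Optional[float] = None
    _torsions: Optional[dict[ResidueID, Torsion]] = field(
        default=None, repr=False, compare=False
    )

    @property
    def entry_id(self) -> str:
        return format_entry_id(self.pdb_code, self.index, self.antigen_type)

    @property
    def is_bound(self) -> bool:
        return self.antigen_type is not None

    def sequence(self, chain: str) -> Optional[str]:
        if chain not in self.chains:
            return None
        return "".join(r.amino_acid for r in self.chains[chain])

    def residue_map(self) -> dict[ResidueID, Residue]:
        return {r.id: r for ch in sorted(self.chains) for r in self.chains[ch]}

    def torsions(self) -> dict[ResidueID, Torsion]:
        if self._torsions is None:
            self._torsions = compute_torsions(self)
        return self._torsions


@dataclass
class CDRLoop:
    """One CDR's residues with backbone atoms and per-residue torsions."""

    cdr: str
    residues: list[Residue]
    torsions: list[Torsion]
    source_id: str = ""

    @property
    def loop_id(self) -> str:
        return f"{self.source_id}:{self.cdr}"

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_ids(self) -> list[ResidueID]:
        return [r.id for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        missing = [str(r.id) for r in self.residues if "CA" not in r.atoms]
        if missing:
            raise StructureError(f"missing CA atoms at {missing} in {self.loop_id}")
        return np.array([r.coord("CA") for r in self.residues])

    def cb_coords(self) -> list[Optional[np.ndarray]]:
        """Per-position CB coordinate, None where absent (glycine, unmodelled)."""
        return [r.coord("CB") if "CB" in r.atoms else None for r in self.residues]


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties keep the first encountered."""
    best = None
    for a in atoms:
        if best is None or a.occ > best.occ + 1e-9:
            best = a
    return best


def read_entry(
    path: str | Path,
    require_both: bool = True,
    chain_map: Optional[Mapping[str, str]] = None,
) -> AntibodyEntry:
    """Read an AbDb-dialect PDB file into an :class:`AntibodyEntry`.

    Only chains mapping to H or L are retained; alternate locations keep
    the highest-occupancy atom.  ``chain_map`` can rename source chain IDs
    (default: identity on "H"/"L").
    """
    path = Path(path)
    pdb_code, index, antigen = parse_abdb_filename(path.name)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unreadable PDB file {path}: {exc}") from exc
    resolution = st.resolution if st.resolution > 0 else None
    chain_map = chain_map or {"H": "H", "L": "L"}

    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        label = chain_map.get(chain.name)
        if label not in ("H", "L"):
            continue
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag == "H" and res.name not in AA_3TO1:
                continue
            icode = res.seqid.icode.strip()
            rid = ResidueID(label, res.seqid.num, icode)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = {}
            for name, alts in by_name.items():
                a = _pick_altloc(alts)
                atoms[name] = Atom((a.pos.x, a.pos.y, a.pos.z), a.b_iso, a.occ)
            aa = AA_3TO1.get(res.name, "X")
            residues.append(Residue(rid, aa, atoms))
        if residues:
            ids = [r.id for r in residues]
            if len(set(ids)) != len(ids):
                raise StructureError(f"duplicate residue IDs in chain {label} of {path}")
            residues.sort(key=lambda r: r.id)
            chains[label] = residues

    if not chains:
        raise StructureError(f"{path.name}: missing both heavy and light chains")
    if require_both:
        if "H" not in chains:
            raise StructureError(f"{path.name}: missing heavy chain")
        if "L" not in chains:
            raise StructureError(f"{path.name}: missing light chain")
    return AntibodyEntry(pdb_code, index, antigen, chains, resolution)


_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def write_entry(entry: AntibodyEntry, path: str | Path) -> Path:
    """Write a standard PDB file (REMARK 2 + ATOM/TER/END) for the entry."""
    path = Path(path)
    lines: list[str] = []
    if entry.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION.    {entry.resolution:.2f} ANGSTROMS."
        )
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    serial = 0
    for chain_label in sorted(entry.chains):
        for res in entry.chains[chain_label]:
            resname = AA_1TO3.get(res.amino_acid, "UNK")
            for atom_name in ("N", "CA", "C", "O", "CB"):
                if atom_name not in res.atoms:
                    continue
                atom = res.atoms[atom_name]
                serial += 1
                x, y, z = atom.coord
                name_field = f" {atom_name:<3s}"
                icode = res.id.insertion or " "
                element = _ATOM_ELEMENTS.get(atom_name, atom_name[0])
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{' '}{resname:>3s} "
                    f"{chain_label}{res.id.number:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occ:6.2f}{atom.b:6.2f}"
                    f"          {element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def extract_cdr(
    entry: AntibodyEntry, cdr: str, region: RegionDefinition = DEFAULT_REGIONS
) -> CDRLoop:
    """Residues whose Martin number falls in the CDR range, insertions included.

    The loop may be empty or incomplete; completeness is judged by the
    quality filter, not here.
    """
    chain, start, end = region.cdr_ranges[cdr]
    if chain not in entry.chains:
        raise StructureError(f"{entry.entry_id}: no chain {chain} for CDR {cdr}")
    torsions = entry.torsions()
    residues = [
        r for r in entry.chains[chain] if start <= r.id.number <= end
    ]
    tors = [torsions.get(r.id, Torsion(None, None, None)) for r in residues]
    return CDRLoop(cdr, residues, tors, source_id=entry.entry_id)


def extract_framework(
    entry: AntibodyEntry, chain: str, region: RegionDefinition = DEFAULT_REGIONS
) -> tuple[list[ResidueID], np.ndarray]:
    """Framework CA coordinates of a chain (non-CDR, non-terminal residues)."""
    if chain not in entry.chains:
        raise StructureError(f"{entry.entry_id}: no chain {chain}")
    ids: list[ResidueID] = []
    coords: list[np.ndarray] = []
    for res in entry.chains[chain]:
        if not region.in_framework(res.id) or "CA" not in res.atoms:
            continue
        ids.append(res.id)
        coords.append(res.coord("CA"))
    if len(ids) < 3:
        raise StructureError(
            f"{entry.entry_id}: only {len(ids)} framework residues in chain "
            f"{chain}; rigid fitting impossible"
        )
    return ids, np.array(coords)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    rad = gemmi.calculate_dihedral(
        gemmi.Position(*p0), gemmi.Position(*p1), gemmi.Position(*p2), gemmi.Position(*p3)
    )
    deg = math.degrees(rad)
    # normalize to (-180, 180]
    if deg <= -180.0:
        deg += 360.0
    return deg


def _bonded(prev: Residue, curr: Residue) -> bool:
    if "C" not in prev.atoms or "N" not in curr.atoms:
        return False
    d = np.linalg.norm(prev.coord("C") - curr.coord("N"))
    return d <= PEPTIDE_BOND_MAX


def compute_torsions(entry: AntibodyEntry) -> dict[ResidueID, Torsion]:
    """Backbone (phi, psi, omega) per residue, degrees in (-180, 180].

    A torsion is ``None`` when any contributing atom is absent, at chain
    termini, or across a chain break (peptide C-N distance > 2.5 A).
    """
    result: dict[ResidueID, Torsion] = {}
    for chain_label in sorted(entry.chains):
        residues = entry.chains[chain_label]
        n = len(residues)
        for i, res in enumerate(residues):
            phi = psi = omega = None
            prev_res = residues[i - 1] if i > 0 else None
            next_res = residues[i + 1] if i + 1 < n else None
            has_bb = res.has_backbone
            if prev_res is not None and has_bb and _bonded(prev_res, res):
                if "C" in prev_res.atoms:
                    phi = _dihedral(
                        prev_res.coord("C"), res.coord("N"),
                        res.coord("CA"), res.coord("C"),
                    )
                if "CA" in prev_res.atoms and "C" in prev_res.atoms:
                    omega = _dihedral(
                        prev_res.coord("CA"), prev_res.coord("C"),
                        res.coord("N"), res.coord("CA"),
                    )
            if next_res is not None and has_bb and _bonded(res, next_res):
                psi = _dihedral(
                    res.coord("N"), res.coord("CA"),
                    res.coord("C"), next_res.coord("N"),
                )
            result[res.id] = Torsion(phi, psi, omega)
    return result


def is_cis(omega: Optional[float], threshold: float = CIS_OMEGA_THRESHOLD) -> bool:
    """True iff the peptide bond preceding the residue is cis (|omega| < 30 deg)."""
    if omega is None:
        raise ValueError(
            "omega undefined; check backbone completeness upstream before "
            "testing for cis peptide bonds"
        )
    return abs(omega) < threshold
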