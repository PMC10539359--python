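"""Structure I/O, Fab domain annotation, gap detection and charge bookkeeping.

Atomic structures are held in :class:`AtomSet`, a column-oriented container
(numpy arrays) holding one row per atom.  PDB and mmCIF parsing is delegated
to :mod:`gemmi`; writing uses a small fixed-width PDB writer so multi-model
trajectory output does not depend on gemmi document assembly.

A Fab is annotated by :func:`annotate_fab` into the four-domain decomposition
(VH, CH1 on the heavy chain; VL, CL on the light chain) using the standard
variable-domain boundaries VL 1-109 and VH 1-117 unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomSet",
    "FabStructure",
    "GapRecord",
    "PkaTable",
    "DEFAULT_PKA",
    "ATOMIC_MASSES",
    "ELECTRON_COUNTS",
    "read_structure",
    "write_pdb",
    "write_multimodel_pdb",
    "annotate_fab",
    "detect_gaps",
    "count_span_residues",
    "total_formal_charge",
    "one_letter_sequence",
]

# ---------------------------------------------------------------------------
# element tables

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078, "D": 2.014,
}

#: electron counts used as constant X-ray form factors in the Debye model
ELECTRON_COUNTS: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "SE": 34,
    "FE": 26, "ZN": 30, "MG": 12, "NA": 11, "CL": 17, "K": 19, "CA": 20,
    "D": 1,
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}

_STANDARD_AA = set(THREE_TO_ONE) - {"MSE", "SEC"}


# ---------------------------------------------------------------------------
# containers

@dataclass
class AtomSet:
    """Column-oriented atom container; one row per atom, coordinates in Å."""

    atom_id: np.ndarray          # int
    element: np.ndarray          # str, upper-case symbol
    atom_name: np.ndarray        # str
    residue_name: np.ndarray     # str, 3-letter code
    residue_number: np.ndarray   # int, author numbering
    insertion_code: np.ndarray   # str, '' when absent
    chain_id: np.ndarray         # str
    coords: np.ndarray           # (N, 3) float, Å
    occupancy: np.ndarray        # float
    b_factor: np.ndarray         # float, Å²
    mass: np.ndarray             # float, amu
    is_hetero: np.ndarray = None  # bool
    space_group: str | None = None
    full_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if self.is_hetero is None:
            self.is_hetero = np.zeros(n, dtype=bool)
        for name in ("atom_id", "element", "atom_name", "residue_name",
                     "residue_number", "insertion_code", "chain_id",
                     "occupancy", "b_factor", "mass", "is_hetero"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"column {name!r} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.mass <= 0):
            raise ValueError("non-positive atomic mass")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "AtomSet":
        """Row-subset by boolean mask or integer index array."""
        return AtomSet(
            atom_id=self.atom_id[mask], element=self.element[mask],
            atom_name=self.atom_name[mask], residue_name=self.residue_name[mask],
            residue_number=self.residue_number[mask],
            insertion_code=self.insertion_code[mask], chain_id=self.chain_id[mask],
            coords=self.coords[mask], occupancy=self.occupancy[mask],
            b_factor=self.b_factor[mask], mass=self.mass[mask],
            is_hetero=self.is_hetero[mask], space_group=self.space_group,
            full_sequences=dict(self.full_sequences),
        )

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        out = replace(self)
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(out.coords) != len(self):
            raise ValueError("coordinate count mismatch")
        return out

    # -- convenience masks ---------------------------------------------------

    def protein_mask(self) -> np.ndarray:
        """Polymer atoms: standard residues, no waters/heteroatoms."""
        is_water = np.isin(self.residue_name, sorted(_WATER_NAMES))
        is_std = np.isin(self.residue_name, sorted(THREE_TO_ONE))
        return is_std & ~is_water & ~self.is_hetero

    def ca_mask(self) -> np.ndarray:
        return (self.atom_name == "CA") & (self.element == "C")

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(c)
        return seen

    def electron_counts(self) -> np.ndarray:
        try:
            return np.array([ELECTRON_COUNTS[e] for e in self.element], dtype=float)
        except KeyError as exc:
            raise KeyError(f"no electron count for element {exc}") from None


@dataclass
class FabStructure:
    """An AtomSet with heavy/light chain roles and domain ranges.

    ``domain_ranges`` maps ``{"VH","VL","CH1","CL"}`` to inclusive
    (first_residue, last_residue) author-numbering ranges.
    """

    atoms: AtomSet
    heavy_chain: str
    light_chain: str
    domain_ranges: dict[str, tuple[int, int]]

    DOMAIN_CHAIN = {"VH": "heavy", "CH1": "heavy", "VL": "light", "CL": "light"}

    def chain_of_domain(self, domain: str) -> str:
        role = self.DOMAIN_CHAIN[domain]
        return self.heavy_chain if role == "heavy" else self.light_chain

    def domain_mask(self, domain: str) -> np.ndarray:
        lo, hi = self.domain_ranges[domain]
        a = self.atoms
        return (a.chain_id == self.chain_of_domain(domain)) \
            & (a.residue_number >= lo) & (a.residue_number <= hi)

    def domain_ca_coords(self, domain: str) -> np.ndarray:
        """Cα coordinates of a domain, ordered by (residue_number, icode)."""
        a = self.atoms
        mask = self.domain_mask(domain) & a.ca_mask() & a.protein_mask()
        idx = np.flatnonzero(mask)
        order = np.lexsort((a.insertion_code[idx], a.residue_number[idx]))
        return a.coords[idx[order]]

    def domain_ca_keys(self, domain: str) -> list[tuple[int, str]]:
        a = self.atoms
        mask = self.domain_mask(domain) & a.ca_mask() & a.protein_mask()
        idx = np.flatnonzero(mask)
        keys = [(int(a.residue_number[i]), str(a.insertion_code[i])) for i in idx]
        return sorted(keys)


@dataclass
class GapRecord:
    """A run of unresolved residues inside a chain."""

    chain_id: str
    last_before: int
    first_after: int
    n_missing: int
    missing_sequence: str | None = None
    ambiguous: bool = False   # insertion codes adjacent to the gap
    c_terminal: bool = False  # truncation relative to the full-sequence record

    def __post_init__(self) -> None:
        if not self.c_terminal and self.n_missing != self.first_after - self.last_before - 1:
            raise ValueError("n_missing inconsistent with flanking residue numbers")
        if self.n_missing < 1:
            raise ValueError("gap must contain at least one residue")


@dataclass
class PkaTable:
    """Model (null) pKa values per ionisable group.

    ``sign`` is the charge carried by the *charged* form of each group:
    +1 for bases (protonated), −1 for acids (deprotonated).
    """

    pka: dict[str, float]
    sign: dict[str, int]
    n_term: float = 8.0
    c_term: float = 3.1

    def __post_init__(self) -> None:
        for name, v in {**self.pka, "N-term": self.n_term, "C-term": self.c_term}.items():
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa for {name} outside (0, 14): {v}")
        missing = {"ASP", "GLU", "HIS", "CYS", "TYR", "LYS", "ARG"} - set(self.pka)
        if missing:
            raise ValueError(f"ionisable residues missing from table: {sorted(missing)}")


DEFAULT_PKA = PkaTable(
    pka={"ASP": 3.8, "GLU": 4.2, "HIS": 6.0, "CYS": 8.3,
         "TYR": 10.1, "LYS": 10.5, "ARG": 12.5},
    sign={"ASP": -1, "GLU": -1, "HIS": +1, "CYS": -1,
          "TYR": -1, "LYS": +1, "ARG": +1},
)


# ---------------------------------------------------------------------------
# reading / writing

def _from_gemmi(st: gemmi.Structure, path: str) -> AtomSet:
    st.setup_entities()
    model = st[0]
    cols: dict[str, list] = {k: [] for k in
                             ("atom_id", "element", "atom_name", "residue_name",
                              "residue_number", "insertion_code", "chain_id",
                              "occupancy", "b_factor", "mass", "is_hetero")}
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            # altloc resolution: keep the highest-occupancy variant per atom
            # name, ties broken by file order
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.occ <= 0:
                    continue
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                el = atom.element.name.upper()
                cols["atom_id"].append(atom.serial)
                cols["element"].append(el)
                cols["atom_name"].append(atom.name)
                cols["residue_name"].append(res.name)
                cols["residue_number"].append(res.seqid.num)
                cols["insertion_code"].append(res.seqid.icode.strip())
                cols["chain_id"].append(chain.name)
                cols["occupancy"].append(atom.occ)
                cols["b_factor"].append(atom.b_iso)
                cols["mass"].append(ATOMIC_MASSES.get(el, atom.element.weight or 12.011))
                cols["is_hetero"].append(res.het_flag == "H" or res.name in _WATER_NAMES)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not coords:
        raise ValueError(f"no atoms with positive occupancy in {path}")

    full_seq: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            seq = "".join(THREE_TO_ONE.get(gemmi.Entity.first_mon(m), "X")
                          for m in ent.full_sequence)
            for sub in ent.subchains:
                ch = sub[:1] if sub else ""
                # map subchain back to the author chain that owns it
                for chain in model:
                    if any(r.subchain == sub for r in chain):
                        full_seq[chain.name] = seq
                        break
                else:
                    if ch:
                        full_seq.setdefault(ch, seq)
    return AtomSet(
        atom_id=np.array(cols["atom_id"], dtype=int),
        element=np.array(cols["element"], dtype=object),
        atom_name=np.array(cols["atom_name"], dtype=object),
        residue_name=np.array(cols["residue_name"], dtype=object),
        residue_number=np.array(cols["residue_number"], dtype=int),
        insertion_code=np.array(cols["insertion_code"], dtype=object),
        chain_id=np.array(cols["chain_id"], dtype=object),
        coords=np.array(coords, dtype=float),
        occupancy=np.array(cols["occupancy"], dtype=float),
        b_factor=np.array(cols["b_factor"], dtype=float),
        mass=np.array(cols["mass"], dtype=float),
        is_hetero=np.array(cols["is_hetero"], dtype=bool),
        space_group=st.spacegroup_hm or None,
        full_sequences=full_seq,
    )


def read_structure(path: str | Path, format: str = "auto") -> AtomSet:
    """Read a PDB or mmCIF file into an :class:`AtomSet`.

    Alternate locations are resolved to the highest-occupancy copy (ties by
    file order); zero-occupancy atoms are dropped.  Space-group and
    full-sequence (SEQRES / entity_poly) metadata are retained when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return _from_gemmi(st, str(path))


def _pdb_atom_line(i: int, a: AtomSet, serial: int) -> str:
    name = str(a.atom_name[i])
    # PDB column rules: 1/2-char element names start at col 13/14
    if len(name) < 4 and len(str(a.element[i])) < 2:
        name = f" {name}"
    record = "HETATM" if a.is_hetero[i] else "ATOM  "
    x, y, z = a.coords[i]
    return (f"{record}{serial:>5d} {name:<4s}{'':1s}{str(a.residue_name[i]):<3s} "
            f"{str(a.chain_id[i]):1s}{int(a.residue_number[i]):>4d}"
            f"{str(a.insertion_code[i]) or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy[i]:6.2f}{a.b_factor[i]:6.2f}"
            f"          {str(a.element[i]):>2s}")


def write_pdb(atoms: AtomSet, path: str | Path) -> None:
    """Write a single-model PDB file (3-decimal coordinates)."""
    write_multimodel_pdb(atoms, [atoms.coords], path)


def write_multimodel_pdb(atoms: AtomSet, frames: Sequence[np.ndarray],
                         path: str | Path) -> None:
    """Write one MODEL block per coordinate frame over a fixed topology."""
    lines: list[str] = []
    multi = len(frames) > 1
    for m, frame in enumerate(frames, start=1):
        moved = atoms.with_coords(frame)
        if multi:
            lines.append(f"MODEL     {m:>4d}")
        prev_chain = None
        serial = 0
        for i in range(len(moved)):
            serial += 1
            if prev_chain is not None and moved.chain_id[i] != prev_chain:
                lines.append(f"TER   {serial:>5d}")
                serial += 1
            lines.append(_pdb_atom_line(i, moved, serial))
            prev_chain = moved.chain_id[i]
        lines.append(f"TER   {serial + 1:>5d}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Fab annotation

DEFAULT_VL = (1, 109)
DEFAULT_VH = (1, 117)


def annotate_fab(atoms: AtomSet, heavy: str, light: str,
                 boundaries: Mapping[str, tuple[int, int]] | None = None,
                 ) -> FabStructure:
    """Annotate a Fab with VH/VL/CH1/CL domain ranges.

    Default variable-domain boundaries are VL 1–109 and VH 1–117, the
    convention used for κ light / γ heavy Fabs; the constant domains take the
    remainder of each chain.  Explicit ``boundaries`` entries override the
    defaults domain-by-domain.
    """
    for chain, role in ((heavy, "heavy"), (light, "light")):
        mask = atoms.chain_mask(chain) & atoms.ca_mask() & atoms.protein_mask()
        if not mask.any():
            raise ValueError(f"{role} chain {chain!r} absent or has no Cα atoms")

    def observed(chain: str) -> np.ndarray:
        m = atoms.chain_mask(chain) & atoms.protein_mask()
        return np.unique(atoms.residue_number[m])

    obs_h, obs_l = observed(heavy), observed(light)
    b = dict(boundaries or {})
    vh = tuple(b.get("VH", DEFAULT_VH))
    vl = tuple(b.get("VL", DEFAULT_VL))
    ch1 = tuple(b.get("CH1", (vh[1] + 1, int(obs_h.max()))))
    cl = tuple(b.get("CL", (vl[1] + 1, int(obs_l.max()))))
    ranges = {"VH": vh, "VL": vl, "CH1": ch1, "CL": cl}

    for dom, (lo, hi) in ranges.items():
        obs = obs_h if dom in ("VH", "CH1") else obs_l
        if lo > hi:
            raise ValueError(f"{dom} range ({lo}, {hi}) inverted")
        if lo < obs.min() or hi > obs.max():
            raise ValueError(
                f"{dom} boundary ({lo}, {hi}) outside observed residues "
                f"[{obs.min()}, {obs.max()}]")
    if ranges["VH"][1] >= ranges["CH1"][0] or ranges["VL"][1] >= ranges["CL"][0]:
        raise ValueError("variable and constant ranges overlap")
    return FabStructure(atoms=atoms, heavy_chain=heavy, light_chain=light,
                        domain_ranges=ranges)


# ---------------------------------------------------------------------------
# gaps and sequence spans

def detect_gaps(fab: FabStructure) -> list[GapRecord]:
    """Report unresolved-residue runs per chain.

    One record per jump > 1 in consecutive observed residue numbers; when the
    entry carries a full-sequence record, the missing one-letter stretch is
    filled in (assuming author numbering equals sequence position) and a
    C-terminal truncation is reported as an additional record.
    """
    atoms = fab.atoms
    records: list[GapRecord] = []
    for chain in (fab.heavy_chain, fab.light_chain):
        m = atoms.chain_mask(chain) & atoms.protein_mask()
        resnums = atoms.residue_number[m]
        icodes = atoms.insertion_code[m]
        pairs = sorted({(int(n), str(c)) for n, c in zip(resnums, icodes)})
        seq = atoms.full_sequences.get(chain)
        for (n0, c0), (n1, c1) in zip(pairs, pairs[1:]):
            if n1 - n0 > 1:
                missing = None
                if seq and n1 - 1 <= len(seq):
                    missing = seq[n0:n1 - 1]
                records.append(GapRecord(
                    chain_id=chain, last_before=n0, first_after=n1,
                    n_missing=n1 - n0 - 1, missing_sequence=missing,
                    ambiguous=bool(c0 or c1)))
        if seq:
            last = pairs[-1][0]
            if len(seq) > last:
                records.append(GapRecord(
                    chain_id=chain, last_before=last, first_after=len(seq) + 1,
                    n_missing=len(seq) - last,
                    missing_sequence=seq[last:], c_terminal=True))
    return records


def _parse_residue_spec(spec: str) -> tuple[str, int]:
    """Parse 'K218' / '218' → (one-letter or '', number)."""
    s = spec.strip()
    if s and s[0].isalpha():
        return s[0].upper(), int(s[1:])
    return "", int(s)


def count_span_residues(start_label: str | int, end_label: str | int) -> int:
    """Inclusive residue count of a numbering span, e.g. K218→A228 = 11."""
    _, start = _parse_residue_spec(str(start_label))
    _, end = _parse_residue_spec(str(end_label))
    if end < start:
        raise ValueError(f"span end {end} precedes start {start}")
    return end - start + 1


# ---------------------------------------------------------------------------
# sequence + charge

def one_letter_sequence(atoms: AtomSet, chain: str) -> str:
    m = atoms.chain_mask(chain) & atoms.protein_mask() & atoms.ca_mask()
    idx = np.flatnonzero(m)
    order = np.lexsort((atoms.insertion_code[idx], atoms.residue_number[idx]))
    return "".join(THREE_TO_ONE.get(str(atoms.residue_name[i]), "X")
                   for i in idx[order])


def total_formal_charge(fab: "FabStructure | AtomSet", pH: float,
                        pka: PkaTable = DEFAULT_PKA,
                        blocked_termini: bool = False,
                        ) -> tuple[int, list[str]]:
    """Integer formal charge at a given pH under the model-pKa null.

    Every ionisable group is assigned its majority protonation state:
    protonated iff pH < pKa.  Protonated bases carry +1, deprotonated acids
    −1.  Chain termini are counted unless ``blocked_termini``.  This is a
    sequence-only null model — it ignores the structural environment, so it
    will not reproduce structure-based pKa-shifted charges.

    Accepts an annotated Fab (heavy + light chains) or a bare
    :class:`AtomSet` (all chains).  Returns ``(charge, excluded)`` where
    ``excluded`` lists nonstandard residue names that were skipped.
    """
    if isinstance(fab, FabStructure):
        atoms = fab.atoms
        chains: Iterable[str] = (fab.heavy_chain, fab.light_chain)
    else:
        atoms = fab
        chains = atoms.chains()
    charge = 0
    excluded: list[str] = []
    for chain in chains:
        m = atoms.chain_mask(chain) & atoms.ca_mask() & ~np.isin(
            atoms.residue_name, sorted(_WATER_NAMES))
        idx = np.flatnonzero(m)
        for i in idx:
            name = str(atoms.residue_name[i])
            if name not in _STANDARD_AA:
                excluded.append(f"{chain}/{name}{int(atoms.residue_number[i])}")
                continue
            if name in pka.pka:
                protonated = pH < pka.pka[name]
                if pka.sign[name] > 0:
                    charge += 1 if protonated else 0
                else:
                    charge += 0 if protonated else -1
        if not blocked_termini and len(idx):
            charge += 1 if pH < pka.n_term else 0
            charge += 0 if pH < pka.c_term else -1
    if excluded:
        warnings.warn(f"{len(excluded)} nonstandard residues excluded from "
                      f"charge: {excluded[:5]}", stacklevel=2)
    return charge, excluded
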