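"""Structures, trajectories, annotation, selections, leaflets and charges.

This module defines the in-memory model every metric consumes:

* :class:`MolecularSystem` — static topology (names, residues, masses, roles,
  lipid grouping, charge classes),
* :class:`Frame` — one set of coordinates with an orthorhombic box,
* :class:`ReceptorAnnotation` — Ballesteros–Weinstein map, helix ranges,
  named motifs and the protonation list,
* :class:`AtomSet` — an ordered, de-duplicated atom selection.

File reading (PDB, multi-model PDB, DCD, XTC) is delegated to MDAnalysis;
writing of multi-model PDB for synthetic systems is a small fixed-width
formatter here. By convention the membrane normal is the Z axis and boxes
are orthorhombic; periodic imaging is applied in X and Y only, never Z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

logger = logging.getLogger("memgate")

# ---------------------------------------------------------------------------
# Constants and lookup tables
# ---------------------------------------------------------------------------

#: Atomic masses (amu) for the elements that occur in receptors and lipids.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845,
}

#: Residue names treated as lipids by default (CHARMM conventions).
LIPID_RESNAMES = {
    "DOPC", "DOPE", "DOPG", "POPC", "POPE", "POPG", "DPPC", "DMPC",
    "DLPC", "DOPS", "POPS", "CHL1",
}

WATER_RESNAMES = {"HOH", "TIP3", "TIP", "WAT", "SOL", "SPC"}
ION_RESNAMES = {"NA", "CL", "K", "SOD", "CLA", "POT", "MG", "CAL", "ZN"}

ROLE_PROTEIN = "protein"
ROLE_LIPID = "lipid"
ROLE_SOLVENT = "solvent"
ROLE_ION = "ion"


class MemgateError(Exception):
    """Base class for all package errors."""


class ParseError(MemgateError):
    pass


class SelectionError(MemgateError):
    pass


class ConfigError(MemgateError):
    pass


def element_from_name(name: str, resname: str = "") -> str:
    """Infer the element from a PDB atom name.

    Ions named like their element (NA, CL, K, MG) are recognised via the
    residue name; otherwise the first alphabetic character of the atom name
    is used, which is correct for protein and phospholipid atoms.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if resname.strip().upper() in ION_RESNAMES and stripped in ELEMENT_MASSES:
        return stripped
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    return stripped[0]


def mass_of(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 12.011)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularSystem:
    """Static topology shared by all frames of a trajectory.

    Atom indices are dense from 0 in file order. ``lipid_id`` groups lipid
    atoms into molecules (-1 for non-lipid atoms); ``charge_class`` holds
    one of ``pos``/``neg``/``neutral`` per atom once :func:`assign_charges`
    has run, and ``""`` before that.
    """

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    residue_seqs: np.ndarray
    residue_names: np.ndarray
    chains: np.ndarray
    roles: np.ndarray
    lipid_ids: np.ndarray
    charge_class: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        if n == 0:
            raise ParseError("empty system: no atoms")
        if self.charge_class is None:
            self.charge_class = np.array([""] * n, dtype=object)
        if np.any(self.masses <= 0):
            raise ParseError("non-positive atomic mass encountered")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def lipid_molecules(self) -> dict[int, np.ndarray]:
        """Map lipid molecule id -> atom indices, in index order."""
        out: dict[int, np.ndarray] = {}
        lip = np.nonzero(self.lipid_ids >= 0)[0]
        for lid in np.unique(self.lipid_ids[lip]):
            out[int(lid)] = lip[self.lipid_ids[lip] == lid]
        return out

    def atom_index(self, residue_seq: int, name: str,
                   chain: str | None = None) -> int:
        mask = (self.residue_seqs == residue_seq) & (self.names == name)
        if chain is not None:
            mask &= self.chains == chain
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise SelectionError(
                f"atom {name!r} of residue {residue_seq} not found"
                + (f" in chain {chain!r}" if chain else ""))
        return int(idx[0])


@dataclass
class Frame:
    """Coordinates (Å) for one time point, with orthorhombic box (Å)."""

    coords: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParseError("coordinates must be an (n, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ParseError("box must be three positive edge lengths")


@dataclass
class AtomSet:
    """Ordered list of atom indices with a provenance label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate atom indices in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ReceptorAnnotation:
    """Ballesteros–Weinstein map, TM helix ranges, motifs, protonation list.

    ``bw_map`` maps codes like ``"3.50"`` to author residue numbers;
    ``tm_ranges`` maps helix id (1–8) to an inclusive residue interval;
    ``motifs`` maps a motif name to BW codes or residue numbers.
    """

    bw_map: dict[str, int]
    tm_ranges: dict[int, tuple[int, int]]
    motifs: dict[str, list]
    protonated_residues: list[int] = field(default_factory=list)
    chain: str = "A"

    REQUIRED_BW = ("3.40", "3.50", "5.50", "6.25", "6.29", "6.30", "6.32",
                   "6.35", "6.44", "7.49", "7.50", "7.51", "7.52", "7.53")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_BW if c not in self.bw_map]
        if missing:
            raise ConfigError(f"annotation missing BW codes: {missing}")
        spans = sorted(self.tm_ranges.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise ConfigError("TM helix ranges overlap")

    def resolve(self, code) -> int:
        """Resolve a BW code or integer residue number to a residue number."""
        if isinstance(code, int):
            return code
        code = str(code)
        if code in self.bw_map:
            return self.bw_map[code]
        raise SelectionError(f"BW code {code!r} absent from annotation")

    def motif_residues(self, motif: str) -> list[int]:
        if motif not in self.motifs:
            raise SelectionError(f"unknown motif {motif!r}")
        return [self.resolve(c) for c in self.motifs[motif]]

    def tm_residues(self, helices: Iterable[int]) -> list[int]:
        out: list[int] = []
        for h in helices:
            if h not in self.tm_ranges:
                raise ConfigError(f"no range for helix {h}")
            lo, hi = self.tm_ranges[h]
            out.extend(range(lo, hi + 1))
        return out

    @classmethod
    def from_yaml(cls, path) -> "ReceptorAnnotation":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ReceptorAnnotation":
        return cls(
            bw_map={str(k): int(v) for k, v in raw["bw_map"].items()},
            tm_ranges={int(k): (int(v[0]), int(v[1]))
                       for k, v in raw["tm_ranges"].items()},
            motifs={str(k): list(v) for k, v in raw.get("motifs", {}).items()},
            protonated_residues=[int(x) for x in
                                 raw.get("protonated_residues", [])],
            chain=str(raw.get("chain", "A")),
        )


def default_annotation() -> ReceptorAnnotation:
    """Packaged Ballesteros–Weinstein annotation for human β2AR."""
    ref = resources.files("memgate.data") / "beta2ar_annotation.yaml"
    return ReceptorAnnotation.from_dict(yaml.safe_load(ref.read_text()))


def default_charge_rules() -> dict:
    """Packaged charge-class rule table (protein side chains + DOPC/E/G)."""
    ref = resources.files("memgate.data") / "charge_rules.yaml"
    return yaml.safe_load(ref.read_text())


# ---------------------------------------------------------------------------
# Periodic distances (XY minimum image, Z direct)
# ---------------------------------------------------------------------------

def min_image_displacement(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention in X and Y only.

    ``d`` is an array of displacement vectors (..., 3). Membrane-normal Z is
    never imaged: bilayer simulations are periodic laterally while the Z
    repeat contains solvent slabs that must not alias into the membrane.
    """
    d = np.asarray(d, dtype=float)
    if box is None:
        return d
    out = d.copy()
    for ax in (0, 1):
        out[..., ax] -= box[ax] * np.round(out[..., ax] / box[ax])
    return out


def pair_distances(a: np.ndarray, b: np.ndarray,
                   box: np.ndarray | None) -> np.ndarray:
    """All pairwise XY-imaged distances between point sets a (n,3), b (m,3)."""
    d = a[:, None, :] - b[None, :, :]
    d = min_image_displacement(d, box)
    return np.sqrt((d ** 2).sum(axis=-1))


# ---------------------------------------------------------------------------
# Reading structures and trajectories (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _universe(path, **kwargs):
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), **kwargs)
        except Exception as exc:  # noqa: BLE001 - normalise parser errors
            raise ParseError(f"cannot parse {path}: {exc}") from exc


def _system_from_atoms(atoms, lipid_resnames: set[str]) -> MolecularSystem:
    n = len(atoms)
    if n == 0:
        raise ParseError("structure contains zero atoms")
    names = np.array([a.name for a in atoms], dtype=object)
    resnames = np.array([a.resname.strip() for a in atoms], dtype=object)
    resseqs = np.array([a.resid for a in atoms], dtype=int)
    try:
        chains = np.array([a.chainID for a in atoms], dtype=object)
    except Exception:  # topology without chain IDs (e.g. DCD/XTC companions)
        chains = np.array([getattr(a, "segid", "") for a in atoms], dtype=object)
    elements = np.empty(n, dtype=object)
    for i, a in enumerate(atoms):
        el = getattr(a, "element", "") or ""
        elements[i] = el.upper() if el.strip() else element_from_name(
            names[i], resnames[i])
    masses = np.array([mass_of(e) for e in elements], dtype=float)

    roles = np.empty(n, dtype=object)
    lipid_ids = np.full(n, -1, dtype=int)
    lid_map: dict[tuple, int] = {}
    for i in range(n):
        rn = resnames[i].upper()
        if rn in lipid_resnames:
            roles[i] = ROLE_LIPID
            key = (chains[i], int(resseqs[i]), rn)
            lipid_ids[i] = lid_map.setdefault(key, len(lid_map))
        elif rn in WATER_RESNAMES:
            roles[i] = ROLE_SOLVENT
        elif rn in ION_RESNAMES:
            roles[i] = ROLE_ION
        else:
            roles[i] = ROLE_PROTEIN
    return MolecularSystem(names=names, elements=elements, masses=masses,
                           residue_seqs=resseqs, residue_names=resnames,
                           chains=chains, roles=roles, lipid_ids=lipid_ids)


def _frame_from_ts(ts, time_ns: float) -> Frame:
    box = None
    if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
        box = np.array(ts.dimensions[:3], dtype=float)
    return Frame(coords=np.array(ts.positions, dtype=float), box=box,
                 time=time_ns)


def read_structure(path, lipid_resnames: set[str] | None = None,
                   altloc: str = "A"):
    """Read a PDB structure into (:class:`MolecularSystem`, :class:`Frame`).

    The first MODEL is used; alternate locations other than '' and *altloc*
    are discarded. Residue names found in *lipid_resnames* (default: the
    packaged dictionary) are assigned the lipid role and grouped into
    molecules by residue.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    u = _universe(path)
    atoms = u.atoms
    if hasattr(atoms, "altLocs"):
        keep = np.array([a.strip() in ("", altloc) for a in atoms.altLocs])
        if not keep.all():
            atoms = atoms[keep]
    system = _system_from_atoms(atoms, lipid_resnames or LIPID_RESNAMES)
    box = _frame_from_ts(u.trajectory.ts, 0.0).box
    frame = Frame(coords=np.array(atoms.positions, dtype=float), box=box)
    if frame.coords.shape[0] != system.n_atoms:
        raise ParseError("coordinate/atom count mismatch in structure")
    return system, frame


def read_trajectory(path, system: MolecularSystem,
                    frame_interval: float | None = None,
                    topology=None) -> Iterator[Frame]:
    """Stream frames from a multi-model PDB, DCD or XTC file.

    Yields :class:`Frame` objects in file order. Times are ``k *
    frame_interval`` (ns) when an interval is given, otherwise taken from
    the file's timestamps (ps, converted to ns) when available. DCD/XTC
    need *topology* (a PDB path) for MDAnalysis.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    suffix = path.suffix.lower()
    fallback_box = None
    if suffix == ".pdb":
        text = path.read_text()
        if "ATOM" not in text and "HETATM" not in text:
            return  # empty trajectory: zero frames, not an error
        for line in text.splitlines():  # header CRYST1 applies to all models
            if line.startswith("CRYST1"):
                edges = np.array([float(line[6:15]), float(line[15:24]),
                                  float(line[24:33])])
                if np.all(edges > 0):
                    fallback_box = edges
                break
    if suffix in (".dcd", ".xtc", ".trr"):
        if topology is None:
            raise ConfigError(f"{suffix} trajectories need a topology file")
        u = _universe(topology)
        u.load_new(str(path))
    else:
        u = _universe(path)
    n_file = len(u.atoms)
    if n_file == 0:
        return
    if n_file != system.n_atoms:
        raise ParseError(
            f"trajectory atom count mismatch: expected {system.n_atoms}, "
            f"found {n_file}")
    for k, ts in enumerate(u.trajectory):
        if frame_interval is not None:
            t = k * frame_interval
        else:
            t = float(getattr(ts, "time", 0.0) or 0.0) / 1000.0
        frame = _frame_from_ts(ts, t)
        if frame.box is None and fallback_box is not None:
            frame.box = fallback_box.copy()
        yield frame


# ---------------------------------------------------------------------------
# Writing multi-model PDB (synthetic systems, round trips)
# ---------------------------------------------------------------------------

def write_pdb(path, system: MolecularSystem,
              frames: Frame | Sequence[Frame]) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise MemgateError("no frames to write")
    lines: list[str] = []
    box = frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1")
    multi = len(frames) > 1
    for m, fr in enumerate(frames, start=1):
        if fr.coords.shape[0] != system.n_atoms:
            raise MemgateError("frame atom count differs from system")
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i in range(system.n_atoms):
            name = system.names[i]
            # PDB column rules: 1-3 char names start in column 14
            aname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            x, y, z = fr.coords[i]
            serial = (i + 1) % 100000
            lines.append(
                f"ATOM  {serial:5d} {aname}{'':1s}{system.residue_names[i]:<4s}"
                f"{str(system.chains[i])[:1] or 'A':1s}"
                f"{int(system.residue_seqs[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {system.elements[i][:2]:>2s}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_KEYWORDS = {"resid", "bw", "name", "heavy", "role", "leaflet", "chain"}


def select(system: MolecularSystem, expr: str,
           annotation: ReceptorAnnotation | None = None,
           leaflets: dict[int, str] | None = None) -> AtomSet:
    """Evaluate a selection expression and return an ordered :class:`AtomSet`.

    Grammar: whitespace-separated clauses, each a keyword followed by its
    values; clauses are AND-combined, values within a clause OR-combined.

    ``resid 131 260-270`` | ``bw 3.50 7.49-7.53`` | ``name CA NH1`` |
    ``heavy`` | ``role protein`` | ``leaflet lower`` | ``chain R``

    BW codes need *annotation*; ``leaflet`` needs a lipid→leaflet map from
    :func:`assign_leaflets`. An expression matching nothing returns an empty
    set (logged), but an unresolvable BW code raises.
    """
    tokens = expr.split()
    mask = np.ones(system.n_atoms, dtype=bool)
    i = 0
    while i < len(tokens):
        kw = tokens[i].lower()
        if kw not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword {tokens[i]!r}")
        i += 1
        values: list[str] = []
        while i < len(tokens) and tokens[i].lower() not in _KEYWORDS:
            values.append(tokens[i])
            i += 1
        if kw == "heavy":
            mask &= system.elements != "H"
            continue
        if not values:
            raise SelectionError(f"keyword {kw!r} needs at least one value")
        if kw == "resid":
            wanted = _expand_ranges(values)
            mask &= np.isin(system.residue_seqs, list(wanted))
        elif kw == "bw":
            if annotation is None:
                raise SelectionError("bw selection requires an annotation")
            seqs = [annotation.resolve(c) for c in _expand_bw(values)]
            sub = np.isin(system.residue_seqs, seqs)
            if annotation.chain and np.any(system.chains == annotation.chain):
                sub &= system.chains == annotation.chain
            mask &= sub
        elif kw == "name":
            mask &= np.isin(system.names, values)
        elif kw == "role":
            mask &= np.isin(system.roles, values)
        elif kw == "chain":
            mask &= np.isin(system.chains, values)
        elif kw == "leaflet":
            if leaflets is None:
                raise SelectionError("leaflet selection requires leaflet map")
            want = {lid for lid, leaf in leaflets.items() if leaf in values}
            mask &= np.isin(system.lipid_ids, list(want))
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        logger.warning("selection %r matched no atoms", expr)
    return AtomSet(indices=idx, label=expr)


def _expand_ranges(values: list[str]) -> set[int]:
    out: set[int] = set()
    for v in values:
        if "-" in v[1:]:
            lo, hi = v.split("-", 1) if not v.startswith("-") else (v, v)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(v))
    return out


def _expand_bw(values: list[str]) -> list[str]:
    """Expand BW range tokens like '7.49-7.53' into individual codes."""
    out: list[str] = []
    for v in values:
        if "-" in v:
            lo, hi = v.split("-")
            h_lo, p_lo = lo.split(".")
            h_hi, p_hi = hi.split(".")
            if h_lo != h_hi:
                raise SelectionError(f"BW range {v!r} spans helices")
            out.extend(f"{h_lo}.{p:02d}"
                       for p in range(int(p_lo), int(p_hi) + 1))
        else:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------

def assign_leaflets(system: MolecularSystem, frame: Frame,
                    anchor_atom_name: str = "P") -> dict[int, str]:
    """Assign each lipid molecule to the upper or lower leaflet.

    The midplane is the mean Z of all anchor atoms (default: phosphorus);
    a lipid is ``upper`` if its anchor sits above the midplane. The mapping
    may be recomputed per frame or frozen from frame 0 by the caller.
    """
    molecules = system.lipid_molecules
    if not molecules:
        raise MemgateError("system contains no lipids")
    anchors: dict[int, int] = {}
    missing: list[int] = []
    for lid, atom_idx in molecules.items():
        hits = [int(i) for i in atom_idx if system.names[i] == anchor_atom_name]
        if len(hits) != 1:
            missing.append(lid)
        else:
            anchors[lid] = hits[0]
    if missing:
        raise MemgateError(
            f"lipids without a unique {anchor_atom_name!r} anchor atom: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    zs = np.array([frame.coords[a, 2] for a in anchors.values()])
    midplane = float(zs.mean())
    leaflets = {lid: ("upper" if frame.coords[a, 2] > midplane else "lower")
                for lid, a in anchors.items()}
    counts = {"upper": sum(v == "upper" for v in leaflets.values()),
              "lower": sum(v == "lower" for v in leaflets.values())}
    for side, cnt in counts.items():
        if cnt == 0:
            logger.warning("%s leaflet is empty", side)
    return leaflets


# ---------------------------------------------------------------------------
# Charge assignment
# ---------------------------------------------------------------------------

def assign_charges(system: MolecularSystem, rules: dict | None = None,
                   protonated: Iterable[int] = (),
                   cationic_his: Iterable[int] = ()) -> MolecularSystem:
    """Fill ``charge_class`` for every atom from a rule table.

    Protein side-chain defaults: Arg NE/NH1/NH2 and Lys NZ positive; Asp
    OD1/OD2 and Glu OE1/OE2 negative; His neutral unless its residue number
    is in *cationic_his*. Lipid rules come from the table's ``lipids``
    section keyed by residue name. Residues listed in *protonated* are
    acidic residues carrying an extra proton: their carboxylate oxygens are
    set to neutral, which is the electrostatic consequence of protonation.
    Rules that reference atom names absent from the system are ignored with
    a warning, not an error.
    """
    rules = rules if rules is not None else default_charge_rules()
    protein_rules = dict(rules.get("protein", {}))
    his_rules = protein_rules.pop("HIS_CATIONIC", {})
    lipid_rules = rules.get("lipids", {})
    acidic = rules.get("acidic_oxygens",
                       {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]})
    protonated = set(int(x) for x in protonated)
    cationic_his = set(int(x) for x in cationic_his)

    cls = np.array(["neutral"] * system.n_atoms, dtype=object)
    seen_rule_atoms: set[tuple[str, str]] = set()
    for i in range(system.n_atoms):
        rn = str(system.residue_names[i]).upper()
        an = str(system.names[i])
        seq = int(system.residue_seqs[i])
        table = None
        if system.roles[i] == ROLE_PROTEIN:
            if rn == "HIS" and seq in cationic_his:
                table = his_rules
            else:
                table = protein_rules.get(rn)
        elif system.roles[i] == ROLE_LIPID:
            table = lipid_rules.get(rn)
        if table and an in table:
            cls[i] = table[an]
            seen_rule_atoms.add((rn, an))
        if (system.roles[i] == ROLE_PROTEIN and seq in protonated
                and rn in acidic and an in acidic[rn]):
            cls[i] = "neutral"
    for rn, table in list(protein_rules.items()) + list(lipid_rules.items()):
        present = np.any(system.residue_names == rn)
        for an in table:
            if present and (rn, an) not in seen_rule_atoms:
                logger.warning("charge rule (%s, %s) matched no atom", rn, an)
    system.charge_class = cls
    return system


def charged_atoms(system: MolecularSystem, within: AtomSet | None = None,
                  signs: tuple[str, ...] = ("pos", "neg")) -> AtomSet:
    """Atoms whose charge_class is in *signs*, optionally within a set."""
    if system.charge_class is None or np.all(system.charge_class == ""):
        raise MemgateError("assign_charges has not run on this system")
    mask = np.isin(system.charge_class, list(signs))
    if within is not None:
        sub = np.zeros(system.n_atoms, dtype=bool)
        sub[within.indices] = True
        mask &= sub
    return AtomSet(indices=np.nonzero(mask)[0],
                   label=f"charged {'/'.join(signs)}")
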