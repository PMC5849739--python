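"""Synthetic ground-truth systems: toy helical receptors, activation paths,
and parametric pseudo-atom bilayers.

Every analysis metric in the package has at least one test that consumes a
system built here, because real multi-microsecond trajectories are neither
shippable nor desk-scale. The generators trade physical realism (no force
field, no water, 4–6 pseudo-atoms per lipid) for *exact* ground truth: each
one emits machine-readable truth alongside coordinates — the planted lock
distances, the analytic leaflet-separation field, the lattice area per
lipid, planted contact pairs — so tests compare measured against
constructed values, not against other code.

Receptor endpoints: an ideal 8-helix bundle whose *active* conformation
differs from the *inactive* one only by a rigid TM6 hinge swing (solved
numerically so the ionic-lock Cα–Cα distance and the TM6 tip displacement
hit their prescribed values; defaults are the crystallographic 18.9 Å /
11.1 Å lock distances and the ~14 Å outward TM6 movement) plus a prescribed
outward shift of the TM7 NPxxY tip. Bilayers: lipids on an nx×ny lattice
per leaflet (area per lipid = spacing², exactly), with a raised-cosine
leaflet-separation bulge D(r) = D0 + A·cos²(πr/2R) for r < R — smooth,
compactly supported, and analytically known for oracle checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .core import (Frame, MemgateError, MolecularSystem, ReceptorAnnotation,
                   assign_charges, assign_leaflets, default_charge_rules,
                   mass_of)
from .receptor import ionic_lock_distance

logger = logging.getLogger("memgate")

DEG = np.pi / 180.0


# ===========================================================================
# Receptor generator
# ===========================================================================

#: Which residue (by BW code) carries which residue type in the toy bundle.
_MOTIF_RESNAMES = {
    "3.40": "ILE", "3.50": "ARG", "5.50": "PRO",
    "6.25": "LYS", "6.29": "LYS", "6.30": "GLU", "6.32": "LYS",
    "6.35": "LYS", "6.44": "PHE",
    "7.49": "ASN", "7.50": "PRO", "7.51": "LEU", "7.52": "ILE", "7.53": "TYR",
}

#: helix -> (BW position - offset) = residue index within the helix.
#: Chosen so every required motif lands inside a 29-residue helix, at the
#: intracellularly correct end given each helix's direction.
_BW_OFFSETS = {3: 25, 5: 35, 6: 23, 7: 25}

#: Helices running extracellular->intracellular (residue number increases
#: downward), as in the native topology; the rest run upward.
_DOWN_HELICES = {1, 3, 5, 7}

#: Azimuths (degrees) of the helix axes on the bundle circle. TM3 sits near
#: 90° and TM6's base directly opposite, so the inactive TM6 is pulled
#: inward along the lock axis; the sector around 0° is deliberately left
#: empty because the lock/displacement targets force the active TM6 swing
#: to run nearly perpendicular to the lock axis, and it exits there.
_HELIX_ANGLES = {1: 249.0, 2: 135.0, 3: 97.0, 4: 173.0, 5: 211.0,
                 6: 277.0, 7: 287.0, 8: 325.0}


@dataclass
class ReceptorSpec:
    """Geometry of the toy receptor bundle and its two state endpoints."""

    n_res: int = 29
    bundle_radius: float = 14.0     # Å, helix axes sit on this circle
    rise: float = 1.5               # Å per residue
    twist: float = 100.0            # degrees per residue
    ca_radius: float = 2.3          # Å, Cα helix radius
    z_top: float = 21.0             # Å, extracellular end
    lock_inactive: float = 11.1     # Å target Cα–Cα, inactive endpoint
    lock_active: float = 18.9       # Å target Cα–Cα, active endpoint
    tm6_tip_displacement: float = 14.0  # Å, prescribed 6.30 Cα movement
    npxxy_shift: float = 2.5        # Å, outward TM7-tip shift when active
    min_separation: float = 1.0     # Å, steric-overlap threshold


@dataclass
class ReceptorTruth:
    """Constructed (not measured) properties of the generated endpoint."""

    lock_distance: float
    tm6_tip_displacement: float
    npxxy_shift: float
    hinge_angle_deg: float


def _helix_atoms(spec: ReceptorSpec, helix: int, axis_xy: np.ndarray):
    """Backbone + CB pseudo-atoms of one ideal helix.

    Returns lists (name, resname-slot index, xyz). Residue i of 29 sits at
    z_top − (i−1)·rise for downward helices, mirrored for upward ones.
    """
    down = helix in _DOWN_HELICES
    zinc = -spec.rise if down else spec.rise
    z0 = spec.z_top if down else spec.z_top - (spec.n_res - 1) * spec.rise
    atoms = []
    for i in range(1, spec.n_res + 1):
        theta = (_HELIX_ANGLES[helix] + 180.0 + (i - 1) * spec.twist) * DEG
        z = z0 + (i - 1) * zinc
        u = np.array([np.cos(theta), np.sin(theta)])
        ca = np.array([*(axis_xy + spec.ca_radius * u), z])
        n = np.array([*(axis_xy + 1.6 * _rot2(u, -28 * DEG)),
                      z - 0.5 * zinc])
        c = np.array([*(axis_xy + 1.7 * _rot2(u, 24 * DEG)),
                      z + 0.55 * zinc])
        o = np.array([*(axis_xy + 3.0 * _rot2(u, 33 * DEG)),
                      z + 0.7 * zinc])
        cb = np.array([*(axis_xy + 3.6 * u), z])
        for nm, xyz in (("N", n), ("CA", ca), ("C", c), ("O", o), ("CB", cb)):
            atoms.append((nm, i, xyz))
    return atoms


def _rot2(u: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])


def _sidechain_extras(resname: str, ca: np.ndarray,
                      center_xy: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Deterministic pseudo-sidechain atoms pointing away from the bundle
    centre (so charged tips face the lipids), staggered vertically so they
    clear the CB bead."""
    u2 = ca[:2] - center_xy
    nrm = np.linalg.norm(u2)
    u2 = u2 / nrm if nrm > 1e-6 else np.array([1.0, 0.0])
    u = np.array([u2[0], u2[1], 0.0])
    up = np.array([0.0, 0.0, 1.0])
    if resname == "ARG":
        return [("NE", ca + 1.8 * u + 1.1 * up),
                ("NH1", ca + 3.2 * u + 2.0 * up),
                ("NH2", ca + 3.2 * u + 0.2 * up)]
    if resname == "GLU":
        return [("OE1", ca + 2.6 * u + 1.8 * up),
                ("OE2", ca + 2.6 * u + 0.2 * up)]
    if resname == "LYS":
        return [("NZ", ca + 3.2 * u + 1.2 * up)]
    return []


def _bw_map(spec: ReceptorSpec) -> dict[str, int]:
    out = {}
    for code in list(_MOTIF_RESNAMES):
        helix, pos = code.split(".")
        h, p = int(helix), int(pos)
        i = p - _BW_OFFSETS[h]
        if not 1 <= i <= spec.n_res:
            raise MemgateError(f"BW {code} does not fit in {spec.n_res} residues")
        out[code] = h * 100 + i
    return out


def make_receptor(spec: ReceptorSpec | None = None, state: str = "inactive"
                  ) -> tuple[MolecularSystem, Frame, ReceptorAnnotation,
                             ReceptorTruth]:
    """Build one endpoint conformation of the toy receptor.

    The inactive bundle places TM6 so the ionic-lock Cα–Cα distance equals
    ``spec.lock_inactive`` (1D root-solve on the constructed geometry). The
    active state rigidly swings TM6 about a hinge at its extracellular end;
    the hinge angle and swing azimuth are solved simultaneously so the lock
    distance *and* the 6.30 Cα displacement hit their targets, and the TM7
    intracellular tip (the NPxxY stretch) is shifted radially outward by
    ``npxxy_shift``. Construction is fully deterministic.
    """
    spec = spec or ReceptorSpec()
    if state not in ("active", "inactive"):
        raise MemgateError(f"unknown state {state!r}")
    bw = _bw_map(spec)

    axes = {h: spec.bundle_radius * np.array([np.cos(a * DEG), np.sin(a * DEG)])
            for h, a in _HELIX_ANGLES.items()}

    def build(tm6_frac: float) -> dict[int, list]:
        ax = dict(axes)
        ax[6] = axes[3] + tm6_frac * (axes[6] - axes[3])
        return {h: _helix_atoms(spec, h, ax[h]) for h in _HELIX_ANGLES}, ax

    def ca_of(helices: dict, code: str) -> np.ndarray:
        h = int(code.split(".")[0])
        i = bw[code] - h * 100
        for nm, ri, xyz in helices[h]:
            if ri == i and nm == "CA":
                return xyz
        raise MemgateError(f"internal: CA of {code} not built")

    def lock_at(frac: float) -> float:
        hel, _ = build(frac)
        return float(np.linalg.norm(ca_of(hel, "3.50") - ca_of(hel, "6.30")))

    frac = brentq(lambda s: lock_at(s) - spec.lock_inactive, 0.02, 1.0,
                  xtol=1e-10)
    helices, ax = build(frac)

    # attach pseudo-sidechains now, so the TM6 hinge moves them rigidly
    code_by_seq = {seq: code for code, seq in bw.items()}
    bundle_center = np.zeros(2)
    for h in list(helices):
        expanded = []
        for nm, ri, xyz in helices[h]:
            expanded.append((nm, ri, xyz))
            if nm == "CA":
                rn = _MOTIF_RESNAMES.get(code_by_seq.get(h * 100 + ri, ""),
                                         "ALA")
                expanded.extend(
                    (xn, ri, xxyz) for xn, xxyz in
                    _sidechain_extras(rn, xyz, bundle_center))
        helices[h] = expanded

    hinge_deg = 0.0
    if state == "active":
        hinge = np.array([ax[6][0], ax[6][1], spec.z_top])
        p350 = ca_of(helices, "3.50")
        p630 = ca_of(helices, "6.30")
        # the swung 6.30 Cα must sit on three spheres at once: hinge radius
        # (rigid swing), the prescribed tip displacement from its inactive
        # position, and the prescribed lock distance from the 3.50 Cα.
        candidates = _trilaterate(hinge, float(np.linalg.norm(p630 - hinge)),
                                  p630, spec.tm6_tip_displacement,
                                  p350, spec.lock_active)
        others = np.array([xyz for h, lst in helices.items() if h != 6
                           for _, _, xyz in lst])
        swung = None
        for target in candidates:  # outward-preferred, then the mirror
            v0 = p630 - hinge
            v1 = target - hinge
            axis = np.cross(v0, v1)
            if np.linalg.norm(axis) < 1e-9:
                continue
            theta = float(np.arccos(np.clip(
                v0 @ v1 / (np.linalg.norm(v0) * np.linalg.norm(v1)), -1, 1)))
            rot = _axis_rotation(axis, theta)
            trial = [(nm, ri, hinge + rot @ (xyz - hinge))
                     for nm, ri, xyz in helices[6]]
            tm6_xyz = np.array([xyz for _, _, xyz in trial])
            sep = np.sqrt(((tm6_xyz[:, None, :] - others[None, :, :]) ** 2
                           ).sum(-1)).min()
            if sep >= spec.min_separation:
                swung = trial
                hinge_deg = float(np.degrees(theta))
                break
        if swung is None:
            raise MemgateError(
                "TM6 hinge swing produces steric overlap for both "
                "candidate directions")
        helices[6] = swung
        # outward shift of the TM7 intracellular tip: the NPxxY stretch
        # moves by the full amount, with a gentle 10-residue taper above it
        # so consecutive backbone atoms are not torn apart
        out7 = np.array([*(ax[7] / np.linalg.norm(ax[7])), 0.0])
        full_from = bw["7.49"] - 700
        helices[7] = [
            (nm, ri, xyz + spec.npxxy_shift * out7
             * max(0.0, 1.0 - 0.1 * max(0, full_from - ri)))
            for nm, ri, xyz in helices[7]]

    # assemble the system in residue order
    names, resnames, resseqs, xyzs = [], [], [], []
    for h in sorted(helices):
        for nm, ri, xyz in helices[h]:
            seq = h * 100 + ri
            names.append(nm)
            resnames.append(_MOTIF_RESNAMES.get(code_by_seq.get(seq, ""),
                                                "ALA"))
            resseqs.append(seq)
            xyzs.append(xyz)
    coords = np.array(xyzs)
    if len(coords) > 1:
        dmin = pdist(coords).min()
        if dmin < spec.min_separation:
            raise MemgateError(
                f"steric overlap in generated bundle: min separation "
                f"{dmin:.2f} Å < {spec.min_separation} Å")
    n = len(names)
    elements = np.array([nm[0] for nm in names], dtype=object)
    system = MolecularSystem(
        names=np.array(names, dtype=object),
        elements=elements,
        masses=np.array([mass_of(e) for e in elements]),
        residue_seqs=np.array(resseqs, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        chains=np.array(["A"] * n, dtype=object),
        roles=np.array(["protein"] * n, dtype=object),
        lipid_ids=np.full(n, -1, dtype=int),
    )
    frame = Frame(coords=coords, box=None, time=0.0)
    annotation = ReceptorAnnotation(
        bw_map=dict(bw),
        tm_ranges={h: (h * 100 + 1, h * 100 + spec.n_res)
                   for h in _HELIX_ANGLES},
        motifs={"ionic_lock": ["3.50", "6.30"],
                "triad_core": ["3.40", "5.50", "6.44"],
                "npxxy": ["7.49", "7.50", "7.51", "7.52", "7.53"],
                "tm6_lysines": ["6.25", "6.29", "6.32", "6.35"]},
        protonated_residues=[bw["6.30"]],
        chain="A",
    )
    truth = ReceptorTruth(
        lock_distance=(spec.lock_active if state == "active"
                       else spec.lock_inactive),
        tm6_tip_displacement=(spec.tm6_tip_displacement
                              if state == "active" else 0.0),
        npxxy_shift=spec.npxxy_shift if state == "active" else 0.0,
        hinge_angle_deg=hinge_deg,
    )
    measured = ionic_lock_distance(frame, system, annotation)
    if abs(measured - truth.lock_distance) > 0.1:
        raise MemgateError(
            f"internal: constructed lock {measured:.3f} Å misses target "
            f"{truth.lock_distance} Å")
    return system, frame, annotation, truth


def _trilaterate(p1: np.ndarray, r1: float, p2: np.ndarray, r2: float,
                 p3: np.ndarray, r3: float) -> list[np.ndarray]:
    """The (up to two) intersection points of three spheres, ordered with
    the one farther from the Z axis (outward from the bundle) first."""
    ex = (p2 - p1) / np.linalg.norm(p2 - p1)
    d = float(np.linalg.norm(p2 - p1))
    i = float(ex @ (p3 - p1))
    ey = p3 - p1 - i * ex
    ey = ey / np.linalg.norm(ey)
    j = float(ey @ (p3 - p1))
    ez = np.cross(ex, ey)
    x = (r1 ** 2 - r2 ** 2 + d ** 2) / (2 * d)
    y = (r1 ** 2 - r3 ** 2 + i ** 2 + j ** 2) / (2 * j) - (i / j) * x
    z2 = r1 ** 2 - x ** 2 - y ** 2
    if z2 < 0:
        raise MemgateError(
            "requested lock distance and tip displacement are jointly "
            "unreachable by a rigid TM6 hinge in this bundle geometry")
    candidates = [p1 + x * ex + y * ey + s * np.sqrt(z2) * ez
                  for s in (+1.0, -1.0)]
    return sorted(candidates, key=lambda q: -float(np.hypot(q[0], q[1])))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# ===========================================================================
# Interpolated activation/deactivation paths
# ===========================================================================

def make_path(start: Frame, end: Frame, n_frames: int,
              noise_sigma: float = 0.0, seed: int = 0,
              frame_interval: float = 4.0,
              schedule: Sequence[float] | None = None
              ) -> tuple[list[Frame], np.ndarray]:
    """Trajectory interpolating between two conformations, plus ground truth.

    Frame k sits at fraction k/(n−1) along the straight-line path (or at
    ``schedule[k]`` when a dwell schedule is given — piecewise-constant
    fractions emulate metastable states), with optional seeded Gaussian
    noise of width *noise_sigma* (Å) on every coordinate. Returns the frame
    list and the per-frame progress fractions.
    """
    if start.coords.shape != end.coords.shape:
        raise MemgateError("endpoint frames differ in atom count")
    if n_frames < 2:
        raise MemgateError("a path needs at least 2 frames")
    if schedule is not None:
        fractions = np.asarray(schedule, dtype=float)
        if len(fractions) != n_frames:
            raise MemgateError("schedule length must equal n_frames")
    else:
        fractions = np.arange(n_frames) / (n_frames - 1)
    rng = np.random.default_rng(seed)
    frames = []
    for k, f in enumerate(fractions):
        coords = (1.0 - f) * start.coords + f * end.coords
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        frames.append(Frame(coords=coords, box=start.box,
                            time=k * frame_interval))
    return frames, fractions


# ===========================================================================
# Bilayer generator
# ===========================================================================

#: Headgroup templates: (atom name, offset along the outward normal (Å),
#: lateral x-offset (Å)). Charge classes come from the packaged rule table
#: (phosphate oxygens negative; choline/ethanolamine N positive; PG's
#: glycerol carbon neutral).
_HEADGROUPS = {
    "PC": [("P", 0.0, 0.0), ("O11", 0.8, 0.6), ("O12", 0.8, -0.6),
           ("N", 2.8, 0.0)],
    "PE": [("P", 0.0, 0.0), ("O11", 0.8, 0.6), ("O12", 0.8, -0.6),
           ("N", 2.4, 0.0)],
    "PG": [("P", 0.0, 0.0), ("O11", 0.8, 0.6), ("O12", 0.8, -0.6),
           ("CG", 2.2, 0.0)],
}

_HEADGROUP_RESNAMES = {"PC": "DOPC", "PE": "DOPE", "PG": "DOPG"}

#: Lattice spacings (Å) whose squares reproduce the time-averaged areas per
#: lipid reported for the three reference membranes: 61 Å² (PE-like), 68 Å²
#: (PC-like) and 71 Å² (PG-like).
DEFAULT_SPACINGS = {"PE": 61.0 ** 0.5, "PC": 68.0 ** 0.5, "PG": 71.0 ** 0.5}


def spacing_for(headgroup: str) -> float:
    """Default lattice spacing reproducing the reference APL of a lipid."""
    if headgroup not in DEFAULT_SPACINGS:
        raise MemgateError(f"unknown headgroup template {headgroup!r}")
    return DEFAULT_SPACINGS[headgroup]


@dataclass
class BilayerSpec:
    """Parametric lattice bilayer.

    ``spacing`` sets the exact area per lipid (spacing²); the leaflet
    separation field is D(x, y) = d0 + A·cos²(π·r / 2R) inside radius R of
    ``bulge_center`` (box centre by default) and d0 outside. Defaults mirror
    a flat, protein-free reference membrane.
    """

    nx: int = 8
    ny: int = 8
    spacing: float = 8.2            # Å; APL = spacing²
    d0: float = 38.0                # Å, base P-to-P leaflet separation
    bulge_amplitude: float = 0.0    # Å
    bulge_radius: float = 10.0      # Å
    bulge_center: tuple[float, float] | None = None
    headgroup: str = "PC"           # PC-like, PE-like or PG-like template
    n_tail: int = 2                 # tail pseudo-atoms per lipid
    jitter: float = 0.0             # Å, Gaussian positional noise
    seed: int = 0
    box_z: float | None = None      # Å; default d0 + 30


@dataclass
class BilayerTruth:
    """Exact constructed properties of a generated bilayer."""

    apl: float
    d0: float
    bulge_amplitude: float
    bulge_radius: float
    bulge_center: tuple[float, float]
    lipids_per_leaflet: int
    pos_atom_names: tuple[str, ...]
    neg_atom_names: tuple[str, ...]

    def thickness_at(self, x: float, y: float) -> float:
        """The analytic leaflet-separation field D(x, y)."""
        r = np.hypot(x - self.bulge_center[0], y - self.bulge_center[1])
        if r < self.bulge_radius:
            return self.d0 + self.bulge_amplitude * float(
                np.cos(np.pi * r / (2 * self.bulge_radius)) ** 2)
        return self.d0


def make_bilayer(spec: BilayerSpec | None = None
                 ) -> tuple[MolecularSystem, Frame, BilayerTruth]:
    """Generate a two-leaflet lattice bilayer of pseudo-atom lipids.

    Each leaflet holds nx·ny lipids at lattice points ((i+½)a, (j+½)a);
    the phosphorus of each lipid sits at z = z_mid ± D(x, y)/2, headgroup
    pseudo-atoms stack outward and tail beads inward. Seeded Gaussian
    jitter (σ < spacing/2, else the lattice identity is lost and an error
    is raised) is the only stochastic element.
    """
    spec = spec or BilayerSpec()
    if spec.headgroup not in _HEADGROUPS:
        raise MemgateError(f"unknown headgroup template {spec.headgroup!r}")
    if spec.jitter >= spec.spacing / 2:
        raise MemgateError("jitter σ must be below spacing/2")
    a = spec.spacing
    lx, ly = spec.nx * a, spec.ny * a
    lz = spec.box_z if spec.box_z is not None else spec.d0 + 30.0
    # default bulge centre: the lattice point nearest the box centre, so the
    # discrete system actually samples the bulge peak
    center = spec.bulge_center or ((spec.nx // 2 + 0.5) * a,
                                   (spec.ny // 2 + 0.5) * a)
    if spec.bulge_amplitude and spec.bulge_radius >= min(lx, ly) / 2:
        raise MemgateError("bulge radius must be below half the box width")
    zmid = lz / 2.0
    template = _HEADGROUPS[spec.headgroup]
    resname = _HEADGROUP_RESNAMES[spec.headgroup]
    truth = BilayerTruth(
        apl=a * a, d0=spec.d0, bulge_amplitude=spec.bulge_amplitude,
        bulge_radius=spec.bulge_radius, bulge_center=center,
        lipids_per_leaflet=spec.nx * spec.ny,
        pos_atom_names=("N",) if spec.headgroup in ("PC", "PE") else (),
        neg_atom_names=("O11", "O12"),
    )
    rng = np.random.default_rng(spec.seed)
    names, resnames, resseqs, lipid_ids, xyzs = [], [], [], [], []
    lid = 0
    for sign in (+1, -1):  # upper, lower
        for i in range(spec.nx):
            for j in range(spec.ny):
                x = (i + 0.5) * a
                y = (j + 0.5) * a
                if spec.jitter > 0:  # lateral jitter first, so the P height
                    x += rng.normal(0.0, spec.jitter)  # samples D at the
                    y += rng.normal(0.0, spec.jitter)  # actual position
                d = truth.thickness_at(x, y)
                pz = zmid + sign * d / 2.0
                if spec.jitter > 0:
                    pz += rng.normal(0.0, spec.jitter)
                for nm, dz, dx in template:
                    names.append(nm)
                    xyzs.append([x + dx, y, pz + sign * dz])
                for k in range(1, spec.n_tail + 1):
                    names.append(f"C{k}")
                    xyzs.append([x, y, pz - sign * 1.8 * k])
                n_added = len(template) + spec.n_tail
                resnames.extend([resname] * n_added)
                resseqs.extend([lid + 1] * n_added)
                lipid_ids.extend([lid] * n_added)
                lid += 1
    coords = np.array(xyzs, dtype=float)
    n = len(names)
    elements = np.array([nm[0] for nm in names], dtype=object)
    system = MolecularSystem(
        names=np.array(names, dtype=object),
        elements=elements,
        masses=np.array([mass_of(e) for e in elements]),
        residue_seqs=np.array(resseqs, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        chains=np.array(["M"] * n, dtype=object),
        roles=np.array(["lipid"] * n, dtype=object),
        lipid_ids=np.array(lipid_ids, dtype=int),
    )
    frame = Frame(coords=coords, box=np.array([lx, ly, lz]), time=0.0)
    return system, frame, truth


# ===========================================================================
# Embedding a receptor into a bilayer with planted contacts
# ===========================================================================

@dataclass
class EmbedTruth:
    """Planted protein–lipid contact pairs (indices into the combined
    system) and the cavity geometry."""

    planted_pairs: list[tuple[int, int]]
    cavity_radius: float
    removed_lipids: int


def embed_receptor(bilayer: tuple[MolecularSystem, Frame],
                   receptor: tuple[MolecularSystem, Frame],
                   annotation: ReceptorAnnotation,
                   planted_contacts: int = 0, seed: int = 0,
                   cavity_pad: float = 6.0,
                   contact_range: tuple[float, float] = (3.5, 4.4)
                   ) -> tuple[MolecularSystem, Frame, EmbedTruth]:
    """Place a receptor in a bilayer cavity and plant exact contact counts.

    The receptor is centred laterally in the box with its mid-height at the
    membrane midplane; lipids whose phosphorus lies within (receptor lateral
    extent + *cavity_pad*) of the axis are removed, which keeps every
    remaining charged lipid atom out of contact range. Exactly
    *planted_contacts* charged lipid atoms are then relocated to within
    ``contact_range`` of randomly chosen charged TM6 atoms such that each
    contributes exactly one charged atom pair under a 4.5 Å cutoff. Charges
    are assigned with the packaged rule table and the annotation's
    protonation list before planting.
    """
    mem_sys, mem_frame = bilayer
    rec_sys, rec_frame = receptor
    box = mem_frame.box
    if box is None:
        raise MemgateError("bilayer frame has no box")
    # position the receptor
    rec_xyz = rec_frame.coords.copy()
    rec_center = rec_xyz.mean(axis=0)
    target = np.array([box[0] / 2.0, box[1] / 2.0, box[2] / 2.0])
    rec_xyz += target - rec_center
    r_prot = float(np.hypot(*(rec_xyz[:, :2] - target[:2]).T).max())
    cavity = r_prot + cavity_pad
    if 2 * cavity > min(box[0], box[1]):
        raise MemgateError("cavity larger than the box")

    # drop lipids inside the cavity (by phosphorus lateral position)
    keep_atoms = np.ones(mem_sys.n_atoms, dtype=bool)
    removed = 0
    for lidx, mol in mem_sys.lipid_molecules.items():
        p = [i for i in mol if mem_sys.names[i] == "P"]
        if not p:
            continue
        if np.hypot(*(mem_frame.coords[p[0], :2] - target[:2])) < cavity:
            keep_atoms[mol] = False
            removed += 1
    kept = np.nonzero(keep_atoms)[0]

    def cat(attr):
        return np.concatenate([getattr(rec_sys, attr),
                               getattr(mem_sys, attr)[kept]])

    lip_ids_mem = mem_sys.lipid_ids[kept].copy()
    remap = {old: new for new, old in
             enumerate(sorted(set(int(x) for x in lip_ids_mem if x >= 0)))}
    lip_ids_mem = np.array([remap.get(int(x), -1) for x in lip_ids_mem])
    combined = MolecularSystem(
        names=cat("names"), elements=cat("elements"), masses=cat("masses"),
        residue_seqs=cat("residue_seqs"), residue_names=cat("residue_names"),
        chains=cat("chains"), roles=cat("roles"),
        lipid_ids=np.concatenate([rec_sys.lipid_ids, lip_ids_mem]),
    )
    coords = np.vstack([rec_xyz, mem_frame.coords[kept]])
    assign_charges(combined, default_charge_rules(),
                   protonated=annotation.protonated_residues)

    # charged TM6 protein atoms
    tm6 = set(annotation.tm_residues([6]))
    prot_charged = [i for i in range(combined.n_atoms)
                    if combined.roles[i] == "protein"
                    and int(combined.residue_seqs[i]) in tm6
                    and combined.charge_class[i] != "neutral"]
    # plant contacts from the lower (intracellular) leaflet only — the
    # leaflet whose interactions with the TM6 face are the observable
    leaflets = assign_leaflets(combined, Frame(coords=coords, box=box))
    lip_charged = [i for i in range(combined.n_atoms)
                   if combined.roles[i] == "lipid"
                   and combined.charge_class[i] != "neutral"
                   and leaflets.get(int(combined.lipid_ids[i])) == "lower"]
    if planted_contacts > len(lip_charged):
        raise MemgateError("more planted contacts than charged lipid atoms")
    if planted_contacts > 0 and not prot_charged:
        raise MemgateError("no charged TM6 atoms to plant contacts against")

    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    if planted_contacts:
        # relocate the charged lipid atoms farthest from the protein
        d_from_center = np.hypot(*(coords[lip_charged][:, :2]
                                   - target[:2]).T)
        order = np.argsort(d_from_center)[::-1]
        movers = [lip_charged[int(k)] for k in order[:planted_contacts]]
        prot_xyz = coords[prot_charged]
        for mover in movers:
            ok = False
            for _ in range(500):
                p_idx = int(rng.integers(len(prot_charged)))
                anchor = prot_xyz[p_idx]
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                dist = rng.uniform(*contact_range)
                cand = anchor + dist * u
                d_all = np.linalg.norm(prot_xyz - cand, axis=1)
                n_close = int((d_all < 4.5).sum())
                if n_close == 1 and d_all[p_idx] < 4.5:
                    coords[mover] = cand
                    pairs.append((prot_charged[p_idx], mover))
                    ok = True
                    break
            if not ok:
                raise MemgateError("could not place a planted contact "
                                   "without side contacts")
    truth = EmbedTruth(planted_pairs=pairs, cavity_radius=cavity,
                       removed_lipids=removed)
    return combined, Frame(coords=coords, box=box.copy(), time=0.0), truth
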