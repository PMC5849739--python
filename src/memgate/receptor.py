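"""Receptor-conformation metrics.

Least-squares (Kabsch) superposition, RMSD time series over named atom
sets (TM domain, TM6, ICL3, NPxxY, triad core), the ionic-lock Cα–Cα
distance (R3.50–E6.30), sidechain-to-lipid-phosphate distances, and the
TM6 intracellular-tip displacement between two structures.

Fitting convention: whole-receptor and per-helix RMSD are fitted on TM
domain Cα atoms; local motifs (triad core, NPxxY) are measured after the
same global TM fit *without re-fitting*, so that re-packing relative to the
helical bundle — not internal motif geometry alone — is what the series
reports. Backbone (N, CA, C, O) atoms are used for helix/loop RMSD, all
heavy atoms for the triad core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import (AtomSet, Frame, MemgateError, MolecularSystem,
                   ReceptorAnnotation, SelectionError, min_image_displacement,
                   select)

logger = logging.getLogger("memgate")

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Terminal (charge-bearing) side-chain atoms used for residue-to-phosphate
#: distances, keyed by residue name.
TERMINAL_ATOMS = {"ARG": ("NH1", "NH2"), "LYS": ("NZ",)}


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile onto a reference point set."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # applied after rotation about the mobile centroid
    fit_rmsd: float

    mobile_centroid: np.ndarray = field(default=None)  # type: ignore

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to arbitrary coordinates."""
        return (coords - self.mobile_centroid) @ self.rotation.T \
            + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares superposition of *mobile* onto *reference*.

    Returns the proper rotation (det +1) and translation minimising the
    (weighted) RMSD, via the SVD of the weighted covariance matrix with the
    standard sign correction that excludes reflections.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise MemgateError(
            f"atom count mismatch: {mobile.shape[0]} vs {reference.shape[0]}")
    n = mobile.shape[0]
    if n < 3:
        raise MemgateError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    cm = (w[:, None] * mobile).sum(axis=0)
    cr = (w[:, None] * reference).sum(axis=0)
    p = mobile - cm
    q = reference - cr
    h = (w[:, None] * p).T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] < 1e-12:  # rank < 2: all points collinear
        raise MemgateError("degenerate (collinear) point set")
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = p @ rot.T
    fit_rmsd = float(np.sqrt((w * ((moved - q) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=cr,
                               fit_rmsd=fit_rmsd, mobile_centroid=cm)


def rmsd(a: np.ndarray, b: np.ndarray,
         weights: np.ndarray | None = None) -> float:
    """Plain (unfitted) RMSD between two equal-shape coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise MemgateError("RMSD needs equal-shape coordinate arrays")
    if weights is None:
        return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return float(np.sqrt((w * ((a - b) ** 2).sum(axis=1)).sum()))


# ---------------------------------------------------------------------------
# Pairing atoms between two systems (crystal gaps are dropped pairwise)
# ---------------------------------------------------------------------------

def match_atoms(sys_a: MolecularSystem, set_a: AtomSet,
                sys_b: MolecularSystem, set_b: AtomSet
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms of two selections by (residue_seq, atom_name).

    Returns index arrays (into each system) of equal length, ordered by
    residue then name. Atoms present on one side only (e.g. crystallographic
    gaps) are dropped, with the count logged.
    """
    def keyed(sys, aset):
        return {(int(sys.residue_seqs[i]), str(sys.names[i])): int(i)
                for i in aset.indices}

    ka, kb = keyed(sys_a, set_a), keyed(sys_b, set_b)
    common = sorted(ka.keys() & kb.keys())
    dropped = (len(ka) - len(common)) + (len(kb) - len(common))
    if dropped:
        logger.info("match_atoms: dropped %d unpaired atoms (%s | %s)",
                    dropped, set_a.label, set_b.label)
    if not common:
        raise SelectionError(
            f"no common atoms between {set_a.label!r} and {set_b.label!r}")
    return (np.array([ka[k] for k in common], dtype=int),
            np.array([kb[k] for k in common], dtype=int))


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

@dataclass
class RmsdSeries:
    times: np.ndarray
    values: np.ndarray
    fit_selection: str = ""
    measure_selection: str = ""
    reference: str = ""


def rmsd_series(traj: Iterable[Frame], traj_system: MolecularSystem,
                ref_frame: Frame, ref_system: MolecularSystem,
                fit_selection: tuple[AtomSet, AtomSet],
                measure_selection: tuple[AtomSet, AtomSet] | None = None,
                reference_label: str = "") -> RmsdSeries:
    """Per-frame fitted RMSD of *measure_selection* after a fit on
    *fit_selection* (no re-fit on the measured set).

    Each selection is a (trajectory-system, reference-system) pair of
    :class:`AtomSet`; atoms are paired by (residue number, atom name) and
    unpaired atoms dropped. With *measure_selection* omitted, the fitted
    RMSD of the fit set itself is reported.
    """
    if measure_selection is None:
        measure_selection = fit_selection
    if len(fit_selection[0]) == 0 or len(measure_selection[0]) == 0:
        raise SelectionError("empty selection for RMSD series")
    fit_a, fit_b = match_atoms(traj_system, fit_selection[0],
                               ref_system, fit_selection[1])
    mea_a, mea_b = match_atoms(traj_system, measure_selection[0],
                               ref_system, measure_selection[1])
    times, values = [], []
    for fr in traj:
        sup = kabsch(fr.coords[fit_a], ref_frame.coords[fit_b])
        moved = sup.transform(fr.coords[mea_a])
        values.append(rmsd(moved, ref_frame.coords[mea_b]))
        times.append(fr.time)
    return RmsdSeries(times=np.array(times), values=np.array(values),
                      fit_selection=fit_selection[0].label,
                      measure_selection=measure_selection[0].label,
                      reference=reference_label)


@dataclass
class DistanceSeries:
    times: np.ndarray
    values: np.ndarray
    endpoints: tuple[str, str] = ("", "")


# ---------------------------------------------------------------------------
# Ionic lock and lipid-contact distances
# ---------------------------------------------------------------------------

def ionic_lock_distance(frame: Frame, system: MolecularSystem,
                        annotation: ReceptorAnnotation) -> float:
    """Cα–Cα distance (Å) between R3.50 (TM3) and E6.30 (TM6).

    A short distance marks a formed (inactive, 'closed') ionic lock; a large
    one the outward-swung active TM6. Direct (non-imaged) distance: the pair
    is intra-protein.
    """
    d = _ca_position(frame, system, annotation, "6.30") \
        - _ca_position(frame, system, annotation, "3.50")
    return float(np.linalg.norm(d))


def _ca_position(frame, system, annotation, bw_code) -> np.ndarray:
    seq = annotation.resolve(bw_code)
    sel = select(system, f"resid {seq} name CA")
    if annotation.chain and np.any(system.chains == annotation.chain):
        sel = select(system, f"resid {seq} name CA chain {annotation.chain}")
    if len(sel) == 0:
        raise SelectionError(f"Cα of residue {seq} (BW {bw_code}) missing")
    return frame.coords[sel.indices[0]]


def sidechain_phosphate_distance(frame: Frame, system: MolecularSystem,
                                 annotation: ReceptorAnnotation,
                                 residue: str = "3.50",
                                 lipid_set: AtomSet | None = None,
                                 phosphate_names: tuple[str, ...] =
                                 ("P", "O11", "O12", "O13", "O14"),
                                 ) -> tuple[float, int]:
    """Distance (Å) from a residue's terminal N atoms to the closest lipid
    phosphate-group centre of mass, with the identity of that lipid.

    The distance is the minimum over phosphate groups of the minimum over
    terminal atoms, using XY minimum-image / direct-Z metric. *lipid_set*
    restricts which lipid atoms are considered (e.g. one leaflet).
    """
    seq = annotation.resolve(residue)
    res_mask = system.residue_seqs == seq
    if annotation.chain and np.any(system.chains == annotation.chain):
        res_mask &= system.chains == annotation.chain
    res_idx = np.nonzero(res_mask)[0]
    if len(res_idx) == 0:
        raise SelectionError(f"residue {residue} not found")
    resname = str(system.residue_names[res_idx[0]]).upper()
    term_names = TERMINAL_ATOMS.get(resname)
    if not term_names:
        raise MemgateError(f"no terminal-atom rule for residue type {resname}")
    term_idx = [i for i in res_idx if system.names[i] in term_names]
    if not term_idx:
        raise SelectionError(f"terminal atoms {term_names} missing on {seq}")
    term_xyz = frame.coords[term_idx]

    allowed = None
    if lipid_set is not None:
        allowed = np.zeros(system.n_atoms, dtype=bool)
        allowed[lipid_set.indices] = True
    best = np.inf
    best_lipid = -1
    any_group = False
    for lid, atom_idx in system.lipid_molecules.items():
        grp = [i for i in atom_idx if system.names[i] in phosphate_names
               and (allowed is None or allowed[i])]
        if not grp:
            continue
        any_group = True
        m = system.masses[grp]
        com = (m[:, None] * frame.coords[grp]).sum(axis=0) / m.sum()
        disp = min_image_displacement(term_xyz - com, frame.box)
        d = float(np.sqrt((disp ** 2).sum(axis=1)).min())
        if d < best:
            best, best_lipid = d, lid
    if not any_group:
        raise MemgateError("no lipid phosphate groups in the given set")
    return best, best_lipid


# ---------------------------------------------------------------------------
# TM6 displacement between two structures
# ---------------------------------------------------------------------------

def tm6_displacement(active: tuple[MolecularSystem, Frame],
                     inactive: tuple[MolecularSystem, Frame],
                     annotation_active: ReceptorAnnotation,
                     annotation_inactive: ReceptorAnnotation | None = None,
                     ) -> float:
    """Outward displacement (Å) of the TM6 intracellular tip between two
    conformations.

    The inactive structure is superposed onto the active one using the Cα
    atoms of TM1–TM5, TM7 and H8 (TM6 excluded so its own motion does not
    bias the fit); the displacement of the Cα of the BW 6.30 residue — the
    conventional TM6 intracellular-end marker — is reported.
    """
    ann_a = annotation_active
    ann_i = annotation_inactive or annotation_active
    sys_a, frame_a = active
    sys_i, frame_i = inactive

    def fit_set(sys, ann):
        seqs = ann.tm_residues([1, 2, 3, 4, 5, 7, 8])
        mask = np.isin(sys.residue_seqs, seqs) & (sys.names == "CA")
        if ann.chain and np.any(sys.chains == ann.chain):
            mask &= sys.chains == ann.chain
        return AtomSet(np.nonzero(mask)[0], "tm-fit (no TM6) CA")

    ia, ii = match_atoms(sys_a, fit_set(sys_a, ann_a),
                         sys_i, fit_set(sys_i, ann_i))
    if len(ia) < 3:
        raise MemgateError("too few paired Cα atoms for the TM fit")
    sup = kabsch(frame_i.coords[ii], frame_a.coords[ia])
    tip_a = _ca_position(frame_a, sys_a, ann_a, "6.30")
    tip_i = _ca_position(frame_i, sys_i, ann_i, "6.30")
    return float(np.linalg.norm(sup.transform(tip_i[None, :])[0] - tip_a))


# ---------------------------------------------------------------------------
# Convenience selections for the standard metrics
# ---------------------------------------------------------------------------

def standard_selections(system: MolecularSystem,
                        annotation: ReceptorAnnotation) -> dict[str, AtomSet]:
    """The named atom sets used by the standard receptor metrics."""
    tm_seqs = annotation.tm_residues(range(1, 9))
    resid = " ".join(str(s) for s in tm_seqs)

    def _sel(expr):
        return select(system, expr, annotation)

    out = {
        "tm_ca": _sel(f"resid {resid} name CA"),
        "tm_backbone": _sel(f"resid {resid} name N CA C O"),
        "tm6_backbone": _sel(
            "resid " + " ".join(str(s) for s in annotation.tm_residues([6]))
            + " name N CA C O"),
        "npxxy_backbone": _sel("bw 7.49-7.53 name N CA C O"),
        "triad_heavy": _sel("bw 3.40 5.50 6.44 heavy"),
    }
    lo6 = annotation.tm_ranges.get(5, (0, 0))[1] + 1
    hi6 = annotation.tm_ranges.get(6, (0, 0))[0] - 1
    if lo6 <= hi6:  # ICL3: the gap between TM5 and TM6
        icl3 = _sel(f"resid {lo6}-{hi6} name N CA C O")
        if len(icl3):
            out["icl3_backbone"] = icl3
    return out
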