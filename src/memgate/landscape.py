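"""Conformational landscape and receptor-state classification.

A trajectory is projected onto two coordinates that together separate
receptor states: the backbone RMSD of the TM7 NPxxY motif against the
inactive reference (after a whole-TM-domain Cα fit) and the ionic-lock
Cα–Cα distance R3.50–E6.30. Each point is classified into one of
{very_inactive, inactive, intermediate, active}.

Default class boundaries derive from the anchor distances of the two
crystal endpoints and the fully-closed lock: 18.9 Å (active), 11.1 Å
(inactive, open lock) and 7.6 Å (closed lock). They are deliberately
conservative and fully configurable; no published figure draws explicit
boundaries, so these are package defaults, not literature constants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence


from .core import (ConfigError, Frame, MemgateError, MolecularSystem,
                   ReceptorAnnotation)
from .receptor import ionic_lock_distance, kabsch, match_atoms, rmsd, \
    standard_selections

#: Ordering from least to most active, used by monotonicity checks and the
#: modal tie-break (ties go to the less active label).
LABEL_ORDER = ("very_inactive", "inactive", "intermediate", "active")


@dataclass(frozen=True)
class StatePoint:
    time: float                     # ns
    npxxy_rmsd_vs_inactive: float   # Å
    ionic_lock: float               # Å


@dataclass(frozen=True)
class Thresholds:
    """Class boundaries (Å) for :func:`classify`."""

    lock_closed: float = 9.0
    lock_open_low: float = 12.0
    lock_active: float = 15.0
    npxxy_inactive_max: float = 1.0
    npxxy_active_min: float = 2.0

    def __post_init__(self) -> None:
        if not (self.lock_closed < self.lock_active):
            raise ConfigError("lock_closed must be below lock_active")
        if not (self.lock_closed <= self.lock_open_low <= self.lock_active):
            raise ConfigError("lock_open_low must sit between the closed "
                              "and active lock boundaries")


def classify(point: StatePoint, thresholds: Thresholds | None = None) -> str:
    """Assign a state label to one landscape point.

    Precedence: a lock shorter than ``lock_closed`` is *very_inactive*
    regardless of NPxxY; then *active* requires a wide-open lock AND a
    displaced NPxxY; *inactive* requires an open-but-short lock AND a
    near-crystal NPxxY; everything else is *intermediate*.
    """
    t = thresholds or Thresholds()
    lock = point.ionic_lock
    npxxy = point.npxxy_rmsd_vs_inactive
    if lock < 0 or npxxy < 0:
        raise MemgateError("state coordinates must be non-negative")
    if lock < t.lock_closed:
        return "very_inactive"
    if lock > t.lock_active and npxxy >= t.npxxy_active_min:
        return "active"
    if lock <= t.lock_open_low and npxxy <= t.npxxy_inactive_max:
        return "inactive"
    return "intermediate"


def landscape(traj: Iterable[Frame], traj_system: MolecularSystem,
              annotation: ReceptorAnnotation,
              inactive_ref: tuple[MolecularSystem, Frame],
              inactive_annotation: ReceptorAnnotation | None = None,
              window: tuple[float, float] | None = None
              ) -> list[StatePoint]:
    """One (NPxxY RMSD vs inactive, ionic-lock distance) point per frame.

    *window* is an inclusive (start, end) time interval in ns; by default
    the final half of the trajectory is used, matching the convention of
    discarding the approach to (meta)stability. NPxxY RMSD is measured on
    backbone atoms after a TM-domain Cα fit onto the inactive reference.
    """
    ref_sys, ref_frame = inactive_ref
    ann_ref = inactive_annotation or annotation
    sel_t = standard_selections(traj_system, annotation)
    sel_r = standard_selections(ref_sys, ann_ref)
    fit_a, fit_b = match_atoms(traj_system, sel_t["tm_ca"],
                               ref_sys, sel_r["tm_ca"])
    mea_a, mea_b = match_atoms(traj_system, sel_t["npxxy_backbone"],
                               ref_sys, sel_r["npxxy_backbone"])
    frames = list(traj)
    if not frames:
        raise MemgateError("empty trajectory")
    if window is None:
        t_end = frames[-1].time
        t_start = frames[0].time
        window = ((t_start + t_end) / 2.0, t_end)
    lo, hi = window
    points: list[StatePoint] = []
    for fr in frames:
        if fr.time < lo - 1e-9 or fr.time > hi + 1e-9:
            continue
        sup = kabsch(fr.coords[fit_a], ref_frame.coords[fit_b])
        npxxy = rmsd(sup.transform(fr.coords[mea_a]), ref_frame.coords[mea_b])
        lock = ionic_lock_distance(fr, traj_system, annotation)
        points.append(StatePoint(time=fr.time,
                                 npxxy_rmsd_vs_inactive=npxxy,
                                 ionic_lock=lock))
    if not points:
        raise MemgateError(f"no frames inside window [{lo}, {hi}] ns")
    return points


def state_summary(points: Sequence[StatePoint],
                  thresholds: Thresholds | None = None
                  ) -> tuple[dict[str, float], str]:
    """Label fractions and the modal label over a set of landscape points.

    Fractions sum to 1; modal ties are broken toward the less active label
    (a conservative call for a (de)activation analysis).
    """
    if not points:
        raise MemgateError("state summary needs at least one point")
    t = thresholds or Thresholds()
    labels = [classify(p, t) for p in points]
    n = len(labels)
    counts = Counter(labels)
    fractions = {lab: counts.get(lab, 0) / n for lab in LABEL_ORDER
                 if counts.get(lab, 0) > 0}
    best = max(counts.values())
    modal = next(lab for lab in LABEL_ORDER if counts.get(lab, 0) == best)
    return fractions, modal


def landscape_table(points: Sequence[StatePoint],
                    thresholds: Thresholds | None = None):
    """Landscape points as a pandas DataFrame with labels (for CSV export)."""
    import pandas as pd
    t = thresholds or Thresholds()
    return pd.DataFrame({
        "time_ns": [p.time for p in points],
        "npxxy_A": [p.npxxy_rmsd_vs_inactive for p in points],
        "lock_A": [p.ionic_lock for p in points],
        "label": [classify(p, t) for p in points],
    })


def plot_landscape(points: Sequence[StatePoint], path,
                   thresholds: Thresholds | None = None) -> None:
    """Optional scatter plot of the landscape (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    t = thresholds or Thresholds()
    colors = {"very_inactive": "#08306b", "inactive": "#4292c6",
              "intermediate": "#969696", "active": "#cb181d"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in LABEL_ORDER:
        xs = [p.npxxy_rmsd_vs_inactive for p in points
              if classify(p, t) == lab]
        ys = [p.ionic_lock for p in points if classify(p, t) == lab]
        if xs:
            ax.scatter(xs, ys, s=8, c=colors[lab], label=lab, alpha=0.7)
    ax.set_xlabel("NPxxY backbone RMSD vs inactive (Å)")
    ax.set_ylabel("ionic-lock Cα–Cα distance (Å)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
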