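"""Thickness map, density profile, area per lipid, contacts and g(r)."""

import numpy as np
import pytest

import memgate as mg
from memgate.core import AtomSet
from memgate.membrane import (area_per_lipid, count_electrostatic_contacts,
                              density_profile, estimate_bulge,
                              protein_cross_section, radial_distribution,
                              thickness_map)
from memgate.synth import BilayerSpec, make_bilayer

from conftest import frame_of, toy_system
from oracles import contact_count_oracle

RNG = np.random.default_rng(7121)


class TestThickness:
    def test_flat_bilayer_uniform(self, flat_bilayer):
        system, frame, truth = flat_bilayer
        tm = thickness_map([frame], system)
        assert tm.mean == pytest.approx(truth.d0, abs=1e-9)
        assert tm.variation == pytest.approx(0.0, abs=1e-9)

    def test_z_translation_invariance(self, flat_bilayer):
        system, frame, _ = flat_bilayer
        tm0 = thickness_map([frame], system)
        moved = mg.Frame(coords=frame.coords + [0.0, 0.0, 7.3],
                         box=frame.box)
        tm1 = thickness_map([moved], system)
        ok = tm0.counts > 0
        np.testing.assert_allclose(tm1.thickness[ok], tm0.thickness[ok],
                                   atol=1e-9)

    def test_single_anchor_per_cell_is_exact(self):
        """One P per leaflet per cell: the map equals the raw z difference."""
        sys = toy_system(2, role="lipid", names=["P", "P"],
                         resnames=["DOPC"] * 2, resseqs=[1, 2],
                         lipid_ids=[0, 1])
        fr = frame_of([[1.0, 1.0, 21.3], [1.0, 1.0, -17.2]],
                      box=[2.0, 2.0, 60.0])
        tm = thickness_map([fr], sys, grid_cell=2.0, smoothing_radius=2.0)
        assert tm.mean == pytest.approx(21.3 + 17.2)

    def test_bulge_recovery(self):
        """Planted raised-cosine bulge (A=3 Å, R=10 Å) is recovered from the
        map: amplitude within 0.5 Å, radius within 2 Å."""
        spec = BilayerSpec(nx=32, ny=32, spacing=2.05, bulge_amplitude=3.0,
                           bulge_radius=10.0)
        system, frame, truth = make_bilayer(spec)
        tm = thickness_map([frame], system, grid_cell=2.0,
                           smoothing_radius=1.5)
        amp, radius, center = estimate_bulge(tm, (frame.box[0], frame.box[1]))
        assert abs(tm.variation - 3.0) <= 0.5
        assert abs(amp - truth.bulge_amplitude) <= 0.5
        assert abs(radius - truth.bulge_radius) <= 2.0
        assert np.hypot(center[0] - truth.bulge_center[0],
                        center[1] - truth.bulge_center[1]) <= 2.0

    def test_empty_leaflet_is_an_error(self):
        sys = toy_system(2, role="lipid", names=["P", "P"],
                         resnames=["DOPC"] * 2, resseqs=[1, 2],
                         lipid_ids=[0, 1])
        fr = frame_of([[0, 0, 19.0], [1, 1, 19.0]], box=[10, 10, 50])
        with pytest.raises(mg.MemgateError):
            thickness_map([fr], sys)


class TestDensityProfile:
    def test_single_atom_arithmetic(self):
        sys = toy_system(1, names=["P"], masses=[31.0])
        fr = frame_of([[5.0, 5.0, 5.0]], box=[10.0, 10.0, 10.0])
        prof = density_profile([fr], sys, AtomSet(np.array([0])),
                               bin_width=1.0)
        nonzero = prof.density[prof.density > 0]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(0.31)

    def test_mass_conservation_random(self):
        for _ in range(5):
            n = int(RNG.integers(5, 60))
            sys = toy_system(n, masses=RNG.uniform(1, 40, n))
            fr = frame_of(RNG.uniform(0, 30, (n, 3)), box=[30, 30, 30])
            sel = AtomSet(np.arange(n))
            prof = density_profile([fr], sys, sel, bin_width=0.7)
            total = (prof.density * prof.bin_volume).sum()
            assert total == pytest.approx(sys.masses.sum(), rel=1e-6)

    def test_denser_lattice_has_higher_headgroup_peak(self):
        peaks = {}
        for label, spacing in (("dense", 7.81), ("loose", 8.426)):
            system, frame, _ = make_bilayer(BilayerSpec(spacing=spacing))
            sel = mg.select(system, "role lipid")
            prof = density_profile([frame], system, sel, bin_width=1.0)
            peaks[label] = prof.density.max()
        assert peaks["dense"] > peaks["loose"]


class TestCrossSectionAndApl:
    def test_square_hull(self):
        sys = toy_system(4)
        fr = frame_of([[5, 5, 0], [-5, 5, 0], [-5, -5, 0], [5, -5, 0]])
        assert protein_cross_section(fr, sys, (-1, 1), probe_radius=0.0) \
            == pytest.approx(100.0)

    def test_triangle_hull(self):
        sys = toy_system(3)
        fr = frame_of([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        assert protein_cross_section(fr, sys, (-1, 1), probe_radius=0.0) \
            == pytest.approx(50.0)

    def test_circle_limit(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.stack([8 * np.cos(th), 8 * np.sin(th), np.zeros(100)], 1)
        area = protein_cross_section(frame_of(pts), toy_system(100), (-1, 1),
                                     probe_radius=0.0)
        assert area == pytest.approx(64 * np.pi, rel=0.02)

    def test_probe_inflation_is_exact_minkowski(self):
        sys = toy_system(4)
        fr = frame_of([[5, 5, 0], [-5, 5, 0], [-5, -5, 0], [5, -5, 0]])
        area = protein_cross_section(fr, sys, (-1, 1), probe_radius=2.0)
        assert area == pytest.approx(100 + 40 * 2.0 + np.pi * 4.0)

    def test_too_few_atoms_in_slab(self):
        sys = toy_system(3)
        fr = frame_of([[0, 0, 50], [1, 0, 50], [0, 1, 50]])
        with pytest.raises(mg.MemgateError):
            protein_cross_section(fr, sys, (-1, 1))

    def test_lattice_apl_exact(self, flat_bilayer):
        system, frame, truth = flat_bilayer
        apl = area_per_lipid([frame], system)
        assert apl.mean == pytest.approx(truth.apl, abs=1e-9)
        assert apl.n_upper == truth.lipids_per_leaflet

    def test_apl_with_protein_matches_arithmetic(self, flat_bilayer):
        """Box area minus an exactly-known hull, divided by N_upper."""
        system, frame, truth = flat_bilayer
        square = toy_system(4, names=["CA"] * 4, resnames=["ALA"] * 4)
        combined_names = np.concatenate([system.names, square.names])
        comb = toy_system(system.n_atoms + 4,
                          names=list(combined_names),
                          resseqs=list(system.residue_seqs) + [9001] * 4,
                          resnames=list(system.residue_names) + ["ALA"] * 4,
                          lipid_ids=list(system.lipid_ids) + [-1] * 4)
        comb.roles = np.array(list(system.roles) + ["protein"] * 4,
                              dtype=object)
        zmid = frame.box[2] / 2
        sq = np.array([[30, 30, zmid], [40, 30, zmid],
                       [40, 40, zmid], [30, 40, zmid]])
        fr = mg.Frame(coords=np.vstack([frame.coords, sq]), box=frame.box)
        apl = area_per_lipid([fr], comb, probe_radius=0.0)
        expect = (frame.box[0] * frame.box[1] - 100.0) \
            / truth.lipids_per_leaflet
        assert apl.mean == pytest.approx(expect, abs=1e-9)


class TestContacts:
    def _charged_pair_system(self, pa, pb):
        n = len(pa) + len(pb)
        sys = toy_system(n, names=["NZ"] * len(pa) + ["O11"] * len(pb))
        sys.roles = np.array(["protein"] * len(pa) + ["lipid"] * len(pb),
                             dtype=object)
        sys.charge_class = np.array(["pos"] * len(pa) + ["neg"] * len(pb),
                                    dtype=object)
        return sys

    @pytest.mark.parametrize("d,expected", [(4.4, 1), (4.5, 0), (4.6, 0)])
    def test_strict_cutoff(self, d, expected):
        pa = np.array([[0.0, 0.0, 0.0]])
        pb = np.array([[d, 0.0, 0.0]])
        sys = self._charged_pair_system(pa, pb)
        fr = frame_of(np.vstack([pa, pb]), box=[50, 50, 50])
        cs = count_electrostatic_contacts(
            [fr], sys, AtomSet(np.array([0])), AtomSet(np.array([1])))
        assert cs.counts[0] == expected

    def test_matches_brute_force_oracle(self):
        for _ in range(25):
            na, nb = RNG.integers(5, 40, size=2)
            box = np.array([22.0, 26.0, 60.0])
            pa = RNG.uniform(0, 1, (na, 3)) * box
            pb = RNG.uniform(0, 1, (nb, 3)) * box
            sys = self._charged_pair_system(pa, pb)
            fr = frame_of(np.vstack([pa, pb]), box=box)
            cs = count_electrostatic_contacts(
                [fr], sys, AtomSet(np.arange(na)),
                AtomSet(np.arange(na, na + nb)))
            assert cs.counts[0] == contact_count_oracle(pa, pb, box, 4.5)

    def test_stride_sampling(self):
        pa = np.array([[0.0, 0.0, 0.0]])
        pb = np.array([[1.0, 0.0, 0.0]])
        sys = self._charged_pair_system(pa, pb)
        frames = [frame_of(np.vstack([pa, pb]), box=[50, 50, 50], time=t)
                  for t in np.arange(0, 20, 2.0)]
        cs = count_electrostatic_contacts(
            [frames[k] for k in range(10)], sys, AtomSet(np.array([0])),
            AtomSet(np.array([1])), stride=4.0)
        assert list(cs.times) == [0.0, 4.0, 8.0, 12.0, 16.0]
        assert cs.mean == 1.0 and cs.sd == 0.0

    def test_empty_set_warns_and_returns_zeros(self, caplog):
        pa = np.array([[0.0, 0.0, 0.0]])
        sys = self._charged_pair_system(pa, pa)
        fr = frame_of(np.vstack([pa, pa]), box=[50, 50, 50])
        with caplog.at_level("WARNING", logger="memgate"):
            cs = count_electrostatic_contacts(
                [fr], sys, AtomSet(np.array([], dtype=int)),
                AtomSet(np.array([1])))
        assert cs.mean == 0.0
        assert "empty" in caplog.text

    def test_opposite_only_switch(self):
        pa = np.array([[0.0, 0.0, 0.0]])
        pb = np.array([[1.0, 0.0, 0.0]])
        sys = self._charged_pair_system(pa, pb)
        sys.charge_class = np.array(["pos", "pos"], dtype=object)
        fr = frame_of(np.vstack([pa, pb]), box=[50, 50, 50])
        both = count_electrostatic_contacts(
            [fr], sys, AtomSet(np.array([0])), AtomSet(np.array([1])))
        opp = count_electrostatic_contacts(
            [fr], sys, AtomSet(np.array([0])), AtomSet(np.array([1])),
            opposite_only=True)
        assert both.counts[0] == 1 and opp.counts[0] == 0


class TestRdf:
    def test_uniform_placement_plateau(self):
        """g(r) of seeded uniform points around mid-plane probes is 1
        within 5% beyond the correlation range."""
        box = np.array([60.0, 60.0, 60.0])
        na, nb, n_frames = 40, 8000, 20
        a_xy = RNG.uniform(0, 60, (na, 2))
        a_z = RNG.uniform(28, 32, na)
        pa = np.column_stack([a_xy, a_z])
        sys = toy_system(na + nb)
        frames = []
        for _ in range(n_frames):
            pb = RNG.uniform(0, 1, (nb, 3)) * box
            frames.append(frame_of(np.vstack([pa, pb]), box=box))
        rdf = radial_distribution(frames, sys, AtomSet(np.arange(na)),
                                  AtomSet(np.arange(na, na + nb)),
                                  r_max=25.0, bin_width=1.0)
        plateau = rdf.g[rdf.r >= 5.0]
        assert np.abs(plateau - 1.0).max() <= 0.05

    def test_hard_core_exclusion_zone(self):
        box = np.array([40.0, 40.0, 40.0])
        pa = np.array([[20.0, 20.0, 20.0]])
        pb = RNG.uniform(0, 1, (4000, 3)) * box
        d = np.linalg.norm(pb - pa[0], axis=1)
        pb = pb[d >= 4.0]
        sys = toy_system(1 + len(pb))
        fr = frame_of(np.vstack([pa, pb]), box=box)
        rdf = radial_distribution([fr], sys, AtomSet(np.array([0])),
                                  AtomSet(np.arange(1, 1 + len(pb))),
                                  r_max=15.0, bin_width=0.5)
        assert np.all(rdf.g[rdf.r < 3.9] == 0.0)

    def test_clustered_first_peak_exceeds_dispersed(self):
        box = np.array([50.0, 50.0, 50.0])
        pa = np.array([[25.0, 25.0, 25.0]])
        disp = RNG.uniform(5, 45, (600, 3))
        shell_dirs = RNG.normal(size=(600, 3))
        shell_dirs /= np.linalg.norm(shell_dirs, axis=1)[:, None]
        clus = pa[0] + shell_dirs * RNG.uniform(4.0, 6.0, (600, 1))
        out = {}
        for label, pb in (("clustered", clus), ("dispersed", disp)):
            sys = toy_system(1 + len(pb))
            fr = frame_of(np.vstack([pa, pb]), box=box)
            rdf = radial_distribution([fr], sys, AtomSet(np.array([0])),
                                      AtomSet(np.arange(1, 1 + len(pb))),
                                      r_max=20.0, bin_width=0.5)
            out[label] = rdf.g[(rdf.r >= 4) & (rdf.r <= 6)].max()
        assert out["clustered"] > out["dispersed"]

    def test_r_max_exceeding_half_box_raises(self):
        sys = toy_system(2)
        fr = frame_of([[0, 0, 0], [5, 5, 5]], box=[20, 20, 20])
        with pytest.raises(mg.MemgateError):
            radial_distribution([fr], sys, AtomSet(np.array([0])),
                                AtomSet(np.array([1])), r_max=15.0)
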