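"""Covered-area metric, ring angles and population-map bookkeeping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peptifiber import (
    AssociationRecord,
    GeneratorSpec,
    ModelError,
    analyze_frame,
    analyze_trajectory,
    covered_area,
    make_association_trajectory,
    make_dimer_topology,
    make_monomer,
    monte_carlo_sasa,
    population_map,
    ring_angle,
    sasa,
)
from peptifiber.association import covered_atom_areas

from conftest import build_model


def _dimer_two_atoms(sep):
    return build_model(
        [[0, 0, 0], [sep, 0, 0]],
        radii=[0.17, 0.17],
        monomer_ids=[1, 2],
        regions=["aromatic", "aromatic"],
    )


class TestCoveredArea:
    def test_separated_monomers_zero_everywhere(self):
        """Beyond occlusion range every region's covered area is exactly 0."""
        d = _dimer_two_atoms(2.0)
        for m in (1, 2):
            for region in ("all", "aromatic"):
                assert covered_area(d, m, region) == 0.0

    def test_single_atom_contact_matches_mc_oracle(self):
        """Covered area of touching single-atom monomers equals the
        isolated-sphere area minus the two-sphere accessible area (MC)."""
        d = _dimer_two_atoms(0.35)
        iso = 4 * np.pi * (0.17 + 0.14) ** 2
        mc_pair = monte_carlo_sasa(d, n_samples=500_000, rng=5)
        expected = iso - mc_pair[0]
        got = covered_area(d, 1)
        assert got == pytest.approx(expected, rel=0.02)

    def test_aromatic_only_contact_partition(self, template):
        """If only aromatic-tagged atoms are occluded, CA_p = 0 and CA = CA_a."""
        topo = make_dimer_topology(template)
        # bring partner's aromatic slab near monomer 1's rings, backbone far
        partner = template.coords.copy()
        partner[:, 2] += 0.45
        partner[:, 0] -= 0.0
        d = topo.with_coords(np.vstack([template.coords, partner]))
        per_atom = covered_atom_areas(d)
        ca1 = per_atom[d.monomer_mask(1)].sum()
        ca1a = per_atom[d.region_mask("aromatic", 1)].sum()
        ca1p = per_atom[d.region_mask("peptide", 1)].sum()
        ca1o = per_atom[d.region_mask("other", 1)].sum()
        assert ca1 == pytest.approx(ca1a + ca1p + ca1o, abs=1e-9)

    def test_cat_symmetric_under_monomer_swap(self, template):
        topo = make_dimer_topology(template)
        partner = template.coords + np.array([0.0, 0.0, 0.4])
        d = topo.with_coords(np.vstack([template.coords, partner]))
        swapped = topo.with_coords(np.vstack([partner, template.coords]))
        cat = covered_area(d, 1) + covered_area(d, 2)
        cat_swapped = covered_area(swapped, 1) + covered_area(swapped, 2)
        assert cat == pytest.approx(cat_swapped, abs=1e-9)

    def test_requires_two_monomers(self, template):
        with pytest.raises(ModelError, match="2 monomers"):
            covered_area(template, 1)

    def test_unknown_monomer(self):
        with pytest.raises(ModelError, match="not present"):
            covered_area(_dimer_two_atoms(0.4), 3)


class TestRingAngle:
    @staticmethod
    def _ring(center, rot=None):
        ang = np.radians(60.0 * np.arange(6))
        pts = np.column_stack([0.14 * np.cos(ang), 0.14 * np.sin(ang), np.zeros(6)])
        if rot is not None:
            pts = pts @ rot.as_matrix().T
        return pts + center

    def _two_ring_model(self, rot):
        coords = np.vstack([self._ring([0, 0, 0]), self._ring([1.0, 0, 0], rot)])
        return build_model(
            coords,
            monomer_ids=[1] * 12,
            regions=["aromatic"] * 12,
            markers={"ringPhe": np.arange(6), "ringMut": np.arange(6, 12)},
        )

    def test_coplanar_rings_zero(self):
        m = self._two_ring_model(None)
        assert ring_angle(m, ("ringPhe", 1), ("ringMut", 1)) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_rings(self):
        m = self._two_ring_model(Rotation.from_rotvec([np.pi / 2, 0, 0]))
        assert ring_angle(m, ("ringPhe", 1), ("ringMut", 1)) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [30.0, 60.0, 120.0, 150.0])
    def test_rotation_about_in_plane_axis_recovered(self, angle):
        """Rotating a ring by theta about an in-plane axis gives theta back,
        including angles beyond 90 (oriented-normal convention)."""
        rot = Rotation.from_rotvec(np.radians(angle) * np.array([1.0, 0, 0]))
        m = self._two_ring_model(rot)
        assert ring_angle(m, ("ringPhe", 1), ("ringMut", 1)) == pytest.approx(angle, abs=1e-6)

    def test_collinear_ring_rejected(self):
        coords = np.vstack(
            [np.column_stack([np.linspace(0, 0.5, 6), np.zeros(6), np.zeros(6)]),
             self._ring([1.0, 0, 0])]
        )
        m = build_model(
            coords, monomer_ids=[1] * 12,
            markers={"ringPhe": np.arange(6), "ringMut": np.arange(6, 12)},
        )
        with pytest.raises(ModelError, match="collinear"):
            ring_angle(m, ("ringPhe", 1), ("ringMut", 1))


class TestAnalyzeTrajectory:
    def test_contact_vs_dissociated_records(self):
        """Dissociated frame records CAT=0; contact frame CAT>0."""
        spec = GeneratorSpec(seed=2, n_frames=2, contact_fraction=0.5, noise_sigma=0.0)
        traj, truth = make_association_trajectory(spec)
        recs = analyze_trajectory(traj, n_points=240)
        by_contact = {bool(truth.in_contact[i]): recs[i] for i in range(2)}
        assert by_contact[False].CAT == 0.0
        assert by_contact[True].CAT > 0.0

    def test_additivity_invariants(self):
        """CAT = CA1 + CA2 and region partition hold on every frame."""
        spec = GeneratorSpec(seed=4, n_frames=10, contact_fraction=0.5, mode="mixed")
        traj, _ = make_association_trajectory(spec)
        for r in analyze_trajectory(traj, n_points=240):
            assert r.CAT == pytest.approx(r.CA1 + r.CA2, abs=1e-6)
            assert r.CATa == pytest.approx(r.CA1a + r.CA2a, abs=1e-6)
            assert r.CATp == pytest.approx(r.CA1p + r.CA2p, abs=1e-6)
            assert r.CA1 == pytest.approx(r.CA1a + r.CA1p + r.CA1o, abs=1e-6)
            assert r.CA2 == pytest.approx(r.CA2a + r.CA2p + r.CA2o, abs=1e-6)

    def test_identical_frames_identical_records(self, template):
        topo = make_dimer_topology(template)
        frame = np.vstack([template.coords, template.coords + [0, 0, 0.45]])
        from peptifiber import Trajectory

        traj = Trajectory(topology=topo, frames=np.stack([frame, frame]))
        r0, r1 = analyze_trajectory(traj, n_points=240)
        for f in ("CAT", "CATa", "CATp", "D1", "D2", "D3", "theta1", "theta2"):
            assert getattr(r0, f) == getattr(r1, f)

    def test_contact_fraction_recovered(self):
        """Planted contact fraction shows up as the share of CAT>0 frames."""
        spec = GeneratorSpec(seed=8, n_frames=40, contact_fraction=0.5)
        traj, truth = make_association_trajectory(spec)
        recs = analyze_trajectory(traj, n_points=120)
        n_zero = sum(1 for r in recs if r.CAT == 0.0)
        assert n_zero == int((~truth.in_contact).sum()) == 20

    def test_peptide_contact_mode_contrast(self):
        """Peptide-contact frames have CATa = 0 with CATp > 0."""
        spec = GeneratorSpec(seed=9, n_frames=4, contact_fraction=1.0, mode="peptide-contact")
        traj, _ = make_association_trajectory(spec)
        for r in analyze_trajectory(traj, n_points=240):
            assert r.CATa == 0.0
            assert r.CATp > 0.0


class TestPopulationMap:
    @staticmethod
    def _record(i, cat, cata=None, **kw):
        cata = cat / 2 if cata is None else cata
        base = dict(
            frame_index=i, CA1=cat / 2, CA2=cat / 2, CAT=cat,
            CA1a=cata / 2, CA2a=cata / 2, CATa=cata,
            CA1p=0.0, CA2p=0.0, CATp=0.0, CA1o=0.0, CA2o=0.0,
        )
        base.update(kw)
        return AssociationRecord(**base)

    def test_zero_exclusion_bookkeeping(self):
        """4 of 10 frames at CAT=0 -> 40% excluded, map mass 100% over 6."""
        records = [self._record(i, 0.0) for i in range(4)]
        records += [self._record(4 + i, 1.0 + 0.1 * i) for i in range(6)]
        pm = population_map(records, x="CAT", y="CATa", bin_width=0.1)
        assert pm.excluded_zero_fraction == pytest.approx(40.0)
        assert pm.values.sum() == pytest.approx(100.0, abs=1e-6)
        assert pm.n_included == 6

    def test_symmetric_records_on_diagonal(self):
        """CA1a = CA2a in every frame puts all mass on diagonal cells."""
        records = [self._record(i, 2.0, cata=1.0 + 0.2 * i) for i in range(5)]
        pm = population_map(records, x="CA1a", y="CA2a", bin_width=0.1)
        nz = np.argwhere(pm.values > 0)
        assert len(nz) > 0
        assert all(i == j for i, j in nz)

    def test_rebinning_preserves_mass(self):
        rng = np.random.default_rng(0)
        records = [self._record(i, c) for i, c in enumerate(rng.uniform(0.5, 3.0, 50))]
        for bw in (0.1, 0.05):
            pm = population_map(records, bin_width=bw)
            assert pm.values.sum() == pytest.approx(100.0, abs=1e-6)

    def test_aromatic_stack_modal_cell_high(self):
        """The aromatic-stack ensemble's CA2a-vs-CA1a mode sits at or above
        (1 nm^2, 1 nm^2) — a single high-density aromatic-association region."""
        spec = GeneratorSpec(seed=12, n_frames=30, contact_fraction=0.8)
        traj, _ = make_association_trajectory(spec)
        recs = analyze_trajectory(traj, n_points=240)
        pm = population_map(recs, x="CA1a", y="CA2a", bin_width=0.1)
        x, y = pm.modal_cell()
        assert x >= 1.0 and y >= 1.0

    def test_errors(self):
        with pytest.raises(ModelError, match="coordinate"):
            population_map([self._record(0, 1.0)], x="bogus", y="CAT")
        with pytest.raises(ModelError, match="CAT = 0"):
            population_map([self._record(0, 0.0)])
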