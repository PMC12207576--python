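"""Contact counting, the stationary-phase limit and retention statistics."""

import numpy as np
import pytest

from rplcpore.contacts import (
    RBP_REFERENCE,
    RDF,
    ContactProfile,
    ContactRadius,
    contact_profile,
    count_contacts,
    derive_rbp,
    reference_rbp,
    stationary_phase_limit,
    stationary_phase_summary,
)
from rplcpore.errors import (
    NoMinimumError,
    NoStationaryPhaseError,
    TruncationError,
    UndefinedAverageError,
    WindowError,
)
from rplcpore.profiles import DensityProfile
from rplcpore.synth import GeneratorConfig, TruncatedGaussianMixture, generate_slitpore

from conftest import brute_count_within, build_frame, simple_topology


def make_contact_profile(c_bp, bin_width=0.05, start_bin=0):
    c_bp = np.asarray(c_bp, float)
    n = len(c_bp) + start_bin
    edges = bin_width * np.arange(n + 1)
    full = np.full(n, np.nan)
    full[start_bin:] = c_bp
    visits = np.where(np.isnan(full), 0.0, 10.0)
    return ContactProfile(bin_edges=edges, c_bp=full, n_visits=visits, window_ns=40.0, n_windows=1)


def make_density(values, bin_width=0.05):
    values = np.asarray(values, float)
    edges = bin_width * np.arange(len(values) + 1)
    return DensityProfile(
        bin_edges=edges, values=values, label="analyte", n_frames=1,
        counts=values.copy(), bin_volume=1.0,
    )


class TestCountContacts:
    def _frame_with_beads(self, bead_offsets, analyte_z=2.0):
        com = np.array([2.0, 2.0, analyte_z])
        particles = [("CH2", "analyte", 0, tuple(com))]
        for k, off in enumerate(bead_offsets):
            particles.append(("CH2", "bonded_phase", 1 + k, tuple(com + off)))
        return build_frame(particles), com

    def test_boundary_inclusive(self):
        # beads at 0.50, 0.79, 0.90 nm; r_bp = 0.79 -> 2 (r <= r_bp)
        frame, _ = self._frame_with_beads(
            [np.array([0.50, 0, 0]), np.array([0, 0.79, 0]), np.array([0, 0, 0.90])]
        )
        topo = simple_topology(frame)
        assert count_contacts(frame, 0, 0.79, topo) == 2

    def test_no_beads(self):
        frame = build_frame([("CH2", "analyte", 0, (2.0, 2.0, 2.0))])
        topo = simple_topology(frame)
        assert count_contacts(frame, 0, 0.79, topo) == 0

    def test_periodic_image_counted(self):
        # bead across the x boundary: direct distance 3.7, image distance 0.3
        frame = build_frame(
            [("CH2", "analyte", 0, (0.1, 2.0, 2.0)), ("CH2", "bonded_phase", 1, (3.8, 2.0, 2.0))]
        )
        topo = simple_topology(frame)
        assert count_contacts(frame, 0, ContactRadius(0.79), topo) == 1

    def test_endcaps_excluded_by_default(self):
        frame = build_frame(
            [
                ("CH2", "analyte", 0, (2.0, 2.0, 2.0)),
                ("CH2", "bonded_phase", 1, (2.3, 2.0, 2.0)),
                ("CH3", "endcap", 2, (2.0, 2.3, 2.0)),
            ]
        )
        topo = simple_topology(frame)
        assert count_contacts(frame, 0, 0.79, topo) == 1
        assert count_contacts(frame, 0, 0.79, topo, include_endcaps=True) == 2

    def test_matches_brute_force(self, rng):
        box = np.array([4.0, 4.0, 12.0])
        for _ in range(20):
            n_beads = int(rng.integers(5, 60))
            beads = rng.random((n_beads, 3)) * np.array([4.0, 4.0, 3.0]) + np.array([0, 0, 1.0])
            com = rng.random(3) * np.array([4.0, 4.0, 2.0]) + np.array([0, 0, 1.0])
            particles = [("CH2", "analyte", 0, tuple(com))] + [
                ("CH2", "bonded_phase", 1 + k, tuple(beads[k])) for k in range(n_beads)
            ]
            frame = build_frame(particles, box=box)
            topo = simple_topology(frame)
            r = 0.5 + 0.5 * rng.random()
            got = count_contacts(frame, 0, r, topo)
            want = brute_count_within(com, beads, r, box)
            assert got == want


class TestContactProfile:
    def test_fixed_molecule_constant_contacts(self):
        # one analyte at z = 0.7 surrounded by 12 beads within r
        com = np.array([2.0, 2.0, 1.7])
        particles = [("CH2", "analyte", 0, tuple(com))]
        for k in range(12):
            ang = 2 * np.pi * k / 12
            off = 0.3 * np.array([np.cos(ang), np.sin(ang), 0.0])
            particles.append(("CH2", "bonded_phase", 1 + k, tuple(com + off)))
        frames = [build_frame(particles, time=t * 0.1) for t in range(4)]
        topo = simple_topology(frames[0])
        prof = contact_profile(frames, 0.79, topo, window_ns=0.4)
        bin_idx = int(0.7 / 0.05)
        assert prof.c_bp[bin_idx] == pytest.approx(12.0)
        others = np.delete(prof.c_bp, bin_idx)
        assert np.all(np.isnan(others))

    def test_two_molecules_same_bin_average(self):
        p1 = np.array([1.0, 1.0, 1.72])
        p2 = np.array([3.0, 3.0, 1.73])
        particles = [("CH2", "analyte", 0, tuple(p1)), ("CH2", "analyte", 1, tuple(p2))]
        for k in range(10):  # 10 beads near molecule 0
            particles.append(("CH2", "bonded_phase", 2 + k, tuple(p1 + [0.05 * (k + 1), 0, 0])))
        for k in range(6):  # 6 beads near molecule 1
            particles.append(("CH2", "bonded_phase", 12 + k, tuple(p2 + [0.05 * (k + 1), 0, 0])))
        frames = [build_frame(particles, time=0.0), build_frame(particles, time=0.5)]
        topo = simple_topology(frames[0])
        prof = contact_profile(frames, 0.6, topo, window_ns=1.0)
        bin_idx = int(0.72 / 0.05)
        assert prof.c_bp[bin_idx] == pytest.approx(8.0)

    def test_window_error(self):
        frame = build_frame([("CH2", "analyte", 0, (2, 2, 2))])
        topo = simple_topology(frame)
        with pytest.raises(WindowError, match="smaller window"):
            contact_profile([frame], 0.79, topo, window_ns=40.0)


class TestStationaryPhaseLimit:
    def test_linear_interpolation_hand_value(self):
        prof = make_contact_profile([12.0, 6.0, 2.0, 0.9, 0.4])
        # last bin >= 1 is index 2 (center 0.125); crossing toward 0.9
        expected = 0.125 + 0.05 * (2.0 - 1.0) / (2.0 - 0.9)
        assert stationary_phase_limit(prof) == pytest.approx(expected)

    def test_step_profile_crossing_at_edge(self):
        prof = make_contact_profile([5.0, 5.0, 0.0, 0.0])
        assert stationary_phase_limit(prof) == pytest.approx(0.10)  # shared bin edge

    def test_scaling_moves_limit_outward(self):
        c = np.array([8.0, 4.0, 2.0, 1.2, 0.7, 0.3])
        z1 = stationary_phase_limit(make_contact_profile(c))
        z2 = stationary_phase_limit(make_contact_profile(2.0 * c))
        assert z2 > z1

    def test_everywhere_below_one(self):
        with pytest.raises(NoStationaryPhaseError):
            stationary_phase_limit(make_contact_profile([0.5, 0.3, 0.1]))

    def test_never_below_one(self):
        with pytest.raises(TruncationError):
            stationary_phase_limit(make_contact_profile([5.0, 4.0, 3.0]))


class TestStationaryPhaseSummary:
    def test_hand_arithmetic(self):
        cprof = make_contact_profile([10.0, 6.0, 2.0])
        rho = make_density([1.0, 2.0, 1.0])
        s = stationary_phase_summary(cprof, rho, z_sp=0.15)
        assert s.mean_contacts == pytest.approx(24.0 / 4.0)

    def test_single_density_bin_position(self):
        cprof = make_contact_profile([10.0, 6.0, 2.0])
        rho = make_density([0.0, 5.0, 0.0])
        s = stationary_phase_summary(cprof, rho, z_sp=0.15)
        assert s.mean_position == pytest.approx(0.075)  # center of bin 1
        assert s.mean_contacts == pytest.approx(6.0)

    def test_density_shift_outward_decreases_contacts(self):
        cprof = make_contact_profile([10.0, 6.0, 2.0])
        s_in = stationary_phase_summary(cprof, make_density([2.0, 1.0, 1.0]), z_sp=0.15)
        s_out = stationary_phase_summary(cprof, make_density([1.0, 1.0, 2.0]), z_sp=0.15)
        assert s_out.mean_contacts < s_in.mean_contacts

    def test_rescaling_invariance_and_bounds(self):
        cprof = make_contact_profile([9.0, 5.0, 2.0])
        rho = make_density([1.0, 3.0, 2.0])
        s1 = stationary_phase_summary(cprof, rho, z_sp=0.15)
        s2 = stationary_phase_summary(cprof, make_density(np.array([1.0, 3.0, 2.0]) * 11), z_sp=0.15)
        assert s1.mean_contacts == pytest.approx(s2.mean_contacts)
        assert 2.0 <= s1.mean_contacts <= 9.0

    def test_missing_bins_with_density_raise(self):
        cprof = make_contact_profile([10.0, 6.0], start_bin=1)  # bin 0 missing
        rho = make_density([1.0, 1.0, 1.0])
        with pytest.raises(UndefinedAverageError, match="missing"):
            stationary_phase_summary(cprof, rho, z_sp=0.15)

    def test_zero_density_raises(self):
        cprof = make_contact_profile([10.0, 6.0, 2.0])
        with pytest.raises(UndefinedAverageError):
            stationary_phase_summary(cprof, make_density([0.0, 0.0, 0.0]), z_sp=0.15)


class TestContactRadius:
    def test_reference_table_printed_values(self):
        assert reference_rbp("phenol", "MeOH").r_bp == 0.79
        assert reference_rbp("naphthalene", "MeOH").r_bp == 0.84
        assert reference_rbp("ethylbenzene", "ACN").r_bp == 0.83
        assert reference_rbp("phenol", "ACN").r_bp == 0.78
        assert reference_rbp("benzene", "MeOH").r_bp == 0.79
        assert reference_rbp("benzyl_alcohol", "MeOH").r_bp == 0.80
        assert reference_rbp("acetophenone", "ACN").r_bp == 0.81
        assert all(0.5 <= v <= 1.2 for v in RBP_REFERENCE.values())

    def test_sanity_window(self):
        with pytest.raises(ValueError):
            ContactRadius(1.5)

    def _synthetic_rdf(self):
        r = np.arange(0.005, 1.5, 0.01)
        g = 2.0 * np.exp(-((r - 0.5) ** 2) / (2 * 0.07**2)) + (
            1.0 - np.exp(-((r - 0.8) ** 2) / (2 * 0.1**2))
        )
        return RDF(r=r, g=g)

    def test_derive_rbp_constructed_minimum(self):
        assert derive_rbp([self._synthetic_rdf()]).r_bp == pytest.approx(0.80)

    def test_averaging_identity(self):
        rdf = self._synthetic_rdf()
        assert derive_rbp([rdf, rdf]).r_bp == derive_rbp([rdf]).r_bp

    def test_monotone_rdf_raises(self):
        r = np.arange(0.005, 1.5, 0.01)
        with pytest.raises(NoMinimumError):
            derive_rbp([RDF(r=r, g=1.0 - np.exp(-r / 0.3))])


class TestSemiAnalyticRecovery:
    def test_contact_profile_matches_density_integral(self):
        """C_BP(z) equals the integral of the bead density over the contact
        sphere (Monte-Carlo vs quadrature oracle)."""
        mixture = TruncatedGaussianMixture(
            weights=(0.0, 1.0, 0.0), means=(0.3, 0.7, 1.6), sigmas=(0.05, 0.25, 0.1), lo=0.0, hi=2.0
        )
        cfg = GeneratorConfig(
            seed=31, n_frames=300, compound="benzene", n_analyte=10,
            n_bp_per_surface=400, n_endcap_per_surface=0, n_residual_oh_per_surface=0,
            n_silica_per_surface=0, n_water=0, n_os=0,
            analyte_mixture=mixture,
        )
        frames, topo, truth = generate_slitpore(cfg)
        r = 0.8
        prof = contact_profile(frames, r, topo, window_ns=300 * 0.4)

        def expected(z):
            zp = np.linspace(z - r, z + r, 400)
            rho = truth.bp_density(np.clip(zp, 0.0, None)) * (zp >= 0)
            disc = np.pi * (r**2 - (z - zp) ** 2)
            return np.trapezoid(rho * disc, zp)

        centers = prof.centers
        for i in np.flatnonzero(prof.n_visits >= 300):
            e_mid = expected(centers[i])
            # tolerance: 3 * Poisson SE + within-bin variation of the expectation
            se = np.sqrt(max(e_mid, 0.1) / prof.n_visits[i])
            slack = abs(expected(centers[i] + 0.025) - expected(centers[i] - 0.025)) / 2
            assert abs(prof.c_bp[i] - e_mid) < 3 * se + slack
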