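"""Concentration profiles, ion-counting excess and helicoidal densities."""

import numpy as np
import pytest

from ionatmos import (
    MOLAR_TO_PER_NM3,
    ConcentrationProfile,
    GeneratorSpec,
    IonFrames,
    RadialLaw,
    SpeciesSpec,
    electroneutrality_residual,
    fraction_excess,
    helicoidal_density,
    ion_excess,
    radial_profile,
    sample_diffuse_ions,
)


class TestRadialProfile:
    def test_uniform_gas_gives_flat_profile(self, dna_model):
        conc, r_max, h = 0.2, 4.0, 10.0
        spec = GeneratorSpec(
            model=dna_model,
            species=[SpeciesSpec("NA", +1, RadialLaw.uniform(conc, r_max))],
            r_max=r_max, z_range=(0.0, h), n_frames=400, seed=42,
        )
        frames = sample_diffuse_ions(spec)
        prof = radial_profile(frames, bin_width=0.2, r_max=r_max,
                              axial_window=(0.0, h))
        # every bin within 3 sigma Poisson of the uniform concentration
        edges = prof.edges
        shell_vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * h
        expect = conc * shell_vol * MOLAR_TO_PER_NM3 * prof.n_frames
        observed = prof.counts["NA"] * prof.n_frames
        pulls = (observed - expect) / np.sqrt(expect)
        assert np.all(np.abs(pulls) < 3.5)
        assert prof.c_bulk["NA"] == pytest.approx(conc, rel=0.02)

    def test_single_ion_lands_in_its_bin(self, dna_model):
        frames = IonFrames(positions={"NA": [np.array([[0.5, 0.0, 1.0]])]})
        prof = radial_profile(frames, bin_width=0.1, r_max=1.0,
                              axial_window=(0.0, 2.0))
        counts = prof.counts["NA"]
        assert counts[5] == 1  # bin [0.5, 0.6)
        assert counts.sum() == 1

    def test_edge_ion_goes_to_upper_bin(self, dna_model):
        # 0.5 is an exact bin edge for width 0.25; half-open binning puts
        # the ion in the upper bin [0.5, 0.75)
        frames = IonFrames(positions={"NA": [np.array([[0.5, 0.0, 1.0]])]})
        prof = radial_profile(frames, bin_width=0.25, r_max=1.0,
                              axial_window=(0.0, 2.0))
        assert prof.counts["NA"][2] == 1

    def test_rejects_empty_inputs(self, dna_model):
        frames = IonFrames(positions={"NA": [np.zeros((0, 3))]})
        with pytest.raises(ValueError):
            radial_profile(frames, bin_width=0.1, r_max=1.0,
                           axial_window=(1.0, 1.0))
        with pytest.raises(ValueError):
            radial_profile(IonFrames(positions={"NA": []}), bin_width=0.1,
                           r_max=1.0, axial_window=(0.0, 1.0))

    def test_recovers_generating_pb_profile(self, dna_solution):
        """Ions sampled from a PB concentration profile are binned back into
        a profile consistent with the generator (reduced chi^2 in [0.5, 2])."""
        sol = dna_solution
        r_max, h = sol.r[-1], sol.cylinder.length
        spec = GeneratorSpec(
            model=None, species=[
                SpeciesSpec("NA", +1, RadialLaw.from_pb_solution(sol, "NA"))
            ],
            r_max=r_max, z_range=(0.0, h), n_frames=1500, seed=5,
        )
        frames = sample_diffuse_ions(spec)
        prof = radial_profile(frames, bin_width=0.05, r_max=r_max,
                              axial_window=(0.0, h))
        # bin-averaged expectation from the generating law (grid includes
        # the law's breakpoints so the hard-core step integrates exactly)
        law = spec.species[0].radial_law
        rr = np.union1d(np.linspace(0, r_max, 20001),
                        law.r[(law.r >= 0) & (law.r <= r_max)])
        w = law.conc_at(rr) * rr
        cum = np.concatenate([[0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                             * np.diff(rr))])
        per_bin = np.interp(prof.edges, rr, cum)
        expect = (np.diff(per_bin) * 2 * np.pi * h * MOLAR_TO_PER_NM3
                  * prof.n_frames)
        observed = prof.counts["NA"] * prof.n_frames
        mask = expect > 10
        chi2 = np.sum((observed[mask] - expect[mask]) ** 2 / expect[mask])
        ndof = int(mask.sum())
        assert 0.5 < chi2 / ndof < 2.0


class TestIonExcess:
    def test_constant_profile_has_zero_excess(self):
        r = np.linspace(0.05, 5.0, 100)
        prof = ConcentrationProfile(
            r=r, concentrations={"NA": np.full_like(r, 0.1)}, h=10.0,
            c_bulk={"NA": 0.1},
        )
        exc = ion_excess(prof, "NA")
        assert np.allclose(exc.gamma_of_r, 0.0)
        assert exc.total == 0.0

    def test_step_profile_matches_hand_integral(self):
        """c = 2 c_inf inside 1 nm, c_inf outside:
        Gamma = N_A V_f h pi (1 nm)^2 c_inf."""
        c_inf, h = 0.1, 10.0
        r = np.arange(0.0025, 5.0, 0.005)
        c = np.where(r < 1.0, 2 * c_inf, c_inf)
        prof = ConcentrationProfile(r=r, concentrations={"NA": c}, h=h,
                                    c_bulk={"NA": c_inf})
        expected = MOLAR_TO_PER_NM3 * h * np.pi * 1.0**2 * c_inf
        assert ion_excess(prof, "NA").total == pytest.approx(expected,
                                                             rel=0.01)

    def test_depletion_yields_negative_gamma(self, dna_solution):
        prof = ConcentrationProfile.from_pb_solution(dna_solution)
        assert ion_excess(prof, "CL").total < 0
        assert ion_excess(prof, "NA").total > 0

    def test_no_plateau_flags_result(self):
        r = np.linspace(0.05, 5.0, 100)
        c = 0.1 + 0.05 * r  # steadily rising, no plateau
        prof = ConcentrationProfile(r=r, concentrations={"NA": c}, h=10.0,
                                    c_bulk={"NA": 0.3})
        with pytest.warns(UserWarning, match="plateau"):
            exc = ion_excess(prof, "NA")
        assert exc.flagged

    def test_negative_concentration_rejected(self):
        r = np.linspace(0.05, 5.0, 10)
        with pytest.raises(ValueError, match="negative"):
            ConcentrationProfile(r=r, concentrations={"NA": r - 1.0}, h=10.0,
                                 c_bulk={"NA": 0.1})


class TestFractionExcess:
    def test_monovalent_fractions_sum_to_one_under_closure(self):
        # constructed exact balance: 50 - (-14) = 64
        gp = fraction_excess(50.0, +1, 64.0)
        gm = fraction_excess(-14.0, -1, 64.0)
        assert gp + gm == pytest.approx(1.0)

    def test_counterion_only_limit(self):
        assert fraction_excess(64.0, +1, 64.0) == 1.0

    def test_divalent_arithmetic(self):
        assert fraction_excess(28.0, +2, 64.0) == pytest.approx(2 * 28 / 64)
        assert fraction_excess(28.0, +2, 64.0) == pytest.approx(0.875)

    def test_anion_reported_positive(self):
        assert fraction_excess(-14.0, -1, 64.0) == pytest.approx(14 / 64)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            fraction_excess(10.0, +1, 0.0)


class TestElectroneutralityResidual:
    def test_constructed_balances(self):
        assert electroneutrality_residual(
            {"NA": 50.0, "CL": -14.0}, {"NA": +1, "CL": -1}, 64.0
        ) == pytest.approx(0.0)
        assert electroneutrality_residual(
            {"NA": 64.0, "CL": 0.0}, {"NA": +1, "CL": -1}, 64.0
        ) == pytest.approx(0.0)

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            electroneutrality_residual({"NA": 64.0}, {"NA": +1}, 64.0)

    def test_pb_solution_closure(self, dna_solution):
        prof = ConcentrationProfile.from_pb_solution(dna_solution)
        gam = {lab: ion_excess(prof, lab).total for lab in ("NA", "CL")}
        res = electroneutrality_residual(gam, {"NA": +1, "CL": -1}, 64.0)
        assert abs(res) <= 0.01


class TestHelicoidalDensity:
    def _phosphate_helix_frames(self, model, n_pairs=30):
        """Ions planted exactly on the O1P shell at the phosphate phase
        angle, following the helical winding."""
        geom = model.geometry
        rho = geom.radius_nm["O1P"]
        phase = geom.phase_deg["O1P"] + 5.0  # half-bin off the 10-deg edges
        pts = []
        for p in range(1, n_pairs):
            th = np.radians(p * model.twist_per_bp + phase)
            pts.append([rho * np.cos(th), rho * np.sin(th),
                        p * model.rise_per_bp])
        return IonFrames(positions={"NA": [np.array(pts)]})

    def test_untwisting_collapses_the_helix_to_one_angle(self, dna_model):
        frames = self._phosphate_helix_frames(dna_model)
        hd = helicoidal_density(frames, dna_model, r_max=1.5, bin_width=0.1,
                                angle_bins=36)
        ang = hd.density["NA"].sum(axis=0)
        assert np.count_nonzero(ang) == 1  # single angular peak
        # without untwisting the same ions spread over many angles
        raw = np.degrees(np.arctan2(
            *[np.concatenate(frames.positions["NA"])[:, i] for i in (1, 0)]
        )) % 360.0
        assert len(np.unique((raw // 10).astype(int))) >= 10

    def test_uniform_gas_is_angularly_flat(self, dna_model):
        spec = GeneratorSpec(
            model=dna_model,
            species=[SpeciesSpec("NA", +1, RadialLaw.uniform(0.3, 3.0))],
            r_max=3.0, z_range=(0.0, 10.0), n_frames=600, seed=11,
        )
        frames = sample_diffuse_ions(spec)
        hd = helicoidal_density(frames, dna_model, r_max=3.0, bin_width=0.5,
                                angle_bins=12, axial_window=(0.0, 10.0))
        # compare angular variation to Poisson noise per cell, outer shells
        d = hd.density["NA"][2:]
        pulls = (d - d.mean(axis=1, keepdims=True)) / d.mean(axis=1,
                                                             keepdims=True)
        assert np.abs(pulls).max() < 0.2

    def test_angular_integral_recovers_radial_profile(self, dna_model):
        spec = GeneratorSpec(
            model=dna_model,
            species=[SpeciesSpec("NA", +1, RadialLaw.uniform(0.2, 3.0))],
            r_max=3.0, z_range=(0.0, 8.0), n_frames=100, seed=13,
        )
        frames = sample_diffuse_ions(spec)
        hd = helicoidal_density(frames, dna_model, r_max=3.0, bin_width=0.1,
                                angle_bins=36, axial_window=(0.0, 8.0))
        prof = radial_profile(frames, bin_width=0.1, r_max=3.0,
                              axial_window=(0.0, 8.0))
        collapsed = hd.angular_integral("NA")
        nz = prof.concentrations["NA"] > 0
        assert np.allclose(collapsed[nz], prof.concentrations["NA"][nz],
                           rtol=0.01)
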