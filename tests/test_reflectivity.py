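"""Specular reflectivity: optical-matrix correctness against closed forms,
stage stacks, instrument emulation and coverage recovery."""

import numpy as np
import pytest

from vesadh import reflectivity as nr
from vesadh.errors import (ConfigurationError, FitFailureError,
                           InvalidParameterError)
from vesadh.rsa import CoverageTrace

D2O = nr.CONTRASTS["D2O"]
SMW = nr.CONTRASTS["SMW"]
H2O = nr.CONTRASTS["H2O"]

Q = np.geomspace(0.006, 0.35, 120)


def fresnel(q, sld0, sld1, rough=0.0):
    """Analytic single-interface reflectivity (Nevot-Croce damped)."""
    k1 = (q / 2).astype(complex)
    k2 = np.sqrt((q / 2) ** 2 - 4 * np.pi * (sld1 - sld0) * 1e-6 + 0j)
    r = (k1 - k2) / (k1 + k2) * np.exp(-2 * k1 * k2 * rough**2)
    return np.abs(r) ** 2


def two_layer_closed_form(q, slds, d, rough):
    """Independent phase-coherent reflectance of fronting|layer1|layer2|backing.

    Written directly from the parallel-stack interference series (oracle for
    the recursive implementation); slds in 1e-6 A^-2.
    """
    slds = np.asarray(slds, dtype=complex) * 1e-6
    kz = np.sqrt((q[:, None] / 2) ** 2 - 4 * np.pi * (slds[None, :] - slds[0]))
    def rij(i, j, s):
        return (kz[:, i] - kz[:, j]) / (kz[:, i] + kz[:, j]) \
            * np.exp(-2 * kz[:, i] * kz[:, j] * s**2)
    r23 = rij(2, 3, rough[2])
    beta2 = np.exp(2j * kz[:, 2] * d[1])
    r12 = (rij(1, 2, rough[1]) + r23 * beta2) / (1 + rij(1, 2, rough[1]) * r23 * beta2)
    beta1 = np.exp(2j * kz[:, 1] * d[0])
    r01 = (rij(0, 1, rough[0]) + r12 * beta1) / (1 + rij(0, 1, rough[0]) * r12 * beta1)
    return np.abs(r01) ** 2


class TestAbeles:
    def test_matched_backing_reflects_nothing(self):
        # Si against Si-matched buffer: zero contrast, zero reflectivity
        R = nr.abeles(Q, [nr.SI_SLD, nr.SI_SLD], [], [0.0])
        assert np.all(R < 1e-25)

    def test_single_interface_equals_fresnel(self):
        for rough in (0.0, 4.0):
            R = nr.abeles(Q, [2.07, 6.36], [], [rough])
            assert np.allclose(R, fresnel(Q, 2.07, 6.36, rough),
                               rtol=1e-10, atol=1e-14)

    def test_total_reflection_below_critical_edge(self):
        # Si | D2O: q_c = sqrt(16 pi (sld_b - sld_f)) ~ 0.0147 A^-1
        qc = np.sqrt(16 * np.pi * (6.36 - 2.07) * 1e-6)
        q = np.linspace(0.006, 0.95 * qc, 20)
        R = nr.abeles(q, [2.07, 6.36], [], [0.0])
        assert np.allclose(R, 1.0, atol=1e-12)

    def test_two_layer_closed_form_oracle(self):
        slds = [2.07, 3.47, -0.2, 6.36]
        d = [12.0, 40.0]
        rough = [3.0, 2.0, 4.0]
        R = nr.abeles(Q, slds, d, rough)
        assert np.allclose(R, two_layer_closed_form(Q, slds, d, rough),
                           rtol=1e-10, atol=1e-16)

    def test_kiessig_fringes_of_thick_film(self):
        """800 A film: fringe spacing 2 pi / thickness ~ 0.0079 A^-1.

        Measured well above the critical edge, where refraction no longer
        distorts the fringe period.
        """
        q = np.linspace(0.06, 0.16, 4001)
        R = nr.abeles(q, [2.07, 4.0, 6.36], [800.0], [0.0, 0.0])
        logR = np.log(R)
        minima = [q[i] for i in range(1, len(q) - 1)
                  if logR[i] < logR[i - 1] and logR[i] < logR[i + 1]]
        spacing = np.diff(minima)
        assert np.mean(spacing) == pytest.approx(2 * np.pi / 800.0, rel=0.02)

    def test_inconsistent_arrays_rejected(self):
        with pytest.raises(InvalidParameterError):
            nr.abeles(Q, [1.0, 2.0, 3.0], [10.0], [0.0])


class TestStageStacks:
    def test_membrane_layer_sequence(self):
        stack = nr.build_stage_stack("membrane", nr.NATIVE01)
        assert [s.name for s in stack.slabs] == \
            ["SiO2", "head1_in", "chain1", "head1_out"]

    def test_mbp_stage_appends_protein_layer(self):
        stack = nr.build_stage_stack("membrane_mbp", nr.NATIVE01, contrast=D2O)
        assert stack.slabs[-1].name == "MBP_sbl"
        assert stack.slabs[-1].sld_dry == D2O.mbp_sld
        assert stack.slabs[-1].solvent_fraction == pytest.approx(0.97)

    def test_double_stage_encodes_coverage_in_chain_solvent(self):
        stack = nr.build_stage_stack("double", nr.MODIFIED1, eta=0.39,
                                     contrast=D2O)
        chain2 = next(s for s in stack.slabs if s.name == "chain2")
        assert chain2.solvent_fraction == pytest.approx(1 - 0.39)
        assert stack.slabs[-1].name == "diffuse"
        assert stack.slabs[-1].thickness == 800.0

    def test_second_membrane_tied_to_first(self):
        stack = nr.build_stage_stack("double", nr.NATIVE01, eta=0.3, contrast=D2O)
        by = {s.name: s for s in stack.slabs}
        assert by["chain2"].thickness == by["chain1"].thickness
        assert by["head2_in"].thickness == by["head1_out"].thickness

    def test_zero_coverage_collapses_to_water_spacer(self):
        """At eta = 0 the vesicle slabs are pure buffer: the stack is exactly
        the bare membrane, one merged water spacer, and the diffuse layer."""
        stack3 = nr.build_stage_stack("double", nr.NATIVE01, eta=0.0,
                                      contrast=D2O)
        base = nr.build_stage_stack("membrane", nr.NATIVE01, contrast=D2O)
        diffuse = stack3.slabs[-1]
        spacer_d = sum(s.thickness for s in stack3.slabs[4:-1])
        spacer = nr.Slab(spacer_d, 0.0, stack3.slabs[4].roughness, 1.0, "water")
        ref = nr.LayerStack(slabs=base.slabs + (spacer, diffuse),
                            stage="manual")
        R3 = nr.reflectivity(stack3, D2O, Q)
        Rref = nr.reflectivity(ref, D2O, Q)
        assert np.allclose(R3, Rref, rtol=1e-8)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ConfigurationError):
            nr.build_stage_stack("sandwich", nr.NATIVE01)


class TestInstrumentEmulation:
    def test_resolution_range(self):
        s = nr.resolution_sigma(np.array([nr.Q_MIN, nr.Q_MAX]))
        assert s[0] == pytest.approx(nr.Q_MIN * 0.02 / 2.3548)
        assert s[1] == pytest.approx(nr.Q_MAX * 0.10 / 2.3548)

    def test_zero_smearing_is_identity(self):
        stack = nr.build_stage_stack("membrane", nr.NATIVE01, contrast=D2O)
        assert np.allclose(nr.smear_reflectivity(stack, D2O, Q, dq=0.0),
                           nr.reflectivity(stack, D2O, Q))

    def test_smearing_conserves_critical_edge(self):
        stack = nr.build_stage_stack("membrane", nr.NATIVE01, contrast=D2O)
        qc = np.sqrt(16 * np.pi * (6.36 - 2.07) * 1e-6)
        q = np.linspace(0.008, 0.025, 400)
        sharp = nr.reflectivity(stack, D2O, q)
        smeared = nr.smear_reflectivity(stack, D2O, q)
        edge_sharp = q[np.argmin(np.gradient(sharp, q))]
        edge_smear = q[np.argmin(np.gradient(smeared, q))]
        assert abs(edge_smear - edge_sharp) <= 3 * nr.resolution_sigma(qc)

    def test_high_statistics_limit(self, rng):
        stack = nr.build_stage_stack("membrane", nr.NATIVE01, contrast=D2O)
        ds = nr.smear_and_noise(stack, D2O, rng, count_scale=1e14)
        smooth = nr.smear_reflectivity(stack, D2O, ds.q) + 2e-7
        assert np.allclose(ds.R, smooth, rtol=1e-3)

    def test_reproducible_from_seed(self):
        stack = nr.build_stage_stack("double", nr.NATIVE01, eta=0.3, contrast=D2O)
        a = nr.smear_and_noise(stack, D2O, np.random.default_rng(3))
        b = nr.smear_and_noise(stack, D2O, np.random.default_rng(3))
        assert np.array_equal(a.R, b.R)

    def test_independent_seeds_uncorrelated(self):
        stack = nr.build_stage_stack("double", nr.NATIVE01, eta=0.3, contrast=D2O)
        smooth = nr.smear_reflectivity(stack, D2O, nr.DEFAULT_Q_GRID) + 2e-7
        a = nr.smear_and_noise(stack, D2O, np.random.default_rng(4))
        b = nr.smear_and_noise(stack, D2O, np.random.default_rng(5))
        ra = (a.R - smooth) / a.dR
        rb = (b.R - smooth) / b.dR
        assert abs(np.corrcoef(ra, rb)[0, 1]) < 0.2


def make_noiseless_dataset(params, eta, contrast=D2O):
    q = nr.DEFAULT_Q_GRID
    stack = nr.build_stage_stack("double", params, eta=eta, contrast=contrast)
    r = nr.smear_reflectivity(stack, contrast, q) + 2e-7
    return nr.ReflectivityDataset(
        q=q, R=r, dR=np.maximum(r * 1e-4, 1e-14), dq=nr.resolution_sigma(q),
        metadata={"contrast": contrast.name, "background": 2e-7})


class TestCoverageFit:
    def test_noiseless_self_fit(self):
        ds = make_noiseless_dataset(nr.NATIVE01, eta=0.26)
        fit = nr.fit_coverage(ds, nr.NATIVE01)
        assert fit.eta.value == pytest.approx(0.26, abs=1e-3)

    def test_recovery_bias_and_spread_at_frame_noise(self):
        """Across the measured coverage range, single-frame fits recover eta
        with bias < 0.01 and spread <= 0.02 (the measured error scale)."""
        rng = np.random.default_rng(2024)
        for eta_true in (0.1, 0.26, 0.34, 0.39):
            vals = []
            for _ in range(8):
                stack = nr.build_stage_stack("double", nr.NATIVE01,
                                             eta=eta_true, contrast=D2O)
                ds = nr.smear_and_noise(stack, D2O, rng,
                                        count_scale=nr.KINETIC_COUNT_SCALE)
                vals.append(nr.fit_coverage(ds, nr.NATIVE01).eta.value)
            vals = np.array(vals)
            assert abs(vals.mean() - eta_true) < 0.01
            assert vals.std() <= 0.02

    def test_misspecified_template_fails_loudly(self):
        stack = nr.build_stage_stack("membrane", nr.NATIVE01, contrast=D2O)
        ds = nr.smear_and_noise(stack, D2O, np.random.default_rng(9))
        with pytest.raises(FitFailureError):
            nr.fit_coverage(ds, nr.NATIVE01)

    def test_contrast_consistency(self):
        """The same structure fitted at D2O/SMW/H2O returns one coverage."""
        for contrast in (D2O, SMW, H2O):
            stack = nr.build_stage_stack("double", nr.NATIVE01, eta=0.26,
                                         contrast=contrast)
            ds = nr.smear_and_noise(stack, contrast, np.random.default_rng(10))
            fit = nr.fit_coverage(ds, nr.NATIVE01, contrast=contrast)
            assert fit.eta.value == pytest.approx(0.26, abs=3 * fit.eta.err + 1e-3)


class TestKineticSeries:
    def test_constant_trace_gives_identical_curves(self):
        tr = CoverageTrace(times=np.arange(0, 3600.0, 60.0),
                           rho=np.full(60, 0.5), n_adsorbed=np.zeros(60))
        series = nr.simulate_kinetic_series(
            tr, nr.NATIVE01, alpha_f=0.15, cadence=600.0,
            rng=np.random.default_rng(0), count_scale=1e14)
        for ds in series[1:]:
            assert np.allclose(ds.R, series[0].R, rtol=1e-3)

    def test_roundtrip_recovers_forward_mapped_trace(self):
        """RSA trace -> synthetic frames -> fitted eta(t) within frame noise."""
        t = np.linspace(0, 7200.0, 100)
        rho = 0.6 * (1 - np.exp(-t / 1500.0))
        tr = CoverageTrace(times=t, rho=rho, n_adsorbed=np.zeros_like(t))
        series = nr.simulate_kinetic_series(tr, nr.MODIFIED1, alpha_f=0.2,
                                            cadence=900.0,
                                            rng=np.random.default_rng(8))
        errors = []
        for ds in series:
            fit = nr.fit_coverage(ds, nr.MODIFIED1)
            errors.append(fit.eta.value - ds.metadata["eta_true"])
        errors = np.array(errors)
        assert np.max(np.abs(errors)) < 0.05
        assert np.abs(errors.mean()) < 0.02


class TestFileIO:
    def test_roundtrip_four_columns(self, tmp_path, rng):
        stack = nr.build_stage_stack("double", nr.NATIVE01, eta=0.3, contrast=D2O)
        ds = nr.smear_and_noise(stack, D2O, rng, metadata={"sample": "x"})
        p = tmp_path / "curve.dat"
        nr.write_dataset(p, ds)
        back = nr.read_dataset(p)
        assert np.allclose(back.q, ds.q)
        assert np.allclose(back.R, ds.R)
        assert np.allclose(back.dq, ds.dq)
        assert back.metadata["sample"] == "x"

    def test_three_column_input_tolerated(self, tmp_path):
        p = tmp_path / "bare.dat"
        np.savetxt(p, np.column_stack([Q, np.full_like(Q, 0.5),
                                       np.full_like(Q, 0.01)]))
        ds = nr.read_dataset(p)
        assert ds.dq is None

    def test_invalid_dataset_rejected(self):
        with pytest.raises(InvalidParameterError):
            nr.ReflectivityDataset(q=np.array([0.01]), R=np.array([-1.0]),
                                   dR=np.array([0.1]))
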