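"""CAT PBPK simulator: rate laws, conservation, limiting behaviour."""

import numpy as np
import pandas as pd
import pytest

from pkdistill import (
    DoseRegimen,
    SolverSettings,
    build_physiology,
    diffusion_coefficient,
    dissolution_rate,
    effective_solubility,
    simulate,
)
from pkdistill.physiology import LUMEN_SEGMENTS, TISSUES

from conftest import make_reference_drug


class TestEffectiveSolubility:
    def test_half_ionized_acid_doubles_solubility(self):
        assert effective_solubility(5.0, pka=4.0, ph=4.0) == pytest.approx(10.0)

    def test_neutral_is_identity(self):
        assert effective_solubility(3.7, pka=2.0, ph=8.0, ionization_type="neutral") == 3.7

    def test_strong_ionization_hits_the_cap(self):
        # 1 * (1 + 10**3) = 1001, capped at 1000x
        assert effective_solubility(1.0, pka=4.0, ph=7.0) == pytest.approx(1000.0)

    def test_base_mirror_symmetry(self):
        acid = effective_solubility(1.0, pka=5.0, ph=6.0, ionization_type="acid")
        base = effective_solubility(1.0, pka=6.0, ph=5.0, ionization_type="base")
        assert acid == pytest.approx(base)


class TestDiffusionCoefficient:
    def test_frozen_value_at_vm_100(self):
        assert diffusion_coefficient(100.0) == pytest.approx(1.0046538469589144e-05)

    def test_power_law_scaling(self):
        ratio = diffusion_coefficient(400.0) / diffusion_coefficient(200.0)
        assert ratio == pytest.approx(2.0 ** (-0.589))

    def test_monotone_decreasing_over_range(self):
        assert diffusion_coefficient(30.0) > diffusion_coefficient(1200.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(0.0)


class TestDissolutionRate:
    _args = dict(
        seg_volume=0.1,
        diffusion=1e-5,
        particle_radius=20.0,
        density=0.4,
        molecular_mass=300.0,
    )

    def test_zero_at_saturation(self):
        assert dissolution_rate(
            undissolved=10.0, dissolved_conc=500.0, solubility_eff=500.0, **self._args
        ) == 0.0

    def test_zero_without_undissolved_mass(self):
        assert dissolution_rate(
            undissolved=0.0, dissolved_conc=0.0, solubility_eff=500.0, **self._args
        ) == 0.0

    def test_clamped_when_supersaturated(self):
        assert dissolution_rate(
            undissolved=10.0, dissolved_conc=900.0, solubility_eff=500.0, **self._args
        ) == 0.0

    def test_halving_radius_quadruples_rate(self):
        args = dict(self._args)
        base = dissolution_rate(10.0, 0.0, solubility_eff=500.0, **args)
        args["particle_radius"] = 10.0
        small = dissolution_rate(10.0, 0.0, solubility_eff=500.0, **args)
        assert small == pytest.approx(4.0 * base)


class TestSimulate:
    def test_zero_dose_gives_identically_zero_states(self, reference_drug):
        res = simulate(reference_drug, regimen=DoseRegimen(dose=0.0, release_rate=100.0))
        assert res.lumen.max() == 0.0
        assert res.blood_conc.max() == 0.0
        assert res.metabolized[-1] == 0.0

    def test_mass_balance_on_random_drugs(self, small_library):
        """Dose is conserved to <1e-6 relative at every output time."""
        for _, drug in small_library.head(25).iterrows():
            res = simulate(drug)
            assert res.mass_balance_error() < 1e-6, drug["id"]

    def test_states_stay_nonnegative(self, small_library):
        for _, drug in small_library.head(25).iterrows():
            res = simulate(drug)
            floor = -1e-9 * res.dose
            assert res.lumen.min() >= floor
            assert res.tissues.min() >= floor
            assert res.blood_amount.min() >= floor

    def test_missing_fupc_raises(self, reference_drug):
        broken = reference_drug.drop("fupc_liver")
        with pytest.raises(ValueError, match="liver"):
            simulate(broken)

    def test_increasing_permeability_raises_absorption(self):
        fracs = [
            simulate(make_reference_drug(effective_permeability=p)).absorbed_fraction()
            for p in (0.1, 1.0, 4.0, 8.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(fracs, fracs[1:]))

    def test_increasing_solubility_raises_absorption(self):
        fracs = [
            simulate(make_reference_drug(solubility=s)).absorbed_fraction()
            for s in (0.001, 0.1, 10.0, 1000.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(fracs, fracs[1:]))

    def test_dose_linearity_in_linear_metabolism_regime(self):
        """With C << Km the system is linear: Cmax/dose and AUC/dose are
        invariant to dose doubling."""
        drug = make_reference_drug(km=10.0, dose=1000.0)  # Km = 10 mM
        lo = simulate(drug)
        hi = simulate(drug, regimen=DoseRegimen(dose=2000.0))
        for metric in ("max", "sum"):
            a = getattr(lo.blood_conc, metric)() / 1000.0
            b = getattr(hi.blood_conc, metric)() / 2000.0
            assert abs(a - b) / a < 1e-3

    def test_saturable_metabolism_raises_auc_per_dose(self):
        """Near Km the clearance saturates, so AUC/dose grows with dose."""
        drug = make_reference_drug(km=0.04, vmax=5e-3)
        lo = simulate(drug, regimen=DoseRegimen(dose=1000.0))
        hi = simulate(drug, regimen=DoseRegimen(dose=10_000.0))
        auc = lambda r: np.trapezoid(r.blood_conc, r.times) / r.dose
        assert auc(hi) > auc(lo) * 1.05

    def test_grid_and_tolerance_convergence(self, reference_drug):
        """Halving the output step and tightening tolerances moves Cmax by
        less than 0.1%."""
        coarse = simulate(reference_drug, settings=SolverSettings())
        fine = simulate(
            reference_drug,
            settings=SolverSettings(dt=0.025, rtol=1e-10, atol_dose_scale=1e-14),
        )
        assert abs(fine.blood_conc.max() - coarse.blood_conc.max()) / (
            fine.blood_conc.max()
        ) < 1e-3

    def test_one_compartment_analytic_limit(self):
        """Fast dissolution + uniform absorption + negligible clearance:
        the model collapses to first-order absorption into one well-mixed
        volume, with AUC(0,T) = (dose/V)(T - (1 - e^{-ka T})/ka)."""
        drug = make_reference_drug(
            solubility=1000.0,
            effective_permeability=8.0,
            molecular_mass=100.0,
            molar_volume=100.0,
            particle_radius=5.0,
            drug_density=0.7,
            vmax=1e-6,
            km=10.0,
            dose=50_000.0,
            pka=14.0,  # acid far above every luminal pH: no ionization boost
        )
        phys = build_physiology(70.0)
        radius = 1.5  # cm, identical for every absorbing segment
        phys = phys.with_overrides(
            segment_radius={s: radius for s in LUMEN_SEGMENTS},
            segment_transit={
                **phys.segment_transit,
                "stomach": 1000.0,  # instant gastric emptying
                "colon": 1e-9,  # no fecal escape within the window
            },
        )
        res = simulate(drug, physiology=phys)
        ka = 2 * 8.0e-4 / radius * 3600.0  # 1/h
        v_total = sum(phys.tissue_volumes.values()) + phys.blood_volume
        t_end = res.times[-1]
        auc_oracle = (res.dose / v_total) * (
            t_end - (1 - np.exp(-ka * t_end)) / ka
        )
        auc_model = np.trapezoid(res.blood_conc, res.times)
        assert abs(auc_model - auc_oracle) / auc_oracle < 0.05

    def test_lumen_chain_reaches_feces(self, reference_drug):
        """An unabsorbable drug transits the whole chain and exits fecally."""
        brick = make_reference_drug(
            effective_permeability=0.015, solubility=0.001, precipitation_rate=1.0
        )
        res = simulate(brick, settings=SolverSettings(t_end=96.0))
        assert res.fecal[-1] / res.dose > 0.9

    def test_result_shapes(self, reference_drug):
        res = simulate(reference_drug)
        nt = len(res.times)
        assert res.lumen.shape == (nt, len(LUMEN_SEGMENTS), 3)
        assert res.tissues.shape == (nt, len(TISSUES))
        assert res.blood_conc.shape == (nt,)
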