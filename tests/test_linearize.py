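"""Linearization table, the affine surrogate model, and the OFV-agreement
properties that justify screening extensions on it."""

import numpy as np
import pytest

from focelin import foce, linearize, simulate
from focelin.foce import EstimationOptions
from focelin.model import ConfigurationError
from focelin.structural import count_structural_calls
from conftest import small_design


@pytest.fixture(scope="module")
def additive_case():
    design = small_design(n_subjects=10, seed=17)
    ds = simulate.simulate_dataset(design)
    base = foce.ofv(design.true_model, ds)
    lin = linearize.linearize(design.true_model, base, ds)
    return design, ds, base, lin


@pytest.fixture(scope="module")
def proportional_case():
    design = small_design(n_subjects=10, seed=18, form="proportional", sigma2=0.04)
    ds = simulate.simulate_dataset(design)
    base = foce.ofv(design.true_model, ds)
    lin = linearize.linearize(design.true_model, base, ds)
    return design, ds, base, lin


class TestTable:
    def test_row_count_and_columns(self, additive_case):
        _, ds, base, lin = additive_case
        t = lin.table
        assert len(t) == ds.n_observations
        for col in ["ID", "TIME", "DV", "OPRED", "D_ETA1", "D_ETA2",
                    "D_EPS1", "D_EPSETA1_1", "OETA1", "OETA2"]:
            assert col in t.columns

    def test_additive_error_has_unit_eps_slope_and_no_interaction(self, additive_case):
        _, _, _, lin = additive_case
        np.testing.assert_allclose(lin.table["D_EPS1"], 1.0)
        np.testing.assert_allclose(lin.table["D_EPSETA1_1"], 0.0)
        np.testing.assert_allclose(lin.table["D_EPSETA1_2"], 0.0)

    def test_proportional_error_interaction_equals_prediction_slope(
        self, proportional_case
    ):
        # h = f * eps: dh/deps = f|Q0 and d/deta(dh/deps) = df/deta|Q0
        _, _, _, lin = proportional_case
        np.testing.assert_allclose(lin.table["D_EPS1"], lin.table["OPRED"],
                                   rtol=1e-10)
        for l in (1, 2):
            np.testing.assert_allclose(
                lin.table[f"D_EPSETA1_{l}"], lin.table[f"D_ETA{l}"], rtol=1e-8,
                atol=1e-12,
            )

    def test_derivatives_match_finite_difference_oracle(self, proportional_case):
        """Independent central-difference recomputation at random rows."""
        design, ds, base, lin = proportional_case
        model = design.true_model
        rng = np.random.default_rng(6)
        subjects = {s.subject_id: s for s in ds.subjects()}
        rows = lin.table.sample(10, random_state=1)
        h = 1e-6
        for _, row in rows.iterrows():
            sd = subjects[row["ID"]]
            eta_hat = base.ebes[row["ID"]]
            j = int(np.flatnonzero(np.isclose(sd.times, row["TIME"]))[0])
            prob = foce.build_subject_problems(model, [sd])[0]
            for l in range(2):
                ep, em = eta_hat.copy(), eta_hat.copy()
                ep[l] += h
                em[l] -= h
                fp, _ = prob.ev(ep[None, :])
                fm, _ = prob.ev(em[None, :])
                fd = np.real(fp[0, j] - fm[0, j]) / (2 * h)
                assert row[f"D_ETA{l + 1}"] == pytest.approx(
                    fd, rel=1e-6, abs=1e-9
                )

    def test_missing_ebe_names_subject(self, additive_case):
        design, ds, base, _ = additive_case
        broken = foce.FitResult(ofv=0.0, iofv={}, ebes={
            k: v for k, v in base.ebes.items() if k != 3
        })
        with pytest.raises(ConfigurationError, match="subject 3"):
            linearize.compute_linearization_table(design.true_model, broken, ds)

    def test_table_csv_round_trip(self, additive_case, tmp_path):
        _, _, _, lin = additive_case
        path = tmp_path / "table.csv"
        linearize.write_table(lin.table, path)
        back = linearize.read_table(path)
        np.testing.assert_allclose(back["OPRED"], lin.table["OPRED"], rtol=1e-10)
        assert list(back.columns) == list(lin.table.columns)


class TestLinearPredict:
    def test_expansion_point_reproduces_base_predictions(self, additive_case):
        _, _, base, lin = additive_case
        for _, row in lin.table.iterrows():
            eta_hat = base.ebes[row["ID"]]
            mean, scale = linearize.linear_predict(lin, eta_hat, row)
            assert mean == pytest.approx(row["OPRED"], abs=1e-12)
            np.testing.assert_allclose(scale, [1.0])  # additive base

    def test_hand_computed_affine_formula(self, proportional_case):
        _, _, base, lin = proportional_case
        row = lin.table.iloc[4]
        eta_hat = base.ebes[row["ID"]]
        delta = np.array([0.3, -0.1])
        mean, scale = linearize.linear_predict(lin, eta_hat + delta, row)
        exp_mean = row["OPRED"] + row["D_ETA1"] * 0.3 + row["D_ETA2"] * (-0.1)
        exp_scale = (
            row["D_EPS1"]
            + row["D_EPSETA1_1"] * 0.3
            + row["D_EPSETA1_2"] * (-0.1)
        )
        assert mean == pytest.approx(exp_mean, rel=1e-12)
        assert scale[0] == pytest.approx(exp_scale, rel=1e-12)


class TestOFVAgreement:
    def test_additive_base_identity(self, preset_datasets, preset_base_evals):
        """Linearized base OFV equals the nonlinear FOCE OFV to < 1e-4
        for the additive-error design."""
        design, ds = preset_datasets["moxonidine_like"]
        base = preset_base_evals["moxonidine_like"]
        lin = linearize.linearize(design.true_model, base, ds)
        res = linearize.evaluate_linearized(lin)
        assert abs(res.ofv - base.ofv) < 1e-4

    @pytest.mark.parametrize("preset", ["pefloxacin_like", "ethambutol_like"])
    def test_interaction_base_agreement_with_mceta(
        self, preset, preset_datasets, preset_base_evals
    ):
        """Proportional/combined error: within 0.5 OFV units at mceta >= 10."""
        design, ds = preset_datasets[preset]
        base = preset_base_evals[preset]
        lin = linearize.linearize(design.true_model, base, ds)
        res = linearize.evaluate_linearized(
            lin, EstimationOptions(mceta=10, seed=7)
        )
        assert abs(res.ofv - base.ofv) < 0.5

    def test_local_minima_at_mceta_zero_are_flagged_and_repaired(self):
        """The proportional-error pathology: at mceta = 0 several subjects
        sit in inner local minima with inflated iOFV; mceta = 100 repairs
        all of them and the mismatch warning goes away."""
        design = simulate.adversarial_proportional(seed=3)
        ds = simulate.simulate_dataset(design)
        # the reference nonlinear fit also needs multi-start inner searches
        # on this deliberately extreme design
        base = foce.ofv(design.true_model, ds,
                        EstimationOptions(mceta=100, seed=7))
        lin = linearize.linearize(design.true_model, base, ds)
        with pytest.warns(RuntimeWarning, match="local minima"):
            bad = linearize.fit_linearized(
                lin, EstimationOptions(mceta=0, max_iter=0), check_against=base
            )
        dev = [bad.iofv[s] - base.iofv[s] for s in bad.iofv]
        assert max(dev) > 1.0
        good = linearize.fit_linearized(
            lin, EstimationOptions(mceta=100, seed=7, max_iter=0),
            check_against=base,
        )
        assert max(good.iofv[s] - base.iofv[s] for s in good.iofv) < 0.5

    def test_log_transform_renders_error_additive_and_removes_local_minima(self):
        """The alternative remedy: modelling log-concentrations turns a
        proportional error into an additive one, so the eps-eta
        interaction vanishes and the linearized base OFV matches the
        nonlinear one even at mceta = 0."""
        design = simulate.adversarial_proportional(seed=3)
        ds = simulate.simulate_dataset(design)
        model = design.true_model.copy()
        model.log_dv = True
        model.residual = type(model.residual)(form="additive", sigma2=(0.04,))
        logged = ds.log_transformed()
        base = foce.ofv(model, logged)
        lin = linearize.linearize(model, base, logged)
        res = linearize.evaluate_linearized(lin)  # mceta = 0
        assert abs(res.ofv - base.ofv) < 1e-4
        np.testing.assert_allclose(lin.table["D_EPSETA1_1"], 0.0, atol=1e-10)

    def test_fitting_linearized_model_makes_no_structural_calls(
        self, additive_case
    ):
        _, _, base, lin = additive_case
        with count_structural_calls() as calls:
            linearize.fit_linearized(lin, EstimationOptions(max_iter=20))
        assert calls["n"] == 0
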