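"""Extension catalogue: nesting, degrees of freedom, placeholder rules."""

import numpy as np
import pytest

from focelin import foce, linearize, simulate
from focelin.extensions import (
    PLACEHOLDER_VARIANCE,
    ExtensionSpec,
    apply_extension,
    extension_battery,
    prepare_base,
)
from focelin.model import ConfigurationError, residual_term
from conftest import small_design, small_oral_model

ALL_RV = ["rv_iiv", "rv_power", "rv_autocorrelation", "rv_time_step"]


def _spec(kind, **kw):
    if kind == "rv_time_step":
        kw.setdefault("hyperparameters", {"cut_time": 6.0})
    if kind == "add_bsv":
        kw.setdefault("targets", ("KA",))
    if kind == "add_bov":
        kw.setdefault("targets", ("CL",))
    if kind == "covariance_block":
        kw.setdefault("targets", ("CL", "V"))
    return ExtensionSpec(kind, **kw)


class TestSpecs:
    def test_degrees_of_freedom(self):
        assert _spec("rv_power").n_new_parameters == 1
        assert _spec("rv_iiv").n_new_parameters == 1
        assert _spec("rv_autocorrelation").n_new_parameters == 1
        assert _spec("rv_time_step").n_new_parameters == 1
        assert _spec("add_bsv").n_new_parameters == 1
        assert _spec("covariance_block").n_new_parameters == 1  # one off-diagonal
        assert ExtensionSpec(
            "covariance_block", targets=("CL", "V", "KA")
        ).n_new_parameters == 3

    def test_battery_contains_all_rv_kinds_and_tagged_df(self):
        battery = extension_battery(
            "additive", bsv_targets=["KA"], covariance_targets=("CL", "V"),
            cut_time=6.0,
        )
        kinds = [b.kind for b in battery]
        for k in ALL_RV:
            assert k in kinds
        assert all(b.n_new_parameters >= 1 for b in battery)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            ExtensionSpec("rv_seasonal")


class TestNullValues:
    def test_power_zero_leaves_h_unchanged(self):
        m = small_oral_model(form="proportional", sigma2=0.04)
        ext = apply_extension(m, _spec("rv_power"))
        assert ext.residual.power_theta == 0.0
        assert residual_term(ext, 10.0, [0.05]) == pytest.approx(
            residual_term(m, 10.0, [0.05])
        )

    def test_rv_eta_zero_leaves_h_unchanged(self):
        m = prepare_base(small_oral_model(), [_spec("rv_iiv")])
        h0 = residual_term(m, 10.0, [0.3], eta=np.zeros(m.m))
        assert h0 == pytest.approx(0.3)

    def test_every_extension_is_exactly_nested_nonlinear(self):
        """Setting the new parameters to their null values reproduces the
        base model's OFV exactly (nonlinear arm)."""
        design = small_design(n_subjects=8, seed=23, form="proportional",
                              sigma2=0.04)
        ds = simulate.simulate_dataset(design)
        battery = [_spec(k) for k in ALL_RV + ["add_bsv", "add_bov", "covariance_block"]]
        base = prepare_base(design.true_model, battery)
        base_ofv = foce.ofv(base, ds).ofv
        for spec in battery:
            if spec.kind == "add_bov":
                continue  # single-occasion design
            ext = apply_extension(base, spec)
            # reset new parameters to the null point
            if spec.kind == "rv_power":
                ext.residual.power_theta = 0.0
            elif spec.kind == "rv_autocorrelation":
                ext.residual.autocorr_tau = 1e-3  # correlation floor
            elif spec.kind == "rv_time_step":
                ext.residual.time_step = (6.0, ext.residual.sigma2[0])
            elif spec.kind in ("rv_iiv", "add_bsv"):
                for b in ext.random_effects.blocks:
                    if b.label.startswith(("ph_", "ext_")):
                        b.values = PLACEHOLDER_VARIANCE * np.eye(b.size)
            ofv = foce.ofv(ext, ds).ofv
            assert ofv == pytest.approx(base_ofv, abs=5e-4), spec.kind

    def test_every_extension_is_exactly_nested_linearized(self):
        design = small_design(n_subjects=8, seed=23, form="proportional",
                              sigma2=0.04)
        ds = simulate.simulate_dataset(design)
        battery = [_spec(k) for k in ALL_RV + ["add_bsv", "covariance_block"]]
        base = prepare_base(design.true_model, battery)
        fit0 = foce.ofv(base, ds)
        lin = linearize.linearize(base, fit0, ds)
        base_ofv = linearize.evaluate_linearized(lin).ofv
        for spec in battery:
            ext = apply_extension(lin, spec)
            if spec.kind == "rv_power":
                ext.residual.power_theta = 0.0
            elif spec.kind == "rv_autocorrelation":
                ext.residual.autocorr_tau = 1e-3
            elif spec.kind == "rv_time_step":
                ext.residual.time_step = (6.0, ext.residual.sigma2[0])
            elif spec.kind in ("rv_iiv", "add_bsv"):
                for b in ext.random_effects.blocks:
                    if b.fixed is False and b.label.startswith("ph_"):
                        b.values = PLACEHOLDER_VARIANCE * np.eye(b.size)
            ofv = linearize.evaluate_linearized(ext).ofv
            assert ofv == pytest.approx(base_ofv, abs=5e-4), spec.kind


class TestPlaceholders:
    def test_prepare_base_adds_fixed_small_variances(self):
        m = small_oral_model()
        base = prepare_base(m, [_spec("rv_iiv"), _spec("add_bsv")])
        labels = [b.label for b in base.random_effects.blocks]
        assert any(l.startswith("ph_rv_iiv") for l in labels)
        assert any(l.startswith("ph_add_bsv") for l in labels)
        for b in base.random_effects.blocks:
            if b.fixed:
                assert np.all(np.diag(b.values) == PLACEHOLDER_VARIANCE)

    def test_placeholder_leaves_base_ofv_essentially_unchanged(self):
        design = small_design(n_subjects=6, seed=2)
        ds = simulate.simulate_dataset(design)
        plain = foce.ofv(design.true_model, ds)
        padded = foce.ofv(prepare_base(design.true_model, [_spec("add_bsv")]), ds)
        # iOFV shifts only by a constant placeholder normalization,
        # identical for base and extended models, so dOFV is unaffected:
        # the shift must be the same on independent datasets
        d1 = plain.ofv - padded.ofv
        design2 = small_design(n_subjects=6, seed=3)
        ds2 = simulate.simulate_dataset(design2)
        d2 = foce.ofv(design2.true_model, ds2).ofv - foce.ofv(
            prepare_base(design2.true_model, [_spec("add_bsv")]), ds2
        ).ofv
        assert d1 == pytest.approx(d2, abs=1e-3)

    def test_linearized_extension_without_placeholder_is_explicit_error(self):
        design = small_design(n_subjects=4, seed=5)
        ds = simulate.simulate_dataset(design)
        fit0 = foce.ofv(design.true_model, ds)
        lin = linearize.linearize(design.true_model, fit0, ds)
        with pytest.raises(ConfigurationError, match="placeholder"):
            apply_extension(lin, _spec("add_bsv"))

    def test_nonlinear_extension_without_placeholder_adds_block(self):
        m = small_oral_model()
        ext = apply_extension(m, _spec("add_bsv"))
        assert ext.m == m.m + 1


class TestCovarianceBlock:
    def test_merges_diagonal_blocks_and_frees_off_diagonal(self):
        m = small_oral_model()
        ext = apply_extension(m, _spec("covariance_block"))
        merged = ext.random_effects.blocks[0]
        assert merged.targets == ("CL", "V")
        assert merged.correlated
        np.testing.assert_allclose(np.diag(merged.values), [0.1, 0.1])

    def test_linearized_covariance_preserves_expansion(self):
        """Reordering eta blocks for the covariance merge permutes table
        columns consistently: the base OFV is unchanged."""
        design = small_design(n_subjects=6, seed=8, form="proportional",
                              sigma2=0.04)
        ds = simulate.simulate_dataset(design)
        base = prepare_base(design.true_model, [_spec("rv_iiv")])
        fit0 = foce.ofv(base, ds)
        lin = linearize.linearize(base, fit0, ds)
        before = linearize.evaluate_linearized(lin).ofv
        ext = apply_extension(lin, _spec("covariance_block"))
        # off-diagonal still zero: same model, permuted representation
        after = linearize.evaluate_linearized(ext).ofv
        assert after == pytest.approx(before, abs=1e-3)
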