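"""End-to-end study workflows.

These functions wire the full comparison pipeline — simulate a preset
dataset, fit the nonlinear base by FOCE-I, linearize, screen a battery of
random-effects extensions through both arms — and the power/type-I-error
study. They are what the command-line ``screen`` command, the acceptance
script and the heavier tests all call, so every consumer runs the
identical procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import foce, simulate
from .diagnostics import ScreeningReport, classify, screening_report
from .extensions import ExtensionSpec, apply_extension, prepare_base
from .linearize import fit_linearized, linearize
from .model import RandomEffectStructure

__all__ = [
    "preset_battery",
    "standard_battery_study",
    "power_study",
]

# time-step cut points per preset (hours), chosen to split each design's
# sampling schedule into populated early/late halves
_CUTS = {
    "moxonidine_like": (6.0,),
    "pefloxacin_like": (4.0, 12.0),
    "ethambutol_like": (24.0,),
}


def preset_battery(preset_name):
    """The screening battery for one preset, as (variant, specs) pairs.

    Variant "with_bsv" is the preset base model itself (BSV on CL and V);
    it carries the residual-variability extensions, BOV additions and the
    CL-V covariance free. Variant "rv_only" strips the BSV blocks so that
    BSV additions are tested against a base with residual variability
    only."""
    rv = [ExtensionSpec("rv_iiv"), ExtensionSpec("rv_power"),
          ExtensionSpec("rv_autocorrelation")]
    rv += [
        ExtensionSpec("rv_time_step", hyperparameters={"cut_time": c})
        for c in _CUTS[preset_name]
    ]
    a = list(rv)
    a.append(ExtensionSpec("covariance_block", targets=("CL", "V")))
    a.append(ExtensionSpec("add_bov", targets=("CL",)))
    if preset_name != "ethambutol_like":
        a.append(ExtensionSpec("add_bov", targets=("V",)))
    if preset_name == "moxonidine_like":
        a.append(ExtensionSpec("add_bsv", targets=("KA",)))
    if preset_name == "ethambutol_like":
        a.append(ExtensionSpec("add_bsv", targets=("KA",)))
        a.append(ExtensionSpec("add_bsv", targets=("MTT",)))
    b = [ExtensionSpec("add_bsv", targets=("CL",)),
         ExtensionSpec("add_bsv", targets=("V",))]
    return [("with_bsv", a), ("rv_only", b)]


def _rv_only_variant(model):
    """Copy of `model` with all BSV/BOV blocks removed (residual
    variability only)."""
    mdl = model.copy()
    mdl.random_effects = RandomEffectStructure(
        blocks=[], n_occasions=mdl.random_effects.n_occasions
    )
    return mdl


@dataclass
class BatteryStudy:
    records: list
    reports: list

    @property
    def n_entries(self):
        return len([r for r in self.records if not r.error])

    @property
    def agreement_fraction(self):
        flags = [r.agreement for r in self.records if r.agreement is not None]
        return float(np.mean(flags)) if flags else None

    @property
    def structural_calls_linearized(self):
        return sum(r.structural_calls_linearized for r in self.reports)


def standard_battery_study(
    seeds=(1, 2, 3),
    mceta_linearized=100,
    alpha=0.05,
    options=None,
    arms="both",
    presets=("moxonidine_like", "pefloxacin_like", "ethambutol_like"),
    progress=None,
):
    """Screen the full extension battery on one simulated dataset per
    preset (seeds pair with presets in order) through the linearized and
    nonlinear arms, and pool the comparison records.

    This is the study whose significance-call agreement fraction is the
    package's headline validation quantity."""
    options = options or foce.EstimationOptions(max_iter=100, outer_tol=1e-6)
    records, reports = [], []
    for seed, preset in zip(seeds, presets):
        design = simulate.PRESETS[preset](seed=seed)
        ds = simulate.simulate_dataset(design)
        for variant, battery in preset_battery(preset):
            model = (
                design.true_model
                if variant == "with_bsv"
                else _rv_only_variant(design.true_model)
            )
            rep = screening_report(
                model, ds, battery,
                options=options, alpha=alpha, arms=arms,
                mceta_linearized=mceta_linearized,
            )
            for rec in rep.records:
                rec.note = f"{preset}/{variant}" + (
                    f"; {rec.note}" if rec.note else ""
                )
            records.extend(rep.records)
            reports.append(rep)
            if progress is not None:
                progress(preset, variant, rep)
    return BatteryStudy(records=records, reports=reports)


# ---------------------------------------------------------------------------
# power / type-I error study

#: effect sizes used when an extension is simulated as truly present
TRUE_EFFECTS = {
    "rv_iiv": 0.25,  # omega^2 of the eta scaling the residual error
    "rv_power": 0.3,  # exponent on the individual prediction
    "rv_autocorrelation": 2.0,  # correlation time constant, hours
}


def _power_design(seed):
    """Compact oral design for replicate studies: 40 subjects, 6 samples,
    proportional error (the form under which RV extensions matter most)."""
    return simulate.SimulationDesign(
        n_subjects=40,
        sampling_times=[[0.5, 1.0, 2.0, 4.0, 8.0, 16.0]],
        dosing=[[(0.0, 100.0, 0.0, 1)]],
        true_model=_power_model(),
        seed=seed,
    )


def _power_model():
    from .model import (
        EtaBlock,
        ParameterModel,
        PopulationModel,
        ResidualModel,
        StructuralModel,
    )

    return PopulationModel(
        structural=StructuralModel("one_compartment_oral"),
        parameters=ParameterModel(theta={"CL": 10.0, "V": 50.0, "KA": 1.5}),
        random_effects=RandomEffectStructure(
            blocks=[EtaBlock(targets=("CL",), values=[[0.1]], label="bsv_CL")]
        ),
        residual=ResidualModel(form="proportional", sigma2=(0.04,)),
    )


def rv_scatter_points(seed=0, options=None, mceta_linearized=100):
    """dOFV pairs (nonlinear, linearized) for residual-variability
    extensions simulated as truly present at their preset effect sizes.

    One compact-design dataset per RV kind; the matching extension is
    fitted in both arms. Together with the null battery entries these
    span the dOFV range over which the two arms' agreement slope is
    assessed."""
    options = options or foce.EstimationOptions(max_iter=80, outer_tol=1e-6)
    points = []
    for j, kind in enumerate(("rv_iiv", "rv_power", "rv_autocorrelation")):
        spec = ExtensionSpec(kind)
        rep_seed = (int(seed) * 99991 + 13 * j + 5) % (2**31)
        design = _power_design(rep_seed)
        true = apply_extension(design.true_model, spec)
        if kind == "rv_iiv":
            true.random_effects.blocks[-1].values = np.array(
                [[TRUE_EFFECTS["rv_iiv"]]]
            )
        elif kind == "rv_power":
            true.residual.power_theta = TRUE_EFFECTS["rv_power"]
        else:
            true.residual.autocorr_tau = TRUE_EFFECTS["rv_autocorrelation"]
        design.true_model = true
        ds = simulate.simulate_dataset(design)

        opts = replace(options, seed=rep_seed)
        base = prepare_base(_power_model(), [spec])
        base_fit = foce.fit(base, ds, opts)
        ext_fit = foce.fit(apply_extension(base_fit.model, spec), ds, opts)
        dofv_nl = base_fit.ofv - ext_fit.ofv

        lin = linearize(base_fit.model, base_fit, ds)
        lin_opts = replace(opts, mceta=mceta_linearized)
        lin_base = fit_linearized(lin, lin_opts)
        lin_ext = fit_linearized(apply_extension(lin, spec), lin_opts)
        points.append((kind, dofv_nl, lin_base.ofv - lin_ext.ofv))
    return points


def power_study(
    extension_kind="rv_iiv",
    n_replicates=100,
    truly_present=True,
    seed=0,
    alpha=0.05,
    mceta_linearized=100,
    options=None,
):
    """Detection rate of one extension over simulated replicates.

    Each replicate simulates the compact design (with the extension active
    at its preset effect size when ``truly_present``), fits the nonlinear
    base by FOCE-I starting from the true values, linearizes, fits the
    extension on the linearized model, and classifies dOFV at ``alpha``.
    With ``truly_present=False`` the detection rate is the type-I error,
    which the boundary-unaware chi-square convention keeps conservative
    for variance-component extensions."""
    options = options or foce.EstimationOptions(max_iter=80, outer_tol=1e-6)
    spec = (
        ExtensionSpec(extension_kind)
        if extension_kind != "rv_time_step"
        else ExtensionSpec(extension_kind, hyperparameters={"cut_time": 4.0})
    )
    hits = 0
    dofvs = []
    for rep in range(n_replicates):
        rep_seed = (int(seed) * 100003 + 7 * rep + 1) % (2**31)
        design = _power_design(rep_seed)
        if truly_present:
            true = apply_extension(design.true_model, spec)
            if extension_kind == "rv_iiv":
                true.random_effects.blocks[-1].values = np.array(
                    [[TRUE_EFFECTS["rv_iiv"]]]
                )
            elif extension_kind == "rv_power":
                true.residual.power_theta = TRUE_EFFECTS["rv_power"]
            elif extension_kind == "rv_autocorrelation":
                true.residual.autocorr_tau = TRUE_EFFECTS["rv_autocorrelation"]
            design.true_model = true
        ds = simulate.simulate_dataset(design)

        base = prepare_base(_power_model(), [spec])
        opts = replace(options, seed=rep_seed)
        base_fit = foce.fit(base, ds, opts)
        lin = linearize(base_fit.model, base_fit, ds)
        lin_opts = replace(opts, mceta=mceta_linearized)
        lin_base = fit_linearized(lin, lin_opts)
        lin_ext = fit_linearized(apply_extension(lin, spec), lin_opts)
        dofv = lin_base.ofv - lin_ext.ofv
        dofvs.append(dofv)
        _, sig = classify(dofv, spec.n_new_parameters, alpha)
        hits += bool(sig)
    return {
        "extension": extension_kind,
        "truly_present": truly_present,
        "rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "dofv": np.asarray(dofvs),
    }
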