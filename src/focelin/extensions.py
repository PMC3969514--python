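"""Catalogue of random-effects model extensions.

Each :class:`ExtensionSpec` declares what is added to Omega, Sigma or the
residual function h, and how many parameters that costs (the degrees of
freedom of the chi-square significance test). Every extension is strictly
nested in its extended form: at the null values (power exponent 0,
placeholder variance, correlation scale -> 0) the base likelihood is
reproduced exactly.

The same spec applies to a nonlinear :class:`~focelin.model.PopulationModel`
(for the reference refit) and to a :class:`~focelin.linearize.LinearizedModel`
(for fast screening). Extensions that give a structural parameter new
variability require a placeholder eta — present in the base model with a
small *fixed* variance — so that the linearization table carries its
derivatives; fixing the variance to zero would zero those derivatives out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linearize import LinearizedModel
from .model import (
    RV_TARGET,
    ConfigurationError,
    EtaBlock,
    PopulationModel,
    RandomEffectStructure,
)

__all__ = [
    "ExtensionSpec",
    "apply_extension",
    "extension_battery",
    "prepare_base",
    "PLACEHOLDER_VARIANCE",
    "EXTENSION_KINDS",
]

#: small strictly-positive variance for placeholder etas (fixed during the
#: base fit so derivatives exist but the eta is effectively inert)
PLACEHOLDER_VARIANCE = 1e-6

#: initial value given to a variance freed from its placeholder
_FREED_INIT = 0.05

EXTENSION_KINDS = (
    "add_bsv",
    "add_bov",
    "covariance_block",
    "rv_iiv",
    "rv_power",
    "rv_autocorrelation",
    "rv_time_step",
)


@dataclass(frozen=True)
class ExtensionSpec:
    """Declarative description of one random-effects extension.

    ``targets`` are parameter names (eta additions / covariance blocks) or
    empty for pure residual-error extensions. ``hyperparameters`` hold
    non-estimated settings such as the time-step cut time or the
    autocorrelation-scale initial value."""

    kind: str
    targets: tuple = ()
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EXTENSION_KINDS:
            raise ConfigurationError(f"unknown extension kind {self.kind!r}")
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.kind == "covariance_block" and len(self.targets) < 2:
            raise ConfigurationError("covariance_block needs >= 2 targets")
        if self.kind in ("add_bsv", "add_bov", "rv_iiv") and self.kind != "rv_iiv":
            if not self.targets:
                raise ConfigurationError(f"{self.kind} needs at least one target")

    @property
    def n_new_parameters(self) -> int:
        """Degrees of freedom added: one variance per new eta, k(k-1)/2
        freed off-diagonals for a covariance block, one parameter for each
        residual-error extension."""
        if self.kind in ("add_bsv", "add_bov"):
            return max(len(self.targets), 1)
        if self.kind == "rv_iiv":
            return 1
        if self.kind == "covariance_block":
            k = len(self.targets)
            return k * (k - 1) // 2
        return 1

    @property
    def label(self) -> str:
        t = ",".join(self.targets)
        return f"{self.kind}({t})" if t else self.kind


def _placeholder_block_for(res: RandomEffectStructure, spec: ExtensionSpec):
    level = "bov" if spec.kind == "add_bov" else "bsv"
    targets = (RV_TARGET,) if spec.kind == "rv_iiv" else spec.targets
    for bi, b in enumerate(res.blocks):
        if b.fixed and b.level == level and b.targets == tuple(targets):
            return bi
    return None


def prepare_base(model: PopulationModel, battery) -> PopulationModel:
    """Return a copy of `model` with placeholder eta blocks added for every
    battery entry that needs one (add_bsv, add_bov, rv_iiv).

    The placeholders carry a small fixed variance so the base fit is
    unaffected but the linearization table includes their derivatives."""
    mdl = model.copy()
    res = mdl.random_effects
    for spec in battery:
        if spec.kind not in ("add_bsv", "add_bov", "rv_iiv"):
            continue
        if _placeholder_block_for(res, spec) is not None:
            continue
        level = "bov" if spec.kind == "add_bov" else "bsv"
        targets = (RV_TARGET,) if spec.kind == "rv_iiv" else spec.targets
        k = len(targets)
        res.blocks.append(
            EtaBlock(
                targets=targets,
                values=PLACEHOLDER_VARIANCE * np.eye(k),
                level=level,
                fixed=True,
                label=f"ph_{spec.kind}_{'_'.join(targets)}",
            )
        )
    return mdl


def apply_extension(model_or_lin, spec: ExtensionSpec):
    """Return an extended copy of a PopulationModel or LinearizedModel.

    Variance-structure extensions unfix the matching placeholder block (or
    merge blocks for a freed covariance); residual extensions activate the
    corresponding term of the residual model at its null/initial value so
    the outer optimization can estimate it."""
    mdl = model_or_lin.copy()
    res = mdl.random_effects
    linearized = isinstance(model_or_lin, LinearizedModel)

    if spec.kind in ("add_bsv", "add_bov", "rv_iiv"):
        bi = _placeholder_block_for(res, spec)
        if bi is None:
            if linearized:
                raise ConfigurationError(
                    f"extension {spec.label} targets variability with no "
                    "placeholder eta in the linearization table; include the "
                    "placeholder (small fixed variance) in the nonlinear base "
                    "model before linearizing"
                )
            # nonlinear models can take a brand-new block directly
            level = "bov" if spec.kind == "add_bov" else "bsv"
            targets = (RV_TARGET,) if spec.kind == "rv_iiv" else spec.targets
            res.blocks.append(
                EtaBlock(
                    targets=targets,
                    values=_FREED_INIT * np.eye(len(targets)),
                    level=level,
                    label=f"ext_{spec.label}",
                )
            )
        else:
            b = res.blocks[bi]
            b.fixed = False
            b.values = _FREED_INIT * np.eye(b.size)
        return mdl

    if spec.kind == "covariance_block":
        idx = []
        for t in spec.targets:
            hits = [
                bi
                for bi, b in enumerate(res.blocks)
                if t in b.targets and b.level == "bsv" and not b.fixed
            ]
            if not hits:
                raise ConfigurationError(
                    f"covariance_block: no estimated BSV eta for {t!r}"
                )
            idx.append(hits[0])
        idx = list(dict.fromkeys(idx))
        merged_targets, diag = [], []
        for bi in idx:
            b = res.blocks[bi]
            merged_targets.extend(b.targets)
            diag.extend(np.diag(b.values))
        merged = EtaBlock(
            targets=tuple(merged_targets),
            values=np.diag(diag),
            level="bsv",
            correlated=True,
            label="cov_" + "_".join(merged_targets),
        )
        keep = [b for bi, b in enumerate(res.blocks) if bi not in idx]
        # keep the merged block first so eta ordering stays deterministic
        res.blocks = [merged] + keep
        if linearized:
            _require_matching_layout(model_or_lin, mdl)
        return mdl

    resid = mdl.residual
    if spec.kind == "rv_power":
        resid.power_theta = float(spec.hyperparameters.get("init", 0.0))
    elif spec.kind == "rv_autocorrelation":
        resid.autocorr_tau = float(spec.hyperparameters.get("init", 1.0))
    elif spec.kind == "rv_time_step":
        cut = spec.hyperparameters.get("cut_time")
        if cut is None:
            raise ConfigurationError("rv_time_step needs a 'cut_time' hyperparameter")
        resid.time_step = (float(cut), resid.sigma2[0])
    return mdl


def _require_matching_layout(lin, mdl):
    """Reordering eta blocks permutes the per-subject eta vector; permute a
    copy of the table columns accordingly so derivatives stay aligned."""
    old = lin.random_effects.layout()
    new = mdl.random_effects.layout()
    if [x[2:] for x in old] == [x[2:] for x in new]:
        return
    perm = []
    remaining = list(range(len(old)))
    for entry in new:
        for i in remaining:
            if old[i][2:] == entry[2:]:
                perm.append(i)
                remaining.remove(i)
                break
        else:
            raise ConfigurationError("eta layout mismatch after extension")
    tau = mdl.residual.tau
    table = lin.table.copy()
    ren = {}
    for newpos, oldpos in enumerate(perm):
        ren[f"D_ETA{oldpos + 1}"] = f"D_ETA{newpos + 1}"
        ren[f"OETA{oldpos + 1}"] = f"OETA{newpos + 1}"
        for v in range(tau):
            ren[f"D_EPSETA{v + 1}_{oldpos + 1}"] = f"D_EPSETA{v + 1}_{newpos + 1}"
    table = table.rename(columns=ren)
    mdl.table = table
    mdl._arrays = None


def extension_battery(residual_form, bsv_targets=(), bov_targets=(),
                      covariance_targets=(), cut_time=None):
    """The standard screening battery for one base model: the four
    residual-variability extensions plus any configured BSV/BOV additions
    and covariance-block frees, each tagged with its degrees of freedom."""
    battery = [
        ExtensionSpec("rv_iiv"),
        ExtensionSpec("rv_power"),
        ExtensionSpec("rv_autocorrelation"),
    ]
    if cut_time is not None:
        battery.append(ExtensionSpec("rv_time_step", hyperparameters={"cut_time": cut_time}))
    for t in bsv_targets:
        battery.append(ExtensionSpec("add_bsv", targets=(t,)))
    for t in bov_targets:
        battery.append(ExtensionSpec("add_bov", targets=(t,)))
    if covariance_targets:
        battery.append(ExtensionSpec("covariance_block", targets=tuple(covariance_targets)))
    return battery
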