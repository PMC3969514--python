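"""Likelihood-ratio screening diagnostics.

An extension is judged by the drop in objective function value it buys:
dOFV = OFV_base - OFV_extended, referred to a chi-square distribution with
as many degrees of freedom as the extension adds parameters (no
boundary-mixture correction, which makes the variance-component tests
conservative). The screening report runs a battery of extensions through
both arms — full nonlinear refit and linearized fit — and tabulates the
agreement of their significance calls, the quantity the method stands on.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import foce as _foce
from .extensions import apply_extension, prepare_base
from .linearize import fit_linearized, linearize
from .model import ConfigurationError
from .structural import count_structural_calls

__all__ = [
    "ComparisonRecord",
    "delta_ofv",
    "classify",
    "iofv_deviation_report",
    "screening_report",
    "comparison_frame",
    "plot_agreement",
]


def delta_ofv(base, extended) -> float:
    """OFV improvement of the extended model: OFV_base - OFV_extended.

    Positive values favour the extension. Both fits must come from the
    same data (checked via the dataset fingerprint)."""
    if base.data_fingerprint and extended.data_fingerprint:
        if base.data_fingerprint != extended.data_fingerprint:
            raise ConfigurationError(
                "base and extended fits come from different datasets"
            )
    return float(base.ofv - extended.ofv)


def classify(dofv, df, alpha=0.05):
    """Chi-square significance call for a dOFV with `df` added parameters.

    Negative dOFV (possible only through numerical noise for nested
    models) is floored at zero. Returns ``(p_value, significant)``."""
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    d = max(float(dofv), 0.0)
    p = float(stats.chi2.sf(d, df))
    return p, p < alpha


def iofv_deviation_report(nonlinear, linearized, threshold=1.0) -> pd.DataFrame:
    """Subjects whose linearized iOFV exceeds the nonlinear one by more
    than `threshold` (the local-minima signature of the eps-eta
    interaction). The suggested remedies are a larger mceta or a
    log-transform of the data."""
    if set(nonlinear.iofv) != set(linearized.iofv):
        raise ConfigurationError("fits cover different subjects")
    rows = []
    for sid in nonlinear.iofv:
        dev = linearized.iofv[sid] - nonlinear.iofv[sid]
        if dev > threshold:
            rows.append(
                {
                    "ID": sid,
                    "iofv_nonlinear": nonlinear.iofv[sid],
                    "iofv_linearized": linearized.iofv[sid],
                    "deviation": dev,
                    "remedy": "raise mceta (>=10) or log-transform the data",
                }
            )
    rows.sort(key=lambda r: -r["deviation"])
    return pd.DataFrame(
        rows,
        columns=["ID", "iofv_nonlinear", "iofv_linearized", "deviation", "remedy"],
    )


@dataclass
class ComparisonRecord:
    """One battery entry compared across the two arms."""

    extension: object
    df: int
    dofv_nonlinear: float = np.nan
    dofv_linearized: float = np.nan
    significant_nonlinear: bool = False
    significant_linearized: bool = False
    p_nonlinear: float = np.nan
    p_linearized: float = np.nan
    max_rel_theta_change: float = np.nan
    error: str = ""
    note: str = ""

    @property
    def agreement(self):
        if self.error:
            return None
        return self.significant_nonlinear == self.significant_linearized


@dataclass
class ScreeningReport:
    records: list
    base_nonlinear: object = None
    base_linearized: object = None
    structural_calls_nonlinear: int = 0
    structural_calls_linearized: int = 0
    runtime_nonlinear: float = 0.0
    runtime_linearized: float = 0.0

    @property
    def agreement_fraction(self):
        flags = [r.agreement for r in self.records if r.agreement is not None]
        if not flags:
            return None  # empty battery: agreement not applicable
        return float(np.mean(flags))

    def frame(self) -> pd.DataFrame:
        return comparison_frame(self.records)


def comparison_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "extension": r.extension.label,
                "df": r.df,
                "dofv_nonlinear": r.dofv_nonlinear,
                "dofv_linearized": r.dofv_linearized,
                "significant_nonlinear": r.significant_nonlinear,
                "significant_linearized": r.significant_linearized,
                "agreement": r.agreement,
                "max_rel_theta_change": r.max_rel_theta_change,
                "error": r.error,
                "note": r.note,
            }
        )
    cols = [
        "extension", "df", "dofv_nonlinear", "dofv_linearized",
        "significant_nonlinear", "significant_linearized", "agreement",
        "max_rel_theta_change", "error", "note",
    ]
    return pd.DataFrame(rows, columns=cols)


def _theta_drift(base_fit, ext_fit):
    if not base_fit.theta_hat or not ext_fit.theta_hat:
        return np.nan
    rel = [
        abs(ext_fit.theta_hat[k] - v) / max(abs(v), 1e-12)
        for k, v in base_fit.theta_hat.items()
        if k in ext_fit.theta_hat
    ]
    return float(max(rel)) if rel else np.nan


def screening_report(
    model,
    dataset,
    battery,
    options=None,
    alpha=0.05,
    arms="both",
    mceta_linearized=None,
    base_fit=None,
):
    """Run every battery entry through the linearized arm and (optionally)
    the nonlinear-refit arm, and compare their significance calls.

    The nonlinear base model is augmented with placeholder etas for the
    battery, fitted by FOCE-I, linearized once, and every extension is
    then estimated on the linearized model without a single structural
    evaluation (instrumented by the call counter). ``mceta_linearized``
    overrides options.mceta in the linearized arm (the inner eta*
    objective is the one prone to local minima). Individual entry failures
    are recorded in the report, not raised."""
    options = options or _foce.EstimationOptions()
    if arms not in ("both", "linearized"):
        raise ConfigurationError("arms must be 'both' or 'linearized'")
    base = prepare_base(model, battery)
    if base_fit is None:
        base_fit = _foce.fit(base, dataset, options)
    lin = linearize(base_fit.model, base_fit, dataset)

    from dataclasses import replace as _rep

    lin_opts = options
    if mceta_linearized is not None:
        lin_opts = _rep(options, mceta=mceta_linearized)

    t0 = time.perf_counter()
    with count_structural_calls() as lin_calls:
        lin_base_fit = fit_linearized(lin, lin_opts)
        lin_results = []
        for spec in battery:
            try:
                ext = apply_extension(lin, spec)
                lin_results.append(fit_linearized(ext, lin_opts))
            except Exception as e:  # recorded, not fatal
                lin_results.append(e)
    t_lin = time.perf_counter() - t0

    records = []
    t_nl = 0.0
    nl_calls = {"n": 0}
    if arms == "both":
        t0 = time.perf_counter()
        with count_structural_calls() as nl_calls:
            for spec, lr in zip(battery, lin_results):
                rec = ComparisonRecord(extension=spec, df=spec.n_new_parameters)
                rec.note = _identifiability_note(spec, lin)
                try:
                    ext = apply_extension(base_fit.model, spec)
                    _seed_from_linearized(ext, lr)
                    ext_fit = _foce.fit(ext, dataset, options)
                    rec.dofv_nonlinear = delta_ofv(base_fit, ext_fit)
                    rec.p_nonlinear, rec.significant_nonlinear = classify(
                        rec.dofv_nonlinear, rec.df, alpha
                    )
                    rec.max_rel_theta_change = _theta_drift(base_fit, ext_fit)
                except Exception as e:
                    rec.error = f"nonlinear: {e}"
                _fill_linearized(rec, lin_base_fit, lr, alpha)
                records.append(rec)
        t_nl = time.perf_counter() - t0
    else:
        for spec, lr in zip(battery, lin_results):
            rec = ComparisonRecord(extension=spec, df=spec.n_new_parameters)
            rec.note = _identifiability_note(spec, lin)
            _fill_linearized(rec, lin_base_fit, lr, alpha)
            records.append(rec)

    return ScreeningReport(
        records=records,
        base_nonlinear=base_fit,
        base_linearized=lin_base_fit,
        structural_calls_nonlinear=nl_calls["n"],
        structural_calls_linearized=lin_calls["n"],
        runtime_nonlinear=t_nl,
        runtime_linearized=t_lin,
    )


def _seed_from_linearized(ext, lin_result):
    """Start a nonlinear refit from the linearized arm's variance
    estimates (same block structure by construction); the fixed effects
    keep their base-fit values. Pure initialization — the refit still
    re-estimates everything."""
    if isinstance(lin_result, Exception) or lin_result is None:
        return
    src = lin_result.model
    if len(src.random_effects.blocks) != len(ext.random_effects.blocks):
        return
    for dst_b, src_b in zip(ext.random_effects.blocks, src.random_effects.blocks):
        if dst_b.targets == src_b.targets and dst_b.size == src_b.size:
            dst_b.values = np.array(src_b.values, dtype=float)
    ext.residual.sigma2 = tuple(src.residual.sigma2)
    for attr in ("power_theta", "autocorr_tau", "time_step"):
        val = getattr(src.residual, attr)
        if getattr(ext.residual, attr) is not None and val is not None:
            setattr(ext.residual, attr, val)


def _identifiability_note(spec, lin):
    if spec.kind == "rv_time_step":
        cut = spec.hyperparameters.get("cut_time", np.inf)
        tmax = float(lin.table["TIME"].max())
        if cut > tmax:
            return (
                f"cut time {cut} lies beyond the last observation ({tmax}); "
                "the post-cut variance is unidentifiable"
            )
    return ""


def _fill_linearized(rec, lin_base_fit, lin_result, alpha):
    if isinstance(lin_result, Exception):
        rec.error = (rec.error + f"; linearized: {lin_result}").lstrip("; ")
        return
    rec.dofv_linearized = delta_ofv(lin_base_fit, lin_result)
    rec.p_linearized, rec.significant_linearized = classify(
        rec.dofv_linearized, rec.df, alpha
    )


def plot_agreement(records, ax=None):
    """Scatter of linearized vs nonlinear dOFV with the identity line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x = [r.dofv_nonlinear for r in records if not r.error]
    y = [r.dofv_linearized for r in records if not r.error]
    ax.scatter(x, y, s=25, alpha=0.8)
    lim = max([1.0] + [abs(v) for v in x + y if np.isfinite(v)])
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
    ax.set_xlabel(r"$\Delta$OFV nonlinear")
    ax.set_ylabel(r"$\Delta$OFV linearized")
    ax.set_title("Extension screening: linearized vs nonlinear")
    return ax
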