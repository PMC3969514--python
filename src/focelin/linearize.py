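"""First-order linearization of a fitted nonlinear base model.

The linearized model replaces the structural model by a first-order Taylor
expansion at the point Q0 = (eps = 0, eta = eta_hat), where eta_hat are the
empirical Bayes estimates from the base fit:

    y_ij ~ f|Q0 + sum_l df/deta_l|Q0 (eta*_l - etahat_l)
          + sum_v [ dh/deps_v|Q0
                    + sum_l d/deta_l(dh/deps_v)|Q0 (eta*_l - etahat_l) ] eps*_v

The per-observation predictions and derivatives form the linearization
table; once it exists, estimating extended random-effect structures only
requires the (cheap) affine model above — no structural-model evaluations
at all. Fixed effects are frozen: they are baked into the table.

The mixed eps-eta term (zero for additive error models) makes the inner
eta* objective potentially multimodal for proportional or combined error
models; the MCETA multi-start or a log-transform of the data are the
standard remedies.
"""

from __future__ import annotations

import copy
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import foce as _foce
from .foce import EstimationOptions, FitResult, SubjectProblem
from .model import ConfigurationError

__all__ = [
    "LinearizedModel",
    "compute_linearization_table",
    "linearize",
    "linear_predict",
    "fit_linearized",
    "write_table",
    "read_table",
]


def compute_linearization_table(model, fit, dataset) -> pd.DataFrame:
    """Per-observation predictions and partial derivatives at Q0.

    Columns: ID, TIME, DV, OCC, OPRED, D_ETA1..m, D_EPS1..tau,
    D_EPSETA{v}_{l}, OETA1..m (PsN 'linearize' dataset convention, plus
    OCC). Derivatives are complex-step evaluations of the base model at
    each subject's EBE; placeholder etas for planned extensions must
    already be present in the base model."""
    subjects = dataset.subjects()
    problems = _foce.build_subject_problems(model, subjects)
    m = model.random_effects.m
    tau = model.residual.tau
    rows = []
    for sd, prob in zip(subjects, problems):
        if sd.subject_id not in fit.ebes:
            raise ConfigurationError(f"no EBE available for subject {sd.subject_id}")
        eta = np.asarray(fit.ebes[sd.subject_id], dtype=float)
        if eta.shape != (m,):
            raise ConfigurationError(
                f"EBE length {eta.size} != m = {m} for subject {sd.subject_id}"
            )
        f0, a0, F, dA = _foce._derivs(prob, eta, interaction=True)
        for j in range(sd.n_obs):
            row = {
                "ID": sd.subject_id,
                "TIME": sd.times[j],
                "DV": sd.y[j],
                "OCC": int(sd.occasions[j]),
                "OPRED": f0[j],
            }
            for l in range(m):
                row[f"D_ETA{l + 1}"] = F[j, l]
            for v in range(tau):
                row[f"D_EPS{v + 1}"] = a0[v, j]
            for v in range(tau):
                for l in range(m):
                    row[f"D_EPSETA{v + 1}_{l + 1}"] = dA[v, j, l]
            for l in range(m):
                row[f"OETA{l + 1}"] = eta[l]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LinearizedModel:
    """Affine surrogate of a fitted base model, ready for extension fits.

    ``random_effects`` and ``residual`` start as copies of the base
    model's structures and are what extension specs modify; ``frozen_theta``
    records the (immutable) base fixed effects for reporting."""

    table: pd.DataFrame
    random_effects: object
    residual: object
    frozen_theta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._arrays = None

    @property
    def m(self) -> int:
        return self.random_effects.m

    def copy(self) -> "LinearizedModel":
        new = LinearizedModel(
            table=self.table,  # immutable by convention; shared
            random_effects=copy.deepcopy(self.random_effects),
            residual=copy.deepcopy(self.residual),
            frozen_theta=dict(self.frozen_theta),
        )
        new._arrays = self._subject_arrays()  # derivative arrays are static
        return new

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.table[["ID", "TIME", "DV"]].to_csv(index=False).encode())
        return h.hexdigest()[:16]

    def _subject_arrays(self):
        if self._arrays is not None:
            return self._arrays
        m = self.m
        tau = self.residual.tau
        need = (
            ["OPRED"]
            + [f"D_ETA{l + 1}" for l in range(m)]
            + [f"D_EPS{v + 1}" for v in range(tau)]
            + [f"D_EPSETA{v + 1}_{l + 1}" for v in range(tau) for l in range(m)]
            + [f"OETA{l + 1}" for l in range(m)]
        )
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ConfigurationError(
                f"linearization table lacks columns {missing}; extensions that "
                "add structural-parameter variability need a placeholder eta "
                "(small fixed variance) in the nonlinear base model so its "
                "derivatives are present"
            )
        out = []
        for sid, g in self.table.groupby("ID", sort=False):
            arr = {
                "sid": sid,
                "y": g["DV"].to_numpy(float),
                "times": g["TIME"].to_numpy(float),
                "occ": g["OCC"].to_numpy(int) if "OCC" in g else np.ones(len(g), int),
                "opred": g["OPRED"].to_numpy(float),
                "Deta": g[[f"D_ETA{l + 1}" for l in range(m)]].to_numpy(float),
                "Deps": np.stack(
                    [g[f"D_EPS{v + 1}"].to_numpy(float) for v in range(tau)]
                ),
                "Depseta": np.stack(
                    [
                        g[[f"D_EPSETA{v + 1}_{l + 1}" for l in range(m)]].to_numpy(float)
                        for v in range(tau)
                    ]
                ),
                "oeta": g[[f"OETA{l + 1}" for l in range(m)]].iloc[0].to_numpy(float),
            }
            out.append(arr)
        self._arrays = out
        return out

    def build_problem_groups(self):
        """Stacked engine problems (subjects grouped by sampling schedule)
        whose evaluator is purely affine in eta*; never touches the
        structural model."""
        from .foce import ProblemGroup

        resid = self.residual
        correlated = resid.autocorr_tau is not None
        groups = {}
        for i, arr in enumerate(self._subject_arrays()):
            groups.setdefault(tuple(arr["times"]), []).append((i, arr))
        out = []
        for times_key, members in groups.items():
            opred = np.stack([a["opred"] for _, a in members])  # (S, n)
            Deta = np.stack([a["Deta"] for _, a in members])  # (S, n, m)
            Deps = np.stack([a["Deps"] for _, a in members], axis=1)  # (tau,S,n)
            Depseta = np.stack(
                [a["Depseta"] for _, a in members], axis=1
            )  # (tau, S, n, m)
            oeta = np.stack([a["oeta"] for _, a in members])  # (S, m)
            power = resid.power_theta

            def ev(etas, opred=opred, Deta=Deta, Deps=Deps, Depseta=Depseta,
                   oeta=oeta, power=power):
                d = etas - oeta[:, None, :]  # (S, c, m)
                f = opred[:, None, :] + np.einsum("snm,scm->scn", Deta, d)
                a = Deps[:, :, None, :] + np.einsum("vsnm,scm->vscn", Depseta, d)
                if power is not None:
                    # F is the linearized model's own individual prediction
                    fpos = np.where(np.real(f) > 1e-12, f, 1e-12)
                    a = a * (fpos**power)[None]
                return f, a

            s2 = np.stack(
                [resid.obs_sigma2(a["times"]) for _, a in members]
            )  # (S, tau, n)
            kern = resid.kernel(np.array(times_key)) if correlated else None
            out.append(
                ProblemGroup(
                    [a["sid"] for _, a in members],
                    np.stack([a["y"] for _, a in members]),
                    s2, ev, [i for i, _ in members], kernel=kern,
                )
            )
        return out

    def build_problems(self):
        """Per-subject engine problems, affine in eta*; no structural-model
        calls are ever made."""
        probs = []
        resid = self.residual
        for i, arr in enumerate(self._subject_arrays()):
            opred, Deta = arr["opred"], arr["Deta"]
            Deps, Depseta, oeta = arr["Deps"], arr["Depseta"], arr["oeta"]
            power = resid.power_theta

            def ev(etas, opred=opred, Deta=Deta, Deps=Deps, Depseta=Depseta,
                   oeta=oeta, power=power):
                d = np.atleast_2d(etas) - oeta[None, :]  # (c, m)
                f = opred[None, :] + d @ Deta.T  # (c, n)
                a = Deps[:, None, :] + np.einsum("vnl,cl->vcn", Depseta, d)
                if power is not None:
                    fpos = np.where(np.real(f) > 1e-12, f, 1e-12)
                    a = a * (fpos**power)[None]
                return f, a

            kern = resid.kernel(arr["times"])
            if resid.autocorr_tau is None:
                kern = None
            probs.append(
                SubjectProblem(
                    arr["sid"], arr["y"], arr["times"], arr["occ"], ev,
                    resid.obs_sigma2(arr["times"]), kern, i,
                )
            )
        return probs


def linearize(model, fit, dataset) -> LinearizedModel:
    """Build the linearized model from a fitted nonlinear base."""
    table = compute_linearization_table(model, fit, dataset)
    return LinearizedModel(
        table=table,
        random_effects=copy.deepcopy(model.random_effects),
        residual=copy.deepcopy(model.residual),
        frozen_theta=dict(model.parameters.theta),
    )


def linear_predict(lin, eta_star, row):
    """Mean and residual-scale vector of one table row at eta*.

    mean = OPRED + sum_l D_ETA_l (eta*_l - etahat_l);
    scale_v = D_EPS_v + sum_l D_EPSETA_vl (eta*_l - etahat_l), times any
    residual-extension factor. Requires no structural-model call."""
    m = lin.m
    tau = lin.residual.tau
    eta_star = np.asarray(eta_star, dtype=float)
    if eta_star.shape != (m,):
        raise ConfigurationError(f"eta_star must have length {m}")
    oeta = np.array([row[f"OETA{l + 1}"] for l in range(m)])
    d = eta_star - oeta
    mean = row["OPRED"] + sum(row[f"D_ETA{l + 1}"] * d[l] for l in range(m))
    scale = np.array(
        [
            row[f"D_EPS{v + 1}"]
            + sum(row[f"D_EPSETA{v + 1}_{l + 1}"] * d[l] for l in range(m))
            for v in range(tau)
        ]
    )
    if lin.residual.power_theta is not None:
        scale = scale * max(mean, 1e-12) ** lin.residual.power_theta
    return float(mean), scale


def fit_linearized(lin, options=None, check_against=None, mismatch_tol=0.5):
    """Estimate the random-effect parameters of a linearized model.

    Only Omega entries, Sigma entries and residual-extension parameters
    are estimated; the fixed effects are frozen inside the table. If
    ``check_against`` (the nonlinear base FitResult) is given, the fitted
    OFV is compared against it and a warning naming the worst iOFV
    outliers is emitted on mismatch — the signature of inner local minima
    under proportional/combined error models."""
    options = options or EstimationOptions()
    lin._subject_arrays()
    result = _foce.fit(
        lin,
        dataset=None,
        options=options,
        estimate_theta=False,
        problems_builder=lambda mdl: mdl.build_problem_groups(),
    )
    result.theta_hat = dict(lin.frozen_theta)
    result.data_fingerprint = lin.fingerprint()
    if check_against is not None:
        diff = result.ofv - check_against.ofv
        if diff > mismatch_tol:
            dev = {
                sid: result.iofv[sid] - check_against.iofv.get(sid, np.nan)
                for sid in result.iofv
            }
            worst = sorted(dev, key=lambda s: -dev[s])[:5]
            warnings.warn(
                f"linearized OFV exceeds the nonlinear base OFV by {diff:.3f}; "
                f"subjects with the largest iOFV deviations: {worst}. This "
                "usually indicates inner local minima — raise mceta (e.g. "
                ">= 10) or log-transform the data to make the error additive.",
                RuntimeWarning,
                stacklevel=2,
            )
    return result


def evaluate_linearized(lin, options=None) -> FitResult:
    """OFV of the linearized model at its current parameter values."""
    options = options or EstimationOptions()
    problems = lin.build_problem_groups()
    omega = lin.random_effects.omega()
    total, iofv, ebes, ok = _foce.evaluate_ofv(problems, omega, options)
    return FitResult(
        ofv=total,
        iofv=iofv,
        ebes=ebes,
        model=lin,
        theta_hat=dict(lin.frozen_theta),
        omega_hat=omega,
        sigma_hat=tuple(lin.residual.sigma2),
        converged=ok,
        n_function_evals=1,
        data_fingerprint=lin.fingerprint(),
        eta_labels=lin.random_effects.labels(),
    )


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
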