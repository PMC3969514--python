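"""Synthetic dataset generation.

Datasets are simulated exactly under the model's stochastic structure:
eta drawn per subject (BSV) and per subject-occasion (BOV) from N(0, Omega),
epsilon per observation from N(0, Sigma) including any extension
correlation (autocorrelation kernel) or variance regime (time step), and
y = f + h. Three presets emulate the designs of classic PK examples:

* ``moxonidine_like`` — oral 1-compartment, additive error;
  74 subjects, 1,022 observations.
* ``pefloxacin_like`` — 1-h IV infusions over two occasions, proportional
  error; 74 subjects, 337 observations.
* ``ethambutol_like`` — oral absorption through one transit compartment,
  combined error; 189 subjects, 1,869 observations.

The true parameter values are illustrative choices documented in
docs/methods.md, selected once for realistic identifiability; they are
not reproductions of any published model. One master seed drives
per-subject substreams, so changing the subject count never reshuffles
earlier subjects, and output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset
from .foce import build_subject_problems
from .model import (
    ConfigurationError,
    EtaBlock,
    ParameterModel,
    PopulationModel,
    RandomEffectStructure,
    ResidualModel,
    StructuralModel,
)

__all__ = [
    "SimulationDesign",
    "simulate_dataset",
    "empirical_moments",
    "moxonidine_like",
    "pefloxacin_like",
    "ethambutol_like",
    "PRESETS",
]


@dataclass
class SimulationDesign:
    """Study design: who is dosed when and sampled when, under which true
    model. ``sampling_times[i]`` and ``dosing[i]`` (list of ``(time, amt,
    rate, occ)``) may vary by subject; lists shorter than ``n_subjects``
    are cycled."""

    n_subjects: int
    sampling_times: list  # per subject: array of times (or list cycled)
    dosing: list  # per subject: list of (time, amount, rate, occasion)
    true_model: PopulationModel
    occasion_of_time: object = None  # callable t -> occ; default from doses
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")

    def subject_times(self, i):
        return np.asarray(self.sampling_times[i % len(self.sampling_times)], float)

    def subject_dosing(self, i):
        return self.dosing[i % len(self.dosing)]


def _obs_occasions(times, doses, n_occasions):
    """Occasion of each observation: that of the latest dose at or before
    it (1 before the first dose)."""
    occ = np.ones(times.size, dtype=int)
    for dt, _, _, do in sorted(doses):
        occ[times >= dt] = do
    return np.clip(occ, 1, n_occasions)


def simulate_dataset(design: SimulationDesign, return_truth=False):
    """Draw one dataset under the design's true model.

    With ``return_truth`` the per-subject eta draws and per-observation
    epsilon draws are returned alongside (the simulation sidecar used by
    recovery tests)."""
    model = design.true_model
    res = model.random_effects
    m = res.m
    omega = res.omega()
    top = float(np.max(np.diag(omega))) if m else 0.0
    try:
        if top == 0.0:
            L = np.zeros((m, m))
        else:
            L = np.linalg.cholesky(omega + 1e-12 * top * np.eye(m))
    except np.linalg.LinAlgError as e:
        raise ConfigurationError("Omega is not positive semi-definite") from e

    rows = []
    truth_eta = []
    truth_eps = []
    for i in range(design.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(design.seed) % (2**31), 7919, i])
        )
        sid = i + 1
        times = design.subject_times(i)
        doses = design.subject_dosing(i)
        occ = _obs_occasions(times, doses, res.n_occasions)
        eta = L @ rng.standard_normal(m)

        # reuse the estimation-side evaluator so simulation and fitting
        # share one definition of f and h
        from .dataset import SubjectData

        sd = SubjectData(
            subject_id=sid,
            times=times,
            y=np.zeros_like(times),
            occasions=occ,
            dose_times=np.array([d[0] for d in doses], float),
            dose_amounts=np.array([d[1] for d in doses], float),
            dose_rates=np.array([d[2] for d in doses], float),
        )
        prob = build_subject_problems(model, [sd])[0]
        f, a = prob.ev(eta[None, :])
        f, a = np.real(f[0]), np.real(a[:, 0, :])

        s2 = model.residual.obs_sigma2(times)  # (tau, n)
        kern = model.residual.kernel(times)
        eps = np.empty_like(s2)
        sd1 = np.sqrt(s2[0])
        if np.max(s2[0]) == 0.0:
            eps[0] = np.zeros(times.size)
            rng.standard_normal(times.size)  # keep the stream layout fixed
        else:
            cov1 = (sd1[:, None] * sd1[None, :]) * kern
            jit = 1e-12 * np.max(s2[0])
            eps[0] = np.linalg.cholesky(cov1 + jit * np.eye(times.size)) @ (
                rng.standard_normal(times.size)
            )
        for v in range(1, s2.shape[0]):
            eps[v] = np.sqrt(s2[v]) * rng.standard_normal(times.size)
        y = f + np.sum(a * eps, axis=0)

        for dt, amt, rate, do in doses:
            rows.append(
                dict(ID=sid, TIME=dt, AMT=amt, RATE=rate, DV=np.nan,
                     EVID=1, MDV=1, OCC=do)
            )
        for j, t in enumerate(times):
            rows.append(
                dict(ID=sid, TIME=t, AMT=np.nan, RATE=0.0, DV=y[j],
                     EVID=0, MDV=0, OCC=int(occ[j]))
            )
        truth_eta.append(dict(ID=sid, **{
            f"ETA{l + 1}": eta[l] for l in range(m)
        }))
        for j, t in enumerate(times):
            truth_eps.append(dict(ID=sid, TIME=t, **{
                f"EPS{v + 1}": eps[v, j] for v in range(s2.shape[0])
            }))

    ds = Dataset(pd.DataFrame(rows))
    if return_truth:
        return ds, {"eta": pd.DataFrame(truth_eta), "eps": pd.DataFrame(truth_eps)}
    return ds


def empirical_moments(dataset, design, truth):
    """Simulation self-check: sample covariance of the drawn etas against
    Omega and epsilon second moments against the per-observation Sigma.

    Returns a dict with the observed and expected values. Meaningful for
    a few hundred subjects or more."""
    res = design.true_model.random_effects
    m = res.m
    eta = truth["eta"][[f"ETA{l + 1}" for l in range(m)]].to_numpy()
    obs_cov = np.cov(eta, rowvar=False).reshape(m, m)
    out = {
        "eta_cov_observed": obs_cov,
        "eta_cov_expected": res.omega(),
        "n_subjects": eta.shape[0],
    }
    epscols = [c for c in truth["eps"].columns if c.startswith("EPS")]
    eps = truth["eps"][epscols].to_numpy()
    out["eps_var_observed"] = np.var(eps, axis=0, ddof=1)
    return out


# ---------------------------------------------------------------------------
# presets: the three study designs


def _moxonidine_model():
    return PopulationModel(
        structural=StructuralModel("one_compartment_oral"),
        parameters=ParameterModel(theta={"CL": 10.0, "V": 50.0, "KA": 1.5}),
        random_effects=RandomEffectStructure(
            blocks=[
                EtaBlock(targets=("CL",), values=[[0.10]], label="bsv_CL"),
                EtaBlock(targets=("V",), values=[[0.10]], label="bsv_V"),
            ],
            n_occasions=2,
        ),
        residual=ResidualModel(form="additive", sigma2=(0.01,)),
    )


def moxonidine_like(seed=0) -> SimulationDesign:
    """74 subjects, 1,022 observations; 100-mg oral doses on two occasions
    (0 h and 12 h), additive error. The first 14 subjects contribute 13
    samples, the rest 14."""
    full = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
            12.5, 13.0, 14.0, 18.0, 24.0]
    times = [full[1:] if i < 14 else full for i in range(74)]
    return SimulationDesign(
        n_subjects=74,
        sampling_times=times,
        dosing=[[(0.0, 100.0, 0.0, 1), (12.0, 100.0, 0.0, 2)]],
        true_model=_moxonidine_model(),
        seed=seed,
    )


def _pefloxacin_model():
    return PopulationModel(
        structural=StructuralModel("one_compartment_infusion"),
        parameters=ParameterModel(theta={"CL": 6.0, "V": 100.0}),
        random_effects=RandomEffectStructure(
            blocks=[
                EtaBlock(targets=("CL",), values=[[0.15]], label="bsv_CL"),
                EtaBlock(targets=("V",), values=[[0.15]], label="bsv_V"),
            ],
            n_occasions=2,
        ),
        residual=ResidualModel(form="proportional", sigma2=(0.04,)),
    )


def pefloxacin_like(seed=0) -> SimulationDesign:
    """74 subjects, 337 observations; two 400-mg 1-h infusions (occasions
    at 0 h and 12 h), proportional error. 41 subjects give 5 samples, 33
    give 4."""
    t5 = [1.0, 2.0, 4.0, 13.0, 16.0]
    t4 = [1.0, 4.0, 13.0, 16.0]
    times = [t5 if i < 41 else t4 for i in range(74)]
    return SimulationDesign(
        n_subjects=74,
        sampling_times=times,
        dosing=[[(0.0, 400.0, 400.0, 1), (12.0, 400.0, 400.0, 2)]],
        true_model=_pefloxacin_model(),
        seed=seed,
    )


def _ethambutol_model():
    return PopulationModel(
        structural=StructuralModel("one_compartment_transit_oral"),
        parameters=ParameterModel(
            theta={"CL": 40.0, "V": 500.0, "KA": 0.6, "MTT": 1.5}
        ),
        random_effects=RandomEffectStructure(
            blocks=[
                EtaBlock(targets=("CL",), values=[[0.12]], label="bsv_CL"),
                EtaBlock(targets=("V",), values=[[0.12]], label="bsv_V"),
            ],
            n_occasions=2,
        ),
        residual=ResidualModel(form="combined", sigma2=(0.04, 0.0064)),
    )


def ethambutol_like(seed=0) -> SimulationDesign:
    """189 subjects, 1,869 observations; 1,200-mg oral doses on two
    occasions (0 h and 24 h), combined error. The first 21 subjects give
    9 samples, the rest 10."""
    full = [0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 24.5, 26.0, 28.0]
    times = [full[1:] if i < 21 else full for i in range(189)]
    return SimulationDesign(
        n_subjects=189,
        sampling_times=times,
        dosing=[[(0.0, 1200.0, 0.0, 1), (24.0, 1200.0, 0.0, 2)]],
        true_model=_ethambutol_model(),
        seed=seed,
    )


def adversarial_proportional(seed=0, omega2=0.4) -> SimulationDesign:
    """Stress design for the inner local-minima pathology.

    Proportional error with large BSV (default omega^2 = 0.4, ~70% CV)
    spreads the EBEs far enough that the linearized residual scale
    changes sign between eta* = 0 and the true optimum for several
    subjects; starting the inner search at zero then reliably terminates
    in a spurious minimum, which MCETA repairs. Used by diagnostics tests;
    not one of the three study-design presets."""
    model = PopulationModel(
        structural=StructuralModel("one_compartment_infusion"),
        parameters=ParameterModel(theta={"CL": 6.0, "V": 100.0}),
        random_effects=RandomEffectStructure(
            blocks=[
                EtaBlock(targets=("CL",), values=[[omega2]], label="bsv_CL"),
                EtaBlock(targets=("V",), values=[[omega2]], label="bsv_V"),
            ],
        ),
        residual=ResidualModel(form="proportional", sigma2=(0.04,)),
    )
    return SimulationDesign(
        n_subjects=30,
        sampling_times=[[1.0, 2.0, 4.0, 8.0, 12.0]],
        dosing=[[(0.0, 400.0, 400.0, 1)]],
        true_model=model,
        seed=seed,
    )


PRESETS = {
    "moxonidine_like": moxonidine_like,
    "pefloxacin_like": pefloxacin_like,
    "ethambutol_like": ethambutol_like,
}
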