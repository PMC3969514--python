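"""FOCE / FOCE-I estimation for population models.

The marginal likelihood of a nonlinear mixed-effects model has no closed
form; FOCE approximates each subject's contribution by a Laplace-type
expansion around the conditional mode (empirical Bayes estimate, EBE) of
the random effects. Writing the joint twice-negative log-density of one
subject as

    q(eta) = log det R(eta) + r(eta)' R(eta)^-1 r(eta)
             + eta' Omega^-1 eta + log det Omega,

with r = y - f(eta) and R the residual covariance (evaluated at eta under
FOCE-I "interaction", at eta = 0 otherwise), the individual objective is

    iOFV_i = q(eta_hat) + log det( H(eta_hat) / 2 ),

where H is the Gauss-Newton approximation of q'' that keeps first-order
sensitivities of both the mean and the residual variance:

    H = 2 F' R^-1 F + tr-terms(dR/deta) + 2 Omega^-1,   F = df/deta.

The n*log(2pi) constant is omitted throughout (NONMEM convention); only
OFV differences carry meaning. For a model linear in eta with additive
error the expansion is exact and the OFV equals the exact Gaussian
marginal -2 log-likelihood — the hinge on which the linearization's
correctness is tested.

Derivatives with respect to eta are obtained by the complex-step method
on the model evaluator (exact to machine precision); tests cross-check
them against central finite differences. Evaluators are batched: a stack
of eta vectors is predicted in one call, so a Newton step, its
complex-step perturbations and the whole line search each cost a single
structural evaluation per subject.

The inner eta search is a damped Newton iteration. The MCETA multi-start
option evaluates q at eta = 0 plus `mceta` random draws from N(0, Omega)
and starts the single Newton run from the best candidate, which guards
against the local minima that the epsilon-eta interaction can create.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize

from .model import RV_TARGET, ConfigurationError, PopulationModel
from .structural import STRUCTURAL_KINDS, dose_geometry, predict_profile

__all__ = [
    "EstimationOptions",
    "FitResult",
    "NumericalGuardError",
    "SubjectProblem",
    "ProblemGroup",
    "build_subject_problems",
    "make_group_builder",
    "conditional_objective",
    "estimate_ebes",
    "evaluate_ofv",
    "ofv",
    "fit",
]

_CSTEP = 1e-20  # complex-step size; effectively exact
_VFLOOR = 1e-14


class NumericalGuardError(RuntimeError):
    """Raised when a variance term or factorization degenerates."""


def _safe_exp(x):
    """exp with the real part clipped to +-60 (guards absurd line-search
    trial etas without disturbing complex-step derivatives)."""
    r = np.clip(np.real(x), -60.0, 60.0)
    if np.iscomplexobj(x):
        return np.exp(r + 1j * np.imag(x))
    return np.exp(r)


@dataclass
class EstimationOptions:
    """Settings shared by the inner (eta) and outer (theta/Omega/Sigma)
    optimizations.

    ``mceta`` is the number of random initial eta vectors tested in
    addition to zero; ``interaction`` selects FOCE-I (residual variance
    evaluated at the conditional mode) over plain FOCE."""

    interaction: bool = True
    mceta: int = 0
    seed: int = 12345
    inner_tol: float = 1e-8
    outer_tol: float = 1e-8
    max_inner_iter: int = 60
    max_iter: int = 150
    use_warm_ebes: bool = True

    def __post_init__(self):
        if self.mceta < 0:
            raise ConfigurationError("mceta must be >= 0")
        if self.inner_tol <= 0 or self.outer_tol <= 0:
            raise ConfigurationError("tolerances must be positive")


@dataclass
class FitResult:
    """Estimates, objective function value and per-subject quantities."""

    ofv: float
    iofv: dict  # subject id -> individual OFV contribution
    ebes: dict  # subject id -> eta-hat vector
    model: object = None  # fitted PopulationModel or LinearizedModel
    theta_hat: dict = None
    omega_hat: np.ndarray = None  # expanded per-subject covariance
    sigma_hat: tuple = None
    converged: bool = True
    n_function_evals: int = 0
    data_fingerprint: str = ""
    eta_labels: list = field(default_factory=list)

    def iofv_series(self):
        import pandas as pd

        return pd.Series(self.iofv, name="iOFV")


# ---------------------------------------------------------------------------
# subject problems


class SubjectProblem:
    """Everything the engine needs for one subject: data arrays, a batched
    evaluator ``ev(etas (c, m)) -> (f (c, n), a (tau, c, n))`` that accepts
    complex eta stacks, per-observation epsilon variances and the residual
    correlation kernel (None when uncorrelated)."""

    def __init__(self, subject_id, y, times, occasions, ev, s2, kernel, index):
        self.subject_id = subject_id
        self.y = np.asarray(y, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.occasions = occasions
        self.ev = ev
        self.s2 = s2  # (tau, n)
        self.kernel = kernel  # (n, n) correlation of eps component 1, or None
        self.index = index  # stable position used to key the MCETA stream

    @property
    def n_obs(self):
        return self.y.size


def build_subject_problems(model: PopulationModel, subjects) -> list:
    """Wrap a PopulationModel and per-subject data into engine problems.

    All model structure (eta-to-parameter maps per occasion, covariate
    multipliers, residual form and extension factors) is resolved here so
    the evaluator itself is a handful of vectorized operations."""
    kind = model.structural.kind
    pnames = STRUCTURAL_KINDS[kind]
    layout = model.random_effects.layout()
    theta = model.parameters.theta
    form = model.residual.form
    power = model.residual.power_theta
    log_dv = model.log_dv
    out = []
    for i, sd in enumerate(subjects):
        occ_list = [int(o) for o in np.unique(sd.occasions)]
        occ_groups = [
            (
                o,
                np.flatnonzero(sd.occasions == o),
                dose_geometry(
                    sd.times[sd.occasions == o], sd.dose_times,
                    sd.dose_amounts, sd.dose_rates,
                ),
            )
            for o in occ_list
        ]
        # eta indices feeding each parameter, per occasion
        pmap = {}
        rvmap = {}
        for o in occ_list:
            for name in pnames:
                pmap[(o, name)] = np.array(
                    [
                        li
                        for li, (_, _, t, lvl, oc) in enumerate(layout)
                        if t == name and (lvl == "bsv" or oc == o)
                    ],
                    dtype=int,
                )
            rvmap[o] = np.array(
                [
                    li
                    for li, (_, _, t, lvl, oc) in enumerate(layout)
                    if t == RV_TARGET and (lvl == "bsv" or oc == o)
                ],
                dtype=int,
            )
        gmult = {}
        for name in pnames:
            g = model.parameters.covariate_functions.get(name)
            if g is None:
                gmult[name] = 1.0
            else:
                try:
                    gmult[name] = float(g(sd.covariates))
                except KeyError as e:
                    raise ConfigurationError(
                        f"unknown covariate {e} for g_{name}"
                    ) from e
        has_rv = any(rvmap[o].size for o in occ_list)

        def ev(etas, sd=sd, occ_groups=occ_groups, pmap=pmap, rvmap=rvmap,
               gmult=gmult, has_rv=has_rv):
            etas = np.atleast_2d(etas)
            c = etas.shape[0]
            n = sd.n_obs
            dtype = complex if np.iscomplexobj(etas) else float
            f = np.empty((c, n), dtype=dtype)
            rvfac = np.ones((c, n), dtype=dtype) if has_rv else None
            for o, idx, geom in occ_groups:
                p = {}
                for name in pnames:
                    ix = pmap[(o, name)]
                    bump = etas[:, ix].sum(axis=1) if ix.size else np.zeros(c, dtype)
                    p[name] = theta[name] * gmult[name] * _safe_exp(bump)
                f[:, idx] = predict_profile(
                    kind, p, None, None, None, None, geometry=geom,
                )
                if has_rv and rvmap[o].size:
                    lf = etas[:, rvmap[o]].sum(axis=1)
                    rvfac[:, idx] = _safe_exp(lf)[:, None]
            if form == "additive":
                a = np.ones((1, c, n), dtype=dtype)
            elif form == "proportional":
                a = f[None, :, :].copy()
            else:
                a = np.stack([f, np.ones((c, n), dtype=dtype)])
            if rvfac is not None:
                a = a * rvfac[None, :, :]
            if power is not None:
                fpos = np.where(np.real(f) > 1e-12, f, 1e-12)
                a = a * (fpos**power)[None, :, :]
            if log_dv:
                fobs = np.log(np.where(np.real(f) > 1e-12, f, 1e-12))
            else:
                fobs = f
            return fobs, a

        kern = model.residual.kernel(sd.times)
        if model.residual.autocorr_tau is None:
            kern = None
        out.append(
            SubjectProblem(
                sd.subject_id, sd.y, sd.times, sd.occasions, ev,
                model.residual.obs_sigma2(sd.times), kern, i,
            )
        )
    return out


# ---------------------------------------------------------------------------
# inner objective


def _q_batch(prob, etas, omega_inv, logdet_omega, interaction, a0_fixed=None):
    """q(eta) for a stack of eta vectors; one evaluator call."""
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    f, a = prob.ev(etas)
    f = np.real(f)
    a = np.real(a) if interaction else np.broadcast_to(
        a0_fixed[:, None, :], (a0_fixed.shape[0], f.shape[0], f.shape[1])
    )
    r = prob.y[None, :] - f  # (c, n)
    pen = np.einsum("ci,ij,cj->c", etas, omega_inv, etas) + logdet_omega
    if prob.kernel is None:
        v = np.maximum(np.einsum("vcn,vn->cn", a * a, prob.s2), _VFLOOR)
        return np.sum(np.log(v) + r * r / v, axis=1) + pen
    qs = np.empty(etas.shape[0])
    for ci in range(etas.shape[0]):
        R = _assemble_R(prob, a[:, ci, :])
        try:
            cfac, low = sla.cho_factor(R, check_finite=False)
        except np.linalg.LinAlgError:
            qs[ci] = np.inf
            continue
        x = sla.cho_solve((cfac, low), r[ci], check_finite=False)
        qs[ci] = 2.0 * np.sum(np.log(np.diag(cfac))) + r[ci] @ x + pen[ci]
    return qs


def _q_value(prob, eta, omega_inv, logdet_omega, interaction, a0_fixed=None):
    q = _q_batch(prob, eta[None, :], omega_inv, logdet_omega, interaction, a0_fixed)[0]
    if np.isinf(q):
        raise NumericalGuardError(
            f"residual covariance not PD for subject {prob.subject_id}"
        )
    return float(q)


def _assemble_R(prob, a):
    """Residual covariance (n x n) from coefficients a (tau, n)."""
    s = a * np.sqrt(prob.s2)
    R = (s[0][:, None] * s[0][None, :]) * prob.kernel
    for v in range(1, s.shape[0]):
        R = R + np.diag(s[v] * s[v])
    return R


def _derivs(prob, eta, interaction, a0_fixed=None):
    """f, a and their eta-derivatives at a real eta, via one batched
    complex-step call. Returns (f (n,), a (tau, n), F (n, m), dA (tau, n, m))."""
    eta = np.asarray(eta, dtype=float)
    m = eta.size
    E = np.tile(eta.astype(complex), (m + 1, 1))
    E[1:] += 1j * _CSTEP * np.eye(m)
    fc, ac = prob.ev(E)
    f0 = np.real(fc[0])
    F = np.imag(fc[1:]).T / _CSTEP  # (n, m)
    if interaction:
        a0 = np.real(ac[:, 0, :])
        dA = np.moveaxis(np.imag(ac[:, 1:, :]), 1, 2) / _CSTEP  # (tau, n, m)
    else:
        a0 = a0_fixed
        dA = np.zeros((a0.shape[0], f0.size, m))
    return f0, a0, F, dA


def _q_grad_hess(prob, eta, omega_inv, logdet_omega, interaction, a0_fixed=None):
    """q, gradient and Gauss-Newton Hessian (with residual-variance
    sensitivities) at a real eta."""
    f, a, F, dA = _derivs(prob, eta, interaction, a0_fixed)
    r = prob.y - f
    m = eta.size
    pen_g = 2.0 * (omega_inv @ eta)
    pen = float(eta @ omega_inv @ eta) + logdet_omega

    if prob.kernel is None:
        v = np.maximum(np.einsum("vn,vn->n", a * a, prob.s2), _VFLOOR)
        dv = 2.0 * np.einsum("vn,vnl->nl", a * prob.s2, dA)  # (n, m)
        q = float(np.sum(np.log(v) + r * r / v) + pen)
        g = dv.T @ (1.0 / v) - 2.0 * F.T @ (r / v) - dv.T @ (r * r / v**2) + pen_g
        H = (
            2.0 * (F / v[:, None]).T @ F
            + (dv / v[:, None] ** 2).T @ dv
            + 2.0 * omega_inv
        )
        return q, g, H

    R = _assemble_R(prob, a)
    try:
        cfac, low = sla.cho_factor(R, check_finite=False)
    except np.linalg.LinAlgError as e:
        raise NumericalGuardError(
            f"residual covariance not PD for subject {prob.subject_id}"
        ) from e
    Rinv_r = sla.cho_solve((cfac, low), r, check_finite=False)
    q = float(2.0 * np.sum(np.log(np.diag(cfac))) + r @ Rinv_r + pen)
    s = a * np.sqrt(prob.s2)
    sq = np.sqrt(prob.s2)
    g = np.empty(m)
    Rinv_dRs = []
    for l in range(m):
        ds = dA[:, :, l] * sq
        dR = (
            ds[0][:, None] * s[0][None, :] + s[0][:, None] * ds[0][None, :]
        ) * prob.kernel
        for v_ in range(1, s.shape[0]):
            dR += np.diag(2.0 * s[v_] * ds[v_])
        Rinv_dR = sla.cho_solve((cfac, low), dR, check_finite=False)
        Rinv_dRs.append(Rinv_dR)
        g[l] = np.trace(Rinv_dR) - 2.0 * F[:, l] @ Rinv_r - Rinv_r @ dR @ Rinv_r
    g = g + pen_g
    Rinv_F = sla.cho_solve((cfac, low), F, check_finite=False)
    H = 2.0 * F.T @ Rinv_F + 2.0 * omega_inv
    for l in range(m):
        for k in range(l, m):
            t = np.trace(Rinv_dRs[l] @ Rinv_dRs[k])
            H[l, k] += t
            if k != l:
                H[k, l] += t
    return q, g, H


def conditional_objective(model, subject_data, eta, options=None):
    """Joint (MAP) objective q(eta) for one subject; the quantity the
    inner estimation minimizes. FOCE-I evaluates the residual variance at
    ``eta``; plain FOCE holds it at eta = 0. Raises
    :class:`NumericalGuardError` on a non-positive residual variance."""
    options = options or EstimationOptions()
    prob = build_subject_problems(model, [subject_data])[0]
    omega = model.random_effects.omega()
    omega_inv, logdet = _omega_inverse(omega)
    eta = np.asarray(eta, dtype=float)
    a0_fixed = None
    if not options.interaction:
        _, a0 = prob.ev(np.zeros((1, eta.size)))
        a0_fixed = np.real(a0[:, 0, :])
    _guard_variance(prob, eta, options.interaction, a0_fixed)
    return _q_value(prob, eta, omega_inv, logdet, options.interaction, a0_fixed)


def _guard_variance(prob, eta, interaction, a0_fixed):
    _, a = prob.ev(np.asarray(eta, dtype=float)[None, :])
    a = np.real(a[:, 0, :]) if interaction else a0_fixed
    if prob.kernel is None:
        v = np.einsum("vn,vn->n", a * a, prob.s2)
        if np.any(v <= 0):
            raise NumericalGuardError(
                f"non-positive residual variance for subject {prob.subject_id}"
            )


def _omega_inverse(omega):
    try:
        c = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as e:
        raise NumericalGuardError("Omega is not positive definite") from e
    inv = np.linalg.inv(omega)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return inv, logdet


# ---------------------------------------------------------------------------
# inner Newton + MCETA

_LS_ALPHAS = 0.5 ** np.arange(11)  # 1, 1/2, ..., 1/1024


def _newton(prob, start, omega_inv, logdet_omega, options, a0_fixed=None):
    eta = np.array(start, dtype=float)
    inter = options.interaction
    if eta.size == 0:  # fixed-effects-only model: nothing to optimize
        q = _q_value(prob, eta, omega_inv, logdet_omega, inter, a0_fixed)
        return eta, q, np.zeros((0, 0)), True
    q, g, H = _q_grad_hess(prob, eta, omega_inv, logdet_omega, inter, a0_fixed)
    lam = 0.0
    converged = False
    for _ in range(options.max_inner_iter):
        if np.max(np.abs(g)) < options.inner_tol * (1.0 + abs(q)):
            converged = True
            break
        try:
            step = -np.linalg.solve(H + lam * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            lam = max(10.0 * lam, 1e-6)
            continue
        slope = float(g @ step)  # negative for a descent direction
        trials = eta[None, :] + _LS_ALPHAS[:, None] * step[None, :]
        qt = _q_batch(prob, trials, omega_inv, logdet_omega, inter, a0_fixed)
        armijo = qt <= q + 1e-4 * _LS_ALPHAS * slope
        if np.any(armijo):
            j = int(np.argmax(armijo))  # largest step passing the test
            eta = trials[j]
            q, g, H = _q_grad_hess(prob, eta, omega_inv, logdet_omega, inter, a0_fixed)
            lam *= 0.25
            continue
        j = int(np.argmin(qt))
        if qt[j] < q - 1e-12 * (1.0 + abs(q)):
            eta = trials[j]
            q, g, H = _q_grad_hess(prob, eta, omega_inv, logdet_omega, inter, a0_fixed)
            lam = max(10.0 * lam, 1e-6)
            continue
        if lam > 1e8:
            break  # stalled: no further descent possible
        lam = max(100.0 * lam, 1e-4)
    return eta, q, H, converged or np.max(np.abs(g)) < 1e-4 * (1.0 + abs(q))


def _mceta_candidates(prob, omega, options, warm=None):
    """Initial eta candidates: zero plus `mceta` draws from N(0, Omega) on
    the subject's dedicated stream. A warm start (the EBE from the
    previous outer iteration) is only used when MCETA is off, so that
    multi-start searches stay deterministic functions of the seed."""
    m = omega.shape[0]
    cands = [np.zeros(m)]
    if options.mceta > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(options.seed) % (2**31), prob.index])
        )
        L = np.linalg.cholesky(omega + 1e-12 * np.eye(m))
        cands.extend(list(rng.standard_normal((options.mceta, m)) @ L.T))
    elif warm is not None and np.any(np.asarray(warm) != 0.0):
        cands.append(np.asarray(warm, dtype=float))
    return np.array(cands)


def _solve_subject(prob, omega, options, warm=None, omega_fact=None):
    if omega_fact is None:
        omega_fact = _omega_inverse(omega)
    omega_inv, logdet = omega_fact
    a0_fixed = None
    if not options.interaction:
        _, a0 = prob.ev(np.zeros((1, omega.shape[0])))
        a0_fixed = np.real(a0[:, 0, :])
    cands = _mceta_candidates(prob, omega, options, warm)
    qs = _q_batch(prob, cands, omega_inv, logdet, options.interaction, a0_fixed)
    qs = np.where(np.isfinite(qs), qs, np.inf)
    best = int(np.argmin(qs))
    return _newton(prob, cands[best], omega_inv, logdet, options, a0_fixed)


def estimate_ebes(model, subject_data, options=None, warm=None):
    """MAP estimate of one subject's eta vector (the EBE) and the inner
    objective value at it.

    With ``mceta = k`` the inner objective is evaluated at zero and at k
    random N(0, Omega) draws, and the Newton iteration starts from the
    best candidate (deterministic given the seed). Returns
    ``(eta_hat, q_value)``."""
    options = options or EstimationOptions()
    prob = build_subject_problems(model, [subject_data])[0]
    omega = model.random_effects.omega()
    eta, q, _, _ = _solve_subject(prob, omega, options, warm)
    return eta, q


# ---------------------------------------------------------------------------
# vectorized multi-subject solver
#
# Subjects that share a sampling/dosing schedule (the common case in the
# preset designs) are stacked into one ProblemGroup and their inner Newton
# iterations run as batched array operations — one structural evaluation
# serves a whole cohort. Subjects with a residual correlation kernel
# (autocorrelation fits) keep the per-subject path above.


class ProblemGroup:
    """A stack of subjects sharing observation times (and, for nonlinear
    models, dosing schedule). ``ev(etas (S, c, m)) -> (f (S, c, n),
    a (tau, S, c, n))``; ``s2`` has shape (S, tau, n); ``kernel`` is the
    shared (n, n) correlation matrix of the first epsilon component, or
    None when residuals are uncorrelated."""

    def __init__(self, sids, y, s2, ev, indices, kernel=None):
        self.sids = list(sids)
        self.y = np.asarray(y, dtype=float)  # (S, n)
        self.s2 = np.asarray(s2, dtype=float)  # (S, tau, n)
        self.ev = ev
        self.indices = np.asarray(indices, dtype=int)  # MCETA stream keys
        self.kernel = kernel

    @property
    def n_subjects(self):
        return self.y.shape[0]


def make_group_builder(model_template, subjects):
    """Precompute schedule groups and geometry once; return a
    ``builder(model) -> [ProblemGroup | SubjectProblem]`` usable for every
    outer iteration of a fit (the grouping depends only on the data and
    the model's structure, not on its parameter values)."""
    kind = model_template.structural.kind
    pnames = STRUCTURAL_KINDS[kind]
    layout = model_template.random_effects.layout()

    groups = {}
    for i, sd in enumerate(subjects):
        key = (
            tuple(sd.times), tuple(sd.occasions), tuple(sd.dose_times),
            tuple(sd.dose_amounts), tuple(sd.dose_rates),
        )
        groups.setdefault(key, []).append((i, sd))

    plans = []
    for key, members in groups.items():
        sd0 = members[0][1]
        occ_list = [int(o) for o in np.unique(sd0.occasions)]
        occ_groups = [
            (
                o,
                np.flatnonzero(sd0.occasions == o),
                dose_geometry(
                    sd0.times[sd0.occasions == o], sd0.dose_times,
                    sd0.dose_amounts, sd0.dose_rates,
                ),
            )
            for o in occ_list
        ]
        pmap, rvmap = {}, {}
        for o in occ_list:
            for name in pnames:
                pmap[(o, name)] = np.array(
                    [
                        li
                        for li, (_, _, t, lvl, oc) in enumerate(layout)
                        if t == name and (lvl == "bsv" or oc == o)
                    ],
                    dtype=int,
                )
            rvmap[o] = np.array(
                [
                    li
                    for li, (_, _, t, lvl, oc) in enumerate(layout)
                    if t == RV_TARGET and (lvl == "bsv" or oc == o)
                ],
                dtype=int,
            )
        plans.append(
            {
                "sids": [sd.subject_id for _, sd in members],
                "indices": [i for i, _ in members],
                "y": np.stack([sd.y for _, sd in members]),
                "times": sd0.times,
                "occ_groups": occ_groups,
                "pmap": pmap,
                "rvmap": rvmap,
                "covs": [sd.covariates for _, sd in members],
                "n": sd0.n_obs,
            }
        )

    def builder(model):
        form = model.residual.form
        power = model.residual.power_theta
        log_dv = model.log_dv
        theta = model.parameters.theta
        correlated = model.residual.autocorr_tau is not None
        out = []
        for plan in plans:
            S = len(plan["sids"])
            gmult = {}
            for name in pnames:
                g = model.parameters.covariate_functions.get(name)
                if g is None:
                    gmult[name] = np.ones(S)
                else:
                    try:
                        gmult[name] = np.array(
                            [float(g(c)) for c in plan["covs"]]
                        )
                    except KeyError as e:
                        raise ConfigurationError(
                            f"unknown covariate {e} for g_{name}"
                        ) from e
            has_rv = any(plan["rvmap"][o].size for o, _, _ in plan["occ_groups"])
            n = plan["n"]

            def ev(etas, plan=plan, gmult=gmult, has_rv=has_rv, n=n,
                   form=form, power=power, log_dv=log_dv, theta=theta):
                S_, c, _m = etas.shape
                dtype = complex if np.iscomplexobj(etas) else float
                f = np.empty((S_, c, n), dtype=dtype)
                rvfac = np.ones((S_, c, n), dtype=dtype) if has_rv else None
                for o, idx, geom in plan["occ_groups"]:
                    p = {}
                    for name in pnames:
                        ix = plan["pmap"][(o, name)]
                        bump = (
                            etas[:, :, ix].sum(axis=2)
                            if ix.size
                            else np.zeros((S_, c), dtype)
                        )
                        p[name] = (
                            theta[name] * gmult[name][:, None] * _safe_exp(bump)
                        ).reshape(-1)
                    prof = predict_profile(
                        kind, p, None, None, None, None, geometry=geom
                    )
                    f[:, :, idx] = prof.reshape(S_, c, idx.size)
                    rvix = plan["rvmap"][o]
                    if has_rv and rvix.size:
                        lf = etas[:, :, rvix].sum(axis=2)
                        rvfac[:, :, idx] = _safe_exp(lf)[:, :, None]
                if form == "additive":
                    a = np.ones((1, S_, c, n), dtype=dtype)
                elif form == "proportional":
                    a = f[None, ...].copy()
                else:
                    a = np.stack([f, np.ones((S_, c, n), dtype=dtype)])
                if rvfac is not None:
                    a = a * rvfac[None, ...]
                if power is not None:
                    fpos = np.where(np.real(f) > 1e-12, f, 1e-12)
                    a = a * (fpos**power)[None, ...]
                if log_dv:
                    f = np.log(np.where(np.real(f) > 1e-12, f, 1e-12))
                return f, a

            s2 = model.residual.obs_sigma2(plan["times"])  # (tau, n)
            kern = model.residual.kernel(plan["times"]) if correlated else None
            out.append(
                ProblemGroup(
                    plan["sids"], plan["y"],
                    np.broadcast_to(s2, (S,) + s2.shape), ev, plan["indices"],
                    kernel=kern,
                )
            )
        return out

    return builder


def _pen_terms(etas, omega_inv, logdet_omega):
    # etas (S, c, m) -> (S, c)
    return np.einsum("scm,mk,sck->sc", etas, omega_inv, etas) + logdet_omega


def _q_group(gp, etas, omega_inv, logdet_omega, interaction, a0_fixed=None):
    """q for a stack of candidate etas per subject; etas (S, c, m)."""
    etas = np.asarray(etas)
    f, a = gp.ev(etas)
    f = np.real(f)
    a = np.real(a)
    if not interaction:
        a = np.broadcast_to(a0_fixed[:, :, None, :], a.shape)
    r = gp.y[:, None, :] - f  # (S, c, n)
    pen = _pen_terms(np.real(etas), omega_inv, logdet_omega)
    if gp.kernel is None:
        with np.errstate(over="ignore", invalid="ignore"):
            v = np.maximum(np.einsum("vscn,svn->scn", a * a, gp.s2), _VFLOOR)
            q = np.sum(np.log(v) + r * r / v, axis=2) + pen
        return np.where(np.isnan(q), np.inf, q)
    with np.errstate(all="ignore"):
        R = _group_R(gp, a)  # (S, c, n, n)
        sign, logdet = np.linalg.slogdet(R)
        x = np.linalg.solve(R, r[..., None])[..., 0]
        q = logdet + np.sum(r * x, axis=2) + pen
    return np.where((sign > 0) & ~np.isnan(q), q, np.inf)


def _group_R(gp, a):
    """Residual covariance stack (S, c, n, n) from coefficients
    a (tau, S, c, n) and the group's shared correlation kernel."""
    sq = np.sqrt(gp.s2).transpose(1, 0, 2)  # (tau, S, n)
    s = a * sq[:, :, None, :]  # (tau, S, c, n)
    R = (s[0][..., :, None] * s[0][..., None, :]) * gp.kernel[None, None]
    n = R.shape[-1]
    idx = np.arange(n)
    for v in range(1, s.shape[0]):
        R[..., idx, idx] += s[v] ** 2
    R[..., idx, idx] = np.maximum(R[..., idx, idx], _VFLOOR)
    return R


def _qgh_group(gp, eta, omega_inv, logdet_omega, interaction, a0_fixed=None):
    """q (S,), gradient (S, m) and GN Hessian (S, m, m) at eta (S, m).

    Transient overflows at extreme trial points are tolerated; the line
    search rejects the resulting non-finite values."""
    S, m = eta.shape
    E = np.repeat(eta[:, None, :], m + 1, axis=1).astype(complex)
    E[:, 1:, :] += 1j * _CSTEP * np.eye(m)[None, :, :]
    fc, ac = gp.ev(E)
    f0 = np.real(fc[:, 0, :])  # (S, n)
    F = np.imag(fc[:, 1:, :]).transpose(0, 2, 1) / _CSTEP  # (S, n, m)
    if interaction:
        a0 = np.real(ac[:, :, 0, :])  # (tau, S, n)
        dA = np.imag(ac[:, :, 1:, :]).transpose(0, 1, 3, 2) / _CSTEP  # (tau,S,n,m)
    else:
        a0 = a0_fixed
        dA = np.zeros(a0.shape + (m,))
    r = gp.y - f0
    pen = np.einsum("sm,mk,sk->s", eta, omega_inv, eta) + logdet_omega
    pen_g = 2.0 * eta @ omega_inv

    if gp.kernel is None:
        with np.errstate(over="ignore", invalid="ignore"):
            v = np.maximum(np.einsum("vsn,svn->sn", a0 * a0, gp.s2), _VFLOOR)
            dv = 2.0 * np.einsum("vsn,svn,vsnm->snm", a0, gp.s2, dA)  # (S,n,m)
            q = np.sum(np.log(v) + r * r / v, axis=1) + pen
            g = (
                np.einsum("snm,sn->sm", dv, 1.0 / v)
                - 2.0 * np.einsum("snm,sn->sm", F, r / v)
                - np.einsum("snm,sn->sm", dv, r * r / v**2)
                + pen_g
            )
            H = (
                2.0 * np.einsum("snl,sn,snk->slk", F, 1.0 / v, F)
                + np.einsum("snl,sn,snk->slk", dv, 1.0 / v**2, dv)
                + 2.0 * omega_inv[None, :, :]
            )
        return q, g, H

    # full residual covariance (autocorrelation kernel)
    K = gp.kernel
    sq = np.sqrt(gp.s2).transpose(1, 0, 2)  # (tau, S, n)
    s = a0 * sq  # (tau, S, n)
    ds = dA * sq[..., None]  # (tau, S, n, m)
    n = r.shape[1]
    idx = np.arange(n)
    R = (s[0][:, :, None] * s[0][:, None, :]) * K[None]
    for v_ in range(1, s.shape[0]):
        R[:, idx, idx] += s[v_] ** 2
    R[:, idx, idx] = np.maximum(R[:, idx, idx], _VFLOOR)
    # dR[s, l, i, j]
    outer = np.einsum("sil,sj->slij", ds[0], s[0])
    dR = (outer + outer.transpose(0, 1, 3, 2)) * K[None, None]
    for v_ in range(1, s.shape[0]):
        dR[:, :, idx, idx] += 2.0 * s[v_][:, None, :] * ds[v_].transpose(0, 2, 1)
    sign, logdet = np.linalg.slogdet(R)
    if np.any(sign <= 0):
        raise NumericalGuardError(
            f"residual covariance not PD for subject "
            f"{gp.sids[int(np.argmax(sign <= 0))]}"
        )
    Rinv_r = np.linalg.solve(R, r[..., None])[..., 0]  # (S, n)
    Rinv_F = np.linalg.solve(R, F)  # (S, n, m)
    Rinv_dR = np.linalg.solve(R[:, None], dR)  # (S, m, n, n)
    q = logdet + np.sum(r * Rinv_r, axis=1) + pen
    g = (
        np.einsum("slii->sl", Rinv_dR)
        - 2.0 * np.einsum("snl,sn->sl", F, Rinv_r)
        - np.einsum("sn,slnk,sk->sl", Rinv_r, dR, Rinv_r)
        + pen_g
    )
    H = (
        2.0 * np.einsum("snl,snk->slk", F, Rinv_F)
        + np.einsum("slij,skji->slk", Rinv_dR, Rinv_dR)
        + 2.0 * omega_inv[None, :, :]
    )
    return q, g, H


def _group_candidates(gp, omega, options, warm=None):
    """Per-subject candidate starts, uniform count K: zero + mceta draws
    (per-subject dedicated streams) or zero + warm."""
    S = gp.n_subjects
    m = omega.shape[0]
    cands = [np.zeros((S, 1, m))]
    if options.mceta > 0:
        L = np.linalg.cholesky(omega + 1e-12 * np.eye(m))
        draws = np.empty((S, options.mceta, m))
        for si, idx in enumerate(gp.indices):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(options.seed) % (2**31), int(idx)])
            )
            draws[si] = rng.standard_normal((options.mceta, m)) @ L.T
        cands.append(draws)
    elif warm is not None:
        cands.append(warm[:, None, :])
    return np.concatenate(cands, axis=1)  # (S, K, m)


def _solve_group(gp, omega, options, warm=None, omega_fact=None):
    """Batched MCETA + damped Newton for one ProblemGroup.

    Returns (eta (S, m), q (S,), H (S, m, m), converged (S,))."""
    if omega_fact is None:
        omega_fact = _omega_inverse(omega)
    omega_inv, logdet = omega_fact
    S = gp.n_subjects
    m = omega.shape[0]
    inter = options.interaction
    a0_fixed = None
    if not inter:
        _, a0 = gp.ev(np.zeros((S, 1, m)))
        a0_fixed = np.real(a0[:, :, 0, :])

    if m == 0:
        eta = np.zeros((S, 0))
        q = _q_group(gp, eta[:, None, :], omega_inv, logdet, inter, a0_fixed)[:, 0]
        return eta, q, np.zeros((S, 0, 0)), np.ones(S, bool)

    cands = _group_candidates(gp, omega, options, warm)
    qc = _q_group(gp, cands, omega_inv, logdet, inter, a0_fixed)  # (S, K)
    eta = cands[np.arange(S), np.argmin(qc, axis=1)]  # (S, m)
    return _newton_group(gp, eta, omega_inv, logdet, options, a0_fixed)


def _newton_group(gp, eta, omega_inv, logdet, options, a0_fixed=None):
    S, m = eta.shape
    inter = options.interaction
    q, g, H = _qgh_group(gp, eta, omega_inv, logdet, inter, a0_fixed)
    lam = np.zeros(S)
    done = np.zeros(S, bool)
    eye = np.eye(m)[None, :, :]
    for _ in range(options.max_inner_iter):
        gnorm = np.max(np.abs(g), axis=1)
        done |= gnorm < options.inner_tol * (1.0 + np.abs(q))
        if done.all():
            break
        Hd = H + lam[:, None, None] * eye
        try:
            step = -np.linalg.solve(Hd, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            lam = np.where(done, lam, np.maximum(10.0 * lam, 1e-6))
            continue
        step = np.where(done[:, None], 0.0, step)
        slope = np.sum(g * step, axis=1)  # (S,)
        trials = eta[:, None, :] + _LS_ALPHAS[None, :, None] * step[:, None, :]
        qt = _q_group(gp, trials, omega_inv, logdet, inter, a0_fixed)  # (S, A)
        armijo = qt <= q[:, None] + 1e-4 * _LS_ALPHAS[None, :] * slope[:, None]
        any_armijo = armijo.any(axis=1)
        j_armijo = np.argmax(armijo, axis=1)
        j_best = np.argmin(qt, axis=1)
        qt_best = qt[np.arange(S), j_best]
        fallback_ok = qt_best < q - 1e-12 * (1.0 + np.abs(q))
        take = ~done & (any_armijo | fallback_ok)
        j = np.where(any_armijo, j_armijo, j_best)
        new_eta = trials[np.arange(S), j]
        eta = np.where(take[:, None], new_eta, eta)
        lam = np.where(
            done, lam,
            np.where(
                any_armijo, lam * 0.25,
                np.where(fallback_ok, np.maximum(10.0 * lam, 1e-6),
                         np.maximum(100.0 * lam, 1e-4)),
            ),
        )
        done |= ~take & (lam > 1e8)  # stalled
        if take.any():
            q, g, H = _qgh_group(gp, eta, omega_inv, logdet, inter, a0_fixed)
    else:
        q, g, H = _qgh_group(gp, eta, omega_inv, logdet, inter, a0_fixed)
    gnorm = np.max(np.abs(g), axis=1)
    conv = gnorm < 1e-4 * (1.0 + np.abs(q))
    return eta, q, H, conv


# ---------------------------------------------------------------------------
# population OFV and outer fit


def evaluate_ofv(problems, omega, options, warm_ebes=None):
    """FOCE(-I) OFV over subject problems and/or problem groups.

    Returns ``(ofv, iofv: dict, ebes: dict, all_converged)``. iOFV_i is
    q_i(eta_hat) + log det(H_i / 2); the n log(2pi) constant is omitted."""
    omega_fact = _omega_inverse(omega)
    m = omega.shape[0]
    iofv, ebes = {}, {}
    ok = True
    for item in problems:
        if isinstance(item, ProblemGroup):
            warm = None
            if warm_ebes is not None:
                warm = np.stack(
                    [
                        np.asarray(w, float)
                        if (w := warm_ebes.get(sid)) is not None
                        and np.shape(w) == (m,)
                        else np.zeros(m)
                        for sid in item.sids
                    ]
                )
            eta, q, H, conv = _solve_group(item, omega, options, warm, omega_fact)
            ok = ok and bool(conv.all())
            if m:
                with np.errstate(invalid="ignore"):
                    sign, logdet_h = np.linalg.slogdet(H / 2.0)
                if np.any(~np.isfinite(logdet_h)):
                    sign = np.where(np.isfinite(logdet_h), sign, -1.0)
                if np.any(sign <= 0):
                    bad = item.sids[int(np.argmax(sign <= 0))]
                    raise NumericalGuardError(
                        f"indefinite inner Hessian for subject {bad}"
                    )
            else:
                logdet_h = np.zeros(len(item.sids))
            for si, sid in enumerate(item.sids):
                iofv[sid] = float(q[si] + logdet_h[si])
                ebes[sid] = eta[si]
            continue
        prob = item
        warm = None if warm_ebes is None else warm_ebes.get(prob.subject_id)
        if warm is not None and np.shape(warm) != (m,):
            warm = None
        eta, q, H, conv = _solve_subject(prob, omega, options, warm, omega_fact)
        ok = ok and conv
        if m:
            sign, logdet_h = np.linalg.slogdet(H / 2.0)
            if sign <= 0:
                raise NumericalGuardError(
                    f"indefinite inner Hessian for subject {prob.subject_id}"
                )
        else:
            logdet_h = 0.0
        iofv[prob.subject_id] = float(q + logdet_h)
        ebes[prob.subject_id] = eta
    return float(sum(iofv.values())), iofv, ebes, ok


def ofv(model, dataset, options=None):
    """Evaluate the FOCE(-I) OFV of a PopulationModel on a dataset at its
    current parameter values (no outer optimization)."""
    options = options or EstimationOptions()
    problems = make_group_builder(model, dataset.subjects())(model)
    omega = model.random_effects.omega()
    total, iofv, ebes, ok = evaluate_ofv(problems, omega, options)
    return FitResult(
        ofv=total,
        iofv=iofv,
        ebes=ebes,
        model=model,
        theta_hat=dict(model.parameters.theta),
        omega_hat=omega,
        sigma_hat=tuple(model.residual.sigma2),
        converged=ok,
        n_function_evals=1,
        data_fingerprint=dataset.fingerprint(),
        eta_labels=model.random_effects.labels(),
    )


# --- parameter packing for the outer optimization --------------------------

_LOG_SD_LO, _LOG_SD_HI = np.log(1e-4), np.log(50.0)


class ParameterPacker:
    """Maps the free parameters of a model (theta on log scale, Omega
    blocks in log-Cholesky form, residual variances as log-sd, extension
    parameters) to and from a flat vector with box bounds. Placeholder
    (fixed) Omega blocks are masked out."""

    def __init__(self, model, estimate_theta=True):
        self.estimate_theta = estimate_theta and hasattr(model, "parameters")
        self.entries = []
        self.bounds = []
        x0 = []
        if self.estimate_theta:
            for name in model.parameters.theta:
                v = np.log(model.parameters.theta[name])
                self.entries.append(("theta", name))
                x0.append(v)
                self.bounds.append((v - 4.0, v + 4.0))
        for bi, b in enumerate(model.random_effects.blocks):
            if b.fixed:
                continue
            L = np.linalg.cholesky(b.values + 1e-12 * np.eye(b.size))
            for i in range(b.size):
                self.entries.append(("omega_diag", (bi, i)))
                x0.append(np.log(max(L[i, i], 1.1e-4)))
                self.bounds.append((_LOG_SD_LO, _LOG_SD_HI))
                if b.correlated:
                    for j in range(i):
                        self.entries.append(("omega_off", (bi, i, j)))
                        x0.append(L[i, j])
                        self.bounds.append((-20.0, 20.0))
        for v in range(len(model.residual.sigma2)):
            self.entries.append(("sigma", v))
            x0.append(np.log(max(np.sqrt(model.residual.sigma2[v]), 1.1e-4)))
            self.bounds.append((_LOG_SD_LO, _LOG_SD_HI))
        if model.residual.power_theta is not None:
            self.entries.append(("power", None))
            x0.append(float(model.residual.power_theta))
            self.bounds.append((-5.0, 5.0))
        if model.residual.autocorr_tau is not None:
            self.entries.append(("autocorr", None))
            x0.append(np.log(max(model.residual.autocorr_tau, 1e-3)))
            self.bounds.append((np.log(1e-3), np.log(1e3)))
        if model.residual.time_step is not None:
            self.entries.append(("step_sigma", None))
            x0.append(np.log(max(np.sqrt(model.residual.time_step[1]), 1.1e-4)))
            self.bounds.append((_LOG_SD_LO, _LOG_SD_HI))
        self.x0 = np.array(x0, dtype=float)

    def unpack(self, x, template):
        """Return a copy of `template` with the packed values applied."""
        mdl = template.copy()
        chol = {}
        for val, (kind, ref) in zip(x, self.entries):
            if kind == "theta":
                mdl.parameters.theta[ref] = float(np.exp(val))
            elif kind == "omega_diag":
                bi, i = ref
                chol.setdefault(bi, {})[(i, i)] = np.exp(val)
            elif kind == "omega_off":
                bi, i, j = ref
                chol.setdefault(bi, {})[(i, j)] = val
            elif kind == "sigma":
                s2 = list(mdl.residual.sigma2)
                s2[ref] = float(np.exp(val) ** 2)
                mdl.residual.sigma2 = tuple(s2)
            elif kind == "power":
                mdl.residual.power_theta = float(val)
            elif kind == "autocorr":
                mdl.residual.autocorr_tau = float(np.exp(val))
            elif kind == "step_sigma":
                cut = mdl.residual.time_step[0]
                mdl.residual.time_step = (cut, float(np.exp(val) ** 2))
        for bi, vals in chol.items():
            b = mdl.random_effects.blocks[bi]
            L = np.zeros((b.size, b.size))
            for (i, j), v in vals.items():
                L[i, j] = v
            b.values = L @ L.T
        return mdl


def fit(model, dataset, options=None, estimate_theta=True, problems_builder=None):
    """Maximum-likelihood fit by FOCE(-I): outer quasi-Newton (L-BFGS-B)
    optimization of theta, Omega and Sigma (log-Cholesky parameterized,
    placeholder blocks masked out) over the subject-wise inner MAP
    problems, with EBE warm starts carried between outer iterations.

    ``problems_builder(model) -> list[SubjectProblem]`` may be supplied to
    fit objects other than a PopulationModel (the linearized model uses
    this hook)."""
    options = options or EstimationOptions()
    if problems_builder is None:
        problems_builder = make_group_builder(model, dataset.subjects())

    packer = ParameterPacker(model, estimate_theta)
    # warm EBEs are anchored to the incumbent best point and only updated
    # when the OFV improves (a ratchet): between improvements every
    # evaluation sees the same warm set, so the objective is a fixed,
    # deterministic function of x — history-dependent warm chains can
    # otherwise flip subjects between inner basins and feed the outer
    # optimizer inconsistent values
    best = {"ofv": np.inf, "warm": None}
    n_evals = {"n": 0}

    def objective(x):
        n_evals["n"] += 1
        mdl = packer.unpack(x, model)
        try:
            omega = mdl.random_effects.omega()
            total, _, ebes, _ = evaluate_ofv(
                problems_builder(mdl), omega, options,
                best["warm"] if options.use_warm_ebes else None,
            )
        except NumericalGuardError:
            return 1e12
        if not np.isfinite(total):
            return 1e12
        if options.use_warm_ebes and total < best["ofv"]:
            best["ofv"] = total
            best["warm"] = ebes
        return total

    if packer.x0.size == 0 or options.max_iter == 0:
        # nothing to optimize (or evaluation-only request)
        res_x, converged = packer.x0, True
    else:
        res = minimize(
            objective,
            packer.x0,
            method="L-BFGS-B",
            bounds=packer.bounds,
            options={
                "maxiter": options.max_iter,
                "ftol": options.outer_tol,
                "gtol": 1e-6,
                "eps": 1e-5,
                "maxcor": 25,
            },
        )
        res_x, converged = res.x, bool(res.success)

    fitted = packer.unpack(res_x, model)
    omega = fitted.random_effects.omega()
    total, iofv, ebes, inner_ok = evaluate_ofv(
        problems_builder(fitted), omega, options,
        best["warm"] if options.use_warm_ebes else None,
    )
    theta_hat = dict(fitted.parameters.theta) if hasattr(fitted, "parameters") else None
    return FitResult(
        ofv=float(total),
        iofv=iofv,
        ebes=ebes,
        model=fitted,
        theta_hat=theta_hat,
        omega_hat=omega,
        sigma_hat=tuple(fitted.residual.sigma2),
        converged=converged and inner_ok,
        n_function_evals=n_evals["n"] + 1,
        data_fingerprint=dataset.fingerprint() if dataset is not None else "",
        eta_labels=fitted.random_effects.labels(),
    )
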