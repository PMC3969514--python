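"""Domain types for nonlinear mixed-effects population PK models.

A :class:`PopulationModel` couples

* a closed-form structural model ``f(p_i, x_ij)`` (see :mod:`.structural`),
* a log-normal parameter model ``p_ki = theta_k * g_k(z_i) * exp(sum eta)``,
* a random-effect structure (blocks of between-subject and between-occasion
  variability with covariance Omega), and
* a residual-error model ``h(eps)`` with covariance Sigma and optional
  extension terms (eta-on-epsilon, power scaling, autocorrelation,
  time-step variances).

The residual model is linear in epsilon for every supported form, so the
per-observation residual-coefficient vector a_v = dh/deps_v fully describes
h; :func:`residual_coefficients` returns it (complex-step safe).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .structural import STRUCTURAL_KINDS, ConfigurationError, predict_profile

__all__ = [
    "StructuralModel",
    "ParameterModel",
    "EtaBlock",
    "RandomEffectStructure",
    "ResidualModel",
    "PopulationModel",
    "ObservationRecord",
    "individual_parameters",
    "predict",
    "residual_term",
    "ConfigurationError",
]

RV_TARGET = "RV"  # pseudo-target for eta-on-epsilon random effects


@dataclass(frozen=True)
class StructuralModel:
    """Closed-form structural model kind plus its parameter names."""

    kind: str

    @property
    def parameter_names(self) -> tuple:
        return STRUCTURAL_KINDS[self.kind]

    def __post_init__(self):
        if self.kind not in STRUCTURAL_KINDS:
            raise ConfigurationError(f"unsupported structural kind: {self.kind!r}")


@dataclass
class ParameterModel:
    """Typical values theta_k and optional multiplicative covariate models.

    ``covariate_functions`` maps a parameter name to a callable
    ``g(covariates: dict) -> float`` applied multiplicatively; absent
    entries default to the constant 1.
    """

    theta: dict
    covariate_functions: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.theta.items():
            if not v > 0:
                raise ConfigurationError(f"theta[{k!r}] must be positive, got {v}")


@dataclass
class EtaBlock:
    """One variance block of the random-effect structure.

    A BSV block contributes one eta per target per subject; a BOV block
    contributes one eta per target per occasion, all occasions sharing the
    same covariance values. ``fixed`` marks a placeholder block whose
    (small) variance is excluded from estimation; placeholders exist so
    that the linearization carries derivatives for planned extensions.
    """

    targets: tuple
    values: np.ndarray
    level: str = "bsv"
    fixed: bool = False
    correlated: bool = False
    label: str = ""

    def __post_init__(self):
        self.targets = tuple(self.targets)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        k = len(self.targets)
        if self.values.shape != (k, k):
            raise ConfigurationError(
                f"block {self.label or self.targets}: covariance shape "
                f"{self.values.shape} does not match {k} targets"
            )
        if self.level not in ("bsv", "bov"):
            raise ConfigurationError(f"unknown eta level {self.level!r}")
        if self.fixed and np.any(np.diag(self.values) <= 0):
            raise ConfigurationError(
                "placeholder variances must be strictly positive; fixing a "
                "variance to zero would leave no derivatives to linearize"
            )
        _check_psd(self.values, f"Omega block {self.label or self.targets}")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class RandomEffectStructure:
    """All eta blocks of a model plus the number of dosing occasions."""

    blocks: list
    n_occasions: int = 1

    @property
    def m(self) -> int:
        """Length of the per-subject eta vector (BOV blocks replicated)."""
        return sum(
            b.size * (self.n_occasions if b.level == "bov" else 1) for b in self.blocks
        )

    def layout(self):
        """Expanded per-subject eta layout.

        Returns a list of ``(block_index, within_block_index, target,
        level, occasion)`` tuples; ``occasion`` is None for BSV entries and
        1-based for BOV entries.
        """
        out = []
        for bi, b in enumerate(self.blocks):
            if b.level == "bsv":
                for wi, t in enumerate(b.targets):
                    out.append((bi, wi, t, "bsv", None))
            else:
                for occ in range(1, self.n_occasions + 1):
                    for wi, t in enumerate(b.targets):
                        out.append((bi, wi, t, "bov", occ))
        return out

    def labels(self):
        return [
            t if occ is None else f"{t}(OCC{occ})" for _, _, t, _, occ in self.layout()
        ]

    def omega(self) -> np.ndarray:
        """Assemble the per-subject (m x m) covariance matrix."""
        m = self.m
        om = np.zeros((m, m))
        i = 0
        for b in self.blocks:
            reps = self.n_occasions if b.level == "bov" else 1
            for _ in range(reps):
                k = b.size
                om[i : i + k, i : i + k] = b.values
                i += k
        return om

    def fixed_mask(self) -> np.ndarray:
        """Boolean per-eta mask, True where the variance is a fixed placeholder."""
        return np.array(
            [self.blocks[bi].fixed for bi, _, _, _, _ in self.layout()], dtype=bool
        )

    def __post_init__(self):
        if self.n_occasions < 1:
            raise ConfigurationError("n_occasions must be >= 1")
        labels = [b.label for b in self.blocks if b.label]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("duplicate eta block labels")


@dataclass
class ResidualModel:
    """Residual-error model h(eps) with optional extension terms.

    ``sigma2`` holds the epsilon variances: ``(s2,)`` for additive or
    proportional, ``(s2_prop, s2_add)`` for combined. Extension state:

    * ``power_theta`` — h multiplied by F**power_theta (F = individual
      prediction); None means the extension is absent, 0.0 is its null.
    * ``autocorr_tau`` — exponential time-correlation scale (h) applied to
      the first epsilon component; None = absent.
    * ``time_step`` — ``(cut_time, sigma2_after)``: the first component's
      variance switches to sigma2_after at t >= cut_time; None = absent.
    """

    form: str
    sigma2: tuple
    power_theta: float = None
    autocorr_tau: float = None
    time_step: tuple = None

    def __post_init__(self):
        if self.form not in ("additive", "proportional", "combined"):
            raise ConfigurationError(f"unknown residual form {self.form!r}")
        self.sigma2 = tuple(float(s) for s in np.atleast_1d(self.sigma2))
        if len(self.sigma2) != self.tau:
            raise ConfigurationError(
                f"{self.form} residual model needs {self.tau} sigma2 value(s)"
            )
        if any(s < 0 for s in self.sigma2):
            raise ConfigurationError("sigma2 entries must be non-negative")

    @property
    def tau(self) -> int:
        return 2 if self.form == "combined" else 1

    def sigma(self) -> np.ndarray:
        """Sigma as a (tau x tau) diagonal covariance matrix."""
        return np.diag(self.sigma2)

    def obs_sigma2(self, times) -> np.ndarray:
        """Per-observation epsilon variances, shape (tau, n).

        Applies the time-step extension to the first component."""
        times = np.asarray(times, dtype=float)
        s2 = np.tile(np.asarray(self.sigma2, dtype=float)[:, None], (1, times.size))
        if self.time_step is not None:
            cut, s2_after = self.time_step
            s2[0, times >= cut] = s2_after
        return s2

    def kernel(self, times) -> np.ndarray:
        """Correlation kernel of the first epsilon component over the
        subject's observation times (identity unless autocorrelation is
        active). Continuous-AR(1): corr = exp(-|t_j - t_j'| / tau_corr)."""
        times = np.asarray(times, dtype=float)
        n = times.size
        if self.autocorr_tau is None:
            return np.eye(n)
        tau = max(float(self.autocorr_tau), 1e-12)
        return np.exp(-np.abs(times[:, None] - times[None, :]) / tau)


@dataclass
class PopulationModel:
    structural: StructuralModel
    parameters: ParameterModel
    random_effects: RandomEffectStructure
    residual: ResidualModel
    log_dv: bool = False  # model log-concentrations (additive error in log space)

    def __post_init__(self):
        names = set(self.structural.parameter_names)
        for k in names:
            if k not in self.parameters.theta:
                raise ConfigurationError(f"theta missing structural parameter {k!r}")
        for b in self.random_effects.blocks:
            for t in b.targets:
                if t != RV_TARGET and t not in names:
                    raise ConfigurationError(
                        f"eta block targets unknown parameter {t!r}"
                    )

    def copy(self) -> "PopulationModel":
        return copy.deepcopy(self)

    @property
    def m(self) -> int:
        return self.random_effects.m


@dataclass(frozen=True)
class ObservationRecord:
    """One row of a longitudinal dataset (dose or observation)."""

    subject_id: object
    time: float
    occasion: int = 1
    dv: float = None
    is_dose: bool = False
    amount: float = None
    rate: float = 0.0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ConfigurationError("time must be non-negative")
        if self.is_dose and self.amount is None:
            raise ConfigurationError("dose records need an amount")
        if not self.is_dose and self.dv is None:
            raise ConfigurationError("observation records need a DV")


def individual_parameters(model, eta, covariates=None, occasion=1):
    """Individual parameters p_ki = theta_k * g_k(z_i) * exp(sum eta_lki).

    BOV entries are selected by ``occasion`` (1-based). Returns a dict
    keyed by parameter name; complex-step safe in ``eta``.
    """
    res = model.random_effects
    eta = np.asarray(eta)
    if eta.shape != (res.m,):
        raise ConfigurationError(f"eta must have length {res.m}, got {eta.shape}")
    if not 1 <= occasion <= res.n_occasions:
        raise ConfigurationError(f"occasion {occasion} out of range")
    log_bump = {}
    for idx, (_, _, target, level, occ) in enumerate(res.layout()):
        if target == RV_TARGET:
            continue
        if level == "bov" and occ != occasion:
            continue
        log_bump[target] = log_bump.get(target, 0.0) + eta[idx]
    p = {}
    for k, th in model.parameters.theta.items():
        g = model.parameters.covariate_functions.get(k)
        if g is not None:
            try:
                gv = g(covariates or {})
            except KeyError as e:
                raise ConfigurationError(f"unknown covariate {e} for g_{k}") from e
        else:
            gv = 1.0
        p[k] = th * gv * np.exp(log_bump.get(k, 0.0))
    return p


def rv_log_factor(model, eta, occasion=1):
    """Sum of eta entries targeting the residual error (eta-on-epsilon)."""
    res = model.random_effects
    tot = 0.0
    for idx, (_, _, target, level, occ) in enumerate(res.layout()):
        if target != RV_TARGET:
            continue
        if level == "bov" and occ != occasion:
            continue
        tot = tot + eta[idx]
    return tot


def predict(model, p, record, dose_history):
    """Predicted concentration f for one observation record.

    ``dose_history`` is a list of dose :class:`ObservationRecord`; doses at
    or after ``record.time`` contribute nothing (prediction is 0 before the
    first dose)."""
    doses = [r for r in dose_history if r.is_dose]
    if not doses:
        raise ConfigurationError("dose history contains no dose records")
    f = predict_profile(
        model.structural.kind,
        p,
        np.array([record.time]),
        np.array([r.time for r in doses]),
        np.array([r.amount for r in doses]),
        np.array([r.rate or 0.0 for r in doses]),
    )
    return float(np.real(f[0]))


def residual_coefficients(model, f, times, eta=None, occasions=None):
    """Residual coefficients a_vj = dh_ij/deps_vj, shape (tau, n).

    Includes extension factors: eta-on-epsilon ``exp(eta_RV)`` and the
    power term ``F**power_theta`` multiply every component. Complex-step
    safe in ``eta`` and ``f``.
    """
    f = np.asarray(f)
    n = f.size
    resid = model.residual
    if resid.form == "additive":
        a = np.ones((1, n), dtype=f.dtype)
    elif resid.form == "proportional":
        a = f[None, :].copy()
    else:  # combined: f*eps1 + eps2
        a = np.vstack([f, np.ones(n, dtype=f.dtype)])
    factor = np.ones(n, dtype=f.dtype)
    if eta is not None:
        if occasions is None:
            occasions = np.ones(n, dtype=int)
        occ_arr = np.asarray(occasions)
        for occ in np.unique(occ_arr):
            lf = rv_log_factor(model, eta, occasion=int(occ))
            sel = occ_arr == occ
            factor = np.where(sel, factor * np.exp(lf), factor)
    if resid.power_theta is not None:
        fpos = np.where(np.real(f) > 1e-12, f, 1e-12)
        factor = factor * fpos ** resid.power_theta
    return a * factor[None, :]


def residual_term(model, f, eps, record=None, eta=None):
    """Residual error h for one observation given an epsilon draw."""
    eps = np.atleast_1d(np.asarray(eps, dtype=float))
    if eps.size != model.residual.tau:
        raise ConfigurationError(
            f"eps must have length {model.residual.tau}, got {eps.size}"
        )
    t = np.array([0.0 if record is None else record.time])
    occ = np.array([1 if record is None else record.occasion])
    a = residual_coefficients(
        model, np.array([f], dtype=float), t, eta=eta, occasions=occ
    )
    return float(np.real(a[:, 0] @ eps))


def _check_psd(mat, what):
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigurationError(f"{what} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if np.min(w) < -1e-10 * max(1.0, np.max(np.abs(w))):
        raise ConfigurationError(f"{what} is not positive semi-definite")


def with_updated_block(res: RandomEffectStructure, index: int, **kw):
    """Return a copy of `res` with block `index` replaced."""
    blocks = list(res.blocks)
    blocks[index] = replace(blocks[index], **kw)
    return RandomEffectStructure(blocks=blocks, n_occasions=res.n_occasions)
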