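"""Closed-form structural PK models.

All predictions are analytic superpositions over the dose history, so no ODE
solver is needed. Every kernel accepts complex-valued parameters: partial
derivatives with respect to parameters (and hence with respect to the random
effects that scale them) are obtained by the complex-step method, which is
exact to machine precision. Piecewise switching is always done on (real)
times, never on parameters, so complex steps remain valid.

Parameters may also be 1-d arrays (a batch of parameter sets); the profile
is then returned with a leading batch axis. The estimation engine exploits
this to evaluate a point and all its complex-step perturbations in a single
call.

A module-level counter tracks every structural-model evaluation. Fitting the
linearized model must not touch the structural model at all; the counter is
the instrument that proves it.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "STRUCTURAL_KINDS",
    "predict_profile",
    "structural_call_count",
    "count_structural_calls",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Invalid model or run configuration."""


#: supported model kinds -> required parameter names (order matters)
STRUCTURAL_KINDS = {
    "one_compartment_oral": ("CL", "V", "KA"),
    "one_compartment_infusion": ("CL", "V"),
    "one_compartment_transit_oral": ("CL", "V", "KA", "MTT"),
}

# number of transit compartments is fixed at one; the transit rate follows
# the (n+1)/MTT convention, so ktr = 2/MTT
N_TRANSIT = 1

_CALLS = {"n": 0}


def structural_call_count() -> int:
    """Total number of structural-model profile evaluations so far."""
    return _CALLS["n"]


@contextmanager
def count_structural_calls():
    """Context manager yielding a dict whose 'n' entry is the number of
    structural evaluations performed inside the block."""
    start = _CALLS["n"]
    box = {"n": 0}
    try:
        yield box
    finally:
        box["n"] = _CALLS["n"] - start


def _batch(x):
    x = np.asarray(x)
    if x.ndim == 0:
        return x.reshape(1, 1, 1), True
    return x[:, None, None], False


def _sep(a, b, rel=1e-9):
    """Nudge entries of b away from a where the two rates (real parts)
    nearly coincide. The multi-exponential solutions have removable
    singularities at equal rates; a relative nudge keeps evaluation finite
    while perturbing the profile by O(rel)."""
    ra, rb = np.real(a), np.real(b)
    close = np.abs(ra - rb) < rel * np.maximum(1.0, np.abs(ra))
    if not close.any():
        return b
    return np.where(close, b * (1.0 + 1e-6) + 1e-12, b)


def dose_geometry(times, dose_times, dose_amounts, dose_rates):
    """Precompute the time-geometry arrays shared by every evaluation of a
    subject's profile (elapsed times, active-dose masks, infusion splits)."""
    times = np.asarray(times, dtype=float)
    dt = np.asarray(dose_times, dtype=float)
    amt = np.asarray(dose_amounts, dtype=float)
    rate = np.asarray(dose_rates, dtype=float)
    if dt.size == 0:
        raise ConfigurationError("dose history is empty")
    delta = times[:, None] - dt[None, :]  # (n, d)
    active = delta > 0.0
    d = np.where(active, delta, 0.0)[None, :, :]
    is_inf = rate > 0.0
    tinf = np.where(is_inf, amt / np.where(is_inf, rate, 1.0), 0.0)
    during = np.minimum(d, tinf[None, None, :])
    return {
        "times": times,
        "amt": amt,
        "rate": rate,
        "active": active[None, :, :],
        "d": d,
        "is_inf": is_inf[None, None, :],
        "during": during,
        "after": d - during,
    }


def predict_profile(kind, params, times, dose_times, dose_amounts, dose_rates,
                    geometry=None):
    """Concentration at `times` for one subject under superposition of doses.

    Parameters
    ----------
    kind : str
        One of ``STRUCTURAL_KINDS``.
    params : mapping
        Parameter values keyed by name; scalars or matching 1-d arrays
        (a batch of parameter sets, possibly complex).
    times : array (n,)
        Observation times in hours, non-negative reals.
    dose_times, dose_amounts, dose_rates : arrays (d,)
        Dose history. ``rate > 0`` denotes a constant-rate infusion of
        duration ``amount / rate``; ``rate == 0`` is a bolus (instantaneous
        input into the absorption site for the oral kinds).

    Returns
    -------
    array (n,) for scalar parameters, (c, n) for a batch of c sets
        Predicted concentrations; zero before the first dose.
    """
    if kind not in STRUCTURAL_KINDS:
        raise ConfigurationError(f"unsupported structural kind: {kind!r}")
    _CALLS["n"] += 1

    if geometry is None:
        geometry = dose_geometry(times, dose_times, dose_amounts, dose_rates)
    amt = geometry["amt"]
    active = geometry["active"]
    d = geometry["d"]

    CL, scalar = _batch(params["CL"])
    V, _ = _batch(params["V"])
    ke = CL / V

    if kind == "one_compartment_infusion":
        rate = geometry["rate"]
        c_inf = (rate[None, None, :] / CL) * (
            1.0 - np.exp(-ke * geometry["during"])
        ) * np.exp(-ke * geometry["after"])
        c_bol = (amt[None, None, :] / V) * np.exp(-ke * d)
        c = np.where(geometry["is_inf"], c_inf, c_bol)
    elif kind == "one_compartment_oral":
        KA, _ = _batch(params["KA"])
        KA = _sep(ke, KA)
        c = (amt[None, None, :] * KA / (V * (KA - ke))) * (
            np.exp(-ke * d) - np.exp(-KA * d)
        )
    else:
        # one transit compartment feeding a first-order absorption
        # compartment: dose -> transit (ktr) -> depot (KA) -> central (ke)
        KA, _ = _batch(params["KA"])
        MTT, _ = _batch(params["MTT"])
        KA = _sep(ke, KA)
        r1 = _sep(ke, _sep(KA, (N_TRANSIT + 1) / MTT))
        r2, r3 = KA, ke
        coef = amt[None, None, :] * r1 * r2 / V
        b1 = np.exp(-r1 * d) / ((r2 - r1) * (r3 - r1))
        b2 = np.exp(-r2 * d) / ((r1 - r2) * (r3 - r2))
        b3 = np.exp(-r3 * d) / ((r1 - r3) * (r2 - r3))
        c = coef * (b1 + b2 + b3)

    conc = np.sum(np.where(active, c, 0.0), axis=2)  # (c, n)
    if np.iscomplexobj(conc):
        conc = np.maximum(np.real(conc), 0.0) + 1j * np.imag(conc)
    else:
        conc = np.maximum(conc, 0.0)
    return conc[0] if scalar else conc
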