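"""State-vector layout, seed state and cached paced steady states.

The ODE unknowns are documented in :mod:`atriasim.rhs` (stable index map).
Because tabulated steady-state initial values are not part of the shipped
inputs, the package derives them: a physically reasonable quiescent seed
state (:func:`seed_state`) is paced at 1 Hz for 10 minutes of model time and
the final diastolic state is cached as a JSON fixture under ``data/``.
:func:`default_initial_state` returns that cached state.
"""

from __future__ import annotations

import json
import math
from importlib import resources

import numpy as np

from . import rhs as R
from .params import Parameters
from .geometry import build_geometry


class StateLayout:
    """Name <-> index mapping for the state vector."""

    names = tuple(R.STATE_NAMES)
    index = {n: i for i, n in enumerate(names)}
    n_states = R.N_STATES

    @classmethod
    def idx(cls, name: str) -> int:
        try:
            return cls.index[name]
        except KeyError:
            raise KeyError(f"unknown state name: {name!r}") from None


VARIANTS = ("vCa", "vCaNass")


def seed_state(params: Parameters | None = None, V: float = -77.0,
               Na_i: float = 9.3, K_i: float = 134.0,
               Ca_i: float = 1.6e-4, Ca_sr: float = 0.62) -> np.ndarray:
    """Quiescent seed state: gates at their V-dependent steady state, uniform
    Ca2+ fields, SERCA intermediate and RyR gates at local equilibrium."""
    p = params or Parameters()
    y = np.zeros(R.N_STATES)
    y[R.IV] = V
    m_inf, _, h_inf, _, _, _ = R.na_gates(V)
    y[R.IM], y[R.IH1], y[R.IH2] = m_inf, h_inf, h_inf
    d_inf, _, f_inf, _, _, _ = R.cal_gates(V)
    y[R.ID], y[R.IF1], y[R.IF2] = d_inf, f_inf, f_inf
    y[R.IFCA] = R.fca_gate(Ca_i, p.k_fca, p.n_fca)
    r_inf, _, s_inf, _, rs_inf, _, ss_inf, _ = R.to_sus_gates(V)
    y[R.IR_TO], y[R.IS_TO] = r_inf, s_inf
    y[R.IR_SUS], y[R.IS_SUS] = rs_inf, ss_inf
    n_inf, _, pa_inf, _ = R.ks_kr_gates(V)
    y[R.IN_KS], y[R.IPA_KR] = n_inf, pa_inf
    y_inf, _ = R.f_gate(V)
    y[R.IY_F] = y_inf
    y[R.INAI] = Na_i
    y[R.IKI] = K_i
    y[R.INASS] = Na_i
    y[R.ICASS] = Ca_i
    y[R.ICAB0:R.ICAB0 + R.N_BULK] = Ca_i
    y[R.ICASR0:R.ICASR0 + R.N_BULK] = Ca_sr
    # SERCA intermediate at its cytosolic-side equilibrium
    k1, k2 = p.serca_k1, p.serca_k2
    A_eq = p.serca_cpumps * k1 * Ca_i**2 / (k1 * Ca_i**2 + k2)
    y[R.ISERCA0:R.ISERCA0 + 4] = A_eq
    # RyR gates at local steady state
    pk = p.pack(build_geometry())
    for u in range(4):
        ca_loc = Ca_i
        o_inf, c_inf, a_inf, _ = R.ryr_steady_states(ca_loc, Ca_sr, 0.2, pk)
        # iterate adaptation to a self-consistent fixed point
        a = a_inf
        for _ in range(5):
            o_inf, c_inf, a_inf, _ = R.ryr_steady_states(ca_loc, Ca_sr, a, pk)
            a = a_inf
        io = R.IRYR0 + 3 * u
        y[io], y[io + 1], y[io + 2] = o_inf, c_inf, a
    return y


def _fixture_name(variant: str) -> str:
    return f"steady_state_1hz_{variant.lower()}.json"


def default_initial_state(variant: str = "vCa") -> np.ndarray:
    """1 Hz paced steady-state initial conditions for a model variant.

    Loads the cached paced state produced by ``scripts``/package tooling
    (10 min of 1 Hz pacing from :func:`seed_state`).  Falls back to the seed
    state if no fixture has been generated for the variant.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    path = resources.files("atriasim").joinpath("data/" + _fixture_name(variant))
    try:
        with path.open("r") as fh:
            data = json.load(fh)
    except FileNotFoundError:
        return seed_state()
    y = np.asarray([data["state"][n] for n in StateLayout.names], dtype=float)
    return y


def quiescent_state(variant: str = "vCa") -> np.ndarray:
    """Quiescent (unpaced) steady state; the starting point of the
    rate-dependence protocols.  Cached fixture for vCa; other variants fall
    back to the paced state of the variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    path = resources.files("atriasim").joinpath("data/quiescent_vca.json")
    try:
        with path.open("r") as fh:
            data = json.load(fh)
    except FileNotFoundError:
        return default_initial_state(variant)
    y = np.asarray([data["state"][n] for n in StateLayout.names], dtype=float)
    return y


def save_steady_state(y: np.ndarray, variant: str, path=None) -> None:
    """Serialize a paced state as the JSON fixture for ``variant``."""
    payload = {
        "variant": variant,
        "protocol": "1 Hz pacing, 600 s from seed_state()",
        "state": {n: float(v) for n, v in zip(StateLayout.names, y)},
    }
    if path is None:
        path = resources.files("atriasim").joinpath("data/" + _fixture_name(variant))
    with open(str(path), "w") as fh:
        json.dump(payload, fh, indent=1)
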