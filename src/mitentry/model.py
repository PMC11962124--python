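"""Deterministic ODE model of mitotic entry under graded PLK1 inhibition.

The network follows the classic bistable mitotic-entry switch: CDK1-cyclin B
is held inactive in G2 by Wee1/Myt1-mediated Thr14/Tyr15 phosphorylation and
is activated by the Cdc25 phosphatase.  Cdc25 itself carries two activating
phosphorylations; the bi-phosphorylated form ``Cdc25pp`` is the active
species.  Two positive feedback loops (CDK1 activates Cdc25, CDK1 inhibits
Wee1) and a double-negative loop through the counteracting phosphatase
PP2A-B55 make activation switch-like and bistable.

PLK1 enters the network as a CDK1-independent activator of Cdc25, operating
downstream of CDK2-cyclin A::

    [Plk1] = f_Plk1 * [CycACdk2_Tot]

where ``f_Plk1`` interpolates between fully active (1) and fully inhibited
(0) PLK1.  The Cdc25 phosphorylation/dephosphorylation balance is

    d[Cdc25]/dt   =  (k_PPX,Y15 + k_B55,Cdc25*[PP2AB55]) * [Cdc25p]
                   - (k_Cdk1,Cdc25*V_Cdk1 + k_Plk1,Cdc25*[Plk1]) * [Cdc25]
    d[Cdc25pp]/dt = -(k_PPX,Y15 + k_B55,Cdc25*[PP2AB55]) * [Cdc25pp]
                   + (k_Cdk1,Cdc25*V_Cdk1 + k_Plk1,Cdc25*[Plk1]) * [Cdc25p]

with the mono-phosphorylated pool given by conservation,
``[Cdc25p] = [Cdc25_Tot] - [Cdc25] - [Cdc25pp]``, and ``V_Cdk1 =
[CycBCdk1]``.  Nuclear envelope breakdown (NEBD) is declared when a generic
CDK1-cyclin B substrate

    d[Subp]/dt = k_Cdk1,Sub*V_Cdk1*([Sub_Tot]-[Subp]) - k_B55,Sub*[PP2AB55]*[Subp]

reaches 30% phosphorylation.

G2 entry is modelled as a step increase of CDK2-cyclin A activity from 0 to
its cell-specific value at t = 0; time is measured in hours from that step.
The auxiliary Tyr15/Wee1 and PP2A-B55 regulation uses mass-action forms (see
``network_rhs``) and can be clamped ("reduced mode") so the Cdc25 and
substrate equations can be exercised in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "NetworkState",
    "CellTrajectory",
    "Clamp",
    "STATE_NAMES",
    "default_parameters",
    "plk1_activity",
    "cdc25_rhs",
    "substrate_rhs",
    "network_rhs",
    "interphase_state",
    "simulate_cell",
    "detect_nebd",
    "IntegrationError",
    "InvariantViolation",
]

#: Order of the dynamical variables in the state vector.
STATE_NAMES = ("cdc25", "cdc25pp", "cycbcdk1", "wee1", "pp2ab55", "subp")


class InvariantViolation(ValueError):
    """A state or parameter set breaks a model invariant."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and pool sizes for one simulated cell.

    Rate constants are in 1/h (first order) or 1/(a.u.*h) (second order);
    concentrations and totals in arbitrary units.  ``f_plk1`` scales PLK1
    activity between fully active (1.0) and completely inhibited (0.0);
    ``cyca_cdk2_tot`` is the cell's CDK2-cyclin A activity after G2 entry
    and is the quantity varied between cells in population simulations.

    The ``aux_*`` constants parameterise the Tyr15/Wee1 and PP2A-B55
    regulation around the printed Cdc25/substrate equations:

    - ``aux_k_cdc25_cdk1``: activation of CDK1 by active Cdc25pp
    - ``aux_k_ppx_t14``: weak constitutive Thr14/Tyr15 dephosphorylation
    - ``aux_k_wee1_cdk1``: Wee1-mediated re-inhibition of CDK1
    - ``aux_k_b55_wee1``: PP2A-B55-mediated re-activation of Wee1
    - ``aux_k_cdk1_wee1``: inhibitory phosphorylation of Wee1 by CDK1
    - ``aux_k_cyca_wee1``: inhibitory phosphorylation of Wee1 by CDK2-cyclin A
    - ``aux_k_b55_act``: re-activation of PP2A-B55
    - ``aux_k_cdk1_b55``: CDK1-driven inhibition of PP2A-B55 (the
      Greatwall/ENSA branch collapsed into a single inhibitory step)
    """

    k_ppx_y15: float
    k_b55_cdc25: float
    k_cdk1_cdc25: float
    k_plk1_cdc25: float
    k_cdk1_sub: float
    k_b55_sub: float
    cdc25_tot: float
    cycbcdk1_tot: float
    sub_tot: float
    cyca_cdk2_tot: float
    f_plk1: float = 1.0
    wee1_tot: float = 1.0
    b55_tot: float = 1.0
    aux_k_cdc25_cdk1: float = 0.0
    aux_k_ppx_t14: float = 0.0
    aux_k_wee1_cdk1: float = 0.0
    aux_k_b55_wee1: float = 0.0
    aux_k_cdk1_wee1: float = 0.0
    aux_k_cyca_wee1: float = 0.0
    aux_k_b55_act: float = 0.0
    aux_k_cdk1_b55: float = 0.0
    nebd_threshold: float = 0.30

    def __post_init__(self) -> None:
        for name in (
            "k_ppx_y15", "k_b55_cdc25", "k_cdk1_cdc25", "k_plk1_cdc25",
            "k_cdk1_sub", "k_b55_sub", "cdc25_tot", "cycbcdk1_tot",
            "sub_tot", "cyca_cdk2_tot", "wee1_tot", "b55_tot",
            "aux_k_cdc25_cdk1", "aux_k_ppx_t14", "aux_k_wee1_cdk1",
            "aux_k_b55_wee1", "aux_k_cdk1_wee1", "aux_k_cyca_wee1",
            "aux_k_b55_act", "aux_k_cdk1_b55",
        ):
            if getattr(self, name) < 0:
                raise InvariantViolation(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f_plk1 <= 1.0:
            raise InvariantViolation(f"f_plk1 must lie in [0, 1], got {self.f_plk1}")
        if not 0.0 < self.nebd_threshold < 1.0:
            raise InvariantViolation(
                f"nebd_threshold must lie in (0, 1), got {self.nebd_threshold}"
            )

    @property
    def plk1(self) -> float:
        """PLK1 activity implied by the inhibition fraction."""
        return plk1_activity(self.f_plk1, self.cyca_cdk2_tot)

    def with_(self, **kwargs) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "KineticParameters":
        return cls(**dict(d))


@dataclass(frozen=True)
class NetworkState:
    """Concentrations of the dynamical species at one instant.

    ``cdc25`` is the unphosphorylated, ``cdc25pp`` the bi-phosphorylated
    (active) form; the mono-phosphorylated pool follows by conservation.
    ``wee1`` and ``pp2ab55`` are the active fractions of the auxiliary
    kinase/phosphatase pools; ``subp`` is the phosphorylated CDK1 substrate
    whose fraction defines NEBD.
    """

    cdc25: float
    cdc25pp: float
    cycbcdk1: float
    wee1: float
    pp2ab55: float
    subp: float

    def cdc25p(self, params: KineticParameters) -> float:
        """Mono-phosphorylated Cdc25 from the conservation relation."""
        rem = params.cdc25_tot - self.cdc25 - self.cdc25pp
        if rem < -1e-7 * max(params.cdc25_tot, 1.0):
            raise InvariantViolation(
                f"cdc25 + cdc25pp = {self.cdc25 + self.cdc25pp} exceeds "
                f"cdc25_tot = {params.cdc25_tot}"
            )
        return max(rem, 0.0)

    @property
    def v_cdk1(self) -> float:
        """CDK1-cyclin B kinase activity (equal to the active complex)."""
        return self.cycbcdk1

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.cdc25, self.cdc25pp, self.cycbcdk1, self.wee1, self.pp2ab55, self.subp]
        )

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "NetworkState":
        if len(y) != 6:
            raise ValueError(f"state vector must have 6 entries, got {len(y)}")
        return cls(*map(float, y))


@dataclass(frozen=True)
class Clamp:
    """Reduced-mode clamps: hold PP2A-B55 and/or CDK1 activity constant.

    With both clamps set the Cdc25 three-state subsystem and the substrate
    equation become linear and can be checked against closed forms.
    """

    v_cdk1: float | None = None
    pp2ab55: float | None = None


@dataclass
class CellTrajectory:
    """A single-cell simulation from G2 entry to the horizon.

    ``nebd_time`` is the first time the substrate fraction reaches the NEBD
    threshold (linearly interpolated); ``None`` means censored at
    ``censor_time``.
    """

    times: np.ndarray
    states: np.ndarray  # (n_times, 6) columns in STATE_NAMES order
    params: KineticParameters
    nebd_time: float | None
    censor_time: float

    @property
    def censored(self) -> bool:
        return self.nebd_time is None

    @property
    def substrate_fraction(self) -> np.ndarray:
        return self.states[:, 5] / self.params.sub_tot

    def state_at(self, index: int) -> NetworkState:
        return NetworkState.from_vector(self.states[index])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df["sub_fraction"] = self.substrate_fraction
        return df


def plk1_activity(f_plk1: float, cyca_cdk2_tot: float) -> float:
    """PLK1 activity as a linear function of CDK2-cyclin A.

    PLK1 is activated downstream of CDK2-cyclin A; pharmacological
    inhibition scales this linearly through ``f_plk1`` in [0, 1].
    """
    if not 0.0 <= f_plk1 <= 1.0:
        raise InvariantViolation(f"f_plk1 must lie in [0, 1], got {f_plk1}")
    if cyca_cdk2_tot < 0:
        raise InvariantViolation(f"cyca_cdk2_tot must be >= 0, got {cyca_cdk2_tot}")
    return f_plk1 * cyca_cdk2_tot


def cdc25_rhs(
    state: NetworkState,
    params: KineticParameters,
    clamp: Clamp | None = None,
) -> tuple[float, float]:
    """Time derivatives of the unphosphorylated and active Cdc25 pools."""
    v_cdk1 = state.v_cdk1 if clamp is None or clamp.v_cdk1 is None else clamp.v_cdk1
    b55 = state.pp2ab55 if clamp is None or clamp.pp2ab55 is None else clamp.pp2ab55
    cdc25p = state.cdc25p(params)
    dephos = params.k_ppx_y15 + params.k_b55_cdc25 * b55
    phos = params.k_cdk1_cdc25 * v_cdk1 + params.k_plk1_cdc25 * params.plk1
    d_cdc25 = dephos * cdc25p - phos * state.cdc25
    d_cdc25pp = -dephos * state.cdc25pp + phos * cdc25p
    return d_cdc25, d_cdc25pp


def substrate_rhs(
    state: NetworkState,
    params: KineticParameters,
    clamp: Clamp | None = None,
) -> float:
    """Time derivative of the phosphorylated CDK1 substrate."""
    v_cdk1 = state.v_cdk1 if clamp is None or clamp.v_cdk1 is None else clamp.v_cdk1
    b55 = state.pp2ab55 if clamp is None or clamp.pp2ab55 is None else clamp.pp2ab55
    return (
        params.k_cdk1_sub * v_cdk1 * (params.sub_tot - state.subp)
        - params.k_b55_sub * b55 * state.subp
    )


def network_rhs(
    state: NetworkState,
    params: KineticParameters,
    clamp: Clamp | None = None,
) -> np.ndarray:
    """Full derivative vector in ``STATE_NAMES`` order.

    The auxiliary submodel uses mass action: CDK1 is activated by Cdc25pp
    (plus a weak constitutive phosphatase) and inhibited by active Wee1;
    Wee1 is re-activated by PP2A-B55 and inhibited by CDK1 and by
    CDK2-cyclin A; PP2A-B55 recovers at a constant rate and is inhibited
    downstream of CDK1.  When a clamp is supplied the clamped species'
    derivative is zero and its clamped value is used everywhere it appears.
    """
    state.cdc25p(params)  # validate the conservation invariant
    return rhs_vector(state.as_vector(), params, clamp)


def rhs_vector(y: np.ndarray, params: KineticParameters,
               clamp: Clamp | None = None) -> np.ndarray:
    """Unvalidated derivative vector for raw state vectors.

    Identical arithmetic to :func:`network_rhs` but without invariant
    enforcement, so ODE solvers and Newton root finders may probe slightly
    outside the physical simplex (their finite-difference steps routinely
    do) without tripping an :class:`InvariantViolation`.
    """
    c0, c2, a, w, b, s = (float(v) for v in y)
    if clamp is not None and clamp.v_cdk1 is not None:
        v_cdk1 = clamp.v_cdk1
    else:
        v_cdk1 = a
    if clamp is not None and clamp.pp2ab55 is not None:
        b55 = clamp.pp2ab55
    else:
        b55 = b
    c1 = params.cdc25_tot - c0 - c2
    dephos = params.k_ppx_y15 + params.k_b55_cdc25 * b55
    phos = params.k_cdk1_cdc25 * v_cdk1 + params.k_plk1_cdc25 * params.plk1
    d_c0 = dephos * c1 - phos * c0
    d_c2 = -dephos * c2 + phos * c1
    d_s = (params.k_cdk1_sub * v_cdk1 * (params.sub_tot - s)
           - params.k_b55_sub * b55 * s)
    if clamp is not None and clamp.v_cdk1 is not None:
        d_a = 0.0
    else:
        d_a = ((params.aux_k_cdc25_cdk1 * c2 + params.aux_k_ppx_t14)
               * (params.cycbcdk1_tot - a)
               - params.aux_k_wee1_cdk1 * w * a)
    if clamp is not None and clamp.pp2ab55 is not None:
        d_b = 0.0
    else:
        d_b = (params.aux_k_b55_act * (params.b55_tot - b)
               - params.aux_k_cdk1_b55 * v_cdk1 * b)
    d_w = (params.aux_k_b55_wee1 * b55 * (params.wee1_tot - w)
           - (params.aux_k_cdk1_wee1 * v_cdk1
              + params.aux_k_cyca_wee1 * params.cyca_cdk2_tot) * w)
    return np.array([d_c0, d_c2, d_a, d_w, d_b, d_s])


def _rhs_vector(t: float, y: np.ndarray, params: KineticParameters,
                clamp: Clamp | None) -> np.ndarray:
    return rhs_vector(y, params, clamp)


def interphase_state(params: KineticParameters) -> NetworkState:
    """Pre-G2 initial condition: the resting state before the CycA step.

    Cdc25 is fully unphosphorylated and no substrate is phosphorylated;
    CDK1 sits at its inactive-branch steady state and Wee1/PP2A-B55 at
    their active-branch steady states, computed with CDK2-cyclin A at zero
    (the G2-entry step has not yet happened).
    """
    pre = params.with_(cyca_cdk2_tot=0.0)
    y0 = np.array([pre.cdc25_tot, 0.0, 0.0, pre.wee1_tot, pre.b55_tot, 0.0])

    def relax_rhs(t, y):
        d = rhs_vector(y, pre)
        d[0] = d[1] = d[5] = 0.0  # pools pinned at their defined start values
        return d

    sol = solve_ivp(relax_rhs, (0.0, 500.0), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise IntegrationError(f"relaxation to interphase state failed: {sol.message}")
    return NetworkState.from_vector(sol.y[:, -1])


def simulate_cell(
    params: KineticParameters,
    horizon: float = 24.0,
    output_step: float = 0.01,
    clamp: Clamp | None = None,
    initial_state: NetworkState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    stop_at_nebd: bool = False,
) -> CellTrajectory:
    """Integrate one cell from G2 entry (t = 0) to ``horizon`` hours.

    G2 entry is the step of CDK2-cyclin A from 0 to ``params.cyca_cdk2_tot``;
    the initial condition is the interphase resting state unless supplied.
    NEBD is the first (event-located) time the substrate fraction crosses
    ``params.nebd_threshold``.  With ``stop_at_nebd`` the integration
    terminates at the event, which is substantially faster for population
    sweeps where only the timing is needed.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    if initial_state is None:
        initial_state = interphase_state(params)
    y0 = initial_state.as_vector()

    target = params.nebd_threshold * params.sub_tot

    def nebd_event(t, y, *_args):
        return y[5] - target

    nebd_event.direction = 1.0
    nebd_event.terminal = bool(stop_at_nebd)

    t_eval = np.arange(0.0, horizon + 0.5 * output_step, output_step)
    t_eval[-1] = min(t_eval[-1], horizon)
    sol = solve_ivp(
        _rhs_vector, (0.0, horizon), y0, args=(params, clamp),
        method="LSODA", rtol=rtol, atol=atol,
        t_eval=t_eval, events=[nebd_event], dense_output=False,
    )
    if sol.status == -1:
        raise IntegrationError(f"integration failed at t={sol.t[-1]:.4g}: {sol.message}")

    nebd_time = float(sol.t_events[0][0]) if sol.t_events[0].size else None
    times = sol.t
    states = sol.y.T
    if nebd_time is not None and stop_at_nebd:
        # append the event sample so the trajectory ends exactly at NEBD
        times = np.append(times, nebd_time)
        states = np.vstack([states, sol.y_events[0][0]])
    return CellTrajectory(
        times=times, states=states, params=params,
        nebd_time=nebd_time, censor_time=horizon,
    )


def detect_nebd(
    trajectory: CellTrajectory, threshold: float | None = None
) -> float | None:
    """First upward crossing of the substrate fraction through ``threshold``.

    Linear interpolation between the bracketing output samples; returns
    ``None`` (censored) if the threshold is never reached.  The default
    threshold is the 30% NEBD definition carried by the trajectory's
    parameters.
    """
    if threshold is None:
        threshold = trajectory.params.nebd_threshold
    t = np.asarray(trajectory.times, dtype=float)
    if t.size < 2:
        raise ValueError("trajectory needs at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    frac = trajectory.substrate_fraction
    if frac[0] >= threshold:
        return float(t[0])
    above = frac >= threshold
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    f0, f1 = frac[i - 1], frac[i]
    if f1 == f0:
        return float(t[i])
    return float(t[i - 1] + (threshold - f0) / (f1 - f0) * (t[i] - t[i - 1]))


def default_parameters(**overrides) -> KineticParameters:
    """The calibrated default parameter set (see ``data/default_params.json``).

    Calibrated so that an uninhibited cell (f_plk1 = 1) at CDK2-cyclin A
    activity 4 a.u. reaches NEBD within ~0.5-2 h of G2 entry, while a fully
    inhibited cell (f_plk1 = 0) at the same activity is delayed by several
    hours, with the saddle-node threshold of CDK2-cyclin A shifted upward
    under inhibition.
    """
    text = resources.files("mitentry.data").joinpath("default_params.json").read_text()
    d = json.loads(text)
    d.update(overrides)
    return KineticParameters.from_dict(d)
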