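"""Closed-form drift-diffusion quantities and a Wiener first-passage simulator.

The decision process is a Brownian motion with drift between two symmetric
absorbing barriers at ``+a`` and ``-a`` (``a`` fixed at 1 by the usual scale
normalization).  The walk starts at 0 and evidence evolves as

    dx = r dt + sigma dw,        dw ~ N(0, dt)

A "left slower" response is coded as the barrier the walk reaches with
probability ``p_left = 1 / (1 + exp(2 r a / sigma^2))``; under the linear
drift-stimulus link ``r = -(sigma^2 / 2) * (beta0 + beta1 * dv)`` this is
exactly the logistic psychometric function ``p_left = logistic(beta0 +
beta1 * dv)``.  With that convention the *lower* barrier carries the left
label (the sign of the drift only relabels the barriers; the decision-time
distribution is even in ``r``).

Mean decision time has the closed form ``E[t_d] = (a / r) tanh(r a / sigma^2)``
which is even in ``r`` and tends to ``a^2 / sigma^2`` as ``r -> 0``.
Observed reaction time is decision time plus a stimulus-independent
non-decision latency ``t_nd`` (stimulus encoding plus motor execution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DDMParams",
    "DriftLink",
    "DDMTrialOutcome",
    "choice_probability",
    "expected_decision_time",
    "expected_rt",
    "simulate_trial",
    "simulate_trials",
    "SimulationOverflowError",
]

#: Default Euler-Maruyama step (s); validated against the closed forms.
DEFAULT_DT = 1e-3

#: Hard cap on Euler steps before declaring non-termination.
MAX_STEPS = 10**6


class SimulationOverflowError(RuntimeError):
    """Raised when a simulated walk fails to absorb within the step cap."""


def _check_sigma(sigma: float) -> None:
    if not sigma > 0:
        raise ValueError(f"diffusion rate sigma must be > 0, got {sigma}")


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the two-barrier Wiener process.

    Attributes
    ----------
    r : float
        Drift rate (evidence units per second, signed).
    sigma : float
        Diffusion rate (evidence units per sqrt-second), > 0.
    a : float
        Barrier height (evidence units).  Fixed at 1 in all fitting; kept
        as a field only so the scale invariance ``(r, sigma, a) -> (kr,
        k sigma, ka)`` can be exercised directly.
    t_nd : float
        Non-decision time in seconds, >= 0.
    """

    r: float
    sigma: float
    a: float = 1.0
    t_nd: float = 0.0

    def __post_init__(self) -> None:
        _check_sigma(self.sigma)
        if not self.a > 0:
            raise ValueError(f"barrier a must be > 0, got {self.a}")
        if self.t_nd < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t_nd}")


@dataclass(frozen=True)
class DriftLink:
    """Linear drift-stimulus link: mu(dv) = beta0 + beta1 * dv.

    ``beta0`` is dimensionless, ``beta1`` has units of 1 / (m/s) so that a
    stimulus ``dv`` in m/s yields a dimensionless logit.  The drift of the
    walk at stimulus ``dv`` is ``r = -(sigma^2 / 2) * mu(dv)``, the sign
    chosen so the left-choice probability is ``logistic(mu)``.
    """

    beta0: float
    beta1: float
    sigma: float = 0.5
    t_nd: float = 0.9

    def __post_init__(self) -> None:
        _check_sigma(self.sigma)
        if self.t_nd < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t_nd}")

    def mu(self, dv):
        """Logit of the left-choice probability at stimulus ``dv`` (m/s)."""
        return self.beta0 + self.beta1 * np.asarray(dv, dtype=float)

    def drift(self, dv):
        """Drift rate of the walk at stimulus ``dv`` (m/s)."""
        return -0.5 * self.sigma**2 * self.mu(dv)

    def params(self, dv: float) -> DDMParams:
        """DDMParams of the walk for a single stimulus value."""
        return DDMParams(r=float(self.drift(dv)), sigma=self.sigma, t_nd=self.t_nd)


@dataclass(frozen=True)
class DDMTrialOutcome:
    """One simulated trial: barrier label, decision time and reaction time."""

    choice: str  # "left" | "right"
    decision_time: float
    rt: float = field(default=0.0)


def choice_probability(params: DDMParams) -> float:
    """Probability of the left choice, ``1 / (1 + exp(2 r a / sigma^2))``.

    Identical to ``logistic(mu)`` under the substitution
    ``mu = -2 r a / sigma^2``.  Invariant to a common rescaling of
    ``(r, sigma, a)``.
    """
    _check_sigma(params.sigma)
    z = 2.0 * params.r * params.a / params.sigma**2
    # logistic(-z); scipy.special.expit clips identically but this keeps
    # the module free of heavyweight imports on the hot path
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(z)))
    ez = np.exp(-z)
    return float(ez / (1.0 + ez))


def expected_decision_time(params: DDMParams) -> float:
    """Mean first-passage time ``(a / r) tanh(r a / sigma^2)`` in seconds.

    Even in ``r``; continuous at ``r = 0`` where it equals ``a^2 / sigma^2``
    (a Taylor branch handles ``|r a / sigma^2| < 1e-4``).
    """
    _check_sigma(params.sigma)
    a, r, s2 = params.a, params.r, params.sigma**2
    z = r * a / s2
    if abs(z) < 1e-4:
        # tanh(z)/z = 1 - z^2/3 + 2 z^4/15 + O(z^6)
        return float(a**2 / s2 * (1.0 - z**2 / 3.0 + 2.0 * z**4 / 15.0))
    return float(a / r * np.tanh(z))


def expected_rt(link: DriftLink, dv) -> float | np.ndarray:
    """Mean reaction time ``t_nd + E[t_d]`` at stimulus ``dv`` (m/s).

    Vectorized over ``dv``.  Maximal at ``dv = -beta0/beta1`` (where the
    drift vanishes) and strictly decreasing in ``|beta0 + beta1 dv|``.
    """
    mu = np.asarray(link.mu(dv), dtype=float)
    s2 = link.sigma**2
    # E[t_d] = (2 / (sigma^2 mu)) * tanh(mu / 2), even in mu
    z = np.abs(mu) / 2.0
    with np.errstate(invalid="ignore"):
        td = np.where(
            z < 5e-5,
            (1.0 - z**2 / 3.0 + 2.0 * z**4 / 15.0) / s2,
            np.tanh(z) / np.where(z == 0.0, 1.0, z) / s2,
        )
    out = link.t_nd + td
    return out if out.ndim else float(out)


def simulate_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float | None = None,
):
    """Euler-Maruyama simulation of ``n`` independent walks.

    Parameters
    ----------
    params : DDMParams
        May carry any drift; ``r`` can also be an array of length ``n`` by
        passing through :func:`simulate_trials_linked`.
    n : int
        Number of trials.
    rng : numpy Generator
        Seeded source of the Wiener increments.
    dt : float
        Euler step in seconds.
    max_time : float, optional
        If given, walks still unabsorbed after ``max_time`` seconds of
        decision time are censored: their decision time is ``nan`` and
        their choice is recorded as unresolved.  If None, a walk exceeding
        ``MAX_STEPS`` steps raises :class:`SimulationOverflowError`.

    Returns
    -------
    (left, t_d) : tuple of ndarray
        ``left`` is a boolean array (True where the left barrier was hit;
        undefined where ``t_d`` is nan), ``t_d`` the decision times.
    """
    r = np.broadcast_to(np.asarray(params.r, dtype=float), (n,)).copy()
    return _simulate_walks(r, params.sigma, params.a, n, rng, dt, max_time)


def _simulate_walks(r, sigma, a, n, rng, dt, max_time):
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    _check_sigma(sigma)
    cap = MAX_STEPS if max_time is None else int(np.ceil(max_time / dt))
    x = np.zeros(n)
    t_d = np.full(n, np.nan)
    left = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sqdt = sigma * np.sqrt(dt)
    step = 0
    var_dt = sigma**2 * dt
    while active.size:
        step += 1
        if step > cap:
            if max_time is None:
                raise SimulationOverflowError(
                    f"{active.size} walks unabsorbed after {MAX_STEPS} steps"
                )
            break  # remaining walks censored (t_d stays nan)
        x_old = x[active]
        x_new = x_old + r[active] * dt + sqdt * rng.standard_normal(active.size)
        # Brownian-bridge correction: an endpoint inside the barriers may
        # still have crossed within the step; without it the Euler scheme
        # systematically under-absorbs (O(sqrt(dt)) bias in hit fractions)
        inside = np.abs(x_new) < a
        p_up = np.where(
            inside & (x_old < a),
            np.exp(-2.0 * np.clip((a - x_old) * (a - x_new), 0.0, None) / var_dt),
            0.0,
        )
        p_dn = np.where(
            inside & (x_old > -a),
            np.exp(-2.0 * np.clip((a + x_old) * (a + x_new), 0.0, None) / var_dt),
            0.0,
        )
        u = rng.random(active.size)
        bridge_up = inside & (u < p_up)
        bridge_dn = inside & ~bridge_up & (u < p_up + p_dn)
        hit = ~inside | bridge_up | bridge_dn
        x[active] = x_new
        if hit.any():
            idx = active[hit]
            t_d[idx] = step * dt
            # lower barrier carries the "left" label (module convention)
            left[idx] = (x_new[hit] <= -a) | bridge_dn[hit]
            active = active[~hit]
    return left, t_d


def simulate_trials_linked(
    link: DriftLink,
    dv: np.ndarray,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float | None = None,
):
    """Simulate one walk per stimulus in ``dv`` (m/s) under ``link``.

    Returns ``(left, t_d)`` as in :func:`simulate_trials`; reaction times
    are ``t_d + link.t_nd``.
    """
    dv = np.asarray(dv, dtype=float)
    r = np.asarray(link.drift(dv), dtype=float)
    return _simulate_walks(r, link.sigma, 1.0, dv.size, rng, dt, max_time)


def simulate_trial(
    params: DDMParams,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
) -> DDMTrialOutcome:
    """Simulate a single trial; see :func:`simulate_trials`."""
    left, t_d = simulate_trials(params, 1, rng, dt=dt)
    td = float(t_d[0])
    return DDMTrialOutcome(
        choice="left" if left[0] else "right",
        decision_time=td,
        rt=td + params.t_nd,
    )
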