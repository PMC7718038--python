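"""Forward simulation of one-step growth experiments.

The model tracks four pools in a well-mixed culture of fixed volume:
free phage P, susceptible cells S, infected (intact) cells I, and lysed
cells.  Free phage adsorb to *intact* cells (susceptible or already
infected) with second-order rate constant k (mL·min⁻¹):

    dP/dt = -k (S + I) P

Only adsorptions landing on a susceptible cell start an infection
(superinfection is unproductive), so infections accrue at rate k·S·P.
An infected cell lyses a latency period after infection, releasing
``burst_size`` progeny.  Progeny re-adsorb only when
``secondary_infection`` is enabled; otherwise they accumulate as
observable but inert free phage.  Bacterial growth is ignored on the
~1 h timescale of the experiment, so S + I + lysed is conserved.

Two integration modes are provided:

* **deterministic** (``latency_cv = 0``): a cohort-based delay recursion
  on the sampling grid.  Cells infected within one sampling interval form
  a cohort timestamped at the interval start; the cohort lyses together
  ``ceil(latency / interval)`` intervals later.  Conservation is exact by
  construction.
* **stochastic**: exact event simulation on phage/cell *counts* in
  ``volume_ml`` of culture (adsorption propensity ``k·(S+I)·P/V``), with
  per-cell lysis delays drawn from a gamma distribution parameterized by
  mean and coefficient of variation (CV = 0 degenerates to the fixed,
  grid-synchronized delay so that the two modes agree in mean).  Above
  ``tau_leap_threshold`` expected events, a tau-leaping approximation
  with Poisson adsorption increments is used instead.

Plating noise (:func:`apply_plating_noise`) turns a simulated trajectory
into an observed :class:`~phagekit.kinetics.TiterSeries` via Poisson
plaque counts.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError
from .kinetics import TiterSeries

__all__ = [
    "SimulationParameters",
    "SimulationResult",
    "simulate_one_step",
    "apply_plating_noise",
    "simulate_od_lysis",
    "simulate_titer_experiment",
]

#: OD600 of the culture at the moment of infection; od_proxy is scaled to it.
OD_AT_INFECTION = 0.6


@dataclass(frozen=True)
class SimulationParameters:
    """Inputs of the one-step growth simulator.

    Defaults are the operating point of a fast T1-like coliphage
    experiment: adsorption rate constant 8.5e-10 mL·min⁻¹, 4e8 CFU/mL of
    mid-log cells, inoculum giving MOI ~= 0.14, 14 min latency, burst of
    13, sampled every 2 min for an hour.
    """

    k: float = 8.5e-10  # adsorption rate constant, mL min^-1
    n0: float = 4e8  # starting cells, CFU/mL
    p0: float = 5.68e7  # starting free phage, PFU/mL (MOI 0.142)
    latency_mean: float = 14.0  # min
    latency_cv: float = 0.0  # dimensionless; 0 => deterministic lysis delay
    burst_size: float = 13.0  # PFU per infected cell
    t_max: float = 60.0  # min
    sample_interval: float = 2.0  # min
    secondary_infection: bool = False
    volume_ml: float = 1.0  # simulated volume (stochastic mode only)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("k", "n0", "p0", "burst_size"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        for name in ("latency_mean", "t_max", "sample_interval", "volume_ml"):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.latency_cv < 0:
            raise InvalidInputError("latency_cv must be >= 0")

    @property
    def moi(self) -> float:
        return self.p0 / self.n0


@dataclass
class SimulationResult:
    """Simulated trajectories, all in per-mL units on the sampling grid."""

    times: np.ndarray
    free_phage: np.ndarray
    susceptible: np.ndarray
    infected: np.ndarray
    lysed_cumulative: np.ndarray
    adsorbed_cumulative: np.ndarray
    od_proxy: np.ndarray
    params: SimulationParameters
    flags: list = field(default_factory=list)

    def cell_balance_error(self) -> float:
        """Max relative deviation of S + I + lysed from N0."""
        total = self.susceptible + self.infected + self.lysed_cumulative
        return float(np.max(np.abs(total - self.params.n0)) / self.params.n0)

    def phage_balance_error(self) -> float:
        """Max relative deviation of free phage from
        P0 - adsorbed + burst_size * lysed (no-secondary-infection mode)."""
        expected = (
            self.params.p0
            - self.adsorbed_cumulative
            + self.params.burst_size * self.lysed_cumulative
        )
        scale = max(self.params.p0, float(np.max(self.free_phage)), 1.0)
        return float(np.max(np.abs(self.free_phage - expected)) / scale)


def _sample_grid(params: SimulationParameters) -> np.ndarray:
    n = int(round(params.t_max / params.sample_interval))
    return np.arange(n + 1) * params.sample_interval


def _latency_steps(params: SimulationParameters) -> int:
    # grid-ceil of the latency; cohorts release this many intervals later
    return max(1, int(math.ceil(params.latency_mean / params.sample_interval - 1e-12)))


def _integrate_interval(p_act, s, i, k, dt, substeps=32):
    """RK4 integration of dP=-k(S+I)P, dS=-kSP, dI=+kSP over one interval.

    dI = -dS at every stage, so S+I is conserved to float precision and the
    cells infected during the interval are exactly S_before - S_after.
    """
    h = dt / substeps

    def deriv(p, s_, i_):
        ads = k * (s_ + i_) * p
        inf = k * s_ * p
        return -ads, -inf, inf

    for _ in range(substeps):
        k1 = deriv(p_act, s, i)
        k2 = deriv(p_act + h / 2 * k1[0], s + h / 2 * k1[1], i + h / 2 * k1[2])
        k3 = deriv(p_act + h / 2 * k2[0], s + h / 2 * k2[1], i + h / 2 * k2[2])
        k4 = deriv(p_act + h * k3[0], s + h * k3[1], i + h * k3[2])
        p_act += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        s += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        i += h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    return p_act, s, i


def _simulate_deterministic(params: SimulationParameters) -> SimulationResult:
    times = _sample_grid(params)
    n_steps = len(times)
    l_steps = _latency_steps(params)

    free = np.empty(n_steps)
    sus = np.empty(n_steps)
    inf = np.empty(n_steps)
    lys = np.empty(n_steps)
    ads = np.empty(n_steps)

    p_act = params.p0  # adsorbing free phage
    p_inert = 0.0  # progeny that never re-adsorb (secondary_infection off)
    s = params.n0
    i = 0.0
    lysed = 0.0
    adsorbed_total = 0.0
    release = np.zeros(n_steps + l_steps + 1)

    for m in range(n_steps):
        r = release[m]
        if r > 0:
            i -= r
            lysed += r
            progeny = params.burst_size * r
            if params.secondary_infection:
                p_act += progeny
            else:
                p_inert += progeny
        free[m] = p_act + p_inert
        sus[m] = s
        inf[m] = i
        lys[m] = lysed
        ads[m] = adsorbed_total
        if m == n_steps - 1:
            break
        s_before, p_before = s, p_act
        p_act, s, i = _integrate_interval(p_act, s, i, params.k, params.sample_interval)
        new_infections = s_before - s
        adsorbed_total += p_before - p_act
        release[m + l_steps] += new_infections

    result = SimulationResult(
        times=times,
        free_phage=free,
        susceptible=sus,
        infected=inf,
        lysed_cumulative=lys,
        adsorbed_cumulative=ads,
        od_proxy=OD_AT_INFECTION * (sus + inf) / params.n0,
        params=params,
    )
    return result


def _draw_latency(rng, params: SimulationParameters):
    if params.latency_cv == 0:
        return params.latency_mean
    cv2 = params.latency_cv**2
    return rng.gamma(shape=1.0 / cv2, scale=params.latency_mean * cv2)


def _snap_lysis_time(t_infect: float, params: SimulationParameters) -> float:
    # cohort-synchronized convention: timestamp at the start of the sampling
    # interval containing the infection, delay = grid-ceil(latency)
    dt = params.sample_interval
    return math.floor(t_infect / dt + 1e-12) * dt + _latency_steps(params) * dt


def _simulate_stochastic_exact(params: SimulationParameters, rng) -> SimulationResult:
    v = params.volume_ml
    n_s = int(round(params.n0 * v))
    n_p = int(round(params.p0 * v))
    n_i = 0
    n_lysed = 0
    n_inert = 0
    adsorbed = 0
    lysis_heap: list = []

    times = _sample_grid(params)
    free = np.empty(len(times))
    sus = np.empty(len(times))
    inf = np.empty(len(times))
    lys = np.empty(len(times))
    ads = np.empty(len(times))

    t = 0.0
    sample_idx = 0

    def record_until(t_new, strict=False):
        # record samples up to t_new; with strict=True only samples strictly
        # before t_new, so events scheduled exactly at a sample time (e.g.
        # grid-synchronized lysis) are applied before the sample is taken
        nonlocal sample_idx
        while sample_idx < len(times) and (
            times[sample_idx] < t_new - 1e-12
            if strict
            else times[sample_idx] <= t_new + 1e-12
        ):
            free[sample_idx] = (n_p + n_inert) / v
            sus[sample_idx] = n_s / v
            inf[sample_idx] = n_i / v
            lys[sample_idx] = n_lysed / v
            ads[sample_idx] = adsorbed / v
            sample_idx += 1

    record_until(0.0)
    t_end = times[-1]
    while sample_idx < len(times):
        rate = params.k / v * (n_s + n_i) * n_p
        t_ads = t + rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_lys = lysis_heap[0] if lysis_heap else math.inf
        t_next = min(t_ads, t_lys)
        if t_next > t_end:
            record_until(t_end)
            break
        record_until(t_next, strict=True)
        t = t_next
        if t_lys <= t_ads:
            heapq.heappop(lysis_heap)
            n_i -= 1
            n_lysed += 1
            progeny = int(round(params.burst_size))
            if params.secondary_infection:
                n_p += progeny
            else:
                n_inert += progeny
        else:
            n_p -= 1
            adsorbed += 1
            if rng.random() < n_s / (n_s + n_i):
                n_s -= 1
                n_i += 1
                if params.latency_cv == 0:
                    t_l = _snap_lysis_time(t, params)
                else:
                    t_l = t + _draw_latency(rng, params)
                heapq.heappush(lysis_heap, t_l)
    record_until(t_end)

    n0_eff = n_s + n_i + n_lysed
    return SimulationResult(
        times=times,
        free_phage=free,
        susceptible=sus,
        infected=inf,
        lysed_cumulative=lys,
        adsorbed_cumulative=ads,
        od_proxy=OD_AT_INFECTION * (sus + inf) * v / max(n0_eff, 1),
        params=params,
    )


def _simulate_stochastic_tau(params: SimulationParameters, rng, substeps=20) -> SimulationResult:
    """Tau-leaping: Poisson adsorption increments on a fixed sub-grid,
    lysis aggregated into sampling-grid bins."""
    v = params.volume_ml
    n_s = float(round(params.n0 * v))
    n_p = float(round(params.p0 * v))
    n_i = 0.0
    n_lysed = 0.0
    n_inert = 0.0
    adsorbed = 0.0

    times = _sample_grid(params)
    dt = params.sample_interval / substeps
    n_bins = len(times) + int(math.ceil(10 * params.latency_mean / params.sample_interval)) + 2
    release = np.zeros(n_bins)

    free = np.empty(len(times))
    sus = np.empty(len(times))
    inf = np.empty(len(times))
    lys = np.empty(len(times))
    ads = np.empty(len(times))

    l_steps = _latency_steps(params)
    for m, t_m in enumerate(times):
        r = release[m]
        if r > 0:
            r = min(r, n_i)
            n_i -= r
            n_lysed += r
            progeny = params.burst_size * r
            if params.secondary_infection:
                n_p += progeny
            else:
                n_inert += progeny
        free[m] = (n_p + n_inert) / v
        sus[m] = n_s / v
        inf[m] = n_i / v
        lys[m] = n_lysed / v
        ads[m] = adsorbed / v
        if m == len(times) - 1:
            break
        for j in range(substeps):
            rate = params.k / v * (n_s + n_i) * n_p
            if rate > 0:
                n_ads = min(rng.poisson(rate * dt), n_p)
            else:
                n_ads = 0
            if n_ads > 0:
                n_p -= n_ads
                adsorbed += n_ads
                frac_s = n_s / (n_s + n_i) if (n_s + n_i) > 0 else 0.0
                n_new = min(rng.binomial(int(n_ads), frac_s), n_s)
                n_s -= n_new
                n_i += n_new
                if n_new > 0:
                    if params.latency_cv == 0:
                        release[m + l_steps] += n_new
                    else:
                        # distribute lysis times over grid bins by gamma draws
                        delays = _draw_latency_array(rng, params, int(n_new))
                        t_infect = t_m + j * dt
                        bins = np.ceil((t_infect + delays) / params.sample_interval)
                        bins = np.clip(bins.astype(int), 0, n_bins - 1)
                        np.add.at(release, bins, 1)
    n0_eff = max(n_s + n_i + n_lysed, 1.0)
    return SimulationResult(
        times=times,
        free_phage=free,
        susceptible=sus,
        infected=inf,
        lysed_cumulative=lys,
        adsorbed_cumulative=ads,
        od_proxy=OD_AT_INFECTION * (sus + inf) * v / n0_eff,
        params=params,
        flags=["tau_leaping"],
    )


def _draw_latency_array(rng, params: SimulationParameters, n: int):
    cv2 = params.latency_cv**2
    return rng.gamma(shape=1.0 / cv2, scale=params.latency_mean * cv2, size=n)


def simulate_one_step(
    params: SimulationParameters,
    method: str = "auto",
    tau_leap_threshold: float = 1e6,
) -> SimulationResult:
    """Simulate a one-step growth experiment.

    Parameters
    ----------
    params:
        See :class:`SimulationParameters`.
    method:
        ``"deterministic"`` (requires ``latency_cv = 0``; seed ignored),
        ``"stochastic"`` (exact event simulation, or tau-leaping when the
        expected event count exceeds ``tau_leap_threshold``), or ``"auto"``
        (deterministic when ``latency_cv = 0``, stochastic otherwise).

    Returns
    -------
    SimulationResult
        Trajectories on the sampling grid.  Conservation invariants
        (cells: S + I + lysed = N0; phage balance) hold exactly up to
        floating point in deterministic mode and exactly in counts in
        stochastic mode.
    """
    if params.t_max < params.latency_mean:
        warnings.warn(
            "t_max is shorter than the latency period: no burst will be observable",
            stacklevel=2,
        )
    if method == "auto":
        method = "deterministic" if params.latency_cv == 0 else "stochastic"
    if method == "deterministic":
        if params.latency_cv != 0:
            raise InvalidInputError("deterministic mode requires latency_cv = 0")
        return _simulate_deterministic(params)
    if method == "stochastic":
        rng = np.random.default_rng(params.seed)
        expected_events = 2 * params.p0 * params.volume_ml * (
            1 + (params.burst_size if params.secondary_infection else 0)
        )
        if expected_events > tau_leap_threshold:
            return _simulate_stochastic_tau(params, rng)
        return _simulate_stochastic_exact(params, rng)
    raise InvalidInputError(f"unknown simulation method {method!r}")


def apply_plating_noise(
    result: SimulationResult,
    dilution_for_counts: Optional[float] = None,
    plate_volume_ml: float = 0.1,
    seed: Optional[int] = None,
    target_count: Optional[float] = None,
) -> TiterSeries:
    """Observe a simulated trajectory through dilution plating.

    The plated expectation is ``titer * dilution * plate_volume``; the
    observed plaque count is Poisson with that mean, and the reported titer
    is ``count / (dilution * plate_volume)``.

    Provide either a fixed ``dilution_for_counts`` (e.g. ``1e-6`` for a
    six-step 1:10 series) applied to every time point, or ``target_count``
    to pick, per point, the 1:10 serial dilution whose expected count is
    closest below ~10x the target (emulating reading the countable plate).
    """
    if dilution_for_counts is None and target_count is None:
        raise InvalidInputError("give either dilution_for_counts or target_count")
    if dilution_for_counts is not None and dilution_for_counts <= 0:
        raise InvalidInputError("dilution_for_counts must be positive")
    if plate_volume_ml <= 0:
        raise InvalidInputError("plate_volume_ml must be positive")
    rng = np.random.default_rng(seed)
    observed = np.empty_like(result.free_phage)
    for idx, titer in enumerate(result.free_phage):
        if dilution_for_counts is not None:
            dilution = dilution_for_counts
        else:
            # deepest 1:10 dilution still expected to give >= target_count
            expected_neat = titer * plate_volume_ml
            if expected_neat <= 0:
                dilution = 1.0
            else:
                steps = int(math.floor(math.log10(max(expected_neat / target_count, 1.0))))
                dilution = 10.0 ** (-steps)
        lam = titer * dilution * plate_volume_ml
        count = rng.poisson(lam) if lam > 0 else 0
        observed[idx] = count / (dilution * plate_volume_ml)
    return TiterSeries(times=result.times.copy(), titers=observed, od600=result.od_proxy.copy())


def simulate_od_lysis(result: SimulationResult) -> np.ndarray:
    """OD600-like readout: proportional to intact (susceptible + infected)
    cell density, normalized to 0.6 at infection.  Lysed-cell debris is
    assumed not to scatter."""
    intact0 = result.susceptible[0] + result.infected[0]
    if intact0 <= 0:
        return np.zeros_like(result.susceptible)
    return OD_AT_INFECTION * (result.susceptible + result.infected) / intact0


def simulate_titer_experiment(
    params: SimulationParameters,
    noise: bool = False,
    n_replicates: int = 1,
    target_count: float = 300.0,
    seed: Optional[int] = None,
) -> TiterSeries:
    """Convenience wrapper: simulate, optionally observe through plating
    noise, and (for replicates) average in log10 space.

    With ``noise=False`` the noiseless trajectory is returned directly.
    """
    from .kinetics import average_replicates

    result = simulate_one_step(params)
    if not noise:
        return TiterSeries(
            times=result.times.copy(),
            titers=result.free_phage.copy(),
            od600=result.od_proxy.copy(),
        )
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    reps = [
        apply_plating_noise(result, target_count=target_count, seed=s)
        for s in seeds
    ]
    return average_replicates(reps) if n_replicates > 1 else reps[0]
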