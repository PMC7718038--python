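"""One-step growth-curve kinetics for lytic bacteriophages.

Estimates the four classical infection parameters from a free-phage titer
time series:

* **MOI** — multiplicity of infection, phage added per bacterium present.
* **k** — adsorption rate constant (mL·min⁻¹), from the two-point formula
  ``k = -ln(P/P0) / (N t)`` applied to the titer drop over the adsorption
  window (conventionally T = 0 to T = 4 min).
* **L** — latency period, the time from phage addition to the first
  significant, persistent rise in free-phage titer.
* **B** — burst size, the post-burst titer divided by the adsorbed titer
  ``P(t_burst) / (P(0) - P(t_adsorb))``.

The module exposes both plain functions (one per estimator) and a
statsmodels-flavoured :class:`OneStepGrowth` model whose :meth:`~OneStepGrowth.fit`
returns a :class:`OneStepGrowthResults` with a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, NoAdsorptionError

__all__ = [
    "TiterSeries",
    "InoculumSpec",
    "KineticsReport",
    "AdsorptionEstimate",
    "compute_moi",
    "estimate_adsorption_rate",
    "detect_latency",
    "estimate_burst_size",
    "default_burst_time",
    "analyze_one_step",
    "average_replicates",
    "OneStepGrowth",
    "OneStepGrowthResults",
]

#: Tolerance (minutes) for matching a requested time to the nearest sample.
#: Titers are plate counts, so no interpolation is ever performed.
TIME_MATCH_TOLERANCE = 0.5


@dataclass(frozen=True)
class TiterSeries:
    """Timestamped free-phage titers from a one-step growth experiment.

    Parameters
    ----------
    times:
        Sampling times in minutes, strictly increasing.
    titers:
        Free-phage concentration in PFU/mL, one per time point, all >= 0.
    od600:
        Optional optical-density readings parallel to ``times``.
    """

    times: np.ndarray
    titers: np.ndarray
    od600: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        titers = np.asarray(self.titers, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "titers", titers)
        if times.ndim != 1 or titers.ndim != 1:
            raise InvalidInputError("times and titers must be 1-D arrays")
        if len(times) != len(titers):
            raise InvalidInputError(
                f"times ({len(times)}) and titers ({len(titers)}) differ in length"
            )
        if len(times) < 2:
            raise InvalidInputError("a titer series needs at least 2 points")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(titers < 0):
            raise InvalidInputError("titers must be non-negative")
        if self.od600 is not None:
            od = np.asarray(self.od600, dtype=float)
            object.__setattr__(self, "od600", od)
            if len(od) != len(times):
                raise InvalidInputError("od600 must be parallel to times")

    def __len__(self) -> int:
        return len(self.times)

    def titer_at(self, t: float, tol: float = TIME_MATCH_TOLERANCE) -> float:
        """Titer at the sample nearest to ``t`` (within ``tol`` minutes)."""
        i = self.index_at(t, tol)
        return float(self.titers[i])

    def index_at(self, t: float, tol: float = TIME_MATCH_TOLERANCE) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > tol:
            raise InvalidInputError(
                f"no sample within {tol} min of t={t} (nearest is {self.times[i]})"
            )
        return i


@dataclass(frozen=True)
class InoculumSpec:
    """Experimental inoculum: what was mixed with what at T = 0.

    ``phage_volume_ml`` of stock at ``phage_titer`` PFU/mL added to
    ``culture_volume_ml`` of culture at ``bacterial_density`` CFU/mL.
    """

    phage_volume_ml: float
    phage_titer: float
    culture_volume_ml: float
    bacterial_density: float

    def __post_init__(self) -> None:
        for name in (
            "phage_volume_ml",
            "phage_titer",
            "culture_volume_ml",
            "bacterial_density",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class AdsorptionEstimate:
    """Two-point adsorption estimate with its intermediate quantities."""

    k: float  # mL * min^-1
    adsorbed_fraction: float
    p_start: float
    p_end: float
    clamped: bool = False  # True when an apparent titer rise forced k = 0


@dataclass
class KineticsReport:
    """Full report from :func:`analyze_one_step`.

    All derived numbers are traceable through the intermediate fields.
    ``flags`` collects soft failures (e.g. ``"latency_undetected"``) that
    produce a partial report rather than an exception.
    """

    moi: Optional[float] = None
    k: Optional[float] = None
    adsorbed_fraction: Optional[float] = None
    latency_min: Optional[float] = None
    burst_size: Optional[float] = None
    burst_plateau_titer: Optional[float] = None
    adsorbed_titer: Optional[float] = None
    t_adsorb: Optional[float] = None
    t_burst: Optional[float] = None
    baseline_window: Optional[tuple] = None
    flags: list = field(default_factory=list)

    def rounded(self) -> dict:
        """Display-rounded values matching conventional reporting:
        MOI to 2 decimals, k to 2 significant figures, burst to integer."""
        out = {}
        if self.moi is not None:
            out["moi"] = round(self.moi, 2)
        if self.k is not None:
            out["k"] = float(f"{self.k:.2g}") if self.k > 0 else 0.0
        if self.latency_min is not None:
            out["latency_min"] = self.latency_min
        if self.burst_size is not None:
            out["burst_size"] = round(self.burst_size)
        return out

    def to_dict(self) -> dict:
        return {
            "moi": self.moi,
            "k_ml_per_min": self.k,
            "adsorbed_fraction": self.adsorbed_fraction,
            "latency_min": self.latency_min,
            "burst_size": self.burst_size,
            "burst_plateau_titer": self.burst_plateau_titer,
            "adsorbed_titer": self.adsorbed_titer,
            "t_adsorb": self.t_adsorb,
            "t_burst": self.t_burst,
            "baseline_window": self.baseline_window,
            "flags": list(self.flags),
        }


def compute_moi(inoculum: InoculumSpec) -> float:
    """Multiplicity of infection: phage added per bacterium present.

    Returns the unrounded ratio
    ``(phage_volume * phage_titer) / (culture_volume * bacterial_density)``;
    reports round to 2 decimal places.
    """
    return (inoculum.phage_volume_ml * inoculum.phage_titer) / (
        inoculum.culture_volume_ml * inoculum.bacterial_density
    )


def estimate_adsorption_rate(
    series: TiterSeries,
    n_cells: float,
    t0: float = 0.0,
    t1: float = 4.0,
) -> AdsorptionEstimate:
    """Two-point adsorption rate constant ``k = -ln(P(t1)/P(t0)) / (N (t1-t0))``.

    Parameters
    ----------
    series:
        Free-phage titers; ``t0`` and ``t1`` must match samples within
        0.5 min (no interpolation — titers are plate counts).
    n_cells:
        Bacterial density N in CFU/mL, assumed constant over the window.
    t0, t1:
        Adsorption window bounds in minutes, ``t1 > t0``.

    Returns
    -------
    AdsorptionEstimate
        ``k`` in mL·min⁻¹ plus the adsorbed fraction ``1 - P(t1)/P(t0)``.
        An apparent titer *rise* (possible under plating noise) clamps
        ``k`` to 0 and sets ``clamped=True`` rather than erroring.
    """
    if not (n_cells > 0):
        raise InvalidInputError("n_cells must be strictly positive")
    if t1 <= t0:
        raise InvalidInputError(f"t1 ({t1}) must be greater than t0 ({t0})")
    p0 = series.titer_at(t0)
    p1 = series.titer_at(t1)
    if p0 <= 0 or p1 <= 0:
        raise InvalidInputError("titers at both adsorption time points must be positive")
    ratio = p1 / p0
    if ratio > 1.0:
        return AdsorptionEstimate(
            k=0.0, adsorbed_fraction=0.0, p_start=p0, p_end=p1, clamped=True
        )
    k = -math.log(ratio) / (n_cells * (t1 - t0))
    return AdsorptionEstimate(
        k=k, adsorbed_fraction=1.0 - ratio, p_start=p0, p_end=p1, clamped=False
    )


def detect_latency(
    series: TiterSeries,
    adsorption_end: float = 4.0,
    rise_factor: float = 2.0,
) -> Optional[float]:
    """Latency period: earliest sampled time with a significant, persistent
    titer rise above the post-adsorption baseline.

    The baseline at candidate time ``t_i`` is the mean mu and standard
    deviation sigma of log10 titer over the samples strictly between
    ``adsorption_end`` and ``t_i``.  ``t_i`` is called significant when its
    log10 titer exceeds ``mu + max(3 sigma, log10(rise_factor))`` and every
    later sample also stays above ``mu`` (persistence).  Returns ``None``
    when no such time exists ("undetected").

    Requires at least 3 samples after ``adsorption_end``.
    """
    if rise_factor <= 1.0:
        raise InvalidInputError("rise_factor must exceed 1")
    mask = series.times > adsorption_end
    times = series.times[mask]
    titers = series.titers[mask]
    if len(times) < 3:
        raise InsufficientDataError(
            f"need at least 3 samples after t={adsorption_end}, got {len(times)}"
        )
    with np.errstate(divide="ignore"):
        logt = np.log10(titers)
    for i in range(2, len(times)):
        base = logt[:i]
        base = base[np.isfinite(base)]
        if len(base) < 2:
            continue
        mu = float(np.mean(base))
        sigma = float(np.std(base))
        threshold = mu + max(3.0 * sigma, math.log10(rise_factor))
        if logt[i] > threshold and np.all(logt[i:] > mu):
            return float(times[i])
    return None


def estimate_burst_size(
    series: TiterSeries,
    t_adsorb: float = 4.0,
    t_burst: float = 26.0,
) -> float:
    """Burst size ``B = P(t_burst) / (P(0) - P(t_adsorb))``.

    The denominator is the adsorbed titer — the free phage lost during the
    adsorption window — so some adsorption must have occurred
    (``P(0) > P(t_adsorb)``), otherwise :class:`NoAdsorptionError` is raised.
    Reported to 0 decimal places in summaries.
    """
    if t_burst <= t_adsorb:
        raise InvalidInputError(f"t_burst ({t_burst}) must exceed t_adsorb ({t_adsorb})")
    p_initial = series.titer_at(0.0)
    p_adsorb = series.titer_at(t_adsorb)
    p_burst = series.titer_at(t_burst)
    adsorbed = p_initial - p_adsorb
    if adsorbed <= 0:
        raise NoAdsorptionError(
            f"no adsorption detected: P(0)={p_initial:g} <= P({t_adsorb})={p_adsorb:g}"
        )
    return p_burst / adsorbed


def estimate_burst_size_legacy(
    series: TiterSeries,
    t_adsorb: float = 4.0,
    t_burst: float = 26.0,
) -> float:
    """Alternative burst quotient used by some earlier characterizations:
    the difference between the free-phage titer (post burst) and the
    un-adsorbed titer, divided by the initial phage titer.  Offered for
    comparison only; the primary estimator is :func:`estimate_burst_size`."""
    p_initial = series.titer_at(0.0)
    p_unadsorbed = series.titer_at(t_adsorb)
    p_burst = series.titer_at(t_burst)
    if p_initial <= 0:
        raise InvalidInputError("initial titer must be positive")
    return (p_burst - p_unadsorbed) / p_initial


def default_burst_time(
    series: TiterSeries,
    latency: float,
    t_adsorb: float,
    strategy: str = "post_lysis",
) -> float:
    """Choose the sample at which to read the post-burst titer.

    ``"post_lysis"`` (default): the last sample strictly before
    ``latency + t_adsorb``.  Cells infected during the adsorption window
    [0, t_adsorb) have all lysed by latency + t_adsorb; sampling at or past
    that time would fold in progeny of later infections and inflate B.

    ``"plateau_mid"``: midpoint of the first run of >= 2 consecutive
    post-rise samples whose successive log10 changes are < 0.1 (a literal
    "after the first burst" plateau read).
    """
    if strategy == "post_lysis":
        cutoff = latency + t_adsorb
        candidates = series.times[(series.times < cutoff) & (series.times >= latency)]
        if len(candidates) == 0:
            # fall back to the first sample at/after latency
            later = series.times[series.times >= latency]
            if len(later) == 0:
                raise InsufficientDataError("no samples at or after the latency time")
            return float(later[0])
        return float(candidates[-1])
    if strategy == "plateau_mid":
        mask = series.times >= latency
        times = series.times[mask]
        with np.errstate(divide="ignore"):
            logt = np.log10(np.maximum(series.titers[mask], np.finfo(float).tiny))
        dlog = np.abs(np.diff(logt))
        # first qualifying run scanned from the left
        run_start = None
        run_end = None
        for j, d in enumerate(dlog):
            if d < 0.1:
                if run_start is None:
                    run_start = j
                run_end = j + 1
            elif run_start is not None:
                break
        if run_start is None:
            raise InsufficientDataError("no post-rise plateau detected")
        mid = (times[run_start] + times[run_end]) / 2.0
        return float(times[int(np.argmin(np.abs(times - mid)))])
    raise InvalidInputError(f"unknown burst-time strategy {strategy!r}")


def analyze_one_step(
    series: TiterSeries,
    inoculum: Optional[InoculumSpec] = None,
    *,
    n_cells: Optional[float] = None,
    t_adsorb: float = 4.0,
    t_burst: Optional[float] = None,
    rise_factor: float = 2.0,
    burst_time_strategy: str = "post_lysis",
) -> KineticsReport:
    """Run all estimators and assemble a :class:`KineticsReport`.

    ``n_cells`` defaults to the inoculum's bacterial density.  ``t_burst``
    defaults to :func:`default_burst_time` applied to the detected latency.
    Estimator failures that stem from the data (undetected latency, no
    adsorption, too few samples) are recorded as flags in a partial report;
    invalid arguments still raise.
    """
    report = KineticsReport(t_adsorb=t_adsorb)
    if inoculum is not None:
        report.moi = compute_moi(inoculum)
        if n_cells is None:
            n_cells = inoculum.bacterial_density
    if n_cells is None:
        raise InvalidInputError("either an inoculum or n_cells is required")

    try:
        ads = estimate_adsorption_rate(series, n_cells, 0.0, t_adsorb)
        report.k = ads.k
        report.adsorbed_fraction = ads.adsorbed_fraction
        report.adsorbed_titer = ads.p_start - ads.p_end
        if ads.clamped:
            report.flags.append("k_clamped_zero")
    except (InvalidInputError, InsufficientDataError) as exc:
        report.flags.append(f"adsorption_failed: {exc}")

    latency: Optional[float] = None
    try:
        latency = detect_latency(series, adsorption_end=t_adsorb, rise_factor=rise_factor)
    except InsufficientDataError:
        report.flags.append("latency_insufficient_data")
    if latency is None and "latency_insufficient_data" not in report.flags:
        report.flags.append("latency_undetected")
    report.latency_min = latency
    report.baseline_window = (t_adsorb, latency if latency is not None else float(series.times[-1]))

    if t_burst is None and latency is not None:
        try:
            t_burst = default_burst_time(series, latency, t_adsorb, burst_time_strategy)
        except InsufficientDataError:
            report.flags.append("burst_time_undetected")
    if t_burst is not None:
        report.t_burst = t_burst
        try:
            report.burst_size = estimate_burst_size(series, t_adsorb, t_burst)
            report.burst_plateau_titer = series.titer_at(t_burst)
        except (NoAdsorptionError, InvalidInputError) as exc:
            report.flags.append(f"burst_undefined: {exc}")
    else:
        report.flags.append("burst_undetected")
    return report


def average_replicates(replicates: Sequence[TiterSeries], log_space: bool = True) -> TiterSeries:
    """Combine replicate titer series sampled on a common grid.

    With ``log_space=True`` (default) titers are averaged as
    ``10^mean(log10 titer)`` — the geometric mean, appropriate for
    dilution-plating counts spanning decades.  Zero titers fall back to the
    arithmetic mean at that time point.
    """
    if len(replicates) == 0:
        raise InvalidInputError("no replicates given")
    base = replicates[0]
    for rep in replicates[1:]:
        if len(rep) != len(base) or not np.allclose(rep.times, base.times):
            raise InvalidInputError("replicates must share the same sampling times")
    stack = np.vstack([rep.titers for rep in replicates])
    if log_space:
        with np.errstate(divide="ignore"):
            logs = np.log10(stack)
        averaged = np.where(
            np.all(np.isfinite(logs), axis=0),
            10 ** np.mean(logs, axis=0),
            np.mean(stack, axis=0),
        )
    else:
        averaged = np.mean(stack, axis=0)
    ods = [rep.od600 for rep in replicates if rep.od600 is not None]
    od = np.mean(np.vstack(ods), axis=0) if len(ods) == len(replicates) else None
    return TiterSeries(times=base.times.copy(), titers=averaged, od600=od)


class OneStepGrowth:
    """One-step growth-curve model in the model/results idiom.

    >>> model = OneStepGrowth(series, inoculum)
    >>> res = model.fit()
    >>> print(res.summary())

    The constructor captures the experiment (titer series + inoculum) and
    the analysis configuration; :meth:`fit` runs the estimators and returns
    an immutable results object.
    """

    def __init__(
        self,
        series: TiterSeries,
        inoculum: Optional[InoculumSpec] = None,
        *,
        n_cells: Optional[float] = None,
        t_adsorb: float = 4.0,
        t_burst: Optional[float] = None,
        rise_factor: float = 2.0,
        burst_time_strategy: str = "post_lysis",
    ) -> None:
        self.series = series
        self.inoculum = inoculum
        self.n_cells = n_cells
        self.t_adsorb = t_adsorb
        self.t_burst = t_burst
        self.rise_factor = rise_factor
        self.burst_time_strategy = burst_time_strategy

    @classmethod
    def from_dataframe(cls, df, inoculum: Optional[InoculumSpec] = None, **kwargs) -> "OneStepGrowth":
        """Build from a DataFrame with columns ``time_min``, ``titer_pfu_ml``
        and optionally ``od600``."""
        od = df["od600"].to_numpy(dtype=float) if "od600" in df.columns else None
        series = TiterSeries(
            times=df["time_min"].to_numpy(dtype=float),
            titers=df["titer_pfu_ml"].to_numpy(dtype=float),
            od600=od,
        )
        return cls(series, inoculum, **kwargs)

    def fit(self) -> "OneStepGrowthResults":
        report = analyze_one_step(
            self.series,
            self.inoculum,
            n_cells=self.n_cells,
            t_adsorb=self.t_adsorb,
            t_burst=self.t_burst,
            rise_factor=self.rise_factor,
            burst_time_strategy=self.burst_time_strategy,
        )
        return OneStepGrowthResults(self, report)


class OneStepGrowthResults:
    """Estimates and diagnostics from a fitted :class:`OneStepGrowth`."""

    def __init__(self, model: OneStepGrowth, report: KineticsReport) -> None:
        self.model = model
        self.report = report

    # convenient attribute passthroughs
    @property
    def moi(self):  # noqa: D102
        return self.report.moi

    @property
    def k(self):  # noqa: D102
        return self.report.k

    @property
    def latency_min(self):  # noqa: D102
        return self.report.latency_min

    @property
    def burst_size(self):  # noqa: D102
        return self.report.burst_size

    def to_dict(self) -> dict:
        return self.report.to_dict()

    def summary(self) -> str:
        """Human-readable report table, rounded in the conventional style
        (MOI 2 d.p., k two significant figures, burst to the nearest
        phage)."""
        r = self.report
        lines = [
            "          One-step growth curve analysis",
            "=" * 50,
        ]

        def row(label, value):
            lines.append(f"{label:<32}{value}")

        if r.moi is not None:
            row("MOI", f"{r.moi:.2f}")
        if r.k is not None:
            row("Adsorption rate constant k", f"{r.k:.2g} mL/min")
        if r.adsorbed_fraction is not None:
            row(f"Adsorbed fraction (0-{r.t_adsorb:g} min)", f"{r.adsorbed_fraction:.3f}")
        row(
            "Latency period",
            "undetected" if r.latency_min is None else f"{r.latency_min:g} min",
        )
        row(
            "Burst size",
            "undetected" if r.burst_size is None else f"{r.burst_size:.0f} PFU/cell",
        )
        if r.t_burst is not None:
            row("Burst read at", f"{r.t_burst:g} min")
        if r.flags:
            lines.append("-" * 50)
            for flag in r.flags:
                lines.append(f"flag: {flag}")
        lines.append("=" * 50)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the growth curve (log10 titer vs time) with the detected
        latency and burst-read annotations.  Returns the matplotlib axes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.semilogy(s.times, s.titers, "o-", label="free phage (PFU/mL)")
        if self.report.latency_min is not None:
            ax.axvline(self.report.latency_min, ls="--", color="gray", label="latency")
        if self.report.t_burst is not None:
            ax.axvline(self.report.t_burst, ls=":", color="tab:red", label="burst read")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("titer (PFU/mL)")
        ax.legend()
        return ax
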