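"""Bounded nonlinear least-squares fitting of marker excretion curves.

The public surface follows the Model/Results idiom: build a
:class:`MarkerCurveModel` from one animal-period's fecal time series, call
:meth:`~MarkerCurveModel.fit`, and read estimates, fit statistics and
diagnostics off the returned :class:`MarkerCurveResults`.

Fitting is fully deterministic: a fixed multi-start grid of initial values
is screened by sum-of-squared-error, the most promising starts are refined
with a bounded damped least-squares solver, and ties are broken toward the
smaller passage rate.  Data-cleaning rules that field studies apply by hand
(background subtraction, out-of-sequence "big dip" flagging, deletion of
near-duplicate adjacent samples that stall convergence) are codified here so
that reruns reproduce byte-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .kinetics import (
    DEFAULT_K2_CAP,
    KineticsDerived,
    MarkerCurveParams,
    MarkerDose,
    derive_all,
    excretion_concentration,
)

__all__ = [
    "FitError",
    "FecalSample",
    "FecalSeries",
    "FitConfig",
    "MarkerCurveModel",
    "MarkerCurveResults",
    "preprocess_series",
    "initial_start_grid",
    "fit_curve",
    "refit_with_deletion",
]

#: Minimum number of included samples required to fit four parameters.
MIN_SAMPLES = 6


class FitError(RuntimeError):
    """Raised when a series cannot be fitted; carries the escalation log."""

    def __init__(self, message: str, log: list[str] | None = None):
        super().__init__(message)
        self.log = log or []


@dataclass
class FecalSample:
    """One time-stamped fecal grab sample."""

    t: float                      #: hours since dose
    conc: float                   #: marker concentration, mg/kg fecal DM
    ash: float | None = None      #: ash fraction of DM, optional
    excluded: bool = False
    reason: str | None = None     #: machine-readable exclusion code

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if self.conc < 0:
            raise ValueError(f"concentration must be >= 0, got {self.conc}")


@dataclass
class FecalSeries:
    """One animal-period's marker time series plus dose and background."""

    samples: list[FecalSample]
    dose: MarkerDose
    background_conc: float = 0.0
    animal_id: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        if self.background_conc < 0:
            raise ValueError("background_conc must be >= 0")
        self.samples = sorted(self.samples, key=lambda s: s.t)

    @classmethod
    def from_arrays(cls, t: Sequence[float], conc: Sequence[float],
                    dose: MarkerDose, background_conc: float = 0.0,
                    animal_id: str = "", period: str = "") -> "FecalSeries":
        samples = [FecalSample(float(ti), float(ci))
                   for ti, ci in zip(t, conc, strict=True)]
        return cls(samples, dose, background_conc, animal_id, period)

    @property
    def included(self) -> list[FecalSample]:
        return [s for s in self.samples if not s.excluded]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, conc) of included samples."""
        inc = self.included
        return (np.array([s.t for s in inc]),
                np.array([s.conc for s in inc]))

    @property
    def mean_ash(self) -> float | None:
        vals = [s.ash for s in self.samples if s.ash is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def n_excluded(self) -> int:
        return sum(s.excluded for s in self.samples)


@dataclass
class FitConfig:
    """All thresholds and knobs of the fitting procedure.

    The defaults reproduce the rangeland-study conventions; every value is
    meant to be echoed into run logs so a fit is reproducible from its
    configuration alone.
    """

    k2_cap: float | None = DEFAULT_K2_CAP  #: None disables the cap
    lambda_max: float = 3.0                #: per h, generous upper bound
    k2_max_uncapped: float = 0.5           #: bound used when the cap is off
    # multi-start grid
    lambda_starts: tuple[float, ...] = (0.1, 0.2, 0.35, 0.6, 0.9)
    k2_starts: tuple[float, ...] = (0.035, 0.045, 0.055, 0.061)
    tau_fracs: tuple[float, ...] = (0.5, 0.8, 1.0)   #: x first nonzero time
    c2_fracs: tuple[float, ...] = (0.5, 1.0, 1.5)    #: x max observed conc
    n_refine: int = 10       #: starts refined with the full solver
    # solver tolerances; the escalation ladder multiplies these
    ftol: float = 1e-10
    xtol: float = 1e-10
    tol_ladder: tuple[float, ...] = (1.0, 4.0, 6.0)
    # data-cleaning rules
    dip_frac: float = 0.20        #: "big dip": < this fraction of both neighbours
    adjacent_dt: float = 2.0      #: h; pairs this close are deletion candidates
    similar_frac: float = 0.10    #: relative conc difference defining "similar"
    max_delete_frac: float = 0.10 #: cap on ladder deletions, fraction of samples
    boundary_rtol: float = 1e-4   #: k2 within this of the cap flags a boundary fit


def preprocess_series(raw: FecalSeries, config: FitConfig | None = None
                      ) -> FecalSeries:
    """Background-correct and flag out-of-sequence dips; never drops rows.

    Subtracts the pre-dose background concentration from every sample
    (clamped at zero) and flags interior samples whose concentration falls
    below ``dip_frac`` of both neighbours' — the "big dip" pattern that does
    not belong on a smooth single-peak excretion curve.  Flagged samples stay
    in the series with ``excluded=True`` and a reason code.
    """
    if config is None:
        config = FitConfig()
    if not raw.samples:
        raise FitError("series has no samples")
    bg = raw.background_conc
    new = [replace(s, conc=max(s.conc - bg, 0.0)) for s in raw.samples]
    # big-dip flagging on the background-corrected curve
    for i in range(1, len(new) - 1):
        left, mid, right = new[i - 1].conc, new[i].conc, new[i + 1].conc
        if left > 0 and right > 0 and mid < config.dip_frac * min(left, right):
            new[i] = replace(new[i], excluded=True, reason="big_dip")
    out = FecalSeries(new, raw.dose, 0.0, raw.animal_id, raw.period)
    if not out.included:
        raise FitError("series empty after preprocessing")
    return out


def initial_start_grid(series: FecalSeries, config: FitConfig | None = None
                       ) -> list[MarkerCurveParams]:
    """Deterministic multi-start grid scaled to the observed series.

    tau starts are fractions of the first time with nonzero (background-
    corrected) concentration; C2 starts are fractions of the maximum
    observed concentration.
    """
    if config is None:
        config = FitConfig()
    t, conc = series.arrays()
    nz = t[conc > 0]
    t_first = float(nz[0]) if nz.size else float(t[0])
    c_max = float(conc.max())
    if c_max <= 0:
        raise FitError("no nonzero concentrations to scale starts from")
    starts = []
    for lam in config.lambda_starts:
        for k2 in config.k2_starts:
            if config.k2_cap is not None:
                k2 = min(k2, config.k2_cap)
            for tf in config.tau_fracs:
                for cf in config.c2_fracs:
                    starts.append(MarkerCurveParams(
                        lambda1=lam, k2=k2, tau=tf * t_first, c2=cf * c_max))
    return starts


@dataclass
class _LadderState:
    log: list[str] = field(default_factory=list)
    n_deleted: int = 0


def _bounds(series: FecalSeries, config: FitConfig
            ) -> tuple[np.ndarray, np.ndarray]:
    t, _ = series.arrays()
    t_last = float(t[-1])
    k2_hi = config.k2_cap if config.k2_cap is not None else config.k2_max_uncapped
    lo = np.array([1e-6, 1e-6, 0.0, 1e-9])
    hi = np.array([config.lambda_max, k2_hi, max(t_last - 1e-6, 1e-3), np.inf])
    return lo, hi


def _sse(theta: np.ndarray, t: np.ndarray, conc: np.ndarray) -> float:
    p = MarkerCurveParams(*theta)
    r = conc - excretion_concentration(t, p)
    return float(r @ r)


def fit_curve(series: FecalSeries, config: FitConfig | None = None,
              tol_factor: float = 1.0, n_deleted: int = 0
              ) -> "MarkerCurveResults":
    """Fit the excretion model to one preprocessed series.

    Screens the full start grid by SSE, refines the ``n_refine`` best starts
    with bounded trust-region least squares, and returns the lowest-SSE
    converged solution.  Ties (within machine tolerance of SSE) break toward
    smaller k2, then smaller lambda1.  Solutions with k2 at the configured
    cap are flagged, never silently accepted as interior.
    """
    if config is None:
        config = FitConfig()
    t, conc = series.arrays()
    n = t.size
    if n <= 4:
        raise FitError("insufficient degrees of freedom")
    if n < MIN_SAMPLES:
        raise FitError(f"insufficient samples: {n} < {MIN_SAMPLES}")
    starts = initial_start_grid(series, config)
    lo, hi = _bounds(series, config)

    def clip(p: MarkerCurveParams) -> np.ndarray:
        return np.clip(p.as_array(), lo + 1e-12, np.where(np.isinf(hi), p.as_array(), hi))

    screened = sorted(
        (( _sse(clip(p), t, conc), i) for i, p in enumerate(starts)),
        key=lambda x: (x[0], x[1]))
    refine_idx = [i for _, i in screened[:max(config.n_refine, 1)]]

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = MarkerCurveParams(max(theta[0], 1e-12), max(theta[1], 1e-12),
                              max(theta[2], 0.0), max(theta[3], 1e-12))
        return excretion_concentration(t, p) - conc

    candidates = []
    for i in refine_idx:
        x0 = clip(starts[i])
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=config.ftol * tol_factor, xtol=config.xtol * tol_factor,
                gtol=1e-12)
        except Exception:  # singular model at a degenerate start
            continue
        if sol.status > 0:
            candidates.append(sol)
    if not candidates:
        raise FitError(
            f"no start converged ({len(refine_idx)} refined of {len(starts)})")

    def rank(sol):
        sse = 2.0 * sol.cost
        return (sse, sol.x[1], sol.x[0])

    # tie-group within 1e-9 relative SSE, then smaller k2 / lambda1
    best_sse = min(2.0 * s.cost for s in candidates)
    tied = [s for s in candidates
            if 2.0 * s.cost <= best_sse * (1 + 1e-9) + 1e-12]
    sol = min(tied, key=rank)
    params = MarkerCurveParams(*sol.x)
    sse = 2.0 * sol.cost
    at_bound = (config.k2_cap is not None and
                abs(params.k2 - config.k2_cap) <= config.boundary_rtol * config.k2_cap)
    return MarkerCurveResults(
        model=MarkerCurveModel(series, config), params=params, sse=sse,
        n_used=n, n_deleted=n_deleted, converged=True,
        n_starts=len(starts), at_k2_bound=at_bound)


def refit_with_deletion(series: FecalSeries, config: FitConfig | None = None,
                        mse_threshold: float | None = None
                        ) -> "MarkerCurveResults":
    """Escalation ladder for series that stall the plain fit.

    Applied when :func:`fit_curve` fails (or, optionally, when its MSE
    exceeds ``mse_threshold``).  Steps, each logged:

    1. relax the solver convergence tolerances by the configured factors;
    2. among sample pairs <= ``adjacent_dt`` hours apart with relative
       concentration difference < ``similar_frac``, delete the member with
       the larger residual against the best provisional fit and refit;
    3. delete samples flagged as big dips and refit.

    Total deletions are capped at ``max_delete_frac`` of the samples.  The
    first successful fit is returned with the ladder log attached; an
    exhausted ladder raises :class:`FitError` carrying the log.
    """
    if config is None:
        config = FitConfig()
    state = _LadderState()
    work = series
    provisional: MarkerCurveResults | None = None

    def attempt(s: FecalSeries, tol_factor: float) -> "MarkerCurveResults | None":
        nonlocal provisional
        try:
            res = fit_curve(s, config, tol_factor=tol_factor,
                            n_deleted=state.n_deleted)
        except FitError:
            return None
        if provisional is None or res.sse < provisional.sse:
            provisional = res
        if mse_threshold is not None and res.mse > mse_threshold:
            return None
        return res

    res = attempt(work, 1.0)
    if res is not None:
        state.log.append("step0: plain fit succeeded")
        res.ladder_log = state.log
        return res

    # step 1: tolerance relaxation
    for f in config.tol_ladder[1:]:
        state.log.append(f"step1: relax tolerances x{f:g}")
        res = attempt(work, f)
        if res is not None:
            res.ladder_log = state.log
            return res

    max_delete = max(1, math.floor(config.max_delete_frac * len(series.samples)))

    # step 2: near-duplicate adjacent pairs
    def similar_pairs(s: FecalSeries):
        inc = s.included
        out = []
        for a, b in zip(inc, inc[1:]):
            if b.t - a.t <= config.adjacent_dt:
                denom = max(a.conc, b.conc)
                if denom > 0 and abs(a.conc - b.conc) / denom < config.similar_frac:
                    out.append((a, b))
        return out

    for a, b in similar_pairs(work):
        if state.n_deleted >= max_delete:
            break
        if provisional is not None:
            ra = abs(a.conc - float(excretion_concentration(a.t, provisional.params)))
            rb = abs(b.conc - float(excretion_concentration(b.t, provisional.params)))
            victim = a if ra >= rb else b
        else:
            victim = b
        victim.excluded = True
        victim.reason = "adjacent_similar"
        state.n_deleted += 1
        state.log.append(
            f"step2: deleted adjacent-similar sample at t={victim.t:g} h")
        res = attempt(work, config.tol_ladder[-1])
        if res is not None:
            res.ladder_log = state.log
            return res

    # step 3: drop flagged dips (they were only flagged so far)
    for s in work.samples:
        if state.n_deleted >= max_delete:
            break
        if s.reason == "big_dip" and not s.excluded:
            s.excluded = True
            state.n_deleted += 1
            state.log.append(f"step3: deleted big-dip sample at t={s.t:g} h")
    res = attempt(work, config.tol_ladder[-1])
    if res is not None:
        res.ladder_log = state.log
        return res

    state.log.append("ladder exhausted")
    raise FitError("refit ladder exhausted without convergence", state.log)


class MarkerCurveModel:
    """Two-compartment marker-excretion model for one animal-period.

    Parameters
    ----------
    series
        The fecal time series (will be preprocessed on ``fit`` unless
        ``preprocessed=True`` was used upstream).
    config
        Fitting configuration; defaults reproduce the rangeland conventions.
    """

    def __init__(self, series: FecalSeries, config: FitConfig | None = None,
                 preprocessed: bool = True):
        self.series = series
        self.config = config or FitConfig()
        self._preprocessed = preprocessed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose: MarkerDose,
                       background_conc: float = 0.0,
                       config: FitConfig | None = None,
                       t_col: str = "hours_since_dose",
                       conc_col: str = "conc_mg_per_kg_dm") -> "MarkerCurveModel":
        """Build a model from a tidy per-sample DataFrame (raw, unprocessed)."""
        samples = [FecalSample(float(r[t_col]), float(r[conc_col]),
                               ash=(float(r["ash_pct"]) / 100.0
                                    if "ash_pct" in df.columns and pd.notna(r.get("ash_pct"))
                                    else None))
                   for _, r in df.iterrows()]
        animal = str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else ""
        period = str(df["period"].iloc[0]) if "period" in df.columns else ""
        series = FecalSeries(samples, dose, background_conc, animal, period)
        return cls(preprocess_series(series, config), config)

    def fit(self, use_ladder: bool = True) -> "MarkerCurveResults":
        """Fit; falls back to the deletion/relaxation ladder on failure."""
        series = self.series
        if not self._preprocessed:
            series = preprocess_series(series, self.config)
        try:
            return fit_curve(series, self.config)
        except FitError:
            if not use_ladder:
                raise
            return refit_with_deletion(series, self.config)


@dataclass
class MarkerCurveResults:
    """Estimates and fit statistics for one fitted excretion curve."""

    model: MarkerCurveModel
    params: MarkerCurveParams
    sse: float               #: (mg/kg)^2
    n_used: int
    n_deleted: int
    converged: bool
    n_starts: int
    at_k2_bound: bool
    ladder_log: list[str] = field(default_factory=list)

    @property
    def df_resid(self) -> int:
        return self.n_used - 4

    @property
    def mse(self) -> float:
        """SSE per residual degree of freedom, (mg/kg)^2."""
        return self.sse / self.df_resid if self.df_resid > 0 else float("nan")

    def predict(self, t) -> np.ndarray:
        return excretion_concentration(t, self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        t, _ = self.model.series.arrays()
        return self.predict(t)

    @property
    def resid(self) -> np.ndarray:
        t, conc = self.model.series.arrays()
        return conc - self.predict(t)

    def peak_time(self) -> float:
        """Hours post-dose of the fitted concentration maximum."""
        p = self.params
        hi = p.tau + 6.0 / p.lambda1 + 3.0 / p.k2
        res = minimize_scalar(lambda t: -float(excretion_concentration(t, p)),
                              bounds=(p.tau, hi), method="bounded",
                              options={"xatol": 1e-8})
        return float(res.x)

    def derive(self, ash_fraction: float | None = None,
               ash_cap: float = 0.15) -> KineticsDerived:
        """All downstream kinetics quantities (residence times, FO, fill)."""
        if ash_fraction is None:
            ash_fraction = self.model.series.mean_ash or 0.0
        return derive_all(self.params, self.model.series.dose,
                          ash_fraction, ash_cap)

    def diagnostics(self) -> pd.DataFrame:
        """Residual table: observed, fitted and residual per included sample."""
        t, conc = self.model.series.arrays()
        fitted = self.predict(t)
        return pd.DataFrame({"t": t, "observed": conc, "fitted": fitted,
                             "residual": conc - fitted})

    def summary(self) -> str:
        s = self.model.series
        p = self.params
        lines = [
            "Marker excretion curve fit (G2 -> G1 -> delay)",
            "=" * 47,
            f"animal: {s.animal_id or '-'}   period: {s.period or '-'}",
            f"n used: {self.n_used}   deleted: {self.n_deleted}   "
            f"starts: {self.n_starts}",
            "-" * 47,
            f"lambda1 (age-dependent rate, /h) {p.lambda1:12.4f}",
            f"k2      (passage rate, /h)       {p.k2:12.4f}"
            + ("  [at cap]" if self.at_k2_bound else ""),
            f"tau     (transit delay, h)       {p.tau:12.2f}",
            f"C2      (scale conc, mg/kg DM)   {p.c2:12.1f}",
            "-" * 47,
            f"SSE {self.sse:12.2f}   MSE {self.mse:12.2f} (mg/kg)^2",
            f"peak time {self.peak_time():8.1f} h post-dose",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 300):
        """Observed points and fitted curve on one axis (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, conc = self.model.series.arrays()
        tg = np.linspace(0.0, float(t[-1]) * 1.05, n_grid)
        ax.plot(tg, self.predict(tg), "-", label="fitted")
        ax.plot(t, conc, "o", label="observed")
        ax.set_xlabel("hours since dose")
        ax.set_ylabel("marker conc (mg/kg fecal DM)")
        ax.legend()
        return ax
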