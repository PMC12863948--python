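"""Closed-form two-compartment marker-excretion kinetics.

The fecal concentration curve that follows a single pulse dose of an
indigestible external marker (here the C32 alkane dotriacontane) is modelled
as the output of a gamma-2 (age-dependent) mixing compartment draining into
an exponential (age-independent) mixing compartment, followed by a pure
tubular transit delay::

    G2(lambda1)  ->  G1(k2)  ->  delay tau  ->  feces

With ``u = t - tau`` and ``delta = lambda1 / (lambda1 - k2)`` the marker
concentration in fecal dry matter is

    C(t) = C2 * delta**2 * [exp(-k2*u) - (1 + (lambda1 - k2)*u)*exp(-lambda1*u)]

for ``u > 0`` and zero otherwise.  ``C(t)`` is ``C2/k2`` times the probability
density of the transit-time sum Erlang2(lambda1) + Exp(k2), which yields the
closed forms used throughout this module:

* area under the curve           AUC  = C2 / k2
* total-tract residence time     RTG  = 2/lambda1 + 1/k2 + tau
* dose dilution (daily output)   FO   = 24 * D * k2 / C2

where D is the administered marker mass (mg) and C2 the fitted scale
concentration (mg marker per kg fecal DM), so D/C2 is in kg of fecal DM.

All functions operate on validated :class:`MarkerCurveParams`; the fitting
front-end lives in :mod:`pulsedose.fitting`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ParamError",
    "MarkerDose",
    "MarkerCurveParams",
    "KineticsDerived",
    "ResidenceTimes",
    "CompartmentMasses",
    "excretion_concentration",
    "excretion_density",
    "curve_auc",
    "fecal_output_dm",
    "residence_times",
    "compartment_masses",
    "derive_all",
    "DEFAULT_K2_CAP",
    "DEFAULT_ASH_CAP",
]

#: Upper bound applied to the passage rate k2 (per hour) when fitting
#: rangeland series; disabled for total-collection validation data.
DEFAULT_K2_CAP = 0.061

#: Fecal ash fraction is capped here before converting dry-matter quantities
#: to an organic-matter basis (soil contamination inflates measured ash).
DEFAULT_ASH_CAP = 0.15

#: Relative |lambda1 - k2| below which the equal-rates limit branch is used.
_EQUAL_RATE_RTOL = 1e-6


class ParamError(ValueError):
    """Raised when kinetic parameters or dose metadata are invalid."""


@dataclass(frozen=True)
class MarkerDose:
    """A pulse dose of external marker.

    Parameters
    ----------
    total_mg
        Total marker mass administered, mg.
    n_boluses, per_bolus_mg
        Optional bolus accounting; when both are given their product must
        match ``total_mg`` to within rounding (1%).
    dose_time
        Reference clock time of administration (hour zero of the series);
        informational only.
    """

    total_mg: float
    n_boluses: int | None = None
    per_bolus_mg: float | None = None
    dose_time: str | None = None

    def __post_init__(self) -> None:
        if not (self.total_mg > 0):
            raise ParamError(f"dose total_mg must be > 0, got {self.total_mg}")
        if self.n_boluses is not None and self.per_bolus_mg is not None:
            expect = self.n_boluses * self.per_bolus_mg
            if abs(expect - self.total_mg) > 0.01 * expect:
                raise ParamError(
                    f"total_mg {self.total_mg} inconsistent with "
                    f"{self.n_boluses} x {self.per_bolus_mg} mg = {expect} mg"
                )

    @classmethod
    def from_boluses(cls, n_boluses: int, per_bolus_mg: float,
                     dose_time: str | None = None) -> "MarkerDose":
        return cls(total_mg=n_boluses * per_bolus_mg, n_boluses=n_boluses,
                   per_bolus_mg=per_bolus_mg, dose_time=dose_time)


@dataclass(frozen=True)
class MarkerCurveParams:
    """The four kinetic parameters of one animal-period excretion curve.

    lambda1 : age-dependent escape rate from the first (gamma-2) mixing
        compartment, per hour.
    k2 : age-independent passage rate from the second mixing compartment
        (rumen passage rate), per hour.
    tau : post-compartment transit delay before the marker first appears in
        feces, hours.
    c2 : marker concentration scale in the slower-turnover compartment under
        instantaneous mixing, mg marker per kg fecal DM.
    """

    lambda1: float
    k2: float
    tau: float
    c2: float

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0):
            raise ParamError(f"lambda1 must be > 0, got {self.lambda1}")
        if not (self.k2 > 0):
            raise ParamError(f"k2 must be > 0, got {self.k2}")
        if not (self.tau >= 0):
            raise ParamError(f"tau must be >= 0, got {self.tau}")
        if not (self.c2 > 0):
            raise ParamError(f"c2 must be > 0, got {self.c2}")

    @property
    def equal_rates(self) -> bool:
        """True when lambda1 and k2 coincide to within the switch tolerance."""
        return abs(self.lambda1 - self.k2) < _EQUAL_RATE_RTOL * self.k2

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.k2, self.tau, self.c2])


class ResidenceTimes(NamedTuple):
    mcrt1: float  #: residence time in the slower compartment, 1/k2 (h)
    mcrt2: float  #: residence time in the faster compartment, 2/lambda1 (h)
    mcrts: float  #: mcrt1 + mcrt2 (h)
    rtg: float    #: total-tract residence time mcrts + tau (h)


class CompartmentMasses(NamedTuple):
    cm1: float  #: mass of undigested matter in the gamma-2 compartment (kg)
    cm2: float  #: mass in the exponential compartment, dose/c2 (kg)
    cms: float  #: total fill, cm1 + cm2 (kg)
    cf2: float  #: daily flux out of the second compartment (kg/d)


@dataclass(frozen=True)
class KineticsDerived:
    """All analytically derived kinetics quantities for one animal-period.

    Masses and fluxes carry a dry-matter (``*_dm`` / bare) and an ash-capped
    organic-matter (``*_om``) version; the OM basis scales the DM basis by
    ``1 - min(ash, ash_cap)`` rather than refitting the curve.
    """

    mcrt1: float
    mcrt2: float
    mcrts: float
    rtg: float
    fo_dm: float
    fo_om: float
    cm1: float
    cm2: float
    cms: float
    cf2: float
    cm1_om: float
    cm2_om: float
    cms_om: float
    cf2_om: float
    om_multiplier: float


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParamError("time since dose must be >= 0")
    return t


def excretion_concentration(t, params: MarkerCurveParams):
    """Marker concentration in fecal DM at ``t`` hours post-dose (mg/kg).

    Vectorised over ``t``.  Returns 0 for ``t <= tau``.  When lambda1 and k2
    agree to within the switch tolerance the continuous equal-rates limit
    ``C2 * (k**2 u**2 / 2) * exp(-k u)`` (an Erlang-3 transit density scaled
    by C2/k) is evaluated instead of the general form, which would divide by
    a vanishing rate difference.
    """
    t = _check_time(t)
    scalar = t.ndim == 0
    u = np.atleast_1d(t) - params.tau
    out = np.zeros_like(u, dtype=float)
    pos = u > 0
    up = u[pos]
    lam, k2, c2 = params.lambda1, params.k2, params.c2
    if params.equal_rates:
        k = k2
        out[pos] = c2 * (k * up) ** 2 / 2.0 * np.exp(-k * up)
    else:
        delta = lam / (lam - k2)
        out[pos] = c2 * delta ** 2 * (
            np.exp(-k2 * up) - (1.0 + (lam - k2) * up) * np.exp(-lam * up)
        )
    # guard tiny negative round-off in the near-equal-rates regime
    np.maximum(out, 0.0, out=out)
    return float(out[0]) if scalar else out


def excretion_density(t, params: MarkerCurveParams):
    """Transit-time probability density at ``t`` (per hour).

    This is ``excretion_concentration / AUC``; it integrates to one and its
    first moment is the total-tract residence time RTG.
    """
    return excretion_concentration(t, params) / curve_auc(params)


def curve_auc(params: MarkerCurveParams) -> float:
    """Area under the excretion curve, ``C2 / k2`` (mg·h/kg).

    Independent of lambda1 and tau: delaying or reshaping the transit does
    not change the total marker passed per kg of fecal DM.
    """
    return params.c2 / params.k2


def fecal_output_dm(params: MarkerCurveParams, dose: MarkerDose) -> float:
    """Daily fecal dry-matter output by dilution of the dose (kg DM/d).

    FO = 24 * D * k2 / C2 = 24 * D / AUC.  With D in mg and C2 in mg/kg the
    ratio D/C2 is directly in kg of fecal DM.
    """
    return 24.0 * dose.total_mg * params.k2 / params.c2


def residence_times(params: MarkerCurveParams) -> ResidenceTimes:
    """Compartment and total-tract mean residence times (h).

    mcrt1 = 1/k2 (slower, exponential compartment); mcrt2 = 2/lambda1
    (gamma-2 compartment holds the marker for two exponential stages);
    rtg = mcrt1 + mcrt2 + tau.
    """
    mcrt1 = 1.0 / params.k2
    mcrt2 = 2.0 / params.lambda1
    mcrts = mcrt1 + mcrt2
    return ResidenceTimes(mcrt1, mcrt2, mcrts, mcrts + params.tau)


def compartment_masses(params: MarkerCurveParams, dose: MarkerDose,
                       fo_rate: float,
                       rtol: float = 1e-6) -> CompartmentMasses:
    """Steady-state compartment masses from flux x residence time (kg).

    Parameters
    ----------
    fo_rate
        Dry-matter fecal output rate in kg/h.  Must be consistent with the
        dose-dilution output implied by ``params`` and ``dose``; when
        ``|fo_rate / k2 - dose/c2|`` exceeds ``rtol * cm2`` a warning is
        issued and the values are still returned.

    Notes
    -----
    cm2 = D/C2 is the steady-state content of the exponential compartment
    (flux/k2 with flux = D*k2/C2); cm1 = fo_rate * 2/lambda1 applies the same
    flux-times-residence-time identity to the gamma-2 compartment; cf2 is the
    daily flux out of compartment 2 and equals daily fecal output on the same
    basis.
    """
    cm2 = dose.total_mg / params.c2
    if abs(fo_rate / params.k2 - cm2) > max(rtol * cm2, 1e-12):
        implied = dose.total_mg * params.k2 / params.c2  # kg/h
        warnings.warn(
            f"fo_rate {fo_rate:.6g} kg/h inconsistent with dose dilution "
            f"({implied:.6g} kg/h)", stacklevel=2)
    cm1 = fo_rate * 2.0 / params.lambda1
    cf2 = params.k2 * cm2 * 24.0
    return CompartmentMasses(cm1, cm2, cm1 + cm2, cf2)


def derive_all(params: MarkerCurveParams, dose: MarkerDose,
               ash_fraction: float,
               ash_cap: float = DEFAULT_ASH_CAP) -> KineticsDerived:
    """Populate every derived kinetics quantity on DM and OM bases.

    ``ash_fraction`` is the measured fecal ash as a fraction of DM; it is
    capped at ``ash_cap`` (default 0.15) before the OM conversion because
    soil picked up with field samples inflates ash.  OM-basis masses and
    fluxes are the DM-basis values times ``1 - min(ash, ash_cap)``.
    """
    if not (0.0 <= ash_fraction < 1.0):
        raise ParamError(f"ash_fraction must be in [0, 1), got {ash_fraction}")
    rt = residence_times(params)
    fo_dm = fecal_output_dm(params, dose)
    om_mult = 1.0 - min(ash_fraction, ash_cap)
    fo_om = fo_dm * om_mult
    masses_dm = compartment_masses(params, dose, fo_dm / 24.0)
    return KineticsDerived(
        mcrt1=rt.mcrt1, mcrt2=rt.mcrt2, mcrts=rt.mcrts, rtg=rt.rtg,
        fo_dm=fo_dm, fo_om=fo_om,
        cm1=masses_dm.cm1, cm2=masses_dm.cm2, cms=masses_dm.cms,
        cf2=masses_dm.cf2,
        cm1_om=masses_dm.cm1 * om_mult, cm2_om=masses_dm.cm2 * om_mult,
        cms_om=masses_dm.cms * om_mult, cf2_om=masses_dm.cf2 * om_mult,
        om_multiplier=om_mult,
    )
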