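"""Cohort-level orchestration: fit every series, derive, compute intake.

Ties the per-animal model objects together into tidy DataFrames with one
row per animal-period, the shape the reporting layer and the group
summaries consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intake as nutrition
from .fitting import FecalSeries, FitConfig, FitError, MarkerCurveModel
from .intake import group_summary

__all__ = ["fit_all", "derived_table", "intake_table", "summary_table",
           "PipelineError"]


class PipelineError(RuntimeError):
    pass


def fit_all(series_list: list[FecalSeries], config: FitConfig | None = None,
            keep_going: bool = False
            ) -> tuple[pd.DataFrame, dict, list[dict]]:
    """Fit every animal-period series.

    Returns ``(fits, results, ledger)``: a tidy frame of parameter
    estimates and fit statistics, the live results objects keyed by
    ``(animal_id, period)``, and a deletion/exclusion ledger with one entry
    per excluded sample and per ladder action.
    """
    config = config or FitConfig()
    rows, results, ledger = [], {}, []
    for series in series_list:
        key = (series.animal_id, series.period)
        model = MarkerCurveModel(series, config)
        try:
            res = model.fit()
        except FitError as e:
            if not keep_going:
                raise PipelineError(
                    f"fit failed for animal {key[0]} period {key[1]}: {e}"
                ) from e
            ledger.append({"animal_id": key[0], "period": key[1],
                           "event": "fit_failed", "detail": str(e)})
            continue
        results[key] = res
        p = res.params
        rows.append({
            "animal_id": series.animal_id, "period": series.period,
            "lambda1": p.lambda1, "k2": p.k2, "tau": p.tau, "c2": p.c2,
            "sse": res.sse, "mse": res.mse, "n_used": res.n_used,
            "n_deleted": res.n_deleted, "at_k2_bound": res.at_k2_bound,
        })
        for s in series.samples:
            if s.excluded:
                ledger.append({"animal_id": key[0], "period": key[1],
                               "event": "sample_excluded",
                               "detail": f"t={s.t:g} reason={s.reason}"})
        for line in res.ladder_log:
            ledger.append({"animal_id": key[0], "period": key[1],
                           "event": "ladder", "detail": line})
    return pd.DataFrame(rows), results, ledger


def derived_table(results: dict, ash_cap: float = 0.15) -> pd.DataFrame:
    """Residence times, fecal output and fill for every fitted series."""
    rows = []
    for (animal, period), res in results.items():
        d = res.derive(ash_cap=ash_cap)
        rows.append({"animal_id": animal, "period": period,
                     "mcrt1": d.mcrt1, "mcrt2": d.mcrt2, "mcrts": d.mcrts,
                     "rtg": d.rtg, "fo_dm": d.fo_dm, "fo_om": d.fo_om,
                     "cm1": d.cm1, "cm2": d.cm2, "cms": d.cms, "cf2": d.cf2,
                     "cm1_om": d.cm1_om, "cm2_om": d.cm2_om,
                     "cms_om": d.cms_om, "cf2_om": d.cf2_om,
                     "om_multiplier": d.om_multiplier})
    return pd.DataFrame(rows)


def intake_table(fits: pd.DataFrame, derived: pd.DataFrame,
                 diet: pd.DataFrame, behavior: pd.DataFrame,
                 animals: pd.DataFrame,
                 convention: str = "range",
                 forage_tdn: float | None = None) -> pd.DataFrame:
    """Per-animal-period intake and energetics.

    ``convention='range'`` divides fecal DM output by (1 - DOM x 1.05), the
    grazing-study convention; ``'validation'`` divides by (1 - TDN) with an
    externally assayed ``forage_tdn``, as in the total-collection trial.
    DOM and CP are the arithmetic means over the sampled days per animal.
    """
    if convention not in ("range", "validation"):
        raise ValueError(f"unknown digestibility convention {convention!r}")
    if convention == "validation" and forage_tdn is None:
        raise ValueError("validation convention requires forage_tdn")

    diet_mean = (diet.groupby(["animal_id", "period"])
                 .agg(dom_pct=("dom_pct", "mean"), cp_pct=("cp_pct", "mean"))
                 .reset_index())
    df = (derived.merge(fits[["animal_id", "period", "lambda1", "k2", "tau",
                              "c2"]], on=["animal_id", "period"])
          .merge(diet_mean, on=["animal_id", "period"], how="left")
          .merge(behavior, on=["animal_id", "period"], how="left")
          .merge(animals[["animal_id", "treatment", "bw_kg"]],
                 on="animal_id", how="left"))

    rows = []
    for _, r in df.iterrows():
        dom = r["dom_pct"] / 100.0 if pd.notna(r.get("dom_pct")) else np.nan
        if convention == "range":
            dig = nutrition.tdn_from_dom(dom) if np.isfinite(dom) else np.nan
        else:
            dig = forage_tdn
        dmi = (nutrition.dmi_from_fecal_output(r["fo_dm"], dig)
               if np.isfinite(dig) else np.nan)
        pb = nutrition.pbwt(dmi, r["bw_kg"]) if np.isfinite(dmi) else np.nan
        om_in = (nutrition.om_intake_from_fecal_output(r["fo_om"], dom)
                 if np.isfinite(dom) else np.nan)
        me = nutrition.me_from_dom(dom) if np.isfinite(dom) else np.nan
        ei = (nutrition.energy_intake(om_in, me, r["bw_kg"])
              if np.isfinite(om_in) else np.nan)
        grazing = r.get("grazing_min_per_day", np.nan)
        he = (nutrition.harvest_efficiency(om_in * 1000.0, r["bw_kg"], grazing)
              if np.isfinite(om_in) and np.isfinite(grazing) and grazing > 0
              else np.nan)
        reps_raw = r.get("bite_rate_reps")
        bite = np.nan
        if isinstance(reps_raw, str) and reps_raw:
            br = nutrition.average_bite_rate(
                [float(x) for x in reps_raw.split(";")])
            bite = br if br is not None else np.nan
        elif isinstance(reps_raw, (int, float)) and np.isfinite(reps_raw):
            bite = float(reps_raw)
        hr = (nutrition.harvest_rate(dmi * 1000.0, grazing, bite)
              if np.isfinite(dmi) and np.isfinite(grazing)
              and np.isfinite(bite) and grazing * bite > 0 else np.nan)
        rows.append({
            "animal_id": r["animal_id"], "period": r["period"],
            "treatment": r.get("treatment"),
            "lambda1": r["lambda1"], "k2": r["k2"], "tau": r["tau"],
            "c2": r["c2"], "cms_om": r["cms_om"], "cms": r["cms"],
            "rtg": r["rtg"], "fo_dm": r["fo_dm"],
            "dom_pct": r.get("dom_pct"), "cp_pct": r.get("cp_pct"),
            "dmi": dmi, "pbwt": pb,
            "adj_pbwt": nutrition.adjusted_pbwt(pb) if np.isfinite(pb) else np.nan,
            "om_intake": om_in, "me": me, "ei": ei,
            "grazing_min": grazing, "bite_rate": bite,
            "he": he, "harvest_rate": hr, "bw_kg": r["bw_kg"],
        })
    return pd.DataFrame(rows)


#: Row order and labels of the study-style group summary.
SUMMARY_ITEMS = [
    ("lambda1", "lambda1, rate"),
    ("k2", "Passage rate (k2), /h"),
    ("tau", "tau, h"),
    ("c2", "C2 (CO1), ppm"),
    ("cms_om", "CMS, kg"),
    ("rtg", "RTG, h"),
    ("fo_dm", "Fecal DM output, kg/d"),
    ("dmi", "DMI, kg/d"),
    ("pbwt", "PBWT, % of BW"),
    ("adj_pbwt", "Adjusted PBWT, % of BW"),
    ("ei", "EI, kcal ME/kg^0.75/d"),
    ("me", "ME of consumed OM, Mcal/kg"),
    ("grazing_min", "Grazing, min/d"),
    ("bite_rate", "Bite rate, bites/min"),
    ("he", "HE, g OM/kg BW/min"),
    ("harvest_rate", "Harvest rate, g DMI/bite"),
]


def summary_table(intake: pd.DataFrame) -> pd.DataFrame:
    """Group means +- SE by treatment x period, one row per summary item."""
    cols = [c for c, _ in SUMMARY_ITEMS if c in intake.columns]
    wide = group_summary(intake, cols, by=["treatment", "period"])
    rows = []
    for col, label in SUMMARY_ITEMS:
        if col not in cols:
            continue
        for _, g in wide.iterrows():
            rows.append({"item": label, "treatment": g["treatment"],
                         "period": g["period"], "mean": g[f"{col}_mean"],
                         "se": g[f"{col}_se"], "n": g[f"{col}_n"]})
    return pd.DataFrame(rows)
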