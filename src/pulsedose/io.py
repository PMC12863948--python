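"""CSV reading/writing, run configuration and run logs.

All interchange is plain CSV: per-sample fecal tables, per-animal-day diet
quality, behaviour and animal records in; per-animal-period parameter and
intake tables plus a treatment x period group summary out.  Every run
writes a JSON-lines log that echoes the configuration and the deletion
ledger so a result file can always be traced to its thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .fitting import FecalSample, FecalSeries, FitConfig
from .kinetics import DEFAULT_ASH_CAP, DEFAULT_K2_CAP, MarkerDose
from .intake import PBWT_ADJUSTMENT

__all__ = ["RunConfig", "read_fecal_samples", "read_diet_quality",
           "read_behavior", "read_animals", "write_results", "IOError_"]


class IOError_(ValueError):
    """Input-table validation error, carrying the offending rows."""


REQUIRED_FECAL_COLS = {"animal_id", "period", "conc_mg_per_kg_dm"}


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    k2_cap: float | None = DEFAULT_K2_CAP
    digestibility_convention: str = "range"   #: "range" | "validation"
    forage_tdn: float | None = None           #: required for "validation"
    ash_cap: float = DEFAULT_ASH_CAP
    pbwt_adjustment: float = PBWT_ADJUSTMENT
    tol_ladder: tuple[float, ...] = (1.0, 4.0, 6.0)
    seed: int = 0
    dose_n_boluses: int = 6
    dose_per_bolus_mg: float = 756.0

    @property
    def dose(self) -> MarkerDose:
        return MarkerDose.from_boluses(self.dose_n_boluses,
                                       self.dose_per_bolus_mg)

    def fit_config(self) -> FitConfig:
        return FitConfig(k2_cap=self.k2_cap,
                         tol_ladder=tuple(self.tol_ladder))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["tol_ladder"] = list(d["tol_ladder"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "tol_ladder" in d:
            d["tol_ladder"] = tuple(d["tol_ladder"])
        return cls(**d)


def _hours_since_dose(df: pd.DataFrame) -> pd.Series:
    if "hours_since_dose" in df.columns:
        return df["hours_since_dose"].astype(float)
    if {"timestamp", "dose_time"}.issubset(df.columns):
        ts = pd.to_datetime(df["timestamp"])
        t0 = pd.to_datetime(df["dose_time"])
        return (ts - t0).dt.total_seconds() / 3600.0
    raise IOError_("need either hours_since_dose or timestamp + dose_time "
                   "columns")


def read_fecal_samples(path: str | Path, dose: MarkerDose
                       ) -> list[FecalSeries]:
    """Read and validate a per-sample fecal marker CSV into series.

    Required columns: ``animal_id``, ``period``, ``conc_mg_per_kg_dm`` and a
    time axis (``hours_since_dose``, or ``timestamp`` + ``dose_time``).
    Optional: ``ash_pct``, ``background_mg_per_kg`` (constant per series).
    Row-level problems are reported with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = REQUIRED_FECAL_COLS - set(df.columns)
    if missing:
        raise IOError_(f"missing required columns: {sorted(missing)}")
    df = df.copy()
    df["_t"] = _hours_since_dose(df)

    bad = df.index[(df["conc_mg_per_kg_dm"] < 0) | df["conc_mg_per_kg_dm"].isna()]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:10])
        raise IOError_(f"negative or missing concentration at data row(s) {rows}")
    bad = df.index[df["_t"] < 0]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:10])
        raise IOError_(f"negative time since dose at data row(s) {rows}")
    dup = df.duplicated(subset=["animal_id", "period", "_t"], keep=False)
    if dup.any():
        rows = ", ".join(str(i + 1) for i in df.index[dup][:10])
        raise IOError_(f"duplicate (animal, period, time) at data row(s) {rows}")

    series_list = []
    for (animal, period), g in df.groupby(["animal_id", "period"], sort=True):
        bg = 0.0
        if "background_mg_per_kg" in g.columns:
            vals = g["background_mg_per_kg"].dropna().unique()
            if len(vals) > 1:
                raise IOError_(
                    f"series ({animal}, {period}) has conflicting background "
                    "values")
            if len(vals):
                bg = float(vals[0])
        samples = [
            FecalSample(float(r["_t"]), float(r["conc_mg_per_kg_dm"]),
                        ash=(float(r["ash_pct"]) / 100.0
                             if "ash_pct" in g.columns and pd.notna(r["ash_pct"])
                             else None))
            for _, r in g.iterrows()]
        series_list.append(FecalSeries(samples, dose, background_conc=bg,
                                       animal_id=str(animal),
                                       period=str(period)))
    return series_list


def read_diet_quality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal_id", "period", "dom_pct"}
    missing = need - set(df.columns)
    if missing:
        raise IOError_(f"diet table missing columns: {sorted(missing)}")
    if ((df["dom_pct"] <= 0) | (df["dom_pct"] >= 100)).any():
        raise IOError_("dom_pct must be a percent in (0, 100)")
    return df


def read_behavior(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal_id", "period", "grazing_min_per_day"}
    missing = need - set(df.columns)
    if missing:
        raise IOError_(f"behavior table missing columns: {sorted(missing)}")
    return df


def read_animals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal_id", "treatment", "bw_kg"}
    missing = need - set(df.columns)
    if missing:
        raise IOError_(f"animal table missing columns: {sorted(missing)}")
    return df


def write_results(outdir: str | Path, config: RunConfig,
                  fits: pd.DataFrame | None = None,
                  derived: pd.DataFrame | None = None,
                  intake: pd.DataFrame | None = None,
                  summary: pd.DataFrame | None = None,
                  ledger: list[dict] | None = None) -> dict[str, Path]:
    """Write result tables, the formatted summary, and the run log.

    CSV floats are written at fixed precision so identical runs produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.6g")
        written[name] = p

    if fits is not None:
        _write(fits, "fits.csv")
    if derived is not None:
        _write(derived, "derived.csv")
    if intake is not None:
        _write(intake, "intake.csv")
    if summary is not None:
        _write(summary, "group_summary.csv")
        txt = outdir / "group_summary.txt"
        pretty = summary.copy()
        pretty["mean +- se"] = [f"{m:.3g} +- {s:.2g}"
                                for m, s in zip(pretty["mean"], pretty["se"])]
        txt.write_text(
            pretty.pivot_table(index="item", columns=["period", "treatment"],
                               values="mean +- se", aggfunc="first",
                               sort=False).to_string() + "\n")
        written["group_summary.txt"] = txt

    log = outdir / "run_log.jsonl"
    with log.open("w") as fh:
        cfg = dataclasses.asdict(config)
        cfg["tol_ladder"] = list(cfg["tol_ladder"])
        fh.write(json.dumps({"event": "config", **cfg}, sort_keys=True) + "\n")
        for entry in ledger or []:
            fh.write(json.dumps({"event": "ledger", **entry}, sort_keys=True)
                     + "\n")
    written["run_log.jsonl"] = log
    return written
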