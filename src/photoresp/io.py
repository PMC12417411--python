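"""CSV/JSON readers and writers and the end-to-end pipeline driver.

The native exchange format is a long CSV, one row per observation:

    species, replicate, o2, par, ca, ci, pn

(``ci`` optional). Instrument-style exports (LI-6400-like headers such
as Photo/CO2S/PARi) can be bridged with a ``column_map``. O2 given in
percent (e.g. 21) is normalized to a fraction with a warning.

:func:`run_pipeline` chains the stages — simulate or load, fit the four
model families on both CO2 axes, partition respiration, regress the
fluxes on C_a, compare fitted against measured respiration — and
writes tidy CSVs, a JSON summary and a plain-text run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fitting import (FitConvergenceError, FitOptions, GasExchangeCurve,
                      ModelFit, compare_fitted_measured, fit_model)
from .partitioning import RespirationSeries, build_respiration_series, recovery_inhibition
from .regression import fit_trend, peak_ca
from .synthetic import SimulationConfig, default_config, simulate_dataset

logger = logging.getLogger("photoresp")

__all__ = ["Dataset", "read_gas_exchange_csv", "write_dataset", "run_pipeline",
            "PipelineResult"]

REQUIRED_COLUMNS = ("species", "replicate", "o2", "par", "ca", "pn")


@dataclass
class Dataset:
    """A collection of gas-exchange curves plus free-form metadata."""

    curves: List[GasExchangeCurve]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(c.species, c.replicate, c.o2_fraction, c.par) for c in self.curves]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (species, replicate, o2, par) curve keys")

    def __len__(self) -> int:
        return len(self.curves)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            for i in range(c.n_points):
                rows.append({
                    "species": c.species, "replicate": c.replicate,
                    "o2": c.o2_fraction, "par": c.par, "ca": c.ca[i],
                    "ci": c.ci[i] if c.ci is not None else np.nan,
                    "pn": c.pn[i],
                })
        return pd.DataFrame(rows)


def read_gas_exchange_csv(path, column_map: Optional[Mapping[str, str]] = None) -> Dataset:
    """Read a long-format gas-exchange CSV into a validated Dataset.

    ``column_map`` maps file headers to native names, e.g.
    ``{"Photo": "pn", "CO2S": "ca", "PARi": "par"}``. Rows with
    non-numeric ca/pn are dropped with their line numbers logged; O2
    values above 1 are taken as percent and divided by 100.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty file")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}. "
            f"Native schema: {list(REQUIRED_COLUMNS)} (+ optional 'ci'); "
            "use column_map to alias instrument headers (e.g. Photo->pn, CO2S->ca).")

    for col in ("o2", "par", "ca", "pn"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    if "ci" in df.columns:
        df["ci"] = pd.to_numeric(df["ci"], errors="coerce")
    else:
        df["ci"] = np.nan
    bad = df.index[df[["o2", "par", "ca", "pn"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        logger.warning("%s: dropped %d non-numeric row(s) at line(s) %s",
                       path, len(bad), [int(i) + 2 for i in bad])
        df = df.drop(index=bad)
    if df.empty:
        raise ValueError(f"{path}: no valid rows")

    if (df["o2"] > 1).any():
        logger.warning("%s: o2 column looks like percent; normalizing to fraction", path)
        df.loc[df["o2"] > 1, "o2"] /= 100.0

    curves = []
    for (sp, rep, o2, par), g in df.groupby(["species", "replicate", "o2", "par"], sort=True):
        ci = g["ci"].to_numpy(dtype=float)
        curves.append(GasExchangeCurve(
            species=str(sp), replicate=rep, o2_fraction=float(o2), par=float(par),
            ca=g["ca"].to_numpy(dtype=float), pn=g["pn"].to_numpy(dtype=float),
            ci=None if np.isnan(ci).all() else ci))
    return Dataset(curves=curves)


def write_dataset(dataset: Dataset, path) -> Path:
    """Write a Dataset to the native long CSV (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr round-trips float64 exactly; pandas' default float formatting does not
    dataset.to_frame().to_csv(path, index=False,
                              float_format=lambda x: repr(float(x)))
    return path


def _fits_frame(fits: Sequence[ModelFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {"species": f.species, "replicate": f.replicate,
               "o2": f.o2_fraction, "model": f.model_id, "x_axis": f.x_axis,
               "respiration_estimate": f.respiration_estimate, "r2": f.r2,
               "ssr": f.ssr, "n_points": f.n_points_used, "converged": f.converged}
        for k, v in vars(f.params).items():
            row[f"param_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    dataset: Dataset
    fits: List[ModelFit]
    series: Dict[str, RespirationSeries]
    profiles: Dict[str, object]
    trends: Dict[str, dict]
    comparisons: Dict[str, object]
    summary: dict
    out_dir: Optional[Path]


def run_pipeline(config: Optional[SimulationConfig] = None,
                 dataset: Optional[Dataset] = None,
                 out_dir=None,
                 seed: Optional[int] = None,
                 models: Sequence[str] = ("fvcb", "rect", "mm", "modrect"),
                 axes: Sequence[str] = ("ca", "ci"),
                 fit_options: FitOptions = FitOptions(),
                 rn_o2: float = 0.21,
                 trend_degree: int = 2) -> PipelineResult:
    """Execute fit → partition → regress → compare on one dataset.

    With no ``dataset``, data are simulated from ``config`` (defaulting
    to the two-species default design) using ``seed``. Stage failures
    propagate with the stage name prefixed. When ``out_dir`` is given,
    writes fits.csv, series.csv, profiles.csv, trends.csv,
    summary.json and run.log; two runs with the same seed and config
    produce byte-identical summaries.
    """
    if config is None:
        config = default_config(seed=0 if seed is None else seed)
    if dataset is None:
        curves = simulate_dataset(config, seed=seed)
        dataset = Dataset(curves=curves, metadata={"source": "simulated"})
    used_seed = config.seed if seed is None else seed

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    # ---- partition first: fitting needs only light curves, comparison needs the series
    series = stage("partition", build_respiration_series, dataset.curves, rn_o2)

    # ---- fit every model family on every light curve, both axes
    fits: List[ModelFit] = []
    skipped = []
    for c in dataset.curves:
        if c.par <= 0:
            continue
        for m in models:
            for ax in axes:
                if ax == "ci" and c.ci is None:
                    continue
                try:
                    fits.append(stage("fit", fit_model, c, m, ax, fit_options))
                except (FitConvergenceError, ValueError) as e:
                    skipped.append({"species": c.species, "replicate": str(c.replicate),
                                    "o2": c.o2_fraction, "model": m, "x_axis": ax,
                                    "error": str(e)})
                    logger.warning("fit skipped: %s", e)

    # ---- recovery/inhibition profiles and trend regressions on the mean series
    profiles = {}
    trends: Dict[str, dict] = {}
    for sp, s in series.items():
        profiles[sp] = stage("partition", recovery_inhibition,
                             list(zip(s.ca, np.maximum(s.rp_mean, 0.0))), sp)
        rn21 = s.rn_mean.get(0.21, next(iter(s.rn_mean.values())))
        trends[sp] = {
            "rp": stage("regress", fit_trend, s.ca, s.rp_mean, "polynomial", trend_degree).to_dict(),
            "rd": stage("regress", fit_trend, s.ca, s.rd_mean, "polynomial", trend_degree).to_dict(),
            "rn": stage("regress", fit_trend, s.ca, rn21, "linear", 1).to_dict(),
            "peak_ca_rp": vars(stage("regress", peak_ca, list(zip(s.ca, s.rp_mean)))),
            "peak_ca_rd": vars(stage("regress", peak_ca, list(zip(s.ca, s.rd_mean)))),
        }

    # ---- fitted vs measured comparison per O2 class
    comparisons = {}
    compare_pairs = ((0.21, "rl"), (0.02, "rd")) if {"ca", "ci"} <= set(axes) else ()
    for o2, meas_key in compare_pairs:
        sub = [f for f in fits if abs(f.o2_fraction - o2) < 1e-9]
        measured = {}
        for sp, s in series.items():
            at0 = np.isclose(s.ca, 0.0)
            if at0.any():
                measured[sp] = float((s.rl_mean if meas_key == "rl" else s.rd_mean)[at0][0])
        if sub and measured:
            comparisons[meas_key] = stage("compare", compare_fitted_measured, sub, measured)

    summary = {
        "seed": used_seed,
        "n_curves": len(dataset.curves),
        "n_fits": len(fits),
        "skipped_fits": skipped,
        "species": sorted(series),
        "trends": trends,
        "comparisons": {k: [vars(r) for r in v.rows] for k, v in comparisons.items()},
        "respiration_at_zero_ca": {
            sp: {"rl": float(s.rl_mean[np.isclose(s.ca, 0)][0]),
                 "rd": float(s.rd_mean[np.isclose(s.ca, 0)][0]),
                 "rp": float(s.rp_mean[np.isclose(s.ca, 0)][0])}
            for sp, s in series.items() if np.isclose(s.ca, 0).any()
        },
    }

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        _fits_frame(fits).to_csv(out_path / "fits.csv", index=False)
        pd.concat([s.to_frame() for s in series.values()]).to_csv(
            out_path / "series.csv", index=False)
        pd.concat([p.to_frame() for p in profiles.values()]).to_csv(
            out_path / "profiles.csv", index=False)
        trend_rows = []
        for sp, t in trends.items():
            for q in ("rp", "rd", "rn"):
                trend_rows.append({"species": sp, "quantity": q, **{
                    k: (json.dumps(v) if isinstance(v, list) else v)
                    for k, v in t[q].items()}})
        pd.DataFrame(trend_rows).to_csv(out_path / "trends.csv", index=False)
        with open(out_path / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out_path / "run.log", "w") as fh:
            fh.write(f"photoresp {__version__}\n")
            fh.write(f"seed: {used_seed}\n")
            fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
            fh.write(f"config: {config!r}\n")
            fh.write(f"curves: {len(dataset.curves)}, fits: {len(fits)}, "
                     f"skipped: {len(skipped)}\n")

    return PipelineResult(dataset=dataset, fits=fits, series=series,
                          profiles=profiles, trends=trends,
                          comparisons=comparisons, summary=summary,
                          out_dir=out_path)
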