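"""End-to-end orchestration of the empirical protocol and the
simulation study.

Two entry points mirror the two arms of the analysis:

* :func:`run_empirical` applies the full protocol to a directory of COP
  recordings: SDA on position, DFA and PSD on both position and velocity
  per axis, AAMV on velocity, then aggregation across recordings into a
  summary table with one-sample t-tests against each method's boundary.
* :func:`run_simulation_study` simulates a cohort from the
  bounded-velocity model, analyzes position and velocity with DFA and
  PSD, and reports mean +/- SD slopes across the cohort.

Both are deterministic given their configuration (and seed, for the
simulation arm).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aamv import DEFAULT_WINDOW_S, compute_aamv
from .bcrw import BcrwParams, simulate_cohort
from .dfa import DEFAULT_N_MAX, DEFAULT_N_MIN, dfa_fluctuation
from .scaling import (
    BOUNDARIES,
    SlopePair,
    bin_loglog,
    classify_crossover,
    one_sample_t,
    two_region_slopes,
)
from .sda import sda_msd
from .series import Series1D, differentiate, read_cop_csv
from .spectral import psd_loglog

__all__ = ["RunConfig", "run_empirical", "run_simulation_study", "analyze_series"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run.

    ``inputs`` lists recording files (empirical arm); simulator
    parameters drive the simulation arm.  ``sda_on_velocity`` enables a
    non-canonical exploratory variant (the standard protocol runs SDA on
    position only).
    """

    inputs: tuple[str, ...] = ()
    dt: float = 0.025
    seed: int = 0
    n_series: int = 100
    bcrw: BcrwParams = field(default_factory=BcrwParams)
    dfa_n_min: int = DEFAULT_N_MIN
    dfa_n_max: int = DEFAULT_N_MAX
    aamv_window_s: float = DEFAULT_WINDOW_S
    sda_on_velocity: bool = False
    rescale_regions_if_short: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bcrw" in d and isinstance(d["bcrw"], dict):
            d["bcrw"] = BcrwParams(**d["bcrw"])
        if "inputs" in d:
            d["inputs"] = tuple(d["inputs"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = list(d["inputs"])
        return d


def _slope_rows(
    sp: SlopePair, method: str, signal: str, axis: str, series_id: str
) -> list[dict]:
    verdict = classify_crossover(sp)
    return [
        {
            "series": series_id,
            "method": method,
            "signal": signal,
            "axis": axis,
            "region": "short",
            "slope": sp.short_term_slope,
            "classification": verdict.classification,
        },
        {
            "series": series_id,
            "method": method,
            "signal": signal,
            "axis": axis,
            "region": "long",
            "slope": sp.long_term_slope,
            "classification": verdict.classification,
        },
    ]


def analyze_series(
    position: Series1D,
    axis: str = "AP",
    series_id: str = "series",
    config: RunConfig | None = None,
    run_sda: bool = True,
) -> tuple[list[dict], float]:
    """Run the per-recording protocol on one position series.

    Returns (slope rows, AAMV of the velocity series).  SDA is applied
    to position; DFA and PSD to both position and its per-sample
    velocity.  Degenerate stages (e.g. a constant series) are skipped
    with a warning and simply produce no rows.
    """
    cfg = config or RunConfig()
    velocity = differentiate(position)
    rows: list[dict] = []

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, FloatingPointError) as exc:
            warnings.warn(
                f"{series_id}/{axis}: {fn.__name__} skipped ({exc})", stacklevel=2
            )
            return None

    targets = {"position": position, "velocity": velocity}
    if run_sda:
        sda_targets = {"position": position}
        if cfg.sda_on_velocity:
            # non-canonical: SDA on the differenced series, for exploration
            sda_targets["velocity"] = velocity.with_values(
                velocity.values, label="position"
            )
        for signal, s in sda_targets.items():
            plot = _try(sda_msd, s)
            if plot is None:
                continue
            binned = _try(bin_loglog, plot)
            if binned is None:
                continue
            sp = _try(
                two_region_slopes,
                binned,
                method="SDA",
                rescale_if_short=cfg.rescale_regions_if_short,
            )
            if sp is not None:
                rows += _slope_rows(sp, "SDA", signal, axis, series_id)

    for signal, s in targets.items():
        # differencing shortens the series by one sample; clamp the DFA
        # window ceiling so a 1024-point recording's 1023-point velocity
        # series is still analyzable
        n_max = min(cfg.dfa_n_max, len(s) // 2)
        fp = _try(dfa_fluctuation, s, cfg.dfa_n_min, n_max)
        if fp is not None:
            binned = _try(bin_loglog, fp.loglog)
            sp = binned and _try(
                two_region_slopes,
                binned,
                method="DFA",
                rescale_if_short=cfg.rescale_regions_if_short,
            )
            if sp:
                rows += _slope_rows(sp, "DFA", signal, axis, series_id)
        plot = _try(psd_loglog, s)
        if plot is not None and len(plot) >= 2:
            binned = _try(bin_loglog, plot)
            sp = binned and _try(
                two_region_slopes,
                binned,
                method="PSD",
                rescale_if_short=cfg.rescale_regions_if_short,
            )
            if sp:
                rows += _slope_rows(sp, "PSD", signal, axis, series_id)

    aamv = np.nan
    res = _try(compute_aamv, velocity, cfg.aamv_window_s)
    if res is not None:
        aamv = res.value
    return rows, aamv


def summarize_slopes(rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-series slopes into a study summary table.

    One row per (method, signal, axis, region) with mean slope, SD, n,
    and a one-sample t-test against the method's boundary value.
    """
    out = []
    for (method, signal, axis, region), grp in rows.groupby(
        ["method", "signal", "axis", "region"], sort=False
    ):
        slopes = grp["slope"].to_numpy()
        boundary = BOUNDARIES[method]
        if slopes.size >= 2:
            t, p, df = one_sample_t(slopes, boundary)
        else:
            t, p, df = np.nan, np.nan, slopes.size - 1
        out.append(
            {
                "method": method,
                "signal": signal,
                "axis": axis,
                "region": region,
                "mean_slope": slopes.mean(),
                "sd": slopes.std(ddof=1) if slopes.size >= 2 else np.nan,
                "n": slopes.size,
                "boundary": boundary,
                "t": t,
                "p": p,
                "df": df,
            }
        )
    return pd.DataFrame(out)


def run_empirical(config: RunConfig) -> dict:
    """Run the empirical protocol over the configured recordings.

    Returns a dict with the per-series slope table (``slopes``), the
    aggregated ``summary``, the per-series ``aamv`` table, and a list of
    per-file ``errors`` (unreadable files are recorded and skipped).
    """
    if not config.inputs:
        raise ValueError("empirical run requires at least one input recording")
    all_rows: list[dict] = []
    aamv_rows: list[dict] = []
    errors: list[dict] = []
    for path in config.inputs:
        try:
            by_axis = read_cop_csv(path, dt=config.dt)
        except Exception as exc:  # ragged/unreadable file: record and move on
            errors.append({"file": str(path), "error": str(exc)})
            continue
        for axis, pos in by_axis.items():
            rows, aamv = analyze_series(
                pos, axis=axis, series_id=Path(str(path)).stem, config=config
            )
            all_rows += rows
            aamv_rows.append(
                {"series": Path(str(path)).stem, "axis": axis, "aamv": aamv}
            )
    if not all_rows:
        raise ValueError(
            "empty cohort: no recording could be analyzed "
            f"({len(errors)} file error(s))"
        )
    slopes = pd.DataFrame(all_rows)
    return {
        "slopes": slopes,
        "summary": summarize_slopes(slopes),
        "aamv": pd.DataFrame(aamv_rows),
        "errors": errors,
        "config": config.to_dict(),
    }


def run_simulation_study(config: RunConfig | None = None) -> dict:
    """Simulate a bounded-velocity cohort and analyze it with DFA and PSD.

    The machine twin of the reference simulation study: ``n_series``
    velocity series from the model, integrated to position, analyzed by
    DFA and PSD (both signals), slopes aggregated across the cohort.
    SDA is not part of this arm.
    """
    cfg = config or RunConfig()
    params = dataclasses.replace(cfg.bcrw, seed=cfg.seed)
    cohort = simulate_cohort(params, cfg.n_series)
    all_rows: list[dict] = []
    aamv_rows: list[dict] = []
    for i, res in enumerate(cohort):
        rows, aamv = analyze_series(
            res.position,
            axis="sim",
            series_id=f"sim{i:03d}",
            config=cfg,
            run_sda=False,
        )
        all_rows += rows
        aamv_rows.append({"series": f"sim{i:03d}", "axis": "sim", "aamv": aamv})
    slopes = pd.DataFrame(all_rows)
    return {
        "slopes": slopes,
        "summary": summarize_slopes(slopes),
        "aamv": pd.DataFrame(aamv_rows),
        "errors": [],
        "config": cfg.to_dict(),
    }
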