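"""End-to-end orchestration: ingest -> uptake -> retention -> inversion -> fits.

One :class:`RunConfig` drives the whole chain reproducibly; every default
that encodes an open methodological choice (day window, linearization
step, rain policy, root-extrapolation sign) is surfaced in the run
manifest so no decision is silent.  Identical config + inputs + seed give
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import time as time_t
from pathlib import Path

import numpy as np
import pandas as pd

from . import timeseries as ts
from . import uptake as up
from .hydraulics import (
    RootLayer,
    invert_kr_psi0,
    kr_given_psi0,
    root_length_at,
    transfer_psi0_to_subsoil,
)
from .retention import RetentionParams, fit_retention, theta_to_psi
from .stats import fit_candidates, split_by_rain


@dataclass
class RunConfig:
    series_csv: str
    retention_csv: str | None = None
    retention_params: RetentionParams | None = None
    roots_csv: str | None = None
    out_dir: str = "rhizoflux_run"
    theta_unit: str = "fraction"
    day_start: time_t = time_t(6, 0)
    day_end: time_t = time_t(20, 0)
    boundary_window_min: int = 240
    rain_threshold: float = 0.01
    rain_window_hours: float = 6.0
    split_date: str | None = None  # before/after-rainfall grouping
    growth_alphas: tuple = (0.0, 0.002)  # d^-1
    growth_sign: str = "printed"
    dpsi_frac: float = 0.05  # linearization step as fraction of |psi|
    topsoil_depth: float | None = None  # defaults to shallowest sensor
    profile_bottom: float = 50.0
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    excluded_days: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    defaults_encoding_open_choices: dict = field(default_factory=dict)


def _analysis_dates(series: ts.MoistureSeries, cfg: RunConfig):
    """Calendar days fully bracketed by a preceding and following night."""
    idx = series.data.index
    first = (idx.min() + pd.Timedelta(days=1)).date()
    last = (idx.max() - pd.Timedelta(days=1)).date()
    return [d.date() for d in pd.date_range(first, last, freq="D")]


def compute_uptake(series: ts.MoistureSeries, cfg: RunConfig):
    """Daily uptake per depth with rain flags, plus T and relative uptake."""
    events = ts.detect_rain_events(
        series,
        threshold=cfg.rain_threshold,
        window=pd.Timedelta(hours=cfg.rain_window_hours),
    )
    wet_days = ts.rain_days(events)
    window_td = pd.Timedelta(minutes=cfg.boundary_window_min)
    rows: list[up.DailyLayerUptake] = []
    transp: list[up.TranspirationEstimate] = []
    rel: list[up.RelativeUptake] = []
    for date in _analysis_dates(series, cfg):
        try:
            windows = ts.segment_diel(
                series,
                date,
                day_start=cfg.day_start,
                day_end=cfg.day_end,
                boundary_window=window_td,
            )
        except ts.WindowIncompleteError:
            continue
        # a rain event invalidates the quiescent-night assumption for the
        # day itself and for the neighbouring days sharing a night; those
        # rows are flagged, never dropped
        one_day = pd.Timedelta(days=1)
        rainy = bool({date, date - one_day, date + one_day} & wet_days)
        day_rows = []
        for depth, w in sorted(windows.items()):
            w = ts.DielWindow(**{**w.__dict__, "rain_flag": rainy})
            day_rows.append(up.daily_uptake_rate(w))
        rows.extend(day_rows)
        if all(r.valid for r in day_rows):
            t_est = up.depth_integrated_transpiration(
                day_rows, bottom=cfg.profile_bottom
            )
            transp.append(t_est)
            rel.extend(up.normalize_uptake(t_est))
    return rows, transp, rel, events


def invert_hydraulics(
    uptake_df: pd.DataFrame,
    params: RetentionParams,
    roots: dict[float, RootLayer],
    cfg: RunConfig,
    series: ts.MoistureSeries,
) -> pd.DataFrame:
    """Per-depth k_r and psi0 from the fitted uptake-potential relations.

    The topsoil (shallowest sensor) relation is inverted with the
    two-parameter local linearization; subsoil layers reuse the topsoil
    psi0(psi) relation (assumed depth-invariant) and invert k_r pointwise.
    Rain-flagged and invalid days are excluded from the fits.
    """
    daily_psi = _daily_mean_psi(series, cfg, params)
    df = uptake_df.merge(daily_psi, on=["date", "depth_cm"], how="left")
    df = df[df["valid"] & ~df["rain_flag"] & np.isfinite(df["psi_mpa"])]
    groups = [("pooled", df)]
    if cfg.split_date:
        before, after = split_by_rain(df, cfg.split_date)
        groups = [("before_rain", before), ("after_rain", after)]
    top = cfg.topsoil_depth if cfg.topsoil_depth is not None else min(roots)
    out_rows = []
    for gname, gdf in groups:
        top_df = gdf[gdf["depth_cm"] == top]
        if len(top_df) < 3:
            continue
        fits = fit_candidates(top_df["psi_mpa"], top_df["s_prime_per_day"], group=gname)
        if fits.best is None:
            continue
        psi_eval = np.quantile(top_df["psi_mpa"], np.linspace(0.1, 0.9, 9))
        anchors = []
        for alpha in cfg.growth_alphas:
            layer = RootLayer(
                depth=top,
                L_m=roots[top].L_m,
                t_m=roots[top].t_m,
                alpha=alpha,
                R=roots[top].R,
            )
            mean_date = pd.Timestamp(top_df["date"].astype(str).min()) + (
                pd.Timestamp(top_df["date"].astype(str).max())
                - pd.Timestamp(top_df["date"].astype(str).min())
            ) / 2
            L = root_length_at(mean_date.date(), layer, cfg.growth_sign)
            for psi in psi_eval:
                try:
                    k_r, psi0, flagged = invert_kr_psi0(
                        fits.best, float(psi), -cfg.dpsi_frac * abs(float(psi)), L
                    )
                except Exception:
                    continue
                out_rows.append(
                    dict(
                        depth_cm=top,
                        psi_mpa=float(psi),
                        k_r=k_r,
                        psi0_mpa=psi0,
                        group=gname,
                        growth_scenario=alpha,
                        flagged=flagged,
                    )
                )
                if alpha == cfg.growth_alphas[0]:
                    anchors.append((float(psi), psi0))
        # subsoil: transfer psi0, invert k_r pointwise along the fitted curve
        for depth in sorted(d for d in roots if d != top):
            sub_df = gdf[gdf["depth_cm"] == depth]
            if len(sub_df) < 3 or not anchors:
                continue
            sub_fits = fit_candidates(
                sub_df["psi_mpa"], sub_df["s_prime_per_day"], group=gname
            )
            if sub_fits.best is None:
                continue
            sub_psi = np.quantile(sub_df["psi_mpa"], np.linspace(0.1, 0.9, 9))
            for alpha in cfg.growth_alphas:
                layer = RootLayer(
                    depth=depth,
                    L_m=roots[depth].L_m,
                    t_m=roots[depth].t_m,
                    alpha=alpha,
                    R=roots[depth].R,
                )
                mid = pd.Timestamp(sub_df["date"].astype(str).min()) + (
                    pd.Timestamp(sub_df["date"].astype(str).max())
                    - pd.Timestamp(sub_df["date"].astype(str).min())
                ) / 2
                L = root_length_at(mid.date(), layer, cfg.growth_sign)
                for psi in sub_psi:
                    psi0, extrap = transfer_psi0_to_subsoil(anchors, float(psi))
                    s_val = float(sub_fits.best(float(psi)))
                    if s_val <= 0 or psi <= psi0:
                        continue
                    k_r = kr_given_psi0(s_val, float(psi), psi0, L)
                    out_rows.append(
                        dict(
                            depth_cm=depth,
                            psi_mpa=float(psi),
                            k_r=k_r,
                            psi0_mpa=psi0,
                            group=gname,
                            growth_scenario=alpha,
                            flagged=bool(extrap),
                        )
                    )
    return pd.DataFrame(out_rows)


def _daily_mean_psi(
    series: ts.MoistureSeries, cfg: RunConfig, params: RetentionParams
) -> pd.DataFrame:
    """Daytime-mean matric potential (MPa) per date and depth.

    Each 15-min sample is converted through the retention curve before
    averaging; converting the mean theta instead would add the curve's
    Jensen gap as spurious convexity at the dry end.
    """
    data = series.data
    hours = data.index.hour + data.index.minute / 60.0
    day_mask = (hours >= cfg.day_start.hour) & (hours < cfg.day_end.hour)
    day_data = data[day_mask].clip(lower=params.theta_r + 1e-6, upper=params.theta_s)
    psi = day_data.apply(lambda c: theta_to_psi(c.to_numpy(), params)) / 1000.0
    grouped = psi.groupby(day_data.index.date).mean()
    long = grouped.stack(future_stack=True).rename("psi_mpa").reset_index()
    long.columns = ["date", "depth_cm", "psi_mpa"]
    return long


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the full chain, writing stage outputs and a manifest."""
    out = Path(cfg.out_dir)
    manifest = RunManifest(
        config={
            k: (str(v) if not isinstance(v, (int, float, str, list, tuple, type(None))) else v)
            for k, v in asdict(cfg).items()
        },
        defaults_encoding_open_choices={
            "day_window": f"{cfg.day_start}-{cfg.day_end}",
            "boundary_window_min": cfg.boundary_window_min,
            "rain_policy": "rain days flagged and excluded from k_r/psi0 fits",
            "dpsi": f"{cfg.dpsi_frac} * |psi|",
            "root_extrapolation_sign": cfg.growth_sign,
        },
    )
    for path in (cfg.series_csv, cfg.retention_csv, cfg.roots_csv):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input path does not exist: {path}")
    out.mkdir(parents=True, exist_ok=True)

    series = ts.read_moisture_csv(cfg.series_csv, theta_unit=cfg.theta_unit)
    manifest.stages.append("ingest")

    rows, transp, rel, events = compute_uptake(series, cfg)
    uptake_df = up.uptake_table(rows)
    uptake_df.to_csv(out / "uptake.csv", index=False)
    pd.DataFrame(
        [{"date": t.date, "T_cm_per_day": t.T} for t in transp]
    ).to_csv(out / "transpiration.csv", index=False)
    pd.DataFrame(
        [{"date": r.date, "depth_cm": r.depth, "fraction": r.fraction} for r in rel]
    ).to_csv(out / "relative_uptake.csv", index=False)
    manifest.stages.append("uptake")
    manifest.excluded_days = sorted(
        {str(r.date) for r in rows if not r.valid or r.rain_flag}
    )

    params = cfg.retention_params
    if params is None and cfg.retention_csv:
        ret_df = pd.read_csv(cfg.retention_csv)
        fit = fit_retention(ret_df["psi_kPa"].to_numpy(), ret_df["theta"].to_numpy())
        params = fit.params
        (out / "retention_params.json").write_text(params.to_json())
        manifest.stages.append("retention")

    if params is not None and cfg.roots_csv:
        roots_df = pd.read_csv(cfg.roots_csv)
        roots = {
            float(r.depth_cm): RootLayer(
                depth=float(r.depth_cm),
                L_m=float(r.L_m_cm_per_cm3),
                t_m=pd.Timestamp(r.t_m).date(),
                alpha=0.0,
                R=float(getattr(r, "radius_cm", 0.015)),
            )
            for r in roots_df.itertuples()
        }
        hyd = invert_hydraulics(uptake_df, params, roots, cfg, series)
        hyd.to_csv(out / "hydraulics.csv", index=False)
        manifest.stages.append("inversion")

        fits_out = {}
        daily_psi = _daily_mean_psi(series, cfg, params)
        df = uptake_df.merge(daily_psi, on=["date", "depth_cm"], how="left")
        df = df[df["valid"] & ~df["rain_flag"] & np.isfinite(df["psi_mpa"])]
        for depth, sub in df.groupby("depth_cm"):
            fits = fit_candidates(sub["psi_mpa"], sub["s_prime_per_day"])
            fits_out[str(depth)] = [
                dict(form=f.form, params=list(f.params), r2=f.r2, p=f.p_value, n=f.n)
                for f in fits.fits
            ] + ([{"best": fits.best.form}] if fits.best else [{"best": None}])
        (out / "fits.json").write_text(json.dumps(fits_out, indent=1))
        manifest.stages.append("fitting")

    manifest.outputs = {p.name: str(p) for p in sorted(out.glob("*"))}
    manifest.outputs["manifest.json"] = str(out / "manifest.json")
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "config": manifest.config,
                "stages": manifest.stages,
                "warnings": manifest.warnings,
                "excluded_days": manifest.excluded_days,
                "outputs": manifest.outputs,
                "defaults_encoding_open_choices": manifest.defaults_encoding_open_choices,
            },
            indent=1,
            default=str,
        )
    )
    return manifest
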