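"""Readers, writers, configuration and the end-to-end analysis pipeline.

Trajectory tables use the deposited-data CSV dialect: a ``time`` column in
minutes and a ``koor`` column giving the distance from the lane center in
micrometers along the long axis.  Multi-cell files carry an additional cell
id column; alternatively each cell lives in its own file listed in a manifest
(columns: file, cell_id, lane_length, width, tip_shape, source).

Every output file starts with a provenance header (version, config hash,
seed), so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, geometry, synth
from .analysis import Trajectory

logger = logging.getLogger("microlane")
if not logger.handlers:  # stderr logging, configurable by the embedding app
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_ID_COLUMNS = ("cell_id", "cell", "id", "track", "track_id")


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(config: dict) -> str:
    """Short stable hash of the scientific configuration.

    Output-location and presentation keys are excluded so that identical
    analyses written to different directories produce identical files.
    """
    cfg = {k: v for k, v in config.items() if k not in ("out_dir", "make_plots")}
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# Trajectory CSV (S1 dialect)
# ---------------------------------------------------------------------------


def read_trajectory_csv(path: str | Path, lane_length: float | None = None,
                        ) -> list[Trajectory]:
    """Read one trajectory CSV; returns one Trajectory per cell id.

    Requires ``time`` and ``koor`` columns (case-insensitive).  Malformed
    numeric rows are reported with their line numbers; non-monotone or
    non-uniform time stamps are rejected.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "time" not in df.columns or "koor" not in df.columns:
        raise ValueError(f"{path}: missing required columns 'time' and 'koor' "
                         f"(found {list(df.columns)})")
    id_col = next((c for c in _ID_COLUMNS if c in df.columns), None)

    numeric = df[["time", "koor"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & df[["time", "koor"]].notna().any(axis=1)
    bad |= df[["time", "koor"]].isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df[["time", "koor"]] = numeric

    if lane_length is None:
        lane_length = float(2 * np.ceil(np.abs(df["koor"]).max() / 5) * 5)
    out = []
    groups = df.groupby(id_col, sort=True) if id_col else [(Path(path).stem, df)]
    for cid, g in groups:
        times = g["time"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            i = int(np.flatnonzero(np.diff(times) <= 0)[0])
            raise ValueError(f"{path}: non-monotone time at line {int(g.index[i + 1]) + 2}")
        steps = np.diff(times)
        if np.ptp(steps) > 1e-6 * steps[0]:
            i = int(np.argmax(np.abs(steps - steps[0])))
            raise ValueError(f"{path}: gap or mixed sampling interval at line "
                             f"{int(g.index[i + 1]) + 2}")
        out.append(Trajectory(times=times, koor=g["koor"].to_numpy(float),
                              lane_length=lane_length, cell_id=str(cid)))
    return out


def write_trajectory_csv(traj: Trajectory, path: str | Path, header: str = "") -> None:
    """Write one track in the S1 dialect, with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# microlane {_version()}{(' ' + header) if header else ''}\n")
        fh.write("time,koor\n")
        for t, x in zip(traj.times, traj.koor):
            fh.write(f"{t:.6g},{x:.6g}\n")


def read_manifest(path: str | Path) -> tuple[pd.DataFrame, list[Trajectory]]:
    """Read a manifest CSV and all trajectory files it references.

    Required columns: ``file`` (relative to the manifest) and ``lane_length``;
    ids default to the file stem.
    """
    path = Path(path)
    mf = pd.read_csv(path, comment="#")
    mf.columns = [str(c).strip().lower() for c in mf.columns]
    for col in ("file", "lane_length"):
        if col not in mf.columns:
            raise ValueError(f"{path}: manifest missing required column {col!r}")
    trajs: list[Trajectory] = []
    seen: set[str] = set()
    for _, row in mf.iterrows():
        for tr in read_trajectory_csv(path.parent / row["file"],
                                      lane_length=float(row["lane_length"])):
            if tr.cell_id in seen:
                raise ValueError(f"duplicate cell id {tr.cell_id!r} in manifest {path}")
            seen.add(tr.cell_id)
            trajs.append(tr)
    return mf, trajs


def write_ensemble(trajs: list[Trajectory], manifest: pd.DataFrame, out_dir: str | Path,
                   header: str = "") -> Path:
    """One CSV per cell plus ``manifest.csv``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mf = manifest.copy()
    files = []
    for tr in trajs:
        fn = f"{tr.cell_id}.csv"
        write_trajectory_csv(tr, out / fn, header=header)
        files.append(fn)
    mf.insert(0, "file", files)
    mpath = out / "manifest.csv"
    with open(mpath, "w") as fh:
        fh.write(f"# microlane {_version()}{(' ' + header) if header else ''}\n")
        mf.to_csv(fh, index=False)
    return mpath


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _lane_groups(trajs: list[Trajectory]) -> dict[float, list[Trajectory]]:
    groups: dict[float, list[Trajectory]] = {}
    for tr in trajs:
        groups.setdefault(float(tr.lane_length), []).append(tr)
    return dict(sorted(groups.items()))


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute filter -> profiles -> change points -> spectrum -> period fit ->
    reversals on a trajectory ensemble and write all result tables.

    ``config`` keys: ``input`` (either ``{"manifest": path}`` or
    ``{"synthetic": {<GeneratorParams fields>, n_cells, lane_lengths}}``),
    optional ``xi0`` (um, default 55), ``bin_width`` (um, default 5),
    ``min_duration`` (min), ``out_dir``, ``make_plots``.  Identical config and
    inputs yield byte-identical outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    chash = config_hash(config)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    xi0 = float(config.get("xi0", analysis.XI0_UM))
    bin_width = float(config.get("bin_width", analysis.BIN_WIDTH_UM))
    min_duration = float(config.get("min_duration", analysis.MIN_DURATION_MIN))
    notices: list[str] = []
    report: dict = {"version": _version(), "config_hash": chash, "notices": notices}
    header = f"config={chash}"

    src = config.get("input")
    if not src:
        raise ValueError("config must name an 'input' (manifest or synthetic)")
    stage = "input"
    try:
        if "manifest" in src:
            _, trajs = read_manifest(src["manifest"])
            logger.info("read %d tracks from %s", len(trajs), src["manifest"])
        elif "synthetic" in src:
            sc = dict(src["synthetic"])
            n_cells = int(sc.pop("n_cells", 100))
            lanes = sc.pop("lane_lengths", None)
            params = synth.GeneratorParams(**sc)
            trajs, _, _ = synth.generate_ensemble(params, n_cells, lanes)
            report["seed"] = params.seed
            logger.info("generated %d synthetic tracks (seed %d)", len(trajs), params.seed)
        else:
            raise ValueError("input must contain 'manifest' or 'synthetic'")

        stage = "filter"
        trajs, frep = analysis.filter_tracks(trajs, min_duration=min_duration, xi0=xi0)
        report["filter"] = {"n_input": frep.n_input, "n_retained": frep.n_retained,
                            **frep.excluded}

        stage = "profiles"
        groups = _lane_groups(trajs)
        prof_rows, cp_rows, spec_rows, rev_rows = [], [], [], []
        periods: dict[float, float] = {}
        for L, group in groups.items():
            prof = analysis.spatial_profiles(group, bin_width=bin_width)
            for i in range(len(prof.bin_centers)):
                prof_rows.append({
                    "lane_length": L, "bin_center": prof.bin_centers[i],
                    "occupancy": prof.occupancy[i],
                    "mean_abs_velocity": prof.mean_abs_velocity[i],
                    "sem": prof.sem[i], "count": prof.counts[i],
                })
            cp = analysis.fit_changepoints(prof)
            cp_rows.append({"lane_length": L, "xi0_left": cp.xi0_left,
                            "xi0_right": cp.xi0_right, "plateau_speed": cp.plateau_speed,
                            "sse": cp.sse, "fully_ramped": cp.fully_ramped})
            sf = analysis.velocity_spectrum(group)
            spec_rows.append({"lane_length": L, "f_max_per_min": sf.f_max,
                              "period_h": sf.period_T, "lognorm_shape": sf.lognorm_shape,
                              "lognorm_scale": sf.lognorm_scale, "fit_ok": sf.fit_ok})
            if sf.fit_ok:
                periods[L] = sf.period_T
            region = geometry.reversal_region(L, xi0)
            for tr in group:
                for ev in analysis.detect_reversals(tr, region):
                    rev_rows.append({"lane_length": L, "cell_id": ev.cell_id,
                                     "tip": ev.tip, "t1": ev.t1, "t2": ev.t2,
                                     "t_R": ev.t_R, "reversed": ev.reversed})

        stage = "speed_distribution"
        edges, density = analysis.speed_distribution(trajs)
        sp_df = pd.DataFrame({"speed_bin_center": (edges[:-1] + edges[1:]) / 2,
                              "density": density})

        stage = "period_vs_length"
        if len(periods) >= 3:
            fit = analysis.period_vs_length(periods)
            report["period_fit"] = {
                "slope_h_per_um": fit.slope, "slope_err": fit.slope_err,
                "x_intercept_um": fit.x_intercept, "v_c_um_per_min": fit.v_c,
                "r_value": fit.r_value,
            }
        else:
            notices.append(f"period-vs-length skipped: only {len(periods)} lane "
                           "length(s) with a reliable spectral fit (need >= 3)")
            logger.info(notices[-1])

        stage = "reversals"
        rev_df = pd.DataFrame(rev_rows)
        if len(rev_df):
            tR = rev_df["t_R"].to_numpy()
            report["reversal"] = {"n_events": int(len(tR)), "mean_min": float(tR.mean()),
                                  "median_min": float(np.median(tR)),
                                  "mode_min": analysis.histogram_mode(tR)}

        stage = "write"
        def _dump(df: pd.DataFrame, name: str) -> None:
            with open(out / name, "w") as fh:
                fh.write(f"# microlane {_version()} config={chash}\n")
                df.to_csv(fh, index=False, float_format="%.6g")

        _dump(pd.DataFrame(prof_rows), "profiles.csv")
        _dump(pd.DataFrame(cp_rows), "changepoints.csv")
        _dump(pd.DataFrame(spec_rows), "spectra.csv")
        _dump(sp_df, "speed_histogram.csv")
        _dump(rev_df, "reversals.csv")
        report["xi0_mean_um"] = float(np.mean([(r["xi0_left"] + r["xi0_right"]) / 2
                                               for r in cp_rows]))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

        if config.get("make_plots"):
            _plot_profiles(pd.DataFrame(prof_rows), out / "profiles.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    logger.info("pipeline done: %s", out)
    return report


def _plot_profiles(prof: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lanes = sorted(prof["lane_length"].unique())
    fig, axes = plt.subplots(len(lanes), 1, figsize=(6, 2.2 * len(lanes)), squeeze=False)
    for ax, L in zip(axes[:, 0], lanes):
        g = prof[prof["lane_length"] == L]
        ax.errorbar(g["bin_center"], g["mean_abs_velocity"], yerr=g["sem"], fmt="o-", ms=3)
        ax.set_title(f"L = {L:g} um")
        ax.set_ylabel("<|v|> (um/min)")
    axes[-1, 0].set_xlabel("position along lane (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def simulation_metadata(record, path: str | Path) -> None:
    """Write run metadata (parameters, seed, sampling) as a JSON sidecar."""
    meta = {"version": _version(), "seed": record.seed,
            "sampling_min": record.sampling,
            "params": dataclasses.asdict(record.params)}
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
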