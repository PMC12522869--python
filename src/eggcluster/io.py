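"""Table readers/writers with schema validation, config loading, pipeline glue.

All tables are UTF-8 delimited text (comma or tab, auto-detected, override
with ``sep=``). Proportions are written with 6 significant digits, counts as
integers. Every writer produces files its reader parses back to equal
values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, SchemaError
from .metrics import EggRecord, ViabilityRecord, VialObservation

logger = logging.getLogger(__name__)

VIAL_COLUMNS = ("vial_id", "group_size", "timepoint_h", "cluster_size", "count")
EGG_COLUMNS = ("egg_id", "vial_id", "x", "y", "maternity", "status", "cluster_id")
VIABILITY_COLUMNS = ("vial_id", "n_eggs", "n_adults_eclosed", "prop_clustered_final")


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, engine="python", encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # delimiter/parse problems
        raise SchemaError(f"{path}: cannot parse delimited table: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: unknown columns {extra} preserved but ignored")


def read_vial_table(path: str | Path, sep: str | None = None) -> list[VialObservation]:
    """Read a tidy vial table: one row per (vial, timepoint, cluster_size).

    Rows with ``cluster_size == 0`` (and count 0) are sentinel records for
    observed-but-empty vials. An optional ``n_eggs`` column is cross-checked
    against the sum of sizes when present.
    """
    df = _read_table(path, sep)
    has_n_eggs = "n_eggs" in df.columns
    required = list(VIAL_COLUMNS) + (["n_eggs"] if has_n_eggs else [])
    _require_columns(df, required, path)

    for col in ("group_size", "cluster_size", "count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals % 1 != 0)]
        if len(bad):
            raise SchemaError(
                f"{path}: non-integer {col} at rows {[int(i) + 2 for i in bad[:5]]}"
            )
        df[col] = vals.astype(int)
    if (df["cluster_size"] < 0).any() or (df["count"] < 0).any():
        raise SchemaError(f"{path}: negative cluster_size or count")

    observations = []
    for (vial_id, group, t), sub in df.groupby(
        ["vial_id", "group_size", "timepoint_h"], sort=True
    ):
        sizes: list[int] = []
        for _, row in sub.iterrows():
            if row["cluster_size"] == 0:
                continue
            sizes.extend([int(row["cluster_size"])] * int(row["count"]))
        n_eggs = sum(sizes)
        if has_n_eggs:
            declared = int(sub["n_eggs"].iloc[0])
            if declared != n_eggs:
                raise SchemaError(
                    f"{path}: vial {vial_id} t={t}: declared n_eggs {declared} != "
                    f"sum of sizes {n_eggs} (rows {[int(i) + 2 for i in sub.index[:5]]})"
                )
        observations.append(
            VialObservation(
                vial_id=str(vial_id),
                group_size=int(group),
                timepoint_h=float(t),
                cluster_sizes=tuple(sorted(sizes)),
                n_eggs=n_eggs,
            )
        )
    return observations


def write_vial_table(observations: Sequence[VialObservation], path: str | Path) -> None:
    rows = []
    for o in sorted(observations, key=lambda o: (o.vial_id, o.timepoint_h)):
        if not o.cluster_sizes:
            rows.append((o.vial_id, o.group_size, o.timepoint_h, 0, 0))
            continue
        sizes, counts = np.unique(np.array(o.cluster_sizes), return_counts=True)
        rows.extend(
            (o.vial_id, o.group_size, o.timepoint_h, int(s), int(c))
            for s, c in zip(sizes, counts)
        )
    pd.DataFrame(rows, columns=list(VIAL_COLUMNS)).to_csv(path, index=False)


def read_egg_table(path: str | Path, sep: str | None = None) -> list[EggRecord]:
    df = _read_table(path, sep)
    _require_columns(df, EGG_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        x, y = pd.to_numeric(row["x"], errors="coerce"), pd.to_numeric(row["y"], errors="coerce")
        if pd.isna(x) or pd.isna(y):
            raise SchemaError(f"{path}: non-numeric coordinate at row {int(i) + 2}")
        cid = row["cluster_id"]
        cluster_id = None if (pd.isna(cid) or str(cid) == "") else str(cid)
        try:
            records.append(
                EggRecord(
                    egg_id=str(row["egg_id"]),
                    vial_id=str(row["vial_id"]),
                    x=float(x),
                    y=float(y),
                    maternity=str(row["maternity"]),
                    status=str(row["status"]),
                    cluster_id=cluster_id,
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {int(i) + 2}: {exc}") from exc
    return records


def write_egg_table(eggs: Sequence[EggRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "egg_id": e.egg_id,
                "vial_id": e.vial_id,
                "x": float(f"{e.x:.6g}"),
                "y": float(f"{e.y:.6g}"),
                "maternity": e.maternity,
                "status": e.status,
                "cluster_id": "" if e.cluster_id is None else e.cluster_id,
            }
            for e in sorted(eggs, key=lambda e: (e.vial_id, e.egg_id))
        ]
    )
    df.to_csv(path, index=False)


def read_viability_table(path: str | Path, sep: str | None = None) -> list[ViabilityRecord]:
    df = _read_table(path, sep)
    _require_columns(df, VIABILITY_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ViabilityRecord(
                    vial_id=str(row["vial_id"]),
                    n_eggs=int(row["n_eggs"]),
                    n_adults_eclosed=int(row["n_adults_eclosed"]),
                    prop_clustered_final=float(row["prop_clustered_final"]),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path}: row {int(i) + 2}: {exc}") from exc
    return records


def write_viability_table(records: Sequence[ViabilityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "vial_id": r.vial_id,
                "n_eggs": r.n_eggs,
                "n_adults_eclosed": r.n_adults_eclosed,
                "prop_clustered_final": float(f"{r.prop_clustered_final:.6g}"),
            }
            for r in sorted(records, key=lambda r: r.vial_id)
        ]
    ).to_csv(path, index=False)


def read_xy_points(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column x-y point export (comma or tab; header optional).

    The format matches multi-point exports from image-annotation tools: two
    numeric columns per egg. Returns an ordered list of (x, y) pairs.
    """
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text:
        warnings.warn(f"{path}: empty coordinate file")
        return []
    lines = text.splitlines()
    sep = "\t" if "\t" in lines[0] else ","
    start = 0
    first = [c.strip() for c in lines[0].split(sep)]
    if any(_not_numeric(c) for c in first[:2]):
        start = 1  # header row
    points = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(sep)]
        if len(cells) < 2 or _not_numeric(cells[0]) or _not_numeric(cells[1]):
            raise SchemaError(f"{path}: line {lineno}: expected two numeric columns")
        points.append((float(cells[0]), float(cells[1])))
    if not points:
        warnings.warn(f"{path}: coordinate file has a header but no points")
    return points


def _not_numeric(cell: str) -> bool:
    try:
        float(cell)
        return False
    except ValueError:
        return True


def load_config(path: str | Path):
    """Load a YAML or JSON config into a SyntheticConfig (by extension)."""
    from .synth import SyntheticConfig

    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    # YAML/JSON mapping keys for per-group dicts arrive as strings
    for key in (
        "true_k", "mean_eggs_per_female", "sd_eggs_per_female", "laying_prob",
        "trials_per_existing", "join_prob", "nonjoin_distance_mean_mm",
    ):
        if key in data and isinstance(data[key], dict):
            data[key] = {int(k): v for k, v in data[key].items()}
    for key in ("treatments", "timepoints_h", "existing_sizes", "night_window_h"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SyntheticConfig(**data)


def run_pipeline(
    config=None,
    *,
    seed: int | None = None,
    outdir: str | Path = "results",
    k_grid: Sequence[float] | None = None,
    n_scan_reps: int = 10,
) -> dict:
    """Run the full synthetic-data pipeline and write its output bundle.

    Generates the three experiments, scans K per vial at the final
    timepoint, runs the nonrandomness test per grouped treatment, computes
    the metric tables, and writes everything plus a machine-readable run
    log. Deterministic given ``seed``. Returns the bundle as a dict of
    DataFrames / results.
    """
    from . import __version__
    from .k_inference import (
        DEFAULT_K_GRID,
        nonrandomness_test,
        paired_null_statistics,
        scan_vials,
    )
    from .metrics import join_metrics, maternity_mix, viability_metrics, vial_summary
    from .simulator import ClusterSizeDistribution
    from .synth import (
        SyntheticConfig,
        generate_existing_cluster_trials,
        generate_maternity_experiment,
        generate_social_density_experiment,
    )

    config = config or SyntheticConfig()
    grid = tuple(k_grid) if k_grid is not None else DEFAULT_K_GRID
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[stage {name}] {exc}") from exc

    observations, viability, truth_social = stage(
        "synth-social", generate_social_density_experiment, config, seeds[0]
    )
    eggs_existing, truth_existing = stage(
        "synth-existing", generate_existing_cluster_trials, config, seeds[1]
    )
    eggs_maternity, truth_maternity = stage(
        "synth-maternity", generate_maternity_experiment, config, seeds[2]
    )

    write_vial_table(observations, outdir / "vials.csv")
    write_egg_table(eggs_existing + eggs_maternity, outdir / "eggs.csv")
    write_viability_table(viability, outdir / "viability.csv")

    # K scan on each vial's final-timepoint distribution
    final_t = max(config.timepoints_h)
    final = [o for o in observations if o.timepoint_h == final_t]
    pairs = [
        (o.vial_id, ClusterSizeDistribution(o.cluster_sizes, o.n_eggs)) for o in final
    ]
    curves = stage(
        "fit-k",
        scan_vials,
        pairs,
        k_grid=grid,
        n_reps=n_scan_reps,
        n_positions=config.n_positions,
        seed=seeds[3],
    )
    curve_rows = [
        {"vial_id": c.vial_id, "k": k, "p_value": float(f"{p:.6g}")}
        for c in curves
        for k, p in zip(c.k_grid, c.p_values)
    ]
    best_rows = [
        {"vial_id": c.vial_id, "best_k": c.best_k, "n_eggs": c.n_eggs_observed}
        for c in curves
    ]
    pd.DataFrame(curve_rows).to_csv(outdir / "k_curves.csv", index=False)
    pd.DataFrame(best_rows).to_csv(outdir / "best_k.csv", index=False)

    # nonrandomness test per grouped treatment
    wilcoxon_rows = []
    group_of = {o.vial_id: o.group_size for o in final}
    null_ss = np.random.SeedSequence(seeds[4])
    group_children = null_ss.spawn(len(config.treatments))
    for group, child in zip(config.treatments, group_children):
        csds = [
            ClusterSizeDistribution(o.cluster_sizes, o.n_eggs)
            for o in final
            if group_of[o.vial_id] == group and o.n_eggs > 0
        ]
        if len(csds) < 3:
            logger.warning("group %d: too few laying vials for the test", group)
            continue
        obs_stats, null_stats = paired_null_statistics(
            csds,
            n_positions=config.n_positions,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        try:
            res = nonrandomness_test(obs_stats, null_stats)
        except Exception as exc:
            logger.warning("group %d: nonrandomness test degenerate (%s)", group, exc)
            continue
        wilcoxon_rows.append(
            {
                "group_size": group,
                "z": float(f"{res.z:.6g}"),
                "p_value": float(f"{res.p_value:.6g}"),
                "effect_r": float(f"{res.effect_r:.6g}"),
                "n_vials": res.n_vials,
            }
        )
    wilcoxon_df = pd.DataFrame(wilcoxon_rows)
    wilcoxon_df.to_csv(outdir / "nonrandomness.csv", index=False)

    # metric tables
    by_vial: dict[str, list[VialObservation]] = {}
    for o in observations:
        by_vial.setdefault(o.vial_id, []).append(o)
    summaries = []
    for vial_obs in by_vial.values():
        s = vial_summary(vial_obs)
        t = s.table.copy()
        t["latency_h"] = s.latency_h if s.latency_h is not None else np.nan
        summaries.append(t)
    summary_df = pd.concat(summaries, ignore_index=True).sort_values(
        ["vial_id", "timepoint_h"], ignore_index=True
    )
    summary_df.to_csv(outdir / "summary.csv", index=False)

    join_rows = []
    by_trial: dict[str, list[EggRecord]] = {}
    for e in eggs_existing:
        by_trial.setdefault(e.vial_id, []).append(e)
    for vial_id, trial in sorted(by_trial.items()):
        jm = join_metrics(trial)
        join_rows.append(
            {
                "vial_id": vial_id,
                "existing_size": truth_existing["trials"][vial_id]["existing_size"],
                "any_joined": jm.any_joined,
                "prop_joined": float(f"{jm.prop_joined:.6g}"),
                "mean_distance": float(f"{jm.mean_distance:.6g}"),
                "n_new": jm.n_new,
            }
        )
    joins_df = pd.DataFrame(join_rows)
    joins_df.to_csv(outdir / "joins.csv", index=False)

    mat_rows = []
    by_mat_vial: dict[str, list[EggRecord]] = {}
    for e in eggs_maternity:
        by_mat_vial.setdefault(e.vial_id, []).append(e)
    for vial_id, vial_eggs in sorted(by_mat_vial.items()):
        try:
            mat_rows.append(
                {"vial_id": vial_id, "maternity_mix": float(f"{maternity_mix(vial_eggs):.6g}")}
            )
        except Exception as exc:
            logger.warning("vial %s: maternity mix undefined (%s)", vial_id, exc)
    maternity_df = pd.DataFrame(mat_rows)
    maternity_df.to_csv(outdir / "maternity.csv", index=False)

    viability_df = viability_metrics(viability)
    viability_df.to_csv(outdir / "viability_metrics.csv", index=False)

    run_log = {
        "package": "eggcluster",
        "version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "k_grid": list(grid),
        "n_scan_reps": n_scan_reps,
        "config": _config_to_jsonable(config),
        "numpy": np.__version__,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")

    return {
        "curves": curves,
        "best_k": pd.DataFrame(best_rows),
        "nonrandomness": wilcoxon_df,
        "summary": summary_df,
        "joins": joins_df,
        "maternity": maternity_df,
        "viability": viability_df,
        "truth": {
            "social": truth_social,
            "existing": truth_existing,
            "maternity": truth_maternity,
        },
    }


def _config_to_jsonable(config) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, dict):
            v = {str(k): val for k, val in v.items()}
        out[f.name] = v
    return out
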