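"""Table and configuration I/O.

Plain CSV throughout, with optional ``#``-prefixed metadata header lines
(version, seed, config hash) so files stay standard-CSV parseable.
Malformed rows are hard errors naming the offending line — silent dropping
of climate or assay rows would bias every downstream fit.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from seedlife.climate import ClimateSeries, DailyClimateRecord, ClimateError
from seedlife.germination import GerminationAssay, GerminationParams
from seedlife.phenology import BoltingModelConfig, ThermalModelParams
from seedlife.simulator import GenotypeConfig

__all__ = [
    "TableFormatError",
    "read_climate_table",
    "write_climate_table",
    "read_assay_table",
    "write_assay_table",
    "load_genotype_config",
    "genotype_from_mapping",
    "write_fitted_model",
    "metadata_header",
]


class TableFormatError(ValueError):
    """A malformed input table (bad value, bad ordering, bad header)."""


def metadata_header(seed: int | None = None, **extra: Any) -> list[str]:
    """Standard ``#`` metadata lines for output files."""
    from seedlife import __version__

    items = {"version": __version__}
    if seed is not None:
        items["seed"] = seed
    items.update(extra)
    return [f"# {k}={v}" for k, v in items.items()]


def _data_lines(path: str | Path):
    """Yield (line_number, raw_line) for non-comment, non-blank lines."""
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() and not line.lstrip().startswith("#"):
                yield lineno, line


def _parse_csv(path: str | Path, required: Sequence[str]):
    rows = list(_data_lines(path))
    if not rows:
        raise TableFormatError(f"{path}: empty input")
    header_line = rows[0][1]
    header = [h.strip() for h in next(csv.reader([header_line]))]
    missing = [c for c in required if c not in header]
    if missing:
        raise TableFormatError(f"{path}:{rows[0][0]}: missing column(s) {missing}")
    parsed = []
    for lineno, line in rows[1:]:
        vals = next(csv.reader([line]))
        if len(vals) != len(header):
            raise TableFormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(vals)}"
            )
        parsed.append((lineno, dict(zip(header, (v.strip() for v in vals)))))
    if not parsed:
        raise TableFormatError(f"{path}: no data rows")
    return parsed


def _float(row: Mapping[str, str], key: str, path, lineno) -> float:
    try:
        return float(row[key])
    except ValueError as exc:
        raise TableFormatError(f"{path}:{lineno}: bad {key} value {row[key]!r}") from exc


def read_climate_table(
    path: str | Path, latitude: float = 52.0, longitude: float = 0.0, label: str = ""
) -> ClimateSeries:
    """Read ``date,tmin,tmean,tmax[,sunrise,sunset]`` into a ClimateSeries.

    ISO-8601 dates; validates t_min <= t_mean <= t_max per row (error names
    the line) and strict date ordering/contiguity across rows.
    """
    parsed = _parse_csv(path, required=("date", "tmin", "tmean", "tmax"))
    recs = []
    for lineno, row in parsed:
        try:
            date = _dt.date.fromisoformat(row["date"])
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: bad date {row['date']!r}") from exc
        try:
            recs.append(
                DailyClimateRecord(
                    date=date,
                    t_min=_float(row, "tmin", path, lineno),
                    t_mean=_float(row, "tmean", path, lineno),
                    t_max=_float(row, "tmax", path, lineno),
                    sunrise=float(row["sunrise"]) if row.get("sunrise") else None,
                    sunset=float(row["sunset"]) if row.get("sunset") else None,
                )
            )
        except ClimateError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return ClimateSeries(recs, latitude=latitude, longitude=longitude, label=label)
    except ClimateError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_climate_table(
    series: ClimateSeries, path: str | Path, seed: int | None = None, **meta: Any
) -> None:
    with open(path, "w", newline="") as fh:
        for line in metadata_header(seed, label=series.label, **meta):
            fh.write(line + "\n")
        has_sun = any(r.sunrise is not None for r in series.records)
        cols = ["date", "tmin", "tmean", "tmax"] + (["sunrise", "sunset"] if has_sun else [])
        w = csv.writer(fh)
        w.writerow(cols)
        for r in series.records:
            row = [r.date.isoformat(), repr(float(r.t_min)), repr(float(r.t_mean)),
                   repr(float(r.t_max))]
            if has_sun:
                row += ["" if r.sunrise is None else repr(float(r.sunrise)),
                        "" if r.sunset is None else repr(float(r.sunset))]
            w.writerow(row)


def read_assay_table(path: str | Path) -> list[GerminationAssay]:
    """Read ``t_m,t_i,day,germinated,total,replicate`` rows into assays.

    Rows are grouped by (t_m, t_i, replicate) and sorted by day within each
    group; duplicate (t_m, t_i, day, replicate) rows are errors rather than
    silently aggregated.
    """
    parsed = _parse_csv(path, required=("t_m", "t_i", "day", "germinated", "total"))
    groups: dict[tuple, list] = {}
    seen: set[tuple] = set()
    for lineno, row in parsed:
        t_m = _float(row, "t_m", path, lineno)
        t_i = _float(row, "t_i", path, lineno)
        day = _float(row, "day", path, lineno)
        germ = _float(row, "germinated", path, lineno)
        total = _float(row, "total", path, lineno)
        rep = int(float(row.get("replicate") or 0))
        if day < 0:
            raise TableFormatError(f"{path}:{lineno}: negative day {day}")
        if germ > total:
            raise TableFormatError(
                f"{path}:{lineno}: germinated {germ} exceeds total {total}"
            )
        key4 = (t_m, t_i, day, rep)
        if key4 in seen:
            raise TableFormatError(
                f"{path}:{lineno}: duplicate row for t_m={t_m}, t_i={t_i}, "
                f"day={day}, replicate={rep}"
            )
        seen.add(key4)
        groups.setdefault((t_m, t_i, rep), []).append((day, germ, total))
    assays = []
    for (t_m, t_i, rep), pts in sorted(groups.items()):
        pts.sort()
        days, germ, tot = (np.array(v, dtype=float) for v in zip(*pts))
        assays.append(
            GerminationAssay(
                t_m=t_m, t_i=t_i, times=days, germinated=germ, total=tot, replicate=rep
            )
        )
    return assays


def write_assay_table(
    assays: Sequence[GerminationAssay], path: str | Path, seed: int | None = None,
    **meta: Any,
) -> None:
    with open(path, "w", newline="") as fh:
        for line in metadata_header(seed, **meta):
            fh.write(line + "\n")
        w = csv.writer(fh)
        w.writerow(["t_m", "t_i", "day", "germinated", "total", "replicate"])
        for a in assays:
            for d, g, t in zip(a.times, a.germinated, a.total):
                w.writerow([repr(float(a.t_m)), repr(float(a.t_i)), repr(float(d)),
                            repr(float(g)), repr(float(t)), a.replicate])


# ---------------------------------------------------------------------------
# genotype configuration


def genotype_from_mapping(cfg: Mapping[str, Any]) -> GenotypeConfig:
    """Build a GenotypeConfig from nested config keys.

    Expected layout::

        label: Col-0
        bolting: {model: fixed|generic, duration_days, t_b, threshold,
                  mode, cold_threshold, vernalization_table}
        seedset: {t_b, threshold, mode}
        germination: {a, b, c, d}
    """
    b = cfg.get("bolting", {})
    model = b.get("model", "fixed")
    if model == "generic":
        vt = b.get("vernalization_table")
        bolting = BoltingModelConfig(
            model="generic",
            params=ThermalModelParams(
                t_b=float(b["t_b"]), threshold=float(b["threshold"]),
                mode=b.get("mode", "photothermal"),
            ),
            cold_threshold=float(b.get("cold_threshold", 4.0)),
            vernalization_table=tuple(map(tuple, vt)) if vt else None,
        )
    else:
        bolting = BoltingModelConfig(model="fixed",
                                     duration_days=int(b.get("duration_days", 30)))
    s = cfg.get("seedset", {})
    seed_set = ThermalModelParams(
        t_b=float(s.get("t_b", 5.25)),
        threshold=float(s.get("threshold", 5370.0)),
        mode=s.get("mode", "thermal"),
    )
    g = cfg.get("germination", {})
    germination = GerminationParams(
        a=float(g.get("a", 1.56)), b=float(g.get("b", -21.79)),
        c=float(g.get("c", 0.05)), d=float(g.get("d", 0.18)),
    )
    return GenotypeConfig(
        bolting=bolting, seed_set=seed_set, germination=germination,
        label=str(cfg.get("label", "Col-0")),
    )


def load_genotype_config(path: str | Path) -> GenotypeConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise TableFormatError(f"{path}: genotype config must be a mapping")
    return genotype_from_mapping(cfg)


def write_fitted_model(fit: Any, path: str | Path, seed: int | None = None) -> None:
    """Write a germination fit as JSON: {a, b, c, d, r_squared, n_points, fit_meta}."""
    p: GerminationParams = fit.params
    payload = {
        "a": p.a, "b": p.b, "c": p.c, "d": p.d,
        "r_squared": fit.r_squared, "n_points": fit.n_points,
        "fit_meta": {"sse": fit.sse, "converged": fit.converged,
                     "seed": seed},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable config (for audit headers)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
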