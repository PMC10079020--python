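"""Readers and writers for the pipeline's file formats.

Supported formats:

* TPS landmark files (the tpsDig dialect: ``LM=``, optional ``CURVES=`` /
  ``POINTS=`` blocks, ``IMAGE=`` (ignored), ``ID=``, ``SCALE=``).
* Suture traces as CSV (``specimen_id,suture,order,x,y``) or a minimal SVG
  path subset (absolute ``M``/``L``/``H``/``V`` commands only — curved
  commands must be polyline-sampled upstream so that no hidden arc-length
  approximation enters the length-ratio statistic).
* Specimen tables as CSV with optional incisor columns.

The TPS y-axis is taken as stored (no image-origin flip); Procrustes
superimposition is rotation-invariant, so the convention is documentation,
not substance.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    Group,
    IncisorMeasurement,
    LandmarkConfiguration,
    Sex,
    SpecimenRecord,
    SutureName,
    SutureTrace,
    ValidationError,
)

PathLike = Union[str, Path]


class TpsParseError(ValueError):
    """Malformed TPS file; message names the offending line."""


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path: PathLike) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file into a list of configurations.

    One configuration per ``LM=`` block.  Curve points from ``CURVES=`` /
    ``POINTS=`` blocks are appended after the fixed landmarks in file order
    and flagged as semilandmarks; coordinates are multiplied by ``SCALE=``
    when present.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n = 0, len(lines)

    def parse_error(lineno: int, msg: str) -> TpsParseError:
        return TpsParseError(f"{path}:{lineno + 1}: {msg}")

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if not m or m.group(1).upper() != "LM":
            raise parse_error(i, f"expected LM= header, got {line!r}")
        try:
            n_fixed = int(m.group(2))
        except ValueError:
            raise parse_error(i, f"bad LM count {m.group(2)!r}") from None
        if n_fixed <= 0:
            raise parse_error(i, "LM=0 blocks are not supported")
        i += 1
        fixed, i = _read_coords(lines, i, n_fixed, parse_error)

        curve_points: list[np.ndarray] = []
        specimen_id: Optional[str] = None
        scale: Optional[float] = None
        while i < n:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            m = _TPS_KEY.match(line)
            if not m:
                raise parse_error(i, f"unexpected content {line!r}")
            key, value = m.group(1).upper(), m.group(2)
            if key == "LM":
                break
            i += 1
            if key == "CURVES":
                n_curves = int(value)
                for _ in range(n_curves):
                    while i < n and not lines[i].strip():
                        i += 1
                    mp = _TPS_KEY.match(lines[i].strip()) if i < n else None
                    if not mp or mp.group(1).upper() != "POINTS":
                        raise parse_error(i if i < n else n - 1, "expected POINTS= after CURVES=")
                    n_pts = int(mp.group(2))
                    i += 1
                    pts, i = _read_coords(lines, i, n_pts, parse_error)
                    curve_points.append(pts)
            elif key == "ID":
                specimen_id = value
            elif key == "SCALE":
                scale = float(value)
            elif key == "IMAGE":
                pass  # provenance only
            else:
                raise parse_error(i - 1, f"unsupported TPS key {key!r}")

        points = np.vstack([fixed] + curve_points) if curve_points else fixed
        if scale is not None:
            points = points * scale
        roles = ["fixed"] * n_fixed + ["semi"] * (points.shape[0] - n_fixed)
        curves, offset = [], n_fixed
        for pts in curve_points:
            curves.append(list(range(offset, offset + len(pts))))
            offset += len(pts)
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id or f"config_{len(configs)}",
                points=points,
                roles=roles,
                curves=curves,
                scale=scale,
            )
        )
    return configs


def _read_coords(lines, i, count, parse_error):
    pts = []
    start = i
    while len(pts) < count:
        if i >= len(lines):
            raise parse_error(start, f"expected {count} coordinate lines, file ended after {len(pts)}")
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if _TPS_KEY.match(line) and not _is_number_pair(line):
            raise parse_error(i, f"expected {count} coordinate lines, found only {len(pts)}")
        parts = line.split()
        if len(parts) != 2:
            raise parse_error(i, f"expected 'x y' coordinate line, got {line!r}")
        try:
            pts.append([float(parts[0]), float(parts[1])])
        except ValueError:
            raise parse_error(i, f"non-numeric coordinates {line!r}") from None
        i += 1
    return np.asarray(pts, dtype=float), i


def _is_number_pair(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(configs: Iterable[LandmarkConfiguration], path: PathLike) -> None:
    """Write configurations in the dialect ``read_tps`` accepts (round-trip safe).

    Coordinates are written post-scale, so ``SCALE=`` is not re-emitted.
    """
    out = []
    for cfg in configs:
        n_fixed = cfg.n_fixed
        out.append(f"LM={n_fixed}")
        for x, y in cfg.points[:n_fixed]:
            out.append(f"{x:.6f} {y:.6f}")
        if cfg.curves:
            out.append(f"CURVES={len(cfg.curves)}")
            for curve in cfg.curves:
                out.append(f"POINTS={len(curve)}")
                for idx in curve:
                    x, y = cfg.points[idx]
                    out.append(f"{x:.6f} {y:.6f}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Suture traces
# ---------------------------------------------------------------------------

def read_suture_traces(path: PathLike, format: str = "csv") -> list[SutureTrace]:
    """Read suture polylines from CSV or the minimal SVG-path subset."""
    if format == "csv":
        return _read_sutures_csv(path)
    if format == "svg_subset":
        return _read_sutures_svg(path)
    raise ValueError(f"unknown suture trace format {format!r}")


def _read_sutures_csv(path: PathLike) -> list[SutureTrace]:
    df = pd.read_csv(path)
    required = {"specimen_id", "suture", "order", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing suture CSV columns {sorted(missing)}")
    traces = []
    for (sid, sname), grp in df.groupby(["specimen_id", "suture"], sort=False):
        suture = SutureName.parse(sname)
        grp = grp.sort_values("order")
        verts = grp[["x", "y"]].to_numpy(dtype=float)
        side = None
        if "side" in grp.columns and grp["side"].notna().any():
            side = str(grp["side"].dropna().iloc[0])
        traces.append(SutureTrace(str(sid), suture, verts, side=side))
    return traces


_SVG_PATH = re.compile(r'<path[^>]*\bd\s*=\s*"([^"]*)"[^>]*>', re.IGNORECASE)
_SVG_ID = re.compile(r'\bid\s*=\s*"([^"]*)"')
_SVG_TOKEN = re.compile(r"[A-DF-Za-df-z]|[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _read_sutures_svg(path: PathLike) -> list[SutureTrace]:
    """Parse paths whose ``id`` is ``<specimen_id>__<suture>``.

    Only absolute ``M``, ``L``, ``H``, ``V`` commands are supported; any other
    command (``C``, ``Q``, ``A``, relative forms, ...) raises, never silently
    approximates.
    """
    text = Path(path).read_text()
    traces = []
    for m in _SVG_PATH.finditer(text):
        tag, d = m.group(0), m.group(1)
        mid = _SVG_ID.search(tag)
        if not mid or "__" not in mid.group(1):
            raise ValidationError(
                f'{path}: every <path> needs id="<specimen_id>__<suture>"'
            )
        sid, sname = mid.group(1).split("__", 1)
        verts = _parse_svg_path(d, path)
        traces.append(SutureTrace(sid, SutureName.parse(sname), np.asarray(verts)))
    return traces


def _parse_svg_path(d: str, path: PathLike) -> list[list[float]]:
    tokens = _SVG_TOKEN.findall(d)
    verts: list[list[float]] = []
    i = 0
    cmd = None
    while i < len(tokens):
        tok = tokens[i]
        if tok.isalpha():
            if tok not in ("M", "L", "H", "V"):
                raise ValidationError(
                    f"{path}: unsupported path command {tok!r} "
                    "(only absolute M/L/H/V are supported; sample curves to polylines upstream)"
                )
            cmd = tok
            i += 1
            continue
        if cmd in ("M", "L"):
            verts.append([float(tokens[i]), float(tokens[i + 1])])
            i += 2
            if cmd == "M":
                cmd = "L"  # SVG: subsequent pairs after M are implicit lineto
        elif cmd == "H":
            verts.append([float(tokens[i]), verts[-1][1]])
            i += 1
        elif cmd == "V":
            verts.append([verts[-1][0], float(tokens[i])])
            i += 1
        else:
            raise ValidationError(f"{path}: coordinates before any path command")
    return verts


# ---------------------------------------------------------------------------
# Specimen tables
# ---------------------------------------------------------------------------

def read_specimen_table(path: PathLike) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Read the specimen CSV; returns records plus the parsed frame.

    Required columns: ``specimen_id``, ``group``, ``sex``.  Optional:
    ``body_mass_g``, ``admixture_q``, ``incisor_ap_mm``, ``incisor_ml_mm``.
    Missing optional fields stay missing (never imputed).
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "group", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    ids = df["specimen_id"].astype(str)
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{path}: duplicate specimen_id values {list(dupes)}")

    records = []
    for _, row in df.iterrows():
        mass = row.get("body_mass_g")
        q = row.get("admixture_q")
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                group=Group.parse(row["group"]),
                sex=Sex.parse(row["sex"]) if pd.notna(row["sex"]) else Sex.UNKNOWN,
                body_mass=float(mass) if pd.notna(mass) else None,
                admixture_q=float(q) if pd.notna(q) else None,
            )
        )
    df = df.copy()
    df["specimen_id"] = ids
    df["group"] = [r.group.value for r in records]
    df["sex"] = [r.sex.value for r in records]
    return records, df


def incisor_measurements(df: pd.DataFrame) -> list[IncisorMeasurement]:
    """Extract incisor measurements from a specimen frame with incisor columns."""
    out = []
    for _, row in df.iterrows():
        ap, ml = row.get("incisor_ap_mm"), row.get("incisor_ml_mm")
        if pd.notna(ap) and pd.notna(ml):
            out.append(IncisorMeasurement(str(row["specimen_id"]), float(ap), float(ml)))
    return out
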