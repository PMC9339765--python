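"""Reading and writing detection datasets: CSV dialect and MARK .inp files.

CSV layout
----------
``detections.csv`` has one row per hibernaculum with fixed leading columns
``hibernaculum_id, plot_id, species, occupancy, lost`` followed by one 0/1
column per surveyor. A surveyor who did not search an individual's plot is an
*empty* cell for that row (a non-search is structurally different from a
failed detection). The within-plot occasion order is the column order
restricted to surveyors with non-empty cells.

``surveyors.csv`` maps ``surveyor_id -> experience`` (expert/novice).

``plots.csv`` (optional) carries ``plot_id, area, host_plants, occasions``
where ``occasions`` is a ``;``-joined surveyor list; it makes round-trips
lossless when per-plot search orders are not a subsequence of one global
column order, and supplies plot areas for density summaries.

MARK .inp
---------
One encounter-history line per individual, ``<history> <freq...>;`` with the
plot encoded as group frequency columns. Group columns require a shared
history length, so when plots have unequal occasion counts one file per plot
is written instead (suffix ``_<plot>``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    DatasetError,
    DetectionDataset,
    IndividualRecord,
    PlotInfo,
    SurveyorInfo,
)

META_COLUMNS = ["hibernaculum_id", "plot_id", "species", "occupancy", "lost"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def read_detections(
    path: str | Path,
    surveyors_path: str | Path | None = None,
    plots_path: str | Path | None = None,
    format: str = "csv",
    column_map: dict[str, str] | None = None,
) -> DetectionDataset:
    """Read a detection dataset.

    Parameters
    ----------
    path
        Detections CSV (or .inp file when ``format="inp"``).
    surveyors_path
        Surveyor metadata CSV; defaults to ``<stem>_surveyors.csv`` next to
        ``path`` if present, else all surveyors are labelled novice.
    plots_path
        Optional plot metadata CSV (areas, host plants, occasion order).
    column_map
        Optional renaming applied to the detections header before parsing,
        to adapt foreign column naming to the fixed dialect.
    """
    path = Path(path)
    if format == "inp":
        return _read_inp(path)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    surveyor_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not surveyor_cols:
        raise ParseError(f"{path}: no surveyor detection columns")

    surveyors = _read_surveyors(path, surveyors_path, surveyor_cols)
    plot_meta, plot_orders = _read_plots(plots_path)

    individuals: dict[str, list[IndividualRecord]] = {}
    detections: dict[str, list[list[int]]] = {}
    occasions: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        plot_id = row["plot_id"]
        hib = row["hibernaculum_id"]
        if (plot_id, hib) in seen:
            raise ParseError(f"{path}: row {idx + 2}: duplicate hibernaculum_id {hib!r} in plot {plot_id!r}")
        seen.add((plot_id, hib))
        present = [c for c in surveyor_cols if row[c] != ""]
        if plot_id not in occasions:
            order = plot_orders.get(plot_id, present)
            if set(order) != set(present):
                raise ParseError(
                    f"{path}: row {idx + 2}: surveyors {sorted(present)} disagree "
                    f"with plots metadata order {order} for plot {plot_id!r}"
                )
            occasions[plot_id] = order
            individuals[plot_id] = []
            detections[plot_id] = []
        elif set(present) != set(occasions[plot_id]):
            raise ParseError(
                f"{path}: row {idx + 2}: inconsistent surveyor set for plot {plot_id!r}"
            )
        vals = []
        for c in occasions[plot_id]:
            v = row[c]
            if v not in ("0", "1"):
                raise ParseError(
                    f"{path}: row {idx + 2}, column {c!r}: detection value must be 0 or 1, got {v!r}"
                )
            vals.append(int(v))
        lost_raw = row["lost"].strip().lower()
        if lost_raw not in ("true", "false", "0", "1", ""):
            raise ParseError(f"{path}: row {idx + 2}: bad lost flag {row['lost']!r}")
        individuals[plot_id].append(
            IndividualRecord(
                hibernaculum_id=hib,
                plot_id=plot_id,
                species=row["species"] or "unknown",
                occupancy=row["occupancy"] or "unknown",
                lost=lost_raw in ("true", "1"),
            )
        )
        detections[plot_id].append(vals)

    surveyors = {
        sid: SurveyorInfo(
            sid,
            info.experience,
            frozenset(p for p, order in occasions.items() if sid in order),
        )
        for sid, info in surveyors.items()
        if any(sid in order for order in occasions.values())
    }
    plots = {
        p: plot_meta.get(p, PlotInfo(p, area=1.0))
        for p in occasions
    }
    return DetectionDataset(
        surveyors=surveyors,
        plots=plots,
        individuals=individuals,
        occasions=occasions,
        matrices={p: np.array(v, dtype=np.int8).reshape(len(v), -1) for p, v in detections.items()},
    )


def _read_surveyors(
    det_path: Path, surveyors_path: str | Path | None, surveyor_cols: list[str]
) -> dict[str, SurveyorInfo]:
    if surveyors_path is None:
        for candidate in (
            det_path.with_name(det_path.stem + "_surveyors.csv"),
            det_path.with_name("surveyors.csv"),
        ):
            if candidate.exists():
                surveyors_path = candidate
                break
    if surveyors_path is None:
        return {c: SurveyorInfo(c, "novice") for c in surveyor_cols}
    sdf = pd.read_csv(surveyors_path, dtype=str)
    if "surveyor_id" not in sdf.columns or "experience" not in sdf.columns:
        raise ParseError(f"{surveyors_path}: needs columns surveyor_id, experience")
    out: dict[str, SurveyorInfo] = {}
    for idx, row in sdf.iterrows():
        sid = row["surveyor_id"]
        if sid in out:
            raise ParseError(f"{surveyors_path}: row {idx + 2}: duplicate surveyor_id {sid!r}")
        out[sid] = SurveyorInfo(sid, row["experience"])
    unknown = [c for c in surveyor_cols if c not in out]
    if unknown:
        raise ParseError(
            f"detection columns {unknown} reference surveyors absent from {surveyors_path}"
        )
    return out


def _read_plots(
    plots_path: str | Path | None,
) -> tuple[dict[str, PlotInfo], dict[str, list[str]]]:
    if plots_path is None:
        return {}, {}
    pdf = pd.read_csv(plots_path, dtype=str, keep_default_na=False)
    meta: dict[str, PlotInfo] = {}
    orders: dict[str, list[str]] = {}
    for _, row in pdf.iterrows():
        pid = row["plot_id"]
        hp = row.get("host_plants", "")
        meta[pid] = PlotInfo(
            pid,
            area=float(row["area"]) if row.get("area", "") else 1.0,
            host_plants=int(hp) if hp else None,
        )
        if row.get("occasions", ""):
            orders[pid] = row["occasions"].split(";")
    return meta, orders


def write_detections(
    ds: DetectionDataset,
    path: str | Path,
    surveyors_path: str | Path | None = None,
    plots_path: str | Path | None = None,
) -> None:
    """Write the CSV triple (detections, surveyors, plots metadata)."""
    path = Path(path)
    surveyor_cols = _global_column_order(ds)
    rows = []
    for plot_id in ds.plot_ids:
        order = ds.occasions[plot_id]
        m = ds.matrices[plot_id]
        for i, rec in enumerate(ds.individuals[plot_id]):
            row: dict[str, object] = {
                "hibernaculum_id": rec.hibernaculum_id,
                "plot_id": plot_id,
                "species": rec.species,
                "occupancy": rec.occupancy,
                "lost": str(rec.lost).lower(),
            }
            for t, sid in enumerate(order):
                row[sid] = int(m[i, t])
            rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + surveyor_cols)
    # keep non-searches as empty cells, not float-upcast "0.0"/"nan"
    for c in surveyor_cols:
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)

    if surveyors_path is None:
        surveyors_path = path.with_name(path.stem + "_surveyors.csv")
    pd.DataFrame(
        [
            {"surveyor_id": s.surveyor_id, "experience": s.experience}
            for s in ds.surveyors.values()
        ]
    ).to_csv(surveyors_path, index=False)

    if plots_path is not None:
        pd.DataFrame(
            [
                {
                    "plot_id": p.plot_id,
                    "area": p.area,
                    "host_plants": "" if p.host_plants is None else p.host_plants,
                    "occasions": ";".join(ds.occasions[p.plot_id]),
                }
                for p in ds.plots.values()
            ]
        ).to_csv(plots_path, index=False)


def _global_column_order(ds: DetectionDataset) -> list[str]:
    # Merge per-plot orders into one global column order that preserves each
    # plot's internal order where possible (topological merge, ties by first
    # appearance). Per-plot order is restored exactly via the plots sidecar.
    cols: list[str] = []
    for order in ds.occasions.values():
        for sid in order:
            if sid not in cols:
                cols.append(sid)
    return cols


# -- MARK encounter-history format ----------------------------------------


def write_inp(ds: DetectionDataset, path: str | Path) -> list[Path]:
    """Write MARK-style encounter histories; returns the file(s) written."""
    path = Path(path)
    lengths = {len(o) for o in ds.occasions.values()}
    if len(lengths) == 1:
        _write_inp_grouped(ds, path, ds.plot_ids)
        return [path]
    written = []
    for plot_id in ds.plot_ids:
        p = path.with_name(f"{path.stem}_{plot_id}{path.suffix or '.inp'}")
        _write_inp_grouped(ds, p, [plot_id])
        written.append(p)
    return written


def _write_inp_grouped(ds: DetectionDataset, path: Path, plot_ids: list[str]) -> None:
    buf = _io.StringIO()
    buf.write("/* groups: " + " ".join(plot_ids) + " */\n")
    for g, plot_id in enumerate(plot_ids):
        m = ds.matrices[plot_id]
        freqs = ["0"] * len(plot_ids)
        freqs[g] = "1"
        for i in range(m.shape[0]):
            history = "".join(str(int(v)) for v in m[i])
            buf.write(f"{history} {' '.join(freqs)};\n")
    Path(path).write_text(buf.getvalue())


def _read_inp(path: Path) -> DetectionDataset:
    """Parse a MARK .inp written by :func:`write_inp`.

    Surveyor metadata is not representable in .inp; occasions become generic
    ids ``occ1..occT`` labelled novice, groups become plots ``G1..Gk`` (or
    the names from a leading ``/* groups: ... */`` comment).
    """
    lines = path.read_text().splitlines()
    group_names: list[str] | None = None
    histories: list[tuple[str, list[int]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("/*"):
            if "groups:" in line:
                group_names = line.split("groups:")[1].split("*/")[0].split()
            continue
        if not line.endswith(";"):
            raise ParseError(f"{path}: line {lineno}: missing trailing ';'")
        parts = line[:-1].split()
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: need history and frequency")
        history, freqs = parts[0], parts[1:]
        if set(history) - {"0", "1"}:
            raise ParseError(f"{path}: line {lineno}: non-binary history {history!r}")
        histories.append((history, [int(f) for f in freqs]))
    if not histories:
        raise ParseError(f"{path}: no encounter histories")
    n_groups = len(histories[0][1])
    if group_names is None:
        group_names = [f"G{i + 1}" for i in range(n_groups)]
    T = len(histories[0][0])
    occ_ids = [f"occ{t + 1}" for t in range(T)]
    individuals: dict[str, list[IndividualRecord]] = {g: [] for g in group_names}
    mats: dict[str, list[list[int]]] = {g: [] for g in group_names}
    counter = {g: 0 for g in group_names}
    for history, freqs in histories:
        if len(history) != T:
            raise ParseError(f"{path}: inconsistent history length {len(history)} != {T}")
        for g, f in zip(group_names, freqs):
            for _ in range(f):
                counter[g] += 1
                individuals[g].append(
                    IndividualRecord(f"{g}-{counter[g]:03d}", g)
                )
                mats[g].append([int(c) for c in history])
    individuals = {g: v for g, v in individuals.items() if v}
    mats = {g: v for g, v in mats.items() if v}
    return DetectionDataset(
        surveyors={s: SurveyorInfo(s, "novice") for s in occ_ids},
        plots={g: PlotInfo(g, area=1.0) for g in individuals},
        individuals=individuals,
        occasions={g: list(occ_ids) for g in individuals},
        matrices={g: np.array(v, dtype=np.int8) for g, v in mats.items()},
    )
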