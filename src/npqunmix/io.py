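"""CSV / JSON serialisation of traces, curves and analysis results.

Curve tables use the tidy dialect: ``curve_id, time_s, npq, qp, phase``
with a companion metadata table ``curve_id, intensity_umol_m2_s,
closure_ss, genotype, treatment``.  Traces are ``time_s, yield`` plus a
schedule table ``pulse_time_s``.  All files are UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nmf import ComponentSet
from .pam import CurveDataset, FluorescenceTrace, InductionCurve
from .pca import PCAResult
from .phasor import TriangleModel
from .synth import GroundTruth

PathLike = Union[str, Path]


def write_curves(dataset: CurveDataset, curves_path: PathLike,
                 meta_path: PathLike) -> None:
    rows, meta = [], []
    for c in dataset.curves:
        cid = c.meta.get("curve_id", f"curve-{id(c):x}")
        for t, n, q, ph in zip(c.times, c.npq, c.qp, c.phase):
            rows.append((cid, t, n, q, ph))
        meta.append((cid, c.light_intensity, c.closure_ss,
                     c.meta.get("genotype", dataset.genotype),
                     c.meta.get("treatment", "none")))
    pd.DataFrame(rows, columns=["curve_id", "time_s", "npq", "qp", "phase"]
                 ).to_csv(curves_path, index=False)
    pd.DataFrame(meta, columns=["curve_id", "intensity_umol_m2_s", "closure_ss",
                                "genotype", "treatment"]
                 ).to_csv(meta_path, index=False)


def read_curves(curves_path: PathLike, meta_path: PathLike) -> CurveDataset:
    df = pd.read_csv(curves_path)
    md = pd.read_csv(meta_path).set_index("curve_id")
    required = {"curve_id", "time_s", "npq", "qp", "phase"}
    if not required.issubset(df.columns):
        raise ValidationError(f"curve CSV must have columns {sorted(required)}")
    curves = []
    genotypes = set()
    for cid, grp in df.groupby("curve_id", sort=False):
        if cid not in md.index:
            raise ValidationError(f"curve {cid!r} missing from metadata CSV")
        m = md.loc[cid]
        closure = m["closure_ss"]
        curves.append(InductionCurve(
            grp["time_s"].to_numpy(), grp["npq"].to_numpy(), grp["qp"].to_numpy(),
            float(m["intensity_umol_m2_s"]),
            closure_ss=None if pd.isna(closure) else float(closure),
            phase=grp["phase"].to_numpy(dtype=object),
            meta={"curve_id": cid, "genotype": m.get("genotype", "wt"),
                  "treatment": m.get("treatment", "none")},
        ))
        genotypes.add(str(m.get("genotype", "wt")))
    genotype = genotypes.pop() if len(genotypes) == 1 else "mixed"
    return CurveDataset(curves, genotype=genotype)


def write_trace(trace: FluorescenceTrace, trace_path: PathLike,
                schedule_path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.time, "yield": trace.fluor}
                 ).to_csv(trace_path, index=False)
    pd.DataFrame({"pulse_time_s": trace.pulse_times}
                 ).to_csv(schedule_path, index=False)


def read_trace(trace_path: PathLike, schedule_path: PathLike, light_on: float,
               light_off: float, intensity: float) -> FluorescenceTrace:
    df = pd.read_csv(trace_path)
    if not {"time_s", "yield"}.issubset(df.columns):
        raise ValidationError("trace CSV must have columns time_s, yield")
    sched = pd.read_csv(schedule_path)
    if "pulse_time_s" not in sched.columns:
        raise ValidationError("schedule CSV must have column pulse_time_s")
    return FluorescenceTrace(
        df["time_s"].to_numpy(), df["yield"].to_numpy(),
        sched["pulse_time_s"].to_numpy(), light_on, light_off, intensity,
    )


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    Path(path).write_text(json.dumps({
        "labels": truth.labels,
        "grid_s": truth.grid.tolist(),
        "profiles": truth.profiles.tolist(),
        "amplitudes": truth.amplitudes.tolist(),
        "closures": truth.closures.tolist(),
        "seed": truth.seed,
    }, indent=1))


def read_ground_truth(path: PathLike) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        labels=d["labels"], grid=np.asarray(d["grid_s"]),
        profiles=np.asarray(d["profiles"]), amplitudes=np.asarray(d["amplitudes"]),
        closures=np.asarray(d["closures"]), seed=d["seed"],
    )


def write_pca(result: PCAResult, path: PathLike) -> None:
    Path(path).write_text(json.dumps({
        "grid_s": result.grid.tolist(),
        "mean_curve": result.mean_curve.tolist(),
        "components": result.components.tolist(),
        "coefficients": result.coefficients.tolist(),
        "explained_fraction": result.explained_fraction.tolist(),
    }, indent=1))


def write_triangle(triangle: Optional[TriangleModel], path: PathLike) -> None:
    if triangle is None:
        Path(path).write_text(json.dumps(None))
        return
    Path(path).write_text(json.dumps({
        "vertices": triangle.vertices.tolist(),
        "centroid": [triangle.centroid.g, triangle.centroid.s],
        "provenance": list(triangle.provenance),
    }, indent=1))


def write_phasor_table(phasors, abundances, flags, curve_ids,
                       path: PathLike) -> None:
    pd.DataFrame({
        "curve_id": curve_ids,
        "g": phasors[:, 0], "s": phasors[:, 1],
        "w1": abundances[:, 0], "w2": abundances[:, 1], "w3": abundances[:, 2],
        "clipped_flag": flags,
    }).to_csv(path, index=False)


def write_components(cset: ComponentSet, grid: np.ndarray, curve_ids,
                     json_path: PathLike, profiles_csv: PathLike) -> None:
    Path(json_path).write_text(json.dumps({
        "grid_s": grid.tolist(),
        "labels": cset.labels,
        "profiles": cset.profiles.tolist(),
        "contributions": {cid: row.tolist()
                          for cid, row in zip(curve_ids, cset.contributions)},
        "adjusted_r2": None if cset.adj_r2 is None else cset.adj_r2.tolist(),
        "loss_trace": None if cset.loss_trace is None else cset.loss_trace.tolist(),
    }, indent=1))
    rows = [(lab, t, v) for lab, prof in zip(cset.labels, cset.profiles)
            for t, v in zip(grid, prof)]
    pd.DataFrame(rows, columns=["label", "time_s", "value"]
                 ).to_csv(profiles_csv, index=False)


def read_components(json_path: PathLike):
    d = json.loads(Path(json_path).read_text())
    cset = ComponentSet(
        profiles=np.asarray(d["profiles"]),
        contributions=np.asarray(list(d["contributions"].values())),
        labels=list(d["labels"]),
        adj_r2=None if d["adjusted_r2"] is None else np.asarray(d["adjusted_r2"]),
        loss_trace=None if d["loss_trace"] is None else np.asarray(d["loss_trace"]),
    )
    return cset, np.asarray(d["grid_s"]), list(d["contributions"].keys())
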