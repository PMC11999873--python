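"""End-to-end orchestration: fields -> contours -> statistics -> kappa report.

A single structured (YAML/dict) config drives the run:

.. code-block:: yaml

    seed: 1
    source:
      kind: percolation          # percolation | sle | simulation | files
      n_traces: 200              # percolation / sle
      width: 128                 # percolation lattice
      height: 128
      n_fields: 4                # percolation cluster fields
      field_size: 256
    contours:
      mode: triangular           # square for vorticity fields
      min_length: 16
    sle:
      method: both               # lpp | driving | both

The report collects the Table-1-style summary: fractal dimensions of the
complete and accessible perimeters, the duality product, the winding-angle
slope, and kappa by left passage and by driving function.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .contours import ChordalTrace, extract_chordal_traces, export_traces, label_clusters
from .fields import VelocityField, binarize_vorticity, compute_vorticity
from .scaling import ScalingFit, WindingStatistics, cluster_geometries, duality_product, fit_fractal_dimension, winding_variance_fit
from .sle import KappaEstimate, compute_driving_function, empirical_left_passage, estimate_kappa_lpp, fit_kappa_driving
from .synthetic import SimulationParams, percolation_interface, run_simulation, sample_percolation_field, sample_sle_trace

__all__ = ["AnalysisReport", "run_pipeline", "compare_report", "report_to_dict"]

log = logging.getLogger("flowsle")


@dataclass
class AnalysisReport:
    fit_complete: Optional[ScalingFit] = None
    fit_accessible: Optional[ScalingFit] = None
    duality: Optional[float] = None
    winding: Optional[WindingStatistics] = None
    kappa_lpp: Optional[KappaEstimate] = None
    kappa_driving: Optional[KappaEstimate] = None
    provenance: dict = field(default_factory=dict)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def report_to_dict(report: AnalysisReport) -> dict:
    out = {}
    for key in ("fit_complete", "fit_accessible", "winding", "kappa_lpp", "kappa_driving"):
        val = getattr(report, key)
        if val is not None:
            d = asdict(val)
            d.pop("diagnostics", None)  # bulky arrays live in stage outputs
            if key == "winding":
                d["gaussian"] = _json_safe(val.gaussian)
            out[key] = _json_safe(d)
        else:
            out[key] = None
    out["duality"] = report.duality
    out["provenance"] = _json_safe(report.provenance)
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(_json_safe(config), sort_keys=True).encode()).hexdigest()[:16]


def _make_traces(source: dict, rng: np.random.Generator) -> list[ChordalTrace]:
    kind = source.get("kind", "percolation")
    n = int(source.get("n_traces", 200))
    if kind == "percolation":
        w = int(source.get("width", 128))
        h = int(source.get("height", w))
        return [percolation_interface(w, h, rng=rng)[0] for _ in range(n)]
    if kind == "sle":
        kappa = float(source.get("kappa", 6.0))
        steps = int(source.get("n_steps", 1000))
        dt = float(source.get("dt", 1e-3))
        return [sample_sle_trace(kappa, steps, dt, rng=rng) for _ in range(n)]
    raise ValueError(f"source kind {kind!r} does not generate chordal traces")


def _binary_fields(source: dict, config: dict, rng: np.random.Generator):
    """Yield (binary sign array, tracing mode) pairs for cluster statistics."""
    kind = source.get("kind", "percolation")
    if kind == "percolation":
        n = int(source.get("n_fields", 4))
        size = int(source.get("field_size", 256))
        for _ in range(n):
            yield sample_percolation_field((size, size), rng=rng), "triangular"
    elif kind == "simulation":
        params = SimulationParams(seed=int(rng.integers(2**31)),
                                  **source.get("params", {}))
        for snap in run_simulation(params, warmup=source.get("warmup")):
            vort = compute_vorticity(snap, boundary="periodic")
            yield binarize_vorticity(vort).sign, "square"
    elif kind == "files":
        from .fields import read_velocity_field

        for path in source["paths"]:
            fld = read_velocity_field(path, dialect=source.get("dialect", "table"))
            vort = compute_vorticity(fld, boundary=source.get("boundary", "crop"))
            yield binarize_vorticity(vort).sign, "square"
    else:
        raise ValueError(f"source kind {kind!r} does not generate fields")


def run_pipeline(config: dict, out_dir: Optional[str | Path] = None) -> AnalysisReport:
    """Execute the full analysis described by ``config``.

    Deterministic given the config seed. When ``out_dir`` is given, stage
    outputs (traces, geometry table), the final ``report.json``, a run log
    and a config snapshot are written there.
    """
    t0 = time.time()
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    source = dict(config.get("source", {"kind": "percolation"}))
    contours_cfg = dict(config.get("contours", {}))
    sle_cfg = dict(config.get("sle", {}))
    report = AnalysisReport()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        for sub in ("fields", "contours", "stats"):
            (out_path / sub).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_path / "run.log")
        fh.setLevel(logging.INFO)
        log.addHandler(fh)
        log.setLevel(logging.INFO)
        (out_path / "config.json").write_text(json.dumps(_json_safe(config), indent=1))

    try:
        kind = source.get("kind", "percolation")
        mode = contours_cfg.get("mode", "triangular" if kind == "percolation" else "square")
        min_len = int(contours_cfg.get("min_length", 16))

        # ---- stage 1-2: fields, clusters, contour geometry ----------------
        stage = "contour_geometry"
        geoms = []
        traces: list[ChordalTrace] = []
        if kind in ("percolation", "simulation", "files"):
            for sign, fmode in _binary_fields(source, config, rng):
                lab = label_clusters(sign, "triangular" if fmode == "triangular" else 4)
                geoms.extend(cluster_geometries(lab, min_size=4, mode=fmode))
                if kind != "percolation":
                    rows = source.get("axis_rows") or [sign.shape[0] // 2]
                    for row in rows:
                        traces.extend(extract_chordal_traces(sign, axis_row=int(row),
                                                             mode=fmode, min_length=min_len))
            log.info("contour_geometry: %d cluster geometries", len(geoms))
        if kind in ("percolation", "sle"):
            traces = _make_traces(source, rng)
        log.info("chordal traces: %d", len(traces))
        if out_path is not None and traces:
            export_traces(traces[: int(config.get("max_exported_traces", 50))],
                          out_path / "contours" / "traces.tsv",
                          out_path / "contours" / "traces.json")

        # ---- stage 3: scaling statistics ----------------------------------
        stage = "scaling_statistics"
        if geoms:
            report.fit_complete = fit_fractal_dimension(geoms, "complete")
            report.fit_accessible = fit_fractal_dimension(geoms, "accessible")
            if report.fit_complete.exponent > 1 and report.fit_accessible.exponent > 1:
                report.duality = duality_product(report.fit_complete.exponent,
                                                 report.fit_accessible.exponent)
            else:
                log.warning("exponents below 1 (lattice-dominated ensemble); "
                            "duality product not defined")
            if out_path is not None:
                with open(out_path / "stats" / "clusters.tsv", "w") as gh:
                    gh.write("label\tsize\tR_g\tl_complete\tl_accessible\n")
                    for g in geoms:
                        gh.write(f"{g.label}\t{g.size}\t{g.gyration_radius:.6g}\t"
                                 f"{g.perimeter_complete:.6g}\t{g.perimeter_accessible:.6g}\n")
        if traces:
            report.winding = winding_variance_fit(traces)

        # ---- stage 4: SLE inference ---------------------------------------
        stage = "sle_inference"
        method = sle_cfg.get("method", "both")
        if traces:
            if method in ("lpp", "both"):
                grid = empirical_left_passage(traces)
                report.kappa_lpp = estimate_kappa_lpp(grid)
            if method in ("driving", "both"):
                dfs = [compute_driving_function(tr, trace_id=i,
                                                max_points=int(sle_cfg.get("max_points", 1200)))
                       for i, tr in enumerate(traces)]
                report.kappa_driving = fit_kappa_driving(dfs)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    from . import __version__ as version

    report.provenance = dict(
        config_hash=_config_hash(config), seed=seed, version=version,
        n_traces=len(traces), n_clusters=len(geoms), elapsed_s=round(time.time() - t0, 3),
    )
    if out_path is not None:
        (out_path / "report.json").write_text(json.dumps(report_to_dict(report), indent=1))
        log.info("pipeline complete in %.1fs", time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# Acceptance-style comparison
# ---------------------------------------------------------------------------

_METRIC_GETTERS = {
    "fractal_dimension_complete": lambda r: (r.fit_complete.exponent, r.fit_complete.stderr) if r.fit_complete else None,
    "fractal_dimension_accessible": lambda r: (r.fit_accessible.exponent, r.fit_accessible.stderr) if r.fit_accessible else None,
    "duality_product": lambda r: (r.duality, 0.0) if r.duality is not None else None,
    "winding_alpha": lambda r: (r.winding.slope_alpha, r.winding.stderr) if r.winding else None,
    "kappa_left_passage": lambda r: (r.kappa_lpp.kappa, r.kappa_lpp.stderr) if r.kappa_lpp else None,
    "kappa_driving": lambda r: (r.kappa_driving.kappa, r.kappa_driving.stderr) if r.kappa_driving else None,
}


def compare_report(report: AnalysisReport, reference: dict) -> list[dict]:
    """Per-metric pass/fail table against a reference of
    ``{metric: {"value": v, "tol": t}}`` entries.

    A metric passes when |measured - reference| <= tol; the z-score uses the
    measurement's standard error where available.
    """
    rows = []
    for name, ref in reference.items():
        getter = _METRIC_GETTERS.get(name)
        if getter is None:
            raise KeyError(f"unknown metric {name!r}")
        got = getter(report)
        if got is None:
            raise ValueError(f"report is missing metric {name!r}")
        value, stderr = got
        dev = value - float(ref["value"])
        tol = float(ref["tol"])
        rows.append(dict(
            metric=name, measured=float(value), reference=float(ref["value"]),
            tol=tol, deviation=float(dev),
            z=float(dev / stderr) if stderr else float("nan"),
            passed=bool(abs(dev) <= tol),
        ))
    return rows
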