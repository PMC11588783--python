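"""Run orchestration: evaluate cases, emit publication-table-shaped reports.

A run reads matched image/label(/prediction) cases — from directories or
from the phantom generator — and writes:

* ``metrics_table.csv``   per case and class: Dice, HD95 [mm], NSD
* ``split_table.csv``     per case and class: reference distinct/completed
  fractions and the B_TP / B_Distinct / B_Completed decomposition
* ``aggregates.json``     mean ± sd per column, re-computable from the CSVs
* ``cases.json``          full-precision per-case records
* ``config.yaml``, ``run.log``  provenance: rerunning the same config and
  seed reproduces the bundle byte-identically.

CSV values are rounded to 3 decimals for readability; full precision
lives in the JSON.  :func:`validate_report` re-checks every invariant
(range, fraction sums, additivity) from the emitted files alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import borders, edges, metrics as M, phantom as ph
from .io import read_volume

logger = logging.getLogger("usborder")

_METRIC_COLS = ["dice", "hd95_mm", "nsd"]
_SPLIT_COLS = ["reference_distinct_pct", "reference_completed_pct",
               "tp_total_pct", "tp_distinct_pct", "tp_completed_pct"]


@dataclass
class RunConfig:
    """Fully serializable description of one evaluation run."""

    out_dir: str = "usborder_report"
    seed: int = 0
    log_level: str = "INFO"
    # inputs: either directories ...
    image_dir: str = None
    labels_dir: str = None
    pred_dir: str = None
    # ... or phantoms with simulated predictions
    n_phantoms: int = 0
    phantom: dict = field(default_factory=dict)
    prediction_error_model: str = "dilate"
    prediction_error_magnitude: float = 1
    # analysis parameters
    edge: dict = field(default_factory=dict)
    tolerance_radius: int = 0
    match_tolerance: int = 1
    nsd_tau_mm: float = None      # default: one voxel (min spacing) in mm

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_cases(config: RunConfig):
    """Yield (case_id, image, gt_labels, pred_labels) tuples."""
    if config.n_phantoms > 0:
        spec = ph.PhantomSpec(**config.phantom)
        cases = ph.phantom_dataset(config.n_phantoms, spec, seed=config.seed)
        for i, case in enumerate(cases):
            pred = ph.simulate_prediction(
                case.labels, config.prediction_error_model,
                config.prediction_error_magnitude,
                seed=(config.seed * 9176 + i) % (2 ** 31))
            yield f"phantom_{i:03d}", case.image, case.labels, pred
        return
    if not (config.image_dir and config.labels_dir):
        raise ValueError("config must set either n_phantoms or input directories")
    img_dir, lab_dir = Path(config.image_dir), Path(config.labels_dir)
    pred_dir = Path(config.pred_dir) if config.pred_dir else None

    def stem(p):
        return p.name.split(".")[0]

    images = {stem(p): p for p in sorted(img_dir.iterdir()) if p.is_file()}
    labels = {stem(p): p for p in sorted(lab_dir.iterdir()) if p.is_file()}
    preds = ({stem(p): p for p in sorted(pred_dir.iterdir()) if p.is_file()}
             if pred_dir else {})
    skipped = sorted(set(images) ^ set(labels))
    if skipped:
        logger.warning("unmatched case ids skipped: %s", skipped)
    matched = sorted(set(images) & set(labels))
    if not matched:
        raise ValueError("no matched image/label cases found")
    for cid in matched:
        image = read_volume(images[cid], "image")
        gt = read_volume(labels[cid], "label")
        pred = read_volume(preds[cid], "label") if cid in preds else None
        yield cid, image, gt, pred


def evaluate_case(image, gt, pred, edge_params=None, tolerance_radius=0,
                  match_tolerance=1, nsd_tau_mm=None):
    """All metric rows for one case; returns (metric_rows, split_rows)."""
    edge_params = edge_params or edges.EdgeParams()
    em = edges.compute_edge_map(image, edge_params)
    splits = borders.split_all_classes(gt, em, tolerance_radius)
    tau = nsd_tau_mm if nsd_tau_mm is not None else min(image.spacing)
    metric_rows, split_rows = [], []
    for split in splits:
        c = split.class_id
        row = {"class_id": c}
        if pred is not None:
            pmask, gmask = pred.data == c, gt.data == c
            row["dice"] = M.dice(pmask, gmask)
            if pmask.any() and gmask.any():
                row["hd95_mm"] = M.hd95(pmask, gmask, image.spacing)
                row["nsd"] = M.nsd(pmask, gmask, image.spacing, tau)
            else:
                row["hd95_mm"] = np.nan
                row["nsd"] = np.nan
                logger.warning("class %d empty in prediction or truth; "
                               "surface metrics undefined", c)
            pred_border = borders.extract_border(pred, c)
            srow = M.tp_decomposition(split, pred_border, match_tolerance)
        else:
            d, comp = M.reference_border_fractions(split)
            srow = M.SplitMetricsRow(c, d, comp, np.nan, np.nan, np.nan)
        metric_rows.append(row)
        split_rows.append(srow)
    return metric_rows, split_rows


def run_evaluation(config: RunConfig):
    """Execute a run and write the report bundle; returns the bundle path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        edge_params = edges.EdgeParams(**config.edge)
        mrows, srows = [], []
        n_cases = 0
        for cid, image, gt, pred in _load_cases(config):
            mr, sr = evaluate_case(image, gt, pred, edge_params,
                                   config.tolerance_radius,
                                   config.match_tolerance, config.nsd_tau_mm)
            for r in mr:
                mrows.append({"case_id": cid, **r})
            for r in sr:
                rec = dataclasses.asdict(r)
                rec["case_id"] = cid
                srows.append(rec)
            n_cases += 1
        logger.info("evaluated %d cases", n_cases)

        mdf = pd.DataFrame(mrows)
        sdf = pd.DataFrame(srows)[["case_id", "class_id"] + _SPLIT_COLS]
        # in-run invariant check mirroring validate_report
        add_err = (sdf["tp_distinct_pct"] + sdf["tp_completed_pct"]
                   - sdf["tp_total_pct"]).abs()
        if add_err.dropna().max() > 1e-9:
            raise AssertionError("TP decomposition additivity violated in-run")
        mdf.round(3).to_csv(out / "metrics_table.csv", index=False)
        sdf.round(3).to_csv(out / "split_table.csv", index=False)

        aggregates = {}
        for name, df, cols in (("metrics", mdf, _METRIC_COLS),
                               ("split", sdf, _SPLIT_COLS)):
            aggregates[name] = {
                col: {"mean": float(np.nanmean(df[col])),
                      "sd": float(np.nanstd(df[col], ddof=1))}
                for col in cols if col in df and df[col].notna().any()
            }
        with open(out / "aggregates.json", "w") as fh:
            json.dump(aggregates, fh, indent=2, sort_keys=True)
        with open(out / "cases.json", "w") as fh:
            json.dump({"metrics": mrows, "split": srows}, fh, indent=2,
                      sort_keys=True, default=float)
        config.to_yaml(out / "config.yaml")
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


def validate_report(path):
    """Re-check report invariants from the CSVs alone.

    Returns ``(ok, findings)``; findings name the offending file/row.
    Tolerances allow for the 3-decimal CSV rounding.
    """
    path = Path(path)
    findings = []
    split_csv = path / "split_table.csv"
    metrics_csv = path / "metrics_table.csv"
    if not split_csv.exists() and not metrics_csv.exists():
        raise FileNotFoundError(f"no report tables found under {path}")
    tol = 2.5e-3  # three-decimal rounding of three combined columns
    if split_csv.exists():
        sdf = pd.read_csv(split_csv)
        for i, row in sdf.iterrows():
            ref_sum = row["reference_distinct_pct"] + row["reference_completed_pct"]
            if abs(ref_sum - 100.0) > tol:
                findings.append(
                    f"split_table row {i}: reference fractions sum to {ref_sum}")
            if not np.isnan(row["tp_total_pct"]):
                err = abs(row["tp_distinct_pct"] + row["tp_completed_pct"]
                          - row["tp_total_pct"])
                if err > tol:
                    findings.append(
                        f"split_table row {i}: additivity violated by {err:.4f}")
            for col in _SPLIT_COLS:
                v = row[col]
                if not np.isnan(v) and not (-tol <= v <= 100 + tol):
                    findings.append(
                        f"split_table row {i}: {col}={v} outside [0, 100]")
    if metrics_csv.exists():
        mdf = pd.read_csv(metrics_csv)
        for i, row in mdf.iterrows():
            for col, lo, hi in (("dice", 0, 1), ("nsd", 0, 1),
                                ("hd95_mm", 0, np.inf)):
                if col in row and not np.isnan(row[col]) and not (
                        lo - tol <= row[col] <= hi + tol):
                    findings.append(
                        f"metrics_table row {i}: {col}={row[col]} outside range")
    return (len(findings) == 0), findings
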