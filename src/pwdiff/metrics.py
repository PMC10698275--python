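"""Evaluation statistics for pointwise predictions and changepoints.

* ``mre`` — mean relative error of the diffusion coefficient,
  mean(|D_true - D_pred| / D_true), pooled over every step of the test set;
* ``mae`` — mean absolute error, used for the anomalous exponent;
* ``jaccard_cps`` — Jaccard index TP / (TP + FP + FN) between changepoint
  sets, where a prediction within ``eps`` steps of an unmatched ground-truth
  changepoint is a true positive (greedy one-to-one matching by distance);
* ``stratified_report`` — the benchmark curves: metric vs segment length,
  D-ratio or |delta alpha| of consecutive segments, and changepoint position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import GroundTruthProfile, PointwiseProfile

__all__ = ["mre", "mae", "jaccard_cps", "stratified_report", "BenchmarkReport"]


def mre(pred_D: np.ndarray, true_D: np.ndarray) -> float:
    """Mean relative error |D_true - D_pred| / D_true over all steps."""
    pred_D = np.asarray(pred_D, dtype=float)
    true_D = np.asarray(true_D, dtype=float)
    if pred_D.shape != true_D.shape:
        raise ValueError("length mismatch")
    if np.any(true_D == 0):
        raise ValueError("true D must be nonzero")
    return float(np.mean(np.abs(true_D - pred_D) / true_D))


def mae(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute error over all steps."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(pred - true)))


def jaccard_cps(true_cps: np.ndarray, pred_cps: np.ndarray, eps: float) -> float:
    """Jaccard index between changepoint sets with position tolerance eps.

    Pairs are matched greedily by increasing |pred - true| (ties broken by
    the earlier true index), one-to-one; matched pairs within eps are true
    positives.  Both sets empty gives 1.
    """
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    t = np.asarray(true_cps, dtype=float)
    p = np.asarray(pred_cps, dtype=float)
    if t.size == 0 and p.size == 0:
        return 1.0
    if t.size == 0 or p.size == 0:
        return 0.0
    dist = np.abs(p[None, :] - t[:, None])
    pairs = [
        (dist[i, j], i, j)
        for i in range(t.size)
        for j in range(p.size)
        if dist[i, j] <= eps
    ]
    pairs.sort(key=lambda x: (x[0], x[1]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        tp += 1
    fp = p.size - tp
    fn = t.size - tp
    return tp / (tp + fp + fn)


@dataclass
class BenchmarkReport:
    """Aggregated benchmark metrics with optional stratified curves."""

    overall: dict[str, float]
    n_trajectories: int
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _segment_records(truth: GroundTruthProfile, errors: np.ndarray) -> list[dict]:
    recs = []
    for a, b in truth.segment_bounds():
        recs.append({"length": b - a, "error": float(np.mean(errors[a:b]))})
    return recs


def stratified_report(
    dataset: list[GroundTruthProfile],
    predictions: list[PointwiseProfile],
    target: str = "D",
    length_bins: np.ndarray | None = None,
    jaccard_eps: float = 5.0,
    pred_cps: list[np.ndarray] | None = None,
) -> BenchmarkReport:
    """Overall and stratified benchmark metrics.

    Pointwise errors (relative for D, absolute for alpha) are pooled over
    every step of the test set for the overall metric and averaged per
    segment for the segment-length curve.  When predicted changepoint sets
    are supplied, the mean per-trajectory Jaccard index and its
    stratifications by property contrast and changepoint position are added.
    """
    if len(dataset) != len(predictions):
        raise ValueError("dataset and predictions must align")
    step_errors: list[np.ndarray] = []
    seg_recs: list[dict] = []
    cp_recs: list[dict] = []
    traj_ji: list[float] = []
    for k, (truth, prof) in enumerate(zip(dataset, predictions)):
        if truth.n != prof.n:
            raise ValueError("profile length mismatch")
        if target == "D":
            pred = 10.0 ** prof.values
            err = np.abs(truth.D_true - pred) / truth.D_true
        else:
            err = np.abs(truth.alpha_true - prof.values)
        step_errors.append(err)
        seg_recs.extend(_segment_records(truth, err))
        if pred_cps is not None:
            ji = jaccard_cps(truth.changepoints, pred_cps[k], jaccard_eps)
            traj_ji.append(ji)
            bounds = truth.segment_bounds()
            for cp in truth.changepoints:
                prev = next(b for b in bounds if b[1] == cp)
                nxt = next(b for b in bounds if b[0] == cp)
                if target == "D":
                    contrast = abs(
                        np.log10(truth.D_true[prev[0]]) - np.log10(truth.D_true[nxt[0]])
                    )
                else:
                    contrast = abs(truth.alpha_true[nxt[0]] - truth.alpha_true[prev[0]])
                cp_recs.append({"position": int(cp), "contrast": contrast, "ji": ji})

    all_err = np.concatenate(step_errors)
    metric_name = "MRE" if target == "D" else "MAE"
    overall = {metric_name: float(all_err.mean())}

    curves: dict[str, pd.DataFrame] = {}
    seg_df = pd.DataFrame(seg_recs)
    if length_bins is None:
        length_bins = np.array([10, 30, 60, 100, 140, 191])
    seg_df["length_bin"] = pd.cut(seg_df["length"], length_bins, include_lowest=True)
    curves["by_segment_length"] = (
        seg_df.groupby("length_bin", observed=True)["error"]
        .agg(["mean", "count"])
        .reset_index()
    )
    if traj_ji:
        overall["JI"] = float(np.mean(traj_ji))  # per-trajectory mean
    if cp_recs:
        cp_df = pd.DataFrame(cp_recs)
        cp_df["contrast_bin"] = pd.cut(cp_df["contrast"], 6)
        cp_df["position_bin"] = pd.cut(cp_df["position"], 6)
        curves["by_contrast"] = (
            cp_df.groupby("contrast_bin", observed=True)["ji"]
            .agg(["mean", "count"])
            .reset_index()
        )
        curves["by_position"] = (
            cp_df.groupby("position_bin", observed=True)["ji"]
            .agg(["mean", "count"])
            .reset_index()
        )
    return BenchmarkReport(
        overall=overall,
        n_trajectories=len(dataset),
        curves=curves,
        meta={"target": target, "jaccard_eps": jaccard_eps, "ji_averaging": "per-trajectory"},
    )
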