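"""Evaluation metrics and printed-table arithmetic.

* VPP (valid-point percent): 100 × target-class points / total points of a
  filtered cloud — higher means less residual background.
* NRR (noise-reduction ratio): 100 × (1 − n_after / n_before) for a
  denoising stage.
* AveEd / AveAn: layering severity of two registered frame meshes — the
  mean plane-to-plane distance over parallel patch pairs and the mean
  inter-plane angle (degrees, folded to [0°, 90°]) over intersecting and
  plane-intersecting pairs, using the same neighbor retrieval as the
  optimizer.
* chamfer_distance: symmetric mean nearest-neighbor distance, used against
  ground-truth surface samplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import Label, LabeledCloud
from .errors import InvalidInputError, UndefinedMetricError
from .registration import (
    OptimizeParams,
    TriangleMesh,
    _classify_arrays,
    _retrieve_pairs,
)
from . import tables

__all__ = [
    "MetricReport",
    "vpp",
    "vpp_from_counts",
    "plant_recall",
    "nrr",
    "layering_metrics",
    "chamfer_distance",
    "table_arithmetic",
]


@dataclass
class MetricReport:
    vpp: Optional[float] = None
    nrr: Optional[float] = None
    ave_ed: Optional[float] = None
    ave_an: Optional[float] = None
    counts: Optional[dict] = None


def vpp_from_counts(valid_points: int, total_points: int) -> float:
    """VPP = 100 × valid / total, as printed (2 decimals carried by caller)."""
    if total_points <= 0:
        raise UndefinedMetricError("VPP undefined for an empty cloud")
    return 100.0 * valid_points / total_points


def vpp(kept: LabeledCloud, valid_label: int = Label.PLANT) -> float:
    """Valid-point percent of a filtered cloud: share of points carrying the
    target (plant) label.  Requires ground-truth labels."""
    if len(kept) == 0:
        raise UndefinedMetricError("VPP undefined for an empty cloud")
    if kept.labels is None:
        raise InvalidInputError("VPP needs ground-truth labels")
    return vpp_from_counts(int(np.sum(kept.labels == valid_label)), len(kept))


def plant_recall(kept: LabeledCloud, total_valid: int, valid_label: int = Label.PLANT) -> float:
    """Share of the frame's ground-truth plant points that survived filtering."""
    if total_valid <= 0:
        raise UndefinedMetricError("recall undefined without ground-truth plant points")
    if kept.labels is None:
        raise InvalidInputError("recall needs ground-truth labels")
    return 100.0 * int(np.sum(kept.labels == valid_label)) / total_valid


def nrr(n_before: int, n_after: int) -> float:
    """Noise-reduction ratio: (1 − n_after/n_before) × 100."""
    if n_before <= 0:
        raise InvalidInputError("n_before must be > 0")
    if n_after > n_before or n_after < 0:
        raise InvalidInputError("need n_before >= n_after >= 0")
    return (1.0 - n_after / n_before) * 100.0


def layering_metrics(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                     params: OptimizeParams = OptimizeParams()) -> Tuple[Optional[float], Optional[float]]:
    """(ave_ed, ave_an) over the optimizer's neighbor pairs.

    ave_ed — mean plane-to-plane (centroid-to-plane) distance in metres
    over PARALLEL pairs; ave_an — mean inter-plane angle (degrees in
    [0, 90]) over INTERSECTING and PLANE_INTERSECTING pairs.  A mean whose
    pair set is empty is None.
    """
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        raise InvalidInputError("layering_metrics needs non-empty meshes")
    ii, jj = _retrieve_pairs(mesh_a, mesh_b, params)
    if len(ii) == 0:
        return None, None
    cls = _classify_arrays(mesh_a.face_vertices()[ii], mesh_b.face_vertices()[jj], params)
    ed_mask = cls["kind"] == 2
    an_mask = (cls["kind"] == 0) | (cls["kind"] == 1)
    # plane-to-plane separation: zero for an exactly coincident mesh pair
    # regardless of how many lateral neighbors the retrieval returns
    ave_ed = float(cls["d_tri"][ed_mask].mean()) if ed_mask.any() else None
    ave_an = float(np.rad2deg(cls["alpha"][an_mask].mean())) if an_mask.any() else None
    return ave_ed, ave_an


def chamfer_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric chamfer: mean of the two directed mean nearest-neighbor
    distances."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 3)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedMetricError("chamfer undefined for empty sets")
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return float(0.5 * (d_ab + d_ba))


def _round2(x) -> float:
    """Half-up rounding to 2 decimals, matching the tables' printing."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _column_summary(values) -> dict:
    arr = tables.as_array(values)
    return {
        "mean": float(arr.mean()),
        "sd_population": float(arr.std(ddof=0)),
        "sd_sample": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "n": int(len(arr)),
    }


def table_arithmetic(report_spec: str) -> dict:
    """Summary arithmetic on a bundled printed table.

    Column means and SDs (population and sample) for every numeric column,
    plus the published derived values of each table: recomputed per-frame
    VPP/NRR from the printed counts, and the per-plant ratio rows of the
    layering summary (whose printed 'Average' is the ratio of the rounded
    column averages — reproduced with the same convention).
    """
    t = tables.get_table(report_spec)
    out: dict = {"table": report_spec, "columns": {}}

    if report_spec == "bn_removal_frames":
        for method in ("passthrough", "mobb"):
            m = t[method]
            out["columns"][f"{method}_vpp"] = _column_summary(m["vpp"])
            out[f"{method}_vpp_from_counts"] = [
                _round2(vpp_from_counts(v, n)) for v, n in zip(m["valid"], m["total"])
            ]
    elif report_spec == "vpp_per_plant":
        for method, vals in t.items():
            out["columns"][method] = _column_summary(vals)
    elif report_spec == "nrr_frames":
        for method in ("radius", "radius_density", "proposed"):
            m = t[method]
            out["columns"][f"{method}_nrr"] = _column_summary(m["nrr"])
            out[f"{method}_nrr_from_counts"] = [
                _round2(nrr(nb, na)) for nb, na in zip(t["original"], m["points"])
            ]
    elif report_spec == "nrr_per_plant":
        for method, vals in t.items():
            out["columns"][method] = _column_summary(vals)
    elif report_spec == "layering_groups":
        for stage, cols in t.items():
            for name, vals in cols.items():
                out["columns"][f"{stage}_{name}"] = _column_summary(vals)
    elif report_spec == "layering_per_plant":
        for row, vals in t.items():
            out["columns"][row] = _column_summary(vals)
        # the summary table prints each ratio row's Average as the ratio of
        # the rounded row averages
        for num, den, key in (("E", "C", "E_over_C_pct"), ("F", "D", "F_over_D_pct")):
            mean_num = tables.printed_mean(t[num])
            mean_den = tables.printed_mean(t[den])
            out[f"{key}_average"] = _round2(100.0 * mean_num / mean_den)
            out[f"{key}_per_plant"] = [
                _round2(100.0 * a / b) for a, b in zip(t[num], t[den])
            ]
    return out
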