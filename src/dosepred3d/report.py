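"""Metric reports: per-plan, per-structure CSV/JSON with cohort summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import PlanComparison

__all__ = ["comparisons_to_frame", "write_metrics_report"]


def comparisons_to_frame(comparisons: list[PlanComparison]) -> pd.DataFrame:
    """One row per (plan, structure, metric)."""
    rows = []
    for c in comparisons:
        for v, delta in c.ptv_delta_pct.items():
            rows.append((c.plan_id, "ptv", f"delta_D{v:g}pct_percent", delta))
        for name, delta in c.oar_delta_mean_Gy.items():
            rows.append((c.plan_id, name, "delta_Dmean_Gy", delta))
        for name, delta in c.oar_delta_max_Gy.items():
            rows.append((c.plan_id, name, "delta_Dmax_Gy", delta))
        rows.append((c.plan_id, "body", "voxel_mean_diff_Gy", c.voxel_mean_diff_Gy))
        for label, metrics in (("pred", c.pred_metrics), ("ref", c.ref_metrics)):
            for name, m in metrics.items():
                rows.append((c.plan_id, name, f"{label}_Dmean_Gy", m.Dmean_Gy))
                rows.append((c.plan_id, name, f"{label}_Dmax_Gy", m.Dmax_Gy))
                if m.CI is not None:
                    rows.append((c.plan_id, name, f"{label}_CI", m.CI))
                if m.HI is not None:
                    rows.append((c.plan_id, name, f"{label}_HI", m.HI))
                for lvl, frac in m.V_Gy.items():
                    rows.append((c.plan_id, name, f"{label}_V{lvl:g}Gy", frac))
        if c.flag is not None:
            rows.append((c.plan_id, "plan", "flagged", float(c.flag)))
    return pd.DataFrame(rows, columns=["plan_id", "structure", "metric", "value"])


def write_metrics_report(comparisons: list[PlanComparison], out_dir: str | Path) -> Path:
    """Write detail rows plus a cohort mean +/- SD summary per metric."""
    if not comparisons:
        raise ValueError("no comparisons to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    detail = comparisons_to_frame(comparisons)
    detail.to_csv(out / "metrics_detail.csv", index=False)

    summary = (
        detail.groupby(["structure", "metric"])["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    summary.to_csv(out / "metrics_summary.csv", index=False)
    payload = {
        "n_plans": len(comparisons),
        "summary": summary.to_dict(orient="records"),
    }
    (out / "metrics_summary.json").write_text(json.dumps(payload, indent=2))
    return out
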