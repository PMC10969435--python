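"""Segmentation scoring: Dice similarity, sensitivity sweeps, cohort stats.

The Dice score of two binary masks A (ground truth) and B (prediction)
is ``DS = 2|A ∩ B| / (|A| + |B|)``, equivalently ``2TP / (2TP + FN + FP)``
over the pixel confusion sets; 0 means disjoint, 1 identical.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import BinaryLesionMask

__all__ = [
    "DiceResult",
    "SweepReport",
    "dice",
    "dice_from_counts",
    "k_sensitivity_sweep",
    "resolution_sensitivity_sweep",
    "cohort_summary",
    "results_table",
    "save_results",
    "boxplot_figure",
]


@dataclass
class DiceResult:
    """Dice score plus the pixel confusion counts it derives from."""

    dice: float
    tp: int
    fp: int
    fn: int
    subject: str = ""
    method: str = ""
    k: int | None = None
    resolution: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def dice_from_counts(tp: int, fp: int, fn: int, **meta) -> DiceResult:
    """Dice from confusion counts; both-empty masks score 1 by convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fn + fp
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1 (agreement on absence)")
        return DiceResult(dice=1.0, tp=0, fp=0, fn=0, **meta)
    return DiceResult(dice=2.0 * tp / denom, tp=tp, fp=fp, fn=fn, **meta)


def _mask_array(m) -> np.ndarray:
    if isinstance(m, BinaryLesionMask):
        return m.values
    return np.asarray(m).astype(bool)


def dice(A, B, **meta) -> DiceResult:
    """Dice similarity between ground truth ``A`` and prediction ``B``."""
    a, b = _mask_array(A), _mask_array(B)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    tp = int(np.sum(a & b))
    fp = int(np.sum(~a & b))
    fn = int(np.sum(a & ~b))
    return dice_from_counts(tp, fp, fn, **meta)


@dataclass
class SweepReport:
    """Grid of Dice results along one swept parameter."""

    axis: str  # "k" or "resolution"
    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(self.axis)["dice"]
        return pd.DataFrame({"median": g.median(),
                             "std": g.std(ddof=1).fillna(0.0)})

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"axis": self.axis,
                   "results": self.table.to_dict(orient="records"),
                   "summary": self.summary().reset_index().to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=2))


def k_sensitivity_sweep(vol, method: str, k_values, config=None) -> SweepReport:
    """Re-run the full pipeline for each neighbourhood size K.

    The volume, resolution and seed are held fixed so the only moving
    part is K, mirroring the neighbourhood-size sensitivity analysis.
    """
    from . import pipeline  # local import; pipeline depends on dice above

    cfg = pipeline.RunConfig() if config is None else config
    rows = []
    for k in k_values:
        if k < 1:
            raise ValueError("K values must be >= 1")
        run_cfg = pipeline.replace_config(cfg, method=method, k=int(k))
        res = pipeline.segment_volume(vol, run_cfg)
        rows.append(res.dice_result.as_dict())
    return SweepReport(axis="k", table=pd.DataFrame(rows))


def resolution_sensitivity_sweep(vol, method: str, resolutions,
                                 config=None) -> SweepReport:
    """Re-run the pipeline at each target resolution (e.g. 256/128/64)."""
    from . import pipeline

    cfg = pipeline.RunConfig() if config is None else config
    rows = []
    for r in resolutions:
        run_cfg = pipeline.replace_config(cfg, method=method, resolution=int(r))
        res = pipeline.segment_volume(vol, run_cfg)
        rows.append(res.dice_result.as_dict())
    return SweepReport(axis="resolution", table=pd.DataFrame(rows))


def cohort_summary(dice_values) -> tuple[float, float]:
    """Median and sample (n-1) standard deviation over subjects."""
    vals = [d.dice if isinstance(d, DiceResult) else float(d) for d in dice_values]
    if not vals:
        raise ValueError("empty result list")
    arr = np.asarray(vals, dtype=np.float64)
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(np.median(arr)), std


def results_table(results) -> pd.DataFrame:
    """Tabulate DiceResults (subject, method, k, resolution, tp/fp/fn, dice)."""
    return pd.DataFrame([r.as_dict() for r in results])


def save_results(results, csv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> pd.DataFrame:
    df = results_table(results)
    med, std = cohort_summary(list(df["dice"]))
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(
            {"results": df.to_dict(orient="records"),
             "summary": {"median_dice": med, "std_dice": std,
                         "n": int(len(df))}}, indent=2))
    return df


def boxplot_figure(results_by_method: dict[str, list], path: str | Path) -> None:
    """Box plot of per-subject Dice scores, one box per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(results_by_method)
    data = [[r.dice if isinstance(r, DiceResult) else float(r)
             for r in results_by_method[m]] for m in labels]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("Dice similarity")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
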