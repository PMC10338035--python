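"""Relative telomere length (T/S) from triplicate qPCR well data.

The model is the standard efficiency-corrected, calibrator-normalized
relative quantification scheme: each well's relative quantity is
``Q = (1+E)^(Cq_ref − Cq)`` against the run's inter-run-calibrator mean for
the same target; replicate quantities are averaged per sample; the T/S
ratio is referenced to the geometric mean of the run's calibrator ratios
(removing inter-run shifts) and finally to the cohort-average T/S, so the
sample-set mean of the reported relative T/S equals 1. Replicate CVs are
reported on the quantity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class QPCRError(ValueError):
    """Raised for malformed or insufficient well tables."""


@dataclass
class EfficiencyFit:
    efficiency: float  # proportion; 1.0 = perfect doubling
    slope: float  # Cq per log10(input)
    r_squared: float
    n_points: int


@dataclass
class TelomereResult:
    sample_id: str
    ts_ratio: float
    relative_ts: float
    replicate_cv_t: float  # %
    replicate_cv_s: float  # %
    cv_ts: float  # %
    flagged: bool = False


def estimate_efficiency(standards: pd.DataFrame, target: str) -> EfficiencyFit:
    """PCR efficiency from a serial-dilution standard curve.

    Fits Cq against log10(input quantity) by least squares;
    ``E = 10^(−1/slope) − 1``. Requires ≥3 distinct dilution points with
    positive input quantities and a monotone decreasing mean Cq.
    """
    df = standards[(standards["target"] == target) & (standards["role"] == "dilution_standard")]
    df = df.dropna(subset=["input_quantity", "cq"])
    if (df["input_quantity"] <= 0).any():
        raise QPCRError(f"non-positive standard input quantity for target {target!r}")
    level_means = df.groupby("input_quantity")["cq"].mean().sort_index()
    if len(level_means) < 3:
        raise QPCRError(f"need >=3 dilution points for target {target!r}, got {len(level_means)}")
    if not level_means.is_monotonic_decreasing:
        raise QPCRError(f"standard curve for target {target!r} is not monotone in input quantity")
    x = np.log10(df["input_quantity"].to_numpy())
    y = df["cq"].to_numpy()
    fit = stats.linregress(x, y)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyFit(
        efficiency=float(efficiency), slope=float(fit.slope), r_squared=float(fit.rvalue**2), n_points=len(level_means)
    )


def _cv_percent(values: np.ndarray) -> float:
    m = float(np.mean(values))
    if m == 0:
        return float("nan")
    return float(np.std(values, ddof=1) / m * 100.0) if len(values) > 1 else 0.0


def relative_ts(
    wells: pd.DataFrame, efficiencies: dict[str, float] | None = None
) -> list[TelomereResult]:
    """Per-child relative T/S ratios from a full well table.

    Steps: (1) per-target efficiencies from the dilution standards (unless
    supplied); (2) per well, ``Q = (1+E)^(Cq_cal − Cq)`` with ``Cq_cal`` the
    run's calibrator-mean Cq for that target; (3) replicate Qs averaged per
    (sample, target); (4) ``ts = Q_T / Q_S`` divided by the geometric mean
    of the run's calibrator ts values; (5) referenced to the cohort mean so
    the reported values average 1. Samples with <2 replicates on either
    target are flagged.
    """
    required = {"sample_id", "target", "run_id", "replicate_index", "cq", "role"}
    missing = required - set(wells.columns)
    if missing:
        raise QPCRError(f"well table is missing columns: {sorted(missing)}")
    if efficiencies is None:
        efficiencies = {t: estimate_efficiency(wells, t).efficiency for t in ("T", "S")}

    results: dict[str, dict] = {}
    run_cal_ts: dict[str, float] = {}
    sample_runs: dict[str, str] = {}

    for run_id, run_df in wells.groupby("run_id"):
        cal = run_df[run_df["role"] == "inter_run_calibrator"]
        if cal.empty or set(cal["target"]) < {"T", "S"}:
            raise QPCRError(f"run {run_id!r} lacks inter-run calibrators on both targets")
        cal_cq = cal.groupby("target")["cq"].mean()

        def quantities(df: pd.DataFrame, target: str) -> pd.Series:
            sub = df[df["target"] == target]
            e = efficiencies[target]
            return pd.Series(
                (1.0 + e) ** (cal_cq[target] - sub["cq"].to_numpy()),
                index=pd.MultiIndex.from_frame(sub[["sample_id", "replicate_index"]]),
            )

        # inter-run calibration factor: geometric mean of calibrator T/S ratios
        cal_qt = quantities(cal, "T").groupby("sample_id").mean()
        cal_qs = quantities(cal, "S").groupby("sample_id").mean()
        cal_ratio = (cal_qt / cal_qs).dropna()
        run_cal_ts[run_id] = float(np.exp(np.mean(np.log(cal_ratio))))

        samples = run_df[run_df["role"] == "sample"]
        qt = quantities(samples, "T")
        qs = quantities(samples, "S")
        for sid in samples["sample_id"].unique():
            t_reps = qt.xs(sid, level="sample_id")
            s_reps = qs.xs(sid, level="sample_id")
            flagged = len(t_reps) < 2 or len(s_reps) < 2
            # replicate-wise T/S for the ratio CV, paired on replicate index
            paired = pd.concat([t_reps.rename("t"), s_reps.rename("s")], axis=1).dropna()
            ratio_reps = (paired["t"] / paired["s"]).to_numpy()
            results[sid] = {
                "ts": float(t_reps.mean() / s_reps.mean()),
                "cv_t": _cv_percent(t_reps.to_numpy()),
                "cv_s": _cv_percent(s_reps.to_numpy()),
                "cv_ts": _cv_percent(ratio_reps) if len(ratio_reps) else float("nan"),
                "flagged": flagged,
            }
            sample_runs[sid] = run_id

    if not results:
        raise QPCRError("no sample wells found")
    # divide by run calibration, then reference to the cohort average
    for sid, rec in results.items():
        rec["ts"] /= run_cal_ts[sample_runs[sid]]
    cohort_mean = float(np.mean([rec["ts"] for rec in results.values()]))
    out = [
        TelomereResult(
            sample_id=sid,
            ts_ratio=rec["ts"],
            relative_ts=rec["ts"] / cohort_mean,
            replicate_cv_t=rec["cv_t"],
            replicate_cv_s=rec["cv_s"],
            cv_ts=rec["cv_ts"],
            flagged=rec["flagged"],
        )
        for sid, rec in sorted(results.items())
    ]
    return out


def results_frame(results: list[TelomereResult]) -> pd.DataFrame:
    """Tidy one-row-per-child results table."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "ts_ratio": [r.ts_ratio for r in results],
            "relative_ts": [r.relative_ts for r in results],
            "replicate_cv_t": [r.replicate_cv_t for r in results],
            "replicate_cv_s": [r.replicate_cv_s for r in results],
            "cv_ts": [r.cv_ts for r in results],
            "flagged": [r.flagged for r in results],
        }
    ).set_index("sample_id")
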