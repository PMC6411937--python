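"""RNase titration design and digestion-optimization analysis.

An RNase titration escalates enzyme amounts geometrically (default
5-fold per step, RNase A and T1 in a fixed cocktail ratio) over a fixed
RNA input, then reads out footprint QC at each step.  Because
incomplete digestion leaves GC-rich, longer footprints, both the
windowed GC content and the modal footprint length fall as enzyme
concentration rises; their Pearson correlation against the log-scale
concentration axis quantifies the trend, and the optimal condition is
the mildest step that reaches target GC (~50%) and length (28-29 nt)
without disassembling monosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qc import QCReport

__all__ = [
    "TitrationDesign",
    "TitrationCorrelations",
    "TitrationResult",
    "plan_titration",
    "correlate_metrics",
    "recommend_condition",
    "analyze_titration",
]


@dataclass(frozen=True)
class TitrationDesign:
    """Geometric titration of an RNase A + T1 cocktail.

    Amounts are per microgram of input RNA (``base_rnaseA`` in ng,
    ``base_rnaseT1`` in units); step k uses base * fold**(k-1).
    ``rna_amount`` (ug), ``volume`` (ml), ``temperature`` (deg C) and
    ``minutes`` record the fixed reaction conditions.
    """

    base_rnaseA: float = 4.8
    base_rnaseT1: float = 0.6
    fold: float = 5.0
    steps: int = 5
    rna_amount: float = 2.0
    volume: float = 0.3
    temperature: float = 25.0
    minutes: int = 30

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")
        for name in ("base_rnaseA", "base_rnaseT1", "rna_amount", "volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def plan_titration(design: TitrationDesign) -> pd.DataFrame:
    """Per-step enzyme amounts: per-ug doses and absolute amounts in the
    reaction (dose x RNA amount).  Consecutive steps differ by exactly
    ``design.fold``."""
    steps = np.arange(1, design.steps + 1)
    factor = design.fold ** (steps - 1.0)
    return pd.DataFrame(
        {
            "step": steps,
            "rnaseA_ng_per_ug": design.base_rnaseA * factor,
            "rnaseT1_U_per_ug": design.base_rnaseT1 * factor,
            "rnaseA_ng_total": design.base_rnaseA * factor * design.rna_amount,
            "rnaseT1_U_total": design.base_rnaseT1 * factor * design.rna_amount,
        }
    )


@dataclass(frozen=True)
class TitrationCorrelations:
    """Pearson r of QC metrics against the log-fold concentration axis
    (None when a metric has zero variance across steps)."""

    gc_r: float | None
    length_r: float | None


def correlate_metrics(
    results: Sequence[tuple[int, QCReport]], fold: float = 5.0
) -> TitrationCorrelations:
    """Correlate windowed GC and peak length with log-scale concentration.

    The concentration at step k is fold**(k-1), so its log base ``fold``
    is simply k-1; Pearson r is computed against that axis.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 steps to correlate")
    steps = np.array([float(k) - 1.0 for k, _ in results])  # log_fold(fold**(k-1))
    gc = np.array([r.gc_window_mean for _, r in results])
    length = np.array([float(r.length_peak) for _, r in results])

    def _pearson(y: np.ndarray, label: str) -> float | None:
        if np.ptp(y) == 0 or np.ptp(steps) == 0:
            warnings.warn(f"{label} has zero variance across steps; correlation undefined")
            return None
        return float(stats.pearsonr(steps, y).statistic)

    return TitrationCorrelations(
        gc_r=_pearson(gc, "windowed GC"), length_r=_pearson(length, "length peak")
    )


def recommend_condition(
    results: Sequence[tuple[int, QCReport]],
    disassembly_flags: Sequence[bool],
    gc_target: float = 50.0,
    length_target: int = 28,
    gc_tolerance: float = 2.0,
    length_extra: int = 1,
) -> tuple[int, str]:
    """Recommend the mildest digestion step meeting the QC targets.

    A step qualifies when its windowed GC is within ``gc_tolerance``
    points of ``gc_target``, its peak length is in
    [length_target, length_target + length_extra], and its monosomes
    are not disassembled (operator-supplied flags from sucrose-gradient
    inspection).  The lowest qualifying step is recommended; if none
    qualifies, the highest non-disassembled step is returned with a
    warning in the rationale.
    """
    if len(disassembly_flags) != len(results):
        raise ValueError("need one disassembly flag per step")
    ordered = sorted(zip(results, disassembly_flags), key=lambda x: x[0][0])
    for (step, report), disassembled in ordered:
        if disassembled:
            continue
        gc_ok = abs(report.gc_window_mean - gc_target) <= gc_tolerance
        len_ok = length_target <= report.length_peak <= length_target + length_extra
        if gc_ok and len_ok:
            return step, (
                f"step {step}: GC {report.gc_window_mean:.1f}% within +/-{gc_tolerance} of "
                f"{gc_target}%, peak length {report.length_peak} nt in "
                f"[{length_target}, {length_target + length_extra}], monosomes intact"
            )
    intact = [step for (step, _), d in ordered if not d]
    if not intact:
        raise ValueError("every step shows monosome disassembly; no condition is usable")
    step = max(intact)
    return step, (
        f"WARNING: no step met GC {gc_target}+/-{gc_tolerance}% and length "
        f"[{length_target}, {length_target + length_extra}] without disassembly; "
        f"falling back to the highest intact step {step} — consider extending the titration"
    )


@dataclass(frozen=True)
class TitrationResult:
    """Bundled titration analysis: plan, per-step QC, correlations and
    the recommended condition."""

    plan: pd.DataFrame
    reports: tuple[tuple[int, QCReport], ...]
    correlations: TitrationCorrelations
    recommended_step: int
    rationale: str


def analyze_titration(
    design: TitrationDesign,
    reports: Sequence[tuple[int, QCReport]],
    disassembly_flags: Sequence[bool],
    gc_target: float = 50.0,
    length_target: int = 28,
) -> TitrationResult:
    corr = correlate_metrics(reports, fold=design.fold)
    step, rationale = recommend_condition(
        reports, disassembly_flags, gc_target=gc_target, length_target=length_target
    )
    return TitrationResult(
        plan=plan_titration(design),
        reports=tuple(reports),
        correlations=corr,
        recommended_step=step,
        rationale=rationale,
    )
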