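"""Comparison of posterior rate estimates with independent rate measurements.

Degradation, transcription and translation rates measured in separate
studies never enter the likelihood; they are compared post hoc to the
model's estimates.  Transcription in the model splits into basal and
factor-induced parts, so the comparable quantity is the *time-averaged
total* transcription rate of each gene over two cell cycles.  Agreement is
judged on log10 scale: a difference below 0.5 counts as matching in order
of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec, ParameterVector, compile_rates
from .simulate import TrajectorySet, time_average

__all__ = [
    "ValidationRates",
    "RATE_KINDS",
    "time_avg_transcription_rate",
    "map_estimate",
    "compare_to_validation",
]

RATE_KINDS = ("mrna_degradation", "transcription", "translation")
VR_COLUMNS = ("kind", "gene", "value", "units", "source")

_EXPECTED_UNITS = {
    "mrna_degradation": "1/s",
    "transcription": "uM/s",
    "translation": "1/s",
}


@dataclass
class ValidationRates:
    """Measured rates used only for validation, in model units.

    Columns: kind (one of :data:`RATE_KINDS`), gene (or ``"shared"``),
    value (1/s or uM/s), units, source.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VR_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"validation table missing columns {missing}")
        bad_kind = set(self.records["kind"].unique()) - set(RATE_KINDS)
        if bad_kind:
            raise ValueError(f"unknown rate kinds {sorted(bad_kind)}")
        vals = self.records["value"].to_numpy(dtype=float)
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError("validation rates must be positive and finite")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def time_avg_transcription_rate(
    traj: TrajectorySet, params: ParameterVector, model: ModelSpec, gene: str
) -> float:
    """Time average of a gene's total transcription rate over [0, 2T].

    The instantaneous rate is ``(beta + alpha * P_act(t)) * f_inh(t)``,
    including the time-varying activator concentration and any Hill
    repression, averaged with the same trapezoidal rule as concentrations.
    """
    c = compile_rates(model, params)
    i = model.gene_index(gene)
    horizon = 2.0 * traj.period
    if traj.t[0] > 1e-9 or traj.t[-1] < horizon - 1e-6 * horizon:
        raise ValueError("trajectory must span [0, 2T]")
    rate = np.full(traj.t.size, c.beta[i])
    if c.act_idx[i] >= 0:
        rate = rate + c.alpha[i] * traj.y[model.n_genes + c.act_idx[i]]
    if c.tinh_idx[i] >= 0:
        x = np.maximum(traj.y[model.n_genes + c.tinh_idx[i]], 0.0)
        rate = rate / (1.0 + (x / c.tinh_K[i]) ** c.tinh_h[i])
    mask = traj.t <= horizon + 1e-9
    t = traj.t[mask]
    return float(np.trapezoid(rate[mask], t) / (t[-1] - t[0]))


def map_estimate(draws: np.ndarray, log_posterior: np.ndarray) -> tuple[np.ndarray, int]:
    """Draw with maximal recorded log-posterior density (ties: first).

    Returns the winning draw and its index.
    """
    draws = np.asarray(draws)
    lp = np.asarray(log_posterior, dtype=float)
    if draws.shape[0] == 0:
        raise ValueError("empty draw set")
    if lp.shape[0] != draws.shape[0]:
        raise ValueError("draws and log-posterior lengths differ")
    i = int(np.argmax(lp))
    return draws[i], i


def compare_to_validation(
    estimates: dict[str, float],
    rates: ValidationRates,
    intervals: dict[str, tuple[float, float]] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-record log10 differences between measured and estimated rates.

    ``estimates`` maps record keys to *linear-scale* estimates; keys are
    ``"<kind>:<gene>"`` with fallback to ``"<kind>:shared"`` (the shared
    mRNA-degradation and translation parameters are compared against
    gene-wise measurements).  ``delta = log10(measured) - log10(estimate)``
    and ``|delta| < threshold`` flags order-of-magnitude agreement.  When
    ``intervals`` provides 90% credible intervals (log10 scale, same keys),
    the table also reports whether each measurement falls inside.
    """
    rows = []
    for rec in rates.records.itertuples(index=False):
        if rec.units != _EXPECTED_UNITS[rec.kind]:
            raise ValueError(
                f"unit mismatch for {rec.kind}/{rec.gene} from {rec.source}: "
                f"expected {_EXPECTED_UNITS[rec.kind]}, got {rec.units}"
            )
        key = f"{rec.kind}:{rec.gene}"
        est = estimates.get(key, estimates.get(f"{rec.kind}:shared"))
        if est is None or est <= 0:
            raise ValueError(f"no estimate available for record {key}")
        delta = math.log10(rec.value) - math.log10(est)
        row = {
            "kind": rec.kind,
            "gene": rec.gene,
            "source": rec.source,
            "measured": rec.value,
            "estimate": est,
            "log10_delta": delta,
            "within_order": abs(delta) < threshold,
        }
        if intervals is not None:
            ci = intervals.get(key, intervals.get(f"{rec.kind}:shared"))
            if ci is not None:
                row["in_ci90"] = bool(ci[0] <= math.log10(rec.value) <= ci[1])
        rows.append(row)
    return pd.DataFrame(rows)
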