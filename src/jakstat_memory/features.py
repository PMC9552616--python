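"""Trajectory quantification mirroring the live-cell imaging analysis.

Per-trajectory features are the area under the baseline-subtracted
nuclear STAT1 curve (AUC) over a stated window, the per-pulse peak
amplitudes (P1, P2) and times-to-peak, and the response fraction (peak
amplitude as percent of the peak response to a reference protocol —
throughout the package a single 1 h pulse of 100 ng/ml IFN-γ).

Baseline convention: the value of each trajectory at t = 0, with the
baseline-subtracted series clipped at zero before integration. The
experimental work leaves the AUC baseline undefined; this choice is
recorded in output metadata by the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

#: Detection floor for a "response", as percent of the reference peak.
RESPONSE_FLOOR_PCT = 5.0

#: Standard AUC windows (minutes).
AUC_WINDOW_10H = (0.0, 600.0)
AUC_WINDOW_14H = (0.0, 840.0)
AUC_WINDOW_7H = (0.0, 420.0)


def auc(
    time: np.ndarray,
    series: np.ndarray,
    window: tuple[float, float] | None = None,
    baseline: float = 0.0,
) -> float:
    """Trapezoidal integral of ``max(series - baseline, 0)`` over a window.

    The window must lie within the sampled support; window edges between
    samples are handled by linear interpolation.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    if window is None:
        window = (float(time[0]), float(time[-1]))
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty AUC window")
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9:
        raise ValueError("AUC window outside series support")
    grid = np.unique(np.concatenate([[t0, t1], time[(time > t0) & (time < t1)]]))
    values = np.interp(grid, time, series)
    return float(np.trapezoid(np.clip(values - baseline, 0.0, None), grid))


@dataclass(frozen=True)
class PulsePeak:
    amplitude: float      # baseline-subtracted
    time_to_peak: float   # minutes from the pulse onset


def peaks(
    time: np.ndarray,
    series: np.ndarray,
    pulse_onsets: list[float] | tuple[float, ...],
    baseline: float | None = None,
) -> list[PulsePeak]:
    """Per-pulse peak amplitude and timing.

    The window of pulse *k* runs from its onset to the next onset (or
    the end of the series). Amplitudes are baseline-subtracted and
    clipped at zero; ties are broken by the earliest time.
    """
    if len(pulse_onsets) == 0:
        raise ValueError("at least one pulse onset is required")
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    if baseline is None:
        baseline = float(series[0])
    onsets = list(pulse_onsets) + [float(time[-1]) + 1e-9]
    result = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        mask = (time >= a - 1e-9) & (time <= b + 1e-9)
        if not np.any(mask):
            result.append(PulsePeak(0.0, 0.0))
            continue
        seg = np.clip(series[mask] - baseline, 0.0, None)
        i = int(np.argmax(seg))  # argmax returns the earliest maximiser
        result.append(PulsePeak(float(seg[i]), float(time[mask][i] - a)))
    return result


def response_fraction(peak_amplitude: float, reference_peak: float) -> float:
    """Peak amplitude as a percentage of the reference peak."""
    if reference_peak <= 0:
        raise ValueError("reference peak must be positive")
    return 100.0 * peak_amplitude / reference_peak


def scale_experimental(
    cells: pd.DataFrame,
    simulated_reference_max: float,
    channel: str = "nuclear_stat1",
) -> tuple[pd.DataFrame, float, float]:
    """Rescale arbitrary-unit trajectories to molecule units.

    Mirrors the fluorescence-to-molecules mapping used to compare
    imaging data with simulations: the dataset-wide minimum is
    subtracted (one offset for the whole dataset, not per cell), and a
    single multiplicative factor equates the dataset-wide maximum with
    the maximal simulated nuclear STAT1 across protocols.

    Returns the rescaled table, the offset removed, and the factor.
    """
    df = cells[cells["channel"] == channel].copy()
    if df.empty:
        raise ValueError(f"no rows for channel {channel!r}")
    lo = float(df["value"].min())
    hi = float(df["value"].max())
    if hi - lo <= 0:
        raise ValueError("dataset has zero dynamic range")
    factor = simulated_reference_max / (hi - lo)
    df["value"] = (df["value"] - lo) * factor
    return df, lo, factor


@dataclass(frozen=True)
class TrajectoryFeatures:
    cell_id: str
    protocol_id: str
    auc: float
    p1_amp: float
    p1_time: float
    p2_amp: float
    p2_time: float
    response_pct: float


def extract_features(
    time: np.ndarray,
    series: np.ndarray,
    pulse_onsets,
    reference_peak: float,
    auc_window: tuple[float, float] | None = None,
    cell_id: str = "sim",
    protocol_id: str = "",
) -> TrajectoryFeatures:
    """All scalar features of one trajectory."""
    baseline = float(series[0])
    a = auc(time, series, auc_window, baseline=baseline)
    pk = peaks(time, series, pulse_onsets, baseline=baseline)
    p1 = pk[0]
    p2 = pk[1] if len(pk) > 1 else PulsePeak(0.0, 0.0)
    last_amp = pk[-1].amplitude
    return TrajectoryFeatures(
        cell_id=cell_id,
        protocol_id=protocol_id,
        auc=a,
        p1_amp=p1.amplitude,
        p1_time=p1.time_to_peak,
        p2_amp=p2.amplitude,
        p2_time=p2.time_to_peak,
        response_pct=response_fraction(last_amp, reference_peak),
    )


def summarize_population(
    cells: pd.DataFrame,
    pulse_onsets,
    reference_peak: float,
    auc_window: tuple[float, float] | None = None,
    channel: str = "nuclear_stat1",
    min_cells: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell feature table plus population rank correlations.

    Cells with missing time points (relative to the modal grid) are
    excluded with a warning collected in the report. Correlations are
    Spearman's rank over per-pulse AUCs and over resting level vs AUC;
    with zero variance they are reported as undefined (NaN).
    """
    df = cells[cells["channel"] == channel]
    n_cells_in = df["cell_id"].nunique()
    if n_cells_in < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {n_cells_in}")

    grids = df.groupby("cell_id")["time_min"].count()
    modal = int(grids.mode().iloc[0])
    excluded = grids.index[grids != modal].tolist()

    rows = []
    resting = {}
    p1_aucs, p2_aucs = {}, {}
    split = pulse_onsets[1] if len(pulse_onsets) > 1 else None
    for cell_id, sub in df.groupby("cell_id"):
        if cell_id in excluded:
            continue
        sub = sub.sort_values("time_min")
        t = sub["time_min"].to_numpy(dtype=float)
        v = sub["value"].to_numpy(dtype=float)
        feats = extract_features(
            t, v, pulse_onsets, reference_peak, auc_window,
            cell_id=str(cell_id),
            protocol_id=str(sub["protocol_id"].iloc[0]),
        )
        rows.append(asdict(feats))
        resting[cell_id] = float(v[0])
        if split is not None:
            baseline = float(v[0])
            p1_aucs[cell_id] = auc(t, v, (t[0], split), baseline=baseline)
            p2_aucs[cell_id] = auc(t, v, (split, t[-1]), baseline=baseline)

    table = pd.DataFrame(rows)
    report: dict = {
        "n_cells": len(table),
        "excluded_cells": [str(c) for c in excluded],
        "correlations": {},
    }

    def _spearman(x, y, label):
        x = np.asarray(x)
        y = np.asarray(y)
        if np.std(x) == 0 or np.std(y) == 0 or len(x) < 3:
            report["correlations"][label] = {"r": None, "p": None, "n": len(x),
                                             "note": "undefined (zero variance)"}
            return
        r, pval = spearmanr(x, y)
        report["correlations"][label] = {"r": float(r), "p": float(pval), "n": len(x)}

    ids = table["cell_id"].tolist()
    _spearman(
        [resting[c] for c in ids], table["auc"].to_numpy(), "resting_vs_auc"
    )
    if split is not None:
        _spearman(
            [p1_aucs[c] for c in ids], [p2_aucs[c] for c in ids], "p1_auc_vs_p2_auc"
        )
    return table, report


def write_features(table: pd.DataFrame, path) -> None:
    cols = ["cell_id", "protocol_id", "auc", "p1_amp", "p1_time",
            "p2_amp", "p2_time", "response_pct"]
    table[cols].to_csv(path, index=False)
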