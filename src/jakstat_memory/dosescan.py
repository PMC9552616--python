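"""Two-pulse dose/interval/ligand scans and iso-response analysis.

A scan simulates the response to a first (priming) pulse of dose ``d1``
followed, after a fixed washout-to-onset interval, by a second pulse of
dose ``d2``, over a full grid of dose combinations. Because the state at
the onset of the second pulse depends only on ``d1``, each first leg is
integrated once and reused across the ``d2`` column, which makes the
~5000-combination default grid tractable.

Within a scan the second-pulse amplitude is the response attributable to
the second pulse: the maximal excess of nuclear STAT1 over the dose2 = 0
counterfactual continuation of the same first leg. When the first
response has decayed by the onset (the usual case at 6 h intervals) this
coincides with the t = 0 baseline convention of the feature module; at
short intervals it avoids scoring the decaying tail of the first
response, in either direction, as part of the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features
from .model import ParameterSet, StimulationProtocol, Pulse, resting_state, SPECIES_INDEX
from .simulate import simulate

IFNG = "IFN-gamma"
IFNAB = "IFN-alpha/beta"

#: Default grids: first dose linear in 1 ng/ml steps, second dose
#: log-spaced, together ~5000 combinations over the 1–100 ng/ml range.
DEFAULT_DOSES1 = np.arange(1.0, 101.0, 1.0)
DEFAULT_DOSES2 = np.unique(np.round(np.logspace(0.0, 2.0, 50), 6))

#: dose1 range over which contour fold ratios are averaged.
FOLD_RANGE = (1.0, 30.0)

PULSE_LEN = 60.0
TAIL = 480.0           # simulated time after the onset of the second pulse


@dataclass(frozen=True)
class DoseScanResult:
    """Feature grids from a two-pulse dose scan."""

    doses1: np.ndarray
    doses2: np.ndarray
    interval: float
    ligand1: str
    ligand2: str
    p2_amp: np.ndarray         # (n1, n2) increment above onset level
    p2_pct: np.ndarray         # (n1, n2) percent of reference peak
    auc_fold: np.ndarray       # (n1, n2) total AUC / reference AUC
    ptp_at_p2: np.ndarray      # (n1,) active PTP at second-pulse onset
    reference_peak: float
    reference_auc: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table of the scan grid."""
        i1, i2 = np.meshgrid(
            np.arange(self.doses1.size), np.arange(self.doses2.size), indexing="ij"
        )
        return pd.DataFrame({
            "dose1": self.doses1[i1.ravel()],
            "dose2": self.doses2[i2.ravel()],
            "interval_min": self.interval,
            "ligand1": self.ligand1,
            "ligand2": self.ligand2,
            "p2_pct": self.p2_pct.ravel(),
            "auc_fold": self.auc_fold.ravel(),
            "ptp_at_p2": self.ptp_at_p2[i1.ravel()],
        })


def reference_response(
    params: ParameterSet, horizon: float, dt_out: float = 5.0
) -> tuple[float, float]:
    """Peak and AUC of the single 1 h 100 ng/ml IFN-γ reference pulse."""
    protocol = StimulationProtocol(
        [Pulse(IFNG, 100.0, 0.0, PULSE_LEN)], horizon, name="reference"
    )
    traj = simulate(params, protocol, dt_out=dt_out)
    series = traj.nuclear_stat1
    baseline = series[0]
    peak = float(np.max(series) - baseline)
    auc = features.auc(traj.time, series, baseline=baseline)
    return peak, auc


def two_pulse_scan(
    params: ParameterSet,
    interval: float,
    ligand1: str = IFNG,
    ligand2: str = IFNG,
    doses1: np.ndarray | None = None,
    doses2: np.ndarray | None = None,
    dt_out: float = 5.0,
) -> DoseScanResult:
    """Simulate the full (dose1, dose2) grid at one pulsing interval."""
    doses1 = DEFAULT_DOSES1 if doses1 is None else np.asarray(doses1, dtype=float)
    doses2 = DEFAULT_DOSES2 if doses2 is None else np.asarray(doses2, dtype=float)
    if np.any(doses1 < 0) or np.any(doses2 < 0) or max(doses1.max(), doses2.max()) > 100:
        raise ValueError("dose grids must lie within [0, 100] ng/ml")

    onset2 = PULSE_LEN + interval
    horizon = onset2 + TAIL
    ref_peak, ref_auc = reference_response(params, horizon, dt_out)
    y_rest = resting_state(params)
    baseline0 = float(y_rest @ _nuc_w())

    leg2_protocol_cache: dict[float, StimulationProtocol] = {}

    n1, n2 = doses1.size, doses2.size
    p2_amp = np.zeros((n1, n2))
    p2_pct = np.zeros((n1, n2))
    auc_fold = np.zeros((n1, n2))
    ptp_at_p2 = np.zeros(n1)

    for i, d1 in enumerate(doses1):
        prefix_protocol = StimulationProtocol(
            [Pulse(ligand1, d1, 0.0, PULSE_LEN)] if d1 > 0 else [], onset2
        )
        try:
            prefix = simulate(params, prefix_protocol, dt_out=dt_out, y0=y_rest)
        except Exception as exc:
            raise RuntimeError(
                f"scan failed at dose1={d1} ng/ml (first leg): {exc}"
            ) from exc
        y_onset = prefix.states[-1]
        ptp_at_p2[i] = y_onset[SPECIES_INDEX["PTP_a"]]
        prefix_series = prefix.nuclear_stat1
        prefix_auc = features.auc(prefix.time, prefix_series, baseline=baseline0)

        # dose2 = 0 counterfactual: the decay of the first response
        null_leg = simulate(params, StimulationProtocol([], TAIL),
                            dt_out=dt_out, y0=y_onset)
        null_series = null_leg.nuclear_stat1

        for j, d2 in enumerate(doses2):
            key = d2
            if key not in leg2_protocol_cache:
                leg2_protocol_cache[key] = StimulationProtocol(
                    [Pulse(ligand2, d2, 0.0, PULSE_LEN)] if d2 > 0 else [], TAIL
                )
            try:
                leg2 = simulate(
                    params, leg2_protocol_cache[key], dt_out=dt_out, y0=y_onset
                )
            except Exception as exc:
                raise RuntimeError(
                    f"scan failed at dose pair ({d1}, {d2}) ng/ml: {exc}"
                ) from exc
            series2 = leg2.nuclear_stat1
            amp = max(float(np.max(series2 - null_series)), 0.0)
            p2_amp[i, j] = amp
            p2_pct[i, j] = features.response_fraction(amp, ref_peak)
            total_auc = prefix_auc + features.auc(
                leg2.time + onset2, leg2.nuclear_stat1, baseline=baseline0
            )
            auc_fold[i, j] = total_auc / ref_auc

    return DoseScanResult(
        doses1=doses1, doses2=doses2, interval=interval,
        ligand1=ligand1, ligand2=ligand2,
        p2_amp=p2_amp, p2_pct=p2_pct, auc_fold=auc_fold, ptp_at_p2=ptp_at_p2,
        reference_peak=ref_peak, reference_auc=ref_auc,
    )


def _nuc_w():
    from .model import NUCLEAR_STAT1_WEIGHTS, weight_vector
    return weight_vector(NUCLEAR_STAT1_WEIGHTS)


def crosstalk_scan(
    params: ParameterSet,
    order: str,
    doses1: np.ndarray | None = None,
    doses2: np.ndarray | None = None,
    interval: float = 360.0,
    dt_out: float = 5.0,
) -> DoseScanResult:
    """Mixed-ligand two-pulse scan at a 6 h interval.

    ``order`` is ``"ab->g"`` (IFN-α/β1 priming, IFN-γ challenge) or
    ``"g->ab"`` (the reverse).
    """
    orders = {"ab->g": (IFNAB, IFNG), "g->ab": (IFNG, IFNAB)}
    if order not in orders:
        raise ValueError(f"unknown order {order!r}; expected one of {list(orders)}")
    l1, l2 = orders[order]
    return two_pulse_scan(
        params, interval, ligand1=l1, ligand2=l2,
        doses1=doses1, doses2=doses2, dt_out=dt_out,
    )


def iso_response_contour(
    scan: DoseScanResult, level: float
) -> pd.DataFrame:
    """Dose pairs (dose1, dose2*) at which the response crosses a level.

    ``level`` is in percent of the reference peak and must lie in
    (0, 100). For each first dose, the crossing second dose is
    interpolated on a log-dose scale; first doses where the level is not
    attainable within the grid are omitted. An empty contour (level
    never attained) is returned with a warning.
    """
    if not (0.0 < level < 100.0):
        raise ValueError("contour level must be in (0, 100) percent")
    rows = []
    logd2 = np.log(scan.doses2)
    for i, d1 in enumerate(scan.doses1):
        resp = scan.p2_pct[i]
        if resp.max() < level:
            continue
        if resp[0] >= level:
            rows.append((d1, float(scan.doses2[0])))
            continue
        k = int(np.argmax(resp >= level))  # first index at/above the level
        denom = resp[k] - resp[k - 1]
        f = 1.0 if denom <= 0 else (level - resp[k - 1]) / denom
        rows.append((d1, float(np.exp(logd2[k - 1] + f * (logd2[k] - logd2[k - 1])))))
    if not rows:
        warnings.warn(f"iso-response level {level}% never attained on the grid")
    return pd.DataFrame(rows, columns=["dose1", "dose2"])


@dataclass(frozen=True)
class ContourFold:
    fold: float            # geometric-mean dose2/dose1 along the contour
    slope: float           # unconstrained log-log slope (linearity diagnostic)
    n_points: int
    dose1_range: tuple[float, float]


def contour_fold_ratio(
    contour: pd.DataFrame, dose1_range: tuple[float, float] = FOLD_RANGE
) -> ContourFold:
    """Fold-change ratio of an iso-response contour.

    Fits ``log dose2 = log a + log dose1`` (slope constrained to one)
    over the stated first-dose range and returns the geometric-mean
    ratio ``a``; the unconstrained slope is reported as a linearity
    diagnostic.
    """
    sel = contour[
        (contour["dose1"] >= dose1_range[0]) & (contour["dose1"] <= dose1_range[1])
    ]
    if len(sel) < 3:
        raise ValueError(
            f"contour has {len(sel)} points in dose1 range {dose1_range}; need >= 3"
        )
    logr = np.log(sel["dose2"].to_numpy() / sel["dose1"].to_numpy())
    slope = float(np.polyfit(np.log(sel["dose1"]), np.log(sel["dose2"]), 1)[0])
    return ContourFold(
        fold=float(np.exp(np.mean(logr))),
        slope=slope,
        n_points=len(sel),
        dose1_range=dose1_range,
    )


def min_contour_fold(contour: pd.DataFrame) -> float:
    """Minimum dose2/dose1 ratio along a contour."""
    if contour.empty:
        raise ValueError("empty contour")
    return float((contour["dose2"] / contour["dose1"]).min())


def auc_insensitivity_threshold(
    scan: DoseScanResult, relative_change_criterion: float = 10.0
) -> float:
    """First-pulse dose above which the total AUC is insensitive to dose2.

    For each first dose the relative range (max − min)/max of the total
    AUC across the second-dose grid is computed; the threshold is the
    smallest first dose above which the range stays below the criterion
    (percent), interpolated between grid points. ``inf`` means the
    criterion is never satisfied on the grid (reported as above-grid).
    """
    rel_range = (
        scan.auc_fold.max(axis=1) - scan.auc_fold.min(axis=1)
    ) / scan.auc_fold.max(axis=1) * 100.0
    crit = relative_change_criterion
    below = rel_range < crit
    if not below[-1]:
        return float("inf")
    if below.all():
        return float(scan.doses1[0])
    last_fail = int(np.where(~below)[0][-1])
    d_lo, d_hi = scan.doses1[last_fail], scan.doses1[last_fail + 1]
    r_lo, r_hi = rel_range[last_fail], rel_range[last_fail + 1]
    if r_lo == r_hi:
        return float(d_hi)
    f = (r_lo - crit) / (r_lo - r_hi)
    return float(d_lo + f * (d_hi - d_lo))
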