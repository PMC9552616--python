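"""Optional rendering of scan heat maps and trajectory panels."""

from __future__ import annotations

import numpy as np

from .dosescan import DoseScanResult, iso_response_contour
from .simulate import Trajectory


def plot_scan(scan: DoseScanResult, path, levels=(5.0, 20.0, 50.0)):
    """Heat map of the second-pulse response fraction with iso-response
    contours overlaid, on log-dose axes. Saves to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.0, 4.0))
    mesh = ax.pcolormesh(
        scan.doses1, scan.doses2, scan.p2_pct.T,
        shading="nearest", cmap="viridis", vmin=0.0,
    )
    fig.colorbar(mesh, ax=ax, label="response to 2nd pulse (% of reference)")
    for level in levels:
        contour = iso_response_contour(scan, level)
        if not contour.empty:
            ax.plot(contour["dose1"], contour["dose2"], "k-", lw=1.2)
            ax.annotate(f"{level:.0f}%", (contour["dose1"].iloc[-1],
                                          contour["dose2"].iloc[-1]),
                        fontsize=8, ha="left")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("1st pulse dose (ng/ml)")
    ax.set_ylabel("2nd pulse dose (ng/ml)")
    ax.set_title(f"{scan.ligand1} → {scan.ligand2}, "
                 f"{scan.interval / 60:.0f} h interval")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(traj: Trajectory, path):
    """Nuclear STAT1 and active PTP over time for one simulation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6.0, 4.5))
    ax1.plot(traj.time, traj.nuclear_stat1, "C0-")
    ax1.set_ylabel("nuclear STAT1\n(molecules)")
    ax2.plot(traj.time, traj.active_ptp, "C3-")
    ax2.set_ylabel("active PTP\n(molecules)")
    ax2.set_xlabel("time (min)")
    for ax in (ax1, ax2):
        for pulse in traj.protocol.pulses:
            end = min(pulse.end, traj.time[-1])
            ax.axvspan(pulse.start, end, color="0.85", zorder=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
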