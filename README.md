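# jakstat-memory

Deterministic modelling of interferon-induced JAK-STAT signalling in
innate immune macrophages, centred on the question of how cells *remember*
past cytokine exposure. A brief pulse of IFN-γ leaves macrophages
refractory to restimulation for many hours; the strength of that
refractoriness depends on the dose, timing and type (type I vs type II
interferon) of the first exposure. The package implements the mechanism
that encodes this memory — a slowly-deactivating protein tyrosine
phosphatase (PTP) activated downstream of the receptor — and the full
analysis around it.

## Who this is for

Systems biologists and quantitative immunologists who want to simulate
pulsatile interferon stimulation protocols, reproduce dose–interval
desensitisation analyses, fit the model to their own nuclear-STAT1
trajectory data, or generate realistic synthetic single-cell datasets
for pipeline testing.

## The model

A 37-species, 65-parameter ODE system (time in minutes, abundances in
molecules/cell, ligand in ng/ml):

* **Receptors.** IFN-γ and IFN-α/β1 bind separate receptors:
  free → ligand-bound → active → internalised. Active complexes decay
  with half-lives t½ = 110 min (IFN-γ) and 60 min (IFN-α/β1); the two
  branches share all other rate constants.
* **STAT core.** Active receptors phosphorylate STAT1 (both branches)
  and STAT2 (type I only); pSTAT1 homodimers (the IFN-γ output) and
  pSTAT1–pSTAT2–IRF9 (ISGF3, the type I output) translocate to the
  nucleus, dissociate, are dephosphorylated and exported. The imaging
  readout is nuclear STAT1 in monomer-equivalents
  (2·homodimer + monomers + heterodimer + ISGF3).
* **Negative feedback (the memory).** Inactive PTP is activated by
  active receptor through a delayed three-intermediate relay and
  deactivates with a half-life beyond 24 h. Active PTP (i) inactivates
  receptor complexes and (ii) binds and dephosphorylates cytoplasmic
  phospho-STATs. Residual PTP from a first pulse suppresses the
  response to a second: for a response upon re-exposure the new dose
  must exceed the old one by a *fold* that grows with the waiting time —
  the network reads relative, not absolute, changes of input.
* **Positive feedback.** Nuclear pSTAT1 → IRF1 → inducible STAT1
  synthesis (mild under default calibration).

Desensitisation here is deliberately post-transcriptional: no
SOCS/USP18-type transcriptional feedback is present.

## Worked example

```python
import numpy as np
from jakstat_memory import default_parameters, simulate, two_pulse_protocol
from jakstat_memory import features

params = default_parameters()

# two 1 h pulses of 100 ng/ml IFN-gamma, 6 h washout-to-onset interval
protocol = two_pulse_protocol("IFN-gamma", 100.0, "IFN-gamma", 100.0, 360.0)
traj = simulate(params, protocol)

peaks = features.peaks(traj.time, traj.nuclear_stat1, [0.0, 420.0])
print(f"P1 = {peaks[0].amplitude:.3g} molecules at {peaks[0].time_to_peak:.0f} min")
print(f"P2 = {peaks[1].amplitude:.3g} molecules -> P2/P1 = "
      f"{peaks[1].amplitude / peaks[0].amplitude:.3f}")
```

```
P1 = 1.64e+05 molecules at 70 min
P2 = 1.51e+04 molecules -> P2/P1 = 0.092
```

The first pulse drives a single nuclear STAT1 translocation peaking
~70 min after onset; at the second, six hours later, the cell is
refractory (P2/P1 ≈ 0.09) — the block is the residual activity of the
slowly-deactivating phosphatase. An in-silico knockout confirms it:

```python
from jakstat_memory import apply_knockout
ko = simulate(apply_knockout(params, "PTP"), protocol)
pk = features.peaks(ko.time, ko.nuclear_stat1, [0.0, 420.0])
print(f"PTP knockout: P2/P1 = {pk[1].amplitude / pk[0].amplitude:.2f}")
```

```
PTP knockout: P2/P1 = 1.05
```

Dose–interval scans quantify the memory as iso-response contours
(`jakstat scan --interval 180 --coarse --out out/` from the shell, or
`dosescan.two_pulse_scan` from Python): under the calibrated defaults a
20% response at a 3 h pulsing interval requires ~7-fold dose
escalation, and at 6 h at least ~36-fold; a 1 ng/ml priming pulse
alone cuts the subsequent saturated-pulse peak by ~59%.

## Command line

```
jakstat simulate pulse_100x2_6h --out runs/two_pulse
jakstat scan --interval 180 --out runs/scan3h
jakstat synth --n-cells 200 --seed 1 --out runs/cells
jakstat fit --out runs/fit
jakstat knockout-report --out runs/ko
```

Each command writes CSV/JSON outputs plus a provenance record (config
hash, seed, package version); deterministic runs are byte-reproducible.

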