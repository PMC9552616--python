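"""Core ODE model of type I/II interferon JAK-STAT signalling with PTP feedback.

The model tracks 37 molecular species: extracellular IFN-γ and IFN-α/β1,
their receptor systems (free, ligand-bound, active, internalised), the
STAT1/STAT2 phosphorylation and dimerisation cycle in cytoplasm and
nucleus, the ISGF3 (pSTAT1–pSTAT2–IRF9) branch specific to type I
interferon, a post-transcriptionally activated protein tyrosine
phosphatase (PTP) with a delayed multi-stage activation relay, and the
STAT1 positive feedback through IRF1 transcription.

Kinetics are mass action except for three saturating terms: PTP
activation driven by total active receptor, and the two
transcription-factor occupancy terms (IRF1 on the STAT1 promoter, nuclear
pSTAT1 homodimer on the GAS element of the IRF1 promoter).

The negative feedback enters the network in exactly two places:
active PTP promotes inactivation of active receptor complexes, and
active PTP binds and dephosphorylates cytoplasmic phospho-STATs through
explicit enzyme–substrate complexes — attacking free pSTAT1/pSTAT2 and
the cytoplasmic pSTAT1 homodimer, whose partner protomer is released
(dephosphorylation dissociates STAT complexes).

Units: time in minutes, intracellular species in molecules per cell,
extracellular ligand in ng/ml.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

LN2 = math.log(2.0)

#: Ordered roster of the 37 model species.
SPECIES: tuple[str, ...] = (
    "IFNG_ext",      # 0  extracellular IFN-γ (ng/ml)
    "IFNAB_ext",     # 1  extracellular IFN-α/β1 (ng/ml)
    "Rg",            # 2  free IFN-γ receptor
    "Rg_b",          # 3  ligand-bound (pre-active) IFN-γ receptor complex
    "Rg_a",          # 4  active IFN-γ receptor complex
    "Rg_i",          # 5  internalised IFN-γ receptor complex
    "Ra",            # 6  free IFN-α/β receptor
    "Ra_b",          # 7  ligand-bound (pre-active) IFN-α/β receptor complex
    "Ra_a",          # 8  active IFN-α/β receptor complex
    "Ra_i",          # 9  internalised IFN-α/β receptor complex
    "S1c",           # 10 cytoplasmic STAT1
    "pS1c",          # 11 cytoplasmic phospho-STAT1
    "pS1d_c",        # 12 cytoplasmic pSTAT1 homodimer
    "pS1d_n",        # 13 nuclear pSTAT1 homodimer
    "pS1n",          # 14 nuclear phospho-STAT1 monomer
    "S1n",           # 15 nuclear STAT1
    "S2c",           # 16 cytoplasmic STAT2
    "pS2c",          # 17 cytoplasmic phospho-STAT2
    "pS2n",          # 18 nuclear phospho-STAT2
    "S2n",           # 19 nuclear STAT2
    "Het_c",         # 20 cytoplasmic pSTAT1–pSTAT2 heterodimer
    "Het_n",         # 21 nuclear pSTAT1–pSTAT2 heterodimer
    "IRF9c",         # 22 cytoplasmic IRF9
    "IRF9n",         # 23 nuclear IRF9
    "ISGF3c",        # 24 cytoplasmic ISGF3
    "ISGF3n",        # 25 nuclear ISGF3
    "PTP_i",         # 26 inactive PTP
    "PTP_a1",        # 27 PTP activation intermediate 1
    "PTP_a2",        # 28 PTP activation intermediate 2
    "PTP_a3",        # 29 PTP activation intermediate 3
    "PTP_a",         # 30 active PTP
    "PTP_pS1",       # 31 PTP·pSTAT1 enzyme–substrate complex
    "PTP_pS2",       # 32 PTP·pSTAT2 enzyme–substrate complex
    "mSTAT1",        # 33 STAT1 mRNA
    "mIRF1",         # 34 IRF1 mRNA
    "IRF1",          # 35 IRF1 protein
    "mSTAT2",        # 36 STAT2 mRNA
)

N_SPECIES = len(SPECIES)
SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Ordered roster of the 65 kinetic constants.
PARAM_NAMES: tuple[str, ...] = (
    "k_on",            # 0  ligand–receptor association (1/(ng/ml·min))
    "k_off",           # 1  ligand dissociation from bound complex (1/min)
    "k_act",           # 2  bound-complex activation (1/min)
    "thalf_rg_a",      # 3  active IFN-γ receptor complex half-life (min)
    "thalf_ra_a",      # 4  active IFN-α/β receptor complex half-life (min)
    "k_inh_r",         # 5  PTP-mediated active-receptor inactivation (1/(molec·min))
    "k_int_deg",       # 6  internalised receptor degradation (1/min)
    "k_recyc",         # 7  internalised receptor recycling (1/min)
    "k_syn_rg",        # 8  IFN-γ receptor synthesis (molec/min)
    "k_syn_ra",        # 9  IFN-α/β receptor synthesis (molec/min)
    "k_deg_r",         # 10 free receptor turnover (1/min)
    "conv_g",          # 11 ng/ml → binding-unit conversion, IFN-γ
    "conv_a",          # 12 ng/ml → binding-unit conversion, IFN-α/β
    "k_phos_s1",       # 13 STAT1 phosphorylation by active receptor (1/(molec·min))
    "k_dephos_s1c",    # 14 basal cytoplasmic pSTAT1 dephosphorylation (1/min)
    "k_dim",           # 15 pSTAT1 homodimerisation (1/(molec·min))
    "k_undim",         # 16 cytoplasmic homodimer dissociation (1/min)
    "k_imp_dim",       # 17 homodimer nuclear import (1/min)
    "k_ndiss_dim",     # 18 nuclear homodimer dissociation (1/min)
    "k_ndephos_s1",    # 19 nuclear pSTAT1 dephosphorylation (1/min)
    "k_exp_s1",        # 20 nuclear STAT1 export (1/min)
    "k_imp_s1",        # 21 basal STAT1 nuclear import (1/min)
    "k_tl_s1",         # 22 STAT1 translation (molec/(mRNA·min))
    "k_deg_s1",        # 23 STAT1 protein turnover (1/min)
    "k_phos_s2",       # 24 STAT2 phosphorylation by active type I receptor (1/(molec·min))
    "k_dephos_s2c",    # 25 basal cytoplasmic pSTAT2 dephosphorylation (1/min)
    "k_het",           # 26 pSTAT1–pSTAT2 heterodimerisation (1/(molec·min))
    "k_unhet",         # 27 cytoplasmic heterodimer dissociation (1/min)
    "k_isgf3",         # 28 ISGF3 assembly from heterodimer + IRF9 (1/(molec·min))
    "k_unisgf3",       # 29 cytoplasmic ISGF3 dissociation (1/min)
    "k_imp_het",       # 30 heterodimer nuclear import (1/min)
    "k_imp_isgf3",     # 31 ISGF3 nuclear import (1/min)
    "k_ndiss_isgf3",   # 32 nuclear ISGF3 dissociation (1/min)
    "k_ndiss_het",     # 33 nuclear heterodimer dissociation (1/min)
    "k_ndephos_s2",    # 34 nuclear pSTAT2 dephosphorylation (1/min)
    "k_exp_s2",        # 35 nuclear STAT2 export (1/min)
    "k_imp_s2",        # 36 basal STAT2 nuclear import (1/min)
    "k_tl_s2",         # 37 STAT2 translation (molec/(mRNA·min))
    "k_deg_s2",        # 38 STAT2 protein turnover (1/min)
    "k_syn_irf9",      # 39 IRF9 synthesis (molec/min)
    "k_deg_irf9",      # 40 IRF9 turnover (1/min)
    "k_imp_irf9",      # 41 IRF9 nuclear import (1/min)
    "k_exp_irf9",      # 42 IRF9 nuclear export (1/min)
    "k_ptp_act",       # 43 receptor-driven PTP activation (1/min at saturation)
    "K_ract",          # 44 active-receptor saturation constant for PTP activation (molec)
    "k_chain",         # 45 PTP activation relay rate (1/min)
    "k_ptp_deact",     # 46 active PTP deactivation (1/min)
    "k_ptp_on_s1",     # 47 PTP·pSTAT1 association (1/(molec·min))
    "k_ptp_cat_s1",    # 48 PTP·pSTAT1 catalysis/release (1/min)
    "k_ptp_on_s2",     # 49 PTP·pSTAT2 association (1/(molec·min))
    "k_ptp_cat_s2",    # 50 PTP·pSTAT2 catalysis/release (1/min)
    "ptp_total",       # 51 total PTP pool (molec)
    "k_txn_s1_basal",  # 52 basal STAT1 transcription (mRNA/min)
    "k_txn_s1_irf1",   # 53 IRF1-driven STAT1 transcription (mRNA/min at saturation)
    "K_irf1",          # 54 IRF1 occupancy constant on the STAT1 promoter (molec)
    "k_deg_ms1",       # 55 STAT1 mRNA decay (1/min)
    "k_txn_irf1_basal",# 56 basal IRF1 transcription (mRNA/min)
    "k_txn_irf1_gas",  # 57 GAS-driven IRF1 transcription (mRNA/min at saturation)
    "K_gas",           # 58 nuclear pSTAT1-dimer occupancy constant on GAS (molec)
    "k_deg_mirf1",     # 59 IRF1 mRNA decay (1/min)
    "k_tl_irf1",       # 60 IRF1 translation (molec/(mRNA·min))
    "k_deg_irf1",      # 61 IRF1 protein turnover (1/min)
    "k_txn_s2",        # 62 basal STAT2 transcription (mRNA/min)
    "k_deg_ms2",       # 63 STAT2 mRNA decay (1/min)
    "fluor_scale",     # 64 fluorescence scaling factor (a.u. per molecule)
)

N_PARAMS = len(PARAM_NAMES)
PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_NAMES)}

# Parameters fixed from prior literature rather than fitted here.
LITERATURE_PARAMS = frozenset({"thalf_rg_a", "thalf_ra_a"})

#: Weights of the nuclear STAT1 readout (monomer-equivalents): nuclear
#: homodimers carry two STAT1 molecules, heterodimer/ISGF3 carry one.
NUCLEAR_STAT1_WEIGHTS: dict[str, float] = {
    "pS1d_n": 2.0,
    "pS1n": 1.0,
    "S1n": 1.0,
    "Het_n": 1.0,
    "ISGF3n": 1.0,
}

#: STAT1 monomer-equivalent weights over the full state (conservation oracle).
STAT1_TOTAL_WEIGHTS: dict[str, float] = {
    "S1c": 1.0, "pS1c": 1.0, "pS1d_c": 2.0, "pS1d_n": 2.0,
    "pS1n": 1.0, "S1n": 1.0, "Het_c": 1.0, "Het_n": 1.0,
    "ISGF3c": 1.0, "ISGF3n": 1.0, "PTP_pS1": 1.0,
}

STAT2_TOTAL_WEIGHTS: dict[str, float] = {
    "S2c": 1.0, "pS2c": 1.0, "pS2n": 1.0, "S2n": 1.0,
    "Het_c": 1.0, "Het_n": 1.0, "ISGF3c": 1.0, "ISGF3n": 1.0,
    "PTP_pS2": 1.0,
}

RECEPTOR_G_WEIGHTS = {"Rg": 1.0, "Rg_b": 1.0, "Rg_a": 1.0, "Rg_i": 1.0}
RECEPTOR_A_WEIGHTS = {"Ra": 1.0, "Ra_b": 1.0, "Ra_a": 1.0, "Ra_i": 1.0}


def weight_vector(weights: Mapping[str, float]) -> np.ndarray:
    """Dense weight vector over the species roster for a linear readout."""
    w = np.zeros(N_SPECIES)
    for name, value in weights.items():
        w[SPECIES_INDEX[name]] = value
    return w


class ParameterSet(Mapping[str, float]):
    """Named, validated set of the 65 kinetic constants.

    Behaves as an immutable mapping; use :meth:`replace` to derive
    modified copies. All constants must be finite and non-negative.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = set(PARAM_NAMES) - set(values)
        extra = set(values) - set(PARAM_NAMES)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        if extra:
            raise ValueError(f"unknown parameters: {sorted(extra)}")
        arr = np.array([float(values[name]) for name in PARAM_NAMES])
        if not np.all(np.isfinite(arr)):
            raise ValueError("parameters must be finite")
        if np.any(arr < 0):
            bad = [PARAM_NAMES[i] for i in np.where(arr < 0)[0]]
            raise ValueError(f"parameters must be non-negative: {bad}")
        self._values = arr
        self._values.flags.writeable = False

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self._values[PARAM_INDEX[name]])

    def __iter__(self):
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return N_PARAMS

    def __repr__(self) -> str:
        return f"ParameterSet({len(self)} constants)"

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and np.array_equal(
            self._values, other._values
        )

    # Convenience ------------------------------------------------------
    def to_array(self) -> np.ndarray:
        """Constants as a float vector in canonical order."""
        return self._values.copy()

    def replace(self, **overrides: float) -> "ParameterSet":
        """Copy with the named constants replaced (validated)."""
        values = dict(self)
        for name, value in overrides.items():
            if name not in PARAM_INDEX:
                raise KeyError(f"unknown parameter {name!r}")
            values[name] = value
        return ParameterSet(values)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ParameterSet":
        arr = list(arr)
        if len(arr) != N_PARAMS:
            raise ValueError(f"expected {N_PARAMS} constants, got {len(arr)}")
        return cls(dict(zip(PARAM_NAMES, arr)))


def _rhs_kernel(t, y, p):
    """Right-hand side of the 37-ODE system. Numba-compiled when possible."""
    dy = np.zeros(37)

    dg = LN2 / p[3]          # active IFN-γ complex decay
    da = LN2 / p[4]          # active IFN-α/β complex decay
    ptp_a = y[30]

    # --- IFN-γ receptor system ---------------------------------------
    vb_g = p[0] * p[11] * y[0] * y[2]
    vu_g = p[1] * y[3]
    va_g = p[2] * y[3]
    vd_g = dg * y[4]
    vi_g = p[5] * ptp_a * y[4]          # PTP feedback target 1 (IFN-γ)
    vid_g = p[6] * y[5]
    vr_g = p[7] * y[5]
    dy[2] = -vb_g + vu_g + vr_g + p[8] - p[10] * y[2]
    dy[3] = vb_g - vu_g - va_g
    dy[4] = va_g - vd_g - vi_g
    dy[5] = vd_g + vi_g - vid_g - vr_g

    # --- IFN-α/β receptor system (same kinetics, shorter half-life) ---
    vb_a = p[0] * p[12] * y[1] * y[6]
    vu_a = p[1] * y[7]
    va_a = p[2] * y[7]
    vd_a = da * y[8]
    vi_a = p[5] * ptp_a * y[8]          # PTP feedback target 1 (IFN-α/β)
    vid_a = p[6] * y[9]
    vr_a = p[7] * y[9]
    dy[6] = -vb_a + vu_a + vr_a + p[9] - p[10] * y[6]
    dy[7] = vb_a - vu_a - va_a
    dy[8] = va_a - vd_a - vi_a
    dy[9] = vd_a + vi_a - vid_a - vr_a

    r_act = y[4] + y[8]

    # --- STAT1 cycle ---------------------------------------------------
    vphos1 = p[13] * r_act * y[10]
    vdeph1 = p[14] * y[11]
    vdim = p[15] * y[11] * y[11]
    vundim = p[16] * y[12]
    vimpd = p[17] * y[12]
    vndd = p[18] * y[13]
    vndeph1 = p[19] * y[14]
    vexp1 = p[20] * y[15]
    vimp1 = p[21] * y[10]
    vp1on = p[47] * ptp_a * y[11]       # PTP feedback target 2 (STAT1)
    vp1cat = p[48] * y[31]
    # PTP also attacks the cytoplasmic homodimer: one protomer enters the
    # enzyme-substrate complex, the partner is released phosphorylated
    # (dephosphorylation dissociates STAT complexes)
    vp1don = p[47] * ptp_a * y[12]

    # --- STAT2 / heterodimer / ISGF3 ----------------------------------
    vphos2 = p[24] * y[8] * y[16]
    vdeph2 = p[25] * y[17]
    vhet = p[26] * y[11] * y[17]
    vunhet = p[27] * y[20]
    visg = p[28] * y[20] * y[22]
    vunisg = p[29] * y[24]
    vimph = p[30] * y[20]
    vimpg = p[31] * y[24]
    vndg = p[32] * y[25]
    vndh = p[33] * y[21]
    vndeph2 = p[34] * y[18]
    vexp2 = p[35] * y[19]
    vimp2 = p[36] * y[16]
    vp2on = p[49] * ptp_a * y[17]       # PTP feedback target 2 (STAT2)
    vp2cat = p[50] * y[32]

    dy[10] = (-vphos1 + vdeph1 + vexp1 - vimp1 + p[22] * y[33]
              - p[23] * y[10] + vp1cat)
    dy[11] = (vphos1 - vdeph1 - 2.0 * vdim + 2.0 * vundim - vhet + vunhet
              - vp1on + vp1don)
    dy[12] = vdim - vundim - vimpd - vp1don
    dy[13] = vimpd - vndd
    dy[14] = 2.0 * vndd + vndh - vndeph1
    dy[15] = vndeph1 - vexp1 + vimp1

    dy[16] = (-vphos2 + vdeph2 + vexp2 - vimp2 + p[37] * y[36]
              - p[38] * y[16] + vp2cat)
    dy[17] = vphos2 - vdeph2 - vhet + vunhet - vp2on
    dy[18] = vndh - vndeph2
    dy[19] = vndeph2 + vimp2 - vexp2
    dy[20] = vhet - vunhet - visg + vunisg - vimph
    dy[21] = vimph + vndg - vndh

    vimpi9 = p[41] * y[22]
    vexpi9 = p[42] * y[23]
    dy[22] = p[39] - p[40] * y[22] - visg + vunisg - vimpi9 + vexpi9
    dy[23] = vimpi9 - vexpi9 + vndg
    dy[24] = visg - vunisg - vimpg
    dy[25] = vimpg - vndg

    # --- PTP activation relay and catalytic cycle ---------------------
    w = r_act / (p[44] + r_act)
    vact = p[43] * w * y[26]
    vc1 = p[45] * y[27]
    vc2 = p[45] * y[28]
    vc3 = p[45] * y[29]
    vdeact = p[46] * ptp_a
    dy[26] = -vact + vdeact
    dy[27] = vact - vc1
    dy[28] = vc1 - vc2
    dy[29] = vc2 - vc3
    dy[30] = vc3 - vdeact - vp1on - vp1don + vp1cat - vp2on + vp2cat
    dy[31] = vp1on + vp1don - vp1cat
    dy[32] = vp2on - vp2cat

    # --- transcription / translation ----------------------------------
    occ_irf1 = y[35] / (p[54] + y[35])
    occ_gas = y[13] / (p[58] + y[13])
    dy[33] = p[52] + p[53] * occ_irf1 - p[55] * y[33]
    dy[34] = p[56] + p[57] * occ_gas - p[59] * y[34]
    dy[35] = p[60] * y[34] - p[61] * y[35]
    dy[36] = p[62] - p[63] * y[36]

    # extracellular ligand is clamped by the stimulation protocol
    dy[0] = 0.0
    dy[1] = 0.0
    return dy


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _rhs_compiled = numba.njit(_rhs_kernel, cache=True, fastmath=False)
except Exception:  # pragma: no cover
    _rhs_compiled = _rhs_kernel


def rhs(t: float, state: np.ndarray, params: ParameterSet | np.ndarray) -> np.ndarray:
    """Time derivative of the full state vector.

    Parameters may be given as a :class:`ParameterSet` or as the raw
    canonical-order array (used in inner loops). Raises ``ValueError``
    on non-finite input, which signals solver divergence upstream.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(f"state must have length {N_SPECIES}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs")
    p = params.to_array() if isinstance(params, ParameterSet) else np.asarray(params, dtype=float)
    return _rhs_compiled(float(t), y, p)


def resting_state(params: ParameterSet, tol: float = 1e-8) -> np.ndarray:
    """Unstimulated steady state of the network.

    In the absence of ligand the phosphorylation cycle, the receptor
    intermediates and the PTP relay are empty and the basal
    synthesis/turnover/shuttling balance is linear, so the resting state
    has a closed form. The result is verified against the right-hand
    side; failure to satisfy the steady-state condition raises.
    """
    p = dict(params)
    y = np.zeros(N_SPECIES)
    ix = SPECIES_INDEX

    y[ix["Rg"]] = p["k_syn_rg"] / p["k_deg_r"]
    y[ix["Ra"]] = p["k_syn_ra"] / p["k_deg_r"]

    m_irf1 = p["k_txn_irf1_basal"] / p["k_deg_mirf1"]
    irf1 = p["k_tl_irf1"] * m_irf1 / p["k_deg_irf1"]
    y[ix["mIRF1"]] = m_irf1
    y[ix["IRF1"]] = irf1

    occ = irf1 / (p["K_irf1"] + irf1)
    m_s1 = (p["k_txn_s1_basal"] + p["k_txn_s1_irf1"] * occ) / p["k_deg_ms1"]
    s1c = p["k_tl_s1"] * m_s1 / p["k_deg_s1"]
    y[ix["mSTAT1"]] = m_s1
    y[ix["S1c"]] = s1c
    y[ix["S1n"]] = p["k_imp_s1"] / p["k_exp_s1"] * s1c

    m_s2 = p["k_txn_s2"] / p["k_deg_ms2"]
    s2c = p["k_tl_s2"] * m_s2 / p["k_deg_s2"]
    y[ix["mSTAT2"]] = m_s2
    y[ix["S2c"]] = s2c
    y[ix["S2n"]] = p["k_imp_s2"] / p["k_exp_s2"] * s2c

    irf9c = p["k_syn_irf9"] / p["k_deg_irf9"]
    y[ix["IRF9c"]] = irf9c
    y[ix["IRF9n"]] = p["k_imp_irf9"] / p["k_exp_irf9"] * irf9c

    y[ix["PTP_i"]] = p["ptp_total"]

    scale = max(1.0, float(np.max(np.abs(y))))
    residual = np.max(np.abs(rhs(0.0, y, params)))
    if residual > tol * scale:
        raise RuntimeError(
            f"resting state did not satisfy steady-state condition "
            f"(max |dy/dt| = {residual:.3e}, scale {scale:.3e})"
        )
    return y


KNOCKOUT_TARGETS = ("PTP", "STAT1-induction")


def apply_knockout(params: ParameterSet, target: str) -> ParameterSet:
    """In-silico knockout of a feedback loop.

    ``"PTP"`` removes the negative feedback by zeroing the PTP
    activation relay; ``"STAT1-induction"`` zeroes the inducible
    (IRF1-driven) STAT1 transcription while retaining the basal rate.
    Both operations are idempotent.
    """
    if target == "PTP":
        return params.replace(k_ptp_act=0.0, k_chain=0.0)
    if target == "STAT1-induction":
        return params.replace(k_txn_s1_irf1=0.0)
    raise ValueError(
        f"unknown knockout target {target!r}; expected one of {KNOCKOUT_TARGETS}"
    )


def _manifest_path():
    return importlib.resources.files("jakstat_memory") / "data" / "parameters.yaml"


def default_parameters() -> ParameterSet:
    """The package's calibrated default parameter set.

    Loaded from the bundled YAML manifest, which records name, value,
    units and provenance for each of the 65 constants.
    """
    with _manifest_path().open("r") as fh:
        manifest = yaml.safe_load(fh)
    values = {entry["name"]: entry["value"] for entry in manifest["parameters"]}
    return ParameterSet(values)


def parameter_manifest() -> list[dict]:
    """Full manifest entries (name, value, units, provenance)."""
    with _manifest_path().open("r") as fh:
        return yaml.safe_load(fh)["parameters"]


@dataclass(frozen=True)
class Pulse:
    """A single ligand application.

    ``duration=None`` denotes continuous stimulation (never washed out).
    Washout at the end of a finite pulse is instantaneous.
    """

    ligand: str                  # "IFN-gamma" or "IFN-alpha/beta"
    dose: float                  # ng/ml
    start: float                 # minutes
    duration: float | None = 60.0

    LIGANDS = ("IFN-gamma", "IFN-alpha/beta")

    def __post_init__(self):
        if self.ligand not in self.LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.start < 0:
            raise ValueError("pulse start must be non-negative")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("pulse duration must be positive (or None)")

    @property
    def end(self) -> float:
        return math.inf if self.duration is None else self.start + self.duration


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered schedule of ligand pulses over a finite horizon.

    Doses of simultaneously active pulses of the same ligand sum.
    The pulsing-interval convention throughout the package is
    end-of-previous-pulse to start-of-next-pulse.
    """

    pulses: tuple[Pulse, ...]
    horizon: float               # minutes
    name: str = ""

    def __init__(self, pulses: Iterable[Pulse], horizon: float, name: str = ""):
        pulses = tuple(pulses)
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        object.__setattr__(self, "pulses", tuple(sorted(pulses, key=lambda q: q.start)))
        object.__setattr__(self, "horizon", float(horizon))
        object.__setattr__(self, "name", name)

    def ligand_levels(self, t: float) -> tuple[float, float]:
        """(IFN-γ, IFN-α/β) concentrations in ng/ml at time ``t``."""
        g = a = 0.0
        for q in self.pulses:
            if q.start <= t < q.end:
                if q.ligand == "IFN-gamma":
                    g += q.dose
                else:
                    a += q.dose
        return g, a

    def boundaries(self) -> list[float]:
        """Sorted pulse edges within the horizon (integration restart points)."""
        edges = {0.0, self.horizon}
        for q in self.pulses:
            if q.start < self.horizon:
                edges.add(q.start)
            if math.isfinite(q.end) and q.end < self.horizon:
                edges.add(q.end)
        return sorted(edges)


def two_pulse_protocol(
    ligand1: str,
    dose1: float,
    ligand2: str,
    dose2: float,
    interval: float,
    pulse_length: float = 60.0,
    horizon: float | None = None,
    name: str = "",
) -> StimulationProtocol:
    """Two-pulse protocol with the interval measured washout-to-onset."""
    start2 = pulse_length + interval
    if horizon is None:
        horizon = start2 + pulse_length + 420.0
    pulses = []
    if dose1 > 0:
        pulses.append(Pulse(ligand1, dose1, 0.0, pulse_length))
    if dose2 > 0:
        pulses.append(Pulse(ligand2, dose2, start2, pulse_length))
    return StimulationProtocol(pulses, horizon, name=name)


def single_pulse_protocol(
    ligand: str,
    dose: float,
    pulse_length: float | None = 60.0,
    horizon: float = 840.0,
    name: str = "",
) -> StimulationProtocol:
    pulses = [Pulse(ligand, dose, 0.0, pulse_length)] if dose > 0 else []
    return StimulationProtocol(pulses, horizon, name=name)
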