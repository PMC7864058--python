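"""Paramagnetic relaxation enhancement (PRE) analysis.

Gamma2 PREs are PARA-minus-DIA amide-proton transverse rate differences.
Residues broadened below detection in the PARA spectrum carry an OVERFLOW
flag: they are qualitative "very close to the spin label" data and never
enter threshold statistics. Significance thresholds come from a three-pass
trimmed mean/SD procedure; the Solomon-Bloembergen forward model with
<r^-6> ensemble averaging back-calculates Gamma2 from distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import SBConstants
from .data_model import MISSING, OK, OVERFLOW, QUANTIFIED, ResidueID

__all__ = [
    "PREValue",
    "PREThreshold",
    "compute_gamma2",
    "flag_disappeared",
    "twice_filtered_threshold",
    "delta_gamma2",
    "classify_significant",
    "sb_gamma2",
    "ensemble_gamma2",
]


@dataclass
class PREValue:
    """Gamma2(1HN) for one residue, rad/s, with status flag."""

    residue: ResidueID
    gamma2: float
    sigma: float
    status: str = QUANTIFIED

    def __post_init__(self):
        if self.status == QUANTIFIED and self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class PREThreshold:
    """Trimmed mean/SD significance bounds: M3 +/- 2*STD3."""

    m3: float
    std3: float
    n_core: int
    passes: list = field(default_factory=list)  # (mean, sd, n) per pass

    @property
    def upper(self) -> float:
        return self.m3 + 2.0 * self.std3

    @property
    def lower(self) -> float:
        return self.m3 - 2.0 * self.std3


def compute_gamma2(para, dia) -> list[PREValue]:
    """Gamma2 = R2,PARA - R2,DIA per matched residue.

    sigma_Gamma is the quadrature sum of the two rate uncertainties. PARA
    OVERFLOW propagates to PREValue OVERFLOW (no numeric Gamma2); MISSING in
    either state propagates MISSING.
    """
    para_by_res = {r.residue.index: r for r in para}
    dia_by_res = {r.residue.index: r for r in dia}
    out = []
    for idx in sorted(set(para_by_res) & set(dia_by_res)):
        p, d = para_by_res[idx], dia_by_res[idx]
        if p.status == MISSING or d.status == MISSING or d.status == OVERFLOW:
            out.append(PREValue(p.residue, np.nan, np.nan, status=MISSING))
        elif p.status == OVERFLOW:
            out.append(PREValue(p.residue, np.nan, np.nan, status=OVERFLOW))
        else:
            out.append(
                PREValue(
                    p.residue,
                    float(p.rate - d.rate),
                    float(np.hypot(p.sigma, d.sigma)),
                    status=QUANTIFIED,
                )
            )
    return out


def flag_disappeared(
    dia_peaks: dict, para_peaks: dict, noise_floor: float, k: float = 3.0
) -> dict[int, str]:
    """Classify residues by per-residue maximum peak intensity.

    OVERFLOW iff the DIA peak is detectable (> k * noise_floor) while the
    PARA peak is not; MISSING if absent in both; QUANTIFIED otherwise.
    """
    if noise_floor <= 0:
        raise ValueError("noise_floor must be positive")
    cut = k * noise_floor
    status = {}
    for idx in sorted(set(dia_peaks) & set(para_peaks)):
        dia_ok = dia_peaks[idx] > cut
        para_ok = para_peaks[idx] > cut
        if dia_ok and not para_ok:
            status[idx] = OVERFLOW
        elif not dia_ok:
            status[idx] = MISSING
        else:
            status[idx] = QUANTIFIED
    return status


def twice_filtered_threshold(values) -> PREThreshold:
    """Three-pass trimmed significance bounds.

    Pass 1: mean M1 and sample SD STD1 (ddof=1) of all values; drop values
    strictly outside [M1-STD1, M1+STD1]. Pass 2: likewise with M2, STD2 on
    the survivors. Pass 3: M3, STD3 on the core; the bounds are M3 +/- 2*STD3.
    Values equal to a filter bound are kept.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise ValueError("need >= 3 finite values")
    passes = []
    core = vals
    for pass_idx in (1, 2):
        m = float(np.mean(core))
        sd = float(np.std(core, ddof=1))
        passes.append((m, sd, core.size))
        # ulp-scaled slack so that exactly-equal values survive a zero-SD
        # filter even when the mean rounds one ulp away
        eps = 4 * np.finfo(float).eps * np.maximum(np.abs(core), abs(m))
        keep = (core >= m - sd - eps) & (core <= m + sd + eps)
        core = core[keep]
        if core.size == 0:
            raise ValueError(f"threshold core emptied at pass {pass_idx}")
    m3 = float(np.mean(core))
    std3 = float(np.std(core, ddof=1)) if core.size > 1 else 0.0
    passes.append((m3, std3, core.size))
    return PREThreshold(m3=m3, std3=std3, n_core=int(core.size), passes=passes)


def delta_gamma2(apo, cdc):
    """Per-residue Delta-Gamma2 = Gamma2,apo - Gamma2,bound plus its trimmed
    threshold, and a qualitative table for residues OVERFLOW in either state.

    Returns (delta_values, threshold, qualitative) where qualitative maps
    residue index -> "reappeared" (apo OVERFLOW only, i.e. contact lost on
    binding), "disappeared" (bound OVERFLOW only) or "overflow_both".
    """
    apo_by_res = {v.residue.index: v for v in apo}
    cdc_by_res = {v.residue.index: v for v in cdc}
    deltas, qualitative = [], {}
    for idx in sorted(set(apo_by_res) & set(cdc_by_res)):
        a, c = apo_by_res[idx], cdc_by_res[idx]
        if a.status == OVERFLOW or c.status == OVERFLOW:
            if a.status == OVERFLOW and c.status == OVERFLOW:
                qualitative[idx] = "overflow_both"
            elif a.status == OVERFLOW:
                qualitative[idx] = "reappeared"
            else:
                qualitative[idx] = "disappeared"
        elif a.status == QUANTIFIED and c.status == QUANTIFIED:
            deltas.append(
                PREValue(
                    a.residue,
                    float(a.gamma2 - c.gamma2),
                    float(np.hypot(a.sigma, c.sigma)),
                    status=QUANTIFIED,
                )
            )
    if len(deltas) < 3:
        raise ValueError("fewer than 3 matched quantified residues")
    thr = twice_filtered_threshold([d.gamma2 for d in deltas])
    return deltas, thr, qualitative


def classify_significant(
    values, threshold: PREThreshold, two_sided: bool = False
) -> dict[int, str]:
    """Per-residue significance flags against a trimmed threshold.

    Gamma2 profiles use the strict upper bound only; difference profiles
    (two_sided=True) flag values strictly outside [lower, upper]. OVERFLOW
    entries are always reported as qualitatively significant.
    """
    flags = {}
    for v in values:
        if v.status == OVERFLOW:
            flags[v.residue.index] = "significant-qualitative"
        elif v.status == QUANTIFIED:
            if two_sided:
                sig = v.gamma2 > threshold.upper or v.gamma2 < threshold.lower
            else:
                sig = v.gamma2 > threshold.upper
            flags[v.residue.index] = "significant" if sig else "ns"
        else:
            flags[v.residue.index] = "missing"
    return flags


def compose_tauc(tau_r: float, tau_elec: float) -> float:
    """Effective correlation time: 1/tau_c = 1/tau_R + 1/tau_elec."""
    if tau_r <= 0 or tau_elec <= 0:
        raise ValueError("correlation times must be positive")
    return 1.0 / (1.0 / tau_r + 1.0 / tau_elec)


def sb_gamma2(
    r_is: float, tau_c: float, constants: SBConstants = SBConstants()
) -> float:
    """Solomon-Bloembergen transverse PRE for a single electron-proton
    distance.

    Gamma2 = K S(S+1) (g mu_B gamma_I)^2 / 15 * r^-6
             * [4 tau_c + 3 tau_c / (1 + (omega_H tau_c)^2)]

    with r_is in Å, tau_c in seconds, K the unit-system prefactor
    ((mu0/4pi)^2 in SI). Result in rad/s.
    """
    if r_is <= 0 or tau_c <= 0:
        raise ValueError("r_is and tau_c must be positive")
    r_m = r_is * 1e-10
    return _sb_from_inv_r6(r_m**-6, tau_c, constants)


def _sb_from_inv_r6(inv_r6_m, tau_c: float, constants: SBConstants) -> float:
    w = constants.omega_h
    spectral = 4.0 * tau_c + 3.0 * tau_c / (1.0 + (w * tau_c) ** 2)
    amp = (
        constants.prefactor
        * constants.s_spin
        * (constants.s_spin + 1.0)
        * (constants.g * constants.mu_b * constants.gamma_i) ** 2
        / 15.0
    )
    return float(amp * inv_r6_m * spectral)


def ensemble_gamma2(
    distance_series,
    tau_c: float,
    weights=None,
    constants: SBConstants = SBConstants(),
) -> float:
    """Gamma2 with <r^-6> = sum_f w_f r_f^-6 substituted into the
    Solomon-Bloembergen expression. Distances in Å; uniform weights by
    default. Weights are normalized to sum to one."""
    r = np.asarray(distance_series, dtype=float)
    if r.size == 0:
        raise ValueError("empty distance series")
    if np.any(r <= 0):
        raise ValueError("all distances must be positive")
    if weights is None:
        w = np.full(r.size, 1.0 / r.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != r.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and match distances")
        w = w / w.sum()
    inv_r6_m = float(np.sum(w * (r * 1e-10) ** -6))
    return _sb_from_inv_r6(inv_r6_m, tau_c, constants)
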