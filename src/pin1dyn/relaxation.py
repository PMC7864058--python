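"""Relaxation-decay fitting, Monte-Carlo uncertainties, domain-mobility
regression, J_eff(0)/tau_c conversion, and combined chemical-shift
perturbations.

Peak intensities are fitted to monoexponential decays I(t) = I0 exp(-R t).
The apo-vs-bound R2-R1/2 regression quantifies relative rotational mobility
of the two domains: a shallower slope for one domain means its rotational
mobility increased more upon complex formation than the other's.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import NMRConstants
from .data_model import (
    LINKER,
    MISSING,
    OK,
    DecaySeries,
    RateEstimate,
    ResidueID,
    ShiftPerturbation,
)

__all__ = [
    "MobilityFit",
    "SpectralDensityResult",
    "fit_monoexponential",
    "estimate_noise",
    "monte_carlo_uncertainty",
    "mobility_regression",
    "jeff0_tauc",
    "combined_csp",
]

#: 15N-to-1H shift weighting in the combined amide CSP
CSP_WEIGHT = 0.154


@dataclass
class MobilityFit:
    """Per-domain OLS fit of bound-state R2-R1/2 against apo-state values."""

    domain: str
    slope: float
    intercept: float
    corr_coeff: float
    n: int
    outliers: list = field(default_factory=list)
    residues: list = field(default_factory=list)


@dataclass
class SpectralDensityResult:
    residue: ResidueID
    jeff0: float  # s/rad
    tau_c: float  # s
    c_n: float
    d_in: float


def _monoexp(t, a, r):
    return a * np.exp(-r * t)


def fit_monoexponential(series: DecaySeries) -> RateEstimate:
    """Least-squares fit of I(t) = I0 exp(-R t); initial guess from a
    log-linear regression on the positive intensities.

    Non-convergence or a non-positive fitted rate yields status MISSING.
    """
    t = series.delays
    y = series.intensities
    if np.allclose(y, y[0]):
        raise ValueError(
            f"residue {series.residue.index}: constant intensities, rate undefined"
        )
    pos = y > 0
    if pos.sum() >= 2:
        b, a = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(a)), float(max(-b, 1e-6)))
    else:
        p0 = (float(np.max(np.abs(y))), 1.0 / float(np.mean(t)))
    try:
        popt, pcov = curve_fit(_monoexp, t, y, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return RateEstimate(
            series.residue, np.nan, np.nan, status=MISSING, amplitude=np.nan
        )
    a_hat, r_hat = popt
    if not np.isfinite(r_hat) or r_hat <= 0:
        return RateEstimate(
            series.residue, np.nan, np.nan, status=MISSING, amplitude=a_hat
        )
    sig = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else 0.0
    return RateEstimate(
        series.residue, float(r_hat), sig, status=OK, amplitude=float(a_hat)
    )


def estimate_noise(series_set) -> float:
    """Pooled intensity noise from duplicate delays: sigma = RMS/sqrt(2) of
    paired differences at duplicated delays, pooled over residues."""
    diffs = []
    for s in series_set:
        vals, counts = np.unique(s.delays, return_counts=True)
        for v in vals[counts > 1]:
            reps = s.intensities[s.delays == v]
            # successive replicate pairs
            for i in range(0, 2 * (reps.size // 2), 2):
                diffs.append(reps[i] - reps[i + 1])
    if not diffs:
        raise ValueError(
            "no duplicated delays found; provide an explicit noise sigma"
        )
    diffs = np.asarray(diffs, dtype=float)
    return float(np.sqrt(np.mean(diffs**2) / 2.0))


def monte_carlo_uncertainty(
    series: DecaySeries,
    sigma: float,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """SD of rates refit to noise-perturbed synthetic decays.

    Synthetic datasets are generated from the fitted curve plus iid Gaussian
    noise of the given sigma. Deterministic for a fixed seed. More than 20%
    refit failures is an error.
    """
    base = fit_monoexponential(series)
    if base.status != OK:
        raise ValueError("Monte-Carlo uncertainty requires a successful base fit")
    if sigma == 0:
        return 0.0
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    model = _monoexp(series.delays, base.amplitude, base.rate)
    rates = []
    failures = 0
    for _ in range(n_draws):
        y = model + rng.normal(0.0, sigma, size=model.shape)
        try:
            popt, _ = curve_fit(
                _monoexp,
                series.delays,
                y,
                p0=(base.amplitude, base.rate),
                maxfev=5000,
            )
            if popt[1] > 0:
                rates.append(popt[1])
            else:
                failures += 1
        except (RuntimeError, ValueError):
            failures += 1
    if failures > 0.2 * n_draws:
        raise RuntimeError(
            f"{failures}/{n_draws} Monte-Carlo refits failed; data too noisy"
        )
    return float(np.std(rates, ddof=1))


def mobility_regression(
    apo,
    bound,
    include_linker: bool = False,
    intercept: bool = True,
    outlier_sd: float = 2.0,
) -> dict[str, MobilityFit]:
    """Per-domain OLS of bound R2-R1/2 (vertical) on apo R2-R1/2 (horizontal).

    Only residues with status OK in both states enter; linker residues are
    excluded from per-domain fits by default. Outliers are residues with
    |internally studentized residual| > ``outlier_sd``; they are flagged but
    the fit is NOT repeated without them.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    apo_by_res = {r.residue.index: r for r in apo if r.status == OK}
    bound_by_res = {r.residue.index: r for r in bound if r.status == OK}
    domains: dict[str, list] = {}
    for idx in sorted(set(apo_by_res) & set(bound_by_res)):
        dom = apo_by_res[idx].residue.domain
        if dom == LINKER and not include_linker:
            continue
        domains.setdefault(dom, []).append(idx)

    fits = {}
    for dom, resids in domains.items():
        if len(resids) < 3:
            raise ValueError(f"domain {dom}: need >= 3 matched residues")
        x = np.array([apo_by_res[i].rate for i in resids])
        y = np.array([bound_by_res[i].rate for i in resids])
        if np.isclose(np.var(x), 0.0):
            raise ValueError(f"domain {dom}: degenerate x-variance")
        X = sm.add_constant(x) if intercept else x[:, None]
        res = sm.OLS(y, X).fit()
        if intercept:
            b0, b1 = res.params
        else:
            b0, b1 = 0.0, res.params[0]
        r = float(np.corrcoef(x, y)[0, 1])
        stud = OLSInfluence(res).resid_studentized_internal
        outliers = [resids[i] for i in np.nonzero(np.abs(stud) > outlier_sd)[0]]
        fits[dom] = MobilityFit(
            domain=dom,
            slope=float(b1),
            intercept=float(b0),
            corr_coeff=r,
            n=len(resids),
            outliers=outliers,
            residues=list(resids),
        )
    return fits


def jeff0_tauc(
    rate: float,
    residue: ResidueID | None = None,
    constants: NMRConstants = NMRConstants(),
) -> SpectralDensityResult:
    """Convert an R2-R1/2 value (rad/s) to J_eff(0) and tau_c.

    J_eff(0) = rate / [(2 C_N / 3)(1 + 3 D_IN / C_N)]; tau_c = 5 J_eff(0) / 2.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    jeff0 = rate / constants.rate_per_jeff0
    return SpectralDensityResult(
        residue=residue if residue is not None else ResidueID(1),
        jeff0=float(jeff0),
        tau_c=float(2.5 * jeff0),
        c_n=constants.c_n,
        d_in=constants.d_in,
    )


def rate_from_tauc(tau_c: float, constants: NMRConstants = NMRConstants()) -> float:
    """Forward model: tau_c (s) -> R2-R1/2 (rad/s). Inverse of jeff0_tauc."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return (2.0 * tau_c / 5.0) * constants.rate_per_jeff0


def combined_csp(
    d_h: float, d_n: float, weight: float = CSP_WEIGHT, squared_weight: bool = False
) -> float:
    """Combined amide CSP in ppm.

    Default convention: sqrt(d_h^2 + (weight * d_n)^2). Setting
    ``squared_weight`` switches to sqrt(d_h^2 + weight * d_n^2).
    """
    if not (np.isfinite(d_h) and np.isfinite(d_n)):
        raise ValueError("shift differences must be finite")
    if squared_weight:
        return float(np.sqrt(d_h**2 + weight * d_n**2))
    return float(np.sqrt(d_h**2 + (weight * d_n) ** 2))


def csp_record(
    residue: ResidueID, d_h: float, d_n: float, **kwargs
) -> ShiftPerturbation:
    return ShiftPerturbation(
        residue=residue, d_h=d_h, d_n=d_n, combined=combined_csp(d_h, d_n, **kwargs)
    )
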