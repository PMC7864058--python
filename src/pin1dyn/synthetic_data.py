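"""Seeded synthetic-data generators with recorded ground truth.

The generators emulate the statistical structure of the pipeline's inputs —
monoexponential peak decays with Gaussian noise, PARA/DIA rate pairs with
fully broadened peaks, and a two-domain bead trajectory with a latent
compact/extended exchange — without attempting to reproduce real force-field
dynamics.

The two-state ensemble is a toy two-domain protein: a WW-like domain of 20
residues, a 2-residue linker, and a PPIase-like domain of 30 residues, each
residue carrying N, H, CA, C, O and a CB side-chain bead. Every frame draws a
Bernoulli(p_compact) state that simultaneously sets (i) the interdomain
separation (design means 32.7 and 50.1 Å plus Gaussian jitter, mirroring the
two-cluster geometry) and (ii) the WW-domain hinge: designated contact pairs
dock and designated H-bond triads close in their assigned state, hard-coding
the anticorrelation between interdomain separation and intradomain
compactness. All randomness flows through one seeded generator per dataset
and is recorded in the returned :class:`SyntheticTruth`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import SBConstants
from .data_model import (
    DomainRanges,
    DecaySeries,
    FrameSeries,
    ResidueID,
    Topology,
)

__all__ = [
    "SyntheticTruth",
    "DEFAULT_DELAYS_S",
    "TOY_RANGES",
    "gen_decay_tables",
    "gen_two_state_ensemble",
    "gen_pre_decay_pair",
    "gen_correlated_series",
    "gen_bimodal_scalar",
    "mixture_pearson",
    "write_ensemble",
]

#: relaxation-delay schedule, seconds (duplicates at 4 and 20 ms)
DEFAULT_DELAYS_S = (
    0.004,
    0.004,
    0.006,
    0.008,
    0.010,
    0.012,
    0.015,
    0.020,
    0.020,
    0.025,
    0.030,
)

#: domain boundaries of the toy chain
TOY_RANGES = DomainRanges(ww=(1, 20), linker=(21, 22), ppiase=(23, 52))

COMPACT = "COMPACT"
EXTENDED = "EXTENDED"

# toy residue geometry: local atom offsets (Å) relative to CA
_ATOM_TEMPLATE = (
    ("N", "N", (-1.2, 0.0, 0.0)),
    ("H", "H", (-2.2, 0.0, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, 0.0, 0.0)),
    ("O", "O", (2.2, 0.0, 0.0)),
    ("CB", "C", (0.0, 0.0, 1.2)),
)
_MASS = {"N": 14.007, "H": 1.008, "C": 12.011, "O": 15.999}
_SPACING = 8.0  # Å between residue anchors along the chain axis

#: WW hinge design: (partner, mobile, closed_state, docking)
#: docking "stack" places the mobile residue 3.5 Å above the partner
#: (several heavy-atom contacts); "hbond" docks it so its amide N-H donates
#: a linear 2.9-Å H-bond to the partner carbonyl (plus a few contacts)
#: EXTENDED-closing pairs dock toward the domain centroid (compacting the
#: WW-like domain when the domains separate); the COMPACT-closing pair docks
#: away from it, so the WW radius of gyration anticorrelates with separation
_DESIGN_PAIRS = (
    {"partner": 11, "mobile": 14, "closed_state": EXTENDED, "docking": "stack"},
    {"partner": 9, "mobile": 16, "closed_state": EXTENDED, "docking": "hbond"},
    {"partner": 19, "mobile": 12, "closed_state": COMPACT, "docking": "stack"},
)
_DOCK_OFFSET = {"stack": (0.0, 0.0, 3.5), "hbond": (6.3, 0.0, 0.0)}

_LABEL_RESID = 2  # spin-label site (Cα proxy) in the WW-like domain
_REPORTER_RESID = 25  # PPIase residue whose Cα tracks the separation exactly
_CLOSE_RESIDS = (26, 27)  # PPIase residues approaching the label when compact
_CLOSE_DX = 20.0  # Å the close residues protrude toward the label


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated dataset.

    Regeneration from (name, seed, params) is bit-identical; ``arrays`` holds
    per-frame ground truth (states, separations, label distances)."""

    name: str
    seed: int
    params: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "seed": self.seed,
            "params": self.params,
            "tables": self.tables,
            "arrays": {k: np.asarray(v).tolist() for k, v in self.arrays.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["arrays"] = {
            k: np.asarray(v) for k, v in payload["arrays"].items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# decay tables
# ---------------------------------------------------------------------------

def gen_decay_tables(
    true_rates: dict,
    delays=DEFAULT_DELAYS_S,
    sigma: float = 2.0,
    i0: float = 100.0,
    seed: int = 0,
    ranges: DomainRanges = TOY_RANGES,
):
    """Noisy monoexponential decays I(t) = i0 exp(-R t) + N(0, sigma).

    ``true_rates`` maps residue index -> rate (rad/s). Duplicate delays in
    the schedule are emitted as separate rows."""
    for r in true_rates.values():
        if r <= 0:
            raise ValueError("true rates must be positive")
    rng = np.random.default_rng(seed)
    delays = np.asarray(delays, dtype=float)
    series = []
    for idx in sorted(true_rates):
        clean = i0 * np.exp(-true_rates[idx] * delays)
        noisy = clean + rng.normal(0.0, sigma, size=delays.shape)
        series.append(
            DecaySeries(
                residue=ResidueID.from_index(idx, ranges=ranges),
                delays=delays,
                intensities=noisy,
            )
        )
    truth = SyntheticTruth(
        name="decay_tables",
        seed=seed,
        params={
            "i0": i0,
            "sigma": sigma,
            "delays_s": list(map(float, delays)),
            "true_rates": {str(k): float(v) for k, v in true_rates.items()},
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# two-state ensemble
# ---------------------------------------------------------------------------

def _toy_topology() -> Topology:
    names, elements, resids, masses = [], [], [], []
    for resid in range(1, 53):
        for name, el, _off in _ATOM_TEMPLATE:
            names.append(name)
            elements.append(el)
            resids.append(resid)
            masses.append(_MASS[el])
    top = Topology(
        name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        resid=np.array(resids, dtype=int),
        resname=np.array(["GLY"] * len(names), dtype=object),
        mass=np.array(masses),
    )
    # amide H attaches to its own backbone N
    h_attached = {}
    for resid in range(1, 53):
        h_attached[top.atom_index(resid, "H")] = top.atom_index(resid, "N")
    top.h_attached = h_attached
    top.donors = np.array(sorted(set(h_attached.values())), dtype=int)
    return top


def _residue_atoms(anchor: np.ndarray) -> np.ndarray:
    return np.asarray([anchor + np.asarray(off) for _n, _e, off in _ATOM_TEMPLATE])


def _ww_template(state: str) -> np.ndarray:
    """Coordinates of WW residues 1-20 (plus linker 21-22) for one hinge
    state; returns ((22)*6, 3)."""
    anchors = {i: np.array([0.0, _SPACING * i, 0.0]) for i in range(1, 21)}
    for d in _DESIGN_PAIRS:
        if d["closed_state"] == state:
            anchors[d["mobile"]] = anchors[d["partner"]] + np.asarray(
                _DOCK_OFFSET[d["docking"]]
            )
    for i in (21, 22):  # linker: parked well away from both domains
        anchors[i] = np.array([-30.0, _SPACING * i, 0.0])
    return np.concatenate(
        [_residue_atoms(anchors[i]) for i in range(1, 23)], axis=0
    )


def _ppiase_template() -> np.ndarray:
    """PPIase coordinates at zero separation; per frame add (s, 0, 0)."""
    blocks = []
    for k, i in enumerate(range(23, 53)):
        if i in _CLOSE_RESIDS:
            anchor = np.array(
                [-_CLOSE_DX, _SPACING * _LABEL_RESID, 6.0 * _CLOSE_RESIDS.index(i)]
            )
        else:
            anchor = np.array([0.0, _SPACING * (i - 23), 0.0])
        blocks.append(_residue_atoms(anchor))
    return np.concatenate(blocks, axis=0)


def _docked_contact_count(docking: str, cutoff: float = 4.5) -> int:
    """Heavy-atom contact count between a partner residue and its docked
    mobile residue (direct enumeration of the template geometry)."""
    a = _residue_atoms(np.zeros(3))
    b = _residue_atoms(np.asarray(_DOCK_OFFSET[docking]))
    heavy = [k for k, (_n, el, _o) in enumerate(_ATOM_TEMPLATE) if el != "H"]
    n = 0
    for i in heavy:
        for j in heavy:
            if np.linalg.norm(a[i] - b[j]) <= cutoff:
                n += 1
    return n


def gen_two_state_ensemble(
    p_compact: float = 0.5,
    n_frames: int = 2000,
    mean_compact: float = 32.7,
    mean_extended: float = 50.1,
    jitter_sd: float = 2.0,
    seed: int = 0,
    frame_interval_ps: float = 200.0,
):
    """Two-domain toy trajectory with a latent compact/extended exchange.

    Returns (Topology, FrameSeries, SyntheticTruth). Truth arrays: per-frame
    ``states`` (1 = compact), ``separations`` (Å, the reporter Cα distance),
    and ``label_h_distances`` (n_frames x 52, spin-label Cα to each residue's
    amide H). Truth tables: the hinge design with docked contact counts and
    the closed-form separation/contact correlation for each designed pair."""
    if not 0 < p_compact < 1:
        raise ValueError("p_compact must be in (0, 1)")
    if mean_compact >= mean_extended:
        raise ValueError("compact mean must be below extended mean")
    rng = np.random.default_rng(seed)
    states = (rng.random(n_frames) < p_compact).astype(int)  # 1 = compact
    mu = np.where(states == 1, mean_compact, mean_extended)
    seps = mu + rng.normal(0.0, jitter_sd, size=n_frames)
    # truncate extreme jitter so close-approach distances stay physical
    seps = np.maximum(seps, mean_compact - 3.0 * jitter_sd)

    top = _toy_topology()
    ww_open_like = {COMPACT: _ww_template(COMPACT), EXTENDED: _ww_template(EXTENDED)}
    pp0 = _ppiase_template()
    n_ww = ww_open_like[COMPACT].shape[0]

    coords = np.empty((n_frames, top.n_atoms, 3))
    for s_name, s_code in ((COMPACT, 1), (EXTENDED, 0)):
        mask = states == s_code
        coords[mask, :n_ww, :] = ww_open_like[s_name]
    coords[:, n_ww:, :] = pp0[None, :, :]
    coords[:, n_ww:, 0] += seps[:, None]

    frames = FrameSeries(coords, frame_interval_ps=frame_interval_ps)

    label_ca = top.ca_index(_LABEL_RESID)
    h_idx = np.array([top.atom_index(i, "H") for i in range(1, 53)])
    label_h = np.linalg.norm(
        coords[:, h_idx, :] - coords[:, label_ca, None, :], axis=2
    )

    design = []
    for d in _DESIGN_PAIRS:
        i, j = sorted((d["partner"], d["mobile"]))
        closed_count = _docked_contact_count(d["docking"])
        expected_sign = 1 if d["closed_state"] == EXTENDED else -1
        design.append(
            {
                "pair": [i, j],
                "closed_state": d["closed_state"],
                "docking": d["docking"],
                "count_closed": closed_count,
                "count_open": 0,
                "expected_corr_sign": expected_sign,
                "true_corr_vs_separation": mixture_pearson(
                    p_compact,
                    mean_compact,
                    mean_extended,
                    jitter_sd,
                    closed_count if d["closed_state"] == COMPACT else 0,
                    closed_count if d["closed_state"] == EXTENDED else 0,
                ),
            }
        )

    hbond_design = []
    for d in _DESIGN_PAIRS:
        if d["docking"] == "hbond":
            hbond_design.append(
                {
                    "donor_res": d["mobile"],
                    "acceptor_res": d["partner"],
                    "closed_state": d["closed_state"],
                }
            )

    truth = SyntheticTruth(
        name="two_state_ensemble",
        seed=seed,
        params={
            "p_compact": p_compact,
            "n_frames": n_frames,
            "mean_compact": mean_compact,
            "mean_extended": mean_extended,
            "jitter_sd": jitter_sd,
            "label_resid": _LABEL_RESID,
            "reporter_resid": _REPORTER_RESID,
            "close_resids": list(_CLOSE_RESIDS),
        },
        tables={"design_pairs": design, "hbond_design": hbond_design},
        arrays={
            "states": states,
            "separations": seps,
            "label_h_distances": label_h,
        },
    )
    return top, frames, truth


def mixture_pearson(p, x1, x0, sigma_x, y1, y0, sigma_y=0.0) -> float:
    """Closed-form Pearson correlation for a two-state mixture where state 1
    (probability p) has means (x1, y1) and state 0 has (x0, y0), with
    independent within-state jitter of SD sigma_x / sigma_y."""
    q = 1.0 - p
    dx = x1 - x0
    dy = y1 - y0
    cov = p * q * dx * dy
    vx = p * q * dx * dx + sigma_x**2
    vy = p * q * dy * dy + sigma_y**2
    if vx == 0 or vy == 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


# ---------------------------------------------------------------------------
# PARA/DIA decay pairs driven by the ensemble
# ---------------------------------------------------------------------------

def gen_pre_decay_pair(
    truth: SyntheticTruth,
    tau_c: float = 5e-9,
    r2_dia: float = 40.0,
    sigma: float = 0.1,
    i0: float = 100.0,
    delays=DEFAULT_DELAYS_S,
    seed: int = 1,
    constants: SBConstants = SBConstants(),
    detect_k: float = 3.0,
):
    """PARA/DIA decay tables consistent with a two-state ensemble.

    The true PRE of each residue is the Solomon-Bloembergen rate for the
    ensemble-averaged <r^-6> of its amide proton to the spin-label site.
    The returned truth records the per-residue true Gamma2, the expected
    status under the k * noise-floor detection rule applied to the realized
    noisy tables, and the planted significant set: the residues whose TRUE
    Gamma2 stands out of the background under the identical trimmed
    threshold rule applied to the noiseless profile. The default noise
    emulates high signal-to-noise spectra (sigma = 0.1% of i0) so that
    significance reflects geometry rather than spectral noise."""
    label_h = np.asarray(truth.arrays["label_h_distances"], dtype=float)
    resids = list(range(1, label_h.shape[1] + 1))
    inv_r6 = np.mean((label_h * 1e-10) ** -6, axis=0)
    w = constants.omega_h
    spectral = 4.0 * tau_c + 3.0 * tau_c / (1.0 + (w * tau_c) ** 2)
    amp = (
        constants.prefactor
        * constants.s_spin
        * (constants.s_spin + 1.0)
        * (constants.g * constants.mu_b * constants.gamma_i) ** 2
        / 15.0
    )
    gamma_true = amp * inv_r6 * spectral

    dia_rates = {i: r2_dia for i in resids}
    para_rates = {i: r2_dia + float(gamma_true[k]) for k, i in enumerate(resids)}
    dia, _ = gen_decay_tables(
        dia_rates, delays=delays, sigma=sigma, i0=i0, seed=seed
    )
    para, _ = gen_decay_tables(
        para_rates, delays=delays, sigma=sigma, i0=i0, seed=seed + 1
    )

    cut = detect_k * sigma
    expected_status = {}
    for series_set, tag in ((dia, "dia"), (para, "para")):
        for s in series_set:
            detected = bool(np.max(s.intensities) > cut)
            expected_status.setdefault(s.residue.index, {})[tag] = detected
    status = {}
    for i in resids:
        d_ok = expected_status[i]["dia"]
        p_ok = expected_status[i]["para"]
        status[i] = (
            "OVERFLOW" if d_ok and not p_ok else "MISSING" if not d_ok else "QUANTIFIED"
        )
    from .pre_analysis import twice_filtered_threshold

    finite_true = [
        float(gamma_true[k])
        for k, i in enumerate(resids)
        if status[i] == "QUANTIFIED"
    ]
    thr_true = twice_filtered_threshold(finite_true)
    planted = sorted(
        i
        for k, i in enumerate(resids)
        if status[i] == "QUANTIFIED" and gamma_true[k] > thr_true.upper
    )
    pre_truth = SyntheticTruth(
        name="pre_decay_pair",
        seed=seed,
        params={
            "tau_c": tau_c,
            "r2_dia": r2_dia,
            "sigma": sigma,
            "i0": i0,
            "detect_k": detect_k,
            "true_threshold_upper": float(thr_true.upper),
        },
        tables={
            "expected_status": {str(i): status[i] for i in resids},
            "planted_significant": planted,
        },
        arrays={"gamma2_true": gamma_true},
    )
    return dia, para, pre_truth


# ---------------------------------------------------------------------------
# simple series generators
# ---------------------------------------------------------------------------

def gen_correlated_series(
    target_r: float,
    n: int,
    seed: int = 0,
    discretize_levels: int | None = None,
):
    """Bivariate-normal (x, y) with correlation ``target_r``.

    With ``discretize_levels`` set, y is quantile-binned into small integers
    (contact-number-like) and the post-discretization true correlation is
    recomputed on the latent pairing and stored as the truth."""
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = target_r * z1 + np.sqrt(1.0 - target_r**2) * z2
    true_r = target_r
    if discretize_levels is not None:
        qs = np.quantile(y, np.linspace(0, 1, discretize_levels + 1)[1:-1])
        y = np.digitize(y, qs).astype(float)
        dxm = x - x.mean()
        dym = y - y.mean()
        true_r = float(
            (dxm @ dym) / np.sqrt((dxm @ dxm) * (dym @ dym))
        )
    truth = SyntheticTruth(
        name="correlated_series",
        seed=seed,
        params={
            "target_r": target_r,
            "n": n,
            "discretize_levels": discretize_levels,
            "true_r": float(true_r),
        },
    )
    return x, y, truth


def gen_bimodal_scalar(
    means=(32.7, 50.1),
    sds=(3.0, 3.0),
    weight: float = 0.5,
    n: int = 2000,
    seed: int = 0,
):
    """Labelled two-component Gaussian mixture for clustering tests.

    Returns (values, labels, truth); labels are 1 for the low-mean
    (compact-like) component."""
    m1, m2 = means
    if m1 == m2:
        raise ValueError("means must be distinct")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < weight).astype(int)  # 1 = first component
    values = np.where(
        labels == 1,
        rng.normal(m1, sds[0], size=n),
        rng.normal(m2, sds[1], size=n),
    )
    truth = SyntheticTruth(
        name="bimodal_scalar",
        seed=seed,
        params={
            "means": list(map(float, means)),
            "sds": list(map(float, sds)),
            "weight": weight,
            "n": n,
        },
        arrays={"labels": labels},
    )
    return values, labels, truth


# ---------------------------------------------------------------------------
# file output (exercises the real readers end-to-end)
# ---------------------------------------------------------------------------

def write_ensemble(
    top: Topology, frames: FrameSeries, truth: SyntheticTruth, out_dir
) -> dict:
    """Write the ensemble as structure.pdb + trajectory (DCD) + truth.json.

    The PDB is valid single-model output so the package's own readers are
    exercised rather than bypassed."""
    import warnings

    import MDAnalysis as mda

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / "structure.pdb"
    dcd_path = out / "trajectory.dcd"

    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=len(top.residues),
        atom_resindex=np.searchsorted(top.residues, top.resid),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in top.name])
    u.add_TopologyAttr("elements", [str(e) for e in top.element])
    u.add_TopologyAttr("resids", [int(r) for r in top.residues])
    u.add_TopologyAttr("resnames", [str(top.resname[top.resid == r][0]) for r in top.residues])
    u.add_TopologyAttr("masses", top.mass)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.positions = frames.coordinates[0]
        u.atoms.write(str(pdb_path))
        with mda.Writer(str(dcd_path), n_atoms=top.n_atoms) as w:
            for f in range(frames.frame_count):
                u.atoms.positions = frames.coordinates[f]
                w.write(u.atoms)
    truth.to_json(out / "truth.json")
    return {
        "structure": str(pdb_path),
        "trajectory": str(dcd_path),
        "truth": str(out / "truth.json"),
    }
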