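"""Per-frame geometric observables from trajectories.

Site specifiers use a small string language:

* ``ca:27``      - the Cα atom of residue 27
* ``com:1-39``   - mass-weighted center of mass of residues 1-39
* ``atom:15``    - the atom with (1-based) serial 15

Contacts count heavy-atom pairs (one atom from each residue) within a 4.5 Å
cutoff (inclusive); H-bonds require donor-heavy-to-acceptor distance <= 3.2 Å
and a D-H...A angle >= 135 deg (180 deg = ideal).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DomainRanges, DEFAULT_RANGES, FrameSeries, Topology, assign_domain

__all__ = [
    "DistanceSeries",
    "ContactSeries",
    "HBondRecord",
    "HBondInventory",
    "resolve_site",
    "distance_series",
    "gyration_radius_series",
    "contact_number_series",
    "select_fluctuating_pairs",
    "hbond_presence",
    "hbond_occupancy",
]

CONTACT_CUTOFF = 4.5  # Å, heavy-atom pair contact
HBOND_DIST_CUTOFF = 3.2  # Å, donor-heavy to acceptor-heavy
HBOND_ANGLE_CUTOFF = 135.0  # deg, D-H...A


@dataclass
class DistanceSeries:
    """Per-frame Euclidean distance (Å) between two resolved sites."""

    label: tuple[str, str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ContactSeries:
    """Per-frame heavy-atom contact counts for a residue pair (i < j)."""

    pair: tuple[int, int]
    counts: np.ndarray

    def __post_init__(self):
        i, j = self.pair
        if not i < j:
            raise ValueError("contact pair must satisfy i < j")
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    @property
    def sequence_separation(self) -> int:
        return self.pair[1] - self.pair[0]


@dataclass
class HBondRecord:
    """All hydrogen bonds between a donor residue X and acceptor residue Y.

    ``occupancies`` maps (donor-H atom index, acceptor atom index) to the
    fraction of frames in which that bond is present; ``pi`` is their sum
    (the per-residue-pair occupancy metric)."""

    donor_res: int
    acceptor_res: int
    occupancies: dict = field(default_factory=dict)

    @property
    def pi(self) -> float:
        return float(sum(self.occupancies.values()))


@dataclass
class HBondInventory:
    """Per-frame presence of every observed hydrogen bond.

    ``bonds`` lists (h_idx, acceptor_idx, donor_res, acceptor_res);
    ``presence`` has shape (n_frames, n_bonds)."""

    bonds: list
    presence: np.ndarray

    def records(self, frame_mask=None) -> list[HBondRecord]:
        """Aggregate to per-residue-pair records, optionally over a frame
        subset."""
        pres = self.presence if frame_mask is None else self.presence[frame_mask]
        by_pair: dict[tuple[int, int], HBondRecord] = {}
        for col, (h, a, dres, ares) in enumerate(self.bonds):
            rec = by_pair.setdefault(
                (dres, ares), HBondRecord(donor_res=dres, acceptor_res=ares)
            )
            rec.occupancies[(h, a)] = float(pres[:, col].mean()) if len(pres) else 0.0
        return [by_pair[k] for k in sorted(by_pair)]


def resolve_site(topology: Topology, spec: str):
    """Resolve a site specifier to (atom indices, masses)."""
    spec = str(spec).strip().lower()
    if ":" not in spec:
        raise ValueError(f"bad site specifier {spec!r}")
    kind, arg = spec.split(":", 1)
    if kind == "ca":
        idx = np.array([topology.ca_index(int(arg))])
    elif kind == "atom":
        serial = int(arg)
        if not 1 <= serial <= topology.n_atoms:
            raise ValueError(f"atom serial {serial} out of range")
        idx = np.array([serial - 1])
    elif kind == "com":
        if "-" in arg:
            lo, hi = (int(x) for x in arg.split("-"))
        else:
            lo = hi = int(arg)
        idx = np.nonzero((topology.resid >= lo) & (topology.resid <= hi))[0]
        if idx.size == 0:
            raise ValueError(f"empty selection for residues {lo}-{hi}")
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    return idx, topology.mass[idx]


def _site_positions(frames: FrameSeries, idx, masses, mass_weighted=True):
    X = frames.coordinates[:, idx, :]
    if idx.size == 1:
        return X[:, 0, :]
    w = masses if mass_weighted else np.ones_like(masses)
    return np.einsum("fax,a->fx", X, w) / w.sum()


def distance_series(
    frames: FrameSeries,
    topology: Topology,
    a: str,
    b: str,
    mass_weighted: bool = True,
) -> DistanceSeries:
    """Per-frame distance between two sites (atoms, Cα's, or domain COMs)."""
    ia, ma = resolve_site(topology, a)
    ib, mb = resolve_site(topology, b)
    pa = _site_positions(frames, ia, ma, mass_weighted)
    pb = _site_positions(frames, ib, mb, mass_weighted)
    return DistanceSeries(label=(a, b), values=np.linalg.norm(pa - pb, axis=1))


def gyration_radius_series(
    frames: FrameSeries,
    topology: Topology,
    residues=None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame radius of gyration (Å) of a residue selection.

    Rg = sqrt( sum_k m_k |x_k - xbar|^2 / sum_k m_k ), equal by construction
    to the square root of the gyration-tensor eigenvalue trace. A single-atom
    selection returns zeros with a warning."""
    import warnings

    if residues is None:
        idx = np.arange(topology.n_atoms)
    else:
        lo, hi = min(residues), max(residues)
        idx = np.nonzero((topology.resid >= lo) & (topology.resid <= hi))[0]
    if idx.size == 0:
        raise ValueError("empty residue selection")
    if idx.size == 1:
        warnings.warn("single-atom selection: Rg is identically 0")
        return np.zeros(frames.frame_count)
    w = topology.mass[idx] if mass_weighted else np.ones(idx.size)
    X = frames.coordinates[:, idx, :]
    com = np.einsum("fax,a->fx", X, w) / w.sum()
    d2 = ((X - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt(np.einsum("fa,a->f", d2, w) / w.sum())


def contact_number_series(
    frames: FrameSeries,
    topology: Topology,
    pair: tuple[int, int],
    cutoff: float = CONTACT_CUTOFF,
) -> ContactSeries:
    """Per-frame count of heavy-atom pairs between two residues within the
    cutoff (inclusive)."""
    i, j = pair
    if i == j:
        raise ValueError("contact pair must involve two distinct residues")
    i, j = (i, j) if i < j else (j, i)
    hi = topology.heavy_indices(i)
    hj = topology.heavy_indices(j)
    diff = (
        frames.coordinates[:, hi, None, :] - frames.coordinates[:, None, hj, :]
    )
    d2 = np.einsum("fabx,fabx->fab", diff, diff)
    counts = (d2 <= cutoff * cutoff).sum(axis=(1, 2))
    return ContactSeries(pair=(i, j), counts=counts)


def intradomain_pairs(
    topology: Topology, ranges: DomainRanges = DEFAULT_RANGES
) -> list[tuple[int, int]]:
    """All same-domain residue pairs (i < j), linker excluded."""
    pairs = []
    resids = [int(r) for r in topology.residues]
    doms = {r: assign_domain(r, ranges) for r in resids}
    for a in range(len(resids)):
        for b in range(a + 1, len(resids)):
            i, j = resids[a], resids[b]
            if doms[i] == doms[j] and doms[i] != "LINKER":
                pairs.append((i, j))
    return pairs


def select_fluctuating_pairs(series_list, ranges: DomainRanges = DEFAULT_RANGES):
    """Retain contact series with nonzero variance.

    Returns (selected series, per-domain counts). Sequence-adjacent pairs are
    eligible; a >= 3-residue sequence separation is recorded separately via
    :attr:`ContactSeries.sequence_separation`."""
    selected = []
    per_domain: dict[str, int] = {}
    for s in series_list:
        if np.var(s.counts) > 0:
            selected.append(s)
            dom = assign_domain(s.pair[0], ranges)
            per_domain[dom] = per_domain.get(dom, 0) + 1
    return selected, per_domain


def hbond_presence(
    frames: FrameSeries,
    topology: Topology,
    dist_cutoff: float = HBOND_DIST_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> HBondInventory:
    """Per-frame hydrogen-bond presence for every donor-H/acceptor pair.

    A bond exists in a frame iff the donor-heavy to acceptor distance is
    <= dist_cutoff and the D-H...A angle is >= angle_cutoff. Same-residue
    pairs are excluded. Only bonds present in at least one frame are kept."""
    if not topology.h_attached:
        raise ValueError("topology has no donors with attached hydrogens")
    X = frames.coordinates
    bonds, cols = [], []
    for h, d in sorted(topology.h_attached.items()):
        dres = int(topology.resid[d])
        vd = X[:, d, :]
        vh = X[:, h, :]
        hd = vd - vh
        nhd = np.linalg.norm(hd, axis=1)
        for a in topology.acceptors:
            a = int(a)
            ares = int(topology.resid[a])
            if ares == dres:
                continue
            da = np.linalg.norm(X[:, a, :] - vd, axis=1)
            close = da <= dist_cutoff
            if not close.any():
                continue
            ha = X[:, a, :] - vh
            nha = np.linalg.norm(ha, axis=1)
            # D-H...A angle = angle at H between H->D and H->A (180 = linear)
            cosang = np.einsum("fx,fx->f", hd, ha) / np.maximum(nhd * nha, 1e-12)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            present = close & (ang >= angle_cutoff)
            if present.any():
                bonds.append((h, a, dres, ares))
                cols.append(present)
    presence = (
        np.stack(cols, axis=1) if cols else np.zeros((frames.frame_count, 0), bool)
    )
    return HBondInventory(bonds=bonds, presence=presence)


def hbond_occupancy(
    frames: FrameSeries,
    topology: Topology,
    dist_cutoff: float = HBOND_DIST_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list[HBondRecord]:
    """Per-residue-pair hydrogen-bond occupancies over the whole trajectory."""
    return hbond_presence(frames, topology, dist_cutoff, angle_cutoff).records()
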