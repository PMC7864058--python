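"""Core domain types, residue/domain bookkeeping, and file readers/writers.

The pipeline operates on a two-domain protein (Pin1 by default): an N-terminal
WW domain, a flexible linker, and a C-terminal PPIase domain. Sequence
positions are 1-based throughout; trajectory frames are 0-based internally and
reported 1-based in output tables. Rates are rad/s, delays seconds, and
coordinates Å.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WW",
    "LINKER",
    "PPIASE",
    "OK",
    "OVERFLOW",
    "MISSING",
    "QUANTIFIED",
    "DomainRanges",
    "DomainAssignmentError",
    "ParseError",
    "ResidueID",
    "DecaySeries",
    "RateEstimate",
    "ShiftPerturbation",
    "Topology",
    "FrameSeries",
    "assign_domain",
    "read_decay_table",
    "read_structure_and_trajectory",
    "write_results",
    "read_results",
]

WW = "WW"
LINKER = "LINKER"
PPIASE = "PPIASE"

# status flags shared across rate/PRE tables
OK = "OK"
OVERFLOW = "OVERFLOW"
MISSING = "MISSING"
QUANTIFIED = "QUANTIFIED"

_HYDROGEN_ELEMENTS = {"H", "D"}

# standard atomic masses, amu
ELEMENT_MASS = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
}


class DomainAssignmentError(ValueError):
    """Raised when a residue index falls outside every configured domain."""


class ParseError(ValueError):
    """Raised when an input table cannot be parsed."""


@dataclass(frozen=True)
class DomainRanges:
    """Inclusive residue-index boundaries of the three chain segments.

    Defaults are the Pin1 convention: WW 1-39, linker 40-52, PPIase 53-163.
    """

    ww: tuple[int, int] = (1, 39)
    linker: tuple[int, int] = (40, 52)
    ppiase: tuple[int, int] = (53, 163)

    def items(self):
        return ((WW, self.ww), (LINKER, self.linker), (PPIASE, self.ppiase))


DEFAULT_RANGES = DomainRanges()


def assign_domain(index: int, ranges: DomainRanges = DEFAULT_RANGES) -> str:
    """Map a 1-based residue index to its domain label (boundaries inclusive)."""
    index = int(index)
    if index < 1:
        raise DomainAssignmentError(f"residue index must be >= 1, got {index}")
    for label, (lo, hi) in ranges.items():
        if lo <= index <= hi:
            return label
    raise DomainAssignmentError(
        f"residue {index} is unassigned under ranges {ranges}"
    )


@dataclass(frozen=True)
class ResidueID:
    """A residue: 1-based sequence index, 3-letter code, domain label."""

    index: int
    name: str = "UNK"
    domain: str = ""

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("residue index must be >= 1")

    @classmethod
    def from_index(
        cls, index: int, name: str = "UNK", ranges: DomainRanges = DEFAULT_RANGES
    ) -> "ResidueID":
        return cls(index=int(index), name=name, domain=assign_domain(index, ranges))


@dataclass
class DecaySeries:
    """Per-residue peak intensity versus relaxation delay.

    ``duplicate_mask`` marks entries whose delay value occurs more than once;
    duplicate pairs drive replicate-based noise estimation.
    """

    residue: ResidueID
    delays: np.ndarray  # seconds
    intensities: np.ndarray
    duplicate_mask: np.ndarray = None

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have matching shapes")
        if np.any(self.delays <= 0):
            raise ValueError("relaxation delays must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.unique(self.delays).size < 4:
            raise ValueError(
                f"residue {self.residue.index}: need >= 4 distinct delays"
            )
        if self.duplicate_mask is None:
            vals, counts = np.unique(self.delays, return_counts=True)
            dup_vals = vals[counts > 1]
            self.duplicate_mask = np.isin(self.delays, dup_vals)
        else:
            self.duplicate_mask = np.asarray(self.duplicate_mask, dtype=bool)

    @property
    def n_points(self) -> int:
        return self.delays.size


@dataclass
class RateEstimate:
    """A fitted transverse relaxation rate (rad/s) with 1-SD uncertainty."""

    residue: ResidueID
    rate: float
    sigma: float
    status: str = OK
    amplitude: float = np.nan

    def __post_init__(self):
        if self.status == OK:
            if not self.rate > 0:
                raise ValueError("rate must be positive when status is OK")
            if self.sigma < 0:
                raise ValueError("sigma must be non-negative")


@dataclass
class ShiftPerturbation:
    """Combined 1H/15N chemical-shift perturbation, ppm."""

    residue: ResidueID
    d_h: float
    d_n: float
    combined: float

    def __post_init__(self):
        if (self.combined == 0) != (self.d_h == 0 and self.d_n == 0):
            raise ValueError("combined CSP is zero iff both components are zero")


@dataclass
class Topology:
    """Atom metadata plus hydrogen-bond donor/acceptor annotations.

    Arrays are parallel over atoms. ``h_attached`` maps the index of each
    polar hydrogen to the index of its heavy donor (N/O); ``donors`` and
    ``acceptors`` are heavy-atom indices.
    """

    name: np.ndarray  # str per atom
    element: np.ndarray  # str per atom
    resid: np.ndarray  # int per atom, 1-based
    resname: np.ndarray  # str per atom
    mass: np.ndarray  # amu
    heavy: np.ndarray = None  # bool
    h_attached: dict = field(default_factory=dict)
    donors: np.ndarray = None
    acceptors: np.ndarray = None

    def __post_init__(self):
        self.name = np.asarray(self.name, dtype=object)
        self.element = np.asarray(
            [str(e).upper() for e in np.asarray(self.element)], dtype=object
        )
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.heavy is None:
            self.heavy = np.array(
                [e not in _HYDROGEN_ELEMENTS for e in self.element], dtype=bool
            )
        else:
            self.heavy = np.asarray(self.heavy, dtype=bool)
        if self.donors is None:
            self.donors = np.array(sorted(set(self.h_attached.values())), dtype=int)
        if self.acceptors is None:
            self.acceptors = np.array(
                [
                    i
                    for i in range(self.n_atoms)
                    if self.heavy[i] and self.element[i] in ("N", "O")
                ],
                dtype=int,
            )

    @property
    def n_atoms(self) -> int:
        return self.resid.size

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.resid)

    def heavy_indices(self, resid: int) -> np.ndarray:
        idx = np.nonzero((self.resid == resid) & self.heavy)[0]
        if idx.size == 0:
            raise ValueError(f"residue {resid} has no heavy atoms")
        return idx

    def atom_index(self, resid: int, name: str) -> int:
        idx = np.nonzero((self.resid == resid) & (self.name == name))[0]
        if idx.size != 1:
            raise ValueError(f"residue {resid} atom {name!r}: found {idx.size}")
        return int(idx[0])

    def ca_index(self, resid: int) -> int:
        return self.atom_index(resid, "CA")


@dataclass
class FrameSeries:
    """Trajectory coordinates: (n_frames, n_atoms, 3) in Å."""

    coordinates: np.ndarray
    frame_interval_ps: float = 200.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[-1] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def frame_count(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def read_decay_table(
    path, ranges: DomainRanges = DEFAULT_RANGES
) -> list[DecaySeries]:
    """Read a delimited decay table into one :class:`DecaySeries` per residue.

    Required columns: ``residue``, ``intensity`` and a delay column named
    ``delay``/``delay_s`` (seconds) or ``delay_ms`` (milliseconds). Duplicate
    delays are preserved, never averaged. Optional column: ``resname``.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    delay_col, scale = None, 1.0
    for cand, sc in (("delay", 1.0), ("delay_s", 1.0), ("delay_ms", 1e-3)):
        if cand in cols:
            delay_col, scale = cols[cand], sc
            break
    missing = [c for c in ("residue", "intensity") if c not in cols]
    if delay_col is None:
        missing.append("delay | delay_s | delay_ms")
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")

    for col in ("residue", delay_col.lower(), "intensity"):
        raw = df[cols.get(col, col)]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any() or raw.isna().any():
            row = int(np.nonzero((coerced.isna() | raw.isna()).to_numpy())[0][0])
            raise ParseError(
                f"{path}: non-numeric or missing value in column {col!r}, row {row}"
            )
        df[cols.get(col, col)] = coerced

    out = []
    for resid, grp in df.groupby(cols["residue"], sort=True):
        resname = (
            str(grp[cols["resname"]].iloc[0]) if "resname" in cols else "UNK"
        )
        delays = grp[delay_col].to_numpy(dtype=float) * scale
        if np.unique(delays).size < 4:
            raise ParseError(
                f"{path}: residue {int(resid)} has fewer than 4 distinct delays"
            )
        out.append(
            DecaySeries(
                residue=ResidueID.from_index(int(resid), resname, ranges),
                delays=delays,
                intensities=grp[cols["intensity"]].to_numpy(dtype=float),
            )
        )
    return out


def _element_from_name(name: str) -> str:
    for ch in str(name):
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure_and_trajectory(
    structure, trajectory=None, frame_interval_ps: float = 200.0
) -> tuple[Topology, FrameSeries]:
    """Load a PDB structure (plus optional DCD/XTC/multi-model PDB trajectory).

    Elements come from the PDB element column when present, falling back to
    the atom-name convention. Donor/acceptor roles are populated for N/O
    heavy atoms; each polar hydrogen is attached to the nearest N/O within
    1.3 Å in the first frame.
    """
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory is None:
                u = mda.Universe(str(structure))
            else:
                u = mda.Universe(str(structure), str(trajectory))
        except (ValueError, OSError, IOError) as exc:
            raise IOError(
                f"cannot read structure {structure!r} with trajectory "
                f"{trajectory!r}: {exc}"
            ) from exc

        atoms = u.atoms
        names = [a.name for a in atoms]
        elements = []
        for a in atoms:
            el = ""
            if hasattr(a, "element"):
                try:
                    el = str(a.element).strip()
                except mda.exceptions.NoDataError:
                    el = ""
            elements.append(el.upper() if el else _element_from_name(a.name))
        masses = [ELEMENT_MASS.get(el, 12.0) for el in elements]
        top = Topology(
            name=np.array(names, dtype=object),
            element=np.array(elements, dtype=object),
            resid=np.array([a.resid for a in atoms], dtype=int),
            resname=np.array([a.resname for a in atoms], dtype=object),
            mass=np.array(masses, dtype=float),
        )

        frames = []
        for i, _ts in enumerate(u.trajectory):
            pos = atoms.positions
            if pos.shape[0] != top.n_atoms:
                raise IOError(
                    f"frame {i}: atom count {pos.shape[0]} does not match "
                    f"structure ({top.n_atoms})"
                )
            frames.append(pos.astype(float).copy())
    coords = np.stack(frames, axis=0)

    # attach polar hydrogens to the nearest N/O in the same residue (frame 0)
    first = coords[0]
    h_attached = {}
    for h in np.nonzero(~top.heavy)[0]:
        same_res = np.nonzero(
            (top.resid == top.resid[h])
            & top.heavy
            & np.isin(top.element, ("N", "O"))
        )[0]
        if same_res.size == 0:
            continue
        d = np.linalg.norm(first[same_res] - first[h], axis=1)
        k = int(np.argmin(d))
        if d[k] <= 1.3:
            h_attached[int(h)] = int(same_res[k])
    top.h_attached = h_attached
    top.donors = np.array(sorted(set(h_attached.values())), dtype=int)

    return top, FrameSeries(coords, frame_interval_ps=frame_interval_ps)


def _flatten_record(rec) -> dict:
    row = {}
    for f in dataclasses.fields(rec):
        val = getattr(rec, f.name)
        if isinstance(val, ResidueID):
            row["residue"] = val.index
            row["resname"] = val.name
            row["domain"] = val.domain
        elif isinstance(val, np.ndarray):
            continue  # array-valued fields are not tabular
        else:
            row[f.name] = val
    return row


def write_results(records, path) -> None:
    """Write a homogeneous collection of result records to CSV/TSV.

    Accepts a DataFrame or a list of dataclass instances. Status flags are
    serialized as strings; floats keep full repr precision so that a
    read/write round trip preserves values to better than 1e-9.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and len({type(r) for r in records}) > 1:
            raise ValueError("records must be homogeneous")
        df = pd.DataFrame([_flatten_record(r) for r in records])
        if df.empty and records == []:
            df = pd.DataFrame(columns=["residue"])
    df.to_csv(path, sep=sep, index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)
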