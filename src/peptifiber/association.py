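"""Covered-area association metric, ring angles and population maps.

The degree of association between two peptide monomers is measured as the
part of each monomer's solvent-accessible surface that its partner occludes:
for every atom of monomer *i*,

    covered(atom) = SASA(atom | partner deleted) - SASA(atom | full dimer)

and CA_i is the sum over the monomer's atoms.  CA_T = CA_1 + CA_2.  Each
CA_i splits by the atom region tags into an aromatic part CA_i,a (Phe side
chain plus the appended aryl unit), a peptide part CA_i,p (backbone plus Val
and Asp), and a residual CA_i,other for atoms outside both regions (caps),
so that CA_i = CA_i,a + CA_i,p + CA_i,other holds exactly.

Dissociated frames give CA_T = 0 exactly: with no cross-monomer sphere
overlap the two SASA evaluations see identical occluder sets point by point.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from math import acos, degrees

import numpy as np
import pandas as pd

from .model import AtomModel, ModelError, Trajectory
from .sasa import DEFAULT_N_POINTS, sasa

_CLAMP_TOL = 1e-6  # nm^2; larger negative covered sums indicate a bug


@dataclass
class AssociationRecord:
    """Per-frame association coordinates (areas nm^2, lengths nm, angles deg)."""

    frame_index: int
    CA1: float
    CA2: float
    CAT: float
    CA1a: float
    CA2a: float
    CATa: float
    CA1p: float
    CA2p: float
    CATp: float
    CA1o: float
    CA2o: float
    D1: float = np.nan
    D2: float = np.nan
    D3: float = np.nan
    theta1: float = np.nan
    theta2: float = np.nan


RECORD_FIELDS = tuple(f.name for f in dc_fields(AssociationRecord))


def _clamp(x: float) -> float:
    if x < -_CLAMP_TOL:
        raise ModelError(f"covered area {x:.3e} nm^2 below -tolerance; inconsistent SASA inputs")
    return max(x, 0.0)


def covered_atom_areas(
    dimer: AtomModel,
    n_points: int = DEFAULT_N_POINTS,
    probe_radius: float | None = None,
) -> np.ndarray:
    """Per-atom covered area (partner-deleted SASA minus in-dimer SASA), nm^2."""
    monomers = dimer.present_monomers
    if len(monomers) != 2:
        raise ModelError(f"covered area needs exactly 2 monomers, got {len(monomers)}")
    full = sasa(dimer, probe_radius=probe_radius, n_points=n_points).areas
    covered = np.zeros(dimer.n_atoms)
    for m in monomers:
        mask = dimer.monomer_mask(m)
        alone = sasa(dimer.select(mask), probe_radius=probe_radius, n_points=n_points).areas
        covered[mask] = alone - full[mask]
    return covered


def covered_area(
    dimer: AtomModel,
    monomer: int,
    region: str = "all",
    n_points: int = DEFAULT_N_POINTS,
    probe_radius: float | None = None,
) -> float:
    """CA of one monomer, optionally restricted to a region tag.

    ``region`` is ``"all"``, ``"aromatic"`` or ``"peptide"`` (or ``"other"``
    for the residual).  Atoms tagged ``other`` count toward ``"all"`` but to
    neither named region.
    """
    if monomer not in dimer.present_monomers:
        raise ModelError(f"monomer {monomer} not present in dimer")
    mask = dimer.region_mask(region, monomer)
    if region != "all" and not mask.any():
        raise ModelError(f"monomer {monomer} has no atoms in region {region!r}")
    per_atom = covered_atom_areas(dimer, n_points=n_points, probe_radius=probe_radius)
    return _clamp(float(per_atom[mask].sum()))


def ring_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Oriented unit normal of the least-squares plane through ring atoms.

    The plane is fit by SVD; its normal's sign is fixed by the Newell polygon
    normal of the atoms *in their given order*, so the result is a signed,
    order-determined orientation (needed to distinguish 120 deg from 60 deg).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ModelError("ring needs >= 3 atoms")
    c = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] < 1e-9:
        raise ModelError("ring atoms are collinear; no plane is definable")
    normal = vt[2]
    newell = np.zeros(3)
    for k in range(len(c)):
        newell += np.cross(c[k], c[(k + 1) % len(c)])
    if np.dot(normal, newell) < 0:
        normal = -normal
    return normal


def ring_angle(
    model: AtomModel,
    ring_a: str | tuple[str, int],
    ring_b: str | tuple[str, int],
) -> float:
    """Angle in degrees, in [0, 180], between two ring planes.

    Rings are named by marker role, optionally scoped to a monomer:
    ``ring_angle(m, ("ringPhe", 1), ("ringMut", 1))``.
    """
    normals = []
    for ring in (ring_a, ring_b):
        role, mono = ring if isinstance(ring, tuple) else (ring, None)
        idx = model.marker_indices(role, mono)
        if len(idx) < 3:
            raise ModelError(f"ring marker {role!r} selects fewer than 3 atoms")
        normals.append(ring_plane_normal(model.coords[idx]))
    cosang = float(np.clip(np.dot(normals[0], normals[1]), -1.0, 1.0))
    return degrees(acos(cosang))


def _marker_distance(model: AtomModel, role_a: str, role_b: str) -> float:
    ia = model.marker_atom(role_a)
    ib = model.marker_atom(role_b)
    return float(np.linalg.norm(model.coords[ia] - model.coords[ib]))


def analyze_frame(
    frame: AtomModel,
    frame_index: int = 0,
    n_points: int = DEFAULT_N_POINTS,
    probe_radius: float | None = None,
) -> AssociationRecord:
    """Association record for one 2-monomer configuration."""
    per_atom = covered_atom_areas(frame, n_points=n_points, probe_radius=probe_radius)

    def region_sum(monomer: int, region: str) -> float:
        return _clamp(float(per_atom[frame.region_mask(region, monomer)].sum()))

    ca = {m: region_sum(m, "all") for m in (1, 2)}
    caa = {m: region_sum(m, "aromatic") for m in (1, 2)}
    cap = {m: region_sum(m, "peptide") for m in (1, 2)}
    cao = {m: region_sum(m, "other") for m in (1, 2)}

    def dist(ra: str, rb: str) -> float:
        try:
            return _marker_distance(frame, ra, rb)
        except ModelError:
            return np.nan

    def theta(mono: int) -> float:
        try:
            return ring_angle(frame, ("ringPhe", mono), ("ringMut", mono))
        except ModelError:
            return np.nan

    return AssociationRecord(
        frame_index=frame_index,
        CA1=ca[1], CA2=ca[2], CAT=ca[1] + ca[2],
        CA1a=caa[1], CA2a=caa[2], CATa=caa[1] + caa[2],
        CA1p=cap[1], CA2p=cap[2], CATp=cap[1] + cap[2],
        CA1o=cao[1], CA2o=cao[2],
        D1=dist("D1a", "D1b"), D2=dist("D2a", "D2b"), D3=dist("D3a", "D3b"),
        theta1=theta(1), theta2=theta(2),
    )


def analyze_trajectory(
    traj: Trajectory,
    n_points: int = DEFAULT_N_POINTS,
    probe_radius: float | None = None,
    start: int = 0,
    stop: int | None = None,
) -> list[AssociationRecord]:
    """One :class:`AssociationRecord` per frame of a 2-monomer trajectory.

    ``start``/``stop`` select an analysis window by frame index (the analysis
    window — e.g. discarding equilibration — is the caller's choice).
    """
    if traj.topology.n_monomers != 2:
        raise ModelError("association analysis requires a 2-monomer topology")
    stop = traj.n_frames if stop is None else stop
    return [
        analyze_frame(traj.frame(i), frame_index=i, n_points=n_points, probe_radius=probe_radius)
        for i in range(start, stop)
    ]


def records_to_dataframe(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{f: getattr(r, f) for f in RECORD_FIELDS} for r in records])


def dataframe_to_records(df: pd.DataFrame) -> list[AssociationRecord]:
    return [
        AssociationRecord(**{f: (int(row[f]) if f == "frame_index" else float(row[f])) for f in RECORD_FIELDS})
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Population maps
# ---------------------------------------------------------------------------


@dataclass
class PopulationMap:
    """2D occupancy histogram over two association coordinates.

    Cell values are percent of *included* frames (frames with CA_T > 0);
    the share of frames dropped because CA_T = 0 is reported separately as
    ``excluded_zero_fraction`` (percent of all frames).
    """

    x_coord: str
    y_coord: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray               # (nx, ny), percent of included frames
    excluded_zero_fraction: float    # percent of all frames
    n_total: int
    n_included: int

    def modal_cell(self) -> tuple[float, float]:
        """(x, y) centre of the most occupied cell."""
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        x = 0.5 * (self.x_edges[i] + self.x_edges[i + 1])
        y = 0.5 * (self.y_edges[j] + self.y_edges[j + 1])
        return x, y

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.values.shape[0]):
            for j in range(self.values.shape[1]):
                rows.append(
                    {
                        f"{self.x_coord}_lo": self.x_edges[i],
                        f"{self.x_coord}_hi": self.x_edges[i + 1],
                        f"{self.y_coord}_lo": self.y_edges[j],
                        f"{self.y_coord}_hi": self.y_edges[j + 1],
                        "percent": self.values[i, j],
                    }
                )
        return pd.DataFrame(rows)


def population_map(
    records: list[AssociationRecord],
    x: str = "CAT",
    y: str = "CATa",
    bin_width: float = 0.1,
) -> PopulationMap:
    """Bin association records into a 2D population map.

    Frames with CA_T = 0 (dissociated) are excluded and accounted for in
    ``excluded_zero_fraction``; included-cell percentages sum to 100.
    """
    if x not in RECORD_FIELDS or y not in RECORD_FIELDS:
        raise ModelError(f"unknown coordinate name: {x!r} / {y!r}")
    if bin_width <= 0:
        raise ModelError("bin_width must be > 0")
    if not records:
        raise ModelError("no records")
    cat = np.array([r.CAT for r in records])
    included = cat > 0.0
    n_total = len(records)
    n_inc = int(included.sum())
    if n_inc == 0:
        raise ModelError("all frames have CAT = 0; nothing to map")
    xs = np.array([getattr(r, x) for r in records])[included]
    ys = np.array([getattr(r, y) for r in records])[included]

    def edges(v: np.ndarray) -> np.ndarray:
        hi = max(float(np.nanmax(v)), bin_width)
        n_bins = int(np.ceil(hi / bin_width - 1e-9))
        return np.arange(n_bins + 1) * bin_width

    xe, ye = edges(xs), edges(ys)
    counts, _, _ = np.histogram2d(xs, ys, bins=(xe, ye))
    values = counts / n_inc * 100.0
    return PopulationMap(
        x_coord=x,
        y_coord=y,
        x_edges=xe,
        y_edges=ye,
        values=values,
        excluded_zero_fraction=100.0 * (n_total - n_inc) / n_total,
        n_total=n_total,
        n_included=n_inc,
    )
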