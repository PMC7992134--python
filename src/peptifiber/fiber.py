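"""Helical protofiber construction from a dimer seed and its characterization.

The seed dimer defines a screw transform (rotation about plus translation
along a common axis) mapping monomer 1 onto monomer 2.  Applying that
transform repeatedly stacks n monomers into a protofiber whose every
sequential pair reproduces the seed geometry — the computational analogue of
indefinite monomer addition onto a nucleation seed.

Characterization covers the helix (pitch = axial rise per 360-degree turn,
periodicity = monomers per turn), a geometric hydrogen-bond census
(donor-acceptor distance and deviation from D-H...A linearity), and
per-residue-group solvent exposure relative to the free monomer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree

from .model import AtomModel, ModelError
from .sasa import DEFAULT_N_POINTS, sasa

MIN_STERIC_DISTANCE_NM = 0.05


@dataclass
class HelixParams:
    """Screw transform per monomer: rise (nm) along ``axis``, twist (deg)."""

    rise: float
    twist: float
    axis: np.ndarray = None
    origin: np.ndarray = None

    def __post_init__(self) -> None:
        self.axis = np.array([0.0, 0.0, 1.0]) if self.axis is None else np.asarray(self.axis, float)
        self.origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ModelError("axis must be non-zero")
        self.axis = self.axis / norm
        if not self.rise > 0:
            raise ModelError("rise must be > 0")
        if not (-180.0 < self.twist <= 180.0):
            raise ModelError("twist must be in (-180, 180] degrees")

    @property
    def pitch(self) -> float:
        """Axial length of one full turn, nm."""
        if self.twist == 0:
            raise ModelError("zero twist has no defined pitch")
        return self.rise * 360.0 / abs(self.twist)

    @property
    def monomers_per_turn(self) -> float:
        if self.twist == 0:
            raise ModelError("zero twist has no defined periodicity")
        return 360.0 / abs(self.twist)

    def rotation(self) -> Rotation:
        return Rotation.from_rotvec(np.radians(self.twist) * self.axis)

    def apply(self, coords: np.ndarray, times: int = 1) -> np.ndarray:
        """Apply the screw transform ``times`` times to coordinates (nm)."""
        out = np.asarray(coords, float)
        rot = self.rotation()
        for _ in range(times):
            out = rot.apply(out - self.origin) + self.origin + self.rise * self.axis
        return out


@dataclass
class HBondCriteria:
    """Geometric H-bond definition: D...A cutoff (nm) and linearity cutoff (deg)."""

    max_da_distance: float = 0.35
    max_angle: float = 25.0

    def validate(self) -> None:
        if not (self.max_da_distance > 0 and self.max_angle > 0):
            raise ModelError("H-bond cutoffs must be positive")


@dataclass
class HBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_monomer: int
    acceptor_monomer: int
    distance: float
    angle: float


@dataclass
class FiberReport:
    n_monomers: int
    pitch: float
    monomers_per_turn: float
    hbonds_backbone_pair: int
    hbonds_other: int
    exposure_by_group: dict[str, float]


# ---------------------------------------------------------------------------
# Screw-transform fitting
# ---------------------------------------------------------------------------

_TWIST_EPS_DEG = 1e-6


def fit_screw_transform(dimer: AtomModel) -> HelixParams:
    """Screw transform best mapping monomer 1 onto monomer 2 (least squares).

    The optimal rotation comes from Kabsch superposition of the two
    same-ordered atom sets; rotation plus residual translation are then
    decomposed into twist about, rise along, and a point on, the screw axis.
    A pure translation (near-zero twist) degenerates to rise = |t| along t;
    near-zero twist combined with near-zero rise is rejected.  The twist sign
    is chosen so the rise is positive; exact 180-degree twists keep that
    convention with axis orientation along positive rise.
    """
    monomers = dimer.present_monomers
    if len(monomers) != 2:
        raise ModelError("screw fit needs a 2-monomer model")
    a = dimer.coords[dimer.monomer_mask(monomers[0])]
    b = dimer.coords[dimer.monomer_mask(monomers[1])]
    if a.shape != b.shape:
        raise ModelError("monomers have mismatched atom counts")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    t = cb - rot.apply(ca)  # full transform: x -> R x + t

    rotvec = rot.as_rotvec()
    angle = np.degrees(np.linalg.norm(rotvec))
    if angle < _TWIST_EPS_DEG:
        rise = float(np.linalg.norm(t))
        if rise < 1e-9:
            raise ModelError("degenerate screw: no rotation and no translation")
        return HelixParams(rise=rise, twist=0.0, axis=t / rise, origin=ca.copy())

    axis = rotvec / np.linalg.norm(rotvec)
    rise = float(np.dot(t, axis))
    if rise < 0:
        axis, rise, angle = -axis, -rise, -angle
    if abs(rise) < 1e-9:
        raise ModelError("degenerate screw: rotation with no rise (closed ring, not a fiber)")
    # point on the axis: solve (I - R) c = t_perp in the plane normal to axis
    t_perp = t - np.dot(t, axis) * axis
    R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    origin, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    origin = origin - np.dot(origin, axis) * axis
    twist = angle if -180.0 < angle <= 180.0 else angle - 360.0 * np.sign(angle)
    return HelixParams(rise=rise, twist=float(twist), axis=axis, origin=origin)


def build_fiber(seed: AtomModel, n: int, check_sterics: bool = True) -> AtomModel:
    """Stack ``n`` monomers by repeated application of the seed's screw transform.

    Monomer k is monomer 1 of the seed transformed (k-1) times; the result
    reproduces the seed's sequential-pair geometry exactly.  Raises on
    steric catastrophe (any interatomic distance below 0.05 nm).
    """
    if n < 2:
        raise ModelError("a fiber needs n >= 2 monomers")
    params = fit_screw_transform(seed)
    base = seed.monomer(seed.present_monomers[0])
    m = base.n_atoms

    coords = np.concatenate([params.apply(base.coords, times=k) for k in range(n)])
    markers = {
        role: np.concatenate([idx + k * m for k in range(n)])
        for role, idx in base.markers.items()
    }
    fiber = AtomModel(
        atom_ids=np.arange(1, n * m + 1),
        monomer_ids=np.repeat(np.arange(1, n + 1), m),
        residues=np.tile(base.residues, n),
        regions=np.tile(base.regions, n),
        elements=np.tile(base.elements, n),
        radii=np.tile(base.radii, n),
        coords=coords,
        markers=markers,
        probe_radius=seed.probe_radius,
    )
    if check_sterics:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(MIN_STERIC_DISTANCE_NM)
        if pairs:
            i, j = sorted(pairs)[0]
            raise ModelError(
                f"steric catastrophe: atoms {i + 1} and {j + 1} closer than "
                f"{MIN_STERIC_DISTANCE_NM} nm"
            )
    return fiber


def sequential_pair(fiber: AtomModel, k: int) -> AtomModel:
    """Monomers k and k+1 of a fiber, relabelled as a dimer (monomers 1, 2)."""
    pair = fiber.select(np.isin(fiber.monomer_ids, [k, k + 1]))
    out = pair.copy()
    out.monomer_ids = np.where(pair.monomer_ids == k, 1, 2)
    # D markers of a fiber template carry no a/b split; derive it from the pair
    for role in ("D1", "D2", "D3"):
        a_role, b_role = role + "a", role + "b"
        if out.has_marker(a_role):
            merged = np.concatenate([out.markers.get(a_role, np.empty(0, int)),
                                     out.markers.get(b_role, np.empty(0, int))])
            out.markers[a_role] = merged[out.monomer_ids[merged] == 1]
            out.markers[b_role] = merged[out.monomer_ids[merged] == 2]
    return out


# ---------------------------------------------------------------------------
# Helix measurement
# ---------------------------------------------------------------------------


def _fit_cylinder_axis(centroids: np.ndarray, axis0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Refine a helix axis so centroid radii become equal (least squares).

    The PCA direction of a helix's centroids is biased by incomplete turns;
    minimizing the spread of radial distances about a common axis removes
    that bias (exactly, for noise-free helices).  Returns (axis, point on axis).
    """
    from scipy.optimize import least_squares

    center = centroids.mean(axis=0)
    # parametrize the axis direction by small rotations about two directions
    # orthogonal to the current estimate, and the axis position in-plane
    def frame(a):
        a = a / np.linalg.norm(a)
        e1 = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(a, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(a, e1)

    def residuals(p):
        a1, a2, c1, c2 = p
        e1, e2 = frame(axis0)
        a = axis0 + a1 * e1 + a2 * e2
        a = a / np.linalg.norm(a)
        f1, f2 = frame(a)
        point = center + c1 * f1 + c2 * f2
        d = centroids - point
        radial = d - np.outer(d @ a, a)
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    sol = least_squares(residuals, x0=np.zeros(4), method="lm", xtol=1e-14, ftol=1e-14)
    a1, a2, c1, c2 = sol.x
    e1, e2 = frame(axis0)
    axis = axis0 + a1 * e1 + a2 * e2
    axis /= np.linalg.norm(axis)
    f1, f2 = frame(axis)
    return axis, center + c1 * f1 + c2 * f2


def measure_helix(fiber: AtomModel, min_monomers: int = 6) -> tuple[float, float]:
    """(pitch nm, monomers per turn) from the fiber's monomer centroids.

    The helix axis is initialized as the principal direction of the
    centroids and refined by a cylinder fit (equal centroid radii); centroid
    azimuths about the axis are unwrapped and regressed on monomer index, as
    is the axial position.  pitch = monomers_per_turn * rise_per_monomer.
    """
    monomers = fiber.present_monomers
    if len(monomers) < min_monomers:
        raise ModelError(f"helix measurement needs >= {min_monomers} monomers")
    centroids = np.array([fiber.coords[fiber.monomer_mask(m)].mean(axis=0) for m in monomers])
    center = centroids.mean(axis=0)
    c = centroids - center
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] < 1e-6 * max(s[0], 1.0):
        raise ModelError("no helix: monomer centroids are collinear")
    axis, point = _fit_cylinder_axis(centroids, vt[0])

    c = centroids - point
    z = c @ axis
    radial = c - np.outer(z, axis)
    r = np.linalg.norm(radial, axis=1)
    if np.max(r) < 1e-6:
        raise ModelError("no helix: monomer centroids are collinear")
    # in-plane basis
    e1 = radial[0] / np.linalg.norm(radial[0])
    e2 = np.cross(axis, e1)
    phi = np.unwrap(np.arctan2(radial @ e2, radial @ e1))

    k = np.arange(len(monomers), dtype=float)
    slope_phi = np.polyfit(k, phi, 1)[0]          # rad per monomer
    slope_z = np.polyfit(k, z, 1)[0]              # nm per monomer
    if abs(slope_phi) < 1e-9:
        raise ModelError("no helix: zero twist per monomer")
    monomers_per_turn = 2.0 * np.pi / abs(slope_phi)
    pitch = monomers_per_turn * abs(slope_z)
    return float(pitch), float(monomers_per_turn)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

_NH_BOND_MAX_NM = 0.15


def find_hbonds(
    model: AtomModel,
    criteria: HBondCriteria | None = None,
    include_intra: bool = False,
) -> list[HBond]:
    """Geometric H-bonds among marked donors/hydrogens/acceptors.

    A bond is reported when the donor-acceptor distance is within the cutoff
    and the D-H...A geometry deviates from linearity by at most the angle
    cutoff, the deviation being measured as the angle between the D->H and
    D->A vectors.  Intra-monomer pairs are excluded unless ``include_intra``.
    """
    criteria = criteria or HBondCriteria()
    criteria.validate()
    donors = model.marker_indices("donorN")
    hydrogens = model.marker_indices("donorH")
    acceptors = model.marker_indices("acceptorO")

    # attach each donor to its nearest marked hydrogen (same monomer, bonded range)
    donor_h: dict[int, int] = {}
    for d in donors:
        same = hydrogens[model.monomer_ids[hydrogens] == model.monomer_ids[d]]
        if len(same) == 0:
            raise ModelError(f"donor atom {int(model.atom_ids[d])} has no marked hydrogen")
        dists = np.linalg.norm(model.coords[same] - model.coords[d], axis=1)
        h = int(same[np.argmin(dists)])
        if dists.min() > _NH_BOND_MAX_NM:
            raise ModelError(
                f"donor atom {int(model.atom_ids[d])}: nearest marked hydrogen "
                f"{dists.min():.3f} nm away is not bonded"
            )
        donor_h[int(d)] = h

    bonds: list[HBond] = []
    for d in donors:
        h = donor_h[int(d)]
        dh = model.coords[h] - model.coords[d]
        for a in acceptors:
            if not include_intra and model.monomer_ids[a] == model.monomer_ids[d]:
                continue
            da = model.coords[a] - model.coords[d]
            dist = float(np.linalg.norm(da))
            if dist > criteria.max_da_distance or dist == 0.0:
                continue
            cosang = float(np.dot(dh, da) / (np.linalg.norm(dh) * dist))
            dev = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if dev <= criteria.max_angle:
                bonds.append(
                    HBond(
                        donor_index=int(d),
                        hydrogen_index=h,
                        acceptor_index=int(a),
                        donor_monomer=int(model.monomer_ids[d]),
                        acceptor_monomer=int(model.monomer_ids[a]),
                        distance=dist,
                        angle=dev,
                    )
                )
    return bonds


def hbond_census(
    model: AtomModel,
    criteria: HBondCriteria | None = None,
    donor_residue: str = "Val",
    acceptor_residue: str = "Phe",
) -> tuple[int, int]:
    """(backbone-pair count, other count) of inter-monomer H-bonds.

    The backbone pair is the Val backbone N donating to the Phe terminal O
    of an adjacent monomer; everything else falls in the second bucket.
    """
    bonds = find_hbonds(model, criteria)
    backbone = 0
    for b in bonds:
        adjacent = abs(b.donor_monomer - b.acceptor_monomer) == 1
        if (
            adjacent
            and str(model.residues[b.donor_index]) == donor_residue
            and str(model.residues[b.acceptor_index]) == acceptor_residue
        ):
            backbone += 1
    return backbone, len(bonds) - backbone


# ---------------------------------------------------------------------------
# Solvent exposure
# ---------------------------------------------------------------------------

DEFAULT_EXPOSURE_GROUPS = {
    "aromatic_mutation": "ARO",
    "Phe": "Phe",
    "Val": "Val",
    "Asp": "Asp",
}


def exposure_fractions(
    fiber: AtomModel,
    monomer_ref: AtomModel,
    groups: dict[str, str] | None = None,
    end_exclude: int = 4,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, float]:
    """Percent solvent exposure of residue groups in the fiber vs the monomer.

    For each group (atoms selected by residue label), the mean per-monomer
    SASA of the group inside the fiber is divided by the group's SASA in the
    isolated reference monomer.  Only interior monomers are averaged — the
    first and last ``end_exclude`` are dropped (clipped so that at least one
    monomer always remains) since fiber ends are artificially exposed.
    """
    groups = groups or DEFAULT_EXPOSURE_GROUPS
    monomers = fiber.present_monomers
    n = len(monomers)
    cut = min(end_exclude, (n - 1) // 2)
    interior = monomers[cut : n - cut]

    ref_res = sasa(monomer_ref, n_points=n_points)
    fib_res = sasa(fiber, n_points=n_points)

    out: dict[str, float] = {}
    for name, residue in groups.items():
        ref_mask = monomer_ref.residues == residue
        if not ref_mask.any():
            raise ModelError(f"group {name!r}: no atoms with residue {residue!r}")
        ref_area = float(ref_res.areas[ref_mask].sum())
        if ref_area <= 0:
            raise ModelError(f"group {name!r}: zero reference SASA")
        per_monomer = []
        for m in interior:
            mask = (fiber.residues == residue) & fiber.monomer_mask(m)
            per_monomer.append(float(fib_res.areas[mask].sum()))
        pct = 100.0 * float(np.mean(per_monomer)) / ref_area
        if pct > 100.0 + 5.0:  # beyond discretization tolerance: inconsistent inputs
            raise ModelError(f"group {name!r}: exposure {pct:.1f}% exceeds the monomer reference")
        out[name] = pct
    return out


def fiber_report(
    fiber: AtomModel,
    monomer_ref: AtomModel,
    hbond_criteria: HBondCriteria | None = None,
    end_exclude: int = 4,
    n_points: int = DEFAULT_N_POINTS,
) -> FiberReport:
    """Full characterization: helix, H-bond census, exposure fractions."""
    pitch, per_turn = measure_helix(fiber)
    backbone, other = hbond_census(fiber, hbond_criteria)
    exposure = exposure_fractions(fiber, monomer_ref, end_exclude=end_exclude, n_points=n_points)
    return FiberReport(
        n_monomers=fiber.n_monomers,
        pitch=pitch,
        monomers_per_turn=per_turn,
        hbonds_backbone_pair=backbone,
        hbonds_other=other,
        exposure_by_group=exposure,
    )
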