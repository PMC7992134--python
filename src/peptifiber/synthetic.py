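"""Seeded generators for toy peptide models, association trajectories and fibers.

The toy monomer is a geometric stand-in for an aryl-appended tripeptide:
an appended two-ring aromatic unit (residue ``ARO``, biphenyl-like) joined
to a Phe ring at a fixed ~120-degree inter-ring plane angle, continuing
into a peptide-region backbone (Phe, Val, Asp) and two cap atoms.  It is NOT chemically faithful
— the analysis pipeline consumes only geometry, radii and annotations, so
bond topology and force-field realism are deliberately absent.  Region tags,
ring markers, D1/D2/D3 marker carbons (para carbons of the appended ring;
a fixed Phe ring carbon) and donor/acceptor markers are all assigned.

Association trajectories plant ground truth: each frame is constructed —
not simulated — in one of three placements (aromatic stacking that satisfies
every seed criterion, peptide-side contact that satisfies none, or full
dissociation at >= 1.5 nm surface separation), so planted per-frame labels
are exact.  Default conditions mirror the emulated study: two monomers
initially 1.5 nm apart, 10 ps frame cadence, and a contact fraction of
0.681 (the associated share of simulation time observed for the coupled
tripeptide).

Fibers are built by directly applying a planted screw transform (rise
0.3667 nm, twist 60 degrees by default: pitch 2.2 nm, 6 monomers per turn),
independently of the fitting/building code under test, with exactly one
Val-N -> Phe-O hydrogen-bond geometry per sequential pair when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .fiber import HelixParams
from .model import AtomModel, ModelError, Trajectory, VDW_RADII_NM

MODES = ("dissociated", "aromatic-stack", "peptide-contact", "mixed")

_RING_RADIUS = 0.14          # nm, hexagon circumradius
_STACK_DZ = 0.30             # nm, face-to-face ring separation in contact frames
_DISSOCIATED_DZ = 2.5        # nm, centre shift guaranteeing >= 1.5 nm surface gap
_TEMPLATE_JITTER = 0.004     # nm, seeded conformational jitter on the template


@dataclass
class GeneratorSpec:
    """Ground-truth-bearing generator parameters (all lengths nm)."""

    seed: int = 0
    n_frames: int = 500
    contact_fraction: float = 0.681
    mode: str = "aromatic-stack"
    noise_sigma: float = 0.01
    helix: HelixParams | None = None
    n_monomers: int = 20
    plant_hbonds: bool = True
    frame_spacing: float = 10.0   # ps, metadata only

    def validate(self) -> None:
        if not (0.0 <= self.contact_fraction <= 1.0):
            raise ModelError("contact_fraction must be in [0, 1]")
        if self.n_frames < 1:
            raise ModelError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ModelError("noise_sigma must be >= 0")
        if self.mode not in MODES:
            raise ModelError(f"mode must be one of {MODES}")
        if self.n_monomers < 2:
            raise ModelError("n_monomers must be >= 2")

    def helix_params(self) -> HelixParams:
        return self.helix if self.helix is not None else HelixParams(rise=0.3667, twist=60.0)


# ---------------------------------------------------------------------------
# Toy monomer
# ---------------------------------------------------------------------------


def _hexagon(center: np.ndarray, rot: np.ndarray | None = None) -> np.ndarray:
    """Hexagon of ring atoms; atom order fixes the oriented plane normal (+z)."""
    ang = np.radians(60.0 * np.arange(6))
    pts = np.column_stack(
        [_RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang), np.zeros(6)]
    )
    if rot is not None:
        pts = pts @ rot.T
    return pts + center


def make_monomer(spec: GeneratorSpec) -> AtomModel:
    """Deterministic ~31-atom toy monomer with full annotation and markers."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    atoms: list[tuple[str, str, str, float, float, float]] = []

    # appended aromatic unit (residue ARO): two coplanar hexagons along -x,
    # plane normal +z; the outer ring carries the D1/D2 marker carbons
    for x, y, z in _hexagon(np.array([0.0, 0.0, 0.0])):
        atoms.append(("C", "ARO", "aromatic", x, y, z))
    for x, y, z in _hexagon(np.array([-(2 * _RING_RADIUS + 0.15), 0.0, 0.0])):
        atoms.append(("C", "ARO", "aromatic", x, y, z))
    # Phe ring, centre 0.43 nm along +x, plane rotated 120 deg about x:
    # oriented normals of the two rings then enclose 120 deg (biaryl twist)
    rot120 = Rotation.from_rotvec(np.radians(120.0) * np.array([1.0, 0.0, 0.0])).as_matrix()
    for x, y, z in _hexagon(np.array([2 * _RING_RADIUS + 0.15, 0.0, 0.0]), rot120):
        atoms.append(("C", "Phe", "aromatic", x, y, z))
    # peptide-region backbone: Phe backbone, Val, Asp, spaced ~0.15 nm along +x
    backbone = [
        ("C", "Phe", 0.72, 0.02, -0.06),    # CA
        ("C", "Phe", 0.87, -0.02, -0.06),   # C
        ("O", "Phe", 0.92, -0.15, -0.06),   # terminal O -> acceptorO
        ("N", "Val", 1.02, 0.05, -0.06),    # backbone N -> donorN
        ("H", "Val", 1.00, 0.15, -0.06),    # amide H -> donorH
        ("C", "Val", 1.17, 0.02, -0.06),    # CA
        ("C", "Val", 1.17, 0.02, -0.21),    # CB
        ("C", "Val", 1.32, -0.02, -0.06),   # C
        ("O", "Val", 1.37, -0.15, -0.06),   # O
        ("N", "Asp", 1.47, 0.05, -0.06),
        ("C", "Asp", 1.62, 0.02, -0.06),    # CA
        ("C", "Asp", 1.62, 0.02, -0.21),    # CB
        ("C", "Asp", 1.70, 0.02, -0.34),    # CG
        ("O", "Asp", 1.65, 0.10, -0.46),    # OD1
        ("O", "Asp", 1.80, -0.06, -0.38),   # OD2
        ("C", "Asp", 1.77, -0.02, -0.06),   # C
        ("O", "Asp", 1.87, -0.12, -0.06),   # OXT
    ]
    for el, res, x, y, z in backbone:
        atoms.append((el, res, "peptide", x, y, z))
    # termination caps, outside both analysis regions
    atoms.append(("C", "CAP", "other", 1.97, 0.08, -0.06))
    atoms.append(("H", "CAP", "other", 2.05, 0.00, -0.06))

    n = len(atoms)
    coords = np.array([[x, y, z] for *_np, x, y, z in atoms], dtype=float)
    coords += rng.normal(scale=_TEMPLATE_JITTER, size=coords.shape)
    elements = np.array([a[0] for a in atoms], dtype=object)
    residues = np.array([a[1] for a in atoms], dtype=object)
    regions = np.array([a[2] for a in atoms], dtype=object)
    radii = np.array([VDW_RADII_NM[e] for e in elements])

    markers = {
        "ringMut": np.arange(0, 6),
        "ringPhe": np.arange(12, 18),
        # para carbons of the outer appended ring (silver/teal pair analogues)
        "D1a": np.array([6 + 3]),
        "D2a": np.array([6 + 2]),
        # fixed Phe ring carbon (the orange atom analogue)
        "D3a": np.array([12 + 3]),
        "donorN": np.array([18 + 3]),
        "donorH": np.array([18 + 4]),
        "acceptorO": np.array([18 + 2]),
    }
    model = AtomModel(
        atom_ids=np.arange(1, n + 1),
        monomer_ids=np.ones(n, dtype=int),
        residues=residues,
        regions=regions,
        elements=elements,
        radii=radii,
        coords=coords,
        markers=markers,
    )
    model.validate()
    return model


def make_dimer_topology(template: AtomModel) -> AtomModel:
    """Two copies of a monomer template as monomers 1 and 2.

    Monomer 2's D markers are re-suffixed a -> b so that marker pairs
    (D1a, D1b) etc. span the two monomers.
    """
    n = template.n_atoms
    markers: dict[str, np.ndarray] = {}
    for role, idx in template.markers.items():
        if role.startswith("D") and role.endswith("a"):
            markers[role] = idx.copy()
            markers[role[:-1] + "b"] = idx + n
        else:
            markers[role] = np.concatenate([idx, idx + n])
    return AtomModel(
        atom_ids=np.arange(1, 2 * n + 1),
        monomer_ids=np.repeat([1, 2], n),
        residues=np.tile(template.residues, 2),
        regions=np.tile(template.regions, 2),
        elements=np.tile(template.elements, 2),
        radii=np.tile(template.radii, 2),
        coords=np.vstack([template.coords, template.coords]),
        markers=markers,
        probe_radius=template.probe_radius,
    )


# ---------------------------------------------------------------------------
# Association trajectories
# ---------------------------------------------------------------------------


def _place_aromatic_stack(mono: np.ndarray) -> np.ndarray:
    """Partner coords: 180-deg flip about the x-axis at z = dz/2.

    Stacks the appended rings face to face (D1, D2 well under 0.6 nm, D3
    under 0.8 nm) while both monomers keep the same internal conformation,
    so both ring angles stay near 120 deg: every seed criterion holds.
    """
    out = mono.copy()
    out[:, 1] = -out[:, 1]
    out[:, 2] = _STACK_DZ - out[:, 2]
    return out


def _place_peptide_contact(mono: np.ndarray) -> np.ndarray:
    """Partner coords: backbones side by side, aromatic rings far apart.

    180-deg rotation about the z-axis through (1.6, 0.25, 0): backbones run
    antiparallel 0.5 nm apart (peptide-region contact) while the ring systems
    end up > 0.7 nm from any partner atom (zero aromatic covered area).
    """
    out = mono.copy()
    out[:, 0] = 3.2 - out[:, 0]
    out[:, 1] = 0.5 - out[:, 1]
    return out


def _place_dissociated(mono: np.ndarray) -> np.ndarray:
    out = mono.copy()
    out[:, 2] += _DISSOCIATED_DZ
    return out


def make_association_trajectory(spec: GeneratorSpec) -> tuple[Trajectory, pd.DataFrame]:
    """Constructed two-monomer trajectory plus planted per-frame truth.

    Returns ``(trajectory, truth)`` where ``truth`` has one row per frame
    with columns ``frame, in_contact, contact_mode, stage1, stage2, stage3``.
    Contact frames are placed constructively (no rejection sampling), so when
    ``contact_fraction * n_frames`` is integral the planted fraction is an
    exact count.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = make_monomer(spec)
    topo = make_dimer_topology(template)
    n_atoms = template.n_atoms

    n_contact = int(round(spec.contact_fraction * spec.n_frames))
    if spec.mode == "dissociated":
        n_contact = 0
    order = rng.permutation(spec.n_frames)
    contact_frames = set(order[:n_contact].tolist())
    # in mixed mode, alternate the two contact geometries over contact frames
    contact_list = sorted(contact_frames)
    mixed_mode = {
        f: ("aromatic-stack" if i % 2 == 0 else "peptide-contact")
        for i, f in enumerate(contact_list)
    }

    frames = np.empty((spec.n_frames, 2 * n_atoms, 3))
    rows = []
    for f in range(spec.n_frames):
        if f in contact_frames:
            mode = spec.mode if spec.mode != "mixed" else mixed_mode[f]
        else:
            mode = "dissociated"
        if mode == "aromatic-stack":
            partner = _place_aromatic_stack(template.coords)
            stages = (True, True, True)
        elif mode == "peptide-contact":
            partner = _place_peptide_contact(template.coords)
            stages = (False, False, False)
        else:
            partner = _place_dissociated(template.coords)
            stages = (False, False, False)
        xyz = np.vstack([template.coords, partner])
        if spec.noise_sigma > 0:
            xyz = xyz + rng.normal(scale=spec.noise_sigma, size=xyz.shape)
        frames[f] = xyz
        rows.append(
            {
                "frame": f,
                "in_contact": f in contact_frames,
                "contact_mode": mode if f in contact_frames else "none",
                "stage1": stages[0],
                "stage2": stages[1],
                "stage3": stages[2],
            }
        )
    traj = Trajectory(topology=topo, frames=frames, frame_spacing=spec.frame_spacing)
    return traj, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fibers
# ---------------------------------------------------------------------------

_HBOND_DA_NM = 0.30       # planted donor-acceptor distance
_NH_NM = 0.10             # planted N-H bond length
_FIBER_RADIAL_OFFSET = 0.25


def make_fiber(spec: GeneratorSpec) -> tuple[AtomModel, HelixParams, int]:
    """Helical n-monomer fiber with planted screw params and H-bond geometry.

    The screw transform is applied directly (independently of the fitting
    and building code this output is used to verify).  The monomer sits with
    its aromatic rings near the helix axis and the Asp residue pointing
    outward, giving the fiber an aromatic core.  With ``plant_hbonds`` the
    template's Val N and amide H are repositioned so each monomer donates
    exactly one ideal H-bond to the previous monomer's Phe terminal O:
    planted count = n_monomers - 1.

    Returns ``(fiber, helix_params, planted_backbone_hbond_count)``.
    """
    spec.validate()
    params = spec.helix_params()
    if abs(params.twist) < 1e-9:
        raise ModelError("degenerate helix params: zero twist")
    rng = np.random.default_rng(spec.seed + 1)
    template = make_monomer(spec)
    coords = template.coords.copy()
    coords[:, 0] += _FIBER_RADIAL_OFFSET  # aromatic rings near, Asp far from, the axis

    planted = 0
    if spec.plant_hbonds:
        i_o = template.marker_atom("acceptorO")
        i_n = template.marker_atom("donorN")
        i_h = template.marker_atom("donorH")
        o = coords[i_o]
        n2_nominal = params.apply(coords[i_n][None])[0]
        direction = n2_nominal - o
        direction /= np.linalg.norm(direction)
        n2 = o + _HBOND_DA_NM * direction          # transformed-N target position
        rot_inv = params.rotation().inv()
        coords[i_n] = rot_inv.apply(n2 - params.origin - params.rise * params.axis) + params.origin
        u_local = rot_inv.apply(o - n2) / _HBOND_DA_NM
        coords[i_h] = coords[i_n] + _NH_NM * u_local
        planted = spec.n_monomers - 1

    n, m = spec.n_monomers, template.n_atoms
    all_coords = np.concatenate([params.apply(coords, times=k) for k in range(n)])
    if spec.noise_sigma > 0:
        all_coords = all_coords + rng.normal(scale=spec.noise_sigma, size=all_coords.shape)
    markers = {
        role: np.concatenate([idx + k * m for k in range(n)])
        for role, idx in template.markers.items()
    }
    fiber = AtomModel(
        atom_ids=np.arange(1, n * m + 1),
        monomer_ids=np.repeat(np.arange(1, n + 1), m),
        residues=np.tile(template.residues, n),
        regions=np.tile(template.regions, n),
        elements=np.tile(template.elements, n),
        radii=np.tile(template.radii, n),
        coords=all_coords,
        markers=markers,
        probe_radius=template.probe_radius,
    )
    fiber.validate()
    return fiber, params, planted


def make_fiber_monomer_reference(spec: GeneratorSpec) -> AtomModel:
    """The isolated reference monomer matching :func:`make_fiber` topology."""
    fiber, _, _ = make_fiber(
        GeneratorSpec(
            seed=spec.seed,
            mode=spec.mode,
            n_monomers=2,
            helix=spec.helix,
            noise_sigma=0.0,
            plant_hbonds=spec.plant_hbonds,
            n_frames=spec.n_frames,
            contact_fraction=spec.contact_fraction,
        )
    )
    return fiber.monomer(1)
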