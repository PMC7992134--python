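"""Domain types and file I/O for annotated peptide structures and trajectories.

All coordinates and lengths are in nanometres internally.  PDB files store
Angstroms; the conversion happens here, at the I/O boundary, and nowhere else.

Atom annotations (monomer membership, residue label, aromatic/peptide region,
marker roles) exceed what PDB columns can carry, so they live in a sidecar
annotation config — a flat key/value text file written and read by
:class:`AnnotationConfig`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NM_PER_ANGSTROM = 0.1

REGIONS = ("aromatic", "peptide", "other")

#: Marker roles understood by the analysis stages.  D1/D2/D3 pairs carry an
#: a/b suffix naming the monomer (a = monomer 1, b = monomer 2) unless the
#: config states the pairing explicitly.
MARKER_ROLES = frozenset(
    {
        "D1a", "D1b", "D2a", "D2b", "D3a", "D3b",
        "ringPhe", "ringMut", "donorN", "donorH", "acceptorO",
    }
)

#: Bondi van der Waals radii, nm.  Used whenever the annotation config does
#: not override an element's radius.
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "P": 0.180,
    "S": 0.180,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
}

DEFAULT_PROBE_RADIUS_NM = 0.14


class ModelError(ValueError):
    """Raised for invalid structures, annotations or file contents."""


# ---------------------------------------------------------------------------
# Annotation config
# ---------------------------------------------------------------------------


@dataclass
class AnnotationConfig:
    """Sidecar annotation: per-atom monomer/residue/region/marker assignment.

    File format is line oriented::

        probe_radius 0.14
        radius C 0.170
        atom 1 monomer=1 residue=Phe region=aromatic element=C marker=ringPhe,D3a

    ``atom`` lines key on the atom id (PDB serial / 1-based XYZ line index).
    Unlisted atoms default to monomer 1, residue ``UNK`` and region ``other``
    (excluded from region sums but still occluding).
    """

    monomer: dict[int, int] = field(default_factory=dict)
    residue: dict[int, str] = field(default_factory=dict)
    region: dict[int, str] = field(default_factory=dict)
    markers: dict[int, tuple[str, ...]] = field(default_factory=dict)
    element: dict[int, str] = field(default_factory=dict)
    radii: dict[str, float] = field(default_factory=dict)
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM
    include_hydrogens: bool = True

    def radius_for(self, element: str) -> float:
        el = element.upper()
        if el in self.radii:
            return self.radii[el]
        if el in VDW_RADII_NM:
            return VDW_RADII_NM[el]
        raise ModelError(f"no van der Waals radius known for element {element!r}")

    def validate(self) -> None:
        if self.probe_radius < 0:
            raise ModelError("probe_radius must be >= 0")
        for aid, reg in self.region.items():
            if reg not in REGIONS:
                raise ModelError(f"atom {aid}: unknown region {reg!r}")
        for aid, roles in self.markers.items():
            for role in roles:
                if role not in MARKER_ROLES:
                    raise ModelError(f"atom {aid}: unknown marker role {role!r}")
        for el, r in self.radii.items():
            if not r > 0:
                raise ModelError(f"radius for {el} must be > 0")

    # -- serialization ------------------------------------------------------

    def dumps(self) -> str:
        out = io.StringIO()
        out.write("# peptifiber annotation config\n")
        out.write(f"probe_radius {self.probe_radius:.6g}\n")
        out.write(f"include_hydrogens {'true' if self.include_hydrogens else 'false'}\n")
        for el in sorted(self.radii):
            out.write(f"radius {el} {self.radii[el]:.6g}\n")
        ids = sorted(set(self.monomer) | set(self.residue) | set(self.region) | set(self.markers) | set(self.element))
        for aid in ids:
            parts = [f"atom {aid}"]
            parts.append(f"monomer={self.monomer.get(aid, 1)}")
            parts.append(f"residue={self.residue.get(aid, 'UNK')}")
            parts.append(f"region={self.region.get(aid, 'other')}")
            if aid in self.element:
                parts.append(f"element={self.element[aid]}")
            if aid in self.markers and self.markers[aid]:
                parts.append("marker=" + ",".join(self.markers[aid]))
            out.write(" ".join(parts) + "\n")
        return out.getvalue()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "AnnotationConfig":
        cfg = cls()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            key = tokens[0]
            try:
                if key == "probe_radius":
                    cfg.probe_radius = float(tokens[1])
                elif key == "include_hydrogens":
                    cfg.include_hydrogens = tokens[1].lower() in ("true", "1", "yes")
                elif key == "radius":
                    cfg.radii[tokens[1].upper()] = float(tokens[2])
                elif key == "atom":
                    aid = int(tokens[1])
                    for kv in tokens[2:]:
                        k, _, v = kv.partition("=")
                        if k == "monomer":
                            cfg.monomer[aid] = int(v)
                        elif k == "residue":
                            cfg.residue[aid] = v
                        elif k == "region":
                            cfg.region[aid] = v
                        elif k == "element":
                            cfg.element[aid] = v
                        elif k == "marker":
                            cfg.markers[aid] = tuple(v.split(","))
                        else:
                            raise ModelError(f"unknown atom attribute {k!r}")
                else:
                    raise ModelError(f"unknown directive {key!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ModelError):
                    raise
                raise ModelError(f"annotation config line {lineno}: cannot parse {raw!r}") from exc
        cfg.validate()
        return cfg

    @classmethod
    def read(cls, path: str | Path) -> "AnnotationConfig":
        return cls.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# AtomModel
# ---------------------------------------------------------------------------


@dataclass
class AtomModel:
    """A labelled set of atoms for one or more peptide monomers.

    Arrays are parallel over atoms.  ``markers`` maps a role name to the
    positional indices (not atom ids) of the atoms carrying that role.
    """

    atom_ids: np.ndarray          # (n,) int
    monomer_ids: np.ndarray       # (n,) int
    residues: np.ndarray          # (n,) str
    regions: np.ndarray           # (n,) str, one of REGIONS
    elements: np.ndarray          # (n,) str
    radii: np.ndarray             # (n,) float, nm
    coords: np.ndarray            # (n, 3) float, nm
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM

    # -- construction -------------------------------------------------------

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        self.monomer_ids = np.asarray(self.monomer_ids, dtype=int)
        self.residues = np.asarray(self.residues, dtype=object)
        self.regions = np.asarray(self.regions, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.radii = np.asarray(self.radii, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.markers = {k: np.asarray(v, dtype=int) for k, v in self.markers.items()}

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise ModelError("model has no atoms")
        for name in ("atom_ids", "monomer_ids", "residues", "regions", "elements", "radii"):
            if len(getattr(self, name)) != n:
                raise ModelError(f"{name} length mismatch")
        if self.coords.shape != (n, 3):
            raise ModelError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ModelError("coordinates must be finite")
        if not np.all(self.radii > 0):
            raise ModelError("radii must be strictly positive")
        bad = set(self.regions) - set(REGIONS)
        if bad:
            raise ModelError(f"unknown regions {bad}")
        for role, idx in self.markers.items():
            if role not in MARKER_ROLES:
                raise ModelError(f"unknown marker role {role!r}")
            if np.any(idx < 0) or np.any(idx >= n):
                raise ModelError(f"marker {role} indexes out of range")

    # -- basic queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def present_monomers(self) -> list[int]:
        return sorted(set(self.monomer_ids.tolist()))

    @property
    def n_monomers(self) -> int:
        return len(set(self.monomer_ids.tolist()))

    def monomer_mask(self, monomer: int) -> np.ndarray:
        return self.monomer_ids == monomer

    def region_mask(self, region: str, monomer: int | None = None) -> np.ndarray:
        if region == "all":
            mask = np.ones(self.n_atoms, dtype=bool)
        else:
            if region not in REGIONS:
                raise ModelError(f"unknown region {region!r}")
            mask = self.regions == region
        if monomer is not None:
            mask = mask & self.monomer_mask(monomer)
        return mask

    def marker_indices(self, role: str, monomer: int | None = None) -> np.ndarray:
        """Positional indices of atoms carrying ``role``, optionally restricted
        to one monomer."""
        idx = self.markers.get(role)
        if idx is None or len(idx) == 0:
            raise ModelError(f"no atoms carry marker {role!r}")
        if monomer is not None:
            idx = idx[self.monomer_ids[idx] == monomer]
            if len(idx) == 0:
                raise ModelError(f"no atoms of monomer {monomer} carry marker {role!r}")
        return idx

    def marker_atom(self, role: str, monomer: int | None = None) -> int:
        """Positional index of the single atom carrying ``role``."""
        idx = self.marker_indices(role, monomer)
        if len(idx) != 1:
            raise ModelError(f"marker {role!r} selects {len(idx)} atoms, expected 1")
        return int(idx[0])

    def has_marker(self, role: str) -> bool:
        return role in self.markers and len(self.markers[role]) > 0

    # -- derived models -----------------------------------------------------

    def select(self, mask: np.ndarray) -> "AtomModel":
        """Sub-model of atoms where ``mask`` is True; markers are remapped."""
        mask = np.asarray(mask, dtype=bool)
        old_to_new = -np.ones(self.n_atoms, dtype=int)
        old_to_new[mask] = np.arange(int(mask.sum()))
        markers = {}
        for role, idx in self.markers.items():
            kept = idx[mask[idx]]
            if len(kept):
                markers[role] = old_to_new[kept]
        return AtomModel(
            atom_ids=self.atom_ids[mask],
            monomer_ids=self.monomer_ids[mask],
            residues=self.residues[mask],
            regions=self.regions[mask],
            elements=self.elements[mask],
            radii=self.radii[mask],
            coords=self.coords[mask],
            markers=markers,
            probe_radius=self.probe_radius,
        )

    def monomer(self, monomer: int) -> "AtomModel":
        return self.select(self.monomer_mask(monomer))

    def with_coords(self, coords: np.ndarray) -> "AtomModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ModelError("replacement coords have wrong shape")
        out = self.copy()
        out.coords = coords.copy()
        return out

    def copy(self) -> "AtomModel":
        return AtomModel(
            atom_ids=self.atom_ids.copy(),
            monomer_ids=self.monomer_ids.copy(),
            residues=self.residues.copy(),
            regions=self.regions.copy(),
            elements=self.elements.copy(),
            radii=self.radii.copy(),
            coords=self.coords.copy(),
            markers={k: v.copy() for k, v in self.markers.items()},
            probe_radius=self.probe_radius,
        )

    def to_config(self) -> AnnotationConfig:
        """Annotation config that reproduces this model's labels."""
        cfg = AnnotationConfig(probe_radius=self.probe_radius)
        for i in range(self.n_atoms):
            aid = int(self.atom_ids[i])
            cfg.monomer[aid] = int(self.monomer_ids[i])
            cfg.residue[aid] = str(self.residues[i])
            cfg.region[aid] = str(self.regions[i])
            cfg.element[aid] = str(self.elements[i])
        for role, idx in self.markers.items():
            for i in idx:
                aid = int(self.atom_ids[int(i)])
                cfg.markers[aid] = cfg.markers.get(aid, ()) + (role,)
        for el in sorted(set(self.elements.tolist())):
            i = int(np.nonzero(self.elements == el)[0][0])
            cfg.radii[el.upper()] = float(self.radii[i])
        return cfg


def annotate(
    atom_ids: np.ndarray,
    coords: np.ndarray,
    config: AnnotationConfig,
    elements: np.ndarray | None = None,
) -> AtomModel:
    """Build an :class:`AtomModel` from bare coordinates plus a config.

    ``elements`` from the structure file take precedence over config
    ``element=`` entries only when the config is silent.
    """
    config.validate()
    atom_ids = np.asarray(atom_ids, dtype=int)
    n = len(atom_ids)
    known = set(atom_ids.tolist())
    for aid in set(config.monomer) | set(config.region) | set(config.markers):
        if aid not in known:
            raise ModelError(f"annotation config references absent atom id {aid}")

    mono = np.array([config.monomer.get(int(a), 1) for a in atom_ids], dtype=int)
    res = np.array([config.residue.get(int(a), "UNK") for a in atom_ids], dtype=object)
    reg = np.array([config.region.get(int(a), "other") for a in atom_ids], dtype=object)
    if elements is None:
        elements = np.array(["C"] * n, dtype=object)
    el = np.array(
        [config.element.get(int(a), str(e)) for a, e in zip(atom_ids, elements)],
        dtype=object,
    )
    radii = np.array([config.radius_for(str(e)) for e in el], dtype=float)

    id_to_pos = {int(a): i for i, a in enumerate(atom_ids)}
    markers: dict[str, list[int]] = {}
    for aid, roles in config.markers.items():
        for role in roles:
            markers.setdefault(role, []).append(id_to_pos[aid])
    marker_arrays = {k: np.array(sorted(v), dtype=int) for k, v in markers.items()}

    model = AtomModel(
        atom_ids=atom_ids,
        monomer_ids=mono,
        residues=res,
        regions=reg,
        elements=el,
        radii=radii,
        coords=np.asarray(coords, dtype=float),
        markers=marker_arrays,
        probe_radius=config.probe_radius,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Fixed-topology coordinate time series.

    ``frames`` is an (n_frames, n_atoms, 3) array in nm.  ``frame_spacing``
    is metadata only (ps between consecutive frames).
    """

    topology: AtomModel
    frames: np.ndarray
    frame_spacing: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ModelError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] == 0:
            raise ModelError("trajectory has zero frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ModelError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )
        if self.frame_spacing is not None and not self.frame_spacing > 0:
            raise ModelError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame(self, i: int) -> AtomModel:
        return self.topology.with_coords(self.frames[i])

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_pdb_arrays(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All models of a PDB file -> (atom_ids, elements, coords_nm (F,N,3))."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises various parse errors
        raise ModelError(f"cannot parse PDB file {path}: {exc}") from exc
    # biotite returns an AtomArrayStack (models, atoms)
    coords_nm = np.asarray(stack.coord, dtype=float) * NM_PER_ANGSTROM
    if coords_nm.ndim == 2:
        coords_nm = coords_nm[None]
    atom_ids = np.asarray(stack.atom_id, dtype=int)
    elements = np.asarray([e.capitalize() if e else "C" for e in stack.element], dtype=object)
    return atom_ids, elements, coords_nm


def _read_xyz_arrays(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenated-XYZ frames -> (atom_ids, elements, coords_nm (F,N,3)).

    XYZ coordinates are taken to be in nm (the package's native unit for this
    simple format).
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    elements = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ModelError(f"bad XYZ atom-count line {i + 1}: {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ModelError("truncated XYZ frame")
        els, xyz = [], []
        for row in block:
            parts = row.split()
            if len(parts) < 4:
                raise ModelError(f"bad XYZ atom line: {row!r}")
            els.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements is None:
            elements = els
        elif els != elements:
            raise ModelError("XYZ frames disagree on atoms")
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise ModelError(f"no frames in XYZ file {path}")
    coords = np.asarray(frames, dtype=float)
    atom_ids = np.arange(1, coords.shape[1] + 1)
    return atom_ids, np.asarray(elements, dtype=object), coords


def _read_any(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise ModelError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return _read_xyz_arrays(path)
    return _read_pdb_arrays(path)


def read_structure(path: str | Path, config: AnnotationConfig) -> AtomModel:
    """Read a single structure (PDB or XYZ; first model if several)."""
    atom_ids, elements, coords = _read_any(path)
    return annotate(atom_ids, coords[0], config, elements)


def read_trajectory(path: str | Path, config: AnnotationConfig) -> Trajectory:
    """Read a multi-model PDB or concatenated XYZ file as a trajectory."""
    atom_ids, elements, coords = _read_any(path)
    topo = annotate(atom_ids, coords[0], config, elements)
    return Trajectory(topology=topo, frames=coords)


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _to_atom_array(model: AtomModel):
    import biotite.structure as struc

    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(model.coords / NM_PER_ANGSTROM, dtype=np.float32)
    # chain per monomer (cycled past 62 chains; the sidecar config keeps exact ids)
    arr.chain_id = np.array(
        [_CHAIN_IDS[(m - 1) % len(_CHAIN_IDS)] for m in model.monomer_ids], dtype="U4"
    )
    arr.res_id = np.asarray(model.monomer_ids, dtype=int)
    arr.res_name = np.array([str(r)[:5].upper() for r in model.residues], dtype="U5")
    arr.atom_name = np.array(
        [f"{str(e).upper()}{i % 100}" for i, e in enumerate(model.elements)], dtype="U6"
    )
    arr.element = np.array([str(e).upper() for e in model.elements], dtype="U2")
    arr.hetero = np.full(n, True)
    arr.set_annotation("atom_id", np.asarray(model.atom_ids, dtype=int))
    return arr


def write_structure(model: AtomModel, path: str | Path, config_path: str | Path | None = None) -> Path:
    """Write a PDB file plus a companion annotation config.

    Monomer ids map to chains; residue labels to residue names.  For models
    beyond the fixed-width PDB serial limit biotite's hybrid-36 extended
    numbering is used rather than truncating.
    """
    from biotite.structure.io.pdb import PDBFile

    model.validate()
    path = Path(path)
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model), hybrid36=model.n_atoms > 99999)
    pdb.write(str(path))
    cfg_path = Path(config_path) if config_path else path.with_suffix(path.suffix + ".annot")
    model.to_config().write(cfg_path)
    return path


def write_trajectory(traj: Trajectory, path: str | Path, config_path: str | Path | None = None) -> Path:
    """Write a multi-model PDB plus companion annotation config."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    arr = _to_atom_array(traj.topology)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.frames / NM_PER_ANGSTROM, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack, hybrid36=traj.topology.n_atoms > 99999)
    pdb.write(str(path))
    cfg_path = Path(config_path) if config_path else path.with_suffix(path.suffix + ".annot")
    traj.topology.to_config().write(cfg_path)
    return path


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    """Write frames as concatenated XYZ (coordinates in nm)."""
    path = Path(path)
    topo = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{topo.n_atoms}\nframe {f}\n")
            for e, (x, y, z) in zip(topo.elements, traj.frames[f]):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")
    return path
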