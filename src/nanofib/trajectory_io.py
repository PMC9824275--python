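"""Structure/trajectory I/O, report serialization and run configuration.

Internal units are nm (lengths), pseudo-ns (times), Da (masses) and e
(charges) everywhere; conversion happens only at the file boundary.
GRO files are nm-native; PDB and XYZ are written/read in Angstrom.
Reading and writing go through MDAnalysis; trajectories interchange as
multi-model PDB or XYZ plus a JSON sidecar manifest carrying the
component index, box, times and masses.
"""

from __future__ import annotations

import json
import logging
import string
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    EncodingError,
    FormatError,
    ParseError,
)

logger = logging.getLogger("nanofib")

_FORMATS = {"gro": "GRO", "pdb": "PDB", "xyz": "XYZ"}
_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt:
        f = fmt.lower()
    else:
        f = Path(path).suffix.lstrip(".").lower()
    if f not in _FORMATS:
        raise FormatError(f"unknown structure format {f!r} for {path}")
    return f


@dataclass
class StructureDocument:
    """Format-neutral structure: names/labels plus positions in nm."""

    atom_names: list[str]
    residue_names: list[str]
    residue_ids: list[int]
    chain_ids: list[str]
    positions: np.ndarray        # (N, 3) nm
    box: np.ndarray | None = None  # (3,) nm

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def read_structure(path: str, fmt: str | None = None) -> StructureDocument:
    """Read a GRO/PDB/XYZ file into nm coordinates."""
    import MDAnalysis as mda

    f = _infer_format(path, fmt)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=f.upper(), to_guess=())
        pos = u.atoms.positions.astype(float) / 10.0  # A -> nm
    except (OSError, FileNotFoundError):
        raise
    except Exception as exc:
        raise ParseError(f"could not parse {path} as {f.upper()}: {exc}") from exc
    n = len(pos)

    def attr(name, default):
        try:
            vals = getattr(u.atoms, name)
            return [str(v) for v in vals] if name != "resids" else [int(v) for v in vals]
        except Exception:
            return [default] * n

    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = u.dimensions[:3].astype(float) / 10.0
    doc = StructureDocument(
        atom_names=attr("names", "X"),
        residue_names=[r for r in attr("resnames", "UNK")],
        residue_ids=[int(v) for v in attr("resids", 1)],
        chain_ids=attr("chainIDs", "A"),
        positions=pos,
        box=box,
    )
    logger.info("read_structure: %s (%s, %d atoms)", path, f.upper(), n)
    return doc


def _build_universe(doc: StructureDocument):
    import MDAnalysis as mda

    n = doc.n_atoms
    # group consecutive atoms with equal (chain, resid) into residues
    res_keys: list[tuple[str, int]] = []
    atom_resindex = np.empty(n, dtype=np.int64)
    for i in range(n):
        key = (doc.chain_ids[i], doc.residue_ids[i])
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    seg_keys: list[str] = []
    residue_segindex = np.empty(len(res_keys), dtype=np.int64)
    for j, (cid, _) in enumerate(res_keys):
        if not seg_keys or seg_keys[-1] != cid:
            seg_keys.append(cid)
        residue_segindex[j] = len(seg_keys) - 1
    if len(seg_keys) > len(_CHAIN_IDS):
        raise EncodingError(
            f"{len(seg_keys)} chains exceed the single-character chain-id space"
        )
    u = mda.Universe.empty(
        n, n_residues=len(res_keys), n_segments=len(seg_keys),
        atom_resindex=atom_resindex, residue_segindex=residue_segindex,
        trajectory=True,
    )
    first_atom = [int(np.nonzero(atom_resindex == j)[0][0]) for j in range(len(res_keys))]
    u.add_TopologyAttr("names", doc.atom_names)
    u.add_TopologyAttr("resnames", [doc.residue_names[i] for i in first_atom])
    u.add_TopologyAttr("resids", [rk[1] for rk in res_keys])
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("chainIDs", [doc.chain_ids[i] for i in range(n)])
    u.add_TopologyAttr("elements", ["C"] * n)
    u.atoms.positions = doc.positions * 10.0  # nm -> A
    if doc.box is not None:
        u.dimensions = [*(doc.box * 10.0), 90.0, 90.0, 90.0]
    return u


def write_structure(doc: StructureDocument, path: str, fmt: str | None = None) -> str:
    """Write a structure document; round trips within format precision."""
    f = _infer_format(path, fmt)
    u = _build_universe(doc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)
    logger.info("write_structure: %s (%s, %d atoms)", path, f.upper(), doc.n_atoms)
    return path


def structure_from_arrays(
    positions: np.ndarray,
    names: list[str] | None = None,
    residue_names: list[str] | None = None,
    residue_ids: list[int] | None = None,
    chain_ids: list[str] | None = None,
    box: np.ndarray | None = None,
) -> StructureDocument:
    n = len(positions)
    return StructureDocument(
        atom_names=names or ["B"] * n,
        residue_names=residue_names or ["UNK"] * n,
        residue_ids=residue_ids or list(range(1, n + 1)),
        chain_ids=chain_ids or ["A"] * n,
        positions=np.asarray(positions, dtype=float),
        box=None if box is None else np.asarray(box, dtype=float),
    )


def fibril_to_document(fibril) -> StructureDocument:
    """One bead per residue, chains mapped to PDB chain identifiers."""
    from .fibril_builder import THREE_LETTER

    chains = [_CHAIN_IDS[c % len(_CHAIN_IDS)] for c in fibril.chain_of_residue]
    return StructureDocument(
        atom_names=["CA"] * fibril.n_residues,
        residue_names=[THREE_LETTER[n] for n in fibril.residue_names],
        residue_ids=[int(i) for i in fibril.residue_index],
        chain_ids=chains,
        positions=fibril.positions,
        box=None,
    )


def nanoparticle_to_document(np_model, box: np.ndarray | None = None) -> StructureDocument:
    return StructureDocument(
        atom_names=list(np_model.bead_names),
        residue_names=[np_model.material] * np_model.n_beads,
        residue_ids=[int(m) + 1 for m in np_model.monomer_of_bead],
        chain_ids=["A"] * np_model.n_beads,
        positions=np_model.positions,
        box=box,
    )


def write_trajectory(traj, path: str, manifest_path: str | None = None) -> str:
    """Write a trajectory as multi-model PDB (or XYZ) + JSON manifest."""
    import MDAnalysis as mda

    f = _infer_format(path, None)
    n = traj.frames.shape[1]
    doc = structure_from_arrays(traj.frames[0], box=traj.box)
    u = _build_universe(doc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=n, multiframe=True) as w:
            for k in range(traj.n_frames):
                u.atoms.positions = traj.frames[k] * 10.0
                w.write(u.atoms)
    manifest_path = manifest_path or str(Path(path).with_suffix(".json"))
    manifest = {
        "format": f,
        "times": traj.times.tolist(),
        "box": traj.box.tolist(),
        "fibril_index": traj.fibril_index.tolist(),
        "np_index": traj.np_index.tolist(),
        "masses": traj.masses.tolist(),
        "species": traj.species,
        "replica": traj.replica,
        "seed": traj.seed,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=1))
    logger.info("write_trajectory: %s + %s (%d frames)", path, manifest_path,
                traj.n_frames)
    return path


def read_trajectory(path: str, manifest_path: str | None = None):
    """Read a multi-model PDB/XYZ trajectory with its JSON manifest."""
    import MDAnalysis as mda

    from .synthetic_data import Trajectory

    manifest_path = manifest_path or str(Path(path).with_suffix(".json"))
    manifest = json.loads(Path(manifest_path).read_text())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, to_guess=())
        frames = np.array([u.atoms.positions.astype(float) / 10.0 for _ in u.trajectory])
    except Exception as exc:
        raise ParseError(f"could not parse trajectory {path}: {exc}") from exc
    return Trajectory(
        times=np.asarray(manifest["times"], dtype=float),
        frames=frames,
        box=np.asarray(manifest["box"], dtype=float),
        fibril_index=np.asarray(manifest["fibril_index"], dtype=np.int64),
        np_index=np.asarray(manifest["np_index"], dtype=np.int64),
        masses=np.asarray(manifest["masses"], dtype=float),
        species=manifest.get("species", ""),
        replica=int(manifest.get("replica", 0)),
        seed=int(manifest.get("seed", 0)),
    )


def topology_to_json(obj) -> dict:
    """Serializable topology (bead names, masses, charges, bonds)."""
    return {
        "material": obj.material,
        "n_monomers": int(obj.n_monomers),
        "bead_names": list(obj.bead_names),
        "masses": np.asarray(obj.masses, dtype=float).tolist(),
        "charges": np.asarray(obj.charges, dtype=float).tolist(),
        "bonds": [[int(i), int(j)] for i, j in obj.bonds],
    }


@dataclass
class RunConfig:
    """Resolved tunables of a pipeline run (defaults mirror the study design)."""

    cutoff: float = 0.8            # nm, contact cutoff
    persistence: int = 1           # frames, first-contact filter
    face_depth: int = 1            # layers per frontal face
    threshold: float = 0.5         # frontal fraction for the type call
    n_repeats: int = 4             # fibril unit repeats (32 chains)
    replicas: int = 8              # per species
    box: float = 20.0              # nm
    min_spacing: float = 4.0       # nm
    n_frames: int = 25
    stride: int = 5
    dt: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        logger.info("RunConfig resolved: %s", asdict(cfg))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def export_report(
    summaries,
    out_dir: str,
    shape_reports: dict | None = None,
    config: RunConfig | None = None,
) -> dict[str, str]:
    """Serialize contact summaries (and optional shape reports) to disk.

    Writes ``contacts.csv`` (per-frame counts over all systems),
    ``residue_profile.csv`` (per-position contact frequencies) and
    ``summary.json`` (per-system first contact, type, class totals,
    plus the resolved configuration for provenance).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(summaries, (list, tuple)):
        summaries = [summaries]

    frames = []
    profiles = []
    systems = []
    for s in summaries:
        pf = s.per_frame.copy()
        pf.insert(0, "species", s.species)
        pf.insert(1, "replica", s.replica)
        frames.append(pf)
        prof = s.residue_frequency.rename_axis("position").reset_index()
        prof.insert(0, "species", s.species)
        prof.insert(1, "replica", s.replica)
        profiles.append(prof)
        systems.append({
            "species": s.species,
            "replica": s.replica,
            "first_contact": s.first_contact,
            "contact_type": s.contact_type,
            "class_totals": s.class_totals,
            "cutoff": s.cutoff,
            "persistence": s.persistence,
        })
    paths = {
        "contacts": str(out / "contacts.csv"),
        "residue_profile": str(out / "residue_profile.csv"),
        "summary": str(out / "summary.json"),
    }
    (pd.concat(frames) if frames else pd.DataFrame()).to_csv(paths["contacts"], index=False)
    (pd.concat(profiles) if profiles else pd.DataFrame()).to_csv(paths["residue_profile"], index=False)
    payload: dict = {"systems": systems}
    if shape_reports:
        payload["shape"] = {
            k: [vars(r) for r in reports] for k, reports in shape_reports.items()
        }
    if config is not None:
        payload["config"] = config.to_dict()
    Path(paths["summary"]).write_text(json.dumps(payload, indent=1))
    logger.info("export_report: %d systems -> %s", len(systems), out_dir)
    return paths
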