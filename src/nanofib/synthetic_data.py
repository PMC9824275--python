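"""Nanoparticle-fibril systems and toy stochastic binding trajectories.

This module stands in for microsecond production coarse-grained MD at
desk scale: it places an assembled nanoparticle at a random pose around
the fibril and propagates it as a rigid body with overdamped Langevin
dynamics in a periodic box. Interactions are deliberately minimal —
short-range attractive wells per residue (depth set by an
:class:`InteractionMatrix`), a soft-core contact repulsion, a screened
monopole electrostatic term between the particle's net charge and each
charged residue, and an optional constant approach bias standing in for
the effective long-range attraction a cutoff pair potential cannot
supply at toy scale.

Frame times are labelled in pseudo-ns spanning a nominal 1000 ns so
downstream plots mirror the production-simulation axes; no physical
time mapping is claimed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InvalidArgumentError,
    NumericalFailureError,
    PlacementError,
)
from .fibril_builder import FibrilModel, build_fibril
from .nanoparticle_assembly import (
    AssemblyParams,
    NanoparticleModel,
    assemble_nanoparticle,
    assign_charges,
)
from .polymer_models import DEFAULT_SYSTEMS, build_chain, replicate_chains

logger = logging.getLogger("nanofib")

#: The full study design: species label -> (material, charge density, sign).
STUDY_SPECIES: dict[str, tuple[str, float, int]] = {
    "PS": ("PS", 0.0, 0),
    "PE": ("PE", 0.0, 0),
    "PP": ("PP", 0.0, 0),
    "PS4+": ("PS", 0.04, +1),
    "PS10+": ("PS", 0.10, +1),
    "PS20+": ("PS", 0.20, +1),
    "PS4-": ("PS", 0.04, -1),
    "PS10-": ("PS", 0.10, -1),
    "PS20-": ("PS", 0.20, -1),
}

REPLICAS_PER_SPECIES = 8
DEFAULT_BOX_NM = 20.0
DEFAULT_MIN_SPACING_NM = 4.0


@dataclass
class InteractionMatrix:
    """Controls of the toy generator (reduced units unless noted).

    ``affinity`` maps a residue selector to a well depth: keys may be a
    class name (``"hydrophobic"``, ``"polar"``, ``"charged"``), a
    one-letter residue code (``"F"``), or a 1-based sequence position
    (``17``). Precedence: position > residue code > class.
    """

    affinity: dict = field(default_factory=lambda: {"hydrophobic": 1.0, "polar": 0.3, "charged": 0.3})
    well_width: float = 0.6          # nm, attraction decay length
    contact_radius: float = 0.47     # nm, soft-core contact distance
    repulsion_k: float = 200.0       # reduced/nm
    cutoff: float = 3.0              # nm, short-range pair cutoff
    electrostatics: bool = True
    coulomb_strength: float = 30.0   # reduced energy*nm per e^2 (monopole surrogate)
    screening_length: float = 1.5    # nm
    temperature: float = 1.0         # reduced kT
    approach_bias: float = 6.0       # reduced force per NP bead toward target
    bias_off_distance: float = 0.7   # nm, bias released once this close
    bias_target: np.ndarray | None = None  # defaults to the fibril centroid
    # mean-field monopole term folded into the bias: the net-charge product
    # of NP and fibril adds (opposite charges) or subtracts (like charges)
    # from the approach force, per unit NP charge
    charge_bias: float = 1.0
    max_force: float = 500.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.affinity.values()):
            raise InvalidArgumentError("well depths must be >= 0")
        if self.screening_length <= 0:
            raise InvalidArgumentError("screening length must be > 0")

    def resolve(self, fibril: FibrilModel) -> np.ndarray:
        """Per-residue well depth array for *fibril*."""
        classes = fibril.classes
        depth = np.zeros(fibril.n_residues)
        for cls in ("hydrophobic", "polar", "charged"):
            if cls in self.affinity:
                depth[classes == cls] = self.affinity[cls]
        names = np.array(fibril.residue_names)
        for key, val in self.affinity.items():
            if isinstance(key, str) and len(key) == 1:
                depth[names == key] = val
        for key, val in self.affinity.items():
            if isinstance(key, (int, np.integer)):
                depth[fibril.residue_index == int(key)] = val
        return depth


def default_interactions(material: str, **overrides) -> InteractionMatrix:
    """Material presets: PS favours aromatic residues, PE/PP generic hydrophobic."""
    if material == "PS":
        aff = {"hydrophobic": 1.2, "polar": 0.3, "charged": 0.3, "F": 2.0, "Y": 1.6, "W": 1.6}
    else:
        aff = {"hydrophobic": 1.0, "polar": 0.3, "charged": 0.2}
    return InteractionMatrix(affinity=aff, **overrides)


@dataclass
class SystemConfiguration:
    """One fibril + one placed nanoparticle in a periodic box."""

    fibril: FibrilModel
    np_model: NanoparticleModel | None
    box: np.ndarray                  # (3,) nm
    fibril_positions: np.ndarray     # (n_res, 3) nm, centred in the box
    np_positions: np.ndarray | None  # (n_beads, 3) nm, placed pose
    species: str = ""
    replica: int = 0
    seed: int = 0

    @property
    def has_np(self) -> bool:
        return self.np_model is not None and self.np_positions is not None


@dataclass
class Trajectory:
    """Time-ordered frames of the fibril + NP system."""

    times: np.ndarray        # (F,) pseudo-ns, strictly increasing
    frames: np.ndarray       # (F, N, 3) nm
    box: np.ndarray          # (3,) nm
    fibril_index: np.ndarray  # bead indices of the fibril component
    np_index: np.ndarray      # bead indices of the NP component
    masses: np.ndarray        # (N,) Da
    species: str = ""
    replica: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.frames):
            raise InvalidArgumentError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidArgumentError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def place_nanoparticle_random(
    fibril: FibrilModel,
    np_model: NanoparticleModel,
    min_spacing: float = DEFAULT_MIN_SPACING_NM,
    box: float | np.ndarray = DEFAULT_BOX_NM,
    seed: int = 0,
    max_retries: int = 500,
    species: str = "",
    replica: int = 0,
) -> SystemConfiguration:
    """Place the NP at a uniformly random pose with a minimum gap.

    The fibril is centred in the box; candidate NP centroids and
    orientations are drawn uniformly until the minimum-image bead-bead
    distance between the two solutes exceeds *min_spacing*.
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    fib_pos = fibril.positions - fibril.positions.mean(axis=0) + box / 2
    tree = cKDTree(np.mod(fib_pos, box), boxsize=box)
    rng = np.random.default_rng(seed)
    centered = np_model.positions - np_model.positions.mean(axis=0)
    for _ in range(max_retries):
        rot = _random_rotation(rng)
        centroid = rng.uniform(0.0, box)
        np_pos = centered @ rot.T + centroid
        d, _ = tree.query(np.mod(np_pos, box), k=1)
        if d.min() > min_spacing:
            logger.info(
                "place_nanoparticle_random: species=%s replica=%d gap=%.2fnm seed=%d",
                species or np_model.material, replica, d.min(), seed,
            )
            return SystemConfiguration(
                fibril=fibril,
                np_model=np_model,
                box=box,
                fibril_positions=fib_pos,
                np_positions=np_pos,
                species=species or np_model.material,
                replica=replica,
                seed=seed,
            )
    raise PlacementError(
        f"could not place NP with a {min_spacing} nm gap in a {box} nm box "
        f"after {max_retries} attempts"
    )


def simulate_toy_trajectory(
    config: SystemConfiguration,
    interactions: InteractionMatrix | None = None,
    n_frames: int = 25,
    dt: float = 0.01,
    seed: int = 0,
    stride: int = 5,
    pseudo_duration: float = 1000.0,
    friction: float = 1.0,
) -> Trajectory:
    """Rigid-body overdamped Langevin motion of the NP around a fixed fibril.

    Emits ``n_frames`` frames (the first is the initial state) at a
    fixed stride of integration steps; bit-reproducible for a fixed
    (config, interactions, seed) triple.
    """
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    fibril = config.fibril
    box = config.box
    fib_pos = config.fibril_positions
    n_fib = len(fib_pos)

    if not config.has_np:
        # control system: fibril alone, static frames
        frames = np.repeat(fib_pos[None], n_frames, axis=0)
        return Trajectory(
            times=np.linspace(0.0, pseudo_duration, n_frames),
            frames=frames,
            box=box,
            fibril_index=np.arange(n_fib),
            np_index=np.arange(0),
            masses=np.full(n_fib, 110.0),
            species=config.species,
            replica=config.replica,
            seed=seed,
        )

    inter = interactions or default_interactions(config.np_model.material)
    npm = config.np_model
    np_pos = config.np_positions.copy()
    n_np = npm.n_beads
    depth = inter.resolve(fibril)
    res_q = fibril.charges
    charged_res = np.nonzero(res_q)[0]
    np_q = npm.charges
    charged_np = np.nonzero(np_q)[0]
    np_total_q = float(np_q.sum())
    fib_total_q = float(res_q.sum())

    fib_tree = cKDTree(np.mod(fib_pos, box), boxsize=box)
    target = inter.bias_target if inter.bias_target is not None else fib_pos.mean(axis=0)

    gamma_t = friction * n_np
    rg2 = float(((np_pos - np_pos.mean(axis=0)) ** 2).sum(axis=1).mean())
    gamma_r = friction * n_np * max(rg2, 1e-6)
    kT = inter.temperature
    noise_t = math.sqrt(2.0 * kT * dt / gamma_t)
    noise_r = math.sqrt(2.0 * kT * dt / gamma_r)
    rng = np.random.default_rng(seed)

    skin = 0.5
    refresh = 5
    pairs_i = pairs_j = None

    frames = np.empty((n_frames, n_fib + n_np, 3))
    frames[0, :n_fib] = fib_pos
    frames[0, n_fib:] = np_pos

    steps_total = (n_frames - 1) * stride
    for step in range(steps_total):
        if step % refresh == 0:
            lists = fib_tree.query_ball_point(
                np.mod(np_pos, box), inter.cutoff + skin, return_sorted=False
            )
            pairs_i = np.repeat(np.arange(n_np), [len(l) for l in lists])
            pairs_j = np.fromiter(
                (j for l in lists for j in l), dtype=np.int64, count=len(pairs_i)
            )
        centroid = np_pos.mean(axis=0)
        force = np.zeros(3)
        torque = np.zeros(3)
        r_min = np.inf
        if len(pairs_i):
            d = _min_image(np_pos[pairs_i] - fib_pos[pairs_j], box)
            r = np.linalg.norm(d, axis=1)
            if not np.all(np.isfinite(r)) or np.any(r == 0):
                raise NumericalFailureError("non-finite or zero pair distance")
            r_min = float(r.min())
            mask = r < inter.cutoff
            if mask.any():
                pi, pj, d, r = pairs_i[mask], pairs_j[mask], d[mask], r[mask]
                rc = inter.contact_radius
                mag = np.where(
                    r < rc,
                    inter.repulsion_k * (rc - r),      # soft-core push apart
                    -depth[pj] * np.exp(-(r - rc) / inter.well_width),
                )
                np.clip(mag, -inter.max_force, inter.max_force, out=mag)
                fv = (mag / r)[:, None] * d
                force += fv.sum(axis=0)
                torque += np.cross(np_pos[pi] - centroid, fv).sum(axis=0)
        if inter.electrostatics and len(charged_np) and len(charged_res):
            # screened Coulomb between charged NP beads and charged residues
            d = _min_image(
                np_pos[charged_np][:, None, :] - fib_pos[charged_res][None, :, :],
                box,
            )
            r = np.sqrt((d**2).sum(axis=2))
            lam = inter.screening_length
            mag = (
                inter.coulomb_strength
                * np.outer(np_q[charged_np], res_q[charged_res])
                * np.exp(-r / lam)
                * (1.0 / r**2 + 1.0 / (lam * r))
            )
            np.clip(mag, -inter.max_force, inter.max_force, out=mag)
            fv = (mag / r)[:, :, None] * d
            f_el = fv.sum(axis=(0, 1))
            force += f_el
            torque += np.cross(
                np_pos[charged_np] - centroid, fv.sum(axis=1)
            ).sum(axis=0)
        # constant approach bias toward the target, released on contact;
        # like-charged solutes see the bias reversed (mean-field monopole)
        eff_bias = inter.approach_bias
        if inter.electrostatics and fib_total_q != 0.0:
            eff_bias -= (
                inter.charge_bias * np_total_q * fib_total_q / abs(fib_total_q)
            )
        if eff_bias != 0.0 and (eff_bias < 0.0 or r_min > inter.bias_off_distance):
            to_target = _min_image(target - centroid, box)
            dist = np.linalg.norm(to_target)
            if dist > 1e-9:
                force += eff_bias * n_np * to_target / dist

        if not np.all(np.isfinite(force)) or not np.all(np.isfinite(torque)):
            raise NumericalFailureError("non-finite net force or torque")
        dc = (dt / gamma_t) * force + noise_t * rng.normal(size=3)
        # translational step cap keeps the overdamped integrator stable
        step_norm = np.linalg.norm(dc)
        if step_norm > 0.3:
            dc *= 0.3 / step_norm
        dtheta = (dt / gamma_r) * torque + noise_r * rng.normal(size=3)
        angle = np.linalg.norm(dtheta)
        if step_norm > 0.0 or angle > 1e-12:
            rel = np_pos - centroid
            if angle > 1e-12:
                axis = dtheta / angle
                k = np.array([
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ])
                rot = np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
                rel = rel @ rot.T
            np_pos = rel + np.mod(centroid + dc, box)

        if (step + 1) % stride == 0:
            f = (step + 1) // stride
            frames[f, :n_fib] = fib_pos
            frames[f, n_fib:] = np_pos

    masses = np.concatenate([np.full(n_fib, 110.0), npm.masses])
    return Trajectory(
        times=np.linspace(0.0, pseudo_duration, n_frames),
        frames=frames,
        box=box,
        fibril_index=np.arange(n_fib),
        np_index=np.arange(n_fib, n_fib + n_np),
        masses=masses,
        species=config.species,
        replica=config.replica,
        seed=seed,
    )


def _derive_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence((master_seed,) + key)
    return int(ss.generate_state(1)[0] % (2**31))


def build_study_nanoparticles(
    master_seed: int,
    assembly_params: AssemblyParams | None = None,
    chain_counts: dict[str, tuple[int, int]] | None = None,
) -> dict[str, NanoparticleModel]:
    """Assemble one NP per study species (charged variants share the PS body)."""
    counts = chain_counts or DEFAULT_SYSTEMS
    bodies: dict[str, NanoparticleModel] = {}
    for mi, (mat, (n_chains, n_mono)) in enumerate(sorted(counts.items())):
        # random-walk conformations keep long chains inside the box
        chain = build_chain(mat, n_mono, seed=_derive_seed(master_seed, 0, mi),
                            conformation="walk")
        system = replicate_chains(chain, n_chains, box=24.0,
                                  seed=_derive_seed(master_seed, 1, mi),
                                  max_retries=2000)
        bodies[mat] = assemble_nanoparticle(
            system, assembly_params, seed=_derive_seed(master_seed, 2, mi)
        )
    nps: dict[str, NanoparticleModel] = {}
    for i, (label, (mat, density, sign)) in enumerate(STUDY_SPECIES.items()):
        if density == 0.0:
            nps[label] = bodies[mat]
        else:
            nps[label] = assign_charges(
                bodies[mat], density, sign, placement="surface",
                seed=_derive_seed(master_seed, 3, i),
            )
    return nps


@dataclass
class FixtureSystem:
    species: str
    replica: int
    config: SystemConfiguration
    trajectory: Trajectory


def generate_study_fixtures(
    master_seed: int,
    scale: float = 1.0,
    fibril: FibrilModel | None = None,
    assembly_params: AssemblyParams | None = None,
    chain_counts: dict[str, tuple[int, int]] | None = None,
    n_frames_base: int = 25,
    stride: int = 5,
) -> list[FixtureSystem]:
    """Enumerate the full study design at toy scale.

    Nine NP species (PS, PE, PP and the six charged PS variants) with
    eight random-pose replicas each, plus eight NP-free control systems:
    80 systems in total. *scale* multiplies the frame count; per-system
    seeds derive deterministically from *master_seed*.
    """
    if scale <= 0:
        raise InvalidArgumentError("scale must be > 0")
    n_frames = max(2, int(round(n_frames_base * scale)))
    fib = fibril if fibril is not None else build_fibril(4, seed=_derive_seed(master_seed, 99))
    nps = build_study_nanoparticles(master_seed, assembly_params, chain_counts)
    out: list[FixtureSystem] = []
    for si, (label, np_model) in enumerate(nps.items()):
        inter = default_interactions(STUDY_SPECIES[label][0])
        for rep in range(REPLICAS_PER_SPECIES):
            cfg = place_nanoparticle_random(
                fib, np_model,
                seed=_derive_seed(master_seed, 10 + si, rep),
                species=label, replica=rep,
            )
            traj = simulate_toy_trajectory(
                cfg, inter, n_frames=n_frames, stride=stride,
                seed=_derive_seed(master_seed, 100 + si, rep),
            )
            out.append(FixtureSystem(label, rep, cfg, traj))
    # NP-free controls
    box = np.full(3, DEFAULT_BOX_NM)
    for rep in range(REPLICAS_PER_SPECIES):
        cfg = SystemConfiguration(
            fibril=fib, np_model=None, box=box,
            fibril_positions=fib.positions - fib.positions.mean(axis=0) + box / 2,
            np_positions=None, species="control", replica=rep,
            seed=_derive_seed(master_seed, 50, rep),
        )
        traj = simulate_toy_trajectory(
            cfg, None, n_frames=n_frames, stride=stride,
            seed=_derive_seed(master_seed, 150, rep),
        )
        out.append(FixtureSystem("control", rep, cfg, traj))
    logger.info("generate_study_fixtures: %d systems, %d frames each", len(out), n_frames)
    return out


def make_probe_nanoparticle(
    n_beads: int = 32,
    radius: float = 0.8,
    material: str = "PS",
    seed: int = 0,
) -> NanoparticleModel:
    """Compact bead-ball probe particle (synthetic, not chain-assembled).

    Used by the constructed-truth recovery checks: its contact footprint
    is smaller than a fibril face, so where it binds is unambiguous.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_beads, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.uniform(0.0, 1.0, n_beads)[:, None] ** (1.0 / 3.0)
    pts -= pts.mean(axis=0)
    return NanoparticleModel(
        material=material,
        positions=pts,
        masses=np.full(n_beads, 50.0),
        charges=np.zeros(n_beads),
        bonds=[(i, i + 1) for i in range(n_beads - 1)],
        n_monomers=n_beads,
        monomer_of_bead=np.arange(n_beads),
        bead_names=["P"] * n_beads,
        seed=seed,
    )


def make_steered_config(
    fibril: FibrilModel,
    np_model: NanoparticleModel,
    target: str | list[int] = "side",
    gap: float = 1.0,
    box: float | np.ndarray = DEFAULT_BOX_NM,
    seed: int = 0,
) -> tuple[SystemConfiguration, InteractionMatrix]:
    """Build a config + interactions steered to bind a designated region.

    *target* is ``"frontal"`` (park beyond one growth end), ``"side"``
    (park against the lateral surface) or a list of sequence positions
    (park against that stripe and deepen only those wells). Used by the
    end-to-end parameter-recovery checks.
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    fib_pos = fibril.positions - fibril.positions.mean(axis=0) + box / 2
    fib_com = fib_pos.mean(axis=0)
    axis = fibril.axis / np.linalg.norm(fibril.axis)
    proj = (fib_pos - fib_com) @ axis
    rng = np.random.default_rng(seed)
    centered = np_model.positions - np_model.positions.mean(axis=0)
    np_radius = np.linalg.norm(centered, axis=1).max()

    if isinstance(target, str) and target == "frontal":
        # park on the fibril axis just beyond the growth end
        direction = axis
        anchor = fib_com + axis * proj.max()
        inter = InteractionMatrix(
            affinity={"hydrophobic": 0.1, "polar": 0.1, "charged": 0.1},
            electrostatics=False, temperature=0.3,
        )
    elif isinstance(target, str) and target == "side":
        mid = np.abs(proj) < 0.15 * (proj.max() - proj.min())
        lateral = fib_pos[mid] - fib_com
        lateral -= np.outer(lateral @ axis, axis)
        k = np.argmax(np.linalg.norm(lateral, axis=1))
        anchor = fib_pos[mid][k]
        direction = lateral[k] / np.linalg.norm(lateral[k])
        inter = InteractionMatrix(
            affinity={"hydrophobic": 0.1, "polar": 0.1, "charged": 0.1},
            electrostatics=False, temperature=0.3,
        )
    else:
        # pick the most laterally exposed chain instance of the target
        # stripe in the mid-fibril region and approach along its outward
        # normal (perpendicular to both the axis and the local backbone)
        targets = np.sort(np.asarray(target, dtype=int))
        mid = np.abs(proj) < 0.3 * (proj.max() - proj.min())
        best_chain, best_lat = -1, -1.0
        for c in range(fibril.n_chains):
            idx = c * 42 + (targets - 1)
            if not mid[idx].all():
                continue
            stripe = fib_pos[idx].mean(axis=0)
            v = stripe - fib_com
            lat = np.linalg.norm(v - (v @ axis) * axis)
            if lat > best_lat:
                best_chain, best_lat = c, lat
        if best_chain < 0:
            best_chain = 0
        idx = best_chain * 42 + (targets - 1)
        anchor = fib_pos[idx].mean(axis=0)
        tangent = fib_pos[idx[-1]] - fib_pos[idx[0]]
        tangent /= max(np.linalg.norm(tangent), 1e-9)
        out = anchor - fib_com
        out -= (out @ axis) * axis
        out -= (out @ tangent) * tangent
        n = np.linalg.norm(out)
        direction = out / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
        aff: dict = {"hydrophobic": 0.05, "polar": 0.05, "charged": 0.05}
        aff.update({int(p): 1.0 for p in targets})
        inter = InteractionMatrix(affinity=aff, electrostatics=False,
                                  temperature=0.3)
    # tweezer-style hold: the bias target is the resting point of the NP
    # centroid, a standoff outside the surface, and the bias never releases
    standoff = 0.45
    inter.bias_target = anchor + direction * (np_radius + standoff)
    inter.bias_off_distance = 0.0

    rot = _random_rotation(rng)
    centroid = inter.bias_target + direction * gap
    cfg = SystemConfiguration(
        fibril=fibril,
        np_model=np_model,
        box=box,
        fibril_positions=fib_pos,
        np_positions=centered @ rot.T + centroid,
        species=f"steered-{target}",
        replica=0,
        seed=seed,
    )
    return cfg, inter
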