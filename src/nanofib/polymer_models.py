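"""Coarse-grained mappings and chain builders for PS, PE and PP.

The bead models follow the 4-heavy-atoms-per-bead convention common in
coarse-grained polymer force fields:

* **PS** — four beads per styrene monomer: one backbone bead for the
  CH2-CH group plus three beads for the phenyl ring.
* **PE** — one bead per four backbone carbons, i.e. one bead per two
  C2H4 monomers (chains should therefore have even monomer counts).
* **PP** — one bead per propylene monomer (three heavy atoms per bead;
  a slightly finer granularity accepted for tacticity-free chains).

Chains are built as zig-zag backbones with a seeded random rigid
orientation; nanoparticle assembly later erases all memory of the
initial conformation, so no attempt is made at equilibrium statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, PackingError, UnsupportedMaterialError

logger = logging.getLogger("nanofib")

#: Monomer molecular weights in Da (styrene, ethylene, propylene).
MONOMER_MASS_DA = {"PS": 104.15, "PE": 28.05, "PP": 42.08}

#: Default clash distance between beads of different chains, nm (one bead diameter).
CLASH_DISTANCE_NM = 0.47

#: Default multi-chain systems per material: (n_chains, n_monomers).
DEFAULT_SYSTEMS = {"PS": (9, 50), "PE": (18, 160), "PP": (12, 160)}


@dataclass(frozen=True)
class BeadTemplate:
    name: str
    mass: float  # Da
    charge: float = 0.0  # e
    vdw_radius: float = 0.235  # nm (half a 0.47 nm bead diameter)


@dataclass(frozen=True)
class MappingSpec:
    """How one chemical monomer maps onto coarse-grained beads."""

    material: str
    beads_per_monomer: Fraction
    bead_templates: tuple[BeadTemplate, ...]
    bonds_within_monomer: tuple[tuple[int, int], ...]
    bond_to_next_monomer: tuple[int, int]
    backbone_bond_length: float = 0.30  # nm
    #: template index of the bead that carries a monomer charge when charged
    charge_carrier: int = 0

    def __post_init__(self) -> None:
        if self.beads_per_monomer <= 0:
            raise InvalidArgumentError("beads_per_monomer must be positive")
        if any(t.mass <= 0 for t in self.bead_templates):
            raise InvalidArgumentError("bead masses must be positive")
        n = len(self.bead_templates)
        for i, j in self.bonds_within_monomer:
            if not (0 <= i < n and 0 <= j < n):
                raise InvalidArgumentError("bond index outside template slots")

    @property
    def monomers_per_emission(self) -> int:
        """Chemical monomers consumed per emitted bead group (PE: 2)."""
        return self.beads_per_monomer.denominator

    @property
    def beads_per_emission(self) -> int:
        return self.beads_per_monomer.numerator


# Bead masses chosen so the CG mass of a monomer equals its chemical mass:
# PS 27.05 (CH2-CH) + 3 x 25.70 (phenyl thirds) = 104.15 Da.
_MAPPINGS: dict[str, MappingSpec] = {
    "PS": MappingSpec(
        material="PS",
        beads_per_monomer=Fraction(4, 1),
        bead_templates=(
            BeadTemplate("BB", 27.05),
            BeadTemplate("R1", 25.70),
            BeadTemplate("R2", 25.70),
            BeadTemplate("R3", 25.70),
        ),
        bonds_within_monomer=((0, 1), (1, 2), (2, 3), (3, 1)),
        bond_to_next_monomer=(0, 0),
        backbone_bond_length=0.27,
        charge_carrier=0,
    ),
    "PE": MappingSpec(
        material="PE",
        beads_per_monomer=Fraction(1, 2),  # one bead per two C2H4 monomers
        bead_templates=(BeadTemplate("C4", 56.10),),
        bonds_within_monomer=(),
        bond_to_next_monomer=(0, 0),
        backbone_bond_length=0.47,
    ),
    "PP": MappingSpec(
        material="PP",
        beads_per_monomer=Fraction(1, 1),
        bead_templates=(BeadTemplate("C3", 42.08),),
        bonds_within_monomer=(),
        bond_to_next_monomer=(0, 0),
        backbone_bond_length=0.36,
    ),
}


def get_cg_mapping(material: str) -> MappingSpec:
    """Return the default coarse-grained mapping for a supported material.

    Raises
    ------
    UnsupportedMaterialError
        If *material* is not one of PS, PE, PP.
    """
    try:
        return _MAPPINGS[material]
    except KeyError:
        raise UnsupportedMaterialError(
            f"no CG mapping for material {material!r}; supported: "
            f"{sorted(_MAPPINGS)}"
        ) from None


@dataclass
class PolymerChain:
    """One linear CG polymer chain.

    ``positions`` are in nm; ``charges`` in e; ``masses`` in Da. Bonds are
    pairs of bead indices. ``monomer_of_bead[i]`` is the 0-based chemical
    monomer index the bead belongs to (for PE one bead spans two monomers
    and is attributed to the first).
    """

    material: str
    n_monomers: int
    bead_names: list[str]
    masses: np.ndarray
    charges: np.ndarray
    positions: np.ndarray
    bonds: list[tuple[int, int]]
    monomer_of_bead: np.ndarray

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def cg_mass(self) -> float:
        """Sum of CG bead masses, Da."""
        return float(self.masses.sum())

    def copy(self) -> "PolymerChain":
        return PolymerChain(
            material=self.material,
            n_monomers=self.n_monomers,
            bead_names=list(self.bead_names),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            positions=self.positions.copy(),
            bonds=list(self.bonds),
            monomer_of_bead=self.monomer_of_bead.copy(),
        )


@dataclass
class ChainSystem:
    """Multiple chains placed in a periodic box (lengths in nm)."""

    chains: list[PolymerChain]
    box: np.ndarray  # (3,) nm

    @property
    def n_beads(self) -> int:
        return sum(c.n_beads for c in self.chains)

    @property
    def n_monomers(self) -> int:
        return sum(c.n_monomers for c in self.chains)

    def concatenated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
        """Stack (positions, masses, charges) and globally renumber bonds."""
        pos = np.concatenate([c.positions for c in self.chains])
        mass = np.concatenate([c.masses for c in self.chains])
        q = np.concatenate([c.charges for c in self.chains])
        bonds: list[tuple[int, int]] = []
        off = 0
        for c in self.chains:
            bonds.extend((i + off, j + off) for i, j in c.bonds)
            off += c.n_beads
        return pos, mass, q, bonds


def build_chain(
    material: str,
    n_monomers: int,
    seed: int = 0,
    conformation: str = "zigzag",
) -> PolymerChain:
    """Build one linear chain of *n_monomers* chemical monomers.

    The default conformation is a planar zig-zag backbone given a seeded
    uniformly random rigid orientation, so equal seeds are bit-identical
    and different seeds differ. ``conformation="walk"`` instead grows a
    correlated random walk backbone.
    """
    if n_monomers < 1:
        raise InvalidArgumentError(f"n_monomers must be >= 1, got {n_monomers}")
    mapping = get_cg_mapping(material)
    mpe = mapping.monomers_per_emission
    if n_monomers % mpe:
        warnings.warn(
            f"{material} maps {mpe} monomers per bead; rounding "
            f"{n_monomers} down to {n_monomers - n_monomers % mpe}",
            stacklevel=2,
        )
        n_monomers -= n_monomers % mpe
        if n_monomers < 1:
            raise InvalidArgumentError(
                f"too few monomers for the {material} mapping granularity"
            )
    n_groups = n_monomers // mpe
    rng = np.random.default_rng(seed)

    b = mapping.backbone_bond_length
    backbone = np.zeros((n_groups, 3))
    if conformation == "zigzag":
        # tetrahedral-ish zig-zag in the xz plane
        half_angle = np.deg2rad(0.5 * 109.5)
        dx = b * np.sin(half_angle)
        dz = b * np.cos(half_angle)
        backbone[:, 0] = np.arange(n_groups) * dx
        backbone[:, 2] = (np.arange(n_groups) % 2) * dz
    elif conformation == "walk":
        # weakly persistent random walk: compact enough to pack many
        # long chains into a working box
        d = _random_unit(rng)
        for i in range(1, n_groups):
            d = d + 1.2 * _random_unit(rng)
            d /= np.linalg.norm(d)
            backbone[i] = backbone[i - 1] + b * d
    else:
        raise InvalidArgumentError(f"unknown conformation {conformation!r}")

    templates = mapping.bead_templates
    k = len(templates)
    names: list[str] = []
    masses = np.empty(n_groups * k)
    charges = np.zeros(n_groups * k)
    positions = np.empty((n_groups * k, 3))
    monomer_of_bead = np.empty(n_groups * k, dtype=np.int64)
    bonds: list[tuple[int, int]] = []

    side = np.array([0.0, 0.23, 0.0])  # ring beads offset off the backbone plane
    for g in range(n_groups):
        base = g * k
        for t, tpl in enumerate(templates):
            names.append(tpl.name)
            masses[base + t] = tpl.mass
            charges[base + t] = tpl.charge
            # side-group beads fan out perpendicular to the backbone
            positions[base + t] = backbone[g] + t * side * (1 if g % 2 == 0 else -1)
            monomer_of_bead[base + t] = g * mpe
        bonds.extend((base + i, base + j) for i, j in mapping.bonds_within_monomer)
        if g:
            i, j = mapping.bond_to_next_monomer
            bonds.append(((g - 1) * k + i, base + j))

    # seeded random rigid orientation
    positions = positions @ _random_rotation(rng).T

    return PolymerChain(
        material=material,
        n_monomers=n_monomers,
        bead_names=names,
        masses=masses,
        charges=charges,
        positions=positions,
        bonds=bonds,
        monomer_of_bead=monomer_of_bead,
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def replicate_chains(
    chain: PolymerChain,
    n_copies: int,
    box: float | np.ndarray = 20.0,
    seed: int = 0,
    clash_distance: float = CLASH_DISTANCE_NM,
    max_retries: int = 500,
) -> ChainSystem:
    """Place *n_copies* rigid copies of *chain* at random non-clashing poses.

    Each copy gets a random rotation and a random translation inside the
    box; a placement is accepted only if every bead is at least
    *clash_distance* from all previously placed beads.

    Raises
    ------
    PackingError
        If a copy cannot be placed within *max_retries* attempts.
    """
    if n_copies < 1:
        raise InvalidArgumentError(f"n_copies must be >= 1, got {n_copies}")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)

    centered = chain.positions - chain.positions.mean(axis=0)
    extent = np.linalg.norm(centered, axis=1).max()
    chains: list[PolymerChain] = []
    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    for _ in range(n_copies):
        for attempt in range(max_retries):
            rot = _random_rotation(rng)
            pos = centered @ rot.T
            lo = np.minimum(extent, box / 2)
            if np.all(box - 2 * lo > 0):
                origin = rng.uniform(lo, box - lo)
            else:
                # chain comparable to the box: drop the containment
                # constraint and rely on the clash check alone
                origin = rng.uniform(0.0, box)
            pos = pos + origin
            if tree is None or not tree.query_ball_point(pos, clash_distance, return_length=True).any():
                c = chain.copy()
                c.positions = pos
                chains.append(c)
                placed.append(pos)
                tree = cKDTree(np.concatenate(placed))
                break
        else:
            raise PackingError(
                f"could not place chain copy {len(chains) + 1}/{n_copies} in a "
                f"{box} nm box after {max_retries} attempts"
            )
    logger.info(
        "replicate_chains: material=%s copies=%d monomers=%d box=%s seed=%d",
        chain.material, n_copies, chains[0].n_monomers, box.tolist(), seed,
    )
    return ChainSystem(chains=chains, box=box)


def chemical_mass(chain: PolymerChain) -> float:
    """Chemical molecular weight of the chain in Da (monomer count x monomer MW).

    The CG bead-mass total is available as ``chain.cg_mass``.
    """
    if chain.n_beads == 0 or chain.n_monomers == 0:
        raise InvalidArgumentError("chain is empty")
    return chain.n_monomers * MONOMER_MASS_DA[chain.material]
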