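"""Collapse multi-chain systems into spheroidal nanoparticles.

The assembly substitutes a desk-scale surrogate for vacuum MD: beads
feel a short-range Lennard-Jones-like attraction, harmonic bonded
springs, an optional Debye-screened Coulomb term when charges are
present, and a weak centering pull (scaled by the attraction strength)
that stands in for the long-range part of cohesion a cutoff pair
potential cannot provide at toy scale. Positions evolve by overdamped
Langevin dynamics followed by a short zero-temperature descent.

The goal is the geometric outcome — a compact spheroidal bead cluster,
or fragmentation when electrostatic repulsion wins — not the energetics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InvalidArgumentError,
    NumericalFailureError,
    UndefinedStatisticError,
)
from .polymer_models import ChainSystem, PolymerChain, get_cg_mapping

logger = logging.getLogger("nanofib")


@dataclass
class AssemblyParams:
    """Tunables of the toy collapse (reduced units unless noted)."""

    epsilon: float = 1.0          # attraction well depth
    sigma: float = 0.47           # nm, bead diameter
    cutoff: float = 1.2           # nm, pair interaction cutoff
    bond_k: float = 500.0         # spring constant, reduced/nm^2
    coulomb_strength: float = 40.0  # reduced energy * nm per e^2
    screening_length: float | None = None  # nm; None = unscreened (vacuum)
    # mean-field cohesion: chains are pulled rigidly (per-chain centroid)
    # toward the system centroid during the gather phase, then the pull is
    # dropped to centering_k_end so late-stage structure is decided by the
    # pair interactions alone
    centering_k_start: float = 12.0
    centering_k_end: float = 0.02
    gather_frac: float = 0.35     # fraction of n_steps in the gather phase
    temperature: float = 0.1      # reduced kT
    dt: float = 2.0e-4            # reduced time step
    n_steps: int = 1200
    n_minimize: int = 150
    friction: float = 1.0
    max_force: float = 500.0      # force cap preventing singular LJ kicks
    electrostatics: bool = True
    neighbor_refresh: int = 10    # steps between neighbor-list rebuilds
    neighbor_skin: float = 0.5    # nm


@dataclass
class NanoparticleModel:
    """An assembled CG nanoparticle."""

    material: str
    positions: np.ndarray       # (N, 3) nm
    masses: np.ndarray          # Da
    charges: np.ndarray         # e
    bonds: list[tuple[int, int]]
    n_monomers: int
    monomer_of_bead: np.ndarray
    bead_names: list[str]
    seed: int = 0
    charge_density: float = 0.0
    n_clusters: int = 1

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def cg_mass(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "NanoparticleModel":
        return NanoparticleModel(
            material=self.material,
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            bonds=list(self.bonds),
            n_monomers=self.n_monomers,
            monomer_of_bead=self.monomer_of_bead.copy(),
            bead_names=list(self.bead_names),
            seed=self.seed,
            charge_density=self.charge_density,
            n_clusters=self.n_clusters,
        )


def _pair_forces(
    pos: np.ndarray,
    charges: np.ndarray,
    p: AssemblyParams,
    pairs: np.ndarray,
) -> np.ndarray:
    """Forces from LJ-like attraction (+ screened Coulomb) on listed pairs."""
    f = np.zeros_like(pos)
    if len(pairs) == 0:
        return f
    i, j = pairs[:, 0], pairs[:, 1]
    d = pos[i] - pos[j]
    r = np.linalg.norm(d, axis=1)
    if not np.all(np.isfinite(r)) or np.any(r == 0.0):
        k = int(np.argmin(r)) if np.all(np.isfinite(r)) else int(
            np.argmax(~np.isfinite(r)))
        raise NumericalFailureError(
            f"overlapping or non-finite bead pair ({i[k]}, {j[k]})"
        )
    mask = r < p.cutoff
    i, j, d, r = i[mask], j[mask], d[mask], r[mask]
    if len(r) == 0:
        return f
    inv = p.sigma / r
    # magnitude of dU/dr for U = 4 eps (inv^12 - inv^6); positive = repulsive
    mag = 24.0 * p.epsilon * (2.0 * inv**12 - inv**6) / r
    np.clip(mag, -p.max_force, p.max_force, out=mag)
    fv = (mag / r)[:, None] * d
    np.add.at(f, i, fv)
    np.add.at(f, j, -fv)
    return f


def _coulomb_forces(pos: np.ndarray, charges: np.ndarray, p: AssemblyParams) -> np.ndarray:
    """Full (uncut) pairwise Coulomb among charged beads; vacuum default."""
    f = np.zeros_like(pos)
    if not p.electrostatics:
        return f
    qi = np.nonzero(charges)[0]
    if len(qi) < 2:
        return f
    d = pos[qi][:, None, :] - pos[qi][None, :, :]
    r2 = (d**2).sum(axis=2)
    np.fill_diagonal(r2, np.inf)
    r = np.sqrt(r2)
    qq = np.outer(charges[qi], charges[qi])
    if p.screening_length is None:
        mag = p.coulomb_strength * qq / r2
    else:
        lam = p.screening_length
        mag = p.coulomb_strength * qq * np.exp(-r / lam) * (1.0 / r2 + 1.0 / (lam * r))
    np.clip(mag, -p.max_force, p.max_force, out=mag)
    f[qi] = ((mag / r)[:, :, None] * d).sum(axis=1)
    return f


def _bond_forces(pos: np.ndarray, bonds: np.ndarray, r0: np.ndarray, k: float) -> np.ndarray:
    f = np.zeros_like(pos)
    if len(bonds) == 0:
        return f
    i, j = bonds[:, 0], bonds[:, 1]
    d = pos[i] - pos[j]
    r = np.linalg.norm(d, axis=1)
    r = np.where(r == 0.0, 1e-12, r)
    fv = (-k * (r - r0) / r)[:, None] * d
    np.add.at(f, i, fv)
    np.add.at(f, j, -fv)
    return f


def _total_forces(pos, charges, bonds, r0, p: AssemblyParams, pairs,
                  centering_k: float, chain_of_bead: np.ndarray,
                  n_chains: int) -> np.ndarray:
    f = _pair_forces(pos, charges, p, pairs)
    f += _coulomb_forces(pos, charges, p)
    f += _bond_forces(pos, bonds, r0, p.bond_k)
    if p.epsilon > 0.0 and centering_k > 0.0:
        # rigid per-chain pull toward the system centroid
        sums = np.zeros((n_chains, 3))
        np.add.at(sums, chain_of_bead, pos)
        counts = np.bincount(chain_of_bead, minlength=n_chains)[:, None]
        chain_centroids = sums / counts
        f -= centering_k * p.epsilon * (chain_centroids[chain_of_bead] - pos.mean(axis=0))
    if not np.all(np.isfinite(f)):
        bad = int(np.argmax(~np.isfinite(f).all(axis=1)))
        raise NumericalFailureError(f"non-finite force on bead {bad}")
    return f


def _neighbor_pairs(pos: np.ndarray, radius: float) -> np.ndarray:
    pairs = cKDTree(pos).query_pairs(radius, output_type="ndarray")
    return pairs


def cluster_count(positions: np.ndarray, cutoff: float = 0.8) -> int:
    """Connected components of the bead neighbor graph at *cutoff* nm."""
    n = len(positions)
    pairs = _neighbor_pairs(positions, cutoff)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    return len({find(i) for i in range(n)})


def assemble_nanoparticle(
    system: ChainSystem,
    params: AssemblyParams | None = None,
    seed: int = 0,
) -> NanoparticleModel:
    """Collapse a dispersed chain system into a nanoparticle.

    Returns the final model with its connected-cluster count (neighbor
    graph at 0.8 nm); a count above one reports fragmentation, which is
    the expected outcome for very high charge densities.
    """
    if not system.chains:
        raise InvalidArgumentError("empty chain system")
    p = params or AssemblyParams()
    pos, masses, charges, bond_list = system.concatenated()
    bonds = np.asarray(bond_list, dtype=np.int64).reshape(-1, 2)
    r0 = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
    rng = np.random.default_rng(seed)
    pos = pos.copy()

    noise_scale = math.sqrt(2.0 * p.temperature * p.dt / p.friction)
    list_radius = p.cutoff + p.neighbor_skin
    chain_of_bead = np.repeat(
        np.arange(len(system.chains)), [c.n_beads for c in system.chains]
    )
    n_chains = len(system.chains)
    gather_steps = int(p.gather_frac * p.n_steps)
    pairs = _neighbor_pairs(pos, list_radius)
    for step in range(p.n_steps):
        if step % p.neighbor_refresh == 0 and step:
            pairs = _neighbor_pairs(pos, list_radius)
        ck = p.centering_k_start if step < gather_steps else p.centering_k_end
        f = _total_forces(pos, charges, bonds, r0, p, pairs, ck,
                          chain_of_bead, n_chains)
        pos += (p.dt / p.friction) * f
        if p.temperature > 0.0:
            pos += noise_scale * rng.normal(size=pos.shape)
    # zero-temperature descent to relax thermal roughness
    for step in range(p.n_minimize):
        if step % p.neighbor_refresh == 0:
            pairs = _neighbor_pairs(pos, list_radius)
        f = _total_forces(pos, charges, bonds, r0, p, pairs, p.centering_k_end,
                          chain_of_bead, n_chains)
        pos += (0.5 * p.dt / p.friction) * f

    pos -= pos.mean(axis=0)
    n_clusters = cluster_count(pos)
    chain0 = system.chains[0]
    mono = np.concatenate([
        c.monomer_of_bead + off
        for c, off in zip(
            system.chains,
            np.cumsum([0] + [c.n_monomers for c in system.chains[:-1]]),
        )
    ])
    names = [n for c in system.chains for n in c.bead_names]
    model = NanoparticleModel(
        material=chain0.material,
        positions=pos,
        masses=masses,
        charges=charges,
        bonds=bond_list,
        n_monomers=system.n_monomers,
        monomer_of_bead=mono,
        bead_names=names,
        seed=seed,
        charge_density=float(np.count_nonzero(charges)) / max(system.n_monomers, 1),
        n_clusters=n_clusters,
    )
    logger.info(
        "assemble_nanoparticle: material=%s beads=%d clusters=%d seed=%d",
        model.material, model.n_beads, n_clusters, seed,
    )
    return model


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def charged_monomer_count(density: float, n_monomers: int) -> int:
    """Monomers carrying a unit charge at a given fractional density."""
    if not 0.0 <= density <= 1.0:
        raise InvalidArgumentError(f"density must be in [0, 1], got {density}")
    return _round_half_away(density * n_monomers)


def assign_system_charges(
    system: ChainSystem,
    density: float,
    sign: int,
    seed: int = 0,
) -> ChainSystem:
    """Charge a fraction of monomers across a chain system (pre-assembly).

    Charges go on each material's designated charge-carrier bead (the
    backbone bead for PS). Monomers are drawn uniformly without
    replacement across the whole system.
    """
    n_mono = system.n_monomers
    n_charged = charged_monomer_count(density, n_mono)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_mono, size=n_charged, replace=False)
    out_chains: list[PolymerChain] = []
    off = 0
    s = float(np.sign(sign)) if sign else 1.0
    for c in system.chains:
        cc = c.copy()
        cc.charges = np.zeros_like(cc.charges)
        carriers = _carrier_beads(c.material, c.n_beads)
        first_mono = c.monomer_of_bead[carriers]
        local = chosen[(chosen >= off) & (chosen < off + c.n_monomers)] - off
        groups = np.searchsorted(first_mono, local, side="right") - 1
        np.add.at(cc.charges, carriers[groups], s)
        out_chains.append(cc)
        off += c.n_monomers
    return ChainSystem(chains=out_chains, box=system.box.copy())


def _carrier_beads(material: str, n_beads: int) -> np.ndarray:
    """Bead indices of the charge-carrier bead of each emission group."""
    mapping = get_cg_mapping(material)
    k = len(mapping.bead_templates)
    return np.arange(mapping.charge_carrier, n_beads, k, dtype=np.int64)


def assign_charges(
    np_model: NanoparticleModel,
    density: float,
    sign: int,
    placement: str = "surface",
    seed: int = 0,
) -> NanoparticleModel:
    """Charge ``round(density * n_monomers)`` monomers of an assembled NP.

    ``placement="uniform"`` samples monomers uniformly;
    ``placement="surface"`` samples with probability proportional to the
    rank of the monomer's distance from the NP centroid, mirroring the
    observation that charges end up on the particle surface.
    """
    n_charged = charged_monomer_count(density, np_model.n_monomers)
    out = np_model.copy()
    out.charges = np.zeros_like(out.charges)
    out.charge_density = density
    if n_charged == 0:
        return out

    carrier_beads = _carrier_beads(np_model.material, out.n_beads)
    first_mono = out.monomer_of_bead[carrier_beads]
    # each chemical monomer contributes one unit charge, deposited on its
    # emission group's carrier bead (beads spanning two monomers may carry 2e)
    carrier_of_monomer = carrier_beads[
        np.searchsorted(first_mono, np.arange(out.n_monomers), side="right") - 1
    ]
    centroid = out.positions.mean(axis=0)
    dist = np.linalg.norm(out.positions[carrier_of_monomer] - centroid, axis=1)
    rng = np.random.default_rng(seed)
    if placement == "uniform":
        weights = None
    elif placement == "surface":
        ranks = np.argsort(np.argsort(dist)) + 1.0
        weights = ranks / ranks.sum()
    else:
        raise InvalidArgumentError(f"unknown placement {placement!r}")
    sel = rng.choice(out.n_monomers, size=n_charged, replace=False, p=weights)
    np.add.at(out.charges, carrier_of_monomer[sel], float(np.sign(sign)) if sign else 1.0)
    logger.info(
        "assign_charges: material=%s density=%.2f sign=%+d placement=%s total=%+.0fe",
        out.material, density, int(np.sign(sign)), placement, out.total_charge,
    )
    return out


def charge_surface_fraction(
    np_model: NanoparticleModel, shell_thickness: float
) -> float:
    """Fraction of charged beads within *shell_thickness* nm of the surface.

    The surface radius is the largest bead distance from the centroid.
    """
    charged = np.nonzero(np_model.charges)[0]
    if len(charged) == 0:
        raise UndefinedStatisticError("nanoparticle carries no charges")
    centroid = np_model.positions.mean(axis=0)
    dist = np.linalg.norm(np_model.positions - centroid, axis=1)
    rmax = dist.max()
    return float(np.mean(dist[charged] >= rmax - shell_thickness))


def estimate_diameter(np_model: NanoparticleModel) -> float:
    """Uniform-sphere-equivalent diameter 2 sqrt(5/3) Rg, nm."""
    if np_model.n_beads < 2:
        raise InvalidArgumentError("need at least 2 beads")
    rg = radius_of_gyration(np_model.positions, np_model.masses)
    return 2.0 * math.sqrt(5.0 / 3.0) * rg


def max_extent(positions: np.ndarray) -> float:
    """Maximum pairwise bead distance, nm (exact on the convex hull)."""
    from scipy.spatial import ConvexHull
    pts = positions
    if len(pts) > 4:
        try:
            pts = positions[ConvexHull(positions).vertices]
        except Exception:  # degenerate (coplanar/collinear) inputs
            pts = positions
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def radius_of_gyration(positions: np.ndarray, masses: np.ndarray | None = None) -> float:
    if masses is None:
        masses = np.ones(len(positions))
    com = np.average(positions, axis=0, weights=masses)
    return float(
        np.sqrt(np.average(((positions - com) ** 2).sum(axis=1), weights=masses))
    )
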