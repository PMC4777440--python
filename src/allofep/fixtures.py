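"""Deterministic toy structures and independent brute-force oracles.

The generators produce small Cα geometries that exercise every pipeline
property without downloading anything: an ideal helix, a random globule, an
exact C2-symmetric dimer (for degeneracy checks), a two-domain hinge (a
minimal allosteric caricature — restraining a patch on one domain measurably
perturbs the other), and a disconnected pair of globules (for the rigid-mode
error path).  Every generator is seeded and emits a manifest recording the
planted truth.

The oracle functions re-derive key quantities by a route independent of the
production code (finite differences, naive double loops, numerical
quadrature) and exist purely for the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .enm import HarmonicModel
from .modes import ModeSet
from .structures import Ligand, Residue, ResidueKey, Structure, write_calpha_pdb

__all__ = [
    "FixtureManifest",
    "make_fixture",
    "oracle_hessian_fd",
    "oracle_intensity",
    "oracle_partition",
]

_AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

FIXTURE_KINDS = (
    "helix",
    "random_globule",
    "symmetric_dimer",
    "two_domain_hinge",
    "disconnected",
)


@dataclass
class FixtureManifest:
    kind: str
    n_residues: int
    seed: int
    parameters: dict = field(default_factory=dict)
    chain_lengths: dict = field(default_factory=dict)
    planted_site: list = field(default_factory=list)     # residue keys as strings
    ligand_id: str | None = None
    ligand_contacts: list = field(default_factory=list)  # truth for detection
    chain_equivalences: list = field(default_factory=list)
    expected_rigid_modes: int = 6
    c2_operator: list | None = None                      # 3×3 rotation, row lists

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "FixtureManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _residues(coords: np.ndarray, chain: str, start: int = 1) -> list[Residue]:
    out = []
    for i, xyz in enumerate(coords):
        key = ResidueKey(chain, start + i)
        out.append(Residue(key, _AA20[i % 20], np.asarray(xyz, dtype=float)))
    return out


def _helix_coords(n: int) -> np.ndarray:
    # ideal α-helix: rise 1.5 Å/residue, 100° twist, 2.3 Å radius
    t = np.arange(n)
    ang = np.deg2rad(100.0) * t
    return np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t])


def _globule_coords(n: int, rng: np.random.Generator, min_sep: float = 3.5) -> np.ndarray:
    radius = max(6.0, 3.1 * n ** (1.0 / 3.0))
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        x = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(x) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - x, axis=1)) < min_sep:
            attempts += 1
            if attempts > 2000:
                radius *= 1.1
                attempts = 0
            continue
        pts.append(x)
        attempts = 0
    return np.array(pts)


def _plant_ligand(
    coords: np.ndarray, rng: np.random.Generator, chain: str = "A"
) -> tuple[Ligand, float]:
    """3-atom ligand draped over a surface patch of the globule.

    One atom sits 3 Å outward of an outermost residue and of each of its two
    nearest neighbors, so the contact set is a genuine multi-residue patch
    for any seed (plus a small jitter so the geometry is not special).
    """
    center = coords.mean(axis=0)
    outer = int(np.argmax(np.linalg.norm(coords - center, axis=1)))
    nearest = np.argsort(np.linalg.norm(coords - coords[outer], axis=1))[:3]
    atoms = []
    for idx in nearest:
        direction = coords[idx] - center
        direction /= np.linalg.norm(direction)
        atoms.append(coords[idx] + 3.0 * direction + rng.normal(scale=0.3, size=3))
    return Ligand(f"{chain}:LIG:900", "LIG", np.array(atoms)), 4.5


def make_fixture(
    kind: str,
    n_residues: int,
    seed: int,
    out_dir: str | None = None,
) -> tuple[Structure, FixtureManifest]:
    """Build a toy structure plus its manifest; optionally write both.

    With ``out_dir`` set, ``fixture.pdb`` and ``manifest.json`` are written
    there so the full file-reading path can be exercised.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(kind=kind, n_residues=n_residues, seed=seed)

    if kind == "helix":
        coords = _helix_coords(n_residues)
        residues = _residues(coords, "A")
        ligands: list[Ligand] = []
        manifest.parameters = {"rise": 1.5, "twist_deg": 100.0, "radius": 2.3}
        manifest.chain_lengths = {"A": n_residues}

    elif kind == "random_globule":
        coords = _globule_coords(n_residues, rng)
        residues = _residues(coords, "A")
        lig, cutoff = _plant_ligand(coords, rng)
        ligands = [lig]
        # detection truth for a Cα-only record: Cα within cutoff + 3.0 Å
        eff = cutoff + 3.0
        contacts = [
            str(residues[i].key)
            for i in range(n_residues)
            if np.min(np.linalg.norm(lig.atoms - coords[i], axis=1)) <= eff
        ]
        manifest.parameters = {"min_separation": 3.5, "contact_cutoff": cutoff}
        manifest.chain_lengths = {"A": n_residues}
        manifest.ligand_id = lig.ligand_id
        manifest.ligand_contacts = contacts

    elif kind == "symmetric_dimer":
        half = n_residues // 2
        coords_a = _globule_coords(half, rng)
        coords_a = coords_a - coords_a.mean(axis=0)
        radius = float(np.max(np.linalg.norm(coords_a, axis=1)))
        shift = np.array([radius + 4.0, 0.0, 0.0])
        coords_a = coords_a + shift
        c2 = np.diag([-1.0, -1.0, 1.0])   # two-fold rotation about z
        coords_b = coords_a @ c2.T
        residues = _residues(coords_a, "A") + _residues(coords_b, "B")
        ligands = []
        manifest.chain_lengths = {"A": half, "B": half}
        manifest.chain_equivalences = [["A", "B"]]
        manifest.c2_operator = c2.tolist()
        manifest.n_residues = 2 * half

    elif kind == "two_domain_hinge":
        n_link = 3
        n_a = (n_residues - n_link) // 2
        n_b = n_residues - n_link - n_a
        dom_a = _globule_coords(n_a, rng)
        dom_a -= dom_a.mean(axis=0)
        dom_b = _globule_coords(n_b, np.random.default_rng(seed + 1))
        dom_b -= dom_b.mean(axis=0)
        r_a = float(np.max(np.linalg.norm(dom_a, axis=1)))
        r_b = float(np.max(np.linalg.norm(dom_b, axis=1)))
        # short gap keeps the inter-domain torsion mode comfortably above the
        # rigid-mode threshold while the linker still dominates the coupling
        gap = 2.5 * (n_link + 1)
        dom_b = dom_b + np.array([r_a + r_b + gap, 0.0, 0.0])
        x0, x1 = r_a, r_a + gap
        # zigzag linker: exact collinearity would create unphysically soft
        # bending modes right at the rigid-mode threshold
        zig = 1.5 * np.array([(-1.0) ** t for t in range(n_link)])
        linker = np.column_stack(
            [np.linspace(x0, x1, n_link + 2)[1:-1], zig, np.zeros(n_link)]
        )
        coords = np.vstack([dom_a, linker, dom_b])
        residues = _residues(coords, "A")
        ligands = []
        # planted binding site: a surface patch of domain A — the residue
        # farthest from domain B plus its 3 nearest domain-A neighbors
        far = int(np.argmin(dom_a[:, 0]))
        d = np.linalg.norm(dom_a - dom_a[far], axis=1)
        patch = list(np.argsort(d)[:4])
        manifest.planted_site = [str(residues[i].key) for i in patch]
        manifest.parameters = {
            "n_domain_a": n_a,
            "n_domain_b": n_b,
            "n_linker": n_link,
            "domain_b_start_index": n_a + n_link,
        }
        manifest.chain_lengths = {"A": len(coords)}
        manifest.n_residues = len(coords)

    elif kind == "disconnected":
        half = n_residues // 2
        g1 = _globule_coords(half, rng)
        g1 -= g1.mean(axis=0)
        g2 = _globule_coords(n_residues - half, np.random.default_rng(seed + 1))
        g2 -= g2.mean(axis=0)
        r1 = float(np.max(np.linalg.norm(g1, axis=1)))
        r2 = float(np.max(np.linalg.norm(g2, axis=1)))
        g2 = g2 + np.array([r1 + r2 + 30.0, 0.0, 0.0])  # gap > 25 Å
        residues = _residues(g1, "A") + _residues(g2, "B", start=1)
        ligands = []
        manifest.chain_lengths = {"A": half, "B": n_residues - half}
        manifest.expected_rigid_modes = 12
        manifest.n_residues = n_residues

    structure = Structure(residues, ligands)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_calpha_pdb(structure, os.path.join(out_dir, "fixture.pdb"))
        manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return structure, manifest


# ---------------------------------------------------------------------------
# oracles — intentionally naive, sharing nothing with the production path
# beyond the data types


def oracle_hessian_fd(model: HarmonicModel, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian of the scalar spring energy."""
    coords0 = model.reference.coords
    n3 = coords0.size

    def energy(flat: np.ndarray) -> float:
        x = flat.reshape(-1, 3)
        total = 0.0
        for i, j, d0, k in zip(*model.all_pairs()):
            d = float(np.linalg.norm(x[i] - x[j]))
            total += k * (d - d0) ** 2
        return total

    flat0 = coords0.ravel()
    H = np.zeros((n3, n3))
    for a in range(n3):
        for b in range(a, n3):
            xpp = flat0.copy(); xpp[a] += step; xpp[b] += step
            xpm = flat0.copy(); xpm[a] += step; xpm[b] -= step
            xmp = flat0.copy(); xmp[a] -= step; xmp[b] += step
            xmm = flat0.copy(); xmm[a] -= step; xmm[b] -= step
            val = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) / (
                4.0 * step**2
            )
            H[a, b] = H[b, a] = val
    return H


def oracle_intensity(
    modes: ModeSet, s: Structure, c: float = 1.0, d_c: float = 11.0
) -> np.ndarray:
    """ε_μ,i by a naive double loop over residues and modes."""
    coords = s.coords
    n = len(s)
    eps = np.zeros((modes.n_modes, n))
    for mu in range(modes.n_modes):
        e = modes.vectors[mu].reshape(-1, 3)
        for i in range(n):
            total = 0.0
            for j in range(n):
                if j == i:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) < d_c:
                    diff = e[i] - e[j]
                    total += c * float(diff @ diff)
            eps[mu, i] = total
    return eps


def oracle_partition(eps_row: np.ndarray, kT: float) -> tuple[float, float]:
    """Per-residue partition function z_i two ways: quadrature and closed form.

    z_i = Π_μ ∫ dσ exp(−ε_μ σ²/(2 kT)) = Π_μ (2π kT / ε_μ)^{1/2}
    """
    quad = 1.0
    for eps in np.asarray(eps_row, dtype=float):
        val, _ = integrate.quad(
            lambda sig: np.exp(-eps * sig**2 / (2.0 * kT)), -np.inf, np.inf
        )
        quad *= val
    closed = float(np.prod(np.sqrt(2.0 * np.pi * kT / np.asarray(eps_row))))
    return quad, closed
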