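"""Cα harmonic model of the free and site-restrained (ligand-bound) systems.

The free system is a pairwise distance-spring network over all Cα pairs
within ``enm_cutoff`` (default 25 Å), with force constants decaying as
k_ij = k0 / (d⁰_ij)^6.  Ligand binding is modeled indirectly: every residue
pair inside a binding site gains an extra harmonic term scaled by a
stiffening factor α, with no distance cutoff, so the ligated site moves more
rigidly without any explicit ligand atoms.

Energy conventions (kept literal on purpose):

    E_free  = Σ_pairs      k_ij (d_ij − d⁰_ij)²
    E_bound = E_free + α Σ_sites ½ Σ_{pairs in site} k_ij (d_ij − d⁰_ij)²

so a site pair's total effective spring constant is k_ij·(1 + α/2) with the
default ``site_term_half=True``, or k_ij·(1 + α) without the half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import BindingSite, Structure, StructureError

__all__ = [
    "HarmonicModel",
    "Hessian",
    "SiteTerm",
    "build_harmonic_model",
    "apply_restraints",
    "hessian",
]

DEFAULT_ENM_CUTOFF = 25.0
DEFAULT_EXPONENT = 6
DEFAULT_ALPHA = 100.0


@dataclass
class SiteTerm:
    """Stiffening springs of one restrained binding site.

    ``k`` already includes the α/2 (or α) factor, so the Hessian treats site
    springs exactly like base springs.
    """

    site_name: str
    i: np.ndarray
    j: np.ndarray
    d0: np.ndarray
    k: np.ndarray
    alpha: float


@dataclass
class HarmonicModel:
    reference: Structure
    i: np.ndarray          # pair indices, i < j
    j: np.ndarray
    d0: np.ndarray         # reference distances, Å
    k: np.ndarray          # base force constants, energy/Å²
    enm_cutoff: float = DEFAULT_ENM_CUTOFF
    exponent: int = DEFAULT_EXPONENT
    k0: float = 1.0
    site_terms: list[SiteTerm] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.reference)

    def all_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Base + site springs concatenated (i, j, d0, k)."""
        ii = [self.i] + [t.i for t in self.site_terms]
        jj = [self.j] + [t.j for t in self.site_terms]
        dd = [self.d0] + [t.d0 for t in self.site_terms]
        kk = [self.k] + [t.k for t in self.site_terms]
        return (
            np.concatenate(ii),
            np.concatenate(jj),
            np.concatenate(dd),
            np.concatenate(kk),
        )

    def energy(self, coords: np.ndarray) -> float:
        """Total spring energy at arbitrary coordinates (N, 3)."""
        i, j, d0, k = self.all_pairs()
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        return float(np.sum(k * (d - d0) ** 2))


@dataclass
class Hessian:
    matrix: np.ndarray     # 3N × 3N, symmetric
    keys: list             # residue identity per index block

    @property
    def n_residues(self) -> int:
        return len(self.keys)


def build_harmonic_model(
    s: Structure,
    enm_cutoff: float = DEFAULT_ENM_CUTOFF,
    exponent: int = DEFAULT_EXPONENT,
    k0: float = 1.0,
) -> HarmonicModel:
    """All-pair distance springs within ``enm_cutoff``, k = k0/d⁰^exponent."""
    if len(s) < 2:
        raise StructureError("harmonic model needs at least 2 residues")
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    coords = s.coords
    pairs = cKDTree(coords).query_pairs(r=enm_cutoff, output_type="ndarray")
    if pairs.size == 0:
        raise StructureError(f"no residue pair within {enm_cutoff} Å")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    i, j = pairs[:, 0], pairs[:, 1]
    d0 = np.linalg.norm(coords[i] - coords[j], axis=1)
    if np.any(d0 <= 0):
        a, b = i[d0 <= 0][0], j[d0 <= 0][0]
        raise StructureError(
            f"coincident residues {s.keys[a]} and {s.keys[b]} (d⁰ = 0)"
        )
    k = k0 * d0 ** (-float(exponent))
    return HarmonicModel(
        reference=s, i=i, j=j, d0=d0, k=k,
        enm_cutoff=enm_cutoff, exponent=exponent, k0=k0,
    )


def apply_restraints(
    m: HarmonicModel,
    sites: list[BindingSite],
    alpha: float = DEFAULT_ALPHA,
    site_term_half: bool = True,
) -> HarmonicModel:
    """Return a new model with the sites' stiffening terms added.

    Every residue pair inside a site gets an extra spring — the 25 Å network
    cutoff does not apply to site terms — with constant (α/2)·k_ij by default
    (see the module docstring for the energy convention).  Base pairs are
    untouched; α = 0 leaves the Hessian identical to the free one.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    coords = m.reference.coords
    key_index = {k: idx for idx, k in enumerate(m.reference.keys)}
    factor = alpha / 2.0 if site_term_half else alpha
    new_terms = list(m.site_terms)
    for site in sites:
        if len(site.members) < 2:
            raise StructureError(
                f"site {site.name!r} has {len(site.members)} residue(s); "
                "a restraint needs at least one pair"
            )
        missing = [k for k in site.members if k not in key_index]
        if missing:
            raise StructureError(
                f"site {site.name!r} references residues not in the model: "
                f"{', '.join(map(str, missing))}"
            )
        idx = np.array(sorted(key_index[k] for k in site.members), dtype=int)
        ii, jj = np.triu_indices(len(idx), k=1)
        pi, pj = idx[ii], idx[jj]
        d0 = np.linalg.norm(coords[pi] - coords[pj], axis=1)
        if np.any(d0 <= 0):
            raise StructureError(f"coincident residues inside site {site.name!r}")
        k = factor * m.k0 * d0 ** (-float(m.exponent))
        new_terms.append(
            SiteTerm(site_name=site.name, i=pi, j=pj, d0=d0, k=k, alpha=alpha)
        )
    return HarmonicModel(
        reference=m.reference,
        i=m.i, j=m.j, d0=m.d0, k=m.k,
        enm_cutoff=m.enm_cutoff, exponent=m.exponent, k0=m.k0,
        site_terms=new_terms,
    )


def hessian(m: HarmonicModel) -> Hessian:
    """Analytic Hessian of the total spring energy at the reference.

    A distance spring k(d − d⁰)² evaluated at d = d⁰ contributes the rank-one
    block 2k·û ûᵀ on the unit bond vector û (no perpendicular curvature at
    the minimum):  H_ii += 2k ûûᵀ, H_jj += 2k ûûᵀ, H_ij = H_ji = −2k ûûᵀ.
    """
    n = m.n_residues
    coords = m.reference.coords
    i, j, d0, k = m.all_pairs()
    u = (coords[i] - coords[j]) / d0[:, None]
    blocks = 2.0 * k[:, None, None] * u[:, :, None] * u[:, None, :]  # (P, 3, 3)

    H = np.zeros((3 * n, 3 * n))
    for a in range(3):
        for b in range(3):
            np.add.at(H, (3 * i + a, 3 * i + b), blocks[:, a, b])
            np.add.at(H, (3 * j + a, 3 * j + b), blocks[:, a, b])
            np.add.at(H, (3 * i + a, 3 * j + b), -blocks[:, a, b])
            np.add.at(H, (3 * j + a, 3 * i + b), -blocks[:, a, b])
    return Hessian(matrix=H, keys=m.reference.keys)
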