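"""Allosteric potential, per-residue free energies, and global free energies.

The allosteric potential assigns every residue i and mode μ an intensity

    ε_μ,i = Σ_{j : d⁰_ij < d_c, j≠i}  c · ‖e_μ,i − e_μ,j‖²

measuring how strongly mode μ deforms residue i's neighborhood (neighbors
taken on the shared reference structure, d_c = 11 Å, c = 1 kcal/mol/Å²).
Treating the mode amplitudes as Gaussian degrees of freedom, the per-residue
partition function is z_i = Π_μ (2πk_BT / ε_μ,i)^{1/2}, and the configura-
tional free energy change between the ligand-free and site-restrained
systems reduces to a log-ratio of intensities:

    Δg_i = (k_BT / 2) Σ_μ ln( ε_μ,i^bound / ε_μ,i^free )

Negative Δg_i means the residue's neighborhood is stabilized (moves less)
upon binding; positive means increased local dynamics.  Sequential-binding
cooperativity is the difference of two such profiles (ΔΔg), and whole-system
analogues use Hessian eigenvalue ratios instead of intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .modes import ModeSet
from .structures import BindingSite, ChainGroups, Structure, write_calpha_pdb

__all__ = [
    "IntensityTable",
    "AllostericProfile",
    "SiteSummary",
    "BOLTZMANN_KCAL",
    "DEFAULT_KT",
    "residue_intensities",
    "allosteric_free_energy",
    "modulation_free_energy",
    "site_free_energy",
    "protein_free_energy",
    "global_free_energy",
    "global_modulation",
    "monomer_average",
    "tube_radii",
    "site_summary",
    "write_profile_table",
    "write_bfactor_pdb",
]

BOLTZMANN_KCAL = 1.987204259e-3   # kcal/mol/K
DEFAULT_KT = 0.5961               # kcal/mol, T ≈ 300 K
DEFAULT_DC = 11.0                 # Å, neighborhood cutoff
DEFAULT_C = 1.0                   # kcal/mol/Å², intensity scale
EPS_FLOOR_FRACTION = 1e-12        # floor relative to the table's median ε


class AllosteryError(ValueError):
    pass


@dataclass
class IntensityTable:
    """Residue intensity parameters ε_μ,i of one system (modes × residues)."""

    eps: np.ndarray                 # (n_modes, N)
    neighbors: list[np.ndarray]     # per residue, indices with d⁰ < d_c
    c: float
    d_c: float
    structure: Structure

    @property
    def n_modes(self) -> int:
        return self.eps.shape[0]

    @property
    def n_residues(self) -> int:
        return self.eps.shape[1]

    @property
    def zero_neighbor_mask(self) -> np.ndarray:
        return np.array([len(nb) == 0 for nb in self.neighbors])


@dataclass
class AllostericProfile:
    """Per-residue Δg (or ΔΔg) in kcal/mol for one binding transition."""

    structure: Structure
    dg: np.ndarray                  # (N,), NaN where undefined
    label: str
    kT: float
    n_modes: int
    flags: list[set] = field(default_factory=list)

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.dg)

    def chain_profile(self, chain: str) -> np.ndarray:
        return self.dg[self.structure.chain_indices(chain)]


@dataclass
class SiteSummary:
    site_name: str
    dg_site: float                  # mean over site residues
    dg_protein: float               # mean over all defined residues
    dg_per_chain: dict              # chain id -> monomer mean
    n_site: int
    n_protein: int


def _neighbor_lists(s: Structure, d_c: float) -> list[np.ndarray]:
    coords = s.coords
    tree = cKDTree(coords)
    # strict inequality d⁰ < d_c: shrink by the tightest representable margin
    pairs = tree.query_pairs(r=d_c, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < d_c]
    lists: list[list[int]] = [[] for _ in range(len(s))]
    for a, b in pairs:
        lists[a].append(b)
        lists[b].append(a)
    return [np.array(sorted(l), dtype=int) for l in lists]


def residue_intensities(
    modes: ModeSet,
    s: Structure,
    c: float = DEFAULT_C,
    d_c: float = DEFAULT_DC,
) -> IntensityTable:
    """ε_μ,i over all modes and residues, neighbors on the reference."""
    if modes.n_modes == 0:
        raise AllosteryError("empty mode set")
    if modes.vectors.shape[1] != 3 * len(s):
        raise AllosteryError(
            f"mode vectors ({modes.vectors.shape[1]} dof) do not match "
            f"structure ({3 * len(s)} dof)"
        )
    if d_c <= 0:
        raise AllosteryError("d_c must be positive")
    neighbors = _neighbor_lists(s, d_c)
    n = len(s)
    eps = np.zeros((modes.n_modes, n))
    pair_i = np.concatenate(
        [np.full(len(nb), i) for i, nb in enumerate(neighbors)]
    ) if n else np.empty(0, dtype=int)
    pair_j = np.concatenate([nb for nb in neighbors]) if n else np.empty(0, dtype=int)
    for mu in range(modes.n_modes):
        e = modes.displacements(mu)
        if len(pair_i):
            sq = np.sum((e[pair_i] - e[pair_j]) ** 2, axis=1)
            np.add.at(eps[mu], pair_i, c * sq)
    return IntensityTable(eps=eps, neighbors=neighbors, c=c, d_c=d_c, structure=s)


def _check_compatible(a: IntensityTable, b: IntensityTable) -> None:
    if a.eps.shape != b.eps.shape:
        raise AllosteryError(
            f"intensity tables differ in shape: {a.eps.shape} vs {b.eps.shape}"
        )
    if a.structure.keys != b.structure.keys:
        raise AllosteryError("intensity tables built on different residue sets")
    if (a.c, a.d_c) != (b.c, b.d_c):
        raise AllosteryError("intensity tables use different (c, d_c)")


def _floored(eps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    positive = eps[eps > 0]
    if positive.size == 0:
        raise AllosteryError("all intensities are zero; no dynamics to compare")
    floor = EPS_FLOOR_FRACTION * float(np.median(positive))
    flagged = np.any(eps < floor, axis=0)
    return np.maximum(eps, floor), flagged


def _log_ratio_profile(
    num_tables: list[tuple[IntensityTable, float]],
    kT: float,
    label: str,
) -> AllostericProfile:
    """Σ over tables of weight · ln ε, the common core of Δg and ΔΔg."""
    ref = num_tables[0][0]
    n = ref.n_residues
    total = np.zeros(n)
    flags: list[set] = [set() for _ in range(n)]
    undefined = np.zeros(n, dtype=bool)
    for table, weight in num_tables:
        zero_nb = table.zero_neighbor_mask
        undefined |= zero_nb
        eps, flagged = _floored(table.eps)
        for i in np.nonzero(flagged)[0]:
            flags[i].add("eps-floored")
        total += weight * np.sum(np.log(eps), axis=0)
    dg = 0.5 * kT * total
    dg[undefined] = np.nan
    for i in np.nonzero(undefined)[0]:
        flags[i].add("no-neighbors")
    return AllostericProfile(
        structure=ref.structure, dg=dg, label=label, kT=kT,
        n_modes=ref.n_modes, flags=flags,
    )


def allosteric_free_energy(
    free: IntensityTable,
    bound: IntensityTable,
    kT: float = DEFAULT_KT,
    label: str = "free->bound",
) -> AllostericProfile:
    """Δg_i = (kT/2) Σ_μ ln(ε_μ,i^bound / ε_μ,i^free).

    Residues with an empty d_c-neighborhood in either table are undefined
    (NaN, flagged ``no-neighbors``) and excluded from all averages; near-zero
    intensities are floored at 1e-12 × median(ε) and flagged rather than
    propagating infinities.
    """
    _check_compatible(free, bound)
    return _log_ratio_profile([(bound, 1.0), (free, -1.0)], kT, label)


def modulation_free_energy(
    free: IntensityTable,
    m_bound: IntensityTable,
    n_bound: IntensityTable,
    kT: float = DEFAULT_KT,
    formula: str = "difference",
    label: str = "m->n",
) -> AllostericProfile:
    """ΔΔg_i upon going from m restrained sites to n restrained sites.

    ``formula="difference"`` (default): ΔΔg_i = Δg_i(0→n) − Δg_i(0→m), the
    form every worked cooperativity number follows.  ``formula="eq17"``:
    the literal log-ratio (kT/2) Σ_μ ln[ε^(n) ε^(0) / (ε^(m))²].
    """
    _check_compatible(free, m_bound)
    _check_compatible(free, n_bound)
    if formula == "difference":
        tables = [(n_bound, 1.0), (m_bound, -1.0)]
    elif formula == "eq17":
        tables = [(n_bound, 1.0), (free, 1.0), (m_bound, -2.0)]
    else:
        raise AllosteryError(f"unknown modulation formula {formula!r}")
    return _log_ratio_profile(tables, kT, label)


def site_free_energy(p: AllostericProfile, site: BindingSite) -> float:
    """Arithmetic mean of Δg over the site's residues (kcal/mol)."""
    idx = [p.structure.index_of(k) for k in sorted(site.members)]
    vals = p.dg[idx]
    if np.any(~np.isfinite(vals)):
        bad = [str(p.structure.keys[i]) for i in idx if not np.isfinite(p.dg[i])]
        raise AllosteryError(
            f"site {site.name!r} has residues with undefined Δg: {', '.join(bad)}"
        )
    return float(np.mean(vals))


def protein_free_energy(p: AllostericProfile) -> float:
    """Mean Δg over every residue with a defined value (kcal/mol)."""
    mask = p.defined_mask()
    if not mask.any():
        raise AllosteryError("no residue has a defined Δg")
    return float(np.mean(p.dg[mask]))


def global_free_energy(
    free: ModeSet, bound: ModeSet, kT: float = DEFAULT_KT
) -> float:
    """Whole-system ΔG = (kT/2) Σ_μ ln(λ_μ^bound / λ_μ^free)."""
    if free.n_modes != bound.n_modes:
        raise AllosteryError("mode sets differ in size")
    return float(0.5 * kT * np.sum(np.log(bound.eigenvalues / free.eigenvalues)))


def global_modulation(
    free: ModeSet,
    m_bound: ModeSet,
    n_bound: ModeSet,
    kT: float = DEFAULT_KT,
    formula: str = "as-printed",
) -> float:
    """Whole-system modulation free energy for sequential binding.

    ``"as-printed"``: (kT/2) Σ_μ ln[λ^(0) λ^(n) / (λ^(m))²].
    ``"difference"``: ΔG(0→n) − ΔG(0→m) = (kT/2) Σ_μ ln(λ^(n)/λ^(m)).
    """
    if not (free.n_modes == m_bound.n_modes == n_bound.n_modes):
        raise AllosteryError("mode sets differ in size")
    lam0, lamm, lamn = free.eigenvalues, m_bound.eigenvalues, n_bound.eigenvalues
    if formula == "as-printed":
        return float(0.5 * kT * np.sum(np.log(lam0 * lamn / lamm**2)))
    if formula == "difference":
        return float(0.5 * kT * np.sum(np.log(lamn / lamm)))
    raise AllosteryError(f"unknown modulation formula {formula!r}")


def monomer_average(
    p: AllostericProfile, g: ChainGroups
) -> list[pd.DataFrame]:
    """Per-aligned-position mean and SEM of Δg across homologous chains.

    Returns one DataFrame per chain group with columns ``position``,
    ``mean_dg``, ``sem_dg``, plus one column per chain.  The standard error
    is the sample standard deviation over chains divided by √n_chains;
    singleton groups get a zero error band.
    """
    out = []
    for chains, corr in zip(g.groups, g.correspondence):
        rows = []
        for pos, mapping in enumerate(corr):
            vals = {
                ch: p.dg[p.structure.index_of(mapping[ch])] for ch in chains
            }
            arr = np.array([vals[ch] for ch in chains])
            defined = arr[np.isfinite(arr)]
            if defined.size == 0:
                mean, sem = np.nan, np.nan
            else:
                mean = float(np.mean(defined))
                sem = (
                    float(np.std(defined, ddof=1) / np.sqrt(defined.size))
                    if defined.size > 1
                    else 0.0
                )
            rows.append({"position": pos, "mean_dg": mean, "sem_dg": sem, **vals})
        out.append(pd.DataFrame(rows))
    return out


def tube_radii(p: AllostericProfile) -> np.ndarray:
    """ρ_i = (Δg_i − min Δg)/(max Δg − min Δg) ∈ [0, 1].

    A constant profile maps to 0.5 everywhere (degenerate-range convention);
    undefined residues stay NaN.
    """
    dg = p.dg
    mask = np.isfinite(dg)
    rho = np.full_like(dg, np.nan)
    if not mask.any():
        return rho
    lo, hi = np.min(dg[mask]), np.max(dg[mask])
    if hi - lo < 1e-300 or np.isclose(hi, lo, rtol=0, atol=1e-12 * max(abs(hi), 1)):
        rho[mask] = 0.5
    else:
        rho[mask] = (dg[mask] - lo) / (hi - lo)
    return rho


def site_summary(
    p: AllostericProfile,
    sites: list[BindingSite],
    groups: ChainGroups | None = None,
) -> list[SiteSummary]:
    """Table-style report: per-site mean, protein mean, per-monomer means."""
    prot = protein_free_energy(p)
    n_prot = int(p.defined_mask().sum())
    per_chain = {}
    for ch in p.structure.chain_ids:
        vals = p.chain_profile(ch)
        defined = vals[np.isfinite(vals)]
        per_chain[ch] = float(np.mean(defined)) if defined.size else float("nan")
    out = []
    for site in sites:
        out.append(
            SiteSummary(
                site_name=site.name,
                dg_site=site_free_energy(p, site),
                dg_protein=prot,
                dg_per_chain=per_chain,
                n_site=len(site.members),
                n_protein=n_prot,
            )
        )
    return out


def write_profile_table(p: AllostericProfile, path: str) -> None:
    """Tab-separated per-residue profile (chain, resnum, icode, resname, Δg)."""
    rows = []
    for i, r in enumerate(p.structure.residues):
        rows.append(
            {
                "chain": r.key.chain,
                "resnum": r.key.number,
                "icode": r.key.icode,
                "resname": r.name,
                "dg_kcal_mol": p.dg[i],
                "flags": ",".join(sorted(p.flags[i])) if p.flags else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_bfactor_pdb(p: AllostericProfile, path: str, scaled: bool = False) -> None:
    """PDB copy with Δg_i (or the [0,1] tube radius ρ_i) in the B-factor column."""
    values = tube_radii(p) if scaled else p.dg
    write_calpha_pdb(p.structure, path, bfactors=values)


def summaries_to_json(summaries: list[SiteSummary], path: str) -> None:
    payload = [
        {
            "site": s.site_name,
            "dg_site_kcal_mol": s.dg_site,
            "dg_protein_kcal_mol": s.dg_protein,
            "dg_per_chain_kcal_mol": s.dg_per_chain,
            "n_site_residues": s.n_site,
            "n_protein_residues": s.n_protein,
        }
        for s in summaries
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
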