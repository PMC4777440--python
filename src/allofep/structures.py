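"""Structure input: Cα extraction, binding sites, homologous-chain grouping.

The model downstream is a pure Cα elastic network, so parsing reduces a
PDB/mmCIF file to an ordered list of Cα records plus the HETATM groups that
may act as ligands.  Full heavy-atom coordinates of the polymer residues are
retained only so that ligand-contact binding sites can be detected with true
heavy-atom distances when the input provides them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

__all__ = [
    "ResidueKey",
    "Residue",
    "Ligand",
    "Structure",
    "BindingSite",
    "ChainGroups",
    "StructureError",
    "read_calpha_structure",
    "detect_binding_site",
    "group_homologous_chains",
    "parse_site_file",
    "write_calpha_pdb",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}


class StructureError(ValueError):
    """Raised for unusable input structures or site definitions."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Unique residue identifier: chain id, residue number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}"


@dataclass
class Residue:
    key: ResidueKey
    name: str
    coord: np.ndarray                      # Cα position, Å
    heavy_atoms: np.ndarray | None = None  # (m, 3) heavy-atom positions incl. Cα


@dataclass
class Ligand:
    ligand_id: str        # "chain:resname:resnum"
    name: str
    atoms: np.ndarray     # (m, 3) heavy-atom positions


@dataclass
class Structure:
    residues: list[Residue]
    ligands: list[Ligand] = field(default_factory=list)
    n_models: int = 1

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate residue identifiers in structure")
        for r in self.residues:
            if not np.all(np.isfinite(r.coord)):
                raise StructureError(f"non-finite coordinate at {r.key}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in residue order."""
        return np.array([r.coord for r in self.residues], dtype=float)

    @property
    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.key.chain not in seen:
                seen.append(r.key.chain)
        return seen

    def index_of(self, key: ResidueKey) -> int:
        try:
            return self.keys.index(key)
        except ValueError:
            raise StructureError(f"residue {key} not in structure") from None

    def chain_indices(self, chain: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.residues) if r.key.chain == chain],
            dtype=int,
        )

    def chain_sequence(self, chain: str) -> str:
        return "".join(
            _one_letter(r.name) for r in self.residues if r.key.chain == chain
        )

    def has_full_atom_record(self) -> bool:
        """True when at least one residue carries more than its Cα."""
        return any(
            r.heavy_atoms is not None and len(r.heavy_atoms) > 1
            for r in self.residues
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved copy (used by invariance tests and fixtures)."""
        out = copy.deepcopy(self)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for r in out.residues:
            r.coord = R @ r.coord + t
            if r.heavy_atoms is not None:
                r.heavy_atoms = r.heavy_atoms @ R.T + t
        for lig in out.ligands:
            lig.atoms = lig.atoms @ R.T + t
        return out


@dataclass
class BindingSite:
    """A named set of residues whose pairwise springs are stiffened."""

    name: str
    members: frozenset[ResidueKey]
    source: str = "explicit"          # "explicit" | "ligand-contact"
    contact_mode: str = ""            # "heavy-atom" | "calpha+3.0" for detected sites

    def __post_init__(self) -> None:
        if not self.members:
            raise StructureError(f"site {self.name!r} has no residues")


@dataclass
class ChainGroups:
    """Chains partitioned into homologous groups with residue correspondence.

    ``correspondence[g]`` is a list over aligned positions; each entry maps
    chain id -> ResidueKey.  Only positions present in every chain of the
    group are kept, so a monomer-length profile can be formed per chain.
    """

    groups: list[list[str]]
    correspondence: list[list[dict[str, ResidueKey]]]


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


# ---------------------------------------------------------------------------
# reading


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        by_name.setdefault(atom.name, []).append(atom)
    return [_pick_altloc(group) for group in by_name.values()]


def _extract_model(model: gemmi.Model) -> tuple[list[Residue], list[Ligand]]:
    residues: list[Residue] = []
    ligands: list[Ligand] = []
    for chain in model:
        for res in chain:
            heavy = _collapse_altlocs(res)
            ca = next((a for a in heavy if a.name == "CA"), None)
            if ca is not None and res.name not in _WATER_NAMES:
                key = ResidueKey(chain.name, res.seqid.num, res.seqid.icode.strip())
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in heavy])
                ca_xyz = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                residues.append(Residue(key, res.name, ca_xyz, coords))
            elif res.name not in _WATER_NAMES and heavy:
                lig_id = f"{chain.name}:{res.name}:{res.seqid.num}"
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in heavy])
                ligands.append(Ligand(lig_id, res.name, coords))
    return residues, ligands


def read_calpha_structure(path: str, model_policy: str | int = "first") -> Structure:
    """Read a PDB or mmCIF file into the Cα representation.

    Parameters
    ----------
    path:
        Structure file; format is auto-detected.
    model_policy:
        ``"first"`` uses model 1, ``"mean"`` averages coordinates over all
        models of an NMR-style bundle (the "mean conformer"), an integer ``k``
        selects model ``k`` (1-based).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.remove_empty_chains()

    if model_policy == "first":
        models = [st[0]]
    elif model_policy == "mean":
        models = list(st)
    else:
        k = int(model_policy)
        if not 1 <= k <= len(st):
            raise StructureError(
                f"model index {k} out of range (file has {len(st)} models)"
            )
        models = [st[k - 1]]

    residues, ligands = _extract_model(models[0])
    if len(models) > 1:
        # arithmetic mean over the bundle, matched by residue identity
        acc_res = {r.key: [r] for r in residues}
        acc_lig = {l.ligand_id: [l] for l in ligands}
        for model in models[1:]:
            more_res, more_lig = _extract_model(model)
            for r in more_res:
                if r.key in acc_res:
                    acc_res[r.key].append(r)
            for l in more_lig:
                if l.ligand_id in acc_lig:
                    acc_lig[l.ligand_id].append(l)
        for r in residues:
            stack = acc_res[r.key]
            r.coord = np.mean([x.coord for x in stack], axis=0)
            shapes = {x.heavy_atoms.shape for x in stack}
            if len(shapes) == 1:
                r.heavy_atoms = np.mean([x.heavy_atoms for x in stack], axis=0)
        for l in ligands:
            stack = acc_lig[l.ligand_id]
            if len({x.atoms.shape for x in stack}) == 1:
                l.atoms = np.mean([x.atoms for x in stack], axis=0)

    if not residues:
        raise StructureError(f"{path}: no residues with a Cα atom")
    for chain_id in {r.key.chain for r in residues}:
        n_ca = sum(1 for r in residues if r.key.chain == chain_id)
        if n_ca == 0:
            raise StructureError(f"{path}: chain {chain_id} has no Cα atoms")
    return Structure(residues, ligands, n_models=len(models))


# ---------------------------------------------------------------------------
# binding sites


def detect_binding_site(
    s: Structure,
    ligand_id: str,
    contact_cutoff: float = 4.5,
    name: str | None = None,
) -> BindingSite:
    """Residues in heavy-atom contact with a ligand.

    When the parse retained full heavy-atom records, a residue is a member if
    any of its heavy atoms lies within ``contact_cutoff`` of any ligand heavy
    atom.  With a Cα-only record the criterion is Cα within
    ``contact_cutoff + 3.0`` Å (the extra 3 Å standing in for a typical
    side-chain reach); the mode used is recorded on the site.
    """
    if contact_cutoff <= 0:
        raise StructureError("contact_cutoff must be positive")
    lig = next((l for l in s.ligands if l.ligand_id == ligand_id), None)
    if lig is None:
        known = ", ".join(l.ligand_id for l in s.ligands) or "none"
        raise StructureError(f"ligand {ligand_id!r} not found (known: {known})")

    tree = cKDTree(lig.atoms)
    members: set[ResidueKey] = set()
    if s.has_full_atom_record():
        mode = "heavy-atom"
        for r in s.residues:
            pts = r.heavy_atoms if r.heavy_atoms is not None else r.coord[None, :]
            if np.any(tree.query(pts)[0] <= contact_cutoff):
                members.add(r.key)
    else:
        mode = "calpha+3.0"
        eff = contact_cutoff + 3.0
        for r in s.residues:
            if tree.query(r.coord)[0] <= eff:
                members.add(r.key)
    if not members:
        raise StructureError(
            f"no residue within {contact_cutoff} Å of ligand {ligand_id}"
        )
    return BindingSite(
        name=name or ligand_id,
        members=frozenset(members),
        source="ligand-contact",
        contact_mode=mode,
    )


def parse_site_file(path: str, s: Structure) -> list[BindingSite]:
    """Parse the plain-text site specification format.

    Lines::

        SITE <name> <chain>:<resnum>[<icode>] <chain>:<resnum> ...
        SITE <name> LIGAND <chain>:<resname>:<resnum> CUTOFF <Å>
    """
    sites: list[BindingSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] != "SITE" or len(parts) < 3:
                raise StructureError(f"{path}:{lineno}: malformed line {line!r}")
            name = parts[1]
            if parts[2] == "LIGAND":
                if len(parts) != 6 or parts[4] != "CUTOFF":
                    raise StructureError(
                        f"{path}:{lineno}: expected "
                        "'SITE <name> LIGAND <id> CUTOFF <Å>'"
                    )
                site = detect_binding_site(
                    s, parts[3], contact_cutoff=float(parts[5]), name=name
                )
            else:
                members = set()
                known = set(s.keys)
                for tok in parts[2:]:
                    chain, _, resspec = tok.partition(":")
                    if not resspec:
                        raise StructureError(
                            f"{path}:{lineno}: bad residue token {tok!r}"
                        )
                    num = "".join(c for c in resspec if c.isdigit() or c == "-")
                    icode = resspec[len(num):]
                    key = ResidueKey(chain, int(num), icode)
                    if key not in known:
                        raise StructureError(
                            f"{path}:{lineno}: residue {key} not in structure"
                        )
                    members.add(key)
                site = BindingSite(name=name, members=frozenset(members))
            sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# homologous chains


def _global_alignment(a: str, b: str) -> Align.Alignment:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner.align(a, b)[0]


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    aln = _global_alignment(a, b)
    matches = sum(
        1
        for ai, bj in zip(*aln.indices)
        if ai >= 0 and bj >= 0 and a[ai] == b[bj]
    )
    return matches / max(len(a), len(b))


def group_homologous_chains(s: Structure, min_identity: float = 0.95) -> ChainGroups:
    """Partition chains into groups of ≥ ``min_identity`` sequence identity.

    Within each group residues are put in correspondence by global alignment
    against the group's first chain; aligned positions missing from any chain
    (e.g. a deletion) are dropped, so every chain contributes one value per
    kept position.
    """
    chains = s.chain_ids
    if not chains:
        raise StructureError("structure has no chains")
    seqs = {c: s.chain_sequence(c) for c in chains}

    parent = {c: c for c in chains}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            if _identity(seqs[a], seqs[b]) >= min_identity:
                parent[find(b)] = find(a)

    groups: list[list[str]] = []
    for c in chains:
        root = find(c)
        for g in groups:
            if find(g[0]) == root:
                g.append(c)
                break
        else:
            groups.append([c])

    keys_by_chain = {
        c: [r.key for r in s.residues if r.key.chain == c] for c in chains
    }
    correspondence: list[list[dict[str, ResidueKey]]] = []
    for g in groups:
        ref = g[0]
        ref_keys = keys_by_chain[ref]
        # per reference position: chain -> residue index in that chain
        pos_maps: list[dict[str, ResidueKey]] = [
            {ref: k} for k in ref_keys
        ]
        for other in g[1:]:
            aln = _global_alignment(seqs[ref], seqs[other])
            other_keys = keys_by_chain[other]
            for ri, oj in zip(*aln.indices):
                if ri >= 0 and oj >= 0:
                    pos_maps[ri][other] = other_keys[oj]
        correspondence.append([m for m in pos_maps if len(m) == len(g)])
    return ChainGroups(groups=groups, correspondence=correspondence)


# ---------------------------------------------------------------------------
# writing


def write_calpha_pdb(
    s: Structure,
    path: str,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write the Cα representation (plus ligands) as a PDB file.

    ``bfactors`` (per residue, structure order) land in the B-factor column,
    clamped to the column's [-99.99, 999.99] range; NaN becomes 0.
    """
    st = gemmi.Structure()
    st.name = "allofep"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for idx, r in enumerate(s.residues):
        ch = chains.get(r.key.chain)
        if ch is None:
            ch = gemmi.Chain(r.key.chain)
            chains[r.key.chain] = ch
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.key.number, r.key.icode or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*r.coord)
        atom.occ = 1.0
        if bfactors is not None:
            b = float(bfactors[idx])
            if not np.isfinite(b):
                b = 0.0
            atom.b_iso = min(max(b, -99.99), 999.99)
        res.add_atom(atom)
        ch.add_residue(res)
    lig_chains: dict[str, gemmi.Chain] = {}
    for lig in s.ligands:
        chain_id, resname, resnum = lig.ligand_id.split(":")
        ch = chains.get(chain_id) or lig_chains.get(chain_id)
        if ch is None:
            ch = gemmi.Chain(chain_id)
            lig_chains[chain_id] = ch
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(int(resnum), " ")
        res.het_flag = "H"
        for j, xyz in enumerate(lig.atoms):
            atom = gemmi.Atom()
            atom.name = f"X{j + 1}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        ch.add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    for ch in lig_chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
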