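"""Structures, conformer ensembles and per-residue profiles.

Coordinates are stored column-wise (one numpy array per atom attribute), a
layout borrowed from biotite's ``AtomArray``; biotite also backs all PDB
parsing and writing.  Residue numbering always follows the source file and is
never rewritten — deletion edits leave a gap in the numbering and attach a
ligation record naming the newly adjacent residues so the constraint engine
can bond them.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from ._geometry import fibonacci_sphere, kabsch

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"}

ResidueKey = tuple[str, int]


@dataclass
class Structure:
    """One model of a molecular structure.

    Atom attributes are parallel arrays of length ``n_atoms``.  ``ligations``
    lists residue pairs made covalently adjacent by an engineered deletion.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    b_factor: np.ndarray
    title: str = ""
    ligations: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("structure contains non-finite coordinates")
        for ch in self.chains():
            ids = self.res_id[self.chain_id == ch]
            uniq = ids[np.concatenate(([True], ids[1:] != ids[:-1]))]
            if not np.all(np.diff(uniq) > 0):
                raise ValueError(f"residue numbers not strictly increasing in chain {ch!r}")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys (chain, number) in atom order."""
        keys: list[ResidueKey] = []
        prev = None
        for c, r in zip(self.chain_id, self.res_id):
            key = (str(c), int(r))
            if key != prev:
                keys.append(key)
                prev = key
        return keys

    def ca_index(self) -> dict[ResidueKey, int]:
        """Map residue key -> index of its Cα atom."""
        out: dict[ResidueKey, int] = {}
        for i in np.flatnonzero(self.atom_name == "CA"):
            out[(str(self.chain_id[i]), int(self.res_id[i]))] = int(i)
        return out

    def atom_mask_for_residues(self, keys: set[ResidueKey]) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        for i in range(self.n_atoms):
            if (str(self.chain_id[i]), int(self.res_id[i])) in keys:
                mask[i] = True
        return mask

    def subset(self, mask: np.ndarray) -> "Structure":
        kept = {(str(c), int(r)) for c, r in zip(self.chain_id[mask], self.res_id[mask])}
        ligs = [lg for lg in self.ligations if lg[0] in kept and lg[1] in kept]
        return Structure(
            atom_name=self.atom_name[mask].copy(),
            element=self.element[mask].copy(),
            res_id=self.res_id[mask].copy(),
            res_name=self.res_name[mask].copy(),
            chain_id=self.chain_id[mask].copy(),
            coord=self.coord[mask].copy(),
            b_factor=self.b_factor[mask].copy(),
            title=self.title,
            ligations=ligs,
        )


@dataclass
class ConformerEnsemble:
    """N conformers of one molecule plus the parent reference structure."""

    reference: Structure
    coords: np.ndarray  # (N, n_atoms, 3), Angstrom
    fit_selection: list[ResidueKey] | None = None
    superposed: bool = False
    seed: int | None = None
    fit_rmsd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[1] != self.reference.n_atoms:
            raise ValueError(
                f"conformer block shape {self.coords.shape} does not match "
                f"reference atom count {self.reference.n_atoms}"
            )

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    def mean_structure_coords(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class ResidueProfile:
    """Per-residue scalar values, optionally with a per-residue sigma."""

    keys: list[ResidueKey]
    values: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.keys)

    def to_tsv(self) -> str:
        lines = ["chain\tresnum\tvalue\tsigma"]
        sig = self.sigma if self.sigma is not None else np.full(len(self.keys), np.nan)
        for (ch, rn), v, s in zip(self.keys, self.values, sig):
            lines.append(f"{ch}\t{rn}\t{v:.6g}\t{s:.6g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, label: str = "") -> "ResidueProfile":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        keys = [(r[0], int(r[1])) for r in rows]
        values = np.array([float(r[2]) for r in rows])
        sigma = np.array([float(r[3]) for r in rows])
        if np.all(np.isnan(sigma)):
            sigma = None
        return cls(keys=keys, values=values, sigma=sigma, label=label)


# ---------------------------------------------------------------------------
# PDB reading / writing

def _from_atom_array(arr: AtomArray, title: str = "") -> Structure:
    return Structure(
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        element=np.asarray(arr.element, dtype="U2"),
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype="U5"),
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        coord=np.asarray(arr.coord, dtype=float).copy(),
        b_factor=np.asarray(arr.get_annotation("b_factor"), dtype=float).copy()
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(arr.array_length()),
        title=title,
    )


def _to_atom_array(s: Structure, coord: np.ndarray | None = None) -> AtomArray:
    n = s.n_atoms
    arr = AtomArray(n)
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.res_id = s.res_id.astype(int)
    arr.res_name = s.res_name.astype("U5")
    arr.chain_id = s.chain_id.astype("U4")
    arr.coord = np.asarray(coord if coord is not None else s.coord, dtype=np.float32)
    arr.set_annotation("b_factor", s.b_factor.astype(float))
    arr.set_annotation("occupancy", np.ones(n))
    return arr


def read_structure(pdb_text: str, model_index: int = 1,
                   chains: set[str] | None = None) -> Structure:
    """Parse one model of a PDB file into a :class:`Structure`.

    Water is discarded; other HETATM residues are kept only if they carry a
    Cα atom (modified residues).  Alternate locations are resolved to the
    highest-occupancy conformation (ties: first encountered).

    Parameters
    ----------
    model_index : 1-based model number.
    chains : optional set of chain ids to retain.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb.get_model_count()
    if not 1 <= model_index <= n_models:
        raise ValueError(
            f"model {model_index} requested but file has models 1..{n_models}"
        )
    arr = pdb.get_structure(
        model=model_index, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
    )
    # drop water, and non-polymer hetero residues without a Calpha
    keep = ~np.isin(arr.res_name, list(_WATER_NAMES))
    if np.any(arr.hetero):
        has_ca: set[tuple[str, int]] = set()
        for i in np.flatnonzero(arr.atom_name == "CA"):
            has_ca.add((str(arr.chain_id[i]), int(arr.res_id[i])))
        for i in np.flatnonzero(arr.hetero):
            if (str(arr.chain_id[i]), int(arr.res_id[i])) not in has_ca:
                keep[i] = False
    arr = arr[keep]
    available = sorted(set(str(c) for c in arr.chain_id))
    if chains is not None:
        missing = set(chains) - set(available)
        if missing:
            raise ValueError(
                f"chains {sorted(missing)} not present; file has {available}"
            )
        arr = arr[np.isin(arr.chain_id, list(chains))]
    s = _from_atom_array(arr)
    s.validate()
    return s


def write_pdb(s: Structure) -> str:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


def write_ensemble_pdb(e: ConformerEnsemble) -> str:
    """Serialize an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    from biotite.structure import stack

    arrs = [_to_atom_array(e.reference, e.coords[i]) for i in range(e.n_conformers)]
    pdb = PDBFile()
    pdb.set_structure(stack(arrs))
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


def read_ensemble_pdb(pdb_text: str) -> ConformerEnsemble:
    """Load a multi-model PDB as an ensemble (first model is the reference)."""
    pdb = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb.get_model_count()
    ref = read_structure(pdb_text, model_index=1)
    coords = np.empty((n_models, ref.n_atoms, 3))
    for m in range(1, n_models + 1):
        coords[m - 1] = read_structure(pdb_text, model_index=m).coord
    return ConformerEnsemble(reference=ref, coords=coords)


# ---------------------------------------------------------------------------
# Editing

def delete_residues(s: Structure, chain: str, first: int, last: int) -> Structure:
    """Remove an inclusive residue range; numbering of the rest is untouched.

    The returned structure carries a ligation record naming the residues that
    are now sequence-adjacent across the gap, for downstream bonding.
    """
    if last < first:
        raise ValueError(f"empty deletion range {first}..{last}")
    chain_ids = s.res_id[s.chain_id == chain]
    present = set(int(r) for r in chain_ids)
    wanted = set(range(first, last + 1))
    if not wanted <= present:
        raise ValueError(
            f"residues {sorted(wanted - present)} of chain {chain!r} not in structure"
        )
    drop = s.atom_mask_for_residues({(chain, r) for r in wanted})
    out = s.subset(~drop)
    before = [r for r in sorted(present) if r < first]
    after = [r for r in sorted(present) if r > last]
    if before and after:
        out.ligations = out.ligations + [((chain, before[-1]), (chain, after[0]))]
    return out


# ---------------------------------------------------------------------------
# Superposition

def superpose(e: ConformerEnsemble,
              selection: list[ResidueKey] | None = None) -> ConformerEnsemble:
    """Rigid-body fit (Kabsch least squares on Cα) of every conformer onto
    the reference over ``selection`` (default: all residues with a Cα)."""
    ca = e.reference.ca_index()
    if selection is None:
        selection = list(ca)
    if not selection:
        raise ValueError("empty fit selection")
    try:
        idx = np.array([ca[k] for k in selection])
    except KeyError as exc:
        raise ValueError(f"selection residue {exc.args[0]} has no Calpha") from exc
    if len(idx) < 3:
        raise ValueError(
            f"fit selection has {len(idx)} Calpha atoms; at least 3 are needed "
            "(rotation underdetermined)"
        )
    target = e.reference.coord[idx]
    coords = np.empty_like(e.coords)
    rmsds = np.empty(e.n_conformers)
    for i in range(e.n_conformers):
        R, t = kabsch(e.coords[i][idx], target)
        coords[i] = e.coords[i] @ R.T + t
        rmsds[i] = np.sqrt(np.mean(np.sum((coords[i][idx] - target) ** 2, axis=1)))
    return replace(e, coords=coords, fit_selection=list(selection),
                   superposed=True, fit_rmsd=rmsds)


# ---------------------------------------------------------------------------
# Profiles

def normalized_profile(values, keys: list[ResidueKey] | None = None,
                       label: str = "") -> ResidueProfile:
    """Z-score a per-residue profile: (v - mean) / population SD.

    Population SD (divide by N) is used throughout; constant input is an
    error because the normalization is undefined.
    """
    if isinstance(values, ResidueProfile):
        keys = values.keys
        label = label or values.label
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 residues to normalize")
    sd = float(values.std())  # population SD
    if sd == 0.0:
        raise ValueError("constant profile: sigma is zero, normalization undefined")
    if keys is None:
        keys = [("A", i + 1) for i in range(values.size)]
    return ResidueProfile(keys=list(keys), values=(values - values.mean()) / sd,
                          label=label, normalized=True)


def ensemble_bfactors(e: ConformerEnsemble, normalize: bool = True) -> ResidueProfile:
    """Ensemble B-factor profile, B = (8 pi^2 / 3) * <|dr_Calpha|^2>.

    Requires a superposed ensemble.  With ``normalize`` the profile is
    z-scored (mean 0, SD 1) for comparison with normalized experimental
    B factors; otherwise raw values in Angstrom^2 are returned.
    """
    if not e.superposed:
        raise ValueError("ensemble must be superposed before computing B factors")
    ca = e.reference.ca_index()
    keys = list(ca)
    idx = np.array(list(ca.values()))
    xyz = e.coords[:, idx, :]
    msf = np.mean(np.sum((xyz - xyz.mean(axis=0)) ** 2, axis=2), axis=0)
    msf[msf < 1e-12] = 0.0  # snap numerical noise from identical conformers
    b = (8.0 * np.pi ** 2 / 3.0) * msf
    if not normalize:
        return ResidueProfile(keys=keys, values=b, label="B_ens [A^2]")
    return normalized_profile(b, keys=keys, label="B_ens (normalized)")


# ---------------------------------------------------------------------------
# SASA

_RADII_CACHE: dict[str, dict] = {}


def _radii_tables() -> dict:
    if not _RADII_CACHE:
        with resources.files("rotormech.data").joinpath("vdw_radii.json").open() as fh:
            _RADII_CACHE.update(json.load(fh))
    return _RADII_CACHE


def atom_radii(s: Structure) -> np.ndarray:
    """Van der Waals radius per atom; side-chain pseudo-atoms (element 'R')
    get a residue-type effective radius.  Unknown elements are an error."""
    tables = _radii_tables()
    elem_tab = tables["element"]
    pseudo_tab = tables["sidechain_pseudo"]
    radii = np.empty(s.n_atoms)
    for i in range(s.n_atoms):
        el = str(s.element[i]).upper()
        if el == "R":
            radii[i] = pseudo_tab.get(str(s.res_name[i]), pseudo_tab["UNK"])
        elif el in elem_tab:
            radii[i] = elem_tab[el]
        else:
            raise ValueError(f"no van der Waals radius for element {el!r}")
    return radii


def shrake_rupley(coord: np.ndarray, radii: np.ndarray, probe_radius: float = 1.4,
                  n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley quadrature).

    Each atom is covered with a Fibonacci lattice of test points on its
    solvent-expanded sphere; points falling inside any neighbour's expanded
    sphere are occluded.  Returns SASA in Angstrom^2.
    """
    from scipy.spatial import cKDTree

    coord = np.asarray(coord, dtype=float)
    n = coord.shape[0]
    sphere = fibonacci_sphere(n_sphere_points)
    expanded = radii + probe_radius
    tree = cKDTree(coord)
    pairs = tree.query_ball_point(coord, r=2.0 * expanded.max())
    sasa = np.empty(n)
    for i in range(n):
        pts = coord[i] + expanded[i] * sphere
        neigh = [j for j in pairs[i]
                 if j != i and np.sum((coord[j] - coord[i]) ** 2)
                 < (expanded[i] + expanded[j]) ** 2]
        if neigh:
            d2 = np.sum((pts[:, None, :] - coord[neigh][None, :, :]) ** 2, axis=2)
            r2 = (expanded[neigh] ** 2)[None, :]
            inside = d2 < r2 - 1e-9
            # exactly-on-surface points (coincident atoms): lower index wins
            boundary = (np.abs(d2 - r2) <= 1e-9) & (np.array(neigh)[None, :] < i)
            buried = np.any(inside | boundary, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return sasa


def sasa_profile(e: ConformerEnsemble, probe_radius: float = 1.4,
                 n_sphere_points: int = 960) -> ResidueProfile:
    """Ensemble mean and SD of per-residue SASA (Angstrom^2)."""
    radii = atom_radii(e.reference)
    keys = e.reference.residue_keys()
    key_of_atom = np.array(
        [keys.index((str(c), int(r))) for c, r in
         zip(e.reference.chain_id, e.reference.res_id)]
    )
    per_res = np.zeros((e.n_conformers, len(keys)))
    for m in range(e.n_conformers):
        atom_sasa = shrake_rupley(e.coords[m], radii, probe_radius, n_sphere_points)
        np.add.at(per_res[m], key_of_atom, atom_sasa)
    return ResidueProfile(keys=keys, values=per_res.mean(axis=0),
                          sigma=per_res.std(axis=0), label="SASA [A^2]")
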