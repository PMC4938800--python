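"""Distance-constraint conformer generation (reduced representation).

Equilibrium conformer ensembles are rebuilt from a single structure by
iterative satisfaction of pair-distance bounds, in the spirit of
distance-geometry ensemble generators: every conformer starts from the
reference coordinates jittered inside a per-atom bounding box, then repeated
sweeps project each violated pair back to its nearest bound until the largest
violation falls below tolerance or an iteration limit (500) is reached.

This engine deliberately works on a reduced representation — backbone
N/CA/C/O plus a single side-chain centroid pseudo-atom — rather than
rebuilding full atomic detail.  Constraint classes:

covalent     sequential (and ligated) Calpha-Calpha virtual bonds, tight
hbond        backbone N...O donor-acceptor pairs, tight unless labile
salt_bridge  opposite-charge side-chain centroid pairs, moderately tight
contact      any remaining Calpha pair within cutoff, loose
ligation     covalent-class bond bridging an engineered deletion

Labile hydrogen bonds — those whose midpoint is surrounded by polar/charged
side-chain atoms or solvent-exposed — are demoted to loose contact bounds,
which is what lets the ensembles cross local conformational barriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .structure import ConformerEnsemble, Structure, superpose

CLASS_NAMES = ("covalent", "hbond", "salt_bridge", "contact", "ligation")
_CLS = {name: i for i, name in enumerate(CLASS_NAMES)}

_POLAR_RES = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS",
              "LYS", "ARG", "ASP", "GLU", "TRP"}
_POSITIVE_RES = {"LYS", "ARG", "HIS"}
_NEGATIVE_RES = {"ASP", "GLU"}


@dataclass
class EngineConfig:
    """Tunable parameters of the constraint engine (distances in Angstrom)."""

    ca_bond_length: float = 3.80
    ca_bond_slack: float = 0.05
    cis_pro_lower: float = 2.90
    hbond_cutoff: float = 3.5
    hbond_slack: float = 0.15
    salt_bridge_cutoff: float = 5.0
    salt_bridge_slack: float = 0.25
    contact_cutoff: float = 8.0
    contact_slack: float = 1.0
    box_halfwidth: float = 1.5
    lability_shell: float = 4.5
    lability_threshold: int = 3
    burial_min_neighbors: int = 10
    tolerance: float = 0.05
    max_iterations: int = 500

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ConstraintSet:
    """Pair-distance bounds over the atoms of one structure."""

    i: np.ndarray
    j: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    cls: np.ndarray  # int codes into CLASS_NAMES
    box_halfwidth: np.ndarray  # per atom
    lability: np.ndarray  # per constraint; NaN except for hbonds

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("constraint with lower bound above upper bound")

    @property
    def n_constraints(self) -> int:
        return len(self.i)

    def of_class(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.cls == _CLS[name])

    def violations(self, coord: np.ndarray) -> np.ndarray:
        """Per-constraint violation magnitude (0 where satisfied).

        Independent vectorized check, used to assert post hoc that retained
        conformers satisfy every bound.
        """
        d = np.linalg.norm(coord[self.i] - coord[self.j], axis=1)
        return np.maximum(self.lower - d, 0.0) + np.maximum(d - self.upper, 0.0)


@dataclass
class GenerationReport:
    n_requested: int
    n_converged: int
    iterations: list[int] = field(default_factory=list)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "iterations": list(self.iterations),
            "seed": self.seed,
            "config": dict(self.config),
        }


# ---------------------------------------------------------------------------
# Reduced representation

def reduce_structure(s: Structure) -> Structure:
    """Keep backbone N/CA/C/O and collapse each side chain to its centroid.

    The centroid pseudo-atom is written with element ``R`` and atom name
    ``SCC``; its effective van der Waals radius is a residue-type property.
    Structures that are already Calpha-only pass through unchanged.
    """
    backbone = np.isin(s.atom_name, ["N", "CA", "C", "O"])
    keys = s.residue_keys()
    rows: list[int] = []
    pseudo: list[tuple] = []
    for key in keys:
        mask = (s.chain_id == key[0]) & (s.res_id == key[1])
        bb = np.flatnonzero(mask & backbone)
        rows.extend(int(x) for x in bb)
        side = np.flatnonzero(mask & ~backbone & (s.element != "H"))
        if len(side):
            pseudo.append((key, s.res_name[side[0]], s.coord[side].mean(axis=0),
                           float(s.b_factor[side].mean())))
    out = s.subset(np.isin(np.arange(s.n_atoms), rows))
    if pseudo:
        out = Structure(
            atom_name=np.concatenate([out.atom_name, np.array(["SCC"] * len(pseudo), dtype="U6")]),
            element=np.concatenate([out.element, np.array(["R"] * len(pseudo), dtype="U2")]),
            res_id=np.concatenate([out.res_id, np.array([k[1] for k, *_ in pseudo], dtype=int)]),
            res_name=np.concatenate([out.res_name, np.array([rn for _, rn, *_ in pseudo], dtype="U5")]),
            chain_id=np.concatenate([out.chain_id, np.array([k[0] for k, *_ in pseudo], dtype="U4")]),
            coord=np.concatenate([out.coord, np.array([c for *_, c, _ in pseudo])]),
            b_factor=np.concatenate([out.b_factor, np.array([b for *_, b in pseudo])]),
            title=s.title,
            ligations=list(s.ligations),
        )
        # restore residue-major atom order
        order = np.lexsort((np.arange(out.n_atoms), out.res_id, out.chain_id))
        out = _reorder(out, order)
    return out


def _reorder(s: Structure, order: np.ndarray) -> Structure:
    return Structure(
        atom_name=s.atom_name[order], element=s.element[order],
        res_id=s.res_id[order], res_name=s.res_name[order],
        chain_id=s.chain_id[order], coord=s.coord[order],
        b_factor=s.b_factor[order], title=s.title, ligations=list(s.ligations),
    )


# ---------------------------------------------------------------------------
# Lability scoring

def score_lability(s: Structure, midpoint: np.ndarray,
                   exclude_atoms: tuple[int, int] = (-1, -1),
                   config: EngineConfig | None = None) -> int:
    """Solvation score of a hydrogen bond at ``midpoint``.

    Counts polar/charged side-chain heavy atoms within the shell radius of
    the bond midpoint, plus a solvent-exposure proxy: one extra point when
    the shell is sparsely packed (fewer than ``burial_min_neighbors`` heavy
    atoms), i.e. the bond sits at the protein surface.  Bonds scoring at or
    above the lability threshold are demoted from tight hbond to loose
    contact bounds.
    """
    cfg = config or EngineConfig()
    shell = cfg.lability_shell
    d = np.linalg.norm(s.coord - np.asarray(midpoint), axis=1)
    in_shell = (d <= shell) & (s.element != "H")
    in_shell[list(exclude_atoms)] = False
    n_heavy = int(np.count_nonzero(in_shell))
    sidechain = ~np.isin(s.atom_name, ["N", "CA", "C", "O"])
    polar = in_shell & sidechain & np.isin(s.res_name, list(_POLAR_RES))
    exposure = 1 if n_heavy < cfg.burial_min_neighbors else 0
    return int(np.count_nonzero(polar)) + exposure


# ---------------------------------------------------------------------------
# Constraint extraction

def extract_constraints(s: Structure, config: EngineConfig | None = None) -> ConstraintSet:
    """Build the pair-distance bound table for a (reduced) structure."""
    cfg = config or EngineConfig()
    ca = s.ca_index()
    keys = s.residue_keys()
    for key in keys:
        if key not in ca:
            raise ValueError(f"residue {key} has no Calpha atom")

    ii: list[int] = []
    jj: list[int] = []
    lo: list[float] = []
    up: list[float] = []
    cl: list[int] = []
    lab: list[float] = []

    def add(i: int, j: int, lower: float, upper: float, cls: str,
            lability: float = np.nan) -> None:
        ii.append(i)
        jj.append(j)
        lo.append(lower)
        up.append(upper)
        cl.append(_CLS[cls])
        lab.append(lability)

    constrained: set[tuple[int, int]] = set()

    # (i) sequential Calpha-Calpha virtual bonds
    for a, b in zip(keys[:-1], keys[1:]):
        if a[0] != b[0] or b[1] != a[1] + 1:
            continue  # chain break or numbering gap
        lower = cfg.ca_bond_length - cfg.ca_bond_slack
        if str(s.res_name[ca[b]]) == "PRO":
            lower = cfg.cis_pro_lower  # cis-proline admits the short bond
        add(ca[a], ca[b], lower, cfg.ca_bond_length + cfg.ca_bond_slack, "covalent")
        constrained.add((min(ca[a], ca[b]), max(ca[a], ca[b])))

    # (v) ligation records from engineered deletions
    for ra, rb in s.ligations:
        add(ca[ra], ca[rb], cfg.ca_bond_length - cfg.ca_bond_slack,
            cfg.ca_bond_length + cfg.ca_bond_slack, "ligation")
        constrained.add((min(ca[ra], ca[rb]), max(ca[ra], ca[rb])))

    # (ii) backbone N...O hydrogen bonds
    n_idx = np.flatnonzero(s.atom_name == "N")
    o_idx = np.flatnonzero(s.atom_name == "O")
    for i in n_idx:
        for j in o_idx:
            if s.chain_id[i] == s.chain_id[j] and abs(int(s.res_id[i]) - int(s.res_id[j])) < 2:
                continue  # local backbone geometry, not a hydrogen bond
            d = float(np.linalg.norm(s.coord[i] - s.coord[j]))
            if d > cfg.hbond_cutoff:
                continue
            mid = 0.5 * (s.coord[i] + s.coord[j])
            score = score_lability(s, mid, exclude_atoms=(int(i), int(j)), config=cfg)
            if score >= cfg.lability_threshold:
                add(int(i), int(j), max(d - cfg.contact_slack, 0.5),
                    d + cfg.contact_slack, "contact", float(score))
            else:
                add(int(i), int(j), d - cfg.hbond_slack, d + cfg.hbond_slack,
                    "hbond", float(score))

    # (iii) salt bridges between charged side-chain centroids
    pseudo = np.flatnonzero(s.element == "R")
    pos = [int(i) for i in pseudo if str(s.res_name[i]) in _POSITIVE_RES]
    neg = [int(i) for i in pseudo if str(s.res_name[i]) in _NEGATIVE_RES]
    for i in pos:
        for j in neg:
            d = float(np.linalg.norm(s.coord[i] - s.coord[j]))
            if d <= cfg.salt_bridge_cutoff:
                add(i, j, d - cfg.salt_bridge_slack, d + cfg.salt_bridge_slack,
                    "salt_bridge")

    # (iv) loose Calpha-Calpha contacts
    ca_list = list(ca.items())
    ca_idx = np.array([v for _, v in ca_list])
    ca_xyz = s.coord[ca_idx]
    from scipy.spatial import cKDTree

    tree = cKDTree(ca_xyz)
    for a, b in sorted(tree.query_pairs(cfg.contact_cutoff)):
        i, j = int(ca_idx[a]), int(ca_idx[b])
        if (min(i, j), max(i, j)) in constrained:
            continue
        d = float(np.linalg.norm(s.coord[i] - s.coord[j]))
        add(i, j, max(d - cfg.contact_slack, 0.5), d + cfg.contact_slack, "contact")

    return ConstraintSet(
        i=np.array(ii, dtype=np.int64), j=np.array(jj, dtype=np.int64),
        lower=np.array(lo), upper=np.array(up), cls=np.array(cl, dtype=np.int8),
        box_halfwidth=np.full(s.n_atoms, cfg.box_halfwidth),
        lability=np.array(lab),
    )


# ---------------------------------------------------------------------------
# Conformer generation

@njit(cache=False)
def _max_violation(coord, ci, cj, lower, upper):  # pragma: no cover
    worst = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = coord[i, 0] - coord[j, 0]
        dy = coord[i, 1] - coord[j, 1]
        dz = coord[i, 2] - coord[j, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d < lower[k]:
            v = lower[k] - d
        elif d > upper[k]:
            v = d - upper[k]
        else:
            v = 0.0
        if v > worst:
            worst = v
    return worst


@njit(cache=False)
def _project_sweeps(coord, ci, cj, lower, upper, perms, tol, max_iter):  # pragma: no cover
    n_iter = 0
    for it in range(max_iter):
        max_viol = 0.0
        for idx in range(perms.shape[1]):
            k = perms[it, idx]
            i = ci[k]
            j = cj[k]
            dx = coord[i, 0] - coord[j, 0]
            dy = coord[i, 1] - coord[j, 1]
            dz = coord[i, 2] - coord[j, 2]
            d = (dx * dx + dy * dy + dz * dz) ** 0.5
            if d < 1e-9:
                coord[i, 0] += 1e-3
                d = 1e-3
                dx = 1e-3
            if d < lower[k]:
                target = lower[k]
            elif d > upper[k]:
                target = upper[k]
            else:
                continue
            viol = abs(d - target)
            if viol > max_viol:
                max_viol = viol
            corr = 0.5 * (target - d) / d
            mx = dx * corr
            my = dy * corr
            mz = dz * corr
            coord[i, 0] += mx
            coord[i, 1] += my
            coord[i, 2] += mz
            coord[j, 0] -= mx
            coord[j, 1] -= my
            coord[j, 2] -= mz
        n_iter = it + 1
        # converged only if a fresh verification pass (no moves) agrees:
        # corrections late in a sweep can re-violate earlier pairs
        if max_viol < tol and _max_violation(coord, ci, cj, lower, upper) < tol:
            return n_iter, True
    return n_iter, False


def generate_conformer(cs: ConstraintSet, reference_coord: np.ndarray,
                       seed, config: EngineConfig | None = None
                       ) -> tuple[np.ndarray | None, int, bool]:
    """One rebuild attempt: random start in the bounding box, then iterative
    pair projection.  Returns (coords or None, iterations, converged).

    Convergence failure after the iteration limit is reported, not raised;
    an infeasible constraint table (the reference itself violates a bound)
    is a caller error and raises immediately.
    """
    cfg = config or EngineConfig()
    ref = np.asarray(reference_coord, dtype=float)
    # ligation bounds are rebuild targets (the edited reference still has the
    # deletion gap open), so they are exempt from the consistency check
    v0 = np.where(cs.cls == _CLS["ligation"], 0.0, cs.violations(ref))
    if np.any(v0 > cfg.tolerance):
        k = int(np.argmax(v0))
        raise ValueError(
            f"constraint set inconsistent with reference: pair ({cs.i[k]}, {cs.j[k]}) "
            f"violated by {v0[k]:.3f} A before iteration"
        )
    rng = np.random.default_rng(seed)
    start = ref + rng.uniform(-1.0, 1.0, ref.shape) * cs.box_halfwidth[:, None]
    m = cs.n_constraints
    perms = np.tile(np.arange(m, dtype=np.int64), (cfg.max_iterations, 1))
    perms = rng.permuted(perms, axis=1)
    coord = np.ascontiguousarray(start)
    n_iter, ok = _project_sweeps(coord, cs.i, cs.j, cs.lower, cs.upper,
                                 perms, cfg.tolerance, cfg.max_iterations)
    return (coord if ok else None), int(n_iter), bool(ok)


def generate_ensemble(s: Structure, n: int, seed: int,
                      config: EngineConfig | None = None,
                      constraints: ConstraintSet | None = None
                      ) -> tuple[ConformerEnsemble, GenerationReport]:
    """Generate ``n`` independent conformers of ``s`` and superpose on Cα.

    Per-conformer seeds are spawned reproducibly from the master seed; only
    converged conformers are retained, and each retained conformer is
    re-checked against every constraint by an independent vectorized pass.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or EngineConfig()
    cs = constraints if constraints is not None else extract_constraints(s, cfg)
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    kept: list[np.ndarray] = []
    iters: list[int] = []
    for cseed in child_seeds:
        coord, n_iter, ok = generate_conformer(cs, s.coord, cseed, cfg)
        iters.append(n_iter)
        if ok:
            if np.any(cs.violations(coord) > cfg.tolerance * (1 + 1e-9)):
                warnings.warn("converged conformer failed the independent "
                              "constraint check; discarded")
                continue
            kept.append(coord)
    report = GenerationReport(n_requested=n, n_converged=len(kept),
                              iterations=iters, seed=seed, config=cfg.to_dict())
    if not kept:
        raise RuntimeError(
            f"no conformer converged out of {n} attempts; report: {report.to_dict()}"
        )
    ens = ConformerEnsemble(reference=s, coords=np.array(kept), seed=seed)
    ens = superpose(ens)
    ens = replace(ens, seed=seed)
    return ens, report
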