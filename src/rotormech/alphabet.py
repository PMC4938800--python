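"""Structural-alphabet encoding of overlapping 4-residue Cα fragments.

Every conformer of an ensemble is turned into a string: each window of four
consecutive residues (indexed by its first residue; windows never bridge
chain breaks or numbering gaps) is assigned the library letter with the
smallest Kabsch-superposed RMSD to its Cα coordinates.  Column statistics of
the resulting letter matrix (per-position frequencies, Shannon entropies)
feed the correlation-network stage.

The default 25-letter library shipped with the package is a synthetic
stand-in built from idealized Cα internal geometry (virtual bond 3.8 Å,
representative virtual-angle/dihedral combinations of helix, sheet and loop
basins); any user library in the same JSON format can be substituted, and
letter -> secondary-structure class is a property of the library file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ._geometry import batch_rmsd_to_template
from .structure import ConformerEnsemble, ResidueKey

_CA_BOND = 3.8  # virtual Calpha-Calpha bond length, Angstrom


@dataclass
class AlphabetLibrary:
    """Canonical 4-residue fragments: ids, centered Cα coordinates, classes."""

    letters: list[str]
    coords: np.ndarray  # (n_letters, 4, 3), centered at origin
    classes: list[str]  # secondary-structure class per letter

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.letters) < 2:
            raise ValueError("library needs at least 2 letters")
        if self.coords.shape != (len(self.letters), 4, 3):
            raise ValueError("coordinate block must be (n_letters, 4, 3)")
        self.coords = self.coords - self.coords.mean(axis=1, keepdims=True)
        for a in range(len(self.letters)):
            for b in range(a + 1, len(self.letters)):
                if batch_rmsd_to_template(self.coords[a:a + 1], self.coords[b])[0] < 1e-6:
                    raise ValueError(
                        f"letters {self.letters[a]} and {self.letters[b]} coincide")

    @property
    def n_letters(self) -> int:
        return len(self.letters)

    def to_json(self) -> str:
        return json.dumps({
            "letters": [
                {"id": l, "class": c, "coords": self.coords[k].round(4).tolist()}
                for k, (l, c) in enumerate(zip(self.letters, self.classes))
            ]
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AlphabetLibrary":
        data = json.loads(text)["letters"]
        return cls(letters=[d["id"] for d in data],
                   coords=np.array([d["coords"] for d in data]),
                   classes=[d["class"] for d in data])


def fragment_from_internal(theta1_deg: float, theta2_deg: float,
                           tau_deg: float) -> np.ndarray:
    """Build a 4-point Cα fragment from virtual angles and dihedral.

    theta1 is the p0-p1-p2 angle, theta2 the p1-p2-p3 angle, tau the dihedral
    about p1-p2.  Bond lengths are the canonical 3.8 Å.
    """
    t1, t2, tau = np.radians([theta1_deg, theta2_deg, tau_deg])
    p0 = np.zeros(3)
    p1 = np.array([_CA_BOND, 0.0, 0.0])
    p2 = p1 + _CA_BOND * np.array([-np.cos(t1), np.sin(t1), 0.0])
    # place p3 at angle theta2 from the p1->p2 direction, rotated by tau
    d = (p2 - p1) / _CA_BOND
    ref = p0 - p1
    n1 = np.cross(ref, d)
    n1 /= np.linalg.norm(n1)
    m = np.cross(n1, d)
    local = _CA_BOND * np.array([-np.cos(t2),
                                 -np.sin(t2) * np.cos(tau),
                                 np.sin(t2) * np.sin(tau)])
    p3 = p2 + local[0] * d + local[1] * m + local[2] * n1
    frag = np.stack((p0, p1, p2, p3))
    return frag - frag.mean(axis=0)


# (theta1, theta2, tau, class) for the synthetic default library; the basins
# roughly tile the Calpha virtual-geometry map (helix ~ (89, 89, 50),
# sheet ~ (120, 120, -170), polyproline and assorted turn/loop geometries).
_SYNTHETIC_BASINS = [
    (89, 89, 50, "helix"), (85, 92, 45, "helix"), (93, 86, 55, "helix"),
    (89, 95, 40, "helix"), (95, 89, 60, "helix"), (100, 95, 55, "helix"),
    (120, 120, -170, "sheet"), (125, 118, -175, "sheet"),
    (115, 124, -160, "sheet"), (130, 128, 178, "sheet"),
    (122, 112, -145, "sheet"), (118, 130, 165, "sheet"),
    (110, 110, -120, "loop"), (100, 120, -80, "loop"), (120, 100, -60, "loop"),
    (95, 110, -30, "loop"), (110, 95, 0, "loop"), (105, 105, 30, "loop"),
    (90, 120, 90, "loop"), (120, 90, 120, "loop"), (100, 100, 150, "loop"),
    (130, 95, -100, "loop"), (95, 130, 75, "loop"), (85, 115, -135, "loop"),
    (115, 85, 105, "loop"),
]


def synthetic_library() -> AlphabetLibrary:
    """The shipped synthetic 25-letter stand-in library (see module docs)."""
    letters = [chr(ord("A") + k) for k in range(len(_SYNTHETIC_BASINS))]
    coords = np.stack([fragment_from_internal(t1, t2, tau)
                       for t1, t2, tau, _ in _SYNTHETIC_BASINS])
    return AlphabetLibrary(letters=letters, coords=coords,
                           classes=[c for *_, c in _SYNTHETIC_BASINS])


def default_library() -> AlphabetLibrary:
    """Load the shipped synthetic library from its data file."""
    path = resources.files("rotormech.data").joinpath("synthetic_alphabet25.json")
    return AlphabetLibrary.from_json(path.read_text())


# ---------------------------------------------------------------------------
# Encoding

def encode_fragment(coords: np.ndarray, lib: AlphabetLibrary) -> str:
    """Letter with minimal superposed RMSD to a 4-point fragment.

    Ties break to the lowest letter index; coincident points are an error.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (4, 3) or not np.all(np.isfinite(coords)):
        raise ValueError("fragment must be 4 finite Calpha positions")
    d = coords[:, None, :] - coords[None, :, :]
    if np.min(np.linalg.norm(d, axis=2) + np.eye(4) * 1e9) < 1e-6:
        raise ValueError("degenerate fragment: coincident Calpha positions")
    rmsds = np.array([batch_rmsd_to_template(coords[None], lib.coords[k])[0]
                      for k in range(lib.n_letters)])
    return lib.letters[int(np.argmin(rmsds))]


@dataclass
class FragmentTrajectory:
    """Letter matrix (N conformers x P positions) over a library."""

    letters: np.ndarray  # int indices into library
    positions: list[ResidueKey]  # first residue of each 4-residue window
    library: AlphabetLibrary

    def __post_init__(self) -> None:
        if self.letters.shape[1] != len(self.positions):
            raise ValueError("letter matrix and position map disagree")

    @property
    def n_conformers(self) -> int:
        return self.letters.shape[0]

    @property
    def n_positions(self) -> int:
        return self.letters.shape[1]

    def strings(self) -> list[str]:
        lut = np.array(self.library.letters)
        return ["".join(lut[row]) for row in self.letters]

    def column_frequencies(self) -> np.ndarray:
        """(P, n_letters) per-position letter frequency table."""
        P, Q = self.n_positions, self.library.n_letters
        freq = np.zeros((P, Q))
        for p in range(P):
            freq[p] = np.bincount(self.letters[:, p], minlength=Q)
        return freq / self.n_conformers

    def populated_fraction(self) -> np.ndarray:
        """Per position, the ensemble fraction of the most populated letter."""
        return self.column_frequencies().max(axis=1)


def _contiguous_windows(e: ConformerEnsemble) -> list[tuple[ResidueKey, list[int]]]:
    ca = e.reference.ca_index()
    keys = list(ca)
    windows = []
    for p in range(len(keys) - 3):
        quad = keys[p:p + 4]
        if all(quad[k][0] == quad[0][0] and quad[k][1] == quad[0][1] + k
               for k in range(4)):
            windows.append((quad[0], [ca[k] for k in quad]))
    return windows


def encode_ensemble(e: ConformerEnsemble, lib: AlphabetLibrary) -> FragmentTrajectory:
    """Encode every conformer x fragment position of a superposed ensemble.

    Chains are segmented at numbering gaps (including deletion sites), so
    windows never bridge a break.  Encoding is batched per position and
    letter over all conformers.
    """
    if not e.superposed:
        raise ValueError("ensemble must be superposed before encoding")
    windows = _contiguous_windows(e)
    if not windows:
        raise ValueError("no contiguous 4-residue window to encode")
    N = e.n_conformers
    out = np.empty((N, len(windows)), dtype=np.int16)
    for p, (_, idx) in enumerate(windows):
        frags = e.coords[:, idx, :]
        rmsds = np.stack([batch_rmsd_to_template(frags, lib.coords[k])
                          for k in range(lib.n_letters)], axis=1)
        out[:, p] = np.argmin(rmsds, axis=1)
    return FragmentTrajectory(letters=out, positions=[w[0] for w in windows],
                              library=lib)


def column_entropy(ft: FragmentTrajectory) -> np.ndarray:
    """Shannon entropy (bits) of each column's letter distribution."""
    freq = ft.column_frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log2(freq), 0.0)
    return -terms.sum(axis=1)
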