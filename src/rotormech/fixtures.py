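"""Ground-truth synthetic inputs for every pipeline stage.

Two generators are provided:

* a segmented rigid-rod polymer — ideal α-helical Cα segments joined by
  hinges at which each conformer receives independent bend (axis
  perpendicular to the preceding segment) and twist (axis parallel to the
  preceding segment) rotations drawn from a harmonic (Gaussian) or two-state
  (symmetric bimodal) well.  The generator knows its own hinge positions and
  angular widths, so difference-angle recovery, hinge calling, amplification
  and PC attribution can all be tested against exact truth.

* a pairwise-coupled (Potts) sequence model, Gibbs-sampled into a paired
  two-protein alignment with synthetic organism and genomic-locus metadata,
  so coevolution scoring can be tested against planted couplings.

Ideal helix geometry: 2.3 Å Cα radius, 1.5 Å rise, 100°/residue.  With 100°
per residue the helical phase repeats every 18 residues, so Cα pairs 18 apart
give a chord exactly parallel to the segment axis and Cα triplets
(i, i+9, i+18) span a plane whose normal is exactly perpendicular to it —
these are the anchors used for the generator's axis and ring vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import rotation_about_axis, unit
from .coevolution import PairedMSA
from .mechanics import AnglePair, VectorDefinition
from .structure import ConformerEnsemble, Structure, superpose

HELIX_RADIUS = 2.3  # Angstrom
HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TURN_DEG = 100.0  # degrees per residue


@dataclass(frozen=True)
class HingeSpec:
    """Angular fluctuation model of one hinge (degrees).

    ``model`` applies to both bend and twist: "gaussian" draws N(0, sigma);
    "two_state" draws N(+/-delta, sigma) with equal state probability.
    """

    bend_sigma: float = 0.0
    twist_sigma: float = 0.0
    model: str = "gaussian"
    bend_delta: float = 0.0
    twist_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "two_state"):
            raise ValueError(f"unknown fluctuation model {self.model!r}")
        if min(self.bend_sigma, self.twist_sigma) < 0:
            raise ValueError("sigma must be non-negative")
        if min(self.bend_delta, self.twist_delta) < 0:
            raise ValueError("two-state separation delta must be non-negative")


@dataclass(frozen=True)
class HingeGroundTruth:
    """Full specification of a segmented-rod fixture."""

    segment_lengths: tuple[int, ...] = (36, 36)
    hinges: tuple[HingeSpec, ...] = (HingeSpec(bend_sigma=10.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.segment_lengths) < 2:
            raise ValueError("need at least 2 segments")
        if min(self.segment_lengths) < 4:
            raise ValueError("segments shorter than 4 residues cannot be "
                             "fragment-encoded")
        if len(self.hinges) != len(self.segment_lengths) - 1:
            raise ValueError("need exactly one hinge spec per segment junction")

    @property
    def n_residues(self) -> int:
        return int(sum(self.segment_lengths))

    def segment_start_indices(self) -> list[int]:
        starts = [0]
        for ln in self.segment_lengths[:-1]:
            starts.append(starts[-1] + ln)
        return starts

    def hinge_boundary_indices(self) -> list[int]:
        """0-based index of the first residue of each post-hinge segment."""
        return self.segment_start_indices()[1:]


def build_reference_trace(segment_lengths: tuple[int, ...],
                          chain: str = "A") -> Structure:
    """Straight ideal-helix Cα trace covering all segments, residues 1..L."""
    n = int(sum(segment_lengths))
    i = np.arange(n)
    # negative azimuthal step keeps the Calpha virtual dihedral at the
    # right-handed alpha-helical value (~ +50 degrees)
    phi = -np.radians(HELIX_TURN_DEG * i)
    coord = np.column_stack((HELIX_RADIUS * np.cos(phi),
                             HELIX_RADIUS * np.sin(phi),
                             HELIX_RISE * i))
    return Structure(
        atom_name=np.array(["CA"] * n, dtype="U6"),
        element=np.array(["C"] * n, dtype="U2"),
        res_id=i + 1,
        res_name=np.array(["ALA"] * n, dtype="U5"),
        chain_id=np.array([chain] * n, dtype="U4"),
        coord=coord,
        b_factor=np.zeros(n),
        title="segmented-helix fixture",
    )


def build_two_domain_trace(domain_len: int = 12, linker_len: int = 4,
                           chain: str = "A") -> tuple[Structure, dict]:
    """Two helical domains joined by an extended linker, for engine tests.

    The linker continues the chain as a straight 3.8 Å/residue strand, so it
    lacks the short-range bracing contacts of the helical domains — under
    the constraint engine it becomes the soft hinge.  Returns the structure
    and the residue ranges (1-based, inclusive) of both domains and linker.
    """
    def helix_block(n: int, phase0: float, origin: np.ndarray) -> np.ndarray:
        i = np.arange(n)
        phi = np.radians(HELIX_TURN_DEG * i) + phase0
        return origin + np.column_stack((
            HELIX_RADIUS * np.cos(phi) - HELIX_RADIUS * np.cos(phase0),
            HELIX_RADIUS * np.sin(phi) - HELIX_RADIUS * np.sin(phase0),
            HELIX_RISE * i))

    d1 = helix_block(domain_len, 0.0, np.zeros(3))
    lk = d1[-1] + np.array([0.0, 0.0, 3.8]) * np.arange(1, linker_len + 1)[:, None]
    d2 = helix_block(domain_len, 0.0, lk[-1] + np.array([0.0, 0.0, 3.8]))
    coord = np.vstack((d1, lk, d2))
    n = len(coord)
    s = Structure(
        atom_name=np.array(["CA"] * n, dtype="U6"),
        element=np.array(["C"] * n, dtype="U2"),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n, dtype="U5"),
        chain_id=np.array([chain] * n, dtype="U4"),
        coord=coord,
        b_factor=np.zeros(n),
        title="two-domain linker fixture",
    )
    ranges = {
        "domain1": (1, domain_len),
        "linker": (domain_len + 1, domain_len + linker_len),
        "domain2": (domain_len + linker_len + 1, n),
    }
    return s, ranges


def build_blob_linker_trace(blob_len: int = 14, linker_len: int = 3,
                            chain: str = "A") -> tuple[Structure, dict]:
    """Two compact solenoid domains joined by an extended linker.

    The solenoid (3.71 Å radius, 60°/residue, 0.8 Å rise — step length kept
    at the canonical 3.8 Å) packs each domain into a dense cylinder whose
    residues are heavily cross-linked by distance constraints, so the domain
    is genuinely rigid under the engine; the straight linker is not.
    """
    def solenoid(n: int, origin: np.ndarray) -> np.ndarray:
        r, turn, c = 3.71, np.radians(60.0), 0.8
        i = np.arange(n)
        return origin + np.column_stack((r * np.cos(turn * i) - r,
                                         r * np.sin(turn * i),
                                         c * i))

    b1 = solenoid(blob_len, np.zeros(3))
    lk = b1[-1] + np.array([0.0, 0.0, 3.8]) * np.arange(1, linker_len + 1)[:, None]
    b2 = solenoid(blob_len, np.zeros(3)) + lk[-1] + np.array([0.0, 0.0, 3.8])
    coord = np.vstack((b1, lk, b2))
    n = len(coord)
    s = Structure(
        atom_name=np.array(["CA"] * n, dtype="U6"),
        element=np.array(["C"] * n, dtype="U2"),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n, dtype="U5"),
        chain_id=np.array([chain] * n, dtype="U4"),
        coord=coord,
        b_factor=np.zeros(n),
        title="two-blob linker fixture",
    )
    ranges = {
        "domain1": (1, blob_len),
        "linker": (blob_len + 1, blob_len + linker_len),
        "domain2": (blob_len + linker_len + 1, n),
    }
    return s, ranges


def two_domain_engine_fixture(blob_len: int = 14, linker_len: int = 3,
                              tight_slack: float = 0.1,
                              loose_slack: float = 1.0):
    """Structure + constraint set with loose inter-domain contacts only.

    Intra-domain contact bounds are tightened to ±``tight_slack``; every
    contact involving the linker or bridging the two domains keeps loose
    ±``loose_slack`` bounds.  Returns (structure, constraints, vector defs,
    angle pairs) where the pairs measure matched-length chords within
    domain 1 (intra) and across the linker (inter).
    """
    import dataclasses as _dc

    from .engine import EngineConfig, extract_constraints
    from .mechanics import AnglePair, VectorDefinition

    s, ranges = build_blob_linker_trace(blob_len, linker_len)
    cfg = EngineConfig(contact_slack=tight_slack)
    cs = extract_constraints(s, cfg)
    rid = s.res_id
    lk_lo, lk_hi = ranges["linker"]
    linker = set(range(lk_lo, lk_hi + 1))
    lo, up = cs.lower.copy(), cs.upper.copy()
    contact_cls = cs.of_class("contact")
    for k in contact_cls:
        ri, rj = int(rid[cs.i[k]]), int(rid[cs.j[k]])
        crosses = (ri <= blob_len) != (rj <= blob_len)
        if ri in linker or rj in linker or crosses:
            mid = 0.5 * (lo[k] + up[k])
            lo[k], up[k] = mid - loose_slack, mid + loose_slack
    cs = _dc.replace(cs, lower=lo, upper=up)
    half = blob_len // 2
    d2_start = blob_len + linker_len + 1
    defs = {
        "intra_a": VectorDefinition("intra_a", "line", "A", (1, half)),
        "intra_b": VectorDefinition("intra_b", "line", "A", (half + 1, blob_len)),
        "inter_b": VectorDefinition("inter_b", "line", "A",
                                    (d2_start, d2_start + half - 1)),
    }
    pairs = {
        "intra": AnglePair("intra_a", "intra_b"),
        "inter": AnglePair("intra_b", "inter_b"),
    }
    return s, cs, defs, pairs


def _segment_frame_anchors(start: int, length: int) -> tuple[tuple[int, int],
                                                             tuple[int, int, int]]:
    """(axis chord, ring plane) anchor indices (0-based) for one segment.

    With 100°/residue the phase repeats every 18 residues, so (a, a+18) is an
    axis-parallel chord and (a, a+9, a+18) spans a plane containing that
    chord and the helix diameter at a's azimuth — its normal is exactly
    perpendicular to the segment axis, pointing along azimuth(a) + 90°.  The
    anchor offset of 4 residues orients that normal (the generator's bend
    axis) perpendicular to the inter-segment junction chord, so hinge
    bending maximally deforms the junction-spanning fragments, as it does at
    real protein hinges.
    """
    if length >= 23:
        axis = (start + 4, start + 22)
        ring = (start + 4, start + 13, start + 22)
    elif length >= 19:
        axis = (start, start + 18)
        ring = (start, start + 9, start + 18)
    else:
        axis = (start, start + length - 1)
        ring = (start, start + length // 2, start + length - 1)
    return axis, ring


def _draw_angle(spec_model: str, sigma: float, delta: float,
                rng: np.random.Generator) -> float:
    if spec_model == "two_state" and delta > 0:
        center = delta if rng.random() < 0.5 else -delta
        return float(rng.normal(center, sigma))
    return float(rng.normal(0.0, sigma))


def make_hinge_ensemble(gt: HingeGroundTruth, n: int = 4096,
                        seed: int | None = None
                        ) -> tuple[ConformerEnsemble, HingeGroundTruth]:
    """Sample a conformer ensemble of the segmented rod from its ground truth.

    Per conformer and hinge, a bend rotation (about the preceding segment's
    ring normal, i.e. perpendicular to its axis) and a twist rotation (about
    the preceding segment's axis chord) are applied to everything downstream,
    pivoting at the last Cα before the hinge.  The ensemble is superposed on
    all Cα before return; the generator truth is attached unchanged.
    """
    ref = build_reference_trace(gt.segment_lengths)
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    starts = gt.segment_start_indices()
    lengths = list(gt.segment_lengths)
    coords = np.empty((n, ref.n_atoms, 3))
    for m in range(n):
        c = ref.coord.copy()
        for h, spec in enumerate(gt.hinges):
            s_prev, l_prev = starts[h], lengths[h]
            axis_idx, ring_idx = _segment_frame_anchors(s_prev, l_prev)
            axis_vec = c[axis_idx[1]] - c[axis_idx[0]]
            ring_normal = np.cross(c[ring_idx[1]] - c[ring_idx[0]],
                                   c[ring_idx[2]] - c[ring_idx[0]])
            pivot = c[starts[h + 1] - 1].copy()
            bend = _draw_angle(spec.model, spec.bend_sigma, spec.bend_delta, rng)
            twist = _draw_angle(spec.model, spec.twist_sigma, spec.twist_delta, rng)
            down = slice(starts[h + 1], None)
            if bend != 0.0:
                R = rotation_about_axis(unit(ring_normal), np.radians(bend))
                c[down] = (c[down] - pivot) @ R.T + pivot
            if twist != 0.0:
                R = rotation_about_axis(unit(axis_vec), np.radians(twist))
                c[down] = (c[down] - pivot) @ R.T + pivot
        coords[m] = c
    ens = ConformerEnsemble(reference=ref, coords=coords,
                            seed=gt.seed if seed is None else seed)
    ens = superpose(ens)
    return ens, gt


def hinge_vector_definitions(gt: HingeGroundTruth,
                             chain: str = "A") -> dict[str, VectorDefinition]:
    """Axis and ring vectors per segment, matching the generator's frames."""
    defs: dict[str, VectorDefinition] = {}
    for k, (start, length) in enumerate(zip(gt.segment_start_indices(),
                                            gt.segment_lengths)):
        axis_idx, ring_idx = _segment_frame_anchors(start, length)
        defs[f"seg{k}_axis"] = VectorDefinition(
            name=f"seg{k}_axis", kind="line", chain=chain,
            res_ids=tuple(i + 1 for i in axis_idx))
        defs[f"seg{k}_ring"] = VectorDefinition(
            name=f"seg{k}_ring", kind="plane_normal", chain=chain,
            res_ids=tuple(i + 1 for i in ring_idx))
    return defs


def hinge_angle_pairs(gt: HingeGroundTruth) -> dict[str, AnglePair]:
    """Signed bend and twist measurement pairs for each hinge, plus the
    distal pair (first vs last segment) used for amplification."""
    pairs: dict[str, AnglePair] = {}
    n_seg = len(gt.segment_lengths)
    for h in range(n_seg - 1):
        pairs[f"hinge{h}_bend"] = AnglePair(
            name_a=f"seg{h}_axis", name_b=f"seg{h + 1}_axis",
            sign=f"seg{h}_ring")
        pairs[f"hinge{h}_twist"] = AnglePair(
            name_a=f"seg{h}_ring", name_b=f"seg{h + 1}_ring",
            sign=f"seg{h}_axis")
    pairs["distal_bend"] = AnglePair(name_a="seg0_axis",
                                     name_b=f"seg{n_seg - 1}_axis",
                                     sign="seg0_ring")
    return pairs


def expected_distal_bend_sigma(gt: HingeGroundTruth, n_mc: int = 200_000,
                               seed: int = 12345) -> float:
    """Generator-derived expectation of the distal bend-angle SD (degrees).

    Monte Carlo over hinge rotations using the truth alone (unit frames, no
    polymer, no pipeline): serial bends about parallel ring normals compose,
    and the signed projection of the final segment axis is measured exactly
    as the analysis does.  Independent of the ensemble machinery.
    """
    rng = np.random.default_rng(seed)
    angles = np.empty(n_mc)
    for m in range(n_mc):
        v = np.array([0.0, 0.0, 1.0])
        b = np.array([1.0, 0.0, 0.0])  # shared bend axis in the aligned reference
        for spec in gt.hinges:
            bend = _draw_angle(spec.model, spec.bend_sigma, spec.bend_delta, rng)
            v = rotation_about_axis(b, np.radians(bend)) @ v
        raw = np.arccos(np.clip(v[2], -1.0, 1.0))
        sign = 1.0 if np.dot(np.cross([0, 0, 1.0], v), b) >= 0 else -1.0
        angles[m] = sign * raw
    return float(np.degrees(np.std(angles)))


# ---------------------------------------------------------------------------
# Potts-model paired alignments

@dataclass(frozen=True)
class PottsGroundTruth:
    """A pairwise-coupled sequence model over two concatenated proteins.

    ``coupled_pairs`` holds (i, j, J) with global column indices; the
    coupling favours identical states at i and j with strength J (Potts
    ferromagnet), which plants a clean mutual-information and DCA signal.
    """

    length_a: int = 8
    length_b: int = 8
    q: int = 8
    coupled_pairs: tuple[tuple[int, int, float], ...] = ((3, 11, 2.0),)
    field_scale: float = 0.3
    n_sequences: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 2 or self.length_a < 2 or self.length_b < 1:
            raise ValueError("need q >= 2 and at least 2+1 columns")
        L = self.length_a + self.length_b
        seen = set()
        for i, j, J in self.coupled_pairs:
            if not (0 <= i < L and 0 <= j < L) or i == j:
                raise ValueError(f"bad coupled pair ({i}, {j})")
            if (min(i, j), max(i, j)) in seen:
                raise ValueError("duplicate coupled pair")
            if not np.isfinite(J):
                raise ValueError("coupling strength must be finite")
            seen.add((min(i, j), max(i, j)))

    @property
    def length(self) -> int:
        return self.length_a + self.length_b


@dataclass
class PottsSample:
    paired: PairedMSA
    truth: PottsGroundTruth
    warnings: list[str] = field(default_factory=list)


_MIXING_J_WARN = 6.0


def sample_potts_msa(gt: PottsGroundTruth, seed: int | None = None,
                     n_burn_sweeps: int = 150) -> PottsSample:
    """Gibbs-sample sequences from the pairwise model and build a paired MSA.

    One independent chain per sequence is swept site-by-site (vectorized over
    chains) for ``n_burn_sweeps`` full sweeps.  Synthetic organism ids and
    genomic loci (gene distance ~ |N(18, 24)|, one gene pair per organism)
    are attached so locus-proximity pairing can be exercised downstream.
    """
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    L, q, n = gt.length, gt.q, gt.n_sequences
    h = rng.normal(0.0, gt.field_scale, size=(L, q))
    partners: dict[int, list[tuple[int, float]]] = {}
    warn: list[str] = []
    for i, j, J in gt.coupled_pairs:
        partners.setdefault(i, []).append((j, J))
        partners.setdefault(j, []).append((i, J))
        if abs(J) > _MIXING_J_WARN:
            msg = (f"coupling |J|={abs(J):.2f} on pair ({i},{j}) may prevent "
                   f"Gibbs mixing within {n_burn_sweeps} sweeps")
            warnings.warn(msg)
            warn.append(msg)

    state = rng.integers(0, q, size=(n, L))
    for _ in range(n_burn_sweeps):
        for i in range(L):
            logits = np.broadcast_to(h[i], (n, q)).copy()
            for j, J in partners.get(i, []):
                # ferromagnetic delta coupling: bonus J when s_i == s_j
                logits[np.arange(n), state[:, j]] += J
            gumbel = rng.gumbel(size=(n, q))
            state[:, i] = np.argmax(logits + gumbel, axis=1)

    alphabet = "ACDEFGHIKLMNPQRSTVWY"[:q]
    organisms = [f"org{k:05d}" for k in range(n)]
    dist = np.abs(np.rint(rng.normal(18.0, 24.0, size=n))).astype(int)
    paired = PairedMSA(
        ids=[f"{org}/fliM-fliG" for org in organisms],
        matrix=state.copy(),
        alphabet=alphabet,
        boundary=gt.length_a,
        organisms=organisms,
        gene_distance=dist,
    )
    return PottsSample(paired=paired, truth=gt, warnings=warn)
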