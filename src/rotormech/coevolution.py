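"""Inter-protein coevolution from paired alignments.

Two families are concatenated organism-by-organism (matching sequences by
genomic locus proximity), redundancy-filtered, and scored for residue
coupling by two routes: mean-field direct coupling analysis (DI, via
inversion of the excess-correlation matrix of reweighted single/pair state
frequencies) and mutual information with average-product correction
(APC-MI).  Significance comes from within-column shuffle nulls; the scored
network's top fraction is compared against structure contacts and the
dynamic (fragment mutual-information) network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import ResidueKey, Structure

logger = logging.getLogger(__name__)

DEFAULT_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"


@dataclass
class Msa:
    """A multiple sequence alignment with integer-coded residues."""

    ids: list[str]
    matrix: np.ndarray  # (n_seq, L) int codes into `alphabet`
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or len(self.ids) != self.matrix.shape[0]:
            raise ValueError("id list and sequence matrix are inconsistent")
        if self.matrix.size and (self.matrix.min() < 0
                                 or self.matrix.max() >= len(self.alphabet)):
            raise ValueError("sequence codes outside the alphabet")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def gap_code(self) -> int | None:
        return self.alphabet.index("-") if "-" in self.alphabet else None

    def sequences(self) -> list[str]:
        lut = np.array(list(self.alphabet))
        return ["".join(row) for row in lut[self.matrix]]

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in zip(self.ids, self.sequences()))

    @classmethod
    def from_fasta(cls, text: str, alphabet: str = DEFAULT_ALPHABET) -> "Msa":
        import io

        from Bio import SeqIO

        ids, rows = [], []
        code = {c: i for i, c in enumerate(alphabet)}
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            ids.append(rec.id)
            try:
                rows.append([code[c] for c in str(rec.seq).upper()])
            except KeyError as exc:
                raise ValueError(f"symbol {exc.args[0]!r} in sequence {rec.id} "
                                 "not in alphabet") from exc
        mat = np.array(rows, dtype=np.int64) if rows else np.empty((0, 0), int)
        if len({len(r) for r in rows}) > 1:
            raise ValueError("alignment rows have unequal length")
        return cls(ids=ids, matrix=mat, alphabet=alphabet)


@dataclass
class PairedMSA(Msa):
    """Concatenated A|B alignment with the boundary and pairing metadata."""

    boundary: int = 0
    organisms: list[str] = field(default_factory=list)
    gene_distance: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 < self.boundary < self.length:
            raise ValueError("A/B boundary must fall inside the alignment")
        self.gene_distance = np.asarray(self.gene_distance, dtype=int)
        if np.any(self.gene_distance < 0):
            raise ValueError("gene distances must be non-negative")

    def subset_rows(self, idx: np.ndarray) -> "PairedMSA":
        return PairedMSA(
            ids=[self.ids[i] for i in idx], matrix=self.matrix[idx],
            alphabet=self.alphabet, boundary=self.boundary,
            organisms=[self.organisms[i] for i in idx] if self.organisms else [],
            gene_distance=self.gene_distance[idx]
            if len(self.gene_distance) else self.gene_distance,
        )


@dataclass
class CouplingNetwork:
    """Symmetric residue-pair coupling scores over alignment columns."""

    scores: np.ndarray  # (L, L), symmetric, zero diagonal
    method: str  # "DI" | "APC_MI"
    boundary: int | None = None
    null_threshold: float | None = None

    def __post_init__(self) -> None:
        s = self.scores
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("score matrix must be symmetric")

    def pair_scores(self, inter_only: bool = False) -> list[tuple[int, int, float]]:
        L = self.scores.shape[0]
        out = []
        for i in range(L):
            for j in range(i + 1, L):
                if inter_only and self.boundary is not None and not (
                        i < self.boundary <= j):
                    continue
                out.append((i, j, float(self.scores[i, j])))
        out.sort(key=lambda e: -e[2])
        return out


# ---------------------------------------------------------------------------
# Redundancy filtering and pairing

def _pairwise_identity(row: np.ndarray, block: np.ndarray,
                       gap: int | None) -> np.ndarray:
    """Identity of one row to each row of a block over non-gap matched columns."""
    eq = block == row[None, :]
    if gap is None:
        return eq.mean(axis=1)
    valid = (block != gap) & (row[None, :] != gap)
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ident = np.where(n_valid > 0, (eq & valid).sum(axis=1) / n_valid, 0.0)
    return ident


def filter_redundancy(msa: Msa, max_identity: float = 0.8) -> Msa:
    """Greedy keep-first filter: drop rows with identity >= ``max_identity``
    to any already retained row.  The output is a fixed point of the filter."""
    kept: list[int] = []
    gap = msa.gap_code
    for i in range(msa.n_sequences):
        if kept:
            ident = _pairwise_identity(msa.matrix[i], msa.matrix[kept], gap)
            if np.any(ident >= max_identity):
                continue
        kept.append(i)
    idx = np.array(kept, dtype=int)
    if isinstance(msa, PairedMSA):
        return msa.subset_rows(idx)
    return Msa(ids=[msa.ids[i] for i in idx], matrix=msa.matrix[idx],
               alphabet=msa.alphabet)


def pair_sequences(msa_a: Msa, msa_b: Msa, metadata,
                   max_gene_distance: int = 100,
                   method: str = "greedy") -> PairedMSA:
    """Concatenate A and B sequences organism-by-organism.

    ``metadata`` is a DataFrame with columns ``seq_id``, ``organism``,
    ``locus`` covering every sequence of both alignments.  Within an
    organism, A/B sequences are paired by smallest genomic gene distance
    (|locus_A - locus_B|), each sequence used at most once; candidate pairs
    at or beyond ``max_gene_distance`` are discarded.  ``method='optimal'``
    solves the minimum-total-distance assignment instead of the greedy
    default (intended for organisms with few paralogs).
    """
    if msa_a.alphabet != msa_b.alphabet:
        raise ValueError("alignments must share one alphabet")
    meta = {str(r.seq_id): (str(r.organism), int(r.locus))
            for r in metadata.itertuples()}
    missing = [i for i in list(msa_a.ids) + list(msa_b.ids) if i not in meta]
    if missing:
        raise ValueError(f"metadata missing for sequences {missing[:5]}")

    by_org: dict[str, tuple[list[int], list[int]]] = {}
    for k, sid in enumerate(msa_a.ids):
        by_org.setdefault(meta[sid][0], ([], []))[0].append(k)
    for k, sid in enumerate(msa_b.ids):
        by_org.setdefault(meta[sid][0], ([], []))[1].append(k)

    ids, orgs, dists, rows = [], [], [], []
    for org in by_org:
        ia, ib = by_org[org]
        if not ia or not ib:
            logger.info("organism %s skipped: no A/B candidate pair", org)
            continue
        da = np.array([meta[msa_a.ids[k]][1] for k in ia])
        db = np.array([meta[msa_b.ids[k]][1] for k in ib])
        dist = np.abs(da[:, None] - db[None, :])
        chosen: list[tuple[int, int]] = []
        if method == "optimal":
            from scipy.optimize import linear_sum_assignment

            r, c = linear_sum_assignment(dist)
            chosen = [(int(a), int(b)) for a, b in zip(r, c)]
        elif method == "greedy":
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            used_a: set[int] = set()
            used_b: set[int] = set()
            for a, b in order:
                if a not in used_a and b not in used_b:
                    chosen.append((int(a), int(b)))
                    used_a.add(int(a))
                    used_b.add(int(b))
        else:
            raise ValueError(f"unknown pairing method {method!r}")
        kept_any = False
        for a, b in chosen:
            if dist[a, b] >= max_gene_distance:
                continue
            kept_any = True
            ka, kb = ia[a], ib[b]
            ids.append(f"{msa_a.ids[ka]}|{msa_b.ids[kb]}")
            orgs.append(org)
            dists.append(int(dist[a, b]))
            rows.append(np.concatenate((msa_a.matrix[ka], msa_b.matrix[kb])))
        if not kept_any:
            logger.info("organism %s skipped: all pairs beyond %d genes",
                        org, max_gene_distance)
    if not rows:
        raise ValueError("no organism yielded a valid A/B pair")
    return PairedMSA(ids=ids, matrix=np.array(rows), alphabet=msa_a.alphabet,
                     boundary=msa_a.length, organisms=orgs,
                     gene_distance=np.array(dists))


# ---------------------------------------------------------------------------
# Scoring

def sequence_weights(msa: Msa, identity: float = 0.8) -> np.ndarray:
    """Inverse cluster-size weights at the given identity cutoff."""
    X = msa.matrix
    n, L = X.shape
    onehot = np.zeros((n, L, len(msa.alphabet)))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    flat = onehot.reshape(n, -1)
    matches = flat @ flat.T  # pairwise identical-column counts
    neighbors = (matches / L) >= identity
    np.fill_diagonal(neighbors, True)  # a sequence is always its own neighbor
    return 1.0 / neighbors.sum(axis=1)


def _frequencies(msa: Msa, weights: np.ndarray, pseudocount: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    X = msa.matrix
    n, L = X.shape
    q = len(msa.alphabet)
    meff = weights.sum()
    fi = np.zeros((L, q))
    for i in range(L):
        fi[i] = np.bincount(X[:, i], weights=weights, minlength=q)
    fi /= meff
    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    wo = onehot * weights[:, None, None]
    fij = np.einsum("nia,njb->iajb", wo, onehot) / meff
    fi = (1.0 - pseudocount) * fi + pseudocount / q
    fij = (1.0 - pseudocount) * fij + pseudocount / (q * q)
    for i in range(L):
        fij[i, :, i, :] = np.diag(fi[i])
    return fi, fij


def _direct_information(W: np.ndarray, fi: np.ndarray, fj: np.ndarray,
                        tol: float = 1e-10, max_iter: int = 1000) -> float:
    """DI of one pair from the two-site model exp(e_ij) with matched
    single-site marginals (self-consistent field iteration)."""
    q = W.shape[0]
    mu1 = np.full(q, 1.0 / q)
    mu2 = np.full(q, 1.0 / q)
    for _ in range(max_iter):
        new1 = fi / (W @ mu2)
        new1 /= new1.sum()
        new2 = fj / (W.T @ new1)
        new2 /= new2.sum()
        if max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max()) < tol:
            mu1, mu2 = new1, new2
            break
        mu1, mu2 = new1, new2
    pdir = W * np.outer(mu1, mu2)
    pdir /= pdir.sum()
    indep = np.outer(fi, fj)
    nz = pdir > 1e-100
    return float(np.sum(pdir[nz] * np.log(pdir[nz] / indep[nz])))


def mfdca(p: PairedMSA, pseudocount: float = 0.5,
          seqid_reweight: float = 0.8) -> CouplingNetwork:
    """Mean-field direct coupling analysis of a paired alignment.

    Sequences are reweighted at the identity cutoff; single/pair frequencies
    with pseudocount enter the excess-correlation matrix over the first q-1
    states, whose negative inverse gives the mean-field couplings; direct
    information per pair is computed from the induced two-site model.  All
    pairs are scored — intra-A, intra-B and inter-boundary alike; the
    boundary is recorded so inter-protein edges can be selected downstream.
    """
    if p.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    w = sequence_weights(p, seqid_reweight)
    fi, fij = _frequencies(p, w, pseudocount)
    L = p.length
    q = len(p.alphabet)
    qr = q - 1
    C = np.empty((L * qr, L * qr))
    for i in range(L):
        for j in range(L):
            C[i * qr:(i + 1) * qr, j * qr:(j + 1) * qr] = (
                fij[i, :qr, j, :qr] - np.outer(fi[i, :qr], fi[j, :qr]))
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; increase the pseudocount"
        ) from exc
    scores = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            e = np.zeros((q, q))
            e[:qr, :qr] = -invC[i * qr:(i + 1) * qr, j * qr:(j + 1) * qr]
            W = np.exp(e)
            scores[i, j] = scores[j, i] = _direct_information(W, fi[i], fi[j])
    return CouplingNetwork(scores=scores, method="DI", boundary=p.boundary)


def mi_matrix(msa: Msa) -> np.ndarray:
    """Plug-in column mutual information in nats, all pairs."""
    X = msa.matrix
    n, L = X.shape
    q = len(msa.alphabet)
    mi = np.zeros((L, L))
    probs = []
    for i in range(L):
        pi = np.bincount(X[:, i], minlength=q) / n
        probs.append(pi)
    for i in range(L):
        for j in range(i + 1, L):
            joint = np.zeros((q, q))
            np.add.at(joint, (X[:, i], X[:, j]), 1.0)
            joint /= n
            nz = joint > 0
            indep = np.outer(probs[i], probs[j])
            val = float(np.sum(joint[nz] * np.log(joint[nz] / indep[nz])))
            mi[i, j] = mi[j, i] = val
    return mi


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: subtract MI_i. * MI_.j / MI_.. computed
    over off-diagonal entries.  Annihilates a rank-one background matrix."""
    L = mi.shape[0]
    off = ~np.eye(L, dtype=bool)
    row_mean = mi.sum(axis=1) / (L - 1)
    overall = mi[off].mean()
    apc = np.outer(row_mean, row_mean) / overall if overall > 0 else np.zeros_like(mi)
    out = mi - apc
    np.fill_diagonal(out, 0.0)
    return out


def apc_mi(p: Msa) -> CouplingNetwork:
    """Mutual information with average-product correction."""
    out = apc_correct(mi_matrix(p))
    boundary = p.boundary if isinstance(p, PairedMSA) else None
    return CouplingNetwork(scores=out, method="APC_MI", boundary=boundary)


# ---------------------------------------------------------------------------
# Edge selection and significance

@dataclass
class TopEdges:
    edges: list[tuple[int, int, float]]
    fraction: float
    tail_fraction_2sigma: float
    tail_fraction_3sigma: float


def top_fraction(net: CouplingNetwork, fraction: float = 0.015,
                 inter_only: bool = False) -> TopEdges:
    """Highest-scoring ceil(fraction * n_pairs) pairs, plus the empirical
    upper-tail fractions at mean + 2 sigma and + 3 sigma of the scores."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    ranked = net.pair_scores(inter_only=inter_only)
    vals = np.array([e[2] for e in ranked])
    n_top = int(np.ceil(fraction * len(ranked))) if fraction > 0 else 0
    if len(vals):
        m, sd = vals.mean(), vals.std()
        t2 = float(np.mean(vals > m + 2 * sd))
        t3 = float(np.mean(vals > m + 3 * sd))
    else:
        t2 = t3 = 0.0
    return TopEdges(edges=ranked[:n_top], fraction=fraction,
                    tail_fraction_2sigma=t2, tail_fraction_3sigma=t3)


def msa_shuffle_null(p: PairedMSA, n_shuffles: int = 20, seed: int = 0,
                     scorer=apc_mi, percentile: float = 95.0) -> float:
    """Shuffle each column independently across rows; return the given
    percentile of the null pair-score distribution."""
    rng = np.random.default_rng(seed)
    null_vals: list[np.ndarray] = []
    for _ in range(n_shuffles):
        mat = np.column_stack([rng.permutation(p.matrix[:, i])
                               for i in range(p.length)])
        shuffled = PairedMSA(ids=list(p.ids), matrix=mat, alphabet=p.alphabet,
                             boundary=p.boundary, organisms=list(p.organisms),
                             gene_distance=p.gene_distance)
        s = scorer(shuffled).scores
        null_vals.append(s[np.triu_indices_from(s, k=1)])
    return float(np.percentile(np.concatenate(null_vals), percentile))


# ---------------------------------------------------------------------------
# Overlap with structure and the dynamic network

@dataclass
class OverlapReport:
    rows: list[dict]
    n_interface_contact: int
    n_long_range: int
    n_long_range_adjacent: int


def overlap_dynamics(edges: list[tuple[int, int, float]], s: Structure,
                     column_to_residue: dict[int, ResidueKey],
                     dynamic_nodes: list[ResidueKey],
                     contact_cutoff: float = 8.0) -> OverlapReport:
    """Classify coevolved edges against structure contacts and dynamic nodes.

    Each edge maps to residue keys via ``column_to_residue``; edges whose Cα
    distance is below the cutoff are interface contacts, the rest are
    long-range and are additionally tested for adjacency (within one
    fragment, i.e. +/- 1 residue position) to dynamic-network nodes.
    """
    ca = s.ca_index()
    node_set = set(dynamic_nodes)

    def adjacent(key: ResidueKey) -> bool:
        return any((key[0], key[1] + d) in node_set for d in (-1, 0, 1))

    rows = []
    n_contact = n_long = n_adj = 0
    for i, j, score in edges:
        ki, kj = column_to_residue[i], column_to_residue[j]
        d = float(np.linalg.norm(s.coord[ca[ki]] - s.coord[ca[kj]]))
        if d < contact_cutoff:
            cls = "interface_contact"
            n_contact += 1
            adj = False
        else:
            cls = "long_range"
            n_long += 1
            adj = adjacent(ki) or adjacent(kj)
            n_adj += int(adj)
        rows.append({"col_i": i, "col_j": j, "res_i": ki, "res_j": kj,
                     "score": score, "ca_distance": d, "class": cls,
                     "adjacent_to_node": adj})
    return OverlapReport(rows=rows, n_interface_contact=n_contact,
                         n_long_range=n_long, n_long_range_adjacent=n_adj)
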