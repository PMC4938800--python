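"""Vector-pair hinge mechanics on conformer ensembles.

Named unit vectors (lines through two Cα anchors, or normals of three-Cα
planes) are resolved per conformer; the difference angle between a vector
pair, referenced to the same angle in the ensemble-average structure, traces
hinge bending and rotation.  The SD of a difference-angle distribution is the
hinge amplitude; its histogram shape (single vs symmetric-double Gaussian)
discriminates harmonic from two-state wells, and the well width converts to a
torsional stiffness via equipartition, kappa = k_B T / sigma_rad^2.

Angles are unsigned unless the pair names a sign vector: then the sign is
that of (v1 x v2) . n_sign, giving the +/- histograms needed for rotation
pairs.  Vector definitions are configuration data (anchor residue ids), not
code, so the same machinery serves crystal structures and synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._geometry import unit
from .structure import ConformerEnsemble, Structure

BOLTZMANN_PN_NM = 1.380649e-2  # pN nm / K


@dataclass(frozen=True)
class VectorDefinition:
    """A named structure vector: line through 2 Cα or normal of a 3-Cα plane."""

    name: str
    kind: str  # "line" | "plane_normal"
    chain: str
    res_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("line", "plane_normal"):
            raise ValueError(f"unknown vector kind {self.kind!r}")
        need = 2 if self.kind == "line" else 3
        if len(self.res_ids) != need or len(set(self.res_ids)) != need:
            raise ValueError(
                f"{self.kind} vector needs {need} distinct anchors, got {self.res_ids}"
            )


@dataclass(frozen=True)
class AnglePair:
    """A measured vector pair; ``sign`` optionally names the sign-axis vector."""

    name_a: str
    name_b: str
    sign: str | None = None

    @property
    def label(self) -> str:
        return f"{self.name_a}.{self.name_b}"


@dataclass
class AngleSeries:
    """Per-conformer difference angles (degrees) for one vector pair."""

    pair: AnglePair
    angles_deg: np.ndarray
    source: str = "ensemble"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("angle series contains non-finite values")


@dataclass
class GaussianFit:
    """Single and symmetric-double Gaussian fits to an angle histogram."""

    single: dict | None
    double: dict | None
    preferred: str
    bin_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class StiffnessEstimate:
    kappa_pn_nm: float
    temperature_k: float
    width_deg: float
    model: str


def single_gaussian(x, a, b, x0):
    return a * np.exp(-0.5 * ((x - x0) / b) ** 2)


def double_gaussian(x, a, b, x0):
    """Symmetric two-state form: equal-weight Gaussians at +/- x0."""
    return a * (np.exp(-0.5 * ((x - x0) / b) ** 2)
                + np.exp(-0.5 * ((x + x0) / b) ** 2))


def load_vector_config(text: str) -> tuple[dict[str, VectorDefinition],
                                           dict[str, AnglePair]]:
    """Parse a JSON vector configuration into definitions and pairs.

    Format: {"vectors": [{name, kind, chain, res_ids}, ...],
             "pairs":   [{name, a, b, sign?}, ...]};  keys starting with an
    underscore are ignored (comments).  Vector anchors are data, not code —
    the shipped FliM/FliG configuration ships with editable residue ids.
    """
    import json

    data = json.loads(text)
    defs = {
        v["name"]: VectorDefinition(name=v["name"], kind=v["kind"],
                                    chain=v["chain"],
                                    res_ids=tuple(v["res_ids"]))
        for v in data["vectors"]
    }
    pairs = {
        p.get("name", f'{p["a"]}.{p["b"]}'): AnglePair(
            name_a=p["a"], name_b=p["b"], sign=p.get("sign"))
        for p in data.get("pairs", [])
    }
    for pr in pairs.values():
        for nm in (pr.name_a, pr.name_b, pr.sign):
            if nm is not None and nm not in defs:
                raise ValueError(f"pair references undefined vector {nm!r}")
    return defs, pairs


# ---------------------------------------------------------------------------
# Vector resolution and angle series

def _ca_lookup(s: Structure) -> dict:
    return s.ca_index()


def resolve_vectors(coord: np.ndarray, structure: Structure,
                    defs: dict[str, VectorDefinition],
                    ca: dict | None = None) -> dict[str, np.ndarray]:
    """Resolve named definitions to unit vectors for one coordinate frame."""
    ca = ca if ca is not None else _ca_lookup(structure)
    out: dict[str, np.ndarray] = {}
    for name, d in defs.items():
        try:
            pts = np.array([coord[ca[(d.chain, r)]] for r in d.res_ids])
        except KeyError as exc:
            raise ValueError(f"vector {name!r}: anchor residue {exc.args[0]} "
                             "missing or has no Calpha") from exc
        if d.kind == "line":
            out[name] = unit(pts[1] - pts[0])
        else:
            n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            if np.linalg.norm(n) < 1e-8:
                raise ValueError(f"plane anchors of vector {name!r} are collinear")
            out[name] = unit(n)
    return out


def _signed_angle(v1: np.ndarray, v2: np.ndarray,
                  n_sign: np.ndarray | None) -> float:
    raw = float(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    if n_sign is None:
        return raw
    s = 1.0 if float(np.dot(np.cross(v1, v2), n_sign)) >= 0.0 else -1.0
    return s * raw


def angle_series(source: ConformerEnsemble, pair: AnglePair,
                 defs: dict[str, VectorDefinition],
                 source_label: str = "ensemble") -> AngleSeries:
    """Difference-angle series of a vector pair over an ensemble.

    Each conformer's pair angle is referenced to the same angle measured in
    the ensemble-average structure (which therefore sits at 0 degrees).
    """
    names = [pair.name_a, pair.name_b] + ([pair.sign] if pair.sign else [])
    missing = [n for n in names if n not in defs]
    if missing:
        raise ValueError(f"undefined vectors {missing}")
    sub = {n: defs[n] for n in names}
    ca = _ca_lookup(source.reference)

    def one(coord: np.ndarray) -> float:
        v = resolve_vectors(coord, source.reference, sub, ca)
        return _signed_angle(v[pair.name_a], v[pair.name_b],
                             v[pair.sign] if pair.sign else None)

    ref_angle = one(source.mean_structure_coords())
    angles = np.array([one(source.coords[m]) for m in range(source.n_conformers)])
    return AngleSeries(pair=pair, angles_deg=np.degrees(angles - ref_angle),
                       source=source_label)


def angle_sigma(s: AngleSeries) -> float:
    """Population SD of the difference-angle series, degrees."""
    return float(np.std(s.angles_deg))


def amplification(distal: AngleSeries, proximal: AngleSeries) -> float:
    """Amplitude ratio sigma_distal / sigma_proximal."""
    sp = angle_sigma(proximal)
    if sp == 0.0:
        raise ValueError("proximal series has zero sigma; amplification undefined")
    return angle_sigma(distal) / sp


# ---------------------------------------------------------------------------
# Histogram model fits

def _freedman_diaconis_bins(x: np.ndarray) -> int:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 10
    h = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    return int(np.clip(np.ceil((x.max() - x.min()) / h), 10, 200))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_angle_models(s: AngleSeries, n_bins: int | None = None) -> GaussianFit:
    """Fit single and symmetric-double Gaussians to the angle histogram.

    Least squares on bin counts at bin centers; both fits are reported with
    R^2 and the higher-R^2 form is marked preferred.  A non-converging fit
    is recorded as absent rather than raised.
    """
    x = s.angles_deg
    bins = n_bins if n_bins is not None else _freedman_diaconis_bins(x)
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sd = max(float(np.std(x)), 1e-6)

    results: dict[str, dict | None] = {}
    for label, fn, p0 in (
        ("single", single_gaussian, (float(counts.max()), sd, float(np.mean(x)))),
        ("double", double_gaussian, (float(counts.max()) / 2.0, sd / 2.0, sd)),
    ):
        try:
            popt, _ = curve_fit(
                fn, centers, counts.astype(float), p0=p0,
                bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            a, b, x0 = (float(v) for v in popt)
            if label == "double":
                x0 = abs(x0)  # +/- x0 is the same symmetric model
            results[label] = {"a": a, "b": b, "x0": x0,
                              "r2": _r_squared(counts.astype(float),
                                               fn(centers, a, b, x0))}
        except (RuntimeError, ValueError):
            results[label] = None

    def r2(label: str) -> float:
        return results[label]["r2"] if results[label] else -np.inf

    preferred = "double" if r2("double") > r2("single") else "single"
    return GaussianFit(single=results["single"], double=results["double"],
                       preferred=preferred, bin_centers=centers, counts=counts)


def torsional_stiffness(width_deg: float, temperature_k: float = 300.0,
                        model: str = "one_state") -> StiffnessEstimate:
    """Equipartition stiffness kappa = k_B T / sigma^2 (sigma in radians).

    ``width_deg`` is the angular well width: the single fit's b for a
    one-state well, or the per-state b of the symmetric-double fit for a
    two-state well.  Returns kappa in pN nm (per rad^2).
    """
    if width_deg <= 0:
        raise ValueError("width must be positive")
    w_rad = np.radians(width_deg)
    kappa = BOLTZMANN_PN_NM * temperature_k / w_rad ** 2
    return StiffnessEstimate(kappa_pn_nm=float(kappa), temperature_k=temperature_k,
                             width_deg=float(width_deg), model=model)


# ---------------------------------------------------------------------------
# Coupling relations between angle series

@dataclass
class RelationFit:
    kind: str  # winner: "linear" | "end_state" | "parabolic"
    params: dict
    r2: dict
    adjusted_r2: dict


def _clamp_model(x, m, L, y0):
    return np.clip(m * x, -abs(L), abs(L)) + y0


def coupling_relation(x, y) -> RelationFit:
    """Classify the x-y relation between two angle series.

    Candidate forms: linear (transmission), saturating end-state
    (plateau / linear / plateau, the signature of bistable coupling), and
    parabolic y = c x^2 + y0 (an elastic constraint well).  The winner is the
    form with the highest adjusted R^2; parameters and R^2 of every candidate
    are reported.
    """
    xv = x.angles_deg if isinstance(x, AngleSeries) else np.asarray(x, float)
    yv = y.angles_deg if isinstance(y, AngleSeries) else np.asarray(y, float)
    if xv.shape != yv.shape:
        raise ValueError("series length mismatch")
    n = len(xv)

    params: dict[str, dict] = {}
    r2: dict[str, float] = {}
    n_par = {"linear": 2, "end_state": 3, "parabolic": 2}

    # linear
    A = np.column_stack((xv, np.ones(n)))
    (slope, icpt), res, *_ = np.linalg.lstsq(A, yv, rcond=None)
    yhat = slope * xv + icpt
    resid = yv - yhat
    dof = max(n - 2, 1)
    sxx = float(np.sum((xv - xv.mean()) ** 2))
    slope_se = float(np.sqrt(np.sum(resid ** 2) / dof / sxx)) if sxx > 0 else np.inf
    params["linear"] = {"slope": float(slope), "intercept": float(icpt),
                        "slope_se": slope_se}
    r2["linear"] = _r_squared(yv, yhat)

    # parabolic elastic well
    B = np.column_stack((xv ** 2, np.ones(n)))
    (c, y0), *_ = np.linalg.lstsq(B, yv, rcond=None)
    params["parabolic"] = {"c": float(c), "y0": float(y0)}
    r2["parabolic"] = _r_squared(yv, c * xv ** 2 + y0)

    # saturating end-state (clamped linear); the plateau parameter is
    # unidentifiable when the data never saturate, which is harmless here
    try:
        import warnings as _w

        span = max(float(np.max(np.abs(yv))), 1e-6)
        with _w.catch_warnings():
            from scipy.optimize import OptimizeWarning

            _w.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_clamp_model, xv, yv,
                                p0=(float(slope) if slope != 0 else 1.0,
                                    0.8 * span, float(np.mean(yv))),
                                maxfev=20000)
        m, L, y0c = (float(v) for v in popt)
        params["end_state"] = {"slope": m, "plateau": abs(L), "y0": y0c}
        r2["end_state"] = _r_squared(yv, _clamp_model(xv, m, L, y0c))
    except (RuntimeError, ValueError):
        params["end_state"] = {}
        r2["end_state"] = -np.inf

    adj = {k: 1.0 - (1.0 - v) * (n - 1) / max(n - n_par[k] - 1, 1)
           if np.isfinite(v) else -np.inf for k, v in r2.items()}
    winner = max(adj, key=lambda k: adj[k])
    return RelationFit(kind=winner, params=params, r2=r2, adjusted_r2=adj)
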