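"""End-to-end orchestration: config, seeding, reports, ensemble comparison.

A single :class:`RunConfig` drives the stages in dependency order
(structure -> ensemble -> PCA + fragment encoding -> networks + hinge
mechanics [-> coevolution]), with one master seed fanned out into named
per-stage streams so any stage can be rerun in isolation and the whole run
is bit-reproducible.  The report is a plain JSON-serializable dict carrying
the verbatim config and its hash as provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coevolution as coev
from . import dynamics, fixtures, mechanics, network
from .alphabet import column_entropy, default_library, encode_ensemble
from .engine import EngineConfig, generate_ensemble
from .structure import delete_residues, read_structure, write_ensemble_pdb

_STAGE_STREAMS = ("ensemble", "shuffles", "bootstrap", "coevolution")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    if stage not in _STAGE_STREAMS:
        raise ValueError(f"unknown stage stream {stage!r}")
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str | None = None
    fixture: dict | None = None  # HingeGroundTruth parameters
    pdb_path: str | None = None
    chains: list[str] | None = None
    use_engine: bool = False  # regenerate fixture ensembles with the engine
    n_conformers: int = 1024
    engine: dict = field(default_factory=dict)
    deletion: dict | None = None  # {"chain", "first", "last"}
    n_pcs: int = 3
    network: dict = field(default_factory=lambda: {"n_bins": 10, "n_shuffles": 50})
    coevolution: dict | None = None  # PottsGroundTruth parameters

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.fixture is None and cfg.pdb_path is None:
            raise ValueError("config needs either a fixture or a pdb_path input")
        bad_engine = set(cfg.engine) - {f.name for f in
                                        dataclasses.fields(EngineConfig)}
        if bad_engine:
            raise ValueError(f"unknown engine keys: {sorted(bad_engine)}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def report_hash(report: dict) -> str:
    return hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()).hexdigest()


def _fixture_truth(d: dict) -> fixtures.HingeGroundTruth:
    hinges = tuple(fixtures.HingeSpec(**h) for h in d.get("hinges", []))
    return fixtures.HingeGroundTruth(
        segment_lengths=tuple(d.get("segment_lengths", (36, 36))),
        hinges=hinges or (fixtures.HingeSpec(bend_sigma=10.0),),
        seed=int(d.get("seed", 0)),
    )


def _analyze(ens, cfg: RunConfig, defs=None, pairs=None) -> dict:
    """PCA + encoding + network + mechanics on one superposed ensemble."""
    out: dict = {}
    pca = dynamics.fit_pca(ens)
    k = min(cfg.n_pcs, pca.n_modes)
    total = float(pca.eigvals.sum())
    out["pca"] = {
        "eigvals_A2": [float(v) for v in pca.eigvals[:10]],
        "cumulative_anisotropy": [float(v) for v in
                                  dynamics.cumulative_anisotropy(pca)[:10]]
        if total > 0 else [],
        "n_conformers": pca.n_conformers,
    }
    if total > 0:
        spread, spread_sd = dynamics.conformer_spread(
            pca, list(range(1, k + 1)), seed=stage_seed(cfg.seed, "bootstrap"))
        out["pca"]["spread_nm"] = spread
        out["pca"]["spread_sd_nm"] = spread_sd
    rmsf = dynamics.rmsf_profile(ens)
    out["rmsf_A"] = [float(v) for v in rmsf.values]

    lib = default_library()
    ft = encode_ensemble(ens, lib)
    nbins = int(cfg.network.get("n_bins", 10))
    profiles = {pc: network.nmi_pc_profile(ft, pca, pc, n_bins=nbins)
                for pc in range(1, k + 1) if pca.eigvals[pc - 1] > 0}
    net = network.MINetwork(
        matrix=network.nmi_matrix(ft), positions=ft.positions,
        pc_profiles=profiles, n_bins=nbins)
    if profiles:
        net.null_threshold = network.shuffle_null(
            ft, pca, 1, n_shuffles=int(cfg.network.get("n_shuffles", 50)),
            seed=stage_seed(cfg.seed, "shuffles"), n_bins=nbins)
    thresholded = net.thresholded()
    out["network"] = {
        "null_threshold": float(net.null_threshold),
        "entropy_bits": [float(v) for v in column_entropy(ft)],
        "n_edges_above_null": int(np.count_nonzero(
            np.triu(thresholded, k=1))),
    }
    if profiles:
        composite = net.composite_pc_profile()
        out["network"]["composite_nmi_pc"] = [float(v) for v in composite]
        nodes = network.call_nodes(composite, ft.positions)
        out["network"]["nodes"] = [[key[0], key[1]] for _, key in nodes]
        if np.any(thresholded):
            cent = network.eigenvector_centrality(net)
            out["network"]["centrality_vs_composite_pcorr"] = (
                network.profile_pcorr(cent, composite)
                if composite.std() > 0 and cent.std() > 0 else None)

    if defs and pairs:
        mech: dict = {}
        for name, pair in pairs.items():
            try:
                series = mechanics.angle_series(ens, pair, defs)
            except ValueError as exc:
                # anchors removed by an edit: record, do not fail the run
                mech[name] = {"skipped": str(exc)}
                continue
            entry = {"sigma_deg": mechanics.angle_sigma(series)}
            if len(series.angles_deg) >= 100 and entry["sigma_deg"] > 0:
                fit = mechanics.fit_angle_models(series)
                entry["preferred_model"] = fit.preferred
                if fit.single:
                    entry["single_r2"] = fit.single["r2"]
                    entry["single_b_deg"] = fit.single["b"]
                if fit.double:
                    entry["double_r2"] = fit.double["r2"]
                    entry["double_x0_deg"] = fit.double["x0"]
                    entry["double_b_deg"] = fit.double["b"]
            mech[name] = entry
        sig0 = mech.get("hinge0_bend", {}).get("sigma_deg", 0.0)
        sigd = mech.get("distal_bend", {}).get("sigma_deg", 0.0)
        if sig0 and sigd:
            mech["amplification_distal_vs_hinge0"] = sigd / sig0
        out["mechanics"] = mech
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages; returns (and optionally writes) the report."""
    report: dict = {"config": cfg.to_dict(), "config_sha256": cfg.sha256()}
    ens_seed = stage_seed(cfg.seed, "ensemble")

    defs = pairs = None
    if cfg.fixture is not None:
        gt = _fixture_truth(cfg.fixture)
        defs = fixtures.hinge_vector_definitions(gt)
        pairs = fixtures.hinge_angle_pairs(gt)
        if cfg.use_engine:
            struct = fixtures.build_reference_trace(gt.segment_lengths)
            ens, gen_report = generate_ensemble(
                struct, cfg.n_conformers, ens_seed,
                EngineConfig(**cfg.engine))
            report["generation"] = gen_report.to_dict()
        else:
            ens, _ = fixtures.make_hinge_ensemble(gt, cfg.n_conformers,
                                                  seed=ens_seed)
    else:
        struct = read_structure(Path(cfg.pdb_path).read_text(),
                                chains=set(cfg.chains) if cfg.chains else None)
        from .engine import reduce_structure

        struct = reduce_structure(struct)
        ens, gen_report = generate_ensemble(
            struct, cfg.n_conformers, ens_seed, EngineConfig(**cfg.engine))
        report["generation"] = gen_report.to_dict()

    report["molecule"] = {
        "n_residues": len(ens.reference.residue_keys()),
        "chains": ens.reference.chains(),
        "residues": [[c, int(r)] for c, r in ens.reference.residue_keys()],
    }
    report["native"] = _analyze(ens, cfg, defs, pairs)

    if cfg.deletion is not None:
        dl = cfg.deletion
        edited = delete_residues(ens.reference, dl["chain"],
                                 int(dl["first"]), int(dl["last"]))
        del_ens, del_report = generate_ensemble(
            edited, cfg.n_conformers, stage_seed(cfg.seed, "ensemble") + 1,
            EngineConfig(**cfg.engine))
        report["deletion"] = {
            "edit": {"chain": dl["chain"], "first": int(dl["first"]),
                     "last": int(dl["last"])},
            "generation": del_report.to_dict(),
            "analysis": _analyze(del_ens, cfg, defs, pairs),
        }
        if defs and pairs:
            nat = report["native"].get("mechanics", {})
            dele = report["deletion"]["analysis"].get("mechanics", {})
            report["deletion"]["delta_sigma_deg"] = {
                name: dele[name]["sigma_deg"] - nat[name]["sigma_deg"]
                for name in nat if name in dele
                and isinstance(nat[name], dict) and "sigma_deg" in nat[name]
                and isinstance(dele[name], dict) and "sigma_deg" in dele[name]
            }

    if cfg.coevolution is not None:
        report["coevolution"] = _run_coevolution(cfg)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        (out / "ensemble.pdb").write_text(write_ensemble_pdb(
            ens if ens.n_conformers <= 64 else
            dataclasses.replace(ens, coords=ens.coords[:64],
                                fit_rmsd=None)))
    return report


def _run_coevolution(cfg: RunConfig) -> dict:
    gt = fixtures.PottsGroundTruth(**cfg.coevolution)
    sample = fixtures.sample_potts_msa(
        gt, seed=stage_seed(cfg.seed, "coevolution"))
    paired = coev.filter_redundancy(sample.paired)
    di = coev.mfdca(paired)
    mi = coev.apc_mi(paired)
    top_di = coev.top_fraction(di, 0.015)
    inter = di.pair_scores(inter_only=True)
    truth_pairs = {(min(i, j), max(i, j)) for i, j, _ in gt.coupled_pairs}
    top_inter = (inter[0][0], inter[0][1]) if inter else None
    return {
        "n_sequences_effective": paired.n_sequences,
        "warnings": sample.warnings,
        "top_inter_pair_di": list(top_inter) if top_inter else None,
        "top_inter_pair_is_planted": bool(top_inter in truth_pairs)
        if top_inter else False,
        "top_inter_pair_apc_mi": list(mi.pair_scores(inter_only=True)[0][:2]),
        "n_top_fraction_edges": len(top_di.edges),
        "tail_fraction_2sigma": top_di.tail_fraction_2sigma,
        "tail_fraction_3sigma": top_di.tail_fraction_3sigma,
    }


def compare_ensembles(report_a: dict, report_b: dict) -> dict:
    """Delta report between two pipeline runs of the same molecule.

    Aligns on common residues; reports differences in hinge sigma, spectra
    and network node sets.  Runs on unrelated molecules are an error.
    """
    res_a = {tuple(r) for r in report_a["molecule"]["residues"]}
    res_b = {tuple(r) for r in report_b["molecule"]["residues"]}
    common = res_a & res_b
    if not common:
        raise ValueError("reports describe unrelated molecules: no common residues")
    out: dict = {"n_common_residues": len(common),
                 "n_only_a": len(res_a - res_b), "n_only_b": len(res_b - res_a)}
    ev_a = report_a["native"]["pca"]["eigvals_A2"]
    ev_b = report_b["native"]["pca"]["eigvals_A2"]
    out["delta_eigvals_A2"] = [b - a for a, b in zip(ev_a, ev_b)]
    mech_a = report_a["native"].get("mechanics", {})
    mech_b = report_b["native"].get("mechanics", {})
    out["delta_sigma_deg"] = {
        name: mech_b[name]["sigma_deg"] - mech_a[name]["sigma_deg"]
        for name in mech_a
        if name in mech_b and isinstance(mech_a[name], dict)
        and "sigma_deg" in mech_a[name]
    }
    nodes_a = {tuple(n) for n in report_a["native"]["network"].get("nodes", [])}
    nodes_b = {tuple(n) for n in report_b["native"]["network"].get("nodes", [])}
    out["nodes_gained"] = sorted(map(list, nodes_b - nodes_a))
    out["nodes_lost"] = sorted(map(list, nodes_a - nodes_b))
    return out
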