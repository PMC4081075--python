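"""Configuration-driven orchestration of the two end-to-end workflows.

``run_cooccupancy`` covers the ChIP-side analyses: overlap clustering,
occupancy signatures, centre-distance profiles, promoter fractions, motif
counting, binned-occupancy correlation and knockdown differential occupancy.
``run_subgroups`` covers the expression/clinical side: quadrant assignment,
per-cohort differential expression, consensus meta-profiles, occupancy and
stage enrichment, survival and mutation association.

Both emit TSV tables plus a reproducibility manifest (parameter hash, seed,
package version, SHA-256 of every output) and are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cistrome as cis
from . import clinical as clin
from . import enrichment as enr
from . import occupancy as occ
from . import subgroups as sub
from . import synthetic as syn

log = logging.getLogger("cofbal")

__all__ = ["PipelineConfig", "run_cooccupancy", "run_subgroups"]

DEFAULT_PARAMS: dict[str, Any] = {
    # printed analysis constants of the method
    "cluster_radius": 250,
    "bin_size": 100,
    "distance_window": 500,
    "motif_window": 100,
    "promoter_flank": 2000,
    "tss_flank": 2000,
    "de_alpha": 0.05,
    "min_support": 4,
    "fdr_alpha": 0.05,
    "kd_fc_threshold": 1.5,
    "stable_fc_threshold": 1.4,
    "max_signature_size": 1000,
    "bootstrap_iter": 10_000_000,
    "pseudocount": 1,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration: inputs, parameters, output dir."""

    outdir: Path
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for key in ("cluster_radius", "bin_size", "motif_window", "promoter_flank"):
            if self.params[key] <= 0:
                raise ValueError(f"parameter {key} must be positive")
        for key in ("de_alpha", "fdr_alpha"):
            if not 0 < self.params[key] < 1:
                raise ValueError(f"parameter {key} must lie in (0, 1)")
        if self.params["stable_fc_threshold"] <= 1 or self.params["kd_fc_threshold"] <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        for kind, path in self.inputs.items():
            if isinstance(path, (str, Path)) and not Path(path).exists():
                raise FileNotFoundError(f"input {kind!r}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            outdir=raw.get("outdir", "cofbal_out"),
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}),
            inputs=raw.get("inputs", {}),
            simulate=raw.get("simulate", {}),
        )

    def params_hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig, workflow: str) -> None:
        self.data: dict[str, Any] = {
            "workflow": workflow,
            "version": __version__,
            "seed": config.seed,
            "params_hash": config.params_hash(),
            "params": config.params,
            "stages": [],
            "outputs": {},
        }
        self.outdir = config.outdir

    def stage(self, name: str) -> None:
        log.info("stage: %s", name)
        self.data["stages"].append(name)

    def emit(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self.data["outputs"][name] = _sha256(path)
        return path

    def emit_text(self, name: str, text: str) -> Path:
        path = self.outdir / name
        path.write_text(text)
        self.data["outputs"][name] = _sha256(path)
        return path

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


class StageError(RuntimeError):
    """A named pipeline stage failed; partial outputs may exist on disk."""


def _run_stage(manifest: _Manifest, name: str, fn):
    manifest.stage(name)
    try:
        return fn()
    except Exception as exc:  # annotate with the failing stage
        raise StageError(f"stage {name!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Co-occupancy workflow

def _simulated_cistrome_inputs(config: PipelineConfig):
    simcfg = config.simulate.get("cistromes", {})
    factors = tuple(simcfg.get("factors", ("IRF4", "SPIB", "PU.1")))
    k = len(factors)
    sharing = np.asarray(simcfg.get("sharing", (np.full((k, k), 0.5) + 0.5 * np.eye(k))))
    spec = syn.CistromeSimSpec(
        factors=factors,
        n_elements_per_factor=int(simcfg.get("n_elements_per_factor", 500)),
        sharing=sharing,
        centre_jitter_sd=float(simcfg.get("centre_jitter_sd", 20.0)),
        seed=config.seed,
    )
    cistromes, truth = syn.gen_cistromes(spec)
    depletion = config.simulate.get("depletion", {})
    table = syn.gen_element_counts(
        truth, factors, depletion,
        library_size=float(config.simulate.get("library_size", 100.0 * len(truth))),
        seed=config.seed + 1,
    )
    genes = syn.gen_gene_models(
        int(config.simulate.get("n_genes", 500)), spec.chrom_lengths, config.seed + 2
    )
    return spec, cistromes, truth, table, genes


def run_cooccupancy(config: PipelineConfig) -> dict[str, Any]:
    """Run the ChIP-side workflow; returns the manifest dictionary."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, "cooccupancy")
    p = config.params

    if config.simulate:
        spec, cistromes, truth, counts, genes = _run_stage(
            manifest, "simulate", lambda: _simulated_cistrome_inputs(config)
        )
        manifest.emit("truth_elements.tsv", truth.reset_index())
    else:
        peak_inputs = config.inputs.get("peaks")
        if not peak_inputs:
            raise ValueError("config must provide inputs.peaks or a simulate block")
        cistromes = {
            name: cis.read_peaks(path, config.inputs.get("dialect", "bed6"), factor=name)
            for name, path in peak_inputs.items()
        }
        genes = None
        counts = None

    tracks = list(cistromes.values())

    clusters = _run_stage(
        manifest, "cluster",
        lambda: cis.cluster_peaks(tracks, radius=p["cluster_radius"]),
    )
    manifest.emit("clusters.tsv", pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "chrom": [c.chrom for c in clusters],
            "index_centre": [c.index_peak.centre for c in clusters],
            "n_members": [len(c.members) for c in clusters],
            "signature": [cis.signature_label(c.signature) for c in clusters],
        }
    ))

    sig_counts = _run_stage(
        manifest, "signatures", lambda: cis.occupancy_signature_counts(clusters)
    )
    manifest.emit("signature_counts.tsv", pd.DataFrame(
        sorted(sig_counts.items()), columns=["signature", "count"]
    ))

    def distances():
        ref = tracks[0]
        rows = []
        for q in tracks[1:]:
            prof = cis.centre_distance_profile(ref, q, window=p["distance_window"])
            rows.append((ref.label, q.label, len(prof.distances), prof.fraction_within_50))
        return pd.DataFrame(rows, columns=["reference", "query", "n_pairs", "fraction_within_50"])

    manifest.emit("distance_profiles.tsv", _run_stage(manifest, "distances", distances))

    if genes is not None:
        def promoters():
            rows = [
                (c.label, cis.promoter_fraction(c, genes, p["promoter_flank"]))
                for c in tracks
            ]
            return pd.DataFrame(rows, columns=["factor", "promoter_fraction"])

        manifest.emit("promoter_fractions.tsv", _run_stage(manifest, "promoters", promoters))

    def correlation():
        binned = [occ.bin_occupancy(c, bin_size=p["bin_size"]) for c in tracks]
        corr = occ.occupancy_correlation_matrix(binned)
        order, Z = occ.hierarchical_order(corr)
        return corr, order, Z

    corr, order, Z = _run_stage(manifest, "correlation", correlation)
    manifest.emit("correlation_matrix.tsv", corr.reset_index(names="track"))
    manifest.emit_text("correlation_tree.nwk", occ.merge_tree_newick(Z, list(corr.index)) + "\n")
    manifest.emit_text("correlation_order.txt", "\n".join(order) + "\n")

    if counts is not None:
        def diff():
            per_element, summary, contrasts = occ.differential_occupancy(
                counts, pseudocount=p["pseudocount"]
            )
            return per_element, summary, contrasts

        per_element, summary, contrasts = _run_stage(manifest, "differential_occupancy", diff)
        manifest.emit("element_log2fc.tsv", per_element)
        manifest.emit("class_log2fc_summary.tsv", summary)
        manifest.emit("class_contrasts.tsv", contrasts)

        focus = config.simulate.get("stable_focus_signature")
        if focus:
            res = _run_stage(
                manifest, "stable_subset",
                lambda: occ.stable_subset_enrichment(
                    counts, focus, fc_threshold=p["stable_fc_threshold"],
                    pseudocount=p["pseudocount"],
                ),
            )
            manifest.emit("stable_subset.tsv", pd.DataFrame([{
                "focus_signature": focus, "k": res.k, "n": res.n,
                "K": res.K, "N": res.N, "p": res.p_value,
            }]))

    manifest.write()
    return manifest.data


# ---------------------------------------------------------------------------
# Subgroup / clinical workflow

def run_subgroups(config: PipelineConfig) -> dict[str, Any]:
    """Run the expression/clinical workflow; returns the manifest dictionary."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, "subgroups")
    p = config.params

    if config.simulate:
        simcfg = dict(config.simulate.get("cohorts", {}))
        simcfg.setdefault("seed", config.seed)
        spec = syn.CohortSimSpec(**simcfg)
        datasets, truth = _run_stage(
            manifest, "simulate", lambda: syn.gen_expression_cohorts(spec)
        )
    else:
        entries = config.inputs.get("expression")
        if not entries:
            raise ValueError("config must provide inputs.expression or a simulate block")
        datasets = [
            sub.read_expression_dataset(e["matrix"], e["annotations"], e.get("id"))
            for e in entries
        ]
        truth = None

    if p["min_support"] > len(datasets):
        raise ValueError(
            f"min_support {p['min_support']} exceeds dataset count {len(datasets)}"
        )

    def quadrant_stage():
        out = {}
        for ds in datasets:
            out[ds.dataset_id] = sub.assign_quadrants(ds)
        return out

    quadrants = _run_stage(manifest, "quadrants", quadrant_stage)
    manifest.emit("quadrants.tsv", pd.concat(
        [q.rename("quadrant").rename_axis("sample").reset_index().assign(dataset=d)
         for d, q in quadrants.items()]
    )[["dataset", "sample", "quadrant"]])

    def de_stage():
        tables = []
        for ds in datasets:
            q = quadrants[ds.dataset_id]
            gx = list(q.index[q == "SPIBhigh_BATFlow"])
            gy = list(q.index[q == "SPIBlow_BATFhigh"])
            tables.append(sub.differential_expression(ds, gx, gy, alpha=p["de_alpha"]))
        return tables

    de_tables = _run_stage(manifest, "differential_expression", de_stage)

    up, down, conflicts = _run_stage(
        manifest, "meta_profiles",
        lambda: sub.consensus_meta_profile(de_tables, min_support=p["min_support"]),
    )
    for profile in (up, down):
        manifest.emit(
            f"meta_profile_{profile.direction}.tsv",
            profile.entries.rename_axis("gene").reset_index(),
        )
    enr.write_gmt(
        enr.SignatureCollection({up.direction: frozenset(up.genes),
                                 down.direction: frozenset(down.genes)}),
        config.outdir / "meta_profiles.gmt",
    )
    manifest.data["outputs"]["meta_profiles.gmt"] = _sha256(config.outdir / "meta_profiles.gmt")

    universe = list(de_tables[0].index)
    marker = _run_stage(
        manifest, "marker_correlations", lambda: sub.marker_correlations(datasets)
    )
    manifest.emit("marker_correlations.tsv", marker[1])

    occupancy_sets = config.inputs.get("occupancy_gmt")
    if occupancy_sets:
        collection = enr.read_gmt(occupancy_sets)
        def occ_enrich():
            rows = []
            for name, genes in collection.sets.items():
                for profile in (up, down):
                    res = enr.hypergeometric_test(
                        profile.genes, genes & set(universe), universe
                    )
                    rows.append((name, profile.direction, res.k, res.n, res.K,
                                 res.N, res.p_value))
            return pd.DataFrame(rows, columns=[
                "occupancy_set", "direction", "k", "n", "K", "N", "p"])
        manifest.emit("occupancy_enrichment.tsv",
                      _run_stage(manifest, "occupancy_enrichment", occ_enrich))

    stage_map_path = config.inputs.get("stage_categories")
    if stage_map_path:
        stage_map = pd.read_csv(stage_map_path, sep="\t", index_col=0)["stage"].to_dict()
        def stage_z():
            rows = []
            for profile in (up, down):
                res = enr.bootstrap_category_zscore(
                    profile.genes, stage_map, universe,
                    n_iter=int(p["bootstrap_iter"]), seed=config.seed + 7,
                )
                for cat, r in sorted(res.items()):
                    rows.append((profile.direction, cat, r.k, r.K, r.z_score, r.p_value))
            return pd.DataFrame(rows, columns=["direction", "category", "k", "K", "z", "p"])
        manifest.emit("stage_zscores.tsv", _run_stage(manifest, "stage_bootstrap", stage_z))

    signatures_path = config.inputs.get("signature_gmt")
    if signatures_path:
        collection = enr.read_gmt(signatures_path)
        def sig_enrich():
            frames = []
            for profile in (up, down):
                df = enr.signature_collection_enrichment(
                    profile.genes, collection, universe,
                    max_set_size=p["max_signature_size"],
                )
                df.insert(0, "direction", profile.direction)
                frames.append(df)
            return pd.concat(frames, ignore_index=True)
        manifest.emit("signature_enrichment.tsv",
                      _run_stage(manifest, "signature_enrichment", sig_enrich))

    def clinical_stage():
        ds = datasets[0]
        q = quadrants[ds.dataset_id]
        groups: dict[str, list[clin.SurvivalRecord]] = {}
        for label in ("SPIBhigh_BATFlow", "SPIBlow_BATFhigh"):
            samples = q.index[q == label]
            groups[label] = [
                clin.SurvivalRecord(
                    s, float(ds.annotations.loc[s, "os_time"]),
                    int(ds.annotations.loc[s, "os_event"]), label,
                )
                for s in samples
            ]
        stat, pval, df = clin.logrank_test(groups)
        curves = {label: clin.km_estimate(records) for label, records in groups.items()}
        mut = clin.mutation_association(q, ds.annotations["myd88"])
        return stat, pval, df, curves, mut

    stat, pval, df, curves, mut = _run_stage(manifest, "clinical", clinical_stage)
    manifest.emit("logrank.tsv", pd.DataFrame(
        [{"dataset": datasets[0].dataset_id, "chi2": stat, "p": pval, "df": df}]
    ))
    curve_rows = [
        {"group": label, "time": t, "at_risk": r, "events": e, "survival": s}
        for label, curve in sorted(curves.items())
        for t, r, e, s in zip(curve.event_times, curve.at_risk, curve.events, curve.survival)
    ]
    manifest.emit("km_curves.tsv", pd.DataFrame(curve_rows))
    manifest.emit("mutation_association.tsv", pd.DataFrame([
        {"quadrant": quad, "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p_value}
        for quad, r in sorted(mut.items())
    ]))

    if truth is not None:
        planted_up = set(truth["up_in_SPIBhigh_BATFlow"])
        planted_down = set(truth["up_in_SPIBlow_BATFhigh"])
        sens = (
            len(up.genes & planted_up) + len(down.genes & planted_down)
        ) / (len(planted_up) + len(planted_down))
        total = len(up.genes) + len(down.genes)
        contam = (
            (len(up.genes - planted_up) + len(down.genes - planted_down)) / total
            if total else 0.0
        )
        manifest.emit("recovery.tsv", pd.DataFrame([{
            "sensitivity": sens, "contamination": contam,
            "n_up": len(up.genes), "n_down": len(down.genes),
        }]))

    manifest.write()
    return manifest.data
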