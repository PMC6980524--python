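"""End-to-end orchestration: curate -> score -> baseline -> network -> structure -> stabilize.

One RunConfig drives the whole analysis; every source of randomness flows
from its master seed and all artifacts land in the output directory with a
machine-readable manifest, so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import covariance, network, null_models, stabilizing, structure
from .alignment import (
    Alignment,
    AlignmentError,
    ReferenceMap,
    attach_taxa,
    build_reference_map,
    curate_by_length,
    extract_perturbation_subset,
    filter_gap_columns,
    read_fasta_alignment,
    read_taxon_table,
    write_column_map,
    write_fasta_alignment,
)
from .matrices import BackgroundFrequencies

log = logging.getLogger("coevnet")


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    alignment: str
    ref_seq_id: str
    ref_start: int = 1207
    taxon_table: str | None = None
    structures: list[dict] = field(default_factory=list)  # {path, chain, start, end}
    algorithms: list[str] = field(default_factory=lambda: ["elsc", "omes", "mcbasc"])
    top_n: int = 200
    n_replicates: int = 10
    seed: int = 0
    min_len: int = 245
    max_len: int = 265
    max_gap_frac: float = 0.35
    perturbations: list[dict] = field(default_factory=list)  # {resnum, residue}
    min_subset_size: int = 50
    stabilizing_params: dict = field(default_factory=dict)
    outdir: str = "results/run"

    def validate(self) -> None:
        for alg in self.algorithms:
            if alg not in covariance.ALGORITHMS:
                raise ValueError(f"unknown algorithm {alg!r}")
        if self.top_n < 1 or self.n_replicates < 1:
            raise ValueError("top_n and n_replicates must be positive")
        for p in self.perturbations:
            if "resnum" not in p or "residue" not in p:
                raise ValueError(f"perturbation needs resnum and residue: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _score_and_network(
    aln: Alignment,
    rmap: ReferenceMap,
    cfg: RunConfig,
    tag: str,
    outdir: Path,
    manifest: dict,
) -> dict[str, network.CouplingNetwork]:
    """Score one alignment with every algorithm; baseline, z-score, top-N."""
    nets: dict[str, network.CouplingNetwork] = {}
    for alg in cfg.algorithms:
        sm = covariance.compute(alg, aln, rmap=rmap)
        nb = null_models.scrambled_baseline(
            aln, alg, n_replicates=cfg.n_replicates, seed=cfg.seed
        )
        zeroed = null_models.apply_baseline(sm, nb)
        zs = null_models.pairwise_zscores(sm)
        base = outdir / f"{tag}_{alg}"
        sm.write_tsv(base.with_suffix(".scores.tsv"))
        zs.write_tsv(base.with_suffix(".zscores.tsv"))
        nb.to_json(base.with_suffix(".baseline.json"))
        net = network.top_pairs(zeroed, cfg.top_n)
        net.write_graphml(base.with_suffix(".graphml"))
        net.write_edge_tsv(base.with_suffix(".edges.tsv"))
        nets[alg] = net
        manifest.setdefault("artifacts", []).extend([
            base.with_suffix(".scores.tsv").name,
            base.with_suffix(".zscores.tsv").name,
            base.with_suffix(".baseline.json").name,
            base.with_suffix(".graphml").name,
            base.with_suffix(".edges.tsv").name,
        ])
    # composite intersection + centrality summaries
    summary: dict = {}
    if len(nets) >= 2:
        comp = network.composite_intersection(list(nets.values()))
        comp.write_edge_tsv(outdir / f"{tag}_composite.edges.tsv")
        summary["composite_edges"] = sorted(map(list, comp.edges))
    for alg, net in nets.items():
        if net.n_edges:
            summary[f"{alg}_central_nodes"] = network.central_nodes(net)
            summary[f"{alg}_eigenvector_centrality"] = {
                str(k): v for k, v in sorted(
                    network.eigenvector_centrality(net).items(),
                    key=lambda kv: -kv[1])[:10]
            }
    (outdir / f"{tag}_networks.json").write_text(json.dumps(summary, indent=2))
    manifest.setdefault("artifacts", []).append(f"{tag}_networks.json")
    return nets


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "artifacts": []}
    cfg.to_yaml(outdir / "config.yaml")

    try:
        # --- curation -----------------------------------------------------
        aln = read_fasta_alignment(cfg.alignment)
        if cfg.taxon_table:
            aln = attach_taxa(aln, read_taxon_table(cfg.taxon_table))
        aln = curate_by_length(aln, cfg.min_len, cfg.max_len)
        aln, rmap = build_reference_map(aln, cfg.ref_seq_id, cfg.ref_start)
        aln, mask, rmap = filter_gap_columns(aln, cfg.max_gap_frac, rmap)
        write_fasta_alignment(aln, outdir / "curated.fasta")
        write_column_map(mask, rmap, outdir / "column_map.tsv")
        manifest["stages"].append("curate")
        manifest["n_seqs"], manifest["n_cols"] = aln.n_seqs, aln.n_cols

        # --- full alignment scoring & networks ----------------------------
        full_nets = _score_and_network(aln, rmap, cfg, "full", outdir, manifest)
        manifest["stages"].append("score_full")

        # --- perturbations -------------------------------------------------
        bg = BackgroundFrequencies.yeast()
        manifest["perturbations"] = {}
        for p in cfg.perturbations:
            name = f"{p['residue']}{p['resnum']}"
            try:
                subset = extract_perturbation_subset(
                    aln, rmap, int(p["resnum"]), p["residue"]
                )
            except AlignmentError as exc:
                log.warning("perturbation %s skipped: %s", name, exc)
                manifest["perturbations"][name] = {"status": "skipped", "reason": str(exc)}
                continue
            if subset.n_seqs < cfg.min_subset_size:
                reason = (f"only {subset.n_seqs} sequences "
                          f"(< floor {cfg.min_subset_size})")
                log.warning("perturbation %s skipped: %s", name, reason)
                manifest["perturbations"][name] = {"status": "skipped", "reason": reason}
                continue
            sub_nets = _score_and_network(subset, rmap, cfg, name, outdir, manifest)
            overlap = {
                alg: network.edge_overlap_count(full_nets[alg], sub_nets[alg])
                for alg in sub_nets
            }
            cands = stabilizing.predict_stabilizing(
                subset, aln, rmap, bg, **cfg.stabilizing_params
            )
            stabilizing.write_candidates(cands, outdir / f"{name}_stabilizing.tsv")
            manifest["perturbations"][name] = {
                "status": "ok",
                "n_seqs": subset.n_seqs,
                "edge_overlap_with_full": overlap,
                "n_stabilizing_candidates": len(cands),
            }
        manifest["stages"].append("perturbations")

        # --- structural validation -----------------------------------------
        if cfg.structures:
            for sdef in cfg.structures:
                rc = structure.read_cbeta_coordinates(
                    sdef["path"], sdef.get("chain", "A"),
                    (sdef["start"], sdef["end"]) if "start" in sdef else None,
                )
                dm = structure.pairwise_distances(rc)
                ungapped = dict(zip(map(int, rmap.positions), aln.ungapped_fraction()))
                for alg in cfg.algorithms:
                    sm = covariance.compute(alg, aln, rmap=rmap)
                    comp = structure.score_distance_table(
                        sm, dm, ungapped_frac=ungapped
                    )
                    comp.write(outdir / f"structure_{rc.source}_{alg}")
                    manifest.setdefault("structure", {})[f"{rc.source}_{alg}"] = {
                        "binomial_p_value": comp.p_value,
                        "n_below_median": comp.n_below_median,
                        "median_retained_A": comp.median_retained,
                    }
            manifest["stages"].append("structure")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
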