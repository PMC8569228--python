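"""End-to-end orchestration with manifests and reproducible seeding.

Runs the stage chain synth → ingest → screen → motifs → align → tree →
classify → summarize over one candidate/query set (the two evasin
families are analysed as two independent runs, one tree each).  Every
artifact is a plain-text file; the manifest records artifact checksums,
the configuration hash, the seed and the package version, so two runs
with the same configuration and seed produce byte-identical manifests.

All randomness flows from the single top-level seed through fixed
per-stage derivations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import progressive_align
from .classify import LineageMap, assign_classes, root_partition
from .ingest import (HeuristicCleavageProvider, TableCleavageProvider,
                     derive_mature, filter_records, locate_protein_start,
                     read_fasta, write_drop_report)
from .motifs import profile, write_profiles
from .screen import ScreenConfig, deduplicate, screen
from .summarize import heatmap_info, species_class_counts
from .synth import SyntheticConfig, generate_dataset
from .tree import (bootstrap_support, identity_distance, midpoint_root,
                   neighbor_joining, write_newick)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_STAGES = ("synth", "ingest", "screen", "motifs", "align", "tree",
           "classify", "summarize")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Parameters for one pipeline run (see module docstring)."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # synth (ignored when input paths are given)
    synth: SyntheticConfig | None = None
    # ingest
    fasta: str | None = None
    cleavage_tsv: str | None = None
    provider: str = "table"  # "table" | "heuristic"
    # screen
    queries_fasta: str | None = None
    evalue_threshold: float = 1e-4
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # tree
    bootstrap: int = 100
    # classify
    scheme: str = "A"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # a location, not a scientific parameter
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()

    def stage_seed(self, stage: str) -> int:
        """Derived per-stage seed, stable across runs."""
        ss = np.random.SeedSequence([self.seed, _STAGES.index(stage)])
        return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the manifest dict.

    A disabled stage whose outputs are required later must have its input
    files supplied in the config, otherwise the gap is reported by name.
    On stage failure a partial manifest (stages completed so far) is
    written before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in _STAGES if s in config.stages)
    artifacts: dict[str, str] = {}
    manifest_path = outdir / "manifest.json"

    def record(name: str, path: Path) -> None:
        artifacts[name] = f"sha256:{_sha256(path)}"

    def write_manifest(status: str) -> dict:
        manifest = {
            "tool": "evasinclass",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "status": status,
            "stages": list(stages),
            "artifacts": dict(sorted(artifacts.items())),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest

    fasta = config.fasta
    cleavage_tsv = config.cleavage_tsv
    queries_fasta = config.queries_fasta

    try:
        if "synth" in stages:
            synth_cfg = config.synth or SyntheticConfig()
            synth_cfg = dataclasses.replace(synth_cfg, seed=config.stage_seed("synth"))
            paths = generate_dataset(synth_cfg, outdir / "synthetic")
            fasta = str(paths["fasta"])
            cleavage_tsv = str(paths["cleavage"])
            queries_fasta = str(paths["queries"])
            for key, p in paths.items():
                record(f"synth.{key}", Path(p))
        if fasta is None:
            raise PipelineError("ingest", "no input FASTA: enable the synth stage "
                                          "or set config.fasta")

        # ingest
        records = read_fasta(fasta)
        for rec in records:
            locate_protein_start(rec)
        if config.provider == "table":
            if cleavage_tsv is None:
                raise PipelineError("ingest", "table provider needs cleavage_tsv")
            provider = TableCleavageProvider(cleavage_tsv)
        elif config.provider == "heuristic":
            provider = HeuristicCleavageProvider()
        else:
            raise PipelineError("ingest", f"unknown provider {config.provider!r}")
        for rec in records:
            derive_mature(rec, provider)
        kept, dropped = filter_records(records)
        if "ingest" in stages:
            write_drop_report(dropped, outdir / "drop_report.tsv")
            with open(outdir / "mature.fasta", "w") as fh:
                for rec in kept:
                    fh.write(f">{rec.id}\n{rec.mature_sequence}\n")
            meta = pd.DataFrame(
                [(r.id, r.genus, r.species, r.meta.get("lineage", "")) for r in kept],
                columns=["id", "genus", "species", "lineage"],
            )
            meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
            record("ingest.drop_report", outdir / "drop_report.tsv")
            record("ingest.mature", outdir / "mature.fasta")
            record("ingest.meta", outdir / "meta.tsv")
        candidates = {r.id: r.mature_sequence for r in kept}
        genus_of = {r.id: r.genus for r in kept}

        # screen
        if "screen" in stages:
            if queries_fasta is None:
                raise PipelineError("screen", "no query FASTA: enable synth or set "
                                              "config.queries_fasta")
            queries = {r.id: r.raw_sequence for r in read_fasta(queries_fasta)}
            scfg = ScreenConfig(matrix_name=config.matrix, gap_open=config.gap_open,
                                gap_extend=config.gap_extend,
                                evalue_threshold=config.evalue_threshold)
            kept_seqs, rows = screen(candidates, queries, scfg)
            pd.DataFrame(rows).to_csv(outdir / "best_hits.tsv", sep="\t", index=False)
            record("screen.best_hits", outdir / "best_hits.tsv")
            distinct, collapse = deduplicate(kept_seqs)
            with open(outdir / "kept.fasta", "w") as fh:
                for cid, seq in distinct.items():
                    fh.write(f">{cid}\n{seq}\n")
            record("screen.kept", outdir / "kept.fasta")
            pd.DataFrame(
                [(rep, member) for rep, members in collapse.items()
                 for member in members],
                columns=["representative", "member"],
            ).to_csv(outdir / "dedup_map.tsv", sep="\t", index=False)
            record("screen.dedup_map", outdir / "dedup_map.tsv")
            candidates = distinct

        if len(candidates) < 4:
            raise PipelineError("align", f"only {len(candidates)} candidates survive; "
                                         "need >=4 for a supported tree")

        # motifs
        profiles = profile(candidates)
        if "motifs" in stages:
            write_profiles(profiles, outdir / "profiles.tsv")
            record("motifs.profiles", outdir / "profiles.tsv")

        # align
        msa = progressive_align(candidates, matrix=config.matrix,
                                gap_open=config.gap_open, gap_extend=config.gap_extend)
        if "align" in stages:
            msa.to_fasta(outdir / "aligned.fasta")
            record("align.msa", outdir / "aligned.fasta")

        # tree
        D = identity_distance(msa)
        nj_tree = neighbor_joining(D)
        support: dict = {}
        if config.bootstrap > 0:
            nj_tree, support = bootstrap_support(
                msa, n_reps=config.bootstrap, seed=config.stage_seed("tree"),
                tree=nj_tree)
        rooted = midpoint_root(nj_tree, support)
        if "tree" in stages:
            D.to_tsv(outdir / "distances.tsv")
            write_newick(rooted, outdir / "tree.nwk")
            record("tree.distances", outdir / "distances.tsv")
            record("tree.newick", outdir / "tree.nwk")

        # classify
        partition = root_partition(rooted)
        clades = assign_classes(partition, genus_of, LineageMap(), scheme=config.scheme)
        assignments = pd.DataFrame(
            [(rid, genus_of[rid],
              next((r.species for r in kept if r.id == rid), ""),
              clades.assignments[rid]) for rid in sorted(clades.assignments)],
            columns=["id", "genus", "species", "class"],
        )
        if "classify" in stages:
            assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
            summary = pd.DataFrame(
                [(label, info["n"], f"{info['purity']:.4f}",
                  ";".join(f"{k}={v}" for k, v in sorted(info["composition"].items())))
                 for label, info in sorted(clades.class_info.items())],
                columns=["class", "n", "purity", "composition"],
            )
            summary.to_csv(outdir / "clade_summary.tsv", sep="\t", index=False)
            record("classify.assignments", outdir / "assignments.tsv")
            record("classify.summary", outdir / "clade_summary.tsv")

        # summarize
        if "summarize" in stages:
            counts = species_class_counts(assignments)
            counts.to_csv(outdir / "species_class_counts.tsv", sep="\t", index=False)
            info = heatmap_info(assignments, profiles)
            info.to_csv(outdir / "heatmap_info.tsv", sep="\t", index=False)
            record("summarize.counts", outdir / "species_class_counts.tsv")
            record("summarize.heatmap", outdir / "heatmap_info.tsv")
    except PipelineError:
        write_manifest("failed")
        raise
    except Exception as exc:  # annotate with the failing stage context
        write_manifest("failed")
        raise PipelineError("pipeline", str(exc)) from exc

    return write_manifest("ok")
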