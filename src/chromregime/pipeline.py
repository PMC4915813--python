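"""End-to-end orchestration: matrix -> cluster -> overlap -> promoter
counts -> enrichment -> group comparison, from a single YAML config.

Every run writes its outputs plus a ``manifest.json`` listing each file
with a SHA-256 checksum, the config hash and the seed; a re-run with the
same config and inputs is byte-identical. ``run_demo`` generates a full
synthetic dataset first and appends a ground-truth recovery report
(mixture-parameter errors, posterior-label accuracy, clustering ARI and
the direction of the simulated group effects).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import (
    enrichment_model,
    group_stats,
    interval_analysis,
    io_formats,
    regime_clustering,
    signal_matrix,
    synthetic_data,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run (see ``from_yaml``)."""

    tracks: dict[str, dict[str, Any]]  # name -> {tags: path, shift: int}
    peaks: str
    annotation: str
    de_table: str
    counts: str | None = None
    peaks_other: dict[str, str] = field(default_factory=dict)
    flank: int = 5100
    bin_size: int = 51
    tss_flank: int = 1500
    k: int = 2
    restarts: int = 10
    cluster_exclude: list[str] = field(default_factory=list)
    chip_track: str = "active_mark"
    control_track: str = "control_input"
    promoter_mark: str = "active_mark"
    pseudo_mass: float = 1.0
    tol: float = 1e-8
    em_restarts: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(self).items()
        }

    def referenced_paths(self) -> list[str]:
        paths = [self.peaks, self.annotation, self.de_table]
        if self.counts:
            paths.append(self.counts)
        paths.extend(t["tags"] for t in self.tracks.values())
        paths.extend(self.peaks_other.values())
        return paths


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, base: str | Path | None = None
) -> Path:
    """Execute all stages; returns the run directory containing the manifest.

    Relative input paths in the config are resolved against ``base``
    (default: the current directory), so a config can travel with its run
    directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base) if base is not None else Path.cwd()

    def loc(p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    missing = [p for p in config.referenced_paths() if not loc(p).exists()]
    if missing:
        raise PipelineError(f"missing input files: {missing}")
    outputs: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        io_formats.write_table(frame, path)
        outputs[name] = path

    try:
        stage = "matrix"
        _, summits = io_formats.read_intervals(loc(config.peaks), "narrowPeak")
        matrices = []
        for track, spec in config.tracks.items():
            geometry = signal_matrix.MatrixGeometry(
                flank=config.flank,
                bin_size=config.bin_size,
                shift=int(spec.get("shift", 100)),
            )
            tags = io_formats.read_tags(loc(spec["tags"]))
            m = signal_matrix.count_matrix(tags, summits, geometry, track=track)
            m = signal_matrix.clip_normalize(m)
            matrices.append(m)
            emit(f"matrix_{track}.tsv", m.to_frame())

        stage = "cluster"
        combined, column_map = signal_matrix.concat_tracks(
            matrices, exclude=config.cluster_exclude
        )
        result = regime_clustering.kmeans_cluster(
            combined, k=config.k, seed=config.seed, restarts=config.restarts
        )
        scores = np.array([s.score for s in summits])
        order = regime_clustering.order_peaks(result, scores)
        rank = np.empty(len(order), dtype=int)
        rank[order] = np.arange(len(order))
        emit(
            "cluster_labels.tsv",
            pd.DataFrame(
                {
                    "peak": [f"{s.chrom}:{s.pos}" for s in summits],
                    "cluster": result.labels,
                    "score": scores,
                    "display_rank": rank,
                }
            ),
        )
        emit("cluster_centers.tsv", pd.DataFrame(result.centers))
        profiles = regime_clustering.cluster_profiles(matrices, result.labels)
        emit(
            "cluster_profiles.tsv",
            pd.DataFrame(
                [
                    {"track": track, "cluster": c,
                     **{f"bin_{j}": v for j, v in enumerate(prof[c])}}
                    for track, prof in profiles.items()
                    for c in range(prof.shape[0])
                ]
            ),
        )

        stage = "overlap"
        main_peaks, _ = io_formats.read_intervals(loc(config.peaks), "narrowPeak")
        overlap_frames = []
        for name, path in config.peaks_other.items():
            other, _ = io_formats.read_intervals(loc(path), "narrowPeak")
            summary = interval_analysis.overlap_summary(
                main_peaks, other, "main", name
            )
            overlap_frames.append(summary.to_frame())
        if overlap_frames:
            emit("overlaps.tsv", pd.concat(overlap_frames, ignore_index=True))

        stage = "promoter_counts"
        annotation = io_formats.read_gene_annotation(loc(config.annotation))
        windows = interval_analysis.tss_windows(annotation, config.tss_flank)
        chip_spec = config.tracks[config.chip_track]
        ctrl_spec = config.tracks[config.control_track]
        chip = signal_matrix.shift_tags(
            io_formats.read_tags(loc(chip_spec["tags"])), int(chip_spec.get("shift", 100))
        )
        ctrl = signal_matrix.shift_tags(
            io_formats.read_tags(loc(ctrl_spec["tags"])), int(ctrl_spec.get("shift", 100))
        )
        prom_counts = interval_analysis.promoter_counts(chip, ctrl, windows)
        emit("promoter_counts.tsv", prom_counts)

        stage = "enrich"
        targets, _ = interval_analysis.assign_targets(main_peaks, windows)
        emit(
            "target_genes.tsv",
            pd.DataFrame({"gene_id": sorted(targets)}),
        )
        if config.counts:
            counts = io_formats.read_table(loc(config.counts))
            scores_frame, fit = enrichment_model.enrichment_scores(
                counts,
                tol=config.tol,
                restarts=config.em_restarts,
                seed=config.seed,
                pseudo_mass=config.pseudo_mass,
            )
            emit("enrichment_scores.tsv", scores_frame)
            emit(
                "enrichment_fit.tsv",
                pd.DataFrame(
                    [
                        {
                            "theta_bg": fit.theta_bg,
                            "theta_sig": fit.theta_sig,
                            "pi_bg": fit.pi_bg,
                            "alpha_s": fit.alpha_s,
                            "alpha_r": fit.alpha_r,
                            "ln_f": fit.ln_f,
                            "n_iter": fit.n_iter,
                            "converged": fit.converged,
                        }
                    ]
                ),
            )
        de_table = io_formats.read_table(loc(config.de_table))
        track_names = sorted(
            c[:-2] for c in de_table.columns if c.endswith("_s")
            and f"{c[:-2]}_r" in de_table.columns
        )
        gene_scores = pd.DataFrame({"gene_id": de_table["gene_id"]})
        for track in track_names:
            counts = pd.DataFrame(
                {
                    "region_id": de_table["gene_id"],
                    "s": de_table[f"{track}_s"],
                    "r": de_table[f"{track}_r"],
                }
            )
            frame, _ = enrichment_model.enrichment_scores(
                counts,
                tol=config.tol,
                restarts=config.em_restarts,
                seed=config.seed,
                pseudo_mass=config.pseudo_mass,
            )
            gene_scores[track] = frame["e"].to_numpy()
        emit("gene_scores.tsv", gene_scores)
        if config.promoter_mark in gene_scores.columns:
            per_tss = annotation.table.merge(
                gene_scores[["gene_id", config.promoter_mark]], on="gene_id"
            )
            chosen = interval_analysis.select_promoter(
                io_formats.GeneAnnotation(
                    per_tss[["gene_id", "chrom", "tss", "strand"]]
                ),
                per_tss[config.promoter_mark].to_numpy(),
            )
            emit("selected_promoters.tsv", chosen)

        stage = "compare"
        comparisons = group_stats.compare_groups(gene_scores, de_table)
        emit("comparisons.tsv", comparisons)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": {
            name: _sha256(path) for name, path in sorted(outputs.items())
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return outdir


def _demo_inputs(seed: int, indir: Path) -> tuple[PipelineConfig, dict[str, Any]]:
    """Generate the synthetic demo dataset and its pipeline config."""
    indir.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_data.SimConfig(seed=seed)

    counts, true_labels = synthetic_data.simulate_counts(cfg)
    io_formats.write_table(counts, indir / "counts.tsv")
    io_formats.write_table(
        pd.DataFrame({"region_id": counts["region_id"], "label": true_labels}),
        indir / "counts_truth.tsv",
    )

    peaks, summits, tags, regimes = synthetic_data.simulate_regime_dataset(cfg)
    io_formats.write_intervals(
        peaks, indir / "peaks.narrowPeak", "narrowPeak", summits=summits
    )
    io_formats.write_table(
        pd.DataFrame(
            {"peak": [p.name for p in peaks], "regime": regimes}
        ),
        indir / "regime_truth.tsv",
    )
    track_cfg: dict[str, dict[str, Any]] = {}
    for track, track_tags in tags.items():
        path = indir / f"tags_{track}.bed"
        io_formats.write_tags(track_tags, path)
        track_cfg[track] = {"tags": str(path), "shift": 100}
    # uniform background track: the control for promoter counting
    rng = np.random.default_rng([seed, 9])
    chrom_span = (len(peaks) + 2) * (2 * max(cfg.flank, 5100) + 2_000)
    n_bg = 20_000
    bg_tags = [
        io_formats.ReadTag(
            "chrS", int(p), "+" if b else "-"
        )
        for p, b in zip(
            rng.integers(0, chrom_span, size=n_bg), rng.random(n_bg) < 0.5
        )
    ]
    bg_path = indir / "tags_control_input.bed"
    io_formats.write_tags(bg_tags, bg_path)
    track_cfg["control_input"] = {"tags": str(bg_path), "shift": 0}

    # an "other" peak set for the overlap stage: regime-A peaks widened,
    # plus decoys between peaks, emulating a mark co-occurring with regime A
    others = [
        io_formats.GenomicInterval(
            p.chrom, max(0, p.start - 500), p.end + 500, ".", p.score, f"other_{i}"
        )
        for i, p in enumerate(peaks)
        if regimes[i] == "A"
    ]
    decoy_rng = np.random.default_rng([seed, 10])
    gap = 2 * max(cfg.flank, 5100) + 2_000
    for j in range(200):
        start = int(decoy_rng.integers(0, chrom_span - 1_000))
        # snap decoys to the dead middle between peak windows
        start = (start // gap) * gap + gap // 2
        others.append(
            io_formats.GenomicInterval(
                "chrS", start, start + 400, ".", 1.0, f"decoy_{j}"
            )
        )
    other_summits = [
        io_formats.PeakSummit(o.chrom, (o.start + o.end) // 2, o.score)
        for o in others
    ]
    io_formats.write_intervals(
        others, indir / "peaks_other.narrowPeak", "narrowPeak",
        summits=other_summits,
    )

    # genes: one at every other peak summit (targets) and far decoy genes;
    # every third target gene gets a second, weaker-signal TSS so promoter
    # selection has real work to do
    rows = []
    for i in range(0, len(summits), 2):
        rows.append(
            {"gene_id": f"gene_{i // 2}", "chrom": "chrS",
             "tss": summits[i].pos, "strand": "+"}
        )
        if (i // 2) % 3 == 0:
            rows.append(
                {"gene_id": f"gene_{i // 2}", "chrom": "chrS",
                 "tss": summits[i].pos + 40_000 + 7, "strand": "+"}
            )
    n_target_genes = len({r["gene_id"] for r in rows})
    for j in range(150):
        rows.append(
            {"gene_id": f"far_gene_{j}", "chrom": "chrFar",
             "tss": 10_000 + 25_000 * j, "strand": "-"}
        )
    annotation = io_formats.GeneAnnotation(pd.DataFrame(rows))
    io_formats.write_table(annotation.table, indir / "annotation.tsv")

    de_table, shifts = synthetic_data.simulate_de_labels(annotation, cfg)
    io_formats.write_table(de_table, indir / "de_table.tsv")
    io_formats.write_table(shifts, indir / "de_shifts.tsv")

    # config paths are relative to the run directory, so the same seed
    # yields byte-identical configs and manifests wherever the run lives
    rel_tracks = {
        name: {"tags": f"inputs/{Path(spec['tags']).name}", "shift": spec["shift"]}
        for name, spec in track_cfg.items()
    }
    config = PipelineConfig(
        tracks=rel_tracks,
        peaks="inputs/peaks.narrowPeak",
        annotation="inputs/annotation.tsv",
        de_table="inputs/de_table.tsv",
        counts="inputs/counts.tsv",
        peaks_other={"regimeA_mark": "inputs/peaks_other.narrowPeak"},
        chip_track="active_mark",
        control_track="control_input",
        promoter_mark="active_mark",
        seed=seed,
    )
    truth = {
        "sim_config": cfg,
        "true_labels": true_labels,
        "regimes": regimes,
        "n_target_genes": n_target_genes,
    }
    return config, truth


def run_demo(seed: int, outdir: str | Path) -> Path:
    """Simulate a dataset, run the full pipeline, and report ground-truth recovery."""
    outdir = Path(outdir)
    config, truth = _demo_inputs(seed, outdir / "inputs")
    with open(outdir / "config.yaml", "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
    run_pipeline(config, outdir, base=outdir)

    cfg: synthetic_data.SimConfig = truth["sim_config"]
    fit_frame = io_formats.read_table(outdir / "enrichment_fit.tsv")
    scores_frame = io_formats.read_table(outdir / "enrichment_scores.tsv")
    labels_hat = np.where(scores_frame["posterior"] >= 0.5, "sig", "bg")
    accuracy = float((labels_hat == truth["true_labels"]).mean())

    cluster_frame = io_formats.read_table(outdir / "cluster_labels.tsv")
    ari = float(
        adjusted_rand_score(truth["regimes"], cluster_frame["cluster"].to_numpy())
    )

    comparisons = io_formats.read_table(outdir / "comparisons.tsv")

    def stars_for(track: str, a: str, b: str, direction: str) -> int:
        row = comparisons[
            (comparisons["track"] == track)
            & (comparisons["group_a"] == a)
            & (comparisons["group_b"] == b)
            & (comparisons["direction"] == direction)
        ]
        return int(row["stars"].iloc[0])

    report = {
        "seed": seed,
        "theta_bg_hat": float(fit_frame["theta_bg"].iloc[0]),
        "theta_sig_hat": float(fit_frame["theta_sig"].iloc[0]),
        "pi_bg_hat": float(fit_frame["pi_bg"].iloc[0]),
        "theta_bg_true": cfg.theta_bg,
        "theta_sig_true": cfg.theta_sig,
        "pi_bg_true": cfg.pi_bg,
        "label_accuracy": accuracy,
        "clustering_ari": ari,
        "n_target_genes_expected": truth["n_target_genes"],
        "n_target_genes_found": int(
            len(io_formats.read_table(outdir / "target_genes.tsv"))
        ),
        "stars_down_gt_unchanged_active": stars_for(
            "active_mark", "down", "unchanged", "greater"
        ),
        "stars_up_gt_down_repressive": stars_for(
            "repressive_mark", "down", "up", "less"
        ),
    }
    with open(outdir / "recovery_report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return outdir
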