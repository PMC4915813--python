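import numpy as np
import pytest

from chromregime import (
    SimConfig,
    clip_normalize,
    concat_tracks,
    count_matrix,
    enrichment_scores,
    kmeans_cluster,
    simulate_counts,
    simulate_regime_dataset,
)
from chromregime.signal_matrix import MatrixGeometry


@pytest.fixture(scope="session")
def mixture_run():
    """The reference parameter-recovery run: 10k regions, depth 20,
    theta (0.5, 0.8), background weight 0.9, seed 1."""
    cfg = SimConfig(seed=1)
    counts, labels = simulate_counts(cfg)
    scores, fit = enrichment_scores(counts, seed=1)
    return {"cfg": cfg, "counts": counts, "labels": labels,
            "scores": scores, "fit": fit}


@pytest.fixture(scope="session")
def regime_run():
    """Two-regime dataset (500 peaks each, two informative tracks, seed 7)
    with its clip-normalized matrices and k-means clustering."""
    cfg = SimConfig(seed=7)
    peaks, summits, tags, regimes = simulate_regime_dataset(cfg)
    geometry = MatrixGeometry(flank=5100, bin_size=51, shift=100)
    matrices = [
        clip_normalize(count_matrix(track_tags, summits, geometry, track=name))
        for name, track_tags in tags.items()
    ]
    combined, _ = concat_tracks(matrices)
    result = kmeans_cluster(combined, k=2, seed=7, restarts=10)
    return {
        "cfg": cfg, "peaks": peaks, "summits": summits, "tags": tags,
        "regimes": regimes, "matrices": matrices, "combined": combined,
        "result": result,
    }


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    from chromregime import run_demo

    outdir = tmp_path_factory.mktemp("demo") / "run"
    run_demo(1, outdir)
    return outdir
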