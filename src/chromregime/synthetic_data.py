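"""Ground-truthed synthetic inputs for every downstream analysis stage.

Three generators, all driven by one master seed (each sub-stream — counts,
read placement, labels, scores — derives its own ``numpy`` Generator so the
stages are individually reproducible):

* :func:`simulate_counts` — paired ChIP/control counts from a two-component
  binomial mixture: for region *i*, total depth n_i ~ Poisson(depth_mean),
  component z_i ~ Bernoulli(1 - pi_bg), ChIP count s_i ~ Binom(n_i, theta_z),
  control count r_i = n_i - s_i. This is exactly the model the enrichment
  module fits, so parameter recovery is a clean end-to-end check.
* :func:`simulate_regime_dataset` — peaks in two chromatin regimes with
  per-track read tags placed around summits; regime A is intense on one
  subset of tracks, regime B on the complement.
* :func:`simulate_de_labels` — differential-expression group labels
  (up / down / unchanged) plus per-track promoter paired counts whose
  ChIP fraction is shifted per group on the logit scale, so configured
  group orderings hold in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, GenomicInterval, PeakSummit, ReadTag

# Fixed stream ids so each sub-stage has an independent, named RNG.
_STREAMS = {"counts": 0, "placement": 1, "labels": 2, "scores": 3, "de": 4}

#: Default per-track mean read counts per peak as (regime A, regime B).
#: "repressive_mark" mimics a Polycomb-type signal confined to regime A,
#: "active_mark" an active-promoter signal confined to regime B.
DEFAULT_TRACKS: dict[str, tuple[float, float]] = {
    "repressive_mark": (200.0, 10.0),
    "active_mark": (10.0, 200.0),
}

#: Default logit-scale ChIP-fraction shifts per DE group and track.
#: active-mark signal is highest on down-regulated (normally active) genes,
#: repressive-mark signal highest on up-regulated (normally silenced) genes.
DEFAULT_DE_SHIFTS: dict[str, dict[str, float]] = {
    "active_mark": {"down": 2.0, "up": 1.0, "unchanged": 0.0},
    "repressive_mark": {"down": 0.0, "up": 2.0, "unchanged": 0.5},
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all three generators.

    theta_bg / theta_sig are the background and signal ChIP fractions of the
    binomial mixture; pi_bg is the background weight. Tracks map a name to
    mean reads per peak in (regime A, regime B). ``flank`` is the half-width
    of the read-placement window around each summit (offsets are uniform on
    +/- flank, strand fair).
    """

    n_regions: int = 10_000
    depth_mean: float = 20.0
    theta_bg: float = 0.5
    theta_sig: float = 0.8
    pi_bg: float = 0.9
    n_peaks_per_regime: int = 500
    tracks: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRACKS)
    )
    flank: int = 1000
    de_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"up": 0.15, "down": 0.15, "unchanged": 0.70}
    )
    de_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DE_SHIFTS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        # theta_bg == theta_sig is allowed as a degenerate limit (identical
        # components); a reversed ordering is a config error.
        if not (0 < self.theta_bg <= self.theta_sig < 1):
            raise ConfigError(
                f"need 0 < theta_bg <= theta_sig < 1, got "
                f"({self.theta_bg}, {self.theta_sig})"
            )
        if not (0 < self.pi_bg < 1):
            raise ConfigError(f"pi_bg must lie in (0, 1), got {self.pi_bg}")
        if self.n_regions <= 0 or self.n_peaks_per_regime <= 0:
            raise ConfigError("counts must be positive")
        if self.depth_mean <= 0 or self.flank <= 0:
            raise ConfigError("depth_mean and flank must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent generator derived from the master seed."""
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw paired ChIP/control counts from the two-component mixture.

    Returns ``(counts, labels)`` where ``counts`` has columns
    (region_id, s, r) and ``labels`` is 'bg'/'sig' per region.
    ``s + r`` equals the Poisson total exactly.
    """
    rng = cfg.rng("counts")
    n = rng.poisson(cfg.depth_mean, size=cfg.n_regions)
    is_sig = rng.random(cfg.n_regions) < (1.0 - cfg.pi_bg)
    theta = np.where(is_sig, cfg.theta_sig, cfg.theta_bg)
    s = rng.binomial(n, theta)
    counts = pd.DataFrame(
        {
            "region_id": [f"region_{i}" for i in range(cfg.n_regions)],
            "s": s.astype(np.int64),
            "r": (n - s).astype(np.int64),
        }
    )
    labels = np.where(is_sig, "sig", "bg")
    return counts, labels


def simulate_regime_dataset(
    cfg: SimConfig,
    chrom: str = "chrS",
    peak_halfwidth: int = 250,
    spacing: int | None = None,
) -> tuple[
    list[GenomicInterval],
    list[PeakSummit],
    dict[str, list[ReadTag]],
    np.ndarray,
]:
    """Simulate two-regime peaks and per-track read tags around their summits.

    Peaks alternate between regimes A and B along one synthetic chromosome,
    spaced far enough apart that their counting windows never overlap. Each
    track draws, per peak, a Poisson number of reads at the regime's mean
    intensity; read 5' offsets are uniform on +/- cfg.flank with a fair
    strand. Peak scores are Gamma(2, 20) distributed.

    Returns ``(peaks, summits, tags_by_track, regimes)``; ``regimes`` is an
    'A'/'B' array aligned with the peaks.
    """
    if len(cfg.tracks) < 2:
        raise ConfigError("simulate_regime_dataset needs >= 2 configured tracks")
    n_peaks = 2 * cfg.n_peaks_per_regime
    if spacing is None:
        spacing = 2 * max(cfg.flank, 5100) + 2_000
    score_rng = cfg.rng("scores")
    place_rng = cfg.rng("placement")

    regimes = np.empty(n_peaks, dtype="<U1")
    regimes[0::2] = "A"
    regimes[1::2] = "B"
    scores = score_rng.gamma(shape=2.0, scale=20.0, size=n_peaks)

    peaks: list[GenomicInterval] = []
    summits: list[PeakSummit] = []
    for i in range(n_peaks):
        summit = spacing * (i + 1)
        summits.append(PeakSummit(chrom, summit, float(scores[i])))
        peaks.append(
            GenomicInterval(
                chrom,
                summit - peak_halfwidth,
                summit + peak_halfwidth,
                ".",
                float(scores[i]),
                f"peak_{i}",
            )
        )

    tags: dict[str, list[ReadTag]] = {}
    for track, (rate_a, rate_b) in cfg.tracks.items():
        rates = np.where(regimes == "A", rate_a, rate_b)
        n_reads = place_rng.poisson(rates)
        track_tags: list[ReadTag] = []
        for i, k in enumerate(n_reads):
            if k == 0:
                continue
            offsets = place_rng.integers(-cfg.flank, cfg.flank + 1, size=k)
            strands = place_rng.random(k) < 0.5
            pos = summits[i].pos + offsets
            for p, plus in zip(pos, strands):
                track_tags.append(ReadTag(chrom, max(0, int(p)), "+" if plus else "-"))
        tags[track] = track_tags
    return peaks, summits, tags, regimes


def simulate_de_labels(
    genes: GeneAnnotation, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign DE groups to genes and draw group-shifted promoter counts.

    Each gene gets a group drawn from ``cfg.de_proportions``. For every
    track in ``cfg.de_shifts`` the gene's promoter receives paired counts
    (s, r): total ~ Poisson(depth_mean), ChIP fraction
    ``sigmoid(logit(theta_bg) + shift[track][group])``. Columns are
    ``{track}_s`` / ``{track}_r``.

    Returns ``(table, shifts)`` where ``shifts`` records the logit offsets
    actually used (track x group).
    """
    props = dict(cfg.de_proportions)
    groups = ["up", "down", "unchanged"]
    if set(props) != set(groups):
        raise ConfigError(f"de_proportions must cover exactly {groups}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"de_proportions must sum to 1, got {total}")

    gene_ids = genes.gene_ids
    rng = cfg.rng("de")
    p = np.array([props[g] for g in groups])
    labels = rng.choice(groups, size=len(gene_ids), p=p)

    base_logit = np.log(cfg.theta_bg / (1.0 - cfg.theta_bg))
    table = pd.DataFrame({"gene_id": gene_ids, "group": labels})
    for track, shift_map in cfg.de_shifts.items():
        shifts = np.array([shift_map.get(g, 0.0) for g in labels])
        theta = 1.0 / (1.0 + np.exp(-(base_logit + shifts)))
        n = rng.poisson(cfg.depth_mean, size=len(gene_ids))
        s = rng.binomial(n, theta)
        table[f"{track}_s"] = s.astype(np.int64)
        table[f"{track}_r"] = (n - s).astype(np.int64)
    shifts_table = pd.DataFrame(
        [
            {"track": track, "group": g, "logit_shift": shift_map.get(g, 0.0)}
            for track, shift_map in cfg.de_shifts.items()
            for g in groups
        ]
    )
    return table, shifts_table


def toy_annotation(
    n_genes: int, chrom: str = "chrS", start: int = 50_000, spacing: int = 20_000
) -> GeneAnnotation:
    """Evenly spaced single-TSS genes on one chromosome (test scaffolding)."""
    rows = [
        {
            "gene_id": f"gene_{i}",
            "chrom": chrom,
            "tss": start + i * spacing,
            "strand": "+" if i % 2 == 0 else "-",
        }
        for i in range(n_genes)
    ]
    return GeneAnnotation(pd.DataFrame(rows))
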