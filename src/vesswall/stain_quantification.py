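"""Depth-resolved staining distributions and per-layer scores.

The core readout is the staining distribution: stained pixels are counted
per depth bin (100 bins spanning the wall from lumen to adventitial edge),
giving a histogram that normalizes to a probability vector over wall depth.
Distributions for vessels stained with the same marker are averaged with
equal per-vessel weight, and layer scores are obtained either by summing
the density over each layer's bins (scores sum to 1) or by the mean DAB
pixel value per layer centered on the whole-wall mean.

Raw counts are reported exactly as tallied: annular geometry gives outer
bins more pixels than inner ones, and no area correction is applied by
default. An area-normalized variant (stained fraction of each bin's pixels)
is available via ``area_normalized=True`` for users who want a per-bin
staining probability instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stain_separation import StainedMask
from .wall_geometry import LAYERS, DepthBinMap, LayerPartition

__all__ = [
    "StainingDistribution",
    "LayerScores",
    "staining_distribution",
    "mean_distribution",
    "layer_scores",
    "intensity_layer_scores",
]


@dataclass
class StainingDistribution:
    """Histogram of stained pixels along normalized wall depth."""

    counts: np.ndarray
    vessel_id: str = ""
    marker: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_stained(self) -> int:
        return int(round(self.counts.sum()))

    @property
    def flagged(self) -> bool:
        """True when no stained pixels exist and the density is undefined."""
        return self.counts.sum() == 0

    @property
    def density(self) -> np.ndarray:
        if self.flagged:
            raise ValueError(
                f"distribution {self.marker}/{self.vessel_id} has no stained pixels; "
                "density undefined"
            )
        return self.counts / self.counts.sum()


@dataclass
class LayerScores:
    intima: float
    media: float
    adventitia: float
    mode: str  # "density_sum" | "intensity_normalized"
    vessel_id: str = ""
    marker: str = ""

    def as_dict(self) -> dict[str, float]:
        return {layer: getattr(self, layer) for layer in LAYERS}

    def as_array(self) -> np.ndarray:
        return np.array([self.intima, self.media, self.adventitia])


def staining_distribution(
    stained: StainedMask | np.ndarray,
    bins: DepthBinMap,
    vessel_id: str = "",
    marker: str = "",
    area_normalized: bool = False,
) -> StainingDistribution:
    """Count stained pixels per depth bin.

    With ``area_normalized=True`` each bin's count is replaced by the stained
    fraction of that bin's wall pixels, removing the annular bin-area bias.
    """
    mask = stained.mask if isinstance(stained, StainedMask) else np.asarray(stained, bool)
    if mask.shape != bins.bins.shape:
        raise ValueError(f"shape mismatch: stained {mask.shape} vs bins {bins.bins.shape}")
    if (mask & ~bins.wall).any():
        raise ValueError("stained mask extends outside the wall of the bin map")
    counts = np.bincount(bins.bins[mask], minlength=bins.n_bins).astype(float)
    if area_normalized:
        wall_counts = bins.counts().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            counts = np.where(wall_counts > 0, counts / wall_counts, 0.0)
    return StainingDistribution(counts=counts, vessel_id=vessel_id, marker=marker)


def mean_distribution(distributions: list[StainingDistribution]) -> StainingDistribution:
    """Average normalized densities across vessels, one vote per vessel.

    Flagged (empty-stain) members are rejected; vessels are weighted equally
    regardless of their stained-pixel counts, so large vessels do not
    dominate the marker's mean profile.
    """
    usable = [d for d in distributions if not d.flagged]
    if not usable:
        raise ValueError("no non-empty distributions to average")
    n_bins = usable[0].n_bins
    if any(d.n_bins != n_bins for d in usable):
        raise ValueError("distributions have mismatched bin counts")
    mean = np.mean([d.density for d in usable], axis=0)
    marker = usable[0].marker if len({d.marker for d in usable}) == 1 else "mixed"
    return StainingDistribution(counts=mean, vessel_id="mean", marker=marker)


def layer_scores(
    dist: StainingDistribution, partition: LayerPartition | None = None
) -> LayerScores:
    """Sum the density over each layer's bins (density_sum mode; sums to 1)."""
    if dist.flagged:
        raise ValueError("cannot score a distribution with no stained pixels")
    partition = partition or LayerPartition(n_bins=dist.n_bins)
    if partition.n_bins != dist.n_bins:
        raise ValueError("partition n_bins does not match distribution")
    density = dist.density
    sums = {name: float(density[sl].sum()) for name, sl in partition.bin_slices().items()}
    return LayerScores(
        mode="density_sum", vessel_id=dist.vessel_id, marker=dist.marker, **sums
    )


def intensity_layer_scores(
    dab: np.ndarray,
    bins: DepthBinMap,
    partition: LayerPartition | None = None,
    vessel_id: str = "",
    marker: str = "",
) -> LayerScores:
    """Mean DAB value per layer, centered by the whole-wall mean.

    ``score_L = mean(dab | layer L) - mean(dab | wall)``; a uniformly stained
    wall therefore scores (0, 0, 0) and positive values flag enrichment.
    """
    dab = np.asarray(dab, dtype=float)
    if dab.shape != bins.bins.shape:
        raise ValueError(f"shape mismatch: dab {dab.shape} vs bins {bins.bins.shape}")
    partition = partition or LayerPartition(n_bins=bins.n_bins)
    layer_of = partition.layer_index_of_bins()
    wall = bins.wall
    pixel_layer = layer_of[bins.bins[wall]]
    vals = dab[wall]
    global_mean = vals.mean()
    scores = {}
    for i, name in enumerate(LAYERS):
        in_layer = pixel_layer == i
        if not in_layer.any():
            raise ValueError(f"layer {name!r} contains no wall pixels (degenerate geometry)")
        scores[name] = float(vals[in_layer].mean() - global_mean)
    return LayerScores(mode="intensity_normalized", vessel_id=vessel_id, marker=marker, **scores)
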