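"""Tangential-sector feature vectors and their 2-D t-SNE embedding.

Each vessel is divided into 20 equal angular sectors; every sector with any
stained pixels contributes one 100-dimensional feature vector — the depth
distribution of its stained pixels. Pooling those vectors across vessels and
markers and embedding them with t-SNE visualizes how similar each marker's
local staining geometry is to a reference marker; an overlap report turns
the visual impression into numbers (centroid distance and the fraction of a
reference point's nearest neighbors carrying the query label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .stain_separation import StainedMask
from .wall_geometry import DepthBinMap

__all__ = [
    "SectorFeatureMatrix",
    "Embedding2D",
    "sector_distributions",
    "embed_tsne",
    "overlap_report",
]


@dataclass
class SectorFeatureMatrix:
    """One row per (vessel, sector) pair with any stained pixels."""

    features: np.ndarray  # (n_rows, n_bins) densities, rows sum to 1
    labels: np.ndarray  # marker per row
    vessel_ids: np.ndarray
    sectors: np.ndarray
    n_bins: int

    def __len__(self) -> int:
        return self.features.shape[0]

    @staticmethod
    def concatenate(parts: list["SectorFeatureMatrix"]) -> "SectorFeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        n_bins = {p.n_bins for p in parts}
        if len(n_bins) != 1:
            raise ValueError("mismatched feature dimensions")
        return SectorFeatureMatrix(
            features=np.vstack([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            vessel_ids=np.concatenate([p.vessel_ids for p in parts]),
            sectors=np.concatenate([p.sectors for p in parts]),
            n_bins=n_bins.pop(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=[f"bin_{i}" for i in range(self.n_bins)])
        df.insert(0, "sector", self.sectors)
        df.insert(0, "vessel_id", self.vessel_ids)
        df.insert(0, "marker", self.labels)
        return df


@dataclass
class Embedding2D:
    coordinates: np.ndarray  # (n_rows, 2)
    labels: np.ndarray
    perplexity: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.labels,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
            }
        )


def sector_distributions(
    stained: StainedMask | np.ndarray,
    bins: DepthBinMap,
    sectors: np.ndarray,
    vessel_id: str = "",
    marker: str = "",
) -> SectorFeatureMatrix:
    """Per-sector depth distributions of stained pixels for one vessel.

    Sectors without stained pixels are excluded (a zero vector is not a
    probability distribution). Counts across all sectors sum bin-by-bin to
    the whole-vessel staining distribution.
    """
    mask = stained.mask if isinstance(stained, StainedMask) else np.asarray(stained, bool)
    sectors = np.asarray(sectors)
    if mask.shape != bins.bins.shape or mask.shape != sectors.shape:
        raise ValueError(
            f"shape mismatch: stained {mask.shape}, bins {bins.bins.shape}, "
            f"sectors {sectors.shape}"
        )
    n_sectors = int(sectors.max()) + 1
    sec = sectors[mask]
    depth_bin = bins.bins[mask]
    rows, labels_s = [], []
    for s in range(n_sectors):
        in_s = sec == s
        if not in_s.any():
            continue
        counts = np.bincount(depth_bin[in_s], minlength=bins.n_bins).astype(float)
        rows.append(counts / counts.sum())
        labels_s.append(s)
    feats = np.vstack(rows) if rows else np.empty((0, bins.n_bins))
    n = len(labels_s)
    return SectorFeatureMatrix(
        features=feats,
        labels=np.full(n, marker, dtype=object),
        vessel_ids=np.full(n, vessel_id, dtype=object),
        sectors=np.asarray(labels_s, dtype=int),
        n_bins=bins.n_bins,
    )


def embed_tsne(
    features: SectorFeatureMatrix | np.ndarray,
    perplexity: float = 10.0,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> Embedding2D:
    """Deterministic 2-D t-SNE of sector feature vectors.

    Requires at least ``3 * perplexity`` rows (the usual validity rule of
    thumb); densities are embedded directly without PCA pre-reduction.
    """
    if isinstance(features, SectorFeatureMatrix):
        x = features.features
        labels = features.labels if labels is None else np.asarray(labels)
    else:
        x = np.asarray(features, dtype=float)
        labels = np.asarray(labels) if labels is not None else np.full(len(x), "", object)
    n = x.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} rows is too few for perplexity {perplexity}; "
            f"need >= {int(np.ceil(3 * perplexity))} rows or perplexity <= {n / 3:.1f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=1000,
    )
    coords = tsne.fit_transform(x)
    return Embedding2D(
        coordinates=np.asarray(coords, dtype=float),
        labels=labels,
        perplexity=perplexity,
        seed=seed,
    )


def overlap_report(
    embedding: Embedding2D,
    reference_label: str,
    k: int = 10,
) -> pd.DataFrame:
    """Quantify each marker's overlap with the reference cloud.

    For every non-reference marker: the Euclidean distance between cloud
    centroids, and the mean fraction of each reference point's ``k`` nearest
    neighbors (searched among reference + that marker's points) that belong
    to the marker. Two perfectly interleaved, equally sized clouds give a
    fraction near 0.5; a displaced cloud gives ~0.
    """
    labels = np.asarray(embedding.labels)
    coords = embedding.coordinates
    if reference_label not in labels:
        raise KeyError(f"reference label {reference_label!r} not present in embedding")
    ref = coords[labels == reference_label]
    ref_centroid = ref.mean(axis=0)
    records = []
    for marker in dict.fromkeys(labels):  # preserves first-seen order
        if marker == reference_label:
            continue
        other = coords[labels == marker]
        pool = np.vstack([ref, other])
        is_other = np.concatenate([np.zeros(len(ref), bool), np.ones(len(other), bool)])
        kk = min(k, len(pool) - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(pool)
        _, idx = nn.kneighbors(ref)
        neigh = idx[:, 1:]  # drop self (each ref point is in the pool)
        frac = is_other[neigh].mean()
        records.append(
            {
                "marker": marker,
                "centroid_distance": float(np.linalg.norm(other.mean(axis=0) - ref_centroid)),
                "neighbor_fraction": float(frac),
                "n_points": int(len(other)),
            }
        )
    return pd.DataFrame.from_records(records).sort_values(
        "neighbor_fraction", ascending=False, kind="stable"
    ).reset_index(drop=True)
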