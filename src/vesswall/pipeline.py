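"""End-to-end orchestration: unmix -> geometry -> quantify -> compare -> embed.

`run_pipeline` drives the whole analysis from a `RunConfig`: for every
manifest entry it unmixes the image, parameterizes the wall, thresholds the
DAB map, and quality-controls the vessel; per marker it averages the
distributions, scores the layers, tests medial enrichment, builds the
similarity matrix against the reference marker, and embeds pooled sector
features with t-SNE. All randomness derives from the seeds recorded in the
config, so identical configs produce identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .marker_statistics import layer_t_test, permutation_layer_test, similarity_matrix
from .sector_embedding import SectorFeatureMatrix, embed_tsne, overlap_report, sector_distributions
from .stain_quantification import (
    intensity_layer_scores,
    layer_scores,
    mean_distribution,
    staining_distribution,
)
from .stain_separation import (
    HDAB_VECTORS,
    StainImage,
    StainVectors,
    rgb_to_optical_density,
    separate_stains,
    threshold_stained,
)
from .wall_geometry import LayerPartition, TopologyError, build_geometry, _wall_regions

logger = logging.getLogger("vesswall")

__all__ = ["RunConfig", "RunRecord", "qc_vessel", "run_pipeline"]


@dataclass
class RunConfig:
    manifest: str  # CSV: image, wall_mask, marker, vessel_id
    out_dir: str
    stain_matrix: list | None = None  # 3x3, columns H/DAB/residual
    threshold_method: str = "otsu"
    threshold_level: float | None = None
    depth_method: str = "distance"
    n_bins: int = 100
    n_sectors: int = 20
    layer_boundaries: tuple[int, int] = (33, 66)
    reference_marker: str | None = None
    alternative: str = "greater"
    n_perm: int = 10_000
    test_seed: int = 17
    perplexity: float = 10.0
    embed_seed: int = 17
    min_stained_pixels: int = 100
    max_failed_spoke_fraction: float = 0.10
    make_plots: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        if isinstance(cfg.layer_boundaries, list):
            cfg.layer_boundaries = tuple(cfg.layer_boundaries)
        return cfg

    def vectors(self) -> StainVectors:
        if self.stain_matrix is None:
            return HDAB_VECTORS
        return StainVectors.from_matrix(np.asarray(self.stain_matrix, float))

    def partition(self) -> LayerPartition:
        return LayerPartition(n_bins=self.n_bins, boundaries=tuple(self.layer_boundaries))


@dataclass
class RunRecord:
    config: dict
    version: str
    vessel_status: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def qc_vessel(
    wall: np.ndarray,
    stained: np.ndarray | None,
    min_stained_pixels: int = 100,
    max_failed_spoke_fraction: float = 0.10,
    failed_spoke_fraction: float = 0.0,
) -> str:
    """Classify one vessel: ok / bad_topology / empty_stain / low_signal.

    QC classifies and never raises; it stands in for the manual selection of
    vessels with acceptable, artifact-free staining.
    """
    try:
        _wall_regions(wall)
    except Exception:
        return "bad_topology"
    if failed_spoke_fraction > max_failed_spoke_fraction:
        return "bad_topology"
    if stained is None:
        return "empty_stain"
    n = int(np.asarray(stained, bool).sum())
    if n == 0:
        return "empty_stain"
    if n < min_stained_pixels:
        return "low_signal"
    return "ok"


def _load_manifest(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image", "wall_mask", "marker", "vessel_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    for col in ("image", "wall_mask"):
        df[col] = df[col].map(lambda p: str((base / p).resolve()) if not Path(p).is_absolute() else p)
    return df


def _process_vessel(row, cfg: RunConfig, vectors: StainVectors):
    """Unmix, parameterize and threshold one vessel. Returns (status, payload)."""
    rgb = np.asarray(iio.imread(row.image))
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    image = StainImage(pixels=rgb, id=str(row.vessel_id))
    wall = np.asarray(iio.imread(row.wall_mask)) > 0
    if wall.ndim == 3:
        wall = wall.any(axis=-1)
    try:
        geom = build_geometry(
            wall,
            depth_method=cfg.depth_method,
            n_bins=cfg.n_bins,
            n_sectors=cfg.n_sectors,
            partition=cfg.partition(),
        )
    except (TopologyError, ValueError) as exc:
        logger.warning("vessel %s: %s", row.vessel_id, exc)
        return "bad_topology", None
    od = rgb_to_optical_density(image)
    conc = separate_stains(od, vectors)
    try:
        stained = threshold_stained(
            conc.dab, geom.wall, method=cfg.threshold_method, level=cfg.threshold_level
        )
    except ValueError:
        # flat DAB signal inside the wall (e.g. blank section): nothing to threshold
        return "empty_stain", None
    frac_failed = geom.failed_spokes / 360.0 if cfg.depth_method == "spokes" else 0.0
    status = qc_vessel(
        geom.wall,
        stained.mask,
        min_stained_pixels=cfg.min_stained_pixels,
        max_failed_spoke_fraction=cfg.max_failed_spoke_fraction,
        failed_spoke_fraction=frac_failed,
    )
    return status, (geom, conc, stained)


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute the full workflow and write the output tree.

    Outputs (CSV unless noted): per-vessel distributions, per-marker mean
    distributions, layer scores (both modes), layer enrichment tests,
    similarity matrix + ranked similarity-to-reference table, sector
    features, t-SNE embedding, overlap report, and a JSON run record with a
    status for every manifest entry.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=asdict(config), version=__version__, started=time.strftime("%FT%T"))
    manifest = _load_manifest(Path(config.manifest))
    vectors = config.vectors()
    partition = config.partition()

    dist_rows, score_rows = [], []
    per_marker_dists: dict[str, list] = {}
    per_marker_scores: dict[str, list] = {}
    sector_parts: list[SectorFeatureMatrix] = []

    for row in manifest.itertuples(index=False):
        vid, marker = str(row.vessel_id), str(row.marker)
        try:
            status, payload = _process_vessel(row, config, vectors)
        except Exception as exc:  # any stage failure is recorded, not fatal
            logger.error("vessel %s failed: %s", vid, exc)
            record.vessel_status[vid] = f"error: {exc}"
            continue
        record.vessel_status[vid] = status
        if status != "ok":
            continue
        geom, conc, stained = payload
        dist = staining_distribution(stained, geom.bin_map, vessel_id=vid, marker=marker)
        scores = layer_scores(dist, partition)
        iscores = intensity_layer_scores(
            conc.dab, geom.bin_map, partition, vessel_id=vid, marker=marker
        )
        per_marker_dists.setdefault(marker, []).append(dist)
        per_marker_scores.setdefault(marker, []).append(scores)
        density = dist.density
        for b in range(dist.n_bins):
            dist_rows.append(
                {"marker": marker, "vessel_id": vid, "bin": b,
                 "count": dist.counts[b], "density": density[b]}
            )
        for s in (scores, iscores):
            for layer, value in s.as_dict().items():
                score_rows.append(
                    {"marker": marker, "vessel_id": vid, "mode": s.mode,
                     "layer": layer, "score": value}
                )
        sector_parts.append(
            sector_distributions(stained, geom.bin_map, geom.sector, vessel_id=vid, marker=marker)
        )

    empty = [m for m in manifest["marker"].unique() if not per_marker_dists.get(str(m))]
    if empty:
        raise RuntimeError(f"markers with zero surviving vessels after QC: {empty}")

    pd.DataFrame(dist_rows).to_csv(out / "distributions.csv", index=False)
    pd.DataFrame(score_rows).to_csv(out / "layer_scores.csv", index=False)

    mean_rows = []
    mean_densities: dict[str, np.ndarray] = {}
    for marker, dists in per_marker_dists.items():
        mean = mean_distribution(dists)
        mean_densities[marker] = mean.density
        for b, d in enumerate(mean.density):
            mean_rows.append({"marker": marker, "bin": b, "density": d})
    pd.DataFrame(mean_rows).to_csv(out / "mean_distributions.csv", index=False)

    test_rows = []
    for marker, scores in per_marker_scores.items():
        by_layer = {lyr: [s.as_dict()[lyr] for s in scores] for lyr in ("intima", "media", "adventitia")}
        for other in ("intima", "adventitia"):
            pair = ("media", other)
            if len(scores) >= 2:
                t = layer_t_test(by_layer["media"], by_layer[other],
                                 alternative=config.alternative, pair=pair)
                p = permutation_layer_test(by_layer["media"], by_layer[other],
                                           alternative=config.alternative,
                                           n_perm=config.n_perm, seed=config.test_seed, pair=pair)
                for res in (t, p):
                    test_rows.append(
                        {"marker": marker, "pair": f"{pair[0]}_vs_{pair[1]}",
                         "method": res.method, "statistic": res.statistic,
                         "p_value": res.p_value, "alternative": res.alternative,
                         "n_per_group": res.n_per_group[0]}
                    )
    pd.DataFrame(test_rows).to_csv(out / "layer_tests.csv", index=False)

    if len(mean_densities) >= 2:
        sim = similarity_matrix(mean_densities, reference=config.reference_marker)
        sim.to_frame("similarity").to_csv(out / "similarity.csv")
        sim.to_frame("distance").to_csv(out / "js_distance.csv")
        if sim.reference_ranking is not None:
            sim.reference_ranking.to_csv(out / "similarity_ranking.csv", index=False)

    features = SectorFeatureMatrix.concatenate(sector_parts)
    features.to_frame().to_csv(out / "sector_features.csv", index=False)
    if len(features) >= 3 * config.perplexity:
        emb = embed_tsne(features, perplexity=config.perplexity, seed=config.embed_seed)
        df = emb.to_frame()
        df.insert(1, "vessel_id", features.vessel_ids)
        df.insert(2, "sector", features.sectors)
        df.to_csv(out / "embedding.csv", index=False)
        (out / "embedding_params.json").write_text(
            json.dumps({"perplexity": config.perplexity, "seed": config.embed_seed,
                        "n_rows": len(features)})
        )
        if config.reference_marker is not None and config.reference_marker in set(features.labels):
            overlap_report(emb, config.reference_marker).to_csv(out / "overlap.csv", index=False)
    else:
        record.notes.append(
            f"embedding skipped: {len(features)} sector rows < 3*perplexity={3 * config.perplexity}"
        )

    if config.make_plots:
        _write_plots(out, mean_densities, config)

    record.finished = time.strftime("%FT%T")
    record.to_json(out / "run_record.json")
    return record


def _write_plots(out: Path, mean_densities: dict[str, np.ndarray], config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = config.reference_marker
    fig, ax = plt.subplots(figsize=(7, 4))
    for marker, dens in mean_densities.items():
        kw = {"color": "black", "lw": 2} if marker == ref else {"alpha": 0.8}
        ax.plot(np.arange(dens.size), dens, label=marker, **kw)
    ax.set_xlabel("wall depth bin (lumen → adventitia)")
    ax.set_ylabel("staining density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "mean_distributions.png", dpi=150)
    plt.close(fig)

    emb_path = out / "embedding.csv"
    if emb_path.exists():
        df = pd.read_csv(emb_path)
        fig, ax = plt.subplots(figsize=(5, 5))
        for marker, grp in df.groupby("marker"):
            ax.scatter(grp["x"], grp["y"], s=8, label=marker,
                       color="blue" if marker == ref else None, alpha=0.7)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "embedding.png", dpi=150)
        plt.close(fig)
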