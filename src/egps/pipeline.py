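"""End-to-end pipeline: preprocess -> ordinal labels -> train -> score -> stats.

`run_pipeline` glues the stages together behind a schema-validated
configuration, writing tiles' scores, the model checkpoint (with the
fitted quantile reference embedded, so new slides can be scored without
retraining), per-slide paintings, a statistics report, and a run log with
the config hash and seed.  Re-running with an identical configuration
reproduces ``scores.csv`` byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field

from . import linknet, scoring, stats as cohort_stats, synthetic
from .train import TrainConfig, split_holdout, train as train_model
from .manifest import manifest_tile_paths, read_manifest
from .nn import F32
from .ordinal import AgeSchedule, build_ordinal_mask, encode_ordinal
from .preprocess import (
    PreprocessConfig,
    Tile,
    downsample_image,
    estimate_tissue_mask,
    filter_tiles,
    normalize_channels,
    pooled_channel_stats,
    tile_image,
    tissue_coverage,
)

__all__ = ["RunConfig", "run_pipeline", "load_slide_tiles", "normalize_slide_tiles", "score_slides"]


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slides_per_group: int = 5
    tiles_per_slide: int = 6
    tile_size: int = 128
    base_lesion_density: float = 5.0
    density_slope: float = 5.0


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tile_size: int = 512
    keep_every: int = 20
    downsample_factor: int = 20
    min_tissue_coverage: float = 0.90
    white_threshold: float = 220.0
    normalize_per_tile: bool = False


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    base_width: int = 64
    activation_head: str = "sigmoid"


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = 60
    batch_size: int = 20
    lr_scale: float = 1.0
    holdout_fraction: float = 0.2
    loss_on_background: bool = True


class ScoringSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_max_size: int = 200_000
    paintings: bool = True


class RunConfig(BaseModel):
    """Declarative pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    schedule: list[int] = Field(..., min_length=2)
    out_dir: str
    seed: int = 0
    manifest: str | None = None
    synth: SynthSection | None = None
    preprocess: PreprocessSection = PreprocessSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    scoring: ScoringSection = ScoringSection()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_slide_tiles(
    row: pd.Series, base_dir: str | Path, pre: PreprocessConfig
) -> list[Tile]:
    """Load a slide's images and cut/collect working-resolution tiles.

    Images already at tile size are taken as single tiles; larger images
    are block-mean downsampled and gridded.  Tissue masks are estimated by
    luminance thresholding.
    """
    tiles: list[Tile] = []
    for path in manifest_tile_paths(row, base_dir):
        px = np.asarray(Image.open(path).convert("RGB"))
        if max(px.shape[0], px.shape[1]) > pre.tile_size and pre.downsample_factor > 1:
            px = downsample_image(px, pre.downsample_factor)
        mask = estimate_tissue_mask(px, pre.white_threshold)
        if px.shape[0] == pre.tile_size and px.shape[1] == pre.tile_size:
            tiles.append(
                Tile(
                    pixels=px,
                    tissue_mask=mask,
                    slide_id=str(row["slide_id"]),
                    row=0,
                    col=len(tiles),
                    age_months=int(row["age_months"]),
                    meta={"source": str(path)},
                )
            )
        else:
            tiles.extend(
                tile_image(
                    px,
                    mask,
                    pre,
                    slide_id=str(row["slide_id"]),
                    age_months=int(row["age_months"]),
                )
            )
    return tiles


def normalize_slide_tiles(tiles: list[Tile], pre: PreprocessConfig) -> np.ndarray:
    """Normalize a slide's tiles; returns (N, 3, H, W) float32.

    Default: z-score against the slide-wide pooled channel statistics
    ("all pixels in that channel" of the slide); optionally per tile.
    """
    if not tiles:
        return np.zeros((0, 3, 1, 1), dtype=F32)
    if pre.normalize_per_tile:
        arrs = [normalize_channels(t.pixels, ddof=pre.std_ddof) for t in tiles]
    else:
        mean, std = pooled_channel_stats([t.pixels for t in tiles], ddof=pre.std_ddof)
        std = np.where(std == 0, 1.0, std)
        arrs = [(np.asarray(t.pixels, dtype=np.float64) - mean) / std for t in tiles]
    return np.stack([a.transpose(2, 0, 1) for a in arrs]).astype(F32)


def _arrays_for_slides(
    manifest: pd.DataFrame,
    slide_ids: list[str],
    base_dir: str | Path,
    pre: PreprocessConfig,
    schedule: AgeSchedule,
    coverage_filter: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (x, ordinal-mask, tissue-mask) arrays for the given slides."""
    xs, ys, ms = [], [], []
    for sid in slide_ids:
        row = manifest.loc[manifest["slide_id"] == sid].iloc[0]
        tiles = load_slide_tiles(row, base_dir, pre)
        if coverage_filter:
            tiles = filter_tiles(tiles, pre.min_tissue_coverage)
        if not tiles:
            continue
        x = normalize_slide_tiles(tiles, pre)
        label = encode_ordinal(int(row["age_months"]), schedule)
        for tile, xt in zip(tiles, x):
            xs.append(xt)
            ys.append(build_ordinal_mask(tile.tissue_mask, label))
            ms.append((tile.tissue_mask > 0).astype(np.uint8))
    if not xs:
        raise ValueError(f"no usable tiles for slides {slide_ids}")
    return np.stack(xs), np.stack(ys), np.stack(ms)


def score_slides(
    model: linknet.LinkNet,
    manifest: pd.DataFrame,
    base_dir: str | Path,
    pre: PreprocessConfig,
    ref: scoring.QuantileReference,
    paintings_dir: str | Path | None = None,
    breakpoints: tuple[float, float, float] | None = None,
    pixel_maps_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score every slide in the manifest against a fitted reference.

    With ``paintings_dir`` a colour heat map per tile is written; with
    ``pixel_maps_dir`` the raw pixel eGPS maps are saved as 32-bit float
    TIFFs (NaN off tissue).
    """
    rows = []
    for _, mrow in manifest.iterrows():
        tiles = load_slide_tiles(mrow, base_dir, pre)
        x = normalize_slide_tiles(tiles, pre)
        pixel_maps = []
        for tile, xt in zip(tiles, x):
            pm = linknet.predict_probability_mask(model, xt)
            if tile.tissue_mask.any():
                pixel_maps.append(scoring.pixel_egps(pm, ref, tile.tissue_mask))
        if not pixel_maps:
            raise ValueError(f"slide {mrow['slide_id']} has no tissue pixels to score")
        egps = scoring.slide_egps(pixel_maps)
        n_px = int(sum(p.tissue_mask.sum() for p in pixel_maps))
        rows.append(
            {
                "slide_id": mrow["slide_id"],
                "age_months": int(mrow["age_months"]),
                "group": mrow.get("group", ""),
                "treatment": mrow.get("treatment", ""),
                "egps": egps,
                "n_tissue_pixels": n_px,
            }
        )
        if paintings_dir is not None:
            pdir = Path(paintings_dir)
            pdir.mkdir(parents=True, exist_ok=True)
            for i, p in enumerate(pixel_maps):
                img = scoring.render_painting(p, breakpoints=breakpoints)
                Image.fromarray(img).save(pdir / f"{mrow['slide_id']}_t{i:02d}.png")
        if pixel_maps_dir is not None:
            import tifffile

            mdir = Path(pixel_maps_dir)
            mdir.mkdir(parents=True, exist_ok=True)
            for i, p in enumerate(pixel_maps):
                tifffile.imwrite(
                    mdir / f"{mrow['slide_id']}_t{i:02d}.tiff",
                    p.scores.astype(np.float32),
                )
    return pd.DataFrame(rows)


def _probability_masks_for_reference(
    model: linknet.LinkNet,
    manifest: pd.DataFrame,
    slide_ids: list[str],
    base_dir: str | Path,
    pre: PreprocessConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    pms, tms = [], []
    for sid in slide_ids:
        row = manifest.loc[manifest["slide_id"] == sid].iloc[0]
        tiles = load_slide_tiles(row, base_dir, pre)
        x = normalize_slide_tiles(tiles, pre)
        for tile, xt in zip(tiles, x):
            pms.append(linknet.predict_probability_mask(model, xt))
            tms.append(tile.tissue_mask)
    return pms, tms


def score_intervention(
    model: linknet.LinkNet,
    ref: scoring.QuantileReference,
    pre: PreprocessConfig,
    cohort_spec: synthetic.SyntheticSpec,
    workdir: str | Path,
    effect_multiplier: float = 0.5,
    n_control: int = 8,
    n_treated: int = 8,
) -> tuple[pd.DataFrame, cohort_stats.StatResult]:
    """Score a two-arm intervention cohort with an already-trained model.

    Generates a same-age cohort whose treated arm has its lesion density
    scaled by ``effect_multiplier``, scores every slide against the fitted
    reference (no retraining), and returns the slide scores plus the Welch
    t-test comparing control vs treated.
    """
    workdir = Path(workdir)
    manifest = synthetic.generate_intervention_cohort(
        cohort_spec, effect_multiplier, n_control, n_treated, workdir
    )
    scores = score_slides(model, manifest, workdir, pre, ref)
    control = scores.loc[scores["treatment"] == "control", "egps"].to_numpy()
    treated = scores.loc[scores["treatment"] == "treated", "egps"].to_numpy()
    welch = cohort_stats.welch_t_test(control, treated)
    return scores, welch


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of artifact paths/results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = AgeSchedule(tuple(config.schedule))
    stage = "setup"
    try:
        # ---- input -------------------------------------------------------
        stage = "input"
        if config.manifest is not None:
            manifest_path = Path(config.manifest)
        elif config.synth is not None:
            spec = synthetic.SyntheticSpec(
                age_groups=schedule.ages,
                slides_per_group=config.synth.slides_per_group,
                tiles_per_slide=config.synth.tiles_per_slide,
                tile_size=config.synth.tile_size,
                base_lesion_density=config.synth.base_lesion_density,
                density_slope=config.synth.density_slope,
                seed=config.seed,
            )
            synthetic.generate_cohort(spec, out_dir / "cohort")
            manifest_path = out_dir / "cohort" / "manifest.csv"
        else:
            raise ValueError("config needs either a manifest or a synth section")
        manifest = read_manifest(manifest_path)
        base_dir = manifest_path.parent

        pre = PreprocessConfig(
            tile_size=config.preprocess.tile_size,
            keep_every=config.preprocess.keep_every,
            downsample_factor=config.preprocess.downsample_factor,
            min_tissue_coverage=config.preprocess.min_tissue_coverage,
            white_threshold=config.preprocess.white_threshold,
            normalize_per_tile=config.preprocess.normalize_per_tile,
        )

        # ---- train -------------------------------------------------------
        stage = "train"
        tcfg = TrainConfig(
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            lr_scale=config.train.lr_scale,
            holdout_fraction=config.train.holdout_fraction,
            seed=config.seed,
            loss_on_background=config.train.loss_on_background,
        )
        train_ids, holdout_ids = split_holdout(
            manifest, tcfg.holdout_fraction, config.seed
        )
        x, y, m = _arrays_for_slides(manifest, train_ids, base_dir, pre, schedule, True)
        if holdout_ids:
            xh, yh, mh = _arrays_for_slides(manifest, holdout_ids, base_dir, pre, schedule, True)
        else:
            xh = yh = mh = None
        mcfg = linknet.ModelConfig(
            out_channels=schedule.n_channels,
            base_width=config.model.base_width,
            activation_head=config.model.activation_head,
        )
        model, history = train_model(
            x,
            y,
            mcfg,
            tcfg,
            x_holdout=xh,
            y_holdout=yh,
            tissue_masks=m,
            holdout_tissue_masks=mh,
        )
        history.as_frame().to_csv(out_dir / "loss_history.csv", index=False)

        # ---- reference + scoring ----------------------------------------
        stage = "score"
        pms, tms = _probability_masks_for_reference(model, manifest, train_ids, base_dir, pre)
        ref = scoring.fit_quantile_reference(
            pms,
            tms,
            cohort_id="train",
            max_size=config.scoring.reference_max_size,
            seed=config.seed,
        )
        linknet.save_checkpoint(
            out_dir / "model.ckpt",
            model,
            meta={
                "schedule": list(schedule.ages),
                "preprocess": config.preprocess.model_dump(),
                "seed": config.seed,
            },
            arrays={f"ref_channel_{c}": ref.channels[c] for c in range(ref.n_channels)},
        )
        paintings_dir = out_dir / "paintings" if config.scoring.paintings else None
        scores = score_slides(model, manifest, base_dir, pre, ref, paintings_dir)
        scores_path = out_dir / "scores.csv"
        scores.to_csv(scores_path, index=False, float_format="%.10g")

        # ---- stats -------------------------------------------------------
        stage = "stats"
        report: dict = {"n_slides": int(len(scores))}
        by_age = {
            str(age): grp["egps"].to_numpy() for age, grp in scores.groupby("age_months")
        }
        if len(by_age) >= 2 and len(scores) > len(by_age):
            anova = cohort_stats.one_way_anova(by_age)
            report["anova"] = {"F": anova.statistic, "p": anova.p_value, "df": list(anova.df)}
            report["tukey"] = [
                {
                    "pair": list(r.pair),
                    "q": r.statistic,
                    "p_adj": r.p_value,
                    "diff": r.estimate,
                }
                for r in cohort_stats.tukey_hsd(by_age)
            ]
        arms = {t: g["egps"].to_numpy() for t, g in scores.groupby("treatment") if t}
        if set(arms) >= {"control", "treated"}:
            w = cohort_stats.welch_t_test(arms["control"], arms["treated"])
            report["welch_control_vs_treated"] = {
                "t": w.statistic,
                "p": w.p_value,
                "df": w.df[0],
                "mean_difference": w.estimate,
            }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

        # ---- provenance --------------------------------------------------
        (out_dir / "run_log.json").write_text(
            json.dumps(
                {
                    "config_hash": config.config_hash(),
                    "seed": config.seed,
                    "config": config.model_dump(),
                    "n_train_slides": len(train_ids),
                    "n_holdout_slides": len(holdout_ids),
                },
                indent=2,
                sort_keys=True,
            )
        )
    except Exception as exc:
        partial = out_dir / "partial"
        partial.mkdir(exist_ok=True)
        (partial / "failure.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)})
        )
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc
    return {
        "scores": scores_path,
        "checkpoint": out_dir / "model.ckpt",
        "report": out_dir / "report.json",
        "loss_history": out_dir / "loss_history.csv",
        "history": history,
        "scores_frame": scores,
        "model": model,
        "reference": ref,
    }
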