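"""Desk-scale reference experiments.

Self-contained, seeded experiments that exercise the whole pipeline at
the 384-px test frame (6.4 px/cm over the same 60 x 60 cm wall) plus the
statistical recovery simulations.  Each returns plain numbers so that
reports and tests can re-run them from scratch.

The segmentation experiment mirrors the field protocol at desk scale:
10 training images -> 360 tiles, one pass per epoch, Adam at 0.001, then
validation on held-out images by comparing truth and predicted
Depth50/Width50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .phenotype import phenotype_image
from .raster_io import FrameSpec, TEST_FRAME
from .segmenter import (TEST_SCALE_MODEL, TrainConfig, TrainedModel, binarize,
                        build_model, predict_image, train)
from .stats import PhenotypeTable, broad_sense_heritability, oneway_anova, pearson
from .synth import SynthConfig, _image_seed, generate_sample
from .tiling import split_tiles

__all__ = [
    "make_variety_panel",
    "desk_segmentation_experiment",
    "heritability_recovery",
    "anova_type1_rate",
]

#: Per-image depth-law rates span median rooting depths of roughly
#: 5-23 cm, the varietal range the phenotype is meant to resolve.
RATE_RANGE = (0.03, 0.14)

#: Root count per desk-scale image; sparse enough that strokes rarely
#: merge on the 384-px wall.
DESK_N_ROOTS = 12


def make_variety_panel(n_images: int, seed: int, frame: FrameSpec = TEST_FRAME,
                       n_roots: int = DESK_N_ROOTS):
    """Generate ``n_images`` synthetic trenches whose depth-law rates are
    log-spaced over :data:`RATE_RANGE` (shuffled), like a panel of
    varieties with distinct rooting depths.  Returns a list of
    (TrenchImage, RootMask, truth RootDistributionParams)."""
    rates = np.random.default_rng(seed).permutation(
        np.geomspace(*RATE_RANGE, n_images))
    out = []
    for i, rate in enumerate(rates):
        cfg = SynthConfig(
            n_roots=n_roots, seed=_image_seed(seed, i),
            depth_law={"kind": "truncated_exponential", "rate_per_cm": float(rate)})
        out.append(generate_sample(cfg, frame))
    return out


@dataclass
class SegmentationReport:
    heldout_dice: float
    r_depth50: float
    r_width50: float
    truth_depth50_cm: list[float]
    pred_depth50_cm: list[float]
    history: list[dict] = field(repr=False, default_factory=list)
    model: TrainedModel | None = field(repr=False, default=None)


def desk_segmentation_experiment(seed: int, n_train: int = 10, n_val: int = 12,
                                 epochs: int = 20,
                                 frame: FrameSpec = TEST_FRAME) -> SegmentationReport:
    """Train the test-scale network and validate on held-out images.

    Held-out Dice is the micro-aggregate over all validation pixels;
    the correlations compare truth vs. predicted Depth50/Width50 across
    validation images, the desk-scale analogue of validating predicted
    phenotypes against manual tracing.
    """
    tile_px = TEST_SCALE_MODEL.input_px
    train_set = make_variety_panel(n_train, seed, frame)
    val_set = make_variety_panel(n_val, seed + 1000, frame)
    pairs = []
    for img, mask, _ in train_set:
        pairs.extend(zip(split_tiles(img.pixels, tile_px).tiles,
                         split_tiles(mask.pixels, tile_px).tiles))
    net = build_model(TEST_SCALE_MODEL, seed=seed)
    tcfg = TrainConfig(epochs=epochs, batch_size=8, seed=seed)
    trained = train(net, pairs, tcfg, AugmentConfig(seed=seed))

    inter = 0
    sizes = 0
    truth_d, pred_d, truth_w, pred_w = [], [], [], []
    for img, mask, truth in val_set:
        prob = predict_image(trained, img)
        pred = binarize(prob, tcfg.threshold)
        inter += int((pred.astype(bool) & mask.pixels.astype(bool)).sum())
        sizes += int(pred.sum()) + int(mask.pixels.sum())
        params = phenotype_image(pred, frame=frame, hill_column=frame.hill_column_px)
        truth_d.append(truth.depth50_cm)
        pred_d.append(params.depth50_cm)
        truth_w.append(truth.width50_cm)
        pred_w.append(params.width50_cm)
    return SegmentationReport(
        heldout_dice=2.0 * inter / sizes,
        r_depth50=pearson(truth_d, pred_d),
        r_width50=pearson(truth_w, pred_w),
        truth_depth50_cm=truth_d,
        pred_depth50_cm=pred_d,
        history=trained.history,
        model=trained,
    )


def heritability_recovery(n_accessions: int = 60, n_reps: int = 3,
                          v_g: float = 3.0, v_e: float = 1.0,
                          n_draws: int = 200, seed: int = 0) -> dict:
    """Monte-Carlo recovery of H2 from simulated replicated accessions.

    Each draw simulates accession effects ~ N(0, v_g) and replicate
    noise ~ N(0, v_e); analytic H2 = v_g / (v_g + v_e).  Returns the
    mean and spread of the estimates.
    """
    rng = np.random.default_rng((seed, 0x42))
    estimates = []
    for _ in range(n_draws):
        g = rng.normal(0.0, np.sqrt(v_g), n_accessions)
        y = g[:, None] + rng.normal(0.0, np.sqrt(v_e), (n_accessions, n_reps))
        df = pd.DataFrame({
            "accession": np.repeat([f"acc{i}" for i in range(n_accessions)], n_reps),
            "depth50_cm": (y - y.min() + 1.0).ravel(),  # phenotypes are >= 0
            "width50_cm": 0.0,
        })
        res = broad_sense_heritability(PhenotypeTable(df), "depth50_cm")
        estimates.append(res.H2)
    est = np.asarray(estimates)
    return {"mean_H2": float(est.mean()), "sd_H2": float(est.std(ddof=1)),
            "analytic_H2": v_g / (v_g + v_e), "n_draws": n_draws}


def anova_type1_rate(k_groups: int = 7, n_per_group: int = 4, n_reps: int = 1000,
                     alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error calibration of the acquisition-date ANOVA under a
    null where every date group draws from one normal law."""
    rng = np.random.default_rng((seed, 0xA07A))
    rejections = 0
    for _ in range(n_reps):
        groups = [rng.normal(10.0, 2.0, n_per_group) for _ in range(k_groups)]
        _, p = oneway_anova(groups)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_reps, "alpha": alpha, "n_reps": n_reps}
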