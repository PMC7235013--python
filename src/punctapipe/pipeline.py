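"""End-to-end orchestration: stacks in, per-synapse records out.

Order of operations mirrors the intended analysis workflow:

1. median filter + Richardson–Lucy deconvolution (both copies kept);
2. optional four-stage timepoint registration, estimated on the green
   channel's deconvolved data and applied to every channel;
3. voxel classification on the deconvolved baseline green stack,
   26-connected grouping into ellipsoidal ROIs;
4. baseline-red rejection of autofluorescent spots;
5. max-intensity extraction from raw median-filtered data at every
   timepoint, population normalization, photoconversion metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect import (SpotROI, VoxelClassifier, compute_features,
                     segment_spots, train_classifier)
from .phantom import PhantomTruth
from .preprocess import (ProcessedPair, preprocess_volume,
                         subtract_median_background)
from .quantify import (RejectionReport, extract_intensities,
                       normalize_population, photoconversion_metrics,
                       reject_autofluorescent)
from .registration import (RegistrationConfig, TransformChain, apply_transform,
                           register_timepoints)
from .volume import ImageVolume


@dataclass
class PipelineConfig:
    median_radius: int = 1
    rl_iterations: int = 10
    psf_fwhm_um: tuple[float, float, float] = (1.5, 0.35, 0.35)
    feature_scales_um: tuple[float, float, float] = (1.0, 2.0, 4.0)
    n_trees: int = 30
    max_depth: int | None = 12
    n_train_per_class: int = 5000
    probability_threshold: float = 0.5
    min_size_voxels: int = 4
    max_size_voxels: int = 2000
    rejection_k: float = 3.0
    register: bool = False
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    records: pd.DataFrame
    rois: list[SpotROI]
    kept_rois: list[SpotROI]
    rejection: RejectionReport
    classifier: VoxelClassifier
    chain: TransformChain | None = None


def training_labels_from_truth(
    truth: PhantomTruth,
    n_per_class: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Sparse voxel labels emulating a user's brush strokes.

    Spot-class voxels are sampled inside the true synapse and clutter
    spheres (the classifier's job is "puncta vs not"; autofluorescent
    puncta are removed later by the baseline-red filter, exactly as a
    human annotator cannot tell them apart in a single green channel).
    Background voxels are sampled outside a safety dilation of the spots.
    """
    rng = np.random.default_rng(seed)
    # Spot strokes hit the bright cores; background strokes are painted both
    # right next to puncta (the shell just outside the object radius) and in
    # empty regions — mimicking how an annotator teaches the boundary.
    core = truth.synapse_mask(0.6) | truth.clutter_mask(0.6)
    object_extent = truth.synapse_mask(1.0) | truth.clutter_mask(1.0)
    wide = truth.synapse_mask(1.6) | truth.clutter_mask(1.6)
    shell = wide & ~object_extent
    far = ~wide
    labels = np.full(truth.volume_shape, -1, dtype=np.int8)
    for cls, mask, n in ((1, core, n_per_class),
                         (0, shell, n_per_class // 2),
                         (0, far, n_per_class - n_per_class // 2)):
        idx = np.argwhere(mask)
        if len(idx) == 0:
            continue
        take = min(n, len(idx))
        sel = idx[rng.choice(len(idx), size=take, replace=False)]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = cls
    return labels


def run_pipeline(
    stacks: dict[str, ImageVolume],
    config: PipelineConfig | None = None,
    truth: PhantomTruth | None = None,
    classifier: VoxelClassifier | None = None,
    training_labels: np.ndarray | None = None,
    soma_center_um: tuple[float, float, float] | None = None,
) -> PipelineResult:
    """Run the full photoconversion analysis on (G0, R0, G1, R1, ...) stacks.

    A classifier is trained on ``training_labels`` (or labels derived from
    ``truth``) unless a fitted one is passed in.  ``soma_center_um`` adds a
    ``distance_um`` column for ring analyses (defaults to the phantom
    truth's soma).
    """
    config = config or PipelineConfig()
    if "G0" not in stacks or "R0" not in stacks:
        raise ValueError("stacks must contain at least G0 and R0")

    pairs: dict[str, ProcessedPair] = {
        key: preprocess_volume(vol, config.median_radius, config.psf_fwhm_um,
                               config.rl_iterations)
        for key, vol in stacks.items()
    }

    chain = None
    if config.register and "G1" in pairs:
        chain = register_timepoints(pairs["G0"].deconvolved,
                                    pairs["G1"].deconvolved,
                                    config.registration)
        for key in pairs:
            if key.endswith("0"):
                continue
            # cubic interpolation: the extraction statistic is a maximum,
            # which linear resampling would systematically attenuate
            moved = apply_transform(
                chain, [pairs[key].raw_medfilt, pairs[key].deconvolved],
                interpolation="bspline")
            pairs[key] = ProcessedPair(
                raw_medfilt=moved[0].volume, deconvolved=moved[1].volume,
                provenance=pairs[key].provenance + [{"step": "apply_transform"}],
            )

    features = compute_features(pairs["G0"].deconvolved, config.feature_scales_um)
    if classifier is None:
        if training_labels is None:
            if truth is None:
                raise ValueError(
                    "need a classifier, training labels, or phantom truth")
            training_labels = training_labels_from_truth(
                truth, config.n_train_per_class, config.seed)
        classifier = train_classifier(
            features, training_labels, n_trees=config.n_trees,
            max_depth=config.max_depth, seed=config.seed)
    prob = classifier.predict_spot_probability(features)
    rois = segment_spots(prob, stacks["G0"].voxel_size,
                         config.min_size_voxels, config.max_size_voxels,
                         config.probability_threshold)

    # flat-background subtraction keeps the dim red baseline channel from
    # being dominated by the DC offset during population normalization
    quant_vols = {k: subtract_median_background(p.raw_medfilt)
                  for k, p in pairs.items()}
    kept_rois, report = reject_autofluorescent(rois, quant_vols["R0"],
                                               k=config.rejection_k)
    records = extract_intensities(
        rois, quant_vols,
        autofluorescent_ids=set(report.rejected_ids))
    records = normalize_population(records)
    records = photoconversion_metrics(records)

    if soma_center_um is None and truth is not None:
        soma_center_um = truth.soma_center
    if soma_center_um is not None:
        soma = np.asarray(soma_center_um)
        records["distance_um"] = np.linalg.norm(
            records[["z_um", "y_um", "x_um"]].to_numpy() - soma, axis=1)

    return PipelineResult(records=records, rois=rois, kept_rois=kept_rois,
                          rejection=report, classifier=classifier, chain=chain)
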