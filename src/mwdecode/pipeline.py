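"""End-to-end chain from a simulation config to decoding results.

``compute_features`` runs simulation -> mastoid re-reference -> broadband
filter and 256 Hz resampling -> 4-s epochs with baseline correction ->
alpha-band filtering -> group ICA -> 384 bin-power features.
``decode_features`` evaluates the three labeling schemes with the shared
LOPOCV / cross-task protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SCHEMES, DecodingRun, attach_probe_ratings, run_lopocv
from .features import (FeatureMatrix, ICADecomposition, bin_mean_power,
                       component_activations, fit_group_ica)
from .preproc import (EpochSet, alpha_oscillation, broadband_filter_and_resample,
                      design_alpha_fir, epoch_and_baseline, rereference)
from .synth.experiment import SimulationConfig, iter_participants
from .synth.montage import build_montage

logger = logging.getLogger(__name__)

__all__ = ["compute_features", "decode_features", "concat_epochs",
            "preprocess_participant", "PipelineOutput"]


def concat_epochs(parts: "list[EpochSet]") -> EpochSet:
    first = parts[0]
    for p in parts[1:]:
        if p.labels != first.labels or p.times.size != first.times.size:
            raise ValueError("epoch sets are not alignable")
    return EpochSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        times=first.times,
        labels=first.labels,
        metadata=pd.concat([p.metadata for p in parts], ignore_index=True),
        rate=first.rate,
    )


def preprocess_participant(pdata, kernel=None) -> EpochSet:
    """Reference, filter, resample, epoch and alpha-filter one participant."""
    kernel = kernel or design_alpha_fir(256.0)
    rec = rereference(pdata.recording)
    rec = broadband_filter_and_resample(rec)
    events = attach_probe_ratings(
        rec.events, pdata.probes.assign(
            onset_sample=pdata.probes["onset_sample"] // 2
        ),
    )
    epochs = epoch_and_baseline(rec, events)
    return alpha_oscillation(epochs, kernel)


@dataclass
class PipelineOutput:
    features: FeatureMatrix
    decomposition: ICADecomposition
    alpha_epochs: EpochSet | None = None


def compute_features(
    cfg: SimulationConfig,
    seed: int,
    *,
    ica_decim: int = 2,
    keep_epochs: bool = False,
) -> PipelineOutput:
    """Simulate an experiment and reduce it to the 384-column features.

    ``ica_decim`` thins the concatenated time series (every n-th sample)
    for the group ICA estimation only; activations and features always
    use the full-rate epochs.
    """
    montage = build_montage()
    kernel = design_alpha_fir(256.0)
    alpha_parts: list[EpochSet] = []
    for pdata in iter_participants(cfg, seed, montage):
        alpha_parts.append(preprocess_participant(pdata, kernel))
        logger.info("preprocessed %s: %d trials", pdata.participant,
                    alpha_parts[-1].n_trials)
    alpha = concat_epochs(alpha_parts)
    del alpha_parts

    if ica_decim > 1:
        thin = EpochSet(
            data=alpha.data[:, :, ::ica_decim],
            times=alpha.times[::ica_decim],
            labels=alpha.labels,
            metadata=alpha.metadata,
            rate=alpha.rate / ica_decim,
        )
        dec = fit_group_ica(thin, seed=seed)
    else:
        dec = fit_group_ica(alpha, seed=seed)
    activations = component_activations(alpha, dec)
    feats = bin_mean_power(activations)
    return PipelineOutput(
        features=feats, decomposition=dec,
        alpha_epochs=alpha if keep_epochs else None,
    )


def decode_features(
    features: FeatureMatrix,
    seed: int,
    schemes: tuple[str, ...] = SCHEMES,
    *,
    inner_cv: bool = True,
    transfer: bool = True,
) -> dict[str, DecodingRun]:
    """Run the LOPOCV (+ across-task) protocol for each labeling scheme."""
    return {
        scheme: run_lopocv(features, scheme, seed, inner_cv=inner_cv,
                           transfer=transfer)
        for scheme in schemes
    }
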