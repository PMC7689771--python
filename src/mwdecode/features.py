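"""Group ICA over alpha-band oscillations and bin-power classifier features.

One unmixing matrix is estimated from the alpha-band oscillations of all
participants concatenated along time (a group decomposition on the shared
32-channel space).  Component activations are the unmixed single-trial
time courses; instantaneous power is the squared magnitude of their
analytic signal, averaged inside twelve 100-ms bins spanning -600..+600 ms
around stimulus onset: 12 bins x 32 components = 384 features per trial.
Percent-change event-related (de)synchronization traces are provided for
reporting only and never enter the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preproc import EpochSet, analytic_power

__all__ = [
    "ICADecomposition",
    "FeatureMatrix",
    "fit_group_ica",
    "component_activations",
    "bin_mean_power",
    "erd_percent_change",
]

FEATURE_WINDOW_S = (-0.6, 0.6)
BIN_WIDTH_S = 0.1
N_BINS = 12
ERD_BASELINE_S = (-0.6, -0.2)


@dataclass
class ICADecomposition:
    """Square unmixing/mixing pair mapping channels <-> components.

    Components are ordered by descending explained variance of the
    concatenated group signal, and each component's sign is fixed so that
    the largest-magnitude entry of its mixing column is positive.
    """

    unmixing: np.ndarray  # (components, channels)
    mixing: np.ndarray  # (channels, components)
    labels: tuple[str, ...]
    algorithm: str = "fastica-logcosh"
    seed: int | None = None
    n_iter: int | None = None

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def topography(self, component: int) -> np.ndarray:
        """Scalp map of one component (1-based), a mixing-matrix column."""
        return self.mixing[:, component - 1]


@dataclass
class FeatureMatrix:
    """Trials x 384 mean bin powers with a (component, bin) column map."""

    values: np.ndarray  # (trials, components * bins)
    columns: pd.MultiIndex  # levels: component (1-based), bin (1-based)
    bin_edges: np.ndarray  # seconds, len n_bins + 1
    trials: pd.DataFrame  # per-trial metadata, aligned with rows

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column map does not match feature count")
        if len(self.trials) != self.values.shape[0]:
            raise ValueError("trial table does not match feature rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def component_slice(self, component: int) -> np.ndarray:
        """The 12 bin features of one component (1-based)."""
        mask = self.columns.get_level_values("component") == component
        return self.values[:, mask]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


def fit_group_ica(
    alpha_epochs: "list[EpochSet] | EpochSet",
    seed: int,
    n_components: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ICADecomposition:
    """Group ICA on alpha-band oscillations concatenated over participants.

    FastICA with the logcosh (tanh) contrast on the temporally concatenated
    channel x time matrix.  Deterministic given ``seed``.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    import warnings

    if isinstance(alpha_epochs, EpochSet):
        alpha_epochs = [alpha_epochs]
    if not alpha_epochs:
        raise ValueError("no epochs supplied")
    labels = alpha_epochs[0].labels
    mats = []
    for ep in alpha_epochs:
        if ep.labels != labels:
            raise ValueError("all epoch sets must share the channel layout")
        mats.append(ep.data.transpose(1, 0, 2).reshape(len(labels), -1))
    X = np.concatenate(mats, axis=1)  # (channels, time)
    n_comp = n_components or len(labels)
    sv = np.linalg.svd(X - X.mean(axis=1, keepdims=True), compute_uv=False)
    if sv[n_comp - 1] < 1e-10 * sv[0]:
        raise ValueError(
            "rank-deficient input: fewer effective channels than components"
        )
    ica = FastICA(
        n_components=n_comp,
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(X.T)  # (time, components), unit variance
    unmixing = ica.components_
    mixing = np.linalg.pinv(unmixing)

    # order by explained variance of the concatenated signal: with
    # unit-variance sources the contribution of component k is the squared
    # norm of its mixing column times the source variance
    contrib = (mixing**2).sum(axis=0) * S.var(axis=0)
    order = np.argsort(contrib)[::-1]
    unmixing = unmixing[order]
    mixing = mixing[:, order]

    # sign convention: largest-|weight| mixing entry positive
    flip = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    unmixing = unmixing * flip[:, None]
    mixing = mixing * flip[None, :]

    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        labels=labels,
        seed=seed,
        n_iter=getattr(ica, "n_iter_", None),
    )


def component_activations(
    epochs: EpochSet, decomposition: ICADecomposition
) -> EpochSet:
    """Unmix channel epochs into component activations (linear, per sample)."""
    if len(epochs.labels) != decomposition.unmixing.shape[1]:
        raise ValueError("channel count does not match the unmixing matrix")
    act = np.einsum("kc,tcs->tks", decomposition.unmixing, epochs.data)
    comp_labels = tuple(f"IC{k + 1}" for k in range(decomposition.n_components))
    return EpochSet(
        data=act,
        times=epochs.times,
        labels=comp_labels,
        metadata=epochs.metadata.reset_index(drop=True),
        rate=epochs.rate,
    )


def _bin_edges() -> np.ndarray:
    return np.round(
        np.arange(N_BINS + 1) * BIN_WIDTH_S + FEATURE_WINDOW_S[0], 10
    )


def bin_mean_power(activations: EpochSet) -> FeatureMatrix:
    """Mean instantaneous power per 100-ms bin over -600..+600 ms.

    Power is the squared analytic-signal magnitude of each activation;
    columns are component-major, bin-minor.  Raw (non-baseline-corrected)
    power enters the features.
    """
    edges = _bin_edges()
    t = activations.times
    if t[0] > edges[0] or t[-1] < edges[-1] - 1e-9:
        raise ValueError("epoch does not cover the -600..+600 ms window")
    _, power = analytic_power(activations.data)
    n_comp = power.shape[1]
    cols = np.empty((power.shape[0], n_comp, N_BINS))
    for b in range(N_BINS):
        mask = (t >= edges[b]) & (t < edges[b + 1])
        cols[:, :, b] = power[:, :, mask].mean(axis=2)
    values = cols.reshape(power.shape[0], n_comp * N_BINS)
    columns = pd.MultiIndex.from_product(
        [np.arange(1, n_comp + 1), np.arange(1, N_BINS + 1)],
        names=["component", "bin"],
    )
    return FeatureMatrix(
        values=values,
        columns=columns,
        bin_edges=edges,
        trials=activations.metadata.reset_index(drop=True),
    )


def erd_percent_change(
    activations: EpochSet, condition_labels: "pd.Series | np.ndarray"
) -> dict[str, np.ndarray]:
    """Per-condition component power as % change from the -600..-200 ms base.

    For each condition the trial-averaged instantaneous power P(t) is
    expressed as ``100 * (P(t) - Pbase) / Pbase`` with ``Pbase`` the mean
    over the baseline window.  Reporting only; never a classifier input.
    """
    labels = np.asarray(condition_labels)
    if labels.shape[0] != activations.n_trials:
        raise ValueError("one condition label per trial required")
    _, power = analytic_power(activations.data)
    t = activations.times
    bmask = (t >= ERD_BASELINE_S[0]) & (t < ERD_BASELINE_S[1])
    out: dict[str, np.ndarray] = {}
    for cond in pd.unique(labels):
        sel = power[labels == cond]
        if sel.shape[0] == 0:
            raise ValueError(f"no trials for condition {cond!r}")
        mean_p = sel.mean(axis=0)  # (components, samples)
        base = mean_p[:, bmask].mean(axis=1, keepdims=True)
        if np.any(base <= 0):
            raise ValueError("zero baseline power; cannot form percent change")
        out[str(cond)] = 100.0 * (mean_p - base) / base
    return out
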