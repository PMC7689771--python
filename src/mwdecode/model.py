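"""Model/Results interface over the decoding protocol.

``AttentionDecoder`` is constructed from a feature matrix (or directly
from a simulation config) and ``fit()`` runs the leave-one-participant-out
protocol for one or all labeling schemes, returning a ``DecodingResults``
object that carries the per-fold accuracies, the corrected chance levels,
the chance tests and the across-task transfer, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import SCHEMES, DecodingRun
from .features import FeatureMatrix
from .pipeline import compute_features, decode_features
from .synth.experiment import SimulationConfig

__all__ = ["AttentionDecoder", "DecodingResults"]


@dataclass
class DecodingResults:
    """Per-scheme decoding runs with a tabular summary."""

    runs: dict[str, DecodingRun]
    seed: int

    def __getitem__(self, scheme: str) -> DecodingRun:
        return self.runs[scheme]

    @property
    def schemes(self) -> tuple[str, ...]:
        return tuple(self.runs)

    def accuracy_table(self):
        import pandas as pd

        rows = []
        for scheme, run in self.runs.items():
            for report in (run.lopocv, run.inner_cv, run.transfer):
                if report is None:
                    continue
                rows.append(
                    dict(scheme=scheme, validation=report.kind,
                         mean_accuracy=report.mean_accuracy,
                         chance=report.chance, t=report.test.t,
                         p=report.test.p, n_test=report.n_test,
                         sensitivity=report.test.sensitivity,
                         specificity=report.test.specificity)
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.accuracy_table()
        lines = ["Alpha-band decoding summary (seed %d)" % self.seed,
                 "=" * 72]
        for _, r in df.iterrows():
            star = "*" if (np.isfinite(r["p"]) and r["p"] < 0.05
                           and r["mean_accuracy"] > r["chance"]) else " "
            lines.append(
                f"{r['scheme']:>10s}  {r['validation']:<8s} "
                f"acc {100 * r['mean_accuracy']:6.2f}%  "
                f"chance {100 * r['chance']:5.2f}%  "
                f"t={r['t']:6.2f}  p={r['p']:8.4f} {star}"
            )
        lines.append("=" * 72)
        lines.append("* mean accuracy above corrected chance at p < 0.05")
        return "\n".join(lines)

    def plot_accuracies(self, ax=None):
        """Bar chart of mean accuracy per scheme and validation stage."""
        import matplotlib.pyplot as plt

        df = self.accuracy_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        kinds = list(df["validation"].unique())
        width = 0.8 / len(self.runs)
        for i, scheme in enumerate(self.runs):
            sub = df[df["scheme"] == scheme].set_index("validation")
            xs = [kinds.index(k) + i * width for k in sub.index]
            ax.bar(xs, sub["mean_accuracy"], width=width, label=scheme)
            for k in sub.index:
                ax.hlines(sub.loc[k, "chance"], kinds.index(k) - 0.1,
                          kinds.index(k) + 0.8, ls="--", color="0.4", lw=0.8)
        ax.set_xticks([k + 0.3 for k in range(len(kinds))])
        ax.set_xticklabels(kinds)
        ax.set_ylabel("accuracy")
        ax.set_ylim(0.35, 1.0)
        ax.legend()
        return ax


@dataclass
class AttentionDecoder:
    """Cross-validated SVM decoding of attentional state from alpha power.

    Build from an existing :class:`FeatureMatrix` or via
    :meth:`from_simulation`; ``fit`` evaluates the requested labeling
    schemes (task demand, vigilance, self-reported mind-wandering) under
    the leave-one-participant-out protocol with across-task transfer to
    the SART.
    """

    features: FeatureMatrix
    inner_cv: bool = True
    transfer: bool = True
    _extras: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_simulation(
        cls, cfg: SimulationConfig, seed: int, **pipeline_kwargs
    ) -> "AttentionDecoder":
        out = compute_features(cfg, seed, **pipeline_kwargs)
        obj = cls(features=out.features)
        obj._extras["decomposition"] = out.decomposition
        obj._extras["alpha_epochs"] = out.alpha_epochs
        return obj

    @property
    def decomposition(self):
        return self._extras.get("decomposition")

    def fit(self, seed: int = 0,
            schemes: tuple[str, ...] = SCHEMES) -> DecodingResults:
        runs = decode_features(self.features, seed, schemes,
                               inner_cv=self.inner_cv, transfer=self.transfer)
        return DecodingResults(runs=runs, seed=seed)
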