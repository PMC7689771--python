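"""Per-component predictiveness testing and the exclusive/shared partition.

Each independent component's 12 bin-power features are used alone to
train the classifier under the identical leave-one-participant-out
protocol (gamma becomes 1/12), its fold accuracies are tested one-sided
against the corrected chance level, and the significant components of the
three schemes are partitioned into the seven regions of a three-set Venn
diagram.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SCHEMES, corrected_chance_level, run_lopocv
from .features import FeatureMatrix, N_BINS

__all__ = [
    "per_component_accuracy",
    "component_accuracy_table",
    "significant_components",
    "partition_components",
    "VENN_REGIONS",
]

VENN_REGIONS = (
    "demand_only",
    "vigilance_only",
    "selfreport_only",
    "demand_vigilance",
    "demand_selfreport",
    "vigilance_selfreport",
    "all_three",
)


def _component_columns(dataset: FeatureMatrix, component: int) -> np.ndarray:
    mask = dataset.columns.get_level_values("component") == component
    cols = np.flatnonzero(mask)
    if cols.size != N_BINS:
        raise ValueError(f"component {component} not present in the features")
    return cols


def per_component_accuracy(
    dataset: FeatureMatrix, scheme: str, component_id: int, seed: int
) -> np.ndarray:
    """LOPOCV fold accuracies using one component's 12 features only."""
    cols = _component_columns(dataset, component_id)
    run = run_lopocv(dataset, scheme, seed, inner_cv=False, transfer=False,
                     feature_columns=cols)
    return run.lopocv.accuracies


def component_accuracy_table(
    dataset: FeatureMatrix,
    seed: int,
    schemes: tuple[str, ...] = SCHEMES,
    components: "list[int] | None" = None,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Accuracy, CI and chance test for every (component, scheme) pair.

    Columns: component, scheme, mean_acc, ci_lo, ci_hi, t, p, significant.
    One-sided ("greater") tests by default: below-chance prediction is not
    meaningful for feature importance.
    """
    if components is None:
        components = sorted(
            set(dataset.columns.get_level_values("component"))
        )
    rows = []
    for scheme in schemes:
        for comp in components:
            acc = per_component_accuracy(dataset, scheme, comp, seed)
            run_chance = corrected_chance_level(_n_test(dataset, scheme), alpha)
            mean = float(acc.mean())
            if acc.size > 1 and acc.std(ddof=1) > 0:
                res = stats.ttest_1samp(acc, run_chance,
                                        alternative=alternative)
                t, p = float(res.statistic), float(res.pvalue)
                half = stats.t.ppf(0.975, acc.size - 1) * acc.std(ddof=1) \
                    / np.sqrt(acc.size)
            else:
                t = 0.0 if np.isclose(mean, run_chance) else np.inf * np.sign(
                    mean - run_chance)
                p = 1.0 if np.isclose(mean, run_chance) else np.nan
                half = 0.0
            rows.append(
                dict(component=comp, scheme=scheme, mean_acc=mean,
                     ci_lo=mean - half, ci_hi=mean + half, t=t, p=p,
                     n_folds=acc.size, significant=bool(p < alpha))
            )
    return pd.DataFrame(rows)


def _n_test(dataset: FeatureMatrix, scheme: str) -> int:
    from .classify import assign_labels

    return len(assign_labels(dataset.trials, scheme, task="VS"))


def significant_components(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
) -> dict[str, set[int]]:
    """Components whose chance test clears ``alpha``, per scheme.

    ``correction`` may be None (default, matching uncorrected practice),
    'bonferroni' or 'fdr' (Benjamini-Hochberg).
    """
    out: dict[str, set[int]] = {}
    for scheme, grp in table.groupby("scheme"):
        p = grp["p"].to_numpy(dtype=float)
        comps = grp["component"].to_numpy()
        ok = np.isfinite(p)
        if correction is None:
            sig = (p < alpha) & ok
        elif correction == "bonferroni":
            sig = (p * ok.sum() < alpha) & ok
        elif correction == "fdr":
            sig = np.zeros_like(ok)
            if ok.any():
                pv = p[ok]
                order = np.argsort(pv)
                m = pv.size
                thresh = alpha * (np.arange(1, m + 1)) / m
                passed = pv[order] <= thresh
                k = np.flatnonzero(passed).max() + 1 if passed.any() else 0
                sel = np.zeros(m, dtype=bool)
                sel[order[:k]] = True
                sig[ok] = sel
        else:
            raise ValueError(f"unknown correction {correction!r}")
        out[str(scheme)] = set(int(c) for c in comps[sig])
    for scheme in SCHEMES:
        out.setdefault(scheme, set())
    return out


def partition_components(sets: dict[str, set[int]]) -> dict[str, set[int]]:
    """Seven-region Venn partition of the three per-scheme component sets.

    Empty regions are listed explicitly.
    """
    d = set(sets.get("demand", set()))
    v = set(sets.get("vigilance", set()))
    s = set(sets.get("selfreport", set()))
    return {
        "demand_only": d - v - s,
        "vigilance_only": v - d - s,
        "selfreport_only": s - d - v,
        "demand_vigilance": (d & v) - s,
        "demand_selfreport": (d & s) - v,
        "vigilance_selfreport": (v & s) - d,
        "all_three": d & v & s,
    }
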