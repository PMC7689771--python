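"""Dipolar alpha sources and their state-dependent modulation.

Each synthetic source is an equivalent current dipole inside the brain
shell that oscillates in the alpha range.  Its amplitude is multiplied,
in a window after each stimulus onset, by a factor that depends on the
latent state of the trial (task demand, vigilance, attention): values
below 1 express event-related desynchronization.  A source whose
multiplier map is empty (or all 1.0) is a null source — label-independent
background alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..dipole import HeadModel, potential_at_electrodes
from .montage import SensorMontage

__all__ = [
    "SourceSpec",
    "simulate_sources",
    "forward_project",
    "source_topography",
]

#: latent factors and their levels; the first level of each pair is the
#: "on" state (high demand / high vigilance / on task)
FACTOR_LEVELS = {
    "demand": ("high", "low"),
    "vigilance": ("high", "low"),
    "attention": ("on_task", "mind_wandering"),
    "task": ("VS", "SART"),
}


@dataclass(frozen=True)
class SourceSpec:
    """One oscillating dipole and its condition-dependent amplitude map.

    ``baseline_amp`` is the pre-stimulus peak scalp amplitude (microvolts)
    of the source at its best electrode; ``modulation`` maps latent factor
    -> level -> post-stimulus amplitude multiplier (all > 0; multiplicative
    across factors; a factor missing from the trial state contributes 1).
    """

    name: str
    position: tuple[float, float, float]
    orientation: tuple[float, float, float]
    center_freq: float
    baseline_amp: float
    modulation: "dict[str, dict[str, float]]" = field(default_factory=dict)

    def __post_init__(self) -> None:
        ori = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(ori)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("orientation must be a unit vector")
        if not 8.5 <= self.center_freq <= 12.0:
            raise ValueError("center frequency must lie within 8.5-12 Hz")
        for key, levels in self.modulation.items():
            factor, _, scope = key.partition("@")
            if factor not in FACTOR_LEVELS:
                raise ValueError(f"unknown latent factor {factor!r}")
            if scope and scope not in FACTOR_LEVELS["task"]:
                raise ValueError(f"unknown task scope {scope!r}")
            if any(m <= 0 for m in levels.values()):
                raise ValueError("amplitude multipliers must be positive")

    def multiplier(self, state: "dict[str, str]") -> float:
        """Post-stimulus amplitude multiplier for one trial's latent state.

        A modulation key may be scoped to one task ("attention@SART"
        applies only on SART trials); unscoped keys apply in every task.
        """
        m = 1.0
        for key, levels in self.modulation.items():
            factor, _, scope = key.partition("@")
            if scope and state.get("task") != scope:
                continue
            level = state.get(factor)
            if level is not None:
                m *= levels.get(level, 1.0)
        return m

    @property
    def is_null(self) -> bool:
        return all(
            np.isclose(m, 1.0)
            for levels in self.modulation.values()
            for m in levels.values()
        )


def _validated(spec: SourceSpec, model: HeadModel) -> SourceSpec:
    pos = np.asarray(spec.position)
    if np.linalg.norm(pos) >= model.brain_radius:
        raise ValueError(
            f"source {spec.name!r} lies outside the brain shell"
        )
    return spec


_MIRROR = (-1.0, 1.0, 1.0)


def _mirrored(name: str, spec: SourceSpec) -> SourceSpec:
    return replace(
        spec,
        name=name,
        position=tuple(m * p for m, p in zip(_MIRROR, spec.position)),
        orientation=tuple(m * o for m, o in zip(_MIRROR, spec.orientation)),
    )


def simulate_sources(
    layout: str = "disjoint",
    seed: int = 0,
    model: HeadModel | None = None,
    attention_erd: float = 0.50,
    freq_jitter: float = 0.25,
) -> list[SourceSpec]:
    """Build the default seeded source set for one simulated experiment.

    ``layout='disjoint'`` gives two demand-modulated posterior sources,
    one deep vigilance source, one lateral temporal attention source and
    two unmodulated background alpha generators — the attention source is
    disjoint from the demand/vigilance ones.  ``layout='shared'`` adds a
    midline parietal source modulated by all three factors in the same
    direction.  ``attention_erd`` is the on-task amplitude multiplier of
    the attention source (its mind-wandering multiplier stays at 1), the
    knob used for effect-injection studies.  Center frequencies get a
    small seeded jitter; the list is reproducible given the seed.
    """
    model = model or HeadModel()
    rng = np.random.default_rng(seed)

    attention_src = SourceSpec(
        "attention_temporal_L", (-0.060, -0.020, 0.005),
        tuple(_unit((-0.9, -0.2, 0.4))), 11.0, 9.0,
        {"attention": {"on_task": attention_erd, "mind_wandering": 1.0}},
    )
    background_l = SourceSpec(
        "background_occipital_L", (-0.020, -0.063, 0.010),
        tuple(_unit((-0.2, -0.9, 0.4))), 10.5, 5.0, {},
    )
    background = [background_l, _mirrored("background_occipital_R",
                                          background_l)]

    if layout == "disjoint":
        demand_l = SourceSpec(
            "demand_parietal_L", (-0.025, -0.055, 0.045),
            tuple(_unit((-0.3, -0.7, 0.65))), 10.0, 7.0,
            {"demand": {"high": 0.55, "low": 0.90}, "task": {"SART": 0.70}},
        )
        specs = [
            demand_l,
            _mirrored("demand_parietal_R", demand_l),
            SourceSpec(
                "vigilance_deep", (0.0, -0.020, -0.030),
                (0.0, 0.0, 1.0), 9.5, 6.0,
                {"vigilance": {"high": 0.60, "low": 0.95}},
            ),
            attention_src,
            *background,
        ]
    elif layout == "shared":
        # the demand and vigilance generators are shared across tasks:
        # during visual search they are driven by demand / vigilance,
        # during the SART the same sources are driven by momentary
        # attention at matching contrast ("on" states suppress alpha)
        shared_l = SourceSpec(
            "shared_parietal_L", (-0.025, -0.055, 0.045),
            tuple(_unit((-0.3, -0.7, 0.65))), 10.0, 7.0,
            {
                "demand": {"high": 0.55, "low": 0.90},
                "attention@SART": {"on_task": 0.55, "mind_wandering": 0.90},
            },
        )
        shared_deep = SourceSpec(
            "shared_deep", (0.0, -0.020, -0.030),
            (0.0, 0.0, 1.0), 9.5, 6.0,
            {
                "vigilance@VS": {"high": 0.60, "low": 0.95},
                "attention@SART": {"on_task": 0.60, "mind_wandering": 0.95},
            },
        )
        specs = [
            shared_l,
            _mirrored("shared_parietal_R", shared_l),
            shared_deep,
            attention_src,
            *background,
        ]
    else:
        raise ValueError(f"unknown source layout {layout!r}")

    jitter = rng.uniform(-freq_jitter, freq_jitter, size=len(specs))
    specs = [
        replace(s, center_freq=float(np.clip(s.center_freq + dj, 8.5, 12.0)))
        for s, dj in zip(specs, jitter)
    ]
    return [_validated(s, model) for s in specs]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def source_topography(
    spec: SourceSpec, model: HeadModel, montage: SensorMontage
) -> np.ndarray:
    """Scalp pattern of a source, normalized to unit peak over the
    analysis (non-mastoid) channels."""
    pos = np.asarray(spec.position, dtype=float)
    mom = np.asarray(spec.orientation, dtype=float)
    v = potential_at_electrodes(pos, mom, model, montage.positions)
    analysis = [i for i, l in enumerate(montage.labels)
                if l not in montage.reference_labels]
    peak = np.abs(v[analysis]).max()
    if peak == 0:
        raise ValueError(f"source {spec.name!r} projects no scalp signal")
    return v / peak


def forward_project(
    sources: "list[SourceSpec]",
    model: HeadModel,
    montage: SensorMontage,
    timecourses: np.ndarray,
) -> np.ndarray:
    """Superpose per-source scalp projections: channels x samples.

    ``timecourses`` is (n_sources, n_samples) in source units; each
    source contributes its unit-peak topography times its timecourse, so
    the output is exactly linear and additive in the timecourses.
    """
    timecourses = np.atleast_2d(timecourses)
    if timecourses.shape[0] != len(sources):
        raise ValueError("one timecourse per source required")
    out = np.zeros((montage.n_channels, timecourses.shape[1]))
    for spec, tc in zip(sources, timecourses):
        out += np.outer(source_topography(spec, model, montage), tc)
    return out
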