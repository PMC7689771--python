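"""Seeded synthetic experiments: schedules, latent states, ratings and EEG.

One simulated session realizes the reference design: a visual search task
whose blocks alternate between counting (high demand) and non-counting
(low demand) conditions in A-B-A-B session order, followed by a
sustained-attention-to-response task (SART) of shuffled digit blocks with
a rare NOGO digit; a thought probe ends every block and is rated on an
integer -5..+5 scale generated from the block's latent attention state
through a noisy monotone link.  EEG is the forward projection of
state-modulated dipolar alpha sources plus 1/f background and white
sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..dipole import HeadModel
from ..preproc import ContinuousRecording
from .montage import SensorMontage, build_montage
from .sources import SourceSpec, forward_project, simulate_sources

__all__ = [
    "ExperimentPlan",
    "SimulationConfig",
    "ParticipantData",
    "generate_schedule",
    "generate_participant",
    "iter_participants",
    "generate_experiment",
]

NOGO_DIGIT = 3


@dataclass(frozen=True)
class ExperimentPlan:
    """Trial counts and timing of one session (defaults match the design:
    21 trials x 10 blocks per visual-search condition, 12 SART blocks of
    2-7 shuffled repetitions of the nine digits, 512 Hz recording)."""

    trials_per_block: int = 21
    blocks_per_condition: int = 10
    sart_blocks: int = 12
    sart_rep_range: tuple[int, int] = (2, 7)
    sample_rate: float = 512.0
    fixation_range: tuple[float, float] = (0.5, 1.5)
    instruction_s: float = 2.0
    panel_s: float = 4.0
    iti_range: tuple[float, float] = (0.5, 1.5)
    sart_stim_s: float = 0.25
    sart_blank_s: float = 1.75
    probe_s: float = 4.0
    rt_median: "dict[str, float]" = field(
        default_factory=lambda: {"counting": 0.65, "noncounting": 0.48}
    )
    rt_sigma: float = 0.30

    def __post_init__(self) -> None:
        durations = (
            self.instruction_s, self.panel_s, self.sart_stim_s,
            self.sart_blank_s, self.probe_s, *self.fixation_range,
            *self.iti_range,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be positive")
        if self.sart_rep_range[0] < 1 or self.sart_rep_range[1] < self.sart_rep_range[0]:
            raise ValueError("invalid SART repetition range")

    def session_conditions(self, participant_index: int) -> list[str]:
        """Block condition sequence in A-B-A-B / B-A-B-A session order,
        counterbalanced by participant index."""
        b = self.blocks_per_condition
        first, second = ("counting", "noncounting")
        if participant_index % 2:
            first, second = second, first
        sizes = [(b + 1) // 2, (b + 1) // 2, b // 2, b // 2]
        order = [first, second, first, second]
        out: list[str] = []
        for cond, size in zip(order, sizes):
            out.extend([cond] * size)
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic experiment."""

    n_participants: int = 30
    plan: ExperimentPlan = field(default_factory=ExperimentPlan)
    source_layout: str = "disjoint"
    sources: "tuple[SourceSpec, ...] | None" = None
    mw_base_rate: float = 0.35
    balanced_attention: bool = True
    rating_gain: float = 2.5
    rating_sigma: float = 1.5
    pink_noise_rms: float = 8.0
    white_noise_rms: float = 2.0
    blink_rate_per_min: float = 0.0
    attention_erd: float = 0.50
    amp_fluctuation: float = 0.25
    head_model: HeadModel = field(default_factory=HeadModel)

    @classmethod
    def reduced(cls, layout: str = "disjoint", n_participants: int = 6,
                **kwargs) -> "SimulationConfig":
        """Desk-scale configuration: 6 participants, 60 visual-search
        trials in 10 blocks, and 12 single-repetition SART blocks (many
        short blocks keep the probe count up, so block-level attentional
        states average out)."""
        plan = ExperimentPlan(trials_per_block=3, blocks_per_condition=10,
                              sart_blocks=12, sart_rep_range=(1, 1))
        return cls(n_participants=n_participants, plan=plan,
                   source_layout=layout, **kwargs)


@dataclass
class ParticipantData:
    participant: str
    recording: ContinuousRecording
    events: pd.DataFrame  # stimulus rows, one per trial
    probes: pd.DataFrame  # one per block, with rating
    truth: pd.DataFrame  # per-trial latent state


def _rating_from_state(attention: str, cfg: SimulationConfig,
                       rng: np.random.Generator) -> int:
    sign = 1.0 if attention == "on_task" else -1.0
    r = cfg.rating_gain * sign + rng.normal(0.0, cfg.rating_sigma)
    return int(np.clip(np.rint(r), -5, 5))


def _block_attention(rng: np.random.Generator, cells: list,
                     cfg: SimulationConfig) -> np.ndarray:
    """Latent attention state per block.

    With ``balanced_attention`` the mind-wandering blocks (a fixed
    round(rate * n) of them) are spread as evenly as possible over the
    design cells (condition x half), so the attention latent is
    independent of demand and time-on-task by construction and the
    disjoint simulation carries a true null; otherwise blocks draw
    i.i.d. Bernoulli(rate).
    """
    n = len(cells)
    if not cfg.balanced_attention:
        return rng.random(n) < cfg.mw_base_rate
    n_mw = int(round(cfg.mw_base_rate * n))
    by_cell: dict = {}
    for i, cell in enumerate(cells):
        by_cell.setdefault(cell, []).append(i)
    order = list(by_cell)
    order = [order[i] for i in rng.permutation(len(order))]
    counts = {c: 0 for c in order}
    for k in range(n_mw):
        counts[order[k % len(order)]] += 1
    mw = np.zeros(n, dtype=bool)
    for cell, idxs in by_cell.items():
        take = min(counts[cell], len(idxs))
        sel = rng.choice(idxs, size=take, replace=False)
        mw[sel] = True
    return mw


def generate_schedule(
    cfg: SimulationConfig, participant_index: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-accurate stimulus events and probe ratings for one session.

    Returns ``(events, probes)``.  Events carry the latent state of every
    trial (demand, attention; the vigilance half is chronological and
    added afterwards).  The SART NOGO digit appears exactly once per nine
    trials by construction (shuffled repetitions of the digits 1-9).
    """
    plan = cfg.plan
    fs = plan.sample_rate
    part = f"P{participant_index:02d}"
    t = 0.0
    ev_rows, probe_rows = [], []

    def u(lo_hi: tuple[float, float]) -> float:
        return float(rng.uniform(*lo_hi))

    conditions = plan.session_conditions(participant_index)
    n_vs = len(conditions)
    vs_cells = [(c, i < n_vs / 2) for i, c in enumerate(conditions)]
    vs_mw = _block_attention(rng, vs_cells, cfg)

    trial_counter = 0
    for block, cond in enumerate(conditions, 1):
        attention = "mind_wandering" if vs_mw[block - 1] else "on_task"
        for trial in range(1, plan.trials_per_block + 1):
            t += u(plan.fixation_range)
            if cond == "counting":
                t += plan.instruction_s
            onset = int(round(t * fs))
            ev_rows.append(
                dict(participant=part, task="VS", condition=cond, block=block,
                     trial=trial_counter, onset_sample=onset,
                     demand="high" if cond == "counting" else "low",
                     attention=attention)
            )
            trial_counter += 1
            t += plan.panel_s
            t += float(rng.lognormal(np.log(plan.rt_median[cond]),
                                     plan.rt_sigma))
            t += u(plan.iti_range)
        probe_rows.append(
            dict(participant=part, task="VS", block=block,
                 onset_sample=int(round(t * fs)),
                 rating=_rating_from_state(attention, cfg, rng),
                 attention=attention)
        )
        t += plan.probe_s

    sart_cells = [i < plan.sart_blocks / 2 for i in range(plan.sart_blocks)]
    sart_mw = _block_attention(rng, sart_cells, cfg)

    trial_counter = 0
    for block in range(1, plan.sart_blocks + 1):
        attention = "mind_wandering" if sart_mw[block - 1] else "on_task"
        reps = int(rng.integers(plan.sart_rep_range[0],
                                plan.sart_rep_range[1] + 1))
        digits = np.concatenate(
            [rng.permutation(np.arange(1, 10)) for _ in range(reps)]
        )
        for trial, digit in enumerate(digits, 1):
            t += u(plan.fixation_range)
            onset = int(round(t * fs))
            ev_rows.append(
                dict(participant=part, task="SART", condition="sart",
                     block=block, trial=trial_counter, onset_sample=onset,
                     demand=None, attention=attention, digit=int(digit),
                     nogo=bool(digit == NOGO_DIGIT))
            )
            trial_counter += 1
            t += plan.sart_stim_s + plan.sart_blank_s
        probe_rows.append(
            dict(participant=part, task="SART", block=block,
                 onset_sample=int(round(t * fs)),
                 rating=_rating_from_state(attention, cfg, rng),
                 attention=attention)
        )
        t += plan.probe_s

    events = pd.DataFrame(ev_rows)
    # chronological median split per task = the vigilance latent
    for task, grp in events.groupby("task"):
        half = grp["trial"].to_numpy() >= len(grp) / 2.0
        events.loc[grp.index, "vigilance"] = np.where(half, "low", "high")
    return events, pd.DataFrame(probe_rows)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, rms: float) -> np.ndarray:
    """1/f-power background via spectral shaping of white noise."""
    from scipy.fft import next_fast_len

    nf = next_fast_len(n_samples)
    freqs = np.fft.rfftfreq(nf, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    for c in range(n_channels):
        spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
        x = np.fft.irfft(spec * shape, n=nf)[:n_samples]
        x *= rms / x.std()
        out[c] = x
    return out


def _smooth_fluctuation(rng: np.random.Generator, n_samples: int, fs: float,
                        cutoff: float = 0.3) -> np.ndarray:
    """Slow unit-variance amplitude fluctuation (low-pass white noise)."""
    from scipy.fft import next_fast_len

    nf = next_fast_len(n_samples)
    freqs = np.fft.rfftfreq(nf, 1.0 / fs)
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    spec[freqs > cutoff] = 0.0
    x = np.fft.irfft(spec, n=nf)[:n_samples]
    sd = x.std()
    return x / sd if sd > 0 else x


def _source_timecourse(
    spec: SourceSpec,
    events: pd.DataFrame,
    n_samples: int,
    fs: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mod_window_s: float = 1.2,
    ramp_s: float = 0.1,
) -> np.ndarray:
    """Amplitude-modulated alpha oscillation of one source."""
    envelope = np.ones(n_samples)
    ramp_n = int(round(ramp_s * fs))
    win_n = int(round(mod_window_s * fs))
    ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ramp_n)))
    for _, ev in events.iterrows():
        state = {
            f: ev[f] for f in ("demand", "vigilance", "attention", "task")
            if f in ev and isinstance(ev[f], str)
        }
        m = spec.multiplier(state)
        if np.isclose(m, 1.0):
            continue
        s0 = int(ev["onset_sample"])
        s1 = min(s0 + win_n, n_samples)
        if s0 >= n_samples:
            continue
        seg = np.full(s1 - s0, m)
        k = min(ramp_n, seg.size)
        seg[:k] = 1.0 + (m - 1.0) * ramp[:k]
        envelope[s0:s1] = seg
        f1 = min(s1 + ramp_n, n_samples)
        if f1 > s1:
            envelope[s1:f1] = m + (1.0 - m) * ramp[: f1 - s1]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tt = np.arange(n_samples) / fs
    osc = np.sin(2.0 * np.pi * spec.center_freq * tt + phase)
    if cfg.amp_fluctuation > 0:
        envelope = envelope * np.clip(
            1.0 + cfg.amp_fluctuation * _smooth_fluctuation(rng, n_samples, fs),
            0.1, None,
        )
    return spec.baseline_amp * envelope * osc


def _blinks(rng: np.random.Generator, montage: SensorMontage, n_samples: int,
            fs: float, rate_per_min: float) -> np.ndarray:
    """Optional stereotyped blink transients with a frontal gradient."""
    out = np.zeros((montage.n_channels, n_samples), dtype=np.float32)
    n_blinks = rng.poisson(rate_per_min * n_samples / fs / 60.0)
    if n_blinks == 0:
        return out
    width = int(0.2 * fs)
    t = np.arange(-width, width)
    wave = 80.0 * np.exp(-0.5 * (t / (0.06 * fs)) ** 2)
    y = montage.positions[:, 1]
    z = montage.positions[:, 2]
    topo = np.clip((y / montage.radius) + 0.3 * (z / montage.radius), 0, None)
    for s in rng.integers(width, n_samples - width, size=n_blinks):
        out[:, s - width:s + width] += np.outer(topo, wave)
    return out


def generate_participant(
    cfg: SimulationConfig,
    participant_index: int,
    seed_seq: np.random.SeedSequence,
    montage: SensorMontage | None = None,
) -> ParticipantData:
    """Simulate one participant's full session (schedule + EEG)."""
    montage = montage or build_montage()
    rng = np.random.default_rng(seed_seq)
    events, probes = generate_schedule(cfg, participant_index, rng)
    if cfg.sources is None:
        raise ValueError(
            "resolve the source set first (see iter_participants)"
        )
    sources = list(cfg.sources)
    fs = cfg.plan.sample_rate
    last = max(events["onset_sample"].max(), probes["onset_sample"].max())
    n_samples = int(last + 5 * fs)

    tcs = np.stack([
        _source_timecourse(s, events, n_samples, fs, cfg, rng)
        for s in sources
    ])
    data = forward_project(sources, cfg.head_model, montage, tcs)
    data = data.astype(np.float32)
    data += _pink_noise(rng, montage.n_channels, n_samples, fs,
                        cfg.pink_noise_rms)
    if cfg.white_noise_rms > 0:
        data += rng.normal(0.0, cfg.white_noise_rms,
                           size=data.shape).astype(np.float32)
    if cfg.blink_rate_per_min > 0:
        data += _blinks(rng, montage, n_samples, fs, cfg.blink_rate_per_min)

    part = f"P{participant_index:02d}"
    rec = ContinuousRecording(
        rate=fs, data=data, labels=montage.labels, events=events,
        participant=part,
    )
    truth = events[
        ["participant", "task", "block", "trial", "demand", "vigilance",
         "attention"]
    ].copy()
    return ParticipantData(participant=part, recording=rec, events=events,
                           probes=probes, truth=truth)


def iter_participants(cfg: SimulationConfig, seed: int,
                      montage: SensorMontage | None = None):
    """Yield participants one at a time (seeded, memory-friendly)."""
    if seed is None:
        raise ValueError("a seed is mandatory; simulations must reproduce")
    montage = montage or build_montage()
    if cfg.sources is None:
        from dataclasses import replace as _replace

        cfg = _replace(
            cfg,
            sources=tuple(
                simulate_sources(cfg.source_layout, seed=seed,
                                 model=cfg.head_model,
                                 attention_erd=cfg.attention_erd)
            ),
        )
    children = np.random.SeedSequence(seed).spawn(cfg.n_participants)
    for i, child in enumerate(children):
        yield generate_participant(cfg, i, child, montage)


def generate_experiment(
    cfg: SimulationConfig, seed: int, montage: SensorMontage | None = None
) -> list[ParticipantData]:
    """Materialize the whole synthetic experiment (all participants)."""
    return list(iter_participants(cfg, seed, montage))
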