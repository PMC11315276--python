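"""Synthetic EEG/LFP with planted aperiodic, oscillatory, state and group structure.

Every downstream stage of the pipeline is validated against recordings in
which the ground truth is known exactly: the aperiodic background follows
log10 P(f) = b − χ·log10 f with a chosen exponent χ and offset b per
vigilance state; state-dependent narrowband oscillations are added as
Gaussian-windowed sinusoid bursts; the state sequence is a semi-Markov
chain with geometric dwell times; amplitude artifacts are large biphasic
transients; and cohorts plant group/sex effect structure on top — including
a "masking" preset in which groups differ within every state but occupy
states so differently that their state-pooled means coincide exactly.

Colored noise is synthesised by spectral shaping: white Gaussian noise is
transformed to the frequency domain, its amplitude multiplied by
f^(−χ/2) (DC zeroed), and transformed back, which hits the target
spectrum exactly in expectation at O(n log n) cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import Channel, Recording
from .score import Hypnogram

__all__ = [
    "StateSpec",
    "GroupSpec",
    "CohortDesign",
    "generate_aperiodic_noise",
    "generate_state_sequence",
    "synthesize_recording",
    "generate_cohort",
    "simulate_exponent_table",
    "mouse_state_specs",
    "human_state_specs",
    "ordering_subject_specs",
    "masking_design",
]

#: defining band of each active state (Hz); oscillation centers must stay inside
_STATE_BANDS = {"a1": (0.2, 3.0), "a2": (3.2, 6.0), "a3": (6.2, 12.0)}


@dataclass(frozen=True)
class StateSpec:
    """Planted spectral ground truth for one vigilance state.

    ``exponent`` and ``offset`` are χ and b of the aperiodic model
    log10 P(f) = b − χ·log10 f (b in log10(µV²/Hz)).  ``oscillations``
    lists (center_hz, amplitude_rel, bandwidth_hz) narrowband components;
    amplitude_rel scales the burst against the SD of the state's aperiodic
    background.  ``emg_level`` sets the relative EMG power for the state.
    """

    name: str
    exponent: float
    offset: float = 0.0
    oscillations: tuple[tuple[float, float, float], ...] = ()
    emg_level: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("a1", "a2", "a3", "rem", "nrem"):
            raise ValueError(f"unknown state name {self.name!r}")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.emg_level < 0:
            raise ValueError("emg_level must be >= 0")
        for c, _a, bw in self.oscillations:
            if bw <= 0:
                raise ValueError("oscillation bandwidth must be > 0")
            if not (0.2 <= c <= 30.0):
                raise ValueError("oscillation center must lie in 0.2-30 Hz")
        if self.name in _STATE_BANDS and self.oscillations:
            lo, hi = _STATE_BANDS[self.name]
            c = max(self.oscillations, key=lambda o: o[1])[0]
            if not (lo <= c <= hi):
                raise ValueError(
                    f"dominant oscillation of {self.name} must lie in {lo}-{hi} Hz"
                )


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a label, an exponent shift per state, and optionally
    its own state-occupancy mix (the lever that creates masking)."""

    name: str
    exponent_shift: float | dict[str, float] = 0.0
    state_mix: dict[str, float] | None = None

    def shift_for(self, state: str) -> float:
        if isinstance(self.exponent_shift, dict):
            return self.exponent_shift.get(state, 0.0)
        return float(self.exponent_shift)


@dataclass
class CohortDesign:
    """Full design of a synthetic cohort.

    ``state_mix`` is the default occupancy-probability row (groups may
    override); ``subject_sd`` is the between-subject SD of the exponent
    (applied as one offset per subject, common to all states);
    ``measurement_sd`` the per-(subject, state) exponent noise used by
    :func:`simulate_exponent_table`; ``sex_effect`` an exponent shift
    applied to female subjects in every state.
    """

    states: list[StateSpec]
    groups: list[GroupSpec]
    state_mix: dict[str, float]
    n_per_group: int = 8
    sex_ratio: float = 0.5
    state_dwell_s: float = 10.0
    duration_s: float = 600.0
    fs: float = 250.0
    n_eeg: int = 1
    artifact_rate: float = 0.5
    subject_sd: float = 0.08
    measurement_sd: float = 0.02
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.fs <= 2 * 70.0:
            raise ValueError("fs must exceed 2 x 70 Hz")
        names = {s.name for s in self.states}
        for mix in [self.state_mix] + [g.state_mix for g in self.groups if g.state_mix]:
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("state_mix must sum to 1")
            if set(mix) - names:
                raise ValueError("state_mix refers to unknown states")

    def mix_for(self, group: GroupSpec) -> dict[str, float]:
        return group.state_mix if group.state_mix is not None else self.state_mix

    def state_by_name(self, name: str) -> StateSpec:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)


def generate_aperiodic_noise(
    n_samples: int,
    fs: float,
    exponent: float,
    offset: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise with one-sided PSD 10^offset · f^(−exponent) µV²/Hz.

    Spectral shaping: the rFFT of unit white noise is multiplied by
    sqrt(fs/2 · S(f)) with the DC bin zeroed, so the periodogram equals the
    target density in expectation.  Pure function of (parameters, seed).
    """
    if n_samples < 2 * fs or fs <= 0:
        raise ValueError("need n_samples >= 2*fs and fs > 0")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_samples)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    amp[1:] = np.sqrt(10.0**offset * f[1:] ** (-exponent) * fs / 2.0)
    return np.fft.irfft(spec * amp, n)


def generate_state_sequence(
    duration_s: float,
    state_mix: dict[str, float],
    state_dwell_s: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """State label per 1-s epoch from a semi-Markov dwell model.

    Successive runs never repeat a state (the next state is drawn from the
    mix excluding the current one) and run lengths are geometric with a
    state-specific mean d_s = c/(1−mix_s) chosen so that (i) long-run
    occupancy equals ``state_mix`` exactly and (ii) the run-average dwell
    equals ``state_dwell_s``.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10")
    probs = {k: v for k, v in state_mix.items() if v > 0}
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9 or any(v < 0 for v in state_mix.values()):
        raise ValueError("state_mix probabilities must be >= 0 and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ep = int(np.floor(duration_s))
    names = list(probs)
    p = np.array([probs[s] for s in names])
    if len(names) == 1:
        return np.full(n_ep, names[0], dtype=object)
    # embedded-chain stationary dist is q_s ∝ mix_s(1-mix_s); with per-state
    # mean dwell d_s = c/(1-mix_s) the occupancy q_s·d_s ∝ mix_s exactly and
    # the run-average dwell is c / sum_s mix_s(1-mix_s).
    c = state_dwell_s * float(np.sum(p * (1 - p)))
    dwell = np.maximum(c / (1 - p), 1.0)
    labels = np.empty(n_ep, dtype=object)
    cur = int(rng.choice(len(names), p=p))
    i = 0
    while i < n_ep:
        run = int(rng.geometric(min(1.0, 1.0 / dwell[cur])))
        run = min(run, n_ep - i)
        labels[i : i + run] = names[cur]
        i += run
        w = p.copy()
        w[cur] = 0.0
        w /= w.sum()
        cur = int(rng.choice(len(names), p=w))
    return labels


_BURST_SIGMA_T = 0.35  # s; temporal envelope width of one burst


def _oscillation_burst(
    fs: float, center_hz: float, bandwidth_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Gaussian-windowed sinusoid burst spanning a 1-s epoch.

    The envelope width is fixed (0.3 s — a long, spindle-like transient
    with a low crest factor); the requested spectral width is realised by
    jittering the carrier frequency across epochs, so the ensemble PSD
    shows a Gaussian peak of SD ≈ bandwidth/2 around ``center_hz``.
    """
    spe = int(round(fs))
    t = np.arange(spe) / fs
    win = np.exp(-0.5 * ((t - 0.5) / _BURST_SIGMA_T) ** 2)
    intrinsic_sd = 1.0 / (2 * np.pi * _BURST_SIGMA_T)
    target_sd = bandwidth_hz / 2.0
    jitter_sd = np.sqrt(max(target_sd**2 - intrinsic_sd**2, 0.0))
    f = max(rng.normal(center_hz, jitter_sd), 0.3)
    return win * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))


def synthesize_recording(
    states: list[StateSpec],
    sequence: np.ndarray,
    fs: float,
    artifact_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_eeg: int = 1,
    include_emg: bool = True,
    subject: str = "s0",
    group: str = "none",
    sex: str = "na",
    age: float | None = None,
) -> tuple[Recording, Hypnogram]:
    """Render a state sequence into a multichannel recording.

    Each run of consecutive same-state epochs is filled with aperiodic
    noise at that state's (χ, b); every epoch of an oscillatory state gets
    its bursts, scaled by ``amplitude_rel`` times the run's background SD.
    The EMG channel is broadband white noise whose amplitude tracks the
    state's ``emg_level``.  Artifacts are biphasic 50–200 ms transients at
    8–15 SD of the clean EEG, at ``artifact_rate`` per minute.  The planted
    labels are returned as a ground-truth hypnogram.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_name = {s.name: s for s in states}
    sequence = np.asarray(sequence, dtype=object)
    unknown = set(sequence) - set(by_name)
    if unknown:
        raise ValueError(f"sequence contains unknown state labels {sorted(unknown)}")
    spe = int(round(fs))
    n_ep = len(sequence)
    n = n_ep * spe

    # run-length encode the sequence
    as_str = sequence.astype(str)
    change = np.flatnonzero(as_str[1:] != as_str[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n_ep]))

    eeg = np.zeros((n_eeg, n))
    emg = np.zeros(n) if include_emg else None
    for s0, s1 in zip(starts, ends):
        spec = by_name[str(sequence[s0])]
        seg = slice(s0 * spe, s1 * spe)
        seg_n = (s1 - s0) * spe
        for k in range(n_eeg):
            base = generate_aperiodic_noise(max(seg_n, 2 * spe), fs, spec.exponent, spec.offset, rng)[:seg_n]
            sd = float(np.std(base)) or 1.0
            for c_hz, amp_rel, bw in spec.oscillations:
                for ep in range(s1 - s0):
                    burst = _oscillation_burst(fs, c_hz, bw, rng)
                    base[ep * spe : (ep + 1) * spe] += amp_rel * sd * burst
            eeg[k, seg] += base
        if emg is not None:
            w = rng.standard_normal(seg_n)
            emg[seg] = np.sqrt(spec.emg_level + 0.01) * w

    # artifacts: biphasic transients on every EEG channel
    n_art = int(rng.poisson(artifact_rate * n_ep / 60.0)) if artifact_rate > 0 else 0
    art_sd = float(np.std(eeg[0]))
    for _ in range(n_art):
        width = rng.uniform(0.05, 0.2)
        amp = rng.uniform(8.0, 15.0) * art_sd
        wlen = max(int(width * fs), 4)
        t0 = int(rng.integers(0, max(n - wlen, 1)))
        shape = amp * np.sin(2 * np.pi * np.arange(wlen) / wlen)  # one biphasic cycle
        eeg[:, t0 : t0 + wlen] += shape

    channels = [Channel(name=f"EEG{k+1}", data=eeg[k], role="eeg") for k in range(n_eeg)]
    if emg is not None:
        channels.append(Channel(name="EMG1", data=emg, role="emg"))
    rec = Recording(channels=channels, fs=fs, subject=subject, group=group, sex=sex, age=age)
    mode = "mouse" if any(s.name in ("rem", "nrem") for s in states) else "human"
    truth = Hypnogram(labels=sequence.copy(), species_mode=mode)
    return rec, truth


# ---------------------------------------------------------------------------
# presets


def equal_power_offset(exponent: float, band: tuple[float, float] = (0.5, 70.0),
                       total_power: float = 10.0) -> float:
    """Offset b making the aperiodic band power equal across exponents.

    Solves ∫_band 10^b f^(−χ) df = total_power (µV²).  With a common
    offset, a flatter spectrum carries far more total power than a steep
    one, so a global amplitude-based artifact threshold would hit the
    flat-spectrum states preferentially; equalising the band power keeps
    the synthetic states amplitude-comparable, as real wake states are.
    """
    lo, hi = band
    if abs(exponent - 1.0) < 1e-12:
        integral = np.log(hi / lo)
    else:
        integral = (hi ** (1 - exponent) - lo ** (1 - exponent)) / (1 - exponent)
    return float(np.log10(total_power / integral))


def _spec(name: str, chi: float, oscillations, emg: float) -> StateSpec:
    return StateSpec(name, chi, equal_power_offset(chi), oscillations, emg)


def mouse_state_specs(exponents: dict[str, float] | None = None) -> list[StateSpec]:
    """Five-state mouse preset: three active states, REM and pooled nREM.

    Default exponents follow the empirically observed ordering
    a1 > a2 > a3 with a steeper spectrum in deep sleep; active states have
    high EMG tone, sleep states low.  Offsets equalise the 0.5–70 Hz
    aperiodic band power across states.
    """
    chi = {"a1": 1.25, "a2": 1.0, "a3": 0.737, "rem": 1.1, "nrem": 1.6}
    if exponents:
        chi.update(exponents)
    return [
        _spec("a1", chi["a1"], ((2.5, 0.8, 1.0),), 1.0),
        _spec("a2", chi["a2"], ((4.5, 1.6, 1.5),), 1.0),
        _spec("a3", chi["a3"], ((9.0, 1.8, 2.0),), 1.0),
        _spec("rem", chi["rem"], ((5.0, 1.6, 1.5),), 0.1),
        _spec("nrem", chi["nrem"], ((1.5, 0.6, 1.0),), 0.15),
    ]


def human_state_specs(exponents: dict[str, float] | None = None) -> list[StateSpec]:
    """Awake-only human preset (a1, a2, a3), equal-band-power offsets."""
    chi = {"a1": 1.25, "a2": 1.0, "a3": 0.737}
    if exponents:
        chi.update(exponents)
    return [
        _spec("a1", chi["a1"], ((2.5, 0.8, 1.0),), 0.0),
        _spec("a2", chi["a2"], ((4.5, 1.6, 1.5),), 0.0),
        _spec("a3", chi["a3"], ((9.0, 1.8, 2.0),), 0.0),
    ]


def ordering_subject_specs() -> list[StateSpec]:
    """One synthetic subject with χ(a1)=1.25 > χ(a2)=1.0 > χ(a3)=0.737."""
    return human_state_specs()


def masking_design(
    n_per_group: int = 27,
    gap: float = 0.2,
    duration_s: float = 600.0,
    fs: float = 250.0,
    seed: int = 0,
) -> CohortDesign:
    """Two-group cohort in which state pooling hides a real group effect.

    The second group sits ``gap`` below the first in *every* state, but
    spends more time in the high-exponent states; the occupancy rows are
    chosen so the occupancy-weighted pooled means coincide exactly:
    0.2·1.3 + 0.2·1.1 + 0.6·0.8 = 0.6·1.1 + 0.2·0.9 + 0.2·0.6 = 0.96.
    """
    base = human_state_specs({"a1": 1.3, "a2": 1.1, "a3": 0.8})
    mix_hc = {"a1": 0.2, "a2": 0.2, "a3": 0.6}
    mix_pt = {"a1": 0.6, "a2": 0.2, "a3": 0.2}
    groups = [
        GroupSpec("hc", 0.0, mix_hc),
        GroupSpec("pt", -gap, mix_pt),
    ]
    return CohortDesign(
        states=base,
        groups=groups,
        state_mix=mix_hc,
        n_per_group=n_per_group,
        duration_s=duration_s,
        fs=fs,
        artifact_rate=0.0,
        seed=seed,
    )


def _planted_exponent(design: CohortDesign, group: GroupSpec, state: str) -> float:
    return design.state_by_name(state).exponent + group.shift_for(state)


def generate_cohort(design: CohortDesign) -> tuple[list[tuple[Recording, Hypnogram]], pd.DataFrame]:
    """Render every subject of a cohort design into signals.

    Returns the per-subject (recording, ground-truth hypnogram) pairs and a
    ground-truth table with one row per subject × state carrying the
    planted exponent (including the subject-level offset).
    """
    root = np.random.SeedSequence(design.seed)
    out: list[tuple[Recording, Hypnogram]] = []
    rows: list[dict] = []
    subject_seeds = root.spawn(len(design.groups) * design.n_per_group)
    idx = 0
    for group in design.groups:
        mix = design.mix_for(group)
        for j in range(design.n_per_group):
            rng = np.random.default_rng(subject_seeds[idx])
            sid = f"{group.name}{j:02d}"
            sex = "f" if rng.random() < 1 - design.sex_ratio else "m"
            subj_off = rng.normal(0.0, design.subject_sd)
            states = []
            for s in design.states:
                chi = _planted_exponent(design, group, s.name) + subj_off
                chi += design.sex_effect if sex == "f" else 0.0
                chi = max(chi, 0.0)
                # tilt the spectrum at constant band power: a group/subject
                # exponent shift should not rescale the signal amplitude
                states.append(replace(s, exponent=chi, offset=equal_power_offset(chi)))
            seq = generate_state_sequence(design.duration_s, mix, design.state_dwell_s, rng)
            rec, truth = synthesize_recording(
                states,
                seq,
                design.fs,
                artifact_rate=design.artifact_rate,
                seed=rng,
                n_eeg=design.n_eeg,
                include_emg=any(s.name in ("rem", "nrem") for s in design.states),
                subject=sid,
                group=group.name,
                sex=sex,
            )
            out.append((rec, truth))
            for s in states:
                rows.append(
                    {
                        "subject": sid,
                        "group": group.name,
                        "sex": sex,
                        "state": s.name,
                        "exponent_true": s.exponent,
                        "mix": mix[s.name] if s.name in mix else 0.0,
                    }
                )
            idx += 1
    return out, pd.DataFrame(rows)


def simulate_exponent_table(design: CohortDesign, seed: int | None = None) -> pd.DataFrame:
    """Draw a subject × state exponent table directly from the design.

    This is the cohort-scale twin of :func:`generate_cohort`: instead of
    rendering signals it samples, per subject, a shared exponent offset
    (SD ``subject_sd``), per-state measurement noise (``measurement_sd``)
    and a multinomial epoch count over states, producing the table the
    statistics stage consumes.  Used for replicate-heavy power studies
    where full signal synthesis is unnecessary.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_ep = int(np.floor(design.duration_s))
    rows = []
    for group in design.groups:
        mix = design.mix_for(group)
        names = [s.name for s in design.states if mix.get(s.name, 0) > 0]
        p = np.array([mix[s] for s in names])
        for j in range(design.n_per_group):
            sid = f"{group.name}{j:02d}"
            sex = "f" if rng.random() < 1 - design.sex_ratio else "m"
            subj_off = rng.normal(0.0, design.subject_sd)
            counts = rng.multinomial(n_ep, p)
            for name, c in zip(names, counts):
                if c == 0:
                    continue
                chi = _planted_exponent(design, group, name) + subj_off
                chi += design.sex_effect if sex == "f" else 0.0
                chi += rng.normal(0.0, design.measurement_sd)
                rows.append(
                    {
                        "subject": sid,
                        "group": group.name,
                        "sex": sex,
                        "state": name,
                        "exponent": chi,
                        "n_epochs": int(c),
                    }
                )
    return pd.DataFrame(rows)
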