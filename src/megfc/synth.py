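"""Synthetic MEG-like data with known ground truth.

Every downstream stage of the pipeline is exercised on data from this module:
1/f background noise per channel, band-limited inter-channel coupling planted
via a shared latent component, and a 3 Hz spike-and-wave discharge (SWD)
morphology during the seizure.  The coupling mechanism is calibrated in closed
form: mixing x_i <- sqrt(1-w)*x_i + sqrt(w)*z of the in-band components of
equal-variance channels yields an expected in-band pairwise correlation of
exactly w, so ``rho_target`` maps directly onto the mixing weight.

All randomness flows from an explicit integer seed per call; identical
configuration and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    REGIONS,
    BandSpec,
    Recording,
    SeizureEvent,
    band_by_name,
    bandpass_array,
)

__all__ = [
    "SimulationConfig",
    "CouplingSpec",
    "SwdSpec",
    "StudyConfig",
    "SeizureSpec",
    "StudyDataset",
    "default_region_scheme",
    "gen_background",
    "inject_coupling",
    "gen_swd",
    "inject_swd",
    "simulate_recording",
    "simulate_study",
    "seizure_plan",
    "gamma_recovery_design",
    "null_design",
    "demo_design",
]


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingSpec:
    """Planted band-limited coupling among a channel group.

    Within ``window`` the in-band components of the grouped channels share a
    common latent source mixed so their expected pairwise in-band correlation
    is ``rho_target``.
    """

    band: BandSpec
    channel_group: frozenset[int]
    rho_target: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_group", frozenset(self.channel_group))
        if len(self.channel_group) < 2:
            raise ValueError("channel_group needs at least 2 channels")
        if not (0.0 <= self.rho_target < 1.0):
            raise ValueError(f"rho_target must be in [0, 1), got {self.rho_target}")
        if self.window[1] <= self.window[0]:
            raise ValueError("coupling window must have positive length")


@dataclass(frozen=True)
class SwdSpec:
    """Spike-and-wave cycle shape: a narrow spike followed by a broad slow wave.

    ``amplitude_ratio`` is the spike amplitude relative to the wave amplitude
    (0 gives a pure wave train).  One spike plus one wave must fit in a cycle.
    """

    repetition_rate: float = 3.0
    spike_width_s: float = 0.08
    wave_width_s: float = 0.20
    amplitude_ratio: float = 3.0
    channel_gains: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.repetition_rate <= 0:
            raise ValueError("repetition_rate must be positive")
        if self.spike_width_s <= 0 or self.wave_width_s <= 0:
            raise ValueError("spike and wave widths must be positive")
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude_ratio must be >= 0")
        if self.spike_width_s + self.wave_width_s > 1.0 / self.repetition_rate:
            raise ValueError(
                "spike_width_s + wave_width_s must fit in one cycle "
                f"(<= {1.0 / self.repetition_rate:.4f} s)"
            )


@dataclass
class SimulationConfig:
    """Everything needed to synthesize one recording (and its seizure, if any)."""

    n_channels: int
    duration_s: float
    fs: float = 6000.0
    seed: int = 0
    background_slope: float = 1.0
    coupling_specs: list[CouplingSpec] = field(default_factory=list)
    swd_spec: SwdSpec | None = None
    swd_amplitude: float = 3.0
    event: tuple[float, float] | None = None
    region_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be a whole number of samples")
        for spec in self.coupling_specs:
            if spec.band.f_hi * 2 >= self.fs:
                raise ValueError(
                    f"fs={self.fs} too low for coupling band up to {spec.band.f_hi} Hz"
                )


# ---------------------------------------------------------------------------
# Channel/region bookkeeping
# ---------------------------------------------------------------------------

_REGION_WEIGHTS = {"frontal": 10, "central": 4, "temporal": 4, "parietal": 6, "occipital": 6}


def channel_labels(n_channels: int) -> list[str]:
    return [f"MEG{i:03d}" for i in range(n_channels)]


def default_region_scheme(n_channels: int) -> dict[str, str]:
    """Deterministic channel->region assignment, frontal-weighted like a
    whole-head sensor layout (10:4:4:6:6 over the five lobes per 30 channels)."""
    labels = channel_labels(n_channels)
    total = sum(_REGION_WEIGHTS.values())
    counts = {r: (n_channels * w) // total for r, w in _REGION_WEIGHTS.items()}
    # distribute the remainder in fixed region order
    rest = n_channels - sum(counts.values())
    for r in REGIONS:
        if rest == 0:
            break
        counts[r] += 1
        rest -= 1
    scheme: dict[str, str] = {}
    i = 0
    for r in REGIONS:
        for _ in range(counts[r]):
            scheme[labels[i]] = r
            i += 1
    return scheme


def channels_in_region(region_of: dict[str, str], labels: list[str], regions) -> list[int]:
    wanted = {regions} if isinstance(regions, str) else set(regions)
    return [i for i, c in enumerate(labels) if region_of[c] in wanted]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_background(
    n_channels: int,
    duration_s: float,
    fs: float,
    slope: float = 1.0,
    seed: int = 0,
    region_of: dict[str, str] | None = None,
) -> Recording:
    """Independent per-channel noise with power spectral density ~ 1/f^slope.

    Pink noise is produced by spectral shaping of white noise (scaling the
    rFFT by f^(-slope/2)), which gives exact slope control.  Channels are
    standardized to zero mean, unit variance.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n))
    if slope != 0:
        spec = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        scale = np.ones_like(f)
        nz = f > 0
        scale[nz] = f[nz] ** (-slope / 2.0)
        scale[0] = 0.0
        data = np.fft.irfft(spec * scale, n=n, axis=-1)
    else:
        data = white
    data = data - data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    data = data / sd
    labels = channel_labels(n_channels)
    return Recording(
        data=data,
        fs=fs,
        channel_labels=labels,
        region_of=region_of or default_region_scheme(n_channels),
    )


def inject_coupling(recording: Recording, spec: CouplingSpec, seed: int = 0) -> Recording:
    """Plant shared-latent coupling in one band/window/channel-group.

    For each grouped channel the in-band component b_i over the window is
    replaced by sqrt(1-w)*b_i + sqrt(w)*sigma_i*z with w = rho_target and z a
    band-limited unit-variance latent, so the expected in-band pairwise
    correlation within the group is rho_target.  Channels outside the group
    and samples outside the window are untouched.
    """
    if not (0.0 <= spec.rho_target < 1.0):
        raise ValueError(f"rho_target must be in [0, 1), got {spec.rho_target}")
    group = sorted(spec.channel_group)
    if group[0] < 0 or group[-1] >= recording.n_channels:
        raise ValueError(f"channel_group {group} out of range for {recording.n_channels} channels")
    t0, t1 = spec.window
    if t0 < 0 or t1 > recording.duration_s + 1e-9:
        raise ValueError(f"window {spec.window} outside recording [0, {recording.duration_s}] s")
    out = recording.copy()
    if spec.rho_target == 0.0:
        return out

    fs = recording.fs
    s0, s1 = int(np.floor(t0 * fs)), int(np.floor(t1 * fs))
    w = spec.rho_target

    # In-band component of each grouped channel over the full record, windowed.
    band_full = bandpass_array(recording.data[group], spec.band, fs)
    b_win = band_full[:, s0:s1]

    # Band-limited unit-variance latent over the window (with filter run-in).
    rng = np.random.default_rng(seed)
    pad = int(round(fs))
    z_raw = rng.standard_normal(s1 - s0 + 2 * pad)
    z = bandpass_array(z_raw, spec.band, fs)[pad:-pad]
    z = (z - z.mean()) / z.std()

    sigma = b_win.std(axis=-1, keepdims=True)
    mixed = np.sqrt(1.0 - w) * b_win + np.sqrt(w) * sigma * z
    out.data[group, s0:s1] += mixed - b_win
    return out


def gen_swd(spec: SwdSpec, duration_s: float, fs: float) -> np.ndarray:
    """One channel of spike-and-wave train: a narrow Gaussian spike of relative
    amplitude ``amplitude_ratio`` followed by a unit-amplitude half-sine slow
    wave, repeating at ``repetition_rate`` Hz."""
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    period = 1.0 / spec.repetition_rate
    if spec.spike_width_s + spec.wave_width_s > period:
        raise ValueError("spike + wave exceed one cycle")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = np.mod(t, period)
    out = np.zeros(n)
    # spike: Gaussian centred mid-spike, sigma = width/4; circular distance in
    # phase keeps the train smooth across cycle boundaries (no jump harmonics)
    sig = spec.spike_width_s / 4.0
    c = spec.spike_width_s / 2.0
    d = phase - c
    d = np.where(d > period / 2.0, d - period, d)
    d = np.where(d < -period / 2.0, d + period, d)
    out += spec.amplitude_ratio * np.exp(-0.5 * (d / sig) ** 2)
    # wave: half-sine occupying [spike_width, spike_width + wave_width), negative
    # deflection (slow wave of opposite polarity to the spike)
    in_wave = (phase >= spec.spike_width_s) & (phase < spec.spike_width_s + spec.wave_width_s)
    out[in_wave] -= np.sin(np.pi * (phase[in_wave] - spec.spike_width_s) / spec.wave_width_s)
    return out


def inject_swd(
    recording: Recording,
    spec: SwdSpec,
    event: SeizureEvent,
    amplitude: float = 3.0,
    seed: int = 0,
) -> Recording:
    """Add the spike-and-wave train to all channels during [onset, offset).

    ``amplitude`` scales the wave deflection in units of each channel's
    standard deviation; per-channel gains come from ``spec.channel_gains``
    (log-normal draws with unit median if unspecified)."""
    out = recording.copy()
    fs = recording.fs
    s0 = int(np.floor(event.onset_s * fs))
    s1 = int(np.floor(event.offset_s * fs))
    wave = gen_swd(spec, (s1 - s0) / fs, fs)
    if spec.channel_gains is not None:
        gains = np.asarray(spec.channel_gains, dtype=float)
        if gains.shape != (recording.n_channels,):
            raise ValueError("channel_gains must have one entry per channel")
    else:
        rng = np.random.default_rng(seed)
        gains = np.exp(rng.normal(0.0, 0.3, size=recording.n_channels))
    ch_sd = recording.data.std(axis=-1)
    out.data[:, s0:s1] += amplitude * (gains * ch_sd)[:, None] * wave[None, :]
    return out


def simulate_recording(config: SimulationConfig) -> tuple[Recording, SeizureEvent | None]:
    """Background + planted couplings + SWD morphology for one recording.

    Child seeds are spawned deterministically from ``config.seed`` so the whole
    recording is reproducible bit-for-bit.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 + len(config.coupling_specs)) % (2**31)
    rec = gen_background(
        config.n_channels,
        config.duration_s,
        config.fs,
        config.background_slope,
        seed=int(seeds[0]),
        region_of=config.region_of,
    )
    for i, spec in enumerate(config.coupling_specs):
        rec = inject_coupling(rec, spec, seed=int(seeds[2 + i]))
    event = None
    if config.event is not None:
        event = SeizureEvent(*config.event)
        if config.swd_spec is not None:
            rec = inject_swd(rec, config.swd_spec, event, config.swd_amplitude, seed=int(seeds[1]))
    return rec, event


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------


@dataclass
class SeizureSpec:
    """One analysed seizure: which patient it belongs to and how to simulate it."""

    recording_id: str
    patient: int
    config: SimulationConfig


@dataclass
class StudyConfig:
    """A cohort of per-seizure simulation configs plus the clinical table."""

    seizures: list[SeizureSpec]
    clinical: "object"  # pandas.DataFrame; typed loosely to keep numpy-only callers light


@dataclass
class StudyDataset:
    """In-memory study: (recording_id, patient, Recording, SeizureEvent) tuples."""

    records: list[tuple[str, int, Recording, SeizureEvent | None]]
    clinical: "object"


def seizure_plan(clinical) -> list[tuple[int, int]]:
    """Seizure count per patient: with 22 patients, the first 11 contribute one
    analysed seizure and the remaining 11 two, giving 33 segments."""
    patients = list(clinical["patient"])
    half = len(patients) // 2
    return [(p, 1 if i < half else 2) for i, p in enumerate(patients)]


def simulate_study(study: StudyConfig, out_dir=None) -> StudyDataset:
    """Simulate every seizure of a study; optionally write the dataset to disk
    in the documented HDF5/TSV formats (see :mod:`megfc.io`)."""
    records = []
    for sz in study.seizures:
        rec, event = simulate_recording(sz.config)
        records.append((sz.recording_id, sz.patient, rec, event))
    ds = StudyDataset(records=records, clinical=study.clinical)
    if out_dir is not None:
        from . import io as _io

        _io.write_study(ds, out_dir)
    return ds


# ---------------------------------------------------------------------------
# Frozen study designs
# ---------------------------------------------------------------------------


def _cross_pairs(frontal: list[int], posterior: list[int], per_frontal: int = 2):
    """Bipartite frontal-posterior pair list, each frontal channel in
    ``per_frontal`` pairs, posterior channels reused round-robin."""
    pairs = []
    k = 0
    for f in frontal:
        for _ in range(per_frontal):
            pairs.append((f, posterior[k % len(posterior)]))
            k += 1
    return pairs


def _study_from_designs(
    per_seizure_couplings,
    clinical,
    n_channels: int,
    fs: float,
    seed: int,
    with_swd: bool,
    duration_s: float,
    onset_s: float,
    offset_s: float,
    background_slope: float = 1.0,
) -> StudyConfig:
    plan = seizure_plan(clinical)
    total = sum(n for _, n in plan)
    seeds = np.random.SeedSequence(seed).generate_state(total) % (2**31)
    region_of = default_region_scheme(n_channels)
    seizures = []
    idx = 0
    for patient, n_sz in plan:
        for k in range(n_sz):
            child = int(seeds[idx])
            couplings = per_seizure_couplings(onset_s, offset_s)
            seizures.append(
                SeizureSpec(
                    recording_id=f"p{patient:02d}_s{k + 1}",
                    patient=patient,
                    config=SimulationConfig(
                        n_channels=n_channels,
                        duration_s=duration_s,
                        fs=fs,
                        seed=child,
                        background_slope=background_slope,
                        coupling_specs=couplings,
                        swd_spec=SwdSpec() if with_swd else None,
                        event=(onset_s, offset_s),
                        region_of=region_of,
                    ),
                )
            )
            idx += 1
    return StudyConfig(seizures=seizures, clinical=clinical)


def gamma_recovery_design(
    seed: int = 0,
    n_channels: int = 30,
    fs: float = 1200.0,
    rho_ictal: float = 0.30,
    rho_cross: float = 0.55,
    pairs_per_frontal: int = 2,
    with_interictal: bool = False,
    clinical=None,
) -> StudyConfig:
    """The planted analogue of the reported 30–80 Hz findings.

    Each seizure carries (a) one frontal-group gamma coupling during the 3-s
    ictal window (rho 0.30 → a frontal-localized network) and (b) twenty
    pairwise frontal↔posterior gamma couplings during the 3-s termination
    window (rho 0.55 per pair → an anterior-posterior network whose retained
    edges are stronger on average than the ictal ones).  Analyse with
    :func:`megfc.pipeline.recovery_config`.
    """
    if clinical is None:
        from .datasets import cae_clinical_table

        clinical = cae_clinical_table()
    region_of = default_region_scheme(n_channels)
    labels = channel_labels(n_channels)
    frontal = channels_in_region(region_of, labels, "frontal")
    posterior = channels_in_region(region_of, labels, {"parietal", "occipital"})
    gamma = band_by_name("gamma")

    onset_s, offset_s = 1.0, 8.0
    duration_s = (offset_s + 10.0 + 30.0 + 1.0) if with_interictal else (offset_s + 1.5)

    def couplings(onset, offset):
        specs = [
            CouplingSpec(gamma, frozenset(frontal), rho_ictal, (onset, onset + 3.0))
        ]
        for f, p in _cross_pairs(frontal, posterior, pairs_per_frontal):
            specs.append(CouplingSpec(gamma, frozenset({f, p}), rho_cross, (offset - 3.0, offset)))
        return specs

    return _study_from_designs(
        couplings, clinical, n_channels, fs, seed, True, duration_s, onset_s, offset_s
    )


def null_design(
    seed: int = 0,
    n_channels: int = 10,
    fs: float = 1200.0,
    clinical=None,
) -> StudyConfig:
    """A cohort with no planted period difference: pure 1/f background, no
    coupling, no SWD — the null for type-I calibration of the whole pipeline."""
    if clinical is None:
        from .datasets import cae_clinical_table

        clinical = cae_clinical_table()
    onset_s, offset_s = 1.0, 8.0
    return _study_from_designs(
        lambda onset, offset: [],
        clinical,
        n_channels,
        fs,
        seed,
        False,
        offset_s + 1.5,
        onset_s,
        offset_s,
    )


def demo_design(
    seed: int = 0,
    n_channels: int = 30,
    fs: float = 1200.0,
    n_patients: int | None = None,
    clinical=None,
) -> StudyConfig:
    """Like :func:`gamma_recovery_design` but with recordings long enough to
    host the 30-s interictal window (the full three-period pipeline demo)."""
    cfg = gamma_recovery_design(
        seed=seed, n_channels=n_channels, fs=fs, with_interictal=True, clinical=clinical
    )
    if n_patients is not None:
        keep = {sz.patient for sz in cfg.seizures[: 2 * n_patients]}
        keep = sorted(keep)[:n_patients]
        cfg = StudyConfig(
            seizures=[sz for sz in cfg.seizures if sz.patient in keep],
            clinical=cfg.clinical[cfg.clinical["patient"].isin(keep)].reset_index(drop=True),
        )
    return cfg
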