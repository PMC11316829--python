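"""Synthetic multi-subject arrhythmic ECG generator.

Each subject is described by five Gaussian wave components (P, Q, R, S, T)
with per-subject amplitudes, widths and latencies relative to the R apex,
plus an RR-interval distribution and a baseline-noise level.  A beat is the
sum of the component Gaussians; an arrhythmia symbol maps to an explicit
perturbation of those parameters (amplitude/width scaling, latency shifts,
extra components such as a pacing spike, and a prematurity factor applied
to the preceding RR interval).  Records are assembled by placing beats at
cumulative RR times on a single lead sampled at ``fs`` Hz (default 360 Hz,
the MIT-BIH rate).

Everything is a pure function of its parameters and seed, so every
downstream stage (segmentation, scalogram imaging, identification) can be
exercised reproducibly without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WaveComponent",
    "PersonParams",
    "PerturbationRule",
    "SUPPORTED_SYMBOLS",
    "DEFAULT_RULES",
    "scale_rules",
    "sample_person",
    "perturb_params",
    "synth_beat",
    "synth_record",
    "SynthRecord",
]

#: Beat-level health-state alphabet handled throughout the package:
#: N normal, V premature ventricular, A atrial premature, F fusion V+N,
#: j junctional escape, a aberrated atrial premature, f fusion paced+normal,
#: | isolated QRS-like artifact, J junctional premature, R right bundle
#: branch block, / paced.
SUPPORTED_SYMBOLS = frozenset("NVAFjaf|JR/")

DEFAULT_FS = 360.0


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: amplitude (mV), width sigma (ms), latency from R (ms)."""

    amplitude: float
    width_ms: float
    offset_ms: float


@dataclass(frozen=True)
class PersonParams:
    """Subject-specific morphology and rhythm parameters."""

    subject_id: str
    waves: dict[str, WaveComponent]  # keys P, Q, R, S, T
    rr_mean_ms: float
    rr_sd_ms: float
    baseline_noise_sd: float = 0.02  # mV

    def __post_init__(self) -> None:
        missing = {"P", "Q", "R", "S", "T"} - set(self.waves)
        if missing:
            raise ValueError(f"missing wave components: {sorted(missing)}")
        if not 500.0 <= self.rr_mean_ms <= 1200.0:
            raise ValueError("rr_mean_ms must lie in [500, 1200] ms")
        for name, w in self.waves.items():
            if w.width_ms <= 0:
                raise ValueError(f"component {name} has non-positive width")


@dataclass(frozen=True)
class PerturbationRule:
    """Explicit parameter edits attached to one health-state symbol.

    ``amp_scale`` of 0 deletes a component (continuously interpolable,
    which is what :func:`scale_rules` exploits).  ``rr_factor`` < 1 marks a
    premature beat: it multiplies the RR interval *preceding* the beat.
    """

    label: str
    amp_scale: dict[str, float] = field(default_factory=dict)
    width_scale: dict[str, float] = field(default_factory=dict)
    offset_shift_ms: dict[str, float] = field(default_factory=dict)
    extra: tuple[WaveComponent, ...] = ()
    rr_factor: float = 1.0

    def is_identity(self) -> bool:
        return (
            all(v == 1.0 for v in self.amp_scale.values())
            and all(v == 1.0 for v in self.width_scale.values())
            and all(v == 0.0 for v in self.offset_shift_ms.values())
            and all(c.amplitude == 0.0 for c in self.extra)
            and self.rr_factor == 1.0
        )


def _default_rules() -> dict[str, PerturbationRule]:
    spike = WaveComponent(amplitude=1.2, width_ms=3.0, offset_ms=-60.0)
    small_spike = WaveComponent(amplitude=0.6, width_ms=3.0, offset_ms=-60.0)
    r_prime = WaveComponent(amplitude=0.55, width_ms=14.0, offset_ms=40.0)
    return {
        "N": PerturbationRule("N"),
        # PVC: no P wave, broad bizarre QRS, discordant (flipped, enlarged) S.
        "V": PerturbationRule(
            "V",
            amp_scale={"P": 0.0, "S": -1.5},
            width_scale={"Q": 2.5, "R": 2.5, "S": 2.5},
            rr_factor=0.8,
        ),
        # Atrial premature: attenuated ectopic P, early beat, QRS untouched.
        "A": PerturbationRule("A", amp_scale={"P": 0.5}, rr_factor=0.7),
        # Paced: stimulus artifact then a widened ventricular complex.
        "/": PerturbationRule(
            "/", width_scale={"Q": 2.0, "R": 2.0, "S": 2.0}, extra=(spike,)
        ),
        # Junctional premature: no P, early.
        "J": PerturbationRule("J", amp_scale={"P": 0.0}, rr_factor=0.8),
        # RBBB: secondary R' deflection, widened QRS.
        "R": PerturbationRule(
            "R", width_scale={"Q": 1.8, "R": 1.8, "S": 1.8}, extra=(r_prime,)
        ),
        # Fusion of V and N: morphology between the two.
        "F": PerturbationRule(
            "F",
            amp_scale={"P": 0.5, "S": -1.2},
            width_scale={"Q": 1.7, "R": 1.7, "S": 1.7},
        ),
        # Junctional escape: no P, *late* beat.
        "j": PerturbationRule("j", amp_scale={"P": 0.0}, rr_factor=1.3),
        # Aberrated atrial premature: ectopic P plus conduction aberrancy.
        "a": PerturbationRule(
            "a",
            amp_scale={"P": 0.5},
            width_scale={"Q": 1.4, "R": 1.4, "S": 1.4},
            rr_factor=0.7,
        ),
        # Fusion of paced and normal: small stimulus spike, mild widening.
        "f": PerturbationRule(
            "f", width_scale={"Q": 1.4, "R": 1.4, "S": 1.4}, extra=(small_spike,)
        ),
        # Isolated QRS-like artifact: narrow QRS-shaped transient, no P/T.
        "|": PerturbationRule(
            "|",
            amp_scale={"P": 0.0, "T": 0.0, "R": 0.8},
            width_scale={"Q": 0.7, "R": 0.7, "S": 0.7},
        ),
    }


#: Symbol -> default perturbation. One table so severity can be varied in tests.
DEFAULT_RULES: dict[str, PerturbationRule] = _default_rules()


def scale_rules(
    rules: dict[str, PerturbationRule], magnitude: float
) -> dict[str, PerturbationRule]:
    """Interpolate every rule between the identity (0) and itself (1).

    Scale factors move linearly toward 1, latency shifts and extra-component
    amplitudes toward 0, so ``magnitude`` acts as a severity dial with the
    defaults at 1.0 and no-op at 0.0; values above 1 extrapolate.
    """

    def lerp(f: float) -> float:
        return 1.0 + (f - 1.0) * magnitude

    out = {}
    for sym, r in rules.items():
        out[sym] = PerturbationRule(
            label=r.label,
            amp_scale={k: lerp(v) for k, v in r.amp_scale.items()},
            width_scale={k: lerp(v) for k, v in r.width_scale.items()},
            offset_shift_ms={k: v * magnitude for k, v in r.offset_shift_ms.items()},
            extra=tuple(
                replace(c, amplitude=c.amplitude * magnitude) for c in r.extra
            ),
            rr_factor=lerp(r.rr_factor),
        )
    return out


# Physiologic sampling ranges (amplitude mV, sigma ms, latency ms). R amplitude
# dominates every other component by construction, and latencies are ordered
# P < Q < R(=0) < S < T because the ranges do not overlap.
_RANGES = {
    "P": ((0.05, 0.20), (12.0, 25.0), (-180.0, -120.0)),
    "Q": ((-0.20, -0.05), (5.0, 10.0), (-35.0, -15.0)),
    "R": ((0.80, 1.60), (7.0, 14.0), (0.0, 0.0)),
    "S": ((-0.40, -0.10), (5.0, 10.0), (15.0, 35.0)),
    "T": ((0.10, 0.40), (35.0, 70.0), (150.0, 250.0)),
}


def sample_person(seed: int, baseline_noise_sd: float = 0.02) -> PersonParams:
    """Draw one subject's parameters; deterministic given ``seed``."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    waves = {}
    for name, ((a0, a1), (w0, w1), (o0, o1)) in _RANGES.items():
        waves[name] = WaveComponent(
            amplitude=float(rng.uniform(a0, a1)),
            width_ms=float(rng.uniform(w0, w1)),
            offset_ms=float(rng.uniform(o0, o1)),
        )
    return PersonParams(
        subject_id=f"S{seed:04d}",
        waves=waves,
        rr_mean_ms=float(rng.uniform(600.0, 1100.0)),
        rr_sd_ms=float(rng.uniform(20.0, 60.0)),
        baseline_noise_sd=baseline_noise_sd,
    )


def perturb_params(
    params: PersonParams,
    label: str,
    rules: dict[str, PerturbationRule] | None = None,
) -> tuple[list[WaveComponent], float]:
    """Apply the rule for ``label``; return (components, rr_factor)."""
    rules = DEFAULT_RULES if rules is None else rules
    if label not in SUPPORTED_SYMBOLS:
        raise ValueError(
            f"unknown health-state symbol {label!r}; allowed: "
            f"{''.join(sorted(SUPPORTED_SYMBOLS))}"
        )
    rule = rules[label]
    comps = []
    for name, w in params.waves.items():
        a = w.amplitude * rule.amp_scale.get(name, 1.0)
        if a == 0.0:
            continue  # deleted component
        comps.append(
            WaveComponent(
                amplitude=a,
                width_ms=w.width_ms * rule.width_scale.get(name, 1.0),
                offset_ms=w.offset_ms + rule.offset_shift_ms.get(name, 0.0),
            )
        )
    comps.extend(c for c in rule.extra if c.amplitude != 0.0)
    return comps, rule.rr_factor


# Single-beat support in ms around the R apex; wide enough for every default
# perturbation (paced spike at -60 ms, shifted T waves) at any subject draw.
_BEAT_PRE_MS = 300.0
_BEAT_POST_MS = 450.0


def gaussian_sum(components: list[WaveComponent], t_ms: np.ndarray) -> np.ndarray:
    """Closed-form beat: sum of amplitude * exp(-(t-offset)^2 / (2 sigma^2))."""
    y = np.zeros_like(t_ms, dtype=np.float64)
    for c in components:
        y += c.amplitude * np.exp(-((t_ms - c.offset_ms) ** 2) / (2.0 * c.width_ms**2))
    return y


def synth_beat(
    params: PersonParams,
    label: str = "N",
    fs: float = DEFAULT_FS,
    noise_sd: float | None = None,
    rules: dict[str, PerturbationRule] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int, float]:
    """Synthesize one beat.

    Returns ``(waveform_mV, r_index, rr_factor)`` where ``r_index`` is the
    sample of the true R apex and ``rr_factor`` the prematurity multiplier
    the label imposes on the preceding RR interval (1.0 for on-time beats).
    ``noise_sd`` defaults to the subject's baseline noise; pass 0 for the
    exact Gaussian-sum waveform.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    comps, rr_factor = perturb_params(params, label, rules)
    n_pre = int(round(_BEAT_PRE_MS * fs / 1000.0))
    n_post = int(round(_BEAT_POST_MS * fs / 1000.0))
    t_ms = (np.arange(-n_pre, n_post + 1)) * 1000.0 / fs
    y = gaussian_sum(comps, t_ms)
    sd = params.baseline_noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        y = y + (rng or np.random.default_rng()).normal(0.0, sd, size=y.shape)
    return y.astype(np.float64), n_pre, rr_factor


@dataclass
class SynthRecord:
    """A generated single-lead record with ground-truth beat annotations."""

    subject_id: str
    signal: np.ndarray  # (n_samples,) mV
    fs: float
    ann_samples: np.ndarray  # (n_beats,) int, true R apex indices
    ann_symbols: np.ndarray  # (n_beats,) unicode symbols
    person: PersonParams | None = None


def _normalize_mix(label_mix: dict[str, float]) -> tuple[list[str], np.ndarray]:
    if not label_mix:
        raise ValueError("label_mix is empty")
    bad = set(label_mix) - SUPPORTED_SYMBOLS
    if bad:
        raise ValueError(f"unknown symbols in label_mix: {sorted(bad)}")
    syms = sorted(label_mix)
    p = np.array([label_mix[s] for s in syms], dtype=np.float64)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("label_mix proportions must be non-negative with a positive sum")
    return syms, p / p.sum()


def synth_record(
    persons: list[PersonParams],
    beats_per_person: int,
    label_mix: dict[str, float] | None = None,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    rules: dict[str, PerturbationRule] | None = None,
) -> list[SynthRecord]:
    """Generate one record per subject, fully reproducible from ``seed``.

    Per subject, a child random stream is spawned from
    ``np.random.SeedSequence(seed)`` in list order; beat labels are drawn
    with ``rng.choice(sorted(symbols), p=proportions)``, RR intervals from
    ``Normal(rr_mean, rr_sd)`` clipped to [400, 2000] ms, prematurity
    factors applied to the RR interval preceding each labeled beat, and
    beats are summed onto the lead at their cumulative R times before
    baseline noise is added.
    """
    if not persons:
        raise ValueError("persons list is empty")
    if beats_per_person < 1:
        raise ValueError("beats_per_person must be >= 1")
    label_mix = {"N": 1.0} if label_mix is None else label_mix
    syms, probs = _normalize_mix(label_mix)

    children = np.random.SeedSequence(seed).spawn(len(persons))
    records = []
    for person, ss in zip(persons, children):
        rng = np.random.default_rng(ss)
        labels = rng.choice(syms, size=beats_per_person, p=probs)
        rr = rng.normal(person.rr_mean_ms, person.rr_sd_ms, size=beats_per_person)
        rr = np.clip(rr, 400.0, 2000.0)
        factors = np.array(
            [(rules or DEFAULT_RULES)[s].rr_factor for s in labels]
        )
        rr = rr * factors  # prematurity acts on the RR preceding the beat
        r_times_ms = _BEAT_PRE_MS + np.cumsum(rr) - rr[0]
        r_samples = np.round(r_times_ms * fs / 1000.0).astype(np.int64)

        n_total = int(r_samples[-1] + round(_BEAT_POST_MS * fs / 1000.0)) + 1
        signal = np.zeros(n_total, dtype=np.float64)
        for r_s, lab in zip(r_samples, labels):
            beat, r_idx, _ = synth_beat(
                person, str(lab), fs=fs, noise_sd=0.0, rules=rules
            )
            start = r_s - r_idx
            lo, hi = max(start, 0), min(start + beat.size, n_total)
            signal[lo:hi] += beat[lo - start : hi - start]
        if person.baseline_noise_sd > 0:
            signal += rng.normal(0.0, person.baseline_noise_sd, size=n_total)
        records.append(
            SynthRecord(
                subject_id=person.subject_id,
                signal=signal,
                fs=fs,
                ann_samples=r_samples,
                ann_symbols=labels.astype("<U1"),
                person=person,
            )
        )
    return records
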