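"""Synthetic two-group cohorts with known regional effects.

Generates desk-scale volumetric data emulating the statistical structure
a resting-state regional-feature analysis assumes: each ROI carries a
band-limited (0.01-0.08 Hz) signal shared by its voxels plus voxel-private
band-limited noise, optional latent signals couple sets of ROIs, and the
structural map is ROI-piecewise-constant plus voxel noise.  Group effects
are injected per (ROI, channel) as standardized mean shifts of the
generative parameter that drives that channel:

* ``ALFF`` - scales the overall amplitude of the ROI's voxel series
  (shared and private parts alike, leaving synchrony and correlations
  untouched);
* ``ReHo`` - raises the shared-variance fraction within the ROI;
* ``RFCS`` - raises the fraction of the ROI-shared signal that is drawn
  from a latent signal common to a set of partner ROIs (the mixing is
  variance-preserving, so amplitude and within-ROI synchrony stay put);
* ``GM``   - shifts the ROI's structural-map mean.

Each parameter has a between-subject standard deviation, and an effect of
size ``d`` shifts the patient group's parameter mean by ``d`` times that
standard deviation, so the injected effect is a Cohen's d on the
generative scale.  Controls never receive a shift; with all effect sizes
zero the two groups are generatively identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .atlas import AtlasParcellation, make_atlas

CHANNELS = ("ALFF", "ReHo", "RFCS", "GM")

# Between-subject SDs of the generative parameters (one Cohen's d unit
# of injected effect shifts the patient mean by exactly this much).
ALFF_AMP_SD = 0.10       # ROI signal-amplitude factor, baseline 1.0
REHO_FRAC_SD = 0.05      # shared-variance fraction, baseline 0.2
RFCS_COUPLING_SD = 0.20  # target ROI's latent mixing fraction, baseline 0.15
GM_BASE = 1.0            # structural-map baseline (arbitrary units)

_BASE_SHARED_FRAC = 0.2
_TARGET_COUPLING_FRAC = 0.15
_PARTNER_COUPLING_FRAC = 0.5
_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class EffectSpec:
    """A single injected group difference.

    Parameters
    ----------
    roi_id : target ROI (must exist in the atlas).
    channel : one of ``ALFF``, ``ReHo``, ``RFCS``, ``GM``.
    effect_size : standardized patient-minus-control shift (Cohen's d)
        of the generative parameter for this channel.
    partners : for ``RFCS`` only, the ROI ids sharing the latent signal
        with the target; ``None`` draws a default set of up to 10 random
        partners when the cohort is simulated.
    """

    roi_id: int
    channel: str
    effect_size: float
    partners: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.roi_id <= 0:
            raise ValueError("roi_id must be a positive atlas label")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated two-group cohort.

    Defaults mirror a small clinical resting-state study: 21 patients and
    28 controls, 150 time points at TR = 2 s, and a 116-region
    parcellation on a 12x12x12 voxel grid.
    """

    n_patients: int = 21
    n_controls: int = 28
    n_timepoints: int = 150
    tr: float = 2.0
    volume_shape: tuple[int, int, int] = (12, 12, 12)
    n_rois: int = 116
    effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_timepoints < 32:
            raise ValueError("n_timepoints must be >= 32")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("volume_shape must be 3 positive integers")
        if self.n_rois > int(np.prod(shape)):
            raise ValueError("n_rois exceeds the number of voxels")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "volume_shape", shape)
        object.__setattr__(self, "effects", tuple(self.effects))

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


@dataclass(frozen=True)
class Subject:
    subject_id: str
    label: str  # "patient" | "control"
    functional: np.ndarray  # (x, y, z, t)
    structural: np.ndarray  # (x, y, z)


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]
    atlas: AtlasParcellation
    config: CohortConfig
    # effects with RFCS partner sets resolved, for ground-truth recovery
    resolved_effects: tuple[EffectSpec, ...]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.subjects]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _band_limited_signal(rng: np.random.Generator, n_timepoints: int, tr: float,
                         size: int | None = None,
                         band: tuple[float, float] = _BAND) -> np.ndarray:
    """Unit-variance stationary Gaussian signals band-limited to ``band``.

    Built in the DFT domain with independent complex-Gaussian
    coefficients on every in-band bin (equivalently, a sum of sinusoids
    with random phases and Rayleigh amplitudes at the in-band
    frequencies).  Gaussianity makes the family closed under
    variance-preserving mixing, so rank- and correlation-based local
    statistics depend only on the correlation structure, never on which
    signals were mixed.  Returns shape ``(T,)`` or ``(size, T)``.
    """
    T = int(n_timepoints)
    freqs = np.fft.rfftfreq(T, d=tr)
    inband = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    n_bins = int(inband.sum())
    if n_bins == 0:
        raise ValueError("no DFT bin falls inside the band; series too short")
    n = 1 if size is None else size
    coef = rng.standard_normal((n, n_bins)) + 1j * rng.standard_normal((n, n_bins))
    spec = np.zeros((n, len(freqs)), dtype=complex)
    spec[:, inband] = coef
    sig = np.fft.irfft(spec, n=T, axis=-1)
    sig = sig / sig.std(axis=-1, keepdims=True)
    return sig[0] if size is None else sig


def _effect_maps(effects: tuple[EffectSpec, ...]) -> dict[str, dict[int, float]]:
    maps: dict[str, dict[int, float]] = {ch: {} for ch in CHANNELS}
    for e in effects:
        maps[e.channel][e.roi_id] = maps[e.channel].get(e.roi_id, 0.0) + e.effect_size
    return maps


def resolve_effects(config: CohortConfig, atlas: AtlasParcellation,
                    rng: np.random.Generator) -> tuple[EffectSpec, ...]:
    """Validate effects against the atlas and draw RFCS partner sets."""
    valid = set(atlas.roi_ids)
    effect_rois = {e.roi_id for e in config.effects}
    resolved = []
    for e in config.effects:
        if e.roi_id not in valid:
            raise ValueError(f"effect references ROI {e.roi_id} absent from the atlas")
        if e.channel == "RFCS":
            if e.partners is None:
                # prefer partners untouched by any injected effect so the
                # coupling manipulation stays orthogonal to other channels
                others = [r for r in atlas.roi_ids if r not in effect_rois]
                if len(others) < 2:
                    others = [r for r in atlas.roi_ids if r != e.roi_id]
                k = min(10, len(others))
                partners = tuple(int(p) for p in rng.choice(others, size=k, replace=False))
            else:
                partners = tuple(int(p) for p in e.partners)
                bad = set(partners) - valid
                if bad:
                    raise ValueError(f"RFCS partners absent from the atlas: {sorted(bad)}")
            resolved.append(replace(e, partners=partners))
        else:
            resolved.append(e)
    return tuple(resolved)


def simulate_subject(atlas: AtlasParcellation, config: CohortConfig, label: str,
                     rng: np.random.Generator,
                     resolved_effects: tuple[EffectSpec, ...] | None = None) -> np.ndarray:
    """Simulate one subject's (functional, structural) volume pair.

    Returns ``(functional, structural)`` arrays; group effects are
    applied only when ``label == "patient"``.
    """
    if label not in ("patient", "control"):
        raise ValueError(f"label must be 'patient' or 'control', got {label!r}")
    if resolved_effects is None:
        resolved_effects = resolve_effects(config, atlas, rng)
    is_pat = label == "patient"
    maps = _effect_maps(resolved_effects)
    shape = config.volume_shape
    T = config.n_timepoints

    # Latent signals couple ROI sets: each member ROI's shared component
    # mixes in a variance-preserving fraction of its latent, so coupling
    # raises inter-ROI correlation without touching amplitude (ALFF) or
    # within-ROI synchrony (ReHo).  Latents exist in both groups; an
    # RFCS effect only shifts the target ROI's mixing fraction.
    latents: list[tuple[np.ndarray, tuple[int, ...], int, float]] = []
    for e in resolved_effects:
        if e.channel == "RFCS":
            latents.append((_band_limited_signal(rng, T, config.tr),
                            (e.roi_id,) + (e.partners or ()),
                            e.roi_id, e.effect_size))

    functional = np.zeros(shape + (T,), dtype=np.float64)
    labels3d = atlas.labels
    for rid in atlas.roi_ids:
        vox = labels3d == rid
        n_vox = int(vox.sum())
        shared = _band_limited_signal(rng, T, config.tr)
        mix_parts, mix_total = [], 0.0
        for latent, members, target, d in latents:
            if rid not in members:
                continue
            base = _TARGET_COUPLING_FRAC if rid == target else _PARTNER_COUPLING_FRAC
            lam = base + rng.normal(0.0, RFCS_COUPLING_SD)
            if is_pat and rid == target:
                lam += d * RFCS_COUPLING_SD
            lam = float(np.clip(lam, 0.0, 0.95))
            mix_parts.append((lam, latent))
            mix_total += lam
        if mix_total >= 0.98:
            scale = 0.95 / mix_total
            mix_parts = [(l * scale, sig) for l, sig in mix_parts]
            mix_total *= scale
        if mix_parts:
            shared = np.sqrt(1.0 - mix_total) * shared
            for lam, sig in mix_parts:
                shared = shared + np.sqrt(lam) * sig
            shared = shared / shared.std()  # exact unit variance after mixing
        amp = 1.0 + rng.normal(0.0, ALFF_AMP_SD)
        if is_pat:
            amp += maps["ALFF"].get(rid, 0.0) * ALFF_AMP_SD
        frac = _BASE_SHARED_FRAC + rng.normal(0.0, REHO_FRAC_SD)
        if is_pat:
            frac += maps["ReHo"].get(rid, 0.0) * REHO_FRAC_SD
        frac = float(np.clip(frac, 0.02, 0.98))
        amp = max(amp, 0.05)
        private = _band_limited_signal(rng, T, config.tr, size=n_vox)
        functional[vox] = amp * (np.sqrt(frac) * shared + np.sqrt(1.0 - frac) * private)

    functional *= config.noise_sd

    structural = np.zeros(shape, dtype=np.float64)
    for rid in atlas.roi_ids:
        vox = labels3d == rid
        mean = GM_BASE + rng.normal(0.0, config.noise_sd)
        if is_pat:
            mean += maps["GM"].get(rid, 0.0) * config.noise_sd
        structural[vox] = mean + rng.normal(0.0, config.noise_sd, size=int(vox.sum()))
    return functional, structural


def demo_effects(atlas: AtlasParcellation, effect_size: float = 3.0,
                 per_channel: int = 2,
                 channels: tuple[str, ...] = CHANNELS) -> tuple[EffectSpec, ...]:
    """A canonical spread-out effect layout: ``per_channel`` ROIs per channel.

    Target ROIs are drawn evenly from the ROIs that keep interior voxels
    under boundary-excluding local statistics, so every channel's effect
    is measurable; assignment is deterministic given the atlas.
    """
    from .atlas import interior_roi_ids

    pool = interior_roi_ids(atlas)
    need = per_channel * len(channels)
    if len(pool) < need:
        raise ValueError(f"atlas has only {len(pool)} usable ROIs; need {need}")
    picks = [pool[int(round(i * (len(pool) - 1) / max(need - 1, 1)))]
             for i in range(need)]
    if len(set(picks)) < need:  # tiny atlases: fall back to first distinct ids
        picks = pool[:need]
    return tuple(EffectSpec(roi_id=picks[i], channel=channels[i % len(channels)],
                            effect_size=effect_size)
                 for i in range(need))


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full two-group cohort, deterministically in ``seed``.

    Patients come first in subject order, then controls; every subject
    gets an independent random substream derived from the cohort seed, so
    the cohort is bit-identical across runs with the same configuration.
    """
    atlas = make_atlas(config.volume_shape, config.n_rois)
    setup_rng = np.random.default_rng([config.seed, 0xC0FFEE])
    resolved = resolve_effects(config, atlas, setup_rng)
    subjects = []
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    for idx, label in enumerate(groups):
        rng = np.random.default_rng([config.seed, 1, idx])
        func, struct = simulate_subject(atlas, config, label, rng, resolved)
        subjects.append(Subject(subject_id=f"sub-{idx + 1:03d}", label=label,
                                functional=func, structural=struct))
    return Cohort(subjects=tuple(subjects), atlas=atlas, config=config,
                  resolved_effects=resolved)
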