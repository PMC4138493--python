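"""Synthetic fMRI-like and structural-MRI-like data with known ground truth.

Functional datasets are built the way SimTB-style simulators build them:
a set of 2D Gaussian spatial sources on a square grid is mixed with
event-modulated time courses (randomized auditory-oddball design convolved
with a canonical haemodynamic response), and Rician noise is added at a
calibrated contrast-to-noise ratio (CNR).  Structural cohorts are smooth
random fields with a class-dependent regional intensity reduction scaled by
a continuous severity covariate.

Everything here is a pure function of its configuration and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter

EVENT_TYPES = ("standard", "target", "novel", "spike")

#: Geometric 12-setting sweep of the source-width multiplier.  The endpoints
#: were fixed once, at packaging time, so that the total-overlap statistic of
#: the default 27-source layout spans from minimal (<= 0.3) to very high
#: (>= 0.88) overlap across the sweep.
DEFAULT_SPREAD_SWEEP = tuple(np.geomspace(1.0, 6.0, 12).tolist())

DEFAULT_CNR_RANGE = (0.65, 1.0)


# ---------------------------------------------------------------------------
# spatial sources


@dataclass(frozen=True)
class SourceSet:
    """A bank of isotropic 2D Gaussian spatial sources on a square grid.

    ``maps`` has one row per source, flattened in C order (row-fastest),
    each scaled to unit peak.  All sources share a common width
    ``base_width * spread`` (in pixels).
    """

    maps: np.ndarray          # (n_sources, grid_side**2)
    centers: np.ndarray       # (n_sources, 2) float pixel coordinates
    widths: np.ndarray        # (n_sources,) pixels
    grid_side: int
    spread: float

    @property
    def n_sources(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


def generate_sources(
    grid_side: int = 64,
    n_sources: int = 27,
    spread: float = 1.0,
    seed: int = 0,
    base_width: float | None = None,
    lattice_side: int | None = None,
) -> SourceSet:
    """Draw source centers on a jittered lattice and evaluate Gaussian maps.

    Centers are placed in distinct cells of a ``lattice_side x lattice_side``
    lattice (default: the smallest lattice that fits ``n_sources``) and
    jittered within their cell, so the default ``spread`` of 1 yields minimal
    overlap between sources.  The center layout depends only on the seed, not
    on ``spread``: widening sources never moves them.
    """
    if grid_side < 16:
        raise ValueError("grid_side must be >= 16")
    if n_sources < 2:
        raise ValueError("n_sources must be >= 2")
    if spread <= 0:
        raise ValueError("spread must be positive")
    if lattice_side is None:
        lattice_side = int(np.ceil(np.sqrt(n_sources)))
    if n_sources > lattice_side**2:
        raise ValueError(
            f"n_sources={n_sources} exceeds lattice capacity {lattice_side**2}"
        )

    rng = np.random.default_rng(seed)
    cell = grid_side / lattice_side
    cells = rng.permutation(lattice_side**2)[:n_sources]
    rows, cols = np.divmod(cells, lattice_side)
    jitter = rng.uniform(-cell / 6, cell / 6, size=(n_sources, 2))
    centers = np.column_stack([(rows + 0.5) * cell, (cols + 0.5) * cell]) + jitter

    if base_width is None:
        base_width = cell / 5.0
    widths = np.full(n_sources, base_width * spread)

    yy, xx = np.mgrid[0:grid_side, 0:grid_side]
    coords = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    d2 = ((coords[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
    maps = np.exp(-d2 / (2.0 * widths[:, None] ** 2))
    maps /= maps.max(axis=1, keepdims=True)
    return SourceSet(maps=maps, centers=centers, widths=widths,
                     grid_side=grid_side, spread=float(spread))


def _zscore_maps(maps: np.ndarray) -> np.ndarray:
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    return (maps - mu) / sd


def active_voxels(sources: SourceSet, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of voxels where any spatially z-scored source exceeds
    ``threshold`` standard deviations."""
    return (_zscore_maps(sources.maps) > threshold).any(axis=0)


def compute_overlap(sources: SourceSet, threshold: float = 0.5) -> float:
    """Fraction of grid voxels where more than one spatially z-scored source
    exceeds ``threshold`` standard deviations."""
    if sources.n_sources < 2:
        raise ValueError("overlap needs at least two sources")
    above = _zscore_maps(sources.maps) > threshold
    return float((above.sum(axis=0) >= 2).mean())


# ---------------------------------------------------------------------------
# event designs and time courses


@dataclass(frozen=True)
class EventDesign:
    """Event-related design: onsets per event type plus per-source modulation.

    ``modulation`` is (n_sources, 4) over the event types
    ``("standard", "target", "novel", "spike")``.  Spike events are noise
    events shared, near-identically, by exactly the two sources in
    ``spike_sources``; all other sources must have zero spike modulation.
    ``spike_amplitudes`` holds the per-event random spike magnitudes and
    ``spike_jitter_sd`` the relative amplitude jitter that makes the two
    spike trains *nearly* (not exactly) identical.
    """

    n_volumes: int
    tr_seconds: float
    event_onsets: dict[str, tuple[int, ...]]
    modulation: np.ndarray
    unique_noise_sd: float
    spike_sources: tuple[int, int]
    spike_amplitudes: tuple[float, ...] = ()
    spike_jitter_sd: float = 0.05
    #: constant source intensity the event modulations ride on.  Magnitude
    #: (Rician) noise is sign-preserving only around a positive baseline, as
    #: in real scanner intensities; the baseline is added at mixing time, not
    #: by generate_timecourses.
    baseline: float = 2.5

    def __post_init__(self) -> None:
        if self.n_volumes < 1 or self.tr_seconds <= 0:
            raise ValueError("need n_volumes >= 1 and tr_seconds > 0")
        if self.unique_noise_sd < 0:
            raise ValueError("unique_noise_sd must be nonnegative")
        for name, onsets in self.event_onsets.items():
            if name not in EVENT_TYPES:
                raise ValueError(f"unknown event type {name!r}")
            arr = np.asarray(onsets)
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_volumes):
                raise ValueError(f"onsets of {name!r} fall outside [0, n_volumes)")
        if self.modulation.shape[1] != len(EVENT_TYPES):
            raise ValueError("modulation must have one column per event type")
        i, j = self.spike_sources
        if i == j:
            raise ValueError("spike_sources must be two distinct sources")
        spike_col = self.modulation[:, EVENT_TYPES.index("spike")]
        others = np.delete(spike_col, [i, j])
        if np.any(others != 0):
            raise ValueError("only the two spike_sources may have spike modulation")

    @property
    def n_sources(self) -> int:
        return self.modulation.shape[0]


def default_design(
    n_sources: int = 27,
    n_volumes: int = 128,
    tr_seconds: float = 2.0,
    seed: int = 0,
    oddball_probs: Sequence[float] = (0.8, 0.1, 0.1),
    n_spikes: int = 6,
    spike_amplitude: float = 3.0,
    unique_noise_sd: float = 0.25,
) -> EventDesign:
    """Randomized oddball design: one task event every second volume with
    type probabilities ``oddball_probs`` (standard/target/novel), plus a
    sparse spike train shared by the last two sources.

    Each source is modulated by a random subset of the task events with
    signed amplitudes, so source activations are temporally correlated to a
    degree but each has its own behavior.
    """
    rng = np.random.default_rng(seed)
    trial_volumes = np.arange(0, n_volumes, 2)
    kinds = rng.choice(3, size=trial_volumes.size, p=list(oddball_probs))
    onsets = {
        name: tuple(int(v) for v in trial_volumes[kinds == k])
        for k, name in enumerate(("standard", "target", "novel"))
    }
    spike_pool = np.arange(1, n_volumes, 2)
    onsets["spike"] = tuple(
        int(v) for v in np.sort(rng.choice(spike_pool, size=n_spikes, replace=False))
    )

    modulation = np.zeros((n_sources, 4))
    for s in range(n_sources):
        modulated = rng.random(3) < 0.6
        if not modulated.any():
            modulated[rng.integers(3)] = True
        amps = rng.uniform(0.5, 1.5, size=3) * rng.choice([-1.0, 1.0], size=3)
        modulation[s, :3] = np.where(modulated, amps, 0.0)
    spike_sources = (n_sources - 2, n_sources - 1)
    modulation[spike_sources[0], 3] = spike_amplitude
    modulation[spike_sources[1], 3] = spike_amplitude
    spike_amplitudes = tuple(rng.normal(1.0, 0.25, size=n_spikes).tolist())

    return EventDesign(
        n_volumes=n_volumes,
        tr_seconds=tr_seconds,
        event_onsets=onsets,
        modulation=modulation,
        unique_noise_sd=unique_noise_sd,
        spike_sources=spike_sources,
        spike_amplitudes=spike_amplitudes,
    )


def hrf_kernel(tr_seconds: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR,
    peak-normalized (positive lobe peaking near 5-6 s, undershoot near 16 s)."""
    t = np.arange(0, duration, tr_seconds)
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.max()


def generate_timecourses(design: EventDesign, seed: int = 0) -> np.ndarray:
    """Per-source time courses: event trains convolved with the HRF, weighted
    by the modulation matrix, plus per-source unique Gaussian noise.

    Returns an (n_volumes, n_sources) matrix, deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_vol, n_src = design.n_volumes, design.n_sources
    kernel = hrf_kernel(design.tr_seconds)

    trains = np.zeros((len(EVENT_TYPES), n_vol))
    for k, name in enumerate(EVENT_TYPES):
        for pos, onset in enumerate(design.event_onsets.get(name, ())):
            amp = 1.0
            if name == "spike" and pos < len(design.spike_amplitudes):
                amp = design.spike_amplitudes[pos]
            trains[k, onset] += amp

    tcs = np.zeros((n_vol, n_src))
    spike_idx = EVENT_TYPES.index("spike")
    for s in range(n_src):
        signal = np.zeros(n_vol)
        for k in range(len(EVENT_TYPES)):
            w = design.modulation[s, k]
            if w == 0.0:
                continue
            train = trains[k]
            if k == spike_idx:
                # near-identical, not identical: independent per-event jitter
                jitter = 1.0 + design.spike_jitter_sd * rng.standard_normal(n_vol)
                train = train * jitter
            signal += w * np.convolve(train, kernel)[:n_vol]
        tcs[:, s] = signal
    tcs += design.unique_noise_sd * rng.standard_normal((n_vol, n_src))
    return tcs


# ---------------------------------------------------------------------------
# noise model and CNR


def compute_cnr(
    clean: np.ndarray, sigma_n: float, active: np.ndarray | None = None
) -> float:
    """Contrast-to-noise ratio of a noise-free dataset against noise level
    ``sigma_n``: the temporal standard deviation of the clean signal averaged
    over active voxels, divided by ``sigma_n``.

    ``active`` is the boolean voxel mask of source support (see
    :func:`active_voxels`); if omitted, all voxels with nonconstant signal
    count as active.
    """
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    clean = np.asarray(clean, dtype=float)
    sd = clean.std(axis=0)
    if active is None:
        active = sd > 1e-12
    if not np.any(active):
        raise ValueError("no active voxels: CNR undefined")
    return float(sd[active].mean() / sigma_n)


def mix_and_add_noise(
    clean: np.ndarray,
    target_cnr: float,
    seed: int = 0,
    active: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Add Rician noise calibrated to a target CNR.

    The noise level is set to ``sigma_n = mean active temporal sd / target``
    so the achieved CNR equals the target by construction; each voxel becomes
    ``sqrt((clean + n1)**2 + n2**2)`` with independent Gaussian n1, n2 of
    standard deviation ``sigma_n`` (the magnitude-image noise model).

    Returns ``(noisy, achieved_cnr, sigma_n)``.
    """
    if target_cnr <= 0:
        raise ValueError("target_cnr must be positive")
    clean = np.asarray(clean, dtype=float)
    if np.allclose(clean, 0):
        raise ValueError("clean data is identically zero: CNR undefined")
    sd = clean.std(axis=0)
    mask = sd > 1e-12 if active is None else np.asarray(active, bool)
    sigma_n = float(sd[mask].mean() / target_cnr)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma_n, size=clean.shape)
    n2 = rng.normal(0.0, sigma_n, size=clean.shape)
    noisy = np.sqrt((clean + n1) ** 2 + n2**2)
    achieved = compute_cnr(clean, sigma_n, active=mask)
    return noisy, achieved, sigma_n


# ---------------------------------------------------------------------------
# full functional datasets


@dataclass(frozen=True)
class GroundTruth:
    """One simulated subject with full ground truth."""

    sources: SourceSet
    tcs: np.ndarray           # (n_volumes, n_sources)
    design: EventDesign
    clean_data: np.ndarray    # tcs @ sources.maps
    noisy_data: np.ndarray
    achieved_cnr: float
    sigma_n: float
    seed: int


@dataclass(frozen=True)
class SimulatedStudy:
    """A multi-subject simulated study sharing one source layout."""

    sources: SourceSet
    subjects: tuple[GroundTruth, ...]
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def concatenated(self) -> np.ndarray:
        """Noisy data of all subjects stacked along the volume axis."""
        return np.vstack([s.noisy_data for s in self.subjects])

    def concatenated_tcs(self) -> np.ndarray:
        return np.vstack([s.tcs for s in self.subjects])


def simulate_subject(
    sources: SourceSet,
    target_cnr: float,
    seed: int,
    design: EventDesign | None = None,
) -> GroundTruth:
    """Simulate one subject: draw a design if none given, generate time
    courses, shift them onto the design's positive baseline, mix with the
    source maps and add calibrated Rician noise.

    The stored ``tcs`` include the baseline, so ``clean_data`` equals
    ``tcs @ sources.maps`` exactly; correlations against estimates are
    unaffected by the constant shift.
    """
    if design is None:
        design = default_design(n_sources=sources.n_sources, seed=seed)
    tcs = generate_timecourses(design, seed=seed) + design.baseline
    clean = tcs @ sources.maps
    act = active_voxels(sources)
    noisy, achieved, sigma_n = mix_and_add_noise(
        clean, target_cnr, seed=seed + 1, active=act
    )
    return GroundTruth(sources=sources, tcs=tcs, design=design,
                       clean_data=clean, noisy_data=noisy,
                       achieved_cnr=achieved, sigma_n=sigma_n, seed=seed)


def simulate_study(
    n_subjects: int = 20,
    grid_side: int = 64,
    n_sources: int = 27,
    spread: float = 1.0,
    cnr_range: tuple[float, float] = DEFAULT_CNR_RANGE,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a multi-subject event-related study.

    All subjects share one source layout; each gets its own randomized
    oddball design, unique time-course noise, and a per-subject target CNR
    drawn uniformly from ``cnr_range``.
    """
    rng = np.random.default_rng(seed)
    sources = generate_sources(grid_side, n_sources, spread, seed=seed)
    targets = rng.uniform(cnr_range[0], cnr_range[1], size=n_subjects)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    subjects = tuple(
        simulate_subject(sources, float(targets[i]), int(subject_seeds[i]))
        for i in range(n_subjects)
    )
    return SimulatedStudy(sources=sources, subjects=subjects, seed=seed)


def spread_sweep_overlaps(
    grid_side: int = 64,
    n_sources: int = 27,
    seed: int = 0,
    sweep: Sequence[float] = DEFAULT_SPREAD_SWEEP,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap statistic across the spread sweep with fixed source centers.

    Returns ``(spreads, overlaps)`` as arrays of equal length.
    """
    spreads = np.asarray(list(sweep), dtype=float)
    overlaps = np.array([
        compute_overlap(generate_sources(grid_side, n_sources, s, seed=seed))
        for s in spreads
    ])
    return spreads, overlaps


def generate_signed_source_data(
    grid_side: int = 32,
    n_sources: int = 8,
    n_volumes: int = 600,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, SourceSet]:
    """Signed-source dataset: source activity symmetric about baseline.

    Each volume activates a random subset of sources at amplitudes of
    either sign (no positive baseline, additive Gaussian noise), and the
    result is z-scored per voxel.  This is the regime where a hidden unit
    must represent activity on *both* sides of baseline: units with a
    symmetric output range can do it with one feature, while nonnegative
    units are pushed to split each source into a duplicate pair of
    opposite-sign receptive fields.

    Returns ``(data, sources)`` with ``data`` of shape
    (n_volumes, grid_side**2).
    """
    rng = np.random.default_rng(seed)
    sources = generate_sources(grid_side=grid_side, n_sources=n_sources,
                               spread=1.0, seed=seed)
    tcs = rng.choice([-1.0, 0.0, 0.0, 1.0], size=(n_volumes, n_sources))
    tcs *= rng.uniform(1.5, 2.5, size=(n_volumes, n_sources))
    clean = tcs @ sources.maps
    data = clean + noise_sd * rng.standard_normal(clean.shape)
    data = (data - data.mean(axis=0)) / data.std(axis=0)
    return data, sources


# ---------------------------------------------------------------------------
# structural cohorts


@dataclass(frozen=True)
class StructuralCohort:
    """Synthetic structural-MRI-like cohort: one nonnegative volume per
    subject, a binary label, and a severity covariate in [0, 1] that is 0
    for controls.  Patients lose intensity inside ``effect_regions`` in
    proportion to ``effect_size * severity``."""

    volumes: np.ndarray       # (n_subjects, n_voxels)
    labels: np.ndarray        # (n_subjects,) 0 = control, 1 = patient
    severity: np.ndarray      # (n_subjects,) in [0, 1]
    effect_regions: tuple[np.ndarray, ...]
    effect_size: float
    grid_side: int


def _smooth_field(rng: np.random.Generator, grid_side: int, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((grid_side, grid_side)), sigma)
    return f / f.std()


def _disk(grid_side: int, center: np.ndarray, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:grid_side, 0:grid_side]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return np.flatnonzero((d2 <= radius**2).ravel())


def generate_structural_cohort(
    n_controls: int = 100,
    n_patients: int = 100,
    grid_side: int = 32,
    effect_size: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.1,
    n_regions: int = 2,
) -> StructuralCohort:
    """Generate a two-class structural cohort with a severity spectrum.

    Every subject is a shared smooth template plus smooth subject noise
    (standard deviation ``noise_sd``); patients additionally lose
    ``effect_size * severity`` of intensity inside ``n_regions`` disk-shaped
    regions, with severity drawn uniformly from [0.1, 1] (controls: 0).
    """
    if n_controls < 1 or n_patients < 1:
        raise ValueError("need at least one subject per class")
    rng = np.random.default_rng(seed)
    template = 1.0 + 0.2 * _smooth_field(rng, grid_side, grid_side / 8)
    template = np.clip(template, 0.3, None)

    radius = grid_side / 6
    margin = radius + 2
    centers = rng.uniform(margin, grid_side - margin, size=(n_regions, 2))
    regions = tuple(_disk(grid_side, c, radius) for c in centers)

    n = n_controls + n_patients
    labels = np.concatenate([np.zeros(n_controls, int), np.ones(n_patients, int)])
    severity = np.zeros(n)
    severity[n_controls:] = rng.uniform(0.1, 1.0, size=n_patients)

    volumes = np.empty((n, grid_side**2))
    for i in range(n):
        vol = template + noise_sd * _smooth_field(rng, grid_side, 2.0)
        vol = vol.ravel().copy()
        if labels[i]:
            for region in regions:
                vol[region] -= effect_size * severity[i]
        volumes[i] = np.clip(vol, 0.0, None)
    return StructuralCohort(volumes=volumes, labels=labels, severity=severity,
                            effect_regions=regions, effect_size=float(effect_size),
                            grid_side=grid_side)


def generate_xor_cohort(
    n_per_class: int = 100,
    grid_side: int = 32,
    signal: float = 1.0,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> StructuralCohort:
    """Cohort with a nonlinearly separable class structure: the label is the
    XOR of the signs of two regional intensity offsets, so no linear readout
    of raw voxels can separate the classes.

    Used to probe whether depth helps a classifier; the ``severity`` field is
    zero throughout (it has no meaning here).
    """
    rng = np.random.default_rng(seed)
    template = 1.0 + 0.2 * _smooth_field(rng, grid_side, grid_side / 8)
    radius = grid_side / 6
    margin = radius + 2
    c1 = np.array([margin + 1, margin + 1])
    c2 = np.array([grid_side - margin - 1, grid_side - margin - 1])
    regions = (_disk(grid_side, c1, radius), _disk(grid_side, c2, radius))

    n = 2 * n_per_class
    signs = rng.choice([-1.0, 1.0], size=(n, 2))
    labels = (signs[:, 0] * signs[:, 1] > 0).astype(int)
    volumes = np.empty((n, grid_side**2))
    for i in range(n):
        vol = template + noise_sd * _smooth_field(rng, grid_side, 2.0)
        vol = vol.ravel().copy()
        vol[regions[0]] += signs[i, 0] * signal
        vol[regions[1]] += signs[i, 1] * signal
        volumes[i] = np.clip(vol, 0.0, None)
    return StructuralCohort(volumes=volumes, labels=labels,
                            severity=np.zeros(n), effect_regions=regions,
                            effect_size=float(signal), grid_side=grid_side)
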