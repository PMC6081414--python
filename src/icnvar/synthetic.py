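"""Synthetic two-group cohort generator for end-to-end pipeline testing.

Emulates a resting-state study of children with ADHD versus typically
developing controls: per-subject network time-courses with a controllable
degree of pairwise phase-difference dispersion, compact spatial template
maps mixed into small 4D volumes, Table-style phenotypes (sex, age, three
IQ scores, mean framewise displacement) and rigid-body motion traces.

The signal model for network i of one subject is

    x_i(t) = cos(2*pi*f*t*TR + eps_i(t)) + eta(t),

where the phase noise decomposes into an independent per-component term
of circular SD ``component_noise_sd`` and, for every unordered pair
(i, j), an antisymmetric pair-coupling term: a shared process zeta_ij(t)
added to phase i and subtracted from phase j.  The phase difference of
pair (i, j) therefore carries 4 * Var(zeta_ij), a dispersion specific to
that pair, while only a quarter of it leaks into the other pairs sharing
a component.  Each subject's pair-noise variance is the group value plus
additive between-subject heterogeneity (``pair_dispersion_hetero_var``,
in rad^2), giving every pair an individual phase-variability trait whose
spread does not scale with its mean - which is what lets a planted group
effect be attributed to the planted pairs rather than to their leakage.
The planted effect raises ``effect_pairs`` to
``effect_dispersion_patients`` in patients (versus
``effect_dispersion_controls`` in controls); all other pairs sit at
``pair_dispersion_base`` in both groups.

Group phenotype moments default to the study cohort they emulate
(100 patients / 140 controls; e.g. full IQ 106.36 +/- 13.02 versus
118.02 +/- 12.12).  IQ draws respect the inclusion criterion IQ > 80 via
a truncated normal whose location is adjusted so the *truncated* mean
matches the target moment.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .records import GROUP_CONTROL, GROUP_PATIENT, SubjectRecord
from .timecourses import DEFAULT_ICN_LABELS, SpatialTemplateSet, TimeSeriesMatrix

# Substream tags keeping the per-purpose random streams independent.
_STREAM_TIMECOURSE = 11
_STREAM_PHENOTYPE = 22
_STREAM_MOTION = 33
_STREAM_BOLD = 44
_GROUP_CODE = {GROUP_PATIENT: 1, GROUP_CONTROL: 0}

#: Default planted pairs: AN-RFPN, CBN-SMN, DMN-LFPN (component-disjoint, so
#: no planted pair shares the leakage of another).
DEFAULT_EFFECT_PAIRS = ((6, 8), (4, 5), (3, 9))


@dataclass(frozen=True)
class GroupPhenotypeParams:
    """Moments of one group's phenotype distributions."""

    male_fraction: float
    age_mean: float
    age_sd: float
    viq_mean: float
    viq_sd: float
    piq_mean: float
    piq_sd: float
    fiq_mean: float
    fiq_sd: float
    fd_mean: float       # mean framewise displacement, mm
    fd_shape: float = 4.0  # gamma shape; scale = fd_mean / fd_shape
    iq_floor: float = 80.0  # inclusion criterion: IQ strictly above this


#: Patient-group moments of the emulated cohort (n = 100, 88 male).
ADHD_PHENOTYPES = GroupPhenotypeParams(
    male_fraction=88 / 100,
    age_mean=12.1, age_sd=2.05,
    viq_mean=111.44, viq_sd=15.57,
    piq_mean=99.03, piq_sd=13.65,
    fiq_mean=106.36, fiq_sd=13.02,
    fd_mean=0.20,
)

#: Control-group moments (n = 140, 81 male).
CONTROL_PHENOTYPES = GroupPhenotypeParams(
    male_fraction=81 / 140,
    age_mean=11.44, age_sd=1.86,
    viq_mean=120.46, viq_sd=13.3,
    piq_mean=111.29, piq_sd=14.33,
    fiq_mean=118.02, fiq_sd=12.12,
    fd_mean=0.15,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic two-group cohort.

    Dispersions are circular SDs in radians.  Every unordered component
    pair carries coupling noise of SD ``pair_dispersion_base``; the pairs
    listed in ``effect_pairs`` are raised to ``effect_dispersion_patients``
    in the patient group (``effect_dispersion_controls`` in controls),
    planting a pair-specific group difference in downstream phase
    variability.  ``pair_dispersion_hetero_var`` (rad^2) is the SD of the
    additive between-subject spread of each pair's noise variance.
    """

    n_patients: int = 100
    n_controls: int = 140
    n_timepoints: int = 235      # 240 acquired volumes minus 5 discarded
    tr_seconds: float = 2.0
    n_components: int = 10
    carrier_freq_hz: float = 0.05
    component_noise_sd: float = 0.05
    pair_dispersion_base: float = 0.1
    effect_dispersion_patients: float = 0.3
    effect_dispersion_controls: float = 0.05
    pair_dispersion_hetero_var: float = 0.01
    effect_pairs: tuple[tuple[int, int], ...] = DEFAULT_EFFECT_PAIRS
    obs_noise_sd: float = 0.2
    phenotypes_patients: GroupPhenotypeParams = ADHD_PHENOTYPES
    phenotypes_controls: GroupPhenotypeParams = CONTROL_PHENOTYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints too small")
        nyquist = 0.5 / self.tr_seconds
        if not (0.0 < self.carrier_freq_hz < nyquist):
            raise ValueError(
                f"carrier_freq_hz={self.carrier_freq_hz} must lie in (0, Nyquist={nyquist:g}) Hz"
            )
        for v in (
            self.component_noise_sd,
            self.pair_dispersion_base,
            self.effect_dispersion_patients,
            self.effect_dispersion_controls,
            self.pair_dispersion_hetero_var,
            self.obs_noise_sd,
        ):
            if v < 0:
                raise ValueError("dispersions and noise SDs must be nonnegative")
        for i, j in self.effect_pairs:
            if i == j or not (0 <= i < self.n_components and 0 <= j < self.n_components):
                raise ValueError(f"invalid effect pair ({i}, {j})")

    @property
    def groups(self) -> tuple[str, str]:
        return (GROUP_PATIENT, GROUP_CONTROL)

    def n_subjects(self, group: str) -> int:
        return self.n_patients if group == GROUP_PATIENT else self.n_controls

    def phenotypes(self, group: str) -> GroupPhenotypeParams:
        return self.phenotypes_patients if group == GROUP_PATIENT else self.phenotypes_controls

    def pair_dispersion(self, group: str, i: int, j: int) -> float:
        """Group-level circular SD of the coupling noise of pair (i, j)."""
        if (i, j) in self.effect_pairs or (j, i) in self.effect_pairs:
            return (
                self.effect_dispersion_patients
                if group == GROUP_PATIENT
                else self.effect_dispersion_controls
            )
        return self.pair_dispersion_base

    def as_null(self) -> "SimulationConfig":
        """A no-effect copy: identical signal and phenotype generators per group."""
        return replace(
            self,
            effect_pairs=(),
            phenotypes_patients=self.phenotypes_controls,
        )


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def simulate_timecourses(
    config: SimulationConfig, group: str, subject_index: int = 0
) -> TimeSeriesMatrix:
    """Network time-courses for one subject of the given group."""
    if group not in _GROUP_CODE:
        raise ValueError(f"unknown group {group!r}")
    rng = _rng(config.seed, _STREAM_TIMECOURSE, _GROUP_CODE[group], subject_index)
    T, N = config.n_timepoints, config.n_components
    t = np.arange(T) * config.tr_seconds
    eps = rng.standard_normal((T, N)) * config.component_noise_sd
    for i in range(N):
        for j in range(i + 1, N):
            # subject-level pair-noise variance: group value + additive trait
            v = config.pair_dispersion(group, i, j) ** 2
            if config.pair_dispersion_hetero_var > 0:
                v += rng.normal(0.0, config.pair_dispersion_hetero_var)
            v = max(v, 0.0)
            if v > 0:
                zeta = rng.normal(0.0, np.sqrt(v), T)
                eps[:, i] += zeta
                eps[:, j] -= zeta
    x = np.cos(2.0 * np.pi * config.carrier_freq_hz * t[:, None] + eps)  # noise wraps inside cos
    if config.obs_noise_sd > 0:
        x = x + rng.normal(0.0, config.obs_noise_sd, size=(T, N))
    labels = tuple(DEFAULT_ICN_LABELS)[:N] + tuple(f"ICN{i+1}" for i in range(len(DEFAULT_ICN_LABELS), N))
    return TimeSeriesMatrix(data=x, tr_seconds=config.tr_seconds, labels=labels)


def simulate_templates(
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    n_components: int = 10,
    seed: int = 0,
    blob_sd_vox: float = 1.0,
    spacing_vox: int = 5,
    support_floor: float = 0.05,
) -> SpatialTemplateSet:
    """Compact Gaussian-blob template maps with unit peak on a shared grid.

    Blob centers sit on a regular lattice with ``spacing_vox`` separation
    and values below ``support_floor`` are zeroed, so with the defaults the
    blob supports are disjoint (support radius ~2.45 voxels at spacing 5)
    and pairwise spatial inner products are exactly zero.  The seed
    shuffles which lattice sites are used.  Raises if the grid cannot host
    ``n_components`` blobs.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must be 3D")
    axes_sites = [
        np.arange(spacing_vox // 2, g - spacing_vox // 4, spacing_vox) for g in grid_shape
    ]
    centers = np.array(
        [(x, y, z) for x in axes_sites[0] for y in axes_sites[1] for z in axes_sites[2]]
    )
    if len(centers) < n_components:
        raise ValueError(
            f"grid {grid_shape} holds only {len(centers)} blobs at spacing {spacing_vox}; "
            f"{n_components} requested"
        )
    rng = _rng(seed, 7)
    centers = centers[rng.permutation(len(centers))[:n_components]]
    coords = np.stack(
        np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    maps = np.empty((n_components, *grid_shape))
    for k, c in enumerate(centers):
        d2 = ((coords - c) ** 2).sum(axis=-1)
        blob = np.exp(-d2 / (2.0 * blob_sd_vox**2))
        blob[blob < support_floor] = 0.0
        maps[k] = blob
    mask = maps.max(axis=0) > 0.0
    labels = tuple(DEFAULT_ICN_LABELS)[:n_components] + tuple(
        f"ICN{i+1}" for i in range(len(DEFAULT_ICN_LABELS), n_components)
    )
    return SpatialTemplateSet(maps=maps, mask=mask, labels=labels)


def simulate_bold(
    templates: SpatialTemplateSet,
    timecourses: TimeSeriesMatrix,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Mix time-courses through the template maps into a 4D volume.

    volume[..., t] = sum_i map_i * x_i(t) + voxelwise Gaussian noise.
    """
    if templates.n_components != timecourses.n_components:
        raise ValueError(
            f"{templates.n_components} templates vs {timecourses.n_components} time-courses"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    # (X,Y,Z,T) = maps^T (N,XYZ) contracted with data (T,N)
    vol = np.tensordot(timecourses.data, templates.maps, axes=(1, 0))  # (T, X, Y, Z)
    vol = np.moveaxis(vol, 0, -1)
    if noise_sd > 0:
        rng = _rng(seed, _STREAM_BOLD)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return vol


@lru_cache(maxsize=None)
def _truncnorm_loc(target_mean: float, sd: float, floor: float) -> float:
    """Location of a floor-truncated normal whose truncated mean hits the target."""

    def truncated_mean_error(loc: float) -> float:
        a = (floor - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - target_mean

    return optimize.brentq(truncated_mean_error, target_mean - 6 * sd, target_mean)


def _draw_iq(rng: np.random.Generator, n: int, mean: float, sd: float, floor: float) -> np.ndarray:
    loc = _truncnorm_loc(mean, sd, floor)
    a = (floor - loc) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=n, random_state=rng)


def simulate_phenotypes(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw a full cohort of phenotype records, patients first."""
    rng = _rng(config.seed, _STREAM_PHENOTYPE)
    records: list[SubjectRecord] = []
    for group in config.groups:
        p = config.phenotypes(group)
        n = config.n_subjects(group)
        sex = np.where(rng.random(n) < p.male_fraction, "M", "F")
        age = rng.normal(p.age_mean, p.age_sd, n)
        viq = _draw_iq(rng, n, p.viq_mean, p.viq_sd, p.iq_floor)
        piq = _draw_iq(rng, n, p.piq_mean, p.piq_sd, p.iq_floor)
        fiq = _draw_iq(rng, n, p.fiq_mean, p.fiq_sd, p.iq_floor)
        fd = rng.gamma(p.fd_shape, p.fd_mean / p.fd_shape, n)
        for k in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{group}_{k:04d}",
                    group=group,
                    sex=str(sex[k]),
                    age=float(age[k]),
                    viq=float(viq[k]),
                    piq=float(piq[k]),
                    fiq=float(fiq[k]),
                    mean_fd=float(fd[k]),
                )
            )
    return records


def simulate_motion(
    n_timepoints: int,
    step_sd: float = 0.02,
    spike_frames: tuple[int, ...] = (),
    spike_mm: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Random-walk rigid-body motion trace (T x 6), optional x-translation spikes.

    Rotations use a step SD scaled by 1/50 so their arc-length contribution
    to framewise displacement matches the translations.  A spike adds
    ``spike_mm`` to the x translation at the listed frames only, so FD at a
    spiked frame rises by exactly ``spike_mm``.
    """
    for f in spike_frames:
        if not 0 <= f < n_timepoints:
            raise ValueError(f"spike frame {f} outside [0, {n_timepoints})")
    rng = _rng(seed, _STREAM_MOTION)
    steps = rng.standard_normal((n_timepoints, 6)) * step_sd
    steps[:, 3:] /= 50.0
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    for f in spike_frames:
        trace[f, 0] += spike_mm
    return trace


@dataclass
class Cohort:
    """A generated cohort: aligned phenotype records and time-course matrices."""

    config: SimulationConfig
    records: list[SubjectRecord]
    timecourses: list[TimeSeriesMatrix]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate phenotypes and time-courses for every subject."""
    records = simulate_phenotypes(config)
    timecourses = []
    for group in config.groups:
        for k in range(config.n_subjects(group)):
            timecourses.append(simulate_timecourses(config, group, k))
    return Cohort(config=config, records=records, timecourses=timecourses)
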