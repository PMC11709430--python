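"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a blocked problem-solving fMRI study across the
adult lifespan: 150 scans at TR 2 s containing eight alternating 30-s
easy/hard blocks, behavioural correct/incorrect counts whose score declines
linearly with age, a task-responsive "MDN-like" region, and candidate
compensation regions whose Hard - Easy amplitude and multivoxel pattern
information vary with age and performance.  Noise is AR(1) over scans;
BOLD amplitude is modulated by an age-dependent vascular gain that is also
expressed in the participant's resting-state fluctuation amplitude (RSFA)
map, so that vascular and neural age effects can be dissociated downstream.

Every draw is keyed off ``SimulationConfig.seed`` plus stable per-purpose
keys, so identical configurations regenerate bit-identical cohorts.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import ParticipantRecord, RSFAMap, VoxelDataset, default_affine, records_to_frame
from .glm import BlockDesign, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_design",
    "simulate_behaviour",
    "simulate_bold",
    "simulate_rsfa",
    "simulate_cohort",
    "region_layout",
    "write_cohort",
]


@dataclass
class RegionSpec:
    """Ground-truth effect structure of one cuboid region.

    Amplitudes are in percent of the 100-unit baseline (so a contrast of
    1.0 is a 1% signal change).  ``*_slope`` fields are per standard
    deviation of the cohort covariate.  ``unique_info_base`` /
    ``unique_info_age_slope`` control the amplitude of a zero-mean
    multivoxel pattern, orthogonal to the region's mean-response profile,
    that carries task information invisible to the region average.
    """

    label: str
    n_voxels: int
    base_contrast: float = 0.0
    age_slope: float = 0.0
    perf_slope: float = 0.0
    interaction_slope: float = 0.0
    unique_info_base: float = 0.0
    unique_info_age_slope: float = 0.0
    vascular_age_slope: float = 0.0
    subject_sd: float = 0.15  # participant-level residual contrast amplitude
    pattern_gain_sd: float = 0.3  # voxel-to-voxel spread of the mean response

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError(f"region {self.label!r} needs at least one voxel")


def default_region_specs() -> list[RegionSpec]:
    """Three-region cohort: a strongly task-positive MDN-like region and
    two candidate compensation regions (one with an age-increasing unique
    pattern and an over-additive age x performance effect, one additive
    with no unique information)."""
    return [
        RegionSpec(
            label="mdn",
            n_voxels=64,
            base_contrast=0.8,
            age_slope=-0.10,
            perf_slope=0.10,
            vascular_age_slope=-0.30,
        ),
        RegionSpec(
            label="cuneal",
            n_voxels=64,
            base_contrast=-0.06,
            age_slope=0.09,
            perf_slope=0.08,
            interaction_slope=0.04,
            unique_info_base=0.15,
            unique_info_age_slope=0.10,
            vascular_age_slope=-0.30,
        ),
        RegionSpec(
            label="frontal",
            n_voxels=64,
            base_contrast=-0.03,
            age_slope=0.08,
            perf_slope=0.08,
            interaction_slope=0.0,
            unique_info_base=0.0,
            unique_info_age_slope=0.0,
            vascular_age_slope=-0.30,
        ),
    ]


@dataclass
class SimulationConfig:
    """Cohort- and acquisition-level parameters of a simulated study.

    Defaults follow the emulated study design: 150 scans at TR 2 s with
    four 30-s blocks per condition in alternating order, a lifespan age
    range, and a behavioural score that declines ~0.7 SD per SD of age.
    """

    n_participants: int = 150
    age_range: tuple[float, float] = (19.0, 87.0)
    n_scans: int = 150
    tr: float = 2.0
    block_length: float = 30.0
    n_blocks_per_condition: int = 4
    region_specs: list[RegionSpec] = field(default_factory=default_region_specs)
    noise_ar1: float = 0.3
    noise_sd: float = 1.0
    # coherent noise shared by all voxels of a region (physiological-like);
    # it bounds the information gained by averaging ever more voxels
    noise_shared_sd: float = 1.5
    behav_age_slope: float = -0.7
    seed: int = 0
    # layout / gap placement
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    baseline: float = 100.0
    gap_placement: str = "split"  # split | start | end
    # behavioural counts
    easy_trials: int = 32
    hard_trials: int = 16
    easy_accuracy: float = 0.90
    hard_accuracy: float = 0.65
    performance_sd: float = 5.0  # SD of the true score, in score units
    # vascular model
    vascular_sd: float = 0.10
    rsfa_voxel_sd: float = 0.05
    rsfa_floor: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        for name in ("n_participants", "n_scans", "n_blocks_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        total_task = 2 * self.n_blocks_per_condition * self.block_length
        if total_task > self.n_scans * self.tr + 1e-9:
            raise ValueError(
                f"task blocks ({total_task:g} s) exceed the run "
                f"({self.n_scans * self.tr:g} s)"
            )
        labels = [s.label for s in self.region_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)


@dataclass
class SyntheticTruth:
    """Recorded ground truth for one participant's BOLD simulation."""

    participant_id: str
    seed: int
    contrast: dict[str, float]  # per-region true mean Hard - Easy (neural)
    measured_contrast: dict[str, float]  # after vascular gain
    vascular_gain: dict[str, float]
    unique_amplitude: dict[str, float]


def _stable_key(*parts) -> list[int]:
    """Deterministic integer key sequence from mixed str/int parts."""
    out = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode()))
    return out


def _rng(seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(_stable_key(seed, *parts)))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(config: SimulationConfig) -> BlockDesign:
    """Alternating easy/hard block design.

    The run is longer than the task (e.g. 300 s vs 8 x 30 s = 240 s); the
    unmodelled remainder is placed as rest according to
    ``config.gap_placement``: split evenly between run start and end
    (default), or entirely at the start or end.
    """
    total = config.n_scans * config.tr
    n_blocks = 2 * config.n_blocks_per_condition
    task_time = n_blocks * config.block_length
    gap = total - task_time
    if config.gap_placement == "split":
        start = gap / 2.0
    elif config.gap_placement == "start":
        start = gap
    elif config.gap_placement == "end":
        start = 0.0
    else:
        raise ValueError(f"unknown gap_placement {config.gap_placement!r}")
    onsets = start + np.arange(n_blocks) * config.block_length
    labels = ["easy" if i % 2 == 0 else "hard" for i in range(n_blocks)]
    return BlockDesign(
        onsets=onsets,
        durations=np.full(n_blocks, config.block_length),
        labels=labels,
        tr=config.tr,
        n_scans=config.n_scans,
    )


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def simulate_behaviour(
    ages: np.ndarray,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[ParticipantRecord]:
    """Draw per-condition correct/incorrect counts for each participant.

    A latent standardised performance trait declines linearly with
    standardised age at rate ``behav_age_slope``.  The trait shifts the
    per-condition success probabilities, and counts are binomial draws over
    the fixed per-condition trial budgets.  The binomial sampling variance
    is folded into the latent noise budget so that the standardised
    age slope of the realised score matches the configured slope in
    expectation.
    """
    if seed is None:
        seed = config.seed
    ages = np.asarray(ages, dtype=float)
    lo, hi = config.age_range
    if np.any(ages < lo) or np.any(ages > hi):
        raise ValueError("ages fall outside the configured age_range")
    rng = _rng(seed, "behaviour")
    sd_age = ages.std()
    z_age = (ages - ages.mean()) / sd_age if sd_age > 0 else np.zeros_like(ages)
    slope = config.behav_age_slope
    sd_s = config.performance_sd
    p_e, p_h = config.easy_accuracy, config.hard_accuracy
    deterministic = sd_s == 0
    if deterministic:
        score_dev = np.zeros(ages.size)
    else:
        # binomial sampling variance of the score at nominal accuracies is
        # folded into the latent noise budget
        binom_var = (
            config.hard_trials * p_h * (1 - p_h)
            + config.easy_trials * p_e * (1 - p_e)
        )
        resid_var = max(0.0, 1.0 - slope**2 - binom_var / sd_s**2)
        latent = slope * z_age + rng.normal(
            0.0, np.sqrt(resid_var), size=ages.size
        )
        score_dev = sd_s * latent  # deviation of the score from its mean

    sexes = np.where(rng.random(ages.size) < 0.5, "F", "M")
    records = []
    for i, age in enumerate(ages):
        # moving the score by d moves each condition's (correct - incorrect)
        # by d, i.e. each success probability by d / (2 n_c)
        ph = float(np.clip(p_h + score_dev[i] / (2 * config.hard_trials), 0.02, 0.98))
        pe = float(np.clip(p_e + score_dev[i] / (2 * config.easy_trials), 0.02, 0.98))
        if deterministic:
            hc = int(round(config.hard_trials * ph))
            ec = int(round(config.easy_trials * pe))
        else:
            hc = int(rng.binomial(config.hard_trials, ph))
            ec = int(rng.binomial(config.easy_trials, pe))
        records.append(
            ParticipantRecord(
                id=f"sub-{i + 1:03d}",
                age=float(age),
                sex=str(sexes[i]),
                hard_correct=hc,
                hard_incorrect=config.hard_trials - hc,
                easy_correct=ec,
                easy_incorrect=config.easy_trials - ec,
            )
        )
    return records


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _cuboid_dims(n: int, max_side: int) -> tuple[int, int, int]:
    """Near-cubic box with at least ``n`` cells, each side <= max_side."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    dims = [side, side, side]
    # shrink trailing dims while capacity still suffices
    while dims[0] * dims[1] * (dims[2] - 1) >= n and dims[2] > 1:
        dims[2] -= 1
    while dims[0] * (dims[1] - 1) * dims[2] >= n and dims[1] > 1:
        dims[1] -= 1
    if any(d > max_side for d in dims):
        raise ValueError("region does not fit in the grid")
    return tuple(dims)


def region_layout(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Place each region as a disjoint cuboid on the grid.

    Cuboids are stacked along the first axis with a one-voxel gap,
    starting at index (1, 1, 1); within its bounding box a region takes
    the first ``n_voxels`` cells in C order (always a connected set).
    """
    shape = config.grid_shape
    masks: dict[str, np.ndarray] = {}
    x0 = 1
    for spec in config.region_specs:
        dims = _cuboid_dims(spec.n_voxels, min(shape) - 2)
        if x0 + dims[0] > shape[0]:
            raise ValueError("regions do not fit along the grid's first axis")
        box = np.zeros(dims, dtype=bool)
        box.ravel()[: spec.n_voxels] = True
        mask = np.zeros(shape, dtype=bool)
        mask[x0 : x0 + dims[0], 1 : 1 + dims[1], 1 : 1 + dims[2]] = box
        masks[spec.label] = mask
        x0 += dims[0] + 1
    return masks


# ---------------------------------------------------------------------------
# vascular state shared by BOLD and RSFA
# ---------------------------------------------------------------------------

def _vascular_gain(
    spec: RegionSpec, participant: ParticipantRecord, config: SimulationConfig,
    seed: int,
) -> float:
    rng = _rng(seed, "vascular", participant.id, spec.label)
    z = participant.z_age if participant.z_age is not None else 0.0
    gain = 1.0 + spec.vascular_age_slope * z + rng.normal(0.0, config.vascular_sd)
    return float(max(gain, config.rsfa_floor))


def _region_profiles(
    spec: RegionSpec, participant: ParticipantRecord, config: SimulationConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mean-response gains and the unique-information pattern.

    The gain profile ``g`` (mean 1) is fixed per region so the multivoxel
    response architecture is shared across participants.  The unique
    pattern ``p`` is drawn per participant, then projected orthogonal to
    the constant and to ``g`` and normalised to unit RMS, so it has zero
    spatial mean (it survives mean removal) and does not move the region
    average or correlate with the mean-response pattern.
    """
    rng_g = _rng(seed, "gains", spec.label)
    g = 1.0 + spec.pattern_gain_sd * rng_g.standard_normal(spec.n_voxels)
    rng_p = _rng(seed, "pattern", participant.id, spec.label)
    p = rng_p.standard_normal(spec.n_voxels)
    if spec.n_voxels > 2:
        basis = np.column_stack([np.ones(spec.n_voxels), g])
        q, _ = np.linalg.qr(basis)
        p = p - q @ (q.T @ p)
    rms = np.sqrt(np.mean(p**2))
    if rms > 0:
        p = p / rms
    return g, p


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def _ar1_noise(
    rng: np.random.Generator, n_scans: int, n_voxels: int, a: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_scans, n_voxels))
    w = rng.standard_normal((n_scans, n_voxels))
    if a == 0:
        return sd * w
    out = np.empty_like(w)
    out[0] = w[0]
    innov_sd = np.sqrt(1.0 - a**2)
    for t in range(1, n_scans):
        out[t] = a * out[t - 1] + innov_sd * w[t]
    return sd * out


def simulate_bold(
    design: BlockDesign,
    region_specs: list[RegionSpec],
    participant: ParticipantRecord,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[VoxelDataset, SyntheticTruth]:
    """Simulate one participant's 4D run over the configured grid.

    Voxels inside each region respond to the hard condition with amplitude
    ``vascular_gain * (c * g_v + u * p_v)`` where ``c`` is the participant's
    true regional contrast (base plus age/performance/interaction slopes
    plus a participant-level residual), ``g`` the fixed voxel gain profile
    and ``p`` the participant's unique-information pattern with amplitude
    ``u``.  All voxels carry baseline plus AR(1) noise.
    """
    if seed is None:
        seed = config.seed
    for spec in region_specs:
        if spec.n_voxels < 1:
            raise ValueError(f"region {spec.label!r} has no voxels")
    z_age = participant.z_age if participant.z_age is not None else 0.0
    z_perf = participant.z_performance if participant.z_performance is not None else 0.0

    layout_cfg = (
        config
        if [s.label for s in config.region_specs] == [s.label for s in region_specs]
        else _config_with_specs(config, region_specs)
    )
    masks = region_layout(layout_cfg)

    dm = build_design(design)
    i_hard = dm.names.index("hard")
    task = dm.values[:, i_hard]  # HRF-convolved hard-block regressor

    shape = config.grid_shape
    n_grid = int(np.prod(shape))
    coords = np.argwhere(np.ones(shape, dtype=bool))
    rng_noise = _rng(seed, "noise", participant.id)
    data = config.baseline + _ar1_noise(
        rng_noise, design.n_scans, n_grid, config.noise_ar1, config.noise_sd
    )
    if config.noise_shared_sd > 0:
        # one coherent series per region plus one for the background
        region_cells = np.zeros(n_grid, dtype=bool)
        for spec in region_specs:
            rng_sh = _rng(seed, "shared", participant.id, spec.label)
            shared = _ar1_noise(
                rng_sh, design.n_scans, 1, config.noise_ar1,
                config.noise_shared_sd,
            )
            cells = masks[spec.label].ravel()
            data[:, cells] += shared
            region_cells |= cells
        rng_bg = _rng(seed, "shared", participant.id, "background")
        shared_bg = _ar1_noise(
            rng_bg, design.n_scans, 1, config.noise_ar1, config.noise_shared_sd
        )
        data[:, ~region_cells] += shared_bg

    truth_c: dict[str, float] = {}
    truth_m: dict[str, float] = {}
    truth_v: dict[str, float] = {}
    truth_u: dict[str, float] = {}
    flat = np.arange(n_grid).reshape(shape)
    for spec in region_specs:
        cols = flat[masks[spec.label]]
        rng_subj = _rng(seed, "contrast", participant.id, spec.label)
        c = (
            spec.base_contrast
            + spec.age_slope * z_age
            + spec.perf_slope * z_perf
            + spec.interaction_slope * z_age * z_perf
            + spec.subject_sd * rng_subj.standard_normal()
        )
        u = spec.unique_info_base + spec.unique_info_age_slope * z_age
        gain = _vascular_gain(spec, participant, config, seed)
        g, p = _region_profiles(spec, participant, config, seed)
        amp = gain * (c * g + u * p)  # per-voxel Hard - Easy amplitude
        data[:, cols] += np.outer(task, amp)
        truth_c[spec.label] = float(c)
        truth_m[spec.label] = float(gain * c)
        truth_v[spec.label] = float(gain)
        truth_u[spec.label] = float(u)

    dataset = VoxelDataset(
        data=data, coords=coords, shape=shape, tr=config.tr,
        affine=config.affine,
    )
    truth = SyntheticTruth(
        participant_id=participant.id,
        seed=int(seed),
        contrast=truth_c,
        measured_contrast=truth_m,
        vascular_gain=truth_v,
        unique_amplitude=truth_u,
    )
    return dataset, truth


def _config_with_specs(config: SimulationConfig, specs: list[RegionSpec]) -> SimulationConfig:
    import copy

    cfg = copy.copy(config)
    cfg.region_specs = list(specs)
    return cfg


def simulate_rsfa(
    region_specs: list[RegionSpec],
    participant: ParticipantRecord,
    config: SimulationConfig,
    seed: int | None = None,
) -> RSFAMap:
    """Per-voxel resting fluctuation amplitude map.

    Region voxels fluctuate with the participant's vascular gain (the same
    gain that scales the simulated BOLD response) plus voxel noise;
    background voxels sit at unit amplitude.  Values are floored at
    ``config.rsfa_floor`` (with a log message) so the map is strictly
    positive.
    """
    if seed is None:
        seed = config.seed
    layout_cfg = (
        config
        if [s.label for s in config.region_specs] == [s.label for s in region_specs]
        else _config_with_specs(config, region_specs)
    )
    masks = region_layout(layout_cfg)
    rng = _rng(seed, "rsfa", participant.id)
    values = 1.0 + config.rsfa_voxel_sd * rng.standard_normal(config.grid_shape)
    for spec in region_specs:
        gain = _vascular_gain(spec, participant, config, seed)
        m = masks[spec.label]
        values[m] = gain + config.rsfa_voxel_sd * rng.standard_normal(int(m.sum()))
    n_clip = int(np.sum(values < config.rsfa_floor))
    if n_clip:
        logger.info(
            "RSFA map for %s: clipped %d non-positive voxels to %.3g",
            participant.id, n_clip, config.rsfa_floor,
        )
        values = np.maximum(values, config.rsfa_floor)
    return RSFAMap(values=values, affine=config.affine)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated cohort plus its shared design and ground truth."""

    config: SimulationConfig
    records: list[ParticipantRecord]
    design: BlockDesign

    def bold_for(self, record: ParticipantRecord) -> tuple[VoxelDataset, SyntheticTruth]:
        return simulate_bold(
            self.design, self.config.region_specs, record, self.config,
            seed=self.config.seed,
        )

    def rsfa_for(self, record: ParticipantRecord) -> RSFAMap:
        return simulate_rsfa(
            self.config.region_specs, record, self.config, seed=self.config.seed
        )

    @property
    def region_masks(self) -> dict[str, np.ndarray]:
        return region_layout(self.config)


def standardise_records(records: list[ParticipantRecord]) -> None:
    """Fill ``z_age`` / ``z_performance`` in place (cohort mean 0, SD 1)."""
    ages = np.array([r.age for r in records], dtype=float)
    perf = np.array([r.performance for r in records], dtype=float)
    if ages.std() == 0 or perf.std() == 0:
        raise ValueError("cannot standardise a constant covariate")
    z_age = (ages - ages.mean()) / ages.std()
    z_perf = (perf - perf.mean()) / perf.std()
    for r, za, zp in zip(records, z_age, z_perf):
        r.z_age = float(za)
        r.z_performance = float(zp)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw ages, behaviour and standardised covariates for a cohort.

    BOLD and RSFA data are generated lazily per participant via
    :meth:`Cohort.bold_for` / :meth:`Cohort.rsfa_for` to bound memory.
    """
    rng = _rng(config.seed, "ages")
    lo, hi = config.age_range
    ages = np.sort(rng.uniform(lo, hi, size=config.n_participants))
    records = simulate_behaviour(ages, config, seed=config.seed)
    standardise_records(records)
    design = generate_design(config)
    return Cohort(config=config, records=records, design=design)


# ---------------------------------------------------------------------------
# on-disk interface
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path, write_bold: bool = True) -> dict[str, str]:
    """Write a cohort in a BIDS-flavoured layout.

    Emits ``participants.tsv``, a shared ``task-cattell_events.tsv``,
    per-participant 4D BOLD and 3D RSFA NIfTIs (optional) and a JSON
    ground-truth sidecar.  Returns a mapping of artifact names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    frame = records_to_frame(cohort.records)
    p_path = out_dir / "participants.tsv"
    frame.to_csv(p_path, sep="\t", index=False)
    artifacts["participants"] = str(p_path)

    e_path = out_dir / "task-cattell_events.tsv"
    cohort.design.to_events_frame().to_csv(e_path, sep="\t", index=False)
    artifacts["events"] = str(e_path)

    truths = {}
    for record in cohort.records:
        if write_bold:
            dataset, truth = cohort.bold_for(record)
            b_path = out_dir / f"{record.id}_task-cattell_bold.nii"
            dataset.to_nifti().to_filename(b_path)
            artifacts[f"bold_{record.id}"] = str(b_path)
            r_path = out_dir / f"{record.id}_rsfa.nii"
            cohort.rsfa_for(record).to_nifti().to_filename(r_path)
            artifacts[f"rsfa_{record.id}"] = str(r_path)
        else:
            _, truth = cohort.bold_for(record)
        truths[record.id] = asdict(truth)

    t_path = out_dir / "ground_truth.json"
    t_path.write_text(json.dumps(truths, indent=1, sort_keys=True))
    artifacts["ground_truth"] = str(t_path)
    return artifacts
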