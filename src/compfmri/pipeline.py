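"""End-to-end orchestration of the compensation analysis.

Stages: ``simulate`` (synthetic cohort to disk) -> ``glm`` (per-participant
prewhitened first-level fit, contrast and RSFA maps) -> ``group``
(behavioural regression, voxel-wise inference with TFCE permutation
correction, intersection ROIs, ROI regression tables) -> ``mvb``
(joint/single/ROI-only decoding fits per participant) -> ``compare``
(boost categories, spread, group logistic/linear models) -> ``report``.

Stages communicate through on-disk artifacts in the run directory, so any
stage can be rerun from cached upstream outputs; a stage is skipped when
its manifest fragment exists and every recorded checksum still matches.
A single master seed determines stage seeds through a fixed spawn order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compensation, group, mvb
from .core import ParticipantRecord, ROIMask, StatMap
from .glm import (
    build_design,
    contrast_image,
    fit_prewhitened_glm,
    grand_mean_scale,
    whitener_from_ar_params,
)
from .simulate import (
    Cohort,
    RegionSpec,
    SimulationConfig,
    simulate_cohort,
    standardise_records,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report", "STAGES"]

STAGES = ("simulate", "glm", "group", "mvb", "compare", "report")


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    # analysis parameters
    n_perm: int = group.N_PERMUTATIONS
    t_threshold: float = group.T_THRESHOLD
    tfce_n_steps: int = 100
    max_greedy_steps: int = 8
    n_shuffles: int = 20
    mdn_label: str = "mdn"
    # stage toggles
    stages: tuple[str, ...] = STAGES
    write_bold: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.simulation.seed = self.seed

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = dict(payload.pop("simulation", {}))
        specs = [RegionSpec(**s) for s in sim.pop("region_specs", [])]
        sim_kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
        }
        if specs:
            sim_kwargs["region_specs"] = specs
        payload["simulation"] = SimulationConfig(**sim_kwargs)
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(config: RunConfig, stage: str) -> int:
    ss = np.random.SeedSequence([config.seed & 0xFFFFFFFF, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class _StageRunner:
    """Checksummed, resumable stage execution."""

    def __init__(self, config: RunConfig, out_dir: Path):
        self.config = config
        self.out = out_dir
        self.manifest: dict[str, dict[str, str]] = {}

    def fragment_path(self, stage: str) -> Path:
        return self.out / f".stage_{stage}.json"

    def is_cached(self, stage: str) -> bool:
        frag = self.fragment_path(stage)
        if not frag.exists():
            return False
        payload = json.loads(frag.read_text())
        if payload.get("config_hash") != self.config.config_hash():
            return False
        for rel, digest in payload.get("artifacts", {}).items():
            p = self.out / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        self.manifest[stage] = payload["artifacts"]
        return True

    def record(self, stage: str, paths: list[Path]) -> None:
        artifacts = {
            str(p.relative_to(self.out)): _sha256(p) for p in paths
        }
        self.manifest[stage] = artifacts
        self.fragment_path(stage).write_text(
            json.dumps(
                dict(config_hash=self.config.config_hash(), artifacts=artifacts),
                indent=1,
                sort_keys=True,
            )
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str, participant: str | None = None):
        self.stage = stage
        self.participant = participant
        who = f" (participant {participant})" if participant else ""
        super().__init__(f"stage {stage!r} failed{who}: {detail}")


def _load_records(out_dir: Path) -> list[ParticipantRecord]:
    frame = pd.read_csv(out_dir / "participants.tsv", sep="\t")
    records = []
    for _, row in frame.iterrows():
        records.append(
            ParticipantRecord(
                id=row["participant_id"],
                age=float(row["age"]),
                sex=str(row["sex"]),
                hard_correct=int(row["hard_correct"]),
                hard_incorrect=int(row["hard_incorrect"]),
                easy_correct=int(row["easy_correct"]),
                easy_incorrect=int(row["easy_incorrect"]),
                z_age=float(row["z_age"]),
                z_performance=float(row["z_performance"]),
            )
        )
    return records


def _analysis_cohort(config: RunConfig, out_dir: Path):
    """Included records with covariates re-standardised post-exclusion.

    Returns (generation_records, included_analysis_records, report).  The
    generation records keep the cohort-wide z values the simulator used;
    the analysis copies are re-standardised over the included subset, as
    the analysis prescribes.
    """
    records = _load_records(out_dir)
    report = group.score_and_exclude(records)
    included = [dataclasses.replace(r) for r in report.included]
    standardise_records(included)
    return records, included, report


def _included_ids(out_dir: Path, config: RunConfig) -> list[str]:
    _, included, _ = _analysis_cohort(config, out_dir)
    return [r.id for r in included]


def _participant_glm(config: RunConfig, cohort: Cohort, record: ParticipantRecord):
    """Simulate, scale and fit one participant (deterministic)."""
    dataset, truth = cohort.bold_for(record)
    scaled, factor = grand_mean_scale(dataset)
    design = build_design(cohort.design)
    glm_result = fit_prewhitened_glm(scaled, design)
    glm_result.scaling = factor
    return dataset, scaled, design, glm_result, truth


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    cohort = simulate_cohort(config.simulation)
    artifacts = write_cohort(cohort, out, write_bold=config.write_bold)
    return [Path(p) for p in artifacts.values()]


def _stage_glm(config: RunConfig, out: Path) -> list[Path]:
    cohort = simulate_cohort(config.simulation)
    # use the records as originally generated (cohort-wide standardisation)
    records, included, _ = _analysis_cohort(config, out)
    gen_by_id = {r.id: r for r in records}
    paths = []
    for rec in included:
        gen_rec = gen_by_id[rec.id]
        try:
            dataset, _scaled, design, glm_result, _truth = _participant_glm(
                config, cohort, gen_rec
            )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("glm", str(exc), participant=rec.id) from exc
        cmap = contrast_image(
            glm_result, design.contrast_vectors["hard_gt_easy"], dataset
        )
        c_path = out / f"{rec.id}_contrast.nii"
        cmap.to_nifti().to_filename(c_path)
        rsfa = cohort.rsfa_for(gen_rec)
        r_path = out / f"{rec.id}_rsfa.nii"
        rsfa.to_nifti().to_filename(r_path)
        report = dict(
            participant_id=rec.id,
            ar1=glm_result.ar1,
            ar_params=list(glm_result.ar_params),
            scaling=glm_result.scaling,
            n_highpass=glm_result.n_highpass,
            conditions=design.condition_names,
            dof=glm_result.dof,
        )
        j_path = out / f"{rec.id}_glm.json"
        j_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        paths += [c_path, r_path, j_path]
    return paths


def _load_maps(out: Path, ids: list[str], suffix: str) -> list[StatMap]:
    import nibabel as nib

    maps = []
    for pid in ids:
        img = nib.load(out / f"{pid}_{suffix}.nii")
        maps.append(StatMap(np.asarray(img.get_fdata(), dtype=float),
                            affine=np.asarray(img.affine)))
    return maps


def _stage_group(config: RunConfig, out: Path) -> list[Path]:
    _, included, excl = _analysis_cohort(config, out)
    ids = [r.id for r in included]
    maps = _load_maps(out, ids, "contrast")
    rsfa_maps = [m.values for m in _load_maps(out, ids, "rsfa")]
    paths = []

    behav = group.behaviour_regression(included)
    b_path = out / "behaviour_regression.tsv"
    behav.to_csv(b_path, sep="\t", index=False)
    paths.append(b_path)

    seed = _stage_seed(config, "group")
    tfce_kwargs = dict(n_steps=config.tfce_n_steps)
    perm_age = group.permutation_inference(
        maps, included, "age", n_perm=config.n_perm,
        t_threshold=config.t_threshold, tfce_kwargs=tfce_kwargs, seed=seed,
    )
    perm_perf = group.permutation_inference(
        maps, included, "performance", n_perm=config.n_perm,
        t_threshold=config.t_threshold, tfce_kwargs=tfce_kwargs, seed=seed + 1,
    )
    for name, res in (("age", perm_age), ("performance", perm_perf)):
        for kind, sm in (("t", res.t_map), ("pfwe", res.p_map)):
            p = out / f"group_{name}_{kind}.nii"
            sm.to_nifti().to_filename(p)
            paths.append(p)

    rois = group.intersection_roi(
        perm_age.sig_mask, perm_perf.sig_mask, label_prefix="comproi",
        affine=maps[0].affine,
    )

    # task-positive (MDN) reference mask from the group Hard > Easy map
    mdn_t = group.one_sample_tmap(maps)
    mdn_mask_arr = np.isfinite(mdn_t.values) & (mdn_t.values > config.t_threshold)
    t_path = out / "group_task_t.nii"
    mdn_t.to_nifti().to_filename(t_path)
    paths.append(t_path)

    roi_meta = []
    table1_rows = []
    for roi in rois:
        m_path = out / f"roi_{roi.label}.nii"
        roi.to_nifti().to_filename(m_path)
        paths.append(m_path)
        roi_meta.append(dict(label=roi.label, file=m_path.name,
                             n_voxels=roi.n_voxels))
        for scaled, rs in (("raw", None), ("rsfa", rsfa_maps)):
            tab = group.roi_regression(
                roi, maps, included, rsfa_maps=rs,
                standardise_outcome=True, n_comparisons=max(len(rois), 1),
            )
            tab.insert(0, "roi", roi.label)
            tab.insert(1, "scaling", scaled)
            table1_rows.append(tab)
    if table1_rows:
        table1 = pd.concat(table1_rows, ignore_index=True)
    else:
        table1 = pd.DataFrame(
            columns=["roi", "scaling", "term", "estimate", "t", "p"]
        )
    t1_path = out / "table1.tsv"
    table1.to_csv(t1_path, sep="\t", index=False)
    paths.append(t1_path)

    meta = dict(
        rois=roi_meta,
        n_included=len(included),
        n_excluded=len(excl.excluded),
        exclusion_reasons=excl.reasons,
        mdn_mask_file="group_mdn_mask.nii",
    )
    import nibabel as nib

    mdn_path = out / "group_mdn_mask.nii"
    nib.Nifti1Image(mdn_mask_arr.astype(np.uint8), maps[0].affine).to_filename(mdn_path)
    paths.append(mdn_path)
    meta_path = out / "group_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    paths.append(meta_path)
    return paths


def _load_rois(out: Path) -> tuple[list[ROIMask], np.ndarray, StatMap]:
    import nibabel as nib

    meta = json.loads((out / "group_meta.json").read_text())
    rois = []
    for entry in meta["rois"]:
        img = nib.load(out / entry["file"])
        rois.append(
            ROIMask(
                mask=np.asarray(img.get_fdata()) > 0.5,
                label=entry["label"],
                affine=np.asarray(img.affine),
            )
        )
    mdn_img = nib.load(out / meta["mdn_mask_file"])
    mdn_mask = np.asarray(mdn_img.get_fdata()) > 0.5
    t_img = nib.load(out / "group_task_t.nii")
    tmap = StatMap(np.asarray(t_img.get_fdata(), dtype=float),
                   kind="t", affine=np.asarray(t_img.affine))
    return rois, mdn_mask, tmap


def _stage_mvb(config: RunConfig, out: Path) -> list[Path]:
    cohort = simulate_cohort(config.simulation)
    records, included, _ = _analysis_cohort(config, out)
    gen_by_id = {r.id: r for r in records}
    rois, mdn_mask_arr, mdn_t = _load_rois(out)
    if not rois:
        logger.warning("no intersection ROIs; MVB stage writes nothing")
        return []
    mdn_roi = ROIMask(mask=mdn_mask_arr, label=config.mdn_label)
    paths = []
    seed = _stage_seed(config, "mvb")
    design = build_design(cohort.design)
    for rec in included:
        gen_rec = gen_by_id[rec.id]
        dataset, _ = cohort.bold_for(gen_rec)
        scaled, _ = grand_mean_scale(dataset)
        report = json.loads((out / f"{rec.id}_glm.json").read_text())
        whitener = whitener_from_ar_params(
            dataset.n_scans, tuple(report["ar_params"])
        )
        for roi in rois:
            try:
                matched = compensation.select_matched_mdn(
                    mdn_t, mdn_roi, roi.n_voxels
                )
                joint_mask = ROIMask(
                    mask=roi.mask | matched.mask,
                    label=f"{roi.label}+{matched.label}",
                )
                fits = {}
                for name, mask in (
                    ("joint", joint_mask), ("mdn_only", matched), ("roi_only", roi)
                ):
                    problem = mvb.build_problem(
                        design, scaled, mask, whitener=whitener
                    )
                    fits[name] = (
                        problem,
                        mvb.fit_mvb(
                            problem, max_greedy_steps=config.max_greedy_steps
                        ),
                    )
                payload = dict(participant_id=rec.id, roi=roi.label)
                for name, (problem, fit) in fits.items():
                    payload[name] = dict(
                        log_evidence=fit.log_evidence,
                        greedy_trace=fit.greedy_trace,
                        weights=np.asarray(fit.weights).tolist(),
                        voxel_ids=np.asarray(problem.voxel_ids).tolist(),
                    )
                if config.n_shuffles > 0:
                    problem, fit = fits["joint"]
                    null = mvb.reliability_check(
                        problem, fit, n_shuffles=config.n_shuffles,
                        seed=seed + zlib.crc32(rec.id.encode()) % 10_000,
                        max_greedy_steps=config.max_greedy_steps,
                    )
                    payload["reliability"] = dict(
                        shuffled=null.shuffled_log_evidences.tolist(),
                        mean_difference=null.mean_difference,
                        reliable=bool(null.reliable),
                    )
                else:
                    payload["reliability"] = dict(reliable=True)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError("mvb", str(exc), participant=rec.id) from exc
            p = out / f"{rec.id}_mvb_{roi.label}.json"
            p.write_text(json.dumps(payload, indent=1, sort_keys=True))
            paths.append(p)
    return paths


def _stage_compare(config: RunConfig, out: Path) -> list[Path]:
    _, included, _ = _analysis_cohort(config, out)
    ids = [r.id for r in included]
    rois, _, _ = _load_rois(out)
    maps = _load_maps(out, ids, "contrast")
    paths = []
    table2_rows = []
    comp_rows = []
    for roi in rois:
        comparisons, spreads, reliable = [], [], []
        uni = group.roi_mean_activation(roi, maps)
        for rec in included:
            payload = json.loads(
                (out / f"{rec.id}_mvb_{roi.label}.json").read_text()
            )
            cmp_ = compensation.ModelComparison(
                logev_joint=payload["joint"]["log_evidence"],
                logev_single=payload["mdn_only"]["log_evidence"],
            )
            comparisons.append(cmp_)
            w = np.asarray(payload["roi_only"]["weights"])
            spreads.append(float(np.std(w)))
            reliable.append(bool(payload["reliability"]["reliable"]))
        table = compensation.build_group_table(
            included, comparisons, spreads, uni, reliable
        )
        table.insert(0, "roi", roi.label)
        comp_rows.append(table)
        try:
            ordinal = (table.category == "reduction").any()
            boost = compensation.boost_model(table, ordinal=ordinal)
            boost.insert(0, "model", "boost")
        except ValueError as exc:
            logger.warning("boost model for %s not fit: %s", roi.label, exc)
            boost = pd.DataFrame()
        spread = compensation.spread_model(table)
        spread.insert(0, "model", "spread")
        both = pd.concat([boost, spread], ignore_index=True)
        both.insert(0, "roi", roi.label)
        table2_rows.append(both)
    comp_path = out / "comparisons.tsv"
    if comp_rows:
        comp = pd.concat(comp_rows, ignore_index=True)
    else:
        comp = pd.DataFrame(
            columns=["roi", "participant_id", "category", "spread", "reliable"]
        )
    comp.to_csv(comp_path, sep="\t", index=False)
    paths.append(comp_path)
    t2_path = out / "table2.tsv"
    if table2_rows:
        pd.concat(table2_rows, ignore_index=True).to_csv(
            t2_path, sep="\t", index=False
        )
    else:
        pd.DataFrame().to_csv(t2_path, sep="\t", index=False)
    paths.append(t2_path)
    return paths


def _stage_report(config: RunConfig, out: Path) -> list[Path]:
    return [make_report(out)]


STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "group": _stage_group,
    "mvb": _stage_mvb,
    "compare": _stage_compare,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    runner = _StageRunner(config, out)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if runner.is_cached(stage):
            logger.info("stage %s: cached, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            paths = STAGE_FUNCS[stage](config, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(stage, str(exc)) from exc
        runner.record(stage, paths)
    manifest = dict(
        config_hash=config.config_hash(),
        stages={s: runner.manifest.get(s, {}) for s in config.stages},
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


def make_report(out_dir: str | Path) -> Path:
    """Summarise a completed run: cohort counts, exclusions, reliability
    drops and the two coefficient tables."""
    out = Path(out_dir)
    lines = ["Compensation analysis run summary", "=" * 34]
    meta_path = out / "group_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing group stage output: {meta_path}")
    meta = json.loads(meta_path.read_text())
    lines.append(f"Participants included: {meta['n_included']}")
    lines.append(
        f"Excluded at chance/no-response: {meta['n_excluded']}"
    )
    for pid, why in sorted(meta.get("exclusion_reasons", {}).items()):
        lines.append(f"  - {pid}: {why}")
    lines.append("Intersection ROIs: " + (
        ", ".join(f"{r['label']} ({r['n_voxels']} voxels)" for r in meta["rois"])
        or "none"
    ))
    comp_path = out / "comparisons.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        for roi, sub in comp.groupby("roi"):
            n_unrel = int((~sub["reliable"]).sum())
            counts = sub["category"].value_counts().to_dict()
            lines.append(
                f"ROI {roi}: unreliable decoding dropped {n_unrel}; "
                f"categories {counts}"
            )
    for name in ("behaviour_regression.tsv", "table1.tsv", "table2.tsv"):
        p = out / name
        if p.exists():
            lines.append("")
            lines.append(name)
            lines.append(p.read_text().rstrip())
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
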