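"""End-to-end orchestration: simulate → reconstruct → voi → stats → voxelwise.

A single :class:`PipelineConfig` drives all stages; every stage records its
outputs (with checksums) in a JSON run report and is skipped on re-runs
when its outputs are intact, unless forced.  One global seed is expanded
into independent per-stage seeds through ``numpy.random.SeedSequence`` so
stages can be re-run individually yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from dnqsm.config import DEFAULT_ALPHA
from dnqsm.containers import DNMask, ChiMap, R2StarMap, EchoSeries
from dnqsm.io import file_sha256, load_nifti, load_table, save_nifti, save_table
from dnqsm.phantom import (
    CohortSpec,
    PhantomSpec,
    make_cohort,
    make_dentate_phantom,
    synthesize_echoes,
)
from dnqsm.recon import InversionConfig, SharpConfig, reconstruct_chi, fit_r2star
from dnqsm.stats import ancova, cohort_summary, partial_spearman, residualize, sidak_adjust
from dnqsm.voi import build_dn_bulk, voi_metrics
from dnqsm.voxelwise import TfceConfig, permutation_fwe, smooth_gaussian

logger = logging.getLogger("dnqsm.pipeline")

STAGES = ("simulate", "reconstruct", "voi", "stats", "voxelwise")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "validate_config",
    "demo_config",
    "run_pipeline",
    "stage_seed",
]


@dataclass
class PipelineConfig:
    workdir: str = "dnqsm_run"
    seed: int = 0
    phantom: PhantomSpec = dc_field(default_factory=PhantomSpec)
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    sharp: SharpConfig = dc_field(default_factory=SharpConfig)
    inversion: InversionConfig = dc_field(default_factory=InversionConfig)
    denoise_strength: float = 0.0
    smoothing_fwhm_mm: float = 1.0
    alpha: float = DEFAULT_ALPHA
    sidak: bool = True
    n_perm: int = 200
    tfce: TfceConfig = dc_field(default_factory=TfceConfig)

    def validate(self) -> None:
        errors = []
        for spec in (self.phantom, self.cohort, self.sharp, self.inversion, self.tfce):
            try:
                spec.validate()
            except ValueError as exc:
                errors.append(str(exc))
        if not 0 < self.alpha < 1:
            errors.append("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        if self.denoise_strength < 0:
            errors.append("denoise_strength must be >= 0")
        if self.smoothing_fwhm_mm < 0:
            errors.append("smoothing_fwhm_mm must be >= 0")
        if errors:
            raise ValueError("; ".join(errors))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "phantom": PhantomSpec,
    "cohort": CohortSpec,
    "sharp": SharpConfig,
    "inversion": InversionConfig,
    "tfce": TfceConfig,
}
_STATS_KEYS = {"alpha", "sidak"}
_VOXELWISE_KEYS = {"n_perm"}
_TOP_KEYS = {"workdir", "seed", "denoise_strength", "smoothing_fwhm_mm", "stats",
             "voxelwise"} | set(_SECTION_TYPES)


def validate_config(raw_config: dict | None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a (possibly nested) dict.

    Missing keys take their defaults (SHARP radii 1–10 with high-pass 0.01,
    R2* CSF cutoff 15 s⁻¹, α = 0.05, the four-echo TE protocol); unknown
    keys, wrong types and out-of-range values are all reported together.
    """
    raw = dict(raw_config or {})
    errors: list[str] = []
    cfg = PipelineConfig()

    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown config key '{key}'")

    def fill(obj, section: dict, prefix: str):
        for k, val in section.items():
            if not hasattr(obj, k):
                errors.append(f"unknown config key '{prefix}{k}'")
                continue
            cur = getattr(obj, k)
            if isinstance(cur, (int, float)) and not isinstance(cur, bool):
                if not isinstance(val, (int, float)):
                    errors.append(f"'{prefix}{k}' must be numeric, got {val!r}")
                    continue
            if isinstance(cur, (tuple, list)) and isinstance(val, (tuple, list)):
                val = tuple(val)
            setattr(obj, k, val)

    for name, _ in _SECTION_TYPES.items():
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                errors.append(f"section '{name}' must be a mapping")
                continue
            fill(getattr(cfg, name), section, f"{name}.")
    for key in ("workdir", "seed", "denoise_strength", "smoothing_fwhm_mm"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "stats" in raw:
        for k, v in raw["stats"].items():
            if k not in _STATS_KEYS:
                errors.append(f"unknown config key 'stats.{k}'")
            else:
                setattr(cfg, k, v)
    if "voxelwise" in raw:
        for k, v in raw["voxelwise"].items():
            if k in _VOXELWISE_KEYS:
                cfg.n_perm = v
            elif hasattr(cfg.tfce, k):
                setattr(cfg.tfce, k, v)
            else:
                errors.append(f"unknown config key 'voxelwise.{k}'")

    try:
        cfg.validate()
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def demo_config(workdir: str = "dnqsm_demo", seed: int = 0) -> PipelineConfig:
    """Small end-to-end configuration (6 subjects per group, 48³ grid)."""
    phantom = PhantomSpec(
        grid_shape=(48, 48, 48),
        brain_radii_mm=(10.5, 10.5, 10.0),
        shell_center_mm=(5.5, 0.0, 0.0),
        shell_radii_mm=(3.8, 4.8, 4.2),
        wall_thickness_mm=1.0,
        corrugation_amplitude_mm=0.4,
        external_source_positions_mm=((10.8, 10.5, 9.0), (-10.5, -10.0, -9.5)),
        external_source_strengths=(2.0e3, -1.5e3),
        noise_sigma=0.02,
    )
    cohort = CohortSpec(n_patients=6, n_controls=6, seed=seed)
    return PipelineConfig(
        workdir=workdir, seed=seed, phantom=phantom, cohort=cohort, n_perm=100
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    config: dict
    stages: dict = dc_field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)

        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")

        Path(path).write_text(json.dumps({"config": self.config, "stages": self.stages},
                                         indent=2, default=default))

    @staticmethod
    def read(path) -> "RunReport":
        raw = json.loads(Path(path).read_text())
        return RunReport(config=raw["config"], stages=raw["stages"])


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _subject_paths(work: Path, sid: str) -> dict:
    d = work / "subjects" / sid
    return {
        "mag": d / "magnitude.nii.gz",
        "phase": d / "phase.nii.gz",
        "brain": d / "brain_mask.nii.gz",
        "dn_sil": d / "dn_sil.nii.gz",
        "chi_true": d / "chi_true.nii.gz",
        "r2star_true": d / "r2star_true.nii.gz",
        "chi": d / "chi.nii.gz",
        "r2star": d / "r2star.nii.gz",
        "dn_bulk": d / "dn_bulk.nii.gz",
    }


def _stage_simulate(cfg: PipelineConfig, work: Path) -> list:
    seed = stage_seed(cfg.seed, "simulate")
    cohort = dataclasses.replace(cfg.cohort, seed=seed)
    table, specs = make_cohort(cohort, cfg.phantom)
    outputs = [save_table(table, work / "cohort.tsv")]
    for row, spec in zip(table.itertuples(), specs):
        paths = _subject_paths(work, row.subject_id)
        truth = make_dentate_phantom(spec)
        s0 = np.where(truth.brain_mask, spec.s0, 0.0)
        echoes = synthesize_echoes(
            truth.field_true_hz,
            s0,
            truth.r2star_true,
            noise_sigma=spec.noise_sigma,
            seed=spec.seed,
            voxel_size_mm=spec.voxel_size_mm,
        )
        v = spec.voxel_size_mm
        outputs.append(save_nifti(np.moveaxis(echoes.magnitude, 0, -1), v, paths["mag"]))
        outputs.append(save_nifti(np.moveaxis(echoes.phase, 0, -1), v, paths["phase"]))
        outputs.append(save_nifti(truth.brain_mask.astype(np.int16), v, paths["brain"]))
        outputs.append(save_nifti(truth.dn_sil_true.labels, v, paths["dn_sil"]))
        outputs.append(save_nifti(truth.chi.data_ppb, v, paths["chi_true"]))
        outputs.append(save_nifti(truth.r2star_true, v, paths["r2star_true"]))
    (work / "tes_s.json").write_text(json.dumps(list(map(float, echoes.tes_s))))
    outputs.append(work / "tes_s.json")
    return outputs


def _load_echoes(work: Path, sid: str) -> tuple:
    paths = _subject_paths(work, sid)
    mag, v = load_nifti(paths["mag"])
    phase, _ = load_nifti(paths["phase"])
    brain, _ = load_nifti(paths["brain"])
    tes = json.loads((work / "tes_s.json").read_text())
    phase = np.moveaxis(phase, -1, 0)
    # guard against float32 round-off pushing stored phase outside (-pi, pi]
    phase = np.clip(phase, np.nextafter(-np.pi, 0.0), np.pi)
    echoes = EchoSeries(np.moveaxis(mag, -1, 0), phase, tes, v)
    return echoes, brain > 0.5


def _stage_reconstruct(cfg: PipelineConfig, work: Path) -> list:
    table = load_table(work / "cohort.tsv")
    outputs = []
    for sid in table["subject_id"]:
        paths = _subject_paths(work, sid)
        echoes, brain = _load_echoes(work, sid)
        chi, tissue, _ = reconstruct_chi(
            echoes, brain, cfg.sharp, cfg.inversion, cfg.denoise_strength
        )
        r2star = fit_r2star(echoes, brain)
        outputs.append(save_nifti(chi.data_ppb, echoes.voxel_size_mm, paths["chi"]))
        outputs.append(save_nifti(np.nan_to_num(r2star.data), echoes.voxel_size_mm, paths["r2star"]))
    sidecar = work / "recon_params.json"
    sidecar.write_text(json.dumps({
        "sharp": dataclasses.asdict(cfg.sharp),
        "inversion": dataclasses.asdict(cfg.inversion),
        "denoise_strength": cfg.denoise_strength,
    }, indent=2))
    outputs.append(sidecar)
    return outputs


def _stage_voi(cfg: PipelineConfig, work: Path) -> list:
    table = load_table(work / "cohort.tsv")
    rows = []
    for sid in table["subject_id"]:
        paths = _subject_paths(work, sid)
        sil_labels, v = load_nifti(paths["dn_sil"])
        chi_data, _ = load_nifti(paths["chi"])
        r2s_data, _ = load_nifti(paths["r2star"])
        dn_sil = DNMask(sil_labels.astype(np.int16), "sil", v)
        r2star = R2StarMap(r2s_data, np.full(r2s_data.shape, np.nan), v)
        chi = ChiMap(chi_data, v)
        dn_bulk = build_dn_bulk(dn_sil, r2star)
        save_nifti(dn_bulk.labels, v, paths["dn_bulk"])
        for kind, mask in (("sil", dn_sil), ("bulk", dn_bulk)):
            m = voi_metrics(chi, mask)
            rows.append({"subject_id": sid, "voi_kind": kind, **m.as_dict()})
    metrics = pd.DataFrame(rows)
    outputs = [save_table(metrics, work / "voi_metrics.tsv")]
    outputs += [_subject_paths(work, sid)["dn_bulk"] for sid in table["subject_id"]]
    return outputs


def _stage_stats(cfg: PipelineConfig, work: Path) -> list:
    table = load_table(work / "cohort.tsv")
    metrics = load_table(work / "voi_metrics.tsv")
    wide = metrics.pivot(index="subject_id", columns="voi_kind")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    df = table.merge(wide.reset_index(), on="subject_id")
    is_control = (df["group"] == "control").to_numpy()

    report: dict = {"alpha": cfg.alpha}
    resid_block = {}
    for kind in ("sil", "bulk"):
        z, model = residualize(df[f"volume_mm3_{kind}"], df["tiv_cm3"], is_control)
        df[f"volume_resid_z_{kind}"] = z
        resid_block[kind] = dataclasses.asdict(model)
    report["residualization"] = resid_block

    dep_cols = [
        "mean_chi_ppb_sil", "mean_chi_ppb_bulk",
        "volume_resid_z_sil", "volume_resid_z_bulk",
        "chi_mass_ppb_cm3_sil", "chi_mass_ppb_cm3_bulk",
    ]
    anc = {}
    raw_ps = []
    for col in dep_cols:
        res = ancova(df[col], df["group"], df["age_years"])
        anc[col] = res.terms
        raw_ps.append(res["group"]["p"])
    if cfg.sidak:
        adj = sidak_adjust(raw_ps)
        for col, p_adj in zip(dep_cols, adj):
            anc[col]["group"]["p_sidak"] = float(p_adj)
    report["ancova"] = anc

    pat = df[~is_control]
    corr = {}
    if len(pat) >= 5:
        for col in ("volume_mm3_sil", "volume_mm3_bulk", "mean_chi_ppb_bulk"):
            c = partial_spearman(pat[col], pat["sara"], pat["age_years"])
            corr[col] = {"r": c.r, "p": c.p, "n": c.n, "method": c.method}
    report["sara_correlations"] = corr
    report["cohort_summary"] = json.loads(
        cohort_summary(df).to_json(orient="records")
    )

    out_json = work / "stats_report.json"
    out_json.write_text(json.dumps(report, indent=2, default=float))
    out_txt = work / "stats_report.txt"
    lines = ["dnqsm VOI statistics", "====================", ""]
    for col in dep_cols:
        g = anc[col]["group"]
        lines.append(
            f"{col}: F({g['df_effect']:.0f},{g['df_error']:.0f}) = {g['F']:.2f}, "
            f"p = {g['p']:.4g}, partial eta^2 = {g['partial_eta_squared']:.3f}"
        )
    for col, c in corr.items():
        lines.append(f"SARA vs {col}: partial Spearman r = {c['r']:.2f}, p = {c['p']:.3g}")
    out_txt.write_text("\n".join(lines) + "\n")
    return [out_json, out_txt]


def _stage_voxelwise(cfg: PipelineConfig, work: Path) -> list:
    table = load_table(work / "cohort.tsv")
    chi_maps, bulks, ages, groups = [], [], [], []
    for row in table.itertuples():
        paths = _subject_paths(work, row.subject_id)
        chi, v = load_nifti(paths["chi"])
        bulk, _ = load_nifti(paths["dn_bulk"])
        chi_maps.append(smooth_gaussian(chi, cfg.smoothing_fwhm_mm, v))
        bulks.append(bulk > 0)
        ages.append(row.age_years)
        groups.append(row.group)
    groups = np.asarray(groups)
    ages = np.asarray(ages)
    mask = np.any(bulks, axis=0)
    pats = [m for m, g in zip(chi_maps, groups) if g == "patient"]
    ctrls = [m for m, g in zip(chi_maps, groups) if g == "control"]
    order = np.concatenate([ages[groups == "patient"], ages[groups == "control"]])
    res = permutation_fwe(
        pats, ctrls, order, n_perm=cfg.n_perm, cfg=cfg.tfce,
        seed=stage_seed(cfg.seed, "voxelwise"), mask=mask,
    )
    outputs = [
        save_nifti(res.t_map, v, work / "voxelwise_t.nii.gz"),
        save_nifti(res.tfce_map, v, work / "voxelwise_tfce.nii.gz"),
        save_nifti(res.p_fwe, v, work / "voxelwise_p_fwe.nii.gz"),
    ]
    summary = {
        "n_permutations": res.n_permutations,
        "n_voxels_mask": int(mask.sum()),
        "n_significant": int(((res.p_fwe < cfg.alpha) & mask).sum()),
        "min_p_fwe": float(res.p_fwe[mask].min()),
    }
    p = work / "voxelwise_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    outputs.append(p)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "reconstruct": _stage_reconstruct,
    "voi": _stage_voi,
    "stats": _stage_stats,
    "voxelwise": _stage_voxelwise,
}


def run_pipeline(config: PipelineConfig, force: bool = False,
                 stages=STAGES) -> RunReport:
    """Run the requested stages in order, skipping intact ones unless forced.

    A stage is skipped when the existing run report lists its outputs and
    every file still exists with a matching checksum; otherwise it is
    (re)computed.  A stage failure aborts the run with the failing stage
    named; outputs of completed stages are retained.
    """
    config.validate()
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    report_path = work / "report.json"
    previous = RunReport.read(report_path) if report_path.exists() else None
    report = RunReport(config=config.to_dict())

    for stage in STAGES:
        if stage not in stages:
            continue
        prev = (previous.stages.get(stage) if previous else None) or {}
        if not force and prev.get("outputs"):
            intact = all(
                Path(f).exists() and file_sha256(f) == sha
                for f, sha in prev["outputs"].items()
            )
            if intact:
                logger.info("stage %s: outputs intact, skipped", stage)
                report.stages[stage] = {**prev, "status": "skipped"}
                report.write(report_path)
                continue
        logger.info("stage %s: running", stage)
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                outputs = _STAGE_FUNCS[stage](config, work)
        except Exception as exc:
            report.stages[stage] = {"status": "failed", "error": str(exc)}
            report.write(report_path)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest = {str(p): file_sha256(p) for p in outputs}
        report.stages[stage] = {
            "status": "completed",
            "outputs": manifest,
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        report.write(report_path)
        logger.info("stage %s: done (%.1fs, %d files)", stage,
                    report.stages[stage]["wall_s"], len(manifest))
    return report
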