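"""Orchestration: run the simulation + analysis stages and write a manifest.

Stages run in dependency order: ``simulate`` feeds ``r1map`` (per-subject
R1 maps and ROI means), whose group table feeds ``quest``; ``simulate`` also
feeds ``abr`` (threshold calling and shifts) and ``histo`` (cytocochleogram
and HO-1 mixed ANOVA).  Every output file is declared in the run manifest
with a checksum; re-running with an identical config and seed reproduces
identical checksums.

Configuration is a YAML mapping; all randomness flows from ``seed`` (no
stage reads the wall clock or global RNG state).  Pixel coordinates are
0-based and row-major throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abr as abr_mod
from . import histology as histo_mod
from . import r1map as r1_mod
from . import stats as stats_mod
from . import synthetic as syn

logger = logging.getLogger(__name__)

VERSION = "0.1.0"

ALL_STAGES = ("simulate", "r1map", "quest", "abr", "histo")

_ALLOWED_KEYS = {
    "seed", "outdir", "stages", "alpha", "contrast_method", "mri", "abr",
    "histology", "group_table", "save_nifti",
}


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for stage graph)."""

    seed: int = 0
    outdir: str = "questmri-out"
    stages: tuple = ALL_STAGES
    alpha: float = 0.05
    contrast_method: str = "scheffe"
    mri: dict = field(default_factory=dict)
    abr: dict = field(default_factory=dict)
    histology: dict = field(default_factory=dict)
    group_table: str | None = None     # external CSV for quest without r1map
    save_nifti: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.contrast_method not in {"scheffe", "planned"}:
            raise ValueError("contrast_method must be 'scheffe' or 'planned'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def canonical_json(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, sort_keys=True)


@dataclass
class RunManifest:
    """Record of a completed run: config hash, version, output checksums."""

    config_hash: str
    version: str
    outputs: dict            # relative path -> sha256
    log_path: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_spec(config: RunConfig) -> syn.CohortSpec:
    m = config.mri
    matrix = tuple(m.get("matrix", (64, 64)))
    protocol = syn.AcquisitionProtocol(matrix=matrix)
    noise = syn.NoiseSpec(
        model=m.get("noise_model", "rician"),
        sigma=float(m.get("noise_sigma", 0.03)),
        jitter_sigma=float(m.get("jitter_sigma", 0.5)),
        seed=config.seed,
    )
    coil = syn.CoilFieldSpec(
        field_kind=m.get("coil_kind", "low-order-polynomial"),
        amplitude_range=tuple(m.get("coil_amplitude_range", (0.8, 1.2))),
    )
    group_sizes = m.get("group_sizes") or dict(syn.DEFAULT_GROUP_SIZES)
    return syn.CohortSpec(group_sizes=group_sizes, protocol=protocol,
                          coil=coil, noise=noise, seed=config.seed)


def run(config: RunConfig) -> RunManifest:
    """Execute the requested stages and write outputs + manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("questmri")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stages = [s for s in ALL_STAGES if s in config.stages]
    outputs: dict[str, str] = {}

    def declare(path: Path) -> None:
        outputs[str(path.relative_to(outdir))] = _sha256(path)

    cohort = None
    group_table = None
    try:
        if "simulate" in stages:
            logger.info("simulate: generating cohort (seed=%d)", config.seed)
            cohort = syn.generate_cohort(_cohort_spec(config),
                                         render_images="r1map" in stages)
            truth_path = outdir / "mri_truth_table.csv"
            cohort.truth_table.to_csv(truth_path, index=False)
            declare(truth_path)

        if "r1map" in stages:
            if cohort is None or not cohort.subjects:
                raise RuntimeError(
                    "r1map stage requires the simulate stage (or real-data "
                    "series paths); missing upstream artifact: image series")
            rows = []
            for subject, (series, _truth) in cohort.subjects.items():
                if config.save_nifti:
                    nii = outdir / f"{subject}_series.nii"
                    r1_mod.save_series_nifti(series, nii)
                    declare(nii)
                    declare(nii.with_suffix(".json"))
                r1map = r1_mod.compute_r1_map(series)
                if config.save_nifti:
                    mpath = outdir / f"{subject}_r1.nii"
                    r1_mod.save_r1_map_nifti(r1map, mpath)
                    declare(mpath)
                group = subject.rsplit("-", 1)[0]
                for ear, roi in cohort.roi_masks[subject].items():
                    mean, n, sd = r1_mod.roi_mean_r1(r1map, roi)
                    rows.append({"subject": subject, "group": group,
                                 "ear": ear, "roi": roi.name,
                                 "mean_r1": mean, "n": n, "sd": sd})
            roi_path = outdir / "roi_summary.csv"
            pd.DataFrame(rows).to_csv(roi_path, index=False)
            declare(roi_path)
            group_table = pd.DataFrame(rows).rename(
                columns={"mean_r1": "value"})[["subject", "group", "ear", "value"]]

        if "quest" in stages:
            if group_table is None:
                if config.group_table:
                    group_table = pd.read_csv(config.group_table)
                elif cohort is not None:
                    group_table = cohort.truth_table
                else:
                    raise RuntimeError(
                        "quest stage requires the r1map stage, a simulated "
                        "cohort, or a group_table CSV; missing upstream "
                        "artifact: group table")
            outcome = stats_mod.quest_assess(group_table, alpha=config.alpha,
                                             method=config.contrast_method)
            anova_path = outdir / "anova_r1.csv"
            outcome.anova.table.to_csv(anova_path)
            declare(anova_path)
            contrasts_path = outdir / "contrasts_r1.csv"
            pd.DataFrame(
                [{"group1": pr[0], "group2": pr[1], "ear": ear,
                  "estimate": est, "p": p}
                 for pr, ear, est, p in outcome.contrasts]
            ).to_csv(contrasts_path, index=False)
            declare(contrasts_path)
            quest_path = outdir / "quest_outcome.json"
            quest_path.write_text(json.dumps(outcome.to_dict(), indent=2,
                                             sort_keys=True))
            declare(quest_path)

        if "abr" in stages:
            a = config.abr
            n_subjects = int(a.get("n_subjects", 6))
            step = int(a.get("level_step", 5))
            noise_sd = float(a.get("noise_sd_uv", 0.15))
            tables = {}
            for stage_name in ("baseline", "post"):
                truths = syn.abr_cohort_thresholds(
                    n_subjects, stage_name, step, seed=config.seed)
                spec = syn.ABRSimSpec(
                    true_thresholds=truths,
                    level_grid_db=tuple(range(100, 5, -step)),
                    baseline_noise_sd_uv=noise_sd, seed=config.seed)
                recs, truth_table = syn.generate_abr_recordings(spec)
                called = abr_mod.build_threshold_table(recs)
                path = outdir / f"abr_thresholds_{stage_name}.csv"
                called.to_csv(path, index=False)
                declare(path)
                tables[stage_name] = called
            shifts = abr_mod.threshold_shift(tables["baseline"], tables["post"])
            shifts_path = outdir / "abr_shifts.csv"
            shifts.to_csv(shifts_path, index=False)
            declare(shifts_path)
            region_path = outdir / "abr_region_shifts.csv"
            abr_mod.region_mean_shifts(shifts).to_csv(region_path, index=False)
            declare(region_path)

        if "histo" in stages:
            h = config.histology
            # cytocochleogram from a simulated noise-exposed ear
            spec = syn.HistologySimSpec(
                missing_prob=syn.ne_missing_prob,
                intensity_sd=float(h.get("intensity_sd", 5.0)),
                seed=config.seed)
            images, truth_grid, _ = syn.generate_histology(spec)
            grids = [histo_mod.score_image(im.phalloidin, im.lattice)
                     for im in images]
            cyto = histo_mod.build_cytocochleogram(
                grids, bin_width=float(h.get("bin_width_pct", 5.0)))
            cyto_path = outdir / "cytocochleogram.csv"
            cyto.to_csv(cyto_path, index=False)
            declare(cyto_path)
            # HO-1 group comparison
            records = syn.generate_histology_cohort(
                group_sizes=h.get("group_sizes"), seed=config.seed)
            records = stats_mod.ho1_percent_change_table(records)
            rec_path = outdir / "ho1_records.csv"
            records.to_csv(rec_path, index=False)
            declare(rec_path)
            mixed = stats_mod.mixed_anova_ho1(records, alpha=config.alpha)
            mixed_path = outdir / "ho1_mixed_anova.json"
            mixed_path.write_text(json.dumps({
                "treatment_F": mixed.treatment_F, "df": [mixed.df_num,
                                                         mixed.df_den],
                "p": mixed.p,
                "lsmeans": mixed.lsmeans.to_dict("records"),
                "pairwise": mixed.pairwise.to_dict("records"),
            }, indent=2, sort_keys=True))
            declare(mixed_path)
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        version=VERSION, outputs=outputs, log_path=str(log_path),
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def report(manifest: RunManifest, outdir) -> str:
    """Human-readable summary of a completed (possibly partial) run."""
    outdir = Path(outdir)
    lines = ["# QUEST MRI run report", "",
             f"config hash: {manifest.config_hash}",
             f"software version: {manifest.version}", ""]
    warnings_: list[str] = []

    def table_section(name, title, fmt=None):
        path = outdir / name
        if name not in manifest.outputs or not path.exists():
            warnings_.append(f"missing output: {name}")
            return
        frame = pd.read_csv(path)
        lines.append(f"## {title}")
        lines.append("")
        lines.append(frame.to_string(index=False,
                                     float_format=fmt or "{:.4g}".format))
        lines.append("")

    if "roi_summary.csv" in manifest.outputs:
        frame = pd.read_csv(outdir / "roi_summary.csv")
        summary = frame.groupby(["group", "ear"])["mean_r1"].agg(
            ["mean", "sem", "count"]).reset_index()
        lines += ["## Group R1 (1/s) by ear", "",
                  summary.to_string(index=False,
                                    float_format="{:.4g}".format), ""]
    elif "mri_truth_table.csv" in manifest.outputs:
        frame = pd.read_csv(outdir / "mri_truth_table.csv")
        summary = frame.groupby(["group", "ear"])["value"].agg(
            ["mean", "sem", "count"]).reset_index()
        lines += ["## Group R1 (1/s) by ear (simulated truth)", "",
                  summary.to_string(index=False,
                                    float_format="{:.4g}".format), ""]

    table_section("anova_r1.csv", "Two-way ANOVA (R1)")
    table_section("contrasts_r1.csv", "Post hoc contrasts (unprotected ear)")
    if "quest_outcome.json" in manifest.outputs:
        outcome = json.loads((outdir / "quest_outcome.json").read_text())
        lines += ["## QUEST outcome", "",
                  f"elevated: {outcome['elevated']}, "
                  f"quenched: {outcome['quenched']}", ""]
    table_section("abr_region_shifts.csv", "ABR threshold shifts by region")
    table_section("cytocochleogram.csv", "Cytocochleogram (% missing)")
    if "ho1_mixed_anova.json" in manifest.outputs:
        mixed = json.loads((outdir / "ho1_mixed_anova.json").read_text())
        lines += ["## HO-1 mixed-factor ANOVA", "",
                  f"treatment F({mixed['df'][0]}, {mixed['df'][1]}) = "
                  f"{mixed['treatment_F']:.3f}, p = {mixed['p']:.4g}", ""]
        lines.append(pd.DataFrame(mixed["lsmeans"]).to_string(
            index=False, float_format="{:.4g}".format))
        lines.append("")

    if not manifest.outputs:
        warnings_.append("manifest lists no outputs")
    if warnings_:
        lines.append("## Warnings")
        lines += [f"- {w}" for w in warnings_]
        lines.append("")
    return "\n".join(lines)
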