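"""Configuration and orchestration of the three-experiment analysis.

The canonical sequence mirrors the study design: (1) within-condition ISC
in the audiovisual group, (2) across-condition ISC between the audio-only
and visual-only groups, (3) their conjunction, (4) across-condition ISC in
a second (sensory-deprived) population restricted to the conjunction
regions, (5) model-mediated ISC with the low-level models assigned
cross-modally and the high-level model removed from both groups, plus the
low-vs-high drop contrast, and (6) TRW profiles with between-condition map
similarity.  Every run writes a JSON manifest (package version, seeds,
parameter hash, output files) sufficient to re-run any stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from . import isc as isc_mod
from . import mediation as med
from . import permutation as perm
from . import simulate as sim
from . import trw as trw_mod
from . import io as io_mod

log = logging.getLogger("crossisc")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``simulate`` holds :class:`~crossisc.simulate.SimSpec` keyword
    arguments (synthetic fixture, no files needed) or the ``*_paths``
    entries point at per-subject NIfTI files plus a mask.
    """

    output_dir: str = "crossisc_out"
    seed: int = 0
    # data: synthetic ...
    simulate: dict | None = None
    # ... or from disk
    av_paths: list[str] = field(default_factory=list)
    a_paths: list[str] = field(default_factory=list)
    v_paths: list[str] = field(default_factory=list)
    sd_a_paths: list[str] = field(default_factory=list)
    sd_v_paths: list[str] = field(default_factory=list)
    mask_path: str | None = None
    tr_seconds: float = 2.0
    run_lengths: list[int] = field(default_factory=lambda: [269] * 6)
    feature_tsvs: dict = field(default_factory=dict)   # level -> path
    # inference
    chunks_per_run: int = 3
    allow_time_reversal: bool = True
    n_permutations: int = 1000
    alpha: float = 0.05
    min_cluster: int = 20
    connectivity: int = 18
    # TRW
    widths_s: list[float] | None = None
    n_null_maps: int = 200
    hrf: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def surrogate_spec(self, n_permutations: int | None = None) -> perm.SurrogateSpec:
        return perm.SurrogateSpec(
            chunks_per_run=self.chunks_per_run,
            allow_time_reversal=self.allow_time_reversal,
            n_permutations=n_permutations or self.n_permutations,
            seed=self.seed,
        )


def _param_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_groups(config: PipelineConfig):
    """Returns (groups dict, geometry, feature models dict or None)."""
    if config.simulate is not None:
        spec_kwargs = dict(config.simulate)
        spec_kwargs.setdefault("seed", config.seed)
        spec = sim.SimSpec(**spec_kwargs)
        models = sim.generate_feature_models(spec)
        group_a, group_v, truth = sim.generate_bold_groups(
            spec, designs=list(models), model_weights=None
        ) if spec.model_amplitude > 0 else sim.generate_bold_groups(spec)
        # second population: an independent draw with weaker shared signal
        sd_kwargs = dict(spec_kwargs)
        sd_kwargs["seed"] = spec.seed + 104729
        sd_kwargs["shared_amplitude"] = 0.6 * spec.shared_amplitude
        sd_kwargs["n_subjects_per_group"] = max(3, spec.n_subjects_per_group - 1)
        sd_spec = sim.SimSpec(**sd_kwargs)
        sd_a, sd_v, _ = sim.generate_bold_groups(sd_spec)
        sd_a = sd_a.with_data(sd_a.data)
        sd_a.population = sd_v.population = "SD"
        av = group_a.with_data(
            group_a.data)  # AV condition shares the same latent structure
        av.condition = "AV"
        geometry = io_mod.geometry_for_grid(truth.grid_shape, spec.n_voxels)
        groups = {"AV": av, "A": group_a, "V": group_v,
                  "SD_A": sd_a, "SD_V": sd_v}
        feats = {"low_auditory": models.low_auditory,
                 "low_visual": models.low_visual,
                 "high_semantic": models.high_semantic,
                 "editing": models.editing}
        return groups, geometry, feats, truth

    if not (config.a_paths and config.v_paths and config.mask_path):
        raise ValueError("config needs either a simulate block or data paths")

    def load(paths, condition, population="TD"):
        group, geom = io_mod.read_bold_group(
            paths, config.mask_path, config.tr_seconds,
            config.run_lengths, condition, population)
        return group, geom

    groups = {}
    geometry = None
    for key, paths, cond, pop in (
        ("AV", config.av_paths, "AV", "TD"),
        ("A", config.a_paths, "A", "TD"),
        ("V", config.v_paths, "V", "TD"),
        ("SD_A", config.sd_a_paths, "A", "SD"),
        ("SD_V", config.sd_v_paths, "V", "SD"),
    ):
        if paths:
            groups[key], geometry = load(paths, cond, pop)
    feats = None
    if config.feature_tsvs:
        feats = {level: io_mod.read_feature_model(path, level)
                 for level, path in config.feature_tsvs.items()}
    return groups, geometry, feats, None


def _infer_map(m: isc_mod.IscMap, groups, config: PipelineConfig,
               grid, statistic="t") -> isc_mod.IscMap:
    spec = config.surrogate_spec()
    null = perm.null_distribution(
        lambda *gs: isc_mod.isc_map_stat(*gs, statistic=statistic), groups, spec)
    stat = m.t_stat if statistic == "t" else m.mean_r
    m.p = perm.gpd_p_map(stat, null.per_voxel_stats)
    m.fwe_threshold = perm.fwe_threshold(null, config.alpha)
    m.significant_mask = perm.cluster_filter_flat(
        stat, m.fwe_threshold, grid,
        min_size=config.min_cluster, connectivity=config.connectivity)
    return m


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the pipeline; returns the manifest dictionary.

    ``stages`` restricts execution to a subset of
    ``{"isc", "mediation", "trw"}``; omitted stages are skipped with a log
    line.  Stage failures abort with the stage name; outputs of earlier
    stages are retained.
    """
    stages = set(stages) if stages is not None else {"isc", "mediation", "trw"}
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "crossisc",
        "version": __version__,
        "seed": config.seed,
        "param_hash": _param_hash(config),
        "stages": {},
        "outputs": [],
    }

    def record(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    def stage(name):
        t0 = time.time()
        log.info("stage %s started (seed=%d)", name, config.seed)
        return t0

    groups, geometry, feats, truth = _load_groups(config)
    grid = geometry.mask if geometry is not None else None
    if geometry is not None:
        geometry.write_mask(out / "mask.nii.gz")
        record(out / "mask.nii.gz")

    sig_av = sig_across = None
    try:
        if "isc" in stages:
            t0 = stage("isc")
            if "AV" in groups:
                m_av = isc_mod.isc_within(groups["AV"])
                m_av = _infer_map(m_av, [groups["AV"]], config, grid)
                io_mod.write_isc_map(m_av, geometry, out / "isc", "av_within")
                sig_av = m_av
            if "A" in groups and "V" in groups:
                m_x = isc_mod.isc_across(groups["A"], groups["V"])
                m_x = _infer_map(m_x, [groups["A"], groups["V"]], config, grid)
                io_mod.write_isc_map(m_x, geometry, out / "isc", "a_vs_v")
                sig_across = m_x
            if sig_av is not None and sig_across is not None:
                conj = isc_mod.conjunction([sig_av, sig_across])
                geometry.write_map(conj.astype(float), out / "isc" / "conjunction.nii.gz")
                record(out / "isc" / "conjunction.nii.gz")
            if "SD_A" in groups and "SD_V" in groups:
                m_sd = isc_mod.isc_across(groups["SD_A"], groups["SD_V"])
                m_sd = _infer_map(m_sd, [groups["SD_A"], groups["SD_V"]],
                                  config, grid)
                io_mod.write_isc_map(m_sd, geometry, out / "isc", "sd_a_vs_v")
            for f in sorted((out / "isc").glob("*")):
                record(f)
            manifest["stages"]["isc"] = {"elapsed_s": round(time.time() - t0, 2),
                                         "n_permutations": config.n_permutations}
        else:
            log.info("stage isc skipped")
    except Exception as exc:
        raise RuntimeError(f"stage 'isc' failed: {exc}") from exc

    try:
        if "mediation" in stages and feats is not None and "A" in groups and "V" in groups:
            t0 = stage("mediation")
            editing = feats["editing"]
            T = groups["A"].n_timepoints
            rl = groups["A"].run_lengths
            tr = groups["A"].tr_seconds

            def design_for(*models):
                orth = [med.orthogonalize(m, editing) for m in models]
                mats = [med.build_design(m, tr, T, rl, hrf=config.hrf)[:, :m.matrix.shape[1]]
                        for m in orth]
                intercept = med.build_design(orth[0], tr, T, rl, hrf=False)[:, orth[0].matrix.shape[1]:]
                return np.column_stack(mats + [intercept])

            # cross-modal low-level assignment: visual features removed from
            # the audio-only group, acoustic features from the visual-only group
            low = med.mediated_isc(groups["A"], groups["V"],
                                   design_for(feats["low_visual"]),
                                   design_for(feats["low_auditory"]))
            low = med.drop_significance(
                low, groups["A"], groups["V"],
                design_for(feats["low_visual"]), design_for(feats["low_auditory"]),
                config.surrogate_spec(), config.alpha, grid,
                config.min_cluster, config.connectivity)
            io_mod.write_mediation_result(low, geometry, out / "mediation", "low")

            high_design = design_for(feats["high_semantic"])
            high = med.mediated_isc(groups["A"], groups["V"], high_design, high_design)
            high = med.drop_significance(
                high, groups["A"], groups["V"], high_design, high_design,
                config.surrogate_spec(), config.alpha, grid,
                config.min_cluster, config.connectivity)
            io_mod.write_mediation_result(high, geometry, out / "mediation", "high")

            contrast = med.compare_model_drops(
                low.pair_drop, high.pair_drop,
                n_permutations=config.n_permutations, seed=config.seed,
                alpha=config.alpha)
            geometry.write_map(contrast.W, out / "mediation" / "low_vs_high_W.nii.gz")
            for f in sorted((out / "mediation").glob("*")):
                record(f)
            manifest["stages"]["mediation"] = {"elapsed_s": round(time.time() - t0, 2)}
        elif "mediation" in stages:
            log.info("stage mediation skipped: no feature models available")
            manifest["stages"]["mediation"] = {"skipped": "no feature models"}
    except Exception as exc:
        raise RuntimeError(f"stage 'mediation' failed: {exc}") from exc

    try:
        if "trw" in stages and "A" in groups and "V" in groups:
            t0 = stage("trw")
            widths = np.asarray(config.widths_s, dtype=float) if config.widths_s \
                else trw_mod.default_widths_s(groups["A"].tr_seconds,
                                              min(240.0, groups["A"].n_timepoints
                                                  * groups["A"].tr_seconds / 4))
            prof_td = trw_mod.trw_profile(groups["A"], groups["V"], widths)
            (out / "trw").mkdir(exist_ok=True)
            np.savetxt(out / "trw" / "td_peak_width_s.tsv",
                       prof_td.peak_width_s, delimiter="\t")
            trw_mod.plot_profile_matrix(prof_td, out / "trw" / "td_profile.png")
            if "SD_A" in groups and "SD_V" in groups:
                prof_sd = trw_mod.trw_profile(groups["SD_A"], groups["SD_V"], widths)
                np.savetxt(out / "trw" / "sd_peak_width_s.tsv",
                           prof_sd.peak_width_s, delimiter="\t")
                nulls = trw_mod.null_peak_maps(
                    groups["A"], groups["V"], widths,
                    n_maps=config.n_null_maps, seed=config.seed,
                    surrogate_spec=config.surrogate_spec())
                mask = np.isfinite(prof_td.peak_width_s) & np.isfinite(prof_sd.peak_width_s)
                simres = trw_mod.map_similarity(
                    prof_td.peak_width_s, prof_sd.peak_width_s, mask, nulls)
                (out / "trw" / "similarity.tsv").write_text(
                    "rho\tp\tn_null_maps\n"
                    f"{simres.rho:.6f}\t{simres.p:.6f}\t{simres.n_null_maps}\n")
            for f in sorted((out / "trw").glob("*")):
                record(f)
            manifest["stages"]["trw"] = {"elapsed_s": round(time.time() - t0, 2),
                                         "n_widths": int(widths.size)}
        elif "trw" in stages:
            log.info("stage trw skipped: A/V groups unavailable")
    except Exception as exc:
        raise RuntimeError(f"stage 'trw' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
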