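"""End-to-end study orchestration: preprocess → masks → PSD → detectors →
metrics → group statistics, from a YAML config or in memory.

Analysis windows mirror the study design: whole-night N2/N3, first-cycle
N2/N3, and whole-night N2.  Detection thresholds are recomputed inside each
window (they must be internal to the analysed data).  Group statistics run
the supra-threshold cluster permutation test on each per-channel metric
topography.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from . import synthetic_data as synth
from .hypnogram_metrics import (EpochSelection, SleepArchitecture,
                                compare_architecture, detect_cycles,
                                score_architecture, stage_mask)
from .preprocess import preprocess_recording, reject_artifacts
from .slow_waves import SW_FEATURES, detect_slow_waves, slow_wave_metrics
from .spectral import band_power, welch_psd
from .spindles import (FAST_RANGE, SLOW_RANGE, WHOLE_RANGE, DetectionParams,
                       detect_spindles, spindle_metrics)
from .stats_topo import ClusterResult, snpm_cluster_test

log = logging.getLogger("somnotype")

DEFAULT_BANDS = {"delta": (1.0, 4.0), "sigma": (12.0, 16.0)}
DEFAULT_WINDOWS = ("wholenight_n2n3", "cycle1_n2n3", "wholenight_n2")
SPINDLE_RANGES = {"whole": WHOLE_RANGE, "slow": SLOW_RANGE, "fast": FAST_RANGE}


@dataclass
class AnalysisParams:
    detection: DetectionParams = field(default_factory=DetectionParams)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    windows: tuple = DEFAULT_WINDOWS
    artifact_factor_low: float = 4.0
    artifact_factor_high: float = 4.0
    log_power: bool = True
    t_thresh: float | None = None   # None -> critical t for the design df
    n_perm: int = 1024
    seed: int = 0


def _window_selection(window: str, hyp, n_channels: int, artifact_mask):
    cycle = None
    if window.startswith("cycle1"):
        cycles = detect_cycles(hyp)
        if not cycles:
            raise ValueError("no sleep cycles found")
        cycle = cycles[0]
    stages = ("N2",) if window.endswith("_n2") else ("N2", "N3")
    return stage_mask(hyp, stages, n_channels, cycle=cycle,
                      epoch_mask=artifact_mask)


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    architecture: SleepArchitecture
    # window -> metric name -> per-channel array
    topographies: dict[str, dict[str, np.ndarray]]
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for window, metrics in self.topographies.items():
            for metric, vals in metrics.items():
                for lb, v in zip(self.labels, vals):
                    rows.append((self.subject_id, self.group, window, metric, lb, v))
        return pd.DataFrame(rows, columns=[
            "subject", "group", "window", "metric", "channel", "value"])


def analyze_subject(rec: iof.Recording, hyp: iof.Hypnogram,
                    subject_id: str = "S01", group: str = "A",
                    params: AnalysisParams | None = None,
                    preprocess: bool = True) -> SubjectResult:
    """Full single-subject analysis over every configured window."""
    params = params or AnalysisParams()
    if preprocess:
        rec = preprocess_recording(rec)
    artifact_mask = reject_artifacts(
        rec, hyp, factor_low=params.artifact_factor_low,
        factor_high=params.artifact_factor_high)

    # band-pass filtering is window-independent; compute once per subject
    from .spindles import detect_spindles_filtered, sigma_filter
    from .slow_waves import detect_slow_waves_filtered, sw_filter

    sigma = sigma_filter(rec, params.detection.band, params.detection.filter_order)
    sw_filt = sw_filter(rec)

    topo: dict[str, dict[str, np.ndarray]] = {}
    for window in params.windows:
        try:
            sel = _window_selection(window, hyp, rec.n_channels, artifact_mask)
        except ValueError as exc:
            log.warning("%s: window %s skipped (%s)", subject_id, window, exc)
            continue
        metrics: dict[str, np.ndarray] = {}

        psd = welch_psd(rec, sel)
        for name, band in params.bands.items():
            bp = band_power(psd, band)
            metrics[f"power_{name}"] = np.log10(bp) if params.log_power else bp

        sp_events = detect_spindles_filtered(sigma, rec.labels, rec.fs, sel,
                                             params.detection)
        for rname, rng_ in SPINDLE_RANGES.items():
            sm = spindle_metrics(sp_events, sel, rec.labels, rng_)
            metrics[f"spindle_density_{rname}"] = sm.density
            metrics[f"spindle_duration_{rname}"] = sm.mean_duration
            metrics[f"isas_{rname}"] = sm.isas

        sw_events = detect_slow_waves_filtered(sw_filt, rec.labels, rec.fs, sel)
        swm = slow_wave_metrics(sw_events, sel, rec.labels)
        metrics["sw_density"] = swm.density
        for feat in SW_FEATURES:
            metrics[f"sw_{feat}"] = swm.means[feat]

        topo[window] = metrics
        log.info("%s: window %s, %d spindles, %d slow waves, %.1f min retained",
                 subject_id, window, len(sp_events), len(sw_events),
                 float(sel.minutes().mean()))

    return SubjectResult(subject_id=subject_id, group=group,
                         architecture=score_architecture(hyp),
                         topographies=topo, labels=list(rec.labels))


@dataclass
class StudyReport:
    subjects: list[SubjectResult]
    architecture_table: pd.DataFrame
    clusters: pd.DataFrame        # window, metric, channels, stat, p
    cluster_objects: dict         # (window, metric) -> list[ClusterResult]

    def significant(self, window: str, metric: str, alpha: float = 0.05) -> bool:
        key = (window, metric)
        return any(c.p < alpha for c in self.cluster_objects.get(key, []))


def group_statistics(results: list[SubjectResult],
                     adjacency: iof.AdjacencyGraph,
                     params: AnalysisParams) -> tuple[pd.DataFrame, dict]:
    """Cluster permutation tests for every window/metric topography."""
    ga = [r for r in results if r.group == "A"]
    gb = [r for r in results if r.group == "B"]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 subjects per group")
    windows = sorted({w for r in results for w in r.topographies})
    rows = []
    objects: dict[tuple[str, str], list[ClusterResult]] = {}
    rng = np.random.default_rng(params.seed)
    for window in windows:
        ga_w = [r for r in ga if window in r.topographies]
        gb_w = [r for r in gb if window in r.topographies]
        if len(ga_w) < 2 or len(gb_w) < 2:
            continue
        metric_names = list(ga_w[0].topographies[window])
        for metric in metric_names:
            a = np.array([r.topographies[window][metric] for r in ga_w])
            b = np.array([r.topographies[window][metric] for r in gb_w])
            if np.isnan(a).any() or np.isnan(b).any():
                # undefined channel means (no events) cannot enter the t-map
                col_ok = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))
                a = np.where(np.isnan(a), 0.0, a)
                b = np.where(np.isnan(b), 0.0, b)
                a[:, ~col_ok] = 0.0
                b[:, ~col_ok] = 0.0
            clusters = snpm_cluster_test(
                a, b, adjacency, t_thresh=params.t_thresh,
                n_perm=params.n_perm, seed=rng)
            objects[(window, metric)] = clusters
            for k, c in enumerate(clusters):
                rows.append((window, metric, k, c.sign, ";".join(c.channels),
                             c.stat, c.p))
    table = pd.DataFrame(rows, columns=[
        "window", "metric", "cluster_id", "sign", "channels", "stat", "p_corrected"])
    return table, objects


def analyze_cohort(subjects: list[synth.Subject],
                   adjacency: iof.AdjacencyGraph,
                   params: AnalysisParams | None = None,
                   preprocess: bool = True) -> StudyReport:
    """In-memory cohort analysis (synthetic subjects or loaded recordings)."""
    params = params or AnalysisParams()
    results = [analyze_subject(s.recording, s.hypnogram, s.subject_id, s.group,
                               params, preprocess=preprocess)
               for s in subjects]
    arch_a = [r.architecture for r in results if r.group == "A"]
    arch_b = [r.architecture for r in results if r.group == "B"]
    arch = compare_architecture(arch_a, arch_b)
    clusters, objects = group_statistics(results, adjacency, params)
    return StudyReport(subjects=results, architecture_table=arch,
                       clusters=clusters, cluster_objects=objects)


# ---------------------------------------------------------------------------
# Disk layout, config, fixtures
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    manifest: list[dict]            # {subject, group, edf, hypnogram}
    montage_path: str
    out_dir: str
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        for key in ("manifest", "montage", "out_dir"):
            if key not in obj:
                raise ValueError(f"config missing required key {key!r}")
        p = obj.get("params", {})
        det = DetectionParams(**p.pop("detection", {}))
        params = AnalysisParams(detection=det, **{
            k: v for k, v in p.items()
            if k in {f.name for f in dataclasses.fields(AnalysisParams)} - {"detection"}})
        if isinstance(params.windows, list):
            params.windows = tuple(params.windows)
        manifest = obj["manifest"]
        groups = {m.get("group") for m in manifest}
        for g in groups:
            if sum(m.get("group") == g for m in manifest) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")
        return cls(manifest=manifest, montage_path=obj["montage"],
                   out_dir=obj["out_dir"], params=params)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full pipeline from files on disk and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = iof.read_montage(config.montage_path)
    adjacency = iof.build_adjacency(montage)

    results = []
    failed = []
    for entry in config.manifest:
        sid, group = entry["subject"], entry["group"]
        try:
            rec = iof.read_recording(entry["edf"])
            hyp = iof.read_hypnogram(entry["hypnogram"])
            res = analyze_subject(rec, hyp, sid, group, config.params)
            results.append(res)
            res.to_frame().to_csv(out / f"metrics_{sid}.csv", index=False)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.error("subject %s failed: %s", sid, exc)
            failed.append((sid, str(exc)))
    for g in ("A", "B"):
        if sum(r.group == g for r in results) < 2:
            raise RuntimeError(
                f"group {g} below minimum after failures: {failed}")

    topo = pd.concat([r.to_frame() for r in results], ignore_index=True)
    topo.to_csv(out / "topographies.csv", index=False)

    arch = compare_architecture([r.architecture for r in results if r.group == "A"],
                                [r.architecture for r in results if r.group == "B"])
    arch.to_csv(out / "architecture_comparison.csv")

    clusters, objects = group_statistics(results, adjacency, config.params)
    clusters.to_csv(out / "clusters.csv", index=False)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"params: {config.params}\n")
        fh.write(f"n_subjects: {len(results)}; failed: {failed}\n")
    return StudyReport(subjects=results, architecture_table=arch,
                       clusters=clusters, cluster_objects=objects)


# short nights need compressed dynamics — quick onset, early REM, and bout
# lengths scaled with the night, otherwise a 20-30-min recording is one or
# two bouts and per-subject stage mix becomes bimodal
SHORT_NIGHT_PROFILE = synth.StageProfile(
    targets={"W": 0.05, "N1": 0.08, "N2": 0.55, "N3": 0.22, "REM": 0.10},
    bout_min={"W": 1.0, "N1": 1.0, "N2": 4.0, "N3": 3.0, "REM": 3.0},
    initial_wake_min=2.0, rem_embargo_min=15.0)

PRESETS = {
    "tiny": dict(n_per_group=4, n_channels=8, total_min=20.0,
                 profile=SHORT_NIGHT_PROFILE),
    "paperlike": dict(n_per_group=16, n_channels=64, total_min=360.0,
                      profile=None),
}


def make_fixture(out_dir, preset: str = "tiny", seed: int = 0,
                 effect: synth.EffectConfig | None = None,
                 force: bool = False) -> Path:
    """Write a synthetic cohort (EDF + hypnogram CSV + truth CSV) to disk.

    Layout: ``cohort/<group>/<subject>/`` plus ``montage.json``,
    ``manifest.csv`` and a ready-to-run ``config.yaml``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    spec = PRESETS[preset]
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    montage = synth.make_montage(spec["n_channels"])
    iof.write_montage(montage, out / "montage.json")
    effect = effect or synth.EffectConfig()
    subjects = synth.generate_cohort(
        spec["n_per_group"], effect, seed, montage=montage,
        total_min=spec["total_min"], profile=spec["profile"])

    manifest_rows = []
    for s in subjects:
        sdir = out / "cohort" / s.group / s.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        iof.write_recording(s.recording, sdir / "eeg.edf")
        iof.write_hypnogram(s.hypnogram, sdir / "hypnogram.csv")
        iof.write_event_table(
            pd.concat([iof.events_to_table(s.truth.by_kind(k), s.subject_id, k)
                       for k in ("spindle", "slow_wave")], ignore_index=True),
            sdir / "truth.csv")
        manifest_rows.append(dict(subject=s.subject_id, group=s.group,
                                  edf=str(sdir / "eeg.edf"),
                                  hypnogram=str(sdir / "hypnogram.csv")))
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)

    cfg = dict(manifest=manifest_rows, montage=str(out / "montage.json"),
               out_dir=str(out / "results"),
               params=dict(n_perm=512, seed=seed))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return out
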