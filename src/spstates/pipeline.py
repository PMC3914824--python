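"""End-to-end orchestration: records in, repertoires and statistics out.

``analyze_study`` runs the full chain in memory:
preprocess -> sliding spectra -> pool -> classifier fit ->
final labels -> segments -> clusters -> repertoires -> universality ->
chance-model statistics. ``run_pipeline`` wraps it with file input
(manifest or synthetic design), output writing and seeding; identical
configuration and seed give a bit-identical output bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .classify import ClassifierConfig, SpectralPatternClassifier, build_pool
from .preprocess import PreprocessConfig, preprocess
from .records import EEGRecord
from .repertoire import (RepertoireConfig, Repertoire, SPCluster,
                         UniversalityTable, build_repertoire,
                         categorize_clusters, cluster_sp_classes,
                         map_to_clusters, band_label)
from .segmentation import run_length_segments, segments_frame
from .spectral import SpectralConfig, sliding_spectra
from .stats import CATEGORIES, category_null, chisq_gof, percent_change
from .synthetic import ClusterSpec, StateDef, StudyDesign, gen_study

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "analyze_study", "run_pipeline", "RunConfig"]

STAGES = ("spectral", "classify", "segment", "repertoire", "stats")


@dataclass
class StudyResult:
    """Everything the pipeline computes for one study."""

    classifier: SpectralPatternClassifier | None = None
    labels: pd.DataFrame | None = None
    segments: pd.DataFrame | None = None
    clusters: list[SPCluster] | None = None
    repertoires: list[Repertoire] | None = None
    universality: UniversalityTable | None = None
    stats_report: dict | None = None
    pool_size: int = 0


def analyze_study(
    records: list[EEGRecord],
    pre_cfg: PreprocessConfig | None = None,
    spec_cfg: SpectralConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    rep_cfg: RepertoireConfig | None = None,
    reference_condition: str | None = None,
    stop_after: str = "stats",
) -> StudyResult:
    """Run the probability-classification analysis on one study."""
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    pre_cfg = pre_cfg or PreprocessConfig()
    spec_cfg = spec_cfg or SpectralConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    rep_cfg = rep_cfg or RepertoireConfig()
    result = StudyResult()

    entries = []
    for rec in records:
        for epoch in preprocess(rec, pre_cfg):
            for ci, ch in enumerate(epoch.channel_labels):
                entries.append({
                    "subject": rec.subject_id, "condition": rec.condition,
                    "channel": ch, "epoch": epoch.index,
                    "spectra": sliding_spectra(epoch.samples[ci], epoch.fs, spec_cfg),
                })
    pool = build_pool(entries)
    result.pool_size = len(pool)
    if stop_after == "spectral":
        return result

    clf = SpectralPatternClassifier(**{f: getattr(clf_cfg, f)
                                       for f in ("cc_accept", "peak_threshold",
                                                 "shift_bins", "mutual_cc_max",
                                                 "min_count")})
    clf.fit(pool.spectra, channels=pool.meta["channel"].to_numpy())
    labels = pool.meta.copy()
    lab = np.empty(len(pool), dtype=int)
    conf = np.empty(len(pool))
    low = np.empty(len(pool), dtype=bool)
    for ch, idx in labels.groupby("channel").groups.items():
        seq = clf.label_sequence(pool.spectra[np.asarray(idx)], ch)
        lab[np.asarray(idx)] = seq.labels
        conf[np.asarray(idx)] = seq.confidence
        low[np.asarray(idx)] = seq.low_confidence
    labels["class_id"] = lab
    labels["confidence"] = conf
    labels["low_confidence"] = low
    result.classifier = clf
    result.labels = labels
    if stop_after == "classify":
        return result

    seg_frames = []
    for (subj, cond, ch, ep), grp in labels.groupby(
            ["subject", "condition", "channel", "epoch"], sort=True):
        grp = grp.sort_values("window")
        segs = run_length_segments(grp["class_id"].to_numpy(), channel_label=ch)
        frame = segments_frame(segs, epoch=ep)
        frame.insert(0, "condition", cond)
        frame.insert(0, "subject", subj)
        seg_frames.append(frame)
    result.segments = pd.concat(seg_frames, ignore_index=True)
    if stop_after == "segment":
        return result

    counts = labels.groupby(["channel", "class_id"]).size()
    cluster_entries = []
    for ch, aset in sorted(clf.actual_sets_.items()):
        for tpl in aset.templates:
            cluster_entries.append(
                (ch, tpl.class_id, tpl.peaks, int(counts.get((ch, tpl.class_id), 0)))
            )
    clusters = cluster_sp_classes(cluster_entries, rep_cfg)
    labels["cluster_id"] = map_to_clusters(labels, clusters)
    conditions = sorted(labels["condition"].unique())
    repertoires = [build_repertoire(labels, c, clusters, rep_cfg)
                   for c in conditions]
    result.clusters = clusters
    result.repertoires = repertoires
    if stop_after == "repertoire":
        return result

    report: dict = {
        "n_clusters": len(clusters),
        "repertoire_sizes": {r.condition: r.size for r in repertoires},
    }
    if len(repertoires) >= 2:
        universality = categorize_clusters(repertoires, rep_cfg)
        result.universality = universality
        observed = [int((universality.table["category"] == c).sum())
                    for c in CATEGORIES]
        total = int(universality.table.shape[0])
        null = category_null(len(repertoires),
                             universal_fraction=rep_cfg.universal_fraction)
        # categories with zero chance mass (possible at small C) carry no
        # information and are dropped from the GOF comparison
        keep = [k for k, pr in enumerate(null.expected_probs) if pr > 0]
        null_k = type(null)(null.n_conditions, null.p_occurrence,
                            tuple(null.expected_probs[k] for k in keep))
        stat, p = chisq_gof([observed[k] for k in keep], null_k, total)
        report.update({
            "category_counts": dict(zip(CATEGORIES, observed)),
            "chance_expected_mean_occurrences": null.expected_mean_occurrences,
            "chisq_statistic": stat,
            "chisq_p": p,
            "chisq_construction": (
                "goodness-of-fit of observed unique/optional/universal counts "
                "against Binomial(C, 0.5) conditioned on >=1 occurrence"
            ),
        })
    if reference_condition is not None:
        sizes = report["repertoire_sizes"]
        if reference_condition not in sizes:
            raise ValueError(f"unknown reference condition {reference_condition!r}")
        ref = sizes[reference_condition]
        report["percent_change_vs_reference"] = {
            c: percent_change(ref, n) for c, n in sizes.items()
            if c != reference_condition
        }
    result.stats_report = report
    return result


# ---------------------------------------------------------------------------
# file-level front end


@dataclass
class RunConfig:
    """Resolved run configuration (from YAML via ``RunConfig.from_file``)."""

    out: Path
    manifest: Path | None = None
    synthetic: dict | None = None
    seed: int = 0
    epoch_len: float = 60.0
    preprocess: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    repertoire: dict = field(default_factory=dict)
    reference_condition: str | None = None
    stop_after: str = "stats"
    write_sp_matrices: bool = False

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'manifest' and 'synthetic' must be supplied")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["out"] = Path(raw.get("out", "sp_states_out"))
        if raw.get("manifest"):
            raw["manifest"] = Path(raw["manifest"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def design_from_dict(d: dict, seed: int = 0) -> StudyDesign:
    """Build a StudyDesign from the 'synthetic' section of a run config."""
    states = {
        sid: StateDef(sid, tuple(s.get("peaks", ())), tuple(s.get("amps", ())),
                      float(s.get("noise_sd", 0.0)), float(s.get("pink_scale", 0.0)))
        for sid, s in d["states"].items()
    }
    matrix = {
        sid: ClusterSpec(tuple(m["conditions"]), float(m.get("probability", 1.0)))
        for sid, m in d["cluster_matrix"].items()
    }
    return StudyDesign(states, matrix, list(d["conditions"]),
                       int(d["n_subjects"]), int(d.get("n_channels", 8)),
                       seed=int(d.get("seed", seed)))


def _write_outputs(result: StudyResult, cfg: RunConfig) -> None:
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    resolved = {k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(cfg).items()}
    with open(out / "config.json", "w") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True, default=str)
    if result.classifier is not None:
        rows = []
        for ch, aset in sorted(result.classifier.actual_sets_.items()):
            for tpl in aset.templates:
                rows.append({"channel": ch, "class_id": tpl.class_id,
                             "fallback": tpl.fallback,
                             **{f"bin_{k}": tpl.template[k] for k in range(59)}})
        pd.DataFrame(rows).to_csv(out / "templates.tsv", sep="\t", index=False)
        result.labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    if result.segments is not None:
        result.segments.to_csv(out / "segments.tsv", sep="\t", index=False)
    if result.repertoires is not None:
        rep_cfg = RepertoireConfig(**cfg.repertoire)
        rows = []
        for r in result.repertoires:
            for cid in sorted(r.cluster_ids):
                cl = next(c for c in result.clusters if c.cluster_id == cid)
                rows.append({
                    "condition": r.condition, "cluster_id": cid,
                    "peaks_hz": ",".join(f"{p:g}" for p in cl.representative_peaks),
                    "bands": ",".join(band_label(p, rep_cfg.band_map)
                                      for p in cl.representative_peaks),
                    "morphology": cl.morphology,
                    "mean_occurrence": float(np.mean(list(r.occurrence[cid].values()))),
                })
        pd.DataFrame(rows).to_csv(out / "repertoire.tsv", sep="\t", index=False)
    if result.universality is not None:
        result.universality.table.to_csv(out / "universality.tsv", sep="\t",
                                         index=False)
        pd.DataFrame(sorted(result.universality.repertoire_sizes.items()),
                     columns=["condition", "n2"]).to_csv(
            out / "repertoire_sizes.tsv", sep="\t", index=False)
    if result.stats_report is not None:
        with open(out / "stats.json", "w") as fh:
            json.dump(result.stats_report, fh, indent=2, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> StudyResult:
    """Run the whole pipeline from a resolved configuration and write outputs."""
    epoch_len = cfg.epoch_len
    if cfg.manifest is not None:
        if not Path(cfg.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {cfg.manifest}")
        records = spio.load_dataset(cfg.manifest)
    else:
        design = design_from_dict(cfg.synthetic, seed=cfg.seed)
        epoch_len = float(cfg.synthetic.get("epoch_len", cfg.epoch_len))
        dataset, _manifest, _truth = gen_study(design, epoch_len=epoch_len)
        records = [rec for rec, _ in dataset]
    pre = dict(cfg.preprocess)
    pre.setdefault("epoch_len", epoch_len)
    result = analyze_study(
        records,
        pre_cfg=PreprocessConfig(**pre),
        clf_cfg=ClassifierConfig(**cfg.classifier),
        rep_cfg=RepertoireConfig(**cfg.repertoire),
        reference_condition=cfg.reference_condition,
        stop_after=cfg.stop_after,
    )
    _write_outputs(result, cfg)
    return result
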