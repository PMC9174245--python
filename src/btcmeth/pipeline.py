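"""End-to-end orchestration of the biomarker discovery workflow.

Stages, in order: sample QC → probe-to-island aggregation →
differential methylation in the discovery cohort → hypermethylated /
normal-low filter → replication in each validation cohort →
disease-specificity filter against other-cancer cohorts → overlap
enrichment → exhaustive panel search. Every stage writes a TSV and the
run ends with a JSON summary carrying the funnel of marker counts.

Cohorts come either from files (β matrix, sample sheet, probe
annotation, CGI BED in the package's formats) or from inline synthetic
specs, in which case all cohorts share one generated CGI universe. The
run is fully deterministic given the config seed: each stage derives a
child seed by stable hashing of its name, so stages can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as bio
from .differential import aggregate_to_cgi, differential_cgi
from .qc import DEFAULT_MAX_INTERMEDIATE, DEFAULT_MIN_BIMODALITY, qc_filter
from .selection import (
    MarkerSet,
    filter_hyper_normal_low,
    overlap_enrichment,
    panel_search,
    panels_to_frame,
    replicate_in,
    specificity_filter,
)
from .simulate import (
    Cohort,
    CohortSpec,
    generate_multidataset,
    generate_on_universe,
)

__all__ = ["PipelineConfig", "run_pipeline", "child_seed"]

logger = logging.getLogger(__name__)


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (crc32 mix, below 2^31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "btcmeth_run"
    # synthetic mode: cohort specs as plain dicts of CohortSpec fields
    synthetic: dict | None = None
    # file mode: {"discovery": {...paths}, "validation": [...], "other_cancers": [...]}
    cohorts: dict | None = None
    delta_thresh: float = 0.20
    p_thresh: float = 0.05
    normal_max: float = 0.20
    qc_enabled: bool = True
    qc_max_intermediate: float = DEFAULT_MAX_INTERMEDIATE
    qc_min_bimodality: float = DEFAULT_MIN_BIMODALITY
    min_probes: int = 3
    combine: str = "fisher"
    panel_max_size: int = 3
    panel_criterion: str = "youden"
    panel_max_candidates: int = 15

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("delta_thresh", "p_thresh", "normal_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if (self.synthetic is None) == (self.cohorts is None):
            raise ValueError(
                "config must set exactly one of 'synthetic' or 'cohorts'"
            )


def _load_cohort_files(paths: dict) -> Cohort:
    beta = bio.read_beta_matrix(paths["beta"])
    sheet = bio.read_sample_sheet(paths["sheet"])
    probes = bio.read_probe_annotation(paths["probes"])
    cgis = bio.read_bed(paths["cgis"])
    from .intervals import map_probes_to_cgis

    if "cgi_id" not in probes.columns:
        probes = map_probes_to_cgis(probes, cgis)
    from .simulate import PlantedTruth

    truth = PlantedTruth(
        cgi_labels=pd.Series(dtype=object), degraded=(),
        purity=pd.Series(dtype=float),
    )
    return Cohort(beta=beta, sheet=sheet, probes=probes, cgis=cgis,
                  truth=truth)


def _build_cohorts(config: PipelineConfig):
    """Return (discovery, validation dict, other-cancer dict, truth|None)."""
    if config.cohorts is not None:
        c = config.cohorts
        discovery = _load_cohort_files(c["discovery"])
        validation = {
            v["name"]: _load_cohort_files(v) for v in c.get("validation", [])
        }
        others = {
            v["name"]: _load_cohort_files(v)
            for v in c.get("other_cancers", [])
        }
        return discovery, validation, others, None

    syn = dict(config.synthetic)
    overlap = float(syn.get("overlap", 0.3))

    def spec_from(entry: dict, base: CohortSpec | None = None) -> CohortSpec:
        entry = dict(entry)
        if base is not None:
            entry.setdefault("n_cgis", base.n_cgis)
            entry.setdefault("probes_per_cgi", base.probes_per_cgi)
        for key in ("probes_per_cgi", "normal_mean_range",
                    "background_mean_range", "purity_range"):
            if key in entry:
                entry[key] = tuple(entry[key])
        return CohortSpec(**entry)

    disc_spec = spec_from(syn.get("discovery", {}))
    if disc_spec.seed == 0:
        disc_spec = dataclasses.replace(
            disc_spec, seed=child_seed(config.seed, "discovery")
        )
    other_specs = {}
    for entry in syn.get("other_cancers", []):
        entry = dict(entry)
        name = entry.pop("name")
        other_specs[name] = spec_from(entry, disc_spec)
    md = generate_multidataset(
        disc_spec, other_specs, overlap,
        seed=child_seed(config.seed, "simulate"),
    )
    validation = {}
    for entry in syn.get("validation", []):
        entry = dict(entry)
        name = entry.pop("name")
        vspec = spec_from(entry, disc_spec)
        # replication cohorts carry the same planted alterations
        validation[name] = generate_on_universe(
            md.btc, md.btc.truth.cgi_labels, vspec,
            seed=child_seed(config.seed, f"validation:{name}"), cohort=name,
        )
    return md.btc, validation, md.others, md


def _stage_differential(cohort: Cohort, config: PipelineConfig,
                        apply_qc: bool):
    """QC (optionally) then island-level differential records.

    Returns (records, cgi_meth, stage info dict, qc report).
    """
    beta = bio.drop_sparse_probes(cohort.beta)
    info: dict = {"n_samples_in": int(beta.shape[1])}
    if apply_qc:
        beta, report = qc_filter(
            beta, cohort.sheet,
            max_intermediate=config.qc_max_intermediate,
            min_bimodality=config.qc_min_bimodality,
            min_probes=min(1000, beta.shape[0]),
        )
        info["n_samples_kept"] = int(beta.shape[1])
        info["excluded"] = sorted(report.index[~report["passed"]])
    else:
        report = pd.DataFrame()
        info["n_samples_kept"] = int(beta.shape[1])
        info["excluded"] = []
    records = differential_cgi(
        beta, cohort.probes, cohort.sheet,
        min_probes=config.min_probes, combine=config.combine,
        delta_thresh=config.delta_thresh, p_thresh=config.p_thresh,
    )
    cgi_meth, _ = aggregate_to_cgi(beta, cohort.probes, config.min_probes)
    info["n_cgis"] = int(len(records))
    info["n_hyper"] = int((records["direction"] == "hyper").sum())
    info["n_hypo"] = int((records["direction"] == "hypo").sum())
    return records, cgi_meth, info, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full discovery→validation→panel workflow.

    Returns the summary dict (also written as ``summary.json``) whose
    ``funnel`` entry carries the marker counts after each filter stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        discovery, validation, others, md = _build_cohorts(config)
    except Exception as exc:
        fail("load", exc)

    try:
        disc_records, disc_cgi_meth, disc_info, qc_report = _stage_differential(
            discovery, config, apply_qc=config.qc_enabled
        )
    except Exception as exc:
        fail("discovery-differential", exc)
    disc_records.to_csv(out / "discovery_differential.tsv", sep="\t")
    if not qc_report.empty:
        qc_report.to_csv(out / "discovery_qc.tsv", sep="\t")
    summary["stages"]["discovery"] = disc_info

    val_records: dict[str, pd.DataFrame] = {}
    val_cgi_meth: dict[str, pd.DataFrame] = {}
    for name, cohort in validation.items():
        try:
            rec, cm, info, _ = _stage_differential(cohort, config,
                                                   apply_qc=False)
        except Exception as exc:
            fail(f"validation-differential:{name}", exc)
        rec.to_csv(out / f"validation_{name}_differential.tsv", sep="\t")
        val_records[name] = rec
        val_cgi_meth[name] = cm
        summary["stages"][f"validation:{name}"] = info

    other_records: dict[str, pd.DataFrame] = {}
    for name, cohort in others.items():
        try:
            rec, _, info, _ = _stage_differential(cohort, config,
                                                  apply_qc=False)
        except Exception as exc:
            fail(f"other-cancer-differential:{name}", exc)
        rec.to_csv(out / f"other_{name}_differential.tsv", sep="\t")
        other_records[name] = rec
        summary["stages"][f"other:{name}"] = info

    funnel: dict[str, int] = {
        "differential_hyper": int(
            (disc_records["direction"] == "hyper").sum()
        )
    }
    try:
        markers = filter_hyper_normal_low(
            disc_records, config.delta_thresh, config.p_thresh,
            config.normal_max,
        )
    except Exception as exc:
        fail("hyper-normal-low-filter", exc)
    funnel["hyper_normal_low"] = len(markers)

    enrichment: dict[str, float] = {}
    for name, rec in val_records.items():
        try:
            hyper_there = rec.index[rec["delta_beta"] > config.delta_thresh]
            n_before = len(markers)
            markers = replicate_in(
                markers, rec, config.delta_thresh, tag=f"replicated:{name}"
            )
            enrichment[name] = overlap_enrichment(
                len(markers), n_before, len(hyper_there),
                len(disc_records.index.union(rec.index)),
            )
        except Exception as exc:
            fail(f"replication:{name}", exc)
        funnel[f"replicated_{name}"] = len(markers)

    if others:
        try:
            markers = specificity_filter(markers, other_records,
                                         config.delta_thresh)
        except Exception as exc:
            fail("specificity-filter", exc)
    else:
        logger.info("no other-cancer cohorts: specificity filter skipped")
    funnel["disease_specific"] = len(markers)

    pd.Series(list(markers), name="cgi_id").to_csv(
        out / "selected_markers.tsv", sep="\t", index=False
    )
    summary["funnel"] = funnel
    summary["enrichment_p"] = enrichment
    summary["markers"] = list(markers)

    panels_frame = pd.DataFrame()
    if len(markers) > 0 and val_cgi_meth:
        # cap candidates for the exhaustive search: best discovery Δβ first
        ranked = (
            disc_records.loc[list(markers), "delta_beta"]
            .sort_values(ascending=False)
        )
        cand = MarkerSet(
            tuple(ranked.index[: config.panel_max_candidates]),
            provenance=markers.provenance + ("candidate_cap",),
        )
        try:
            panels = panel_search(
                disc_cgi_meth, discovery.sheet, cand,
                {
                    name: (val_cgi_meth[name], validation[name].sheet)
                    for name in validation
                },
                max_size=config.panel_max_size,
                criterion=config.panel_criterion,
            )
        except Exception as exc:
            fail("panel-search", exc)
        panels_frame = panels_to_frame(panels)
        panels_frame.to_csv(out / "panels.tsv", sep="\t", index=False)
        best = panels[0]
        summary["best_panel"] = {
            "markers": list(best.markers),
            "thresholds": {m: float(t) for m, t in best.thresholds.items()},
            "train_auc": best.train_auc,
            "validation": best.validation,
        }

    if md is not None:
        summary["truth"] = {
            "planted_hyper": list(md.btc.truth.hyper_cgis),
            "btc_specific": list(md.btc_specific),
            "shared_with_other_cancers": list(md.shared),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
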