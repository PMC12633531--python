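"""Pipeline orchestration: simulate -> detect -> time -> apobec -> svprox ->
report, driven by one YAML config, with a machine-readable run manifest and
hash-based stage skipping.

A single global seed is set in the config; each stage derives its own
substream by salting the seed with the stage name, so re-running one stage
reproduces it exactly regardless of which other stages run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .apobec import attribute_cohort
from .datamodel import DetectionParams, GenomeRef
from .detect import KataegisEvent, detect_cohort, expected_imd_diagnostic
from .simulate import SimConfig, generate_cohort, emit_cohort
from .stats import build_cohort_table, compare_many, percentage, survival_strata
from .svprox import run_proximity_analysis, sv_type_proximity
from .timing import annotate_epochs, epoch_proportions, event_epoch_label, refine_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "time", "apobec", "svprox", "report")

_TOP_KEYS = {"seed", "out_dir", "stages", "sim", "detect", "apobec", "svprox",
             "report"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-name-salted substream seed (stable across runs, < 2**31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    sim_keys = {f.name for f in fields(SimConfig)}
    bad = set(cfg.get("sim", {}) or {}) - sim_keys
    if bad:
        raise ValueError(f"unknown sim config keys: {sorted(bad)}")
    det_keys = {f.name for f in fields(DetectionParams)}
    for section in ("detect", "apobec", "svprox"):
        bad = set(cfg.get(section, {}) or {}) - det_keys
        if bad:
            raise ValueError(f"unknown {section} config keys: {sorted(bad)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _params_from(cfg: dict) -> DetectionParams:
    kw = {}
    for section in ("detect", "apobec", "svprox"):
        kw.update(cfg.get(section, {}) or {})
    kw.setdefault("rng_seed", cfg.get("seed", 0))
    return DetectionParams(**kw)


class PipelineRun:
    """Stateful run over one output directory."""

    def __init__(self, cfg: dict, out_dir):
        self.cfg = load_config(cfg)
        self.out = Path(out_dir or self.cfg.get("out_dir", "run"))
        self.out.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(self.cfg)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()

    # -- manifest ---------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            try:
                m = json.loads(self.manifest_path.read_text())
                if m.get("config_hash") == self.hash:
                    return m
            except json.JSONDecodeError:
                pass
        return {"config_hash": self.hash, "seed": self.cfg.get("seed", 0),
                "stages": {}}

    def _save_manifest(self):
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1,
                                                 default=str))

    def _record(self, stage: str, inputs: Sequence[Path],
                outputs: Sequence[Path], counts: dict):
        self.manifest["stages"][stage] = {
            "status": "ok",
            "inputs": {str(p.relative_to(self.out)): _file_hash(p)
                       for p in inputs if p.exists()},
            "outputs": {str(p.relative_to(self.out)): _file_hash(p)
                        for p in outputs if p.exists()},
            "counts": counts,
        }
        self._save_manifest()

    def _can_skip(self, stage: str, inputs: Sequence[Path],
                  outputs: Sequence[Path]) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec or rec.get("status") != "ok":
            return False
        for p in outputs:
            key = str(p.relative_to(self.out))
            if not p.exists() or rec["outputs"].get(key) != _file_hash(p):
                return False
        for p in inputs:
            key = str(p.relative_to(self.out))
            if not p.exists() or rec["inputs"].get(key) != _file_hash(p):
                return False
        return True

    # -- stage I/O shortcuts ----------------------------------------------
    @property
    def cohort_dir(self) -> Path:
        return self.out / "cohort"

    def _sample_ids(self) -> List[str]:
        return sorted(p.stem for p in self.cohort_dir.glob("*.vcf"))

    def _genome(self) -> GenomeRef:
        return GenomeRef.from_fasta(self.cohort_dir / "reference.fa")

    def _load_snvs(self, genome) -> Dict[str, list]:
        return {sid: kio.read_snvs(self.cohort_dir / f"{sid}.vcf", "vcf",
                                   genome=genome, sample_id=sid)
                for sid in self._sample_ids()}

    # -- stages -----------------------------------------------------------
    def run(self, stages: Optional[Sequence[str]] = None, force: bool = False):
        for stage in stages or STAGES:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            getattr(self, f"stage_{stage}")(force=force)
        return self.manifest

    def stage_simulate(self, force: bool = False):
        outputs = [self.cohort_dir / "truth.json", self.cohort_dir / "reference.fa",
                   self.cohort_dir / "clinical.tsv"]
        if not force and self._can_skip("simulate", [], outputs):
            log.info("simulate: outputs up to date, skipped")
            self.manifest["stages"]["simulate"]["status"] = "skipped"
            return
        sim_kw = dict(self.cfg.get("sim", {}) or {})
        sim_kw["seed"] = stage_seed(self.cfg["seed"], "simulate")
        config = SimConfig(**sim_kw)
        cohort = generate_cohort(config)
        emit_cohort(cohort, self.cohort_dir)
        outputs = sorted(self.cohort_dir.iterdir())
        self._record("simulate", [], outputs, {
            "samples": len(cohort.samples),
            "truth_events": len(cohort.truth_events),
        })

    def stage_detect(self, force: bool = False):
        inputs = [self.cohort_dir / f"{sid}.vcf" for sid in self._sample_ids()]
        outputs = [self.out / "events.tsv", self.out / "events.bed",
                   self.out / "imd_diagnostic.tsv"]
        if not force and self._can_skip("detect", inputs, outputs):
            log.info("detect: outputs up to date, skipped")
            self.manifest["stages"]["detect"]["status"] = "skipped"
            return
        params = _params_from(self.cfg)
        genome = self._genome()
        snvs = self._load_snvs(genome)
        events = detect_cohort(snvs, params, genome)
        flat = [e for sid in sorted(events) for e in events[sid]]
        kio.write_events(flat, self.out / "events.tsv", self.out / "events.bed")
        diag = pd.DataFrame([{
            "sample_id": sid, "n_snvs": len(snvs[sid]),
            "expected_imd": expected_imd_diagnostic(max(len(snvs[sid]), 1),
                                                    genome.total_length),
            "d_max": params.d_max,
        } for sid in sorted(snvs)])
        diag.to_csv(self.out / "imd_diagnostic.tsv", sep="\t", index=False)
        self._record("detect", inputs, outputs, {
            "samples_in": len(snvs), "events_called": len(flat),
            "samples_positive": sum(bool(v) for v in events.values()),
        })

    def stage_time(self, force: bool = False):
        inputs = [self.out / "events.tsv", self.cohort_dir / "cn_segments.tsv",
                  self.cohort_dir / "purity.tsv"]
        outputs = [self.out / "events_timed.tsv", self.out / "evo_events.tsv"]
        if not force and self._can_skip("time", inputs, outputs):
            log.info("time: outputs up to date, skipped")
            self.manifest["stages"]["time"]["status"] = "skipped"
            return
        params = _params_from(self.cfg)
        genome = self._genome()
        snvs = self._load_snvs(genome)
        segments = kio.read_cn_segments(self.cohort_dir / "cn_segments.tsv")
        seg_by_sample: Dict[str, list] = {}
        for seg in segments:
            seg_by_sample.setdefault(seg.sample_id, []).append(seg)
        events = self._events_by_sample(self.out / "events.tsv")
        for sid in sorted(snvs):
            annotate_epochs(snvs[sid], seg_by_sample.get(sid, ()),
                            params.clonal_ccf_threshold)
        for sid, evs in events.items():
            for e in evs:
                e.epoch = event_epoch_label(e, snvs[sid])
        evo = refine_cohort(events, snvs, params)
        flat = [e for sid in sorted(events) for e in events[sid]]
        kio.write_events(flat, self.out / "events_timed.tsv")
        evo_rows = [{
            "sample_id": e.sample_id, "parent_index": e.parent_index,
            "chrom": e.chrom, "epoch": e.epoch, "n_snv": e.n_snv,
            "start": e.member_positions[0], "end": e.member_positions[-1],
        } for sid in sorted(evo) for e in evo[sid]]
        pd.DataFrame(evo_rows, columns=["sample_id", "parent_index", "chrom",
                                        "epoch", "n_snv", "start", "end"]
                     ).to_csv(self.out / "evo_events.tsv", sep="\t", index=False)
        self._record("time", inputs, outputs, {
            "events_in": len(flat), "evo_events": len(evo_rows),
        })

    def stage_apobec(self, force: bool = False):
        inputs = [self.out / "events_timed.tsv"]
        outputs = [self.out / "events_apobec.tsv", self.out / "apobec.tsv"]
        if not force and self._can_skip("apobec", inputs, outputs):
            log.info("apobec: outputs up to date, skipped")
            self.manifest["stages"]["apobec"]["status"] = "skipped"
            return
        params = _params_from(self.cfg)
        genome = self._genome()
        snvs = self._load_snvs(genome)
        events = self._events_by_sample(self.out / "events_timed.tsv")
        results = attribute_cohort(events, snvs, genome, params)
        flat_events = [e for sid in sorted(events) for e in events[sid]]
        kio.write_events(flat_events, self.out / "events_apobec.tsv")
        rows = []
        for sid in sorted(results):
            for e, r in zip(events[sid], results[sid]):
                rows.append({
                    "sample_id": sid, "chrom": e.chrom, "start": e.start,
                    "mut_tcw_event": r.table[0][0],
                    "mut_other_event": r.table[0][1],
                    "bg_tcw_adj": r.table[1][0], "bg_other": r.table[1][1],
                    "odds_ratio": r.odds_ratio, "p": r.p, "fdr": r.fdr,
                    "apobec_enriched": int(r.apobec_enriched),
                    "a3_class": r.a3_class, "p_a3a": r.p_a3a, "p_a3b": r.p_a3b,
                    "note": r.note,
                })
        pd.DataFrame(rows).to_csv(self.out / "apobec.tsv", sep="\t", index=False)
        self._record("apobec", inputs, outputs, {
            "events_in": len(flat_events),
            "events_enriched": sum(r["apobec_enriched"] for r in rows),
        })

    def stage_svprox(self, force: bool = False):
        inputs = [self.out / "events_apobec.tsv"]
        outputs = [self.out / "events_final.tsv", self.out / "proximity.tsv"]
        if not force and self._can_skip("svprox", inputs, outputs):
            log.info("svprox: outputs up to date, skipped")
            self.manifest["stages"]["svprox"]["status"] = "skipped"
            return
        params = _params_from(self.cfg)
        genome = self._genome()
        snvs = self._load_snvs(genome)
        events = self._events_by_sample(self.out / "events_apobec.tsv")
        breakpoints = {sid: kio.read_sv_bedpe(self.cohort_dir / f"{sid}.bedpe",
                                              sample_id=sid, genome=genome)
                       for sid in self._sample_ids()}
        clinical = kio.read_clinical(self.cohort_dir / "clinical.tsv")
        group_of = {c.sample_id: c.group for c in clinical}
        rng = np.random.default_rng(stage_seed(self.cfg["seed"], "svprox"))
        nulls = run_proximity_analysis(events, snvs, breakpoints, genome,
                                       params, rng, group_of)
        flat_events = [e for sid in sorted(events) for e in events[sid]]
        kio.write_events(flat_events, self.out / "events_final.tsv")
        rows = []
        for gid in sorted(nulls):
            n = nulls[gid]
            for b in range(len(n.observed_counts)):
                rows.append({
                    "group": gid, "bin_low": n.bin_edges[b],
                    "bin_high": n.bin_edges[b + 1],
                    "observed": int(n.observed_counts[b]),
                    "sim_mean": float(n.sim_counts[:, b].mean()),
                    "p_enrich": n.p_enrich[b], "p_sparse": n.p_sparse[b],
                    "fdr_enrich": n.fdr_enrich[b], "fdr_sparse": n.fdr_sparse[b],
                    "bin_class": n.bin_class[b],
                })
        pd.DataFrame(rows).to_csv(self.out / "proximity.tsv", sep="\t",
                                  index=False)
        typed = sv_type_proximity(events, breakpoints, window=1e4,
                                  alpha=params.alpha)
        pd.DataFrame(typed).to_csv(self.out / "sv_type_proximity.tsv", sep="\t",
                                   index=False)
        self._record("svprox", inputs, outputs, {
            "events_in": len(flat_events),
            "events_sv_associated": sum(e.sv_class == "SV_associated"
                                        for e in flat_events),
            "events_sv_independent": sum(e.sv_class == "SV_independent"
                                         for e in flat_events),
        })

    def stage_report(self, force: bool = False):
        inputs = [self.out / "events_final.tsv", self.cohort_dir / "clinical.tsv"]
        outputs = [self.out / "report" / "cohort.tsv",
                   self.out / "report" / "summary.json"]
        if not force and self._can_skip("report", inputs, outputs):
            log.info("report: outputs up to date, skipped")
            self.manifest["stages"]["report"]["status"] = "skipped"
            return
        params = _params_from(self.cfg)
        report_dir = self.out / "report"
        report_dir.mkdir(exist_ok=True)
        genome = self._genome()
        snvs = self._load_snvs(genome)
        events = self._events_by_sample(self.out / "events_final.tsv")
        segments = kio.read_cn_segments(self.cohort_dir / "cn_segments.tsv")
        seg_by_sample: Dict[str, list] = {}
        for seg in segments:
            seg_by_sample.setdefault(seg.sample_id, []).append(seg)
        for sid in sorted(snvs):
            annotate_epochs(snvs[sid], seg_by_sample.get(sid, ()),
                            params.clonal_ccf_threshold)
        clinical = kio.read_clinical(self.cohort_dir / "clinical.tsv")
        breakpoints = {sid: kio.read_sv_bedpe(self.cohort_dir / f"{sid}.bedpe",
                                              sample_id=sid)
                       for sid in self._sample_ids()}
        covariates = pd.DataFrame({
            "sv_burden": {sid: len(breakpoints.get(sid, ())) // 2
                          for sid in snvs},
            "tmb": {sid: len(snvs[sid]) for sid in snvs},
        })
        cohort = build_cohort_table({sid: len(events.get(sid, ()))
                                     for sid in snvs},
                                    clinical, covariates, params.outlier_z)
        cohort.to_csv(report_dir / "cohort.tsv", sep="\t", index=False)
        kept = cohort[~cohort.excluded_flag]
        flat_events = [e for sid in sorted(events) for e in events[sid]]
        _, epoch_res = epoch_proportions(events, snvs)
        summary = {
            "n_samples": int(len(cohort)),
            "n_excluded": int(cohort.excluded_flag.sum()),
            "n_positive": int(kept.positive.sum()),
            "prevalence_pct": percentage(int(kept.positive.sum()), len(kept)),
            "n_events": len(flat_events),
            "median_burden_positive": float(
                kept.loc[kept.positive, "kataegis_count"].median())
            if kept.positive.any() else None,
            "median_event_snvs": float(np.median([e.n_snv for e in flat_events]))
            if flat_events else None,
            "median_event_span_kb": float(np.median([e.span for e in flat_events]))
            / 1e3 if flat_events else None,
            "pct_events_apobec_enriched": percentage(
                sum(bool(e.apobec_enriched) for e in flat_events),
                len(flat_events)) if flat_events else None,
            "epoch_proportions": epoch_res,
        }
        burden_tests = {}
        for col in ("sv_burden", "tmb"):
            pos = kept.loc[kept.positive, col].dropna()
            neg = kept.loc[~kept.positive, col].dropna()
            if len(pos) and len(neg):
                burden_tests[col] = (pos.to_numpy(), neg.to_numpy())
        if burden_tests:
            cmp_df = compare_many(burden_tests, alpha=params.alpha)
            cmp_df.to_csv(report_dir / "group_comparisons.tsv", sep="\t",
                          index=False)
            summary["group_comparisons"] = {
                r["test"]: {"p": r["p"], "fdr": r["fdr"]}
                for r in cmp_df.to_dict("records")}
        try:
            surv = survival_strata(cohort, mode="burden_gt_1",
                                   endpoint="met_only",
                                   burden_split=params.burden_split)
            summary["survival_logrank_p"] = surv.get("logrank_p")
        except Exception as exc:  # small cohorts may lack events
            summary["survival_logrank_p"] = None
            summary["survival_note"] = str(exc)
        (report_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, default=float))
        self._record("report", inputs, outputs, {
            "samples": int(len(cohort)),
            "excluded": int(cohort.excluded_flag.sum()),
        })

    def _events_by_sample(self, path) -> Dict[str, List[KataegisEvent]]:
        flat = kio.read_events(path)
        out: Dict[str, List[KataegisEvent]] = {sid: [] for sid in self._sample_ids()}
        for e in flat:
            out.setdefault(e.sample_id, []).append(e)
        return out


def run_pipeline(config, out_dir=None, stages: Optional[Sequence[str]] = None,
                 force: bool = False) -> dict:
    """Execute the requested stages (all by default); returns the manifest."""
    run = PipelineRun(config, out_dir)
    return run.run(stages, force=force)
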