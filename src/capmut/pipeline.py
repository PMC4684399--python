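"""End-to-end orchestration: classify -> annotate -> match -> spectra ->
CNV -> report, from real inputs or a simulation block, with a
machine-readable run manifest.

The pipeline writes into a staging directory and renames it into place on
success, so a failed run leaves no partial output directory behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalogue import Catalogue, detection_counts, flag_novel
from .cnv import (
    CnvThresholds,
    concordance,
    filter_low_coverage,
    gene_calls,
    gene_calls_to_frame,
    read_windows,
    segment,
    window_log_ratios,
)
from .effects import annotate_effect
from .formats import (
    read_catalogue,
    read_fasta,
    read_gene_models,
    read_regions,
    read_segments,
    read_vcf_pairs,
    write_segments,
)
from .report import recurrence_matrix, sanger_concordance
from .simulate import CnvEvent, SimulationConfig, simulate_cohort, simulate_coverage, simulate_panel
from .somatic import (
    FilterThresholds,
    IndelFilterThresholds,
    SnvFilterThresholds,
    SomaticHighThresholds,
    classify_somatic,
    summarize_counts,
)
from .spectrum import mutation_rate, spectrum_report, stratum_composition, titv_ratio

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _thresholds_from_config(cfg: dict) -> FilterThresholds:
    t = cfg.get("thresholds", {}) or {}
    return FilterThresholds(
        min_call_quality_emit=t.get("min_call_quality_emit", 10.0),
        snv=SnvFilterThresholds(**t.get("snv", {})),
        indel=IndelFilterThresholds(**t.get("indel", {})),
        somatic_high=SomaticHighThresholds(**t.get("somatic_high", {})),
    )


def _cnv_thresholds_from_config(cfg: dict) -> CnvThresholds:
    return CnvThresholds(**{
        k: v
        for k, v in (cfg.get("cnv", {}) or {}).items()
        if k in {"gain_log2", "deletion_log2", "min_gene_bp", "min_deletion_segment_bp"}
    })


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    variants: pd.DataFrame
    summary: pd.DataFrame
    spectrum: Any
    compositions: dict
    rates: pd.DataFrame
    titv: pd.DataFrame
    gene_cnv: Optional[pd.DataFrame] = None
    segments: Optional[Any] = None
    concordance_r: Optional[float] = None
    recurrence_mutation: Optional[pd.DataFrame] = None
    recurrence_integrated: Optional[pd.DataFrame] = None
    sanger: Optional[pd.DataFrame] = None
    manifest: dict = field(default_factory=dict)


def load_config(config_file: Union[str, Path]) -> dict:
    with open(config_file) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def run_pipeline(
    config: Union[str, Path, dict],
    out: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run all stages and write the output directory atomically.

    ``config`` is a YAML path or an equivalent dict with either a
    ``simulate`` block or an ``inputs`` block naming reference, regions,
    gene models, per-sample VCFs, and optional catalogue / coverage /
    external segment and Sanger tables.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(out if out is not None else cfg.get("out", "capmut_out"))
    seed = seed if seed is not None else int(cfg.get("seed", 1))
    staging = out.parent / (out.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        result = _run_stages(cfg, staging, seed)
    except PipelineError:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        shutil.rmtree(staging, ignore_errors=True)
        raise PipelineError("unknown", exc)
    if out.exists():
        shutil.rmtree(out)
    staging.rename(out)
    result.outdir = out
    return result


def _run_stages(cfg: dict, outdir: Path, seed: int) -> PipelineResult:
    thresholds = _thresholds_from_config(cfg)
    cnv_thresholds = _cnv_thresholds_from_config(cfg)
    flank = int(cfg.get("flank_bp", 30))
    include_flanks = bool(cfg.get("include_flanks_in_noncoding", True))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "flank_bp": flank,
        "thresholds": dataclasses.asdict(thresholds),
        "cnv_thresholds": dataclasses.asdict(cnv_thresholds),
        "inputs": {},
    }

    # ---------------- io stage: load or simulate inputs
    stage = "io"
    try:
        truth = None
        coverage_windows = None
        external_segments = None
        compare_segments = None
        if "simulate" in cfg:
            sim_kwargs = dict(cfg.get("simulate") or {})
            events = tuple(
                CnvEvent(**e) if isinstance(e, dict) else CnvEvent(*e)
                for e in sim_kwargs.pop("cnv_events", ())
            )
            sim_config = SimulationConfig(seed=seed, **sim_kwargs, cnv_events=events)
            rng = np.random.default_rng(seed)
            panel = simulate_panel(sim_config, rng)
            cohort = simulate_cohort(panel, sim_config, rng)
            coverage = simulate_coverage(panel, sim_config, rng=rng)
            input_dir = outdir / "inputs"
            paths = panel.write(input_dir)
            paths.update(cohort.write(input_dir))
            paths.update(coverage.write(input_dir))
            reference = read_fasta(paths["reference"])
            regions = read_regions(paths["regions"], flank=flank)
            gene_models = read_gene_models(paths["gene_models"])
            calls_by_sample = {s: cohort.calls[s] for s in cohort.samples}
            catalogue_entries = cohort.catalogue
            coverage_windows = coverage.windows
            compare_segments = coverage.truth_track
            truth = cohort.truth
            manifest["inputs"] = {k: _digest(p) for k, p in paths.items()}
            manifest["simulation"] = {
                **{k: v for k, v in dataclasses.asdict(sim_config).items() if k != "cnv_events"},
                "cnv_events": [dataclasses.asdict(e) for e in events],
            }
        else:
            inputs = cfg.get("inputs")
            if not inputs:
                raise ValueError("config needs a 'simulate' or 'inputs' block")
            for key in ("reference", "regions", "gene_models", "vcfs"):
                if key not in inputs:
                    raise ValueError(f"inputs block missing {key!r}")
            reference = read_fasta(inputs["reference"])
            regions = read_regions(inputs["regions"], flank=flank)
            gene_models = read_gene_models(inputs["gene_models"])
            calls_by_sample = {}
            for sample, vcf_path in sorted(inputs["vcfs"].items()):
                tumor = inputs.get("tumor_sample", f"{sample}_T")
                normal = inputs.get("normal_sample", f"{sample}_N")
                calls_by_sample[sample] = read_vcf_pairs(vcf_path, tumor, normal)
            catalogue_entries = (
                read_catalogue(inputs["catalogue"]) if "catalogue" in inputs else []
            )
            if "coverage" in inputs:
                coverage_windows = read_windows(inputs["coverage"])
            if "segments" in inputs:
                external_segments = read_segments(inputs["segments"])
            if "segments_compare" in inputs:
                compare_segments = read_segments(inputs["segments_compare"])
            for key, p in inputs.items():
                if isinstance(p, (str, Path)) and Path(p).exists():
                    manifest["inputs"][key] = _digest(Path(p))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc)

    # ---------------- classify + annotate + match
    stage = "classify"
    try:
        catalogue = Catalogue(catalogue_entries, reference)
        rows = []
        for sample in sorted(calls_by_sample):
            calls = calls_by_sample[sample]
            somatic_calls = []
            for call in calls:
                sv = classify_somatic(call, thresholds, regions)
                row = {
                    "sample": sample,
                    "chrom": call.chrom,
                    "pos": call.pos,
                    "ref": call.ref,
                    "alt": call.alt,
                    "kind": call.kind,
                    "somatic": sv is not None,
                    "zygosity": sv.zygosity if sv else "",
                    "confidence": sv.confidence if sv else "",
                    "passed_filters": (
                        sv.passed_filters if sv else not bool(call.call_quality < thresholds.min_call_quality_emit)
                    ),
                    "filter_reasons": ";".join(sv.filter_reasons) if sv else "",
                    "region_class": regions.classify(call.chrom, call.pos - 1),
                    "stratum": regions.stratum_of(call.chrom, call.pos - 1, include_flanks),
                    "category": None,
                    "gene": "",
                    "hgvs_c": "",
                    "hgvs_p": "",
                }
                if sv is not None:
                    ann = annotate_effect(
                        call, gene_models, reference,
                        splice_window=int(cfg.get("splice_window", 2)),
                    )
                    row.update(
                        category=ann.category, gene=ann.gene,
                        hgvs_c=ann.hgvs_c, hgvs_p=ann.hgvs_p,
                    )
                    somatic_calls.append(call)
                rows.append(row)
        variants = pd.DataFrame(
            rows,
            columns=[
                "sample", "chrom", "pos", "ref", "alt", "kind", "somatic",
                "zygosity", "confidence", "passed_filters", "filter_reasons",
                "region_class", "stratum", "category", "gene", "hgvs_c", "hgvs_p",
            ],
        )
        if len(variants):
            som_mask = variants["somatic"]
            som = variants[som_mask]
            flags = flag_novel(
                list(zip(som["chrom"], som["pos"], som["ref"], som["alt"])),
                catalogue,
                window=int(cfg.get("loose_match_window", 5)),
            )
            variants.loc[som_mask, "match_status"] = flags["match_status"].to_numpy()
            variants.loc[som_mask, "catalogue_id"] = flags["catalogue_id"].to_numpy()
            variants["novel"] = variants["match_status"] == "novel"
        else:
            variants["match_status"] = pd.Series(dtype=str)
            variants["catalogue_id"] = pd.Series(dtype=str)
            variants["novel"] = pd.Series(dtype=bool)
        variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        summary = summarize_counts(variants) if len(variants) else summarize_counts([])
        flat = summary.copy()
        flat.columns = [f"{a}|{b}" for a, b in flat.columns]
        flat.to_csv(outdir / "summary.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(stage, exc)

    # ---------------- spectra and enrichment
    stage = "spectrum"
    try:
        compositions = {
            s: stratum_composition(regions, reference, s, include_flanks)
            for s in ("coding", "non_coding")
        }
        high_snv = variants[
            (variants["somatic"])
            & (variants["confidence"] == "high")
            & (variants["kind"] == "SNV")
            & (variants["stratum"].notna())
        ]
        spec = spectrum_report(
            high_snv[["sample", "chrom", "pos", "ref", "alt", "stratum"]],
            compositions,
            reference,
            m_tests_classes=int(cfg.get("m_tests_classes", 6)),
            m_tests_contexts=int(cfg.get("m_tests_contexts", 32)),
        )
        spec.class_enrichment.to_csv(outdir / "class_enrichment.tsv", sep="\t")
        spec.context_enrichment.to_csv(outdir / "context_enrichment.tsv", sep="\t")
        cc = spec.class_counts.copy()
        cc.columns = [f"{a}|{b}" for a, b in cc.columns]
        cc.to_csv(outdir / "class_counts.tsv", sep="\t")
        xc = spec.context_counts.copy()
        xc.columns = [f"{a}|{b}" for a, b in xc.columns]
        xc.to_csv(outdir / "context_counts.tsv", sep="\t")

        # per-sample and pooled mutation rates, plus Ti/Tv
        rate_rows, titv_rows = [], []
        samples = sorted(variants["sample"].unique()) if len(variants) else []
        high = variants[(variants["somatic"]) & (variants["confidence"] == "high")]
        for stratum in ("coding", "non_coding"):
            bases = compositions[stratum].total_bases
            for sample in samples:
                n = int(((high["sample"] == sample) & (high["stratum"] == stratum)).sum())
                rate_rows.append(
                    {
                        "sample": sample, "stratum": stratum, "mutations": n,
                        "bases": bases,
                        "per_mbp": mutation_rate(n, bases) if bases else float("nan"),
                    }
                )
            n_all = int((high["stratum"] == stratum).sum())
            pooled_bases = bases * max(len(samples), 1)
            rate_rows.append(
                {
                    "sample": "pooled", "stratum": stratum, "mutations": n_all,
                    "bases": pooled_bases,
                    "per_mbp": mutation_rate(n_all, pooled_bases) if pooled_bases else float("nan"),
                }
            )
        germ_snv = variants[
            (~variants["somatic"]) & (variants["kind"] == "SNV") & variants["passed_filters"]
        ]
        for sample in samples:
            sub = germ_snv[germ_snv["sample"] == sample]
            titv_rows.append(
                {
                    "sample": sample, "set": "germline_pass",
                    "titv": titv_ratio(zip(sub["ref"], sub["alt"])),
                    "n": len(sub),
                }
            )
        titv_rows.append(
            {
                "sample": "pooled", "set": "germline_pass",
                "titv": titv_ratio(zip(germ_snv["ref"], germ_snv["alt"])),
                "n": len(germ_snv),
            }
        )
        rates = pd.DataFrame(rate_rows)
        titv = pd.DataFrame(titv_rows)
        rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
        titv.to_csv(outdir / "titv.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc)

    # ---------------- copy number
    stage = "cnv"
    gene_cnv = None
    track = None
    r = None
    try:
        if external_segments is not None:
            track = external_segments
        elif coverage_windows is not None:
            windows = filter_low_coverage(
                window_log_ratios(
                    coverage_windows,
                    gc_correct=bool(cfg.get("cnv", {}).get("gc_correct", False)),
                ),
                float(cfg.get("cnv", {}).get("min_normal_depth", 20.0)),
            )
            track = segment(
                windows, float(cfg.get("cnv", {}).get("merge_tolerance", 0.4))
            )
        if track is not None:
            write_segments(track, outdir / "segments.tsv")
            calls = gene_calls(track, gene_models, cnv_thresholds)
            gene_cnv = gene_calls_to_frame(calls)
            gene_cnv.to_csv(outdir / "gene_cnv.tsv", sep="\t", index=False)
            if compare_segments is not None:
                conc = concordance(track, compare_segments)
                r = conc.r
                pd.DataFrame(
                    [{"r": conc.r, "p": conc.p, "n": conc.n, "dropped": conc.n_dropped}]
                ).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc)

    # ---------------- report
    stage = "report"
    try:
        nonsilent = variants[
            variants["somatic"] & (variants["confidence"] == "high") & variants["gene"].astype(bool)
        ][["sample", "gene", "category", "zygosity"]]
        rec_mut = recurrence_matrix(nonsilent, min_samples=int(cfg.get("min_recurrent_samples", 2)))
        rec_mut.to_csv(outdir / "recurrence_mutation.tsv", sep="\t")
        rec_int = rec_mut
        if gene_cnv is not None:
            cnv_cells = gene_cnv.assign(sample="pooled")[["sample", "gene", "status"]]
            rec_int = recurrence_matrix(
                nonsilent,
                cnv_cells,
                min_samples=int(cfg.get("min_recurrent_samples", 2)),
                integrated=True,
            )
        rec_int.to_csv(outdir / "recurrence_integrated.tsv", sep="\t")
        sanger = None
        if cfg.get("sanger_table"):
            sanger = sanger_concordance(pd.read_csv(cfg["sanger_table"], sep="\t"))
            sanger.to_csv(outdir / "sanger_concordance.tsv", sep="\t", index=False)
        if truth is not None:
            truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:
        raise PipelineError(stage, exc)

    return PipelineResult(
        outdir=outdir,
        variants=variants,
        summary=summary,
        spectrum=spec,
        compositions=compositions,
        rates=rates,
        titv=titv,
        gene_cnv=gene_cnv,
        segments=track,
        concordance_r=r,
        recurrence_mutation=rec_mut,
        recurrence_integrated=rec_int,
        sanger=sanger,
        manifest=manifest,
    )
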