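"""End-to-end orchestration: simulate -> call -> annotate -> context -> ses ->
mirna-rescan, with deterministic seeding, provenance headers and a final
summary report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import context as ctx
from . import editcall as ec
from . import mirnascan as mir
from . import specificity as spec
from . import synthdata as syn
from .reference import ReferenceBundle, build_repeat_index, build_transcript_index

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    outdir: str = "editome_run"
    seed: int = 0
    samples_per_tissue: int = 1
    entropy_threshold: float = 0.5
    context_flank: int = 5
    mirna_flank: int = 150
    synth: syn.SynthConfig = field(default_factory=syn.SynthConfig)
    thresholds: ec.FilterThresholds = field(default_factory=ec.FilterThresholds)
    scan: mir.ScanParams = field(default_factory=mir.ScanParams)

    def __post_init__(self) -> None:
        self.synth.rng_seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = syn.SynthConfig(**raw.pop("synth", {}))
        thresholds = ec.FilterThresholds(**raw.pop("thresholds", {}))
        scan = mir.ScanParams(**raw.pop("scan", {}))
        return cls(synth=synth, thresholds=thresholds, scan=scan, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["synth"]["tissue_names"] = list(raw["synth"]["tissue_names"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, Any]) -> None:
    """TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# editome {__version__}\n")
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[""])


def call_sample(
    sam_path: str | Path,
    ref: ReferenceBundle,
    thresholds: ec.FilterThresholds,
    sample_id: str,
    snp_positions: set[tuple[str, int]],
    tx_index=None,
    repeat_index=None,
    blacklist=frozenset(),
) -> tuple[list[ec.SiteCall], dict[str, np.ndarray]]:
    """Pileup -> candidates -> filters -> strand/type for one sample.

    Also returns per-chromosome depth arrays, used by the atlas merge to
    distinguish covered-but-unedited from unmeasured tissues.
    """
    counts = ec.pileup_counts(sam_path, ref.chrom_lengths, thresholds)
    depth = {c: arr.sum(axis=0).astype(np.uint32) for c, arr in counts.items()}
    columns = ec.iter_pileup_columns(counts, ref.genome, skip_pure_ref=True)
    stats: dict = {}
    cands = ec.call_candidates(columns, sample_id=sample_id, stats=stats)
    kept = ec.apply_filters(cands, thresholds, snp_positions, blacklist)
    tx_index = tx_index if tx_index is not None else build_transcript_index(ref.transcripts)
    repeat_index = (
        repeat_index if repeat_index is not None else build_repeat_index(ref.repeats)
    )
    calls = [ec.resolve_strand_type(c, tx_index, repeat_index) for c in kept]
    logger.info(
        "%s: %d candidates, %d passed filters (%s)",
        sample_id,
        len(cands),
        len(kept),
        stats,
    )
    return calls, depth


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage on synthetic data and write outputs under ``outdir``.

    Returns the report dict (also written as ``report.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "thresholds": dataclasses.asdict(cfg.thresholds)}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        ref = syn.generate_reference(cfg.synth)
        truth = syn.plant_truth(ref, cfg.synth)
        paths = ref.write(outdir)
        syn.write_truth(truth, outdir / "truth.tsv")
        sam_paths: dict[str, Path] = {}
        sample_tissue: dict[str, str] = {}
        for tissue in cfg.synth.tissue_names:
            for k in range(cfg.samples_per_tissue):
                sample_id = f"{tissue}_s{k + 1}"
                sam = outdir / f"{sample_id}.sam"
                syn.simulate_reads(ref, truth, tissue, sample_id, cfg.synth, sam)
                sam_paths[sample_id] = sam
                sample_tissue[sample_id] = tissue
        designs = syn.generate_mirnas(ref, truth, cfg.synth)
        syn.write_mirna_fasta(designs, outdir / "mirnas.fa")
        write_tsv(syn.design_table(designs), outdir / "mirna_design.tsv", meta)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"simulate: {exc}") from exc

    try:
        stage("call")
        snp_positions = {(s.chrom, s.pos) for s in ref.snps}
        tx_index = build_transcript_index(ref.transcripts)
        repeat_index = build_repeat_index(ref.repeats)
        calls_by_sample = {}
        depth_by_sample = {}
        for sample_id, sam in sam_paths.items():
            calls, depth = call_sample(
                sam, ref, cfg.thresholds, sample_id, snp_positions, tx_index, repeat_index
            )
            calls_by_sample[sample_id] = calls
            depth_by_sample[sample_id] = depth
        atlas = ec.merge_atlas(
            calls_by_sample,
            sample_tissue,
            depth_by_sample,
            min_depth=cfg.thresholds.min_depth,
            tissues=list(cfg.synth.tissue_names),
        )
        write_tsv(atlas, outdir / "atlas.tsv", meta)
        tsum = ec.summarize_types(atlas)
        write_tsv(tsum.reset_index(), outdir / "type_summary.tsv", meta)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"call: {exc}") from exc

    try:
        stage("annotate")
        a2i = atlas[atlas["type"] == "A-to-I"]
        sites = list(zip(a2i["chrom"], a2i["pos"]))
        genic = ann.assign_genic_regions(sites, tx_index)
        repeats = ann.intersect_repeats(sites, repeat_index)
        asum = ann.summarize_annotation(genic, repeats)
        per_site = pd.DataFrame(
            {
                "chrom": [g.chrom for g in genic],
                "pos": [g.pos for g in genic],
                "region": [g.region for g in genic],
                "in_repeat": [r.in_repeat for r in repeats],
                "repeat_class": [r.class_family or "" for r in repeats],
                "repeat_element": [r.element or "" for r in repeats],
            }
        )
        write_tsv(per_site, outdir / "annotation.tsv", meta)
        write_tsv(asum.regions.reset_index(), outdir / "region_summary.tsv", meta)
        write_tsv(asum.repeat.reset_index(), outdir / "repeat_summary.tsv", meta)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"annotate: {exc}") from exc

    try:
        stage("context")
        triples = list(zip(a2i["chrom"], a2i["pos"], a2i["strand"]))
        contexts, dropped = ctx.extract_contexts(triples, ref.genome, cfg.context_flank)
        if contexts:
            matrix = ctx.frequency_matrix(contexts)
            freq = matrix.freq.copy()
            freq.insert(0, "base", freq.index)
            write_tsv(freq, outdir / "context_matrix.tsv", meta)
        else:
            matrix = None
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"context: {exc}") from exc

    try:
        stage("ses")
        em, n_dropped = spec.build_matrix(atlas, list(cfg.synth.tissue_names))
        records = spec.detect_ses(em, cfg.entropy_threshold)
        write_tsv(spec.ses_table(records), outdir / "ses.tsv", meta)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"ses: {exc}") from exc

    try:
        stage("mirna-rescan")
        utrs = {}
        for d in designs:
            tx = next(t for t in ref.transcripts if t.transcript_id == d.transcript_id)
            utrs[d.transcript_id] = syn.utr3_sequence(tx, ref.genome)
        pairs = []
        for d in designs:
            pairs.append((d.transcript_id, d.utr_offset, d.mirna_id, d.sequence))
            pairs.append((d.transcript_id, d.utr_offset, d.control_id, d.control_sequence))
        rescan = mir.rescan_table(utrs, pairs=pairs, flank=cfg.mirna_flank, params=cfg.scan)
        write_tsv(rescan, outdir / "rescan.tsv", meta)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"mirna-rescan: {exc}") from exc

    stage("report")
    report = build_report(cfg, ref, truth, atlas, asum, matrix, records, rescan)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def build_report(cfg, ref, truth, atlas, asum, matrix, ses_records, rescan) -> dict:
    tsum = ec.summarize_types(atlas)
    strands = ec.strand_partition(atlas)
    truth_keys = set(zip(truth["chrom"], truth["pos"]))
    atlas_keys = set(zip(atlas["chrom"], atlas["pos"]))
    snp_keys = {(s.chrom, s.pos) for s in ref.snps}
    recovered = len(truth_keys & atlas_keys)
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "n_atlas_sites": int(len(atlas)),
        "type_counts": {str(k): int(v) for k, v in tsum["count"].items()},
        "type_percent": {str(k): float(v) for k, v in tsum["percent"].items()},
        "a2i_strand_counts": {str(k): int(v) for k, v in strands.items()},
        "region_percent": {
            str(k): float(v) for k, v in asum.regions["percent"].items()
        },
        "repeat_percent": {
            str(k): float(v) for k, v in asum.repeat["percent"].items()
        },
        "n_planted": int(len(truth)),
        "n_planted_recovered": recovered,
        "planted_sensitivity": recovered / len(truth) if len(truth) else None,
        "n_snp_positions_called": int(len(snp_keys & atlas_keys)),
        "n_ses": len(ses_records),
        "ses_per_tissue": spec.ses_counts(ses_records),
        "rescan_status_counts": rescan["status"].value_counts().to_dict()
        if len(rescan)
        else {},
    }
    if matrix is not None:
        report["context_g_plus1"] = float(matrix.frequency("G", 1))
        report["context_g_minus1"] = float(matrix.frequency("G", -1))
    return report
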