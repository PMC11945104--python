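"""End-to-end orchestration: simulate (or load) inputs, run every stage in
dependency order, write per-stage outputs and a machine-readable run report.

The configuration is a plain dictionary (YAML on disk); every parameter used
is echoed into the report so a run is reproducible from its output directory
alone. Reruns with identical config and seed produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import discovery, expression, genome as genome_mod, io, preprocess, targets
from . import synthetic_data as synth
from ._utils import to_rna

log = logging.getLogger("curesmir")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


DEFAULT_PARAMS: dict[str, Any] = {
    "min_len": 15,
    "max_mismatch_homology": 3,
    "flank": 300,
    "flank_long": 4000,
    "duplex_mismatch_ceiling": 5,
    "bulge_ceiling": 3,
    "target_max_mismatch": 6,
    "promoter_length": 2000,
    "min_identity": 95.0,
    "reference_gene": "reference",
    "calibrator_sample": "control",
}


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "curesmir_run"
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    version: str = "1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def merged_params(self) -> dict[str, Any]:
        p = dict(DEFAULT_PARAMS)
        p.update(self.params or {})
        return p


def _require(config: PipelineConfig, key: str) -> Any:
    try:
        value = config.inputs[key]
    except KeyError:
        raise PipelineError("inputs", f"missing input path {key!r}") from None
    if isinstance(value, str) and not Path(value).exists():
        raise PipelineError("inputs", f"input path does not exist: {value}")
    if isinstance(value, Mapping):
        for v in value.values():
            if not Path(v).exists():
                raise PipelineError("inputs", f"input path does not exist: {v}")
    return value


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.merged_params()
    report: dict[str, Any] = {
        "version": config.version, "seed": config.seed,
        "parameters": params, "stages": {}, "outputs": {},
    }

    def stage_done(name: str, **info: Any) -> None:
        log.info("stage %s done: %s", name, info)
        report["stages"][name] = info

    def save_tsv(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        io.write_tsv(path, df)
        report["outputs"][name] = {"path": str(path), "rows": int(len(df))}

    truth = None
    # ---------------- simulate or load inputs ----------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        gen_cfg = synth.GeneratorConfig(**sim.get("generator", {}))
        noise = (synth.NoiseSettings.off() if sim.get("noise") == "off"
                 else synth.NoiseSettings(**sim.get("noise", {}))
                 if isinstance(sim.get("noise"), dict) else synth.NoiseSettings())
        genome, transcripts, ann_records, truth = synth.generate_genome_and_transcripts(
            gen_cfg, seed=config.seed)
        libraries, design = synth.generate_srna_libraries(
            truth, depth=int(sim.get("depth", 200_000)), noise=noise, seed=config.seed + 1)
        degradome = synth.generate_degradome(
            truth, depth=int(sim.get("degradome_depth", 100_000)),
            seed=config.seed + 2, libraries=tuple(sim.get("degradome_libraries", ("DEG1",))))
        ct_table = synth.generate_ct_table(
            truth.ct_design, replicates=3,
            noise_sd=float(sim.get("ct_noise_sd", 0.0)), seed=config.seed + 3)
        references = truth.reference_matures
        annotations = truth.annotation_seqs
        motifs = pd.DataFrame(genome_mod.DEMO_MOTIFS, columns=["name", "motif", "category"])

        io.write_fasta(outdir / "genome.fa", genome)
        io.write_fasta(outdir / "transcripts.fa", transcripts)
        io.write_gff3(outdir / "truth_loci.gff3", ann_records)
        for lib, reads in libraries.items():
            io.write_collapsed_fasta(outdir / f"reads_{lib}.fa", reads)
        save_tsv("library_design", design)
        save_tsv("ct_table", ct_table)
        stage_done("simulate", n_mirnas=len(truth.planted_mirnas),
                   n_targets=len(truth.planted_targets),
                   n_transcripts=len(transcripts))
    else:
        read_paths = _require(config, "reads")
        libraries = {}
        for lib, path in read_paths.items():
            seqs, _ = io.load_reads(path)
            libraries[lib] = seqs
        references = {k: to_rna(v) for k, v in io.read_fasta(_require(config, "references")).items()}
        transcripts = io.read_fasta(_require(config, "transcripts"))
        genome = io.read_fasta(config.inputs["genome"]) if "genome" in config.inputs else {}
        annotations = {}
        if "annotations" in config.inputs:
            for cls, path in config.inputs["annotations"].items():
                annotations[cls] = list(io.read_fasta(path).values())
        degradome = {}
        if "degradome" in config.inputs:
            for lib, path in config.inputs["degradome"].items():
                if str(path).endswith((".tsv", ".txt")):
                    degradome[lib] = io.read_tag_table(path)
                else:
                    degradome[lib] = io.read_collapsed_fasta(path)
        ct_table = io.read_tsv(config.inputs["ct_table"]) if "ct_table" in config.inputs else None
        if "motifs" in config.inputs:
            motifs = io.read_tsv(config.inputs["motifs"])
        else:
            motifs = pd.DataFrame(genome_mod.DEMO_MOTIFS, columns=["name", "motif", "category"])
        stage_done("load", libraries=list(libraries))

    # ---------------- preprocess ----------------
    try:
        table, clean_report = preprocess.clean_reads(libraries, min_len=params["min_len"])
        save_tsv("clean_report", clean_report)
        libs = table.library_ids
        if len(libs) >= 2:
            comparison = preprocess.compare_libraries(table, libs[0], libs[1])
            save_tsv("library_comparison", comparison.to_frame())
        for lib in libs:
            save_tsv(f"length_distribution_{lib}", preprocess.length_distribution(table, lib))
        breakdown, residual = preprocess.annotate_reads(table, annotations)
        save_tsv("annotation_breakdown", breakdown)
        clean_totals = {lib: int(t) for lib, t in table.totals.items()}
        stage_done("preprocess", unique_reads=int(len(table.counts)),
                   residual_reads=int(len(residual.counts)))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    # ---------------- discovery ----------------
    try:
        srna_reads = set(table.sequences())
        candidates, hairpins = discovery.discover_mirnas(
            residual, references, transcripts,
            max_mismatch=params["max_mismatch_homology"],
            flank=params["flank"], flank_long=params["flank_long"],
            srna_reads=srna_reads, totals=clean_totals,
        )
        cand_df = pd.DataFrame(
            [(c.sequence, c.family, c.best_reference, c.reference_mismatches,
              *[c.counts[lib] for lib in libs], *[round(c.tpm[lib], 3) for lib in libs])
             for c in candidates],
            columns=["sequence", "family", "best_reference", "mismatches",
                     *[f"count_{lib}" for lib in libs], *[f"tpm_{lib}" for lib in libs]],
        )
        save_tsv("mirna_candidates", cand_df)
        hp_df = pd.DataFrame(
            [(h.precursor_id, h.transcript_id, *h.precursor_span, *h.mature_span,
              *h.star_span, h.duplex_mismatches, h.star_detected, round(h.mfe, 2))
             for h in hairpins],
            columns=["precursor_id", "transcript_id", "pre_start", "pre_end",
                     "mature_start", "mature_end", "star_start", "star_end",
                     "duplex_mismatches", "star_detected", "mfe"],
        )
        save_tsv("hairpins", hp_df)
        io.write_fasta(outdir / "precursors.fa",
                       {h.precursor_id: h.precursor_seq for h in hairpins})
        stage_done("discovery", candidates=len(candidates), hairpins=len(hairpins))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("discovery", str(exc)) from exc

    # ---------------- genome localization + promoters + cis elements ----------
    loci = []
    try:
        if genome:
            precursor_seqs = {h.precursor_id: h.precursor_seq for h in hairpins}
            loci = genome_mod.locate_loci(precursor_seqs, genome,
                                          min_identity=params["min_identity"])
            loci_df = pd.DataFrame(
                [(l.precursor_id, l.chromosome, l.start, l.end, l.strand, l.identity)
                 for l in loci],
                columns=["precursor_id", "chromosome", "start", "end", "strand",
                         "identity"],
            )
            save_tsv("loci", loci_df)
            io.write_gff3(outdir / "loci.gff3",
                          [(l.chromosome, "pre_miRNA", l.start, l.end, l.strand,
                            {"ID": l.precursor_id}) for l in loci])
            promoters = [genome_mod.extract_promoter(l, genome,
                                                     upstream=params["promoter_length"])
                         for l in loci]
            io.write_fasta(outdir / "promoters.fa",
                           {p.locus_id: p.sequence for p in promoters})
            all_hits = []
            for p in promoters:
                hits, _cats = genome_mod.scan_cis_elements(p, motifs)
                all_hits.extend(hits)
            save_tsv("cis_element_hits", genome_mod.hits_to_frame(all_hits))
            stage_done("genome", loci=len(loci), promoters=len(promoters),
                       cis_hits=len(all_hits))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("genome", str(exc)) from exc

    # ---------------- degradome targets ----------------
    calls: list[targets.CleavageCall] = []
    try:
        if degradome:
            mirna_seqs = {}
            for c in candidates:
                mirna_seqs.setdefault(c.family + ":" + c.sequence, c.sequence)
            for lib, tags in degradome.items():
                lib_size = sum(tags.values())
                for tid, tx in transcripts.items():
                    profile = None
                    for mid, mseq in mirna_seqs.items():
                        alignments = targets.align_mirna_target(
                            mseq, tx, transcript_id=tid, mirna_id=mid,
                            max_mismatch=params["target_max_mismatch"])
                        if not alignments:
                            continue
                        if profile is None:
                            profile = targets.build_profile(
                                tags, tx, lib_size, transcript_id=tid, library_id=lib)
                        aln = alignments[0]
                        call = targets.call_cleavage(aln, profile)
                        if call is None:
                            continue
                        targets.categorize_target(call, profile)
                        calls.append(call)
            if calls:
                summaries = targets.summarize_targets(calls)
                sum_df = pd.DataFrame(
                    [(s.mirna_id, s.transcript_id, s.representative.mismatch_count,
                      s.representative.wobble_count,
                      ";".join(f"{k}:{v}" for k, v in sorted(s.categories.items())),
                      s.best_category)
                     for s in summaries],
                    columns=["mirna", "transcript", "mismatches", "wobbles",
                             "categories", "best_category"],
                )
                save_tsv("target_summary", sum_df)
            stage_done("targets", calls=len(calls))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("targets", str(exc)) from exc

    # ---------------- expression ----------------
    try:
        if len(libs) >= 2 and len(cand_df):
            fc_rows = []
            for _, row in cand_df.iterrows():
                try:
                    rec = expression.log2_fold_change(
                        row[f"tpm_{libs[0]}"], row[f"tpm_{libs[1]}"],
                        entity_id=row["sequence"])
                except ValueError:
                    continue
                fc_rows.append(rec.to_row())
            fc_df = pd.DataFrame(
                fc_rows, columns=["entity_id", "tpm_control", "tpm_treatment",
                                  "fc", "log2fc"])
            save_tsv("fold_changes", fc_df)
        if ct_table is not None:
            ref_gene = params["reference_gene"]
            if ref_gene not in set(ct_table["gene"]):
                ref_gene = ct_table["gene"].iloc[-1]
            results = expression.delta_delta_ct(
                ct_table, reference_gene=ref_gene,
                calibrator_sample=params["calibrator_sample"])
            save_tsv("relative_expression", expression.results_to_frame(results))
            mat, _missing = expression.expression_matrix(results)
            io.write_tsv(outdir / "neg_ddct_matrix.tsv", mat.reset_index())
            stage_done("expression", qpcr_results=len(results))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc

    # ---------------- planted-truth tallies (simulated runs) ----------------
    if truth is not None:
        recovered_seqs = {c.sequence for c in candidates}
        recovered_stars = {h.star_seq for h in hairpins}
        planted_loci = [pl for m in truth.planted_mirnas for pl in m.loci]

        def locus_recovered(pl) -> bool:
            # reported precursors are trimmed stem-loops, so a planted locus
            # counts as recovered when a found locus lies inside it
            return any(
                l.chromosome == pl.chromosome and l.strand == pl.strand
                and l.start >= pl.start and l.end <= pl.end
                for l in loci
            )
        call_positions = {
            (c.alignment.transcript_id, c.peak_position) for c in calls
        }
        truth_tally = {
            "planted_mirnas": len(truth.planted_mirnas),
            "recovered_mirnas": sum(
                m.mature in recovered_seqs for m in truth.planted_mirnas),
            "recovered_stars": sum(
                m.star in recovered_stars for m in truth.planted_mirnas),
            "planted_loci": len(planted_loci),
            "recovered_loci": sum(locus_recovered(pl) for pl in planted_loci),
            "planted_targets": len(truth.planted_targets),
            "recovered_cleavage_sites": sum(
                any((t.transcript_id, p) in call_positions
                    for p in range(t.window[0], t.window[1] + 1))
                for t in truth.planted_targets),
        }
        report["planted_vs_recovered"] = truth_tally
        stage_done("truth_tally", **truth_tally)

    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["outputs"]["run_report"] = {"path": str(report_path), "rows": 1}
    return report
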