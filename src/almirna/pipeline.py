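"""End-to-end pipeline: simulate -> preprocess -> classify -> express ->
targets -> degradome, with a reproducible run manifest.

A single structured YAML config drives all stages; every stage writes its
artifacts under the output directory and the manifest records SHA-256
digests of each file, so a rerun with the same config and seed reproduces
identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import time
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from . import classify as _classify
from . import degradome as _degradome
from . import expression as _expression
from . import fold as _fold
from . import simulate as _simulate
from . import targets as _targets
from .io import write_collapsed_fasta, write_fasta, write_fastq, write_gff3
from .preprocess import length_distribution, preprocess_libraries

__all__ = ["load_config", "run_pipeline", "reproduce_table2", "table2_fixture_path"]

#: SHA-256 of the packaged fold-change fixture (integrity check)
TABLE2_SHA256 = "1211083bff0140157aac7ed81706a1aa45e4e9506c63ac4e328dcd5b46df1279"


def table2_fixture_path() -> Path:
    return Path(importlib.resources.files("almirna") / "data" / "table2_foldchanges.tsv")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path) -> _simulate.SimulationConfig:
    """Read a YAML run config; the ``simulation`` block maps to
    SimulationConfig fields, ``design`` entries are (genotype, treatment,
    replicate) triples."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.get("simulation", raw)
    if "design" not in sim:
        raise ValueError("config schema error: missing 'design' block")
    sim = dict(sim)
    sim["design"] = [tuple(d[:2]) + (int(d[2]),) for d in sim["design"]]
    known = {f.name for f in dataclasses.fields(_simulate.SimulationConfig)}
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"config schema error: unknown keys {sorted(unknown)}")
    cfg = _simulate.SimulationConfig(**sim)
    cfg.validate()
    return cfg


def default_config(seed: int = 0, **overrides) -> _simulate.SimulationConfig:
    cfg = _simulate.SimulationConfig(seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def run_pipeline(
    config: _simulate.SimulationConfig | str | Path,
    outdir: str | Path,
    write_fastq_files: bool = False,
) -> Dict:
    """Run every stage on a simulated experiment; returns the result dict.

    Artifacts: genome/reference FASTAs, GFF3 locus table, collapsed reads,
    accounting and length-distribution tables, classification summaries,
    the responsiveness report with degradome Y/N, a ground-truth comparison
    and ``manifest.json``.
    """
    if not isinstance(config, _simulate.SimulationConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def record(stage: str, *paths):
        manifest["stages"].setdefault(stage, {})
        for p in paths:
            manifest["stages"][stage][Path(p).name] = _sha256(p)

    # --- simulate
    truth, refs, reads, expected = _simulate.simulate_experiment(config)
    write_fasta(outdir / "genome.fa", [("chr1", truth.genome)])
    for klass in ("mature", "precursor", "rfam", "mrna", "repeat"):
        write_fasta(outdir / f"ref_{klass}.fa", refs.get(klass, []))
    write_gff3(
        outdir / "loci.gff3",
        [
            (l.chrom, "almirna_sim", "pre_miRNA", l.start, l.end, l.strand,
             {"ID": l.name, "class": l.class_label, "mature": l.mature_seq})
            for l in truth.loci
        ],
    )
    expected.to_csv(outdir / "expected_counts.tsv", sep="\t")
    if write_fastq_files:
        for lib, lib_reads in reads.items():
            expanded = (
                (f"{lib}_r{i}_{k}", seq)
                for i, (seq, count) in enumerate(lib_reads)
                for k in range(count)
            )
            write_fastq(outdir / f"{lib}.fastq", expanded)
    record(
        "simulate",
        outdir / "genome.fa",
        *(outdir / f"ref_{k}.fa" for k in ("mature", "precursor", "rfam", "mrna", "repeat")),
        outdir / "loci.gff3",
        outdir / "expected_counts.tsv",
    )

    # --- preprocess
    tags, accounting = preprocess_libraries(
        reads, config.adapter,
        rfam_ref=refs["rfam"], mrna_ref=refs["mrna"], repeat_ref=refs["repeat"],
    )
    if not accounting.verify_partition():
        raise RuntimeError("stage preprocess: accounting partition failed")
    accounting.table.to_csv(outdir / "accounting.tsv", sep="\t")
    valid_tags = {s: t for s, t in tags.items() if t.bin == "valid"}
    count_matrix = pd.DataFrame(
        {lib: {s: t.counts.get(lib, 0) for s, t in valid_tags.items()} for lib in config.libraries}
    ).fillna(0).astype(int)
    count_matrix.to_csv(outdir / "tag_counts.tsv", sep="\t")
    for lib in config.libraries:
        write_collapsed_fasta(
            outdir / f"{lib}.collapsed.fa",
            sorted(((s, t.counts.get(lib, 0)) for s, t in valid_tags.items() if t.counts.get(lib, 0)),
                   key=lambda x: (-x[1], x[0])),
        )
    length_distribution(tags, config.libraries).to_csv(outdir / "length_distribution.tsv", sep="\t")
    record("preprocess", outdir / "accounting.tsv", outdir / "tag_counts.tsv",
           outdir / "length_distribution.tsv")

    # --- classify
    result = _classify.classify_all(
        tags, refs["mature"], refs["precursor"], truth.genome
    )
    mirna_rows = []
    for rec in result.records:
        mirna_rows.append({
            "name": rec.name, "class": rec.class_label, "mature_seq": rec.mature_seq,
            "reference": rec.match.reference_id if rec.match else "",
            "mismatches": rec.match.mismatches if rec.match else "",
            "arm": rec.arm or "",
            "locus": f"{rec.locus[0]}:{rec.locus[1]}-{rec.locus[2]}({rec.locus[3]})" if rec.locus else "",
            "mfei": round(rec.metrics.mfei, 4) if rec.metrics else "",
        })
    pd.DataFrame(mirna_rows).to_csv(outdir / "mirnas.tsv", sep="\t", index=False)
    result.length_summary.to_csv(outdir / "class_length_summary.tsv", sep="\t")
    pd.Series(result.venn).to_csv(outdir / "venn_counts.tsv", sep="\t", header=False)
    candidates = [r for r in result.records if r.class_label == "candidate"]
    if candidates:
        write_fasta(outdir / "candidates.fa", [(r.name, r.mature_seq) for r in candidates])
        write_gff3(
            outdir / "candidates.gff3",
            [(r.locus[0], "almirna", "miRNA", r.locus[1], r.locus[2], r.locus[3],
              {"ID": r.name}) for r in candidates],
        )
        _fold.write_dotbracket(
            outdir / "candidates.dotbracket",
            [(r.name, r.precursor) for r in candidates],
        )
    record("classify", outdir / "mirnas.tsv", outdir / "class_length_summary.tsv",
           outdir / "venn_counts.tsv")

    # --- expression
    cpm, cond_means = _expression.normalize(count_matrix)
    name_by_seq = {s: r.name for s, r in result.by_sequence.items()}
    mirna_means = cond_means.loc[[s for s in cond_means.index if s in name_by_seq]]
    mirna_means.index = [name_by_seq[s] for s in mirna_means.index]
    profiles = _expression.build_profiles(mirna_means)
    rec_by_name = {r.name: r for r in result.records}
    responsive_report = _expression.call_responsive(profiles, rec_by_name)
    responsive_report.to_csv(outdir / "responsive.tsv", sep="\t", index=False)
    record("expression", outdir / "responsive.tsv")

    # --- targets + degradome
    transcripts = truth.transcripts
    interactions = []
    for rec in result.records:
        interactions.extend(
            _targets.scan_transcriptome(rec.mature_seq, transcripts, mirna_name=rec.name)
        )
    deg_reads, cleavage_truth = _simulate.simulate_degradome(truth, config)
    deg_profiles = _degradome.map_degradome(deg_reads, transcripts)
    _degradome.annotate_interactions(interactions, deg_profiles)
    _targets.interactions_table(interactions).to_csv(
        outdir / "interactions.tsv", sep="\t", index=False
    )
    _degradome.profiles_table(deg_profiles).to_csv(
        outdir / "degradome_profiles.tsv", sep="\t", index=False
    )
    record("targets", outdir / "interactions.tsv", outdir / "degradome_profiles.tsv")

    # --- ground-truth comparison
    comparison = compare_to_truth(truth, result, profiles, interactions)
    with open(outdir / "truth_comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)
    record("compare", outdir / "truth_comparison.json")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "truth": truth,
        "refs": refs,
        "tags": tags,
        "accounting": accounting,
        "classification": result,
        "profiles": profiles,
        "responsive_report": responsive_report,
        "interactions": interactions,
        "degradome_profiles": deg_profiles,
        "comparison": comparison,
        "manifest": manifest,
    }


def compare_to_truth(truth, classification, profiles, interactions) -> Dict:
    """Recovery metrics of a simulated run against its ground truth."""
    planted = {l.mature_seq: l for l in truth.loci}
    recovered_correct = 0
    contaminant_known = 0
    for seq, rec in classification.by_sequence.items():
        loc = planted.get(seq)
        if loc is not None:
            if rec.class_label == loc.class_label:
                recovered_correct += 1
        elif rec.class_label in ("known", "new_member"):
            contaminant_known += 1
    truth_resp = truth.responsive_truth()
    name_by_seq = {
        seq: rec.name for seq, rec in classification.by_sequence.items()
    }
    truth_resp_names = {
        name_by_seq.get(truth.locus(n).mature_seq, n) for n in truth_resp
    }
    called = {name for name, p in profiles.items() if p.responsive}
    union = truth_resp_names | called
    jaccard = len(truth_resp_names & called) / len(union) if union else 1.0
    true_pairs = {(p.mirna, p.transcript_id): p for p in truth.target_pairs}
    mirna_names = {l.name: name_by_seq.get(l.mature_seq) for l in truth.loci}
    deg_y = 0
    for (mirna, tid), pair in true_pairs.items():
        rec_name = mirna_names.get(mirna)
        for it in interactions:
            if it.mirna == rec_name and it.transcript == tid and it.degradome_detected == "Y":
                deg_y += 1
                break
    return {
        "planted": len(truth.loci),
        "recovered_correct_class": recovered_correct,
        "recovery_rate": recovered_correct / len(truth.loci) if truth.loci else 1.0,
        "contaminants_as_known_or_new": contaminant_known,
        "responsive_truth": sorted(truth_resp_names),
        "responsive_called": sorted(called),
        "responsive_jaccard": jaccard,
        "true_target_pairs": len(true_pairs),
        "degradome_detected_pairs": deg_y,
    }


def reproduce_table2(fixture_path: Optional[str | Path] = None) -> Dict:
    """Regulation counts from the packaged published fold-change table.

    Applies the inclusive +/-0.5 thresholds per genotype (exclusive-flagged
    0.00 entries count as absent) and reports per-genotype
    up/down/unchanged/exclusive counts plus the union responsive count.
    """
    path = Path(fixture_path) if fixture_path else table2_fixture_path()
    if fixture_path is None and TABLE2_SHA256 != "REPLACED_AT_BUILD":
        if _sha256(path) != TABLE2_SHA256:
            raise RuntimeError("fixture integrity error: checksum mismatch")
    table = pd.read_csv(path, sep="\t")
    counts, union = _expression.classify_table(table)
    out = {g: dict(c) for g, c in counts.items()}
    for g in counts:
        out[g]["responsive"] = counts[g]["up"] + counts[g]["down"]
    out["union_responsive"] = union
    out["rows"] = int(len(table))
    return out
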