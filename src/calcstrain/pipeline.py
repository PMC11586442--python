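"""End-to-end orchestration: config, manifests, stage ordering, artifacts.

The pipeline runs the analysis stages in their dependency order —
preservation screening → community variability (FAVA) → strain comparison
(popANI) → polymorphism (dN/dS) → phylogeny — over a sample manifest, and
writes one artifact file per stage into a run directory.  Samples excluded
at any gate (preservation failure, phylogeny QC) are recorded with the
failing criterion, never silently dropped.  TSV artifacts carry a header
comment with the tool version, a config hash and the seed; a ``run.json``
snapshot captures the full configuration, so a rerun with the same inputs
and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, fava as fava_mod, phylogeny, preservation, strain, synthdata

__all__ = ["RunConfig", "run_pipeline", "validate_formats", "load_manifest"]


@dataclass
class RunConfig:
    """All thresholds of the pipeline, at their protocol defaults."""

    seed: int
    preservation_cutoff: float = 50.0
    burn_in: str | int = "adaptive"
    mask_by_udg_class: dict = field(
        default_factory=lambda: {"none": 0, "half": 1, "non_udg": 11})
    min_insert: int = 12
    min_cov: int = 5
    min_base_quality: int = 30
    dominant_freq: float = 0.8
    homozygous_threshold: float = 0.9
    min_snps: int = 1000
    min_mean_cov: float = 5.0
    bootstrap_replicates: int = 200
    permutations: int = 99
    stages: tuple[str, ...] = ("preservation", "fava", "strain", "dnds", "phylogeny")

    def validate(self) -> None:
        if not 0 <= self.preservation_cutoff <= 100:
            raise ValueError("preservation_cutoff outside [0,100]")
        for k, v in self.mask_by_udg_class.items():
            if v < 0:
                raise ValueError(f"negative mask for {k}")
        if self.min_insert < 0 or self.min_cov < 1:
            raise ValueError("bad min_insert/min_cov")
        if not 0 < self.dominant_freq <= 1 or not 0 < self.homozygous_threshold <= 1:
            raise ValueError("frequency thresholds must be in (0,1]")
        if self.bootstrap_replicates < 0 or self.permutations < 1:
            raise ValueError("bad resampling counts")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_manifest(path: str) -> pd.DataFrame:
    """Sample manifest TSV: columns sample, udg_class, sam, group (optional age)."""
    m = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "udg_class", "group"}
    if not required.issubset(m.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(m.columns))}")
    if m["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    bad = set(m["udg_class"]) - {"none", "half", "non_udg"}
    if bad:
        raise ValueError(f"unknown udg_class values: {sorted(bad)}")
    return m.set_index("sample")


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# calcstrain {__version__} config={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(
    config: RunConfig,
    manifest: pd.DataFrame,
    taxon_table: preservation.TaxonTable,
    reference: synthdata.Genome,
    outdir: str,
) -> dict[str, str]:
    """Run the staged analysis and return a map of stage → artifact path.

    ``manifest`` must carry a ``sam`` column pointing at per-sample SAM
    files aligned to ``reference`` (whose ``genes`` feed the dN/dS stage).
    Missing inputs abort with the stage named; partial outputs from an
    aborted run keep their files so the failure is inspectable.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}
    with open(os.path.join(outdir, "run.json"), "w") as fh:
        json.dump({"version": __version__, "config": dataclasses.asdict(config)},
                  fh, indent=2, default=str)

    # --- preservation gate -------------------------------------------------
    passing = list(manifest.index)
    if "preservation" in config.stages:
        screen = preservation.screen_samples(
            taxon_table, config.preservation_cutoff, config.burn_in)
        screen = screen.reindex(manifest.index)
        screen["reason"] = np.where(screen["passed"], "",
                                    f"decay curve below {config.preservation_cutoff}%")
        path = os.path.join(outdir, "preservation.tsv")
        _write_tsv(screen, path, config)
        artifacts["preservation"] = path
        passing = list(screen.index[screen["passed"].fillna(False)])

    # --- community variability --------------------------------------------
    if "fava" in config.stages:
        table = taxon_table.abundances.loc[passing]
        groups = manifest.loc[passing, "group"]
        results, pooled = fava_mod.fava_by_group(table, groups)
        path = os.path.join(outdir, "fava.tsv")
        _write_tsv(fava_mod.results_frame(results, pooled), path, config, index=False)
        artifacts["fava"] = path

    pileups: dict[str, strain.Pileup] = {}
    needs_reads = {"strain", "dnds", "phylogeny"} & set(config.stages)
    if needs_reads:
        if "sam" not in manifest.columns:
            raise FileNotFoundError("stage strain: manifest has no 'sam' column")
        for sid in passing:
            sam_path = manifest.loc[sid, "sam"]
            if not os.path.exists(sam_path):
                raise FileNotFoundError(f"stage strain: missing SAM for {sid}: {sam_path}")
            reads = synthdata.read_sam(sam_path, udg_class=manifest.loc[sid, "udg_class"])
            reads = strain.mask_reads(reads, config.mask_by_udg_class)
            pileups[sid] = strain.build_pileup(
                reads, config.min_base_quality, config.min_insert,
                reference_length=len(reference), sample_id=sid)

    # --- strain identity ---------------------------------------------------
    if "strain" in config.stages:
        rows = []
        ids = list(pileups)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                c = strain.compare_popani(pileups[ids[i]], pileups[ids[j]],
                                          min_cov=config.min_cov)
                rows.append({
                    "sample_a": c.sample_a, "sample_b": c.sample_b,
                    "compared_positions": c.compared_positions,
                    "popani": c.popani, "conani": c.conani,
                    "coverage_overlap": c.coverage_overlap,
                    "reason": c.reason or "",
                })
        path = os.path.join(outdir, "popani.tsv")
        _write_tsv(pd.DataFrame(rows), path, config, index=False)
        artifacts["strain"] = path

    # --- polymorphism ------------------------------------------------------
    if "dnds" in config.stages:
        from . import polymorphism
        rows = []
        for sid, pileup in pileups.items():
            r = polymorphism.dnds(pileup, reference.genes,
                                  min_cov=config.min_cov,
                                  dominant_freq=config.dominant_freq)
            rows.append({"sample": sid, "n_nonsynonymous": r.n_nonsynonymous,
                         "n_synonymous": r.n_synonymous,
                         "n_considered": r.n_considered,
                         "ratio": r.ratio if r.defined else np.nan,
                         "reason": r.reason or ""})
        path = os.path.join(outdir, "dnds.tsv")
        _write_tsv(pd.DataFrame(rows), path, config, index=False)
        artifacts["dnds"] = path

    # --- phylogeny ---------------------------------------------------------
    if "phylogeny" in config.stages and len(pileups) >= 3:
        calls = {}
        qc_stats = {}
        for sid, pileup in pileups.items():
            c = phylogeny.call_variants(pileup, reference.codes, config.min_cov)
            hom = phylogeny.filter_homozygous(c, config.homozygous_threshold)
            calls[sid] = hom
            qc_stats[sid] = {
                "n_snps": int((hom["major"] != hom["ref"]).sum()),
                "mean_coverage": float(pileup.depth.mean()),
            }
        qc = phylogeny.sample_qc(pd.DataFrame.from_dict(qc_stats, orient="index"),
                                 config.min_snps, config.min_mean_cov)
        path = os.path.join(outdir, "phylo_qc.tsv")
        _write_tsv(qc, path, config)
        artifacts["phylo_qc"] = path
        kept = [s for s in calls if qc.loc[s, "included"]]
        if len(kept) >= 3:
            aln = phylogeny.build_snp_alignment({s: calls[s] for s in kept},
                                                reference.codes)
            if aln.n_columns == 0:
                # no sample carries a homozygous non-reference allele: the
                # tree is refused, recorded rather than aborting the run
                with open(os.path.join(outdir, "phylogeny_skipped.txt"), "w") as fh:
                    fh.write("no variant columns; tree refused\n")
                artifacts["phylogeny_skipped"] = os.path.join(
                    outdir, "phylogeny_skipped.txt")
                return artifacts
            aln_path = os.path.join(outdir, "snp_alignment.fasta")
            aln.to_fasta(aln_path)
            artifacts["snp_alignment"] = aln_path
            dm, reasons = phylogeny.tn93_distance(aln)
            _write_tsv(dm, os.path.join(outdir, "distances.tsv"), config)
            artifacts["distances"] = os.path.join(outdir, "distances.tsv")
            if not reasons:
                tree, _ = phylogeny.bootstrap_support(
                    aln, config.bootstrap_replicates, seed=config.seed)
                tree = phylogeny.midpoint_root(tree)
                tree_path = os.path.join(outdir, "tree.nwk")
                tree.write(tree_path)
                artifacts["tree"] = tree_path
    return artifacts


def validate_formats(paths: list[str]) -> list[dict]:
    """Sanity-check input files by extension; reports, never raises.

    Returns a list of ``{"path", "check", "message"}`` dicts, empty when
    everything passes.  SAM files are checked for headers and in-bounds
    coordinates, FASTA for alphabet, GFF3 for frame-divisible CDS lengths,
    TSV tables for non-negative numeric content.
    """
    import pysam

    errors: list[dict] = []

    def err(path: str, check: str, message: str) -> None:
        errors.append({"path": path, "check": check, "message": message})

    for path in paths:
        if not os.path.exists(path):
            err(path, "exists", "file not found")
            continue
        low = path.lower()
        try:
            if low.endswith((".sam", ".bam")):
                with pysam.AlignmentFile(path, check_sq=True) as fh:
                    lengths = dict(zip(fh.references, fh.lengths))
                    if not lengths:
                        err(path, "sam-header", "no @SQ lines")
                    for a in fh:
                        if a.is_unmapped:
                            continue
                        ln = lengths.get(a.reference_name, 0)
                        if a.reference_end is not None and a.reference_end > ln:
                            err(path, "sam-coordinates",
                                f"read {a.query_name} ends at {a.reference_end} > {ln}")
            elif low.endswith((".fa", ".fasta", ".fna")):
                from Bio import SeqIO
                for rec in SeqIO.parse(path, "fasta"):
                    bad = set(str(rec.seq).upper()) - set("ACGTN")
                    if bad:
                        err(path, "fasta-alphabet",
                            f"{rec.id}: non-ACGTN characters {sorted(bad)}")
            elif low.endswith((".gff", ".gff3")):
                with open(path) as fh:
                    for lineno, line in enumerate(fh, 1):
                        if line.startswith("#") or not line.strip():
                            continue
                        parts = line.split("\t")
                        if len(parts) < 8:
                            err(path, "gff-columns", f"line {lineno}: <8 columns")
                            continue
                        if parts[2] == "CDS":
                            length = int(parts[4]) - int(parts[3]) + 1
                            if length % 3:
                                err(path, "gff-frame",
                                    f"line {lineno}: CDS length {length} not divisible by 3")
            elif low.endswith((".tsv", ".txt")):
                df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
                numeric = df.select_dtypes(include=[np.number])
                if (numeric.to_numpy() < 0).any():
                    err(path, "tsv-negative", "negative numeric entries")
        except Exception as exc:  # reporting contract: never raise
            err(path, "parse", str(exc))
    return errors
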