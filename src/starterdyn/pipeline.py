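"""End-to-end orchestration: simulate -> map -> snv -> lineages -> spacers
-> phage, driven by one config, emitting a structured report bundle.

Every output file carries the config hash; positions are 1-based in
VCF-flavored exports and 0-based half-open in BED and truth tables (each
file header says which).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import community as comm
from . import io as sio
from .mapping import align_reads
from .phage import phage_state_report
from .simulate import simulate_sample
from .snv import (
    SnvTable,
    annotate_and_filter,
    call_snvs,
    cluster_trajectories,
    lineage_diagnostic_snvs,
    quantify_lineages,
    species_abundance,
)
from .spacers import (
    SpacerRecord,
    dereplicate_spacers,
    extract_metagenomic_spacers,
    isolate_spacer_records,
)

log = logging.getLogger("starterdyn")

STAGES = ("simulate", "map", "snv", "lineages", "spacers", "phage", "report")
_DEPS = {
    "map": ("simulate",),
    "snv": ("map",),
    "lineages": ("snv",),
    "spacers": ("simulate",),
    "phage": ("map",),
    "report": (),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "starterdyn_run"
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    # community / simulation
    n_samples: int = 3
    host_length: int = 30_000
    minor_length: int = 20_000
    phage_length: int = 8_000
    n_lineages: int = 4
    snvs_per_lineage: int = 30
    phage_copies: float = 10.0
    integrated_cell_fraction: float = 0.05
    depth: float = 50.0
    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    # thresholds (defaults follow the analysis conventions documented in docs)
    min_identity: float = 0.9
    min_alt_count: int = 5
    min_alt_frac: float = 0.05
    min_depth: int = 10
    detection_limit: float = 0.05
    linkage_threshold: float = 0.10
    spacer_identity: float = 0.90
    min_flank: int = 10
    gzip_fastq: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        enabled = set(self.stages)
        unknown = enabled - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for st in self.stages:
            for dep in _DEPS.get(st, ()):
                if dep not in enabled:
                    raise ConfigurationError(
                        f"stage '{st}' requires missing input from stage '{dep}'"
                    )


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute enabled stages in dependency order; returns the report bundle."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(out / "config.yaml")
    bundle: Dict[str, object] = {"config_hash": chash, "outdir": str(out)}
    summary: Dict[str, object] = {"config_hash": chash, "stages": {}}
    ctx: Dict[str, object] = {}

    def _stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.time()
        n_in, n_out = fn()
        summary["stages"][name] = {
            "n_in": n_in,
            "n_out": n_out,
            "elapsed_s": round(time.time() - t0, 3),
        }
        log.info("stage=%s n_in=%s n_out=%s", name, n_in, n_out)

    def do_simulate():
        com = comm.build_community(
            config.seed,
            n_samples=config.n_samples,
            host_length=config.host_length,
            minor_length=config.minor_length,
            phage_length=config.phage_length,
            n_lineages=config.n_lineages,
            snvs_per_lineage=config.snvs_per_lineage,
            phage_copies=config.phage_copies,
            integrated_cell_fraction=config.integrated_cell_fraction,
        )
        rng = np.random.default_rng(config.seed + 1)
        reads = {}
        for s in com.sample_ids:
            rd = simulate_sample(
                com, s, config.depth, config.read_len, config.insert_mean,
                config.insert_sd, config.error_rate, seed=int(rng.integers(2**31)),
            )
            reads[s] = rd
            suffix = ".fastq.gz" if config.gzip_fastq else ".fastq"
            rd.write_fastq(out / f"{s}_R1{suffix}", out / f"{s}_R2{suffix}")
        sio.write_references(out / "references.fasta", com)
        for sp in com.species:
            sio.write_gene_models(
                out / f"{sp.chromosome_id}_genes.tsv", com.genomes[sp.chromosome_id]
            )
        com.to_json(out / "truth.json")
        ctx["community"] = com
        ctx["reads"] = reads
        return config.n_samples, sum(len(r) for r in reads.values())

    def do_map():
        com: comm.Community = ctx.get("community")
        if com is None:
            raise ConfigurationError("map stage: missing input from 'simulate'")
        refs = {gid: g.sequence for gid, g in com.genomes.items()}
        alns = {}
        cov_rows = []
        for s in com.sample_ids:
            aln = align_reads(ctx["reads"][s], refs, min_identity=config.min_identity)
            alns[s] = aln
            for rid in sorted(refs):
                st = aln.coverage_stats(rid)
                cov_rows.append((s, rid, st["mean_depth"], st["median_depth"], st["breadth"]))
        with open(out / "coverage.tsv", "w") as fh:
            fh.write(f"# config={chash}\n")
            fh.write("sample\tref_id\tmean_depth\tmedian_depth\tbreadth\n")
            for row in cov_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        ctx["alignments"] = alns
        ctx["coverage"] = cov_rows
        return sum(len(a) for a in alns.values()), len(cov_rows)

    def do_snv():
        com = ctx["community"]
        host = com.species[0]
        pileups = {
            s: ctx["alignments"][s].pileup_counts(host.chromosome_id)
            for s in com.sample_ids
        }
        table = call_snvs(
            pileups, com.genomes[host.chromosome_id],
            config.min_alt_count, config.min_alt_frac, config.min_depth,
        )
        filtered = annotate_and_filter(table, com.genomes[host.chromosome_id])
        filtered.to_tsv(out / "snv_table.tsv")
        ctx["snvs"] = filtered
        if len(com.sample_ids) >= 3:
            phases = cluster_trajectories(
                filtered, config.detection_limit, config.linkage_threshold
            )
            ctx["phases"] = phases
            with open(out / "phases.tsv", "w") as fh:
                fh.write(f"# config={chash}\n")
                fh.write("phase_id\tn_members\t" + "\t".join(phases.samples) + "\n")
                for p in phases.phases:
                    fh.write(
                        f"{p.phase_id}\t{p.n_members}\t"
                        + "\t".join(f"{v:.4f}" for v in p.centroid)
                        + "\n"
                    )
        return len(table), len(filtered)

    def do_lineages():
        com = ctx["community"]
        host = com.species[0]
        truth_haps = {
            st.lineage_id: {
                (host.chromosome_id, v.pos, v.alt_base) for v in st.snvs
            }
            for st in host.strains
        }
        diag = lineage_diagnostic_snvs(
            truth_haps, {lin: lin for lin in truth_haps}
        )
        ab = quantify_lineages(ctx["snvs"], diag, config.min_depth)
        with open(out / "lineage_abundance.tsv", "w") as fh:
            fh.write(f"# config={chash}\n")
            ab.to_csv(fh, sep="\t", index=False)
        sp_rows = []
        for s in com.sample_ids:
            depths = {
                sp.species_id: ctx["alignments"][s].coverage_stats(sp.chromosome_id)[
                    "mean_depth"
                ]
                for sp in com.species
            }
            for k, v in species_abundance(depths).items():
                sp_rows.append((s, k, v))
        with open(out / "species_abundance.tsv", "w") as fh:
            fh.write(f"# config={chash}\nsample\tspecies\tabundance\n")
            for row in sp_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        ctx["lineage_abundance"] = ab
        return len(diag), len(ab)

    def do_spacers():
        com = ctx["community"]
        consensi = {
            arr.array_id: arr.repeat
            for g in com.genomes.values()
            for arr in g.arrays
        }
        records = []
        for s in com.sample_ids:
            res = extract_metagenomic_spacers(
                ctx["reads"][s], consensi, min_flank=config.min_flank, sample_id=s
            )
            records.extend(res.records)
        for sp in com.species:
            for st in sp.strains:
                for aid, seqs in com.strain_array_spacers(st.lineage_id).items():
                    for d, seq in enumerate(seqs):
                        records.append(
                            SpacerRecord(seq, aid, "isolate_genome", st.lineage_id, d)
                        )
        clusters = dereplicate_spacers(records, config.spacer_identity)
        with open(out / "spacer_catalog.fasta", "w") as fh:
            for cl in clusters:
                r = cl.representative
                fh.write(
                    f">{cl.cluster_id}|{r.array_id}|{r.source}|{r.source_id}|"
                    f"{r.leader_distance}\n{r.sequence}\n"
                )
        with open(out / "spacer_clusters.tsv", "w") as fh:
            fh.write(f"# config={chash}\ncluster_id\tn_members\tsources\tarray_id\n")
            for cl in clusters:
                fh.write(
                    f"{cl.cluster_id}\t{len(cl.members)}\t"
                    f"{','.join(sorted(cl.sources))}\t{cl.representative.array_id}\n"
                )
        ctx["spacer_clusters"] = clusters
        return len(records), len(clusters)

    def do_phage():
        com = ctx["community"]
        bact = com.bacterial_replicons()
        reports = []
        for p in com.phages:
            for s in com.sample_ids:
                rep = phage_state_report(
                    ctx["alignments"][s], s, p.genome_id, p.host_genome_id, bact,
                    config.insert_mean, config.insert_sd,
                )
                reports.append(rep)
        with open(out / "phage_state.tsv", "w") as fh:
            fh.write(f"# config={chash}\n")
            fh.write(
                "sample\tphage\tphage_depth\thost_depth\tcopies_per_bacterium\t"
                "integrated_cell_fraction\tintegrated_phage_fraction\tn_sites\n"
            )
            for r in reports:
                fh.write(
                    f"{r.sample_id}\t{r.phage_id}\t{r.phage_mean_depth:.3f}\t"
                    f"{r.host_mean_depth:.3f}\t{r.copies_per_bacterium:.4f}\t"
                    f"{r.integrated_cell_fraction:.5f}\t"
                    f"{r.integrated_phage_fraction:.5f}\t{len(r.sites)}\n"
                )
        with open(out / "integration_sites.bed", "w") as fh:
            fh.write(f"# config={chash}; coordinates 0-based half-open\n")
            for r in reports:
                for site in r.sites:
                    fh.write(
                        f"{site.host_ref_id}\t{site.host_pos}\t{site.host_pos + 1}\t"
                        f"{r.phage_id}_{site.phage_end}\t{site.spanning_pair_count}\t"
                        f"{r.sample_id}\n"
                    )
        ctx["phage_reports"] = reports
        return len(com.phages) * len(com.sample_ids), len(reports)

    def do_report():
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return 0, 1

    _stage("simulate", do_simulate)
    _stage("map", do_map)
    _stage("snv", do_snv)
    _stage("lineages", do_lineages)
    _stage("spacers", do_spacers)
    _stage("phage", do_phage)
    _stage("report", do_report)
    bundle["summary"] = summary
    bundle.update(ctx)
    return bundle
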