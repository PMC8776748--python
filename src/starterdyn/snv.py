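"""Pooled SNV calling, trajectory phasing, and lineage quantification.

The caller reproduces the count/fraction/depth gates of pooled-continuous
variant calling on metagenomes (alt reads >= 5, alt fraction >= 0.05, depth
>= 10 in at least one sample; indels are never emitted because the
substitution-only pipeline produces none and the downstream filter would
discard them anyway).  The central statistic is the alternative allele
frequency AAF = alt_count / depth per site and sample; lineage abundance
is the mean AAF of SNVs diagnostic for that lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .community import Genome, classify_substitution
from .dna import encode
from .mapping import AlignmentSet

SnvKey = Tuple[str, int, str]  # (ref_id, pos, alt_base)


class SnvCallingError(ValueError):
    pass


@dataclass
class SnvTable:
    """Per-site, per-sample alternative allele frequencies.

    ``df`` columns: ref_id, pos (0-based), ref, alt, then per sample
    ``ao_<s>``, ``dp_<s>``, ``aaf_<s>``; after annotation also synonymy,
    gene_id, copy_class.
    """

    df: pd.DataFrame
    samples: List[str]

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> List[SnvKey]:
        return list(zip(self.df.ref_id, self.df.pos.astype(int), self.df.alt))

    def aaf_matrix(self) -> np.ndarray:
        return self.df[[f"aaf_{s}" for s in self.samples]].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "CHROM", out.pop("ref_id"))
        out.insert(1, "POS", out.pop("pos").astype(int) + 1)  # 1-based on export
        out.insert(2, "REF", out.pop("ref"))
        out.insert(3, "ALT", out.pop("alt"))
        with open(path, "w") as fh:
            fh.write("# positions are 1-based in this export\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnvTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(
            columns={"CHROM": "ref_id", "POS": "pos", "REF": "ref", "ALT": "alt"}
        )
        df["pos"] = df["pos"].astype(int) - 1
        samples = [c[4:] for c in df.columns if c.startswith("aaf_")]
        return cls(df, samples)


def call_snvs(
    pileups: Mapping[str, np.ndarray],
    reference: Genome | Tuple[str, str],
    min_alt_count: int = 5,
    min_alt_frac: float = 0.05,
    min_depth: int = 10,
) -> SnvTable:
    """Emit sites passing all three gates in at least one sample.

    ``pileups`` maps sample_id -> (ref_len, 4) base-count matrix as produced
    by :meth:`AlignmentSet.pileup_counts`.  Per-sample AAF is reported for
    every emitted site in every sample (0 when below detection).
    """
    if isinstance(reference, Genome):
        ref_id, ref_seq = reference.genome_id, reference.sequence
    else:
        ref_id, ref_seq = reference
    if not pileups:
        raise SnvCallingError("need pileups from at least one sample")
    samples = sorted(pileups)
    ref_codes = encode(ref_seq)
    L = len(ref_codes)
    stack = np.stack([np.asarray(pileups[s]) for s in samples])  # (S, L, 4)
    if stack.shape[1] != L:
        raise SnvCallingError("pileup length does not match reference")
    dp = stack.sum(axis=2)  # (S, L)
    nonref = stack.copy()
    nonref[:, np.arange(L), ref_codes] = 0
    ao_best = nonref.max(axis=2)  # (S, L) best alt count per sample
    with np.errstate(divide="ignore", invalid="ignore"):
        aaf_best = np.where(dp > 0, ao_best / np.maximum(dp, 1), 0.0)
    emit = (
        (dp >= min_depth) & (ao_best >= min_alt_count) & (aaf_best >= min_alt_frac)
    ).any(axis=0)
    sites = np.nonzero(emit)[0]
    # site-level alt = base with the largest total non-reference support
    total_nonref = nonref.sum(axis=0)  # (L, 4)
    alt_codes = total_nonref[sites].argmax(axis=1)
    rows = {
        "ref_id": ref_id,
        "pos": sites,
        "ref": [ref_seq[p] for p in sites],
        "alt": ["ACGT"[c] for c in alt_codes],
    }
    df = pd.DataFrame(rows)
    for si, s in enumerate(samples):
        ao = stack[si, sites, alt_codes]
        d = dp[si, sites]
        df[f"ao_{s}"] = ao
        df[f"dp_{s}"] = d
        df[f"aaf_{s}"] = np.where(d > 0, ao / np.maximum(d, 1), 0.0)
    return SnvTable(df.reset_index(drop=True), samples)


def annotate_snvs(snvs: SnvTable, genome: Genome) -> SnvTable:
    """Add synonymy / gene_id / copy_class columns (strand-aware)."""
    syn, gid, cc = [], [], []
    for pos, alt in zip(snvs.df.pos.astype(int), snvs.df.alt):
        ann = classify_substitution(genome, pos, alt)
        syn.append(ann.synonymy)
        gid.append(ann.gene_id)
        cc.append(ann.copy_class)
    df = snvs.df.copy()
    df["synonymy"] = syn
    df["gene_id"] = gid
    df["copy_class"] = cc
    return SnvTable(df, snvs.samples)


def annotate_and_filter(snvs: SnvTable, genome: Genome) -> SnvTable:
    """Keep non-synonymous SNVs inside single-copy genes."""
    ann = annotate_snvs(snvs, genome)
    keep = (ann.df.synonymy == "non_synonymous") & (ann.df.copy_class == "single_copy")
    return SnvTable(ann.df[keep].reset_index(drop=True), ann.samples)


@dataclass
class SnvPhase:
    phase_id: str
    member_index: List[int]  # row positions in the clustered table
    centroid: np.ndarray  # mean AAF per sample

    @property
    def n_members(self) -> int:
        return len(self.member_index)


@dataclass
class PhaseClustering:
    phases: List[SnvPhase]
    unexplained_index: List[int]
    samples: List[str]


def cluster_trajectories(
    snvs: SnvTable,
    detection_limit: float = 0.05,
    linkage_threshold: float = 0.10,
    min_phase_size: int = 5,
) -> PhaseClustering:
    """Average-linkage clustering of AAF trajectories into strain phases.

    AAF values below ``detection_limit`` are zeroed first, mirroring the
    detection floor of pooled calling.  The distance between two
    trajectories is the per-sample RMS difference (Euclidean / sqrt(n));
    this keeps ``linkage_threshold`` comparable across designs with
    different numbers of samples.  Clusters smaller than
    ``min_phase_size`` are reported as unexplained leftovers, not phases.
    """
    if len(snvs.samples) < 3:
        raise SnvCallingError("trajectory clustering needs >= 3 samples")
    X = snvs.aaf_matrix().copy()
    X[X < detection_limit] = 0.0
    n = X.shape[0]
    if n == 0:
        return PhaseClustering([], [], snvs.samples)
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(X, method="average", metric="euclidean")
        cut = linkage_threshold * np.sqrt(X.shape[1])
        labels = fcluster(Z, t=cut, criterion="distance")
    phases = []
    unexplained: List[int] = []
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    # order phases by mean abundance, highest first
    ordered = sorted(
        groups.values(), key=lambda idx: -float(X[idx].mean())
    )
    k = 0
    for idx in ordered:
        if len(idx) >= min(min_phase_size, n):
            k += 1
            phases.append(SnvPhase(f"P{k}", idx, X[idx].mean(axis=0)))
        else:
            unexplained.extend(idx)
    return PhaseClustering(phases, sorted(unexplained), snvs.samples)


def lineage_diagnostic_snvs(
    isolate_haplotypes: Mapping[str, Set[SnvKey]],
    lineage_assignment: Mapping[str, str],
) -> Dict[str, Set[SnvKey]]:
    """SNVs present in every isolate of one lineage and absent from all others."""
    lineages: Dict[str, List[Set[SnvKey]]] = {}
    for iso, hap in isolate_haplotypes.items():
        lineages.setdefault(lineage_assignment[iso], []).append(set(hap))
    if not lineages:
        raise ValueError("no isolates given")
    out: Dict[str, Set[SnvKey]] = {}
    for lin, haps in lineages.items():
        core = set.intersection(*haps)
        others = set().union(
            *(h for l2, hs in lineages.items() if l2 != lin for h in hs)
        ) if len(lineages) > 1 else set()
        diag = core - others
        if not diag:
            warnings.warn(f"lineage {lin} has no diagnostic SNVs; unquantifiable")
        out[lin] = diag
    return out


def quantify_lineages(
    snvs: SnvTable,
    diagnostic_sets: Mapping[str, Iterable[SnvKey]],
    min_depth: int = 10,
) -> pd.DataFrame:
    """Lineage abundance = mean AAF of its diagnostic SNVs, per sample.

    Returns a tidy frame (lineage, sample, abundance, n_snvs_used);
    abundance is NaN when no diagnostic SNV is covered at ``min_depth``.
    """
    key_to_row = {k: i for i, k in enumerate(snvs.keys())}
    records = []
    for lin, keys in sorted(diagnostic_sets.items()):
        rows = [key_to_row[k] for k in keys if k in key_to_row]
        for s in snvs.samples:
            if rows:
                dp = snvs.df[f"dp_{s}"].to_numpy()[rows]
                aaf = snvs.df[f"aaf_{s}"].to_numpy()[rows]
                ok = dp >= min_depth
            else:
                ok = np.array([], dtype=bool)
            if ok.sum() == 0:
                records.append((lin, s, np.nan, 0))
            else:
                records.append((lin, s, float(aaf[ok].mean()), int(ok.sum())))
    return pd.DataFrame(records, columns=["lineage", "sample", "abundance", "n_snvs_used"])


def explained_snv_fraction(
    metagenome_snvs: Iterable[SnvKey], isolate_snv_union: Iterable[SnvKey]
) -> float:
    """Fraction of metagenome SNVs present in the isolate union (pos+alt match)."""
    meta = set(metagenome_snvs)
    if not meta:
        raise ValueError("empty metagenome SNV set")
    return len(meta & set(isolate_snv_union)) / len(meta)


def species_abundance(mean_depths: Mapping[str, float]) -> Dict[str, float]:
    """Depth-based relative abundance; depths are genome-length-normalized."""
    total = float(sum(mean_depths.values()))
    if total <= 0:
        raise ValueError("all-zero depth")
    return {k: v / total for k, v in sorted(mean_depths.items())}


def plasmid_copy_number(plasmid_mean_depth: float, host_mean_depth: float) -> float:
    if host_mean_depth <= 0:
        raise ValueError("host depth must be positive")
    return plasmid_mean_depth / host_mean_depth


def count_syn_nonsyn_sites(genome: Genome, gene) -> Tuple[float, float]:
    """(N_sites, S_sites) by enumerating all 3 substitutions per position.

    Each position contributes (non-synonymous alternatives)/3 to N_sites and
    (synonymous alternatives)/3 to S_sites, so N_sites + S_sites equals the
    gene length.  Substitutions to or from stop codons count as
    non-synonymous.
    """
    n_sites = 0.0
    s_sites = 0.0
    for pos in range(gene.start, gene.end):
        ref = genome.sequence[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            ann = classify_substitution(genome, pos, alt)
            if ann.synonymy == "synonymous":
                s_sites += 1 / 3
            else:
                n_sites += 1 / 3
    return n_sites, s_sites


def pnps(snvs: SnvTable, genome: Genome) -> pd.DataFrame:
    """Per-gene and genome-wide pN/pS from a synonymy-annotated table.

    pN/pS = (N_obs / N_sites) / (S_obs / S_sites); genes with S_obs = 0 get
    NaN (undefined, not infinite).  The final row (gene_id = "_genome")
    pools observations and sites over all genes.
    """
    if "synonymy" not in snvs.df.columns:
        snvs = annotate_snvs(snvs, genome)
    obs = snvs.df[snvs.df.gene_id.notna()]
    rows = []
    tot = dict(n_obs=0, s_obs=0, n_sites=0.0, s_sites=0.0)
    for gene in genome.genes:
        if gene.length % 3:
            warnings.warn(f"gene {gene.gene_id} has invalid frame; skipped")
            continue
        n_sites, s_sites = count_syn_nonsyn_sites(genome, gene)
        sub = obs[obs.gene_id == gene.gene_id]
        n_obs = int((sub.synonymy == "non_synonymous").sum())
        s_obs = int((sub.synonymy == "synonymous").sum())
        ratio = (
            (n_obs / n_sites) / (s_obs / s_sites) if s_obs > 0 and n_sites > 0 else np.nan
        )
        rows.append((gene.gene_id, n_obs, s_obs, n_sites, s_sites, ratio))
        tot["n_obs"] += n_obs
        tot["s_obs"] += s_obs
        tot["n_sites"] += n_sites
        tot["s_sites"] += s_sites
    gratio = (
        (tot["n_obs"] / tot["n_sites"]) / (tot["s_obs"] / tot["s_sites"])
        if tot["s_obs"] > 0 and tot["n_sites"] > 0
        else np.nan
    )
    rows.append(("_genome", tot["n_obs"], tot["s_obs"], tot["n_sites"], tot["s_sites"], gratio))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_obs", "s_obs", "n_sites", "s_sites", "pnps"]
    )
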