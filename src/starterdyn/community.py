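"""Synthetic two-species starter-culture communities with known ground truth.

The generator emulates the structure of a thermophilic cheese starter
culture: a dominant *Streptococcus*-like species carrying several
near-identical strain lineages distinguished by planted SNVs and private
leader-proximal CRISPR spacers, a minor *Lactobacillus*-like species, a
temperate phage present both as free particles (high copy) and integrated
at a known attB site in a small fraction of host cells, and a plasmid with
a configurable copy number.  Every random choice flows from one seed, and
the full generative description is kept in a :class:`CommunityTruth` so
that downstream estimators can be scored by parameter recovery.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dna import decode, encode, random_seq, revcomp, translate_codon


class CommunitySizingError(ValueError):
    """Requested features do not fit in the requested sequence length."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneModel:
    gene_id: str
    start: int
    end: int  # half-open
    strand: str  # '+' or '-'
    copy_class: str = "single_copy"  # or "multi_copy"
    frame: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CrisprArray:
    array_id: str
    repeat: str
    spacers: List[str]  # index 0 = leader-proximal (newest)
    leader_side: str = "left"
    start: int = 0
    end: int = 0
    leader_len: int = 30

    def span(self) -> Tuple[int, int]:
        return self.start, self.end


@dataclass
class Genome:
    genome_id: str
    sequence: str
    genes: List[GeneModel] = field(default_factory=list)
    arrays: List[CrisprArray] = field(default_factory=list)
    kind: str = "bacterial"  # bacterial | phage | plasmid

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence alphabet must be ACGT")
        spans = []
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(self.sequence)):
                raise ValueError(f"gene {g.gene_id} out of bounds")
            if g.length % 3:
                raise ValueError(f"CDS {g.gene_id} length not divisible by 3")
            spans.append((g.start, g.end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("overlapping genes")
        for a in self.arrays:
            for g in self.genes:
                if a.start < g.end and g.start < a.end:
                    raise ValueError(f"array {a.array_id} overlaps CDS {g.gene_id}")


@dataclass
class Snv:
    pos: int
    ref_base: str
    alt_base: str
    synonymy: str = "non_coding"  # synonymous | non_synonymous | non_coding
    gene_id: Optional[str] = None
    copy_class: Optional[str] = None


@dataclass
class StrainDefinition:
    lineage_id: str
    base_genome_id: str
    snvs: List[Snv] = field(default_factory=list)
    # per-array private spacers, newest first (inserted at the leader)
    private_spacers: Dict[str, List[str]] = field(default_factory=dict)
    abundance_by_sample: Dict[str, float] = field(default_factory=dict)


@dataclass
class PhageSpec:
    genome_id: str
    host_genome_id: str
    att_sites: List[int]  # alternative attB positions; lysogens split evenly
    copies_by_sample: Dict[str, float] = field(default_factory=dict)
    integrated_by_sample: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for s, c in self.copies_by_sample.items():
            icf = self.integrated_by_sample.get(s, 0.0)
            if not 0 <= icf <= 1:
                raise ValueError("integrated_cell_fraction outside [0,1]")
            if icf > c:
                raise ValueError("integrated copies exceed total copies")


@dataclass
class SpeciesDef:
    species_id: str
    chromosome_id: str
    plasmid_ids: List[str] = field(default_factory=list)
    strains: List[StrainDefinition] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    length: int,
    gene_density: float,
    n_arrays: int,
    seed: int,
    *,
    genome_id: str = "ref",
    kind: str = "bacterial",
    single_copy_frac: float = 0.8,
    repeat_len: int = 36,
    spacers_per_array: int = 12,
    spacer_len: int = 30,
    array_id_prefix: str = "CR",
) -> Genome:
    """Generate a random annotated replicon.

    Genes are non-overlapping CDS intervals with length divisible by 3;
    CRISPR arrays (leader + alternating repeat/spacer) are placed in
    intergenic space, disjoint from every CDS.  Deterministic per seed.
    """
    if length < 10_000:
        raise CommunitySizingError("length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    n_genes = max(1, int(round(length / 1000.0 * gene_density)))

    gene_lens = (rng.integers(100, 300, size=n_genes) * 3).tolist()
    leader_len = 30
    array_span = leader_len + repeat_len + spacers_per_array * (spacer_len + repeat_len)
    features: List[Tuple[str, int]] = [("gene", L) for L in gene_lens]
    features += [("array", array_span)] * n_arrays
    order = rng.permutation(len(features))
    features = [features[i] for i in order]

    min_gap = 20
    used = sum(L for _, L in features) + min_gap * (len(features) + 1)
    if used > length:
        raise CommunitySizingError(
            f"{n_genes} genes and {n_arrays} arrays need {used} bp > {length} bp"
        )
    slack = length - used
    # distribute slack over the gaps
    gap_extra = rng.multinomial(slack, np.full(len(features) + 1, 1.0 / (len(features) + 1)))

    seq = list(random_seq(rng, length))
    genes: List[GeneModel] = []
    arrays: List[CrisprArray] = []
    pos = min_gap + int(gap_extra[0])
    for i, (ftype, flen) in enumerate(features):
        if ftype == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel("", pos, pos + flen, strand))
        else:
            repeat = random_seq(rng, repeat_len)
            spacers = [random_seq(rng, spacer_len) for _ in range(spacers_per_array)]
            body = "".join(repeat + s for s in spacers) + repeat
            arr_seq = random_seq(rng, leader_len) + body
            seq[pos : pos + flen] = arr_seq
            arrays.append(
                CrisprArray("", repeat, spacers, "left", pos, pos + flen, leader_len)
            )
        pos += flen + min_gap + int(gap_extra[i + 1])

    genes.sort(key=lambda g: g.start)
    for i, g in enumerate(genes):
        g.gene_id = f"{genome_id}_g{i:04d}"
    n_multi = int((1.0 - single_copy_frac) * len(genes))
    multi_idx = rng.choice(len(genes), size=n_multi, replace=False)
    for i in multi_idx:
        genes[i].copy_class = "multi_copy"
    arrays.sort(key=lambda a: a.start)
    for i, a in enumerate(arrays):
        a.array_id = f"{array_id_prefix}{i + 1}"

    genome = Genome(genome_id, "".join(seq), genes, arrays, kind)
    genome.validate()
    return genome


def classify_substitution(genome: Genome, pos: int, alt_base: str) -> Snv:
    """Annotate a single-base substitution: synonymy, gene, copy class.

    Strand-aware codon substitution under the standard genetic code.
    """
    ref_base = genome.sequence[pos]
    if alt_base == ref_base:
        raise ValueError("alt equals ref")
    for g in genome.genes:
        if g.start <= pos < g.end:
            if g.length % 3:
                raise ValueError(f"gene {g.gene_id} length not divisible by 3")
            if g.strand == "+":
                off = pos - g.start
                cstart = g.start + (off // 3) * 3
                codon = genome.sequence[cstart : cstart + 3]
                cpos = off % 3
            else:
                off = g.end - 1 - pos  # distance from the 5' end on the minus strand
                cidx = off // 3
                cend = g.end - cidx * 3
                codon = revcomp(genome.sequence[cend - 3 : cend])
                cpos = off % 3
                alt_base_c = revcomp(alt_base)
            if g.strand == "+":
                alt_codon = codon[:cpos] + alt_base + codon[cpos + 1 :]
            else:
                alt_codon = codon[:cpos] + alt_base_c + codon[cpos + 1 :]
            syn = (
                "synonymous"
                if translate_codon(codon) == translate_codon(alt_codon)
                else "non_synonymous"
            )
            return Snv(pos, ref_base, alt_base, syn, g.gene_id, g.copy_class)
    return Snv(pos, ref_base, alt_base, "non_coding", None, None)


def derive_lineages(
    genome: Genome,
    n_lineages: int,
    snvs_per_lineage: int,
    seed: int,
    *,
    nonsyn_frac: float = 0.9,
    private_spacers_per_lineage: int = 2,
    spacer_len: int = 30,
    lineage_prefix: str = "L",
) -> List[StrainDefinition]:
    """Derive strain lineages by planting disjoint SNV sets and private spacers.

    Planted SNVs sit in CDS; at least ``nonsyn_frac`` of them are
    non-synonymous changes inside single-copy genes (the remainder are
    synonymous changes in single-copy genes, which exercise the downstream
    annotation filter).  Each lineage also receives private leader-proximal
    spacers in one of the genome's CRISPR arrays.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    rng = np.random.default_rng(seed)
    cds_pos = []
    for g in genome.genes:
        if g.copy_class == "single_copy":
            cds_pos.extend(range(g.start, g.end))
    # exclude positions inside arrays (none by construction) — CDS only anyway
    cds_pos = np.array(cds_pos)
    rng.shuffle(cds_pos)
    need = n_lineages * snvs_per_lineage
    if len(cds_pos) < 4 * need:
        raise CommunitySizingError("not enough eligible CDS positions")

    n_nonsyn = int(np.ceil(nonsyn_frac * snvs_per_lineage))
    strains: List[StrainDefinition] = []
    cursor = 0
    bases = "ACGT"
    for li in range(n_lineages):
        snvs: List[Snv] = []
        want_nonsyn = n_nonsyn
        want_syn = snvs_per_lineage - n_nonsyn
        while (want_nonsyn or want_syn) and cursor < len(cds_pos):
            pos = int(cds_pos[cursor])
            cursor += 1
            ref = genome.sequence[pos]
            alts = [b for b in bases if b != ref]
            rng.shuffle(alts)
            chosen = None
            for alt in alts:
                cand = classify_substitution(genome, pos, alt)
                if want_nonsyn and cand.synonymy == "non_synonymous":
                    chosen, want_nonsyn = cand, want_nonsyn - 1
                    break
                if not want_nonsyn and want_syn and cand.synonymy == "synonymous":
                    chosen, want_syn = cand, want_syn - 1
                    break
            if chosen is not None:
                snvs.append(chosen)
        if want_nonsyn or want_syn:
            raise CommunitySizingError("not enough eligible CDS positions")
        snvs.sort(key=lambda s: s.pos)
        private: Dict[str, List[str]] = {}
        if genome.arrays:
            arr = genome.arrays[li % len(genome.arrays)]
            private[arr.array_id] = [
                random_seq(rng, spacer_len) for _ in range(private_spacers_per_lineage)
            ]
        strains.append(
            StrainDefinition(f"{lineage_prefix}{li + 1}", genome.genome_id, snvs, private)
        )
    return strains


def simulate_spacer_acquisition(
    rate: float, generations: float, rng: np.random.Generator
) -> List[float]:
    """Poisson spacer acquisition; returns acquisition ages, newest first.

    Element ``i`` is the age (generations before present) of the spacer at
    leader distance ``i``.
    """
    n = rng.poisson(rate * generations)
    times = rng.uniform(0.0, generations, size=n)
    return sorted(float(generations - t) for t in times)


# ---------------------------------------------------------------------------
# community assembly


@dataclass
class Community:
    """Two-species community plus phages/plasmids and the per-sample truth."""

    genomes: Dict[str, Genome]
    species: List[SpeciesDef]
    phages: List[PhageSpec]
    plasmid_copy_number: Dict[str, float]
    sample_ids: List[str]
    species_fractions: Dict[str, Dict[str, float]]  # sample -> species -> fraction
    realized_fragments: Dict[str, Dict[str, int]] = field(default_factory=dict)
    expected_depth: Dict[str, Dict[str, float]] = field(default_factory=dict)

    # -- derived views -----------------------------------------------------
    def strain(self, lineage_id: str) -> Tuple[SpeciesDef, StrainDefinition]:
        for sp in self.species:
            for st in sp.strains:
                if st.lineage_id == lineage_id:
                    return sp, st
        raise KeyError(lineage_id)

    def lineage_fractions(self, sample_id: str) -> Dict[str, float]:
        return {
            st.lineage_id: st.abundance_by_sample[sample_id]
            for sp in self.species
            for st in sp.strains
        }

    def bacterial_replicons(self) -> List[str]:
        return [sp.chromosome_id for sp in self.species]

    def strain_sequence(self, lineage_id: str) -> str:
        """Realized strain chromosome: base + SNVs + private leader spacers."""
        sp, st = self.strain(lineage_id)
        base = self.genomes[sp.chromosome_id]
        seq = list(base.sequence)
        for v in st.snvs:
            if seq[v.pos] != v.ref_base:
                raise ValueError("truth SNV ref mismatch")
            seq[v.pos] = v.alt_base
        insertions = []
        for arr in base.arrays:
            priv = st.private_spacers.get(arr.array_id)
            if priv:
                if arr.leader_side != "left":
                    raise NotImplementedError("right-leader arrays not generated")
                ins = "".join(arr.repeat + s for s in priv)
                insertions.append((arr.start + arr.leader_len, ins))
        out = "".join(seq)
        for pos, ins in sorted(insertions, reverse=True):
            out = out[:pos] + ins + out[pos:]
        return out

    def insertion_spans(self, lineage_id: str) -> List[Tuple[int, int]]:
        """Private-spacer insertion intervals in strain coordinates.

        Reads overlapping these spans are chimeric relative to the base
        reference (insertion junctions), like lysogen junction reads.
        """
        sp, st = self.strain(lineage_id)
        base = self.genomes[sp.chromosome_id]
        spans = []
        shift = 0
        for arr in sorted(base.arrays, key=lambda a: a.start):
            priv = st.private_spacers.get(arr.array_id)
            if priv:
                ins_len = sum(len(arr.repeat) + len(s) for s in priv)
                start = arr.start + arr.leader_len + shift
                spans.append((start, start + ins_len))
                shift += ins_len
        return spans

    def _insertion_shift(self, lineage_id: str, base_pos: int) -> int:
        sp, st = self.strain(lineage_id)
        base = self.genomes[sp.chromosome_id]
        shift = 0
        for arr in base.arrays:
            priv = st.private_spacers.get(arr.array_id)
            if priv and arr.start + arr.leader_len <= base_pos:
                shift += sum(len(arr.repeat) + len(s) for s in priv)
        return shift

    def lysogen_sequence(self, lineage_id: str, phage: PhageSpec, att_site: int) -> str:
        """Recombinant host-with-integrated-phage molecule at one attB site."""
        host = self.strain_sequence(lineage_id)
        att = att_site + self._insertion_shift(lineage_id, att_site)
        ph = self.genomes[phage.genome_id].sequence
        return host[:att] + ph + host[att:]

    def strain_array_spacers(self, lineage_id: str) -> Dict[str, List[str]]:
        """Per-array spacers of a strain, newest (leader-proximal) first."""
        sp, st = self.strain(lineage_id)
        base = self.genomes[sp.chromosome_id]
        out = {}
        for arr in base.arrays:
            out[arr.array_id] = list(st.private_spacers.get(arr.array_id, [])) + list(
                arr.spacers
            )
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coordinates": "0-based half-open",
            "genomes": {
                gid: asdict(g) for gid, g in sorted(self.genomes.items())
            },
            "species": [asdict(sp) for sp in self.species],
            "phages": [asdict(p) for p in self.phages],
            "plasmid_copy_number": self.plasmid_copy_number,
            "sample_ids": self.sample_ids,
            "species_fractions": self.species_fractions,
            "realized_fragments": self.realized_fragments,
            "expected_depth": self.expected_depth,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "Community":
        genomes = {
            gid: Genome(
                g["genome_id"],
                g["sequence"],
                [GeneModel(**gm) for gm in g["genes"]],
                [CrisprArray(**ar) for ar in g["arrays"]],
                g["kind"],
            )
            for gid, g in d["genomes"].items()
        }
        species = [
            SpeciesDef(
                sp["species_id"],
                sp["chromosome_id"],
                sp["plasmid_ids"],
                [
                    StrainDefinition(
                        st["lineage_id"],
                        st["base_genome_id"],
                        [Snv(**v) for v in st["snvs"]],
                        st["private_spacers"],
                        st["abundance_by_sample"],
                    )
                    for st in sp["strains"]
                ],
            )
            for sp in d["species"]
        ]
        phages = [PhageSpec(**p) for p in d["phages"]]
        return cls(
            genomes,
            species,
            phages,
            d["plasmid_copy_number"],
            d["sample_ids"],
            d["species_fractions"],
            d.get("realized_fragments", {}),
            d.get("expected_depth", {}),
        )

    @classmethod
    def from_json(cls, path) -> "Community":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _plant_protospacers(
    host: Genome, phage: Genome, n: int, rng: np.random.Generator
) -> List[Tuple[str, int]]:
    """Replace ``n`` host array spacers with phage subsequences.

    Returns (array_id, spacer_index) of the planted protospacer-matching
    spacers.  The host genome sequence is edited in place (same length).
    """
    slots = [
        (ai, si)
        for ai, arr in enumerate(host.arrays)
        for si in range(1, len(arr.spacers))  # keep index 0 free for private spacers
    ]
    idx = rng.choice(len(slots), size=min(n, len(slots)), replace=False)
    planted = []
    seq = list(host.sequence)
    for i in sorted(int(j) for j in idx):
        ai, si = slots[i]
        arr = host.arrays[ai]
        sl = len(arr.spacers[si])
        start = int(rng.integers(0, len(phage.sequence) - sl))
        proto = phage.sequence[start : start + sl]
        arr.spacers[si] = proto
        # spacer si occupies: arr.start + leader + (si+1)*repeat + sum(prev spacers)
        off = arr.start + arr.leader_len + (si + 1) * len(arr.repeat)
        off += sum(len(s) for s in arr.spacers[:si])
        seq[off : off + sl] = proto
        planted.append((arr.array_id, si))
    host.sequence = "".join(seq)
    return planted


def _intergenic_position(genome: Genome, rng: np.random.Generator) -> int:
    """A position outside every gene and array (for attB placement)."""
    blocked = sorted(
        [(g.start, g.end) for g in genome.genes] + [(a.start, a.end) for a in genome.arrays]
    )
    gaps = []
    prev = 0
    for s, e in blocked:
        if s - prev > 12:
            gaps.append((prev + 5, s - 5))
        prev = max(prev, e)
    if len(genome.sequence) - prev > 12:
        gaps.append((prev + 5, len(genome.sequence) - 5))
    if not gaps:
        raise CommunitySizingError("no intergenic space for attB site")
    s, e = gaps[int(rng.integers(0, len(gaps)))]
    return int(rng.integers(s, e))


DEFAULT_LINEAGE_FRACTIONS = (0.4, 0.3, 0.2, 0.1)


def build_community(
    seed: int,
    *,
    n_samples: int = 11,
    host_length: int = 50_000,
    minor_length: int = 50_000,
    phage_length: int = 10_000,
    minor_phage_length: int = 10_000,
    plasmid_length: int = 10_000,
    n_lineages: int = 4,
    snvs_per_lineage: int = 50,
    lineage_fractions: Optional[Sequence[float]] = None,
    species_fractions: Tuple[float, float] = (0.8, 0.2),
    phage_copies: float = 10.0,
    integrated_cell_fraction: float = 0.05,
    minor_phage_copies: float = 0.1,
    plasmid_pcn: float = 3.2,
    n_protospacer_spacers: int = 4,
    include_minor_species: bool = True,
    include_minor_phage: bool = True,
    include_plasmid: bool = True,
    n_att_sites: int = 1,
    lineage_fraction_overrides: Optional[Dict[str, Dict[str, float]]] = None,
) -> Community:
    """Assemble the default toy community (2 species, 4+1 lineages, 11 samples).

    ``lineage_fraction_overrides`` maps sample_id -> {lineage_id: fraction}
    and is re-normalized per species per sample; it is how one plants a
    phase that transiently drops below the detection limit.
    """
    if lineage_fractions is None:
        if n_lineages <= len(DEFAULT_LINEAGE_FRACTIONS):
            base = DEFAULT_LINEAGE_FRACTIONS[:n_lineages]
        else:
            base = [0.5**i for i in range(n_lineages)]
        tot = sum(base)
        lineage_fractions = [b / tot for b in base]
    if len(lineage_fractions) != n_lineages:
        raise ValueError("lineage_fractions length must equal n_lineages")
    if abs(sum(lineage_fractions) - 1.0) > 1e-9:
        raise ValueError("lineage fractions must sum to 1")
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]

    host = generate_reference(
        host_length, 1.0, 3, int(rng.integers(2**31)), genome_id="stherm",
        array_id_prefix="CR",
    )
    phage = generate_reference(
        phage_length, 0.5, 0, int(rng.integers(2**31)), genome_id="phiST", kind="phage"
    )
    _plant_protospacers(host, phage, n_protospacer_spacers, rng)
    host.validate()

    strains = derive_lineages(
        host, n_lineages, snvs_per_lineage, int(rng.integers(2**31)), lineage_prefix="STL"
    )
    for st in strains:
        for s in sample_ids:
            st.abundance_by_sample[s] = float(
                lineage_fractions[strains.index(st)]
            )
    if lineage_fraction_overrides:
        for s, over in lineage_fraction_overrides.items():
            for st in strains:
                if st.lineage_id in over:
                    st.abundance_by_sample[s] = float(over[st.lineage_id])
            tot = sum(st.abundance_by_sample[s] for st in strains)
            for st in strains:
                st.abundance_by_sample[s] /= tot

    genomes = {host.genome_id: host, phage.genome_id: phage}
    species = [SpeciesDef("st", host.genome_id, [], strains)]
    # alternative attB sites kept well separated so junction clusters resolve
    att_sites: List[int] = []
    for _ in range(200):
        if len(att_sites) == n_att_sites:
            break
        cand = _intergenic_position(host, rng)
        if all(abs(cand - a) >= 1500 for a in att_sites):
            att_sites.append(cand)
    if len(att_sites) < n_att_sites:
        raise CommunitySizingError("could not place separated attB sites")
    att_sites.sort()
    phages = [
        PhageSpec(
            phage.genome_id,
            host.genome_id,
            att_sites,
            {s: float(phage_copies) for s in sample_ids},
            {s: float(integrated_cell_fraction) for s in sample_ids},
        )
    ]
    plasmid_pcns: Dict[str, float] = {}

    sf = {s: {"st": float(species_fractions[0])} for s in sample_ids}
    if include_minor_species:
        minor = generate_reference(
            minor_length, 1.0, 2, int(rng.integers(2**31)), genome_id="ldelb",
            array_id_prefix="CR",
        )
        # rename minor-species arrays to continue the CR numbering (CR4, CR5)
        for i, arr in enumerate(minor.arrays):
            arr.array_id = f"CR{len(host.arrays) + i + 1}"
        minor_strains = derive_lineages(
            minor, 1, 10, int(rng.integers(2**31)), lineage_prefix="LDL"
        )
        for st in minor_strains:
            for s in sample_ids:
                st.abundance_by_sample[s] = 1.0
        genomes[minor.genome_id] = minor
        plasmids = []
        if include_plasmid:
            plasmid = generate_reference(
                plasmid_length, 0.5, 0, int(rng.integers(2**31)),
                genome_id="pWS58L", kind="plasmid",
            )
            genomes[plasmid.genome_id] = plasmid
            plasmids = [plasmid.genome_id]
            plasmid_pcns[plasmid.genome_id] = float(plasmid_pcn)
        species.append(SpeciesDef("ld", minor.genome_id, plasmids, minor_strains))
        for s in sample_ids:
            sf[s]["ld"] = float(species_fractions[1])
        if include_minor_phage:
            mphage = generate_reference(
                minor_phage_length, 0.5, 0, int(rng.integers(2**31)),
                genome_id="phiLD", kind="phage",
            )
            genomes[mphage.genome_id] = mphage
            phages.append(
                PhageSpec(
                    mphage.genome_id, minor.genome_id,
                    [_intergenic_position(minor, rng)],
                    {s: float(minor_phage_copies) for s in sample_ids},
                    {s: 0.0 for s in sample_ids},
                )
            )
    else:
        for s in sample_ids:
            sf[s]["st"] = 1.0

    for p in phages:
        p.validate()
    return Community(genomes, species, phages, plasmid_pcns, sample_ids, sf)
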