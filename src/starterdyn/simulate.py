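"""Paired-end read simulation from a :class:`~starterdyn.community.Community`.

Fragments are drawn multinomially across all source molecules (strain
chromosomes, lysogen recombinants, free phage, plasmids) with weights
proportional to per-molecule depth x length; the per-base error model is
uniform substitution only.  The ``depth`` parameter is the target mean
per-base depth of the first (dominant) species' chromosome; every other
replicon scales by relative cell abundance and copy number, so coverage
ratios carry the community composition.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .community import Community, PhageSpec
from .dna import decode, encode

_CODE_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


class ReadSimulationError(ValueError):
    pass


@dataclass
class SampleReads:
    """In-memory paired reads; rows of ``r1``/``r2`` are uint8 base codes."""

    sample_id: str
    names: List[str]
    r1: np.ndarray
    r2: np.ndarray
    read_len: int
    qualities: Optional[np.ndarray] = None  # unused by the simulator (all Q40)

    def __len__(self) -> int:
        return len(self.names)

    def pairs(self) -> Iterator[Tuple[str, str, str]]:
        for i, name in enumerate(self.names):
            yield name, decode(self.r1[i]), decode(self.r2[i])

    def write_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_len
        for path, mat, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            opener = (
                (lambda p: gzip.GzipFile(filename="", mode="wb", fileobj=open(p, "wb"), mtime=0))
                if str(path).endswith(".gz")
                else (lambda p: open(p, "wb"))
            )
            with opener(path) as fh:
                for i, name in enumerate(self.names):
                    rec = f"@{name}/{mate}\n{decode(mat[i])}\n+\n{qual}\n"
                    fh.write(rec.encode())

    @classmethod
    def from_fastq(cls, path1, path2, sample_id: str = "sample") -> "SampleReads":
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        def _open(p):
            return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

        names, seqs1, seqs2 = [], [], []
        with _open(path1) as f1, _open(path2) as f2:
            for (n1, s1, _), (n2, s2, _) in zip(
                FastqGeneralIterator(f1), FastqGeneralIterator(f2)
            ):
                base1 = n1.split()[0].removesuffix("/1")
                names.append(base1)
                seqs1.append(s1)
                seqs2.append(s2)
        if not names:
            raise ReadSimulationError(f"no reads in {path1}")
        L = len(seqs1[0])
        r1 = np.vstack([encode(s) for s in seqs1])
        r2 = np.vstack([encode(s) for s in seqs2])
        return cls(sample_id, names, r1, r2, L)


def sample_molecules(
    community: Community, sample_id: str
) -> List[Tuple[str, str, float]]:
    """Source molecules for one sample: (molecule_id, sequence, weight).

    Weights are in cell-copy units relative to one cell of the dominant
    species, so ``depth * weight`` is the molecule's expected depth.
    """
    sf = community.species_fractions[sample_id]
    c0 = sf[community.species[0].species_id]
    mols: List[Tuple[str, str, float]] = []
    for sp in community.species:
        c = sf[sp.species_id] / c0
        host_phages = [
            p
            for p in community.phages
            if p.host_genome_id == sp.chromosome_id
            and p.integrated_by_sample.get(sample_id, 0.0) > 0
        ]
        if len(host_phages) > 1:
            raise ReadSimulationError("at most one integrating phage per host species")
        icf = host_phages[0].integrated_by_sample[sample_id] if host_phages else 0.0
        for st in sp.strains:
            f = st.abundance_by_sample[sample_id]
            if f <= 0:
                continue
            mols.append((st.lineage_id, community.strain_sequence(st.lineage_id), c * f * (1 - icf)))
            if icf > 0:
                p = host_phages[0]
                per_site = icf / len(p.att_sites)
                for att in p.att_sites:
                    mols.append(
                        (
                            f"{st.lineage_id}+{p.genome_id}@{att}",
                            community.lysogen_sequence(st.lineage_id, p, att),
                            c * f * per_site,
                        )
                    )
        for p in community.phages:
            if p.host_genome_id == sp.chromosome_id:
                free = p.copies_by_sample.get(sample_id, 0.0) - p.integrated_by_sample.get(
                    sample_id, 0.0
                )
                if free > 0:
                    mols.append(
                        (p.genome_id, community.genomes[p.genome_id].sequence, c * free)
                    )
        for pid in sp.plasmid_ids:
            pcn = community.plasmid_copy_number.get(pid, 1.0)
            if pcn > 0:
                mols.append((pid, community.genomes[pid].sequence, c * pcn))
    return mols


def molecule_source_replicon(community: Community, molecule_id: str) -> Optional[str]:
    """Reference replicon a molecule's reads should map to (None = chimeric)."""
    if "+" in molecule_id:
        return None  # lysogen recombinant: spans host and phage
    for sp in community.species:
        for st in sp.strains:
            if st.lineage_id == molecule_id:
                return sp.chromosome_id
    if molecule_id in community.genomes:
        return molecule_id
    raise KeyError(molecule_id)


def expected_depths(community: Community, sample_id: str, depth: float) -> Dict[str, float]:
    sf = community.species_fractions[sample_id]
    c0 = sf[community.species[0].species_id]
    out: Dict[str, float] = {}
    for sp in community.species:
        c = sf[sp.species_id] / c0
        out[sp.chromosome_id] = depth * c
        for pid in sp.plasmid_ids:
            out[pid] = depth * c * community.plasmid_copy_number.get(pid, 1.0)
    for p in community.phages:
        host_sp = next(
            sp for sp in community.species if sp.chromosome_id == p.host_genome_id
        )
        c = sf[host_sp.species_id] / c0
        out[p.genome_id] = out.get(p.genome_id, 0.0) + depth * c * p.copies_by_sample.get(
            sample_id, 0.0
        )
    return out


def simulate_sample(
    community: Community,
    sample_id: str,
    depth: float = 50.0,
    read_len: int = 100,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> SampleReads:
    """Simulate one sample's paired reads; records realized counts in truth."""
    if depth <= 0:
        raise ReadSimulationError("depth must be positive")
    if read_len < 50:
        raise ReadSimulationError("read_len must be >= 50")
    if insert_mean < read_len:
        raise ReadSimulationError("insert_mean must be >= read_len")
    if sample_id not in community.sample_ids:
        raise KeyError(sample_id)
    rng = np.random.default_rng(seed)
    mols = sample_molecules(community, sample_id)
    lens = np.array([len(seq) for _, seq, _ in mols], dtype=float)
    weights = np.array([w for _, _, w in mols], dtype=float)
    exp_frags = depth * weights * lens / (2.0 * read_len)
    total = int(round(exp_frags.sum()))
    counts = rng.multinomial(total, exp_frags / exp_frags.sum())

    names: List[str] = []
    r1_parts: List[np.ndarray] = []
    r2_parts: List[np.ndarray] = []
    serial = 0
    for (mol_id, seq, _), n in zip(mols, counts):
        if n == 0:
            continue
        enc = encode(seq)
        L = len(enc)
        frag = np.clip(
            np.round(rng.normal(insert_mean, insert_sd, size=n)).astype(int),
            read_len,
            L,
        )
        starts = (rng.random(n) * (L - frag + 1)).astype(int)
        idx = np.arange(read_len)
        m1 = enc[starts[:, None] + idx]
        ends = starts + frag
        m2 = (3 - enc[(ends - read_len)[:, None] + idx])[:, ::-1]
        if error_rate > 0:
            for m in (m1, m2):
                mask = rng.random(m.shape) < error_rate
                n_err = int(mask.sum())
                if n_err:
                    m[mask] = (m[mask] + rng.integers(1, 4, size=n_err)) % 4
        r1_parts.append(m1)
        r2_parts.append(m2)
        for j in range(n):
            names.append(f"{sample_id}.{serial}|{mol_id}|{starts[j]}|{frag[j]}")
            serial += 1
    community.realized_fragments.setdefault(sample_id, {})
    community.realized_fragments[sample_id] = {
        mol_id: int(n) for (mol_id, _, _), n in zip(mols, counts)
    }
    community.expected_depth[sample_id] = expected_depths(community, sample_id, depth)
    r1 = np.vstack(r1_parts) if r1_parts else np.empty((0, read_len), dtype=np.uint8)
    r2 = np.vstack(r2_parts) if r2_parts else np.empty((0, read_len), dtype=np.uint8)
    return SampleReads(sample_id, names, r1, r2, read_len)
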