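"""Read alignment, pileups, and coverage summaries.

The aligner is a k-mer-seed + ungapped-extension mapper: reads are seeded
against an exact k-mer index of the references and scored by full-length
mismatch count on each candidate diagonal.  This is sufficient for the
substitution-only error model of the simulator; the downstream estimators
only see the :class:`AlignmentRecord` contract, so any SAM-producing
aligner could stand in.

Multi-mapping tie-break: lowest edit distance, then forward strand, then
lexicographically smallest reference id, then leftmost position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dna import decode, encode, kmer_codes
from .simulate import SampleReads


class MappingError(ValueError):
    pass


@dataclass
class AlignmentRecord:
    read_id: str
    mate: int  # 1 or 2
    ref_id: str
    pos: int  # 0-based leftmost
    strand: str  # '+' or '-'
    aligned_length: int
    edit_distance: int
    mate_ref_id: Optional[str]
    mate_pos: Optional[int]
    primary_flag: bool = True


class _RefIndex:
    """Concatenated references with a sorted exact k-mer index.

    Global coordinates index into the concatenation of the (sorted)
    reference sequences; k-mers never span a reference boundary.
    """

    def __init__(self, references: Dict[str, str], k: int):
        if not references:
            raise MappingError("empty reference set")
        self.k = k
        self.ref_ids = sorted(references)
        self.seqs = [encode(references[r]) for r in self.ref_ids]
        self.lens = [len(s) for s in self.seqs]
        self.starts = np.concatenate(([0], np.cumsum(self.lens))).astype(np.int64)
        self.cat = np.concatenate(self.seqs)
        kms = []
        gpos = []
        for ri, codes in enumerate(self.seqs):
            km = kmer_codes(codes, k)
            kms.append(km)
            gpos.append(np.arange(len(km), dtype=np.int64) + self.starts[ri])
        all_k = np.concatenate(kms)
        all_p = np.concatenate(gpos)
        order = np.argsort(all_k, kind="stable")
        self.sorted_kmers = all_k[order]
        self.sorted_gpos = all_p[order]

    def ref_of(self, g: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.starts, g, side="right") - 1


def _expand_hits(lo, hi, read_idx):
    """Vectorized range expansion: (flat index into sorted_gpos, read index)."""
    cnt = hi - lo
    nz = np.nonzero(cnt)[0]
    cnz = cnt[nz]
    total = int(cnz.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    csum = np.concatenate(([0], np.cumsum(cnz)[:-1]))
    flat = np.arange(total, dtype=np.int64) - np.repeat(csum, cnz) + np.repeat(lo[nz], cnz)
    return flat, np.repeat(read_idx[nz], cnz)


def _align_matrix(
    reads: np.ndarray, idx: _RefIndex, min_identity: float, seed_step: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align each row; returns (ref_idx, pos, strand, nm); ref_idx=-1 unaligned."""
    n, L = reads.shape
    k = idx.k
    max_mm = int(np.floor(L * (1.0 - min_identity)))
    out_ref = np.full(n, -1, dtype=np.int32)
    out_pos = np.zeros(n, dtype=np.int32)
    out_strand = np.zeros(n, dtype=np.int8)  # 0='+', 1='-'
    out_nm = np.zeros(n, dtype=np.int32)
    if n == 0:
        return out_ref, out_pos, out_strand, out_nm

    fwd = reads
    rev = (3 - reads)[:, ::-1]
    offsets = [0, (L - k) // 2, L - k]
    all_read, all_strand, all_g = [], [], []
    ridx = np.arange(n, dtype=np.int64)
    for strand, mat in ((0, fwd), (1, rev)):
        for off in offsets:
            km = np.zeros(n, dtype=np.int64)
            for j in range(k):
                km = km * 4 + mat[:, off + j]
            lo = np.searchsorted(idx.sorted_kmers, km, side="left")
            hi = np.searchsorted(idx.sorted_kmers, km, side="right")
            flat, rid = _expand_hits(lo, hi, ridx)
            if len(flat) == 0:
                continue
            g = idx.sorted_gpos[flat] - off
            all_read.append(rid)
            all_strand.append(np.full(len(rid), strand, dtype=np.int8))
            all_g.append(g)

    hit_reads = np.zeros(n, dtype=bool)
    if all_read:
        c_read = np.concatenate(all_read)
        c_strand = np.concatenate(all_strand)
        c_g = np.concatenate(all_g)
        # validity: candidate window fully inside one reference
        ref_idx = idx.ref_of(np.clip(c_g, 0, idx.starts[-1] - 1))
        valid = (
            (c_g >= 0)
            & (c_g >= idx.starts[ref_idx])
            & (c_g + L <= idx.starts[ref_idx + 1])
        )
        c_read, c_strand, c_g, ref_idx = (
            c_read[valid], c_strand[valid], c_g[valid], ref_idx[valid]
        )
        # dedup (read, strand, diagonal)
        key = (c_read * 2 + c_strand) * idx.starts[-1] + c_g
        _, uniq = np.unique(key, return_index=True)
        c_read, c_strand, c_g, ref_idx = (
            c_read[uniq], c_strand[uniq], c_g[uniq], ref_idx[uniq]
        )
        # mismatch counts, chunked
        nm = np.empty(len(c_read), dtype=np.int32)
        span = np.arange(L)
        chunk = max(1, 200_000 // max(L, 1) * 16)
        for s in range(0, len(c_read), chunk):
            e = min(s + chunk, len(c_read))
            q = np.where(
                (c_strand[s:e] == 0)[:, None], fwd[c_read[s:e]], rev[c_read[s:e]]
            )
            refmat = idx.cat[c_g[s:e, None] + span]
            nm[s:e] = (refmat != q).sum(axis=1)
        ok = nm <= max_mm
        c_read, c_strand, c_g, ref_idx, nm = (
            c_read[ok], c_strand[ok], c_g[ok], ref_idx[ok], nm[ok]
        )
        if len(c_read):
            # best per read: lowest nm, then '+' strand, then smallest global
            # position (= lexicographic ref_id, then leftmost pos)
            order = np.lexsort((c_g, c_strand, nm, c_read))
            first = np.concatenate(
                ([True], c_read[order][1:] != c_read[order][:-1])
            )
            sel = order[first]
            rr = c_read[sel]
            out_ref[rr] = ref_idx[sel].astype(np.int32)
            out_pos[rr] = (c_g[sel] - idx.starts[ref_idx[sel]]).astype(np.int32)
            out_strand[rr] = c_strand[sel]
            out_nm[rr] = nm[sel]
            hit_reads[rr] = True

    # sparse fallback: scan additional seed offsets for still-unplaced reads
    misses = np.nonzero(~hit_reads)[0]
    for i in misses:
        best = (max_mm + 1, 0, 0)  # nm, strand, g
        for strand, q in ((0, fwd[i]), (1, rev[i])):
            kms = kmer_codes(q, k)
            for off in range(0, L - k + 1, seed_step):
                km = int(kms[off])
                lo = int(np.searchsorted(idx.sorted_kmers, km, side="left"))
                hi = int(np.searchsorted(idx.sorted_kmers, km, side="right"))
                for j in range(lo, hi):
                    g = int(idx.sorted_gpos[j]) - off
                    ri = int(idx.ref_of(np.array([max(g, 0)]))[0])
                    if g < idx.starts[ri] or g + L > idx.starts[ri + 1]:
                        continue
                    nm_v = int(np.count_nonzero(idx.cat[g : g + L] != q))
                    cand = (nm_v, strand, g)
                    if cand < best:
                        best = cand
        if best[0] <= max_mm:
            g = best[2]
            ri = int(idx.ref_of(np.array([g]))[0])
            out_ref[i] = ri
            out_pos[i] = g - int(idx.starts[ri])
            out_strand[i] = best[1]
            out_nm[i] = best[0]
    return out_ref, out_pos, out_strand, out_nm


class AlignmentSet:
    """Alignments of a paired read set against a reference collection."""

    def __init__(
        self,
        reads: SampleReads,
        references: Dict[str, str],
        min_identity: float = 0.9,
        k: int = 21,
        seed_step: int = 7,
    ):
        self.reads = reads
        self.references = dict(references)
        self.min_identity = min_identity
        self._index = _RefIndex(self.references, k)
        self.ref_ids = self._index.ref_ids
        self.ref1, self.pos1, self.strand1, self.nm1 = _align_matrix(
            reads.r1, self._index, min_identity, seed_step
        )
        self.ref2, self.pos2, self.strand2, self.nm2 = _align_matrix(
            reads.r2, self._index, min_identity, seed_step
        )
        self._pileups: Dict[str, np.ndarray] = {}

    @property
    def read_len(self) -> int:
        return self.reads.read_len

    def __len__(self) -> int:
        return len(self.reads)

    def ref_length(self, ref_id: str) -> int:
        try:
            return self._index.lens[self.ref_ids.index(ref_id)]
        except ValueError:
            raise MappingError(f"unknown reference {ref_id!r}") from None

    def unaligned_reads(self) -> List[Tuple[str, int]]:
        out = []
        for mate, refs in ((1, self.ref1), (2, self.ref2)):
            for i in np.nonzero(refs < 0)[0]:
                out.append((self.reads.names[i], mate))
        return out

    def records(self) -> Iterator[AlignmentRecord]:
        names = self.reads.names
        for i in range(len(names)):
            for mate, (refs, poss, strands, nms) in (
                (1, (self.ref1, self.pos1, self.strand1, self.nm1)),
                (2, (self.ref2, self.pos2, self.strand2, self.nm2)),
            ):
                if refs[i] < 0:
                    continue
                other = (self.ref2, self.pos2) if mate == 1 else (self.ref1, self.pos1)
                mref = self.ref_ids[other[0][i]] if other[0][i] >= 0 else None
                mpos = int(other[1][i]) if other[0][i] >= 0 else None
                yield AlignmentRecord(
                    names[i],
                    mate,
                    self.ref_ids[refs[i]],
                    int(poss[i]),
                    "+" if strands[i] == 0 else "-",
                    self.read_len,
                    int(nms[i]),
                    mref,
                    mpos,
                    True,
                )

    # -- pileup / coverage -------------------------------------------------
    def pileup_counts(self, ref_id: str) -> np.ndarray:
        """(ref_len, 4) base counts; depth at a column is the row sum."""
        if ref_id in self._pileups:
            return self._pileups[ref_id]
        ri = self.ref_ids.index(ref_id) if ref_id in self.ref_ids else None
        if ri is None:
            raise MappingError(f"unknown reference {ref_id!r}")
        L = self._index.lens[ri]
        R = self.read_len
        counts = np.zeros(L * 4, dtype=np.int64)
        idx = np.arange(R)
        for mat, refs, poss, strands in (
            (self.reads.r1, self.ref1, self.pos1, self.strand1),
            (self.reads.r2, self.ref2, self.pos2, self.strand2),
        ):
            sel = np.nonzero(refs == ri)[0]
            for chunk in np.array_split(sel, max(1, len(sel) // 2000)):
                if len(chunk) == 0:
                    continue
                rows = mat[chunk].astype(np.int64)
                rev = strands[chunk] == 1
                if rev.any():
                    rows[rev] = (3 - rows[rev])[:, ::-1]
                flat = (poss[chunk][:, None] + idx) * 4 + rows
                valid = rows < 4
                counts += np.bincount(flat[valid].ravel(), minlength=L * 4)
        result = counts.reshape(L, 4)
        self._pileups[ref_id] = result
        return result

    def coverage_stats(self, ref_id: str) -> Dict[str, float]:
        counts = self.pileup_counts(ref_id)
        depth = counts.sum(axis=1)
        if depth.sum() == 0:
            return {"mean_depth": 0.0, "median_depth": 0.0, "breadth": 0.0}
        return {
            "mean_depth": float(depth.mean()),
            "median_depth": float(np.median(depth)),
            "breadth": float(np.mean(depth >= 1)),
        }

    # -- export ------------------------------------------------------------
    def write_sam(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for rid in self.ref_ids:
                fh.write(f"@SQ\tSN:{rid}\tLN:{self.ref_length(rid)}\n")
            R = self.read_len
            for i, name in enumerate(self.reads.names):
                for mate, refs, poss, strands, nms, mat in (
                    (1, self.ref1, self.pos1, self.strand1, self.nm1, self.reads.r1),
                    (2, self.ref2, self.pos2, self.strand2, self.nm2, self.reads.r2),
                ):
                    flag = 0x1 | (0x40 if mate == 1 else 0x80)
                    if refs[i] < 0:
                        flag |= 0x4
                        fh.write(
                            f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t"
                            f"{decode(mat[i])}\t{'I' * R}\n"
                        )
                        continue
                    if strands[i] == 1:
                        flag |= 0x10
                    seq = decode(mat[i] if strands[i] == 0 else (3 - mat[i])[::-1])
                    fh.write(
                        f"{name}\t{flag}\t{self.ref_ids[refs[i]]}\t{poss[i] + 1}\t60\t"
                        f"{R}M\t*\t0\t0\t{seq}\t{'I' * R}\tNM:i:{nms[i]}\n"
                    )


def align_reads(
    reads: Union[SampleReads, Tuple[str, str]],
    references: Union[Dict[str, str], Sequence[Tuple[str, str]], str],
    min_identity: float = 0.9,
    k: int = 21,
) -> AlignmentSet:
    """Align paired reads against references; see module tie-break rules."""
    if isinstance(reads, tuple):
        reads = SampleReads.from_fastq(*reads)
    if isinstance(references, str):
        from .io import read_fasta

        references = read_fasta(references)
    elif not isinstance(references, dict):
        references = dict(references)
    return AlignmentSet(reads, references, min_identity=min_identity, k=k)


@dataclass
class PileupColumn:
    ref_id: str
    pos: int
    depth: int
    base_counts: Dict[str, int]


def pileup(alignments: AlignmentSet, ref_id: str) -> List[PileupColumn]:
    """Materialized per-column pileup (convenience view over the counts)."""
    counts = alignments.pileup_counts(ref_id)
    cols = []
    for pos in np.nonzero(counts.sum(axis=1))[0]:
        row = counts[pos]
        cols.append(
            PileupColumn(
                ref_id,
                int(pos),
                int(row.sum()),
                {b: int(row[i]) for i, b in enumerate("ACGT")},
            )
        )
    return cols


def coverage_stats(alignments: AlignmentSet, ref_id: str) -> Dict[str, float]:
    return alignments.coverage_stats(ref_id)
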