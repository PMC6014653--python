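"""FASTQ-to-consensus pipeline for a small circular genome.

Stages mirror a standard ancient-DNA mitochondrial workflow: paired reads
are adapter-trimmed and collapsed into merged fragments (quality >= 25
terminal trimming, minimum length 35), mapped to the circular reference by
k-mer seeding plus alignment extension, filtered to mapping quality >= 20,
PCR-deduplicated by alignment coordinates, piled up counting only bases with
Phred >= 30, and consensus-called with masking of low-depth (< 3) and
high-mismatch (> 30%) sites.

The mapper is deliberately simple: a unique best-scoring locus earns mapping
quality 37, tied loci 0, so that only the interaction with the ">= 20"
retention filter matters.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import ValidationError
from .mito import MitoReference, VariantToken, diff_to_reference, revcomp

log = logging.getLogger(__name__)

ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP_GAP = str.maketrans("ACGTN-", "TGCAN-")
_CIGAR_RE = __import__("re").compile(r"(\d+)([=XID])")


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities.

    ``trim5``/``trim3`` record how many bases quality/N-trimming removed
    from each end of a merged fragment; a trimmed terminus no longer exposes
    the molecular fragment end, which matters for damage statistics.
    """

    name: str
    sequence: str
    quality: np.ndarray  # Phred, uint8
    trim5: int = 0
    trim3: int = 0

    def __post_init__(self):
        self.quality = np.asarray(self.quality, dtype=np.uint8)
        if len(self.sequence) != len(self.quality):
            raise ValidationError(f"read {self.name}: |sequence| != |quality|")

    def __len__(self):
        return len(self.sequence)


def read_fastq(path) -> list[ReadRecord]:
    """Plain (Phred+33) FASTQ reader."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append(ReadRecord(name=header[1:].split()[0], sequence=seq,
                                  quality=np.frombuffer(qual.encode(), dtype=np.uint8) - 33))
    return out


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n"
                     f"{(r.quality + 33).tobytes().decode()}\n")


# ---------------------------------------------------------------------------
# trim + merge


def _overlap_candidates(q1: str, q2rc: str, seed: int = 12) -> set[int]:
    shifts = set()
    for off in range(0, max(1, len(q2rc) - seed + 1), 8):
        probe = q2rc[off:off + seed]
        start = 0
        while True:
            i = q1.find(probe, start)
            if i < 0:
                break
            shifts.add(i - off)
            start = i + 1
    for off in range(0, max(1, len(q1) - seed + 1), 8):
        probe = q1[off:off + seed]
        start = 0
        while True:
            i = q2rc.find(probe, start)
            if i < 0:
                break
            shifts.add(off - i)
            start = i + 1
    return shifts


def trim_merge(pairs: list[tuple[ReadRecord, ReadRecord]], *,
               min_quality: int = 25, min_length: int = 35,
               min_overlap: int = 11) -> list[ReadRecord]:
    """Collapse overlapping mate pairs into merged fragments.

    The mate overlap is located by shared 12-mers and scored by matches minus
    mismatches; adapter read-through (fragments shorter than the read length)
    falls out naturally because only the overlap consensus is kept when the
    implied fragment is shorter than the reads. At conflicting positions the
    higher-quality base wins with quality ``|q1 - q2|``; at agreeing
    positions the larger quality is kept. Terminal Ns and bases below
    ``min_quality`` are then trimmed, and merged reads shorter than
    ``min_length`` are discarded.
    """
    merged: list[ReadRecord] = []
    for r1, r2 in pairs:
        if r1.name.split("/")[0] != r2.name.split("/")[0]:
            raise ValidationError(f"mate ID mismatch: {r1.name} vs {r2.name}")
        q1, q2rc = r1.sequence, revcomp(r2.sequence)
        qual1, qual2 = r1.quality, r2.quality[::-1]
        n1, n2 = len(q1), len(q2rc)

        best, best_score = None, -1
        for s in _overlap_candidates(q1, q2rc):
            lo, hi = max(0, s), min(n1, n2 + s)
            ov = hi - lo
            if ov < min_overlap:
                continue
            a = np.frombuffer(q1[lo:hi].encode(), dtype=np.uint8)
            b = np.frombuffer(q2rc[lo - s:hi - s].encode(), dtype=np.uint8)
            m = int(np.sum(a == b))
            score = 2 * m - ov  # matches - mismatches
            if m < 0.75 * ov:
                continue
            if score > best_score:
                best_score, best = score, s
        if best is None:
            continue
        s = best
        lo, hi = max(0, s), min(n1, n2 + s)
        a = np.frombuffer(q1[lo:hi].encode(), dtype=np.uint8)
        b = np.frombuffer(q2rc[lo - s:hi - s].encode(), dtype=np.uint8)
        qa, qb = qual1[lo:hi].astype(np.int16), qual2[lo - s:hi - s].astype(np.int16)
        take_a = (a == b) | (qa >= qb)
        cons = np.where(take_a, a, b)
        qcons = np.where(a == b, np.maximum(qa, qb), np.maximum(np.abs(qa - qb), 2))

        seq = q1[:lo] + cons.tobytes().decode() + (q2rc[hi - s:] if n2 + s > n1 else "")
        qual = np.concatenate([qual1[:lo].astype(np.int16), qcons,
                               qual2[hi - s:].astype(np.int16) if n2 + s > n1
                               else np.empty(0, dtype=np.int16)])
        # terminal trimming of Ns and low-quality bases
        keep = np.array([c != "N" for c in seq]) & (qual >= min_quality)
        nz = np.flatnonzero(keep)
        if nz.size == 0:
            continue
        t5, t3 = int(nz[0]), int(len(seq) - 1 - nz[-1])
        seq = seq[nz[0]:nz[-1] + 1]
        qual = np.clip(qual[nz[0]:nz[-1] + 1], 0, 93)
        if len(seq) < min_length:
            continue
        merged.append(ReadRecord(name=r1.name.split("/")[0], sequence=seq,
                                 quality=qual.astype(np.uint8),
                                 trim5=t5, trim3=t3))
    return merged


# ---------------------------------------------------------------------------
# mapping


@dataclass
class AlignedRead:
    """A merged read aligned to the circular reference.

    ``refpos``/``refbase`` are stored in read orientation (index 0 is the
    read's 5' end as sequenced): ``refpos[i]`` is the 1-based, circularly
    unwrapped reference coordinate under read base ``i`` (0 for inserted
    bases) and ``refbase[i]`` the reference base complemented into read
    orientation ('-' for insertions).
    """

    name: str
    sequence: str
    quality: np.ndarray
    start: int          # 1-based; may exceed reference length before wrapping
    end: int            # 1-based inclusive, unwrapped (start <= end)
    strand: str         # '+' or '-'
    mapq: int
    refpos: np.ndarray
    refbase: str
    deletions: list[tuple[int, str]] = field(default_factory=list)
    trim5: int = 0      # merged-read terminal trimming (read orientation)
    trim3: int = 0

    def __len__(self):
        return len(self.sequence)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class _RefIndex:
    def __init__(self, ref: MitoReference, k: int, max_read: int = 600):
        self.k = k
        self.L = len(ref)
        self.ext = ref.sequence + ref.sequence[:max_read + k]
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(self.L):
            index[self.ext[i:i + k]].append(i)
        self.index = index


_INDEX_CACHE: dict[tuple[str, int], _RefIndex] = {}


def _ref_index(ref: MitoReference, k: int) -> _RefIndex:
    key = (ref.name + str(len(ref)), k)
    if key not in _INDEX_CACHE:
        _INDEX_CACHE[key] = _RefIndex(ref, k)
    return _INDEX_CACHE[key]


def _affine_score(cigar: str) -> int:
    score = 0
    for count, op in _CIGAR_RE.findall(cigar):
        c = int(count)
        if op == "=":
            score += c
        elif op == "X":
            score -= c
        else:  # gap: open -2, extend -1
            score -= 2 + (c - 1)
    return score


def map_reads(reads: list[ReadRecord], ref: MitoReference, *, k: int = 13,
              pad: int = 8) -> list[AlignedRead]:
    """Map merged reads to the circular reference.

    Exact k-mer seeds on the doubled reference propose candidate loci on both
    strands; each candidate is extended by alignment and scored (+1 match,
    -1 mismatch, -2 gap open, -1 gap extend). A unique best locus gets
    mapping quality 37; ties get 0; unmapped reads are dropped (counted via
    the logger).
    """
    ridx = _ref_index(ref, k)
    L = ridx.L
    out: list[AlignedRead] = []
    unmapped = 0
    for read in reads:
        n = len(read)
        if n < k:
            unmapped += 1
            continue
        oriented = {"+": read.sequence, "-": revcomp(read.sequence)}
        candidates: set[tuple[int, str]] = set()
        # dense seeding so reads with several scattered mismatches (damage at
        # both termini plus interior errors) still propose their true locus
        offsets = set(range(0, n - k + 1, 7)) | {n - k}
        for strand, seq in oriented.items():
            for off in offsets:
                for p in ridx.index.get(seq[off:off + k], ()):
                    candidates.add(((p - off) % L, strand))
        if not candidates:
            unmapped += 1
            continue
        scored = []
        for cstart, strand in candidates:
            seq = oriented[strand]
            wlo = cstart - pad if cstart - pad >= 0 else 0
            window = ridx.ext[wlo:cstart + n + pad]
            res = edlib.align(seq, window, task="path", mode="HW")
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            score = _affine_score(res["cigar"])
            scored.append((score, wlo + loc[0], strand, res["cigar"]))
        if not scored:
            unmapped += 1
            continue
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        best = scored[0]
        mapq = 37 if (len(scored) == 1 or scored[1][0] < best[0]) else 0
        out.append(_build_aligned(read, best, ridx, L, mapq))
    if unmapped:
        log.info("map_reads: %d reads unmapped", unmapped)
    return out


def _normalize_terminal_gaps(ops: list[tuple[int, str]], astart: int,
                             zone: int = 3) -> int:
    """Rewrite gaps at read termini as substitutions (in place).

    Edit-distance alignment ties terminal substitutions with terminal
    indels, which would strip the reference context off exactly the bases
    where the deamination signal lives; like common read mappers we
    disallow gaps within ``zone`` bases of either read end and realign
    those bases against the flanking reference. Returns the adjusted
    alignment start.
    """
    if len(ops) > 1 and ops[0][1] == "I" and astart >= ops[0][0]:
        astart -= ops[0][0]
        ops[0] = (ops[0][0], "X")
    if len(ops) > 1 and ops[-1][1] == "I":
        ops[-1] = (ops[-1][0], "X")
    if len(ops) > 2 and ops[0][1] in "=X" and ops[0][0] <= zone:
        a, b = ops[0][0], ops[1][0]
        if ops[1][1] == "D":
            astart += b
            del ops[1]
            ops[0] = (a, "X")
        elif ops[1][1] == "I" and astart >= b:
            astart -= b
            del ops[1]
            ops[0] = (a + b, "X")
    if len(ops) > 2 and ops[-1][1] in "=X" and ops[-1][0] <= zone:
        a, b = ops[-1][0], ops[-2][0]
        if ops[-2][1] == "D":
            del ops[-2]
            ops[-1] = (a, "X")
        elif ops[-2][1] == "I":
            del ops[-2]
            ops[-1] = (a + b, "X")
    return astart


def _build_aligned(read: ReadRecord, best, ridx: _RefIndex, L: int,
                   mapq: int) -> AlignedRead:
    _, astart, strand, cigar = best
    seq = read.sequence if strand == "+" else revcomp(read.sequence)
    refpos = np.zeros(len(seq), dtype=np.int64)
    refbases = []
    deletions: list[tuple[int, str]] = []
    ops = [(int(c), op) for c, op in _CIGAR_RE.findall(cigar)]
    astart = _normalize_terminal_gaps(ops, astart)
    gi, ri = 0, astart  # ri is 0-based on extended reference
    for c, op in ops:
        if op in "=X":
            for t in range(c):
                refpos[gi + t] = ri + t + 1
                refbases.append(ridx.ext[ri + t])
            gi += c
            ri += c
        elif op == "I":
            for t in range(c):
                refpos[gi + t] = 0
                refbases.append("-")
            gi += c
        elif op == "D":
            deletions.append((ri, ridx.ext[ri:ri + c]))
            ri += c
    refbase = "".join(refbases)
    start, end = astart + 1, ri  # 1-based inclusive
    if strand == "-":
        # convert to read orientation (read 5' first)
        refpos = refpos[::-1].copy()
        refbase = refbase.translate(_COMP_GAP)[::-1]
    return AlignedRead(name=read.name, sequence=read.sequence, quality=read.quality,
                       start=start, end=end, strand=strand, mapq=mapq,
                       refpos=refpos, refbase=refbase, deletions=deletions,
                       trim5=read.trim5, trim3=read.trim3)


# ---------------------------------------------------------------------------
# filtering, pileup, consensus


def filter_and_dedup(aligned: list[AlignedRead], *, min_mapq: int = 20) -> list[AlignedRead]:
    """Drop mapq < ``min_mapq``; keep one read per (start, end, strand),
    preferring the highest summed base quality (PCR-duplicate removal)."""
    kept: dict[tuple[int, int, str], AlignedRead] = {}
    for r in aligned:
        if r.mapq < min_mapq:
            continue
        key = (r.start, r.end, r.strand)
        prev = kept.get(key)
        if prev is None or int(r.quality.sum()) > int(prev.quality.sum()):
            kept[key] = r
    return [kept[k] for k in sorted(kept)]


@dataclass
class Pileup:
    """Per-position base counts after the base-quality filter."""

    ref_length: int
    counts: np.ndarray                       # (L, 4) A/C/G/T
    insertions: dict[int, Counter] = field(default_factory=dict)  # anchor pos -> seqs
    del_support: np.ndarray | None = None    # (L,) reads deleting this position
    min_base_quality: int = 30

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_pileup(aligned: list[AlignedRead], ref: MitoReference, *,
                 min_base_quality: int = 30) -> Pileup:
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int64)
    del_support = np.zeros(L, dtype=np.int64)
    insertions: dict[int, Counter] = defaultdict(Counter)
    for r in aligned:
        seq = r.sequence if r.strand == "+" else r.sequence.translate(_COMP_GAP)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        base_idx = np.full(len(codes), -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            base_idx[codes == ord(b)] = i
        ok = (r.quality >= min_base_quality) & (r.refpos > 0) & (base_idx >= 0)
        pos = (r.refpos[ok] - 1) % L
        np.add.at(counts, (pos, base_idx[ok]), 1)
        for ri0, seq in r.deletions:
            del_support[np.arange(ri0, ri0 + len(seq)) % L] += 1
        # inserted read bases: anchor on the preceding aligned reference base
        ins_mask = (r.refpos == 0)
        if ins_mask.any():
            i = 0
            n = len(r.sequence)
            while i < n:
                if ins_mask[i]:
                    j = i
                    while j < n and ins_mask[j]:
                        j += 1
                    if r.strand == "+":
                        if i > 0 and r.refpos[i - 1] > 0:
                            anchor = int((r.refpos[i - 1] - 1) % L) + 1
                            insertions[anchor][r.sequence[i:j]] += 1
                    else:
                        # read coords descend along the reference: the anchor
                        # (preceding ref base) is the next aligned read base
                        if j < n and r.refpos[j] > 0:
                            anchor = int((r.refpos[j] - 1) % L) + 1
                            insertions[anchor][revcomp(r.sequence[i:j])] += 1
                    i = j
                else:
                    i += 1
    return Pileup(ref_length=L, counts=counts, insertions=dict(insertions),
                  del_support=del_support, min_base_quality=min_base_quality)


@dataclass
class ConsensusSequence:
    """Called base (or 'N') per reference position, plus indel calls."""

    bases: np.ndarray            # unicode array: A/C/G/T, 'N' masked, '' deleted
    depth: np.ndarray
    majority_frac: np.ndarray
    insertions: dict[int, str] = field(default_factory=dict)  # anchor -> inserted seq

    def masked_positions(self) -> np.ndarray:
        return np.flatnonzero(self.bases == "N") + 1

    def sequence(self) -> str:
        """Linear consensus with masks; deletions removed, insertions added."""
        parts = []
        for i, b in enumerate(self.bases):
            parts.append(b)
            ins = self.insertions.get(i + 1)
            if ins:
                parts.append(ins)
        return "".join(parts)


def call_consensus(pileup: Pileup, *, min_depth: int = 3,
                   max_mismatch: float = 0.30) -> ConsensusSequence:
    """Majority base where depth >= ``min_depth`` and the non-majority
    fraction does not exceed ``max_mismatch`` (a site at exactly the
    threshold is still called); 'N' otherwise. Indels are called when
    supported by >= 50% of covering reads at depth >= ``min_depth``."""
    counts = pileup.counts
    depth = counts.sum(axis=1)
    maj_idx = counts.argmax(axis=1)
    maj = counts.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, maj / np.maximum(depth, 1), 0.0)
    letters = np.array(list("ACGT"))
    bases = letters[maj_idx].astype(object)
    masked = (depth < min_depth) | ((1.0 - frac) > max_mismatch + 1e-12)
    bases[masked] = "N"
    # deletions: reads deleting the position dominate reads showing a base
    if pileup.del_support is not None:
        total = depth + pileup.del_support
        dele = (pileup.del_support >= min_depth) & (pileup.del_support >= 0.5 * total)
        bases[dele] = ""
    insertions = {}
    for anchor, ctr in pileup.insertions.items():
        seg, n = ctr.most_common(1)[0]
        if n >= min_depth and anchor <= len(depth) and n >= 0.5 * depth[anchor - 1]:
            insertions[anchor] = seg
    return ConsensusSequence(bases=bases.astype(str), depth=depth,
                             majority_frac=frac, insertions=insertions)


@dataclass
class CoverageStats:
    breadth_pct: float   # % of reference positions with depth >= 1
    mean_depth: float

    def __str__(self):
        return f"coverage {self.breadth_pct:.2f}%, depth {self.mean_depth:.1f}x"


def coverage_stats(pileup: Pileup, ref: MitoReference) -> CoverageStats:
    depth = pileup.depth()
    breadth = 100.0 * float((depth >= 1).sum()) / len(ref)
    return CoverageStats(breadth_pct=round(breadth, 2),
                         mean_depth=round(float(depth.sum()) / len(ref), 1))


def rescue_masked_diagnostics(variants, consensus: ConsensusSequence,
                              pileup: Pileup, tree) -> list:
    """Re-identify haplogroup-diagnostic SNPs lost to masking.

    A diagnostic site masked for low depth still usually shows the derived
    allele in the few reads that do cover it; this mirrors the manual rescue
    step of re-reading such sites. For every haplotree defining SNP whose
    position is masked but whose pileup majority equals the derived allele
    (depth >= 1), the variant is appended. Non-diagnostic masked sites stay
    masked.
    """
    letters = "ACGT"
    have = {str(v) for v in variants}
    masked = set(int(p) for p in consensus.masked_positions())
    out = list(variants)
    for node in tree.nodes.values():
        for tok in node.variants:
            if len(tok.ref) != 1 or len(tok.alt) != 1:
                continue
            if tok.pos not in masked or str(tok) in have:
                continue
            row = pileup.counts[tok.pos - 1]
            if row.sum() >= 1 and letters[int(row.argmax())] == tok.alt:
                out.append(tok)
                have.add(str(tok))
    return sorted(out, key=lambda t: t.pos)


def consensus_to_variants(consensus: ConsensusSequence,
                          ref: MitoReference) -> list[VariantToken]:
    """Variant tokens at called (non-'N') positions differing from the
    reference; masked positions never yield tokens (see
    :meth:`ConsensusSequence.masked_positions`). Normalisation is delegated
    to the alignment diff: masked sites are substituted with the reference
    base before diffing so they stay silent."""
    bases = consensus.bases.copy()
    refarr = np.array(list(ref.sequence))
    bases[bases == "N"] = refarr[bases == "N"]
    parts = []
    for i, b in enumerate(bases):
        parts.append(b)
        ins = consensus.insertions.get(i + 1)
        if ins:
            parts.append(ins)
    genome = "".join(parts)
    return diff_to_reference(genome, ref)
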