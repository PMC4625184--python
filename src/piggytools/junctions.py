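"""From paired reads to base-pair-resolved transposon-genome junctions.

The chain mirrors an amplicon integration-site pipeline at desk scale:
quality-trim (Q>20 running-sum rule), exclude adapter-dimer pairs,
optionally collapse PCR duplicates, map against a hybrid reference
(genome contigs + the reporter plasmid contig) with exact k-mer seeding
and ungapped extension, and call a junction whenever a read partitions
into a plasmid-aligned part and a genome-aligned part.  Breakpoints are
then resolved to base-pair accuracy, assigning any junction microhomology
to the transposon side so a joint exactly at the ITR terminal GGG/CCC
motif reports ``transposon_offset == 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .reference import ReferenceSet, encode_bases, revcomp
from .simulate import ADAPTER_P5, ADAPTER_P7, ReadPair

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class MalformedReadError(ValueError):
    pass


@dataclass
class TrimReport:
    input_pairs: int = 0
    dimer_excluded: int = 0
    quality_trimmed_bases: int = 0
    surviving_pairs: int = 0
    deduplicated_pairs: int = 0


def _quality_cut(qual: np.ndarray, cutoff: int) -> int:
    """Length to keep after 3' quality trimming.

    Trims the suffix maximizing the running sum of (cutoff - q) computed
    from the 3' end (the cutadapt/BWA -q rule); among equal-sum suffixes
    the longest trim wins.
    """
    s = 0
    best = 0
    cut = len(qual)
    for i in range(len(qual) - 1, -1, -1):
        s += cutoff - int(qual[i])
        if s >= best and s > 0:
            best = s
            cut = i
    return cut


def _is_dimer(seq: str, dimer_ref: str, max_mismatch_frac: float = 0.10) -> bool:
    n = min(len(seq), len(dimer_ref))
    if n < 20:
        return False
    mism = sum(1 for a, b in zip(seq[:n], dimer_ref[:n]) if a != b)
    return mism <= max_mismatch_frac * n


def trim_and_filter(
    pairs: list[ReadPair],
    quality_cutoff: int = 20,
    adapters: tuple[str, str] = (ADAPTER_P7, ADAPTER_P5),
    dedup: bool = True,
) -> tuple[list[ReadPair], TrimReport]:
    """Quality-trim, drop adapter-dimer pairs, optionally deduplicate."""
    report = TrimReport(input_pairs=len(pairs))
    dimer_ref = adapters[0] + adapters[1]
    kept: list[ReadPair] = []
    for p in pairs:
        if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
            raise MalformedReadError(f"read {p.read_id}: seq/qual length mismatch")
        c1 = _quality_cut(p.qual1, quality_cutoff)
        c2 = _quality_cut(p.qual2, quality_cutoff)
        report.quality_trimmed_bases += (len(p.seq1) - c1) + (len(p.seq2) - c2)
        s1, s2 = p.seq1[:c1], p.seq2[:c2]
        if _is_dimer(s1, dimer_ref) or _is_dimer(s2, dimer_ref):
            report.dimer_excluded += 1
            continue
        kept.append(
            ReadPair(p.read_id, s1, s2, p.qual1[:c1], p.qual2[:c2], p.source, p.duplicate_of)
        )
    report.surviving_pairs = len(kept)
    if dedup:
        seen: dict[tuple[str, str], None] = {}
        unique: list[ReadPair] = []
        for p in kept:
            key = (p.seq1, p.seq2)
            if key in seen:
                continue
            seen[key] = None
            unique.append(p)
        kept = unique
    report.deduplicated_pairs = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# hybrid reference and k-mer index


class HybridReferenceError(ValueError):
    pass


def _kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer 2-bit encodings of a code array; -1 where a window has N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    v = codes.astype(np.int64)
    km = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        w = v[i : i + n]
        km = (km << 2) | np.where(w < 4, w, 0)
        bad |= w >= 4
    km[bad] = -1
    return km


class HybridReference:
    """Genome + plasmid contigs with a sorted k-mer position index."""

    def __init__(self, refset: ReferenceSet, plasmid_name: str, k: int = 21,
                 element_span: tuple[int, int] | None = None):
        self.refset = refset
        self.plasmid_name = plasmid_name
        self.k = k
        self.names = refset.names
        self.plasmid_idx = self.names.index(plasmid_name)
        plen = len(refset[plasmid_name])
        self.element_span = element_span if element_span is not None else (0, plen)
        self.codes = [encode_bases(refset[c]) for c in self.names]
        lengths = np.array([len(c) for c in self.codes], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        kmer_chunks = []
        pos_chunks = []
        for ci, codes in enumerate(self.codes):
            km = _kmer_ints(codes, k)
            kmer_chunks.append(km)
            pos_chunks.append(np.arange(len(km), dtype=np.int64) + self.offsets[ci])
        allk = np.concatenate(kmer_chunks) if kmer_chunks else np.empty(0, np.int64)
        allp = np.concatenate(pos_chunks) if pos_chunks else np.empty(0, np.int64)
        order = np.argsort(allk, kind="stable")
        self._sorted_kmers = allk[order]
        self._sorted_pos = allp[order]

    def __getitem__(self, name: str) -> str:
        return self.refset[name]

    def global_to_local(self, g: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.offsets, g, side="right")) - 1
        return ci, int(g - self.offsets[ci])

    def lookup(self, kmer: int, cap: int = 32) -> list[tuple[int, int]]:
        """(contig_idx, position) hits of one k-mer integer."""
        lo = int(np.searchsorted(self._sorted_kmers, kmer, side="left"))
        hi = int(np.searchsorted(self._sorted_kmers, kmer, side="right"))
        if hi - lo > cap:
            return []
        return [self.global_to_local(int(g)) for g in self._sorted_pos[lo:hi]]

    def locate(self, query: str) -> list[tuple[str, int]]:
        """Exact occurrences of ``query`` (len >= k) on the forward strands."""
        if len(query) < self.k:
            raise ValueError(f"query shorter than k={self.k}")
        codes = encode_bases(query)
        km = _kmer_ints(codes, self.k)
        if km.size == 0 or km[0] < 0:
            return []
        out = []
        for ci, pos in self.lookup(int(km[0]), cap=10_000):
            ref = self.refset[self.names[ci]]
            if ref[pos : pos + len(query)] == query:
                out.append((self.names[ci], pos))
        return out


def build_hybrid_reference(
    genome: ReferenceSet,
    plasmid: str,
    plasmid_name: str = "plasmid",
    k: int = 21,
    element_span: tuple[int, int] | None = None,
) -> HybridReference:
    """Append the plasmid contig to the genome and index everything.

    ``element_span`` locates the transposon element within the plasmid
    contig (0-based half-open); by default the whole plasmid is the
    element.
    """
    if not plasmid:
        raise HybridReferenceError("empty plasmid sequence")
    if plasmid_name in genome:
        raise HybridReferenceError(f"contig name clash: {plasmid_name!r}")
    hybrid = genome.with_contig(plasmid_name, plasmid)
    return HybridReference(hybrid, plasmid_name, k=k, element_span=element_span)


# ---------------------------------------------------------------------------
# split-read calling


@dataclass
class JunctionCall:
    """Per-read chimeric alignment evidence for one transposon-genome junction.

    ``genome_pos`` is the junction coordinate on the genome contig
    (forward strand); ``tsd_start`` the start of the 4-bp target sequence
    implied by the strand convention (both junctions of one TSD-flanked
    insertion report the same ``tsd_start``).
    """

    read_id: str
    contig: str
    genome_pos: int
    transposon_end: str  # 5prime | 3prime
    transposon_offset: int
    orientation: str
    target_tetra: str
    microhomology: int = 0
    support: str = "split_read"
    tsd_start: int = -1
    # geometry internals used by resolve_breakpoint
    plasmid_pos: int = -1
    plasmid_strand: str = "+"
    genome_strand: str = "+"
    plasmid_is_prefix: bool = True


@dataclass
class _Cand:
    contig_idx: int
    strand: str
    diag: int
    votes: int
    match: np.ndarray  # bool per read position


def _candidates(hybrid: HybridReference, R: str, step: int) -> list[_Cand]:
    L = len(R)
    k = hybrid.k
    out: dict[tuple[int, str, int], int] = {}
    strands = {"+": R, "-": revcomp(R)}
    kmers = {}
    for s, S in strands.items():
        km = _kmer_ints(encode_bases(S), k)
        kmers[s] = km
        if km.size == 0:
            continue
        idxs = list(range(0, len(km), step))
        if idxs[-1] != len(km) - 1:
            idxs.append(len(km) - 1)
        for i in idxs:
            v = int(km[i])
            if v < 0:
                continue
            for ci, pos in hybrid.lookup(v):
                key = (ci, s, pos - i)
                out[key] = out.get(key, 0) + 1
    cands: list[_Cand] = []
    for (ci, s, diag), votes in out.items():
        refc = hybrid.codes[ci]
        S = strands[s]
        sc = encode_bases(S)
        p = diag + np.arange(L)
        valid = (p >= 0) & (p < len(refc))
        pc = np.clip(p, 0, len(refc) - 1)
        m_s = valid & (refc[pc] == sc) & (sc < 4)
        m = m_s[::-1].copy() if s == "-" else m_s
        cands.append(_Cand(ci, s, diag, votes, m))
    # keep the strongest few per contig class to bound work
    cands.sort(key=lambda c: -int(c.match.sum()))
    plasmid = [c for c in cands if c.contig_idx == hybrid.plasmid_idx][:4]
    genome = [c for c in cands if c.contig_idx != hybrid.plasmid_idx][:4]
    return plasmid + genome


def _split_one(
    hybrid: HybridReference,
    read_id: str,
    R: str,
    min_anchor: int,
    max_mismatch_rate: float,
    step: int,
) -> JunctionCall | None:
    L = len(R)
    if L < 2 * min_anchor:
        return None
    cands = _candidates(hybrid, R, step)
    plasmid_cands = [c for c in cands if c.contig_idx == hybrid.plasmid_idx]
    genome_cands = [c for c in cands if c.contig_idx != hybrid.plasmid_idx]
    if not plasmid_cands or not genome_cands:
        return None

    cs = np.arange(min_anchor, L - min_anchor + 1)
    best = None  # (score, t_anchor, -gjunction, payload)
    for pc in plasmid_cands:
        cum_p = np.concatenate([[0], np.cumsum(pc.match)])
        for gc in genome_cands:
            cum_g = np.concatenate([[0], np.cumsum(gc.match)])
            for plasmid_first in (True, False):
                if plasmid_first:
                    pre_cum, suf_cum, pre, suf = cum_p, cum_g, pc, gc
                else:
                    pre_cum, suf_cum, pre, suf = cum_g, cum_p, gc, pc
                pref_m = pre_cum[cs]
                suff_m = suf_cum[L] - suf_cum[cs]
                pref_ok = (cs - pref_m) <= max_mismatch_rate * cs
                suff_ok = ((L - cs) - suff_m) <= max_mismatch_rate * (L - cs)
                ok = pref_ok & suff_ok
                if not ok.any():
                    continue
                score = np.where(ok, pref_m + suff_m, -1)
                smax = int(score.max())
                for ci_ in np.nonzero(score == smax)[0]:
                    c = int(cs[ci_])
                    t_anchor = c if plasmid_first else L - c
                    gj = gc.diag + c if gc.strand == "+" else gc.diag + (L - c)
                    key = (smax, t_anchor, -gj)
                    if best is None or key > best[0]:
                        best = (key, (pc, gc, plasmid_first, c, smax))
    if best is None:
        return None
    pc, gc, plasmid_first, c, score = best[1]
    jp = pc.diag + c if pc.strand == "+" else pc.diag + (L - c)
    jg = gc.diag + c if gc.strand == "+" else gc.diag + (L - c)
    pdir = -1 if (plasmid_first == (pc.strand == "+")) else 1
    gdir = -1 if ((not plasmid_first) == (gc.strand == "+")) else 1
    e0, e1 = hybrid.element_span
    if pdir == -1:
        end, terminus = "3prime", e1
    else:
        end, terminus = "5prime", e0
    orientation = "+" if (end == "5prime") == (gdir == -1) else "-"
    contig = hybrid.names[gc.contig_idx]
    gseq = hybrid.refset[contig]
    tsd_start = jg - 4 if gdir == -1 else jg
    tetra = gseq[tsd_start : tsd_start + 4] if 0 <= tsd_start <= len(gseq) - 4 else "NNNN"
    return JunctionCall(
        read_id=read_id,
        contig=contig,
        genome_pos=jg,
        transposon_end=end,
        transposon_offset=abs(jp - terminus),
        orientation=orientation,
        target_tetra=tetra,
        tsd_start=tsd_start,
        plasmid_pos=jp,
        plasmid_strand=pc.strand,
        genome_strand=gc.strand,
        plasmid_is_prefix=plasmid_first,
    )


def find_split_reads(
    pairs: list[ReadPair],
    hybrid: HybridReference,
    min_anchor: int = 20,
    max_mismatch_rate: float = 0.04,
    step: int = 7,
) -> list[JunctionCall]:
    """Chimeric plasmid/genome partitions of every mate.

    A mate yields a call iff it splits into a prefix and suffix (either
    order, either strand), one on the plasmid contig and one on a genomic
    contig, each at least ``min_anchor`` bases with mismatch rate at most
    ``max_mismatch_rate``; the partition maximizing total matches wins,
    ties broken by longer transposon anchor then leftmost genome position.
    Unmappable mates are dropped and counted in a log summary.
    """
    calls: list[JunctionCall] = []
    dropped = 0
    for p in pairs:
        for mate, seq in ((1, p.seq1), (2, p.seq2)):
            call = _split_one(hybrid, f"{p.read_id}/{mate}", seq, min_anchor, max_mismatch_rate, step)
            if call is None:
                dropped += 1
            else:
                calls.append(call)
    log.info("find_split_reads: %d calls, %d mates without a junction", len(calls), dropped)
    return calls


def _expected_base(ref: str, strand: str, jref: int, t: int) -> str | None:
    """Reference base a read would need at signed offset ``t`` from the junction."""
    if strand == "+":
        p = jref + t
        return ref[p] if 0 <= p < len(ref) else None
    p = jref - 1 - t
    return _COMP.get(ref[p]) if 0 <= p < len(ref) else None


def resolve_breakpoint(
    call: JunctionCall,
    hybrid: HybridReference,
    max_slide: int = 10,
) -> JunctionCall:
    """Canonical breakpoint placement under junction microhomology.

    Bases compatible with both references make the exact breakpoint
    ambiguous within a window; the window length is recorded as
    ``microhomology`` and the junction is placed so the transposon side
    is maximal with ``transposon_offset`` minimized (a joint at the ITR
    terminus reports offset 0).  Idempotent for unambiguous junctions.
    """
    if call.contig not in hybrid.refset:
        raise HybridReferenceError(f"unknown contig {call.contig!r}")
    pseq = hybrid.refset[hybrid.plasmid_name]
    gseq = hybrid.refset[call.contig]

    # prefix side = the side whose segment precedes the junction in the read
    if call.plasmid_is_prefix:
        pre = ("p", pseq, call.plasmid_strand, call.plasmid_pos)
        suf = ("g", gseq, call.genome_strand, call.genome_pos)
    else:
        pre = ("g", gseq, call.genome_strand, call.genome_pos)
        suf = ("p", pseq, call.plasmid_strand, call.plasmid_pos)

    def agree(t: int) -> bool:
        a = _expected_base(pre[1], pre[2], pre[3], t)
        b = _expected_base(suf[1], suf[2], suf[3], t)
        return a is not None and b is not None and a == b

    right = 0
    while right < max_slide and agree(right):
        right += 1
    left = 0
    while left < max_slide and agree(-1 - left):
        left += 1

    e0, e1 = hybrid.element_span
    terminus = e1 if call.transposon_end == "3prime" else e0
    p_sign = 1 if call.plasmid_strand == "+" else -1
    g_sign = 1 if call.genome_strand == "+" else -1
    gdir = -1 if ((not call.plasmid_is_prefix) == (call.genome_strand == "+")) else 1
    # transposon anchor grows with larger shift when the plasmid is the prefix
    shifts = range(-left, right + 1)
    def shift_key(s: int) -> tuple[int, int]:
        off = abs(call.plasmid_pos + p_sign * s - terminus)
        extent = s if call.plasmid_is_prefix else -s
        return (off, -extent)
    s_best = min(shifts, key=shift_key)

    jp = call.plasmid_pos + p_sign * s_best
    jg = call.genome_pos + g_sign * s_best
    tsd_start = jg - 4 if gdir == -1 else jg
    tetra = gseq[tsd_start : tsd_start + 4] if 0 <= tsd_start <= len(gseq) - 4 else "NNNN"
    return replace(
        call,
        genome_pos=jg,
        plasmid_pos=jp,
        transposon_offset=abs(jp - terminus),
        microhomology=left + right,
        tsd_start=tsd_start,
        target_tetra=tetra,
    )
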