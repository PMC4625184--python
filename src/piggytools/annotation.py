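"""Annotation of piggyBac-like repeat families.

The Table-1/Table-2 style procedure: extract annotated family members with
50-bp flanks, multiple-align each family, call the inverted terminal
repeats as the maximal terminal runs of alignment columns conserved at
>= 70%, classify members as intact (both ITRs align gap-free to the family
consensus AND the TTAA target-site duplication is present on both flanks),
and compute the pairwise ITR identity matrix with

    identity = 100 * identical_aligned_residues / len(shortest sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import GAP_CHAR, center_star_align, needleman_wunsch
from .reference import ReferenceSet, revcomp

log = logging.getLogger(__name__)


@dataclass
class RepeatElement:
    """One annotated family member, extracted with flanking sequence.

    ``sequence_with_flanks`` is in element orientation (minus-strand
    members are reverse-complemented), with ``flank_len_5`` bases of
    genomic flank before the element and ``flank_len_3`` after.
    """

    family: str
    contig: str
    start: int
    end: int
    strand: str
    sequence_with_flanks: str
    flank_len_5: int
    flank_len_3: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"element end {self.end} <= start {self.start}")
        expect = (self.end - self.start) + self.flank_len_5 + self.flank_len_3
        if len(self.sequence_with_flanks) != expect:
            raise ValueError("sequence length inconsistent with span and flanks")

    @property
    def core(self) -> str:
        """Element sequence without flanks."""
        s = self.sequence_with_flanks
        return s[self.flank_len_5 : len(s) - self.flank_len_3]

    @property
    def flank5(self) -> str:
        return self.sequence_with_flanks[: self.flank_len_5]

    @property
    def flank3(self) -> str:
        s = self.sequence_with_flanks
        return s[len(s) - self.flank_len_3 :] if self.flank_len_3 else ""


@dataclass
class RepeatFamilyAlignment:
    family: str
    rows: list[str]
    row_ids: list[str]
    conservation: np.ndarray = field(repr=False)
    element_columns: np.ndarray = field(repr=False)  # bool per column

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows differ in length")


@dataclass
class ITRConsensus:
    family: str
    side: str  # 5prime | 3prime
    sequence: str
    alignment_start_col: int


@dataclass
class IntactCall:
    element_id: str
    intact: bool | None  # None = non-classifiable
    reasons: list[str]


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


class AnnotationFormatError(ValueError):
    """Malformed annotation record."""


def extract_elements(
    annotation: pd.DataFrame,
    genome: ReferenceSet,
    family: str,
    flank: int = 50,
) -> list[RepeatElement]:
    """Extract all members of ``family`` with up to ``flank`` bp flanks.

    ``annotation`` holds BED-like 0-based half-open records with columns
    (contig, start, end, family, strand).  Minus-strand members are
    reverse-complemented so every returned element reads in element
    orientation; flanks are truncated at contig edges with the captured
    lengths recorded.
    """
    required = {"contig", "start", "end", "family", "strand"}
    missing = required - set(annotation.columns)
    if missing:
        raise AnnotationFormatError(f"annotation lacks columns: {sorted(missing)}")
    sub = annotation[annotation["family"] == family]
    if sub.empty:
        log.warning("family %r absent from annotation", family)
        return []
    out: list[RepeatElement] = []
    for idx, row in sub.iterrows():
        contig = row["contig"]
        if contig not in genome:
            raise AnnotationFormatError(f"record {idx}: unknown contig {contig!r}")
        seq = genome[contig]
        start, end = int(row["start"]), int(row["end"])
        if not (0 <= start < end <= len(seq)):
            raise AnnotationFormatError(
                f"record {idx}: span [{start},{end}) outside contig {contig!r}"
            )
        left = max(0, start - flank)
        right = min(len(seq), end + flank)
        chunk = seq[left:right]
        fl5, fl3 = start - left, right - end
        strand = row["strand"]
        if strand == "-":
            chunk = revcomp(chunk)
            fl5, fl3 = fl3, fl5
        out.append(
            RepeatElement(
                family=family,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                sequence_with_flanks=chunk,
                flank_len_5=fl5,
                flank_len_3=fl3,
            )
        )
    return out


def _column_stats(rows: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-column (conservation, non-gap fraction, modal base)."""
    arr = np.array([list(r) for r in rows])
    ncol = arr.shape[1]
    conservation = np.zeros(ncol)
    nongap_frac = np.zeros(ncol)
    modal: list[str] = []
    for j in range(ncol):
        col = arr[:, j]
        nongap = col[col != GAP_CHAR]
        nongap_frac[j] = len(nongap) / len(col)
        if len(nongap) == 0:
            modal.append(GAP_CHAR)
            continue
        vals, counts = np.unique(nongap, return_counts=True)
        # ties resolved alphabetically (np.unique sorts) -> deterministic
        best = int(np.argmax(counts))
        modal.append(str(vals[best]))
        conservation[j] = counts[best] / len(nongap)
    return conservation, nongap_frac, modal


def align_family(
    elements: list[RepeatElement],
    ids: list[str] | None = None,
) -> RepeatFamilyAlignment:
    """Center-star multiple alignment of family members (with flanks).

    Columns are flagged as element columns when the majority of their
    non-gap residues fall inside the contributing row's element span.
    """
    if len(elements) < 2:
        raise ValueError("align_family needs at least 2 elements")
    seqs = [e.sequence_with_flanks for e in elements]
    rows = center_star_align(seqs)
    if ids is None:
        ids = [f"{e.contig}:{e.start}-{e.end}({e.strand})" for e in elements]

    conservation, _, _ = _column_stats(rows)

    # element-region flags threaded through the alignment
    ncol = len(rows[0])
    in_elem = np.zeros(ncol)
    nongap = np.zeros(ncol)
    for row, elem in zip(rows, elements):
        lo = elem.flank_len_5
        hi = len(elem.sequence_with_flanks) - elem.flank_len_3
        res = 0
        for j, ch in enumerate(row):
            if ch == GAP_CHAR:
                continue
            nongap[j] += 1
            if lo <= res < hi:
                in_elem[j] += 1
            res += 1
    # columns carried by fewer than half the rows are private insertions,
    # not family consensus positions
    element_columns = (nongap * 2 >= len(rows)) & (in_elem * 2 >= nongap)

    return RepeatFamilyAlignment(
        family=elements[0].family,
        rows=rows,
        row_ids=ids,
        conservation=conservation,
        element_columns=element_columns,
    )


def detect_itrs(
    alignment: RepeatFamilyAlignment,
    cutoff: float = 0.70,
) -> tuple[ITRConsensus | None, ITRConsensus | None]:
    """Terminal conserved runs of the element region define the ITRs.

    Scanning inward from each end of the element region, the ITR is the
    maximal terminal run of columns whose modal-base conservation (among
    non-gap rows, requiring a non-gap majority) is >= ``cutoff``.  Returns
    (5', 3') consensus, either of which is None when no terminal column
    reaches the cutoff.
    """
    cons, nongap_frac, modal = _column_stats(alignment.rows)
    ok = (cons >= cutoff) & (nongap_frac >= 0.5)
    elem_cols = np.nonzero(alignment.element_columns)[0]
    if elem_cols.size == 0:
        return None, None

    def run(cols: np.ndarray) -> list[int]:
        out = []
        for j in cols:
            if ok[j]:
                out.append(int(j))
            else:
                break
        return out

    five_cols = run(elem_cols)
    three_cols = run(elem_cols[::-1])[::-1]

    five = (
        ITRConsensus(
            family=alignment.family,
            side="5prime",
            sequence="".join(modal[j] for j in five_cols),
            alignment_start_col=five_cols[0],
        )
        if five_cols
        else None
    )
    three = (
        ITRConsensus(
            family=alignment.family,
            side="3prime",
            sequence="".join(modal[j] for j in three_cols),
            alignment_start_col=three_cols[0],
        )
        if three_cols
        else None
    )
    return five, three


def classify_intact(
    element: RepeatElement,
    itr5: ITRConsensus,
    itr3: ITRConsensus,
    element_id: str | None = None,
) -> IntactCall:
    """Intact <=> gap-free ITR alignments AND TTAA TSD on both flanks.

    Each element's terminal region (same length as the consensus) is
    globally aligned to the consensus; any gap disqualifies.  The 4 bp
    immediately flanking the element on both sides must read TTAA.
    Elements with <4 bp of captured flank are non-classifiable.
    """
    if itr5 is None or itr3 is None:
        raise ValueError("both ITR consensi are required")
    eid = element_id or f"{element.contig}:{element.start}-{element.end}({element.strand})"
    if element.flank_len_5 < 4 or element.flank_len_3 < 4:
        return IntactCall(eid, None, ["flank shorter than 4 bp: non-classifiable"])
    reasons: list[str] = []
    core = element.core
    n5, n3 = len(itr5.sequence), len(itr3.sequence)
    _, a5, b5 = needleman_wunsch(core[:n5], itr5.sequence)
    if GAP_CHAR in a5 or GAP_CHAR in b5:
        reasons.append("gap in 5' ITR alignment to consensus")
    _, a3, b3 = needleman_wunsch(core[-n3:], itr3.sequence)
    if GAP_CHAR in a3 or GAP_CHAR in b3:
        reasons.append("gap in 3' ITR alignment to consensus")
    if element.flank5[-4:] != "TTAA":
        reasons.append("no TTAA immediately 5' of element")
    if element.flank3[:4] != "TTAA":
        reasons.append("no TTAA immediately 3' of element")
    return IntactCall(eid, not reasons, reasons)


def identity_matrix(named_seqs: list[tuple[str, str]]) -> IdentityMatrix:
    """Pairwise percent identity over global alignments.

    identity = 100 * identical aligned residues / length of the shortest
    raw sequence.  N never counts as identical; comparison is
    case-insensitive (uppercased); the matrix is symmetric with a 100
    diagonal.
    """
    if len(named_seqs) < 2:
        raise ValueError("identity_matrix needs at least 2 sequences")
    labels = [n for n, _ in named_seqs]
    seqs = [s.upper() for _, s in named_seqs]
    if any(not s for s in seqs):
        raise ValueError("empty sequence in identity_matrix input")
    k = len(seqs)
    vals = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            _, ai, aj = needleman_wunsch(seqs[i], seqs[j])
            ident = sum(
                1
                for x, y in zip(ai, aj)
                if x == y and x != GAP_CHAR and x != "N"
            )
            pct = 100.0 * ident / min(len(seqs[i]), len(seqs[j]))
            vals[i, j] = vals[j, i] = pct
    return IdentityMatrix(labels=labels, values=vals)


def family_summary(calls: list[IntactCall]) -> dict:
    """Table-1 shaped counts: total members vs intact members."""
    total = len(calls)
    intact = sum(1 for c in calls if c.intact)
    unclassifiable = sum(1 for c in calls if c.intact is None)
    return {"total": total, "intact": intact, "non_classifiable": unclassifiable}
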