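"""Insertion-site aggregation, classification, logo and contingency stats.

Junction calls sharing a genomic target position merge into insertion
sites; sites are classified TTAA_ITR when the 4-bp target reads TTAA and
every supporting junction sits exactly at the ITR terminal GGG/CCC motif
(transposon_offset == 0).  The +/-flank sequence context of all sites
yields a sequence logo as per-position information content in bits,
2 - H with H the Shannon entropy of the base distribution.  Two-condition
site class counts form the 2x2 table tested with the exact Fisher test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .junctions import JunctionCall
from .reference import ReferenceSet
from .stats import fisher_exact, odds_ratio

log = logging.getLogger(__name__)


@dataclass
class InsertionSite:
    contig: str
    tsd_start: int
    n_reads: int
    n_5prime: int
    n_3prime: int
    target_tetra: str
    site_class: str | None = None  # TTAA_ITR | non_ITR
    genic: bool | None = None
    max_offset: int = 0  # largest transposon_offset among supporting calls


@dataclass
class LogoMatrix:
    positions: np.ndarray  # offsets relative to tsd_start
    base_freq: pd.DataFrame  # rows = positions, columns = A/C/G/T
    info_bits: np.ndarray
    n_sites: int
    small_sample_correction: bool


@dataclass
class ContingencyTable2x2:
    row_labels: list[str]
    col_labels: list[str]
    counts: list[list[int]]

    def row_percentages(self) -> list[list[float]]:
        out = []
        for row in self.counts:
            tot = sum(row)
            out.append([100.0 * x / tot if tot else float("nan") for x in row])
        return out


def aggregate_sites(calls: list[JunctionCall], min_support: int = 1) -> list[InsertionSite]:
    """Merge calls sharing (contig, tsd_start) into insertion sites.

    The two junctions of one TSD-duplicating insertion report the same
    ``tsd_start`` under the strand convention, so a fully recovered
    insertion contributes a single site with support from both ends.
    ``min_support`` drops sites with fewer supporting reads (a standard
    guard against breakpoints shifted by isolated sequencing errors).
    """
    grouped: dict[tuple[str, int], list[JunctionCall]] = {}
    for c in calls:
        grouped.setdefault((c.contig, c.tsd_start), []).append(c)
    sites: list[InsertionSite] = []
    for (contig, tsd), group in sorted(grouped.items()):
        if len(group) < min_support:
            continue
        n5 = sum(1 for c in group if c.transposon_end == "5prime")
        n3 = len(group) - n5
        # modal target tetramer guards against a rare read error at the site
        tetras = pd.Series([c.target_tetra for c in group])
        tetra = tetras.mode().iloc[0]
        sites.append(
            InsertionSite(
                contig=contig,
                tsd_start=tsd,
                n_reads=len(group),
                n_5prime=n5,
                n_3prime=n3,
                target_tetra=tetra,
                max_offset=max(c.transposon_offset for c in group),
            )
        )
    return sites


def classify_sites(sites: list[InsertionSite], strict: bool = True) -> list[InsertionSite]:
    """Assign TTAA_ITR / non_ITR classes in place (and return the list).

    strict (default): TTAA_ITR requires the TTAA target AND every
    supporting junction at the ITR terminus (offset 0).  With
    ``strict=False`` the TTAA target alone qualifies.
    """
    for s in sites:
        is_ttaa = s.target_tetra == "TTAA"
        at_terminus = s.max_offset == 0
        s.site_class = "TTAA_ITR" if (is_ttaa and (at_terminus or not strict)) else "non_ITR"
    return sites


def build_logo(
    sites: list[InsertionSite],
    genome: ReferenceSet,
    flank: int = 10,
    correction: bool = False,
) -> LogoMatrix:
    """Information content of the insertion-site context.

    Offsets run from -flank to 4+flank-1 relative to ``tsd_start``; the
    target tetramer occupies offsets 0..3.  info = 2 - H bits per
    position; the optional small-sample correction subtracts
    e(n) = 3 / (2 ln2 n).
    """
    if not sites:
        raise ValueError("build_logo needs at least one site")
    offsets = np.arange(-flank, 4 + flank)
    rows = []
    dropped = 0
    for s in sites:
        seq = genome[s.contig]
        lo, hi = s.tsd_start - flank, s.tsd_start + 4 + flank
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        rows.append(seq[lo:hi])
    if dropped:
        log.warning("build_logo: dropped %d sites at contig edges", dropped)
    if not rows:
        raise ValueError("no usable sites within contig bounds")
    arr = np.array([list(r) for r in rows])
    n = len(rows)
    freq = np.zeros((len(offsets), 4))
    for bi, base in enumerate("ACGT"):
        freq[:, bi] = (arr == base).sum(axis=0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    H = -plogp.sum(axis=1)
    info = 2.0 - H
    if correction:
        info = info - 3.0 / (2.0 * np.log(2.0) * n)
    base_freq = pd.DataFrame(freq, index=offsets, columns=list("ACGT"))
    return LogoMatrix(
        positions=offsets,
        base_freq=base_freq,
        info_bits=info,
        n_sites=n,
        small_sample_correction=correction,
    )


def annotate_genic(
    sites: list[InsertionSite],
    genes: pd.DataFrame,
    contig_names: list[str] | None = None,
) -> pd.DataFrame:
    """Flag sites falling inside gene intervals; per-contig count table.

    ``genes`` is BED-like (contig, start, end, half-open).  Intervals on
    contigs absent from the sites' genome are ignored with a warning.
    Returns a table of genic/intergenic counts per contig.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for _, row in genes.iterrows():
        c = row["contig"]
        if contig_names is not None and c not in contig_names:
            log.warning("annotate_genic: ignoring interval on unknown contig %r", c)
            continue
        by_contig.setdefault(c, []).append((int(row["start"]), int(row["end"])))
    for s in sites:
        ivs = by_contig.get(s.contig, [])
        s.genic = any(a <= s.tsd_start < b for a, b in ivs)
    counts: dict[str, dict[str, int]] = {}
    for s in sites:
        d = counts.setdefault(s.contig, {"genic": 0, "intergenic": 0})
        d["genic" if s.genic else "intergenic"] += 1
    return (
        pd.DataFrame.from_dict(counts, orient="index")
        .rename_axis("contig")
        .reset_index()
        .sort_values("contig")
        .reset_index(drop=True)
    )


def contingency(sites_by_condition: dict[str, list[InsertionSite]]) -> ContingencyTable2x2:
    """TTAA_ITR vs non_ITR site counts for exactly two conditions."""
    if len(sites_by_condition) != 2:
        raise ValueError("contingency needs exactly two conditions")
    rows = []
    labels = []
    for cond, sites in sites_by_condition.items():
        unclassified = [s for s in sites if s.site_class is None]
        if unclassified:
            raise ValueError(f"condition {cond!r} has unclassified sites")
        a = sum(1 for s in sites if s.site_class == "TTAA_ITR")
        b = len(sites) - a
        rows.append([a, b])
        labels.append(cond)
    return ContingencyTable2x2(row_labels=labels, col_labels=["TTAA_ITR", "non_ITR"], counts=rows)


def contingency_stats(table: ContingencyTable2x2) -> dict:
    """Fisher p-value, odds ratio and row percentages for reporting."""
    return {
        "rows": table.row_labels,
        "columns": table.col_labels,
        "counts": table.counts,
        "row_percentages": table.row_percentages(),
        "p_value": fisher_exact(table.counts),
        "odds_ratio": odds_ratio(table.counts),
    }
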