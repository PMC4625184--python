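"""Planting of synthetic piggyBac-like repeat families.

A desk-scale stand-in for MER75/MER85-like MITE families: ``n`` copies of
an ITR-flanked consensus are inserted into a genome, each flanked by a
TTAA target-site duplication unless dropped, optionally corrupted by a
1-bp indel inside one ITR, and diverged by i.i.d. substitutions.  The
returned truth table labels each copy intact by construction:
intact <=> TSD present AND both ITRs indel-free.

Substitutions are applied to the element body only (not to the TSD
flanks), so truth labels stay exactly re-derivable by string comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import ReferenceSet, revcomp
from .simulate import BASES, SimulationParameterError


@dataclass
class PlantedCopy:
    copy_id: str
    contig: str
    start: int  # element span in the planted genome, 0-based half-open
    end: int
    strand: str
    tsd_present: bool
    itr5_indel: bool
    itr3_indel: bool
    n_substitutions: int

    @property
    def intact(self) -> bool:
        return self.tsd_present and not (self.itr5_indel or self.itr3_indel)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii"), int(hit.size)


def _indel(rng: np.random.Generator, itr: str) -> str:
    """Delete one internal base of an ITR (corruption event)."""
    if len(itr) < 2:
        return itr
    pos = int(rng.integers(0, len(itr)))
    return itr[:pos] + itr[pos + 1 :]


def plant_repeat_family(
    genome: ReferenceSet,
    consensus_itr5: str,
    consensus_internal: str,
    consensus_itr3: str,
    n: int,
    per_base_mutation: float = 0.0,
    corrupt_itr_fraction: float = 0.0,
    drop_tsd_fraction: float = 0.0,
    seed: int = 0,
    family: str = "MERtoy",
    spacing: int = 500,
) -> tuple[ReferenceSet, pd.DataFrame, pd.DataFrame]:
    """Plant ``n`` family copies; returns (genome, annotation, truth).

    The annotation frame has BED-like columns (contig, start, end, family,
    score, strand) with element spans (TSDs excluded) in the coordinates
    of the *returned* genome.  The truth frame carries the per-copy labels.
    """
    for name, v in (
        ("per_base_mutation", per_base_mutation),
        ("corrupt_itr_fraction", corrupt_itr_fraction),
        ("drop_tsd_fraction", drop_tsd_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise SimulationParameterError(f"{name}={v} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    elem_len = len(consensus_itr5) + len(consensus_internal) + len(consensus_itr3)
    total = genome.total_length()
    if total < n * (elem_len + spacing):
        raise SimulationParameterError(
            f"genome ({total} bp) too short to plant {n} copies with spacing {spacing}"
        )

    # allocate copies to contigs proportional to length, positions spaced
    contigs = genome.names
    lens = np.array([len(genome[c]) for c in contigs], dtype=float)
    alloc = rng.multinomial(n, lens / lens.sum())

    copies: list[PlantedCopy] = []
    out_records: dict[str, str] = {}
    copy_no = 0
    for cname, k in zip(contigs, alloc):
        seq = genome[cname]
        positions = sorted(
            int(p)
            for p in rng.choice(
                np.arange(4, max(len(seq) - 4, 5), spacing), size=int(k), replace=False
            )
        ) if k else []
        pieces: list[str] = []
        cursor = 0
        offset = 0
        for p in positions:
            itr5, internal, itr3 = consensus_itr5, consensus_internal, consensus_itr3
            itr5_indel = itr3_indel = False
            if rng.random() < corrupt_itr_fraction:
                if rng.random() < 0.5:
                    itr5, itr5_indel = _indel(rng, itr5), True
                else:
                    itr3, itr3_indel = _indel(rng, itr3), True
            body, nsub = _mutate(rng, itr5 + internal + itr3, per_base_mutation)
            tsd = rng.random() >= drop_tsd_fraction
            strand = "+" if rng.random() < 0.5 else "-"
            insert_body = body if strand == "+" else revcomp(body)
            insert = ("TTAA" + insert_body + "TTAA") if tsd else insert_body
            pieces.append(seq[cursor:p])
            pieces.append(insert)
            elem_start = p + offset + (4 if tsd else 0)
            copies.append(
                PlantedCopy(
                    copy_id=f"{family}_{copy_no}",
                    contig=cname,
                    start=elem_start,
                    end=elem_start + len(body),
                    strand=strand,
                    tsd_present=tsd,
                    itr5_indel=itr5_indel,
                    itr3_indel=itr3_indel,
                    n_substitutions=nsub,
                )
            )
            copy_no += 1
            offset += len(insert)
            cursor = p
        pieces.append(seq[cursor:])
        out_records[cname] = "".join(pieces)

    annotation = pd.DataFrame(
        {
            "contig": [c.contig for c in copies],
            "start": [c.start for c in copies],
            "end": [c.end for c in copies],
            "family": family,
            "score": 0,
            "strand": [c.strand for c in copies],
        }
    )
    truth = pd.DataFrame(
        {
            "copy_id": [c.copy_id for c in copies],
            "contig": [c.contig for c in copies],
            "start": [c.start for c in copies],
            "end": [c.end for c in copies],
            "strand": [c.strand for c in copies],
            "tsd_present": [c.tsd_present for c in copies],
            "itr5_indel": [c.itr5_indel for c in copies],
            "itr3_indel": [c.itr3_indel for c in copies],
            "n_substitutions": [c.n_substitutions for c in copies],
            "intact": [c.intact for c in copies],
        }
    )
    return ReferenceSet(out_records), annotation, truth
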