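"""Cut-and-paste transposition simulator with known ground truth.

Emulates the whole experimental chain at desk scale: a toy genome with
controllable TTAA density, TTAA-targeted integrations that duplicate the
target site around the ITR-flanked element, precise excision, and
FLEA-PCR-like junction amplicons sequenced as paired reads with
substitution errors, PCR duplicates and adapter-dimer artifacts.

The integration model: transposase inserts the element at a TTAA target
site and the host repair duplicates the TTAA so the integrated locus reads

    ...TTAA [element] TTAA...

where the unmodified genome had a single TTAA.  Precise excision removes
the element together with one TTAA copy, byte-exactly restoring the donor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .reference import ReferenceSet, revcomp
from .reporter import TransposonReporter

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Illumina-style adapter sequences used for adapter-dimer artifacts.  The
#: second is the generic P5 read-through adapter seen in dimer reads.
ADAPTER_P7 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ADAPTER_P5 = "GATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATT"


class SimulationParameterError(ValueError):
    """A simulation parameter is out of range or jointly infeasible."""


@dataclass
class SimulationConfig:
    """Knobs of the simulator; defaults are the study conditions.

    ``read_length`` 300 matches a 300/300 paired-end run;
    ``duplicate_fraction`` 0.6 sits inside the observed 56-87% PCR
    duplication range; ``substitution_rate`` 0.005 is a conservative
    per-base MiSeq error rate; ``depth`` 20 read pairs per junction keeps
    every insertion comfortably covered.
    """

    genome_length: int = 5_000_000
    contig_count: int = 5
    gc_fraction: float = 0.41
    n_events: int = 200
    ttaa_fidelity: float = 1.0
    read_length: int = 300
    mean_amplicon: int = 600
    depth: float = 20.0
    substitution_rate: float = 0.005
    duplicate_fraction: float = 0.6
    adapter_dimer_fraction: float = 0.05
    background_fraction: float = 0.0
    primer_offset: int = 100
    min_event_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "gc_fraction",
            "ttaa_fidelity",
            "substitution_rate",
            "duplicate_fraction",
            "adapter_dimer_fraction",
            "background_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationParameterError(f"{name}={v} must be in [0, 1]")
        for name in ("genome_length", "contig_count", "read_length", "mean_amplicon", "primer_offset"):
            if getattr(self, name) <= 0:
                raise SimulationParameterError(f"{name} must be positive")
        if self.n_events < 0:
            raise SimulationParameterError("n_events must be non-negative")
        if self.depth <= 0:
            raise SimulationParameterError("depth must be positive")
        if self.contig_count > self.genome_length:
            raise SimulationParameterError("contig_count exceeds genome_length")
        contig_len = self.genome_length // self.contig_count
        if self.n_events and contig_len < 8 * self.n_events:
            raise SimulationParameterError(
                f"genome too short for n_events: contig length {contig_len} < "
                f"8 * n_events = {8 * self.n_events}"
            )


@dataclass
class IntegrationEvent:
    """Ground truth for one simulated insertion.

    ``tsd_start`` is the 0-based position of the targeted TTAA in the
    *unmodified* genome; ``mod_elem_start``/``mod_elem_end`` locate the
    inserted element in the modified genome (artifact bookkeeping, filled
    by :func:`simulate_integrations`).
    """

    contig: str
    tsd_start: int
    orientation: str
    reporter_name: str
    on_ttaa: bool
    mod_elem_start: int = -1
    mod_elem_end: int = -1


@dataclass
class ReadPair:
    """One paired-end read with Phred qualities and provenance."""

    read_id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray
    source: str  # junction | background | adapter_dimer
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        for seq, qual, mate in ((self.seq1, self.qual1, 1), (self.seq2, self.qual2, 2)):
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {self.read_id} mate {mate}: sequence/quality length mismatch"
                )


def _sample_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return BASES[codes].tobytes().decode("ascii")


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def make_genome(config: SimulationConfig) -> ReferenceSet:
    """Generate an i.i.d. random genome matching ``gc_fraction``.

    Deterministic for a fixed seed.  Guarantees at least ``n_events`` TTAA
    occurrences on every contig by injecting TTAA at random positions when
    the random composition falls short (only relevant for tiny or extreme-GC
    genomes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig_len = config.genome_length // config.contig_count
    records: dict[str, str] = {}
    for i in range(config.contig_count):
        seq = _sample_sequence(rng, contig_len, config.gc_fraction)
        if config.n_events:
            have = len(_find_all(seq, "TTAA"))
            guard = 0
            while have < config.n_events:
                # inject TTAA at a random position, then recount
                pos = int(rng.integers(0, contig_len - 4))
                seq = seq[:pos] + "TTAA" + seq[pos + 4 :]
                have = len(_find_all(seq, "TTAA"))
                guard += 1
                if guard > 10 * config.n_events:
                    raise SimulationParameterError(
                        "cannot satisfy TTAA density: genome_length too small "
                        "for n_events"
                    )
        records[f"chr{i + 1}"] = seq
    return ReferenceSet(records)


def _pick_spaced(rng: np.random.Generator, candidates: np.ndarray, n: int, spacing: int) -> list[int]:
    """Greedy random subset of positions pairwise separated by >= spacing."""
    order = rng.permutation(len(candidates))
    chosen: list[int] = []
    taken = np.zeros(0, dtype=np.int64)
    for idx in order:
        p = int(candidates[idx])
        if taken.size and np.min(np.abs(taken - p)) < spacing:
            continue
        chosen.append(p)
        taken = np.append(taken, p)
        if len(chosen) == n:
            break
    return chosen


def simulate_integrations(
    genome: ReferenceSet,
    reporter: TransposonReporter,
    config: SimulationConfig,
) -> tuple[ReferenceSet, list[IntegrationEvent]]:
    """Insert ``n_events`` reporter copies, duplicating TTAA target sites.

    A fraction ``ttaa_fidelity`` of events is placed at TTAA sites with
    target-site duplication; the remainder lands at random non-TTAA
    positions without duplication (off-target background).  Orientation is
    +/- with equal probability; '-' inserts the reverse complement of the
    element.  Events are non-overlapping and returned sorted by
    (contig, tsd_start).
    """
    rng = np.random.default_rng(config.seed + 1)
    element = reporter.element
    n_on = int(round(config.n_events * config.ttaa_fidelity))
    n_off = config.n_events - n_on

    # allocate events to contigs proportionally to available TTAA sites
    contig_names = genome.names
    ttaa_sites = {name: np.array(_find_all(genome[name], "TTAA"), dtype=np.int64) for name in contig_names}
    total_sites = sum(len(v) for v in ttaa_sites.values())
    if n_on and total_sites < n_on:
        raise SimulationParameterError(
            f"genome has {total_sites} TTAA sites but {n_on} on-target events requested"
        )

    events: list[IntegrationEvent] = []
    # round-robin proportional allocation of on-target events
    weights = np.array([max(len(ttaa_sites[c]), 1) for c in contig_names], dtype=float)
    weights /= weights.sum()
    alloc = rng.multinomial(n_on, weights)
    for cname, k in zip(contig_names, alloc):
        if k == 0:
            continue
        chosen = _pick_spaced(rng, ttaa_sites[cname], int(k), config.min_event_spacing)
        if len(chosen) < k:
            raise SimulationParameterError(
                f"contig {cname}: cannot place {k} events with spacing "
                f"{config.min_event_spacing}; only {len(chosen)} TTAA sites usable"
            )
        for p in chosen:
            orient = "+" if rng.random() < 0.5 else "-"
            events.append(IntegrationEvent(cname, p, orient, reporter.name, True))

    # off-target events at non-TTAA positions
    alloc_off = rng.multinomial(n_off, weights) if n_off else []
    for cname, k in zip(contig_names, alloc_off if n_off else []):
        seq = genome[cname]
        taken = np.array(
            [e.tsd_start for e in events if e.contig == cname], dtype=np.int64
        )
        placed = 0
        guard = 0
        while placed < k:
            guard += 1
            if guard > 1000 * max(k, 1):
                raise SimulationParameterError(
                    f"contig {cname}: cannot place {k} off-target events"
                )
            p = int(rng.integers(4, len(seq) - 4))
            if seq[p : p + 4] == "TTAA":
                continue
            if taken.size and np.min(np.abs(taken - p)) < config.min_event_spacing:
                continue
            orient = "+" if rng.random() < 0.5 else "-"
            events.append(IntegrationEvent(cname, p, orient, reporter.name, False))
            taken = np.append(taken, p)
            placed += 1

    events.sort(key=lambda e: (e.contig, e.tsd_start))

    # build the modified genome, tracking modified coordinates
    modified: dict[str, str] = {}
    for cname in contig_names:
        seq = genome[cname]
        pieces: list[str] = []
        cursor = 0
        offset = 0
        for ev in (e for e in events if e.contig == cname):
            elem = element if ev.orientation == "+" else revcomp(element)
            if ev.on_ttaa:
                cut = ev.tsd_start + 4  # keep the original TTAA on the left
                pieces.append(seq[cursor:cut])
                pieces.append(elem)
                pieces.append("TTAA")
                ev.mod_elem_start = cut + offset
                ev.mod_elem_end = cut + offset + len(elem)
                offset += len(elem) + 4
                cursor = cut
            else:
                cut = ev.tsd_start
                pieces.append(seq[cursor:cut])
                pieces.append(elem)
                ev.mod_elem_start = cut + offset
                ev.mod_elem_end = cut + offset + len(elem)
                offset += len(elem)
                cursor = cut
        pieces.append(seq[cursor:])
        modified[cname] = "".join(pieces)
    return ReferenceSet(modified), events


class ExcisionError(ValueError):
    """Donor does not contain exactly one excisable cassette."""


def simulate_excision(donor: str, reporter: TransposonReporter) -> str:
    """Precisely excise the element and one duplicated TTAA from ``donor``.

    The donor must contain exactly one occurrence of TTAA+element+TTAA (in
    either orientation); the occurrence is replaced by a single TTAA,
    restoring the pre-integration sequence.
    """
    hits: list[tuple[int, str]] = []
    for elem in dict.fromkeys((reporter.element, revcomp(reporter.element))):
        cassette = "TTAA" + elem + "TTAA"
        for p in _find_all(donor, cassette):
            hits.append((p, cassette))
    if len(hits) != 1:
        raise ExcisionError(
            f"expected exactly one TTAA+element+TTAA cassette, found {len(hits)}"
        )
    p, cassette = hits[0]
    return donor[:p] + "TTAA" + donor[p + len(cassette) :]


def excise_all(modified: ReferenceSet, reporter: TransposonReporter) -> ReferenceSet:
    """Excise every TTAA-flanked element cassette from every contig."""
    out: dict[str, str] = {}
    cassettes = [
        "TTAA" + e + "TTAA"
        for e in dict.fromkeys((reporter.element, revcomp(reporter.element)))
    ]
    for name, seq in modified.items():
        changed = True
        while changed:
            changed = False
            for cassette in cassettes:
                p = seq.find(cassette)
                if p != -1:
                    seq = seq[:p] + "TTAA" + seq[p + len(cassette) :]
                    changed = True
        out[name] = seq
    return ReferenceSet(out)


def _quality_profile(rng: np.random.Generator, length: int, tail: int = 60) -> np.ndarray:
    """Q~35 with a linearly decaying 3' tail ending in [2, 20]."""
    q = np.full(length, 35, dtype=np.int64)
    t = min(tail, length)
    if t > 1:
        q_end = int(rng.integers(2, 21))
        q[length - t :] = np.linspace(35, q_end, t).round().astype(np.int64)
    return q


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hit.size == 0:
        return seq
    # substitute with a uniformly random *different* base
    for i in hit:
        cur = arr[i]
        choices = BASES[BASES != cur]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def _sample_extension(rng: np.random.Generator, mean: float, low: int, high: int) -> int:
    """Geometric amplicon extension with given mean, clamped to [low, high]."""
    mean = max(mean, 1.0)
    g = int(rng.geometric(1.0 / mean))
    return int(np.clip(g, low, high))


def generate_reads(
    modified: ReferenceSet,
    events: list[IntegrationEvent],
    reporter: TransposonReporter,
    config: SimulationConfig,
) -> list[ReadPair]:
    """FLEA-PCR-like junction amplicons as paired reads.

    Each event receives ~Poisson(depth) amplicons split randomly between
    its two junctions.  An amplicon starts at a fixed primer offset inside
    the element, crosses one junction and extends a geometric length (mean
    ``mean_amplicon``) into the flanking genome; mate 1 is the first
    ``read_length`` bases, mate 2 the reverse complement of the last.
    PCR duplicates and adapter-dimer pairs are appended so their fractions
    of the final pool match the configured values.
    """
    rng = np.random.default_rng(config.seed + 2)
    rl = config.read_length
    pairs: list[ReadPair] = []

    def finish(amp: str, rid: str, source: str) -> None:
        if len(amp) < rl:
            # paranoid guard; callers resample length to avoid this
            warnings.warn(f"{rid}: amplicon shorter than read_length, resampled")
            amp = amp + amp[::-1]
            amp = (amp * ((rl // len(amp)) + 2))[: rl + 1]
        s1 = _apply_substitutions(rng, amp[:rl], config.substitution_rate)
        s2 = _apply_substitutions(rng, revcomp(amp[-rl:]), config.substitution_rate)
        pairs.append(
            ReadPair(
                rid,
                s1,
                s2,
                _quality_profile(rng, rl),
                _quality_profile(rng, rl),
                source,
            )
        )

    for ei, ev in enumerate(events):
        if ev.mod_elem_start < 0:
            raise ValueError("events lack modified-genome coordinates; run simulate_integrations first")
        seq = modified[ev.contig]
        e0, e1 = ev.mod_elem_start, ev.mod_elem_end
        po = min(config.primer_offset, e1 - e0)
        n_amp = int(rng.poisson(config.depth))
        for j in range(n_amp):
            left = rng.random() < 0.5
            ext_mean = max(config.mean_amplicon - po, rl)
            ext = _sample_extension(rng, ext_mean, max(rl - po, 1), 2000 - po)
            if left:
                a0 = max(0, e0 - ext)
                amp = revcomp(seq[a0 : e0 + po])
            else:
                a1 = min(len(seq), e1 + ext)
                amp = seq[max(0, e1 - po) : a1]
            if len(amp) < rl:
                # junction too close to a contig edge; extend on the element side
                if left:
                    amp = revcomp(seq[a0 : min(len(seq), a0 + max(rl, len(amp)))])
                else:
                    amp = seq[max(0, a1 - rl) : a1]
            finish(amp, f"evt{ei}_amp{j}", "junction")

    n_junction = len(pairs)
    # background: purely genomic amplicons (mispriming)
    f_bg = config.background_fraction
    f_dup = config.duplicate_fraction
    f_dim = config.adapter_dimer_fraction
    denom = 1.0 - f_dup - f_dim - f_bg
    base = n_junction if n_junction else int(round(config.depth * max(config.n_events, 1)))

    if denom <= 0:
        # degenerate configurations: artifact-only pools
        if f_dim >= 1.0:
            dimers: list[ReadPair] = []
            for j in range(base or 1):
                _make_dimer(rng, rl, dimers, f"dimer{j}")
            return dimers
        raise SimulationParameterError(
            "duplicate_fraction + adapter_dimer_fraction + background_fraction must be < 1"
        )

    n_bg = int(round(f_bg * base / denom))
    contigs = modified.names
    lens = np.array([len(modified[c]) for c in contigs], dtype=float)
    for j in range(n_bg):
        ci = int(rng.choice(len(contigs), p=lens / lens.sum()))
        seq = modified[contigs[ci]]
        alen = _sample_extension(rng, config.mean_amplicon, rl, 2000)
        start = int(rng.integers(0, max(len(seq) - alen, 1)))
        finish(seq[start : start + alen], f"bg{j}", "background")

    # PCR duplicates: exact copies of existing junction/background pairs
    n_main = len(pairs)
    n_dup = int(round(f_dup * n_main / (1.0 - f_dup))) if f_dup < 1.0 and n_main else 0
    for j in range(n_dup):
        src = pairs[int(rng.integers(0, n_main))]
        pairs.append(
            ReadPair(
                f"dup{j}",
                src.seq1,
                src.seq2,
                src.qual1.copy(),
                src.qual2.copy(),
                src.source,
                duplicate_of=src.read_id,
            )
        )

    # adapter dimers
    n_nondim = len(pairs)
    n_dim = int(round(f_dim * n_nondim / (1.0 - f_dim))) if f_dim < 1.0 else 0
    for j in range(n_dim):
        _make_dimer(rng, rl, pairs, f"dimer{j}")

    return pairs


def _make_dimer(rng: np.random.Generator, rl: int, pairs: list[ReadPair], rid: str) -> None:
    dimer = (ADAPTER_P7 + ADAPTER_P5) * (rl // len(ADAPTER_P7 + ADAPTER_P5) + 1)
    pairs.append(
        ReadPair(
            rid,
            dimer[:rl],
            dimer[:rl],
            _quality_profile(rng, rl),
            _quality_profile(rng, rl),
            "adapter_dimer",
        )
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    return replace(config, **kwargs)
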