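"""Transposon reporter construction.

A piggyBac-like reporter is a cargo sequence flanked by 13-bp inverted
terminal repeats (ITRs).  On the top strand the 5' ITR begins with CCC and
the 3' ITR ends with GGG; this GGG/CCC terminal motif is the sequence at
which transposase-mediated joining to the TTAA target site occurs.  Three
variants are modelled:

``intact``
    wild-type ITRs with the canonical CCC...GGG termini;
``mutant``
    both terminal trinucleotides substituted (CCC->TAT on the 5' ITR,
    GGG->ATA on the 3' ITR), disrupting the hairpin intermediate;
``deleted``
    no ITRs at all — the element is the bare cargo, a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import revcomp

#: 13-bp T. ni piggyBac ITR (top strand, element-leftmost first), as read
#: from the cloned TTAA|CCCTAGAAAGATA... reporter flank.
PIGGYBAC_ITR5 = "CCCTAGAAAGATA"
PIGGYBAC_ITR3 = revcomp(PIGGYBAC_ITR5)  # TATCTTTCTAGGG

VARIANTS = ("intact", "mutant", "deleted")


class ReporterError(ValueError):
    """Reporter definition violates the ITR terminal-motif contract."""


@dataclass(frozen=True)
class TransposonReporter:
    """ITR-flanked cargo; the substrate of all simulations and junction checks."""

    name: str
    itr5: str
    cargo: str
    itr3: str
    variant: str

    @property
    def element(self) -> str:
        """Full element sequence, itr5 + cargo + itr3."""
        return self.itr5 + self.cargo + self.itr3

    def __len__(self) -> int:
        return len(self.element)


def build_reporter(
    itr5: str,
    cargo: str,
    itr3: str,
    variant: str = "intact",
    name: str = "reporter",
) -> TransposonReporter:
    """Assemble a transposon reporter of the requested variant.

    ``itr5``/``itr3`` are always given as the intact top-strand ITRs; the
    mutant variant derives its termini from them, and the deleted variant
    discards them.

    Raises
    ------
    ReporterError
        if intact ITRs lack the canonical CCC/GGG termini, or the variant
        is unknown.
    """
    if variant not in VARIANTS:
        raise ReporterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if not cargo:
        raise ReporterError("cargo must be non-empty")
    if variant == "deleted":
        return TransposonReporter(name, "", cargo, "", "deleted")
    if not itr5.startswith("CCC"):
        raise ReporterError("intact 5' ITR must begin with CCC (top strand)")
    if not itr3.endswith("GGG"):
        raise ReporterError("intact 3' ITR must end with GGG (top strand)")
    if variant == "mutant":
        itr5 = "TAT" + itr5[3:]
        itr3 = itr3[:-3] + "ATA"
    return TransposonReporter(name, itr5, cargo, itr3, variant)


def default_reporter(cargo: str, variant: str = "intact", name: str = "PB-reporter") -> TransposonReporter:
    """Reporter with the canonical 13-bp piggyBac ITRs around ``cargo``."""
    if variant == "deleted":
        return build_reporter("", cargo, "", "deleted", name)
    return build_reporter(PIGGYBAC_ITR5, cargo, PIGGYBAC_ITR3, variant, name)
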