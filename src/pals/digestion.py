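"""In-silico trypsin digestion and barcode-release verification.

Trypsin cleaves C-terminal to lysine or arginine except when the next
residue is proline (the classic rule, without the rarer Keil exceptions).
The design loop is closed here: a barcoded construct is digested and the
products are checked against the panel -- each designed barcode peptide
must be released intact, exactly once, and no carrier-derived peptide may
be isobaric with a barcode.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .chem import DEFAULT_MASS_TABLE, ResidueMassTable, monoisotopic_mass
from .design import BarcodeCandidate, BarcodePanel

__all__ = [
    "Annotation",
    "ProteinConstruct",
    "DigestPeptide",
    "DigestResult",
    "ReleaseReport",
    "trypsin_digest",
    "cleavage_sites",
    "verify_barcode_release",
    "append_barcode",
    "concatenate_constructs",
]


@dataclass(frozen=True)
class Annotation:
    """A labelled span (carrier, barcode, flank, tag) on a construct."""

    label: str
    start: int
    end: int
    kind: str = "region"


@dataclass(frozen=True)
class ProteinConstruct:
    """A full protein sequence with optional non-overlapping annotations."""

    sequence: str
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("construct sequence must be non-empty")
        spans = sorted((a.start, a.end, a.label) for a in self.annotations)
        prev_end = 0
        for start, end, label in spans:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"annotation {label!r} out of bounds: [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"annotation {label!r} overlaps a previous span")
            prev_end = end

    def barcodes(self) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == "barcode"]


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class DigestResult:
    """Tryptic peptides of one construct.

    ``peptides`` lists fully cleaved products first, in N->C order -- their
    concatenation reconstructs the input exactly -- followed by the
    missed-cleavage products (if requested), ordered by start position.
    """

    peptides: tuple[DigestPeptide, ...]

    def fully_cleaved(self) -> list[DigestPeptide]:
        return [p for p in self.peptides if p.missed_cleavages == 0]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cuts (cut between i and i+1)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def trypsin_digest(
    protein: ProteinConstruct | str, max_missed: int = 0
) -> DigestResult:
    """Digest ``protein`` with trypsin, allowing up to ``max_missed`` skips."""
    sequence = protein.sequence if isinstance(protein, ProteinConstruct) else protein
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + [i + 1 for i in cleavage_sites(sequence)] + [len(sequence)]
    peptides: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for skip in range(0, max_missed + 1):
            j = i + 1 + skip
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(DigestPeptide(sequence[start:end], start, end, skip))
    peptides.sort(key=lambda p: (p.missed_cleavages > 0, p.start, p.end))
    return DigestResult(peptides=tuple(peptides))


@dataclass
class ReleaseReport:
    """Outcome of checking that a construct releases its designed barcodes."""

    released: dict[str, bool] = field(default_factory=dict)
    release_counts: dict[str, int] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    isobaric_carrier_peptides: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def all_released(self) -> bool:
        return bool(self.released) and all(self.released.values())


def _matches_release(product: str, full_peptide: str) -> bool:
    # A barcode internal to a construct carries the junction K/R that
    # directed its release; a C-terminal barcode does not.
    if product == full_peptide:
        return True
    return product[:-1] == full_peptide and product[-1] in "KR"


def verify_barcode_release(
    construct: ProteinConstruct,
    panel: BarcodePanel,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
    ms1_min_separation: float = 0.01,
) -> ReleaseReport:
    """Check each annotated barcode is released intact by tryptic digestion.

    A barcode annotation's label must equal the core of a panel member.  A
    release is "intact" when a fully cleaved product equals the panel
    ``full_peptide`` (with an optional single junction K/R for internal
    barcodes).  Carrier-derived products whose mass falls within
    ``ms1_min_separation`` of any barcode mass are flagged -- such peptides
    would interfere with barcode quantitation.
    """
    report = ReleaseReport()
    by_core = {m.core: m for m in panel.members}
    digest = trypsin_digest(construct, max_missed=0)
    products = digest.fully_cleaved()

    for ann in construct.barcodes():
        member = by_core.get(ann.label)
        if member is None:
            report.released[ann.label] = False
            report.failures[ann.label] = "not a member of the panel"
            continue
        hits = [p for p in products if _matches_release(p.sequence, member.full_peptide)]
        report.release_counts[ann.label] = len(hits)
        if len(hits) == 1:
            report.released[ann.label] = True
        else:
            report.released[ann.label] = False
            spanning = [
                p for p in products if p.start < ann.end and p.end > ann.start
            ]
            context = ", ".join(
                f"{p.sequence} [{p.start}, {p.end})" for p in spanning
            )
            report.failures[ann.label] = (
                f"released {len(hits)} times; products overlapping the "
                f"annotation: {context}"
            )

    barcode_products = {
        p.sequence
        for p in products
        for m in panel.members
        if _matches_release(p.sequence, m.full_peptide)
    }
    for p in products:
        if p.sequence in barcode_products:
            continue
        mass = monoisotopic_mass(p.sequence, table)
        for m in panel.members:
            if abs(mass - m.mass) < ms1_min_separation:
                report.isobaric_carrier_peptides.append((p.sequence, m.core, mass))
                break
    return report


def append_barcode(
    carrier: str,
    candidate: BarcodeCandidate,
    terminal: bool = True,
) -> ProteinConstruct:
    """Attach a barcode to the C-terminus of a carrier protein.

    If the carrier does not end in K/R an arginine junction is inserted so
    trypsin separates carrier and barcode.  With ``terminal=False`` an
    arginine is also appended after the barcode, as needed when another
    segment (e.g. the next unit of a concatemer) will follow.
    """
    junction = "" if carrier and carrier[-1] in "KR" else "R"
    seq = carrier + junction + candidate.full_peptide
    if not terminal:
        seq += "R"
    start = len(carrier) + len(junction)
    anns = (
        Annotation("carrier", 0, len(carrier), kind="carrier"),
        Annotation(candidate.core, start, start + len(candidate.full_peptide), kind="barcode"),
    )
    return ProteinConstruct(sequence=seq, annotations=anns)


def concatenate_constructs(constructs: Sequence[ProteinConstruct]) -> ProteinConstruct:
    """Join constructs end to end, shifting annotations accordingly.

    All but the last unit should have been built with ``terminal=False`` so
    each internal barcode is followed by a tryptic junction.
    """
    seq_parts: list[str] = []
    anns: list[Annotation] = []
    offset = 0
    for c in constructs:
        seq_parts.append(c.sequence)
        for a in c.annotations:
            anns.append(Annotation(a.label, a.start + offset, a.end + offset, a.kind))
        offset += len(c.sequence)
    return ProteinConstruct(sequence="".join(seq_parts), annotations=tuple(anns))
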