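"""Reverse translation with a GC-content target and mRNA layout assembly.

A barcoded protein must be encoded back into an open reading frame before a
DNA template and in-vitro-transcribed mRNA can be made.  Synonymous codons
differ in G+C count, so the ORF's GC fraction is a design degree of freedom;
higher GC (around 60%) favours mRNA stability and expression, and the
reverse translator here hits a requested GC fraction as closely as the
codon repertoire of the protein allows.

The mRNA itself is ``5'UTR + ORF + 3'UTR + poly(A)``; UTR sequences are
user-supplied and the default poly(A) tail is 120 adenosines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "CODON_CHOICES",
    "MrnaLayout",
    "ReverseTranslation",
    "reverse_translate",
    "translate",
    "gc_fraction",
    "gc_envelope",
    "assemble_mrna",
    "T7_PROMOTER_CORE",
    "IVT_FORWARD_PRIMER",
]

# T7 RNA polymerase promoter core; every IVT template's forward primer must
# carry it for transcription to initiate.
T7_PROMOTER_CORE = "TAATACGACTCACTATA"
# Forward primer used to amplify the IVT template (EcoRI site + T7 promoter
# + transcription start context).
IVT_FORWARD_PRIMER = "CGAATTCTAATACGACTCACTATAAGGAAATAAGAGAG"


def _build_codon_choices() -> Mapping[str, tuple[str, ...]]:
    """residue -> synonymous codons, lexicographically sorted (61 sense codons)."""
    table: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in table.items()}


CODON_CHOICES: Mapping[str, tuple[str, ...]] = _build_codon_choices()


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(seq.count(b) for b in "GC") / len(seq)


def _gc_count(codon: str) -> int:
    return sum(codon.count(b) for b in "GC")


def gc_envelope(protein: str) -> tuple[float, float]:
    """Feasible (min, max) GC fraction for any codon choice of ``protein``."""
    if not protein:
        return (0.0, 0.0)
    total = 3 * len(protein)
    lo = sum(min(_gc_count(c) for c in CODON_CHOICES[aa]) for aa in protein)
    hi = sum(max(_gc_count(c) for c in CODON_CHOICES[aa]) for aa in protein)
    return (lo / total, hi / total)


@dataclass(frozen=True)
class ReverseTranslation:
    """An ORF realising a protein at a requested GC target."""

    orf: str
    gc_achieved: float
    gc_target: float
    gc_feasible: tuple[float, float]
    clamped: bool


def reverse_translate(protein: str, gc_target: float) -> ReverseTranslation:
    """Encode ``protein`` as DNA with GC fraction as close to ``gc_target``
    as synonymous codon choice allows.

    The achievable total GC count is the sum over residues of each codon
    repertoire's GC counts; for the standard genetic code every residue's
    repertoire covers a contiguous integer range, so every total between
    the all-minimum and all-maximum assignments is achievable.  The nearest
    achievable total to ``gc_target * 3n`` is realised by starting from the
    minimum-GC codon at every position and raising positions left to right.
    The result is deterministic (ties broken lexicographically) and the
    achieved GC is non-decreasing in the target.
    """
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError(f"gc_target must be in [0, 1], got {gc_target}")
    for aa in protein:
        if aa not in CODON_CHOICES:
            raise ValueError(f"cannot encode residue {aa!r}")
    if not protein:
        return ReverseTranslation("", 0.0, gc_target, (0.0, 0.0), False)

    total_len = 3 * len(protein)
    per_aa = [sorted({_gc_count(c) for c in CODON_CHOICES[aa]}) for aa in protein]
    min_total = sum(v[0] for v in per_aa)
    max_total = sum(v[-1] for v in per_aa)
    desired = round(gc_target * total_len)
    clamped = not (min_total <= desired <= max_total)
    target_total = min(max(desired, min_total), max_total)

    gc_per_pos = [v[0] for v in per_aa]
    deficit = target_total - min_total
    for i, choices in enumerate(per_aa):
        if deficit == 0:
            break
        room = choices[-1] - choices[0]
        step = min(room, deficit)
        gc_per_pos[i] += step
        deficit -= step

    codons = []
    for aa, want in zip(protein, gc_per_pos):
        # lexicographically smallest codon with the chosen GC count
        codon = min(c for c in CODON_CHOICES[aa] if _gc_count(c) == want)
        codons.append(codon)
    orf = "".join(codons)
    return ReverseTranslation(
        orf=orf,
        gc_achieved=gc_fraction(orf),
        gc_target=gc_target,
        gc_feasible=(min_total / total_len, max_total / total_len),
        clamped=clamped,
    )


def translate(orf: str) -> str:
    """Translate a DNA ORF to protein (standard code, no stop expected)."""
    if len(orf) % 3:
        raise ValueError("ORF length must be divisible by 3")
    return str(Seq(orf).translate())


@dataclass(frozen=True)
class MrnaLayout:
    """UTRs and tail wrapped around an ORF (DNA alphabet throughout)."""

    utr5: str = ""
    utr3: str = ""
    polya_length: int = 120

    def __post_init__(self) -> None:
        if self.polya_length < 0:
            raise ValueError("polya_length must be >= 0")


def assemble_mrna(orf: str, layout: MrnaLayout, require_start: bool = False) -> str:
    """``utr5 + orf + utr3 + A*polya_length`` as a DNA-template string."""
    if len(orf) % 3:
        raise ValueError("ORF length must be divisible by 3")
    if require_start and not orf.startswith("ATG"):
        raise ValueError("full CDS requested but ORF does not start with ATG")
    return layout.utr5 + orf + layout.utr3 + "A" * layout.polya_length
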