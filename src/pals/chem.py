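"""Peptide mass and fragment-ion chemistry.

Monoisotopic masses, precursor m/z at arbitrary charge, and the
singly-protonated b/y fragment series used to decide whether two barcode
peptides can be told apart at the MS1 or MS2 level.  All masses are in
daltons (Da); all m/z values assume protonation (positive-ion mode).

The mass model is the standard one for peptides: a peptide's monoisotopic
mass is the sum of its residue masses plus one water (the N- and C-terminal
H and OH).  Isoleucine and leucine share an elemental composition and are
therefore exactly isobaric -- a fact the barcode-design layer has to deal
with explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "ResidueMassTable",
    "FragmentSpectrum",
    "DEFAULT_MASS_TABLE",
    "STANDARD_AMINO_ACIDS",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_ions",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Monoisotopic residue masses (Da) for the 20 standard amino acids.
# mass(I) == mass(L) exactly: identical elemental composition C6H11NO.
_RESIDUE_MONO: Mapping[str, float] = MappingProxyType(
    {
        "G": 57.02146,
        "A": 71.03711,
        "S": 87.03203,
        "P": 97.05276,
        "V": 99.06841,
        "T": 101.04768,
        "C": 103.00919,
        "L": 113.08406,
        "I": 113.08406,
        "N": 114.04293,
        "D": 115.02694,
        "Q": 128.05858,
        "K": 128.09496,
        "E": 129.04259,
        "M": 131.04049,
        "H": 137.05891,
        "F": 147.06841,
        "R": 156.10111,
        "Y": 163.06333,
        "W": 186.07931,
    }
)

WATER_MONO = 18.010565
PROTON = 1.007276

# Carbamidomethylation of cysteine (iodoacetamide alkylation), the usual
# fixed modification in in-solution tryptic digests.
CARBAMIDOMETHYL = 57.02146


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the water and proton constants.

    ``residue_masses`` covers exactly the 20 standard one-letter codes.
    Fixed modifications are expressed as a new table (see
    :meth:`with_fixed_modification`) so call sites never special-case them.
    """

    residue_masses: Mapping[str, float] = field(default_factory=lambda: _RESIDUE_MONO)
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON

    def __post_init__(self) -> None:
        missing = set(STANDARD_AMINO_ACIDS) - set(self.residue_masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.residue_masses[residue]
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None

    def with_fixed_modification(self, residue: str, delta: float) -> "ResidueMassTable":
        """Return a table with ``delta`` Da added to ``residue``.

        ``table.with_fixed_modification("C", CARBAMIDOMETHYL)`` models the
        alkylated cysteine of a standard digestion workflow.  Barcode cores
        exclude cysteine by design, so for barcodes the default (unmodified)
        table is always correct.
        """
        masses = dict(self.residue_masses)
        masses[residue] = masses[residue] + delta
        return ResidueMassTable(MappingProxyType(masses), self.water_mass, self.proton_mass)


DEFAULT_MASS_TABLE = ResidueMassTable()


def _validate_sequence(sequence: str, table: ResidueMassTable) -> None:
    for ch in sequence:
        if ch not in table.residue_masses:
            raise ValueError(f"unknown residue {ch!r} in peptide {sequence!r}")


def monoisotopic_mass(sequence: str, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic mass in Da of ``sequence`` (N->C, one-letter codes).

    The empty peptide is defined as one water, so mass is additive:
    ``mass(a + b) == mass(a) + mass(b) - water``.
    """
    _validate_sequence(sequence, table)
    return sum(table.residue_masses[ch] for ch in sequence) + table.water_mass


def precursor_mz(
    sequence: str, charge: int, table: ResidueMassTable = DEFAULT_MASS_TABLE
) -> float:
    """m/z of the [M + zH]^z+ precursor ion at the given charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(sequence, table) + charge * table.proton_mass) / charge


@dataclass(frozen=True)
class FragmentSpectrum:
    """Singly-protonated b/y fragment series of one peptide.

    ``b_ions[i-1]`` is ``(i, m/z of b_i)`` and ``y_ions[j-1]`` is
    ``(j, m/z of y_j)`` for a peptide of length n, i and j running 1..n-1.
    ``diagnostic_y`` is the subset of y ions whose N-terminal residue is
    proline: the amide bond N-terminal to proline fragments preferentially,
    making these ions prominent, so a proline placed in the barcode core
    yields a predictable confirming fragment in every MS2 spectrum.
    """

    peptide: str
    b_ions: tuple[tuple[int, float], ...]
    y_ions: tuple[tuple[int, float], ...]
    diagnostic_y: tuple[tuple[int, float], ...]


def fragment_ions(
    sequence: str, table: ResidueMassTable = DEFAULT_MASS_TABLE
) -> FragmentSpectrum:
    """Compute the charge-1 b/y series of ``sequence``.

    b_i is the sum of the first i residue masses plus a proton; y_j is the
    sum of the last j residue masses plus water plus a proton.  The series
    obey b_i + y_(n-i) == M + 2*proton for every cleavage position i.
    """
    _validate_sequence(sequence, table)
    n = len(sequence)
    if n < 2:
        raise ValueError(f"need >= 2 residues to fragment, got {sequence!r}")
    masses = [table.residue_masses[ch] for ch in sequence]
    b: list[tuple[int, float]] = []
    acc = table.proton_mass
    for i in range(n - 1):
        acc += masses[i]
        b.append((i + 1, acc))
    y: list[tuple[int, float]] = []
    acc = table.water_mass + table.proton_mass
    for j in range(n - 1):
        acc += masses[n - 1 - j]
        y.append((j + 1, acc))
    diagnostic = tuple(
        (j, mz) for j, mz in y if sequence[n - j] == "P"
    )
    return FragmentSpectrum(sequence, tuple(b), tuple(y), diagnostic)
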