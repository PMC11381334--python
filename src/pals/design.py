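"""Barcode panel design: enumerate, filter, assemble, select.

The design cascade mirrors how MS-resolvable peptide barcodes are chosen:

1. enumerate every core of a fixed length over a restricted amino-acid
   alphabet (residues prone to variable modification -- M, W, N, Q, C -- and
   the tryptic/charged residues R, K, D, E are excluded);
2. keep cores satisfying the proline rule (a proline in the variable region
   provides the MS2 diagnostic fragment);
3. assemble each core between constant six-residue flanks, giving the full
   tryptic release peptide and its mass/fragment attributes;
4. select a mutually mass-resolvable panel (MS1), or group near-isobaric
   candidates and keep those distinguishable by their fragment ions (MS2).

Under the default constraints the allowed alphabet has 11 residues, so the
enumeration yields 11^5 = 161,051 cores and the exactly-one-proline filter
leaves 5 * 10^4 = 50,000.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    DEFAULT_MASS_TABLE,
    STANDARD_AMINO_ACIDS,
    FragmentSpectrum,
    ResidueMassTable,
    fragment_ions,
    monoisotopic_mass,
    precursor_mz,
)

__all__ = [
    "DesignConstraints",
    "BarcodeCandidate",
    "BarcodePanel",
    "IsobaricGroup",
    "IsobaricLibrary",
    "CalibrationResult",
    "enumerate_cores",
    "filter_proline",
    "assemble_barcode",
    "assemble_barcodes",
    "select_panel",
    "calibrate_separation",
    "build_isobaric_library",
]

DEFAULT_EXCLUDED = frozenset("MWNQCRKDE")


@dataclass(frozen=True)
class DesignConstraints:
    """Everything the design cascade needs to know.

    ``ms1_min_separation`` is the precursor-mass gap (Da) below which two
    barcodes are considered unresolvable at MS1; ``ms2_min_separation`` is
    the analogous gap for individual b/y fragment ions.  ``mz_window`` is
    the instrument's full-scan range and ``isolation_window`` the MS2
    precursor isolation width (m/z) used for co-selection warnings.
    """

    excluded_residues: frozenset[str] = DEFAULT_EXCLUDED
    core_length: int = 5
    proline_rule: str = "exactly_one"  # or "at_least_one"
    n_term_flank: str = "GSGSGA"
    c_term_flank: str = "AGSGSG"
    ms1_min_separation: float = 0.01
    ms2_min_separation: float = 0.01
    mz_window: tuple[float, float] = (350.0, 2000.0)
    isolation_window: float = 1.2
    charges_considered: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.core_length < 1:
            raise ValueError("core_length must be >= 1")
        if not self.allowed_alphabet:
            raise ValueError("excluded_residues leaves an empty alphabet")
        if self.proline_rule not in ("exactly_one", "at_least_one"):
            raise ValueError(f"unknown proline_rule {self.proline_rule!r}")
        if self.ms1_min_separation <= 0:
            raise ValueError("ms1_min_separation must be > 0")
        for flank in (self.n_term_flank, self.c_term_flank):
            bad = set(flank) & self.excluded_residues
            if bad:
                raise ValueError(f"flank {flank!r} contains excluded residues {sorted(bad)}")

    @property
    def allowed_alphabet(self) -> str:
        return "".join(sorted(set(STANDARD_AMINO_ACIDS) - set(self.excluded_residues)))


@dataclass(frozen=True)
class BarcodeCandidate:
    """An assembled barcode: variable core between constant flanks."""

    core: str
    full_peptide: str
    mass: float
    precursor_mzs: tuple[tuple[int, float], ...]

    def fragment_spectrum(
        self, table: ResidueMassTable = DEFAULT_MASS_TABLE
    ) -> FragmentSpectrum:
        return fragment_ions(self.full_peptide, table)

    def mz_in_window(self, window: tuple[float, float]) -> bool:
        lo, hi = window
        return any(lo <= mz <= hi for _, mz in self.precursor_mzs)


@dataclass
class BarcodePanel:
    """A selected, mutually MS1-resolvable set of barcodes.

    ``assignment`` maps barcode ids ("BC0001", ...) to LNP labels once the
    panel is attached to a screen; ids are assigned in panel order.
    """

    members: list[BarcodeCandidate]
    mode: str
    tolerance_used: float
    assignment: dict[str, str | None] = field(default_factory=dict)
    target_size_unmet: bool = False
    coisolation_warnings: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignment:
            self.assignment = {bid: None for bid in self.barcode_ids()}

    def barcode_ids(self) -> list[str]:
        return [f"BC{i + 1:04d}" for i in range(len(self.members))]

    def assign_lnps(self, labels: Sequence[str]) -> None:
        if len(labels) > len(self.members):
            raise ValueError(
                f"{len(labels)} labels for {len(self.members)} barcodes"
            )
        ids = self.barcode_ids()
        self.assignment = {
            bid: (labels[i] if i < len(labels) else None) for i, bid in enumerate(ids)
        }

    def min_pairwise_separation(self) -> float:
        masses = sorted(c.mass for c in self.members)
        if len(masses) < 2:
            return float("inf")
        return min(b - a for a, b in zip(masses, masses[1:]))


def enumerate_cores(constraints: DesignConstraints) -> list[str]:
    """All ``core_length``-mers over the allowed alphabet, lexicographic.

    Count is ``|alphabet| ** core_length`` (161,051 under the defaults).
    """
    alphabet = constraints.allowed_alphabet
    return [
        "".join(t) for t in itertools.product(alphabet, repeat=constraints.core_length)
    ]


def filter_proline(cores: Iterable[str], constraints: DesignConstraints) -> list[str]:
    """Keep cores whose proline count obeys the proline rule, order preserved."""
    if constraints.proline_rule == "exactly_one":
        return [c for c in cores if c.count("P") == 1]
    return [c for c in cores if "P" in c]


def assemble_barcode(
    core: str,
    constraints: DesignConstraints,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> BarcodeCandidate:
    """Assemble ``flank + core + flank`` and populate mass attributes.

    Flanks must be free of internal K/R: a tryptic site inside a flank would
    split the barcode peptide on digestion.
    """
    for flank in (constraints.n_term_flank, constraints.c_term_flank):
        if set(flank) & set("KR"):
            raise ValueError(
                f"flank {flank!r} contains K/R and would be cleaved by trypsin"
            )
    full = constraints.n_term_flank + core + constraints.c_term_flank
    mass = monoisotopic_mass(full, table)
    mzs = tuple(
        (z, (mass + z * table.proton_mass) / z) for z in constraints.charges_considered
    )
    return BarcodeCandidate(core=core, full_peptide=full, mass=mass, precursor_mzs=mzs)


def assemble_barcodes(
    cores: Sequence[str],
    constraints: DesignConstraints,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[BarcodeCandidate]:
    """Vectorised :func:`assemble_barcode` over many cores."""
    for flank in (constraints.n_term_flank, constraints.c_term_flank):
        if set(flank) & set("KR"):
            raise ValueError(
                f"flank {flank!r} contains K/R and would be cleaved by trypsin"
            )
    flank_mass = monoisotopic_mass(
        constraints.n_term_flank + constraints.c_term_flank, table
    )
    out = []
    res = table.residue_masses
    for core in cores:
        mass = flank_mass + sum(res[ch] for ch in core)
        full = constraints.n_term_flank + core + constraints.c_term_flank
        mzs = tuple(
            (z, (mass + z * table.proton_mass) / z)
            for z in constraints.charges_considered
        )
        out.append(
            BarcodeCandidate(core=core, full_peptide=full, mass=mass, precursor_mzs=mzs)
        )
    return out


def _dedupe_exact_mass(
    candidates: Sequence[BarcodeCandidate], atol: float = 1e-9
) -> list[BarcodeCandidate]:
    """One representative per exact-mass class, lexicographically smallest core.

    Sequence permutations of one residue composition -- and I/L exchanges --
    are exactly isobaric, so without this collapse no core's mass could ever
    be called unique.
    """
    by_mass = sorted(candidates, key=lambda c: (c.mass, c.core))
    reps: list[BarcodeCandidate] = []
    for cand in by_mass:
        if reps and abs(cand.mass - reps[-1].mass) <= atol:
            continue
        reps.append(cand)
    return reps


def _coisolation_pairs(
    members: Sequence[BarcodeCandidate], ids: Sequence[str], window: float
) -> list[tuple[str, str, int]]:
    pairs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            for (zi, mi), (zj, mj) in zip(
                members[i].precursor_mzs, members[j].precursor_mzs
            ):
                if zi == zj and abs(mi - mj) < window / 2:
                    pairs.append((ids[i], ids[j], zi))
                    break
    return pairs


def select_panel(
    candidates: Sequence[BarcodeCandidate],
    constraints: DesignConstraints,
    mode: str = "strict_unique",
    target_size: int | None = None,
) -> BarcodePanel:
    """Select an MS1-resolvable panel from assembled candidates.

    ``strict_unique``: collapse exact-mass classes to one representative,
    then keep representatives whose mass is at least ``ms1_min_separation``
    from every other class.  ``max_separated``: greedy sweep over the sorted
    mass line keeping each candidate at least the separation above the last
    kept one -- for points on a line this greedy attains the maximum-
    cardinality subset.  Candidates with no precursor charge state inside
    the scan window are dropped first.
    """
    if mode not in ("strict_unique", "max_separated"):
        raise ValueError(f"unknown mode {mode!r}")
    sep = constraints.ms1_min_separation
    in_window = [c for c in candidates if c.mz_in_window(constraints.mz_window)]
    reps = _dedupe_exact_mass(in_window)

    if mode == "strict_unique":
        kept = []
        for i, cand in enumerate(reps):
            left_ok = i == 0 or cand.mass - reps[i - 1].mass >= sep
            right_ok = i == len(reps) - 1 or reps[i + 1].mass - cand.mass >= sep
            if left_ok and right_ok:
                kept.append(cand)
    else:
        kept = []
        for cand in reps:
            if not kept or cand.mass - kept[-1].mass >= sep:
                kept.append(cand)

    unmet = False
    if target_size is not None:
        if target_size > len(kept):
            unmet = True
            warnings.warn(
                f"requested panel size {target_size} exceeds achievable "
                f"{len(kept)} at separation {sep} Da; returning best achievable",
                stacklevel=2,
            )
        else:
            kept = kept[:target_size]

    panel = BarcodePanel(
        members=kept, mode=mode, tolerance_used=sep, target_size_unmet=unmet
    )
    panel.coisolation_warnings = _coisolation_pairs(
        kept, panel.barcode_ids(), constraints.isolation_window
    )
    return panel


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of searching for the MS1 tolerance giving a desired panel size."""

    tolerance: float
    panel_size: int
    desired_size: int
    achievable: bool
    # (largest tolerance giving size >= desired, smallest tolerance giving
    # size < desired): the band within which the panel crosses desired_size
    band: tuple[float, float]


def calibrate_separation(
    candidates: Sequence[BarcodeCandidate],
    desired_panel_size: int,
    constraints: DesignConstraints | None = None,
    mode: str = "strict_unique",
) -> tuple[CalibrationResult, BarcodePanel]:
    """Largest MS1 separation whose panel still has >= ``desired_panel_size``.

    Panel size is non-increasing in the tolerance, so the search reduces to
    scanning the sorted nearest-neighbour distances of the deduplicated
    mass line.
    """
    if desired_panel_size < 1:
        raise ValueError("desired_panel_size must be >= 1")
    constraints = constraints or DesignConstraints()
    in_window = [c for c in candidates if c.mz_in_window(constraints.mz_window)]
    reps = _dedupe_exact_mass(in_window)
    masses = np.array([c.mass for c in reps])

    if mode == "strict_unique":
        gaps_left = np.diff(masses, prepend=-np.inf)
        gaps_right = np.diff(masses, append=np.inf)
        nn = np.minimum(gaps_left, gaps_right)
        nn_desc = np.sort(nn)[::-1]
        if desired_panel_size > len(nn_desc):
            tol = 0.0
            achievable = False
        else:
            tol = float(nn_desc[desired_panel_size - 1])
            achievable = np.isfinite(tol) and tol > 0
        if not achievable:
            warnings.warn(
                f"panel size {desired_panel_size} unreachable in strict_unique mode",
                stacklevel=2,
            )
            tol = float(np.nextafter(0.0, 1.0))
        larger = nn_desc[nn_desc > tol]
        upper = float(larger[-1]) if len(larger) else np.inf
    else:
        # max_separated: binary-search the greedy sweep over candidate gaps.
        def size_at(tol: float) -> int:
            kept = 0
            last = -np.inf
            for m in masses:
                if m - last >= tol:
                    kept += 1
                    last = m
            return kept

        gaps = np.unique(np.diff(masses))
        gaps = gaps[gaps > 0]
        lo, hi = 0, len(gaps) - 1
        best = None
        while lo <= hi:
            mid = (lo + hi) // 2
            if size_at(float(gaps[mid])) >= desired_panel_size:
                best = mid
                lo = mid + 1
            else:
                hi = mid - 1
        achievable = best is not None
        if not achievable:
            warnings.warn(
                f"panel size {desired_panel_size} unreachable in max_separated mode",
                stacklevel=2,
            )
            tol = float(np.nextafter(0.0, 1.0))
            upper = float(gaps[0]) if len(gaps) else np.inf
        else:
            tol = float(gaps[best])
            upper = float(gaps[best + 1]) if best + 1 < len(gaps) else np.inf

    cal_constraints = DesignConstraints(
        excluded_residues=constraints.excluded_residues,
        core_length=constraints.core_length,
        proline_rule=constraints.proline_rule,
        n_term_flank=constraints.n_term_flank,
        c_term_flank=constraints.c_term_flank,
        ms1_min_separation=tol,
        ms2_min_separation=constraints.ms2_min_separation,
        mz_window=constraints.mz_window,
        isolation_window=constraints.isolation_window,
        charges_considered=constraints.charges_considered,
    )
    panel = select_panel(candidates, cal_constraints, mode=mode)
    result = CalibrationResult(
        tolerance=tol,
        panel_size=len(panel.members),
        desired_size=desired_panel_size,
        achievable=achievable,
        band=(tol, upper),
    )
    return result, panel


@dataclass(frozen=True)
class IsobaricGroup:
    """Candidates sharing precursor mass but separable by fragment ions."""

    members: tuple[BarcodeCandidate, ...]
    mass_range: tuple[float, float]


@dataclass(frozen=True)
class IsobaricLibrary:
    groups: tuple[IsobaricGroup, ...]
    members_total: int


def _fragment_matrix(
    candidates: Sequence[BarcodeCandidate], table: ResidueMassTable
) -> np.ndarray:
    """(n_candidates, 2*(L-1)) array of b then y fragment m/z values."""
    n = len(candidates)
    length = len(candidates[0].full_peptide)
    res = table.residue_masses
    seq_mass = np.empty((n, length))
    for i, cand in enumerate(candidates):
        seq_mass[i] = [res[ch] for ch in cand.full_peptide]
    b = np.cumsum(seq_mass[:, :-1], axis=1) + table.proton_mass
    y = (
        np.cumsum(seq_mass[:, ::-1][:, :-1], axis=1)
        + table.water_mass
        + table.proton_mass
    )
    return np.hstack([b, y])


def build_isobaric_library(
    candidates: Sequence[BarcodeCandidate],
    constraints: DesignConstraints,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> IsobaricLibrary:
    """Group near-isobaric candidates and keep MS2-distinguishable subsets.

    Groups are single-linkage clusters on the sorted mass line at
    ``ms1_min_separation``.  Within each group a maximal subset is retained
    greedily in lexicographic core order, admitting a candidate only if at
    least one of its b/y fragments differs by >= ``ms2_min_separation`` from
    every already-retained member.  ``members_total`` counts retained
    candidates across groups that keep >= 2 members -- the pool of barcodes
    usable beyond the strictly mass-unique panel.
    """
    if not candidates:
        return IsobaricLibrary(groups=(), members_total=0)
    sep = constraints.ms1_min_separation
    ms2_sep = constraints.ms2_min_separation
    by_mass = sorted(candidates, key=lambda c: (c.mass, c.core))

    clusters: list[list[BarcodeCandidate]] = [[by_mass[0]]]
    for cand in by_mass[1:]:
        if cand.mass - clusters[-1][-1].mass < sep:
            clusters[-1].append(cand)
        else:
            clusters.append([cand])

    groups: list[IsobaricGroup] = []
    total = 0
    for cluster in clusters:
        if len(cluster) < 2:
            continue
        cluster = sorted(cluster, key=lambda c: c.core)
        frags = _fragment_matrix(cluster, table)
        kept_idx: list[int] = []
        kept_frags = np.empty((0, frags.shape[1]))
        for i in range(len(cluster)):
            if kept_idx:
                dists = np.abs(kept_frags - frags[i]).max(axis=1)
                if dists.min() < ms2_sep:
                    continue
            kept_idx.append(i)
            kept_frags = np.vstack([kept_frags, frags[i : i + 1]])
        if len(kept_idx) < 2:
            continue
        members = tuple(cluster[i] for i in kept_idx)
        groups.append(
            IsobaricGroup(
                members=members,
                mass_range=(
                    min(c.mass for c in members),
                    max(c.mass for c in members),
                ),
            )
        )
        total += len(members)
    return IsobaricLibrary(groups=tuple(groups), members_total=total)
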