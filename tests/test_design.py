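"""Design cascade: enumeration, filtering, assembly, panel selection."""

import dataclasses

import numpy as np
import pytest

from pals.chem import monoisotopic_mass
from pals.design import (
    BarcodeCandidate,
    DesignConstraints,
    assemble_barcode,
    assemble_barcodes,
    build_isobaric_library,
    calibrate_separation,
    enumerate_cores,
    filter_proline,
    select_panel,
)


def tiny_constraints(**kw) -> DesignConstraints:
    """Small alphabet for combinatorial examples (exclude all but A, P...)."""
    defaults = dict(
        excluded_residues=frozenset("CDEFGHIKLMNQRSTVWY"),  # leaves A, P
        core_length=2,
        n_term_flank="AAAAAA",
        c_term_flank="AAAAAA",
    )
    defaults.update(kw)
    return DesignConstraints(**defaults)


class TestEnumerate:
    def test_two_letter_alphabet_squared(self):
        cores = enumerate_cores(tiny_constraints())
        assert cores == ["AA", "AP", "PA", "PP"]

    def test_single_letter(self):
        c = tiny_constraints(
            excluded_residues=frozenset(set("ACDEFGHIKLMNPQRSTVWY") - {"A"}),
            core_length=5,
        )
        assert enumerate_cores(c) == ["AAAAA"]

    def test_default_count_is_eleven_to_the_fifth(self, default_constraints):
        assert len(default_constraints.allowed_alphabet) == 11
        assert len(enumerate_cores(default_constraints)) == 11**5 == 161051

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            DesignConstraints(excluded_residues=frozenset("ACDEFGHIKLMNPQRSTVWY"))


class TestProlineFilter:
    def test_exactly_one_on_tiny_alphabet(self):
        c = tiny_constraints()
        assert filter_proline(enumerate_cores(c), c) == ["AP", "PA"]

    def test_at_least_one_keeps_multi_proline(self):
        c = tiny_constraints(proline_rule="at_least_one")
        assert filter_proline(enumerate_cores(c), c) == ["AP", "PA", "PP"]

    def test_default_exactly_one_count(self, default_constraints):
        cores = filter_proline(enumerate_cores(default_constraints), default_constraints)
        assert len(cores) == 5 * 10**4

    def test_default_at_least_one_count(self, default_constraints):
        c = dataclasses.replace(default_constraints, proline_rule="at_least_one")
        cores = filter_proline(enumerate_cores(c), c)
        assert len(cores) == 11**5 - 10**5  # 61,051


class TestAssemble:
    def test_full_peptide_structure(self, default_constraints):
        cand = assemble_barcode("APGLS", default_constraints)
        assert len(cand.full_peptide) == 17
        assert cand.full_peptide == "GSGSGA" + "APGLS" + "AGSGSG"
        assert cand.mass == pytest.approx(monoisotopic_mass(cand.full_peptide))

    def test_mass_additivity_of_assembly(self, default_constraints):
        cand = assemble_barcode("APGLS", default_constraints)
        flanks_only = monoisotopic_mass(
            default_constraints.n_term_flank + default_constraints.c_term_flank
        )
        water = 18.010565
        assert cand.mass == pytest.approx(
            flanks_only + monoisotopic_mass("APGLS") - water
        )

    def test_il_swap_isobaric_but_distinct(self, default_constraints):
        a = assemble_barcode("APGIS", default_constraints)
        b = assemble_barcode("APGLS", default_constraints)
        assert a.mass == b.mass
        assert a.full_peptide != b.full_peptide

    def test_kr_flank_rejected(self):
        # K is not excluded here, so the constraints admit it -- but a K in a
        # flank would split the barcode peptide on digestion
        bad = DesignConstraints(
            excluded_residues=frozenset("MWNQC"), n_term_flank="GSKSGA"
        )
        with pytest.raises(ValueError, match="K/R"):
            assemble_barcode("APGLS", bad)

    def test_batch_matches_single(self, default_constraints):
        batch = assemble_barcodes(["APGLS", "PVVVV"], default_constraints)
        for cand in batch:
            single = assemble_barcode(cand.core, default_constraints)
            assert cand.mass == pytest.approx(single.mass, abs=1e-9)
            assert cand.full_peptide == single.full_peptide
            assert cand.precursor_mzs == tuple(
                (z, pytest.approx(mz)) for z, mz in single.precursor_mzs
            )


def _candidate(core: str, mass: float) -> BarcodeCandidate:
    return BarcodeCandidate(
        core=core,
        full_peptide=core,
        mass=mass,
        precursor_mzs=((1, mass + 1.007276),),
    )


def _constraints_with(sep: float) -> DesignConstraints:
    return DesignConstraints(ms1_min_separation=sep, mz_window=(0.0, 1e6))


class TestSelectPanel:
    def test_colliding_middle_pair_dropped(self):
        cands = [
            _candidate("AAAAA", 100.0),
            _candidate("AAAAP", 100.0005),
            _candidate("AAAPA", 200.0),
        ]
        panel = select_panel(cands, _constraints_with(0.01), mode="strict_unique")
        assert [c.mass for c in panel.members] == [200.0]
        panel = select_panel(cands, _constraints_with(0.01), mode="max_separated")
        assert len(panel.members) == 2

    def test_all_distinct_spaced_masses_retained(self):
        cands = [_candidate(f"C{i}", 100.0 + i) for i in range(10)]
        for mode in ("strict_unique", "max_separated"):
            panel = select_panel(cands, _constraints_with(0.01), mode=mode)
            assert len(panel.members) == 10

    def test_exact_duplicates_keep_lexicographically_smallest(self):
        cands = [_candidate("BBBBB", 100.0), _candidate("AAAAA", 100.0)]
        panel = select_panel(cands, _constraints_with(0.01), mode="strict_unique")
        assert [c.core for c in panel.members] == ["AAAAA"]

    def test_greedy_matches_exhaustive_maximum(self, rng):
        """Greedy sweep attains the true maximum separated subset (DP oracle)."""

        def dp_max_subset(masses, sep):
            # longest chain over sorted masses with consecutive gaps >= sep
            ms = sorted(masses)
            best = [1] * len(ms)
            for i in range(len(ms)):
                for j in range(i):
                    if ms[i] - ms[j] >= sep:
                        best[i] = max(best[i], best[j] + 1)
            return max(best, default=0)

        for trial in range(30):
            n = int(rng.integers(2, 21))
            masses = np.round(rng.uniform(100, 110, size=n), 4)
            sep = float(rng.uniform(0.05, 2.0))
            cands = [_candidate(f"C{i:02d}", float(m)) for i, m in enumerate(masses)]
            panel = select_panel(cands, _constraints_with(sep), mode="max_separated")
            assert len(panel.members) == dp_max_subset(masses, sep)
            assert panel.min_pairwise_separation() >= sep

    def test_target_size_truncates_or_warns(self):
        cands = [_candidate(f"C{i}", 100.0 + i) for i in range(5)]
        panel = select_panel(
            cands, _constraints_with(0.01), mode="strict_unique", target_size=3
        )
        assert len(panel.members) == 3 and not panel.target_size_unmet
        with pytest.warns(UserWarning, match="exceeds achievable"):
            panel = select_panel(
                cands, _constraints_with(0.01), mode="strict_unique", target_size=99
            )
        assert panel.target_size_unmet and len(panel.members) == 5

    def test_determinism(self, default_candidates, default_constraints):
        a = select_panel(default_candidates[:2000], default_constraints)
        b = select_panel(default_candidates[:2000], default_constraints)
        assert [c.full_peptide for c in a.members] == [c.full_peptide for c in b.members]

    def test_panel_mz_within_scan_window(self, default_candidates, default_constraints):
        panel = select_panel(default_candidates, default_constraints)
        lo, hi = default_constraints.mz_window
        for cand in panel.members:
            assert any(lo <= mz <= hi for _, mz in cand.precursor_mzs)

    def test_pairwise_separation_honoured(self, default_candidates, default_constraints):
        panel = select_panel(default_candidates, default_constraints)
        assert panel.min_pairwise_separation() >= panel.tolerance_used


class TestCalibration:
    def test_singleton_always_achievable(self):
        cands = [_candidate("AAAAA", 100.0), _candidate("AAAAP", 150.0)]
        result, panel = calibrate_separation(cands, 1, _constraints_with(0.01))
        assert result.achievable
        assert len(panel.members) >= 1

    def test_panel_size_non_increasing_in_tolerance(self, rng):
        masses = rng.uniform(100, 200, size=200)
        cands = [_candidate(f"C{i:03d}", float(m)) for i, m in enumerate(masses)]
        sizes = []
        for tol in [0.001, 0.01, 0.1, 0.5, 1.0, 5.0]:
            panel = select_panel(cands, _constraints_with(tol), mode="strict_unique")
            sizes.append(len(panel.members))
        assert sizes == sorted(sizes, reverse=True)

    def test_calibrated_tolerance_reproduces_requested_size(self, rng):
        masses = rng.uniform(100, 200, size=300)
        cands = [_candidate(f"C{i:03d}", float(m)) for i, m in enumerate(masses)]
        result, panel = calibrate_separation(cands, 50, _constraints_with(0.01))
        assert result.panel_size == len(panel.members) >= 50
        # a tolerance above the band's upper edge gives a smaller panel
        above = select_panel(
            cands, _constraints_with(result.band[1] * 1.001), mode="strict_unique"
        )
        assert len(above.members) < 50


class TestIsobaricLibrary:
    def test_groups_require_ms2_distinguishability(self, default_constraints):
        # same composition, different arrangement -> same mass, different b/y
        a = assemble_barcode("APGLS", default_constraints)
        b = assemble_barcode("ASGLP", default_constraints)
        lib = build_isobaric_library([a, b], default_constraints)
        assert len(lib.groups) == 1
        assert lib.members_total == 2

    def test_il_swap_within_one_fragment_indistinguishable(self, default_constraints):
        # I<->L at the same position: every b/y ion identical
        a = assemble_barcode("APGIS", default_constraints)
        b = assemble_barcode("APGLS", default_constraints)
        lib = build_isobaric_library([a, b], default_constraints)
        assert lib.members_total == 0  # group collapses to one member

    def test_singleton_groups_excluded(self, default_constraints):
        a = assemble_barcode("APGLS", default_constraints)
        b = assemble_barcode("PVVVV", default_constraints)  # far away in mass
        lib = build_isobaric_library([a, b], default_constraints)
        assert lib.members_total == 0
        assert lib.groups == ()
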