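"""One-off profiles: enumeration, normalization, degeneracy, tolerance rule."""

import dataclasses
import itertools

import numpy as np
import pytest

from lhekit.sites import Mismatch, MismatchSet, TargetSite, hamming
from lhekit.specificity import (
    SpecificityProfile,
    classify_positions,
    combined_score,
    enumerate_one_off,
    normalize_profile,
    predict_tolerance,
    tolerated_single_mismatches,
)
from lhekit.simulate import gen_profile

from conftest import random_site


def all_cells(site):
    return [
        (lab, b)
        for lab in site.labels()
        for b in "ACGT"
        if b != site.base_at(lab)
    ]


def make_profile(site, values, theta=0.5):
    """Profile with a constant or per-cell dict of r values."""
    if isinstance(values, dict):
        r = values
    else:
        r = {cell: values for cell in all_cells(site)}
    return SpecificityProfile(enzyme="test", site=site, r=r, theta=theta)


class TestEnumeration:
    def test_sixty_variants_for_a_20bp_site(self, xid_site):
        variants = enumerate_one_off(xid_site)
        assert len(variants) == 60
        seqs = {v.sequence for _, v in variants}
        assert len(seqs) == 60
        assert all(hamming(v.sequence, xid_site.sequence) == 1 for _, v in variants)

    def test_trivial_length_two_site(self):
        assert len(enumerate_one_off(TargetSite("t", "AC"))) == 6

    def test_matches_exhaustive_enumeration_at_L4(self):
        site = TargetSite("toy", "ACGT")
        got = {v.sequence for _, v in enumerate_one_off(site)}
        brute = {
            "".join(s)
            for s in itertools.product("ACGT", repeat=4)
            if hamming("".join(s), site.sequence) == 1
        }
        assert got == brute

    def test_deterministic_order(self, xid_site):
        variants = enumerate_one_off(xid_site)
        keys = [(e.position, e.base) for (m, _) in variants for e in m]
        idx = [xid_site.labels().index(p) for p, _ in keys]
        assert idx == sorted(idx)

    def test_each_variant_rederives_its_own_entry(self, xid_site):
        from lhekit.sites import mismatches

        for m, variant in enumerate_one_off(xid_site):
            assert mismatches(xid_site, variant).entries == m.entries


class TestNormalization:
    def test_uniform_raw_normalizes_to_one(self, xid_site):
        raw = {cell: 0.37 for cell in all_cells(xid_site)}
        p = normalize_profile(raw, on_target=0.37, site=xid_site)
        assert all(v == pytest.approx(1.0) for v in p.r.values())

    def test_zero_cell_stays_zero(self, xid_site):
        raw = {cell: 0.5 for cell in all_cells(xid_site)}
        raw[(-5, "T")] = 0.0
        p = normalize_profile(raw, on_target=0.5, site=xid_site)
        assert p.r[(-5, "T")] == 0.0

    def test_matches_elementwise_division(self, xid_site):
        rng = np.random.default_rng(1)
        raw = {cell: float(rng.uniform(0, 2)) for cell in all_cells(xid_site)}
        on = 0.8
        p = normalize_profile(raw, on_target=on, site=xid_site)
        for cell, v in raw.items():
            assert p.r[cell] == pytest.approx(v / on)

    def test_zero_on_target_rejected(self, xid_site):
        raw = {cell: 0.1 for cell in all_cells(xid_site)}
        with pytest.raises(ZeroDivisionError):
            normalize_profile(raw, on_target=0.0, site=xid_site)

    def test_profile_requires_exactly_three_cells_per_position(self, xid_site):
        raw = {cell: 0.1 for cell in all_cells(xid_site)[:-1]}
        with pytest.raises(ValueError):
            SpecificityProfile(enzyme="x", site=xid_site, r=raw)


class TestClassification:
    def test_all_zero_profile_is_fully_specific(self, xid_site):
        parts = classify_positions(make_profile(xid_site, 0.0))
        assert parts["degenerate"] == []
        assert len(parts["specific"]) == 20

    def test_all_one_profile_is_fully_degenerate(self, xid_site):
        parts = classify_positions(make_profile(xid_site, 1.0))
        assert parts["specific"] == []
        assert len(parts["degenerate"]) == 20

    def test_boundary_r_equal_theta_is_specific(self, xid_site):
        # the threshold is strict: ">50%" is degenerate, 50% exactly is not
        parts = classify_positions(make_profile(xid_site, 0.5, theta=0.5))
        assert len(parts["specific"]) == 20

    def test_partition_covers_all_positions_disjointly(self, xid_site):
        rng = np.random.default_rng(7)
        r = {cell: float(rng.uniform(0, 1.2)) for cell in all_cells(xid_site)}
        parts = classify_positions(make_profile(xid_site, r))
        assert sorted(parts["specific"] + parts["degenerate"]) == sorted(
            xid_site.labels()
        )
        assert set(parts["specific"]).isdisjoint(parts["degenerate"])

    def test_generator_designated_degenerate_set_is_recovered(self, xid_site):
        rng = np.random.default_rng(3)
        degenerate = sorted(
            int(l) for l in rng.choice(xid_site.labels(), size=11, replace=False)
        )
        cells = {
            (lab, next(b for b in "ACGT" if b != xid_site.base_at(lab)))
            for lab in degenerate
        }
        p, _ = gen_profile(xid_site, cells, seed=5)
        parts = classify_positions(p)
        assert sorted(parts["degenerate"]) == degenerate
        assert len(parts["specific"]) == 9

    def test_raising_theta_never_adds_degenerate_positions(self, xid_site):
        rng = np.random.default_rng(11)
        r = {cell: float(rng.uniform(0, 1.2)) for cell in all_cells(xid_site)}
        counts = []
        for theta in (0.2, 0.5, 0.8, 1.1):
            parts = classify_positions(make_profile(xid_site, r, theta=theta))
            counts.append(len(parts["degenerate"]))
        assert counts == sorted(counts, reverse=True)


class TestToleratedSet:
    def test_boundary_cell_not_tolerated(self, xid_site):
        p = make_profile(xid_site, 0.5, theta=0.5)
        assert tolerated_single_mismatches(p) == set()

    def test_theta_zero_tolerates_everything_positive(self, xid_site):
        rng = np.random.default_rng(2)
        r = {cell: float(rng.uniform(0.01, 1)) for cell in all_cells(xid_site)}
        p = make_profile(xid_site, r, theta=0.0)
        assert tolerated_single_mismatches(p) == set(r)

    def test_count_matches_bruteforce_over_matrix(self, xid_site):
        rng = np.random.default_rng(4)
        r = {cell: float(rng.uniform(0, 1.2)) for cell in all_cells(xid_site)}
        p = make_profile(xid_site, r)
        brute = sum(v > 0.5 for v in r.values())
        assert len(tolerated_single_mismatches(p)) == brute

    def test_raising_theta_shrinks_the_tolerated_set(self, xid_site):
        rng = np.random.default_rng(8)
        r = {cell: float(rng.uniform(0, 1.2)) for cell in all_cells(xid_site)}
        prev = None
        for theta in (0.1, 0.4, 0.7, 1.0):
            cur = tolerated_single_mismatches(make_profile(xid_site, r, theta=theta))
            if prev is not None:
                assert cur <= prev
            prev = cur


def random_mismatch_set(site, rng, k):
    idxs = sorted(rng.choice(site.length, size=k, replace=False))
    entries = []
    for i in idxs:
        alts = [b for b in "ACGT" if b != site.sequence[i]]
        from lhekit.sites import index_to_label

        entries.append(
            Mismatch(index_to_label(int(i), site.length), alts[int(rng.integers(3))])
        )
    return MismatchSet(tuple(entries))


class TestToleranceRule:
    def test_both_entries_above_theta_tolerated(self, xid_site):
        r = {cell: 0.1 for cell in all_cells(xid_site)}
        r[(-10, "G")], r[(-8, "A")] = 0.8, 0.6
        p = make_profile(xid_site, r)
        pred = predict_tolerance(MismatchSet.parse("-10G-8A"), p)
        assert pred.tolerated
        assert pred.per_entry_r == (0.8, 0.6)

    def test_one_intolerant_entry_fails_the_site(self, xid_site):
        r = {cell: 0.1 for cell in all_cells(xid_site)}
        r[(-10, "G")], r[(-8, "A")] = 0.8, 0.2
        pred = predict_tolerance(MismatchSet.parse("-10G-8A"), make_profile(xid_site, r))
        assert not pred.tolerated

    def test_empty_set_always_tolerated(self, xid_site):
        assert predict_tolerance(MismatchSet(()), make_profile(xid_site, 0.0)).tolerated

    def test_reference_base_entry_rejected(self, xid_site):
        p = make_profile(xid_site, 0.3)
        with pytest.raises(ValueError):
            predict_tolerance(MismatchSet((Mismatch(-5, xid_site.base_at(-5)),)), p)

    def test_agrees_with_bruteforce_all_entries_check(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            site = random_site(rng)
            r = {cell: float(rng.uniform(0, 1.2)) for cell in all_cells(site)}
            p = make_profile(site, r)
            m = random_mismatch_set(site, rng, int(rng.integers(1, 5)))
            brute = all(r[(e.position, e.base)] > p.theta for e in m)
            assert predict_tolerance(m, p).tolerated == brute

    def test_adding_a_mismatch_never_rescues_a_site(self, xid_site):
        rng = np.random.default_rng(10)
        r = {cell: float(rng.uniform(0, 1.2)) for cell in all_cells(xid_site)}
        p = make_profile(xid_site, r)
        for _ in range(50):
            m = random_mismatch_set(xid_site, rng, int(rng.integers(1, 4)))
            base_call = predict_tolerance(m, p).tolerated
            taken = {e.position for e in m}
            free = [l for l in xid_site.labels() if l not in taken]
            lab = int(rng.choice(free))
            alts = [b for b in "ACGT" if b != xid_site.base_at(lab)]
            bigger = MismatchSet(
                tuple(sorted(m.entries + (Mismatch(lab, alts[0]),), key=lambda e: e.position))
            )
            if not base_call:
                assert not predict_tolerance(bigger, p).tolerated

    def test_combined_score_is_product_of_entry_values(self, xid_site):
        r = {cell: 0.1 for cell in all_cells(xid_site)}
        r[(-10, "G")], r[(-8, "A")] = 0.8, 0.5
        p = make_profile(xid_site, r)
        assert combined_score(MismatchSet.parse("-10G-8A"), p) == pytest.approx(0.4)
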