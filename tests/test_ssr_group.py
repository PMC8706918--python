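import math
from dataclasses import replace

import numpy as np
import pytest

from mitocompare.genome_io import CircularSequence, GenomeBundle
from mitocompare.karlin import evalue, karlin_params
from mitocompare.published import noncommon_groups
from mitocompare.ssr_detect import scan_ssrs
from mitocompare.ssr_group import (AlignScoring, build_groups, extract_flanks,
                                   group_report, score_pair)

from conftest import random_sequence


class TestKarlin:
    def test_lambda_matches_closed_form(self):
        # for +1/-2 at uniform composition, exp(lambda) solves
        # x^3 - 4x^2 + 3 = 0 => x = (3 + sqrt(21)) / 2
        lam, K, H = karlin_params(1, -2)
        assert lam == pytest.approx(math.log((3 + math.sqrt(21)) / 2), abs=1e-9)
        assert 0 < K < 1 and H > 0

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError, match="invalid scoring scheme"):
            karlin_params(1, 0)  # non-negative expected score

    def test_evalue_decreases_with_score(self):
        es = [evalue(s, 130, 130) for s in (20, 60, 130)]
        assert es[0] > es[1] > es[2]


class TestScorePair:
    def test_identical_probes_far_below_cutoff(self):
        rng = np.random.default_rng(0)
        probe = random_sequence(rng, 130, at_rich=False)
        ps = score_pair(probe, probe)
        assert ps.raw_score == 130 and ps.aligned_identity == 1.0
        assert ps.e_value < 1e-10

    def test_unrelated_probes_above_cutoff(self):
        rng = np.random.default_rng(1)
        above = 0
        for _ in range(200):
            a = random_sequence(rng, 130, at_rich=False)
            b = random_sequence(rng, 130, at_rich=False)
            if score_pair(a, b).e_value > 1e-10:
                above += 1
        assert above == 200

    def test_reversed_probe_not_matched(self):
        rng = np.random.default_rng(2)
        a = random_sequence(rng, 130, at_rich=False)
        assert score_pair(a, a[::-1]).e_value > 1e-10

    def test_empty_probe_rejected(self):
        with pytest.raises(ValueError):
            score_pair("", "ACGT")


class TestExtractFlanks:
    def test_interior_locus_full_flanks(self):
        rng = np.random.default_rng(3)
        s = random_sequence(rng, 2000)
        bundle = GenomeBundle(CircularSequence("g", s, True))
        interior = [l for l in scan_ssrs(bundle) if 100 < l.start < 1800]
        assert interior, "AT-rich draw must contain an interior locus"
        locus = interior[0]
        f = extract_flanks(locus, bundle)
        assert f.left_flank == s[locus.start - 61 : locus.start - 1]
        assert f.right_flank == s[locus.end : locus.end + 60]
        assert f.probe == f.left_flank + s[locus.start - 1 : locus.end] + f.right_flank

    def test_linear_truncates(self):
        s = "GATCGTACGGATCCTAGCA" + "A" * 12 + "CATGC"
        bundle = GenomeBundle(CircularSequence("g", s, False))
        locus = next(l for l in scan_ssrs(bundle) if l.unit_seq == "A")
        f = extract_flanks(locus, bundle)
        assert f.left_flank == "GATCGTACGGATCCTAGC"  # truncated, repeat absorbs trailing A
        assert f.right_flank == "CATGC"

    def test_circular_wraps(self):
        s = "GC" * 60 + "TT" + "A" * 12  # locus ends at the origin join
        bundle = GenomeBundle(CircularSequence("g", s, True))
        locus = next(l for l in scan_ssrs(bundle) if l.unit_seq == "A")
        assert locus.end == len(s)
        f = extract_flanks(locus, bundle)
        assert len(f.right_flank) == 60  # wraps past the origin
        assert f.right_flank == s[:60]


def _trio(seed: int = 20, length: int = 6000):
    """Three synthetic near-identical genomes with shared SSRs."""
    from mitocompare.synthetic_data import generate_mitogenome, mutate_genome

    base, _ = generate_mitogenome(length=length, control_region_length=800, seed=seed)
    g2, _ = mutate_genome(base, n_snps=6, indel_spec=[(2, "del")], seed=seed + 1)
    g3, _ = mutate_genome(base, n_snps=5, indel_spec=[(3, "ins")], seed=seed + 2)
    bundles = [base,
               GenomeBundle(replace(g2.sequence, seq_id="g2")),
               GenomeBundle(replace(g3.sequence, seq_id="g3"))]
    return bundles


def _flank_all(bundles):
    return [extract_flanks(l, b) for b in bundles for l in scan_ssrs(b)]


class TestBuildGroups:
    def test_identical_genomes_all_common(self):
        rng = np.random.default_rng(4)
        s = random_sequence(rng, 3000)
        bundles = [GenomeBundle(CircularSequence(f"g{i}", s, True)) for i in range(3)]
        groups = build_groups(_flank_all(bundles))
        assert groups and all(g.category == "common" for g in groups)
        rep = group_report(groups)
        assert list(rep["venn"]) == [("g0", "g1", "g2")]

    def test_conservation_every_locus_in_one_group(self):
        bundles = _trio()
        flanked = _flank_all(bundles)
        groups = build_groups(flanked)
        assert sum(len(g.members) for g in groups) == len(flanked)
        assert all(len({m.source_genome for m in g.members}) == len(g.members)
                   for g in groups)

    def test_permutation_invariance(self):
        bundles = _trio(seed=30)
        flanked = _flank_all(bundles)
        key = lambda gs: sorted(
            tuple(sorted((m.source_genome, m.locus.start) for m in g.members))
            for g in gs)
        rng = np.random.default_rng(0)
        shuffled = list(flanked)
        rng.shuffle(shuffled)
        assert key(build_groups(flanked)) == key(build_groups(shuffled))

    def test_coordinate_shift_keeps_pair_grouped(self):
        # same locus shifted 1 bp by an upstream indel still groups
        rng = np.random.default_rng(5)
        s = random_sequence(rng, 1000)
        s = s[:500] + "C" + "ATATA" * 2 + "C" + s[511:]
        s2 = s[:300] + s[301:]  # 1 bp deletion upstream shifts coordinates
        b1 = GenomeBundle(CircularSequence("a", s, True))
        b2 = GenomeBundle(CircularSequence("b", s2, True))
        f1 = [f for f in _flank_all([b1]) if f.locus.unit_seq == "ATATA"]
        f2 = [f for f in _flank_all([b2]) if f.locus.unit_seq == "ATATA"]
        assert f1 and f2 and f1[0].locus.start == f2[0].locus.start + 1
        groups = build_groups(f1 + f2)
        # spans both inputs, so the group is "common" for this 2-genome run
        assert [g.category for g in groups] == ["common"]
        assert len(groups[0].members) == 2

    def test_unrelated_flanks_split(self):
        rng = np.random.default_rng(6)
        mk = lambda: random_sequence(rng, 300) + "G" + "TACAC" * 2 + "A" + random_sequence(rng, 300)
        b1 = GenomeBundle(CircularSequence("a", mk(), True))
        b2 = GenomeBundle(CircularSequence("b", mk(), True))
        f = [x for x in _flank_all([b1, b2]) if x.locus.unit_seq == "TACAC"]
        assert len(f) == 2
        groups = build_groups(f)
        assert all(g.category == "singleton" for g in groups)

    def test_cutoff_monotonicity(self):
        flanked = _flank_all(_trio(seed=40))
        n_strict = len(build_groups(flanked, cutoff=1e-30))
        n_default = len(build_groups(flanked, cutoff=1e-10))
        n_loose = len(build_groups(flanked, cutoff=1e-3))
        assert n_strict >= n_default >= n_loose

    def test_one_member_per_genome(self):
        flanked = _flank_all(_trio(seed=50))
        for g in build_groups(flanked):
            genomes = [m.source_genome for m in g.members]
            assert len(genomes) == len(set(genomes))


class TestGroupReport:
    def test_categories_on_trio(self):
        groups = build_groups(_flank_all(_trio(seed=60)))
        rep = group_report(groups)
        assert rep["n_groups"] == sum(rep["per_category"].values())
        assert rep["per_category"]["common"] >= 0.8 * rep["n_groups"]

    def test_published_noncommon_membership(self):
        # published non-common groups: 5 pairwise (3 HN+YN, 2 with TA) and
        # 5 singletons (2 HN, 3 TA, none YN)
        df = noncommon_groups()
        pairwise = df[df["group"].str.startswith("SSRGroup")]
        singles = df[df["group"].str.startswith("Singleton")]
        assert pairwise["group"].nunique() == 5
        assert singles["group"].nunique() == 5
        combos = pairwise.groupby("group")["genome"].apply(lambda g: frozenset(g))
        assert sum(c == frozenset({"WBPHHN", "WBPHYN"}) for c in combos) == 3
        assert singles["genome"].value_counts().to_dict() == {"WBPHTA": 3, "WBPHHN": 2}
        assert "WBPHYN" not in set(singles["genome"])
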