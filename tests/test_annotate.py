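"""Hit-table dialect, best-hit selection and the domain decision rules."""

from __future__ import annotations

import io

import numpy as np
import pytest

from marinepde import annotate, synthetic
from marinepde.align import AlignmentHit
from marinepde.annotate import (
    AnnotationError,
    AnnotationThresholds,
    decide_candidate,
    domain_in_match_coverage,
    parse_tabular_hits,
    select_best_hit,
)
from marinepde.refdb import DomainSpan, ReferenceEnzyme, ReferenceSet


def _hit(**overrides) -> AlignmentHit:
    base = dict(
        query_id="q1", stitle="ref1 some description", pident=60.0,
        qcovs=90.0, qlen=100, slen=120, aln_len=95, mismatches=30,
        gap_opens=1, qstart=3, qend=97, sstart=10, send=105,
        evalue=1e-30, bitscore=120.0,
    )
    base.update(overrides)
    return AlignmentHit(**base)


class TestTabularDialect:
    def test_positional_column_mapping(self):
        row = ("q1\tref9 chitinase from somewhere\t45.5\t80\t200\t180\t150"
               "\t70\t2\t20\t169\t15\t160\t1e-40\t155.2\n")
        hits = parse_tabular_hits(io.StringIO(row))
        h = hits[0]
        assert h.query_id == "q1"
        assert h.subject_id == "ref9"
        assert (h.qstart, h.qend) == (20, 169)   # fields 10-11
        assert (h.sstart, h.send) == (15, 160)   # fields 12-13
        assert h.pident == 45.5 and h.bitscore == 155.2

    def test_wrong_field_count_reports_line_number(self):
        rows = "\t".join(["a"] * 14)
        with pytest.raises(AnnotationError, match="line 1"):
            parse_tabular_hits(io.StringIO(rows + "\n"))

    def test_non_numeric_coordinate_reports_line_number(self):
        good = ("q\tr\t50\t80\t100\t100\t90\t40\t1\t1\t90\t1\t90"
                "\t1e-10\t100\n")
        bad = good.replace("\t90\t1e-10", "\tXX\t1e-10")
        with pytest.raises(AnnotationError, match="line 2"):
            parse_tabular_hits(io.StringIO(good + bad))

    def test_write_parse_roundtrip_of_random_hits(self):
        rng = np.random.default_rng(5)
        hits = []
        for i in range(100):
            qlen = int(rng.integers(50, 400))
            slen = int(rng.integers(50, 400))
            qs = int(rng.integers(1, qlen))
            ss = int(rng.integers(1, slen))
            hits.append(_hit(
                query_id=f"q{i}", stitle=f"ref{i} desc {i}",
                pident=round(float(rng.uniform(20, 100)), 3),
                qlen=qlen, slen=slen,
                qstart=qs, qend=int(rng.integers(qs, qlen + 1)),
                sstart=ss, send=int(rng.integers(ss, slen + 1)),
                evalue=float(f"{10.0 ** -rng.uniform(3, 60):.3e}"),
                bitscore=round(float(rng.uniform(40, 400)), 1),
            ))
        buf = io.StringIO(annotate.hits_to_string(hits))
        assert parse_tabular_hits(buf) == hits


class TestBestHit:
    def test_highest_bitscore_wins(self):
        low = _hit(bitscore=50.0)
        high = _hit(bitscore=80.0, stitle="ref2 x")
        assert select_best_hit([low, high]) is high

    def test_tie_broken_by_lower_evalue(self):
        a = _hit(evalue=1e-10)
        b = _hit(evalue=1e-20, stitle="ref2 x")
        assert select_best_hit([a, b]) is b

    def test_full_tie_broken_by_subject_id_every_run(self):
        a = _hit(stitle="refA x")
        b = _hit(stitle="refB x")
        for ordering in ([a, b], [b, a]):
            assert select_best_hit(ordering).subject_id == "refA"

    def test_empty_input_is_no_annotation(self):
        assert select_best_hit([]) is None


class TestDomainCoverage:
    @pytest.mark.parametrize(
        ("domain", "match", "expected"),
        [
            ((101, 200), (1, 180), 0.80),   # overlap 180-101+1 = 80 of 100
            ((50, 99), (1, 200), 1.0),
            ((10, 20), (100, 200), 0.0),
        ],
    )
    def test_overlap_fractions(self, domain, match, expected):
        span = DomainSpan("GH18", *domain)
        assert domain_in_match_coverage(span, *match) == pytest.approx(expected)


def _ref_with_domain(ref_id="ref1", family="GH18", start=10, end=69,
                     enzyme_type="chitinase", length=120):
    return ReferenceEnzyme(
        ref_id=ref_id, sequence="A" * length, enzyme_type=enzyme_type,
        cazy_family=family,
        domains=(DomainSpan(family, start, end),),
    )


class TestDecideCandidate:
    thresholds = AnnotationThresholds()

    def test_same_family_full_coverage_accepts(self):
        ref = _ref_with_domain()
        hit = _hit(qlen=120, slen=120, qstart=1, qend=120, sstart=1,
                   send=120)
        qdoms = [DomainSpan("GH18", 20, 79)]
        accepted, ann, trace = decide_candidate(qdoms, ref, hit,
                                                self.thresholds, "gX")
        assert accepted
        assert ann.enzyme_type == "chitinase"
        assert ann.matched_family == "GH18"
        assert any("accept" in line for line in trace)

    def test_query_coverage_just_below_threshold_rejects(self):
        ref = _ref_with_domain(start=1, end=60)
        # query domain 100 long, match covers 79 of it -> 0.79 < 0.80
        hit = _hit(qlen=200, slen=120, qstart=1, qend=179, sstart=1,
                   send=120)
        qdoms = [DomainSpan("GH18", 101, 200)]
        accepted, ann, trace = decide_candidate(qdoms, ref, hit,
                                                self.thresholds)
        assert not accepted and ann is None
        assert any("0.790" in line for line in trace)

    def test_reference_without_domains_rejects_with_reason(self):
        ref = ReferenceEnzyme("bare", "A" * 120, "chitinase", "GH18")
        accepted, _, trace = decide_candidate(
            [DomainSpan("GH18", 1, 50)], ref, _hit(), self.thresholds)
        assert not accepted
        assert "reject: ref-no-domain" in trace

    def test_family_mismatch_rejects(self):
        ref = _ref_with_domain(family="GH18")
        accepted, _, trace = decide_candidate(
            [DomainSpan("GH19", 10, 69)], ref,
            _hit(qlen=120, slen=120, qstart=1, qend=120, sstart=1, send=120),
            self.thresholds)
        assert not accepted
        assert any("no family match" in line for line in trace)

    def test_pure_function_same_trace(self):
        ref = _ref_with_domain()
        hit = _hit(qlen=120, slen=120, qstart=1, qend=120, sstart=1,
                   send=120)
        qdoms = [DomainSpan("GH18", 20, 79)]
        results = [decide_candidate(qdoms, ref, hit, self.thresholds)
                   for _ in range(3)]
        assert results[0] == results[1] == results[2]


@pytest.fixture(scope="module")
def refset():
    refset, _, _ = synthetic.generate_reference_set(n_per_type=2, seed=8)
    return refset


@pytest.fixture(scope="module")
def sweep_inputs(refset):
    refs = list(refset.ids)
    specs = [
        synthetic.PlantSpec(refs[i % len(refs)], target,
                            mutation_profile="uniform")
        for i, target in enumerate(
            [24, 27, 31, 33, 37, 42, 47, 55, 65, 80, 90])
    ]
    proteome, _, qdoms = synthetic.generate_proteome(
        refset, specs, n_decoys=2, seed=6, genome_id="gS")
    hits = annotate.search_proteome(proteome, refset, max_evalue=10.0)
    return refset, qdoms, {"gS": hits}


class TestAnnotateGenome:
    def test_planted_intact_homolog_annotated(self, refset):
        ref_id = next(r.ref_id for r in refset
                      if r.enzyme_type == "chitinase")
        proteome, truth, qdoms = synthetic.generate_proteome(
            refset, [synthetic.PlantSpec(ref_id, 90.0)], n_decoys=0,
            seed=3, genome_id="g1")
        anns = annotate.annotate_genome(proteome, refset, qdoms,
                                        genome_id="g1")
        assert len(anns) == 1
        assert anns[0].enzyme_type == "chitinase"
        assert anns[0].genome_id == "g1"

    def test_scrambled_domain_rejected(self, refset):
        ref_id = refset.ids[0]
        proteome, _, qdoms = synthetic.generate_proteome(
            refset, [synthetic.PlantSpec(ref_id, 90.0, domain_intact=False)],
            n_decoys=0, seed=3, genome_id="g1")
        anns = annotate.annotate_genome(proteome, refset, qdoms,
                                        genome_id="g1")
        assert anns == []

    def test_decoy_only_proteome_yields_nothing(self, refset):
        proteome, _, qdoms = synthetic.generate_proteome(
            refset, [], n_decoys=8, seed=4, genome_id="g1")
        anns = annotate.annotate_genome(proteome, refset, qdoms,
                                        genome_id="g1")
        assert anns == []

    def test_empty_proteome(self, refset):
        assert annotate.annotate_genome({}, refset, {}) == []

    def test_id_collision_is_error(self, refset):
        rid = refset.ids[0]
        with pytest.raises(AnnotationError, match="collision"):
            annotate.annotate_genome({rid: "MKLV"}, refset, {})


class TestThresholdSweep:
    def test_single_cell_equals_annotate_genome(self, sweep_inputs):
        refset, qdoms, hits_by_genome = sweep_inputs
        counts, accepted = annotate.threshold_sweep(
            hits_by_genome, qdoms, refset, [30.0], [0.8])
        direct = annotate.annotate_from_hits(
            hits_by_genome["gS"], qdoms, refset, genome_id="gS")
        assert counts.loc[30.0, 0.8] == len(direct)
        assert accepted[(30.0, 0.8)] == {("gS", a.protein_id)
                                         for a in direct}

    def test_monotone_in_both_axes_by_set_inclusion(self, sweep_inputs):
        refset, qdoms, hits_by_genome = sweep_inputs
        identities = [25.0, 30.0, 35.0, 50.0]
        coverages = [0.6, 0.8, 0.9]
        counts, accepted = annotate.threshold_sweep(
            hits_by_genome, qdoms, refset, identities, coverages)
        for cov in coverages:
            for lo, hi in zip(identities, identities[1:]):
                assert accepted[(hi, cov)] <= accepted[(lo, cov)]
        for ident in identities:
            for lo, hi in zip(coverages, coverages[1:]):
                assert accepted[(ident, hi)] <= accepted[(ident, lo)]
        # distant uniform-profile homologs make the identity axis strict
        assert counts.loc[50.0, 0.8] < counts.loc[25.0, 0.8]

    def test_empty_grid_is_error(self, sweep_inputs):
        refset, qdoms, hits_by_genome = sweep_inputs
        with pytest.raises(AnnotationError):
            annotate.threshold_sweep(hits_by_genome, qdoms, refset, [], [0.8])
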