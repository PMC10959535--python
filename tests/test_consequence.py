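"""Event application, consequence classification, damage proportions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chemreprog.consequence import (DAMAGING_CATEGORIES, ConsequenceCall,
                                    alt_is_inclusion, apply_event,
                                    classify_consequence, reference_form,
                                    splicing_damage_differential,
                                    splicing_damage_standing)
from chemreprog.errors import UndefinedResultError, ValidationError
from chemreprog.gene_models import spliced_sequence
from chemreprog.splicing import psi_matrix
from chemreprog.synthetic import (simulate_genome_annotation,
                                  simulate_splicing_counts)


def _events_of(annotation, etype=None, category=None):
    truth = annotation.truth
    mask = pd.Series(True, index=truth.index)
    if etype:
        mask &= truth["type"] == etype
    if category:
        mask &= truth["category"] == category
    ids = set(truth.loc[mask, "event_id"])
    return [e for e in annotation.events if e.event_id in ids]


@pytest.fixture(scope="module")
def big_annotation():
    return simulate_genome_annotation(seed=5, n_genes=60)


class TestApplyEvent:
    def test_se_exclusion_shortens_by_exon_length(self, big_annotation,
                                                  ):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        for e in _events_of(big_annotation, etype="SE"):
            t = tr[e.transcript_id]
            ref = apply_event(t, e, big_annotation.genome, "inclusion")
            alt = apply_event(t, e, big_annotation.genome, "exclusion")
            exon_len = e.alt_region[0][1] - e.alt_region[0][0]
            assert len(ref.mrna) - len(alt.mrna) == exon_len

    def test_ri_inclusion_lengthens_by_intron_length(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        for e in _events_of(big_annotation, etype="RI"):
            t = tr[e.transcript_id]
            ref = apply_event(t, e, big_annotation.genome, "exclusion")
            alt = apply_event(t, e, big_annotation.genome, "inclusion")
            intron_len = e.alt_region[0][1] - e.alt_region[0][0]
            assert len(alt.mrna) - len(ref.mrna) == intron_len

    def test_a5ss_matches_per_base_resplicing_oracle(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        genome = big_annotation.genome
        for e in (_events_of(big_annotation, etype="A5SS")
                  + _events_of(big_annotation, etype="A3SS")):
            t = tr[e.transcript_id]
            alt = apply_event(t, e, genome, "exclusion")
            seg = e.alt_region[0]
            # oracle: drop the segment's bases from the reference exon set
            # base by base and re-splice
            kept = [p for a, b in t.exons for p in range(a, b)
                    if not (seg[0] <= p < seg[1])]
            seq = "".join(genome[t.chrom][p] for p in kept)
            if t.strand == "-":
                from Bio.Seq import Seq
                seq = str(Seq(seq).reverse_complement())
            assert alt.mrna == seq
            assert abs(len(alt.mrna) - t.spliced_length) == seg[1] - seg[0]

    def test_requesting_reference_form_is_identity(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        for e in big_annotation.events[:10]:
            t = tr[e.transcript_id]
            form = reference_form(t, e)
            applied = apply_event(t, e, big_annotation.genome, form)
            assert applied.mrna == spliced_sequence(t, big_annotation.genome)
            assert applied.cds_offset == t.cds_offset

    def test_incompatible_region_rejected(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        e = big_annotation.events[0]
        other_t = next(t for t in big_annotation.transcripts
                       if t.transcript_id != e.transcript_id)
        with pytest.raises(ValidationError):
            apply_event(other_t, e, big_annotation.genome, "inclusion")


class TestClassify:
    def test_all_constructed_categories_recovered(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        truth = big_annotation.truth.set_index("event_id")
        for e in big_annotation.events:
            call = classify_consequence(tr[e.transcript_id], e,
                                        big_annotation.genome,
                                        big_annotation.domains)
            assert call.category == truth.at[e.event_id, "category"], \
                f"{e.event_id} ({truth.at[e.event_id, 'type']})"

    def test_frameshift_implies_non_multiple_of_three(self, big_annotation):
        from chemreprog.consequence import (_alternative_exons, _coding_change)
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        for e in big_annotation.events:
            t = tr[e.transcript_id]
            call = classify_consequence(t, e, big_annotation.genome,
                                        big_annotation.domains)
            _, removed, inserted = _alternative_exons(t, e)
            rem, ins = _coding_change(t, removed, inserted)
            if call.category == "frameshift":
                assert (ins - rem) % 3 != 0

    def test_premature_stop_reports_new_stop_position(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        for e in _events_of(big_annotation, category="premature_stop"):
            t = tr[e.transcript_id]
            call = classify_consequence(t, e, big_annotation.genome,
                                        big_annotation.domains)
            ref_len = t.spliced_cds_length // 3 - 1  # minus stop codon
            assert call.new_stop_aa is not None and call.new_stop_aa <= ref_len

    def test_utr_event_is_noncoding(self, big_annotation):
        tr = {t.transcript_id: t for t in big_annotation.transcripts}
        for e in _events_of(big_annotation, category="noncoding_region"):
            t = tr[e.transcript_id]
            call = classify_consequence(t, e, big_annotation.genome,
                                        big_annotation.domains)
            assert call.category == "noncoding_region"
            assert not call.damaging


class TestDamage:
    @staticmethod
    def _calls(categories):
        return {f"e{i}": ConsequenceCall(f"e{i}", "t", c)
                for i, c in enumerate(categories)}

    def test_proportion_three_of_ten(self):
        cats = ["frameshift", "premature_stop", "domain_loss"] + \
               ["no_disruption"] * 7
        calls = self._calls(cats)
        rec = pd.DataFrame({"event_id": list(calls), "selected": [True] * 10})
        report = splicing_damage_differential(calls, rec)
        assert report.proportion == pytest.approx(0.3)

    def test_zero_selected_events_undefined(self):
        calls = self._calls(["frameshift"])
        rec = pd.DataFrame({"event_id": ["e0"], "selected": [False]})
        with pytest.raises(UndefinedResultError):
            splicing_damage_differential(calls, rec)

    def test_order_invariance(self, rng):
        cats = ["frameshift"] * 4 + ["no_disruption"] * 6
        calls = self._calls(cats)
        rec = pd.DataFrame({"event_id": list(calls), "selected": [True] * 10})
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert splicing_damage_differential(calls, rec).proportion == \
            splicing_damage_differential(calls, shuffled).proportion

    def test_standing_mode_counts_present_damaging_isoforms(self):
        calls = {"e0": ConsequenceCall("e0", "t", "frameshift"),
                 "e1": ConsequenceCall("e1", "t", "no_disruption")}
        psi = pd.DataFrame({
            "event_id": ["e0", "e1", "e0", "e1"],
            "sample": ["s1", "s1", "s2", "s2"],
            "psi": [0.95, 0.5, 0.5, 0.5],  # e0 damaging form = exclusion
            "coverage": [50] * 4,
        })
        out = splicing_damage_standing(calls, psi, {"e0": False, "e1": False},
                                       presence_threshold=0.1)
        out = out.set_index("sample")
        # s1: exclusion psi of e0 = 0.05 < 0.1 -> absent; s2: 0.5 -> present
        assert out.at["s1", "proportion"] == pytest.approx(0.0)
        assert out.at["s2", "proportion"] == pytest.approx(0.5)


def test_damage_fraction_recovered_through_full_pipeline():
    """A 0.3 damaging mix survives simulation, testing, and selection."""
    mix = {"frameshift": 0.1, "premature_stop": 0.1, "domain_loss": 0.1,
           "no_disruption": 0.4, "noncoding_region": 0.3}
    ann = simulate_genome_annotation(seed=21, n_genes=100, category_mix=mix)
    tr = {t.transcript_id: t for t in ann.transcripts}
    counts, _ = simulate_splicing_counts(ann.events, psi_control=0.5,
                                         delta=0.3, n_reps=4, depth=500,
                                         seed=21)
    psi = psi_matrix(counts)
    groups = dict(zip(counts["sample"], counts["group"]))
    from chemreprog.splicing import differential_splicing
    rec = differential_splicing(psi, groups, "control", "treated")
    calls = {e.event_id: classify_consequence(tr[e.transcript_id], e,
                                              ann.genome, ann.domains)
             for e in ann.events}
    report = splicing_damage_differential(calls, rec)
    lo, hi = sps.binom.interval(0.95, report.n_events, 0.3)
    assert lo / report.n_events <= report.proportion <= hi / report.n_events
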