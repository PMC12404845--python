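import pytest

from picoscreen.corpus_io import deduplicate
from picoscreen.criteria_prompt import CHAIN_ORDER
from picoscreen.llm_backend import BackendParams, MockBackend
from picoscreen.pdf_structure import structure_pages
from picoscreen.screening import (
    default_task_suite,
    screen_full_text,
    screen_records,
)
from picoscreen.synthetic_corpus import (
    CorpusProfile,
    GoldLabel,
    generate_corpus,
    generate_fulltext_pages,
    inject_duplicates,
    read_gold_csv,
    stratified_sample,
    strip_sentinels,
    write_gold_csv,
)


class TestGenerateCorpus:
    def test_class_counts_and_determinism(self):
        profile = CorpusProfile(n_records=100, prevalence=0.1, seed=11)
        records, labels = generate_corpus(profile)
        assert len(records) == 100
        assert sum(l.decision == "include" for l in labels) == 10
        assert sum(l.decision == "exclude" for l in labels) == 90
        records2, labels2 = generate_corpus(profile)
        assert records == records2 and labels == labels2

    def test_sentinels_consistent_with_labels(self):
        records, labels = generate_corpus(CorpusProfile(50, 0.2, seed=3))
        for record, label in zip(records, labels):
            if label.decision == "include":
                assert "«INC»" in record.abstract
                assert "«EXC:" not in record.abstract
            else:
                assert f"«EXC:{label.reason_dimension}»" in record.abstract

    def test_reason_mix_concentrated(self):
        profile = CorpusProfile(60, 0.1, reason_mix={"outcome": 1.0}, seed=2)
        records, labels = generate_corpus(profile)
        for record, label in zip(records, labels):
            if label.decision == "exclude":
                assert label.reason_dimension == "outcome"
                assert "«EXC:outcome»" in record.abstract

    def test_two_seeds_same_counts_different_content(self):
        r1, l1 = generate_corpus(CorpusProfile(80, 0.1, seed=1))
        r2, l2 = generate_corpus(CorpusProfile(80, 0.1, seed=2))
        count = lambda ls: sum(l.decision == "include" for l in ls)
        assert count(l1) == count(l2) == 8
        assert [r.title for r in r1] != [r.title for r in r2]

    def test_invalid_profiles(self):
        with pytest.raises(ValueError):
            CorpusProfile(10, prevalence=0.0)
        with pytest.raises(ValueError):
            CorpusProfile(10, reason_mix={"outcome": 0.5})
        with pytest.raises(ValueError):
            CorpusProfile(10, reason_mix={"bogus": 1.0})

    def test_reason_labels_come_from_taxonomy(self, taxonomy):
        _, labels = generate_corpus(CorpusProfile(40, 0.1, seed=4))
        for label in labels:
            if label.decision == "exclude":
                assert label.reason_label == taxonomy.label_for(label.reason_dimension)


@pytest.fixture(scope="module")
def pool():
    return generate_corpus(CorpusProfile(n_records=1500, prevalence=0.1, seed=21))


class TestStratifiedSample:
    def test_first_stage_split_400_at_1_to_9(self, pool):
        records, labels = stratified_sample(*pool, total=400,
                                            ratio_included_to_excluded=(1, 9), seed=0)
        assert len(records) == 400
        assert sum(l.decision == "include" for l in labels) == 40
        assert sum(l.decision == "exclude" for l in labels) == 360

    def test_second_stage_split_80_at_3_to_1(self, pool):
        records, labels = stratified_sample(*pool, total=80,
                                            ratio_included_to_excluded=(3, 1), seed=0)
        assert sum(l.decision == "include" for l in labels) == 60
        assert sum(l.decision == "exclude" for l in labels) == 20

    def test_empty_total(self, pool):
        assert stratified_sample(*pool, total=0, ratio_included_to_excluded=(1, 9)) == ([], [])

    def test_non_integral_split_errors(self, pool):
        with pytest.raises(ValueError, match="evenly"):
            stratified_sample(*pool, total=100, ratio_included_to_excluded=(1, 2))

    def test_insufficient_pool_errors(self):
        pool = generate_corpus(CorpusProfile(50, 0.1, seed=1))
        with pytest.raises(ValueError, match="too small"):
            stratified_sample(*pool, total=400, ratio_included_to_excluded=(1, 9))

    def test_seed_deterministic_no_replacement(self, pool):
        s1 = stratified_sample(*pool, total=400, ratio_included_to_excluded=(1, 9), seed=7)
        s2 = stratified_sample(*pool, total=400, ratio_included_to_excluded=(1, 9), seed=7)
        assert s1 == s2
        ids = [r.record_id for r in s1[0]]
        assert len(ids) == len(set(ids))


class TestInjectDuplicates:
    def test_rate_zero(self):
        records, _ = generate_corpus(CorpusProfile(20, 0.1, seed=1))
        augmented, report = inject_duplicates(records, 0.0, seed=1)
        assert augmented == records
        assert report.removed_count == 0 and report.clusters == []

    def test_dedup_recovers_ground_truth(self):
        records, _ = generate_corpus(CorpusProfile(100, 0.1, seed=8))
        augmented, expected = inject_duplicates(records, 0.1, seed=8)
        assert len(augmented) == 110
        kept, observed = deduplicate(augmented)
        assert kept == records  # originals kept, order preserved
        assert observed == expected

    def test_no_false_merges(self):
        records, _ = generate_corpus(CorpusProfile(100, 0.1, seed=9))
        augmented, _ = inject_duplicates(records, 0.2, seed=9)
        _, report = deduplicate(augmented)
        assert report.unique_count == len(records)


class TestFulltextPages:
    def test_imrad_layout_yields_canonical_sections(self, taxonomy):
        records, labels = generate_corpus(CorpusProfile(5, 0.2, seed=6))
        article = structure_pages(
            generate_fulltext_pages(records[0], labels[0], layout="imrad"),
            record_id=records[0].record_id,
        )
        canonical = {"methods", "results", "discussion", "conclusion"}
        assert canonical <= set(article.sections)
        assert "title" in article.sections

    def test_headingless_layout_front_matter_only(self):
        records, labels = generate_corpus(CorpusProfile(5, 0.2, seed=6))
        article = structure_pages(
            generate_fulltext_pages(records[0], labels[0], layout="headingless"),
            record_id=records[0].record_id,
        )
        assert set(article.sections) <= {"title", "abstract"}

    def test_outcome_sentinel_lands_in_results(self):
        records, _ = generate_corpus(CorpusProfile(3, 0.2, seed=1))
        gold = GoldLabel(records[0].record_id, "exclude", "outcome", "reason")
        article = structure_pages(generate_fulltext_pages(records[0], gold),
                                  record_id=records[0].record_id)
        assert "«EXC:outcome»" in article.sections["results"]
        assert "«EXC:" not in article.sections.get("abstract", "")

    def test_exclude_on_outcome_chains_to_outcome_reason(
        self, criteria, taxonomy, ft_tasks, params
    ):
        records, _ = generate_corpus(CorpusProfile(3, 0.2, seed=1))
        gold = GoldLabel(records[0].record_id, "exclude", "outcome",
                         taxonomy.label_for("outcome"))
        article = structure_pages(generate_fulltext_pages(records[0], gold),
                                  record_id=records[0].record_id)
        decision = screen_full_text(article, ft_tasks, MockBackend(), params, criteria)
        assert decision.decision == "exclude"
        assert decision.exclusion_reason == taxonomy.label_for("outcome")

    def test_unknown_layout(self):
        records, labels = generate_corpus(CorpusProfile(1, 0.5, seed=1))
        with pytest.raises(ValueError):
            generate_fulltext_pages(records[0], labels[0], layout="two_column")


class TestEndToEndIdentity:
    def test_zero_noise_reproduces_gold_exactly(self, criteria, taxonomy, ta_tasks, params):
        records, labels = generate_corpus(CorpusProfile(120, 0.1, seed=13))
        decisions = screen_records(records, ta_tasks, MockBackend(), params, criteria)
        for decision, label in zip(decisions, labels):
            assert decision.decision == label.decision
            assert decision.exclusion_reason == label.reason_label


class TestGoldCsv:
    def test_round_trip(self, tmp_path):
        _, labels = generate_corpus(CorpusProfile(20, 0.1, seed=2))
        path = tmp_path / "gold.csv"
        write_gold_csv(labels, path)
        assert read_gold_csv(path) == labels


def test_strip_sentinels():
    assert strip_sentinels("a «INC» b «EXC:outcome» c") == "a b c"


def test_chain_order_constant():
    assert CHAIN_ORDER == ("intervention_comparator", "population", "outcome", "study_design")
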