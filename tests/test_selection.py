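"""Day-level subsets, slot quotas, and the two core-question filters."""

import numpy as np
import pytest
from scipy import stats

from uemasim.banks import default_core_bank, default_engagement_bank
from uemasim.selection import (QuestionSpec, SelectionState,
                               SequentialCursor, allocate_slot_types,
                               draw_day_subset, eligible_core,
                               record_outcome, select_question, slot_quotas)

YSN = ("Yes", "Sort of", "No")


def minimal_bank():
    mk = lambda i, cat: QuestionSpec(f"{cat[:3]}{i}", f"q{i}?", cat, YSN,
                                     max_per_day=4)
    return ([mk(i, "internal") for i in range(4)]
            + [mk(i, "external") for i in range(2)]
            + [mk(i, "reflective") for i in range(2)]
            + [mk(i, "reactive") for i in range(2)])


def make_state(subset, rng):
    return SelectionState(
        day_subset=subset,
        engagement_cursor=SequentialCursor(default_engagement_bank(20), rng),
        validation_cursor=SequentialCursor(default_engagement_bank(20), rng))


class TestQuestionSpec:
    def test_rejects_bad_category_and_answer_counts(self):
        with pytest.raises(ValueError, match="category"):
            QuestionSpec("x", "?", "emotional", YSN)
        with pytest.raises(ValueError, match="2-3 answer"):
            QuestionSpec("x", "?", "internal", ("Yes",))

    def test_validation_item_needs_consistent_correct_answer(self):
        with pytest.raises(ValueError, match="correct_answer"):
            QuestionSpec("x", "?", "validation", ("Yes", "No"))
        with pytest.raises(ValueError, match="not among"):
            QuestionSpec("x", "?", "validation", ("Yes", "No"),
                         correct_answer="Maybe")


class TestDaySubset:
    def test_composition_4_2_2_2(self, core_bank, rng):
        subset = draw_day_subset(core_bank, rng)
        cats = [q.category for q in subset]
        assert len(subset) == 10 == len({q.id for q in subset})
        assert cats.count("internal") == 4
        assert cats.count("external") == 2
        assert cats.count("reflective") == 2
        assert cats.count("reactive") == 2

    def test_minimal_bank_forces_unique_subset(self, rng):
        bank = minimal_bank()
        subset = draw_day_subset(bank, rng)
        assert {q.id for q in subset} == {q.id for q in bank}

    def test_insufficient_category_is_reported(self, rng):
        bank = [q for q in minimal_bank() if q.category != "reactive"]
        with pytest.raises(ValueError, match="reactive"):
            draw_day_subset(bank, rng)

    def test_internal_inclusion_matches_hypergeometric(self, core_bank, rng):
        # each of the 13 internal items enters the 4-item draw with
        # probability 4/13 ~ 30.8%
        n = 10_000
        target = core_bank[0].id
        hits = sum(target in {q.id for q in draw_day_subset(core_bank, rng)}
                   for _ in range(n))
        assert hits / n == pytest.approx(4 / 13, abs=0.02)


class TestSlotQuotas:
    def test_canonical_62_prompt_day(self):
        q = slot_quotas(62)
        assert (q["core"], q["engagement"], q["validation"]) == (55, 5, 1)
        assert q["spare"] == 1

    def test_empty_day(self):
        assert allocate_slot_types(0, np.random.default_rng(0)) == []

    @pytest.mark.parametrize("n", [1, 2, 5, 31, 48, 62, 70])
    def test_quotas_sum_and_validation_floor(self, n):
        q = slot_quotas(n)
        assert q["core"] + q["engagement"] + q["validation"] + q["spare"] == n
        assert q["validation"] >= 1

    def test_allocation_counts_and_interleaving(self, rng):
        labels = allocate_slot_types(62, rng)
        assert len(labels) == 62
        assert labels.count("core") == 56  # spare slot folded into core
        assert labels.count("engagement") == 5
        assert labels.count("validation") == 1


class TestFilters:
    def test_60_minute_reask_gap(self, core_bank, rng):
        subset = draw_day_subset(core_bank, rng)
        state = make_state(subset, rng)
        q = next(x for x in subset if x.max_per_day > 1)
        record_outcome(state, q, answered=True, time_min=600.0)  # 10:00
        assert q.id not in {c.id for c in eligible_core(state, 640.0)}  # 10:40
        assert q.id in {c.id for c in eligible_core(state, 665.0)}      # 11:05

    def test_cap_excludes_for_rest_of_day(self, core_bank, rng):
        subset = draw_day_subset(core_bank, rng)
        state = make_state(subset, rng)
        q = subset[0]
        for k in range(q.max_per_day):
            record_outcome(state, q, answered=True, time_min=61.0 * (k + 1))
        assert q.id not in {c.id for c in eligible_core(state, 1400.0)}

    def test_unanswered_item_repeats_immediately(self, core_bank, rng):
        subset = draw_day_subset(core_bank, rng)
        state = make_state(subset, rng)
        q = subset[0]
        record_outcome(state, q, answered=False, time_min=600.0)
        assert state.answered_count == {} and state.last_answered_min == {}
        assert q.id in {c.id for c in eligible_core(state, 600.1)}

    def test_single_candidate_is_returned(self, rng):
        bank = minimal_bank()
        state = make_state(list(bank), rng)
        survivor = bank[-1]
        for q in bank:
            if q.id != survivor.id:
                record_outcome(state, q, answered=True, time_min=600.0)
        assert select_question(state, 610.0, rng).id == survivor.id

    def test_empty_candidates_fall_back_to_engagement(self, rng):
        bank = minimal_bank()
        state = make_state(list(bank), rng)
        for q in bank:
            record_outcome(state, q, answered=True, time_min=600.0)
        chosen = select_question(state, 610.0, rng)
        assert chosen.category == "engagement"

    def test_no_item_answered_twice_within_an_hour(self, core_bank, rng):
        # replay 50 simulated days and assert both filters held
        for _ in range(50):
            subset = draw_day_subset(core_bank, rng)
            state = make_state(subset, rng)
            answered_at: dict[str, list[float]] = {}
            for slot in range(55):
                t = slot * 15.0
                q = select_question(state, t, rng)
                if q.category == "engagement":
                    continue
                if rng.random() < 0.75:
                    record_outcome(state, q, True, t)
                    answered_at.setdefault(q.id, []).append(t)
            for q in subset:
                times = answered_at.get(q.id, [])
                assert len(times) <= q.max_per_day
                assert all(b - a >= 60.0 for a, b in zip(times, times[1:]))

    def test_reduces_to_uniform_sampling_without_filters(self, rng):
        # caps lifted and re-ask gap zero: selection is uniform over the
        # day subset (chi-square goodness of fit)
        bank = [QuestionSpec(f"q{i}", "?", cat, YSN, max_per_day=10**9)
                for i, cat in enumerate(["internal"] * 4 + ["external"] * 2
                                        + ["reflective"] * 2
                                        + ["reactive"] * 2)]
        state = make_state(list(bank), rng)
        n = 100_000
        counts = {q.id: 0 for q in bank}
        for k in range(n):
            q = select_question(state, float(k), rng, reask_gap_min=0.0)
            record_outcome(state, q, True, float(k))
            counts[q.id] += 1
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 0.001


class TestSequentialCursor:
    def test_no_repeat_until_bank_exhausted(self, rng):
        bank = default_engagement_bank(50)
        cur = SequentialCursor(bank, rng)
        first_pass = [cur.next().id for _ in range(50)]
        assert len(set(first_pass)) == 50
        second_pass = [cur.next().id for _ in range(50)]
        assert len(set(second_pass)) == 50

    def test_horizon_matches_bank_size(self, rng):
        # 280 engagement items at 5 slots/day last 56 days without repeats
        cur = SequentialCursor(default_engagement_bank(280), rng)
        seen = set()
        for day in range(56):
            for _ in range(5):
                q = cur.next()
                assert q.id not in seen
                seen.add(q.id)
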