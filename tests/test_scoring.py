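import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliquant.dosage import DosageQuotient, dq_profile
from ampliquant.panel import builtin_nb_panels
from ampliquant.scoring import (
    MAQ_RULES,
    MLPA_RULES,
    RuleSet,
    classify_sample,
    get_ruleset,
    save_ruleset,
    score_mycn,
    score_segmental,
    score_whole_chromosome,
)
from ampliquant.simulate import NoiseModel, SimulatedGenome, CopyNumberEvent, simulate_copy_numbers, simulate_peaks

from .conftest import dqs
from .oracles import literal_mycn, literal_segmental, literal_whole_chromosome

GRID = [0.70, 0.75, 0.78, 0.80, 0.85, 1.0, 1.15, 1.2, 1.25, 1.3]


class TestSegmental:
    @pytest.mark.parametrize(
        "values, rules, expected",
        [
            ([0.79, 0.78, 1.01, 0.99], MAQ_RULES, "loss"),        # 2 consecutive at 1-0.2
            ([0.79, 1.00, 0.79, 1.00], MAQ_RULES, "normal"),      # adjacency required
            ([1.20, 1.20], MAQ_RULES, "gain"),                    # inclusive boundary
            ([0.80, 0.80], MAQ_RULES, "loss"),                    # inclusive boundary
            ([0.79, 0.79], MLPA_RULES, "loss"),                   # via the fraction clause (2/2 at >=0.15)
            ([0.79, 0.99, 0.79, 0.99], MLPA_RULES, "normal"),     # neither clause: 2/4 not > 75%
            ([0.79, 0.99, 0.79, 0.99], MAQ_RULES, "normal"),
            ([0.75, 0.75], MLPA_RULES, "loss"),                   # MLPA inclusive boundary
            ([1.22, 0.99, 1.22, 0.99], MLPA_RULES, "normal"),     # MAQ-only zone
            ([1.22, 0.99, 1.22, 0.99], MAQ_RULES, "normal"),      # adjacency still required
            ([1.22, 1.22, 0.99, 0.99], MAQ_RULES, "gain"),
        ],
    )
    def test_consecutive_rule(self, values, rules, expected):
        assert score_segmental(dqs(values), rules).status == expected

    def test_mlpa_fraction_rule_without_consecutive_hit(self):
        # 7 of 8 loci at <= 0.85 but never 2 consecutive <= 0.75
        values = [0.85, 0.76, 1.0, 0.84, 0.83, 0.82, 0.80, 0.85]
        call = score_segmental(dqs(values), MLPA_RULES)
        assert call.status == "loss"
        assert call.rule_fired == "fraction_loss"
        assert len(call.supporting_loci) == 7

    def test_missing_dq_breaks_adjacency(self):
        values = [0.7, None, 0.7, 1.0]
        assert score_segmental(dqs(values), MAQ_RULES).status == "normal"

    def test_mixed_direction_runs_never_call(self):
        assert score_segmental(dqs([0.7, 1.3, 0.7, 1.3]), MAQ_RULES).status == "normal"

    def test_fewer_than_two_numeric_loci_is_no_data(self):
        assert score_segmental(dqs([0.5, None, None]), MAQ_RULES).status == "no_data"
        assert score_segmental(dqs([]), MAQ_RULES).status == "no_data"

    def test_supporting_loci_recorded_in_position_order(self):
        call = score_segmental(dqs([1.0, 0.75, 0.74, 0.73]), MAQ_RULES)
        assert call.supporting_loci == ("amp-01", "amp-02")

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=0.05, max_value=3.0), min_size=2, max_size=8),
        lower=st.booleans(),
        index=st.integers(0, 7),
        shift=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_monotonicity(self, values, lower, index, shift):
        """Decreasing a DQ never turns a loss into normal; increasing never
        turns a gain into normal."""
        index %= len(values)
        base = score_segmental(dqs(values), MAQ_RULES).status
        moved = list(values)
        moved[index] = moved[index] - shift if lower else moved[index] + shift
        if moved[index] <= 0:
            return
        new = score_segmental(dqs(moved), MAQ_RULES).status
        if base == "loss" and lower:
            assert new == "loss"
        if base == "gain" and not lower:
            assert new == "gain"


class TestWholeChromosome:
    def test_loss_when_both_arms_consistent_and_majority_deviates(self):
        # both arms 100% below 1; 3 of 5 DQs (60% > half) deviate by >= 0.1
        call = score_whole_chromosome(dqs([0.92, 0.88, 0.85]), dqs([0.87, 0.94]), MAQ_RULES)
        assert call.status == "loss"

    def test_majority_delta_clause_blocks_shallow_shift(self):
        call = score_whole_chromosome(dqs([0.95, 0.96]), dqs([0.94, 0.97]), MAQ_RULES)
        assert call.status == "normal"

    def test_arms_disagreeing_in_direction_is_normal(self):
        call = score_whole_chromosome(dqs([1.15, 1.15]), dqs([0.85, 0.85]), MAQ_RULES)
        assert call.status == "normal"

    def test_gain_symmetric(self):
        call = score_whole_chromosome(dqs([1.12, 1.09, 1.15]), dqs([1.11, 1.13]), MAQ_RULES)
        assert call.status == "gain"

    def test_empty_arm_is_no_data(self):
        assert score_whole_chromosome(dqs([]), dqs([0.9]), MAQ_RULES).status == "no_data"
        assert score_whole_chromosome(dqs([None]), dqs([0.9]), MAQ_RULES).status == "no_data"


class TestMycn:
    @pytest.mark.parametrize(
        "values, rules, expected",
        [
            ([12.1, 10.4, 15.0], MAQ_RULES, "amplified"),
            ([3.5, 4.2, 4.1], MAQ_RULES, "normal"),      # one locus below 4.0
            ([4.0, 4.0, 4.0], MAQ_RULES, "amplified"),   # inclusive boundary
            ([4.2, 4.1], MAQ_RULES, "no_data"),          # MAQ needs 3 numeric loci
            ([4.2, 4.1], MLPA_RULES, "amplified"),       # MLPA needs only 2
            ([1.0, 1.0, 1.0], MAQ_RULES, "normal"),
        ],
    )
    def test_mycn_rule(self, values, rules, expected):
        assert score_mycn(dqs(values), rules) == expected


class TestGridAgainstLiteralOracle:
    """Exhaustive scan of rule-set behavior against a word-for-word
    transcription of the published scoring clauses."""

    def _check(self, combo, rules):
        expected = literal_segmental(
            combo, rules.segmental_delta, rules.fraction_rule_enabled
        )
        got = score_segmental(dqs(combo), rules).status
        assert got == expected, (combo, rules.name)

    @pytest.mark.parametrize("rules", [MAQ_RULES, MLPA_RULES], ids=lambda r: r.name)
    def test_exhaustive_small_lengths(self, rules):
        for n in (2, 3, 4):
            for combo in itertools.product(GRID, repeat=n):
                self._check(combo, rules)

    @pytest.mark.parametrize("rules", [MAQ_RULES, MLPA_RULES], ids=lambda r: r.name)
    def test_sampled_longer_lengths(self, rules):
        rng = np.random.default_rng(2024)
        for _ in range(3000):
            n = int(rng.integers(5, 9))
            combo = tuple(GRID[i] for i in rng.integers(0, len(GRID), size=n))
            self._check(combo, rules)

    def test_whole_chromosome_grid(self):
        sub = [0.80, 0.85, 1.0, 1.15, 1.2]
        for np_, nq in ((2, 2), (3, 2)):
            for p in itertools.product(sub, repeat=np_):
                for q in itertools.product(sub, repeat=nq):
                    expected = literal_whole_chromosome(p, q)
                    got = score_whole_chromosome(dqs(p), dqs(q), MAQ_RULES).status
                    assert got == expected, (p, q)

    def test_mycn_grid(self):
        sub = [1.0, 3.0, 3.9, 4.0, 4.1, 12.0]
        for combo in itertools.product(sub, repeat=3):
            assert score_mycn(dqs(combo), MAQ_RULES) == literal_mycn(combo, 3)


class TestClassifySample:
    def _profiles(self, genome, panels, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        copies = simulate_copy_numbers(genome, panels)
        profiles = {}
        for kit_id, panel in panels.items():
            kit_copies = {a.id: copies[a.id] for a in panel.amplicons}
            run = simulate_peaks(kit_copies, NoiseModel(sigma=sigma), rng, sample_id=genome.sample_id)
            ctrl = simulate_peaks({a.id: 2 for a in panel.amplicons}, NoiseModel(sigma=sigma), rng,
                                  sample_id="C", kind="control")
            profiles[kit_id] = dq_profile(run, [ctrl], panel)
        return profiles

    def test_segmental_profile_with_mycn(self, panels):
        """1p deletion + MYCN amplification + 3p deletion + 17q gain: the
        classic unfavorable cell-line pattern."""
        genome = SimulatedGenome(
            "SJ", background_ploidy=2,
            events=(
                CopyNumberEvent("1p", -1), CopyNumberEvent("3p", -1), CopyNumberEvent("17q", +1),
            ),
            mycn_copies=25,
        )
        cls = classify_sample(self._profiles(genome, panels), panels, MAQ_RULES, sample_id="SJ")
        assert cls.category == "segmental"
        assert cls.mycn_amplified is True
        status = {c.region: c.status for c in cls.region_calls}
        assert status["1p"] == "loss" and status["3p"] == "loss" and status["17q"] == "gain"
        assert status["MYCN"] == "amplified"
        # precedence: no whole-chromosome calls alongside segmental ones
        assert all(c.scope != "whole_chromosome" for c in cls.region_calls)

    def test_numerical_profile_via_whole_chromosome_rule(self, panels):
        """Whole-chromosome DQ shifts inside the segmental window classify as
        numerical: chromosomes 1, 2 and 17 up, 3 and 11 down."""
        profiles = {}
        for kit_id, panel in panels.items():
            prof = []
            for a in panel.targets_sorted():
                dq = 1.15 if a.chromosome in ("1", "2", "17") else 0.85
                prof.append(DosageQuotient("N", a.id, dq, 0.0, 4))
            profiles[kit_id] = prof
        cls = classify_sample(profiles, panels, MAQ_RULES, sample_id="N")
        assert cls.category == "numerical"
        status = {c.region: c.status for c in cls.region_calls if c.scope == "whole_chromosome"}
        assert status == {"chr1": "gain", "chr2": "gain", "chr17": "gain",
                          "chr3": "loss", "chr11": "loss"}

    def test_all_normal_dqs_classify_as_none(self, panels):
        genome = SimulatedGenome("D", background_ploidy=2)
        cls = classify_sample(self._profiles(genome, panels), panels, MAQ_RULES, sample_id="D")
        assert cls.category == "none"
        assert cls.mycn_amplified is False

    def test_mycn_loci_excluded_from_chr2_numerical_when_amplified(self, panels):
        profiles = {}
        for kit_id, panel in panels.items():
            prof = []
            for a in panel.targets_sorted():
                dq = 12.0 if a.region == "MYCN" else 1.0
                prof.append(DosageQuotient("M", a.id, dq, 0.0, 4))
            profiles[kit_id] = prof
        cls = classify_sample(profiles, panels, MAQ_RULES, sample_id="M")
        assert cls.mycn_amplified is True
        chr2 = next(c for c in cls.region_calls if c.region == "chr2")
        assert chr2.status == "normal"  # amplification must not mimic chromosome-2 gain

    def test_determinism(self, panels):
        genome = SimulatedGenome("S", events=(CopyNumberEvent("11q", -1),))
        profiles = self._profiles(genome, panels, sigma=0.05, seed=3)
        a = classify_sample(profiles, panels, MAQ_RULES, sample_id="S")
        b = classify_sample(profiles, panels, MAQ_RULES, sample_id="S")
        assert a == b


class TestRuleSetConfig:
    def test_presets(self):
        assert get_ruleset("MAQ").segmental_delta == 0.2
        assert get_ruleset("MLPA").segmental_delta == 0.25
        assert get_ruleset("MAQ").mycn_required_loci == 3
        assert get_ruleset("MLPA").mycn_required_loci == 2

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        save_ruleset(MLPA_RULES, path)
        assert get_ruleset(str(path)) == MLPA_RULES

    def test_alternative_mycn_reading_as_override(self, tmp_path):
        """DQ >= 3.0 reading of the amplification clause via config."""
        rules = RuleSet(name="MAQ-alt", segmental_delta=0.2, mycn_delta=2.0, mycn_required_loci=3)
        assert score_mycn(dqs([3.2, 3.5, 3.1]), rules) == "amplified"
        assert score_mycn(dqs([3.2, 3.5, 3.1]), MAQ_RULES) == "normal"
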