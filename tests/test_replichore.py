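"""Replication geometry, array aggregation, cassette metrics,
classification."""

import numpy as np
import pandas as pd
import pytest

from attcfold.attc import reverse_complement
from attcfold.replichore import (
    IntegronRecord,
    OrientationIndeterminateError,
    ReplichoreMap,
    aggregate_array,
    cassette_metrics,
    classify_integron,
    gc_disparity_profile,
    infer_replichores,
    orient_integron,
    template_class,
)
from attcfold.synthetic import generate_replicon


class TestDisparityProfile:
    def test_hand_count(self):
        assert list(gc_disparity_profile("GGCC")) == [1, 2, 1, 0]

    def test_reverse_complement_negates_total(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        f = gc_disparity_profile(seq)[-1]
        r = gc_disparity_profile(reverse_complement(seq))[-1]
        assert r == -f

    def test_final_value_matches_counting(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=10000))
        assert gc_disparity_profile(seq)[-1] == \
            seq.count("G") - seq.count("C")

    def test_ambiguity_codes_contribute_zero(self):
        assert list(gc_disparity_profile("GNC")) == [1, 1, 0]


class TestInferReplichores:
    def test_recovers_planted_oric(self):
        rep = generate_replicon(length=30000, oric=0,
                                arrays=[("lagging_template", 2, 600)],
                                skew_strength=0.5, seed=0)
        rmap = infer_replichores(gc_disparity_profile(rep.sequence))
        n = len(rep.sequence)
        dist = min(abs(rmap.oric - rep.oric), n - abs(rmap.oric - rep.oric))
        assert dist <= 0.02 * n

    def test_explicit_oric_passes_through(self):
        profile = gc_disparity_profile("GC" * 1000)
        rmap = infer_replichores(profile, oric=123)
        assert rmap.oric == 123

    def test_all_a_genome_indeterminate(self):
        with pytest.raises(OrientationIndeterminateError):
            infer_replichores(gc_disparity_profile("A" * 5000))

    def test_unbiased_composition_indeterminate(self):
        rep = generate_replicon(length=30000, oric=0,
                                arrays=[("lagging_template", 2, 600)],
                                skew_strength=0.0, seed=1)
        with pytest.raises(OrientationIndeterminateError):
            infer_replichores(gc_disparity_profile(rep.sequence))

    def test_linear_replicon_rejected(self):
        with pytest.raises(ValueError):
            infer_replichores(np.arange(100), circular=False)


class TestTemplateClass:
    rmap = ReplichoreMap(replicon_length=1000, oric=0, ter=500)

    def test_complement_flip(self):
        for p in (10, 499, 501, 990):
            a = template_class(p, "+", self.rmap)
            b = template_class(p, "-", self.rmap)
            assert {a, b} == {"leading_template", "lagging_template"}

    def test_replichore_flip(self):
        assert template_class(100, "+", self.rmap) != \
            template_class(900, "+", self.rmap)

    def test_double_flip_identity(self):
        for p in (100, 900):
            for s in "+-":
                other = "-" if s == "+" else "+"
                sym = (self.rmap.ter + (self.rmap.ter - p)) \
                    % self.rmap.replicon_length
                once = template_class(p, s, self.rmap)
                twice = template_class(sym, other, self.rmap)
                assert once == twice

    def test_convention(self):
        # on the increasing arc the minus strand is the leading template
        assert template_class(100, "-", self.rmap) == "leading_template"
        assert template_class(100, "+", self.rmap) == "lagging_template"


class TestAggregateArray:
    sites = [((0, 100), "+"), ((1100, 1200), "+"), ((2200, 2300), "+"),
             ((22300, 22400), "+")]  # gaps: 1 kb, 1 kb, 20 kb

    def test_default_threshold_splits(self):
        arrays = aggregate_array(self.sites, 4000)
        assert [len(a) for a in arrays] == [3, 1]

    def test_fifteen_kb_still_splits(self):
        assert [len(a) for a in aggregate_array(self.sites, 15000)] == [3, 1]

    def test_large_threshold_merges(self):
        assert [len(a) for a in aggregate_array(self.sites, 25000)] == [4]


class TestOrientIntegron:
    rmap = ReplichoreMap(replicon_length=10000, oric=0, ter=5000)

    def test_unanimous(self):
        rec = IntegronRecord("r", [((100, 160), "+"), ((800, 860), "+")])
        call = orient_integron(rec, self.rmap)
        assert call.label == "leading_template" and not call.mixed

    def test_majority_with_flag(self):
        rec = IntegronRecord("r", [((100, 160), "+"), ((800, 860), "+"),
                                   ((1500, 1560), "+"), ((2200, 2260), "-")])
        call = orient_integron(rec, self.rmap)
        assert call.label == "leading_template"
        assert call.mixed and call.n_lagging == 1

    def test_array_spanning_ter_flips_class(self):
        rec = IntegronRecord("r", [((4800, 4860), "+"), ((5200, 5260), "+"),
                                   ((5600, 5660), "+")])
        call = orient_integron(rec, self.rmap)
        assert call.mixed
        assert call.label == "lagging_template"  # majority past ter

    def test_tie_is_mixed(self):
        rec = IntegronRecord("r", [((100, 160), "+"), ((800, 860), "-")])
        assert orient_integron(rec, self.rmap).label == "mixed"


class TestCassetteMetrics:
    def test_start_to_start_subtraction(self):
        rec = IntegronRecord("r", [((100, 160), "+"), ((700, 760), "+")])
        cassettes, _ = cassette_metrics(rec)
        assert len(cassettes) == 1 and cassettes[0].length == 600

    def test_single_site_no_cassettes(self):
        rec = IntegronRecord("r", [((100, 160), "+")])
        cassettes, summary = cassette_metrics(rec)
        assert cassettes == [] and summary["n_cassettes"] == 0

    def test_overlapping_sites_rejected(self):
        rec = IntegronRecord("r", [((100, 200), "+"), ((150, 260), "+")])
        with pytest.raises(ValueError, match="overlapping"):
            cassette_metrics(rec)

    def test_lognormal_median_recovered(self):
        rng = np.random.default_rng(0)
        median = 700.0
        lengths = np.round(
            median * np.exp(0.3 * rng.standard_normal(200))).astype(int)
        starts = np.concatenate(([0], np.cumsum(lengths)))
        rec = IntegronRecord(
            "r", [((int(s), int(s) + 60), "+") for s in starts])
        cassettes, _ = cassette_metrics(rec)
        emp = np.median([c.length for c in cassettes])
        assert abs(emp - median) / median < 0.10

    def test_circular_sum_closes(self):
        # fully tiled circular array: cassette lengths sum to the replicon
        L = 5000
        starts = [0, 1200, 2600, 3900]
        rec = IntegronRecord(
            "r", [((s, s + 60), "+") for s in starts])
        cassettes, _ = cassette_metrics(rec, replicon_length=L)
        wrap = (starts[0] - starts[-1]) % L
        assert sum(c.length for c in cassettes) + wrap == L

    def test_cds_partition_and_arg_exclusion(self):
        rec = IntegronRecord("r", [((100, 160), "+"), ((900, 960), "+")])
        cds = pd.DataFrame([
            {"cds_id": "in1", "start": 200, "end": 500, "strand": "+"},
            {"cds_id": "argX", "start": 550, "end": 850, "strand": "+"},
            {"cds_id": "out1", "start": 2000, "end": 3000, "strand": "+"},
        ])
        _, summary = cassette_metrics(rec, annotations=cds,
                                      arg_ids={"argX"}, exclude_args=True)
        assert summary["mean_cds_length_inside"] == 300.0
        assert summary["mean_cds_length_outside"] == 1000.0
        assert summary["replicon_minus_integron_mean_cds"] == 700.0


class TestClassification:
    def test_twenty_sites_is_sedentary(self):
        rec = IntegronRecord(
            "r", [((i * 1000, i * 1000 + 60), "+") for i in range(20)])
        assert classify_integron(rec).label == "SCI"

    def test_plasmid_is_mobile(self):
        rec = IntegronRecord("r", [((0, 60), "+"), ((1000, 1060), "+"),
                                   ((2000, 2060), "+")])
        assert classify_integron(rec, {"on_plasmid": True}).label == "MI"

    def test_strain_fraction_rule(self):
        rec = IntegronRecord(
            "r", [((i * 1000, i * 1000 + 60), "+") for i in range(5)])
        assert classify_integron(
            rec, {"fraction_of_strains_present": 1.0}).label == "SCI"
        assert classify_integron(
            rec, {"fraction_of_strains_present": 0.5}).label == "MI"

    def test_mobile_integrase_class(self):
        rec = IntegronRecord("r", [((0, 60), "+")],
                             integrase=((200, 1200), "+", "1"))
        assert classify_integron(rec).label == "MI"

    def test_conflict_keeps_sedentary_with_flag(self):
        rec = IntegronRecord(
            "r", [((i * 1000, i * 1000 + 60), "+") for i in range(25)])
        res = classify_integron(rec, {"on_plasmid": True})
        assert res.label == "SCI" and res.conflict

    def test_no_evidence_unknown(self):
        rec = IntegronRecord("r", [((0, 60), "+")])
        assert classify_integron(rec).label == "unknown"
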