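"""Cohort census arithmetic on fixture compositions and random recounts."""

from collections import Counter

import numpy as np
import pytest

from mepsurvey import (
    ConfigError,
    candidate_breakdown,
    class_census,
    classify,
    genus_census,
    neither_genome_stats,
    shunt_census,
)
from mepsurvey.census import full_census, render_percent, write_report
from mepsurvey.classifier import GENOTYPE_CLASSES, PathwayStatus


def make_status(gid, cls, missing=frozenset(), shunt="none"):
    """Construct a PathwayStatus of a given class directly."""
    mep = {"MEP_only": "complete", "both": "complete"}.get(
        cls, "absent" if cls == "neither" else "incomplete"
    )
    if cls in ("MEP_only", "both"):
        missing = frozenset()
    mva = "present" if cls in ("MVA_only", "both") else "absent"
    return PathwayStatus(
        genome_id=gid,
        mep_status=mep,
        missing_mep_roles=frozenset(missing),
        mva_gene_count=2 if mva == "present" else 0,
        mva_status=mva,
        genotype_class=cls,
        shunt_flags=shunt,
    )


def survey_fixture():
    """A status list with the survey's published cohort composition:
    3411 MEP-only, 541 MVA-only, 83 both, 136 neither; 229 candidates of
    which 181 miss only Dxs (4 methylsulfurase-only + 5 both-shunt),
    1 misses only IspG, 2 miss only IspH, 45 other."""
    statuses = []
    i = 0

    def add(n, cls, missing=frozenset(), shunt="none"):
        nonlocal i
        for _ in range(n):
            statuses.append(make_status(f"g{i}", cls, missing, shunt))
            i += 1

    add(3411, "MEP_only")
    add(541, "MVA_only")
    add(83, "both")
    add(136, "neither")
    add(172, "candidate", {"Dxs"})
    add(4, "candidate", {"Dxs"}, "methylsulfurase_only")
    add(5, "candidate", {"Dxs"}, "both_shunt")
    add(1, "candidate", {"IspG"})
    add(2, "candidate", {"IspH"})
    add(45, "candidate", {"Dxs", "IspE"})
    return statuses


class TestRenderPercent:
    def test_below_ten_gets_one_decimal(self):
        assert render_percent(136, 4400) == 3.1
        assert render_percent(229, 4400) == 5.2

    def test_ten_or_more_rounds_to_integer(self):
        assert render_percent(3411, 4400) == 78
        assert render_percent(541, 4400) == 12

    def test_half_rounds_up(self):
        assert render_percent(1, 16) == 6.3  # 6.25 -> half up, not banker's
        assert render_percent(25, 200) == 13  # 12.5 -> half up


class TestClassCensus:
    def test_survey_composition_percentages(self):
        census = class_census(survey_fixture())
        assert {k: v["count"] for k, v in census.items()} == {
            "MEP_only": 3411, "MVA_only": 541, "both": 83,
            "neither": 136, "candidate": 229,
        }
        assert census["MEP_only"]["percent"] == 78
        assert census["MVA_only"]["percent"] == 12
        assert census["both"]["percent"] == 1.9  # 100*83/4400 = 1.886...
        assert census["neither"]["percent"] == 3.1
        assert census["candidate"]["percent"] == 5.2

    def test_single_genome_is_its_class_at_100(self):
        census = class_census([make_status("g", "MVA_only")])
        assert census["MVA_only"] == {"count": 1, "percent": 100, "fraction": 1.0}

    def test_counts_match_recount_oracle(self, rng):
        classes = [GENOTYPE_CLASSES[i] for i in rng.integers(0, 5, size=500)]
        statuses = [make_status(f"g{i}", c) for i, c in enumerate(classes)]
        census = class_census(statuses)
        recount = Counter(classes)
        for cls in GENOTYPE_CLASSES:
            assert census[cls]["count"] == recount.get(cls, 0)
        assert sum(v["count"] for v in census.values()) == 500

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ConfigError):
            class_census([make_status("g", "both"), make_status("g", "both")])


class TestCandidateBreakdown:
    def test_survey_composition_shares(self):
        bd = candidate_breakdown(survey_fixture())
        assert bd["Dxs_only"]["count"] == 181
        assert bd["Dxs_only"]["percent"] == 79
        assert bd["IspG_only"]["count"] == 1
        assert bd["IspH_only"]["count"] == 2
        assert bd["other"]["count"] == 45

    def test_multi_gene_missing_set_is_other(self):
        s = [make_status("g", "candidate", {"Dxs", "IspG"})]
        assert candidate_breakdown(s)["other"]["count"] == 1

    def test_buckets_partition_candidates(self, rng):
        patterns = [{"Dxs"}, {"IspG"}, {"IspH"}, {"Dxs", "IspH"}, {"IspE"}]
        statuses = [
            make_status(f"g{i}", "candidate", patterns[int(p)])
            for i, p in enumerate(rng.integers(0, 5, size=200))
        ]
        bd = candidate_breakdown(statuses)
        assert sum(v["count"] for v in bd.values()) == 200


class TestShuntCensus:
    def test_survey_composition_fractions(self):
        sc = shunt_census(survey_fixture())
        assert sc["denominator"] == 181
        assert sc["methylsulfurase_only_count"] == 4
        assert sc["methylsulfurase_only_percent"] == 2
        assert sc["both_shunt_count"] == 5
        assert sc["both_shunt_percent"] == 3

    def test_zero_carriers(self):
        sc = shunt_census([make_status("g", "candidate", {"Dxs"})])
        assert sc["methylsulfurase_only_percent"] == 0
        assert sc["both_shunt_percent"] == 0


class TestGenusCensus:
    def test_staphylococcus_style_bifurcation(self):
        statuses = [make_status(f"s{i}", "MVA_only") for i in range(27)]
        statuses += [make_status(f"m{i}", "MEP_only") for i in range(8)]
        tax = {s.genome_id: "Staphylococcus" for s in statuses}
        table = genus_census(statuses, tax)
        row = table.iloc[0]
        assert row["n_species"] == 35
        assert bool(row["bifurcated"])
        assert row["pct_MVA_only"] == 77
        assert row["pct_MEP_only"] == 23

    def test_cellulomonas_style_bifurcation(self):
        statuses = [make_status(f"c{i}", "MEP_only") for i in range(9)]
        statuses.append(make_status("taurus", "MVA_only"))
        table = genus_census(statuses, {s.genome_id: "Cellulomonas" for s in statuses})
        assert bool(table.iloc[0]["bifurcated"])

    def test_singleton_genus_never_bifurcated(self):
        table = genus_census([make_status("g", "MVA_only")], {"g": "Weissella"})
        assert not bool(table.iloc[0]["bifurcated"])

    def test_both_class_counts_toward_mep_side(self):
        statuses = [make_status("a", "both"), make_status("b", "MVA_only")]
        table = genus_census(statuses, {"a": "X", "b": "X"})
        assert bool(table.iloc[0]["bifurcated"])

    def test_candidates_do_not_bifurcate(self):
        statuses = [make_status("a", "candidate", {"Dxs"}), make_status("b", "MVA_only")]
        table = genus_census(statuses, {"a": "X", "b": "X"})
        assert not bool(table.iloc[0]["bifurcated"])

    def test_genus_rows_sum_to_cohort(self, rng):
        statuses = [
            make_status(f"g{i}", GENOTYPE_CLASSES[int(c)])
            for i, c in enumerate(rng.integers(0, 5, size=120))
        ]
        tax = {s.genome_id: f"Genus{i % 7}" for i, s in enumerate(statuses)}
        table = genus_census(statuses, tax)
        assert table["n_species"].sum() == 120

    def test_missing_taxonomy_rejected(self):
        with pytest.raises(ConfigError):
            genus_census([make_status("g", "both")], {})


class TestNeitherGenomeStats:
    def test_odd_count_median(self):
        statuses = [make_status(f"g{i}", "neither") for i in range(3)]
        sizes = {"g0": 800000, "g1": 843495, "g2": 900000}
        assert neither_genome_stats(statuses, sizes) == 843495

    def test_even_count_median_is_mean_of_central_pair(self):
        statuses = [make_status(f"g{i}", "neither") for i in range(2)]
        assert neither_genome_stats(statuses, {"g0": 8, "g1": 10}) == 9

    def test_matches_sort_oracle(self, rng):
        n = 31
        statuses = [make_status(f"g{i}", "neither") for i in range(n)]
        sizes = {f"g{i}": int(v) for i, v in enumerate(rng.integers(10**5, 10**7, n))}
        got = neither_genome_stats(statuses, sizes)
        assert got == sorted(sizes.values())[n // 2]


class TestFullReport:
    def test_report_is_consistent_and_writable(self, tmp_path):
        statuses = survey_fixture()[::20]  # thin but same machinery
        tax = {s.genome_id: f"G{i % 5}" for i, s in enumerate(statuses)}
        sizes = {s.genome_id: 10**6 for s in statuses}
        report = full_census(statuses, taxonomy=tax, genome_sizes=sizes)
        assert report.total_genomes == len(statuses)
        assert sum(v["count"] for v in report.class_counts.values()) == len(statuses)
        write_report(report, tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "class_census.tsv").exists()

    def test_classify_feeds_census(self):
        row = {r: True for r in
               ("Dxs", "DxrI", "IspD", "IspE", "IspF", "IspG", "IspH")}
        status = classify("g", row)
        census = class_census([status])
        assert census["MEP_only"]["count"] == 1
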