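"""Metadata validation, cohort join, and SV-carrier stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from svsurv import (ColumnMap, GeneTally, ValidationError, arm_sv_crosstab,
                    join_cohort, read_metadata, stratify_by_sv)

CM = ColumnMap(id_col="patient_ID", arm_col="Phenotype",
               event_col="survival.status_bin", time_col="time", time_unit="years")


def write_meta(tmp_path, rows, header="patient_ID,Phenotype,survival.status_bin,time"):
    p = tmp_path / "meta.csv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


def make_tally(counts: dict, gene="G"):
    samples = list(counts)
    return GeneTally(samples=samples, genes=[gene],
                     counts=np.array([[counts[s]] for s in samples]))


class TestReadMetadata:
    def test_binary_coercion_of_trial_columns(self, tmp_path):
        p = write_meta(tmp_path, ["P1,placebo,1,2.5", "P2,treatment,0,3.0",
                                  "P3,placebo,0,1.0", "P4,treatment,1,4.0"])
        ct = read_metadata(p, CM)
        assert ct.frame["arm"].tolist() == [0, 1, 0, 1]
        assert ct.frame["event"].tolist() == [1, 0, 0, 1]
        assert ct.arm_levels == {"placebo": 0, "treatment": 1}
        assert ct.time_unit == "years"

    def test_three_level_arm_rejected_naming_levels(self, tmp_path):
        p = write_meta(tmp_path, ["P1,a,1,1", "P2,b,0,1", "P3,c,1,1"])
        with pytest.raises(ValidationError, match=r"\['a', 'b', 'c'\]"):
            read_metadata(p, CM)

    def test_duplicate_patient_id_rejected(self, tmp_path):
        p = write_meta(tmp_path, ["P1,a,1,1", "P1,b,0,2"])
        with pytest.raises(ValidationError, match="P1"):
            read_metadata(p, CM)

    def test_nonpositive_time_rejected(self, tmp_path):
        p = write_meta(tmp_path, ["P1,a,1,0", "P2,b,0,2"])
        with pytest.raises(ValidationError, match="time"):
            read_metadata(p, CM)

    def test_numeric_covariate_parsing(self, tmp_path):
        cm = ColumnMap(**{**CM.__dict__, "covariate_cols": [("age", "numeric")]})
        p = write_meta(tmp_path, ["P1,a,1,1,50.5", "P2,b,0,2,60"],
                       header="patient_ID,Phenotype,survival.status_bin,time,age")
        ct = read_metadata(p, cm)
        assert ct.frame["age"].tolist() == [50.5, 60.0]

    def test_explicit_level_map(self, tmp_path):
        cm = ColumnMap(**{**CM.__dict__, "arm_levels": {"drug": 1, "ctrl": 0}})
        p = write_meta(tmp_path, ["P1,drug,1,1", "P2,ctrl,0,2"])
        ct = read_metadata(p, cm)
        assert ct.frame["arm"].tolist() == [1, 0]

    def test_tsv_detected_by_extension(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("patient_ID\tPhenotype\tsurvival.status_bin\ttime\nP1\ta\t1\t1\nP2\tb\t0\t2\n")
        assert len(read_metadata(p, CM).frame) == 2


def clinical_of(tmp_path, rows, **kw):
    return read_metadata(write_meta(tmp_path, rows), CM)


class TestJoin:
    def test_counts_pulled_by_id(self, tmp_path):
        ct = clinical_of(tmp_path, ["P1,a,1,1", "P2,b,0,2", "P3,a,1,3"])
        cohort = join_cohort(make_tally({"P1": 2, "P2": 0, "P3": 1}), ct, "G")
        assert cohort.frame["sv_count"].tolist() == [2, 0, 1]

    def test_patient_missing_from_vcf_gets_zero(self, tmp_path):
        ct = clinical_of(tmp_path, ["P1,a,1,1", "P4,b,0,2"])
        cohort = join_cohort(make_tally({"P1": 2}), ct, "G")
        assert cohort.frame["sv_count"].tolist() == [2, 0]
        assert cohort.n_missing_in_vcf == 1

    def test_gene_absent_from_tally(self, tmp_path):
        ct = clinical_of(tmp_path, ["P1,a,1,1", "P2,b,0,2"])
        cohort = join_cohort(make_tally({"P1": 2, "P2": 1}), ct, "NOT_A_GENE")
        assert cohort.frame["sv_count"].tolist() == [0, 0]

    def test_zero_id_overlap_is_hard_error(self, tmp_path):
        ct = clinical_of(tmp_path, ["P1,a,1,1", "P2,b,0,2"])
        with pytest.raises(ValidationError, match="id scheme"):
            join_cohort(make_tally({"X1": 2, "X2": 1}), ct, "G")


def cohort_with_counts(tmp_path, counts):
    rows = [f"P{i},{'placebo' if i % 2 else 'treatment'},1,{i + 1}"
            for i in range(len(counts))]
    ct = clinical_of(tmp_path, rows)
    return join_cohort(make_tally({f"P{i}": c for i, c in enumerate(counts)}), ct, "G")


class TestStratify:
    def test_default_min_one_partitions_cohort(self, tmp_path):
        cohort = stratify_by_sv(cohort_with_counts(tmp_path, [0, 1, 3, 5]))
        assert cohort.frame["carrier"].tolist() == [False, True, True, True]
        assert not cohort.frame["excluded"].any()

    def test_min_three_excludes_intermediate_counts(self, tmp_path):
        cohort = stratify_by_sv(cohort_with_counts(tmp_path, [0, 1, 3, 5]), min_sv=3)
        assert cohort.frame["carrier"].tolist() == [False, False, True, True]
        assert cohort.frame["excluded"].tolist() == [False, True, False, False]
        assert len(cohort.analyzed()) == 3

    def test_inverted_window_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            stratify_by_sv(cohort_with_counts(tmp_path, [0, 1]), min_sv=2, max_sv=1)

    def test_window_excluding_everyone_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="exclude"):
            stratify_by_sv(cohort_with_counts(tmp_path, [1, 1]), min_sv=5)

    def test_max_window(self, tmp_path):
        cohort = stratify_by_sv(cohort_with_counts(tmp_path, [0, 2, 7]), min_sv=1, max_sv=3)
        assert cohort.frame["carrier"].tolist() == [False, True, False]
        assert cohort.frame["excluded"].tolist() == [False, False, True]


class TestCrosstab:
    def test_margins_match_arm_sizes(self, tmp_path):
        cohort = stratify_by_sv(cohort_with_counts(tmp_path, [0, 1, 3, 5, 0, 2]))
        tab = arm_sv_crosstab(cohort)
        df = cohort.analyzed()
        assert tab.loc["placebo", "n"] == (df["arm"] == 0).sum()
        assert tab.loc["treatment", "n"] == (df["arm"] == 1).sum()
        assert (tab["non_carrier"] + tab["carrier"]).tolist() == tab["n"].tolist()

    def test_all_noncarriers(self, tmp_path):
        cohort = stratify_by_sv(cohort_with_counts(tmp_path, [0, 0, 0, 0]))
        tab = arm_sv_crosstab(cohort)
        assert tab["carrier"].sum() == 0


def test_column_map_invariants():
    with pytest.raises(ValidationError):
        ColumnMap(id_col="a", arm_col="a", event_col="c", time_col="d")
    with pytest.raises(ValidationError):
        ColumnMap(id_col="a", arm_col="b", event_col="c", time_col="d",
                  time_unit="fortnights")
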