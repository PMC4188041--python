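import numpy as np
import pytest

from rastriage import catalog
from rastriage.catalog import (
    MutationRecord,
    Origin,
    Region,
    RegionKind,
    RegionMap,
    ValidationError,
    assign_region,
    origin_summary,
    parse_mutations,
    parse_regions,
    region_counts,
)

HEADER = "gene\tposition\twt_aa\tmut_aa\torigin\tdisease\tgold_set\n"


def write_table(tmp_path, rows, header=HEADER, name="catalog.tsv"):
    path = tmp_path / name
    path.write_text(header + "".join(r + "\n" for r in rows))
    return path


def make_record(gene="KRAS", position=12, wt="G", mut="V", origin=Origin.SOMATIC, **kw):
    return MutationRecord(gene, position, wt, mut, origin, **kw)


class TestParseMutations:
    def test_germline_and_somatic_duplicates_collapse_to_both(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "KRAS\t12\tG\tV\tsomatic\tcolorectal cancer\t0",
                "KRAS\t12\tG\tV\tgermline\tNoonan syndrome\t1",
            ],
        )
        records = parse_mutations(path)
        assert len(records) == 1
        rec = records[0]
        assert rec.origin is Origin.BOTH
        assert rec.gold_set is True  # ORed across duplicate rows
        assert rec.disease_labels == ("Noonan syndrome", "colorectal cancer")

    def test_duplicates_differing_only_in_disease_label_merge(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "PTPN11\t61\tA\tG\tgermline\tNoonan syndrome\t0",
                "PTPN11\t61\tA\tG\tgermline\tLEOPARD syndrome\t0",
            ],
        )
        records = parse_mutations(path)
        assert len(records) == 1
        assert records[0].disease_labels == ("LEOPARD syndrome", "Noonan syndrome")

    def test_empty_table_with_valid_header_gives_empty_list(self, tmp_path):
        assert parse_mutations(write_table(tmp_path, [])) == []

    def test_comma_separated_tables_are_accepted(self, tmp_path):
        path = tmp_path / "catalog.csv"
        path.write_text(
            "gene,position,wt_aa,mut_aa,origin,disease,gold_set\n"
            "HRAS,13,G,D,germline,Costello syndrome,0\n"
        )
        (rec,) = parse_mutations(path)
        assert rec.gene == "HRAS" and rec.position == 13

    def test_synonymous_row_is_a_validation_error_with_row_number(self, tmp_path):
        path = write_table(tmp_path, ["KRAS\t12\tG\tG\tsomatic\tx\t0"])
        with pytest.raises(ValidationError, match="row 2"):
            parse_mutations(path)

    def test_malformed_amino_acid_reports_all_bad_rows(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "KRAS\t12\tG\tV\tsomatic\tx\t0",
                "KRAS\t13\tB\tV\tsomatic\tx\t0",
                "KRAS\t14\tG\tZ\tsomatic\tx\t0",
            ],
        )
        with pytest.raises(ValidationError, match=r"2 invalid row\(s\)") as exc:
            parse_mutations(path)
        assert "row 3" in str(exc.value) and "row 4" in str(exc.value)

    def test_missing_mandatory_column_is_a_file_level_error(self, tmp_path):
        path = write_table(
            tmp_path, ["KRAS\t12\tG\tV\tsomatic\t0"],
            header="gene\tposition\twt_aa\tmut_aa\torigin\tgold_set\n",
        )
        with pytest.raises(ValidationError, match="disease"):
            parse_mutations(path)


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(wt="G", mut="G"),
            dict(wt="X", mut="V"),
            dict(wt="G", mut="-"),
            dict(position=0),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_record(**kwargs)


class TestOriginSummary:
    def test_disjoint_counts(self):
        records = (
            [make_record(position=i, origin=Origin.GERMLINE) for i in range(1, 4)]
            + [make_record(position=i, origin=Origin.SOMATIC) for i in range(10, 12)]
            + [make_record(position=20, origin=Origin.BOTH)]
        )
        assert tuple(origin_summary(records)) == (3, 2, 1)

    def test_empty_list(self):
        assert tuple(origin_summary([])) == (0, 0, 0)

    def test_components_sum_to_deduplicated_total(self, small_dataset):
        records = parse_mutations(small_dataset["catalog"])
        summary = origin_summary(records)
        assert sum(summary) == len(records)

    def test_counting_conventions_reported(self):
        summary = origin_summary(
            [make_record(position=1, origin=Origin.GERMLINE), make_record(position=2, origin=Origin.BOTH)]
        )
        conv = summary.conventions()
        assert conv["exclusive"] == (1, 0, 1)
        assert conv["inclusive_germline"] == (2, 0, 1)
        assert conv["inclusive_somatic"] == (1, 1, 1)


@pytest.fixture(scope="module")
def sh2_map():
    return RegionMap(
        gene="KRAS",
        regions=(
            Region("D1", 10, 39, RegionKind.DOMAIN),
            Region("SH2", 40, 60, RegionKind.DOMAIN),
            Region("I1", 61, 80, RegionKind.INTER_DOMAIN),
            Region("D2", 95, 150, RegionKind.DOMAIN),
        ),
    )


class TestAssignRegion:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (50, "SH2"),     # inside a domain
            (1, "N"),        # before the first region
            (60, "SH2"),     # closed interval: end coordinate included
            (61, "I1"),      # start coordinate of next region
            (85, "I1"),      # gap between I1 and D2 -> preceding region
            (151, "C"),      # past the last region
            (10, "D1"),      # first start coordinate
        ],
    )
    def test_region_assignment(self, sh2_map, position, expected):
        rec = make_record(position=position)
        assert assign_region(rec, sh2_map) == expected

    def test_assignment_is_total(self, sh2_map):
        labels = {"N", "C", *sh2_map.labels}
        for pos in range(1, 200):
            assert assign_region(make_record(position=pos), sh2_map) in labels

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            RegionMap(
                gene="X",
                regions=(
                    Region("A", 1, 50, RegionKind.DOMAIN),
                    Region("B", 40, 60, RegionKind.DOMAIN),
                ),
            )


class TestRegionCounts:
    def test_single_mutation_single_cell(self, sh2_map):
        rec = make_record(position=50, origin=Origin.GERMLINE)
        table = region_counts([rec], {"KRAS": sh2_map})
        assert table.loc[("KRAS", "SH2"), "germline"] == 1
        assert table.values.sum() == 1

    def test_zero_regions_retained(self, sh2_map):
        table = region_counts([], {"KRAS": sh2_map})
        assert set(table.index.get_level_values("region")) == {"N", "C", *sh2_map.labels}
        assert (table.values == 0).all()

    def test_counts_match_brute_force_scan(self, small_dataset, small_config):
        """Counts on a generated two-gene fixture equal an exhaustive re-count."""
        from rastriage.synth import gen_region_maps

        records = parse_mutations(small_dataset["catalog"])
        maps = parse_regions(small_dataset["regions"])
        assert maps == gen_region_maps(("KRAS", "PTPN11"), seed=small_config.seed)
        subset = [r for r in records if r.gene in maps]
        table = region_counts(subset, maps)
        assert table.values.sum() == len(subset)
        # brute force: scan every record against every (gene, region) cell
        for (gene, label), row in table.iterrows():
            for origin in Origin:
                expected = sum(
                    1
                    for r in subset
                    if r.gene == gene
                    and r.origin is origin
                    and assign_region(r, maps[gene]) == label
                )
                assert row[origin.value] == expected

    def test_invariant_under_input_permutation(self, small_dataset, rng):
        records = parse_mutations(small_dataset["catalog"])
        maps = parse_regions(small_dataset["regions"])
        subset = [r for r in records if r.gene in maps]
        shuffled = list(subset)
        rng.shuffle(shuffled)
        assert region_counts(subset, maps).equals(region_counts(shuffled, maps))

    def test_unmapped_gene_is_an_error(self, sh2_map):
        with pytest.raises(ValidationError, match="BRAF"):
            region_counts([make_record(gene="BRAF")], {"KRAS": sh2_map})
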