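"""BIDS/tabular ingestion, name normalization and dataset graph round trips."""

from __future__ import annotations

import json
import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_annotated_dataset
from neuroterms.dataset_ingest import (
    AnnotatedDataset,
    DatasetError,
    SUFFIX_TABLE,
    infer_image_annotations,
    ingest_bids,
    ingest_tabular,
    normalize_variable_name,
    read_dataset_graph,
    read_participants_table,
    read_sidecar,
    write_dataset_graph,
)
from neuroterms.term_model import FormatError, build_data_element


@pytest.fixture()
def bids_root(tmp_path):
    root = tmp_path / "ds"
    root.mkdir()
    (root / "participants.tsv").write_text(
        "participant_id\tage\tsex\nsub-01\t12\tM\nsub-02\tn/a\tF\n"
    )
    (root / "participants.json").write_text(
        json.dumps(
            {
                "age": {"Description": "age of participant", "Units": "years"},
                "sex": {"Levels": {"M": "male", "F": "female"}},
            }
        )
    )
    for sub in ("sub-01", "sub-02"):
        anat = root / sub / "anat"
        anat.mkdir(parents=True)
        (anat / f"{sub}_T1w.nii.gz").touch()
    return root


class TestParticipantsTable:
    def test_header_and_row_cardinality(self, tmp_path):
        path = tmp_path / "participants.tsv"
        path.write_text("participant_id\tage\tsex\nsub-01\t10\tM\nsub-02\t11\tF\n")
        names, rows = read_participants_table(path)
        assert names == ["participant_id", "age", "sex"]
        assert len(rows) == 2

    def test_na_becomes_missing(self, tmp_path):
        path = tmp_path / "participants.tsv"
        path.write_text("participant_id\tage\nsub-01\tn/a\n")
        _, rows = read_participants_table(path)
        assert rows[0]["age"] is None

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "participants.tsv"
        path.write_text("participant_id\tage\n")
        names, rows = read_participants_table(path)
        assert names == ["participant_id", "age"] and rows == []

    def test_missing_participant_id_column(self, tmp_path):
        path = tmp_path / "participants.tsv"
        path.write_text("subject\tage\ns1\t10\n")
        with pytest.raises(FormatError, match="participant_id"):
            read_participants_table(path)

    def test_ragged_row_error_names_line(self, tmp_path):
        path = tmp_path / "participants.tsv"
        path.write_text("participant_id\tage\nsub-01\t10\nsub-02\n")
        with pytest.raises(FormatError, match="line 3"):
            read_participants_table(path)


class TestSidecar:
    def test_units_map_to_unit_code(self, tmp_path):
        path = tmp_path / "s.json"
        path.write_text(json.dumps({"age": {"Description": "age of participant", "Units": "years"}}))
        props = read_sidecar(path)["age"]
        assert props["unitCode"] == "years"
        assert props["description"] == "age of participant"

    def test_levels_map_to_choices(self, tmp_path):
        path = tmp_path / "s.json"
        path.write_text(
            json.dumps({"handedness": {"Levels": {"1": "Right", "5": "Left", "10": "Ambidextrous"}}})
        )
        choices = read_sidecar(path)["handedness"]["choices"]
        assert {c.code: c.meaning for c in choices}[10] == "Ambidextrous"

    def test_is_about_url_is_kept(self, tmp_path):
        path = tmp_path / "s.json"
        path.write_text(
            json.dumps(
                {
                    "handedness": {
                        "isAbout": {
                            "url": "http://uri.interlex.org/base/ilx_0104886",
                            "label": "handedness assessment",
                        }
                    }
                }
            )
        )
        refs = read_sidecar(path)["handedness"]["isAbout"]
        assert refs[0]["url"].endswith("ilx_0104886")

    def test_non_object_document_rejected(self, tmp_path):
        path = tmp_path / "s.json"
        path.write_text("[1, 2]")
        with pytest.raises(FormatError):
            read_sidecar(path)


class TestImageAnnotations:
    @pytest.mark.parametrize(
        "path, contrast, usage, subject, session",
        [
            ("sub-01/anat/sub-01_T2w.nii.gz", "T2-weighted", "Anatomical", "01", None),
            ("sub-02/func/sub-02_task-rest_bold.nii.gz", "T2*-weighted", "Functional", "02", None),
            ("sub-01/ses-2/anat/sub-01_ses-2_T1w.nii.gz", "T1-weighted", "Anatomical", "01", "2"),
            ("sub-03/dwi/sub-03_dwi.nii", "Diffusion-weighted", "Diffusion", "03", None),
        ],
    )
    def test_suffix_typing(self, path, contrast, usage, subject, session):
        (record,) = infer_image_annotations([path])
        assert record.imageContrastType == contrast
        assert record.imageUsageType == usage
        assert record.subjectId == subject
        assert record.sessionId == session

    def test_unparseable_paths_skipped_not_fatal(self, caplog):
        records = infer_image_annotations(
            ["README.txt", "sub-01/anat/sub-01_T1w.nii.gz", "sub-01/anat/strange.nii"]
        )
        assert len(records) == 1

    def test_every_pair_comes_from_the_suffix_table(self):
        paths = [f"sub-01/anat/sub-01_{s}.nii.gz" for s in SUFFIX_TABLE]
        for record in infer_image_annotations(paths):
            assert (record.imageContrastType, record.imageUsageType) in SUFFIX_TABLE.values()


class TestNormalizeVariableName:
    @pytest.mark.parametrize("variant", ["Age Months", "age_months", "AGE-MONTHS", " age  months "])
    def test_variants_collapse_to_one_key(self, variant):
        assert normalize_variable_name(variant) == "age_months"

    def test_fixed_point(self):
        assert normalize_variable_name("ehi") == "ehi"

    @given(st.text(min_size=1).filter(lambda s: any(ch.isalnum() for ch in s)))
    @settings(deadline=None)
    def test_idempotence(self, name):
        once = normalize_variable_name(name)
        assert normalize_variable_name(once) == once

    @pytest.mark.parametrize("bad", ["", "___", "  "])
    def test_empty_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_variable_name(bad)


class TestIngestBids:
    def test_assembly_from_parts(self, bids_root):
        ds = ingest_bids(bids_root)
        assert len(ds.subjectRows) == 2
        assert len(ds.acquisitions) == 2
        assert ds.dataDictionary["age"].unitCode == "years"

    def test_external_dictionary_overrides_sidecar(self, bids_root):
        override = build_data_element(
            "sex", {"description": "harmonized sex", "choices": {"0": "female", "1": "male"}}
        )
        ds = ingest_bids(bids_root, dictionary={"sex": override})
        codes = [c.code for c in ds.dataDictionary["sex"].choices]
        assert codes == [0, 1]

    def test_phenotype_directory_variables_included(self, bids_root):
        pheno = bids_root / "phenotype"
        pheno.mkdir()
        (pheno / "ehi.tsv").write_text("participant_id\tehi\nsub-01\t30\nsub-02\t-10\n")
        ds = ingest_bids(bids_root)
        assert "ehi" in ds.dataDictionary
        assert dict(ds.subjectRows)["sub-01"]["ehi"] == "30"

    def test_missing_participants_tsv(self, tmp_path):
        with pytest.raises(DatasetError, match="participants.tsv"):
            ingest_bids(tmp_path)

    def test_conservation_of_rows(self, bids_root, tmp_path):
        table = tmp_path / "extra.csv"
        table.write_text("participant_id,iq\nsub-10,100\nsub-11,90\n")
        ds = ingest_bids(bids_root)
        merged = ingest_tabular(table, existing=ds)
        assert len(merged.subjectRows) == len(ds.subjectRows) + 2


class TestIngestTabular:
    def test_merge_combines_imaging_and_new_variables(self, bids_root, tmp_path):
        table = tmp_path / "pheno.csv"
        table.write_text("participant_id,iq\nsub-01,100\nsub-02,90\n")
        merged = ingest_tabular(table, existing=ingest_bids(bids_root))
        assert merged.acquisitions  # imaging kept
        assert "iq" in merged.dataDictionary
        assert len(merged.subjectRows) == 2

    def test_idempotent_reingestion(self, bids_root, tmp_path):
        table = tmp_path / "pheno.csv"
        table.write_text("participant_id,iq\nsub-01,100\n")
        once = ingest_tabular(table, existing=ingest_bids(bids_root))
        twice = ingest_tabular(table, existing=once)
        assert once == twice

    def test_conflicting_values_listed(self, tmp_path):
        a = tmp_path / "a.csv"
        a.write_text("participant_id,iq\nsub-01,100\n")
        b = tmp_path / "b.csv"
        b.write_text("participant_id,iq\nsub-01,90\n")
        ds = ingest_tabular(a)
        with pytest.raises(DatasetError, match="100.*90"):
            ingest_tabular(b, existing=ds)

    def test_missing_subject_column(self, tmp_path):
        table = tmp_path / "pheno.csv"
        table.write_text("id,iq\ns1,100\n")
        with pytest.raises(FormatError, match="participant_id"):
            ingest_tabular(table)


class TestGraphRoundTrip:
    @pytest.mark.parametrize("fmt", ["jsonld", "nquads"])
    @pytest.mark.parametrize("seed", range(4))
    def test_write_read_identity_random_datasets(self, fmt, seed):
        ds = random_annotated_dataset(random.Random(seed), f"ds-{seed}")
        assert read_dataset_graph(write_dataset_graph(ds, fmt), fmt) == ds

    @pytest.mark.parametrize("fmt", ["jsonld", "nquads"])
    def test_write_read_identity_bids(self, bids_root, fmt):
        ds = ingest_bids(bids_root)
        assert read_dataset_graph(write_dataset_graph(ds, fmt), fmt) == ds

    def test_contrast_statement_present(self, bids_root):
        ds = ingest_bids(bids_root)
        text = write_dataset_graph(ds, "nquads")
        assert "hadImageContrastType" in text and "T1-weighted" in text

    def test_empty_acquisitions_mean_no_contrast_statements(self):
        ds = AnnotatedDataset(datasetId="empty")
        assert "hadImageContrastType" not in write_dataset_graph(ds, "nquads")

    def test_unsupported_format_rejected(self):
        with pytest.raises(ValueError, match="jsonld, nquads"):
            write_dataset_graph(AnnotatedDataset(datasetId="x"), "turtle")


def test_name_merge_across_heterogeneous_sites(tmp_path):
    """Sites whose headers differ only in case/separators produce identical
    dictionary key sets."""
    for i, header in enumerate(("Age Months\tSEX", "age_months\tsex", "AGE-MONTHS\tSex")):
        root = tmp_path / f"site-{i}"
        root.mkdir()
        (root / "participants.tsv").write_text(f"participant_id\t{header}\nsub-01\t12\tM\n")
    key_sets = {
        frozenset(ingest_bids(tmp_path / f"site-{i}").dataDictionary) for i in range(3)
    }
    assert key_sets == {frozenset({"age_months", "sex"})}
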