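"""Problem-bundle dialect: parsing, validation, mapping, round-trip."""

import copy

import numpy as np
import pytest
from lxml import etree

from cellabc.problem import (
    PathError,
    ProblemFormatError,
    map_parameters,
    parse_problem,
    read_path,
    resolve_path,
    sample_space,
    validate_problem,
    write_problem,
)


class TestPathGrammar:
    @pytest.fixture
    def doc(self):
        return etree.fromstring(
            '<Model kind="viral"><Param name="beta" value="0.1"/>'
            "<Note>hello</Note><Lattice width='5' height='5'/></Model>"
        )

    def test_attribute_selector(self, doc):
        assert read_path(doc, "Model/Param[@name='beta']/@value") == "0.1"

    def test_text_selector(self, doc):
        assert read_path(doc, "Model/Note/text()") == "hello"

    def test_missing_step_raises(self, doc):
        with pytest.raises(PathError, match="not found"):
            resolve_path(doc, "Model/Param[@name='gamma']/@value")

    def test_missing_selector_raises(self, doc):
        with pytest.raises(PathError, match="end in|selector"):
            resolve_path(doc, "Model/Param[@name='beta']")

    def test_missing_attribute_raises(self, doc):
        with pytest.raises(PathError, match="absent"):
            resolve_path(doc, "Model/Lattice/@depth")


class TestParse:
    def test_viral_fixture_counts(self, viral_problem):
        assert len(viral_problem.estimated) == 2
        assert len(viral_problem.condition_table) == 1
        assert len(viral_problem.measurement_table) == 16  # 11 counts + 5 radial bins
        assert validate_problem(viral_problem) == []

    def test_missing_column_reported_with_table_and_column(self, tmp_path, invalid_corpus):
        bundle = next(b for b in invalid_corpus if b.name == "missing_column")
        with pytest.raises(ProblemFormatError, match="parameter_table: prior_kind"):
            parse_problem(bundle.index_path, strict=True)

    def test_dangling_condition_named_in_error(self, invalid_corpus):
        bundle = next(b for b in invalid_corpus if b.name == "dangling_condition")
        with pytest.raises(ProblemFormatError, match="c99"):
            parse_problem(bundle.index_path, strict=True)

    def test_missing_index_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no_such"):
            parse_problem(tmp_path / "no_such.yaml")

    def test_unknown_columns_are_preserved_but_ignored(self, tmp_path, gaussian_bundle):
        lines = (gaussian_bundle.index_path.parent / "parameters.tsv").read_text().splitlines()
        extra = [lines[0] + "\tcustom_note"] + [ln + "\tx" for ln in lines[1:]]
        out = tmp_path / "bundle"
        out.mkdir()
        for name in ("model.xml", "conditions.tsv", "measurements.tsv", "statistics.tsv",
                     "problem.yaml"):
            (out / name).write_text((gaussian_bundle.index_path.parent / name).read_text())
        (out / "parameters.tsv").write_text("\n".join(extra) + "\n")
        p = parse_problem(out / "problem.yaml")
        assert validate_problem(p) == []
        assert "custom_note" in p.raw_tables["parameter_table"].columns


class TestValidate:
    def test_valid_fixtures_produce_empty_reports(self, gaussian_problem, viral_problem):
        assert validate_problem(gaussian_problem) == []
        assert validate_problem(viral_problem) == []

    def test_invalid_corpus_triggers_exactly_its_code(self, invalid_corpus):
        assert len(invalid_corpus) >= 6
        for bundle in invalid_corpus:
            report = validate_problem(parse_problem(bundle.index_path))
            codes = [issue.code for issue in report]
            assert codes == [bundle.expected_error_code], bundle.name

    def test_fixing_the_defect_restores_validity(self, tmp_path, invalid_corpus):
        bundle = next(b for b in invalid_corpus if b.name == "inverted_bounds")
        src = bundle.index_path.parent
        out = tmp_path / "fixed"
        out.mkdir()
        for f in src.iterdir():
            (out / f.name).write_text(f.read_text())
        fixed = (out / "parameters.tsv").read_text().replace("\t2\t1\t", "\t1\t2\t")
        (out / "parameters.tsv").write_text(fixed)
        assert validate_problem(parse_problem(out / "problem.yaml")) == []


class TestSampleSpace:
    def test_log10_bounds_transformed(self, viral_problem):
        space = sample_space(viral_problem)
        ids = [s[0] for s in space]
        assert ids == ["beta_cf", "beta_cc"]
        (_, lo, hi, scale) = space[0]
        assert (lo, hi) == (pytest.approx(np.log10(0.005)), pytest.approx(np.log10(0.5)))
        assert scale == "log10"

    def test_fixed_parameters_excluded(self, tmp_path, gaussian_bundle):
        src = gaussian_bundle.index_path.parent
        out = tmp_path / "b"
        out.mkdir()
        for f in src.iterdir():
            (out / f.name).write_text(f.read_text())
        params = (out / "parameters.tsv").read_text().rstrip("\n")
        params += "\nnoise\tuniform\t0\t2\tlin\tfalse\t1.0\tModel/Param[@name='noise_sd']/@value\n"
        (out / "parameters.tsv").write_text(params)
        p = parse_problem(out / "problem.yaml")
        assert [s[0] for s in sample_space(p)] == ["theta"]


class TestMapParameters:
    def test_writes_value_at_target(self, gaussian_problem):
        doc = map_parameters(gaussian_problem, np.array([0.3]), "c0")
        assert read_path(doc, "Model/Param[@name='theta']/@value") == "0.3"

    def test_log10_back_transform(self, viral_problem):
        doc = map_parameters(viral_problem, np.array([-2.0, -1.0]), "c0")
        assert float(read_path(doc, "Model/Param[@name='beta_cf']/@value")) == pytest.approx(0.01)
        assert float(read_path(doc, "Model/Param[@name='beta_cc']/@value")) == pytest.approx(0.1)

    def test_pure_and_deterministic(self, viral_problem):
        before = etree.tostring(viral_problem.model_document)
        d1 = map_parameters(viral_problem, np.array([-1.5, -0.5]), "c0")
        d2 = map_parameters(viral_problem, np.array([-1.5, -0.5]), "c0")
        assert etree.tostring(d1) == etree.tostring(d2)
        assert etree.tostring(viral_problem.model_document) == before

    def test_unknown_condition_raises(self, gaussian_problem):
        with pytest.raises(KeyError, match="c99"):
            map_parameters(gaussian_problem, np.array([0.0]), "c99")

    def test_wrong_theta_length_raises(self, gaussian_problem):
        with pytest.raises(ValueError, match="length"):
            map_parameters(gaussian_problem, np.array([0.0, 1.0]), "c0")


class TestRoundTrip:
    @pytest.mark.parametrize("which", ["gaussian", "viral"])
    def test_write_then_reparse_is_equal(self, tmp_path, which, gaussian_problem, viral_problem):
        p = {"gaussian": gaussian_problem, "viral": viral_problem}[which]
        out = tmp_path / "rt" / "problem.yaml"
        write_problem(p, out)
        q = parse_problem(out)
        assert validate_problem(q) == []
        assert [x.parameter_id for x in q.parameter_table] == [
            x.parameter_id for x in p.parameter_table
        ]
        assert len(q.measurement_table) == len(p.measurement_table)
        for a, b in zip(p.measurement_table, q.measurement_table):
            assert a.observable_id == b.observable_id
            assert a.time == pytest.approx(b.time)
            assert (a.value is None) == (b.value is None)
            if a.value is not None:
                assert a.value == pytest.approx(b.value, rel=1e-12)
        assert [s.args for s in q.statistic_table] == [s.args for s in p.statistic_table]
        assert etree.tostring(q.model_document).replace(b" ", b"").replace(
            b"\n", b""
        ) == etree.tostring(p.model_document).replace(b" ", b"").replace(b"\n", b"")

    def test_fingerprint_stable_under_round_trip(self, tmp_path, gaussian_problem):
        out = tmp_path / "rt2" / "problem.yaml"
        write_problem(gaussian_problem, out)
        q = parse_problem(out)
        out2 = tmp_path / "rt3" / "problem.yaml"
        write_problem(q, out2)
        r = parse_problem(out2)
        assert q.fingerprint() == r.fingerprint()
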