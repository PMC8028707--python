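import pytest

from csca import paper_scenario


@pytest.fixture(scope="session")
def scenario():
    """The deterministic study-scale synthetic bundle (seed 1)."""
    return paper_scenario(1)


@pytest.fixture(scope="session")
def scenario_dir(scenario, tmp_path_factory):
    """The same bundle written to disk, as the pipeline consumes it."""
    outdir = tmp_path_factory.mktemp("scenario")
    paths = scenario.write(outdir)
    return paths


CUFFDIFF_HEADER = (
    "test_id\tgene_id\tgene\tlocus\tsample_1\tsample_2\tstatus\tvalue_1\t"
    "value_2\tlog2(fold_change)\ttest_stat\tp_value\tq_value\tsignificant"
)


def cuffdiff_line(test_id="T1", gene_id="XLOC_1", gene="GAD2",
                  locus="chr1:100-200", status="OK", value_1="5.0",
                  value_2="10.0", log2fc="1.0", test_stat="2.0",
                  p_value="0.001", q_value="0.01", significant="yes"):
    return "\t".join([test_id, gene_id, gene, locus, "q1", "q2", status,
                      value_1, value_2, log2fc, test_stat, p_value, q_value,
                      significant])


@pytest.fixture
def write_cuffdiff(tmp_path):
    """Write a gene_exp.diff file from row strings; returns the path."""
    def _write(*rows, header=CUFFDIFF_HEADER):
        path = tmp_path / "gene_exp.diff"
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path
    return _write
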