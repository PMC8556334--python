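"""Technical-validation analytics: parse checks, multiplicity, recounts."""

from collections import Counter

import pandas as pd
import pytest

from bbbcurate import (
    CuratedRow,
    multiplicity_tables,
    recount_released,
    summarize_distributions,
    validate_parse,
)
from bbbcurate.curation import CuratedCategoricalRecord, CuratedNumericRecord


def _rows(*smiles):
    return [CuratedRow(smiles=s, inchi=f"I{i}", group="A") for i, s in enumerate(smiles)]


def test_second_parser_accepts_valid_curated_output():
    fraction, failures = validate_parse(_rows("CCO", "c1ccccc1", "NCC(=O)O"))
    assert fraction == 1.0 and failures == []


def test_injected_corrupt_row_is_caught_and_listed():
    rows = _rows("CCO", "C1CC", "CCN", "CCC")
    fraction, failures = validate_parse(rows)
    assert fraction == pytest.approx(3 / 4)
    assert [r.smiles for r in failures] == ["C1CC"]


def test_empty_input_reports_missing_fraction():
    assert validate_parse([]) == (None, [])


def _numeric(group, n_values, n_unique):
    return CuratedNumericRecord(key=f"{group}{n_values}{n_unique}", logbb=0.0,
                                group=group, n_values=n_values, n_unique=n_unique,
                                sources=["R"] * n_values)


def _categorical(group, n_labels, n_unique):
    return CuratedCategoricalRecord(key=f"{group}{n_labels}", label="BBB+", group=group,
                                    threshold_used=None, sources=["R"] * n_labels,
                                    n_labels=n_labels, n_unique_labels=n_unique)


def test_multiplicity_tables_cell_placement():
    numeric = [_numeric("A", 1, 1), _numeric("B", 3, 2)]
    tables = multiplicity_tables(numeric, [])
    assert tables["numeric_source"].loc[1, "A"] == 1
    assert tables["numeric_source"].loc[3, "B"] == 1
    assert tables["numeric_unique"].loc[2, "B"] == 1


def test_multiplicity_counts_sum_to_dataset_sizes():
    numeric = [_numeric("A", 1, 1), _numeric("B", 3, 2), _numeric("B", 2, 1),
               _numeric("D", 5, 3)]
    categorical = [_categorical("B", 2, 1), _categorical("C", 4, 1),
                   _categorical("D", 3, 2)]
    tables = multiplicity_tables(numeric, categorical)
    assert tables["numeric_source"].to_numpy().sum() == len(numeric)
    assert tables["numeric_unique"].to_numpy().sum() == len(numeric)
    assert tables["categorical_source"].to_numpy().sum() == len(categorical)
    assert tables["categorical_unique"].to_numpy().sum() == len(categorical)


def test_multiplicity_agrees_with_brute_force_recount():
    numeric = [_numeric(g, n, u) for g, n, u in
               [("A", 1, 1), ("B", 2, 2), ("B", 2, 2), ("C", 2, 2), ("D", 4, 3)]]
    tab = multiplicity_tables(numeric, [])["numeric_source"]
    brute = Counter((len(r.sources), r.group) for r in numeric)
    for (mult, group), count in brute.items():
        assert tab.loc[mult, group] == count
    assert tab.to_numpy().sum() == sum(brute.values())


def test_histogram_counts_sum_to_dataset_size_with_overflow_bins():
    numeric = [_numeric("A", 1, 1) for _ in range(5)]
    for rec, v in zip(numeric, [-5.0, -1.1, 0.0, 1.9, 3.5]):  # under/overflow included
        rec.logbb = v
    summary = summarize_distributions(numeric)
    assert sum(summary["logbb_histogram"]["counts"]) == 5
    assert summary["fraction_logbb_in_minus2_2"] == pytest.approx(3 / 5)


def test_distribution_summary_empty_class_is_missing():
    summary = summarize_distributions([], [])
    assert summary["fraction_logbb_in_minus2_2"] is None
    assert summary["class_summaries"] == {}


def test_recount_released_on_known_frames():
    numeric = pd.DataFrame({"group": ["A", "B", "B", "D"], "logBB": [0.1, 0.2, -0.3, 1.0]})
    categorical = pd.DataFrame({
        "group": ["A", "A", "B", "C", "D"],
        "BBB+/BBB-": ["BBB+", "BBB−", "BBB+", "BBB-", "BBB+"],
        "SMILES": ["CCO", "c1ccccc1", "CCCCC", "C" * 40, "CCN"],
    })
    out = recount_released(numeric, categorical)
    assert out["numeric_rows"] == 4 and out["categorical_rows"] == 5
    assert out["numeric_groups"] == {"A": 1, "B": 2, "C": 0, "D": 1}
    assert out["categorical_groups"] == {"A": 2, "B": 1, "C": 1, "D": 1}
    assert out["n_bbb_plus"] == 3 and out["n_bbb_minus"] == 2
    # all three BBB+ SMILES are light molecules -> 100% under 500 Da
    assert out["bbb_plus_mw_lt500_pct"] == pytest.approx(100.0)
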