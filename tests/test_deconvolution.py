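"""Report filtering, pair matching, normalization, testing and gene aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dilac.deconvolution import (
    aggregate_genes,
    benjamini_hochberg,
    deconvolve,
    load_and_filter,
    match_pairs,
    normalize,
    precursor_tests,
    qc_samples,
)
from dilac.errors import MissingColumnsError


def report_row(
    run="r1",
    sequence="AAVLK",
    charge=2,
    label="heavy",
    quantity=100.0,
    quality=0.9,
    protein="P1",
    gene="G1",
    proteotypic=1,
):
    return {
        "Run": run,
        "Stripped.Sequence": sequence,
        "Precursor.Charge": charge,
        "Label": label,
        "Precursor.Quantity": quantity,
        "Quantity.Quality": quality,
        "Protein.Group": protein,
        "Genes": gene,
        "Proteotypic": proteotypic,
    }


def test_load_and_filter_rules(scheme):
    df = pd.DataFrame(
        [
            report_row(sequence="AAVLK", quality=0.9),  # kept
            report_row(sequence="AKVLR", quality=0.9),  # internal K
            report_row(sequence="AAVLK", quality=0.7),  # strict inequality: dropped
            report_row(sequence="AAVLK", quality=0.9, proteotypic=0),  # not proteotypic
            report_row(sequence="AKVLK", quality=0.9),  # two lysines
            report_row(sequence="AAVLR", quality=0.9),  # no lysine
        ]
    )
    kept = load_and_filter(df, scheme)
    assert len(kept) == 1
    assert kept["quality"].iloc[0] == 0.9


def test_missing_columns_reported(scheme):
    df = pd.DataFrame([report_row()]).drop(columns=["Quantity.Quality", "Genes"])
    with pytest.raises(MissingColumnsError) as err:
        load_and_filter(df, scheme)
    assert set(err.value.missing) == {"Quantity.Quality", "Genes"}


def test_data_file_alias_accepted(scheme):
    df = pd.DataFrame([report_row()]).rename(columns={"Run": "Data.File"})
    assert len(load_and_filter(df, scheme)) == 1


def test_match_pairs_basic(scheme):
    df = load_and_filter(
        pd.DataFrame(
            [
                report_row(label="heavy", quantity=80.0),
                report_row(label="light", quantity=40.0),
                report_row(sequence="GGVLK", label="heavy"),  # heavy only
                report_row(sequence="TTVLK", label="heavy"),
                report_row(sequence="TTVLK", label="heavy", quantity=50.0),  # duplicate heavy
                report_row(sequence="TTVLK", label="light"),
            ]
        ),
        scheme,
    )
    pairs, rep = match_pairs(df)
    assert rep.n_pairs == 1 and rep.n_unmatched == 1 and rep.n_ambiguous == 1
    assert pairs["ratio"].iloc[0] == pytest.approx(2.0)


def test_nonpositive_quantities_excluded(scheme):
    df = load_and_filter(
        pd.DataFrame(
            [
                report_row(label="heavy", quantity=0.0),
                report_row(label="light", quantity=40.0),
            ]
        ),
        scheme,
    )
    pairs, rep = match_pairs(df)
    assert len(pairs) == 0 and rep.n_nonpositive == 1


def test_normalize_log2_median_centering():
    pairs = pd.DataFrame(
        {
            "run": ["r1"] * 3 + ["r2"],
            "sequence": ["A", "B", "C", "A"],
            "charge": [2] * 4,
            "ratio": [0.5, 1.0, 2.0, 7.0],
        }
    )
    out = normalize(pairs)
    assert np.allclose(out.loc[out["run"] == "r1", "norm_log2_ratio"], [-1.0, 0.0, 1.0])
    # a single pair in a sample normalizes to zero
    assert out.loc[out["run"] == "r2", "norm_log2_ratio"].iloc[0] == 0.0


def test_normalize_constant_ratios_all_zero():
    pairs = pd.DataFrame(
        {"run": ["r"] * 4, "sequence": list("ABCD"), "charge": [2] * 4, "ratio": [3.0] * 4}
    )
    assert np.allclose(normalize(pairs)["norm_log2_ratio"], 0.0)


def _pairs_frame(values_by_precursor):
    rows = []
    for (seq, charge), values in values_by_precursor.items():
        for i, v in enumerate(values, start=1):
            rows.append(
                {
                    "run": f"r{i}",
                    "sequence": seq,
                    "charge": charge,
                    "ratio": 2.0**v,
                    "norm_log2_ratio": v,
                    "gene": seq[0],
                    "protein_group": f"P_{seq[0]}",
                }
            )
    return pd.DataFrame(rows)


def test_t_statistic_hand_checked():
    """values (0.8, 1.0, 1.2) -> t = mean / (sd/sqrt(3)) = 8.660."""
    stats_df = precursor_tests(_pairs_frame({("AAK", 2): [0.8, 1.0, 1.2]}))
    row = stats_df.iloc[0]
    assert row["t"] == pytest.approx(1.0 / (0.2 / np.sqrt(3)), abs=1e-6)
    assert row["tested"]


def test_zero_vector_gives_p_one():
    stats_df = precursor_tests(_pairs_frame({("AAK", 2): [0.0, 0.0, 0.0]}))
    assert stats_df.iloc[0]["t"] == 0.0
    assert stats_df.iloc[0]["p"] == 1.0


def test_degenerate_variance_flagged():
    stats_df = precursor_tests(_pairs_frame({("AAK", 2): [0.5, 0.5, 0.5]}))
    row = stats_df.iloc[0]
    assert row["degenerate_variance"] and row["p"] == 0.0


def test_min_samples_excludes_from_testing_but_keeps_descriptive():
    stats_df = precursor_tests(
        _pairs_frame({("AAK", 2): [0.8, 1.0, 1.2], ("GGK", 2): [0.5, 0.6]})
    )
    by_seq = stats_df.set_index("sequence")
    assert not by_seq.loc["GGK", "tested"]
    assert by_seq.loc["GGK", "median_log2_ratio"] == pytest.approx(0.55)
    # BH runs only over the tested set
    assert np.isnan(by_seq.loc["GGK", "p_adj"])


def test_bh_hand_example():
    adjusted = benjamini_hochberg([0.01, 0.02, 0.04])
    assert np.allclose(adjusted, [0.03, 0.03, 0.04])


@given(
    st.lists(st.floats(min_value=1e-12, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
)
def test_bh_matches_step_up_oracle(p_values):
    """BH adjusted p-values equal the textbook step-up procedure."""
    p = np.asarray(p_values)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    oracle = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        oracle[idx] = running_min
    assert np.allclose(benjamini_hochberg(p), oracle, atol=1e-12)
    # monotone non-decreasing in raw p rank
    adj = benjamini_hochberg(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def _gene_stats(rows):
    return pd.DataFrame(
        [
            {
                "sequence": f"S{i}K",
                "charge": 2,
                "gene": gene,
                "median_log2_ratio": med,
                "significant": sig,
                "tested": True,
            }
            for i, (gene, med, sig) in enumerate(rows)
        ]
    )


@pytest.mark.parametrize(
    "precursors,expected_hit",
    [
        ([("G", 1.0, True), ("G", 0.8, False)], True),  # mean 0.9 > 0.75, concordant
        ([("G", 1.0, True), ("G", -0.2, False)], False),  # discordant signs
        ([("G", 0.6, True), ("G", 0.5, False)], False),  # mean 0.55 <= 0.75
        ([("G", 1.0, False), ("G", 0.9, False)], False),  # nothing significant
    ],
)
def test_gene_hit_rule(precursors, expected_hit):
    genes = aggregate_genes(_gene_stats(precursors))
    assert bool(genes.iloc[0]["hit"]) is expected_hit


def test_qc_excludes_low_id_sample(scheme):
    rows = []
    for run in [f"r{i}" for i in range(8)]:
        n = 2 if run == "r7" else 20  # r7 has 10% of the cohort median IDs
        for j in range(n):
            rows.append(report_row(run=run, sequence=f"AAV{'L' * (j + 1)}K", label="heavy"))
            rows.append(
                report_row(run=run, sequence=f"AAV{'L' * (j + 1)}K", label="light", quantity=50.0)
            )
    kept, excluded, report = qc_samples(load_and_filter(pd.DataFrame(rows), scheme))
    assert excluded == ["r7"]
    assert len(kept) == 7


def test_qc_identical_samples_kept(scheme):
    rows = []
    for run in ["r1", "r2", "r3"]:
        for j in range(4):
            rows.append(report_row(run=run, sequence=f"AAV{'L' * (j + 1)}K", label="heavy"))
            rows.append(
                report_row(run=run, sequence=f"AAV{'L' * (j + 1)}K", label="light", quantity=50.0)
            )
    kept, excluded, _ = qc_samples(load_and_filter(pd.DataFrame(rows), scheme))
    assert excluded == []


def test_pipeline_invariant_to_row_order_and_scaling(scheme, rng):
    rows = []
    for run in ["r1", "r2", "r3"]:
        for j in range(6):
            seq = f"AAV{'L' * (j + 1)}K"
            h = float(rng.lognormal(5, 0.5))
            rows.append(report_row(run=run, sequence=seq, label="heavy", quantity=h))
            rows.append(report_row(run=run, sequence=seq, label="light", quantity=h / (j + 1)))
    df = pd.DataFrame(rows)
    base = deconvolve(df, scheme, run_qc=False)

    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    scaled = shuffled.copy()
    scale_map = {"r1": 1.0, "r2": 10.0, "r3": 0.1}
    scaled["Precursor.Quantity"] *= scaled["Run"].map(scale_map)
    alt = deconvolve(scaled, scheme, run_qc=False)

    a = base["precursor_stats"].sort_values("sequence").reset_index(drop=True)
    b = alt["precursor_stats"].sort_values("sequence").reset_index(drop=True)
    assert np.allclose(a["mean_log2_ratio"], b["mean_log2_ratio"], atol=1e-9)
    assert np.allclose(a["p"], b["p"], atol=1e-9, equal_nan=True)
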