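"""Fragment specificity, top-3 ranking and the state-fraction averaging chain."""

import numpy as np
import pandas as pd
import pytest

from dilac.errors import UnquantifiableError
from dilac.labelling_quant import (
    fragment_specificity,
    parse_fragment,
    pattern_light_count,
    precursor_level_fractions,
    rank_fragments,
    site_patterns,
    state_fractions,
)

PEP = "KYSLAPVAKE"  # lysines at positions 1 and 9


def make_report(rows):
    return pd.DataFrame(rows, columns=["sample", "condition", "peptide", "state", "fragment", "area"])


def test_fragment_specificity_classes(scheme):
    y5 = fragment_specificity(PEP, "y5", scheme)
    assert y5.diagnostic and y5.covered_sites == (9,)
    b9 = fragment_specificity(PEP, "b9", scheme)
    assert not b9.diagnostic and b9.covered_sites == (1, 9)
    y1 = fragment_specificity(PEP, "y1", scheme)  # "E", zero sites
    assert not y1.diagnostic and y1.covered_sites == ()


def test_parse_fragment_rejects_garbage():
    assert parse_fragment("y12") == ("y", 12)
    with pytest.raises(ValueError):
        parse_fragment("a3")


def test_site_patterns_order_and_counts():
    assert site_patterns(2) == ["HH", "HL", "LH", "LL"]
    assert [pattern_light_count(s) for s in site_patterns(2)] == [0, 1, 1, 2]


def test_rank_fragments_mean_rank_cutoff():
    """Mean ranks {f1: 1.0, f2: 2.5, f3: 2.5, f4: 4.0} -> top3 = {f1, f2, f3}."""
    rows = []
    # sample s1: areas f1 > f2 > f3 > f4 ; sample s2: f1 > f3 > f2 > f4
    for sample, areas in [("s1", [40, 30, 20, 10]), ("s2", [40, 20, 30, 10])]:
        for frag, area in zip(["y3", "y4", "y5", "y6"], areas):
            rows.append({"sample": sample, "fragment": frag, "area": area})
    ranks, top = rank_fragments(pd.DataFrame(rows))
    lookup = dict(zip(ranks["fragment"], ranks["mean_rank"]))
    assert lookup == {"y3": 1.0, "y4": 2.5, "y5": 2.5, "y6": 4.0}
    assert top == ["y3", "y4", "y5"]


def test_rank_fragments_tie_at_cutoff_broken_lexicographically():
    rows = [{"sample": "s1", "fragment": f, "area": a} for f, a in [("y3", 5), ("y5", 3), ("y4", 3)]]
    _, top = rank_fragments(pd.DataFrame(rows), top_k=2)
    assert top == ["y3", "y4"]


def test_rank_fragments_single_fragment():
    _, top = rank_fragments(pd.DataFrame([{"sample": "s", "fragment": "y4", "area": 1.0}]))
    assert top == ["y4"]


def test_single_fragment_state_normalization(scheme):
    rows = [
        ("s1", "c", PEP, "HH", "y5", 30.0),
        ("s1", "c", PEP, "HL", "y5", 7.0),
        ("s1", "c", PEP, "LH", "y5", 8.0),
        ("s1", "c", PEP, "LL", "y5", 55.0),
    ]
    prof = state_fractions(make_report(rows), scheme)["c"]
    assert np.allclose(prof.fractions, [0.30, 0.15, 0.55])
    assert prof.mixed_fraction == pytest.approx(0.15)
    # the site-resolved mixed components sum to the reported mixed fraction
    assert prof.pattern_fractions["HL"] + prof.pattern_fractions["LH"] == pytest.approx(0.15)


def test_unweighted_mean_across_fragments(scheme):
    rows = []
    for frag, areas in [("y5", (20, 0, 20, 60)), ("y4", (40, 0, 20, 40))]:
        for state, area in zip(site_patterns(2), areas):
            rows.append(("s1", "c", PEP, state, frag, float(area)))
    prof = state_fractions(make_report(rows), scheme)["c"]
    assert np.allclose(prof.fractions, [0.3, 0.2, 0.5])


def test_non_diagnostic_fragments_ignored(scheme):
    rows = [
        ("s1", "c", PEP, "HH", "y5", 25.0),
        ("s1", "c", PEP, "LL", "y5", 75.0),
        # b9 covers both sites, y1 covers none: both must be ignored
        ("s1", "c", PEP, "HH", "b9", 1000.0),
        ("s1", "c", PEP, "LL", "b9", 0.0),
        ("s1", "c", PEP, "HH", "y1", 0.0),
        ("s1", "c", PEP, "LL", "y1", 1000.0),
    ]
    prof = state_fractions(make_report(rows), scheme)["c"]
    assert np.allclose(prof.fractions, [0.25, 0.0, 0.75])


def test_missing_state_rows_treated_as_zero_with_warning(scheme):
    rows = [
        ("s1", "c", PEP, "HH", "y5", 60.0),
        ("s1", "c", PEP, "LL", "y5", 40.0),
    ]
    with pytest.warns(UserWarning, match="missing state"):
        prof = state_fractions(make_report(rows), scheme)["c"]
    assert np.allclose(prof.fractions, [0.6, 0.0, 0.4])


def test_all_zero_fragment_dropped_and_unquantifiable_raises(scheme):
    rows = [
        ("s1", "c", PEP, state, "y5", 0.0) for state in site_patterns(2)
    ] + [
        ("s1", "c", PEP, "HH", "y4", 10.0),
        ("s1", "c", PEP, "HL", "y4", 0.0),
        ("s1", "c", PEP, "LH", "y4", 0.0),
        ("s1", "c", PEP, "LL", "y4", 10.0),
    ]
    prof = state_fractions(make_report(rows), scheme)["c"]
    assert np.allclose(prof.fractions, [0.5, 0.0, 0.5])
    with pytest.raises(UnquantifiableError):
        state_fractions(make_report([("s1", "c", PEP, "HH", "b9", 5.0)]), scheme)


def test_profile_permutation_invariance(scheme, rng):
    rows = []
    for sample in ("s1", "s2"):
        for frag in ("y5", "y4", "y3", "b3"):
            for state in site_patterns(2):
                rows.append(("c", sample, PEP, state, frag, float(rng.uniform(1, 100))))
    df = make_report([(s, c, p, st_, f, a) for c, s, p, st_, f, a in rows])
    shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
    a = state_fractions(df, scheme)["c"]
    b = state_fractions(shuffled, scheme)["c"]
    assert np.allclose(a.fractions, b.fractions)


def test_precursor_level_merges_mixed_states():
    rows = [
        ("s1", "c", PEP, "0", "precursor", 1.0),
        ("s1", "c", PEP, "1", "precursor", 2.0),
        ("s1", "c", PEP, "2", "precursor", 1.0),
    ]
    prof = precursor_level_fractions(make_report(rows), n_sites=2)["c"]
    assert np.allclose(prof.fractions, [0.25, 0.5, 0.25])


def test_precursor_single_state():
    rows = [("s1", "c", PEP, "2", "precursor", 5.0)]
    prof = precursor_level_fractions(make_report(rows), n_sites=2)["c"]
    assert np.allclose(prof.fractions, [0.0, 0.0, 1.0])


def test_fragment_and_precursor_levels_agree_noise_free(scheme):
    """MS1 profile equals the fragment profile with mixed components summed."""
    pattern_abundance = {"HH": 28.0, "HL": 7.0, "LH": 5.0, "LL": 60.0}
    frag_rows = [
        ("s1", "c", PEP, state, frag, abundance)
        for frag in ("y5", "y3")
        for state, abundance in pattern_abundance.items()
    ]
    ms1_rows = [
        ("s1", "c", PEP, "0", "precursor", pattern_abundance["HH"]),
        ("s1", "c", PEP, "1", "precursor", pattern_abundance["HL"] + pattern_abundance["LH"]),
        ("s1", "c", PEP, "2", "precursor", pattern_abundance["LL"]),
    ]
    frag_prof = state_fractions(make_report(frag_rows), scheme)["c"]
    ms1_prof = precursor_level_fractions(make_report(ms1_rows), n_sites=2)["c"]
    assert np.allclose(frag_prof.fractions, ms1_prof.fractions)


def test_replicate_sd_reported(scheme):
    rows = []
    for sample, hh in [("s1", 30.0), ("s2", 50.0)]:
        rows += [
            (sample, "c", PEP, "HH", "y5", hh),
            (sample, "c", PEP, "LL", "y5", 100.0 - hh),
            (sample, "c", PEP, "HL", "y5", 0.0),
            (sample, "c", PEP, "LH", "y5", 0.0),
        ]
    prof = state_fractions(make_report(rows), scheme)["c"]
    assert prof.n_replicates == 2
    assert prof.fractions[0] == pytest.approx(0.4)
    assert prof.sd[0] == pytest.approx(np.std([0.3, 0.5], ddof=1))
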