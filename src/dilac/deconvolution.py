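"""Producer/consumer proteome deconvolution from bulk DIA report tables.

Tryptic peptides with a single C-terminal target residue (lysine) exist in
exactly two labelled forms: the heavy-site variant made by producer cells
and the light-site variant made by consumers (all other residues are heavy
in both, since every cell builds them from labelled glucose).  Matching the
two variants of each precursor within a run therefore splits each protein's
bulk signal into its producer- and consumer-derived parts.  The pipeline:

1. filter report rows (proteotypic, exactly one C-terminal target residue,
   quantification quality above threshold);
2. sample-level QC on pair counts and median heavy/light ratio;
3. pair heavy and light rows per (run, sequence, charge);
4. per-sample median normalization of heavy/light ratios, log2 transform;
5. one-sample t-test per precursor across replicates, Benjamini-Hochberg
   correction;
6. gene-level aggregation with a three-part hit rule (>= one significant
   precursor, |mean of per-precursor median log2 FC| above threshold, all
   precursors sign-concordant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AllSamplesExcludedError, MissingColumnsError
from .isotope_model import LabelScheme

DEFAULT_COLUMNS: dict[str, str] = {
    "run": "Run",
    "sequence": "Stripped.Sequence",
    "charge": "Precursor.Charge",
    "label": "Label",  # "heavy" (producer) / "light" (consumer)
    "quantity": "Precursor.Quantity",
    "quality": "Quantity.Quality",
    "protein_group": "Protein.Group",
    "gene": "Genes",
    "proteotypic": "Proteotypic",
}

#: accepted alternative for the run column in DIA-NN style reports
RUN_ALIASES = ("Run", "Data.File")

HEAVY, LIGHT = "heavy", "light"


def _internal_frame(report: pd.DataFrame, columns: Optional[Mapping[str, str]]) -> pd.DataFrame:
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if colmap["run"] not in report.columns:
        for alias in RUN_ALIASES:
            if alias in report.columns:
                colmap["run"] = alias
                break
    missing = [v for v in colmap.values() if v not in report.columns]
    if missing:
        raise MissingColumnsError(missing)
    df = report.rename(columns={v: k for k, v in colmap.items()})[list(colmap)]
    return df.copy()


def load_and_filter(
    report: pd.DataFrame,
    scheme: LabelScheme,
    quality_threshold: float = 0.7,
    columns: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Retain proteotypic rows with one C-terminal target residue and quality > threshold.

    The quality comparison is a strict inequality.  Returns an
    internally-named frame (run, sequence, charge, label, quantity, quality,
    protein_group, gene, proteotypic).
    """
    df = _internal_frame(report, columns)
    target = scheme.target_residue
    seq = df["sequence"].astype(str)
    one_cterm_site = (seq.str.count(target) == 1) & seq.str.endswith(target)
    keep = (
        df["proteotypic"].astype(bool)
        & one_cterm_site
        & (df["quality"].astype(float) > quality_threshold)
    )
    return df[keep].reset_index(drop=True)


@dataclass(frozen=True)
class PairingReport:
    n_pairs: int
    n_unmatched: int  # keys with only one side observed
    n_ambiguous: int  # keys with duplicate rows on a side
    n_nonpositive: int  # pairs dropped for zero/negative quantities


def match_pairs(records: pd.DataFrame) -> tuple[pd.DataFrame, PairingReport]:
    """Form heavy/light pairs keyed by (run, sequence, charge).

    A pair needs exactly one heavy and one light row; keys with a missing
    side or duplicated rows are dropped and counted.  Pairs with a
    non-positive quantity on either side are excluded (no ratio exists).
    """
    if records.empty:
        empty = pd.DataFrame(
            columns=["run", "sequence", "charge", "heavy", "light", "ratio", "gene", "protein_group"]
        )
        return empty, PairingReport(0, 0, 0, 0)
    agg = (
        records.groupby(["run", "sequence", "charge", "label"])["quantity"]
        .agg(["count", "first"])
        .unstack("label")
    )
    zeros = pd.Series(0, index=agg.index)
    n_heavy = agg.get(("count", HEAVY), zeros).fillna(0)
    n_light = agg.get(("count", LIGHT), zeros).fillna(0)
    ambiguous = (n_heavy > 1) | (n_light > 1)
    unmatched = ((n_heavy == 0) | (n_light == 0)) & ~ambiguous
    valid = (n_heavy == 1) & (n_light == 1)

    if ("first", HEAVY) in agg.columns and ("first", LIGHT) in agg.columns:
        pairs = pd.DataFrame(
            {
                "heavy": agg.loc[valid, ("first", HEAVY)],
                "light": agg.loc[valid, ("first", LIGHT)],
            }
        ).reset_index()
    else:
        pairs = pd.DataFrame(columns=["run", "sequence", "charge", "heavy", "light"])
    positive = (pairs["heavy"] > 0) & (pairs["light"] > 0)
    n_nonpositive = int((~positive).sum())
    pairs = pairs[positive].reset_index(drop=True)
    pairs["ratio"] = pairs["heavy"] / pairs["light"]

    gene_map = records.drop_duplicates(["sequence", "charge"]).set_index(["sequence", "charge"])[
        ["gene", "protein_group"]
    ]
    pairs = pairs.join(gene_map, on=["sequence", "charge"])
    report = PairingReport(
        n_pairs=len(pairs),
        n_unmatched=int(unmatched.sum()),
        n_ambiguous=int(ambiguous.sum()),
        n_nonpositive=n_nonpositive,
    )
    return pairs, report


def qc_samples(
    records: pd.DataFrame,
    min_id_fraction: float = 0.5,
    max_median_ratio_deviation: float = 1.0,
) -> tuple[list, list, pd.DataFrame]:
    """Exclude outlier samples by pair count and median heavy/light ratio.

    A sample is excluded when its pair count is below ``min_id_fraction``
    times the cohort median count, or when its log2 median ratio deviates
    from the cohort median of log2 median ratios by more than
    ``max_median_ratio_deviation`` (strict inequalities: a sample exactly at
    a threshold is kept).
    """
    runs = records["run"].unique()
    if len(runs) < 2:
        raise ValueError("sample QC needs at least two samples")
    pairs, _ = match_pairs(records)
    counts = pairs.groupby("run").size().reindex(runs, fill_value=0)
    log2_medians = pairs.groupby("run")["ratio"].median().apply(np.log2).reindex(runs)

    cohort_count = counts.median()
    cohort_log2 = log2_medians.median()
    low_ids = counts < min_id_fraction * cohort_count
    off_ratio = (log2_medians - cohort_log2).abs() > max_median_ratio_deviation
    off_ratio = off_ratio.fillna(True)  # no ratio at all

    report = pd.DataFrame(
        {
            "run": runs,
            "n_pairs": counts.values,
            "log2_median_ratio": log2_medians.values,
            "excluded_low_ids": low_ids.values,
            "excluded_ratio_deviation": off_ratio.values,
        }
    )
    excluded = [r for r in runs if low_ids[r] or off_ratio[r]]
    kept = [r for r in runs if r not in excluded]
    if not kept:
        raise AllSamplesExcludedError("sample QC excluded every sample")
    return kept, excluded, report


def normalize(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median normalization: ratio / median(ratios), then log2.

    After normalization the per-sample median of ``norm_log2_ratio`` is 0.
    """
    out = pairs.copy()
    med = out.groupby("run")["ratio"].transform("median")
    out["norm_log2_ratio"] = np.log2(out["ratio"] / med)
    return out


def precursor_tests(
    pairs: pd.DataFrame,
    min_samples: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample t-tests of the mean normalized log2 ratio against zero.

    Precursors observed in fewer than ``min_samples`` samples are retained
    descriptively but excluded from testing and from the BH correction,
    which is applied once over all tested precursors.  A zero-variance
    precursor with nonzero mean gets p = 0 and a degenerate-variance flag.
    """
    rows = []
    for (seq, charge), grp in pairs.groupby(["sequence", "charge"], sort=False):
        vals = grp["norm_log2_ratio"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        median = float(np.median(vals))
        tested = n >= min_samples
        t = p = np.nan
        degenerate = False
        if tested:
            sd = vals.std(ddof=1)
            if sd == 0.0:
                degenerate = mean != 0.0
                t = 0.0 if mean == 0.0 else math.inf * np.sign(mean)
                p = 1.0 if mean == 0.0 else 0.0
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
        rows.append(
            {
                "sequence": seq,
                "charge": charge,
                "gene": grp["gene"].iloc[0],
                "protein_group": grp["protein_group"].iloc[0],
                "n": n,
                "mean_log2_ratio": mean,
                "median_log2_ratio": median,
                "t": float(t),
                "p": float(p),
                "tested": tested,
                "degenerate_variance": degenerate,
            }
        )
    stats_df = pd.DataFrame(rows)
    stats_df["p_adj"] = np.nan
    stats_df["significant"] = False
    tested_mask = stats_df["tested"].to_numpy()
    if tested_mask.any():
        _, p_adj, _, _ = multipletests(stats_df.loc[tested_mask, "p"], method="fdr_bh")
        stats_df.loc[tested_mask, "p_adj"] = p_adj
        stats_df.loc[tested_mask, "significant"] = p_adj < alpha
    return stats_df


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper kept for direct use)."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return p_adj


def aggregate_genes(stats_df: pd.DataFrame, fc_threshold: float = 0.75) -> pd.DataFrame:
    """Gene-level hit calls from tested precursors.

    hit <=> at least one significant precursor AND |mean of per-precursor
    median log2 FC| > fc_threshold AND all per-precursor median log2 FCs
    share the same sign.
    """
    tested = stats_df[stats_df["tested"]]
    rows = []
    for gene, grp in tested.groupby("gene", sort=False):
        medians = grp["median_log2_ratio"].to_numpy()
        signs = np.sign(medians)
        concordant = bool(len(set(signs)) == 1 and signs[0] != 0)
        mean_fc = float(medians.mean())
        any_sig = bool(grp["significant"].any())
        rows.append(
            {
                "gene": gene,
                "n_precursors": len(grp),
                "mean_log2_fc": mean_fc,
                "any_significant": any_sig,
                "sign_concordant": concordant,
                "hit": any_sig and abs(mean_fc) > fc_threshold and concordant,
            }
        )
    return pd.DataFrame(rows)


def summarize(pairs: pd.DataFrame, stats_df: pd.DataFrame, genes_df: pd.DataFrame) -> dict:
    """Run-level summary: counts plus the per-sample median raw H/L ratio."""
    return {
        "n_precursors_tested": int(stats_df["tested"].sum()),
        "n_precursors_significant": int(stats_df["significant"].sum()),
        "n_genes_tested": int(len(genes_df)),
        "n_gene_hits": int(genes_df["hit"].sum()) if len(genes_df) else 0,
        "median_ratio_per_sample": {
            str(run): float(med) for run, med in pairs.groupby("run")["ratio"].median().items()
        },
    }


def deconvolve(
    report: pd.DataFrame,
    scheme: LabelScheme,
    quality_threshold: float = 0.7,
    min_samples: int = 3,
    alpha: float = 0.05,
    fc_threshold: float = 0.75,
    run_qc: bool = True,
    columns: Optional[Mapping[str, str]] = None,
) -> dict:
    """Full pipeline; returns dict with pairs, precursor stats, gene table, summary."""
    records = load_and_filter(report, scheme, quality_threshold, columns)
    excluded: list = []
    qc_report = None
    if run_qc and records["run"].nunique() >= 2:
        kept, excluded, qc_report = qc_samples(records)
        records = records[records["run"].isin(kept)]
    pairs, pairing = match_pairs(records)
    pairs = normalize(pairs)
    stats_df = precursor_tests(pairs, min_samples=min_samples, alpha=alpha)
    genes_df = aggregate_genes(stats_df, fc_threshold=fc_threshold)
    return {
        "pairs": pairs,
        "pairing_report": pairing,
        "excluded_samples": excluded,
        "qc_report": qc_report,
        "precursor_stats": stats_df,
        "genes": genes_df,
        "summary": summarize(pairs, stats_df, genes_df),
    }
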