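"""Producer/mixed/consumer labelling-state quantification from transition reports.

Input is a long-format table of integrated fragment-ion areas (one row per
sample x peptide x precursor labelling state x fragment), the shape a
targeted-proteomics tool exports.  Quantification follows three rules:

* only *diagnostic* fragments — those covering exactly one target residue —
  are used, because their mass is unique to one labelling state of the
  precursor and in particular resolves the two isobaric 1-of-2 mixed states;
* within each peptide, fragments are ranked by abundance within each sample
  and only the top three by average rank across samples are kept;
* labelling-state ratios are formed per fragment first, then averaged
  (unweighted) across fragments, then peptides, then replicates; the
  standard deviation is reported at the final averaging level.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UnquantifiableError
from .isotope_model import LabelScheme, fragment_covered_sites

DEFAULT_COLUMNS: dict[str, str] = {
    "sample": "sample",
    "condition": "condition",
    "peptide": "peptide",
    "state": "state",
    "fragment": "fragment",
    "area": "area",
}

_FRAGMENT_RE = re.compile(r"^([yb])(\d+)$")


def parse_fragment(name: str) -> tuple[str, int]:
    m = _FRAGMENT_RE.match(name)
    if not m:
        raise ValueError(f"unrecognized fragment name {name!r} (expected e.g. 'y5', 'b3')")
    return m.group(1), int(m.group(2))


def site_patterns(n_sites: int) -> list[str]:
    """All site-resolved state labels for n sites, e.g. ['HH','HL','LH','LL'].

    H = heavy (self-synthesized), L = light (imported); lexicographic order.
    """
    return ["".join(bits) for bits in product("HL", repeat=n_sites)] if n_sites else [""]


def pattern_light_count(state: str) -> int:
    return state.count("L")


@dataclass(frozen=True)
class FragmentSpecificity:
    series: str
    ordinal: int
    covered_sites: tuple[int, ...]
    diagnostic: bool  # covers exactly one target site


def fragment_specificity(peptide: str, fragment: str, scheme: LabelScheme) -> FragmentSpecificity:
    """Classify a fragment by the number of target sites it covers.

    A fragment covering exactly one site discriminates every labelling state
    of the precursor (including the two isobaric mixed states); fragments
    covering zero or two or more sites are non-diagnostic.
    """
    series, ordinal = parse_fragment(fragment)
    covered = fragment_covered_sites(peptide, series, ordinal, scheme)
    return FragmentSpecificity(series, ordinal, covered, diagnostic=len(covered) == 1)


@dataclass
class LabellingStateProfile:
    """Relative abundances of the k-of-n labelling states for one condition.

    ``fractions[k]`` is the fraction of peptide molecules with k imported
    (light) target residues: k = 0 is the producer state, k = n the consumer
    state, intermediate k the mixed states.  ``pattern_fractions`` keeps the
    site-resolved split of the mixed states when fragment-level data allowed
    resolving it.  ``sd`` is the across-replicate standard deviation.
    """

    condition: str
    level: str  # "fragment" | "precursor"
    n_sites: int
    fractions: np.ndarray
    sd: Optional[np.ndarray] = None
    pattern_fractions: Optional[dict[str, float]] = None
    n_replicates: int = 0
    quantifiable: bool = True

    @property
    def mixed_fraction(self) -> float:
        return float(self.fractions[1:-1].sum())

    def as_rows(self) -> list[dict]:
        rows = []
        for k in range(self.n_sites + 1):
            rows.append(
                {
                    "condition": self.condition,
                    "level": self.level,
                    "n_sites": self.n_sites,
                    "k_imported": k,
                    "fraction": self.fractions[k],
                    "sd": self.sd[k] if self.sd is not None else np.nan,
                    "n_replicates": self.n_replicates,
                }
            )
        return rows


def _rename(records: pd.DataFrame, columns: Optional[Mapping[str, str]]) -> pd.DataFrame:
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    inverse = {v: k for k, v in colmap.items()}
    df = records.rename(columns=inverse)
    required = {"sample", "peptide", "state", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transition report lacks column(s): {sorted(missing)}")
    if "condition" not in df.columns:
        df = df.assign(condition="")
    return df


def rank_fragments(records: pd.DataFrame, top_k: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Order fragments of one peptide by mean within-sample abundance rank.

    ``records`` must already be restricted to diagnostic fragments of a
    single peptide.  Within each sample, fragments are ranked by total area
    (1 = most abundant, ties get average ranks); fragments are then ordered
    by mean rank across samples, ties at the cutoff broken by fragment name.
    """
    if records.empty:
        raise UnquantifiableError("no diagnostic fragments to rank")
    totals = records.groupby(["sample", "fragment"], sort=False)["area"].sum().reset_index()
    totals["rank"] = totals.groupby("sample")["area"].rank(ascending=False, method="average")
    mean_ranks = (
        totals.groupby("fragment")["rank"].mean().rename("mean_rank").reset_index()
    ).sort_values(["mean_rank", "fragment"], kind="mergesort")
    top = mean_ranks["fragment"].head(top_k).tolist()
    return mean_ranks.reset_index(drop=True), top


def _per_fragment_fractions(
    group: pd.DataFrame, states: Sequence[str], missing_state_policy: str
) -> Optional[np.ndarray]:
    """Fractions over ``states`` for one (sample, peptide, fragment) group."""
    areas = group.groupby("state")["area"].sum()
    missing = [s for s in states if s not in areas.index]
    if missing:
        if missing_state_policy == "drop":
            return None
        warnings.warn(
            f"missing state(s) {missing} treated as zero area", stacklevel=2
        )
    vec = np.array([float(areas.get(s, 0.0)) for s in states])
    total = vec.sum()
    if total <= 0:
        return None  # all-zero fragment: dropped
    return vec / total


def state_fractions(
    records: pd.DataFrame,
    scheme: LabelScheme,
    columns: Optional[Mapping[str, str]] = None,
    top_k: int = 3,
    missing_state_policy: str = "zero",
) -> dict[str, LabellingStateProfile]:
    """Fragment-level labelling-state profiles, one per condition.

    The ``state`` column holds site-resolved labels ('HH', 'HL', ...).  The
    top-``top_k`` diagnostic fragments are chosen per peptide by average rank
    across *all* samples; fractions are then averaged across fragments,
    peptides and replicates in that order.
    """
    df = _rename(records, columns)
    n_by_pep = {p: len(scheme.target_sites(p)) for p in df["peptide"].unique()}
    n_values = set(n_by_pep.values())
    if len(n_values) != 1:
        raise ValueError(f"peptides with differing target-site counts in one report: {n_by_pep}")
    n_sites = n_values.pop()
    states = site_patterns(n_sites)

    # restrict to diagnostic fragments, then to the per-peptide top-k set
    spec_cache = {
        (pep, frag): fragment_specificity(pep, frag, scheme)
        for pep, frag in df[["peptide", "fragment"]].drop_duplicates().itertuples(index=False)
    }
    df = df[[spec_cache[(p, f)].diagnostic for p, f in zip(df["peptide"], df["fragment"])]]
    if df.empty:
        raise UnquantifiableError("no diagnostic fragments in report")

    kept = []
    for pep, pep_df in df.groupby("peptide", sort=False):
        _, top = rank_fragments(pep_df, top_k=top_k)
        kept.append(pep_df[pep_df["fragment"].isin(top)])
    df = pd.concat(kept, ignore_index=True)

    profiles: dict[str, LabellingStateProfile] = {}
    for condition, cond_df in df.groupby("condition", sort=False):
        sample_means = []
        for _sample, s_df in cond_df.groupby("sample", sort=False):
            peptide_means = []
            for _pep, p_df in s_df.groupby("peptide", sort=False):
                frac = [
                    f
                    for _frag, f_df in p_df.groupby("fragment", sort=False)
                    if (f := _per_fragment_fractions(f_df, states, missing_state_policy))
                    is not None
                ]
                if frac:
                    peptide_means.append(np.mean(frac, axis=0))
            if peptide_means:
                sample_means.append(np.mean(peptide_means, axis=0))
        if not sample_means:
            profiles[condition] = LabellingStateProfile(
                condition=condition,
                level="fragment",
                n_sites=n_sites,
                fractions=np.full(n_sites + 1, np.nan),
                quantifiable=False,
            )
            continue
        stacked = np.vstack(sample_means)
        pattern_mean = stacked.mean(axis=0)
        pattern_sd = stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else np.zeros(len(states))
        k_index = np.array([pattern_light_count(s) for s in states])
        k_mean = np.array([pattern_mean[k_index == k].sum() for k in range(n_sites + 1)])
        k_sd = np.array(
            [
                np.std(stacked[:, k_index == k].sum(axis=1), ddof=1)
                if stacked.shape[0] > 1
                else 0.0
                for k in range(n_sites + 1)
            ]
        )
        profiles[condition] = LabellingStateProfile(
            condition=condition,
            level="fragment",
            n_sites=n_sites,
            fractions=k_mean,
            sd=k_sd,
            pattern_fractions=dict(zip(states, pattern_mean)),
            n_replicates=stacked.shape[0],
        )
    return profiles


def precursor_level_fractions(
    records: pd.DataFrame,
    n_sites: int,
    columns: Optional[Mapping[str, str]] = None,
) -> dict[str, LabellingStateProfile]:
    """MS1-level profiles over the n+1 precursor mass states.

    The ``state`` column holds the number of imported (light) residues as an
    integer; the two 1-of-2 mixed states share a precursor mass and are
    inherently merged.  Same normalization and averaging chain as the
    fragment level, minus the fragment dimension.
    """
    df = _rename(records, columns)
    profiles: dict[str, LabellingStateProfile] = {}
    ks = list(range(n_sites + 1))
    for condition, cond_df in df.groupby("condition", sort=False):
        sample_means = []
        for _sample, s_df in cond_df.groupby("sample", sort=False):
            peptide_means = []
            for _pep, p_df in s_df.groupby("peptide", sort=False):
                areas = p_df.groupby(p_df["state"].astype(int))["area"].sum()
                vec = np.array([float(areas.get(k, 0.0)) for k in ks])
                if vec.sum() > 0:
                    peptide_means.append(vec / vec.sum())
            if peptide_means:
                sample_means.append(np.mean(peptide_means, axis=0))
        if not sample_means:
            profiles[condition] = LabellingStateProfile(
                condition=condition,
                level="precursor",
                n_sites=n_sites,
                fractions=np.full(n_sites + 1, np.nan),
                quantifiable=False,
            )
            continue
        stacked = np.vstack(sample_means)
        profiles[condition] = LabellingStateProfile(
            condition=condition,
            level="precursor",
            n_sites=n_sites,
            fractions=stacked.mean(axis=0),
            sd=stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else np.zeros(n_sites + 1),
            n_replicates=stacked.shape[0],
        )
    return profiles


def profiles_to_frame(profiles: Mapping[str, LabellingStateProfile]) -> pd.DataFrame:
    rows: list[dict] = []
    for prof in profiles.values():
        rows.extend(prof.as_rows())
    return pd.DataFrame(rows)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
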