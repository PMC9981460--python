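"""In-silico relabelling of a spectral library to the DILAC labelling state.

A library built from unlabelled material is converted so a DIA search engine
can look for both labelling variants of every precursor: fixed 13C label
shifts on every residue except the target amino acid, and the target site
expanded into a heavy (producer) and a light (consumer) variant.  Because
the label is a pure mass shift, retention-time columns pass through
unchanged.  Fragments that do not cover exactly one target site cannot tell
the two variants apart and get their ``ExcludeFromAssay`` flag set; for
tryptic peptides ending in the target residue this reduces to the familiar
"exclude b-series, keep y-series" rule.

The expected library dialect is a tab-separated long format with one row per
fragment (OpenSWATH-style); column names are remappable.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import pandas as pd

from .errors import MissingColumnsError, UnknownResidueError
from .isotope_model import (
    LabelScheme,
    fragment_covered_sites,
    fragment_species,
    mz_from_mass,
    residue_carbon_count,
    species_mass,
)

DEFAULT_LIBRARY_COLUMNS: dict[str, str] = {
    "sequence": "PeptideSequence",
    "modified_sequence": "ModifiedPeptideSequence",
    "precursor_charge": "PrecursorCharge",
    "precursor_mz": "PrecursorMz",
    "fragment_series": "FragmentType",
    "fragment_ordinal": "FragmentSeriesNumber",
    "fragment_charge": "FragmentCharge",
    "product_mz": "ProductMz",
    "exclude": "ExcludeFromAssay",
}


def modified_sequence(sequence: str, pattern, scheme: LabelScheme) -> str:
    """Mass-delta bracket notation, e.g. ``A[+3.010064]K`` (six decimals, bit-stable)."""
    shift = scheme.label_mass_shift_per_carbon
    sites = scheme.target_sites(sequence)
    heavy_sites = {s for s, p in zip(sites, pattern) if p}
    out = []
    for pos, res in enumerate(sequence, start=1):
        if res in scheme.fixed_labelled_residues or pos in heavy_sites:
            out.append(f"{res}[+{residue_carbon_count(res) * shift:.6f}]")
        else:
            out.append(res)
    return "".join(out)


def flag_fragments(
    sequence: str,
    fragments: pd.DataFrame,
    scheme: LabelScheme,
) -> list[bool]:
    """Exclude flag per fragment row: True unless the fragment covers exactly one target site."""
    n_sites = len(scheme.target_sites(sequence))
    if n_sites == 0:
        warnings.warn(f"peptide {sequence!r} has no target site; all fragments excluded")
    flags = []
    for series, ordinal in zip(fragments["fragment_series"], fragments["fragment_ordinal"]):
        covered = fragment_covered_sites(sequence, str(series), int(ordinal), scheme)
        flags.append(len(covered) != 1)
    return flags


def relabel_library(
    library: pd.DataFrame,
    scheme: LabelScheme,
    charges: tuple[int, ...] = (2, 3),
    length_range: tuple[int, int] = (7, 30),
    columns: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Expand each retained precursor into its heavy- and light-target variants.

    Precursors outside the allowed charges or the inclusive length range are
    dropped; precursor and fragment m/z are recomputed from the mass model;
    every column not understood by the mapper (retention time, protein and
    gene annotations, ...) passes through unchanged.  Entries containing
    residues absent from the composition table are dropped with a warning.

    With a scheme carrying no labels at all (``target_residue=None`` and an
    empty fixed set) the operation is the identity on retained entries.
    """
    colmap = dict(DEFAULT_LIBRARY_COLUMNS)
    if columns:
        colmap.update(columns)
    missing = [v for k, v in colmap.items() if v not in library.columns and k != "modified_sequence"]
    if missing:
        raise MissingColumnsError(missing)
    inv = {v: k for k, v in colmap.items()}
    df = library.rename(columns=inv)
    if "modified_sequence" not in df.columns:
        df["modified_sequence"] = df["sequence"]

    lo, hi = length_range
    out_groups = []
    group_cols = ["sequence", "precursor_charge"]
    for (seq, charge), entry in df.groupby(group_cols, sort=False):
        charge = int(charge)
        if charge not in charges or not lo <= len(seq) <= hi:
            continue
        try:
            n_sites = len(scheme.target_sites(seq))
            variants = (
                [("heavy", (True,) * n_sites), ("light", (False,) * n_sites)]
                if n_sites
                else [("none", ())]
            )
            for variant_name, pattern in variants:
                var = entry.copy()
                mass = species_mass(seq, pattern, scheme)
                var["precursor_mz"] = mz_from_mass(mass, charge)
                var["modified_sequence"] = modified_sequence(seq, pattern, scheme)
                var["product_mz"] = [
                    fragment_species(seq, str(s), int(o), pattern, scheme, int(z)).mz
                    for s, o, z in zip(
                        var["fragment_series"], var["fragment_ordinal"], var["fragment_charge"]
                    )
                ]
                if scheme.target_residue is not None:
                    var["exclude"] = flag_fragments(seq, var, scheme)
                var["label_variant"] = variant_name
                out_groups.append(var)
        except UnknownResidueError as err:
            warnings.warn(f"dropping library entry {seq!r}: {err}")
            continue
    if not out_groups:
        result = df.iloc[0:0].copy()
        result["label_variant"] = pd.Series(dtype=str)
    else:
        result = pd.concat(out_groups, ignore_index=True)
    return result.rename(columns={k: v for k, v in colmap.items()} | {"label_variant": "LabelVariant"})


def read_library(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_library(library: pd.DataFrame, path) -> None:
    library.to_csv(path, sep="\t", index=False)
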