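"""In-silico digestion and selection of DILAC-suitable peptides.

Detecting mixed labelling states needs peptides that carry two (or more)
copies of the target amino acid.  Two digestion routes yield them: gluC
(cuts after glutamate, leaving lysines internal) and trypsin with missed
cleavages (cuts after K/R, so a missed cleavage leaves an internal lysine).
Candidates must also be free of residues whose preparation chemistry or
oxidation would complicate the isotope pattern (C, M by default) and be
proteotypic, i.e. map to exactly one protein in the proteome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import UnknownProteaseError
from .isotope_model import LabelScheme

#: residues C-terminal to which each protease cleaves
PROTEASE_RULES: dict[str, str] = {
    "trypsin": "KR",
    "gluc": "E",
}


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    protein_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    missed_cleavages: int


@dataclass(frozen=True)
class DilacCandidate:
    peptide: DigestPeptide
    target_sites: tuple[int, ...]  # 1-based positions within the peptide
    proteotypic: bool
    score: float


def digest(
    sequence: str,
    protease: str,
    max_missed_cleavages: int = 0,
    protein_id: str = "",
    suppress_before_proline: bool = False,
    gluc_cuts_aspartate: bool = False,
) -> list[DigestPeptide]:
    """Cleave a protein into peptides with 0..max retained missed cleavages.

    gluC cuts after E (optionally also D); trypsin after K or R, with an
    optional "not before proline" suppression (off by default).  At zero
    missed cleavages the returned peptides partition the protein exactly.
    """
    try:
        cut_after = set(PROTEASE_RULES[protease])
    except KeyError:
        raise UnknownProteaseError(f"unknown protease {protease!r}") from None
    if protease == "gluc" and gluc_cuts_aspartate:
        cut_after.add("D")

    # segment boundaries: indices after which a cut occurs
    cuts = []
    for i, res in enumerate(sequence[:-1]):
        if res in cut_after:
            if suppress_before_proline and sequence[i + 1] == "P":
                continue
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(sequence)]
    segments = [(bounds[j], bounds[j + 1]) for j in range(len(bounds) - 1)]

    peptides = []
    for i in range(len(segments)):
        for mc in range(max_missed_cleavages + 1):
            if i + mc >= len(segments):
                break
            start = segments[i][0]
            end = segments[i + mc][1]
            peptides.append(
                DigestPeptide(
                    sequence=sequence[start:end],
                    protein_id=protein_id,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                )
            )
    return peptides


def digest_proteome(
    proteome: Mapping[str, str], protease: str, max_missed_cleavages: int = 0, **kwargs
) -> list[DigestPeptide]:
    out: list[DigestPeptide] = []
    for pid, seq in proteome.items():
        out.extend(digest(seq, protease, max_missed_cleavages, protein_id=pid, **kwargs))
    return out


def score_candidate(sequence: str, target_sites: Sequence[int]) -> float:
    """Geometry score favouring well-separated sites with one near the C terminus.

    score = separation/(L-1) + (1 - dist_of_last_site_to_C_terminus/(L-1)),
    both terms in [0, 1].  Only the ordering of scores is meaningful.
    """
    if len(target_sites) < 2:
        raise ValueError("scoring requires at least two target sites")
    length = len(sequence)
    sites = sorted(target_sites)
    separation = sites[-1] - sites[0]
    dist_c = length - sites[-1]
    return separation / (length - 1) + (1 - dist_c / (length - 1))


def select_candidates(
    peptides: Iterable[DigestPeptide],
    scheme: LabelScheme,
    n_target: int = 2,
    forbidden: frozenset = frozenset("CM"),
    proteome: Optional[Mapping[str, str]] = None,
) -> list[DilacCandidate]:
    """Keep peptides with exactly ``n_target`` target residues and none forbidden.

    Proteotypic means the stripped sequence occurs as a substring in exactly
    one protein of ``proteome`` (I/L treated as distinct).  Without a
    proteome, every candidate is marked proteotypic.
    """
    out = []
    seen: dict[str, bool] = {}
    for pep in peptides:
        sites = scheme.target_sites(pep.sequence)
        if len(sites) != n_target:
            continue
        if any(res in forbidden for res in pep.sequence):
            continue
        if pep.sequence not in seen:
            if proteome is None:
                seen[pep.sequence] = True
            else:
                n_hits = sum(1 for seq in proteome.values() if pep.sequence in seq)
                seen[pep.sequence] = n_hits == 1
        score = score_candidate(pep.sequence, sites) if n_target >= 2 else 0.0
        out.append(
            DilacCandidate(
                peptide=pep, target_sites=sites, proteotypic=seen[pep.sequence], score=score
            )
        )
    out.sort(key=lambda c: (-c.score, c.peptide.sequence))
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_candidates_tsv(candidates: Iterable[DilacCandidate], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["protein", "peptide", "start", "end", "missed_cleavages", "sites", "proteotypic", "score"]
        )
        for c in candidates:
            writer.writerow(
                [
                    c.peptide.protein_id,
                    c.peptide.sequence,
                    c.peptide.start,
                    c.peptide.end,
                    c.peptide.missed_cleavages,
                    ";".join(map(str, c.target_sites)),
                    int(c.proteotypic),
                    f"{c.score:.6f}",
                ]
            )
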