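"""Ground-truthed population simulator emitting analysis-ready report tables.

The generator emulates a colony of cells that each either synthesize the
target amino acid from labelled glucose (heavy residues) or import it from
the medium (light residues).  A population model assigns each cell an import
probability: a single shared value (homogeneous), a two-point
producer/consumer mixture, or a mixture of Beta components for gradual
transitions.  Each peptide molecule from a cell labels each target site
independently with the cell's import probability; a cell's contribution to
the bulk signal is weighted by its subpopulation's protein synthesis rate,
reproducing the bias that makes label-based subpopulation fractions differ
from cell-count fractions.  Measured areas/quantities get multiplicative
log-normal noise.

Two writers produce files in the exact dialects the analysis modules read:
a transition-level CSV for labelling-state quantification and a DIA-style
report TSV for proteome deconvolution.  All randomness flows from the
config seed; identical configs give byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import betaln, comb

from .labelling_quant import pattern_light_count, site_patterns

_PEPTIDE_ALPHABET = "ADEFGHILNPQSTVWY"  # no K/R: tryptic-like peptides get K appended


@dataclass(frozen=True)
class SubpopulationComponent:
    """One mixture component: weight (cell fraction), import law, synthesis rate.

    Either ``import_prob`` (point mass) or ``beta`` (alpha, beta shape pair)
    must be given.  ``synthesis_rate`` scales the component's per-cell
    protein output relative to the others.
    """

    weight: float
    import_prob: Optional[float] = None
    beta: Optional[tuple[float, float]] = None
    synthesis_rate: float = 1.0

    def __post_init__(self):
        if (self.import_prob is None) == (self.beta is None):
            raise ValueError("give exactly one of import_prob or beta")
        if self.import_prob is not None and not 0 <= self.import_prob <= 1:
            raise ValueError("import_prob must be in [0, 1]")
        if self.weight < 0 or self.synthesis_rate <= 0:
            raise ValueError("weight must be >= 0 and synthesis_rate > 0")

    @property
    def mean_import_prob(self) -> float:
        if self.import_prob is not None:
            return self.import_prob
        a, b = self.beta
        return a / (a + b)

    def moment(self, k: int, n: int) -> float:
        """E[p^k (1-p)^(n-k)] under the component's import-probability law."""
        if self.import_prob is not None:
            p = self.import_prob
            return p**k * (1 - p) ** (n - k)
        a, b = self.beta
        return math.exp(betaln(a + k, b + n - k) - betaln(a, b))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.import_prob is not None:
            return np.full(size, self.import_prob)
        a, b = self.beta
        return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class GeneSpec:
    name: str
    log2_fc: float  # producer vs consumer expression fold change
    n_peptides: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    components: tuple[SubpopulationComponent, ...]
    n_cells: int = 10_000
    n_molecules: Optional[int] = None  # multinomial sampling depth; None = infinite
    noise_sigma: float = 0.2  # log-normal sigma on areas/quantities
    n_replicates: int = 6
    genes: tuple[GeneSpec, ...] = ()
    fragment_response_sigma: float = 0.5
    low_quality_fraction: float = 0.1
    condition: str = "sim"
    seed: int = 0

    def __post_init__(self):
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"component weights sum to {total}, not 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    # -- convenience constructors -------------------------------------------------
    @staticmethod
    def homogeneous(p: float, **kwargs) -> "SimulationConfig":
        return SimulationConfig(
            components=(SubpopulationComponent(weight=1.0, import_prob=p),), **kwargs
        )

    @staticmethod
    def two_point(
        f_producer: float,
        producer_rate: float = 1.0,
        consumer_rate: float = 1.0,
        **kwargs,
    ) -> "SimulationConfig":
        """Producers (import prob 0) vs consumers (import prob 1)."""
        return SimulationConfig(
            components=(
                SubpopulationComponent(
                    weight=f_producer, import_prob=0.0, synthesis_rate=producer_rate
                ),
                SubpopulationComponent(
                    weight=1.0 - f_producer, import_prob=1.0, synthesis_rate=consumer_rate
                ),
            ),
            **kwargs,
        )

    @staticmethod
    def beta_mixture(components: Sequence[tuple[float, float, float]], **kwargs):
        """Components given as (weight, alpha, beta) triples, unit rates."""
        return SimulationConfig(
            components=tuple(
                SubpopulationComponent(weight=w, beta=(a, b)) for w, a, b in components
            ),
            **kwargs,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Deterministic population-level expectations, computed before any noise."""

    true_p: float
    signal_shares: tuple[float, ...]  # per component: weight x rate, normalized
    state_fractions_2: tuple[float, ...]
    state_fractions_3: tuple[float, ...]


def ground_truth(config: SimulationConfig) -> GroundTruth:
    comps = config.components
    shares = np.array([c.weight * c.synthesis_rate for c in comps])
    shares = shares / shares.sum()
    true_p = float(sum(s * c.mean_import_prob for s, c in zip(shares, comps)))

    def fractions(n: int) -> tuple[float, ...]:
        return tuple(
            float(
                comb(n, k) * sum(s * c.moment(k, n) for s, c in zip(shares, comps))
            )
            for k in range(n + 1)
        )

    return GroundTruth(
        true_p=true_p,
        signal_shares=tuple(float(s) for s in shares),
        state_fractions_2=fractions(2),
        state_fractions_3=fractions(3),
    )


@dataclass(frozen=True)
class SimulatedStates:
    """One realized cell population's labelling-state composition."""

    n_sites: int
    patterns: tuple[str, ...]
    cell_fractions: np.ndarray  # infinite-molecule limit over the drawn cells
    sampled_fractions: np.ndarray  # after multinomial sampling (== cell_fractions if exact)

    def k_fractions(self, sampled: bool = False) -> np.ndarray:
        src = self.sampled_fractions if sampled else self.cell_fractions
        ks = np.array([pattern_light_count(p) for p in self.patterns])
        return np.array([src[ks == k].sum() for k in range(self.n_sites + 1)])


def simulate_states(
    config: SimulationConfig, n_sites: int, rng: Optional[np.random.Generator] = None
) -> SimulatedStates:
    """Draw a cell population and aggregate its labelling-pattern fractions.

    Each cell gets a component (by weight), an import probability from that
    component's law and a signal weight equal to the component's synthesis
    rate; pattern fractions are the rate-weighted average of the per-cell
    independent-site probabilities, optionally followed by a multinomial
    draw of ``n_molecules`` observed molecules.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    weights = np.array([c.weight for c in config.components])
    idx = rng.choice(len(config.components), size=config.n_cells, p=weights)
    p_cell = np.empty(config.n_cells)
    rate = np.empty(config.n_cells)
    for i, comp in enumerate(config.components):
        mask = idx == i
        p_cell[mask] = comp.draw(rng, int(mask.sum()))
        rate[mask] = comp.synthesis_rate

    patterns = tuple(site_patterns(n_sites))
    fractions = np.empty(len(patterns))
    for j, pat in enumerate(patterns):
        n_light = pattern_light_count(pat)
        per_cell = p_cell**n_light * (1 - p_cell) ** (n_sites - n_light)
        fractions[j] = np.average(per_cell, weights=rate)
    fractions = fractions / fractions.sum()

    if config.n_molecules is None:
        sampled = fractions.copy()
    else:
        counts = rng.multinomial(config.n_molecules, fractions)
        sampled = counts / counts.sum()
    return SimulatedStates(
        n_sites=n_sites, patterns=patterns, cell_fractions=fractions, sampled_fractions=sampled
    )


# ---------------------------------------------------------------------------
# transition-level report (targeted workflow)
# ---------------------------------------------------------------------------


def _fragment_names(peptide: str) -> list[str]:
    """y/b ions from ordinal 3 up to peptide length - 2 (common extraction range)."""
    hi = len(peptide) - 2
    return [f"{series}{o}" for series in ("y", "b") for o in range(3, hi + 1)]


@dataclass(frozen=True)
class TransitionReportTruth:
    analytic: GroundTruth
    per_replicate_pattern_fractions: tuple[dict[str, float], ...]

    def mean_k_fractions(self, n_sites: int) -> np.ndarray:
        pats = site_patterns(n_sites)
        mat = np.array([[rep[p] for p in pats] for rep in self.per_replicate_pattern_fractions])
        mean = mat.mean(axis=0)
        ks = np.array([pattern_light_count(p) for p in pats])
        return np.array([mean[ks == k].sum() for k in range(n_sites + 1)])


def write_transition_report(
    config: SimulationConfig,
    peptides: Sequence[str],
    path,
    n_sites: int = 2,
    base_intensity: float = 1.0e6,
) -> TransitionReportTruth:
    """Emit a transition-level CSV consumable by the labelling-state quantifier.

    One row per replicate x peptide x labelling state x fragment; both
    diagnostic and non-diagnostic fragments are emitted (the pipeline must
    ignore the latter).  Fragment response factors are drawn once per
    (peptide, fragment) so abundance ranking is nontrivial; areas then get
    per-row log-normal noise of width ``noise_sigma``.
    """
    rng = np.random.default_rng(config.seed)
    patterns = site_patterns(n_sites)

    response = {
        (pep, frag): rng.lognormal(0.0, config.fragment_response_sigma)
        for pep in peptides
        for frag in _fragment_names(pep)
    }

    rows = []
    rep_truths = []
    for rep in range(1, config.n_replicates + 1):
        states = simulate_states(config, n_sites, rng=rng)
        rep_truths.append(dict(zip(states.patterns, states.sampled_fractions)))
        sample = f"{config.condition}_r{rep}"
        for pep in peptides:
            for frag in _fragment_names(pep):
                for pat, frac in zip(states.patterns, states.sampled_fractions):
                    noise = (
                        math.exp(config.noise_sigma * rng.standard_normal())
                        if config.noise_sigma > 0
                        else 1.0
                    )
                    area = base_intensity * frac * response[(pep, frag)] * noise
                    rows.append((sample, config.condition, rep, pep, pat, frag, area))

    with Path(path).open("w", newline="") as fh:
        fh.write("sample,condition,replicate,peptide,state,fragment,area\n")
        for sample, cond, rep, pep, pat, frag, area in rows:
            fh.write(f"{sample},{cond},{rep},{pep},{pat},{frag},{area:.6f}\n")
    return TransitionReportTruth(
        analytic=ground_truth(config), per_replicate_pattern_fractions=tuple(rep_truths)
    )


# ---------------------------------------------------------------------------
# DIA-style precursor report (proteome deconvolution workflow)
# ---------------------------------------------------------------------------


def make_gene_panel(
    n_null: int = 40,
    n_moderate: int = 10,
    n_strong: int = 10,
    moderate_fc: float = 0.3,
    strong_fc: float = 1.8,
    n_peptides: int = 3,
) -> tuple[GeneSpec, ...]:
    """A balanced panel of null, moderately and strongly changing genes."""
    genes = [GeneSpec(f"NUL{i:03d}", 0.0, n_peptides) for i in range(n_null)]
    genes += [
        GeneSpec(f"MOD{i:03d}", moderate_fc * (1 if i % 2 == 0 else -1), n_peptides)
        for i in range(n_moderate)
    ]
    genes += [
        GeneSpec(f"STR{i:03d}", strong_fc * (1 if i % 2 == 0 else -1), n_peptides)
        for i in range(n_strong)
    ]
    return tuple(genes)


@dataclass(frozen=True)
class DiaReportTruth:
    gene_log2_fc: dict[str, float]
    producer_share: float  # heavy-signal share for a null gene
    log2_share_offset: float  # log2(producer share / consumer share)


def _random_peptide(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        length = int(rng.integers(6, 14))
        seq = "".join(rng.choice(list(_PEPTIDE_ALPHABET), size=length)) + "K"
        if seq not in used:
            used.add(seq)
            return seq


def write_dia_report(config: SimulationConfig, path) -> DiaReportTruth:
    """Emit a DIA-style TSV consumable by the deconvolution pipeline.

    Requires a two-component population (producer-like and consumer-like).
    Heavy rows carry the producer-attributable quantity, light rows the
    consumer part; per-gene expression fold changes are applied
    symmetrically (x 2^(fc/2) in producers, x 2^(-fc/2) in consumers).  A
    per-run global scale factor, low-quality rows and filter-violating decoy
    rows (non-proteotypic, internal-K, orphan heavy) are included to
    exercise the downstream filters.
    """
    if len(config.components) != 2:
        raise ValueError("the DIA writer models a two-subpopulation colony")
    if not config.genes:
        raise ValueError("config.genes must be non-empty for a DIA report")
    rng = np.random.default_rng(config.seed)

    prod, cons = sorted(config.components, key=lambda c: c.mean_import_prob)
    w_p = prod.weight * prod.synthesis_rate
    w_c = cons.weight * cons.synthesis_rate
    # heavy/light signal of a one-site peptide from each subpopulation
    heavy_base = w_p * (1 - prod.mean_import_prob) + w_c * (1 - cons.mean_import_prob)
    light_base = w_p * prod.mean_import_prob + w_c * cons.mean_import_prob
    if heavy_base <= 0 or light_base <= 0:
        raise ValueError("population puts no signal on one labelling variant")

    used: set[str] = set()
    peptide_specs = []  # (sequence, gene, baseline)
    for gene in config.genes:
        for _ in range(gene.n_peptides):
            seq = _random_peptide(rng, used)
            baseline = rng.lognormal(math.log(1.0e5), 1.0)
            peptide_specs.append((seq, gene, baseline))

    def expr(fc: float, producer: bool) -> float:
        return 2.0 ** (fc / 2.0) if producer else 2.0 ** (-fc / 2.0)

    rows = []
    for rep in range(1, config.n_replicates + 1):
        run = f"{config.condition}_r{rep}"
        scale = rng.lognormal(0.0, 0.3)
        for seq, gene, baseline in peptide_specs:
            h = (
                w_p * (1 - prod.mean_import_prob) * expr(gene.log2_fc, True)
                + w_c * (1 - cons.mean_import_prob) * expr(gene.log2_fc, False)
            )
            l = (
                w_p * prod.mean_import_prob * expr(gene.log2_fc, True)
                + w_c * cons.mean_import_prob * expr(gene.log2_fc, False)
            )
            for label, signal in (("heavy", h), ("light", l)):
                noise = math.exp(config.noise_sigma * rng.standard_normal())
                qty = scale * baseline * signal * noise
                low = rng.random() < config.low_quality_fraction
                quality = rng.uniform(0.3, 0.7) if low else rng.uniform(0.75, 1.0)
                rows.append(
                    (run, seq, 2, label, qty, quality, f"P_{gene.name}", gene.name, 1)
                )
        # decoys exercising the filters: never expected to reach pairing
        rows.append((run, "AHAILDEK", 2, "heavy", 1000.0, 0.95, "P_DECOY", "DECOY1", 0))
        rows.append((run, "AKVLHGDR", 2, "heavy", 1000.0, 0.95, "P_DECOY", "DECOY2", 1))
        rows.append((run, "ORPHANVK", 2, "heavy", 1000.0, 0.95, "P_DECOY", "DECOY3", 1))

    with Path(path).open("w", newline="") as fh:
        fh.write(
            "Run\tStripped.Sequence\tPrecursor.Charge\tLabel\tPrecursor.Quantity"
            "\tQuantity.Quality\tProtein.Group\tGenes\tProteotypic\n"
        )
        for run, seq, charge, label, qty, quality, pg, gene, proteo in rows:
            fh.write(
                f"{run}\t{seq}\t{charge}\t{label}\t{qty:.6f}\t{quality:.4f}\t{pg}\t{gene}\t{proteo}\n"
            )
    return DiaReportTruth(
        gene_log2_fc={g.name: g.log2_fc for g in config.genes},
        producer_share=heavy_base / (heavy_base + light_base),
        log2_share_offset=math.log2(heavy_base / light_base),
    )


# ---------------------------------------------------------------------------
# config file support (flat YAML for the command line)
# ---------------------------------------------------------------------------


def config_from_yaml(path) -> SimulationConfig:
    """Build a SimulationConfig from a flat YAML mapping.

    Keys: ``population`` (homogeneous | two_point | beta_mixture) plus its
    parameters (``p``; ``f_producer``/``producer_rate``/``consumer_rate``;
    ``components`` as weight/alpha/beta triples), and any of the
    SimulationConfig scalar fields (n_cells, noise_sigma, n_replicates,
    n_molecules, seed, ...).  ``genes`` may be a list of
    ``{name, log2_fc, n_peptides}`` mappings or ``default_panel: true``.
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    population = raw.pop("population", "homogeneous")
    genes_spec = raw.pop("genes", None)
    kwargs = {}
    for key in (
        "n_cells",
        "n_molecules",
        "noise_sigma",
        "n_replicates",
        "fragment_response_sigma",
        "low_quality_fraction",
        "condition",
        "seed",
    ):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if genes_spec:
        if genes_spec is True or genes_spec == "default_panel":
            kwargs["genes"] = make_gene_panel()
        else:
            kwargs["genes"] = tuple(
                GeneSpec(g["name"], float(g["log2_fc"]), int(g.get("n_peptides", 3)))
                for g in genes_spec
            )
    if population == "homogeneous":
        return SimulationConfig.homogeneous(float(raw.pop("p", 0.5)), **kwargs)
    if population == "two_point":
        return SimulationConfig.two_point(
            float(raw.pop("f_producer", 0.5)),
            producer_rate=float(raw.pop("producer_rate", 1.0)),
            consumer_rate=float(raw.pop("consumer_rate", 1.0)),
            **kwargs,
        )
    if population == "beta_mixture":
        comps = [tuple(map(float, c)) for c in raw.pop("components")]
        return SimulationConfig.beta_mixture(comps, **kwargs)
    raise ValueError(f"unknown population model {population!r}")


def truth_to_json(truth, path) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        raise TypeError(type(obj))

    with Path(path).open("w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=default)
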