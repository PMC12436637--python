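"""Synthetic screen generator with planted ground truth.

Forward model of a FACS-sorted knockout screen: a lentiviral guide library
is delivered to a cell population, knockouts of "required" genes shift the
probability that a cell sorts into the cargo-low gate (cells that fail to
take up the labelled cargo), and guide abundances in the two sorted gates
are read out as negative-binomial counts. Every generator is a pure
function of (scenario, seed) and writes its ground truth separately from
the analysis inputs; analysis code never reads the truth.

The default scenario is a desk-scale version of a genome-wide library
(~18k genes x 5 guides, with a second 5-guide set for ~10% of genes):
1,000 genes, 50 required, two replicates, 500 reads per guide.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cargoscreen.io import (
    CountMatrix,
    GuideLibrary,
    LocalizationMatrix,
    MitabRecord,
)

_BASES = np.array(list("ACGT"))


def derive_seed(seed: int, name: str) -> int:
    """Stable child seed for a named stage; stage insertion does not shift
    other stages' random streams."""
    return (zlib.crc32(name.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31 - 1)


@dataclass(frozen=True)
class ScreenScenario:
    """Parameters of the synthetic screen.

    gate_prob_null is the probability that a cell carrying a neutral guide
    sorts into the cargo-low gate (0.5: the two collected gates split the
    population evenly); gate_prob_required is the same probability for an
    effective knockout of a required gene. guide_efficacy_fraction is the
    chance a given guide actually cuts; alpha-RRA exists because some
    guides are inert, so the generator must produce inert guides.
    """

    n_genes: int = 1000
    guides_per_gene: int = 5
    fraction_with_second_set: float = 0.10
    n_required_genes: int = 50
    gate_prob_required: float = 0.9
    gate_prob_null: float = 0.5
    guide_efficacy_fraction: float = 0.8
    nb_dispersion: float = 0.05
    reads_per_guide: float = 500.0
    n_replicates: int = 2
    abundance_sigma: float = 0.5
    guide_length: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gate_prob_null < self.gate_prob_required <= 1.0):
            raise ValueError("need 0 <= gate_prob_null < gate_prob_required <= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.reads_per_guide <= 0:
            raise ValueError("reads_per_guide must be > 0")
        if self.n_required_genes >= self.n_genes:
            raise ValueError("n_required_genes must be < n_genes")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    required_genes: list[str] = field(default_factory=list)
    guide_efficacy: dict[str, bool] = field(default_factory=dict)
    planted_compartment: str | None = None
    module_members: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def _random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Unique random DNA sequences, deterministic in draw order."""
    seen: dict[str, None] = {}
    while len(seen) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(seen), length))]
        for row in block:
            seen.setdefault("".join(row), None)
    return list(seen)[:n]


def make_library(scenario: ScreenScenario) -> GuideLibrary:
    """Guide library: every gene gets one guide set, a configured fraction
    gets a second set of the same size."""
    rng = np.random.default_rng(derive_seed(scenario.seed, "library"))
    genes = [f"G{i:05d}" for i in range(1, scenario.n_genes + 1)]
    n_second = int(round(scenario.fraction_with_second_set * scenario.n_genes))
    second = set(rng.choice(genes, size=n_second, replace=False)) if n_second else set()
    rows = []
    for gene in genes:
        sets = ["set1", "set2"] if gene in second else ["set1"]
        for gset in sets:
            for j in range(1, scenario.guides_per_gene + 1):
                rows.append((f"{gene}_{gset}_g{j}", gene, gset))
    seqs = _random_sequences(len(rows), scenario.guide_length, rng)
    table = pd.DataFrame(rows, columns=["guide_id", "gene_id", "guide_set"])
    table["sequence"] = seqs
    return GuideLibrary(table)


# ---------------------------------------------------------------------------
# screen counts
# ---------------------------------------------------------------------------

def _nb_draw(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Counts with variance mu + phi*mu^2 (Poisson when phi == 0)."""
    mu = np.clip(mu, 0.0, None)
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    # gamma-Poisson mixture
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_screen(
    library: GuideLibrary, scenario: ScreenScenario
) -> tuple[CountMatrix, PlantedTruth]:
    """Simulate sorted-population counts for the library.

    Each guide g has a log-normal abundance a_g (plasmid skew, shared
    across replicates since they derive from the same library prep);
    its cells sort into the cargo-low gate with probability
    p = gate_prob_required if the gene is required and the guide is
    efficacious, else gate_prob_null. Expected counts are proportional to
    a_g * p * depth (low gate) and a_g * (1-p) * depth (high gate), drawn
    negative-binomially with dispersion phi.
    """
    rng = np.random.default_rng(derive_seed(scenario.seed, "screen"))
    t = library.table
    guides = t["guide_id"].to_numpy()
    genes = t["gene_id"].to_numpy()
    unique_genes = library.genes
    required = set(
        np.random.default_rng(derive_seed(scenario.seed, "required")).choice(
            unique_genes, size=scenario.n_required_genes, replace=False
        )
    )
    efficacious = rng.random(len(guides)) < scenario.guide_efficacy_fraction
    is_required = np.isin(genes, list(required))
    p_low = np.where(
        is_required & efficacious,
        scenario.gate_prob_required,
        scenario.gate_prob_null,
    )

    depth = scenario.reads_per_guide
    a = rng.lognormal(mean=0.0, sigma=scenario.abundance_sigma,
                      size=len(guides))
    cols: dict[str, np.ndarray] = {}
    sample_rows = []
    for rep in range(1, scenario.n_replicates + 1):
        # scale so that an average guide at p=0.5 yields ~depth reads
        mu_low = 2.0 * depth * a * p_low
        mu_high = 2.0 * depth * a * (1.0 - p_low)
        cols[f"tau_low_r{rep}"] = _nb_draw(mu_low, scenario.nb_dispersion, rng)
        cols[f"tau_high_r{rep}"] = _nb_draw(mu_high, scenario.nb_dispersion, rng)
        sample_rows.append((f"tau_low_r{rep}", "tau_low", rep))
        sample_rows.append((f"tau_high_r{rep}", "tau_high", rep))

    counts = pd.DataFrame(cols, index=pd.Index(guides, name="sgRNA"))
    samples = pd.DataFrame(sample_rows,
                           columns=["sample", "condition", "replicate"])
    cm = CountMatrix(counts, pd.Series(genes, index=counts.index, name="gene"),
                     samples)
    truth = PlantedTruth(
        required_genes=sorted(required),
        guide_efficacy={g: bool(e) for g, e in zip(guides, efficacious)},
    )
    return cm, truth


def write_fastq_from_counts(
    cm: CountMatrix,
    library: GuideLibrary,
    sample: str,
    path: str | Path,
    offset: int = 0,
    seed: int = 0,
) -> None:
    """Emit one read per count unit for a sample column (noiseless; exact
    counting recovers the column). With offset > 0 reads get a random
    prefix of that length."""
    rng = np.random.default_rng(derive_seed(seed, f"fastq:{sample}"))
    seq_of = dict(zip(library.table["guide_id"], library.table["sequence"]))
    with open(path, "w") as fh:
        i = 0
        for guide_id, n in cm.counts[sample].items():
            seq = seq_of[guide_id]
            for _ in range(int(n)):
                prefix = "".join(_BASES[rng.integers(0, 4, size=offset)])
                read = prefix + seq
                fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
                i += 1


# ---------------------------------------------------------------------------
# localization, networks, external hit lists
# ---------------------------------------------------------------------------

def make_localization(
    genes: Sequence[str],
    n_compartments: int = 20,
    planted_compartment: str | None = None,
    hit_genes: Iterable[str] = (),
    effect: float = 0.0,
    density: float = 0.15,
    seed: int = 0,
) -> LocalizationMatrix:
    """Sparse right-skewed gene x compartment scores on [0, 5].

    Background: each (gene, compartment) cell is nonzero with probability
    ``density``, scores drawn from a truncated exponential (most evidence
    weak, little strong). ``effect`` is added to hit genes' scores in the
    planted compartment (clipped to 5); effect=0 leaves the planted
    compartment at background.
    """
    rng = np.random.default_rng(derive_seed(seed, "localization"))
    genes = [g.upper() for g in genes]
    comp_ids = [f"C{i:03d}" for i in range(1, n_compartments + 1)]
    mask = rng.random((len(genes), n_compartments)) < density
    raw = np.minimum(rng.exponential(scale=1.3, size=mask.shape), 5.0)
    scores = np.where(mask, raw, 0.0)
    df = pd.DataFrame(scores, index=pd.Index(genes, name="gene"),
                      columns=comp_ids)
    if planted_compartment is not None and effect != 0.0:
        if planted_compartment not in comp_ids:
            raise ValueError(f"unknown compartment {planted_compartment!r}")
        hits = [g.upper() for g in hit_genes if g.upper() in df.index]
        df.loc[hits, planted_compartment] = np.clip(
            df.loc[hits, planted_compartment] + effect, 0.0, 5.0)
    names = {c: f"compartment {c[1:].lstrip('0') or '0'}" for c in comp_ids}
    return LocalizationMatrix(df.sort_index(), names)


def make_network(
    genes: Sequence[str],
    background_edge_prob: float = 0.01,
    module_members: Sequence[str] = (),
    module_edge_prob: float = 0.9,
    seed: int = 0,
) -> list[MitabRecord]:
    """Erdos-Renyi background over all genes plus a planted dense module."""
    rng = np.random.default_rng(derive_seed(seed, "network"))
    genes = [g.upper() for g in genes]
    module = {g.upper() for g in module_members}
    unknown = module - set(genes)
    if unknown:
        raise ValueError(f"module members not in gene list: {sorted(unknown)}")
    records: list[MitabRecord] = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genes[i], genes[j]
            prob = (module_edge_prob if a in module and b in module
                    else background_edge_prob)
            if rng.random() < prob:
                records.append(MitabRecord(a, b, 9606, 9606, "synthdb"))
    return records


def make_external_hitlists(
    truth: PlantedTruth,
    all_genes: Sequence[str],
    n_lists: int = 3,
    overlap_fraction: float = 0.5,
    noise: float = 0.5,
    seed: int = 0,
) -> list[tuple[str, set[str], set[str]]]:
    """External screen hit lists with controlled overlap with the planted
    required genes.

    Each list keeps ``overlap_fraction`` of the required genes and pads with
    ``noise * n_required`` random non-required genes; returns
    (name, hit set, analysed-gene universe) triples. overlap_fraction=1 and
    noise=0 reproduce the required set exactly; overlap_fraction=0 yields
    lists unrelated to the truth.
    """
    rng = np.random.default_rng(derive_seed(seed, "hitlists"))
    required = [g.upper() for g in truth.required_genes]
    universe = {g.upper() for g in all_genes}
    others = sorted(universe - set(required))
    n_keep = int(round(overlap_fraction * len(required)))
    n_noise = int(round(noise * len(required)))
    out = []
    for i in range(1, n_lists + 1):
        kept = set(rng.choice(required, size=n_keep, replace=False)) if n_keep else set()
        pad = set(rng.choice(others, size=min(n_noise, len(others)),
                             replace=False)) if n_noise else set()
        out.append((f"external_{i}", kept | pad, set(universe)))
    return out
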