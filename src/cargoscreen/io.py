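"""Readers, writers and domain containers for every external format the
pipeline touches.

Formats are deliberately plain: tab-separated count tables in the MAGeCK
dialect (``sgRNA<TAB>gene<TAB><sample...>``), a sample sheet mapping sample
columns to sorted-population roles, GMT gene-set collections, PSI-MITAB 2.5
interaction records, and a long-format TSV of gene-to-compartment
localization scores on the COMPARTMENTS 0-5 confidence scale.

Sample roles are experiment metadata, not format: they come from a separate
sample sheet (columns ``sample``, ``condition``, ``replicate``), never from
parsing count-column names. Gene symbols are upper-cased at ingestion and
may be remapped through an optional two-column alias TSV.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cargoscreen")

VALID_CONDITIONS = ("tau_low", "tau_high", "plasmid")

_DNA_RE = re.compile(r"^[ACGT]+$")


class FormatError(ValueError):
    """A file violates its declared dialect or an invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideLibrary:
    """sgRNA library: guide -> (gene, guide-set) map with optional sequences.

    ``guide_set`` distinguishes a gene's first and second sgRNA set; most
    genes carry one set, a subset carries two (the screened library adds a
    second five-guide set for ~10% of genes). Sequences, when present, are
    uppercase DNA of one uniform length.
    """

    table: pd.DataFrame  # columns: guide_id, gene_id, guide_set, sequence

    def __post_init__(self) -> None:
        t = self.table
        required = ["guide_id", "gene_id", "guide_set"]
        for col in required:
            if col not in t.columns:
                raise FormatError(f"library table lacks column {col!r}")
        if "sequence" not in t.columns:
            object.__setattr__(
                self, "table", t.assign(sequence=pd.array([None] * len(t)))
            )
            t = self.table
        dup = t["guide_id"][t["guide_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicated guide id {dup.iloc[0]!r}")
        seqs = t["sequence"].dropna()
        if len(seqs):
            lengths = seqs.str.len().unique()
            if len(lengths) != 1:
                raise FormatError(
                    f"guide sequences have mixed lengths {sorted(lengths)}"
                )
            bad = seqs[~seqs.str.match(_DNA_RE)]
            if len(bad):
                raise FormatError(f"non-ACGT guide sequence {bad.iloc[0]!r}")

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())

    @property
    def guide_length(self) -> int | None:
        seqs = self.table["sequence"].dropna()
        return int(seqs.str.len().iloc[0]) if len(seqs) else None

    def guide_to_gene(self) -> dict[str, str]:
        return dict(zip(self.table["guide_id"], self.table["gene_id"]))

    def sequence_to_guides(self) -> dict[str, list[str]]:
        """Sequence -> guide ids (a sequence may recur across guides)."""
        out: dict[str, list[str]] = {}
        for gid, seq in zip(self.table["guide_id"], self.table["sequence"]):
            if isinstance(seq, str):
                out.setdefault(seq, []).append(gid)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GuideLibrary":
        t = pd.read_csv(path, sep="\t", dtype=str)
        return cls(t)


@dataclass(frozen=True)
class CountMatrix:
    """sgRNA x sample integer counts plus per-sample role annotations.

    ``samples`` has one row per count column: (sample, condition, replicate)
    with condition in {tau_low, tau_high, plasmid}. A comparison needs at
    least one tau_low and one tau_high sample.
    """

    counts: pd.DataFrame          # index guide_id, one column per sample
    genes: pd.Series              # guide_id -> gene_id, aligned to counts
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicated guide row {dup!r}")
        if (np.asarray(c.values) < 0).any():
            raise FormatError("negative counts are not allowed")
        if self.samples is not None:
            s = self.samples
            missing = set(s["sample"]) - set(c.columns)
            if missing:
                raise FormatError(
                    f"sample sheet names absent from counts: {sorted(missing)}"
                )
            bad = set(s["condition"]) - set(VALID_CONDITIONS)
            if bad:
                raise FormatError(f"unknown condition(s) {sorted(bad)}")

    def attach_samples(self, samples: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(self.counts, self.genes, samples)

    def columns_for(self, condition: str) -> list[str]:
        if self.samples is None:
            raise FormatError("no sample sheet attached")
        s = self.samples
        return list(s.loc[s["condition"] == condition, "sample"])

    def require_comparison(self) -> None:
        if not self.columns_for("tau_low") or not self.columns_for("tau_high"):
            raise FormatError(
                "comparison requires at least one tau_low and one tau_high sample"
            )


@dataclass(frozen=True)
class LocalizationMatrix:
    """Gene x compartment localization confidence, scores in [0, 5].

    Sparse: a missing (gene, compartment) pair means "no evidence", score 0.
    """

    scores: pd.DataFrame          # index gene, columns compartment_id, float
    compartment_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.scores.values
        if (v < 0).any() or (v > 5).any():
            raise FormatError("localization scores must lie in [0, 5]")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    @property
    def compartments(self) -> pd.Index:
        return self.scores.columns


@dataclass(frozen=True)
class MitabRecord:
    symbol_a: str
    symbol_b: str
    taxon_a: int | None
    taxon_b: int | None
    source_db: str


@dataclass
class RunConfig:
    """Run configuration mirrored by the YAML config file."""

    normalization: str = "median_ratio"
    alpha: float = 0.05
    permutations: int = 1000
    p_threshold: float = 0.01
    n_boot: int = 10000
    fdr_method: str = "bh"
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("hit p-threshold must lie in (0, 1)")
        if self.permutations < 1 or self.n_boot < 1:
            raise ValueError("permutation and bootstrap counts must be >= 1")

    def hash(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# count tables and sample sheets
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path, sample_sheet: str | Path | None = None
) -> CountMatrix:
    """Read a MAGeCK-style count table (``sgRNA<TAB>gene<TAB><samples...>``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["sgRNA", "gene"]:
        raise FormatError(
            f"{path}: header must start with 'sgRNA<TAB>gene', "
            f"got {list(df.columns[:2])}"
        )
    if df.shape[1] < 3:
        raise FormatError(f"{path}: no sample columns")
    sample_cols = list(df.columns[2:])
    for col in sample_cols:
        vals = df[col]
        as_num = pd.to_numeric(vals, errors="coerce")
        if as_num.isna().any():
            raise FormatError(f"{path}: non-numeric count in column {col!r}")
        if not np.allclose(as_num, np.round(as_num)):
            raise FormatError(f"{path}: non-integer count in column {col!r}")
        df[col] = as_num.astype(np.int64)
    counts = df.set_index("sgRNA")[sample_cols]
    genes = df.set_index("sgRNA")["gene"].str.upper()
    samples = read_sample_sheet(sample_sheet) if sample_sheet else None
    return CountMatrix(counts, genes, samples)


def write_count_table(cm: CountMatrix, path: str | Path,
                      header: str | None = None) -> None:
    """Write counts in the same dialect, rows sorted by guide id."""
    df = cm.counts.copy().astype(np.int64)
    df.insert(0, "gene", cm.genes)
    df = df.sort_index()
    df.index.name = "sgRNA"
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    s = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    for col in ("sample", "condition", "replicate"):
        if col not in s.columns:
            raise FormatError(f"{path}: sample sheet lacks column {col!r}")
    s["replicate"] = s["replicate"].astype(int)
    return s


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member genes} (upper-cased symbols)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
        name = fields[0]
        members = {m.strip().upper() for m in fields[2:] if m.strip()}
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# PSI-MITAB 2.5
# ---------------------------------------------------------------------------

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_GENE_ALIAS_RE = re.compile(r"uniprotkb:([A-Za-z0-9._-]+)\(gene name\)")
_ID_RE = re.compile(r"^[a-z]+:(.+)$")


def _mitab_symbol(id_field: str, alias_field: str) -> str | None:
    """Best-effort gene symbol: prefer a 'uniprotkb:SYMBOL(gene name)' alias,
    fall back to the bare identifier after its namespace prefix."""
    m = _GENE_ALIAS_RE.search(alias_field or "")
    if m:
        return m.group(1).upper()
    m = _ID_RE.match(id_field or "")
    if m:
        return m.group(1).upper()
    return None


def _mitab_taxon(field_: str) -> int | None:
    m = _TAXID_RE.search(field_ or "")
    return int(m.group(1)) if m else None


def read_mitab(path: str | Path) -> tuple[list[MitabRecord], int]:
    """Tolerant PSI-MITAB 2.5 reader.

    Returns (records, n_skipped). Unparseable lines are logged and skipped;
    taxon filtering happens downstream, so non-human records are retained
    with their taxon noted.
    """
    records: list[MitabRecord] = []
    skipped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 11:
            logger.warning("mitab %s:%d: too few columns, skipped", path, lineno)
            skipped += 1
            continue
        sym_a = _mitab_symbol(cols[0], cols[4] if len(cols) > 4 else "")
        sym_b = _mitab_symbol(cols[1], cols[5] if len(cols) > 5 else "")
        if not sym_a or not sym_b:
            logger.warning("mitab %s:%d: unresolvable interactor, skipped",
                           path, lineno)
            skipped += 1
            continue
        tax_a = _mitab_taxon(cols[9]) if len(cols) > 9 else None
        tax_b = _mitab_taxon(cols[10]) if len(cols) > 10 else None
        source = cols[12] if len(cols) > 12 and cols[12] else "unknown"
        source = source.split(":")[-1].strip("()")
        records.append(MitabRecord(sym_a, sym_b, tax_a, tax_b, source))
    if skipped:
        logger.warning("mitab %s: skipped %d unparseable line(s)", path, skipped)
    return records, skipped


def write_mitab(records: Sequence[MitabRecord], path: str | Path) -> None:
    """Write minimal valid PSI-MITAB 2.5 lines re-readable by read_mitab."""
    with open(path, "w") as fh:
        for r in records:
            tax_a = f"taxid:{r.taxon_a}" if r.taxon_a is not None else "-"
            tax_b = f"taxid:{r.taxon_b}" if r.taxon_b is not None else "-"
            cols = [
                f"uniprotkb:{r.symbol_a}",
                f"uniprotkb:{r.symbol_b}",
                "-", "-",
                f"uniprotkb:{r.symbol_a}(gene name)",
                f"uniprotkb:{r.symbol_b}(gene name)",
                "-", "-", "-",
                tax_a, tax_b, "-",
                f"psi-mi:{r.source_db}",
                "-", "-",
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# localization scores
# ---------------------------------------------------------------------------

def read_localization_tsv(path: str | Path) -> LocalizationMatrix:
    """Read long-format (gene, compartment_id, compartment_name, score)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={
        "gene": str, "compartment_id": str, "compartment_name": str})
    for col in ("gene", "compartment_id", "compartment_name", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df["gene"] = df["gene"].str.upper()
    if ((df["score"] < 0) | (df["score"] > 5)).any():
        bad = df.loc[(df["score"] < 0) | (df["score"] > 5)].iloc[0]
        raise FormatError(
            f"{path}: score {bad['score']} outside [0,5] for "
            f"({bad['gene']}, {bad['compartment_id']})")
    dup = df.duplicated(subset=["gene", "compartment_id"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate entry for ({bad['gene']}, "
            f"{bad['compartment_id']})")
    wide = df.pivot(index="gene", columns="compartment_id",
                    values="score").fillna(0.0)
    wide.columns.name = None
    wide.index.name = "gene"
    names = dict(zip(df["compartment_id"], df["compartment_name"]))
    return LocalizationMatrix(wide.sort_index(), names)


def write_localization_tsv(loc: LocalizationMatrix, path: str | Path) -> None:
    long = loc.scores.stack().rename("score").reset_index()
    long.columns = ["gene", "compartment_id", "score"]
    long = long[long["score"] > 0]
    long["compartment_name"] = long["compartment_id"].map(
        lambda c: loc.compartment_names.get(c, c))
    long = long[["gene", "compartment_id", "compartment_name", "score"]]
    long.sort_values(["gene", "compartment_id"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# aliases, gene lists, output headers
# ---------------------------------------------------------------------------

def read_alias_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (old symbol, current symbol) for symbol remapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["old", "new"],
                     dtype=str, comment="#")
    return {o.upper(): n.upper() for o, n in zip(df["old"], df["new"])}


def apply_alias(genes: Iterable[str], alias: Mapping[str, str]) -> list[str]:
    return [alias.get(g.upper(), g.upper()) for g in genes]


def read_gene_list(path: str | Path) -> list[str]:
    """Plain one-gene-per-line list, comments (#) ignored, upper-cased."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.upper())
    return out


def write_gene_list(genes: Iterable[str], path: str | Path,
                    header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def output_header(config: RunConfig | None = None) -> str:
    """Header comment carried by every output table: version, config hash, seed."""
    from cargoscreen import __version__
    if config is None:
        return f"cargoscreen {__version__}"
    return (f"cargoscreen {__version__} config={config.hash()} "
            f"seed={config.seed}")


def write_table(df: pd.DataFrame, path: str | Path,
                config: RunConfig | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {output_header(config)}\n")
        df.to_csv(fh, sep="\t", index=index)
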