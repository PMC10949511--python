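"""OTU tables, taxonomy, metadata and sequence I/O.

The canonical in-memory container is :class:`OtuTable`, a thin validated
wrapper around a ``pandas.DataFrame`` of non-negative integer counts with
taxa as rows and samples as columns.  Everything downstream (diversity,
neutral-model fitting, network inference, guild and dark-matter accounting)
consumes this container or the relative-abundance matrix derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

SAMPLE_TYPES = frozenset({"IN", "AS", "EFF"})

ID_COLUMN = "#OTU ID"


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant."""


@dataclass
class OtuTable:
    """Taxa x samples table of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with unique taxon ids as the index and unique sample ids
        as columns; every cell a non-negative integer.
    depth_note
        Rarefaction depth applied to this table, if any.
    """

    counts: pd.DataFrame
    depth_note: int | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        self.counts = c.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(sample_ids)].copy(), self.depth_note)

    def drop_empty_taxa(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(self.counts.loc[keep].copy(), self.depth_note)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)


def read_otu_table(path: str | Path, orientation_hint: str | None = None) -> OtuTable:
    """Read a TSV OTU table.

    Canonical orientation is taxa-as-rows with first column ``#OTU ID``.
    If the first header cell names samples instead (or
    ``orientation_hint="samples_rows"`` is given) the table is transposed
    on read.  ``orientation_hint`` accepts ``"taxa_rows"``,
    ``"samples_rows"`` or ``None`` (auto-detect: taxa rows unless the id
    header suggests otherwise).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if orientation_hint not in (None, "taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    orientation = orientation_hint
    if orientation is None:
        header = (df.index.name or "").strip().lower()
        orientation = "samples_rows" if header in {"sample", "sample id", "#sample id", "sample_id"} else "taxa_rows"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    if orientation == "samples_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = ID_COLUMN
    return OtuTable(numeric)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = ID_COLUMN
    out.to_csv(path, sep="\t")


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop taxa whose total count across all samples equals 1."""
    totals = table.counts.sum(axis=1)
    return OtuTable(table.counts.loc[totals != 1].copy(), table.depth_note)


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning.  Drawing is multivariate hypergeometric, so no count can
    increase and retained column totals equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_cols = []
    data = {}
    for sample in table.sample_ids:
        total = int(totals[sample])
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < {depth} reads; dropped from rarefied table",
                stacklevel=2,
            )
            continue
        col = table.counts[sample].to_numpy()
        data[sample] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sample)
    if not kept_cols:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(data, index=table.counts.index, columns=kept_cols)
    out.index.name = table.counts.index.name
    return OtuTable(out, depth_note=depth)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Close each sample to relative abundances (columns sum to 1)."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    return table.counts / totals


def filter_by_mean_abundance(table: OtuTable, min_mean_rel: float = 1e-4) -> OtuTable:
    """Keep taxa whose mean relative abundance strictly exceeds the threshold.

    The default 1e-4 is the 0.01% screen applied before network inference.
    """
    if not 0 <= min_mean_rel < 1:
        raise ValueError("min_mean_rel must be in [0, 1)")
    mean_rel = relative_abundance(table).mean(axis=1)
    return OtuTable(table.counts.loc[mean_rel > min_mean_rel].copy(), table.depth_note)


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class TaxonomyTable:
    """Per-taxon lineage over the seven Silva-style ranks.

    ``lineages`` maps taxon id to a 7-tuple (domain ... species) in which
    unassigned ranks are empty strings.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, ranks in self.lineages.items():
            if len(ranks) > len(RANKS):
                raise ValidationError(f"taxon {tid!r} has {len(ranks)} ranks > 7")
            self.lineages[tid] = tuple(ranks) + ("",) * (len(RANKS) - len(ranks))

    def rank_of(self, taxon_id: str, rank: str) -> str:
        idx = RANKS.index(rank)
        return self.lineages.get(taxon_id, ("",) * 7)[idx]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a semicolon lineage string (``d__...;p__...;...``) to 7 ranks."""
    out = [""] * len(RANKS)
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        for i, prefix in enumerate(RANK_PREFIXES):
            if token.lower().startswith(prefix):
                out[i] = token[len(prefix):].strip()
                break
    return tuple(out)


def format_lineage(ranks: Sequence[str]) -> str:
    return ";".join(p + r for p, r in zip(RANK_PREFIXES, ranks))


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column TSV of taxon id and semicolon lineage string."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError(f"taxonomy file {path} needs id and lineage columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValidationError(f"duplicate taxon ids in taxonomy: {ids[ids.duplicated()].tolist()}")
    return TaxonomyTable({tid: parse_lineage(lin) for tid, lin in zip(ids, df.iloc[:, 1])})


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for tid, ranks in tax.lineages.items():
            fh.write(f"{tid}\t{format_lineage(ranks)}\n")


# ---------------------------------------------------------------------------
# sample metadata and operational parameters


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata CSV: sample_id, plant, date (YYYY-MM), sample_type."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "plant", "date", "sample_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata {path} missing columns: {sorted(missing)}")
    bad = set(df["sample_type"]) - SAMPLE_TYPES
    if bad:
        raise ValidationError(f"unknown sample_type values: {sorted(bad)} (allowed {sorted(SAMPLE_TYPES)})")
    key = df[["plant", "date", "sample_type"]]
    if key.duplicated().any():
        raise ValidationError("duplicate (plant, date, sample_type) rows in metadata")
    return df


def read_operational(path: str | Path) -> pd.DataFrame:
    """Read operational-parameter CSV: plant, date, then numeric parameters.

    Typical parameters: temperature (degC), mcrt (d), hrt (h).
    """
    df = pd.read_csv(path)
    for col in ("plant", "date"):
        if col not in df.columns:
            raise FormatError(f"operational table {path} missing column {col!r}")
    params = [c for c in df.columns if c not in ("plant", "date")]
    if not params:
        raise FormatError(f"operational table {path} has no parameter columns")
    df[params] = df[params].apply(pd.to_numeric)
    return df


# ---------------------------------------------------------------------------
# sequences

_IUPAC_EXTRA = set("RYSWKMBDHVN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence mapping.

    Non-ACGT IUPAC codes trigger a warning (they never match under the
    exact criterion); other characters are format errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        extra = set(s) - set("ACGT")
        if extra & _IUPAC_EXTRA:
            warnings.warn(
                f"sequence {rec.id!r} contains IUPAC ambiguity codes {sorted(extra & _IUPAC_EXTRA)}",
                stacklevel=2,
            )
        if extra - _IUPAC_EXTRA:
            raise FormatError(f"sequence {rec.id!r} has non-nucleotide characters {sorted(extra - _IUPAC_EXTRA)}")
        if rec.id in seqs:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def collapse_rank(table: OtuTable, taxonomy: TaxonomyTable, rank: str = "phylum") -> OtuTable:
    """Sum counts of taxa sharing the same label at ``rank``.

    Taxa unassigned at that rank are pooled under ``"unassigned"``.
    """
    labels = [taxonomy.rank_of(t, rank) or "unassigned" for t in table.taxon_ids]
    grouped = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    return OtuTable(grouped, table.depth_note)
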