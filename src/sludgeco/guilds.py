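"""Functional-guild extraction and summaries.

Guilds are the process-relevant groups of an activated-sludge plant:
ammonia oxidizers (AOB), nitrite oxidizers (NOB), polyphosphate
accumulators (PAO), bulking/foaming filaments (BFB) and anammox
bacteria.  Membership is assigned by matching taxonomy labels at stated
ranks against a user-replaceable YAML definition file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .tables import RANKS, OtuTable, TaxonomyTable, relative_abundance


@dataclass
class GuildDefinition:
    """Rank-level taxon patterns defining one guild."""

    name: str
    patterns: list[tuple[str, str]]  # (rank, label)

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"guild {self.name!r} has no patterns")
        for rank, _ in self.patterns:
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} in guild {self.name!r}")


def _normalize_label(label: str) -> str:
    label = label.strip().lower()
    if label.startswith("candidatus "):
        label = label[len("candidatus "):]
    return label


def load_guild_definitions(path: str | Path | None = None) -> list[GuildDefinition]:
    """Load guild definitions from YAML; the packaged defaults when no
    path is given."""
    if path is None:
        text = resources.files("sludgeco.data").joinpath("default_guilds.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs = []
    for name, patterns in raw.items():
        defs.append(GuildDefinition(name, [(p["rank"], str(p["label"])) for p in patterns]))
    return defs


@dataclass
class GuildSummary:
    """Guild membership plus abundance summaries.

    ``members`` maps guild name to member taxon ids; ``per_sample`` is a
    guild x sample relative-abundance matrix (summed over members);
    ``mean_abundance`` and ``prevalence`` are per guild.
    """

    members: dict[str, list[str]]
    per_sample: pd.DataFrame
    mean_abundance: pd.Series
    prevalence: pd.Series
    rel_abundance: pd.DataFrame  # member-OTU x sample relative abundances


def extract_guilds(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    defs: Sequence[GuildDefinition] | None = None,
) -> GuildSummary:
    """Assign table taxa to guilds by taxonomy patterns and summarize.

    A taxon joins a guild when its lineage label at a pattern's rank
    equals the pattern label (case-insensitive; "Candidatus " prefixes
    stripped on both sides).  Within a guild, patterns above genus rank
    only apply when the genus is unassigned or itself matches, so a
    family pattern cannot double-count a named non-member genus — it
    sweeps up unclassified members of the family instead.  Overlap
    across guilds is allowed but warned about.
    """
    if defs is None:
        defs = load_guild_definitions()
    if not defs:
        raise ValueError("no guild definitions given")
    rel = relative_abundance(table)
    members: dict[str, list[str]] = {d.name: [] for d in defs}
    for tid in table.taxon_ids:
        lineage = taxonomy.lineages.get(tid)
        if lineage is None:
            continue
        labels = {rank: _normalize_label(lab) for rank, lab in zip(RANKS, lineage)}
        for d in defs:
            genus_patterns = {_normalize_label(lab) for rank, lab in d.patterns if rank == "genus"}
            hit = False
            for rank, lab in d.patterns:
                if labels.get(rank, "") != _normalize_label(lab):
                    continue
                if rank in ("genus", "species"):
                    hit = True
                else:
                    genus = labels.get("genus", "")
                    if genus == "" or genus in genus_patterns:
                        hit = True
                if hit:
                    break
            if hit:
                members[d.name].append(tid)
    assigned: dict[str, str] = {}
    for name, tids in members.items():
        for tid in tids:
            if tid in assigned:
                warnings.warn(
                    f"taxon {tid!r} matches both {assigned[tid]!r} and {name!r}", stacklevel=2
                )
            else:
                assigned[tid] = name
    per_sample = pd.DataFrame(
        {name: rel.loc[tids].sum(axis=0) if tids else pd.Series(0.0, index=rel.columns)
         for name, tids in members.items()}
    ).T
    per_sample.index.name = "guild"
    member_ids = [tid for tids in members.values() for tid in dict.fromkeys(tids)]
    return GuildSummary(
        members=members,
        per_sample=per_sample,
        mean_abundance=per_sample.mean(axis=1),
        prevalence=(per_sample > 0).mean(axis=1),
        rel_abundance=rel.loc[list(dict.fromkeys(member_ids))],
    )


def aob_nob_ratio(
    summary: GuildSummary,
    sample_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Ratio of mean AOB to mean NOB total abundance, per group.

    ``sample_groups`` maps sample id to a group label (e.g., plant); when
    omitted a single "overall" group is used.  Where the NOB mean is
    zero the ratio is not a number: ``nob_absent`` is flagged instead.
    """
    for g in ("AOB", "NOB"):
        if g not in summary.per_sample.index:
            raise ValueError(f"guild {g!r} not summarized")
    samples = summary.per_sample.columns
    groups = pd.Series(
        [sample_groups.get(s, "overall") if sample_groups else "overall" for s in samples],
        index=samples,
    )
    rows = []
    for label, cols in groups.groupby(groups).groups.items():
        aob = summary.per_sample.loc["AOB", cols].mean()
        nob = summary.per_sample.loc["NOB", cols].mean()
        if nob == 0:
            rows.append({"group": label, "aob_mean": aob, "nob_mean": nob,
                         "ratio": np.nan, "nob_absent": True})
        else:
            rows.append({"group": label, "aob_mean": aob, "nob_mean": nob,
                         "ratio": aob / nob, "nob_absent": False})
    return pd.DataFrame(rows).set_index("group")


def guild_abundance_matrix(
    summary: GuildSummary,
    rank: str = "otu",
    min_mean_rel: float | None = None,
    log10: bool = False,
) -> pd.DataFrame:
    """Display matrix of guild-member abundances.

    ``rank="otu"`` gives per-member-OTU rows, ``rank="guild"`` the summed
    per-guild rows.  Optional strict ``min_mean_rel`` mean filter (the
    display screen is 1e-4, i.e. >0.01%) and log10 transform in which
    zeros become NaN rather than -inf.
    """
    if rank == "otu":
        mat = summary.rel_abundance.copy()
    elif rank == "guild":
        mat = summary.per_sample.copy()
    else:
        raise ValueError("rank must be 'otu' or 'guild'")
    if min_mean_rel is not None:
        mat = mat.loc[mat.mean(axis=1) > min_mean_rel]
    if log10:
        with np.errstate(divide="ignore"):
            mat = pd.DataFrame(
                np.where(mat > 0, np.log10(mat.to_numpy(), where=mat.to_numpy() > 0), np.nan),
                index=mat.index, columns=mat.columns,
            )
    return mat
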