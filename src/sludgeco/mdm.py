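"""Genome-sequenced proportions ("microbial dark matter" accounting).

Two match criteria against a reference 16S set:

* exact — the query (or its reverse complement) occurs as a contiguous
  substring of a reference: 100% query coverage at 100% identity;
* identity — semi-global alignment (query-global, reference-local) with
  a configurable identity cutoff, 97% by default, as used for assigning
  nitrifier OTUs to genomes.

From the matches, P_number is the fraction of taxa with a sequenced
relative and P_abundance the fraction of community abundance they carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .tables import OtuTable, relative_abundance

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MatchResult:
    """Outcome of matching one query against the reference set."""

    query_id: str
    reference_id: str | None
    identity: float
    coverage: float
    criterion: str

    @property
    def matched(self) -> bool:
        return self.reference_id is not None


@dataclass
class MdmReport:
    """Genome-sequenced proportions and their per-OTU evidence."""

    p_number: float
    p_abundance: float
    per_group: pd.DataFrame  # group x (p_number, p_abundance, n_taxa)
    matches: list[MatchResult]
    thresholds: dict = field(default_factory=dict)


def match_exact(queries: Mapping[str, str], references: Mapping[str, str]) -> list[MatchResult]:
    """Exact-substring matching on either strand.

    A query matches when it, or its reverse complement, is a contiguous
    substring of a reference (full query coverage, zero mismatches).
    The first hit in reference order is reported.  Ambiguity codes never
    match under this criterion.
    """
    if not queries:
        raise ValueError("empty query set")
    out = []
    for qid, q in queries.items():
        q = q.upper()
        rc = reverse_complement(q)
        hit = None
        for rid, ref in references.items():
            ref = ref.upper()
            if q in ref or rc in ref:
                hit = rid
                break
        out.append(
            MatchResult(
                query_id=qid,
                reference_id=hit,
                identity=1.0 if hit else 0.0,
                coverage=1.0 if hit else 0.0,
                criterion="exact",
            )
        )
    return out


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # reference-local: reference overhangs beyond the query are free
    aligner.end_deletion_score = 0
    return aligner


def _alignment_identity(alignment) -> float:
    """Identity over alignment columns, excluding reference overhangs
    (columns where the query has leading/trailing gaps)."""
    q_aln, t_aln = alignment[1], alignment[0]
    s = 0
    e = len(q_aln)
    while s < e and q_aln[s] == "-":
        s += 1
    while e > s and q_aln[e - 1] == "-":
        e -= 1
    cols = e - s
    if cols == 0:
        return 0.0
    matches = sum(1 for a, b in zip(q_aln[s:e], t_aln[s:e]) if a == b and a != "-")
    return matches / cols


def match_identity(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    min_identity: float = 0.97,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[MatchResult]:
    """Best-identity ("top hit") semi-global matching at a cutoff.

    Each query is aligned query-globally against each reference (and its
    reverse complement); identity is matched columns over alignment
    columns.  The best-identity reference is reported when it reaches
    ``min_identity``.
    """
    if not queries:
        raise ValueError("empty query set")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    aligner = _make_aligner(match, mismatch, gap)
    out = []
    for qid, q in queries.items():
        q = q.upper()
        best_id, best_ref = 0.0, None
        for rid, ref in references.items():
            ref = ref.upper()
            for target in (ref, reverse_complement(ref)):
                aln = aligner.align(target, q)[0]
                ident = _alignment_identity(aln)
                if ident > best_id:
                    best_id, best_ref = ident, rid
        ok = best_id >= min_identity
        out.append(
            MatchResult(
                query_id=qid,
                reference_id=best_ref if ok else None,
                identity=best_id,
                coverage=1.0,
                criterion=f"identity>={min_identity:g}",
            )
        )
    return out


def mdm_proportions(
    table: OtuTable,
    matches: Sequence[MatchResult],
    sample_groups: Mapping[str, str] | None = None,
) -> MdmReport:
    """P_number and P_abundance overall and per sample group.

    P_number = matched taxa / taxa present; P_abundance = summed mean
    relative abundance of matched taxa / total.  Per group, only taxa
    with at least one read in that group's samples count.
    """
    status = {m.query_id: m.matched for m in matches}
    missing = [t for t in table.taxon_ids if t not in status]
    if missing:
        raise ValueError(f"no match result for taxa: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    rel = relative_abundance(table)
    matched_mask = np.array([status[t] for t in table.taxon_ids])

    def _props(cols: Sequence[str]) -> tuple[float, float, int]:
        sub = table.counts[list(cols)]
        present = sub.sum(axis=1).to_numpy() > 0
        n = int(present.sum())
        if n == 0:
            return np.nan, np.nan, 0
        p_num = float((matched_mask & present).sum() / n)
        mean_rel = rel[list(cols)].mean(axis=1).to_numpy()
        total = mean_rel[present].sum()
        p_ab = float(mean_rel[matched_mask & present].sum() / total) if total > 0 else np.nan
        return p_num, p_ab, n

    overall = _props(table.sample_ids)
    rows = {"overall": overall}
    if sample_groups:
        groups: dict[str, list[str]] = {}
        for s in table.sample_ids:
            groups.setdefault(sample_groups.get(s, "ungrouped"), []).append(s)
        for g, cols in sorted(groups.items()):
            rows[g] = _props(cols)
    per_group = pd.DataFrame(
        {g: {"p_number": v[0], "p_abundance": v[1], "n_taxa": v[2]} for g, v in rows.items()}
    ).T
    per_group.index.name = "group"
    return MdmReport(
        p_number=overall[0],
        p_abundance=overall[1],
        per_group=per_group,
        matches=list(matches),
        thresholds={"criterion": matches[0].criterion if matches else None},
    )


def wanted_list_map(
    queries: Mapping[str, str],
    wanted: Mapping[str, str],
    table: OtuTable,
    min_mean_rel: float = 1e-3,
    sample_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Locate "wanted list" sequences among the study's OTUs.

    Wanted sequences are matched to study OTUs under the exact
    criterion; a wanted entry is *listed* when its matching OTU exceeds
    ``min_mean_rel`` mean relative abundance (overall, plus per group
    when groups are given).  Returns one row per wanted id.
    """
    if not wanted:
        raise ValueError("empty wanted list")
    matches = match_exact(wanted, queries)
    rel = relative_abundance(table)
    mean_rel = rel.mean(axis=1)
    rows = []
    for m in matches:
        otu = m.reference_id
        abundance = float(mean_rel.get(otu, 0.0)) if otu else 0.0
        row = {
            "wanted_id": m.query_id,
            "matched_otu": otu,
            "mean_abundance": abundance,
            "listed": bool(otu) and abundance > min_mean_rel,
        }
        if sample_groups and otu is not None and otu in rel.index:
            for g in sorted(set(sample_groups.values())):
                cols = [s for s in table.sample_ids if sample_groups.get(s) == g]
                row[f"mean_abundance_{g}"] = float(rel.loc[otu, cols].mean()) if cols else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("wanted_id")
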