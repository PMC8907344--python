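"""Differential-acetylation calls and direct/indirect target classification.

A site-arm pair is "up" when its protein-normalized fold change strictly
exceeds the threshold (default 1.5) and "down" when it is strictly below
the reciprocal.  A peptide (identical sequence + acetyl-site set) is a
*direct* deacetylase target when it is up in the knockdown arm AND down in
the overexpression arm (acetylation anti-correlated with enzyme level), and
*indirect* for the opposite pattern.  At the protein level the any-site
rule applies: each arm's condition may be satisfied by a different site of
the same protein.  Records sharing a gene symbol are consolidated into one
protein (case-insensitive exact match; no alias resolution).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .design import KNOCKDOWN, OVEREXPRESSION
from .errors import ValidationError

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
EXCLUDED = "excluded"

DIRECT = "direct"
INDIRECT = "indirect"
NEITHER = "neither"
BOTH = "direct+indirect"  # protein with both patterns at different sites


def call_dex(changes: pd.DataFrame, threshold: float = 1.5) -> pd.DataFrame:
    """Add a per-(site, arm) direction column at a fold threshold (strict >)."""
    if threshold <= 1:
        raise ValidationError("fold threshold must be > 1")
    dex = changes.copy()
    ratio = dex["normalized_ratio"]
    direction = pd.Series(UNCHANGED, index=dex.index, dtype=object)
    direction[ratio > threshold] = UP
    direction[ratio < 1.0 / threshold] = DOWN
    direction[dex["excluded"]] = EXCLUDED
    dex["direction"] = direction
    dex.attrs["threshold"] = threshold
    return dex


def _record_class(kd: str, oe: str) -> str:
    if kd == UP and oe == DOWN:
        return DIRECT
    if kd == DOWN and oe == UP:
        return INDIRECT
    return NEITHER


def classify_targets(dex: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(peptide-level, protein-level) target classes from both-arm calls.

    Peptide level requires the identical peptide to satisfy both arm
    conditions; protein level uses the any-site rule per arm, so a protein
    can be direct without any single peptide being direct.
    """
    if dex.empty:
        peptides = pd.DataFrame(
            columns=["peptide_key", "accession", "gene", "sites",
                     "direct", "indirect", "target_class"]
        )
        proteins = pd.DataFrame(
            columns=["gene", "up_knockdown", "down_knockdown", "up_overexpression",
                     "down_overexpression", "direct", "indirect", "target_class"]
        )
        return peptides, proteins
    wide = dex.pivot_table(
        index="record",
        columns="arm",
        values="direction",
        aggfunc="first",
        observed=True,
    )
    for arm in (KNOCKDOWN, OVEREXPRESSION):
        if arm not in wide.columns:
            raise ValidationError(f"both arms must be called; missing {arm!r}")
    meta = (
        dex.groupby("record", sort=True)
        .agg(
            peptide_key=("peptide_key", "first"),
            accession=("accession", "first"),
            gene=("gene", "first"),
            sites=("sites", "first"),
        )
        .join(wide)
        .rename(columns={KNOCKDOWN: "dir_knockdown", OVEREXPRESSION: "dir_overexpression"})
    )
    meta["target_class"] = [
        _record_class(kd, oe)
        for kd, oe in zip(meta["dir_knockdown"], meta["dir_overexpression"])
    ]
    peptides = (
        meta.groupby("peptide_key", sort=True)
        .agg(
            accession=("accession", "first"),
            gene=("gene", "first"),
            sites=("sites", "first"),
            direct=("target_class", lambda c: (c == DIRECT).any()),
            indirect=("target_class", lambda c: (c == INDIRECT).any()),
        )
        .reset_index()
    )
    peptides["target_class"] = peptides.apply(
        lambda r: DIRECT if r["direct"] else (INDIRECT if r["indirect"] else NEITHER),
        axis=1,
    )

    meta["gene_upper"] = meta["gene"].str.upper()
    by_gene = meta.groupby("gene_upper", sort=True)
    proteins = by_gene.agg(
        up_knockdown=("dir_knockdown", lambda c: (c == UP).any()),
        down_knockdown=("dir_knockdown", lambda c: (c == DOWN).any()),
        up_overexpression=("dir_overexpression", lambda c: (c == UP).any()),
        down_overexpression=("dir_overexpression", lambda c: (c == DOWN).any()),
    )
    proteins["direct"] = proteins["up_knockdown"] & proteins["down_overexpression"]
    proteins["indirect"] = proteins["down_knockdown"] & proteins["up_overexpression"]

    def protein_class(row) -> str:
        if row["direct"] and row["indirect"]:
            return BOTH
        if row["direct"]:
            return DIRECT
        if row["indirect"]:
            return INDIRECT
        return NEITHER

    proteins["target_class"] = proteins.apply(protein_class, axis=1)
    proteins.index.name = "gene"
    return peptides, proteins.reset_index()


@dataclass(frozen=True)
class VennSummary:
    """Margin and overlap counts of the two-arm comparison Venn diagrams."""

    sites_up: dict[str, int]
    sites_down: dict[str, int]
    peptides_up: dict[str, int]
    peptides_down: dict[str, int]
    proteins_up: dict[str, int]
    proteins_down: dict[str, int]
    direct_peptides: int
    indirect_peptides: int
    direct_sites: int
    indirect_sites: int
    direct_proteins: int
    indirect_proteins: int

    def to_dict(self) -> dict:
        return asdict(self)


def venn_summary(dex: pd.DataFrame) -> VennSummary:
    """Counts of up/down sites, peptides and proteins per arm plus the
    direct/indirect overlaps.  Sites are counted globally as unique
    (accession, position) pairs; proteins consolidate on the gene symbol."""
    peptides, proteins = classify_targets(dex)
    arms = (KNOCKDOWN, OVEREXPRESSION)
    sites_up: dict[str, int] = {}
    sites_down: dict[str, int] = {}
    peptides_up: dict[str, int] = {}
    peptides_down: dict[str, int] = {}
    proteins_up: dict[str, int] = {}
    proteins_down: dict[str, int] = {}
    for arm in arms:
        sub = dex[dex["arm"] == arm]
        for direction, sites_out, peps_out, prots_out in (
            (UP, sites_up, peptides_up, proteins_up),
            (DOWN, sites_down, peptides_down, proteins_down),
        ):
            hit = sub[sub["direction"] == direction]
            sites_out[arm] = len(
                {(a, p) for a, ss in zip(hit["accession"], hit["sites"]) for p in ss}
            )
            peps_out[arm] = hit["peptide_key"].nunique()
            prots_out[arm] = hit["gene"].str.upper().nunique()

    direct_pep = peptides[peptides["target_class"] == DIRECT]
    indirect_pep = peptides[peptides["target_class"] == INDIRECT]

    def unique_sites(frame: pd.DataFrame) -> int:
        return len(
            {(a, p) for a, ss in zip(frame["accession"], frame["sites"]) for p in ss}
        )

    return VennSummary(
        sites_up=sites_up,
        sites_down=sites_down,
        peptides_up=peptides_up,
        peptides_down=peptides_down,
        proteins_up=proteins_up,
        proteins_down=proteins_down,
        direct_peptides=len(direct_pep),
        indirect_peptides=len(indirect_pep),
        direct_sites=unique_sites(direct_pep),
        indirect_sites=unique_sites(indirect_pep),
        direct_proteins=int(proteins["direct"].sum()),
        indirect_proteins=int(proteins["indirect"].sum()),
    )


def overlap_known(
    direct_proteins: set[str], known: set[str]
) -> tuple[set[str], float]:
    """Intersection of called direct targets with a curated substrate list,
    and the recovered fraction of the known list."""
    if not known:
        raise ValidationError("the known-substrate list must be non-empty")
    direct_upper = {g.upper() for g in direct_proteins}
    known_upper = {g.upper() for g in known}
    intersection = direct_upper & known_upper
    return intersection, len(intersection) / len(known_upper)
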