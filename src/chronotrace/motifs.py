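"""Motif-site annotation and differential-accessibility motif-set enrichment.

Motif occurrences arrive as genomic intervals (PWM scanning happens
upstream).  Each site is assigned to genes by strand-aware window rules —
gene body, promoter (−1107 to +107 bp around the TSS in transcription
orientation), or distal (within 10 kb upstream of the TSS or downstream of
the TTS) — with per-gene precedence gene_body > promoter > distal.
Differential-accessibility (DA) motif sets are built from per-contrast
log2FC rules gated at FDR < 0.1, and per-motif enrichment of a target set
against a background is computed with the upper-tail hypergeometric test
and BH adjustment.

All coordinates are 0-based half-open (BED convention); the window offsets
are inclusive base offsets relative to the TSS/TTS in transcription
orientation.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .stats import adjust_pvalues, hypergeom_enrichment

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "MotifSetRule",
    "AnnotatedMotifSite",
    "annotate_sites",
    "build_motif_sets",
    "enrich_motifs",
]

_FEATURE_PRECEDENCE = {"gene_body": 0, "promoter": 1, "distal": 2}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand-consistent TSS/TTS.

    The span is the gene body (UTRs, coding exons, introns).  For a +
    strand gene TSS = start and TTS = end - 1 (last transcribed base); for
    a - strand gene TSS = end - 1 and TTS = start.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed gene span for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def windows(
        self,
        promoter_window: tuple[int, int] = (-1107, 107),
        distal_bp: int = 10_000,
    ) -> list[tuple[str, int, int]]:
        """Feature windows as (feature_type, start, end) half-open tuples.

        Promoter covers inclusive offsets ``promoter_window`` around the
        TSS in transcription orientation; distal covers ``distal_bp`` bases
        upstream of the TSS (excluding it) and downstream of the TTS
        (excluding it).  Overlap between windows is resolved downstream by
        feature precedence, not by coordinate subtraction.
        """
        lo_off, hi_off = promoter_window
        wins = [("gene_body", self.start, self.end)]
        if self.strand == "+":
            wins.append(("promoter", self.tss + lo_off, self.tss + hi_off + 1))
            wins.append(("distal", self.tss - distal_bp, self.tss))
            wins.append(("distal", self.tts + 1, self.tts + distal_bp + 1))
        else:
            wins.append(("promoter", self.tss - hi_off, self.tss - lo_off + 1))
            wins.append(("distal", self.tss + 1, self.tss + distal_bp + 1))
            wins.append(("distal", self.tts - distal_bp, self.tts))
        return [(f, max(0, s), e) for f, s, e in wins if e > max(0, s)]


@dataclass
class AnnotatedMotifSite:
    site_id: str
    interval: GenomicInterval
    motif_id: str
    gene_assignments: dict[str, str] = field(default_factory=dict)  # gene -> feature
    set_memberships: set[str] = field(default_factory=set)


def annotate_sites(
    sites: Sequence[AnnotatedMotifSite] | pd.DataFrame,
    gene_models: Iterable[GeneModel],
    promoter_window: tuple[int, int] = (-1107, 107),
    distal_bp: int = 10_000,
) -> list[AnnotatedMotifSite]:
    """Assign motif sites to genes by window overlap.

    ``sites`` may be AnnotatedMotifSite objects or a BED-like frame with
    columns chrom, start, end, motif_id (and optionally site_id, strand).
    A site overlaps a window when they share >= 1 base under half-open
    arithmetic.  A site may be assigned to several genes; per gene the
    highest-precedence feature type is kept (gene_body > promoter >
    distal).  Unknown site strands are tolerated (site strand is irrelevant
    to window overlap).
    """
    if isinstance(sites, pd.DataFrame):
        objs = []
        for i, row in sites.reset_index(drop=True).iterrows():
            sid = str(row["site_id"]) if "site_id" in sites.columns else f"site{i}"
            strand = str(row.get("strand", "."))
            if strand not in {"+", "-", "."}:
                strand = "."
            objs.append(AnnotatedMotifSite(
                sid,
                GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), strand),
                str(row["motif_id"]),
            ))
        sites = objs
    trees: dict[str, IntervalTree] = {}
    for gm in gene_models:
        tree = trees.setdefault(gm.chrom, IntervalTree())
        for feature, s, e in gm.windows(promoter_window, distal_bp):
            tree.addi(s, e, (gm.gene_id, feature))
    for site in sites:
        site.gene_assignments = {}
        tree = trees.get(site.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(site.interval.start, site.interval.end):
            gene, feature = hit.data
            prev = site.gene_assignments.get(gene)
            if prev is None or _FEATURE_PRECEDENCE[feature] < _FEATURE_PRECEDENCE[prev]:
                site.gene_assignments[gene] = feature
    return list(sites)


@dataclass(frozen=True)
class MotifSetRule:
    """OR-combined log2FC clauses defining a DA motif set.

    Each clause is (contrast_name, comparator, threshold) with comparator
    ">" or "<"; a site joins the set when its FDR in a clause's contrast is
    below ``da_fdr_max`` and the clause's fold-change condition holds.
    """

    set_name: str
    clauses: tuple[tuple[str, str, float], ...]
    da_fdr_max: float = 0.1

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("a motif-set rule needs at least one clause")
        for contrast, comp, _thr in self.clauses:
            if comp not in {">", "<"}:
                raise ValueError(f"comparator must be > or <, got {comp!r} for {contrast}")


def build_motif_sets(
    da_table: pd.DataFrame,
    rules: Sequence[MotifSetRule],
    region_col: str = "region_id",
) -> dict[str, set[str]]:
    """Evaluate DA motif-set rules over a long-format DA table.

    ``da_table`` columns: region_id, contrast, log2fc, fdr (one row per
    region x contrast).  Returns set_name -> region_id membership.  A rule
    referencing a contrast absent from the table raises, naming it.
    """
    present = set(da_table["contrast"].unique())
    ops = {">": operator.gt, "<": operator.lt}
    out: dict[str, set[str]] = {}
    for rule in rules:
        members: set[str] = set()
        for contrast, comp, thr in rule.clauses:
            if contrast not in present:
                raise KeyError(f"contrast {contrast!r} referenced by rule "
                               f"{rule.set_name!r} absent from DA table")
            sub = da_table[da_table["contrast"] == contrast]
            hit = sub[(sub["fdr"] < rule.da_fdr_max) & ops[comp](sub["log2fc"], thr)]
            members |= set(hit[region_col].astype(str))
        out[rule.set_name] = members
    return out


def enrich_motifs(
    target_sites: Iterable[str],
    background_sites: Iterable[str],
    site_motifs: pd.DataFrame,
    site_col: str = "site_id",
    motif_col: str = "motif_id",
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of a target set vs. a background.

    ``site_motifs`` maps sites to the motifs they contain (presence/absence:
    a motif occurring twice in one site counts once).  For each motif, the
    universe is the background site count, draws the target size, successes
    the motif's background occurrences, and the observed value its target
    occurrences; p-values are BH-adjusted across motifs.  The target must be
    a subset of the background.
    """
    target = set(map(str, target_sites))
    background = set(map(str, background_sites))
    if not target <= background:
        raise ValueError("target sites must be a subset of the background")
    sm = site_motifs[[site_col, motif_col]].astype(str).drop_duplicates()
    sm = sm[sm[site_col].isin(background)]
    n_bg, n_tgt = len(background), len(target)
    rows = []
    for motif, grp in sm.groupby(motif_col, sort=True):
        in_bg = set(grp[site_col])
        k_bg = len(in_bg)
        k_tgt = len(in_bg & target)
        res = hypergeom_enrichment(k_tgt, n_tgt, k_bg, n_bg)
        rows.append({
            "motif_id": motif,
            "n_target": n_tgt, "n_background": n_bg,
            "k_target": k_tgt, "k_background": k_bg,
            "odds_ratio": res.odds_ratio,
            "log2_odds_ratio": res.log2_odds_ratio,
            "p": res.p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), "bh")
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
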