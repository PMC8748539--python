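"""Characterization of insertion sets.

Covers the hallmark signatures of LINE-1-mediated retrotransposition —
target-site-duplication length (mode near 15 bp for genuine events),
AT-rich flanking sequence — and the genomic placement of insertions:
intronic/intergenic context against representative (longest) transcript
isoforms, preference for longer genes, overlap with common fragile
sites, recurrently hit genes across patients, intersection with an
external cancer-gene list, and proximity of intronic insertions to exon
boundaries (potential splicing disruption).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .model import GeneSet, PatientClass

CONTEXT_LABELS = ("CDS", "UTR5", "UTR3", "intron", "intergenic")
_PRECEDENCE = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def percent(n: float, total: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up (the convention of printed summary tables)."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(str(n)) / Decimal(str(total)) * 100).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# TSD lengths
# ---------------------------------------------------------------------------


def tsd_length_histogram(calls) -> tuple[pd.Series, int | None, int]:
    """Histogram of TSD lengths over calls carrying a TSD sequence.

    Returns ``(histogram, mode, n_without_tsd)``; the mode breaks ties to
    the smallest length and is None when no call carries a TSD.
    """
    lengths = [len(c.tsd_sequence) for c in calls if c.tsd_sequence]
    n_missing = sum(1 for c in calls if not c.tsd_sequence)
    if not lengths:
        return pd.Series(dtype=int, name="count"), None, n_missing
    hist = pd.Series(lengths).value_counts().sort_index()
    hist.name = "count"
    mode = int(hist.index[np.argmax(hist.to_numpy())])
    return hist, mode, n_missing


# ---------------------------------------------------------------------------
# Flanking base composition
# ---------------------------------------------------------------------------


def flanking_composition(
    genome, calls, flank_bp: int = 50
) -> tuple[pd.DataFrame, int, int]:
    """Per-position A/C/G/T fractions within ±flank_bp of insertion sites.

    ``genome`` is a FASTA path, a pyfaidx Fasta, or a name→sequence dict.
    Position 0 is the reference base at the insertion coordinate; N bases
    are dropped from each position's denominator; sites whose window runs
    off a contig edge are excluded and counted.  Returns
    ``(fractions, n_sites_used, n_sites_excluded)``.
    """
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        genome = Fasta(str(genome))
    positions = np.arange(-flank_bp, flank_bp + 1)
    counts = {b: np.zeros(len(positions), dtype=np.int64) for b in "ACGT"}
    n_used = n_excluded = 0
    for call in calls:
        if call.chrom not in genome:
            raise ValueError(f"chromosome {call.chrom!r} absent from genome")
        contig = genome[call.chrom]
        clen = len(contig)
        pos = getattr(call, "final_pos", None) or call.pos
        p0 = pos - 1
        lo, hi = p0 - flank_bp, p0 + flank_bp + 1
        if lo < 0 or hi > clen:
            n_excluded += 1
            continue
        seq = str(contig[lo:hi]).upper()
        n_used += 1
        for offset, base in enumerate(seq):
            if base in counts:
                counts[base][offset] += 1
    table = pd.DataFrame(counts, index=positions)
    denom = table.sum(axis=1)
    fractions = table.div(denom.replace(0, np.nan), axis=0)
    fractions.index.name = "position"
    return fractions, n_used, n_excluded


def at_fraction(fractions: pd.DataFrame, lo: int, hi: int) -> float:
    """Mean A+T fraction over positions lo..hi inclusive (absolute offsets)."""
    window = fractions.loc[lo:hi]
    return float((window["A"] + window["T"]).mean())


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContextLabel:
    chrom: str
    pos: int  # 1-based insertion coordinate
    te_family: str
    patient_id: str | None
    label: str  # highest-precedence label across overlapped genes
    gene_ids_overlapped: tuple[str, ...]

    @property
    def overlapping_flag(self) -> bool:
        """Insertion falls inside representative transcripts of >= 2 genes."""
        return len(self.gene_ids_overlapped) >= 2


def _gene_trees(genes: GeneSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        rep = gene.representative
        if rep.end > rep.start:
            trees.setdefault(gene.chrom, IntervalTree()).addi(
                rep.start, rep.end, gene.gene_id
            )
    return trees


def _within_gene_label(p0: int, gene) -> str:
    """Label a point inside the representative transcript of one gene."""
    rep = gene.representative
    for s, e in rep.cds:
        if s <= p0 < e:
            return "CDS"
    in_exon = any(s <= p0 < e for s, e in rep.exons)
    if in_exon and rep.cds:
        cds_start = rep.cds[0][0]
        cds_end = rep.cds[-1][1]
        if p0 < cds_start:
            return "UTR5" if gene.strand == "+" else "UTR3"
        if p0 >= cds_end:
            return "UTR3" if gene.strand == "+" else "UTR5"
    # non-coding exons and everything else inside the span count as intronic
    return "intron"


def assign_genomic_context(calls, genes: GeneSet) -> list[ContextLabel]:
    """Place each insertion against representative transcripts.

    Within a gene the precedence is CDS > UTR5 > UTR3 > intron; across
    several overlapped genes the insertion's summary label is the
    highest-precedence one, with every overlapped gene id retained.
    """
    trees = _gene_trees(genes)
    labels: list[ContextLabel] = []
    for call in calls:
        pos = getattr(call, "final_pos", None) or call.pos
        p0 = pos - 1
        tree = trees.get(call.chrom)
        hits = sorted(iv.data for iv in tree[p0]) if tree is not None else []
        if not hits:
            label = "intergenic"
        else:
            label = min(
                (_within_gene_label(p0, genes[gid]) for gid in hits),
                key=_PRECEDENCE.__getitem__,
            )
        labels.append(
            ContextLabel(
                chrom=call.chrom,
                pos=pos,
                te_family=call.te_family.value,
                patient_id=getattr(call, "patient_id", None),
                label=label,
                gene_ids_overlapped=tuple(hits),
            )
        )
    return labels


def summarize_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Counts plus half-up percentages of the total, in vocabulary order."""
    total = sum(counts.values())
    rows = [
        {"label": lab, "count": counts.get(lab, 0), "pct": percent(counts.get(lab, 0), total)}
        for lab in CONTEXT_LABELS
        if lab in counts or counts.get(lab, 0)
    ]
    if not rows:
        rows = [{"label": lab, "count": 0, "pct": float("nan")} for lab in CONTEXT_LABELS]
    return pd.DataFrame(rows)


def context_summary(
    labels: Sequence[ContextLabel], by_family: bool = False
) -> pd.DataFrame:
    """Per-label counts and percentages, optionally broken down by family."""
    counts: dict[str, int] = {lab: 0 for lab in CONTEXT_LABELS}
    for l in labels:
        counts[l.label] += 1
    table = summarize_counts(counts)
    if by_family:
        families = sorted({l.te_family for l in labels})
        for fam in families:
            fam_counts = {lab: 0 for lab in CONTEXT_LABELS}
            for l in labels:
                if l.te_family == fam:
                    fam_counts[l.label] += 1
            table[fam] = [fam_counts[lab] for lab in table["label"]]
    table.attrs["n_overlapping"] = sum(1 for l in labels if l.overlapping_flag)
    return table


# ---------------------------------------------------------------------------
# Gene-length stratification
# ---------------------------------------------------------------------------


def gene_length_strata(genes: GeneSet, labels: Sequence[ContextLabel]) -> dict:
    """Representative-transcript lengths for inserted vs non-inserted genes."""
    inserted_ids = set()
    for l in labels:
        inserted_ids.update(l.gene_ids_overlapped)
    inserted, non_inserted = [], []
    for gene in genes:
        (inserted if gene.gene_id in inserted_ids else non_inserted).append(
            gene.representative.span
        )
    inserted_arr = np.asarray(inserted, dtype=float)
    non_arr = np.asarray(non_inserted, dtype=float)
    return {
        "inserted_lengths": inserted_arr,
        "non_inserted_lengths": non_arr,
        "median_inserted": float(np.median(inserted_arr)) if len(inserted_arr) else None,
        "median_non_inserted": float(np.median(non_arr)) if len(non_arr) else None,
        "n_genes": len(genes),
        "n_inserted": len(inserted_arr),
        "inserted_fraction_pct": percent(len(inserted_arr), len(genes)),
    }


# ---------------------------------------------------------------------------
# Common fragile sites
# ---------------------------------------------------------------------------


def cfs_overlap_summary(
    calls, cfs_intervals: Mapping[str, Sequence[tuple[int, int]]]
) -> dict:
    """Fraction of insertions inside CFSs and fraction of CFSs hit."""
    trees = {
        chrom: IntervalTree.from_tuples(
            (s, e, i) for i, (s, e) in enumerate(ivs)
        )
        for chrom, ivs in cfs_intervals.items()
        if ivs
    }
    n_cfs = sum(len(ivs) for ivs in cfs_intervals.values())
    calls = list(calls)
    n_in = 0
    hit: set[tuple[str, int]] = set()
    for call in calls:
        pos = getattr(call, "final_pos", None) or call.pos
        p0 = pos - 1
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        overlaps = tree[p0]
        if overlaps:
            n_in += 1
            hit.update((call.chrom, iv.data) for iv in overlaps)
    defined = n_cfs > 0 and len(calls) > 0
    return {
        "n_calls": len(calls),
        "n_in_cfs": n_in,
        "frac_in_cfs": percent(n_in, len(calls)) if defined else float("nan"),
        "n_cfs": n_cfs,
        "n_cfs_hit": len(hit),
        "frac_cfs_hit": percent(len(hit), n_cfs) if defined else float("nan"),
        "defined": defined,
    }


# ---------------------------------------------------------------------------
# Recurrence, cancer-gene intersection, exon proximity
# ---------------------------------------------------------------------------


def gene_patient_table(classified, genes: GeneSet) -> pd.DataFrame:
    """Per-gene table of affected-patient counts and insertion classes.

    A patient "affects" a gene when at least one of their insertions
    overlaps the gene's representative transcript; multiple insertions in
    the same gene from one patient count once.
    """
    labels = assign_genomic_context(classified, genes)
    patients: dict[str, set[str]] = {}
    classes: dict[str, set[str]] = {}
    for call, label in zip(classified, labels):
        for gid in label.gene_ids_overlapped:
            patients.setdefault(gid, set()).add(call.patient_id)
            classes.setdefault(gid, set()).add(call.patient_class.value)
    rows = [
        {
            "gene_id": gid,
            "name": genes[gid].name,
            "n_patients": len(pids),
            "patients": ",".join(sorted(pids)),
            "classes": ",".join(sorted(classes[gid])),
        }
        for gid, pids in patients.items()
    ]
    df = pd.DataFrame(
        rows, columns=["gene_id", "name", "n_patients", "patients", "classes"]
    )
    return df.sort_values(
        ["n_patients", "name"], ascending=[False, True]
    ).reset_index(drop=True)


def recurrent_gene_report(
    classified, genes: GeneSet, min_patients: int = 3
) -> pd.DataFrame:
    """Genes affected in at least ``min_patients`` patients."""
    table = gene_patient_table(classified, genes)
    return table[table["n_patients"] >= min_patients].reset_index(drop=True)


def gene_list_intersection(
    affected: pd.DataFrame, external_gene_list: Sequence[str]
) -> pd.DataFrame:
    """Intersect an affected-gene table with an external symbol list.

    Matching is by gene symbol, case-insensitive; the matched external
    spelling is kept as provenance.
    """
    lookup = {sym.lower(): sym for sym in external_gene_list}
    if affected.empty:
        return affected.assign(matched_symbol=pd.Series(dtype=str))
    mask = affected["name"].str.lower().isin(lookup)
    out = affected[mask].copy()
    out["matched_symbol"] = [lookup[n.lower()] for n in out["name"]]
    return out.reset_index(drop=True)


def _exon_distance(p0: int, exons: Sequence[tuple[int, int]]) -> int | None:
    best = None
    for s, e in exons:
        if s <= p0 < e:
            d = 0
        elif p0 < s:
            d = s - p0
        else:
            d = p0 - e + 1
        best = d if best is None else min(best, d)
    return best


def exon_proximity(
    labels: Sequence[ContextLabel], genes: GeneSet, max_dist_bp: int = 100
) -> pd.DataFrame:
    """Intronic insertions within max_dist_bp (inclusive) of an exon boundary."""
    rows = []
    for label in labels:
        if label.label != "intron":
            continue
        p0 = label.pos - 1
        best_gene, best_d = None, None
        for gid in label.gene_ids_overlapped:
            d = _exon_distance(p0, genes[gid].representative.exons)
            if d is not None and (best_d is None or d < best_d):
                best_gene, best_d = gid, d
        if best_d is not None and best_d <= max_dist_bp:
            rows.append(
                {
                    "chrom": label.chrom,
                    "pos": label.pos,
                    "patient_id": label.patient_id,
                    "gene_id": best_gene,
                    "distance_bp": best_d,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "patient_id", "gene_id", "distance_bp"]
    )
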