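"""Readers and writers for the file formats the pipeline touches.

External formats keep their native coordinate conventions (VCF and GFF3
are 1-based; BED is 0-based half-open); conversion to the internal
0-based half-open convention happens here and only here.

MEI call files are valid minimal VCF 4.2 text carrying the insertion
coordinate plus INFO keys ``MEITYPE`` (required), ``SUBFAMILY``, ``TSD``
and ``CILO``/``CIHI``.  They are parsed line-by-line so malformed records
can be reported with their line number and the offending value.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .model import (
    Caller,
    ClassifiedInsertion,
    ClinicalRecord,
    ConsensusInsertion,
    Gene,
    GeneSet,
    PatientClass,
    ProbeRecord,
    RepeatElement,
    RepeatSet,
    TECall,
    TEFamily,
    Tissue,
    Transcript,
)

BETA_EPS = 1e-6  # beta values of exactly 0/1 are clamped before the M transform


class FormatError(ValueError):
    """A file did not conform to its expected format."""


# ---------------------------------------------------------------------------
# VCF-like MEI calls
# ---------------------------------------------------------------------------

_VCF_INFO_HEADER = [
    '##INFO=<ID=MEITYPE,Number=1,Type=String,Description="TE family">',
    '##INFO=<ID=SUBFAMILY,Number=1,Type=String,Description="TE subfamily">',
    '##INFO=<ID=TSD,Number=1,Type=String,Description="Target site duplication sequence">',
    '##INFO=<ID=CILO,Number=1,Type=Integer,Description="Confidence interval lower bound (1-based)">',
    '##INFO=<ID=CIHI,Number=1,Type=Integer,Description="Confidence interval upper bound (1-based)">',
]


def read_mei_calls(
    path, caller: Caller | str, patient_id: str, tissue: Tissue | str
) -> list[TECall]:
    """Read one caller's insertion calls for one sample.

    Raises :class:`FormatError` naming the line number for malformed
    records, and listing the accepted values for unknown TE families.
    """
    caller = Caller(caller)
    tissue = Tissue(tissue)
    sample_id = f"{patient_id}_{tissue.value}"
    calls: list[TECall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated VCF "
                    f"columns, got {len(fields)}"
                )
            chrom, pos_s = fields[0], fields[1]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: POS {pos_s!r} is not an integer"
                ) from None
            info = _parse_info(fields[7], path, lineno)
            if "MEITYPE" not in info:
                raise FormatError(
                    f"{path}: line {lineno}: missing required INFO key MEITYPE"
                )
            fam_s = info["MEITYPE"]
            try:
                family = TEFamily(fam_s)
            except ValueError:
                accepted = ", ".join(f.value for f in TEFamily)
                raise FormatError(
                    f"{path}: line {lineno}: unknown TE family {fam_s!r}; "
                    f"accepted values: {accepted}"
                ) from None
            ci_lo = int(info["CILO"]) if "CILO" in info else None
            ci_hi = int(info["CIHI"]) if "CIHI" in info else None
            try:
                call = TECall(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    tissue=tissue,
                    chrom=chrom,
                    pos=pos,
                    te_family=family,
                    subfamily=info.get("SUBFAMILY"),
                    tsd_sequence=info.get("TSD") or None,
                    caller=caller,
                    ci_lo=ci_lo,
                    ci_hi=ci_hi,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            calls.append(call)
    return calls


def _parse_info(info_field: str, path, lineno: int) -> dict[str, str]:
    info: dict[str, str] = {}
    if info_field in (".", ""):
        return info
    for item in info_field.split(";"):
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            info[key] = value
        else:
            info[item] = ""
    return info


def write_mei_calls(calls: list[TECall], path, contigs: dict[str, int]) -> None:
    """Write calls as minimal VCF 4.2 (REF/ALT are symbolic placeholders)."""
    lines = ["##fileformat=VCFv4.2"]
    for name in sorted(contigs):
        lines.append(f"##contig=<ID={name},length={contigs[name]}>")
    lines.extend(_VCF_INFO_HEADER)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.te_family.value)):
        info = [f"MEITYPE={call.te_family.value}"]
        if call.subfamily:
            info.append(f"SUBFAMILY={call.subfamily}")
        if call.tsd_sequence:
            info.append(f"TSD={call.tsd_sequence}")
        if call.ci_lo is not None:
            info.append(f"CILO={call.ci_lo};CIHI={call.ci_hi}")
        alt = f"<INS:ME:{call.te_family.value}>"
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\tN\t{alt}\t.\tPASS\t" + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gene_models(path) -> GeneSet:
    """Load a gene/mRNA/exon(/CDS) GFF3 hierarchy.

    GFF3 1-based closed intervals are converted to 0-based half-open.
    Exons or CDS without a resolvable parent transcript raise
    :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    transcript_ids: set[str] = set()
    transcripts_by_id: dict[str, Transcript] = {}
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        gene = Gene(
            gene_id=g.id,
            name=g.attributes.get("Name", [g.id])[0],
            chrom=g.seqid,
            strand=g.strand,
        )
        for t in db.children(g, featuretype=("mRNA", "transcript"), level=1):
            tr = Transcript(
                transcript_id=t.id, start=t.start - 1, end=t.end, exons=[], cds=[]
            )
            transcript_ids.add(t.id)
            transcripts_by_id[t.id] = tr
            gene.transcripts.append(tr)
        if not gene.transcripts:
            raise FormatError(f"{path}: gene {g.id} has no transcripts")
        genes.append(gene)
    for feat_type, attr in (("exon", "exons"), ("CDS", "cds")):
        for f in db.features_of_type(feat_type):
            parents = f.attributes.get("Parent", [])
            hit = [p for p in parents if p in transcript_ids]
            if not hit:
                raise FormatError(
                    f"{path}: orphan {feat_type} at {f.seqid}:{f.start}-{f.end} "
                    f"(Parent={parents or 'missing'})"
                )
            for p in hit:
                getattr(transcripts_by_id[p], attr).append((f.start - 1, f.end))
    for tr in transcripts_by_id.values():
        tr.exons.sort()
        tr.cds.sort()
    return GeneSet(genes)


def write_gene_models(genes: GeneSet, path) -> None:
    lines = ["##gff-version 3"]
    for gene in genes:
        g_start = min(t.start for t in gene.transcripts)
        g_end = max(t.end for t in gene.transcripts)
        lines.append(
            f"{gene.chrom}\tretroscope\tgene\t{g_start + 1}\t{g_end}\t.\t"
            f"{gene.strand}\t.\tID={gene.gene_id};Name={gene.name}"
        )
        for tr in gene.transcripts:
            lines.append(
                f"{gene.chrom}\tretroscope\tmRNA\t{tr.start + 1}\t{tr.end}\t.\t"
                f"{gene.strand}\t.\tID={tr.transcript_id};Parent={gene.gene_id}"
            )
            for i, (s, e) in enumerate(tr.exons, 1):
                lines.append(
                    f"{gene.chrom}\tretroscope\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\tID={tr.transcript_id}.exon{i};"
                    f"Parent={tr.transcript_id}"
                )
            for i, (s, e) in enumerate(tr.cds, 1):
                lines.append(
                    f"{gene.chrom}\tretroscope\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t0\tID={tr.transcript_id}.cds{i};"
                    f"Parent={tr.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Repeat annotation, BED intervals, catalogs
# ---------------------------------------------------------------------------


def read_repeats(path) -> RepeatSet:
    """Read a RepeatMasker-style table: chrom, start, end, strand, subfamily."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "strand", "subfamily"],
        dtype={"chrom": str, "subfamily": str},
    )
    elements = []
    for row in df.itertuples(index=False):
        try:
            elements.append(
                RepeatElement(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    subfamily=row.subfamily,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return RepeatSet(elements)


def write_repeats(repeats: RepeatSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tsubfamily\n")
        for el in sorted(repeats, key=lambda e: (e.chrom, e.start, e.subfamily)):
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\t{el.strand}\t{el.subfamily}\n")


def read_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3+ rows into 0-based half-open intervals keyed by chromosome."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: BED requires >= 3 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer interval bounds"
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            intervals.setdefault(fields[0], []).append((start, end))
    for ivs in intervals.values():
        ivs.sort()
    return intervals


def write_intervals(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_catalog(path) -> pd.DataFrame:
    """Read a polymorphic-insertion catalog (BED4: name = family[:subfamily]).

    Returns a frame with 1-based point positions (the BED start converted),
    ready for distance comparison against call coordinates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: catalog BED requires 4 columns"
                )
            try:
                start = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer start"
                ) from None
            name = fields[3]
            fam_s, _, sub = name.partition(":")
            try:
                family = TEFamily(fam_s)
            except ValueError:
                accepted = ", ".join(f.value for f in TEFamily)
                raise FormatError(
                    f"{path}: line {lineno}: unknown TE family {fam_s!r}; "
                    f"accepted values: {accepted}"
                ) from None
            rows.append((fields[0], start + 1, family.value, sub or None))
    return pd.DataFrame(rows, columns=["chrom", "pos", "family", "subfamily"])


def write_catalog(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df.sort_values(["chrom", "pos"]).itertuples(index=False):
            name = row.family if not row.subfamily else f"{row.family}:{row.subfamily}"
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{name}\n")


# ---------------------------------------------------------------------------
# Methylation matrices and clinical tables
# ---------------------------------------------------------------------------


def clamp_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Clamp beta values into (0, 1); log2(b/(1-b)) is undefined at 0 and 1."""
    if (beta.values < 0).any() or (beta.values > 1).any():
        raise FormatError("beta values outside [0, 1]")
    return beta.clip(lower=BETA_EPS, upper=1 - BETA_EPS)


def read_beta_and_manifest(beta_csv, manifest_csv):
    """Read the probe x sample beta matrix and its probe manifest.

    Every probe row in the beta matrix must appear in the manifest;
    missing probes are reported by id.  Returns ``(beta, probes)`` with
    beta clamped into the open unit interval.
    """
    beta = pd.read_csv(beta_csv, index_col=0)
    if beta.index.duplicated().any():
        dupes = sorted(beta.index[beta.index.duplicated()].unique())
        raise FormatError(f"{beta_csv}: duplicated probe ids: {dupes}")
    manifest = pd.read_csv(manifest_csv, dtype={"probe_id": str, "chrom": str})
    if manifest["probe_id"].duplicated().any():
        dupes = sorted(manifest.loc[manifest["probe_id"].duplicated(), "probe_id"])
        raise FormatError(f"{manifest_csv}: duplicated probe ids: {dupes}")
    missing = sorted(set(beta.index) - set(manifest["probe_id"]))
    if missing:
        raise FormatError(
            f"{beta_csv}: probes absent from manifest: {missing[:20]}"
            + (" ..." if len(missing) > 20 else "")
        )
    probes = []
    for row in manifest.itertuples(index=False):
        regions = ()
        raw = getattr(row, "regions", None)
        if isinstance(raw, str) and raw:
            regions = tuple(raw.split(";"))
        probes.append(
            ProbeRecord(
                probe_id=row.probe_id,
                chrom=row.chrom,
                pos=int(row.pos),
                region_annotations=regions,
            )
        )
    return clamp_beta(beta), probes


def write_beta_and_manifest(beta: pd.DataFrame, probes: list[ProbeRecord], beta_csv, manifest_csv) -> None:
    beta.to_csv(beta_csv, index_label="probe_id")
    rows = [
        {
            "probe_id": p.probe_id,
            "chrom": p.chrom,
            "pos": p.pos,
            "regions": ";".join(p.region_annotations),
        }
        for p in probes
    ]
    pd.DataFrame(rows).to_csv(manifest_csv, index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(
                ClinicalRecord(
                    patient_id=row.patient_id,
                    efs_time=float(row.efs_time),
                    event=int(row.event),
                    age_dx=float(row.age_dx),
                    disease_status_dx=row.disease_status_dx,
                    primary_site=row.primary_site,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return records


def write_clinical(records: list[ClinicalRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "efs_time": r.efs_time,
                "event": r.event,
                "age_dx": r.age_dx,
                "disease_status_dx": r.disease_status_dx,
                "primary_site": r.primary_site,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Call tables (stage outputs) and reports
# ---------------------------------------------------------------------------

_CONSENSUS_COLS = [
    "patient_id",
    "sample_id",
    "tissue",
    "chrom",
    "final_pos",
    "te_family",
    "subfamily",
    "tsd_sequence",
    "primary_pos",
    "secondary_pos",
]


def consensus_to_frame(calls: list[ConsensusInsertion]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "sample_id": c.sample_id,
            "tissue": c.tissue.value,
            "chrom": c.chrom,
            "final_pos": c.final_pos,
            "te_family": c.te_family.value,
            "subfamily": c.subfamily or "",
            "tsd_sequence": c.tsd_sequence or "",
            "primary_pos": c.primary_pos,
            "secondary_pos": c.secondary_pos,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=_CONSENSUS_COLS)
    return df.sort_values(
        ["patient_id", "tissue", "chrom", "final_pos", "te_family"]
    ).reset_index(drop=True)


def frame_to_consensus(df: pd.DataFrame) -> list[ConsensusInsertion]:
    return [
        ConsensusInsertion(
            patient_id=row.patient_id,
            sample_id=row.sample_id,
            tissue=Tissue(row.tissue),
            chrom=row.chrom,
            final_pos=int(row.final_pos),
            te_family=TEFamily(row.te_family),
            subfamily=row.subfamily or None,
            tsd_sequence=row.tsd_sequence or None,
            primary_pos=int(row.primary_pos),
            secondary_pos=int(row.secondary_pos),
        )
        for row in df.fillna({"subfamily": "", "tsd_sequence": ""}).itertuples(
            index=False
        )
    ]


def classified_to_frame(calls: list[ClassifiedInsertion]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "chrom": c.chrom,
            "final_pos": c.final_pos,
            "te_family": c.te_family.value,
            "subfamily": c.subfamily or "",
            "tsd_sequence": c.tsd_sequence or "",
            "patient_class": c.patient_class.value,
            "patient_specific": c.patient_specific,
            "partner_pos": c.partner_pos if c.partner_pos is not None else "",
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "chrom",
            "final_pos",
            "te_family",
            "subfamily",
            "tsd_sequence",
            "patient_class",
            "patient_specific",
            "partner_pos",
        ],
    )
    return df.sort_values(
        ["patient_id", "chrom", "final_pos", "patient_class"]
    ).reset_index(drop=True)


def frame_to_classified(df: pd.DataFrame) -> list[ClassifiedInsertion]:
    out = []
    for row in df.fillna({"subfamily": "", "tsd_sequence": "", "partner_pos": ""}).itertuples(
        index=False
    ):
        partner = row.partner_pos
        out.append(
            ClassifiedInsertion(
                patient_id=row.patient_id,
                chrom=row.chrom,
                final_pos=int(row.final_pos),
                te_family=TEFamily(row.te_family),
                subfamily=row.subfamily or None,
                tsd_sequence=row.tsd_sequence or None,
                patient_class=PatientClass(row.patient_class),
                patient_specific=bool(row.patient_specific),
                partner_pos=int(partner) if partner not in ("", None) else None,
            )
        )
    return out


def write_report(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each table as <name>.tsv; deterministic over insertion order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
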