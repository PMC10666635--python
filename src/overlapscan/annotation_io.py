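"""Reading and writing genome annotations and gene-pair tables.

Coordinates are 1-based inclusive throughout (the GFF3 convention); records
are normalized into the internal ``start < stop`` format of
:class:`~overlapscan.pair_analysis.GeneRecord` on the way in.

Formats
-------
* GFF3 (read): CDS features become protein-coding records; stable-RNA
  feature types (tRNA, rRNA, …) become records with
  ``is_protein_coding=False``; container features (gene, mRNA, exon,
  region, …) are skipped.  Multi-segment (joined) CDS are rejected —
  prokaryotic annotations are single-span.
* TSV gene table (read/write): tab-separated with a header row, columns
  ``replicon  start  stop  strand  locus_tag  gene_name  cog_id  attributes``;
  "." marks a missing optional field; strand is "+"/"-".  Curation flags
  (``truncated_start``, ``truncated_stop``, ``transposase_internal``) live in
  the free-form ``attributes`` column as ``key=value`` tokens separated by
  ";"; absent keys default to false.
* TSV pair table (write/read) and FASTA (read, for boundary-motif checks).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from gffutils.iterators import DataIterator

from .pair_analysis import GenePair, GeneRecord

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "write_pairs_table",
    "read_pairs_table",
    "read_fasta",
]

MISSING = "."

#: GFF3 feature types mapped to non-protein-coding gene records.
STABLE_RNA_TYPES = frozenset(
    {"tRNA", "rRNA", "ncRNA", "tmRNA", "SRP_RNA", "RNase_P_RNA", "antisense_RNA", "misc_RNA"}
)
#: GFF3 container/structural feature types that never become records.
_SKIPPED_TYPES = frozenset(
    {"gene", "mRNA", "exon", "region", "sequence_feature", "repeat_region",
     "pseudogene", "operon", "origin_of_replication", "transcript"}
)

_FLAG_KEYS = ("truncated_start", "truncated_stop", "transposase_internal")
_TRUE_TOKENS = {"true", "1", "yes"}

GENE_TABLE_COLUMNS = [
    "replicon", "start", "stop", "strand", "locus_tag", "gene_name", "cog_id", "attributes",
]
PAIR_TABLE_COLUMNS = [
    "replicon", "first_locus", "second_locus", "upstream_locus", "downstream_locus",
    "upstream_name", "downstream_name", "orientation", "distance", "phase", "anomalous_overlap",
]


class AnnotationParseError(ValueError):
    """Malformed annotation input; message names the offending line."""


class UnsupportedFeatureError(ValueError):
    """Feature shape the internal format cannot represent (e.g. joined CDS)."""


def _parse_flags(attr_text: str) -> dict[str, bool]:
    flags = dict.fromkeys(_FLAG_KEYS, False)
    if not attr_text or attr_text == MISSING:
        return flags
    for token in attr_text.split(";"):
        token = token.strip()
        if not token or "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key in _FLAG_KEYS:
            flags[key] = value.strip().lower() in _TRUE_TOKENS
    return flags


def _first_attr(feature, *keys: str) -> str | None:
    for key in keys:
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return None


def _read_gff3(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    cds_ids: set[str] = set()
    for feature in DataIterator(str(path)):
        ftype = feature.featuretype
        if ftype in _SKIPPED_TYPES:
            continue
        coding = ftype == "CDS"
        if not coding and ftype not in STABLE_RNA_TYPES:
            continue
        if coding:
            fid = _first_attr(feature, "ID")
            if fid is not None:
                if fid in cds_ids:
                    raise UnsupportedFeatureError(
                        f"{path}: multi-segment (joined) CDS {fid!r} is not supported"
                    )
                cds_ids.add(fid)
        locus = _first_attr(feature, "locus_tag", "ID", "Name")
        if locus is None:
            locus = f"{feature.seqid}:{feature.start}-{feature.end}"
        attr_flags = {
            key: (feature.attributes.get(key, ["false"])[0].lower() in _TRUE_TOKENS)
            for key in _FLAG_KEYS
        }
        if feature.start >= feature.end:
            raise AnnotationParseError(
                f"{path}: feature {locus!r} has start >= stop after normalization "
                f"({feature.start} >= {feature.end})"
            )
        records.append(
            GeneRecord(
                replicon_id=feature.seqid,
                start=int(feature.start),
                stop=int(feature.end),
                strand=feature.strand if feature.strand in ("+", "-") else "+",
                locus_tag=locus,
                gene_name=_first_attr(feature, "gene", "Name"),
                cog_id=_first_attr(feature, "cog_id", "COG"),
                is_protein_coding=coding,
                **attr_flags,
            )
        )
    return records


def _read_tsv(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AnnotationParseError(f"{path}: empty gene table") from None
        required = GENE_TABLE_COLUMNS[:5]
        if header[: len(required)] != required:
            raise AnnotationParseError(
                f"{path}, line 1: expected columns {required}, got {header[:len(required)]}"
            )
        col = {name: i for i, name in enumerate(header)}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(required):
                raise AnnotationParseError(
                    f"{path}, line {lineno}: expected at least {len(required)} fields, got {len(row)}"
                )

            def cell(name: str) -> str | None:
                idx = col.get(name)
                if idx is None or idx >= len(row):
                    return None
                value = row[idx].strip()
                return None if value in ("", MISSING) else value

            try:
                start = int(row[col["start"]])
                stop = int(row[col["stop"]])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}, line {lineno}: non-integer coordinate ({exc})"
                ) from None
            strand = row[col["strand"]].strip()
            flags = _parse_flags(cell("attributes") or "")
            coding_text = cell("is_protein_coding")
            try:
                records.append(
                    GeneRecord(
                        replicon_id=row[col["replicon"]].strip(),
                        start=start,
                        stop=stop,
                        strand=strand,  # type: ignore[arg-type]
                        locus_tag=row[col["locus_tag"]].strip(),
                        gene_name=cell("gene_name"),
                        cog_id=cell("cog_id"),
                        is_protein_coding=(
                            True if coding_text is None else coding_text.lower() in _TRUE_TOKENS
                        ),
                        **flags,
                    )
                )
            except ValueError as exc:
                raise AnnotationParseError(f"{path}, line {lineno}: {exc}") from None
    return records


def read_gene_table(path: str | Path, format: Literal["gff3", "tsv"] = "tsv") -> list[GeneRecord]:
    """Read an annotation into the internal coordinate format.

    Every returned record satisfies ``start < stop``; 1-based inclusive
    coordinates are preserved unchanged from the input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        return _read_gff3(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _attributes_text(record: GeneRecord) -> str:
    tokens = [f"{key}=true" for key in _FLAG_KEYS if getattr(record, key)]
    return ";".join(tokens) if tokens else MISSING


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records as a TSV gene table (round-trips via :func:`read_gene_table`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "replicon": r.replicon_id,
                "start": r.start,
                "stop": r.stop,
                "strand": r.strand,
                "locus_tag": r.locus_tag,
                "gene_name": r.gene_name or MISSING,
                "cog_id": r.cog_id or MISSING,
                "is_protein_coding": "true" if r.is_protein_coding else "false",
                "attributes": _attributes_text(r),
            }
        )
    columns = GENE_TABLE_COLUMNS[:7] + ["is_protein_coding", "attributes"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_pairs_table(pairs: Iterable[GenePair], path: str | Path) -> None:
    """Write one TSV row per pair, in replicon-then-coordinate order.

    Serial pairs carry distance, phase and transcription-order loci; for
    convergent/divergent pairs those columns hold ".".  Overlaps deeper than
    60 nt are flagged in ``anomalous_overlap`` (likely misannotations) but
    never dropped.
    """
    ordered = sorted(pairs, key=lambda p: (p.replicon_id, p.first.start, p.first.stop))
    rows = []
    for p in ordered:
        rows.append(
            {
                "replicon": p.replicon_id,
                "first_locus": p.first.locus_tag,
                "second_locus": p.second.locus_tag,
                "upstream_locus": p.upstream_locus or MISSING,
                "downstream_locus": p.downstream_locus or MISSING,
                "upstream_name": (p.upstream.gene_name or MISSING) if p.orientation == "serial" else MISSING,
                "downstream_name": (p.downstream.gene_name or MISSING) if p.orientation == "serial" else MISSING,
                "orientation": p.orientation or MISSING,
                "distance": p.distance if p.distance is not None else MISSING,
                "phase": p.phase if p.phase is not None else MISSING,
                "anomalous_overlap": "true" if p.anomalous_overlap else "false",
            }
        )
    pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    """Read a pair table written by :func:`write_pairs_table`.

    Returns a DataFrame with ``distance``/``phase`` as nullable integers and
    "." decoded to missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace(MISSING, pd.NA)
    for column in ("distance", "phase"):
        if column in df.columns:
            df[column] = pd.to_numeric(df[column], errors="raise").astype("Int64")
    if "anomalous_overlap" in df.columns:
        df["anomalous_overlap"] = df["anomalous_overlap"] == "true"
    if "complex_flag" in df.columns:
        df["complex_flag"] = df["complex_flag"].map(
            lambda v: v if v is pd.NA else v.lower() in _TRUE_TOKENS
        )
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read replicon sequences keyed by sequence id (must match replicon ids)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
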