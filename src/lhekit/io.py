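"""Readers and writers for the standard formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tabular data through pandas. All genomic
intervals are written 0-based half-open (BED convention); mismatch labels
use the ASCII grammar of :mod:`lhekit.sites`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .offtarget import OfftargetHit
from .readout import AmpliconRef
from .sites import TargetSite
from .specificity import SpecificityProfile

__all__ = [
    "ParseError",
    "read_amplicon_locus",
    "read_fasta",
    "read_fastq",
    "read_profile_tsv",
    "read_sites_tsv",
    "write_bed",
    "write_fasta",
    "write_fastq",
    "write_hits_tsv",
    "write_profile_tsv",
    "write_sites_tsv",
    "write_summary_json",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending record."""


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: sequence}; empty files are an explicit error."""
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """FASTQ -> [(read_id, sequence)]; truncated records raise a ParseError
    naming the offending read."""
    out = []
    last = "<start of file>"
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append((rec.id, str(rec.seq).upper()))
            last = rec.id
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTQ after read {last!r}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: no FASTQ records found")
    return out


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write reads with uniform placeholder qualities (synthetic data has
    no meaningful per-base quality)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_sites_tsv(path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "sequence"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: site TSV needs columns {sorted(required)}")
    return [
        TargetSite(
            name=row["name"],
            sequence=row["sequence"],
            description=str(row.get("description", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def write_sites_tsv(sites: list[TargetSite], path) -> None:
    pd.DataFrame(
        [
            {"name": s.name, "sequence": s.sequence, "description": s.description}
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(
    path, site: TargetSite, enzyme: str = "", theta: float = 0.5
) -> SpecificityProfile:
    """Profile TSV (position_label, alt_base, r[, se, n]) -> profile."""
    df = pd.read_csv(path, sep="\t")
    required = {"position_label", "alt_base", "r"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: profile TSV needs columns {sorted(required)}")
    r, se, n = {}, {}, {}
    for i, row in df.iterrows():
        try:
            label = int(str(row["position_label"]).replace("−", "-"))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 2}: bad position label") from exc
        cell = (label, str(row["alt_base"]).upper())
        r[cell] = float(row["r"])
        if "se" in df.columns and pd.notna(row["se"]):
            se[cell] = float(row["se"])
        if "n" in df.columns and pd.notna(row["n"]) and int(row["n"]) > 0:
            n[cell] = int(row["n"])
    return SpecificityProfile(
        enzyme=enzyme, site=site, r=r, theta=theta, se=se, n=n
    )


def write_profile_tsv(profile: SpecificityProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_bed(hits: list[OfftargetHit], path) -> None:
    """BED6: chrom, start, end, name = mismatch label, score = n mismatches,
    strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.name}\t{h.n_mismatches}\t{h.strand}\n"
            )


def write_hits_tsv(hits: list[OfftargetHit], path) -> None:
    rows = [
        {
            "chrom": h.chrom,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "site_sequence": h.site_sequence,
            "mismatches": h.name,
            "n_mismatches": h.n_mismatches,
            "prediction": h.prediction,
            "per_mismatch_r": ",".join(f"{r:.4f}" for r in (h.per_mismatch_r or ())),
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "site_sequence",
            "mismatches", "n_mismatches", "prediction", "per_mismatch_r",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_amplicon_locus(fasta_path, locus_json_path) -> AmpliconRef:
    """Reference FASTA plus a JSON locus descriptor -> AmpliconRef.

    The JSON carries site_span, optional cut_window, and optional
    donor_signature as [[index, base], ...].
    """
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ParseError(f"{fasta_path}: expected exactly one reference record")
    with open(locus_json_path) as fh:
        locus = json.load(fh)
    return AmpliconRef(
        sequence=next(iter(seqs.values())),
        site_span=tuple(locus["site_span"]),
        cut_window=tuple(locus["cut_window"]) if "cut_window" in locus else None,
        donor_signature=tuple(
            (int(i), str(b).upper()) for i, b in locus.get("donor_signature", [])
        ),
    )


def write_summary_json(obj, path) -> None:
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
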