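"""File formats: FASTA/FASTQ, BED12, GFF3, PSL and the TSV reports.

Coordinates are converted at these boundaries only: BED is 0-based
half-open like the internal model, GFF3 is 1-based inclusive, PSL is
0-based half-open with minus-strand query starts in the
reverse-complemented frame (the internal convention matches PSL).
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clones import SangerRead
from .core import Block, GenomeAlignment, GenomeInterval
from .reads import ShortRead


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[ShortRead]:
    return [
        ShortRead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(path, reads: list[ShortRead]) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# BED12


def write_bed12(path, rows: list[tuple[str, str, str, list[GenomeInterval]]]) -> None:
    """rows: (name, chrom, strand, exon intervals in genomic order)."""
    with open(path, "w") as fh:
        for name, chrom, strand, exons in rows:
            start = exons[0].start
            end = exons[-1].end
            sizes = ",".join(str(len(e)) for e in exons) + ","
            starts = ",".join(str(e.start - start) for e in exons) + ","
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}"
                f"\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path) -> list[tuple[str, str, str, list[GenomeInterval]]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 needs 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomeInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offs, sizes)
            ]
            out.append((name, chrom, strand, exons))
    return out


# ---------------------------------------------------------------------------
# GFF3 (gene models written by the simulator; CDS features read back)


def write_gff3(path, genes) -> None:
    """genes: iterable of CloneTruth-like records (clone_id, chrom,
    strand, exon_chain, plus cds genomic intervals via ``cds_genomic``
    attribute or provided tuples)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = g.exon_chain[0].start + 1
            end = g.exon_chain[-1].end
            gid = g.clone_id
            fh.write(
                f"{g.chrom}\t.\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID=gene:{gid}\n"
            )
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID=mrna:{gid};Parent=gene:{gid}\n"
            )
            for e in g.exon_chain:
                fh.write(
                    f"{g.chrom}\t.\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                    f"Parent=mrna:{gid}\n"
                )
            for c in getattr(g, "cds_genomic", lambda: [])():
                fh.write(
                    f"{g.chrom}\t.\tCDS\t{c.start + 1}\t{c.end}\t.\t{g.strand}\t0\t"
                    f"ID=cds:{gid};Parent=mrna:{gid}\n"
                )


def read_cds_gff3(path) -> dict[str, list[GenomeInterval]]:
    """CDS exon intervals per transcript, keyed by the parent mRNA id
    stripped of its ``mrna:`` prefix."""
    out: dict[str, list[GenomeInterval]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 needs 9 columns")
            if f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            parent = attrs.get("Parent", attrs.get("ID", f"line{ln}"))
            key = parent.split(":", 1)[-1]
            out.setdefault(key, []).append(
                GenomeInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    for exons in out.values():
        exons.sort(key=lambda e: e.start)
    return out


# ---------------------------------------------------------------------------
# PSL

_PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        \t"
    "Q   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     \t"
    "size\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    + "-" * 159 + "\n"
)


def write_psl(path, alignments: list[GenomeAlignment], t_sizes: dict[str, int],
              header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(_PSL_HEADER)
        for a in alignments:
            q_num = t_num = 0
            q_bases = a.insertions
            t_bases = a.deletions
            for x, y in zip(a.blocks, a.blocks[1:]):
                if y.q_start > x.q_end:
                    q_num += 1
                if y.t.start > x.t.end:
                    t_num += 1
            qlen = a.query_len
            if a.strand == "+":
                q_start, q_end = a.q_start, a.q_end
            else:
                q_start, q_end = qlen - a.q_end, qlen - a.q_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.matches, a.mismatches, 0, 0,
                        q_num, q_bases, t_num, t_bases,
                        a.strand, a.query_id, qlen, q_start, q_end,
                        a.chrom, t_sizes.get(a.chrom, 0), a.t_start, a.t_end,
                        len(a.blocks),
                        ",".join(str(len(b)) for b in a.blocks) + ",",
                        ",".join(str(b.q_start) for b in a.blocks) + ",",
                        ",".join(str(b.t.start) for b in a.blocks) + ",",
                    )
                )
                + "\n"
            )


def import_psl(path) -> list[GenomeAlignment]:
    """Parse PSL (with or without the 5-line header) into alignments.

    Blocks, counts and strand map losslessly; repeat matches fold into
    the match count.  Malformed lines raise with their line number.
    """
    out: list[GenomeAlignment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.rstrip("\n")
            if not s.strip():
                continue
            first = s.split("\t")[0].strip()
            if not first or not first[0].isdigit():
                continue  # header lines
            if set(s.strip()) == {"-"}:
                continue
            f = s.split("\t")
            if len(f) < 21:
                raise ValueError(f"{path}:{ln}: PSL needs 21 columns, got {len(f)}")
            try:
                matches, mism, rep = int(f[0]), int(f[1]), int(f[2])
                q_num, q_bases = int(f[4]), int(f[5])
                t_num, t_bases = int(f[6]), int(f[7])
                strand = f[8]
                qname, qlen = f[9], int(f[10])
                tname = f[13]
                sizes = [int(x) for x in f[18].rstrip(",").split(",")]
                q_starts = [int(x) for x in f[19].rstrip(",").split(",")]
                t_starts = [int(x) for x in f[20].rstrip(",").split(",")]
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}:{ln}: malformed PSL line: {e}") from None
            total = matches + mism + rep
            blocks = []
            assigned = 0
            for sz, qs, ts in zip(sizes, q_starts, t_starts):
                m = min(sz, max(0, matches + rep - assigned))
                blocks.append(
                    Block(qs, qs + sz, GenomeInterval(tname, ts, ts + sz, "+"),
                          matches=m, mismatches=sz - m)
                )
                assigned += sz
            if sum(sizes) != total:
                raise ValueError(
                    f"{path}:{ln}: block sizes disagree with match counts"
                )
            out.append(
                GenomeAlignment(
                    query_id=qname,
                    query_len=qlen,
                    strand=strand,
                    blocks=blocks,
                    matches=matches + rep,
                    mismatches=mism,
                    insertions=q_bases,
                    deletions=t_bases,
                    gap_openings=q_num + t_num,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV helpers


def read_clone_map(path) -> dict[str, tuple[str, str]]:
    """read_id -> (clone_id, end) from a 3-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"read_id", "clone_id", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"clone map needs columns {sorted(need)}")
    return {r.read_id: (r.clone_id, r.end) for r in df.itertuples()}


def write_clone_map(path, sanger: list[SangerRead]) -> None:
    pd.DataFrame(
        [{"read_id": r.id, "clone_id": r.clone_id, "end": r.end} for r in sanger]
    ).to_csv(path, sep="\t", index=False)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "write_bed12", "read_bed12", "write_gff3", "read_cds_gff3",
    "write_psl", "import_psl", "read_clone_map", "write_clone_map",
    "write_table",
]
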