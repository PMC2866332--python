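"""End-to-end orchestration: anchor, merge, close gaps, assign clones,
and evaluate against finished reference sequences.

Stage statistics mirror the classic assembly report: contig count and
N50 after each stage, with the count non-increasing through merging and
gap closing on well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aligner import Genome, align_contig_spliced, best_hit
from .anchoring import AnchoredContig, AnchoringReport, anchor_contigs, merge_overlapping
from .clones import CloneAssembly, SangerRead, assign_clones
from .core import GenomeInterval, Params, n50
from .evaluate import (
    CONSISTENT,
    BaseAccuracy,
    CdsStructure,
    ConsistencyResult,
    base_accuracy,
    classify_consistency,
    clone_coverages,
    coverage_bins,
    map_transcript_range,
)
from .gapfill import GapOutcome, close_exon_gaps, close_intron_gaps
from .readstore import ReadStore
from .reads import ShortRead, preprocess_reads, revcomp


@dataclass
class StageRow:
    stage: str
    n_contigs: int
    n50: int


@dataclass
class AssemblyResult:
    assemblies: list[CloneAssembly]
    contigs: list[AnchoredContig]
    unassigned: list[AnchoredContig]
    stages: list[StageRow]
    anchoring: AnchoringReport
    gap_outcomes: list[GapOutcome]
    filter_report: object

    def stage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s.stage, "n_contigs": s.n_contigs, "n50_bp": s.n50} for s in self.stages]
        )


def _n50_of(contigs: list[AnchoredContig]) -> int:
    lens = [len(c) for c in contigs]
    return n50(lens) if lens else 0


def run_assemble(
    genome: Genome,
    contigs: list[tuple[str, str]],
    reads: list[ShortRead],
    sanger: list[SangerRead],
    params: Params | None = None,
) -> AssemblyResult:
    """The full hybrid assembly: de novo contigs in, clone sequences out."""
    params = params or Params()
    qc_reads, filter_report = preprocess_reads(reads)
    store = ReadStore(qc_reads)
    stages: list[StageRow] = []
    lens = [len(s) for _, s in contigs]
    stages.append(StageRow("de novo contigs", len(contigs), n50(lens) if lens else 0))

    anchored, anch_report = anchor_contigs(contigs, genome, params)
    merged = merge_overlapping(anchored)
    stages.append(StageRow("After merging overlapping contigs", len(merged), _n50_of(merged)))

    exon_closed, exon_outcomes = close_exon_gaps(merged, store, genome, params)
    stages.append(StageRow("After exon gaps are closed", len(exon_closed), _n50_of(exon_closed)))

    intron_closed, intron_outcomes = close_intron_gaps(exon_closed, store, genome, params)
    stages.append(
        StageRow("After intron gaps are closed", len(intron_closed), _n50_of(intron_closed))
    )

    assemblies, unassigned = assign_clones(intron_closed, sanger, params)
    associated = [c for c in intron_closed if c.id not in {u.id for u in unassigned}]
    stages.append(
        StageRow("After association with clones", len(associated), _n50_of(associated))
    )
    return AssemblyResult(
        assemblies=assemblies,
        contigs=intron_closed,
        unassigned=unassigned,
        stages=stages,
        anchoring=anch_report,
        gap_outcomes=exon_outcomes + intron_outcomes,
        filter_report=filter_report,
    )


def gap_table(outcomes: list[GapOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": o.candidate.kind,
                "chrom": o.candidate.interval.chrom,
                "start": o.candidate.interval.start,
                "end": o.candidate.interval.end,
                "length": len(o.candidate.interval),
                "filled": o.filled,
                "n_alignments": o.n_alignments,
                "min_coverage": o.min_coverage,
                "mean_coverage": round(o.mean_coverage, 2),
                "junction": (
                    f"{o.junction.donor_end}-{o.junction.acceptor_start}"
                    if o.junction else ""
                ),
            }
            for o in outcomes
        ]
    )


# ---------------------------------------------------------------------------
# evaluation harness


def reference_structures(
    reference_seqs: dict[str, str],
    cds_ranges: dict[str, tuple[int, int]],
    genome: Genome,
    params: Params | None = None,
) -> dict[str, CdsStructure]:
    """Derive the reference CDS structure by aligning each finished
    reference sequence to the genome — the same route the outputs take,
    so junction registers in microhomologies cancel out."""
    params = params or Params()
    out: dict[str, CdsStructure] = {}
    for cid, seq in reference_seqs.items():
        if cid not in cds_ranges:
            continue
        hit = best_hit(align_contig_spliced(seq, genome, params, query_id=cid))
        if hit is None:
            continue
        cs, ce = cds_ranges[cid]
        exons = map_transcript_range(hit, cs, ce)
        if exons:
            out[cid] = CdsStructure(cid, exons)
    return out


def reconstructed_chains(
    asm: CloneAssembly,
    contigs_by_id: dict[str, AnchoredContig],
    genome: Genome,
    params: Params,
) -> list[list[GenomeInterval]]:
    """Exon chains of a clone's reconstruction, by genome alignment of
    the output sequence (keeping the evaluator independent of the
    assembler's bookkeeping).  An unlinked secondary contig contributes
    a second chain."""
    chains: list[list[GenomeInterval]] = []
    seqs = [asm.sequence]
    if asm.secondary_contig_id and asm.secondary_contig_id in contigs_by_id:
        seqs.append(contigs_by_id[asm.secondary_contig_id].transcript_sequence())
    for seq in seqs:
        hit = best_hit(
            align_contig_spliced(seq, genome, params, query_id=asm.clone_id)
        )
        if hit is None:
            continue
        exons = map_transcript_range(hit, 0, hit.query_len)
        if exons:
            chains.append(exons)
    return chains


@dataclass
class EvalResult:
    per_clone: pd.DataFrame
    n_reference: int = 0
    n_amplified: int = 0
    n_with_cds: int = 0
    n_consistent: int = 0
    accuracy: BaseAccuracy | None = None
    cds_accuracy: BaseAccuracy | None = None

    @property
    def pct_consistent(self) -> float:
        return 100.0 * self.n_consistent / self.n_with_cds if self.n_with_cds else 0.0

    def summary_table(self) -> pd.DataFrame:
        rows = [
            ("Reference full-length cDNA clones (A)", self.n_reference),
            ("Reference clones amplified by PCR (B)", self.n_amplified),
            ("Clones with CDS annotation (C)", self.n_with_cds),
            ("Clones with consistent CDS structure (D)", self.n_consistent),
            ("Clones with inconsistent CDS structure (E)",
             self.n_with_cds - self.n_consistent),
            ("% consistent (D/C)", round(self.pct_consistent, 1)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def _oriented_accuracy(output_seq: str, ref_seq: str) -> BaseAccuracy:
    fwd = base_accuracy(output_seq, ref_seq)
    rev = base_accuracy(revcomp(output_seq), ref_seq)
    return fwd if fwd.matches >= rev.matches else rev


def run_evaluate(
    result: AssemblyResult,
    reference_seqs: dict[str, str],
    cds_ranges: dict[str, tuple[int, int]],
    genome: Genome,
    reads: list[ShortRead] | None = None,
    params: Params | None = None,
    ref_structs: dict[str, CdsStructure] | None = None,
) -> EvalResult:
    """Consistency classification, base accuracy and coverage binning
    against the finished reference clones."""
    params = params or Params()
    if ref_structs is None:
        ref_structs = reference_structures(reference_seqs, cds_ranges, genome, params)
    contigs_by_id = {c.id: c for c in result.contigs}
    coverages = (
        clone_coverages(reads, reference_seqs) if reads is not None else {}
    )
    rows = []
    tot = dict(ref_len=0, aligned_len=0, matches=0, mismatches=0,
               insertions=0, deletions=0)
    cds_tot = dict(ref_len=0, aligned_len=0, matches=0, mismatches=0,
                   insertions=0, deletions=0)
    n_consistent = 0
    n_amplified = 0
    n_with_cds = 0
    for asm in sorted(result.assemblies, key=lambda a: a.clone_id):
        cid = asm.clone_id
        ref = reference_seqs.get(cid)
        row = {
            "clone_id": cid,
            "status": asm.status,
            "verdict": "",
            "failure": "",
            "coverage": round(coverages.get(cid, 0.0), 2),
            "extended_5p": asm.extended_5p,
            "extended_3p": asm.extended_3p,
        }
        if asm.status == "assembled" and ref is not None:
            n_amplified += 1
            acc = _oriented_accuracy(asm.sequence, ref)
            for k in tot:
                tot[k] += getattr(acc, k)
            if cid in ref_structs:
                n_with_cds += 1
                chains = reconstructed_chains(asm, contigs_by_id, genome, params)
                res = classify_consistency(chains, ref_structs[cid])
                row["verdict"] = res.verdict
                row["failure"] = res.failure
                if res.verdict == CONSISTENT:
                    n_consistent += 1
                    cs, ce = cds_ranges[cid]
                    cacc = _oriented_accuracy(asm.sequence, ref[cs:ce])
                    # insertions here include UTR overhang; only the CDS
                    # match/mismatch budget is meaningful
                    cds_tot["ref_len"] += cacc.ref_len
                    cds_tot["aligned_len"] += cacc.ref_len
                    cds_tot["matches"] += cacc.matches
                    cds_tot["mismatches"] += cacc.mismatches
                    cds_tot["deletions"] += cacc.deletions
        rows.append(row)
    return EvalResult(
        per_clone=pd.DataFrame(rows),
        n_reference=len(reference_seqs),
        n_amplified=n_amplified,
        n_with_cds=n_with_cds,
        n_consistent=n_consistent,
        accuracy=BaseAccuracy(**tot) if n_amplified else None,
        cds_accuracy=BaseAccuracy(**cds_tot) if n_consistent else None,
    )


def evaluate_sequences(
    outputs: dict[str, str],
    reference_seqs: dict[str, str],
    cds_ranges: dict[str, tuple[int, int]],
    genome: Genome,
    reads: list[ShortRead] | None = None,
    params: Params | None = None,
) -> EvalResult:
    """Evaluate bare per-clone output sequences (e.g. read back from a
    FASTA) without an in-memory assembly result."""
    assemblies = [
        CloneAssembly(clone_id=cid, status="assembled", sequence=seq)
        for cid, seq in sorted(outputs.items())
    ]
    fake = AssemblyResult(
        assemblies=assemblies, contigs=[], unassigned=[], stages=[],
        anchoring=AnchoringReport(), gap_outcomes=[], filter_report=None,
    )
    return run_evaluate(fake, reference_seqs, cds_ranges, genome, reads, params)


def coverage_consistency_table(eval_result: EvalResult) -> pd.DataFrame:
    df = eval_result.per_clone
    mask = df["verdict"] != ""
    return coverage_bins(
        df.loc[mask, "coverage"].tolist(), df.loc[mask, "verdict"].tolist()
    )


__all__ = [
    "StageRow",
    "AssemblyResult",
    "EvalResult",
    "run_assemble",
    "run_evaluate",
    "reference_structures",
    "reconstructed_chains",
    "gap_table",
    "coverage_consistency_table",
]
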