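"""Query readers, the SAM writer, and the end-to-end alignment pipeline.

Coordinates are 0-based half-open internally and 1-based in SAM output.
Minus-strand records carry the reverse-complemented SEQ with FLAG bit 16;
every non-primary record (FBS secondaries and report-all extras) sets bit
256.  MAPQ is emitted as 255 (unavailable): no mapping-quality model is
defined here, and the alignment-score tag AS:i carries the exact affine-gap
score instead.  Secondary records carry the full SEQ so downstream
split-read clustering tools can use them.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

from Bio import SeqIO

from . import __version__
from ._util import cigar_to_string, encode_seq, revcomp_codes, revcomp_str
from .chaining import (
    AGSParams,
    ChainParams,
    filter_minmatch,
    iterate_uncovered,
    partition_regions,
)
from .coverage import (
    CoverageResult,
    FBSParams,
    OQCParams,
    filter_by_similarity,
    optimal_query_coverage,
    report_all_mode,
)
from .dp_align import Alignment, AlignmentDropped, DPParams, complete_alignment
from .index import Index
from .seeding import seed_query_both_strands

log = logging.getLogger(__name__)


@dataclass
class QueryRecord:
    name: str
    sequence: str
    qualities: str | None = None


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_queries(path):
    """Yield :class:`QueryRecord` from a FASTA or FASTQ file (gzip ok)."""
    fmt = _sniff_format(path)
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            if rec.id in seen:
                log.warning("duplicate query name %s", rec.id)
            seen.add(rec.id)
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield QueryRecord(rec.id, str(rec.seq), qual)


def read_reference(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, reads):
    """``reads``: iterable of (name, sequence, quality-or-None)."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class AlignerConfig:
    ags: AGSParams = field(default_factory=AGSParams)
    chain: ChainParams = field(default_factory=ChainParams)
    dp: DPParams = field(default_factory=DPParams)
    oqc: OQCParams = field(default_factory=OQCParams)
    fbs: FBSParams = field(default_factory=FBSParams)
    min_score: int = 1  # completed alignments below this are dropped


@dataclass
class QueryResult:
    record: QueryRecord
    alignments: list  # every completed alignment
    coverage: CoverageResult | None  # None in report-all mode
    stats: dict = field(default_factory=dict)

    @property
    def reported(self) -> list:
        if self.coverage is None:
            return self.alignments
        return self.coverage.primaries + self.coverage.secondaries


def align_query(index: Index, record: QueryRecord, cfg: AlignerConfig | None = None) -> QueryResult:
    """Run one query through seeding, chaining, DP completion and OQC/FBS."""
    if cfg is None:
        cfg = AlignerConfig()
    stats: dict = {}
    codes = encode_seq(record.sequence)
    rc_codes = revcomp_codes(codes)
    frags_by_strand = seed_query_both_strands(index, codes, stats)
    stats["n_fragments"] = sum(len(v) for v in frags_by_strand.values())

    potentials = []
    region_counter = 0
    for strand, frags in frags_by_strand.items():
        if not frags:
            continue
        for group in partition_regions(frags, cfg.chain.region_gap_for(len(codes)), index.ref_offsets):
            pas = iterate_uncovered(group, cfg.ags, region_id=region_counter)
            region_counter += 1
            potentials.extend(pa for pa in pas if filter_minmatch(pa, cfg.chain.min_match))
    stats["n_potentials"] = len(potentials)

    alignments = []
    oriented = {"+": codes, "-": rc_codes}
    for pa in potentials:
        try:
            aln = complete_alignment(pa, index, oriented[pa.strand], record.name, cfg.ags, cfg.dp)
        except AlignmentDropped as exc:
            log.debug("alignment dropped for %s: %s", record.name, exc)
            continue
        if aln.score >= cfg.min_score:
            alignments.append(aln)
    stats["n_completed"] = len(alignments)

    if not cfg.oqc.enabled:
        report_all_mode(alignments)
        stats["n_primary"] = sum(a.is_primary for a in alignments)
        return QueryResult(record, alignments, None, stats)

    cov = optimal_query_coverage(alignments, cfg.oqc)
    if cfg.fbs.enabled:
        filter_by_similarity(cov, alignments, cfg.fbs)
    stats["n_primary"] = len(cov.primaries)
    stats["n_secondary"] = len(cov.secondaries)
    return QueryResult(record, alignments, cov, stats)


# ---------------------------------------------------------------------------
# SAM output


def sam_header(index: Index, pg_args: str = "") -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in zip(index.ref_names, index.ref_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{int(length)}")
    lines.append(f"@PG\tID:splitmap\tPN:splitmap\tVN:{__version__}\tCL:{pg_args}".rstrip())
    return "\n".join(lines) + "\n"


def alignment_to_sam(aln: Alignment, record: QueryRecord) -> str:
    flag = 0
    if aln.strand == "-":
        flag |= 16
    if not aln.is_primary:
        flag |= 256
    if aln.strand == "-":
        seq = revcomp_str(record.sequence)
        qual = record.qualities[::-1] if record.qualities else None
    else:
        seq = record.sequence
        qual = record.qualities
    lead = aln.q_start
    trail = aln.query_length - aln.q_end
    cigar = []
    if lead:
        cigar.append(("S", lead))
    cigar.extend(aln.cigar)
    if trail:
        cigar.append(("S", trail))
    fields = [
        record.name,
        str(flag),
        aln.ref_name,
        str(aln.r_start + 1),
        "255",
        cigar_to_string(cigar),
        "*",
        "0",
        "0",
        seq,
        qual or "*",
        f"AS:i:{aln.score}",
    ]
    return "\t".join(fields)


def unmapped_to_sam(record: QueryRecord) -> str:
    fields = [
        record.name,
        "4",
        "*",
        "0",
        "0",
        "*",
        "*",
        "0",
        "0",
        record.sequence,
        record.qualities or "*",
    ]
    return "\t".join(fields)


def write_sam(out, index: Index, results, pg_args: str = ""):
    """Write SAM for an iterable of :class:`QueryResult` to a file object."""
    out.write(sam_header(index, pg_args))
    for res in results:
        reported = res.reported
        if not reported:
            out.write(unmapped_to_sam(res.record) + "\n")
            continue
        for aln in reported:
            if aln.ref_name not in index.ref_names:  # pragma: no cover
                raise RuntimeError(f"alignment references unknown sequence {aln.ref_name}")
            out.write(alignment_to_sam(aln, res.record) + "\n")


def align_file(index: Index, query_path, out_path, cfg: AlignerConfig | None = None, pg_args: str = "") -> dict:
    """Stream a query file through the pipeline into a SAM file.

    Returns aggregate per-stage counts (seeds, fragments, potential
    alignments, completed, primaries, secondaries).
    """
    if cfg is None:
        cfg = AlignerConfig()
    totals = {
        "queries": 0,
        "seeds": 0,
        "fragments": 0,
        "potentials": 0,
        "completed": 0,
        "primaries": 0,
        "secondaries": 0,
        "unmapped": 0,
    }

    def run():
        for record in read_queries(query_path):
            res = align_query(index, record, cfg)
            totals["queries"] += 1
            totals["seeds"] += res.stats.get("n_seeds+", 0) + res.stats.get("n_seeds-", 0)
            totals["fragments"] += res.stats.get("n_fragments", 0)
            totals["potentials"] += res.stats.get("n_potentials", 0)
            totals["completed"] += res.stats.get("n_completed", 0)
            totals["primaries"] += res.stats.get("n_primary", 0)
            totals["secondaries"] += res.stats.get("n_secondary", 0)
            if not res.reported:
                totals["unmapped"] += 1
            yield res

    with open(out_path, "w") as out:
        write_sam(out, index, run(), pg_args)
    log.info("alignment run complete: %s", totals)
    return totals
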