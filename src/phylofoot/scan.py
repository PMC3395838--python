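"""Phylogenetic-footprint scanning of promoter alignments.

Promoter windows are the +/-3000 bp regions around transcription start sites
with coding intervals removed.  Multi-species alignment blocks (MAF) are then
scanned position by position: a reference window of W consecutive ungapped
reference bases is called a conserved site for matrix m only if the score of
the characters in the *same alignment columns* reaches the calibrated
threshold t_m in every required species.  Both strands are scanned (forward
matrix and its reverse complement).  Hits are reported in reference
coordinates and annotated with the owning gene(s).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .calibration import CalibratedThreshold, snap_weights
from .pwm import LogOddsMatrix, _NUC_INDEX

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 3000


class MafFormatError(ValueError):
    """Raised for structurally invalid alignment blocks."""


# ---------------------------------------------------------------------------
# Promoter windows


@dataclass
class PromoterRegion:
    """Scan region of one gene: TSS flanks minus coding sequence."""

    gene_id: str
    gene_symbol: str
    chrom: str
    tss: int
    intervals: list[tuple[int, int]]  # disjoint, sorted, 0-based half-open


def _subtract_intervals(start, end, blockers):
    """Yield the parts of [start, end) not covered by sorted ``blockers``."""
    cur = start
    for b0, b1 in blockers:
        if b1 <= cur or b0 >= end:
            continue
        if b0 > cur:
            yield (cur, min(b0, end))
        cur = max(cur, b1)
        if cur >= end:
            return
    if cur < end:
        yield (cur, end)


def _merge_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def define_promoter_windows(
    tss_table: pd.DataFrame,
    cds_table: pd.DataFrame | None = None,
    flank: int = DEFAULT_FLANK,
    chrom_sizes: dict[str, int] | None = None,
) -> list[PromoterRegion]:
    """Build per-gene promoter regions.

    ``tss_table`` needs columns chrom, tss, gene_id, symbol (strand is
    accepted and ignored for window arithmetic: flanks are symmetric).
    ``cds_table`` needs chrom, start, end.  Windows are [tss-flank, tss+flank)
    clipped at 0 and the chromosome end, minus the union of coding intervals;
    windows of the same gene are merged.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if cds_table is not None and len(cds_table):
        for chrom, grp in cds_table.groupby("chrom"):
            cds_by_chrom[str(chrom)] = _merge_intervals(
                list(zip(grp["start"].astype(int), grp["end"].astype(int))))

    regions: dict[str, PromoterRegion] = {}
    for row in tss_table.itertuples(index=False):
        chrom = str(row.chrom)
        tss = int(row.tss)
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"TSS on unknown chromosome {chrom!r}")
            end_cap = chrom_sizes[chrom]
        else:
            end_cap = None
        start = max(0, tss - flank)
        end = tss + flank if end_cap is None else min(tss + flank, end_cap)
        ivs = list(_subtract_intervals(start, end, cds_by_chrom.get(chrom, [])))
        gid = str(row.gene_id)
        if gid in regions:
            reg = regions[gid]
            if reg.chrom != chrom:
                raise ValueError(f"gene {gid} has TSSs on several chromosomes")
            reg.intervals = _merge_intervals(reg.intervals + ivs)
        else:
            regions[gid] = PromoterRegion(
                gene_id=gid, gene_symbol=str(getattr(row, "symbol", gid)),
                chrom=chrom, tss=tss, intervals=ivs)
    return list(regions.values())


class PromoterIndex:
    """Interval index answering 'which genes own this window?'."""

    def __init__(self, regions):
        self._trees: dict[str, IntervalTree] = {}
        for reg in regions:
            tree = self._trees.setdefault(reg.chrom, IntervalTree())
            for s, e in reg.intervals:
                if e > s:
                    tree.addi(s, e, (reg.gene_id, reg.gene_symbol))

    def genes_containing(self, chrom, start, end):
        """Genes with a promoter interval fully containing [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end)
                if iv.begin <= start and iv.end >= end}
        return sorted(hits)


# ---------------------------------------------------------------------------
# MAF alignment blocks


@dataclass
class SpeciesRow:
    species: str
    chrom: str
    start: int          # 0-based, counted on the row's own strand (MAF)
    size: int           # ungapped bases
    strand: str         # '+' or '-'
    src_size: int
    gapped_seq: str


@dataclass
class AlignmentBlock:
    rows: list[SpeciesRow]

    def __post_init__(self):
        if not self.rows:
            raise MafFormatError("empty alignment block")
        ncols = len(self.rows[0].gapped_seq)
        for r in self.rows:
            if len(r.gapped_seq) != ncols:
                raise MafFormatError(
                    f"row {r.species}.{r.chrom} has gapped length "
                    f"{len(r.gapped_seq)} != {ncols}")
            ungapped = sum(1 for c in r.gapped_seq if c != "-")
            if ungapped != r.size:
                raise MafFormatError(
                    f"row {r.species}.{r.chrom}: ungapped length {ungapped} "
                    f"!= declared size {r.size}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0].gapped_seq)

    @property
    def reference(self) -> SpeciesRow:
        return self.rows[0]

    def row_for_species(self, species: str) -> SpeciesRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def read_maf_blocks(source):
    """Iterate :class:`AlignmentBlock` from a MAF stream, string or path."""
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    elif isinstance(source, str):
        handle = open(source)
    else:
        handle = source
    for msa in AlignIO.parse(handle, "maf"):
        rows = []
        for rec in msa:
            sp, chrom = _split_src(rec.id)
            ann = rec.annotations
            rows.append(SpeciesRow(
                species=sp, chrom=chrom,
                start=int(ann["start"]), size=int(ann["size"]),
                strand="+" if int(ann["strand"]) >= 0 else "-",
                src_size=int(ann["srcSize"]),
                gapped_seq=str(rec.seq).upper()))
        yield AlignmentBlock(rows)


def write_maf_blocks(blocks, stream) -> None:
    """Write blocks back to MAF (byte-stable round trip of coordinates/sequence)."""
    msas = []
    for block in blocks:
        recs = []
        for r in block.rows:
            rec = SeqRecord(Seq(r.gapped_seq), id=f"{r.species}.{r.chrom}",
                            description="")
            rec.annotations = {
                "start": r.start, "size": r.size,
                "strand": 1 if r.strand == "+" else -1,
                "srcSize": r.src_size,
            }
            recs.append(rec)
        msas.append(MultipleSeqAlignment(recs))
    AlignIO.write(msas, stream, "maf")


# ---------------------------------------------------------------------------
# Conserved-site scanning


@dataclass
class TfbsHit:
    """One conserved binding-site call in reference coordinates."""

    chrom: str
    start: int
    end: int
    pwm_id: str
    names: str
    score: float
    strand: str
    gene_id: str
    gene_symbol: str
    per_species_scores: dict[str, float] = field(default_factory=dict)


def _char_indices(seq_chars):
    """Map A,C,G,T to 0..3 and everything else (gaps, N, IUPAC) to -1."""
    return np.array([_NUC_INDEX.get(c, -1) for c in seq_chars], dtype=np.int64)


def _window_scores(charidx: np.ndarray, wbins: np.ndarray):
    """Scores (in grid bins) and validity for all sliding windows.

    charidx: (N,) per-position base index, -1 when unscoreable.
    Returns (scores (N-W+1,), valid (N-W+1,) bool).
    """
    W = wbins.shape[0]
    N = charidx.shape[0]
    if N < W:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    n_win = N - W + 1
    scores = np.zeros(n_win, dtype=np.int64)
    invalid = (charidx < 0).astype(np.int64)
    bad = np.convolve(invalid, np.ones(W, dtype=np.int64), mode="valid")
    safe = np.where(charidx < 0, 0, charidx)
    for w in range(W):
        scores += wbins[w][safe[w:w + n_win]]
    return scores, bad == 0


def scan_conserved_sites(
    block: AlignmentBlock,
    lom: LogOddsMatrix,
    threshold: CalibratedThreshold,
    required_species: list[str],
    regions: PromoterIndex,
    names: str = "",
) -> list[TfbsHit]:
    """Call sites conserved above t_m in every required species.

    Conservation is evaluated on the alignment columns carrying the W
    reference bases; a gap or unscoreable character in any required species
    inside the window disqualifies the position.  Score comparisons happen on
    the calibration bin grid ('above t_m' is >= t_m on the grid), making scan
    results bit-reproducible against the calibration.
    """
    ref = block.reference
    if ref.species not in required_species:
        raise ValueError(
            f"reference species {ref.species!r} must be in required_species")
    if not threshold.attainable:
        return []
    sp_rows = {}
    for sp in required_species:
        row = block.row_for_species(sp)
        if row is None:
            logger.info("block %s:%d skipped: species %s absent",
                        ref.chrom, ref.start, sp)
            return []
        sp_rows[sp] = row
    if ref.strand != "+":
        logger.info("block %s:%d skipped: negative-strand reference row",
                    ref.chrom, ref.start)
        return []

    gapped = np.frombuffer(ref.gapped_seq.encode(), dtype="S1")
    refcols = np.nonzero(gapped != b"-")[0]
    n_ref = len(refcols)
    W = lom.width
    if n_ref < W:
        return []

    # per-species base indices at the reference-base columns
    charidx = {
        sp: _char_indices([row.gapped_seq[c] for c in refcols])
        for sp, row in sp_rows.items()
    }

    t_bin = threshold.threshold_bin
    bw = threshold.bin_width
    hits: list[TfbsHit] = []
    for strand, mat in (("+", lom), ("-", lom.reverse_complement())):
        wbins = snap_weights(mat, bw)
        passing = None
        scores = {}
        for sp in required_species:
            s, valid = _window_scores(charidx[sp], wbins)
            scores[sp] = s
            ok = valid & (s >= t_bin)
            passing = ok if passing is None else (passing & ok)
        for i in np.nonzero(passing)[0]:
            g_start = ref.start + int(i)
            g_end = g_start + W
            for gene_id, symbol in regions.genes_containing(
                    ref.chrom, g_start, g_end):
                hits.append(TfbsHit(
                    chrom=ref.chrom, start=g_start, end=g_end,
                    pwm_id=lom.pwm_id, names=names,
                    score=float(scores[ref.species][i]) * bw,
                    strand=strand, gene_id=gene_id, gene_symbol=symbol,
                    per_species_scores={
                        sp: float(scores[sp][i]) * bw
                        for sp in required_species},
                ))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.pwm_id, h.gene_id))
    return hits


def scan_collection(blocks, loms, thresholds, required_species, regions,
                    names_by_pwm=None):
    """Scan every block with every calibrated matrix; concatenated hits."""
    names_by_pwm = names_by_pwm or {}
    hits = []
    for block in blocks:
        for lom in loms:
            thr = thresholds[lom.pwm_id]
            hits.extend(scan_conserved_sites(
                block, lom, thr, required_species, regions,
                names=names_by_pwm.get(lom.pwm_id, "")))
    return hits


# ---------------------------------------------------------------------------
# Hit export / summaries


def write_hits_bed(hits, stream) -> None:
    """Write the 8-field BED dialect: chrom, chromStart, chromEnd,
    name (pwm_id|names, pipe-separated), score, strand, gene id, geneSymbol."""
    for h in hits:
        name = h.pwm_id if not h.names else f"{h.pwm_id}|{h.names}"
        stream.write("\t".join([
            h.chrom, str(h.start), str(h.end), name, str(h.score),
            h.strand, h.gene_id, h.gene_symbol]) + "\n")


def read_hits_bed(source) -> list[TfbsHit]:
    stream = io.StringIO(source) if isinstance(source, str) else source
    hits = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise ValueError(f"line {lineno}: expected 8 fields, got {len(fields)}")
        pwm_id, _, names = fields[3].partition("|")
        hits.append(TfbsHit(
            chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
            pwm_id=pwm_id, names=names, score=float(fields[4]),
            strand=fields[5], gene_id=fields[6], gene_symbol=fields[7]))
    return hits


def build_target_sets(hits):
    """Collapse hits to per-PWM target-gene sets and per-gene regulator sets."""
    by_pwm: dict[str, set[str]] = {}
    by_gene: dict[str, set[str]] = {}
    for h in hits:
        by_pwm.setdefault(h.pwm_id, set()).add(h.gene_id)
        by_gene.setdefault(h.gene_id, set()).add(h.pwm_id)
    return by_pwm, by_gene


def regulator_counts(per_gene: dict[str, set], top_fraction: float = 0.01):
    """Summary of the non-redundant regulator count per gene, plus the genes
    in the top ``top_fraction`` (boundary ties all included)."""
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if not per_gene:
        return {"summary": {}, "top_genes": []}
    counts = {g: len(s) for g, s in per_gene.items()}
    values = np.array(sorted(counts.values()))
    n_top = int(np.ceil(top_fraction * len(counts)))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ranked[n_top - 1][1]
    top = [g for g, c in ranked if c >= cutoff]
    return {
        "summary": {
            "n_genes": len(counts),
            "median": float(np.median(values)),
            "mean": float(values.mean()),
            "min": int(values.min()),
            "max": int(values.max()),
        },
        "top_genes": top,
    }


def hit_count_stats(target_sets: dict[str, set], pwm_stats: dict[str, dict]) -> pd.DataFrame:
    """Per-PWM target counts joined with GC/information content, the table
    behind the hits-versus-GC diagnostic plot."""
    rows = [
        {"pwm_id": pwm_id, "n_hits": len(genes),
         "gc": pwm_stats.get(pwm_id, {}).get("gc_content", np.nan),
         "ic": pwm_stats.get(pwm_id, {}).get("information_content", np.nan)}
        for pwm_id, genes in sorted(target_sets.items())
    ]
    return pd.DataFrame(rows, columns=["pwm_id", "n_hits", "gc", "ic"])
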