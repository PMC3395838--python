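"""Deterministic synthetic inputs with planted, known answers.

Every generator is a pure function of its parameters and seed (its own
:func:`numpy.random.default_rng` stream, never global state), so reruns are
byte-identical and each pipeline stage can be tested against planted truth:
alignments with conserved consensus sites, annotation universes with planted
enrichments, binary matrices with planted all-ones blocks, and interaction
flat files.

Cross-species independence is deliberate: background columns are drawn
independently per species rather than down a substitution model, which is
the conservative null for a conservation-based caller (any dependence would
only make random columns look *more* conserved).
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .graph import InteractionRecord, make_record, write_interaction_table
from .enrichment import AnnotationUniverse
from .pwm import NUCLEOTIDES, PositionWeightMatrix, reverse_complement_pwm
from .scan import AlignmentBlock, SpeciesRow

#: Default species mirroring the four-genome conservation requirement
#: (human, mouse, rat, dog).
DEFAULT_SPECIES = ["hg", "mm", "rn", "cf"]


def generate_random_pwm(width: int, concentration: float = 0.3,
                        seed: int = 0, pwm_id: str | None = None
                        ) -> PositionWeightMatrix:
    """Dirichlet-random motif; low concentration gives high information content."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 4, size=width)
    # floor to keep log-odds finite without visibly moving the columns
    probs = (probs + 1e-4) / (1 + 4e-4)
    return PositionWeightMatrix(
        id=pwm_id or f"SIM{seed}_W{width}", probs=probs,
        names=[f"SimTF{seed}"], source_dialect="generic")


def generate_planted_alignment(
    species: list[str] | None = None,
    length: int = 2000,
    pwm: PositionWeightMatrix | None = None,
    plant_positions=(),
    per_species_mutation: float = 0.0,
    gap_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "chrSim",
    ref_start: int = 0,
):
    """Multi-species alignment block with consensus sites planted in all species.

    ``plant_positions`` is a list of reference positions or (position,
    strand) pairs; at each one the motif consensus (reverse-complemented for
    '-' plants) is written into every species, then independently mutated per
    species at rate ``per_species_mutation``.  Background columns are drawn
    independently per species; gaps (rate ``gap_rate``) only ever land in
    non-reference species outside planted windows, so reference coordinates
    stay dense.  Returns (AlignmentBlock, truth) where truth lists
    ``{"start", "end", "strand"}`` in reference coordinates.
    """
    species = list(species or DEFAULT_SPECIES)
    rng = np.random.default_rng(seed)
    plants = []
    for p in plant_positions:
        pos, strand = (p, "+") if isinstance(p, (int, np.integer)) else p
        if pwm is None:
            raise ValueError("plant_positions given without a pwm")
        if pos < 0 or pos + pwm.width > length:
            raise ValueError(f"planted window at {pos} outside alignment")
        plants.append((int(pos), strand))
    plants.sort()
    for (a, _), (b, _) in zip(plants, plants[1:]):
        if b < a + pwm.width:
            raise ValueError("overlapping planted windows")

    seqs = rng.integers(0, 4, size=(len(species), length))
    planted_cols = np.zeros(length, dtype=bool)
    truth = []
    for pos, strand in plants:
        motif = pwm if strand == "+" else reverse_complement_pwm(pwm)
        consensus = motif.probs.argmax(axis=1)
        for s in range(len(species)):
            copy = consensus.copy()
            if per_species_mutation > 0:
                mut = rng.random(pwm.width) < per_species_mutation
                if mut.any():
                    shift = rng.integers(1, 4, size=int(mut.sum()))
                    copy[mut] = (copy[mut] + shift) % 4
            seqs[s, pos:pos + pwm.width] = copy
        planted_cols[pos:pos + pwm.width] = True
        truth.append({"start": ref_start + pos, "end": ref_start + pos + pwm.width,
                      "strand": strand})

    gapped = np.array([[NUCLEOTIDES[b] for b in row] for row in seqs],
                      dtype="<U1")
    if gap_rate > 0:
        for s in range(1, len(species)):
            gaps = (rng.random(length) < gap_rate) & ~planted_cols
            gapped[s, gaps] = "-"
    rows = []
    for s, sp in enumerate(species):
        seq = "".join(gapped[s])
        size = sum(1 for c in seq if c != "-")
        rows.append(SpeciesRow(
            species=sp, chrom=chrom if s == 0 else f"{chrom}_{sp}",
            start=ref_start if s == 0 else 0, size=size, strand="+",
            src_size=ref_start + length if s == 0 else length,
            gapped_seq=seq))
    return AlignmentBlock(rows), truth


def promoter_table_for_blocks(blocks, gene_ids, symbols=None) -> pd.DataFrame:
    """TSS table placing one gene's promoter over each block's reference span."""
    symbols = symbols or gene_ids
    rows = []
    for block, gid, sym in zip(blocks, gene_ids, symbols):
        ref = block.reference
        rows.append({"chrom": ref.chrom, "tss": ref.start + ref.size // 2,
                     "gene_id": gid, "symbol": sym, "strand": "+"})
    return pd.DataFrame(rows)


def generate_annotation_universe(n_genes: int = 1000, n_terms: int = 20,
                                 planted=(), background_rate: float = 0.02,
                                 seed: int = 0,
                                 gene_ids=None) -> AnnotationUniverse:
    """Random gene-term memberships plus planted term -> gene-set pairs."""
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else [
        f"g{i:05d}" for i in range(n_genes)]
    universe = set(genes)
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        term_id = f"T{t:04d}"
        mask = rng.random(len(genes)) < background_rate
        terms[term_id] = {g for g, m in zip(genes, mask) if m}
    for term_id, gene_set in planted:
        gene_set = set(gene_set)
        if not gene_set <= universe:
            raise ValueError(f"planted genes of {term_id!r} outside universe")
        terms[term_id] = terms.get(term_id, set()) | gene_set
    return AnnotationUniverse(source="synthetic", terms=terms,
                              universe=universe)


def generate_binary_matrix_with_biclusters(shape=(20, 15), planted_blocks=(),
                                           noise_density: float = 0.1,
                                           seed: int = 0):
    """Noise matrix with planted all-ones blocks.

    ``planted_blocks``: list of (rows, cols) index collections.  Returns
    (matrix, truth) with truth echoing the planted index sets.
    """
    rng = np.random.default_rng(seed)
    n, m = shape
    mat = (rng.random((n, m)) < noise_density).astype(np.int8)
    truth = []
    for rows, cols in planted_blocks:
        rows = sorted(int(r) for r in rows)
        cols = sorted(int(c) for c in cols)
        if rows and (rows[0] < 0 or rows[-1] >= n):
            raise ValueError("planted block rows outside matrix")
        if cols and (cols[0] < 0 or cols[-1] >= m):
            raise ValueError("planted block cols outside matrix")
        mat[np.ix_(rows, cols)] = 1
        truth.append((frozenset(rows), frozenset(cols)))
    return mat, truth


DEFAULT_DENSITIES = {
    "tf_target_curated": 0.02,
    "tf_target_predicted": 0.03,
    "mirna_target": 0.01,
    "kinase_substrate": 0.01,
    "ppi": 0.03,
}


def generate_interaction_table(n_genes: int = 30, densities=None, seed: int = 0):
    """Random typed interaction compendium as (tsv text, records).

    ``densities`` maps category -> probability of each ordered gene pair
    carrying such an interaction (unordered for ppi).
    """
    densities = DEFAULT_DENSITIES if densities is None else densities
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    records: list[InteractionRecord] = []
    for category in sorted(densities):
        dens = densities[category]
        if not (0 <= dens <= 1):
            raise ValueError(f"density for {category} outside [0, 1]")
        for i, a in enumerate(genes):
            for j, b in enumerate(genes):
                if i == j:
                    continue
                if category == "ppi" and j < i:
                    continue
                if rng.random() < dens:
                    if category == "ppi":
                        sign = None
                    elif category == "mirna_target":
                        sign = None  # defaults to repression
                    else:
                        sign = ["activation", "repression", "ambiguous"][
                            int(rng.integers(0, 3))]
                    records.append(make_record(a, b, category, sign,
                                               provenance="synthetic"))
    buf = io.StringIO()
    write_interaction_table(records, buf)
    return buf.getvalue(), records


def generate_cc_map(genes, tree_terms, max_compartments: int = 2, seed: int = 0):
    """Random gene -> compartment-term annotation over ``tree_terms``."""
    rng = np.random.default_rng(seed)
    terms = sorted(tree_terms)
    out: dict[str, list[str]] = {}
    for g in genes:
        k = int(rng.integers(1, max_compartments + 1))
        out[g] = sorted(rng.choice(terms, size=min(k, len(terms)),
                                   replace=False).tolist())
    return out
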