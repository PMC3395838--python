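"""Functional-enrichment matrix and BiMax biclustering of target sets.

Every (annotation term, PWM target set) pair is scored by a one-sided
Fisher's exact test p-value f over the annotated gene universe; the
term x PWM matrix of -log10(f) is binarized at a p-value cutoff and mined
for inclusion-maximal all-ones submatrices with the divide-and-conquer
BiMax recursion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_P = 1e-300  # floor before -log10 to keep scores finite
DEFAULT_BINARIZE_P = 1e-3
DEFAULT_MIN_ROWS = 2
DEFAULT_MIN_COLS = 2


@dataclass
class AnnotationUniverse:
    """Term -> gene-set map over a universe of annotated genes."""

    source: str
    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        if not self.universe:
            raise ValueError("annotation universe must be non-empty")
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")


def read_annotation_tsv(source, source_name: str = "user") -> AnnotationUniverse:
    """Parse the 3-column annotation dialect: gene_id, term_id, source."""
    stream = io.StringIO(source) if isinstance(source, str) else source
    df = pd.read_csv(stream, sep="\t", header=None,
                     names=["gene_id", "term_id", "source"], dtype=str,
                     comment="#")
    terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        terms.setdefault(term, set()).add(gene)
    return AnnotationUniverse(
        source=source_name, terms=terms, universe=set(df["gene_id"]))


@dataclass
class EnrichmentCell:
    term_id: str
    pwm_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    score: float = field(init=False)

    def __post_init__(self):
        self.score = -np.log10(max(self.p_value, MIN_P))


def fisher_enrichment_test(targets: set, term_genes: set, universe: set):
    """One-sided (enrichment) Fisher exact test.

    The 2x2 table is [[targets&term, targets-term], [term-targets, rest]];
    the 'greater' p-value equals the hypergeometric upper tail of the overlap.
    Targets are intersected with the universe before tabulation.
    """
    if not universe:
        raise ValueError("empty universe")
    targets = targets & universe
    term_genes = term_genes & universe
    a = len(targets & term_genes)
    b = len(targets) - a
    c = len(term_genes) - a
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {"table": ((a, b), (c, d)), "p_value": float(p)}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= p, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_enrichment_matrix(target_sets: dict[str, set],
                            annos: AnnotationUniverse):
    """Term x PWM matrix of -log10(f) plus the per-cell test details.

    Returns (scores DataFrame indexed by term_id with pwm_id columns,
    dict[(term_id, pwm_id)] -> EnrichmentCell).
    """
    term_ids = sorted(annos.terms)
    pwm_ids = sorted(target_sets)
    scores = np.zeros((len(term_ids), len(pwm_ids)))
    cells: dict[tuple[str, str], EnrichmentCell] = {}
    for j, pwm_id in enumerate(pwm_ids):
        targets = target_sets[pwm_id] & annos.universe
        for i, term_id in enumerate(term_ids):
            res = fisher_enrichment_test(targets, annos.terms[term_id],
                                         annos.universe)
            cell = EnrichmentCell(term_id=term_id, pwm_id=pwm_id,
                                  table=res["table"], p_value=res["p_value"])
            cells[(term_id, pwm_id)] = cell
            scores[i, j] = cell.score
    return pd.DataFrame(scores, index=term_ids, columns=pwm_ids), cells


def binarize_matrix(scores, p_threshold: float = DEFAULT_BINARIZE_P) -> np.ndarray:
    """Cell is 1 iff f < p_threshold, i.e. score strictly above -log10(cutoff)."""
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    arr = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    return (arr > -np.log10(p_threshold)).astype(np.int8)


@dataclass(frozen=True)
class Bicluster:
    """Inclusion-maximal all-ones submatrix: row and column index sets."""

    rows: frozenset[int]
    cols: frozenset[int]

    def sort_key(self):
        return (tuple(sorted(self.rows)), tuple(sorted(self.cols)))


def _row_masks(binary: np.ndarray) -> list[int]:
    """Column bitmask of each row's ones."""
    masks = []
    for row in binary:
        m = 0
        for j in np.nonzero(row)[0]:
            m |= 1 << int(j)
        masks.append(m)
    return masks


def _is_maximal(binary, rows, cols) -> bool:
    sub_rows = sorted(rows)
    sub_cols = sorted(cols)
    for r in range(binary.shape[0]):
        if r not in rows and binary[r, sub_cols].all():
            return False
    for c in range(binary.shape[1]):
        if c not in cols and binary[sub_rows, c].all():
            return False
    return True


def _validate_binary(binary) -> np.ndarray:
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("matrix entries must be 0 or 1")
    return binary.astype(np.int8)


def bimax_biclusters(binary, min_rows: int = DEFAULT_MIN_ROWS,
                     min_cols: int = DEFAULT_MIN_COLS) -> list[Bicluster]:
    """All inclusion-maximal all-ones submatrices meeting the size minima.

    Divide and conquer on the column set: a template row splits the columns
    into its ones (CU) and the rest (CV); biclusters either live entirely in
    CU (first branch) or must use a CV column (second branch, enforced by a
    mandatory-column set).  Candidates are then deduplicated and checked for
    maximality against the full matrix (no outside row or column is all-ones
    on the candidate), which is exact.  Output order is deterministic:
    lexicographic by row set then column set.
    """
    if min_rows < 1 or min_cols < 1:
        raise ValueError("size minima must be >= 1")
    binary = _validate_binary(binary)
    n_rows, n_cols = binary.shape
    if n_rows == 0 or n_cols == 0:
        return []
    masks = _row_masks(binary)
    full = (1 << n_cols) - 1
    found: set[tuple[int, frozenset]] = set()
    candidates: list[Bicluster] = []

    def conquer(row_idx: tuple[int, ...], colmask: int, mandatory: tuple[int, ...]):
        rows = [r for r in row_idx if masks[r] & colmask]
        if not rows or bin(colmask).count("1") < min_cols:
            return
        template = None
        for r in rows:
            if masks[r] & colmask != colmask:
                template = r
                break
        if template is None:
            # all remaining rows are full on colmask -> all-ones leaf
            if all(colmask & m for m in mandatory):
                key = (colmask, frozenset(rows))
                if key not in found:
                    found.add(key)
                    if len(rows) >= min_rows:
                        cols = frozenset(
                            j for j in range(n_cols) if colmask >> j & 1)
                        candidates.append(
                            Bicluster(rows=frozenset(rows), cols=cols))
            return
        cu = masks[template] & colmask
        cv = colmask & ~cu
        conquer(tuple(rows), cu, mandatory)
        rows_v = tuple(r for r in rows if masks[r] & cv)
        conquer(rows_v, colmask, mandatory + (cv,))

    conquer(tuple(range(n_rows)), full, ())
    out = [
        bc for bc in candidates
        if len(bc.cols) >= min_cols
        and _is_maximal(binary, set(bc.rows), set(bc.cols))
    ]
    # dedup (distinct leaves can collapse to the same maximal bicluster)
    uniq = {(bc.rows, bc.cols): bc for bc in out}
    return sorted(uniq.values(), key=Bicluster.sort_key)


def brute_force_biclusters(binary, min_rows: int = DEFAULT_MIN_ROWS,
                           min_cols: int = DEFAULT_MIN_COLS,
                           max_rows: int = 14) -> list[Bicluster]:
    """Row-subset-closure enumeration oracle (exponential in rows).

    For every nonempty row subset, the common all-ones columns define a
    candidate; closing it back over rows and filtering for maximality yields
    every inclusion-maximal bicluster.  Refuses more than ``max_rows`` rows.
    """
    binary = _validate_binary(binary)
    n_rows, n_cols = binary.shape
    if n_rows > max_rows:
        raise ValueError(f"brute force refuses {n_rows} rows > {max_rows}")
    if n_rows == 0 or n_cols == 0:
        return []
    masks = _row_masks(binary)
    full = (1 << n_cols) - 1
    seen: set[tuple[frozenset, frozenset]] = set()
    out = []
    for subset in range(1, 1 << n_rows):
        colmask = full
        for r in range(n_rows):
            if subset >> r & 1:
                colmask &= masks[r]
        if not colmask:
            continue
        rows = frozenset(r for r in range(n_rows)
                         if masks[r] & colmask == colmask)
        cols = frozenset(j for j in range(n_cols) if colmask >> j & 1)
        key = (rows, cols)
        if key in seen:
            continue
        seen.add(key)
        if len(rows) >= min_rows and len(cols) >= min_cols:
            out.append(Bicluster(rows=rows, cols=cols))
    return sorted(out, key=Bicluster.sort_key)


def write_biclusters(biclusters, row_labels, col_labels, stream) -> None:
    """One line per bicluster: semicolon-joined term ids TAB pwm ids."""
    for bc in biclusters:
        terms = ";".join(row_labels[i] for i in sorted(bc.rows))
        pwms = ";".join(col_labels[j] for j in sorted(bc.cols))
        stream.write(f"{terms}\t{pwms}\n")
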