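"""Convenience composition of the full footprint-to-bicluster pipeline.

Runs the whole chain on synthetic inputs with planted signal: motif
collections -> exact threshold calibration -> conserved-site scanning of
planted promoter alignments -> target sets -> enrichment matrix over a
planted annotation universe -> binarization -> BiMax.  Used for end-to-end
validation: the planted PWM-term association must come back as a bicluster.
"""

from __future__ import annotations

import numpy as np

from . import calibration, enrichment, scan, simulate
from .pwm import log_odds_transform


def run_planted_pipeline(
    seed: int = 0,
    n_genes: int = 30,
    n_causal_targets: int = 20,
    n_decoy_pwms: int = 2,
    universe_size: int = 300,
    promoter_length: int = 400,
    alpha: float = calibration.DEFAULT_PVALUE,
    binarize_p: float = enrichment.DEFAULT_BINARIZE_P,
) -> dict:
    """Full pipeline on planted data; returns intermediates and outcome.

    Two causal high-information motifs are planted in the promoters of the
    first ``n_causal_targets`` genes; two annotation terms are planted over
    exactly those genes.  If every stage works, the 2x2 (terms x causal
    PWMs) association survives binarization and is contained in a BiMax
    bicluster (``result["recovered"]``).
    """
    rng = np.random.default_rng(seed)
    causal = [simulate.generate_random_pwm(
        10, 0.05, seed=int(rng.integers(2**31)), pwm_id=f"CAUSAL{i}")
        for i in range(2)]
    decoys = [simulate.generate_random_pwm(
        8, 0.05, seed=int(rng.integers(2**31)), pwm_id=f"DECOY{i}")
        for i in range(n_decoy_pwms)]
    pwms = causal + decoys
    loms = {p.id: log_odds_transform(p) for p in pwms}
    thresholds = calibration.calibrate_collection(loms.values(), alpha=alpha)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    targets = genes[:n_causal_targets]
    blocks = []
    for i, gene in enumerate(genes):
        plants = []
        if gene in targets:
            plants = [(50, "+"), (200, "-")]  # CAUSAL0 fwd, CAUSAL1 rev
        block0, _ = simulate.generate_planted_alignment(
            length=promoter_length, pwm=causal[0],
            plant_positions=plants[:1], seed=int(rng.integers(2**31)),
            chrom=f"chr{i}", ref_start=0)
        if plants[1:]:
            # overwrite a second window with the other causal motif
            block1, _ = simulate.generate_planted_alignment(
                length=promoter_length, pwm=causal[1],
                plant_positions=plants[1:], seed=int(rng.integers(2**31)),
                chrom=f"chr{i}", ref_start=0)
            for row0, row1 in zip(block0.rows, block1.rows):
                row0.gapped_seq = (row0.gapped_seq[:200]
                                   + row1.gapped_seq[200:210]
                                   + row0.gapped_seq[210:])
        blocks.append(block0)

    tss = simulate.promoter_table_for_blocks(blocks, genes)
    regions = scan.define_promoter_windows(tss, None)
    index = scan.PromoterIndex(regions)
    hits = scan.scan_collection(blocks, list(loms.values()), thresholds,
                                simulate.DEFAULT_SPECIES, index)
    target_sets, per_gene = scan.build_target_sets(hits)

    universe_genes = genes + [f"u{i:05d}" for i in range(universe_size - n_genes)]
    annos = simulate.generate_annotation_universe(
        n_terms=20, planted=[("Tplant0", targets), ("Tplant1", targets)],
        background_rate=0.02, seed=int(rng.integers(2**31)),
        gene_ids=universe_genes)
    scores, cells = enrichment.build_enrichment_matrix(target_sets, annos)
    binary = enrichment.binarize_matrix(scores, binarize_p)
    biclusters = enrichment.bimax_biclusters(binary)

    term_index = {t: i for i, t in enumerate(scores.index)}
    pwm_index = {p: j for j, p in enumerate(scores.columns)}
    recovered = False
    if "Tplant0" in term_index and "CAUSAL0" in pwm_index:
        r, c = term_index["Tplant0"], pwm_index["CAUSAL0"]
        recovered = any(r in bc.rows and c in bc.cols for bc in biclusters)
    return {
        "pwms": pwms,
        "thresholds": thresholds,
        "hits": hits,
        "target_sets": target_sets,
        "per_gene": per_gene,
        "scores": scores,
        "cells": cells,
        "binary": binary,
        "biclusters": biclusters,
        "recovered": recovered,
    }
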