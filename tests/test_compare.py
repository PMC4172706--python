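"""Dot plots, polymorphism counts, intron lengths, breakpoint detection."""

from __future__ import annotations

import numpy as np
import pytest

from ibismhc import (count_polymorphic_residues, count_polymorphic_sites,
                     detect_breakpoint, dotplot, measure_intron_length)


def brute_dotplot(a, b, window, threshold):
    need = int(np.ceil(threshold * window - 1e-9))
    return sorted(
        (i, j)
        for i in range(len(a) - window + 1)
        for j in range(len(b) - window + 1)
        if sum(x == y for x, y in zip(a[i:i + window], b[j:j + window])) >= need
    )


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def test_self_dotplot_has_full_main_diagonal():
    rng = np.random.default_rng(1)
    s = random_dna(rng, 120)
    dm = dotplot(s, s, window=20, step=1, threshold=1.0)
    diag = {(i, i) for i in range(len(s) - 20 + 1)}
    assert diag <= set(dm.anchors)


def test_dotplot_matches_bruteforce_on_random_pairs():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a, b = random_dna(rng, 120), random_dna(rng, 150)
        dm = dotplot(a, b, window=15, step=1, threshold=0.8)
        assert list(dm.anchors) == brute_dotplot(a, b, 15, 0.8)


def test_dotplot_grid_step_matches_bruteforce_subset():
    rng = np.random.default_rng(3)
    a, b = random_dna(rng, 200), random_dna(rng, 200)
    dm = dotplot(a, b, window=15, step=7, threshold=0.8)
    full = set(brute_dotplot(a, b, 15, 0.8))
    expected = sorted(p for p in full if p[0] % 7 == 0 and p[1] % 7 == 0)
    assert list(dm.anchors) == expected


def test_dotplot_symmetry_under_swap():
    rng = np.random.default_rng(4)
    a, b = random_dna(rng, 100), random_dna(rng, 130)
    dm = dotplot(a, b, window=12, threshold=0.75)
    assert dotplot(b, a, window=12, threshold=0.75).anchors == dm.transpose().anchors


def _post_exon2(gene):
    start, _ = gene.part_interval("intron", 2)
    return gene.seq[start:]


def test_dotplot_reveals_hybrid_identity_runs(reference):
    """DAB1*01 matches the DAB1 donor 5' of the switch and DAB3 3' of it."""
    q = _post_exon2(reference.genes["DAB1*01"])
    da = _post_exon2(reference.genes["DAB1*03"])
    db = _post_exon2(reference.genes["DAB3*03"])
    anchors_a = {i for i, j in dotplot(q, da, window=20, step=5, threshold=1.0).anchors if i == j}
    anchors_b = {i for i, j in dotplot(q, db, window=20, step=5, threshold=1.0).anchors if i == j}
    # perfect-identity diagonal runs cover the 5' segment against the DAB1
    # donor and the 3' segment (exon 3 onward) against the DAB3 donor
    assert {0, 50, 100} <= anchors_a
    assert {300, 400, 500} <= anchors_b
    # beyond the switch the query no longer tracks the DAB1-lineage intron 2
    assert 300 not in anchors_a


def test_polymorphic_site_counts(reference):
    genes = reference.genes
    daa1_introns = [genes[f"DAA1*0{i}"].part_seq("intron", 1) for i in (1, 2, 3)]
    assert count_polymorphic_sites(daa1_introns).n_polymorphic == 2

    promoters = [reference.components.promoters[k] for k in ("P23", "P23v")]
    assert count_polymorphic_sites(promoters).n_polymorphic == 1

    assert count_polymorphic_sites(["ACGT", "ACGT"]).n_polymorphic == 0
    with pytest.raises(ValueError):
        count_polymorphic_sites(["ACGT", "ACG"])


def test_polymorphic_residue_counts(reference):
    family = reference.exon2_family
    dab1_exon2 = [family[t] for t in ("II", "IV", "III")]
    assert count_polymorphic_residues(dab1_exon2).n_polymorphic == 12

    genes = reference.genes
    exon3 = [genes["DAB2*03"].part_seq("exon", 3),
             genes["DAB3*03"].part_seq("exon", 3)]
    assert count_polymorphic_residues(exon3).n_polymorphic == 7

    exon1 = [genes["DAB2*03"].part_seq("exon", 1),
             genes["DAB3*03"].part_seq("exon", 1)]
    assert count_polymorphic_residues(exon1).n_polymorphic == 1

    same = [genes["DAB3*02"].part_seq("exon", 3),
            genes["DAB3*03"].part_seq("exon", 3)]
    assert count_polymorphic_residues(same).n_polymorphic == 0


def test_internal_stop_codon_is_an_error():
    with pytest.raises(ValueError, match="stop"):
        count_polymorphic_residues(["ATGTAAACG", "ATGTAAACG"])


def test_intron_lengths_from_annotations(reference):
    feats_hp1 = reference.haplotypes["hp1"].features
    feats_hp3 = reference.haplotypes["hp3"].features
    assert measure_intron_length(feats_hp1, "DAB1*01", 1) == 661
    assert measure_intron_length(feats_hp3, "DAB3*03", 1) == 285
    with pytest.raises(KeyError):
        measure_intron_length(feats_hp1, "DAB1*01", 9)


def test_breakpoint_recovered_for_hybrid_allele(reference):
    q = _post_exon2(reference.genes["DAB1*01"])
    da = _post_exon2(reference.genes["DAB1*03"])
    db = _post_exon2(reference.genes["DAB3*03"])
    call = detect_breakpoint(q, da, db, window=20)
    assert call.verdict == "hybrid"
    lo, hi = call.breakpoint
    assert lo <= 200 <= hi  # engineered switch at intron-2 midpoint


def test_pure_queries_have_no_switch(reference):
    da = _post_exon2(reference.genes["DAB1*03"])
    db = _post_exon2(reference.genes["DAB3*03"])
    assert detect_breakpoint(db, da, db, window=20).verdict == "pure_b"
    assert detect_breakpoint(da, da, db, window=20).verdict == "pure_a"


def test_double_recombinant_is_complex():
    rng = np.random.default_rng(7)
    a = random_dna(rng, 300)
    b = list(a)
    for p in range(3, 300, 11):
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    b = "".join(b)
    q = a[:100] + b[100:200] + a[200:]
    assert detect_breakpoint(q, a, b, window=20).verdict == "complex"


def test_breakpoint_parameter_recovery_on_simulated_recombinants():
    """50 random recombinants with window-dense markers: error <= window."""
    rng = np.random.default_rng(8)
    window = 20
    for _ in range(50):
        a = random_dna(rng, 500)
        b = list(a)
        # one informative site per 10-bp block: every window sees a marker
        for block in range(0, 500, 10):
            p = block + int(rng.integers(0, 10))
            b[p] = "ACGT"[(("ACGT".index(b[p])) + 1 + int(rng.integers(0, 3))) % 4]
        b = "".join(b)
        true_bp = int(rng.integers(60, 440))
        q = a[:true_bp] + b[true_bp:]
        call = detect_breakpoint(q, a, b, window=window)
        assert call.verdict == "hybrid"
        lo, hi = call.breakpoint
        assert lo - window <= true_bp <= hi + window
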