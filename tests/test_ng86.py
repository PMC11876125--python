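"""NG86 estimator: site counts, path decomposition, back-translation.

The difference decomposition is checked against an independent brute-force
oracle that enumerates substitution paths recursively, and the whole
estimator against Biopython's NG86 implementation on simulated pairs.
"""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import analysis as bio_analysis
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from paleoks.ng86 import (
    SENSE_CODONS,
    CodonAlignment,
    CodonError,
    backtranslate,
    codon_differences,
    ng86_ks,
    ng86_sites,
    pair_ks,
)
from paleoks.simulate import simulate_codon_pair

_CODE = dict(standard_dna_table.forward_table)


# --------------------------------------------------------------------------
# independent oracle: recursive path enumeration


def _oracle_paths(codon_a, codon_b):
    """All substitution paths a -> b, each a list of (syn?, step) flags."""
    if codon_a == codon_b:
        return [[]]
    paths = []
    for pos in range(3):
        if codon_a[pos] == codon_b[pos]:
            continue
        nxt = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
        syn = (
            codon_a in _CODE
            and nxt in _CODE
            and _CODE[codon_a] == _CODE[nxt]
        )
        for rest in _oracle_paths(nxt, codon_b):
            paths.append([syn] + rest)
    return paths


def oracle_differences(codon_a, codon_b):
    paths = _oracle_paths(codon_a, codon_b)
    sd = np.mean([sum(p) for p in paths])
    nd = np.mean([len(p) - sum(p) for p in paths])
    return sd, nd


# --------------------------------------------------------------------------
# site counts


def test_site_counts_worked_examples():
    s, n = ng86_sites("TTT")  # Phe: only TTC is synonymous, at position 3
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)
    s, n = ng86_sites("ATG")  # Met has no synonymous neighbour
    assert (s, n) == (0.0, 3.0)


def test_site_conservation_over_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = ng86_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        assert 0.0 <= s <= 3.0


def test_stop_codon_rejected():
    with pytest.raises(CodonError):
        ng86_sites("TAA")
    with pytest.raises(CodonError):
        codon_differences("TAA", "TTT")


# --------------------------------------------------------------------------
# difference decomposition vs the oracle


def test_decomposition_matches_oracle_for_all_sense_pairs():
    """Sd/Nd equal the exhaustive path enumeration and sum to the Hamming
    distance, for every one of the 61 x 61 sense-codon pairs."""
    for a in SENSE_CODONS:
        for b in SENSE_CODONS:
            sd, nd = codon_differences(a, b)
            osd, ond = oracle_differences(a, b)
            hamming = sum(x != y for x, y in zip(a, b))
            assert sd == pytest.approx(osd, abs=1e-12), (a, b)
            assert nd == pytest.approx(ond, abs=1e-12), (a, b)
            assert sd + nd == pytest.approx(hamming, abs=1e-12)


# --------------------------------------------------------------------------
# back-translation


def test_backtranslate_gap_mapping():
    aln = backtranslate("M-A", "MKA", "ATGGCT", "ATGAAAGCT")
    assert aln.codons_a == ["ATG", "---", "GCT"]
    assert aln.codons_b == ["ATG", "AAA", "GCT"]


def test_backtranslate_strips_terminal_stop():
    aln = backtranslate("MA", "MA", "ATGGCTTAA", "ATGGCT")
    assert aln.codons_a == ["ATG", "GCT"]


def test_backtranslate_reports_offending_position():
    with pytest.raises(CodonError, match="residue 1"):
        backtranslate("MK", "MK", "ATGGCT", "ATGAAA")  # GCT is Ala, not Lys
    with pytest.raises(CodonError, match="codons"):
        backtranslate("MKA", "MKA", "ATGAAA", "ATGAAAGCT")


def test_backtranslate_round_trips_simulated_pairs():
    for seed in range(5):
        ca, cb, pa, pb = simulate_codon_pair(
            40, 0.4, 0.1, seed=seed, n_gap_columns=4
        )
        aln = backtranslate(pa, pb, ca, cb)
        # re-translating each codon row reproduces the aligned proteins
        for row, prot in ((aln.codons_a, pa), (aln.codons_b, pb)):
            rebuilt = "".join(
                "-" if c == "---" else _CODE[c] for c in row
            )
            assert rebuilt == prot


# --------------------------------------------------------------------------
# the estimator


def test_identical_sequences_give_zero():
    est = pair_ks("ATGGCTTTT", "ATGGCTTTT", "MAF", "MAF")
    assert est.ks == 0.0
    assert est.ka == 0.0
    assert est.S + est.N == pytest.approx(3 * est.n_codons_used)


def test_symmetry_under_sequence_swap():
    ca, cb, pa, pb = simulate_codon_pair(60, 0.6, 0.1, seed=3)
    e1 = pair_ks(ca, cb, pa, pb)
    e2 = pair_ks(cb, ca, pb, pa)
    assert e1 == e2


def test_gap_columns_excluded_not_trimmed():
    aln = CodonAlignment(
        codons_a=["ATG", "---", "TTT", "GCT"],
        codons_b=["ATG", "AAA", "---", "GCT"],
    )
    est = ng86_ks(aln)
    assert est.n_codons_used == 2  # only the two shared sense columns


def test_saturation_flagged_undefined():
    # every column TTA vs CTG: 2 synonymous differences per ~1 synonymous
    # site, so pS >= 3/4 and the Jukes-Cantor argument is non-positive
    aln = CodonAlignment(codons_a=["TTA"] * 5, codons_b=["CTG"] * 5)
    est = ng86_ks(aln)
    assert est.ks is None
    assert est.ka is not None


def test_all_gap_alignment_rejected():
    with pytest.raises(CodonError, match="no counted"):
        ng86_ks(CodonAlignment(codons_a=["---"], codons_b=["ATG"]))


def test_matches_biopython_ng86_on_simulated_pairs():
    """Independent implementation cross-check on gapless codon pairs."""
    for seed, ds in ((0, 0.2), (1, 0.6), (2, 1.2)):
        ca, cb, _, _ = simulate_codon_pair(150, ds, 0.1, seed=seed)
        est = ng86_ks(
            CodonAlignment(
                codons_a=[ca[i : i + 3] for i in range(0, len(ca), 3)],
                codons_b=[cb[i : i + 3] for i in range(0, len(cb), 3)],
            )
        )
        dn, ds_bio = bio_analysis.calculate_dn_ds(
            Align.Alignment([Seq(ca), Seq(cb)]), method="NG86"
        )
        assert est.ks == pytest.approx(ds_bio, abs=1e-9)
        assert est.ka == pytest.approx(dn, abs=1e-9)


def test_consistency_on_calibrated_simulation():
    """Mean estimate over seeded replicates sits within 3 SE of the target."""
    target = 0.5
    vals = []
    for seed in range(60):
        ca, cb, pa, pb = simulate_codon_pair(300, target, 0.02, seed=seed)
        vals.append(pair_ks(ca, cb, pa, pb).ks)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - target) < 3 * se
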