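"""Nei–Gojobori (1986) Ka/Ks estimation from protein-guided codon alignments.

The estimator counts synonymous (S) and nonsynonymous (N) sites per codon by
enumerating the nine single-nucleotide neighbours under the standard genetic
code, decomposes observed per-codon differences into synonymous and
nonsynonymous substitutions by averaging over all minimal substitution
orderings, and applies the Jukes–Cantor correction
``d = -(3/4) ln(1 - (4/3) p)`` to the proportions ``pS = Sd/S`` and
``pN = Nd/N``.

Changes to (or from) stop codons count as nonsynonymous; columns containing
gaps, ambiguity codes or stop codons are excluded from counting.  Protein
alignments are inputs — aligning is upstream of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
_STOPS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_CODE))
_NUCS = "ACGT"
GAP_CODON = "---"


class CodonError(ValueError):
    """Raised on invalid codons or inconsistent codon alignments."""


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, ``None`` for a stop codon."""
    if codon in _STOPS:
        return None
    try:
        return _CODE[codon]
    except KeyError:
        raise CodonError(f"not an unambiguous DNA codon: {codon!r}") from None


def is_sense(codon: str) -> bool:
    return codon in _CODE


# ---------------------------------------------------------------------------
# site counting


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for one sense codon.

    At each of the three positions, s accrues the fraction of the three
    possible single-nucleotide changes that preserve the encoded amino acid;
    changes to stop codons are nonsynonymous.  Always ``s + n == 3``.
    """
    if codon not in _CODE:
        raise CodonError(f"ng86_sites requires a sense codon, got {codon!r}")
    aa = _CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for nuc in _NUCS
            if nuc != codon[pos]
            and _CODE.get(codon[:pos] + nuc + codon[pos + 1 :]) == aa
        )
        s += syn / 3.0
    return s, 3.0 - s


# ---------------------------------------------------------------------------
# difference decomposition


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Decompose the differences between two sense codons into expected
    synonymous and nonsynonymous substitutions (sd, nd).

    For codons differing at k positions, every one of the k! orderings of
    single-nucleotide steps is weighted equally; each step is synonymous
    when both endpoint codons encode the same amino acid (steps through a
    stop codon are nonsynonymous).  ``sd + nd`` equals the nucleotide
    Hamming distance.
    """
    if codon_a not in _CODE or codon_b not in _CODE:
        raise CodonError(
            f"difference decomposition requires sense codons, "
            f"got {codon_a!r}, {codon_b!r}"
        )
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    total_s = 0.0
    total_n = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if (
                current in _CODE
                and nxt in _CODE
                and _CODE[current] == _CODE[nxt]
            ):
                total_s += 1.0
            else:
                total_n += 1.0
            current = nxt
        n_paths += 1
    return total_s / n_paths, total_n / n_paths


# ---------------------------------------------------------------------------
# codon alignments


@dataclass
class CodonAlignment:
    """Two aligned codon sequences over {A,C,G,T,-} triples.

    A codon is either a gap triple ``---`` or three unambiguous
    nucleotides; mixed gap/nucleotide triples are rejected.
    """

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise CodonError(
                f"codon rows differ in length: "
                f"{len(self.codons_a)} vs {len(self.codons_b)}"
            )
        for row in (self.codons_a, self.codons_b):
            for i, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if len(codon) != 3 or any(c not in _NUCS for c in codon):
                    raise CodonError(
                        f"column {i}: invalid codon {codon!r}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def counted_columns(self) -> list[tuple[str, str]]:
        """Columns where both codons are sense codons (no gaps, no stops)."""
        return [
            (a, b)
            for a, b in zip(self.codons_a, self.codons_b)
            if a in _CODE and b in _CODE
        ]


def backtranslate(
    protein_aln_a: str,
    protein_aln_b: str,
    cds_a: str,
    cds_b: str,
) -> CodonAlignment:
    """Thread two CDS onto their aligned proteins, codon by codon.

    A terminal stop codon on a CDS is stripped first.  Each CDS must
    translate to its ungapped protein under the standard code; mismatches
    raise :class:`CodonError` naming the offending position.
    """
    if len(protein_aln_a) != len(protein_aln_b):
        raise CodonError(
            "aligned proteins differ in length: "
            f"{len(protein_aln_a)} vs {len(protein_aln_b)}"
        )
    row_a = _thread_one(protein_aln_a, cds_a, label="a")
    row_b = _thread_one(protein_aln_b, cds_b, label="b")
    return CodonAlignment(codons_a=row_a, codons_b=row_b)


def _thread_one(protein_aln: str, cds: str, label: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise CodonError(f"CDS {label}: length {len(cds)} not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    ungapped = protein_aln.replace("-", "")
    if len(codons) != len(ungapped):
        raise CodonError(
            f"CDS {label}: {len(codons)} codons vs "
            f"{len(ungapped)} aligned residues"
        )
    out: list[str] = []
    k = 0
    for col, aa in enumerate(protein_aln):
        if aa == "-":
            out.append(GAP_CODON)
            continue
        codon = codons[k]
        translated = _CODE.get(codon)
        if translated is None:
            raise CodonError(
                f"CDS {label}, residue {k}: codon {codon!r} is not a sense "
                f"codon (alignment column {col})"
            )
        if translated != aa.upper() and aa.upper() != "X":
            raise CodonError(
                f"CDS {label}, residue {k}: codon {codon!r} translates to "
                f"{translated!r}, protein has {aa!r} (alignment column {col})"
            )
        out.append(codon)
        k += 1
    return out


# ---------------------------------------------------------------------------
# the estimate


@dataclass(frozen=True)
class KsEstimate:
    """NG86 estimate for one paralog pair.

    ``ks``/``ka`` are ``None`` when the Jukes–Cantor argument is
    non-positive (proportion of differences at or beyond 3/4: saturation).
    ``S + N == 3 * n_codons_used`` by construction.
    """

    ks: float | None
    ka: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons_used: int


def _jukes_cantor(p: float) -> float | None:
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return max(-0.75 * math.log(arg), 0.0)


def ng86_ks(aln: CodonAlignment) -> KsEstimate:
    """NG86 Ka/Ks from a codon alignment.

    Sites are averaged over the two sequences; differences are decomposed
    per codon via :func:`codon_differences`.  The result is symmetric in
    the two sequences.  Raises on zero counted columns.
    """
    columns = aln.counted_columns()
    if not columns:
        raise CodonError("no counted codon columns (all gapped/stop/ambiguous)")
    S = N = Sd = Nd = 0.0
    for codon_a, codon_b in columns:
        sa, na = ng86_sites(codon_a)
        sb, nb = ng86_sites(codon_b)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = codon_differences(codon_a, codon_b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return KsEstimate(
        ks=_jukes_cantor(pS),
        ka=_jukes_cantor(pN),
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        n_codons_used=len(columns),
    )


def pair_ks(
    cds_a: str,
    cds_b: str,
    protein_aln_a: str,
    protein_aln_b: str,
) -> KsEstimate:
    """Convenience wrapper: back-translate then estimate."""
    return ng86_ks(backtranslate(protein_aln_a, protein_aln_b, cds_a, cds_b))
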