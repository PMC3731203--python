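"""Genetic-code tables and the ribosomal-site coordinate conventions.

All positional arithmetic in this package is ORF-relative: position 0 is the
first nucleotide of the start codon, positions increase 3'-ward, and upstream
(5' UTR) positions are negative.  Footprint 5' ends that have been shifted
into the 28-mer frame sit 12 nt upstream of the first nucleotide of the codon
in the ribosomal P site.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard code, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

#: the three stop codons
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: codon -> one-letter amino acid (sense codons only)
AA_OF_CODON: dict[str, str] = dict(_STANDARD.forward_table)

#: valid one-letter amino-acid codes
AMINO_ACIDS: frozenset[str] = frozenset(AA_OF_CODON.values())

#: ribosomal sites, ordered as they appear across the metacodon window.
#: "-2"/"-1" hold codons the ribosome has not yet reached (3' of the A site);
#: "+1"/"+2" hold codons that have already transited through the E site.
SITES: tuple[str, ...] = ("-2", "-1", "A", "P", "E", "+1", "+2")

#: distance (nt) from a frame-shifted (28-mer frame) 5' end to the first
#: nucleotide of the codon occupying each site
SITE_FIVEPRIME_OFFSET: dict[str, int] = {
    "-2": 21, "-1": 18, "A": 15, "P": 12, "E": 9, "+1": 6, "+2": 3,
}

#: metacodon-window index (0..20) of each site's peak
SITE_WINDOW_INDEX: dict[str, int] = {
    "-2": 0, "-1": 3, "A": 6, "P": 9, "E": 12, "+1": 15, "+2": 18,
}

#: codon-index displacement of the codon sitting in each site, relative to
#: the codon in the P site (A site holds the next codon to be decoded, etc.)
SITE_CODON_DELTA: dict[str, int] = {
    "-2": 3, "-1": 2, "A": 1, "P": 0, "E": -1, "+1": -2, "+2": -3,
}

#: window indices of the outer sites used as the metacodon normalizer
OUTER_SITE_INDICES: tuple[int, ...] = (0, 3, 15, 18)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_codon(s: str) -> bool:
    return len(s) == 3 and all(c in "ACGT" for c in s)
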