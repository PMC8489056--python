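"""Small sequence utilities: ORF discovery, translation, motif scanning.

Covers the sequence-side bookkeeping of a cloning study: find ATG-initiated,
stop-terminated open reading frames on both strands of a nucleotide
sequence, translate them with the standard genetic code, and scan the
proteins for degenerate motifs (X = any residue), e.g. the NADPH-binding
TGXXGF and active-site YXXXK motifs of fatty acyl-CoA reductases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = ["OrfHit", "find_orfs", "translate_cds", "motif_scan"]

VALID_NT = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class OrfHit:
    """One open reading frame, 0-based half-open on the input sequence.

    ``start``/``end`` include the stop codon, so (end − start) is a
    multiple of 3 and the protein has (end − start)/3 − 1 residues.
    Coordinates always refer to the forward strand of the input.
    """

    sequence_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0, 1, 2 on the reported strand
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def translate_cds(cds: str) -> str:
    """Translate a stop-terminated CDS (standard code), dropping the stop."""
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    return protein


def _orfs_one_strand(seq: str, sequence_id: str, strand: str, length: int, min_aa: int):
    """Scan the three frames of one strand; yield stop-terminated ORFs.

    A codon containing N cannot be translated, so it closes any open
    reading without producing an ORF (the scan restarts after it).
    Coordinates are on the scanned strand and mapped to the forward strand
    by the caller for strand "-".
    """
    hits = []
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, length - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                start = None  # untranslatable codon splits the ORF
                continue
            if codon in STOP_CODONS:
                if start is not None:
                    n_aa = (pos - start) // 3
                    if n_aa >= min_aa:
                        protein = str(Seq(seq[start:pos]).translate())
                        hits.append((start, pos + 3, frame, protein))
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        # ORFs without a stop codon are not reported
    for start, end, frame, protein in hits:
        if strand == "+":
            yield OrfHit(sequence_id, start, end, "+", frame, protein)
        else:
            yield OrfHit(sequence_id, length - end, length - start, "-", frame, protein)


def find_orfs(seq: str, min_aa: int = 1, sequence_id: str = "seq") -> list[OrfHit]:
    """All ATG-initiated, stop-terminated ORFs on both strands.

    Returns hits with at least ``min_aa`` residues, sorted by protein
    length descending (ties: forward strand first, then start coordinate).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")

    length = len(seq)
    hits = list(_orfs_one_strand(seq, sequence_id, "+", length, min_aa))
    rc = str(Seq(seq).reverse_complement())
    hits += list(_orfs_one_strand(rc, sequence_id, "-", length, min_aa))
    hits.sort(key=lambda h: (-len(h.protein), h.strand, h.start))
    return hits


def motif_scan(protein: str, motif: str) -> list[int]:
    """0-based start positions of all (overlapping) matches of a degenerate
    motif, where X matches any residue."""
    protein = protein.upper()
    motif = motif.upper()
    bad = set(motif) - AA_LETTERS - {"X"}
    if bad:
        raise ValueError(f"invalid motif letters: {sorted(bad)}")
    if not motif:
        raise ValueError("empty motif")
    pattern = re.compile("(?=(" + motif.replace("X", ".") + "))")
    return [m.start() for m in pattern.finditer(protein)]
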