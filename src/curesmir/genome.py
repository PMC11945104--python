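"""Genomic placement of validated precursors, promoter extraction and
cis-acting element scanning.

Locus finding assumes precursors are near-identical to the genome (same
species, possibly different cultivar), so it uses exact 20-mer seeding with
full-length ungapped verification instead of a general aligner. Promoters are
the 2-kb region upstream of the precursor's 5' end on its strand; cis-element
motifs are plain IUPAC strings supplied as a table and matched exactly under
IUPAC expansion on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._utils import IUPAC_DNA, iupac_revcomp, revcomp, to_dna

SEED_LENGTH = 20
MIN_IDENTITY_DEFAULT = 95.0
PROMOTER_LENGTH = 2000


@dataclass
class GenomicLocus:
    precursor_id: str
    chromosome: str
    start: int  # 1-based inclusive, forward strand projection
    end: int
    strand: str
    identity: float  # percent matching bases over the full precursor length


@dataclass
class Promoter:
    locus_id: str
    sequence: str  # 5'->3' relative to the gene
    length: int
    short: bool  # clipped at a chromosome end


@dataclass
class CisElementHit:
    locus_id: str
    element: str
    motif: str
    position: int  # relative to feature start; -1 is the base just upstream
    strand: str


def _identity(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def locate_loci(
    precursors: Mapping[str, str],
    genome: Mapping[str, str],
    min_identity: float = MIN_IDENTITY_DEFAULT,
    max_loci_per_precursor: int | None = None,
) -> list[GenomicLocus]:
    """All near-exact genomic occurrences of each precursor, both strands.

    A hit must cover the full precursor length at >= ``min_identity`` percent
    matching bases (ungapped). Results are sorted by chromosome then start;
    ``max_loci_per_precursor`` keeps only the highest-identity hits.
    """
    loci: list[GenomicLocus] = []
    genome_dna = {c: to_dna(s) for c, s in genome.items()}
    for pid, pre in precursors.items():
        pre_dna = to_dna(pre)
        n = len(pre_dna)
        if n < SEED_LENGTH:
            continue
        seed_offsets = list(range(0, n - SEED_LENGTH + 1, SEED_LENGTH))
        seen: set[tuple[str, str, int]] = set()
        hits: list[GenomicLocus] = []
        for chrom, chrom_seq in genome_dna.items():
            for strand in "+-":
                hay = chrom_seq if strand == "+" else revcomp(chrom_seq)
                starts: set[int] = set()
                for off in seed_offsets:
                    seed = pre_dna[off:off + SEED_LENGTH]
                    pos = hay.find(seed)
                    while pos != -1:
                        starts.add(pos - off)
                        pos = hay.find(seed, pos + 1)
                for s0 in sorted(starts):
                    if s0 < 0 or s0 + n > len(hay):
                        continue
                    ident = _identity(pre_dna, hay[s0:s0 + n])
                    if ident < min_identity:
                        continue
                    if strand == "+":
                        span = (s0 + 1, s0 + n)
                    else:  # project onto the forward strand
                        span = (len(hay) - (s0 + n) + 1, len(hay) - s0)
                    key = (chrom, strand, span[0])
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(GenomicLocus(
                        precursor_id=pid, chromosome=chrom,
                        start=span[0], end=span[1], strand=strand,
                        identity=round(ident, 2),
                    ))
        if max_loci_per_precursor is not None and len(hits) > max_loci_per_precursor:
            hits.sort(key=lambda l: (-l.identity, l.chromosome, l.start))
            hits = hits[:max_loci_per_precursor]
        loci.extend(hits)
    loci.sort(key=lambda l: (l.chromosome, l.start, l.precursor_id))
    return loci


def extract_promoter(
    locus: GenomicLocus,
    genome: Mapping[str, str],
    upstream: int = PROMOTER_LENGTH,
) -> Promoter:
    """Strand-aware upstream region of a locus, clipped at chromosome ends.

    For '+' loci this is the ``upstream`` nt before the start; for '-' loci
    the reverse complement of the nt after the end, so the returned sequence
    always reads 5'->3' toward the gene.
    """
    chrom_seq = to_dna(genome[locus.chromosome])
    if locus.start < 1 or locus.end > len(chrom_seq):
        raise ValueError(
            f"locus {locus.precursor_id} at {locus.chromosome}:{locus.start}-{locus.end} "
            f"is off the chromosome (length {len(chrom_seq)})"
        )
    if locus.strand == "+":
        lo = max(1, locus.start - upstream)
        seq = chrom_seq[lo - 1:locus.start - 1]
    else:
        hi = min(len(chrom_seq), locus.end + upstream)
        seq = revcomp(chrom_seq[locus.end:hi])
    return Promoter(
        locus_id=f"{locus.precursor_id}@{locus.chromosome}:{locus.start}-{locus.end}({locus.strand})",
        sequence=seq,
        length=len(seq),
        short=len(seq) < upstream,
    )


def _iupac_pattern(motif: str) -> re.Pattern:
    parts = []
    for c in motif.upper():
        if c not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC character {c!r} in motif {motif!r}")
        exp = IUPAC_DNA[c]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_cis_elements(
    promoter: Promoter | str,
    motifs: pd.DataFrame | Sequence[tuple[str, str, str]],
) -> tuple[list[CisElementHit], dict[str, int]]:
    """Match every motif on both strands of a promoter.

    ``motifs`` rows are (name, IUPAC motif, category). Hit positions are
    relative to the feature start: the promoter's last base is position -1.
    Returns the hits plus per-category summary counts.
    """
    if isinstance(promoter, str):
        promoter = Promoter(locus_id="promoter", sequence=promoter,
                            length=len(promoter), short=False)
    if isinstance(motifs, pd.DataFrame):
        rows = list(motifs.itertuples(index=False, name=None))
    else:
        rows = list(motifs)

    seq = to_dna(promoter.sequence)
    P = len(seq)
    hits: list[CisElementHit] = []
    categories: dict[str, int] = {}
    for name, motif, category in rows:
        for strand, pattern in (("+", _iupac_pattern(motif)),
                                ("-", _iupac_pattern(iupac_revcomp(motif)))):
            for m in pattern.finditer(seq):
                hits.append(CisElementHit(
                    locus_id=promoter.locus_id, element=str(name), motif=str(motif),
                    position=m.start() - P, strand=strand,
                ))
                categories[str(category)] = categories.get(str(category), 0) + 1
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits, categories


# Small demonstration motif catalogue (name, IUPAC motif, category). Real
# analyses supply their own table; matrices of dedicated promoter databases
# are out of scope for the plain-IUPAC scanner.
DEMO_MOTIFS = [
    ("TATA-box", "TATAAA", "core promoter"),
    ("CAAT-box", "CCAAT", "core promoter"),
    ("ABRE", "ACGTG", "hormone-responsive"),
    ("MYB-binding-site", "CAACTG", "stress-responsive"),
    ("E-box", "CANNTG", "light-responsive"),
]


def hits_to_frame(hits: Sequence[CisElementHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.locus_id, h.element, h.motif, h.position, h.strand) for h in hits],
        columns=["locus_id", "element", "motif", "position", "strand"],
    )
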